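{
  "comment": "Synthetic 21-exon SLC26A4-like transcript model (GRCh37-style chr7 coordinates). Coordinates are constructed, not the real NM_000441.2 annotation: exon 3 ends at c.304, exon 9 starts at c.919, exon 12 starts at c.1264, exon 14 ends at c.1614, and the exon groups 1-3, 5-6 and 9-10 sit inside the published deletion windows.",
  "transcript_id": "NM_000441.2",
  "chrom": "chr7",
  "strand": "+",
  "cds_start": 1,
  "cds_end": 2343,
  "exons": [
    [107300800, 107300919],
    [107302000, 107302099],
    [107303800, 107303883],
    [107308000, 107308109],
    [107314400, 107314509],
    [107315600, 107315709],
    [107317000, 107317109],
    [107318000, 107318173],
    [107330000, 107330109],
    [107333000, 107333109],
    [107335000, 107335124],
    [107336000, 107336109],
    [107337000, 107337109],
    [107338000, 107338130],
    [107339000, 107339109],
    [107340000, 107340109],
    [107341000, 107341109],
    [107342000, 107342109],
    [107343000, 107343109],
    [107344000, 107344109],
    [107345000, 107345125]
  ]
}
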