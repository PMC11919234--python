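"""The synthetic-data generator: depth model, reads, transcripts, fixtures."""

import math

import numpy as np
import pytest

from evadx import simulate
from evadx.genemodel import GenomicInterval
from evadx.splice import PseudoexonEvent


def small_spec(panel, events=(), **kw):
    kw.setdefault("seed", 3)
    return simulate.CohortSpec(
        n_trios=5, panel=panel, planted_events=list(events), **kw
    )


class TestReference:
    def test_landmarks_planted(self, model, genome):
        # canonical splice contexts around every internal intron
        for i, ex in enumerate(model.exons):
            if i > 0:
                assert genome.subseq(ex.start - 2, ex.start - 1) == "AG"
            if i < model.n_exons - 1:
                assert genome.subseq(ex.end + 1, ex.end + 2) == "GT"
        assert genome.subseq(model.exons[0].start, model.exons[0].start + 2) == "ATG"

    def test_deterministic(self, model):
        a = simulate.simulate_reference(5, model)
        b = simulate.simulate_reference(5, model)
        c = simulate.simulate_reference(6, model)
        assert a.seq == b.seq
        assert a.seq != c.seq

    def test_wildtype_cds_has_no_internal_stop(self, model, genome):
        from evadx.splice import _translate_cds

        from evadx.genemodel import cdna_sequence

        prot = _translate_cds(cdna_sequence(model, genome), model.cds_start)
        expected_aa = (model.cds_end - model.cds_start + 1) // 3 - 1
        assert len(prot) == expected_aa


class TestDepthMatrix:
    def test_no_events_flat_expectation(self, panel):
        spec = small_spec(
            panel,
            depth_dispersion=math.inf,
            efficiency_sd=0.0,
            throughput_sd=0.0,
        )
        dm, truth = simulate.simulate_depth_matrix(spec)
        assert (truth.copy_number.to_numpy() == 2).all()
        mu0 = spec.mean_total_bases / panel.lengths.sum()
        # Poisson limit: every amplicon mean within 3 SE of the flat model
        n = dm.depth.shape[0]
        for a in panel.ids:
            se = math.sqrt(mu0 / n)
            assert abs(dm.depth[a].mean() - mu0) < 3 * se + 1

    def test_hom_deletion_zeroes_amplicons(self, panel):
        ev = simulate.PlantedEvent(
            "F01", "deletion", "Exons 5–6 deletion (1845 bp)", "hom", "biparental"
        )
        spec = small_spec(panel, [ev])
        dm, truth = simulate.simulate_depth_matrix(spec)
        hit = panel.overlapping(simulate.DELETION_INTERVALS[ev.allele])
        assert (truth.copy_number.loc["F01-1", hit] == 0).all()
        assert (dm.depth.loc["F01-1", hit] == 0).all()
        assert (truth.copy_number.loc["F01-F", hit] == 1).all()

    def test_depth_scales_with_copy_number(self, panel):
        """Empirical per-CN depth means track the forward model (3 SE)."""
        ev = simulate.PlantedEvent(
            "F01", "deletion", "Exons 1–3 deletion (7666 bp)", "het", "maternal"
        )
        ratios = []
        for seed in range(200):
            spec = small_spec(panel, [ev], seed=seed, efficiency_sd=0.0,
                              throughput_sd=0.0)
            dm, truth = simulate.simulate_depth_matrix(spec)
            hit = panel.overlapping(simulate.DELETION_INTERVALS[ev.allele])
            other = [a for a in panel.ids if a not in hit]
            ratios.append(
                dm.depth.loc["F01-1", hit].mean() / dm.depth.loc["F01-1", other].mean()
            )
        mean_ratio = float(np.mean(ratios))
        se = float(np.std(ratios) / math.sqrt(len(ratios)))
        assert abs(mean_ratio - 0.5) < 3 * se + 0.01

    def test_deterministic_given_seed(self, panel, table2_cohort):
        spec, dm, _ = table2_cohort
        dm2, _ = simulate.simulate_depth_matrix(spec)
        assert dm.depth.equals(dm2.depth)

    def test_event_outside_panel_rejected(self, panel):
        bad = simulate.PlantedEvent("F01", "deletion", "nonsense-allele")
        with pytest.raises(ValueError, match="unknown deletion allele"):
            simulate.simulate_depth_matrix(small_spec(panel, [bad]))

    def test_mendelian_consistency_of_truth(self, table2_cohort):
        """Every proband allele has a matching carrier parent (or is de novo)."""
        spec, _, truth = table2_cohort
        by_sample = {}
        for e in truth.events:
            by_sample.setdefault(e.sample, []).append(e)
        for e in truth.events:
            if not e.sample.endswith("-1") or e.origin == "de_novo":
                continue
            fam = e.sample.rsplit("-", 1)[0]
            parents = {
                "paternal": [f"{fam}-F"],
                "maternal": [f"{fam}-M"],
                "biparental": [f"{fam}-F", f"{fam}-M"],
            }[e.origin]
            for parent in parents:
                assert any(
                    pe.allele == e.allele for pe in by_sample.get(parent, [])
                )

    def test_table2_truth_has_seven_deletion_probands(self, table2_cohort):
        _, _, truth = table2_cohort
        probands = {
            e.sample
            for e in truth.events
            if e.kind == "deletion" and e.sample.endswith("-1")
        }
        assert len(probands) == 7


class TestLongReads:
    def test_error_free_reads_are_reference_substrings(self, genome):
        reads, truth = simulate.simulate_long_reads(
            genome, None, n_reads=20, read_len_range=(500, 1500), seed=4
        )
        for (_, seq), t in zip(reads, truth):
            assert seq in genome.seq
            assert not t.spans_junction

    def test_deletion_reads_omit_the_segment(self, genome):
        iv = simulate.DELETION_INTERVALS["Exons 5–6 deletion (1845 bp)"]
        reads, truth = simulate.simulate_long_reads(
            genome, iv, n_reads=50, read_len_range=(3000, 6000), seed=4
        )
        hap = genome.without(iv)
        assert len(hap) == len(genome.seq) - 1845
        spanning = [
            (r, t) for (r, t) in zip(reads, truth) if t.spans_junction
        ]
        assert spanning
        for (_, seq), t in spanning:
            assert seq in hap
            assert seq not in genome.seq  # junction absent from wild type

    def test_fasta_deterministic(self, genome, tmp_path):
        iv = simulate.DELETION_INTERVALS["Exons 9–10 deletion (4979 bp)"]
        paths = []
        for name in ("a.fa", "b.fa"):
            reads, _ = simulate.simulate_long_reads(
                genome, iv, n_reads=10, error_rate=0.01, seed=11
            )
            p = tmp_path / name
            simulate.write_fasta(p, reads)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
        back = simulate.read_fasta(tmp_path / "a.fa")
        assert back == reads

    def test_deletion_outside_reference_rejected(self, genome):
        with pytest.raises(Exception):
            simulate.simulate_long_reads(
                genome, GenomicInterval("chr7", 1, 100), n_reads=1
            )


class TestTranscripts:
    def test_wildtype_only(self, model, genome):
        tr = simulate.simulate_transcripts(model, None, genome)
        assert set(tr) == {"wildtype"}
        assert len(tr["wildtype"]) == model.cdna_length

    @pytest.mark.parametrize("length, diff", [(126, 126), (125, 125)])
    def test_pseudoexon_length_difference(self, model, genome, length, diff):
        pe = PseudoexonEvent(
            3,
            simulate.PSEUDOEXON_ACCEPTOR,
            simulate.PSEUDOEXON_ACCEPTOR + length - 1,
            "chr7",
        )
        tr = simulate.simulate_transcripts(model, pe, genome)
        assert len(tr["mutant"]) - len(tr["wildtype"]) == diff

    def test_pseudoexon_overlapping_exon_rejected(self, model, genome):
        pe = PseudoexonEvent(3, model.exons[2].end - 5, model.exons[2].end + 50, "chr7")
        with pytest.raises(ValueError, match="intron"):
            simulate.simulate_transcripts(model, pe, genome)


class TestTableFixtures:
    def test_homozygous_deletion_patient(self):
        patients, _ = simulate.build_table_fixtures()
        by_id = {p.patient_id: p for p in patients}
        p = by_id["3312285-1"]
        assert p.paternal == p.maternal == "Exons 5–6 deletion (1845 bp)"

    def test_undiagnosed_patient_has_no_alleles(self):
        patients, _ = simulate.build_table_fixtures()
        by_id = {p.patient_id: p for p in patients}
        assert by_id["3310066-1"].alleles() == []

    def test_nonsense_variant_evidence(self):
        _, profiles = simulate.build_table_fixtures()
        prof = next(p for p in profiles if p.variant_id == "c.946G>T")
        assert prof.variant_class == "nonsense"
        assert set(prof.printed_criteria) == {"PVS1", "PM2", "PM3_VeryStrong", "PP4"}

    def test_round_trip_writers(self, panel, table2_cohort, tmp_path):
        spec, dm, truth = table2_cohort
        panel.write_bed(tmp_path / "panel.bed")
        dm.write_tsv(tmp_path / "depths.tsv")
        truth.to_json(tmp_path / "truth.json")
        spec.pedigree().write(tmp_path / "trios.ped")

        from evadx.cnv import AmpliconPanel, DepthMatrix
        from evadx.pedigree import Pedigree

        panel2 = AmpliconPanel.read_bed(tmp_path / "panel.bed")
        assert panel2.ids == panel.ids
        assert [a.interval for a in panel2.amplicons] == [
            a.interval for a in panel.amplicons
        ]
        dm2 = DepthMatrix.read_tsv(tmp_path / "depths.tsv", panel2)
        assert np.allclose(dm2.depth.to_numpy(), dm.depth.to_numpy())
        truth2 = simulate.TruthTable.from_json(tmp_path / "truth.json")
        assert truth2.copy_number.loc[truth.copy_number.index].equals(
            truth.copy_number
        )
        assert truth2.events == truth.events
        ped2 = Pedigree.read(tmp_path / "trios.ped")
        assert ped2.rows == spec.pedigree().rows
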