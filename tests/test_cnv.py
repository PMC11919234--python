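"""Depth normalisation, ratio calling, segmentation and trio inheritance."""

import numpy as np
import pandas as pd
import pytest

from evadx import cnv, simulate
from evadx.cnv import CN0, CN1, CN2, CN3, DepthMatrix, RatioResult
from evadx.genemodel import GenomicInterval


def tiny_matrix(values, lengths=None):
    df = pd.DataFrame(values).T if isinstance(values, dict) else pd.DataFrame(values)
    lengths = lengths or {c: 100 for c in df.columns}
    return DepthMatrix(df, pd.Series(lengths)[df.columns])


class TestNormalize:
    def test_sample_at_target_total_unchanged(self):
        dm = tiny_matrix({"s1": {"a": 50_000.0, "b": 50_000.0}})
        out = cnv.normalize(dm, target_total=1e7)
        assert np.allclose(out.depth.loc["s1"], dm.depth.loc["s1"])

    def test_throughput_scale_invariance(self):
        dm = tiny_matrix(
            {"s1": {"a": 100.0, "b": 300.0}, "s2": {"a": 200.0, "b": 600.0}}
        )
        out = cnv.normalize(dm)
        assert np.allclose(out.depth.loc["s1"], out.depth.loc["s2"])

    def test_conservation_on_simulated_cohort(self, panel):
        spec = simulate.CohortSpec(n_trios=5, panel=panel, seed=1)
        dm, _ = simulate.simulate_depth_matrix(spec)
        out = cnv.normalize(dm)
        assert np.allclose(out.total_bases(), 1e7, rtol=1e-6)

    def test_all_zero_sample_named(self):
        dm = tiny_matrix({"good": {"a": 10.0}, "dead": {"a": 0.0}})
        with pytest.raises(ValueError, match="dead"):
            cnv.normalize(dm)


class TestRatios:
    def test_identical_samples_give_unit_ratios_zero_z(self):
        dm = tiny_matrix({f"s{i}": {"a": 10.0, "b": 20.0} for i in range(5)})
        rr = cnv.ratios(dm)
        assert np.allclose(rr.ratios, 1.0)
        assert np.allclose(rr.z, 0.0)

    def test_het_deletion_ratio_near_half(self, panel, model):
        """Forward-model expectation: CN1 amplicons at ratio ~0.5 (200 reps)."""
        ev = simulate.PlantedEvent(
            "F01", "deletion", "Exons 1–3 deletion (7666 bp)", "het", "de_novo"
        )
        hit = panel.overlapping(simulate.DELETION_INTERVALS[ev.allele])
        vals = []
        for seed in range(200):
            spec = simulate.CohortSpec(
                n_trios=5, panel=panel, planted_events=[ev], seed=seed
            )
            dm, _ = simulate.simulate_depth_matrix(spec)
            rr = cnv.ratios(cnv.normalize(dm))
            vals.append(rr.ratios.loc["F01-1", hit].mean())
        assert abs(np.mean(vals) - 0.5) < 0.02

    def test_zero_reference_amplicon_masked(self):
        rows = {f"s{i}": {"a": 10.0, "b": 0.0} for i in range(4)}
        rr = cnv.ratios(tiny_matrix(rows))
        assert rr.masked == ["b"]
        assert rr.ratios["b"].isna().all()

    def test_requires_three_samples_for_median_reference(self):
        dm = tiny_matrix({"s1": {"a": 1.0}, "s2": {"a": 1.0}})
        with pytest.raises(ValueError, match=">= 3"):
            cnv.ratios(dm)


def make_rr(ratio_rows, z_rows):
    r = pd.DataFrame(ratio_rows)
    z = pd.DataFrame(z_rows)
    return RatioResult(r, z, pd.Series(1.0, index=r.columns), [])


class TestCallStates:
    def test_threshold_table(self):
        rr = make_rr(
            {"a": [0.51], "b": [0.03], "c": [0.65], "d": [1.0], "e": [1.5]},
            {"a": [-8.0], "b": [-12.0], "c": [-1.2], "d": [0.1], "e": [4.0]},
        )
        sr = cnv.call_states(rr)
        row = sr.states.iloc[0]
        assert row["a"] == CN1
        assert row["b"] == CN0
        assert row["c"] == CN2  # z-gated
        assert sr.suspect.iloc[0]["c"]
        assert row["d"] == CN2
        assert row["e"] == CN3

    def test_thresholds_must_increase(self):
        rr = make_rr({"a": [1.0]}, {"a": [0.0]})
        with pytest.raises(ValueError):
            cnv.call_states(rr, thresholds=(0.7, 0.2, 1.3))


class TestSegment:
    def _states(self, panel, assignments):
        samples = sorted({s for s, _ in assignments})
        raw = pd.DataFrame(CN2, index=samples, columns=panel.ids)
        for s, row in assignments:
            for a, st in row.items():
                raw.loc[s, a] = st
        return cnv.StateResult(states=raw.copy(), raw=raw, suspect=raw != raw)

    def test_six_amplicons_merge_to_one_exon_range_call(self, panel, model):
        amps = ["e01a", "e01b", "e02a", "e02b", "e03a", "e03b"]
        sr = self._states(panel, [("p1", {a: CN1 for a in amps})])
        calls = cnv.segment(sr, panel, model)
        assert len(calls) == 1
        c = calls[0]
        assert (c.state, c.n_amplicons, c.low_confidence) == (CN1, 6, False)
        assert (c.exon_range.first_exon, c.exon_range.last_exon) == (1, 3)
        assert c.exon_label == "Exons 1–3"

    def test_isolated_amplicon_is_low_confidence(self, panel, model):
        sr = self._states(panel, [("p1", {"e07a": CN1})])
        calls = cnv.segment(sr, panel, model)
        assert len(calls) == 1
        assert calls[0].low_confidence

    def test_all_diploid_gives_no_calls(self, panel, model):
        sr = self._states(panel, [("p1", {})])
        assert cnv.segment(sr, panel, model) == []

    def test_suspect_amplicon_inside_run_absorbed(self, panel, model):
        amps = ["e05a", "e05b", "e06a", "e06b"]
        raw = pd.DataFrame(CN2, index=["p1"], columns=panel.ids)
        raw.loc["p1", amps] = CN1
        gated = raw.copy()
        gated.loc["p1", "e05b"] = CN2  # z-gate failed on one member
        suspect = raw != gated
        sr = cnv.StateResult(states=gated, raw=raw, suspect=suspect)
        calls = cnv.segment(sr, panel, model)
        assert len(calls) == 1
        assert calls[0].n_amplicons == 4
        assert calls[0].exon_label == "Exons 5–6"

    def test_all_suspect_run_not_called(self, panel, model):
        raw = pd.DataFrame(CN2, index=["p1"], columns=panel.ids)
        raw.loc["p1", ["e05a", "e05b"]] = CN1
        gated = pd.DataFrame(CN2, index=["p1"], columns=panel.ids)
        sr = cnv.StateResult(states=gated, raw=raw, suspect=raw != gated)
        assert cnv.segment(sr, panel, model) == []


class TestInheritance:
    def _call(self, sample, state, panel, amps=("e05a", "e05b", "e06a", "e06b")):
        ivs = [panel[a].interval for a in amps]
        from evadx.genemodel import exons_overlapped, load_transcript

        iv = GenomicInterval(ivs[0].chrom, min(v.start for v in ivs), max(v.end for v in ivs))
        model = load_transcript("slc26a4_fixture")
        return cnv.CnvCall(
            sample=sample,
            interval=iv,
            exon_range=exons_overlapped(model, iv),
            state=state,
            mean_ratio=0.5,
            z=-5.0,
            n_amplicons=len(amps),
            amplicon_ids=tuple(amps),
        )

    def _ped(self):
        from evadx.pedigree import Pedigree

        ped = Pedigree()
        ped.add_trio("F", "child", "dad", "mum")
        return ped

    def test_maternal_transmission(self, panel):
        calls = [self._call("child", CN1, panel), self._call("mum", CN1, panel)]
        out = cnv.annotate_inheritance(calls, self._ped())
        assert out[0].inheritance == "maternal"

    def test_homozygous_biparental(self, panel):
        calls = [
            self._call("child", CN0, panel),
            self._call("dad", CN1, panel),
            self._call("mum", CN1, panel),
        ]
        out = cnv.annotate_inheritance(calls, self._ped())
        assert out[0].inheritance == "homozygous_biparental"

    def test_de_novo_when_no_parent_carries(self, panel):
        out = cnv.annotate_inheritance([self._call("child", CN1, panel)], self._ped())
        assert out[0].inheritance == "de_novo"

    def test_missing_parents_unknown(self, panel):
        from evadx.pedigree import Pedigree

        ped = Pedigree()
        ped.rows.append(("F", "child", "0", "0", "1", "2"))
        out = cnv.annotate_inheritance([self._call("child", CN1, panel)], ped)
        assert out[0].inheritance == "unknown"


class TestProperties:
    def test_scale_invariance_of_calls(self, panel, model, table2_cohort):
        """Multiplying one sample's raw depths by c > 0 leaves calls unchanged."""
        spec, dm, _ = table2_cohort
        base, _ = cnv.call_cnvs(dm, panel, model, spec.pedigree())
        for c in (0.1, 7.3):
            depth = dm.depth.copy()
            depth.loc["3312177-1"] *= c
            scaled = DepthMatrix(depth, dm.lengths)
            got, _ = cnv.call_cnvs(scaled, panel, model, spec.pedigree())
            key = lambda cl: (cl.sample, cl.state, cl.amplicon_ids)  # noqa: E731
            assert sorted(map(key, got)) == sorted(map(key, base))

    def test_reference_robust_to_few_carriers(self, panel):
        """<=10% carrier samples shift the median reference by < 5%."""
        ev = simulate.PlantedEvent(
            "F01", "deletion", "Exons 9–10 deletion (4979 bp)", "het", "paternal"
        )
        spec_clean = simulate.CohortSpec(n_trios=10, panel=panel, seed=9)
        spec_carrier = simulate.CohortSpec(
            n_trios=10, panel=panel, planted_events=[ev], seed=9
        )
        ref_clean = cnv.ratios(cnv.normalize(simulate.simulate_depth_matrix(spec_clean)[0])).reference
        ref_car = cnv.ratios(cnv.normalize(simulate.simulate_depth_matrix(spec_carrier)[0])).reference
        rel = ((ref_car - ref_clean).abs() / ref_clean).max()
        assert rel < 0.05

    def test_recall_degrades_with_overdispersion(self, panel, model):
        """More counting noise (smaller NB size) can only hurt recovery."""
        recalls = []
        for disp in (200.0, 2.0):
            tp = fn = 0
            for seed in range(20):
                spec = simulate.table2_cohort_spec(panel, seed=seed, depth_dispersion=disp)
                dm, truth = simulate.simulate_depth_matrix(spec)
                calls, _ = cnv.call_cnvs(dm, panel, model, spec.pedigree())
                exp = truth.expected_calls(panel, model)
                got = {
                    (c.sample, c.state, c.exon_range.first_exon, c.exon_range.last_exon)
                    for c in calls
                    if c.exon_range
                }
                tp += len(exp & got)
                fn += len(exp - got)
            recalls.append(tp / (tp + fn))
        assert recalls[1] <= recalls[0]


def test_calls_vcf_round_trips_through_pysam(panel, model, table2_cohort, tmp_path):
    from pysam import VariantFile

    spec, dm, _ = table2_cohort
    calls, _ = cnv.call_cnvs(dm, panel, model, spec.pedigree())
    path = tmp_path / "calls.vcf"
    cnv.write_calls_vcf(calls, path)
    with VariantFile(str(path)) as vf:
        recs = list(vf)
    assert len(recs) == len([c for c in calls if c.state != CN2])
    for rec in recs:
        assert rec.info["SVTYPE"] in ("DEL", "DUP")
        assert rec.stop >= rec.pos
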