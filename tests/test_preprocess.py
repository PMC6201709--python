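import numpy as np
import pytest

from prognae import preprocess as pp
from prognae.errors import ValidationError
from prognae.survival import bh_fdr
from prognae.types import GeneModel, OmicsMatrix, SegmentedCNA, SurvivalTable


class TestFloorLogFpkm:
    def test_hand_traced_rule(self):
        # per-sample nonzero minima (4, 2) -> U=4, L=2; all values < 4
        # floored to 2, then log2
        m = OmicsMatrix(["g1", "g2"], ["s1", "s2"], [[0.0, 2.0], [4.0, 8.0]])
        out = pp.floor_log_fpkm(m)
        np.testing.assert_allclose(out.values, [[1.0, 1.0], [2.0, 3.0]])
        assert out.normalized == "log2"
        assert out.meta["fpkm_floor"] == {"L": 2.0, "U": 4.0}

    def test_all_ones_passes_through_to_zero(self):
        m = OmicsMatrix(["g1"], ["s1", "s2"], [[1.0, 1.0]])
        out = pp.floor_log_fpkm(m)
        np.testing.assert_allclose(out.values, 0.0)

    def test_bounds_recomputed_from_data(self, rng):
        values = rng.uniform(1e-7, 10, size=(50, 8))
        values[rng.random(values.shape) < 0.2] = 0.0
        m = OmicsMatrix([f"g{i}" for i in range(50)], [f"s{j}" for j in range(8)], values)
        low, high = pp.fpkm_floor_bounds(m)
        mins = [values[:, j][values[:, j] > 0].min() for j in range(8)]
        assert low == pytest.approx(min(mins)) and high == pytest.approx(max(mins))
        out = pp.floor_log_fpkm(m)
        assert np.isfinite(out.values).all()
        assert out.values.min() >= np.log2(low) - 1e-12

    def test_all_zero_sample_is_error(self):
        m = OmicsMatrix(["g1"], ["s1", "s2"], [[0.0, 1.0]])
        with pytest.raises(ValidationError, match="all zero"):
            pp.floor_log_fpkm(m)


class TestZscore:
    def test_closed_form_row(self):
        m = OmicsMatrix(["g"], ["a", "b", "c"], [[1.0, 2.0, 3.0]])
        out = pp.zscore_by_gene(m)
        np.testing.assert_allclose(out.values, [[-1.2247, 0.0, 1.2247]], atol=1e-3)

    def test_constant_row_zeroed_with_warning(self, caplog):
        m = OmicsMatrix(["g1", "g2"], ["a", "b", "c"],
                        [[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        with caplog.at_level("WARNING"):
            out = pp.zscore_by_gene(m)
        np.testing.assert_allclose(out.values[0], 0.0)
        assert any("constant" in r.message for r in caplog.records)

    def test_population_moments_and_idempotence(self, rng):
        m = OmicsMatrix([f"g{i}" for i in range(20)], [f"s{j}" for j in range(15)],
                        rng.normal(2, 5, size=(20, 15)))
        out = pp.zscore_by_gene(m)
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-8)
        np.testing.assert_allclose(out.values.std(axis=1), 1.0, atol=1e-6)
        # standardising an already standardised row changes nothing
        again = pp.zscore_by_gene(
            OmicsMatrix(out.feature_ids, out.sample_ids, out.values))
        np.testing.assert_allclose(again.values, out.values, atol=1e-8)


def brute_force_gene_value(segments, gene, sample):
    """Per-base average oracle on toy genomes: assign each covered base
    its segment mean and average over covered bases of the gene body."""
    covered = {}
    for s in segments:
        if s.sample_id != sample or s.chrom != gene.chrom:
            continue
        for pos in range(max(s.start, gene.start), min(s.end, gene.end) + 1):
            covered.setdefault(pos, []).append(s.segment_mean)
    if not covered:
        return 0.0
    # length-weighted mean == mean over covered bases when segments
    # do not overlap each other; overlapping bases contribute each mean
    vals = [v for means in covered.values() for v in means]
    return float(np.mean(vals))


class TestCnaGeneMatrix:
    GENES = [GeneModel("gA", "chr1", 101, 200), GeneModel("gB", "chr1", 301, 400)]

    def test_fully_contained_gene_takes_segment_value(self):
        segs = [SegmentedCNA("S1", "chr1", 1, 1000, 1.0)]
        m = pp.cna_gene_matrix(segs, self.GENES, ["S1"])
        np.testing.assert_allclose(m.values, [[1.0], [1.0]])
        assert m.omics_kind == "cna" and m.normalized == "log2cn"

    def test_diploid_and_uncovered_are_zero(self):
        segs = [SegmentedCNA("S1", "chr1", 1, 250, 0.0)]
        m = pp.cna_gene_matrix(segs, self.GENES, ["S1"])
        np.testing.assert_allclose(m.values, [[0.0], [0.0]])

    def test_length_weighted_split(self):
        # gene 101..200 covered 50 bp at mean 1.0 and 50 bp at mean 0.0
        segs = [SegmentedCNA("S1", "chr1", 101, 150, 1.0),
                SegmentedCNA("S1", "chr1", 151, 200, 0.0)]
        m = pp.cna_gene_matrix(segs, self.GENES, ["S1"])
        assert m.values[0, 0] == pytest.approx(0.5)

    def test_matches_per_base_oracle_on_random_toys(self, rng):
        genes = [GeneModel(f"g{i}", "chr1", 1 + 60 * i, 50 + 60 * i) for i in range(5)]
        for _ in range(10):
            segs = []
            for sample in ("S1", "S2"):
                pos = 1
                while pos < 400:
                    length = int(rng.integers(10, 120))
                    segs.append(SegmentedCNA(sample, "chr1", pos, pos + length - 1,
                                             float(rng.normal())))
                    pos += length + int(rng.integers(0, 40))
            m = pp.cna_gene_matrix(segs, genes, ["S1", "S2"])
            for i, g in enumerate(genes):
                for j, s in enumerate(["S1", "S2"]):
                    assert m.values[i, j] == pytest.approx(
                        brute_force_gene_value(segs, g, s), abs=1e-9)

    def test_unknown_chromosome_skipped_with_warning(self, caplog):
        segs = [SegmentedCNA("S1", "chrUn", 1, 100, 2.0)]
        with caplog.at_level("WARNING"):
            m = pp.cna_gene_matrix(segs, self.GENES, ["S1"])
        np.testing.assert_allclose(m.values, 0.0)
        assert any("unknown chromosome" in r.message for r in caplog.records)

    def test_empty_gene_list_is_error(self):
        with pytest.raises(ValidationError):
            pp.cna_gene_matrix([], [], ["S1"])


class TestCoxScreen:
    def test_constant_feature_never_selected(self, rng, survival_factory):
        time, event = survival_factory(rng, 40)
        ids = [f"s{i}" for i in range(40)]
        surv = SurvivalTable.from_records(ids, time, event, time, event)
        m = OmicsMatrix(["flat", "x"], ids,
                        np.vstack([np.ones(40), rng.normal(size=40)]))
        kept, report = pp.cox_screen_features(m, surv, alpha=0.05)
        assert not report.loc["flat", "kept"]
        assert report.loc["flat", "p_efs"] == pytest.approx(1.0)

    def test_strong_feature_power(self, rng):
        hits = 0
        reps = 60
        for _ in range(reps):
            group = rng.integers(0, 2, size=200)
            t_event = rng.exponential(np.where(group == 1, 1 / 3, 1.0) * 10)
            c = rng.exponential(23, size=200)  # ~30% censoring
            time, event = np.minimum(t_event, c), (t_event <= c).astype(int)
            ids = [f"s{i}" for i in range(200)]
            surv = SurvivalTable.from_records(ids, time, event, time, event)
            m = OmicsMatrix(["hr3"], ids, group[None, :].astype(float))
            _, report = pp.cox_screen_features(m, surv)
            hits += int(report["kept"].iloc[0])
        assert hits / reps >= 0.95

    def test_selection_invariant_to_positive_scaling(self, rng, survival_factory):
        time, event = survival_factory(rng, 60)
        ids = [f"s{i}" for i in range(60)]
        surv = SurvivalTable.from_records(ids, time, event, time, event)
        X = rng.normal(size=(30, 60))
        m1 = OmicsMatrix([f"g{i}" for i in range(30)], ids, X)
        m2 = OmicsMatrix([f"g{i}" for i in range(30)], ids, X * 11.0)
        _, r1 = pp.cox_screen_features(m1, surv)
        _, r2 = pp.cox_screen_features(m2, surv)
        assert (r1["kept"] == r2["kept"]).all()

    def test_too_few_events_endpoint_skipped(self, rng):
        ids = [f"s{i}" for i in range(30)]
        time = rng.exponential(10, size=30)
        efs_event = np.zeros(30, dtype=int)  # no EFS events at all
        os_event = rng.integers(0, 2, size=30)
        os_event[:5] = 1
        surv = SurvivalTable.from_records(ids, time, efs_event, time, os_event)
        m = OmicsMatrix(["g"], ids, rng.normal(size=(1, 30)))
        _, report = pp.cox_screen_features(m, surv)
        assert np.isnan(report["p_efs"].iloc[0])
        assert np.isfinite(report["p_os"].iloc[0])


class TestStack:
    def _m(self, genes, samples, kind="expression", norm="zscore", seed=0):
        rng = np.random.default_rng(seed)
        return OmicsMatrix(genes, samples, rng.normal(size=(len(genes), len(samples))),
                           omics_kind=kind, normalized=norm)

    def test_concatenation_shape_and_prefixes(self):
        e = self._m(["G1", "G2", "G3"], ["a", "b", "c", "d"])
        c = self._m(["G1", "G4"], ["a", "b", "c", "d"], kind="cna", norm="log2cn")
        s = pp.stack_omics(e, c)
        assert s.values.shape == (5, 4)
        assert s.feature_ids == ["GE:G1", "GE:G2", "GE:G3", "CNA:G1", "CNA:G4"]
        assert s.meta["row_provenance"] == ["expression"] * 3 + ["cna"] * 2

    def test_sample_intersection_keeps_expression_order(self):
        e = self._m(["G1"], ["a", "b", "c"])
        c = self._m(["G2"], ["c", "b", "d"], kind="cna", norm="log2cn")
        s = pp.stack_omics(e, c)
        assert s.sample_ids == ["b", "c"]
        np.testing.assert_allclose(s.values[0], e.values[0, 1:])

    def test_empty_intersection_is_error(self):
        e = self._m(["G1"], ["a", "b"])
        c = self._m(["G2"], ["x", "y"], kind="cna", norm="log2cn")
        with pytest.raises(ValidationError):
            pp.stack_omics(e, c)
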