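"""cpm, the three-stage filter cascade, and the enrichment estimator."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_counts
from lncscreen.screen import (
    cpm,
    estimate_enrichment,
    filter_cascade,
    size_factors_median_of_ratios,
)


class TestCpm:
    def test_arithmetic(self):
        counts = pd.DataFrame({"s": [10, 990]}, index=["a", "b"])
        assert cpm(counts).loc["a", "s"] == pytest.approx(10_000)

    def test_uniform_column(self):
        counts = pd.DataFrame({"s": [7] * 4}, index=list("abcd"))
        assert np.allclose(cpm(counts)["s"], 1e6 / 4)

    def test_columns_sum_to_1e6(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, (50, 3)) + 1)
        assert np.allclose(cpm(counts).sum(axis=0), 1e6, rtol=1e-9)

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError, match="empty sample"):
            cpm(pd.DataFrame({"s": [0, 0]}))


class TestFilterCascade:
    def base_counts(self, day0_a=(5, 4)):
        # column totals fixed at 1,000,000 so cpm equals the raw count;
        # guide 'a' is the probe, fillers absorb the remainder
        vals = {
            "a": [day0_a[0], day0_a[1], 200, 200, 200, 200],
            "b": [600, 600, 600, 600, 600, 600],
            "c": [700, 700, 700, 700, 700, 700],
        }
        filler_total = [1_000_000 - sum(v[i] for v in vals.values())
                        for i in range(6)]
        vals["filler"] = filler_total
        counts, samples = make_counts(vals)
        targets = pd.Series(
            {"a": "T1", "b": "T1", "c": "T1", "filler": "T2"}
        )
        return counts, samples, targets

    def test_boundary_exactly_5cpm_kept(self):
        counts, samples, targets = self.base_counts(day0_a=(5, 5))
        rep = filter_cascade(counts, samples, targets)
        assert "a" in rep.stage1

    def test_just_below_5cpm_removed(self):
        # day0 cpm (5.0, 4.0): fails the "in both replicates" rule
        counts, samples, targets = self.base_counts(day0_a=(5, 4))
        rep = filter_cascade(counts, samples, targets)
        assert "a" not in rep.stage1
        assert {"b", "c"} <= rep.stage1

    def test_stage3_needs_three_guides_per_tss(self):
        counts, samples, targets = self.base_counts(day0_a=(5, 4))
        rep = filter_cascade(counts, samples, targets)
        # T1 keeps only b,c after stages 1-2 -> both die at stage 3
        assert rep.stage3 & {"b", "c"} == set()
        assert rep.n_tss_after == 0

    def test_scrambled_exempt_from_stage3(self):
        vals = {
            "scr": [10_000, 10_000, 10_000, 10_000, 10_000, 10_000],
            "g1": [90_000, 90_000, 90_000, 90_000, 90_000, 90_000],
        }
        counts, samples = make_counts(vals)
        targets = pd.Series({"scr": "SCRAMBLED", "g1": "T1"})
        rep = filter_cascade(counts, samples, targets)
        assert "scr" in rep.stage3  # survives despite having no TSS
        assert "g1" not in rep.stage3  # T1 has < 3 guides
        assert rep.n_scrambled_after == 1

    def test_monotone_stages(self, screen_bundle):
        rep = screen_bundle["filter"]
        assert rep.stage3 <= rep.stage2 <= rep.stage1
        c = rep.counts
        assert (
            c["input_guides"] >= c["after_stage1_day0_cpm"]
            >= c["after_stage2_undiff_cpm"] >= c["after_stage3_min_guides"]
        )

    def test_low_abundance_guides_die_at_stage1(self):
        # expected day0 cpm below 5 -> removed with probability -> 1 at depth
        rng = np.random.default_rng(3)
        n = 2_000
        weights = np.ones(n)
        weights[:100] = 0.004  # cpm ~ 4, below the floor of 5
        p = weights / weights.sum()
        depth = 500 * n
        vals = {}
        draws = [rng.multinomial(depth, p) for _ in range(6)]
        for i in range(n):
            vals[f"g{i}"] = [int(d[i]) for d in draws]
        counts, samples = make_counts(vals)
        targets = pd.Series({f"g{i}": f"T{i // 10}" for i in range(n)})
        rep = filter_cascade(counts, samples, targets)
        low = {f"g{i}" for i in range(100)}
        assert len(low & rep.stage1) / 100 <= 0.01

    def test_missing_population_rejected(self):
        counts = pd.DataFrame({"day0_rep1": [10]}, index=["a"])
        samples = pd.DataFrame(
            [{"sample": "day0_rep1", "population": "day0", "replicate": 1}]
        )
        with pytest.raises(ValueError, match="undifferentiated"):
            filter_cascade(counts, samples, pd.Series({"a": "T1"}))


class TestEnrichment:
    def test_hand_arithmetic_40_vs_10(self):
        # probe has 40 vs 10 in both replicates; fillers are symmetric so
        # size factors are 1 and log2fc = log2(40.5/10.5)
        vals = {"probe": [40, 40, 40, 40, 10, 10]}
        for i in range(9):
            vals[f"f{i}"] = [100] * 6
        counts, samples = make_counts(vals)
        enr = estimate_enrichment(counts, samples, set(counts.index))
        assert enr.loc["probe", "log2fc"] == pytest.approx(
            np.log2(40.5 / 10.5), abs=1e-9
        )
        assert enr.loc["probe", "standard_error"] == pytest.approx(0.0, abs=1e-9)

    def test_identical_populations_give_zero(self):
        vals = {f"g{i}": [50] * 6 for i in range(5)}
        counts, samples = make_counts(vals)
        enr = estimate_enrichment(counts, samples, set(counts.index))
        assert np.allclose(enr.log2fc, 0.0)

    def test_size_factors_absorb_depth(self):
        # doubling one column's depth must not shift log2fc
        vals = {f"g{i}": [50, 50, 50, 50, 50, 50] for i in range(20)}
        counts, samples = make_counts(vals)
        counts["undiff_rep1"] *= 2
        enr = estimate_enrichment(counts, samples, set(counts.index))
        assert np.allclose(enr.log2fc, 0.0, atol=1e-9)

    def test_median_of_ratios_identity(self):
        counts = pd.DataFrame(
            {"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=list("abc")
        )
        sf = size_factors_median_of_ratios(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_incomplete_replicate_pair_rejected(self):
        counts = pd.DataFrame({"undiff_rep1": [5]}, index=["a"])
        samples = pd.DataFrame(
            [{"sample": "undiff_rep1", "population": "undifferentiated",
              "replicate": 1}]
        )
        with pytest.raises(ValueError):
            estimate_enrichment(counts, samples)

    def test_planted_dropout_gives_positive_lfc(self, screen_bundle):
        lib, truth = screen_bundle["library"], screen_bundle["truth"]
        enr = screen_bundle["enrichment"]
        eff = [
            g for g, t in zip(lib.guide_id, lib.target_tss_id)
            if t in truth.functional_tss_ids and truth.guide_efficiency[g] == 1.0
            and g in enr.index
        ]
        null = [
            g for g, t in zip(lib.guide_id, lib.target_tss_id)
            if t == "SCRAMBLED" and g in enr.index
        ]
        assert enr.log2fc[eff].mean() > enr.log2fc[null].mean() + 0.5
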