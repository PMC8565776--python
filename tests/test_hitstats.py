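"""Validation scores, Mann-Whitney / Fisher tests vs enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncscreen.hitstats import (
    compare_hit_features,
    de_hit_association,
    validation_score,
)


class TestValidationScore:
    def test_no_enrichment_is_zero(self):
        assert validation_score(50, 50, 50, 50) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # target 20/80 vs scrambled 5/95
        expected = math.log2((20 / 80) / (5 / 95))
        assert validation_score(20, 80, 5, 95) == pytest.approx(expected)

    def test_strictly_monotone_in_pct_undiff(self):
        scores = [validation_score(u, 80, 5, 95) for u in (10, 20, 40, 80)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_zero_percentage_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            s = validation_score(0, 80, 5, 95)
        assert np.isfinite(s)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            validation_score(120, 50, 50, 50)


def exact_mannwhitney_p(a, b):
    """Two-sided exact p by enumerating all group assignments of the
    pooled values (oracle; independent of scipy's implementation)."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = sum(ranks[:n_a]) - n_a * (n_a + 1) / 2
    mean_u = n_a * len(b) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        u = sum(ranks[list(idx)]) - n_a * (n_a + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def feature_table(self, hit_vals, nonhit_vals):
        genes = [f"h{i}" for i in range(len(hit_vals))] + [
            f"n{i}" for i in range(len(nonhit_vals))
        ]
        tbl = pd.DataFrame(
            {"gene_id": genes, "feat": list(hit_vals) + list(nonhit_vals)}
        ).set_index("gene_id", drop=False)
        return tbl, genes[: len(hit_vals)], genes[len(hit_vals):]

    def test_exact_example_123_vs_456(self):
        # all 20 arrangements enumerable by hand: two-sided p = 0.1
        tbl, hits, nonhits = self.feature_table([1, 2, 3], [4, 5, 6])
        out = compare_hit_features(tbl, hits, nonhits, features=["feat"])
        assert out.loc["feat", "p_value"] == pytest.approx(0.1)
        assert exact_mannwhitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(3, 6))
        n_b = int(rng.integers(3, 6))
        a = rng.normal(size=n_a).round(2)
        b = rng.normal(rng.uniform(-1, 1), 1, size=n_b).round(2)
        tbl, hits, nonhits = self.feature_table(a, b)
        out = compare_hit_features(tbl, hits, nonhits, features=["feat"])
        assert out.loc["feat", "p_value"] == pytest.approx(
            exact_mannwhitney_p(a, b), abs=1e-9
        )

    def test_identical_groups_p1(self):
        tbl, hits, nonhits = self.feature_table([1, 2, 3], [1, 2, 3])
        out = compare_hit_features(tbl, hits, nonhits, features=["feat"])
        assert out.loc["feat", "p_value"] == pytest.approx(1.0)

    def test_null_bh_calibration(self):
        # 11 independent null features: average fraction flagged at BH 0.1
        # stays at or below 0.1
        rng = np.random.default_rng(7)
        flagged = []
        for _ in range(300):
            tbl = pd.DataFrame(
                rng.normal(size=(30, 11)),
                columns=[f"f{i}" for i in range(11)],
            )
            tbl.insert(0, "gene_id", [f"g{i}" for i in range(30)])
            tbl = tbl.set_index("gene_id", drop=False)
            out = compare_hit_features(
                tbl, [f"g{i}" for i in range(12)],
                [f"g{i}" for i in range(12, 30)],
            )
            flagged.append(out.significant.mean())
        assert np.mean(flagged) <= 0.1

    def test_all_missing_feature_skipped(self):
        tbl, hits, nonhits = self.feature_table([1, 2, 3], [4, 5, 6])
        tbl["empty"] = np.nan
        with pytest.warns(UserWarning, match="all-missing"):
            out = compare_hit_features(tbl, hits, nonhits,
                                       features=["feat", "empty"])
        assert "empty" not in out.index


class TestFisher:
    def flags(self, hit_de, hit_not, non_de, non_not):
        ids, vals = [], []
        for label, n, v in [("hd", hit_de, True), ("hn", hit_not, False),
                            ("nd", non_de, True), ("nn", non_not, False)]:
            ids += [f"{label}{i}" for i in range(n)]
            vals += [v] * n
        hits = [i for i in ids if i.startswith("h")]
        nons = [i for i in ids if i.startswith("n")]
        return hits, nons, pd.Series(vals, index=ids)

    def test_sample_odds_ratio(self):
        hits, nons, fl = self.flags(2, 3, 3, 2)
        out = de_hit_association(hits, nons, fl)
        assert out["odds_ratio"] == pytest.approx(4 / 9)

    def test_independence_table(self):
        hits, nons, fl = self.flags(5, 5, 5, 5)
        out = de_hit_association(hits, nons, fl)
        assert out["odds_ratio"] == pytest.approx(1.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_zero_margin_is_nan(self):
        hits, nons, fl = self.flags(0, 5, 0, 5)
        assert math.isnan(de_hit_association(hits, nons, fl)["odds_ratio"])

    @pytest.mark.parametrize("seed", range(8))
    def test_p_matches_hypergeometric_enumeration(self, seed):
        # enumerate all tables with the observed margins (n <= 30)
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 8, 4))
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            return
        hits, nons, fl = self.flags(a, b, c, d)
        out = de_hit_association(hits, nons, fl)
        n, r1, c1 = a + b + c + d, a + b, a + c
        probs = {}
        for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
            probs[x] = stats.hypergeom.pmf(x, n, r1, c1)
        p_exact = sum(p for x, p in probs.items()
                      if p <= probs[a] * (1 + 1e-9))
        assert out["p_value"] == pytest.approx(p_exact, abs=1e-9)
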