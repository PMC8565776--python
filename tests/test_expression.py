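"""Expression thresholding, tau, and the plumbing DE test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lncscreen.expression import (
    expressed_set,
    gene_level,
    lineage_means,
    simple_de_test,
    specificity_compare,
    tau,
    tau_table,
)


def make_table(rows):
    """rows: transcript_id -> (gene_id, [hESC x2, endoderm x2, mesoderm x2])"""
    cols = [f"{lin}_rep{r}" for lin in ("hESC", "endoderm", "mesoderm")
            for r in (1, 2)]
    data = []
    for tid, (gid, vals) in rows.items():
        data.append({"transcript_id": tid, "gene_id": gid, "biotype": "lncRNA",
                     **dict(zip(cols, vals))})
    table = pd.DataFrame(data).set_index("transcript_id", drop=False)
    samples = pd.DataFrame(
        [{"sample": c, "lineage": c.rsplit("_", 1)[0],
          "replicate": int(c[-1])} for c in cols]
    )
    return table, samples


class TestExpressedSet:
    def test_single_passing_lineage_suffices(self):
        table, samples = make_table(
            {"t1": ("g1", [0.05, 0.05, 0.2, 0.2, 0.0, 0.0])}
        )
        assert expressed_set(table, samples) == {"t1"}

    def test_all_zero_excluded(self):
        table, samples = make_table({"t1": ("g1", [0.0] * 6)})
        assert expressed_set(table, samples) == set()

    def test_replicate_mean_vs_any_sample_modes(self):
        # one replicate at 0.15, the other at 0: lineage mean 0.075 < 0.1
        table, samples = make_table({"t1": ("g1", [0.15, 0.0, 0.0, 0.0, 0.0, 0.0])})
        assert expressed_set(table, samples, mode="lineage_mean") == set()
        assert expressed_set(table, samples, mode="any_sample") == {"t1"}

    def test_gene_level_sums_transcripts(self):
        table, samples = make_table(
            {"t1": ("g1", [0.06, 0.06, 0, 0, 0, 0]),
             "t2": ("g1", [0.06, 0.06, 0, 0, 0, 0])}
        )
        # neither transcript passes alone; the gene (sum 0.12) does
        assert expressed_set(table, samples, level="transcript") == set()
        assert expressed_set(table, samples, level="gene") == {"g1"}
        g = gene_level(table)
        assert g.loc["g1", "hESC_rep1"] == pytest.approx(0.12)


class TestTau:
    @pytest.mark.parametrize(
        "x,expected",
        [
            ((5, 5, 5), 0.0),        # ubiquitous limit
            ((7, 0, 0), 1.0),        # single-lineage limit
            ((10, 5, 0), 0.75),      # ((1-1)+(1-0.5)+(1-0))/2
        ],
    )
    def test_hand_values(self, x, expected):
        assert tau(x).tau == pytest.approx(expected)

    def test_silent_gene_is_missing(self):
        assert math.isnan(tau((0, 0, 0)).tau)

    @given(
        x=st.lists(st.floats(0, 1e4), min_size=2, max_size=6),
        c=st.floats(1e-3, 1e3),
    )
    @settings(derandomize=True, max_examples=200)
    def test_scale_invariant_and_bounded(self, x, c):
        if max(x) == 0:
            return
        t1 = tau(np.array(x)).tau
        t2 = tau(c * np.array(x)).tau
        assert t1 == pytest.approx(t2, rel=1e-9)
        assert 0.0 <= t1 <= 1.0

    def test_monotone_under_concentration_small_grid(self):
        # moving mass from a non-maximal lineage into the maximal one never
        # decreases tau: exhaustive check on a small grid
        grid = range(0, 6)
        for a, b, c in itertools.product(grid, repeat=3):
            x = np.array([a, b, c], dtype=float)
            if x.max() == 0 or x.argmax() == 1 or x[1] == 0:
                continue
            y = x.copy()
            y[x.argmax()] += 1
            y[1] -= 1
            assert tau(y).tau >= tau(x).tau - 1e-12

    def test_tau_table_matches_scalar(self):
        table, samples = make_table(
            {"t1": ("g1", [10, 10, 5, 5, 0, 0]),
             "t2": ("g2", [3, 3, 3, 3, 3, 3])}
        )
        tt = tau_table(table, samples)
        assert tt["t1"] == pytest.approx(0.75)
        assert tt["t2"] == pytest.approx(0.0)


class TestSpecificityCompare:
    def test_identical_groups_not_significant(self):
        vals = pd.Series(np.linspace(0.1, 0.9, 30))
        out = specificity_compare({"a": vals, "b": vals.copy()})
        assert out.p_value.iloc[0] > 0.9
        assert out.median_a.iloc[0] == out.median_b.iloc[0]

    def test_small_group_skipped(self):
        out = specificity_compare(
            {"a": pd.Series([0.5]), "b": pd.Series([0.1, 0.2, 0.3])}
        )
        assert out.empty

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(0)
        hi = pd.Series(rng.uniform(0.7, 1.0, 50))
        lo = pd.Series(rng.uniform(0.0, 0.3, 50))
        out = specificity_compare({"lnc": hi, "mrna": lo})
        assert out.p_value.iloc[0] < 1e-6


class TestSimpleDe:
    def test_exact_fold_change_without_noise(self):
        table, samples = make_table(
            {"t1": ("g1", [8.0, 8.0, 1.0, 1.0, 1.0, 1.0])}
        )
        de = simple_de_test(table, samples, "hESC", "endoderm", pseudo_tpm=0.0)
        assert de.loc["t1", "log2fc"] == pytest.approx(3.0)

    def test_zero_variance_flagged_p1(self):
        table, samples = make_table({"t1": ("g1", [2, 2, 2, 2, 2, 2])})
        de = simple_de_test(table, samples, "hESC", "endoderm")
        assert de.loc["t1", "p_value"] == 1.0
        assert bool(de.loc["t1", "zero_variance"])

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(1)
        rows = {
            f"t{i}": ("g", list(rng.lognormal(1, 0.3, 6))) for i in range(400)
        }
        table, samples = make_table(rows)
        de = simple_de_test(table, samples, "hESC", "endoderm")
        ks = stats.kstest(de.p_value, "uniform")
        assert ks.pvalue > 0.01

    def test_power_for_8fold_change(self):
        # 8x fold change, 10% CV, n=2: q < 0.05 in >= 90% of simulations
        rng = np.random.default_rng(2)
        hits = 0
        n_sim = 50
        for _ in range(n_sim):
            rows = {
                f"null{i}": ("g", list(rng.lognormal(1, 0.1, 6)))
                for i in range(50)
            }
            de_vals = list(8 * rng.lognormal(0, 0.1, 2)) + list(
                rng.lognormal(0, 0.1, 4)
            )
            rows["de"] = ("g", de_vals)
            table, samples = make_table(rows)
            de = simple_de_test(table, samples, "hESC", "endoderm")
            hits += de.loc["de", "q_value"] < 0.05
        assert hits / n_sim >= 0.9

    def test_output_flagged_as_plumbing(self):
        table, samples = make_table({"t1": ("g1", [1, 2, 3, 4, 5, 6])})
        de = simple_de_test(table, samples, "hESC", "endoderm")
        assert (de.method == "pooled_t_plumbing_not_screen_de").all()
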