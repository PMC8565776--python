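"""Generator round trips: every planted property is recovered downstream."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncscreen import annotation, expression, screen, simulate


class TestAnnotationGenerator:
    def test_category_mix_round_trip_exact(self):
        mix = {"intergenic": 10, "promoter_overlapping": 10,
               "transcript_overlapping": 10, "gene_nearby": 10}
        ts, _ = simulate.gen_annotation(n_mrna=15, n_lnc=40,
                                        category_mix=mix, rng_seed=3)
        cats = annotation.categorize_all(ts)
        assert cats.value_counts().to_dict() == mix

    @pytest.mark.parametrize("seed", [0, 7, 23])
    def test_round_trip_across_seeds_and_uneven_mixes(self, seed):
        mix = {"intergenic": 5, "promoter_overlapping": 8,
               "transcript_overlapping": 2, "gene_nearby": 6}
        ts, _ = simulate.gen_annotation(n_mrna=9, n_lnc=21,
                                        category_mix=mix, rng_seed=seed)
        assert annotation.categorize_all(ts).value_counts().to_dict() == mix

    def test_mrna_only_annotation_valid(self):
        ts, genome = simulate.gen_annotation(n_mrna=5, n_lnc=0,
                                             category_mix={}, rng_seed=0)
        assert all(t.biotype == "protein_coding" for t in ts)
        assert len(genome["chrS1"]) > 0

    def test_gtf_bytes_deterministic(self, tmp_path):
        for name in ("a.gtf", "b.gtf"):
            ts, _ = simulate.gen_annotation(n_mrna=6, n_lnc=8, rng_seed=5)
            annotation.write_gtf(ts, tmp_path / name)
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_rna_mechanism_genes_have_mrna_like_structure(self):
        ts, _ = simulate.gen_annotation(n_mrna=8, n_lnc=12, rng_seed=1,
                                        n_rna_mechanism=3)
        rm = [t for t in ts if t.gene_id.startswith("LNCRM")]
        plain = [t for t in ts if t.gene_id.startswith("LNC") and
                 not t.gene_id.startswith("LNCRM")]
        assert len({t.gene_id for t in rm}) == 3
        assert min(t.locus_length for t in rm) > max(t.locus_length for t in plain)


class TestExpressionGenerator:
    def test_specific_gene_realizes_high_tau(self):
        ts, _ = simulate.gen_annotation(n_mrna=10, n_lnc=20, rng_seed=2)
        expr, samples, truth = simulate.gen_expression(ts, rng_seed=4)
        spliced = expr[~expr.is_unspliced].drop(columns="is_unspliced")
        taus = expression.tau_table(expression.gene_level(spliced), samples)
        spec = [g for g, v in truth["genes"].items()
                if v["specific"] and not v["silent"]]
        ubi = [g for g, v in truth["genes"].items()
               if not v["specific"] and not v["silent"]]
        assert taus[spec].median() >= 0.8
        assert taus[ubi].median() < 0.5

    def test_zero_noise_gives_identical_replicates(self):
        ts, _ = simulate.gen_annotation(n_mrna=4, n_lnc=4, rng_seed=0)
        expr, samples, _ = simulate.gen_expression(ts, rng_seed=1, noise_cv=0.0)
        for lin in ("hESC", "endoderm", "mesoderm"):
            assert np.allclose(expr[f"{lin}_rep1"], expr[f"{lin}_rep2"])

    def test_splicing_truth_recovered(self):
        ts, _ = simulate.gen_annotation(n_mrna=10, n_lnc=20, rng_seed=2)
        expr, _, truth = simulate.gen_expression(ts, rng_seed=6)
        est = simulate.estimated_splicing(expr)
        errs = [
            abs(est[g] - truth["genes"][g]["splicing_efficiency"])
            for g in est.index if np.isfinite(est[g])
        ]
        assert np.mean(errs) <= 0.05
        # exact at zero noise
        expr0, _, truth0 = simulate.gen_expression(ts, rng_seed=6, noise_cv=0.0)
        est0 = simulate.estimated_splicing(expr0)
        errs0 = [
            abs(est0[g] - truth0["genes"][g]["splicing_efficiency"])
            for g in est0.index if np.isfinite(est0[g])
        ]
        assert max(errs0) < 1e-9


class TestScreenGenerator:
    def test_fixed_seed_identical_counts(self):
        a = simulate.simulate_screen_dataset(rng_seed=9, n_tss=50,
                                             n_scrambled=100, n_functional=5)
        b = simulate.simulate_screen_dataset(rng_seed=9, n_tss=50,
                                             n_scrambled=100, n_functional=5)
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_null_guides_match_scrambled_distribution(self):
        rejections = 0
        n_seeds = 10
        for seed in range(n_seeds):
            lib, counts, samples, truth = simulate.simulate_screen_dataset(
                rng_seed=seed, n_tss=100, n_scrambled=300, n_functional=0
            )
            enr = screen.estimate_enrichment(counts, samples, set(lib.guide_id))
            is_scr = (lib.target_tss_id == "SCRAMBLED").reindex(enr.index)
            p = stats.mannwhitneyu(
                enr.log2fc[is_scr], enr.log2fc[~is_scr],
                alternative="two-sided",
            ).pvalue
            rejections += p <= 0.01
        assert rejections / n_seeds <= 0.05 + 1 / n_seeds

    def test_fully_effective_tss_guides_in_top_decile(self):
        lib = simulate.make_screen_library_frame(200, 10, 200)
        truth = simulate.make_sim_truth(lib, n_functional=1, effect_log2=2.0,
                                        pi=1.0, rng_seed=3)
        counts, samples = simulate.gen_screen_counts(lib, truth, rng_seed=4)
        enr = screen.estimate_enrichment(counts, samples, set(lib.guide_id))
        func = next(iter(truth.functional_tss_ids))
        func_guides = lib.guide_id[lib.target_tss_id == func]
        cutoff = enr.log2fc.quantile(0.9)
        assert (enr.log2fc[func_guides] >= cutoff).all()

    def test_truth_serialization_round_trip(self, tmp_path):
        lib = simulate.make_screen_library_frame(20, 5, 30)
        truth = simulate.make_sim_truth(lib, n_functional=3, rng_seed=5)
        truth.to_json(tmp_path / "truth.json")
        back = simulate.SimTruth.from_json(tmp_path / "truth.json")
        assert back.functional_tss_ids == truth.functional_tss_ids
        assert back.guide_efficiency == truth.guide_efficiency
        assert back.batch_offsets == truth.batch_offsets

    def test_nonfunctional_tss_have_zero_effect(self):
        lib = simulate.make_screen_library_frame(30, 5, 10)
        truth = simulate.make_sim_truth(lib, n_functional=4, rng_seed=6)
        for tss, eff in truth.tss_effect.items():
            if tss not in truth.functional_tss_ids:
                assert eff == 0.0
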