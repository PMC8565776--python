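"""Calibration and recovery suites for the screen statistics.

The published hit landscape of a real screen embeds fits on real biology
and cannot be re-derived from synthetic data; what *can* be verified is
that the re-implemented statistics behave correctly under known truth:

* pure-null calibration — with zero functional TSSs, the empirical false
  discovery proportion at nominal FDR 0.1 stays near nominal;
* planted recovery — with 50/1,000 functional TSSs, guide efficiency
  pi = 0.5, and an effect two empirical-null SDs wide, most functional TSSs
  are recovered at FDR < 0.1 with controlled FDP;
* estimator bias — enrichment log2FC and the top-3 effect size are
  unbiased for the planted effect at 500 reads/guide (the effect-size check
  uses 3-guide TSSs so the top-3 statistic is selection-free; with more
  guides than 3 the published definition carries a known order-statistic
  lift).

Each suite re-simulates from scratch given a seed.
"""

from __future__ import annotations

import numpy as np

from . import mixture, screen, simulate


def _spawn_seeds(rng_seed: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(rng_seed).spawn(n)
    ]


def _run_one(seed: int, n_functional: int, effect_log2: float, **kwargs):
    lib, counts, samples, truth = simulate.simulate_screen_dataset(
        rng_seed=seed, n_functional=n_functional, effect_log2=effect_log2,
        **kwargs,
    )
    rep = screen.filter_cascade(counts, samples, lib.target_tss_id)
    enr = screen.estimate_enrichment(counts, samples, rep.survivors)
    model, calls = mixture.call_screen(
        enr, lib.target_tss_id, rep.survivors, rng_seed=seed
    )
    hits = set(calls.index[calls.is_hit])
    func = truth.functional_tss_ids
    sens = len(hits & func) / len(func) if func else float("nan")
    fdp = len(hits - func) / len(hits) if hits else 0.0
    return {
        "n_hits": len(hits), "n_false": len(hits - func),
        "sensitivity": sens, "fdp": fdp, "null_sd": model.null_sd,
        "pi_hat": model.pi_guide,
    }


def measure_null_sd(rng_seed: int = 0) -> float:
    """Empirical null SD (scrambled-guide log2FC spread) under the default
    generator settings, from one zero-functional dataset."""
    lib, counts, samples, _ = simulate.simulate_screen_dataset(
        rng_seed=rng_seed, n_functional=0
    )
    rep = screen.filter_cascade(counts, samples, lib.target_tss_id)
    enr = screen.estimate_enrichment(counts, samples, rep.survivors)
    scr = enr.log2fc[
        (lib.target_tss_id == "SCRAMBLED").reindex(enr.index).fillna(False)
    ]
    return float(scr.std(ddof=1))


def null_fdr_suite(rng_seed: int = 0, n_seeds: int = 50) -> dict:
    """Pure-null simulations (1,000 TSSs x 10 guides, 0 functional)."""
    res = [
        _run_one(s, n_functional=0, effect_log2=0.0)
        for s in _spawn_seeds(rng_seed, n_seeds)
    ]
    fdps = np.array([r["fdp"] for r in res])
    return {
        "n_seeds": n_seeds,
        "mean_fdp": float(fdps.mean()),
        "mean_hits": float(np.mean([r["n_hits"] for r in res])),
        "max_hits": int(max(r["n_hits"] for r in res)),
    }


def planted_recovery_suite(
    rng_seed: int = 0, n_seeds: int = 50, shift_null_sd: float = 2.0
) -> dict:
    """Planted simulations: 50/1,000 functional, pi = 0.5, effect =
    ``shift_null_sd`` empirical null SDs."""
    seeds = _spawn_seeds(rng_seed, n_seeds + 1)
    null_sd = measure_null_sd(seeds[0])
    effect = shift_null_sd * null_sd
    res = [
        _run_one(s, n_functional=simulate.N_FUNCTIONAL_DEFAULT,
                 effect_log2=effect)
        for s in seeds[1:]
    ]
    return {
        "n_seeds": n_seeds,
        "effect_log2": float(effect),
        "null_sd": float(null_sd),
        "median_sensitivity": float(np.median([r["sensitivity"] for r in res])),
        "median_fdp": float(np.median([r["fdp"] for r in res])),
        "mean_sensitivity": float(np.mean([r["sensitivity"] for r in res])),
        "mean_fdp": float(np.mean([r["fdp"] for r in res])),
    }


def estimator_bias_suite(
    rng_seed: int = 0, n_reps: int = 200, effect_log2: float = 1.0
) -> dict:
    """Bias of the enrichment estimator (10-guide TSSs, fully effective
    guides) and of the top-3 effect size (3-guide TSSs, selection-free),
    each against the planted effect at 500 reads/guide."""
    seeds = _spawn_seeds(rng_seed, 2 * n_reps)
    lfc_means = []
    for s in seeds[:n_reps]:
        lib = simulate.make_screen_library_frame(50, 10, 100)
        truth = simulate.make_sim_truth(
            lib, n_functional=5, effect_log2=effect_log2, pi=1.0, rng_seed=s
        )
        counts, samples = simulate.gen_screen_counts(lib, truth, rng_seed=s + 1)
        enr = screen.estimate_enrichment(counts, samples, set(lib.guide_id))
        eff = [
            g for g, t in zip(lib.guide_id, lib.target_tss_id)
            if t in truth.functional_tss_ids
        ]
        lfc_means.append(float(enr.log2fc[eff].mean()))
    es_means = []
    for s in seeds[n_reps:]:
        lib = simulate.make_screen_library_frame(50, 3, 100)
        truth = simulate.make_sim_truth(
            lib, n_functional=5, effect_log2=effect_log2, pi=1.0, rng_seed=s
        )
        counts, samples = simulate.gen_screen_counts(lib, truth, rng_seed=s + 1)
        enr = screen.estimate_enrichment(counts, samples, set(lib.guide_id))
        per_tss = [
            mixture.effect_size(
                enr.log2fc[lib.guide_id[lib.target_tss_id == t]]
            )
            for t in truth.functional_tss_ids
        ]
        es_means.append(float(np.nanmean(per_tss)))
    return {
        "n_reps": n_reps,
        "effect_log2": effect_log2,
        "enrichment_mean": float(np.mean(lfc_means)),
        "enrichment_bias": float(np.mean(lfc_means) - effect_log2),
        "effect_size_mean": float(np.mean(es_means)),
        "effect_size_bias": float(np.mean(es_means) - effect_log2),
    }
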