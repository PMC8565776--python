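"""Hierarchical-mixture hit calling with an empirical null from scrambled guides.

The model, fit on per-guide log2 fold-changes of filtered guides:

* the null density f0 is a normal fit to scrambled (non-targeting) guides —
  an empirical null, since scrambled guides experience the full screen
  noise (sorting, sampling, batch) without biology;
* each targeted TSS is functional with prior probability p;
* conditional on a functional TSS, each of its guides is *effective* with
  probability pi (guide efficiency varies — only a subset of guides work);
  effective guides draw from a shifted normal f1, ineffective ones from f0;
* guides of non-functional TSSs all draw from f0.

The marginal likelihood of TSS g with guide values x_1..x_m is

    L_g = p * prod_i [pi f1(x_i) + (1-pi) f0(x_i)] + (1-p) * prod_i f0(x_i)

p, pi, and the alternative component (mu1, sd1) are fit by EM (null fixed);
the per-TSS posterior null probability 1 - P(functional | data) is converted
to a global FDR by the q-value convention: the running mean of posterior
null probabilities in decreasing-score order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_FDR_HIT = 0.1
DEFAULT_FDR_STRINGENT_NONHIT = 0.9
DEFAULT_MIN_STRINGENT_GUIDES = 9
MIN_SCRAMBLED_FOR_NULL = 100
EM_TOL = 1e-6
EM_MAX_ITER = 500
DEFAULT_N_RESTARTS = 5
TOP_K_EFFECT = 3


def fit_empirical_null(values, robust: bool = False) -> tuple[float, float]:
    """Location/scale of the null from scrambled-guide log2 fold-changes.

    ``robust=True`` uses median and MAD (scaled to the normal)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need >= 2 scrambled log2fc values for the null")
    if robust:
        mu = float(np.median(x))
        sd = float(1.4826 * np.median(np.abs(x - mu)))
    else:
        mu, sd = float(x.mean()), float(x.std(ddof=1))
    if sd <= 0:
        raise ValueError("degenerate null scale")
    return mu, sd


@dataclass
class MixtureModel:
    """Fitted parameters of the two-level mixture."""

    null_mean: float
    null_sd: float
    alt_mean: float
    alt_sd: float
    pi_guide: float
    p_functional_prior: float
    log_likelihood: float
    n_iter: int
    converged: bool
    n_scrambled: int
    degraded_null: bool = False
    restart_logliks: list[float] = field(default_factory=list)


def _log_normal_pdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd * np.sqrt(2 * np.pi))


def _em_once(
    x: np.ndarray,
    group_starts: np.ndarray,
    group_ids: np.ndarray,
    mu0: float,
    sd0: float,
    init: tuple[float, float, float, float],
    tol: float,
    max_iter: int,
) -> tuple[dict, np.ndarray, bool, int]:
    """One EM run. Returns (params, per-TSS posterior functional prob,
    converged, n_iter)."""
    mu1, sd1, pi, p = init
    log_f0 = _log_normal_pdf(x, mu0, sd0)
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_f1 = _log_normal_pdf(x, mu1, sd1)
        # per-guide mixture under a functional TSS
        log_a = np.logaddexp(np.log(pi) + log_f1, np.log1p(-pi) + log_f0)
        log_A = np.add.reduceat(log_a, group_starts)
        log_B = np.add.reduceat(log_f0, group_starts)
        log_num = np.log(p) + log_A
        log_den = np.logaddexp(log_num, np.log1p(-p) + log_B)
        ll = float(log_den.sum())
        r = np.exp(log_num - log_den)  # P(TSS functional | data)
        w = np.exp(np.log(pi) + log_f1 - log_a)  # P(guide effective | functional)

        r_guide = r[group_ids]
        rw = r_guide * w
        denom = rw.sum()
        if denom > 0:
            mu1_new = float((rw * x).sum() / denom)
            sd1_new = float(np.sqrt((rw * (x - mu1_new) ** 2).sum() / denom))
        else:
            mu1_new, sd1_new = mu1, sd1
        pi = float(np.clip(rw.sum() / max(r_guide.sum(), 1e-12), 1e-4, 1 - 1e-4))
        p = float(np.clip(r.mean(), 1e-6, 1 - 1e-6))
        # identifiability: the alternative is a genuinely *shifted*
        # drop-out component on the enriched side (>= 0.5 null SD), no
        # narrower than half the null — effective guides see the full
        # screen noise plus effect heterogeneity. Without these floors a
        # centered or needle-width component can absorb sampling
        # fluctuations of the empirical null in near-null data and
        # mis-call TSSs
        mu1 = max(mu1_new, mu0 + 0.5 * sd0)
        sd1 = max(sd1_new, 0.5 * sd0)

        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return {"mu1": mu1, "sd1": sd1, "pi": pi, "p": p, "ll": prev_ll}, r, converged, it


def fit_mixture(
    lfc: pd.Series,
    guide_tss: pd.Series,
    scrambled_lfc,
    *,
    robust_null: bool = False,
    n_restarts: int = DEFAULT_N_RESTARTS,
    rng_seed: int = 0,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> tuple[MixtureModel, pd.DataFrame]:
    """Fit the hierarchical mixture and score every TSS.

    Parameters
    ----------
    lfc
        log2 fold-change per targeting guide (index = guide_id).
    guide_tss
        guide_id -> tss_id for the same guides (multi-target guides should
        be pre-expanded to one row per target).
    scrambled_lfc
        log2 fold-changes of filtered scrambled guides (empirical null).

    Returns the fitted model and a per-TSS frame with posterior null
    probability and global FDR. EM non-convergence is flagged on the model,
    never silent.
    """
    scrambled = np.asarray(scrambled_lfc, dtype=float)
    scrambled = scrambled[np.isfinite(scrambled)]
    degraded = scrambled.size < MIN_SCRAMBLED_FOR_NULL
    if degraded:
        warnings.warn(
            f"only {scrambled.size} scrambled guides survive filtering "
            f"(< {MIN_SCRAMBLED_FOR_NULL}); empirical null is degraded"
        )
    mu0, sd0 = fit_empirical_null(scrambled, robust=robust_null)

    df = pd.DataFrame({"lfc": lfc.to_numpy(dtype=float), "tss": guide_tss.to_numpy()})
    df = df.sort_values("tss", kind="stable").reset_index(drop=True)
    x = df.lfc.to_numpy()
    tss_codes, tss_index = pd.factorize(df.tss, sort=True)
    group_starts = np.flatnonzero(np.r_[1, np.diff(tss_codes)])
    n_guides_per_tss = np.diff(np.r_[group_starts, len(x)])

    rng = np.random.default_rng(rng_seed)
    best = None
    best_r = None
    logliks = []
    for _ in range(max(n_restarts, 1)):
        init = (
            mu0 + sd0 * rng.uniform(1.0, 3.0),
            sd0 * rng.uniform(0.5, 1.5),
            rng.uniform(0.2, 0.8),
            rng.uniform(0.02, 0.3),
        )
        params, r, conv, it = _em_once(
            x, group_starts, tss_codes, mu0, sd0, init, tol, max_iter
        )
        logliks.append(params["ll"])
        if best is None or params["ll"] > best[0]["ll"]:
            best = (params, conv, it)
            best_r = r
    params, conv, it = best
    if not conv:
        warnings.warn(f"EM did not converge within {max_iter} iterations")

    model = MixtureModel(
        null_mean=mu0,
        null_sd=sd0,
        alt_mean=params["mu1"],
        alt_sd=params["sd1"],
        pi_guide=params["pi"],
        p_functional_prior=params["p"],
        log_likelihood=params["ll"],
        n_iter=it,
        converged=conv,
        n_scrambled=int(scrambled.size),
        degraded_null=degraded,
        restart_logliks=logliks,
    )

    posterior_null = 1.0 - best_r
    fdr = global_fdr(posterior_null)
    calls = pd.DataFrame(
        {
            "tss_id": tss_index,
            "n_filtered_guides": n_guides_per_tss,
            "posterior_null": posterior_null,
            "fdr": fdr,
        }
    ).set_index("tss_id", drop=False)
    return model, calls


def global_fdr(posterior_null: np.ndarray) -> np.ndarray:
    """q-value-style global FDR: running mean of posterior null
    probabilities in order of increasing posterior null (ties share the
    worst value of their tie group)."""
    q = np.asarray(posterior_null, dtype=float)
    order = np.argsort(q, kind="stable")
    sorted_q = q[order]
    running = np.cumsum(sorted_q) / np.arange(1, len(q) + 1)
    # ties: every TSS with the same score gets the same (largest) FDR
    fdr_sorted = running.copy()
    i = len(q) - 1
    while i > 0:
        if sorted_q[i - 1] == sorted_q[i]:
            fdr_sorted[i - 1] = fdr_sorted[i]
        i -= 1
    out = np.empty_like(q)
    out[order] = fdr_sorted
    return out


def effect_size(lfc_values, k: int = TOP_K_EFFECT) -> float:
    """Mean of the k most enriched (largest) guide log2 fold-changes; NaN
    when fewer than k guides survive filtering."""
    x = np.asarray(lfc_values, dtype=float)
    if x.size < k:
        return float("nan")
    return float(np.mean(np.sort(x)[-k:]))


def add_effect_sizes(
    calls: pd.DataFrame, lfc: pd.Series, guide_tss: pd.Series, k: int = TOP_K_EFFECT
) -> pd.DataFrame:
    grouped = pd.DataFrame({"lfc": lfc.to_numpy(), "tss": guide_tss.to_numpy()})
    es = grouped.groupby("tss")["lfc"].apply(lambda v: effect_size(v, k))
    out = calls.copy()
    out["effect_size"] = es.reindex(out.index).to_numpy()
    return out


def classify_tss(
    calls: pd.DataFrame,
    fdr_hit: float = DEFAULT_FDR_HIT,
    fdr_stringent: float = DEFAULT_FDR_STRINGENT_NONHIT,
    min_stringent_guides: int = DEFAULT_MIN_STRINGENT_GUIDES,
    tss_gene: pd.Series | None = None,
) -> pd.DataFrame:
    """Flag hits (FDR < ``fdr_hit``) and stringent non-hits
    (FDR > ``fdr_stringent`` with >= ``min_stringent_guides`` filtered
    guides — well-powered negatives). When ``tss_gene`` maps TSS -> gene,
    a ``stringent_nonhit_gene`` flag marks one TSS per unique gene."""
    out = calls.copy()
    out["is_hit"] = out.fdr < fdr_hit
    out["is_stringent_nonhit"] = (out.fdr > fdr_stringent) & (
        out.n_filtered_guides >= min_stringent_guides
    )
    assert not (out.is_hit & out.is_stringent_nonhit).any()
    if tss_gene is not None:
        out["gene_id"] = tss_gene.reindex(out.index).to_numpy()
        first = (
            out[out.is_stringent_nonhit]
            .sort_values(["gene_id", "fdr"], ascending=[True, False])
            .drop_duplicates("gene_id")
            .index
        )
        out["stringent_nonhit_gene"] = out.index.isin(first)
    return out


def expand_guide_targets(guide_targets: pd.Series) -> pd.DataFrame:
    """Expand ';'-joined multi-target guides to one (guide_id, tss_id) row
    per target; scrambled guides (NaN/'SCRAMBLED') are dropped — they are
    never assigned to TSS-level calls."""
    rows = []
    for gid, tgt in guide_targets.items():
        if pd.isna(tgt) or tgt == "SCRAMBLED":
            continue
        for tss in str(tgt).split(";"):
            rows.append((gid, tss))
    return pd.DataFrame(rows, columns=["guide_id", "tss_id"])


def call_screen(
    enrichment: pd.DataFrame,
    guide_targets: pd.Series,
    filtered_guides: set[str],
    *,
    rng_seed: int = 0,
    robust_null: bool = False,
    n_restarts: int = DEFAULT_N_RESTARTS,
    fdr_hit: float = DEFAULT_FDR_HIT,
    fdr_stringent: float = DEFAULT_FDR_STRINGENT_NONHIT,
    min_stringent_guides: int = DEFAULT_MIN_STRINGENT_GUIDES,
    tss_gene: pd.Series | None = None,
) -> tuple[MixtureModel, pd.DataFrame]:
    """End-to-end hit calling from a per-guide enrichment table."""
    enr = enrichment.loc[enrichment.index.isin(filtered_guides)]
    targets = guide_targets.reindex(enr.index)
    scrambled_mask = targets.isna() | (targets == "SCRAMBLED")
    scrambled_lfc = enr.loc[scrambled_mask, "log2fc"]

    expanded = expand_guide_targets(targets[~scrambled_mask])
    lfc = enr.log2fc.reindex(expanded.guide_id)
    model, calls = fit_mixture(
        lfc,
        expanded.tss_id,
        scrambled_lfc,
        robust_null=robust_null,
        n_restarts=n_restarts,
        rng_seed=rng_seed,
    )
    calls = add_effect_sizes(calls, lfc, expanded.tss_id)
    calls = classify_tss(
        calls,
        fdr_hit=fdr_hit,
        fdr_stringent=fdr_stringent,
        min_stringent_guides=min_stringent_guides,
        tss_gene=tss_gene,
    )
    return model, calls
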