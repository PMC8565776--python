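import numpy as np
import pandas as pd
import pytest

from lncscreen import mixture, screen, simulate


@pytest.fixture(scope="session")
def toy_annotation():
    """Small annotation with all four lncRNA categories plus RM analogues."""
    transcripts, genome = simulate.gen_annotation(
        n_mrna=15, n_lnc=24, rng_seed=3, n_rna_mechanism=3
    )
    return transcripts, genome


@pytest.fixture(scope="session")
def screen_bundle():
    """One default synthetic screen run through filtering + enrichment + calls."""
    lib, counts, samples, truth = simulate.simulate_screen_dataset(rng_seed=11)
    rep = screen.filter_cascade(counts, samples, lib.target_tss_id)
    enr = screen.estimate_enrichment(counts, samples, rep.survivors)
    model, calls = mixture.call_screen(
        enr, lib.target_tss_id, rep.survivors, rng_seed=11
    )
    return {
        "library": lib, "counts": counts, "samples": samples, "truth": truth,
        "filter": rep, "enrichment": enr, "model": model, "calls": calls,
    }


def make_counts(values: dict[str, list[int]], n_reps: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tiny count table helper: values maps guide_id -> per-sample counts in
    the fixed column order day0_rep1..n, undiff_rep1..n, diff_rep1..n."""
    cols = (
        [f"day0_rep{r}" for r in range(1, n_reps + 1)]
        + [f"undiff_rep{r}" for r in range(1, n_reps + 1)]
        + [f"diff_rep{r}" for r in range(1, n_reps + 1)]
    )
    counts = pd.DataFrame.from_dict(values, orient="index", columns=cols)
    counts.index.name = "guide_id"
    samples = pd.DataFrame(
        [
            {"sample": c,
             "population": {"day0": "day0", "undiff": "undifferentiated",
                            "diff": "differentiated"}[c.rsplit("_", 1)[0]],
             "replicate": int(c[-1])}
            for c in cols
        ]
    )
    return counts, samples
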