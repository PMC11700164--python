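"""Shared helpers: seed fan-out, FDR, small numeric utilities."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

# Stage codes for the seed fan-out scheme: a global seed plus a fixed stage
# code feed a SeedSequence, so every stage is independently re-runnable.
STAGE_CODES = {
    "annotation": 1,
    "atlas": 2,
    "gwas": 3,
    "fmri": 4,
    "tdep": 5,
    "enrich": 6,
    "regions": 7,
    "genesets": 8,
    "folds": 9,
    "experiment": 10,
}


def stage_rng(seed: int, stage: str, extra: int | None = None) -> np.random.Generator:
    """Generator for a named pipeline stage derived from the global seed.

    ``extra`` distinguishes replicates within a stage.
    """
    if stage not in STAGE_CODES:
        raise KeyError(f"unknown stage {stage!r}")
    entropy = [int(seed), STAGE_CODES[stage]]
    if extra is not None:
        entropy.append(int(extra))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def check_positive(name: str, value) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value}")
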