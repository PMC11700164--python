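"""Minimal plot exports (heatmaps and AUC traces); display-only helpers."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def plot_heatmap(mat: pd.DataFrame | np.ndarray, path: str | Path, title: str = "") -> None:
    arr = mat.to_numpy() if isinstance(mat, pd.DataFrame) else np.asarray(mat)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(arr, cmap="viridis", aspect="auto")
    fig.colorbar(im, ax=ax)
    if isinstance(mat, pd.DataFrame):
        ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(mat.index)), mat.index, fontsize=6)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_auc_trace(traces, path: str | Path) -> None:
    """Held-out AUC against the number of retained ROIs, per fold."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for trace in traces:
        n_retained = [len(r.retained) for r in trace.runs]
        aucs = [r.auc for r in trace.runs]
        ax.plot(n_retained, aucs, marker="o", ms=3, label=f"fold {trace.fold}")
    ax.invert_xaxis()
    ax.set_xlabel("retained ROIs")
    ax.set_ylabel("held-out AUC")
    ax.axhline(0.5, color="grey", ls="--", lw=0.8)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
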