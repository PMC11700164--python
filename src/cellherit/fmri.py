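"""Connectivity-based case/control classification with permutation feature
importance and recursive ROI elimination.

Per subject the ROI x ROI Pearson correlation matrix is computed; its upper
triangle (off-diagonal) is the feature vector of a binary cross-entropy
classifier. Feature importance of a connection is

    FI = mean_e_perm / e_orig,

computed only when the original model error e_orig falls outside the central
95% interval of the errors obtained by shuffling that connection's values
across subjects (otherwise FI = 0). Recursive feature elimination repeatedly
removes the ROI with the lowest summed FI until ``min_rois`` remain; per-model
FI matrices are aggregated as FI / max(FI) * AUC summed across models, and
top-n hypergeometric tests ask whether connections touching a flagged ROI
group are over-represented among the top-ranked connections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .config import ClassifierConfig
from .simulate import ConnectivityDataset

_EPS = 1e-12


def compute_connectivity(ts: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of a (time x ROI) series (diagonal 1)."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("time series must be 2-D with at least 3 time points")
    sd = ts.std(axis=0)
    scale = np.maximum(np.abs(ts).max(axis=0), 1.0)
    dead = np.where(sd <= 1e-10 * scale)[0]
    if dead.size:
        raise ValueError(f"zero-variance ROI(s): {dead.tolist()}")
    c = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(c, 1.0)
    return c


def upper_triangle(mat: np.ndarray) -> np.ndarray:
    """Vectorized strict upper triangle (the classifier's feature order)."""
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def make_folds(ds: ConnectivityDataset, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Near-equal, class-balanced portions stratified by time-series length.

    Within each class, subjects are ordered by series length (random
    tie-break) and dealt round-robin, so portions have similar size and
    balanced lengths. Returns a fold id per subject.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2 (no held-out data otherwise)")
    labels = np.asarray(ds.labels)
    rng = np.random.default_rng(seed)
    lengths = np.array([s.shape[0] for s in ds.series])
    folds = np.full(len(labels), -1, dtype=int)
    for cls in (0, 1):
        idx = np.where(labels == cls)[0]
        if idx.size < n_folds:
            raise ValueError(f"class {cls} has {idx.size} subjects < n_folds={n_folds}")
        order = idx[np.lexsort((rng.random(idx.size), lengths[idx]))]
        folds[order] = np.arange(order.size) % n_folds
    return folds


# ---------------------------------------------------------------------------
# classifier


def _cross_entropy(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _auc(y: np.ndarray, score: np.ndarray) -> float:
    # rank-based ROC AUC (Mann-Whitney)
    r = stats.rankdata(score)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: one class absent from evaluation set")
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


class ConnectivityClassifier:
    """Cross-entropy-trained binary classifier on connectivity features.

    Backends: a 2-hidden-layer feed-forward network (default) or logistic
    regression; both are trained on the cross-entropy objective and evaluated
    by held-out ROC AUC. Standardization is fitted on training data only.
    """

    def __init__(self, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        self.scaler: StandardScaler | None = None
        self.model = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "ConnectivityClassifier":
        cfg = self.config
        self.scaler = StandardScaler().fit(x)
        xs = self.scaler.transform(x)
        if cfg.backend == "mlp":
            self.model = MLPClassifier(
                hidden_layer_sizes=cfg.hidden,
                alpha=cfg.alpha,
                learning_rate_init=cfg.learning_rate,
                max_iter=cfg.max_iter,
                random_state=cfg.seed,
            )
        else:
            self.model = LogisticRegression(C=1.0 / max(cfg.alpha, _EPS), max_iter=cfg.max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence warnings at small max_iter
            self.model.fit(xs, y)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(self.scaler.transform(x))[:, 1]

    def error(self, x: np.ndarray, y: np.ndarray) -> float:
        e = _cross_entropy(np.asarray(y, float), self.predict_proba(x))
        if not np.isfinite(e):
            raise ValueError("non-finite cross-entropy loss")
        return e

    def auc(self, x: np.ndarray, y: np.ndarray) -> float:
        return _auc(np.asarray(y), self.predict_proba(x))


def train_eval(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    config: ClassifierConfig | None = None,
) -> tuple[ConnectivityClassifier, float, float]:
    """Train on the training split; return (model, test AUC, e_orig).

    ``e_orig`` is the cross-entropy of the trained model on the evaluation
    split — the reference error of the permutation feature importance.
    """
    clf = ConnectivityClassifier(config).fit(x_train, y_train)
    return clf, clf.auc(x_test, y_test), clf.error(x_test, y_test)


# ---------------------------------------------------------------------------
# permutation feature importance


def fi_from_errors(e_orig: float, perm_errors: np.ndarray) -> float:
    """Gated feature importance from permuted model errors.

    If ``e_orig`` lies outside the central 95% interval of the permuted
    errors the connection is considered contributing and
    FI = mean(perm_errors) / e_orig; otherwise FI = 0.
    """
    perm_errors = np.asarray(perm_errors, dtype=float)
    lo, hi = np.percentile(perm_errors, [2.5, 97.5])
    if e_orig < lo or e_orig > hi:
        return float(perm_errors.mean() / e_orig)
    return 0.0


def permutation_fi(
    clf: ConnectivityClassifier,
    x_eval: np.ndarray,
    y_eval: np.ndarray,
    e_orig: float | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    features: Sequence[int] | None = None,
) -> np.ndarray:
    """Permutation feature importance per connection feature.

    Each feature column is shuffled across evaluation subjects ``n_perm``
    times; the permuted model errors define a central 95% interval. When
    e_orig falls outside that interval the feature is considered contributing
    and FI = mean_e_perm / e_orig; otherwise FI = 0.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    y = np.asarray(y_eval, float)
    if e_orig is None:
        e_orig = clf.error(x_eval, y_eval)
    n_eval, n_feat = x_eval.shape
    feat_idx = range(n_feat) if features is None else features
    rng = np.random.default_rng(seed)
    fi = np.zeros(n_feat)
    for f in feat_idx:
        keys = rng.random((n_perm, n_eval))
        perm = np.argsort(keys, axis=1)
        permuted = x_eval[:, f][perm]  # (n_perm, n_eval)
        big = np.repeat(x_eval[None, :, :], n_perm, axis=0)
        big[:, :, f] = permuted
        probs = clf.predict_proba(big.reshape(n_perm * n_eval, n_feat)).reshape(n_perm, n_eval)
        p = np.clip(probs, _EPS, 1 - _EPS)
        errors = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean(axis=1)
        fi[f] = fi_from_errors(e_orig, errors)
    return fi


def fi_to_matrix(fi: np.ndarray, rois: Sequence[int], n_total: int) -> np.ndarray:
    """Embed an upper-triangle FI vector into a full symmetric R x R matrix."""
    rois = list(rois)
    mat = np.zeros((n_total, n_total))
    iu = np.triu_indices(len(rois), k=1)
    for (a, b), v in zip(zip(iu[0], iu[1]), fi):
        i, j = rois[a], rois[b]
        mat[i, j] = mat[j, i] = v
    return mat


# ---------------------------------------------------------------------------
# recursive ROI elimination


@dataclass
class RFERun:
    run_index: int
    retained: List[int]
    eliminated_roi: int
    auc: float
    e_orig: float
    fi_matrix: np.ndarray  # full R x R, zeros outside retained


@dataclass
class RFETrace:
    fold: int
    n_rois: int
    runs: List[RFERun] = field(default_factory=list)

    @property
    def preserved_runs(self) -> np.ndarray:
        """Per ROI, the number of runs it participated in."""
        counts = np.zeros(self.n_rois, dtype=int)
        for run in self.runs:
            counts[run.retained] += 1
        return counts

    def to_dict(self) -> dict:
        return {
            "fold": self.fold,
            "n_rois": self.n_rois,
            "preserved_runs": self.preserved_runs.tolist(),
            "runs": [
                {
                    "run_index": r.run_index,
                    "retained": r.retained,
                    "eliminated_roi": r.eliminated_roi,
                    "auc": r.auc,
                    "e_orig": r.e_orig,
                }
                for r in self.runs
            ],
        }


def rfe(
    ds: ConnectivityDataset,
    folds: np.ndarray,
    fold: int,
    config: ClassifierConfig | None = None,
    n_perm: int = 1000,
    min_rois: int = 2,
    seed: int = 0,
    connectivity: List[np.ndarray] | None = None,
) -> RFETrace:
    """Recursive ROI elimination for one cross-validation fold.

    Each run trains the classifier on the retained ROIs' connections,
    evaluates AUC and e_orig on the held-out portion, computes permutation FI
    on the evaluation split, sums FI over each ROI's connections, and removes
    the lowest-contributing ROI (ties broken by lowest ROI index). Stops when
    ``min_rois`` remain.
    """
    r = ds.n_rois
    if r < 3:
        raise ValueError("at least 3 ROIs required to start elimination")
    if min_rois < 2:
        raise ValueError("min_rois must be >= 2")
    conn = connectivity or [compute_connectivity(ts) for ts in ds.series]
    labels = np.asarray(ds.labels)
    test_mask = folds == fold
    if not test_mask.any() or test_mask.all():
        raise ValueError(f"fold {fold} leaves no train/test split")

    retained = list(range(r))
    trace = RFETrace(fold=fold, n_rois=r)
    run_idx = 0
    while len(retained) > min_rois:
        sub = np.ix_(retained, retained)
        feats = np.array([upper_triangle(c[sub]) for c in conn])
        clf, auc, e_orig = train_eval(
            feats[~test_mask], labels[~test_mask], feats[test_mask], labels[test_mask], config
        )
        fi = permutation_fi(
            clf, feats[test_mask], labels[test_mask], e_orig=e_orig,
            n_perm=n_perm, seed=seed + run_idx,
        )
        fi_mat = fi_to_matrix(fi, retained, r)
        contribution = fi_mat.sum(axis=0)[retained]
        victim = retained[int(np.argmin(contribution))]  # argmin ties -> lowest index
        trace.runs.append(
            RFERun(run_idx, list(retained), victim, auc, e_orig, fi_mat)
        )
        retained.remove(victim)
        run_idx += 1
    return trace


def aggregate_fi(
    traces: Iterable[RFETrace],
    run_selector: Callable[[RFERun], bool] | None = None,
) -> np.ndarray:
    """AUC-weighted aggregation of per-model FI matrices.

    Per model (run): FI / max(FI) * AUC, summed elementwise across models.
    All-zero FI matrices are skipped with a warning.
    """
    agg = None
    used = 0
    for trace in traces:
        for run in trace.runs:
            if run_selector is not None and not run_selector(run):
                continue
            fmax = run.fi_matrix.max()
            if agg is None:
                agg = np.zeros_like(run.fi_matrix)
            if fmax <= 0:
                warnings.warn(f"all-zero FI matrix skipped (fold {trace.fold}, run {run.run_index})")
                continue
            agg += run.fi_matrix / fmax * run.auc
            used += 1
    if agg is None or used == 0:
        raise ValueError("no FI matrix with positive maximum to aggregate")
    return agg


# ---------------------------------------------------------------------------
# top-n enrichment and cross-dataset comparison


def topn_enrichment(
    agg: np.ndarray,
    flagged_rois: Iterable[int],
    n_grid: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of flagged-ROI connections among top-n entries.

    Connections are ranked over all R^2 matrix entries (diagonal carries FI 0,
    symmetric duplicates included; ties broken by flat index); a connection is
    flagged iff either endpoint ROI is flagged. ``n_grid`` defaults to the
    even numbers 2..R^2.
    """
    flagged = set(int(i) for i in flagged_rois)
    if not flagged:
        raise ValueError("flagged_rois must be nonempty")
    r = agg.shape[0]
    mat = agg.copy()
    np.fill_diagonal(mat, 0.0)
    flat = mat.ravel()
    ii, jj = np.divmod(np.arange(r * r), r)
    is_flagged = np.array([(a in flagged) or (b in flagged) for a, b in zip(ii, jj)])
    order = np.argsort(-flat, kind="stable")
    flagged_cum = np.cumsum(is_flagged[order])

    m = r * r
    k = int(is_flagged.sum())
    if n_grid is None:
        n_grid = np.arange(2, m + 1, 2)
    n_grid = np.asarray(list(n_grid), dtype=int)
    overlaps = flagged_cum[n_grid - 1]
    p = stats.hypergeom.sf(overlaps - 1, m, k, n_grid)
    return pd.DataFrame(
        {"n": n_grid, "overlap": overlaps, "flagged_total": k, "entries_total": m,
         "p_hypergeometric": np.clip(p, np.finfo(float).tiny, 1.0)}
    )


def preserved_run_correlation(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    roi_subset: Sequence[int] | None = None,
) -> tuple[float, float]:
    """Pearson correlation of mean preserved-run counts across two datasets."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("preserved-run count vectors must share the ROI universe")
    if roi_subset is not None:
        idx = list(roi_subset)
        if len(idx) < 3:
            raise ValueError("roi_subset must have at least 3 ROIs")
        a, b = a[idx], b[idx]
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def mean_preserved_runs(traces: Iterable[RFETrace]) -> np.ndarray:
    """Mean preserved-run counts per ROI across folds."""
    stacks = np.array([t.preserved_runs for t in traces], dtype=float)
    return stacks.mean(axis=0)
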