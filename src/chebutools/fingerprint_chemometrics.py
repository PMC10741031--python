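"""Chromatographic fingerprint chemometrics.

Common-peak alignment across batches by retention time, cosine
(congruence) fingerprint similarity against a reference profile, and the
multivariate toolbox used on herbal-medicine fingerprints: hierarchical
cluster analysis, PCA, and OPLS-DA with VIP-based marker selection.

Pre-treatment is unit-variance autoscaling (column mean 0, variance 1),
the SIMCA-style default.  OPLS-DA follows the orthogonal-signal-corrected
PLS construction: orthogonal components are deflated from X before a
single predictive PLS component is fitted; Q² comes from k-fold
cross-validation (7 contiguous blocks by default) and VIP from the
SSY-weighted loading-weights formula over all components, so that the
mean squared VIP is exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "PeakTable",
    "SimilarityReport",
    "PcaResult",
    "OplsdaResult",
    "align_common_peaks",
    "fingerprint_similarity",
    "autoscale",
    "hca",
    "pca",
    "oplsda",
    "vip_select",
]


@dataclass
class PeakTable:
    """Batches × common peaks area matrix.

    ``areas`` is a pandas DataFrame (rows = batches, columns = peak ids,
    non-negative, no missing cells — an absent peak is 0); ``rt`` maps peak
    id to retention time in minutes when known.
    """

    areas: pd.DataFrame
    rt: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.areas.values < 0).any():
            raise ValueError("peak areas must be non-negative")
        if self.areas.isna().any().any():
            raise ValueError("peak table contains missing cells")

    @property
    def batch_ids(self) -> List[str]:
        return list(self.areas.index)

    @property
    def peak_ids(self) -> List[str]:
        return list(self.areas.columns)

    @classmethod
    def from_csv(cls, path: str) -> "PeakTable":
        frame = pd.read_csv(path, index_col=0)
        return cls(areas=frame)

    def to_csv(self, path: str) -> None:
        self.areas.to_csv(path)


@dataclass
class SimilarityReport:
    """Per-batch cosine similarity against a reference fingerprint."""

    reference: str
    scores: Dict[str, float]


@dataclass
class PcaResult:
    scores: pd.DataFrame          # batches × components
    loadings: pd.DataFrame        # peaks × components
    explained_variance_fraction: np.ndarray


@dataclass
class OplsdaResult:
    predictive_scores: np.ndarray
    predictive_loadings: np.ndarray
    orthogonal_scores: np.ndarray
    orthogonal_loadings: np.ndarray
    r2x: float
    r2y: float
    q2: float
    vip: pd.Series
    classes: Tuple[str, str]


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_common_peaks(
    per_batch_peaks: Dict[str, Sequence[Tuple[float, float]]],
    rt_tol: float = 0.1,
) -> Tuple[PeakTable, List[str]]:
    """Cluster peaks across batches by retention time (single linkage).

    Clusters whose members span every batch become common peaks (named
    ``P1..Pn`` in retention-time order); the rest are retained in the table
    but reported as non-common.  When one batch contributes several peaks
    to a cluster the one nearest the cluster mean retention time wins.

    Returns ``(table, common_peak_ids)``.
    """
    if rt_tol <= 0:
        raise ValueError("rt_tol must be positive")
    if not per_batch_peaks:
        raise ValueError("no batches supplied")
    batches = sorted(per_batch_peaks)
    rows = []
    for batch in batches:
        for rt, area in per_batch_peaks[batch]:
            rows.append((batch, float(rt), float(area)))
    if not rows:
        raise ValueError("no peaks supplied")
    rts = np.array([[r[1]] for r in rows])
    if len(rows) == 1:
        labels = np.array([1])
    else:
        link = linkage(rts, method="single")
        labels = fcluster(link, t=rt_tol, criterion="distance")

    clusters: Dict[int, List[int]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(idx)

    cluster_info = []
    for members in clusters.values():
        mean_rt = float(np.mean([rows[i][1] for i in members]))
        cluster_info.append((mean_rt, members))
    cluster_info.sort(key=lambda c: c[0])

    peak_ids = [f"P{i}" for i in range(1, len(cluster_info) + 1)]
    table = pd.DataFrame(0.0, index=batches, columns=peak_ids)
    rt_map: Dict[str, float] = {}
    common: List[str] = []
    for pid, (mean_rt, members) in zip(peak_ids, cluster_info):
        rt_map[pid] = round(mean_rt, 4)
        chosen: Dict[str, Tuple[float, float]] = {}
        for i in members:
            batch, rt, area = rows[i]
            if batch in chosen and abs(chosen[batch][0] - mean_rt) <= abs(rt - mean_rt):
                warnings.warn(
                    f"batch {batch}: overlapping peaks near rt {mean_rt:.2f}; "
                    "keeping the nearest", stacklevel=2)
                continue
            chosen[batch] = (rt, area)
        for batch, (_, area) in chosen.items():
            table.loc[batch, pid] = area
        if len(chosen) == len(batches):
            common.append(pid)
    return PeakTable(areas=table, rt=rt_map), common


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------

def fingerprint_similarity(
    table: PeakTable, reference: str = "mean"
) -> SimilarityReport:
    """Cosine (congruence) coefficient of each batch vs a reference profile.

    ``reference`` is "mean", "median", or a batch id.  Scale-invariant per
    batch; an all-zero batch or reference is an error.
    """
    X = table.areas.values.astype(float)
    if reference == "mean":
        ref = X.mean(axis=0)
    elif reference == "median":
        ref = np.median(X, axis=0)
    elif reference in table.batch_ids:
        ref = table.areas.loc[reference].values.astype(float)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    ref_norm = np.linalg.norm(ref)
    if ref_norm == 0:
        raise ValueError("reference fingerprint is all zero")
    scores = {}
    for batch, row in zip(table.batch_ids, X):
        row_norm = np.linalg.norm(row)
        if row_norm == 0:
            raise ValueError(f"batch {batch}: all-zero fingerprint")
        scores[batch] = float(row @ ref / (row_norm * ref_norm))
    return SimilarityReport(reference=reference, scores=scores)


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

def autoscale(table: PeakTable | pd.DataFrame) -> pd.DataFrame:
    """Unit-variance autoscaling: per-peak mean 0, variance 1.

    Constant peaks carry no information after scaling and are dropped with
    a warning.
    """
    frame = table.areas if isinstance(table, PeakTable) else table
    if len(frame) < 2:
        raise ValueError("autoscaling needs at least 2 batches")
    std = frame.std(axis=0, ddof=1)
    constant = std[std == 0].index
    if len(constant):
        warnings.warn(f"dropping constant peaks: {list(constant)}", stacklevel=2)
        frame = frame.drop(columns=constant)
        std = std.drop(constant)
    return (frame - frame.mean(axis=0)) / std


# ---------------------------------------------------------------------------
# HCA
# ---------------------------------------------------------------------------

def hca(
    table: PeakTable | pd.DataFrame,
    k: Optional[int] = None,
    method: str = "ward",
    metric: str = "euclidean",
    scale: bool = True,
) -> Tuple[np.ndarray, List[str], Optional[Dict[str, int]]]:
    """Hierarchical clustering of batches.

    Returns ``(linkage_matrix, leaf_order, assignment)`` where
    ``assignment`` maps batch id to cluster label 1..k (None when ``k`` is
    not given).  ``metric="correlation"`` uses 1 − Pearson distance.
    Agglomeration is deterministic (scipy's lowest-index tie-breaking);
    heatmap row ordering should follow ``leaf_order``.
    """
    frame = table.areas if isinstance(table, PeakTable) else table
    if len(frame) < 2:
        raise ValueError("clustering needs at least 2 batches")
    if k is not None and k > len(frame):
        raise ValueError("k exceeds the number of batches")
    data = autoscale(frame) if scale else frame
    dist = pdist(data.values, metric=metric)
    link = linkage(dist, method=method)
    order = [frame.index[i] for i in leaves_list(link)]
    assignment = None
    if k is not None:
        labels = fcluster(link, t=k, criterion="maxclust")
        assignment = {batch: int(lab) for batch, lab in zip(frame.index, labels)}
    return link, order, assignment


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(scaled: pd.DataFrame, n_components: Optional[int] = None) -> PcaResult:
    """PCA by singular value decomposition of the (already scaled) matrix.

    Sign convention: each loading vector's largest-magnitude entry is made
    positive, so results are deterministic.  Explained fractions are
    eigenvalues over total variance and sum to 1 at full rank.
    """
    X = scaled.values.astype(float)
    n, p = X.shape
    rank = min(n - 1, p)
    if n_components is None:
        n_components = rank
    if not 1 <= n_components <= rank:
        raise ValueError(f"n_components must be in [1, {rank}]")
    Xc = X - X.mean(axis=0)
    total_var = float((Xc ** 2).sum())
    if total_var == 0:
        raise ValueError("degenerate (zero-variance) matrix")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    for comp in range(n_components):
        pivot = np.argmax(np.abs(Vt[comp]))
        if Vt[comp, pivot] < 0:
            Vt[comp] *= -1.0
            U[:, comp] *= -1.0
    scores = U * S
    explained = (S ** 2) / total_var
    comp_names = [f"PC{i}" for i in range(1, n_components + 1)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=scaled.index, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=scaled.columns, columns=comp_names),
        explained_variance_fraction=explained,
    )


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

def _encode_two_class(y: Sequence) -> Tuple[np.ndarray, Tuple[str, str]]:
    classes = sorted({str(v) for v in y})
    if len(classes) != 2:
        raise ValueError(f"OPLS-DA needs exactly 2 classes, got {classes}")
    encoded = np.array([1.0 if str(v) == classes[1] else -1.0 for v in y])
    return encoded, (classes[0], classes[1])


def _opls_fit(X: np.ndarray, y: np.ndarray, n_orthogonal: int):
    """Core O-PLS fit on centered data.  Returns the model pieces."""
    Xd = X.copy()
    w = Xd.T @ y / float(y @ y)
    w /= np.linalg.norm(w)
    W_o, P_o, T_o = [], [], []
    for _ in range(n_orthogonal):
        t = Xd @ w
        p = Xd.T @ t / float(t @ t)
        w_o = p - float(w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / float(t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
        w = Xd.T @ y / float(y @ y)
        w /= np.linalg.norm(w)
    t = Xd @ w
    p = Xd.T @ t / float(t @ t)
    q = float(y @ t / (t @ t))
    return w, t, p, q, W_o, P_o, T_o


def _opls_predict(X: np.ndarray, model) -> np.ndarray:
    w, t, p, q, W_o, P_o, T_o = model
    Xd = X.copy()
    for w_o, p_o in zip(W_o, P_o):
        t_o = Xd @ w_o
        Xd = Xd - np.outer(t_o, p_o)
    return (Xd @ w) * q


def oplsda(
    scaled: pd.DataFrame,
    y: Sequence,
    n_orthogonal: int = 1,
    cv_folds: int = 7,
    shuffle_seed: Optional[int] = None,
) -> OplsdaResult:
    """Two-class OPLS-DA with VIP scores.

    ``y`` holds two class labels; they are encoded ±1 and centered.  R²X and
    R²Y are fitted variance fractions; Q² uses k-fold cross-validation with
    contiguous blocks in batch order (or a seeded shuffle).  With
    ``n_orthogonal=0`` the model reduces to single-component PLS-DA.
    """
    X = scaled.values.astype(float)
    n, p = X.shape
    y_enc, classes = _encode_two_class(y)
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if cv_folds > n:
        raise ValueError("more folds than samples")
    y_c = y_enc - y_enc.mean()
    Xc = X - X.mean(axis=0)

    model = _opls_fit(Xc, y_c, n_orthogonal)
    w, t, p_load, q, W_o, P_o, T_o = model

    ssx = float((Xc ** 2).sum())
    ssx_pred = float((np.outer(t, p_load) ** 2).sum())
    ssx_orth = sum(float((np.outer(t_o, p_o) ** 2).sum()) for t_o, p_o in zip(T_o, P_o))
    r2x = (ssx_pred + ssx_orth) / ssx
    ssy = float((y_c ** 2).sum())
    resid = y_c - t * q
    r2y = 1.0 - float((resid ** 2).sum()) / ssy

    # cross-validated Q2
    indices = np.arange(n)
    if shuffle_seed is not None:
        indices = np.random.default_rng(shuffle_seed).permutation(n)
    folds = np.array_split(indices, cv_folds)
    press = 0.0
    for fold in folds:
        train = np.setdiff1d(indices, fold)
        if len(np.unique(y_enc[train])) < 2:
            raise ValueError("a CV fold left a single class in training")
        X_tr = X[train] - X[train].mean(axis=0)
        y_tr = y_enc[train] - y_enc[train].mean()
        sub = _opls_fit(X_tr, y_tr, n_orthogonal)
        X_te = X[fold] - X[train].mean(axis=0)
        pred = _opls_predict(X_te, sub) + y_enc[train].mean()
        press += float(((y_enc[fold] - pred) ** 2).sum())
    q2 = 1.0 - press / float(((y_enc - y_enc.mean()) ** 2).sum())

    # VIP: SSY-weighted squared loading weights over all components
    comps_w = [w] + list(W_o)
    comps_t = [t] + list(T_o)
    ssy_comp = [float((tt * qq) @ (tt * qq)) for tt, qq in
                zip(comps_t, [q] + [0.0] * len(T_o))]
    total_ssy = sum(ssy_comp)
    vip_sq = np.zeros(p)
    for weight_vec, ssy_a in zip(comps_w, ssy_comp):
        wnorm = weight_vec / np.linalg.norm(weight_vec)
        vip_sq += ssy_a * wnorm ** 2
    vip = np.sqrt(p * vip_sq / total_ssy)

    return OplsdaResult(
        predictive_scores=t,
        predictive_loadings=p_load,
        orthogonal_scores=np.column_stack(T_o) if T_o else np.empty((n, 0)),
        orthogonal_loadings=np.column_stack(P_o) if P_o else np.empty((p, 0)),
        r2x=float(r2x),
        r2y=float(r2y),
        q2=float(q2),
        vip=pd.Series(vip, index=scaled.columns, name="VIP"),
        classes=classes,
    )


def vip_select(result: OplsdaResult, threshold: float = 1.0) -> pd.Series:
    """Peaks with VIP above ``threshold``, sorted descending."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    selected = result.vip[result.vip > threshold]
    return selected.sort_values(ascending=False)
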