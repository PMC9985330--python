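"""Evaluation metrics for corrected meta-experiments.

Six scores, all in [0, 1], are computed per corrected matrix:

=====  ============================================================
e1     PVCA batch variance proportion (batch effect; lower better)
e2     |mean silhouette| with batch labels (lower better)
e3     eigenvalue-scaled principal-component regression on batch
       (lower better)
e4     PVCA biological-covariate variance proportion (higher better)
e5     normalized regional entropy of batch mixing on PC1-2
       (higher better)
e6     fraction of the union of per-experiment highly variable genes
       conserved after correction (higher better)
=====  ============================================================

PVCA fits, per retained principal component, a mixed model with random
effects {batch, bio, batch x bio} by restricted maximum likelihood and
averages the variance-component proportions weighted by eigenvalues.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "PcaEmbedding",
    "MetricScores",
    "pca_embed",
    "eval_pvca",
    "eval_silhouette",
    "eval_pcregression",
    "eval_entropy",
    "detect_hvg",
    "eval_hvg_union",
]


@dataclass
class PcaEmbedding:
    """Sample scores, eigenvalues and variance proportions from PCA."""

    scores: np.ndarray          # samples x components
    eigenvalues: np.ndarray     # non-increasing, >= 0
    proportions: np.ndarray     # fraction of total variance per component
    sample_ids: list = field(default_factory=list)


@dataclass
class MetricScores:
    e1: float  # PVCA batch
    e2: float  # |mean silhouette|
    e3: float  # scaled pcRegression
    e4: float  # PVCA bio
    e5: float  # normalized mixing entropy
    e6: float  # HVG union ratio

    def __post_init__(self) -> None:
        for name in ("e1", "e2", "e3", "e4", "e5", "e6"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 - 1e-9 <= v <= 1.0 + 1e-9):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in ("e1", "e2", "e3", "e4", "e5", "e6")})


def pca_embed(matrix: pd.DataFrame, n_components: int = 20) -> PcaEmbedding:
    """PCA of the gene-centred matrix (samples are observations).

    Scores come from the SVD of the centred matrix; eigenvalues are the PC
    variances (squared singular values / (n-1)); proportions are relative to
    the total per-gene variance.
    """
    n = matrix.shape[1]
    if n < 3:
        raise ValueError("PCA needs >= 3 samples")
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    total_var = (Xc**2).sum() / (n - 1)
    if total_var <= 0:
        raise ValueError("zero variance: constant matrix")
    k = min(n_components, n - 1, matrix.shape[0])
    U, s, Vt = np.linalg.svd(Xc.T, full_matrices=False)   # samples x genes
    scores = U[:, :k] * s[:k]
    eigenvalues = s[:k] ** 2 / (n - 1)
    return PcaEmbedding(scores=scores, eigenvalues=eigenvalues,
                        proportions=eigenvalues / total_var,
                        sample_ids=list(matrix.columns))


# ---------------------------------------------------------------------------
# PVCA
# ---------------------------------------------------------------------------

def _indicator(labels: np.ndarray) -> np.ndarray:
    levels = pd.unique(labels)
    Z = np.zeros((len(labels), len(levels)))
    for j, lev in enumerate(levels):
        Z[labels == lev, j] = 1.0
    return Z


def _reml_components(y: np.ndarray, Zs: list[np.ndarray]) -> np.ndarray:
    """REML variance components for y = mu + sum_f u_f + e, u_f ~ N(0, s2_f).

    Zs are the random-effect indicator matrices; returns the variance
    estimates [s2_1, ..., s2_F, s2_e].  Optimizes the restricted
    log-likelihood over log variances with a moment-based start; falls back
    to the moment estimates if the optimizer fails.
    """
    n = len(y)
    sd = y.std()
    if sd <= 0:
        return np.array([0.0] * len(Zs) + [1.0])
    ys = (y - y.mean()) / sd
    K = [Z @ Z.T for Z in Zs]
    X = np.ones((n, 1))

    def nll(log_s2):
        s2 = np.exp(log_s2)
        V = s2[-1] * np.eye(n)
        for kmat, s in zip(K, s2[:-1]):
            V = V + s * kmat
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e10
        logdetV = 2 * np.log(np.diag(L)).sum()
        Vi_y = np.linalg.solve(V, ys)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        resid = ys - X @ beta
        quad = resid @ np.linalg.solve(V, resid)
        return 0.5 * (logdetV + np.log(np.linalg.det(XtViX)) + quad)

    init = _moment_components(ys, Zs)
    x0 = np.log(np.maximum(init, 1e-4))
    try:
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                bounds=[(-18.0, 6.0)] * len(x0))
        if res.success or np.isfinite(res.fun):
            s2 = np.exp(res.x)
        else:
            raise RuntimeError(res.message)
    except Exception as exc:  # pragma: no cover - optimizer pathologies
        warnings.warn(f"REML failed ({exc}); using moment estimator")
        s2 = np.maximum(init, 0.0)
    return s2 * sd**2


def _moment_components(y: np.ndarray, Zs: list[np.ndarray]) -> np.ndarray:
    """ANOVA-type moment start: between-level variance of level means minus
    the within-cell noise share; crude but only used as an initial value and
    fallback."""
    n = len(y)
    resid_var = None
    # finest grouping = last Z (interaction when provided)
    cells = Zs[-1]
    within = []
    for j in range(cells.shape[1]):
        members = y[cells[:, j] > 0]
        if len(members) >= 2:
            within.append(members.var(ddof=1))
    resid_var = float(np.mean(within)) if within else y.var(ddof=1)
    out = []
    for Z in Zs:
        counts = Z.sum(axis=0)
        means = (Z.T @ y) / counts
        if len(means) >= 2:
            between = means.var(ddof=1) - resid_var * float(np.mean(1.0 / counts))
        else:
            between = 0.0
        out.append(max(between, 1e-6))
    out.append(max(resid_var, 1e-6))
    return np.array(out)


def eval_pvca(matrix: pd.DataFrame, batch: pd.Series, bio: pd.Series,
              var_threshold: float = 0.6, min_pcs: int = 3,
              n_components: int = 20) -> tuple[float, float, pd.DataFrame]:
    """Principal variance component analysis.

    Retains leading PCs until their cumulative share of total variance
    reaches ``var_threshold`` (>= ``min_pcs``), fits the random-effects
    decomposition per PC and returns eigenvalue-weighted proportions for
    batch (e1) and the biological covariate (e4) plus the full table.
    """
    batch_arr = np.asarray(batch.reindex(matrix.columns))
    bio_arr = np.asarray(bio.reindex(matrix.columns))
    if len(pd.unique(batch_arr)) < 2:
        raise ValueError("batch must have >= 2 levels")
    if len(pd.unique(bio_arr[~pd.isna(bio_arr)])) < 2:
        raise ValueError("biological covariate must have >= 2 levels")
    emb = pca_embed(matrix, n_components=n_components)
    cum = np.cumsum(emb.proportions)
    n_keep = int(np.searchsorted(cum, var_threshold) + 1)
    n_keep = min(max(n_keep, min_pcs), len(emb.eigenvalues))

    inter = np.array([f"{a}|{b}" for a, b in zip(batch_arr, bio_arr)])
    Zs = [_indicator(batch_arr), _indicator(bio_arr), _indicator(inter)]
    rows = []
    for i in range(n_keep):
        s2 = _reml_components(emb.scores[:, i], Zs)
        rows.append(s2 / s2.sum())
    table = pd.DataFrame(rows, columns=["batch", "bio", "batch_x_bio", "residual"])
    table.insert(0, "eigenvalue", emb.eigenvalues[:n_keep])
    w = emb.eigenvalues[:n_keep] / emb.eigenvalues[:n_keep].sum()
    weighted = (table[["batch", "bio", "batch_x_bio", "residual"]].to_numpy() * w[:, None]).sum(axis=0)
    e1, e4 = float(weighted[0]), float(weighted[1])
    summary = table.copy()
    summary.attrs["weighted"] = dict(zip(["batch", "bio", "batch_x_bio", "residual"], weighted))
    return e1, e4, summary


# ---------------------------------------------------------------------------
# silhouette / pcRegression / entropy
# ---------------------------------------------------------------------------

def eval_silhouette(embedding: PcaEmbedding, batch: pd.Series) -> float:
    """|mean silhouette| with batches as clusters, Euclidean in PC space."""
    labels = np.asarray(batch.reindex(embedding.sample_ids))
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValueError("silhouette needs >= 2 batches")
    if (counts < 2).any():
        raise ValueError("every batch needs >= 2 samples for the silhouette")
    s = silhouette_samples(embedding.scores, labels, metric="euclidean")
    return float(abs(s.mean()))


def eval_pcregression(embedding: PcaEmbedding, batch: pd.Series) -> float:
    """Eigenvalue-weighted R^2 of PC scores regressed on batch indicators."""
    labels = np.asarray(batch.reindex(embedding.sample_ids))
    if len(pd.unique(labels)) < 2:
        raise ValueError("pcRegression needs a non-constant batch")
    lam = embedding.eigenvalues
    r2 = np.empty(len(lam))
    for i in range(len(lam)):
        y = embedding.scores[:, i]
        sst = ((y - y.mean()) ** 2).sum()
        if sst <= 0:
            r2[i] = 0.0
            continue
        ssb = 0.0
        for lev in pd.unique(labels):
            grp = y[labels == lev]
            ssb += len(grp) * (grp.mean() - y.mean()) ** 2
        r2[i] = ssb / sst
    return float((lam * r2).sum() / lam.sum())


def eval_entropy(embedding: PcaEmbedding, batch: pd.Series,
                 n_queries: int | None = None, k_neighbours: int | None = None,
                 seed: int = 0) -> float:
    """Mean normalized Shannon entropy of batch labels among each query
    sample's nearest neighbours in the PC1-PC2 plane.  1 = perfectly mixed.
    """
    if embedding.scores.shape[1] < 2:
        raise ValueError("entropy needs >= 2 principal components")
    S = embedding.scores.shape[0]
    if S < 4:
        raise ValueError("entropy needs >= 4 samples")
    # canonicalize sample order before seeding so the score is order-invariant
    order = np.argsort(np.asarray(embedding.sample_ids, dtype=object))
    coords = embedding.scores[order, :2]
    labels = np.asarray(batch.reindex(embedding.sample_ids))[order]
    batches = pd.unique(labels)
    if len(batches) < 2:
        raise ValueError("entropy needs >= 2 batches")
    n_queries = min(100, S) if n_queries is None else min(n_queries, S)
    k = min(15, S - 1) if k_neighbours is None else min(k_neighbours, S - 1)
    rng = np.random.default_rng(seed)
    queries = rng.choice(S, size=n_queries, replace=False)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    neigh = nn.kneighbors(coords[queries], return_distance=False)[:, 1:]  # drop self
    ent = np.empty(n_queries)
    for qi, row in enumerate(neigh):
        _, counts = np.unique(labels[row], return_counts=True)
        p = counts / counts.sum()
        ent[qi] = -(p * np.log(p)).sum() / np.log(len(batches))
    return float(ent.mean())


# ---------------------------------------------------------------------------
# highly variable genes
# ---------------------------------------------------------------------------

def detect_hvg(matrix: pd.DataFrame, n_top: int | None = None) -> list[str]:
    """Top genes by variance in excess of a quadratic mean-variance trend."""
    if matrix.shape[1] < 4:
        raise ValueError("HVG detection needs >= 4 samples")
    G = matrix.shape[0]
    if n_top is None:
        n_top = max(50, min(1000, int(round(0.1 * G))))
    X = matrix.to_numpy(dtype=float)
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    design = np.column_stack([np.ones(G), mean, mean**2])
    coef, *_ = np.linalg.lstsq(design, var, rcond=None)
    score = var - design @ coef
    if n_top >= G:
        if G < 50:
            warnings.warn("fewer genes than the HVG minimum; returning all genes")
        return list(matrix.index)
    order = np.lexsort((matrix.index.to_numpy(), -score))  # score desc, id tie-break
    return matrix.index.to_numpy()[order[:n_top]].tolist()


def eval_hvg_union(corrected: pd.DataFrame, experiment_matrices: list[pd.DataFrame],
                   n_top: int | None = None) -> float:
    """Fraction of the union of per-experiment HVGs conserved after correction."""
    union: set = set()
    for mat in experiment_matrices:
        union |= set(detect_hvg(mat.loc[corrected.index], n_top=n_top))
    if not union:
        raise ValueError("empty HVG union")
    after = set(detect_hvg(corrected, n_top=n_top))
    return float(len(after & union) / len(union))
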