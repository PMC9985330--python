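"""Batch corrections for (approximately) Gaussian log-scale expression.

Implements the location/scale family of corrections used on log-intensity
microarray data (and on log-CPM for RNA-seq):

* quantile normalization,
* design-based batch removal (limma-style OLS with sum-to-zero batch
  contrasts),
* empirical-Bayes location/scale adjustment with parametric or
  non-parametric priors (the ComBat model), and the quantile-normalized
  composition Q_ComBat,
* naive remove-unwanted-variation (RUV) using control genes — either a
  packaged human housekeeping list or empirically selected least-variable
  genes — with an optional quantile-normalization pre-step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import CorrectionResult, MetaExperiment

logger = logging.getLogger(__name__)

VAR_FLOOR = 1e-8

__all__ = [
    "quantile_normalize",
    "correct_limma",
    "CombatFit",
    "fit_combat",
    "apply_combat",
    "correct_combat",
    "correct_q_combat",
    "RuvFit",
    "correct_naive_ruv",
    "load_housekeeping_genes",
]


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common distribution of row-wise
    mean order statistics.  Ties within a column receive the mean of the
    reference values at their tied rank positions.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged")
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(reference)
        ranked[order] = reference
        # average reference values over tied positions
        s = pd.Series(ranked)
        out[:, j] = s.groupby(col, sort=False).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _sum_to_zero_contrasts(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """n x (n_levels-1) sum-to-zero (deviation) coding; last level = -1 row."""
    n = len(codes)
    contrasts = np.zeros((n, n_levels - 1))
    for j in range(n_levels - 1):
        contrasts[codes == j, j] = 1.0
    contrasts[codes == n_levels - 1, :] = -1.0
    return contrasts


def _bio_dummies(bio: pd.Series) -> np.ndarray:
    levels = sorted(bio.dropna().unique())
    if len(levels) < 2:
        raise ValueError("biological covariate needs >= 2 categories to be preserved")
    cols = [np.asarray(bio == lev, dtype=float) for lev in levels[1:]]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# limma-style removal
# ---------------------------------------------------------------------------

def correct_limma(meta: MetaExperiment, preserve_bio: bool = True,
                  matrix: pd.DataFrame | None = None) -> CorrectionResult:
    """Remove additive batch effects by per-gene least squares.

    Expression is regressed on [intercept, bio indicators (optional),
    sum-to-zero batch contrasts]; the fitted batch component is subtracted,
    so per-gene grand means are preserved.
    """
    Y = (matrix if matrix is not None else meta.matrix).to_numpy(dtype=float)
    codes, labels = meta.batch_codes()
    n = Y.shape[1]
    parts = [np.ones((n, 1))]
    if preserve_bio and meta.bio.notna().any():
        parts.append(_bio_dummies(meta.bio))
    if len(labels) >= 2:
        batch_part = _sum_to_zero_contrasts(codes, len(labels))
    else:
        batch_part = np.zeros((n, 0))
    X = np.column_stack(parts + [batch_part])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: batch is confounded with the biological covariate")
    if batch_part.shape[1] == 0:
        corrected = Y.copy()
    else:
        beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
        batch_beta = beta[-batch_part.shape[1]:, :]
        corrected = Y - (batch_part @ batch_beta).T
    source = matrix if matrix is not None else meta.matrix
    out = pd.DataFrame(corrected, index=source.index, columns=source.columns)
    return CorrectionResult("limma", out, {"preserve_bio": preserve_bio})


# ---------------------------------------------------------------------------
# ComBat: empirical-Bayes location/scale adjustment
# ---------------------------------------------------------------------------

@dataclass
class CombatFit:
    """Fitted ComBat model: standardization pieces and EB posteriors."""

    mode: str                      # "parametric" | "nonparametric"
    batch_labels: list
    grand_mean: np.ndarray         # per gene
    var_pooled: np.ndarray         # per gene
    stand_mean: np.ndarray         # gene x sample (grand mean + covariate fit)
    gamma_hat: np.ndarray          # gene x batch location estimates
    delta_hat: np.ndarray          # gene x batch scale estimates
    gamma_star: np.ndarray         # gene x batch EB posterior locations
    delta_star: np.ndarray         # gene x batch EB posterior scales
    gamma_bar: np.ndarray          # per batch prior mean of gamma
    t2: np.ndarray                 # per batch prior variance of gamma
    a_prior: np.ndarray            # per batch inverse-gamma shape
    b_prior: np.ndarray            # per batch inverse-gamma scale
    preserve_bio: bool
    mean_only: bool = False


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _parametric_posteriors(Z_b, gamma_hat, delta_hat, gamma_bar, t2, a, b,
                           tol=1e-4, max_iter=100):
    """Fixed-point iteration for the parametric EB posteriors of one batch."""
    n = Z_b.shape[1]
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for it in range(max_iter):
        g_new = (t2 * n * gamma_hat + d_old * gamma_bar) / (t2 * n + d_old)
        sum2 = ((Z_b - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change <= tol:
            break
    else:
        warnings.warn("ComBat EB fixed-point iteration did not converge; proceeding")
    return g_old, d_old


def _nonparametric_posteriors(Z_b, gamma_hat, delta_hat):
    """Monte-Carlo-free empirical posterior: for each gene, likelihood-weight
    the other genes' (gamma_hat, delta_hat) estimates."""
    G, n = Z_b.shape[0], Z_b.shape[1]
    gamma_star = np.empty(G)
    delta_star = np.empty(G)
    sum2 = (Z_b**2).sum(axis=1)
    sum1 = Z_b.sum(axis=1)
    for i in range(G):
        g = np.delete(gamma_hat, i)
        d = np.delete(delta_hat, i)
        # log N(Z_i | g_j, d_j) summed over samples, vectorized over j
        ssq = sum2[i] - 2 * g * sum1[i] + n * g**2
        loglik = -0.5 * n * np.log(2 * np.pi * d) - ssq / (2 * d)
        w = np.exp(loglik - loglik.max())
        w_sum = w.sum()
        gamma_star[i] = (w * g).sum() / w_sum
        delta_star[i] = (w * d).sum() / w_sum
    return gamma_star, delta_star


def fit_combat(meta: MetaExperiment, mode: str = "parametric",
               preserve_bio: bool = True, mean_only: bool = False,
               matrix: pd.DataFrame | None = None) -> CombatFit:
    """Estimate the empirical-Bayes location/scale batch model.

    Standardizes each gene using the grand mean, the (optional) biological
    covariate fit and the pooled variance, then shrinks per-batch per-gene
    location (gamma) and scale (delta^2) estimates toward batch-level priors
    — a normal / inverse-gamma pair fitted by moments in parametric mode, or
    likelihood-weighted empirical posteriors in non-parametric mode.
    """
    if mode not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown ComBat mode {mode!r}")
    Y = (matrix if matrix is not None else meta.matrix).to_numpy(dtype=float)
    codes, labels = meta.batch_codes()
    B = len(labels)
    n = Y.shape[1]
    n_b = np.array([(codes == b).sum() for b in range(B)])
    if (n_b < 2).any():
        raise ValueError("every batch needs >= 2 samples for ComBat")

    batch_design = np.zeros((n, B))
    batch_design[np.arange(n), codes] = 1.0
    parts = [batch_design]
    use_bio = preserve_bio and meta.bio.notna().any() and meta.bio.nunique() >= 2
    if use_bio:
        parts.append(_bio_dummies(meta.bio))
    X = np.column_stack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: batch confounded with the biological covariate")
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)      # p x genes
    grand_mean = (n_b / n) @ beta[:B, :]                 # per gene
    resid = Y.T - X @ beta
    var_pooled = np.maximum((resid**2).mean(axis=0), VAR_FLOOR)

    stand_mean = np.tile(grand_mean[:, None], (1, n))
    if use_bio:
        stand_mean = stand_mean + (X[:, B:] @ beta[B:, :]).T
    Z = (Y - stand_mean) / np.sqrt(var_pooled)[:, None]

    G = Y.shape[0]
    gamma_hat = np.empty((G, B))
    delta_hat = np.empty((G, B))
    for b in range(B):
        Z_b = Z[:, codes == b]
        gamma_hat[:, b] = Z_b.mean(axis=1)
        d = Z_b.var(axis=1, ddof=1)
        if (d < VAR_FLOOR).any():
            warnings.warn("zero-variance gene within a batch: variance floored")
        delta_hat[:, b] = np.maximum(d, VAR_FLOOR)

    gamma_bar = gamma_hat.mean(axis=0)
    t2 = gamma_hat.var(axis=0, ddof=1)
    a_prior = np.array([_aprior(delta_hat[:, b]) for b in range(B)])
    b_prior = np.array([_bprior(delta_hat[:, b]) for b in range(B)])

    gamma_star = np.empty((G, B))
    delta_star = np.empty((G, B))
    for b in range(B):
        Z_b = Z[:, codes == b]
        if delta_hat[:, b].var(ddof=1) < 1e-12 or not (
            np.isfinite(a_prior[b]) and np.isfinite(b_prior[b])
        ):
            # degenerate scale prior (e.g. quantile-constant data): the
            # inverse-gamma moments blow up, so skip the scale shrinkage and
            # shrink the location only
            n_bb = Z_b.shape[1]
            g = (t2[b] * n_bb * gamma_hat[:, b] + delta_hat[:, b] * gamma_bar[b]) / (
                t2[b] * n_bb + delta_hat[:, b]
            )
            d = delta_hat[:, b].copy()
        elif mode == "parametric":
            g, d = _parametric_posteriors(
                Z_b, gamma_hat[:, b], delta_hat[:, b],
                gamma_bar[b], t2[b], a_prior[b], b_prior[b],
            )
        else:
            g, d = _nonparametric_posteriors(Z_b, gamma_hat[:, b], delta_hat[:, b])
        gamma_star[:, b] = g
        delta_star[:, b] = np.ones(G) if mean_only else np.maximum(d, VAR_FLOOR)
    if mean_only:
        delta_star[:] = 1.0

    return CombatFit(
        mode=mode, batch_labels=labels, grand_mean=grand_mean,
        var_pooled=var_pooled, stand_mean=stand_mean,
        gamma_hat=gamma_hat, delta_hat=delta_hat,
        gamma_star=gamma_star, delta_star=delta_star,
        gamma_bar=gamma_bar, t2=t2, a_prior=a_prior, b_prior=b_prior,
        preserve_bio=use_bio, mean_only=mean_only,
    )


def apply_combat(meta: MetaExperiment, fit: CombatFit,
                 matrix: pd.DataFrame | None = None,
                 method_label: str | None = None) -> CorrectionResult:
    """Remove the EB-shrunken batch location/scale effects and rescale."""
    source = matrix if matrix is not None else meta.matrix
    Y = source.to_numpy(dtype=float)
    codes, labels = meta.batch_codes()
    if labels != fit.batch_labels:
        raise ValueError("meta-experiment batches do not match the fit")
    Z = (Y - fit.stand_mean) / np.sqrt(fit.var_pooled)[:, None]
    adjusted = (Z - fit.gamma_star[:, codes]) / np.sqrt(fit.delta_star[:, codes])
    corrected = adjusted * np.sqrt(fit.var_pooled)[:, None] + fit.stand_mean
    label = method_label or ("ComBat1" if fit.mode == "parametric" else "ComBat2")
    out = pd.DataFrame(corrected, index=source.index, columns=source.columns)
    return CorrectionResult(label, out, {"mode": fit.mode, "preserve_bio": fit.preserve_bio})


def correct_combat(meta: MetaExperiment, mode: str = "parametric",
                   preserve_bio: bool = True,
                   matrix: pd.DataFrame | None = None,
                   method_label: str | None = None) -> CorrectionResult:
    fit = fit_combat(meta, mode=mode, preserve_bio=preserve_bio, matrix=matrix)
    return apply_combat(meta, fit, matrix=matrix, method_label=method_label)


def correct_q_combat(meta: MetaExperiment, preserve_bio: bool = True,
                     matrix: pd.DataFrame | None = None) -> CorrectionResult:
    """Quantile normalization followed by parametric ComBat."""
    source = matrix if matrix is not None else meta.matrix
    qn = quantile_normalize(source)
    result = correct_combat(meta, mode="parametric", preserve_bio=preserve_bio,
                            matrix=qn, method_label="Q_ComBat")
    result.params["pre_quantile"] = True
    return result


# ---------------------------------------------------------------------------
# naive RUV on control genes
# ---------------------------------------------------------------------------

@dataclass
class RuvFit:
    controls: list
    k: int
    nu: float
    W: np.ndarray       # samples x k unwanted-factor scores
    alpha: np.ndarray   # k x genes loadings


def load_housekeeping_genes(path: str | Path | None = None) -> list[str]:
    """Packaged human housekeeping symbols, or a user-supplied one-per-line file."""
    if path is None:
        text = resources.files("batchrank.data").joinpath("housekeeping_human.txt").read_text()
    else:
        text = Path(path).read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def _empirical_controls(meta: MetaExperiment, matrix: pd.DataFrame, m: int | None) -> list:
    """The m least-variable genes after removing per-batch gene means."""
    Y = matrix.to_numpy(dtype=float)
    codes, labels = meta.batch_codes()
    centred = Y.copy()
    for b in range(len(labels)):
        mask = codes == b
        centred[:, mask] -= Y[:, mask].mean(axis=1, keepdims=True)
    var = centred.var(axis=1, ddof=1)
    G = len(var)
    if m is None:
        m = max(100, int(np.ceil(0.05 * G)))
    m = min(m, G)
    order = np.lexsort((matrix.index.to_numpy(), var))  # variance, gene id tie-break
    return matrix.index.to_numpy()[order[:m]].tolist()


def correct_naive_ruv(meta: MetaExperiment, controls: str = "empirical",
                      k: int = 2, nu: float | None = None,
                      pre_quantile: bool = False,
                      n_empirical: int | None = None,
                      housekeeping_path: str | Path | None = None,
                      matrix: pd.DataFrame | None = None,
                      method_label: str | None = None) -> CorrectionResult:
    """Remove unwanted variation estimated from control genes.

    W holds the first k left singular vectors (scaled by singular values) of
    the sample-by-control submatrix; loadings alpha come from a ridge solve
    with coefficient nu, and W alpha is subtracted from the whole matrix.
    """
    source = matrix if matrix is not None else meta.matrix
    work = quantile_normalize(source) if pre_quantile else source
    if controls == "housekeeping":
        hk = load_housekeeping_genes(housekeeping_path)
        ctrl = sorted(set(hk) & set(work.index))
        if not ctrl:
            raise ValueError(
                "housekeeping intersection empty: no packaged housekeeping gene is "
                "present in the meta-experiment; try controls='empirical'"
            )
    elif controls == "empirical":
        ctrl = _empirical_controls(meta, work, n_empirical)
    else:
        raise ValueError(f"unknown control mode {controls!r}")
    if k < 1 or k > min(len(ctrl), work.shape[1]):
        raise ValueError(
            f"k={k} out of bounds: must satisfy 1 <= k <= min(#controls={len(ctrl)}, "
            f"#samples={work.shape[1]})"
        )
    Yt = work.to_numpy(dtype=float).T                 # samples x genes
    ctrl_idx = work.index.get_indexer(ctrl)
    Yc = Yt[:, ctrl_idx]
    U, s, _ = np.linalg.svd(Yc, full_matrices=False)
    if nu is None:
        nu = 1e-2 * float(s.mean()) ** 2
    W = U[:, :k] * s[:k]
    alpha = np.linalg.solve(W.T @ W + nu * np.eye(k), W.T @ Yt)
    corrected = (Yt - W @ alpha).T
    label = method_label or (
        ("Q_" if pre_quantile else "") + (
            "naiveRandRUV_HK" if controls == "housekeeping" else "naiveRandRUV_empi"
        )
    )
    out = pd.DataFrame(corrected, index=work.index, columns=work.columns)
    result = CorrectionResult(label, out, {"controls": controls, "k": k, "nu": nu,
                                           "pre_quantile": pre_quantile,
                                           "n_controls": len(ctrl)})
    result._fit = RuvFit(controls=list(ctrl), k=k, nu=nu, W=W, alpha=alpha)
    return result
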