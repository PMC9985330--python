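"""Count-native batch corrections for bulk RNA-seq.

Raw counts are modelled as negative binomial (NB).  Two corrections operate
directly on the counts:

* a NB-regression batch adjustment (the ComBat-seq idea): per gene, estimate
  batch-specific means (log-linear model with a library-size offset) and
  batch-specific dispersions, then map every observed count through its
  batch's NB cumulative distribution onto the quantile of a batch-free NB,
  producing adjusted non-negative integer counts;
* RUVs-style factor removal using groups of samples that replicate the same
  biological condition across batches.

``log_transform_counts`` provides the variance-stabilizing log2-CPM matrix
that feeds the linear (Gaussian-scale) corrections when the technology is
RNA-seq.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, digamma, polygamma

from .dataset import CorrectionResult, MetaExperiment

logger = logging.getLogger(__name__)

DISP_FLOOR = 1e-8
DISP_CEIL = 1e3

__all__ = [
    "log_transform_counts",
    "NbBatchFit",
    "fit_nb_batch",
    "correct_combatseq",
    "correct_ruvs",
    "replicate_groups_from_bio",
]


def log_transform_counts(meta: MetaExperiment, matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Library-size-normalized log2(CPM + 1)."""
    source = matrix if matrix is not None else meta.matrix
    counts = source.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("negative values: log transform expects raw counts")
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        bad = source.columns[libsize == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    cpm = counts / libsize * 1e6
    return pd.DataFrame(np.log2(cpm + 1.0), index=source.index, columns=source.columns)


# ---------------------------------------------------------------------------
# NB batch model (ComBat-seq style)
# ---------------------------------------------------------------------------

@dataclass
class NbBatchFit:
    """Per-gene NB batch model: means with and without batch, dispersions."""

    model: str                    # "null" | "full"
    batch_labels: list
    mu_batch: np.ndarray          # gene x sample fitted means (with batch)
    mu_free: np.ndarray           # gene x sample batch-free target means
    disp_batch: np.ndarray        # gene x batch dispersions
    disp_pooled: np.ndarray       # gene pooled dispersions
    beta: np.ndarray              # p x gene coefficients
    nonzero: np.ndarray           # boolean mask of genes actually modelled


def _poisson_irls(X: np.ndarray, Y: np.ndarray, offset: np.ndarray,
                  max_iter: int = 25, tol: float = 1e-8) -> np.ndarray:
    """Vectorized per-gene Poisson IRLS for a shared design matrix.

    Y is genes x samples; returns beta with shape (p, genes).  The Poisson
    score equations give the NB mean MLE for categorical designs, which is
    all the quantile mapping needs.
    """
    G, n = Y.shape
    p = X.shape[1]
    # init from log means on the offset scale
    beta, *_ = np.linalg.lstsq(X, np.log((Y + 0.5) / np.exp(offset)[None, :]).T, rcond=None)
    for _ in range(max_iter):
        eta = (X @ beta).T + offset[None, :]          # genes x samples
        mu = np.exp(np.clip(eta, -50, 50))
        z = eta - offset[None, :] + (Y - mu) / mu      # working response
        # batched weighted normal equations: A[g] = X' diag(mu_g) X
        A = np.einsum("ni,gn,nj->gij", X, mu, X)
        rhs = np.einsum("ni,gn->gi", X, mu * z)
        A += 1e-10 * np.eye(p)[None, :, :]
        new_beta = np.linalg.solve(A, rhs[:, :, None])[:, :, 0].T   # p x genes
        step = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if step < tol:
            break
    return beta


def _nb_disp_mle(Y: np.ndarray, mu: np.ndarray, init: np.ndarray,
                 max_iter: int = 50) -> np.ndarray:
    """Per-gene NB dispersion MLE by Newton iteration on theta = log(phi).

    Y, mu: genes x samples (means held fixed); init: genes.  Falls back to
    the method-of-moments value where Newton fails to move to a finite
    optimum.
    """
    G, n = Y.shape
    phi = np.clip(init, 1e-4, DISP_CEIL)
    moments = init.copy()
    for _ in range(max_iter):
        r = 1.0 / phi                                 # size parameter
        rr = r[:, None]
        # d loglik / d r
        dl_dr = (digamma(Y + rr) - digamma(rr) + np.log(rr) + 1.0
                 - np.log(rr + mu) - (Y + rr) / (rr + mu)).sum(axis=1)
        d2l_dr2 = (polygamma(1, Y + rr) - polygamma(1, rr) + 1.0 / rr
                   - 2.0 / (rr + mu) + (Y + rr) / (rr + mu) ** 2).sum(axis=1)
        # chain rule to theta = log(phi); r = e^{-theta}
        dl_dtheta = dl_dr * (-r)
        d2l_dtheta2 = d2l_dr2 * r**2 + dl_dr * r
        with np.errstate(divide="ignore", invalid="ignore"):
            step = dl_dtheta / d2l_dtheta2
        step = np.where(np.isfinite(step), step, 0.0)
        step = np.clip(step, -2.0, 2.0)
        theta = np.log(phi) - step
        new_phi = np.clip(np.exp(theta), DISP_FLOOR, DISP_CEIL)
        if np.max(np.abs(np.log(new_phi) - np.log(phi))) < 1e-6:
            phi = new_phi
            break
        phi = new_phi
    bad = ~np.isfinite(phi)
    if bad.any():
        phi[bad] = np.clip(moments[bad], DISP_FLOOR, DISP_CEIL)
    return phi


def _moments_disp(Y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Method-of-moments dispersion: solve sum((y-mu)^2 - mu) = phi sum(mu^2)."""
    num = ((Y - mu) ** 2 - mu).sum(axis=1)
    den = (mu**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = num / den
    phi = np.where(np.isfinite(phi), phi, 0.0)
    return np.clip(phi, DISP_FLOOR, DISP_CEIL)


def fit_nb_batch(meta: MetaExperiment, model: str = "null") -> NbBatchFit:
    """Fit the per-gene NB batch model used by the count correction."""
    if model not in ("null", "full"):
        raise ValueError(f"unknown model {model!r}")
    counts = meta.matrix.to_numpy(dtype=float)
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("count correction expects non-negative integer counts")
    codes, labels = meta.batch_codes()
    B = len(labels)
    n = counts.shape[1]
    nonzero = counts.sum(axis=1) > 0
    Y = counts[nonzero]
    libsize = counts.sum(axis=0)
    offset = np.log(libsize)

    batch_design = np.zeros((n, B))
    batch_design[np.arange(n), codes] = 1.0
    parts = [batch_design]
    if model == "full":
        bio = meta.bio
        if bio.isna().all() or bio.nunique() < 2:
            logger.info("full model requested but no usable bio covariate; behaves as null")
        else:
            levels = sorted(bio.dropna().unique())
            parts.append(np.column_stack([np.asarray(bio == lev, float) for lev in levels[1:]]))
    X = np.column_stack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("confounded: biological covariate is not estimable alongside batch")

    beta = _poisson_irls(X, Y, offset)
    eta = (X @ beta).T + offset[None, :]
    mu_batch = np.exp(np.clip(eta, -50, 50))

    # batch-free target: replace each batch coefficient by the sample-share
    # weighted average of batch coefficients
    n_b = np.array([(codes == b).sum() for b in range(B)])
    gamma = beta[:B, :]                                # B x genes
    gamma_bar = (n_b / n) @ gamma                      # per gene
    eta_free = eta - gamma[codes, :].T + gamma_bar[:, None]
    mu_free = np.exp(np.clip(eta_free, -50, 50))

    disp_batch = np.empty((Y.shape[0], B))
    for b in range(B):
        mask = codes == b
        mom = _moments_disp(Y[:, mask], mu_batch[:, mask])
        disp_batch[:, b] = _nb_disp_mle(Y[:, mask], mu_batch[:, mask], mom)
    mom_all = _moments_disp(Y, mu_free)
    disp_pooled = _nb_disp_mle(Y, mu_free, mom_all)

    return NbBatchFit(model=model, batch_labels=labels, mu_batch=mu_batch,
                      mu_free=mu_free, disp_batch=disp_batch,
                      disp_pooled=disp_pooled, beta=beta, nonzero=nonzero)


def _nb_cdf(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB CDF, Poisson limit when the dispersion is at the floor."""
    out = np.empty_like(mu)
    poisson = phi <= DISP_FLOOR * 1.01
    if poisson.any():
        out[poisson] = stats.poisson.cdf(y[poisson], mu[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mu[nb])
        out[nb] = stats.nbinom.cdf(y[nb], r, p)
    return out


def _nb_ppf(q: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    out = np.empty_like(mu)
    poisson = phi <= DISP_FLOOR * 1.01
    if poisson.any():
        out[poisson] = stats.poisson.ppf(q[poisson], mu[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mu[nb])
        out[nb] = stats.nbinom.ppf(q[nb], r, p)
    return out


def correct_combatseq(meta: MetaExperiment, model: str = "null") -> CorrectionResult:
    """Quantile-map counts from their batch NB onto a batch-free NB.

    Each count c is mapped through the CDF midpoint (F(c-1)+F(c))/2 of its
    batch-specific NB, then inverted on the batch-free NB with pooled
    dispersion — a deterministic tie rule that avoids random jitter.
    All-zero genes pass through unchanged; outputs are non-negative integers.
    """
    fit = fit_nb_batch(meta, model=model)
    counts = meta.matrix.to_numpy(dtype=np.int64)
    codes, _ = meta.batch_codes()
    out = counts.copy()
    Y = counts[fit.nonzero].astype(float)
    mu_b = fit.mu_batch
    phi_b = fit.disp_batch[:, codes]                  # gene x sample
    mu_f = fit.mu_free
    phi_f = np.repeat(fit.disp_pooled[:, None], Y.shape[1], axis=1)

    upper = _nb_cdf(Y, mu_b, phi_b)
    lower = np.where(Y > 0, _nb_cdf(Y - 1.0, mu_b, phi_b), 0.0)
    q = np.clip(0.5 * (lower + upper), 1e-12, 1.0 - 1e-12)
    mapped = _nb_ppf(q, mu_f, phi_f)
    mapped = np.where(np.isfinite(mapped), mapped, Y)
    out[fit.nonzero] = np.maximum(np.round(mapped), 0).astype(np.int64)
    label = "ComBatseq_full" if model == "full" else "ComBatseq_null"
    result = CorrectionResult(label, pd.DataFrame(out, index=meta.genes, columns=meta.samples),
                              {"model": model})
    result._fit = fit
    return result


# ---------------------------------------------------------------------------
# RUVs: replicate-based unwanted variation removal
# ---------------------------------------------------------------------------

def replicate_groups_from_bio(meta: MetaExperiment) -> dict[str, list[str]]:
    """Groups of samples replicating the same biological condition.

    A usable group is a bio category observed in >= 2 batches — within such a
    group, differences between samples are (up to noise) batch effects.
    """
    groups: dict[str, list[str]] = {}
    spans_batches = False
    for cat, idx in meta.bio.groupby(meta.bio).groups.items():
        samples = list(idx)
        if len(samples) >= 2:
            groups[str(cat)] = samples
            if meta.batch.loc[samples].nunique() >= 2:
                spans_batches = True
    if not spans_batches:
        raise ValueError("no cross-batch replicates: no bio category spans >= 2 batches")
    return groups


def correct_ruvs(meta: MetaExperiment, replicate_groups: dict[str, list[str]] | None = None,
                 k: int = 1, controls: list | None = None) -> CorrectionResult:
    """Estimate unwanted factors from within-group centred log counts.

    On log2(count+1): centre each replicate group at its mean, SVD the
    centred sample-by-control matrix, take the top-k factors, regress them
    out of all genes, then exponentiate back and round to non-negative
    integers.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if replicate_groups is None:
        replicate_groups = replicate_groups_from_bio(meta)
    counts = meta.matrix.to_numpy(dtype=float)
    log_counts = np.log2(counts + 1.0)
    samples = meta.samples
    if controls is None:
        controls = list(meta.genes)                   # default: all genes
    ctrl_idx = meta.genes.get_indexer(controls)
    if (ctrl_idx < 0).any():
        raise ValueError("control genes absent from the meta-experiment")

    centred = log_counts.copy()
    in_group = np.zeros(len(samples), dtype=bool)
    for members in replicate_groups.values():
        cols = samples.get_indexer(members)
        if (cols < 0).any():
            raise ValueError("replicate group names a sample absent from the meta-experiment")
        centred[:, cols] -= centred[:, cols].mean(axis=1, keepdims=True)
        in_group[cols] = True
    centred[:, ~in_group] = 0.0                        # ungrouped samples carry no signal

    Zc = centred[ctrl_idx, :].T                        # samples x controls
    U, s, _ = np.linalg.svd(Zc, full_matrices=False)
    if k > len(s):
        raise ValueError(f"k={k} exceeds the available factors ({len(s)})")
    W = U[:, :k] * s[:k]                               # samples x k
    alpha, *_ = np.linalg.lstsq(W, log_counts.T, rcond=None)
    corrected_log = log_counts - (W @ alpha).T
    corrected = np.maximum(np.round(2.0**corrected_log - 1.0), 0).astype(np.int64)
    result = CorrectionResult("RUVs", pd.DataFrame(corrected, index=meta.genes, columns=samples),
                              {"k": k, "n_controls": len(controls),
                               "groups": {g: len(m) for g, m in replicate_groups.items()}})
    result._log_corrected = pd.DataFrame(corrected_log, index=meta.genes, columns=samples)
    result._W = W
    return result
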