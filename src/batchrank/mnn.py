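"""Mutual-nearest-neighbours batch correction.

Samples are cosine-normalized, batches merged sequentially (experiment-id
order): mutual nearest neighbour pairs between the growing reference and the
next batch define per-pair correction vectors (reference minus target),
which are smoothed over the target batch with a Gaussian kernel and added.
The reference is never modified; the output is returned on the original
scale by re-applying each sample's stored norm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .dataset import CorrectionResult, MetaExperiment

logger = logging.getLogger(__name__)

__all__ = ["MnnPairs", "find_mutual_nn", "correct_mnn"]


@dataclass
class MnnPairs:
    """Mutual kNN pairs between a reference and a target batch."""

    reference: str
    target: str
    pairs: list[tuple[int, int]]   # (index in reference, index in target)
    k: int


def find_mutual_nn(ref: np.ndarray, tgt: np.ndarray, k: int) -> list[tuple[int, int]]:
    """All (i, j) with ref_i among tgt_j's k NNs in ref AND vice versa.

    ``ref``/``tgt`` are samples x genes; Euclidean distance.
    """
    k_rt = min(k, tgt.shape[0])
    k_tr = min(k, ref.shape[0])
    nn_of_ref = NearestNeighbors(n_neighbors=k_rt).fit(tgt).kneighbors(ref, return_distance=False)
    nn_of_tgt = NearestNeighbors(n_neighbors=k_tr).fit(ref).kneighbors(tgt, return_distance=False)
    tgt_neigh = [set(row) for row in nn_of_ref]        # for each ref i: its NNs in tgt
    pairs = []
    for j, row in enumerate(nn_of_tgt):                # for each tgt j: its NNs in ref
        for i in row:
            if j in tgt_neigh[i]:
                pairs.append((int(i), int(j)))
    return sorted(pairs)


def cosine_normalize(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """L2-normalize columns (samples); returns (normalized, norms)."""
    norms = np.linalg.norm(matrix, axis=0)
    if (norms == 0).any():
        raise ValueError("cannot cosine-normalize an all-zero sample")
    return matrix / norms, norms


def correct_mnn(meta: MetaExperiment, k: int = 20, sigma: float = 0.1,
                cosine: bool = True,
                matrix: pd.DataFrame | None = None) -> CorrectionResult:
    """Sequentially align batches on their mutual nearest neighbours."""
    source = matrix if matrix is not None else meta.matrix
    Y = source.to_numpy(dtype=float)
    codes, labels = meta.batch_codes()
    sizes = {b: int((codes == i).sum()) for i, b in enumerate(labels)}
    k = min(k, min(sizes.values()) - 1)
    if k < 1:
        raise ValueError("k must be >= 1 and smaller than every batch")

    if cosine:
        norm_data, norms = cosine_normalize(Y)
    else:
        norm_data, norms = Y.copy(), np.ones(Y.shape[1])
    X = norm_data.T                                    # samples x genes, corrected in place

    ref_mask = codes == 0
    all_pairs = []
    for b in range(1, len(labels)):
        tgt_mask = codes == b
        ref = X[ref_mask]
        tgt = X[tgt_mask]
        pairs = find_mutual_nn(ref, tgt, k)
        if not pairs:
            raise ValueError(f"no MNN pairs found for batch {labels[b]!r}")
        all_pairs.append(MnnPairs(reference="+".join(labels[:b]), target=labels[b],
                                  pairs=pairs, k=k))
        ref_ids = np.array([p[0] for p in pairs])
        tgt_ids = np.array([p[1] for p in pairs])
        vectors = ref[ref_ids] - tgt[tgt_ids]          # pairs x genes
        anchors = tgt[tgt_ids]
        # Gaussian-kernel smoothing of pair vectors over target locations
        d2 = ((tgt[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-d2 / (2.0 * sigma**2))
        wsum = w.sum(axis=1, keepdims=True)
        flat = wsum[:, 0] < 1e-12
        if flat.any():                                 # too far from every pair: plain mean
            w[flat] = 1.0
            wsum[flat] = w[flat].sum(axis=1, keepdims=True)
        correction = (w @ vectors) / wsum
        tgt_idx = np.where(tgt_mask)[0]
        X[tgt_idx] = tgt + correction
        ref_mask = ref_mask | tgt_mask

    corrected = X.T * norms
    out = pd.DataFrame(corrected, index=source.index, columns=source.columns)
    result = CorrectionResult("mnnCorrect", out,
                              {"k": k, "sigma": sigma, "cosine": cosine})
    result._pairs = all_pairs
    return result
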