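"""Model/Results interface for the batch-correction benchmark.

:class:`BCMSelector` is built from a :class:`~batchrank.dataset.MetaExperiment`
(or directly from experiments via :meth:`BCMSelector.from_experiments`);
``fit()`` runs every applicable batch-correction method, scores each
corrected matrix with the six evaluation metrics and aggregates the scores
into the sumRank prioritization, returning a :class:`BCMSelectionResult`
that carries the corrected matrices, the evaluation matrix, the rank table
and a ``summary()``.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import countbcm, linearbcm, metrics, mnn, ranking
from .dataset import CorrectionResult, Experiment, MetaExperiment, link_experiments, merge_experiments

logger = logging.getLogger(__name__)

__all__ = ["BCMSelector", "BCMSelectionResult", "MICROARRAY_METHODS", "RNASEQ_METHODS"]

MICROARRAY_METHODS = [
    "limma",
    "ComBat1",
    "ComBat2",
    "Q_ComBat",
    "naiveRandRUV_HK",
    "naiveRandRUV_empi",
    "Q_naiveRandRUV_HK",
    "Q_naiveRandRUV_empi",
    "mnnCorrect",
]
COUNT_METHODS = ["ComBatseq_null", "ComBatseq_full", "RUVs"]
RNASEQ_METHODS = MICROARRAY_METHODS + COUNT_METHODS


@dataclass
class MetricParams:
    """Tunable metric settings (the paper-facing defaults)."""

    n_pcs: int = 20
    pvca_threshold: float = 0.6
    pvca_min_pcs: int = 3
    entropy_n_queries: int | None = None    # min(100, n samples)
    entropy_k: int | None = None            # min(15, n-1)
    hvg_n_top: int | None = None            # max(50, min(1000, 10% of genes))


class BCMSelector:
    """Benchmark of batch-correction methods on one meta-experiment.

    Parameters
    ----------
    meta
        The merged meta-experiment (counts for rnaseq, log scale for
        microarray).
    methods
        Method labels to run; defaults to every method applicable to the
        technology.  "uncorrected" is always evaluated.
    metric_params
        Metric settings; see :class:`MetricParams`.
    seed
        Master seed; the entropy metric's query sampling derives a
        per-method substream from it.
    external_corrected
        Mapping label -> pre-corrected gene-by-sample DataFrame (e.g. from a
        method run outside this package) to be scored and ranked alongside.
    """

    def __init__(self, meta: MetaExperiment, methods: Sequence[str] | None = None,
                 metric_params: MetricParams | None = None, seed: int = 0,
                 external_corrected: dict[str, pd.DataFrame] | None = None,
                 ruv_k: int = 2, ruvs_k: int = 1, mnn_k: int = 20,
                 mnn_sigma: float = 0.1,
                 housekeeping_path: str | None = None):
        self.meta = meta
        available = RNASEQ_METHODS if meta.technology == "rnaseq" else MICROARRAY_METHODS
        if methods is None:
            methods = list(available)
        bad = [m for m in methods if m not in available and m != "uncorrected"]
        if bad:
            raise ValueError(
                f"methods not applicable to technology {meta.technology!r}: {bad}"
            )
        self.methods = [m for m in methods if m != "uncorrected"]
        self.metric_params = metric_params or MetricParams()
        self.seed = int(seed)
        self.external_corrected = external_corrected or {}
        self.ruv_k = ruv_k
        self.ruvs_k = ruvs_k
        self.mnn_k = mnn_k
        self.mnn_sigma = mnn_sigma
        self.housekeeping_path = housekeeping_path

    @classmethod
    def from_experiments(cls, experiments: Sequence[Experiment], bio_covariate: str,
                         **kwargs) -> "BCMSelector":
        """Link, filter and merge experiments, then build the selector."""
        _, retained, discarded = link_experiments(experiments, bio_covariate)
        meta = merge_experiments(retained, bio_covariate)
        obj = cls(meta, **kwargs)
        obj.discarded = discarded
        return obj

    # -- correction dispatch -------------------------------------------------

    def _linear_input(self) -> pd.DataFrame:
        """Matrix fed to Gaussian-scale methods: log2-CPM for counts."""
        if self.meta.technology == "rnaseq":
            return countbcm.log_transform_counts(self.meta)
        return self.meta.matrix

    def _run_method(self, label: str, linear_matrix: pd.DataFrame) -> CorrectionResult:
        meta = self.meta
        m = linear_matrix
        if label == "limma":
            return linearbcm.correct_limma(meta, matrix=m)
        if label == "ComBat1":
            return linearbcm.correct_combat(meta, mode="parametric", matrix=m,
                                            method_label="ComBat1")
        if label == "ComBat2":
            return linearbcm.correct_combat(meta, mode="nonparametric", matrix=m,
                                            method_label="ComBat2")
        if label == "Q_ComBat":
            return linearbcm.correct_q_combat(meta, matrix=m)
        if label == "naiveRandRUV_HK":
            return linearbcm.correct_naive_ruv(meta, controls="housekeeping", k=self.ruv_k,
                                               matrix=m, housekeeping_path=self.housekeeping_path)
        if label == "naiveRandRUV_empi":
            return linearbcm.correct_naive_ruv(meta, controls="empirical", k=self.ruv_k, matrix=m)
        if label == "Q_naiveRandRUV_HK":
            return linearbcm.correct_naive_ruv(meta, controls="housekeeping", k=self.ruv_k,
                                               pre_quantile=True, matrix=m,
                                               housekeeping_path=self.housekeeping_path)
        if label == "Q_naiveRandRUV_empi":
            return linearbcm.correct_naive_ruv(meta, controls="empirical", k=self.ruv_k,
                                               pre_quantile=True, matrix=m)
        if label == "mnnCorrect":
            return mnn.correct_mnn(meta, k=self.mnn_k, sigma=self.mnn_sigma, matrix=m)
        if label == "ComBatseq_null":
            return countbcm.correct_combatseq(meta, model="null")
        if label == "ComBatseq_full":
            return countbcm.correct_combatseq(meta, model="full")
        if label == "RUVs":
            return countbcm.correct_ruvs(meta, k=self.ruvs_k)
        raise ValueError(f"unknown method {label!r}")

    def _analysis_matrix(self, label: str, result: CorrectionResult) -> pd.DataFrame:
        """Corrected matrix on the (log) scale the metrics operate on."""
        if self.meta.technology == "rnaseq" and label in COUNT_METHODS:
            return countbcm.log_transform_counts(self.meta, matrix=result.matrix)
        return result.matrix

    # -- evaluation ----------------------------------------------------------

    def _entropy_seed(self, label: str) -> int:
        return (self.seed * 1_000_003 + zlib.crc32(label.encode())) % (2**31 - 1)

    def _score(self, label: str, analysis: pd.DataFrame,
               member_matrices: list[pd.DataFrame]) -> metrics.MetricScores:
        p = self.metric_params
        emb = metrics.pca_embed(analysis, n_components=p.n_pcs)
        e1, e4, _ = metrics.eval_pvca(analysis, self.meta.batch, self.meta.bio,
                                      var_threshold=p.pvca_threshold,
                                      min_pcs=p.pvca_min_pcs, n_components=p.n_pcs)
        e2 = metrics.eval_silhouette(emb, self.meta.batch)
        e3 = metrics.eval_pcregression(emb, self.meta.batch)
        e5 = metrics.eval_entropy(emb, self.meta.batch, n_queries=p.entropy_n_queries,
                                  k_neighbours=p.entropy_k, seed=self._entropy_seed(label))
        e6 = metrics.eval_hvg_union(analysis, member_matrices, n_top=p.hvg_n_top)
        return metrics.MetricScores(e1=e1, e2=e2, e3=e3, e4=e4, e5=e5, e6=e6)

    def fit(self) -> "BCMSelectionResult":
        meta = self.meta
        linear_matrix = self._linear_input()
        uncorrected = CorrectionResult("uncorrected", linear_matrix.copy(),
                                       {"scale": "log"})
        corrections: dict[str, CorrectionResult] = {"uncorrected": uncorrected}
        skipped: dict[str, str] = {}
        for label in self.methods:
            try:
                result = self._run_method(label, linear_matrix)
                result.check_against(meta)
                corrections[label] = result
            except Exception as exc:
                skipped[label] = str(exc)
                logger.warning("method %s skipped: %s", label, exc)
        for label, matrix in self.external_corrected.items():
            ext = CorrectionResult(label, matrix.loc[meta.genes, meta.samples],
                                   {"external": True})
            ext.check_against(meta)
            corrections[label] = ext

        # per-experiment matrices (shared genes, analysis scale) for HVG union
        member_matrices = []
        for exp_id in sorted(meta.batch.unique()):
            cols = meta.samples[meta.batch == exp_id]
            member_matrices.append(linear_matrix[cols])

        rows = {}
        for label, result in corrections.items():
            analysis = self._analysis_matrix(label, result)
            rows[label] = self._score(label, analysis, member_matrices).as_series()
        evaluation = pd.DataFrame(rows).T.loc[list(corrections)]
        per_metric = ranking.transform_and_rank(evaluation)
        rank_table = ranking.sum_rank(per_metric)
        return BCMSelectionResult(selector=self, corrections=corrections,
                                  skipped=skipped, evaluation_matrix=evaluation,
                                  rank_table=rank_table)


@dataclass
class BCMSelectionResult:
    """Fitted benchmark: corrected matrices, scores, ranks and reports."""

    selector: BCMSelector
    corrections: dict[str, CorrectionResult]
    skipped: dict[str, str]
    evaluation_matrix: pd.DataFrame
    rank_table: pd.DataFrame

    @property
    def meta(self) -> MetaExperiment:
        return self.selector.meta

    @property
    def recommended(self) -> str:
        """The sumRank-1 method (alphabetically first among ties)."""
        best = self.rank_table[self.rank_table["sumRank"] == 1]
        return sorted(best.index)[0]

    def sum_rank_of(self, method: str) -> int:
        return int(self.rank_table.loc[method, "sumRank"])

    def summary(self) -> str:
        lines = [
            "Batch-correction method selection",
            "=" * 64,
            f"technology: {self.meta.technology}   genes: {self.meta.matrix.shape[0]}"
            f"   samples: {self.meta.matrix.shape[1]}   batches: {self.meta.batch.nunique()}",
            f"methods evaluated: {len(self.corrections)} (incl. uncorrected)"
            + (f"; skipped: {sorted(self.skipped)}" if self.skipped else ""),
            "",
            "Evaluation matrix (raw scores; e1-e3 lower is better, e4-e6 higher):",
            self.evaluation_matrix.round(4).to_string(),
            "",
            "Rank table (dense ranks; sumRank 1 = recommended):",
            self.rank_table.to_string(),
            "",
            f"recommended method: {self.recommended}",
        ]
        return "\n".join(lines)

    def save(self, out_dir, write_matrices: bool = True) -> Path:
        """Write evaluation matrix, rank table, plots and corrected matrices."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ranking.diagnostic_report(self.evaluation_matrix, self.rank_table, out_dir)
        if write_matrices:
            mat_dir = out_dir / "corrected"
            mat_dir.mkdir(exist_ok=True)
            for label, result in self.corrections.items():
                result.matrix.to_csv(mat_dir / f"{label}.tsv", sep="\t",
                                     float_format="%.10g")
        if self.skipped:
            lines = [f"{k}\t{v}" for k, v in sorted(self.skipped.items())]
            (out_dir / "skipped_methods.tsv").write_text("\n".join(lines) + "\n")
        return out_dir
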