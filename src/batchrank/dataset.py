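"""Domain types, file I/O and meta-experiment assembly.

A bulk-transcriptome benchmark starts from several independently produced
experiments (one study = one batch).  Experiments are linked through shared
categories of a designated biological covariate (e.g. ``disease``), unlinked
studies are discarded, and the linked set is merged over the intersection of
their gene spaces into a single :class:`MetaExperiment` whose ``batch``
vector records the experiment of origin.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MICROARRAY = "microarray"
RNASEQ = "rnaseq"
TECHNOLOGIES = (MICROARRAY, RNASEQ)

__all__ = [
    "Experiment",
    "MetaExperiment",
    "CorrectionResult",
    "read_experiment",
    "link_experiments",
    "merge_experiments",
    "write_meta",
    "read_meta",
]


@dataclass
class Experiment:
    """One study: a gene-by-sample matrix plus per-sample annotation.

    ``matrix`` holds log-scale intensities for microarray data or raw
    non-negative integer counts for RNA-seq.  ``sample_meta`` is indexed by
    sample id and carries categorical biological covariates.
    """

    id: str
    matrix: pd.DataFrame
    sample_meta: pd.DataFrame
    technology: str

    def __post_init__(self) -> None:
        self.validate()

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def samples(self) -> pd.Index:
        return self.matrix.columns

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def validate(self) -> None:
        if self.technology not in TECHNOLOGIES:
            raise ValueError(
                f"unknown technology {self.technology!r}; expected one of {TECHNOLOGIES}"
            )
        if self.matrix.index.has_duplicates:
            dups = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in experiment {self.id!r}: {dups}")
        if self.matrix.columns.has_duplicates:
            dups = self.matrix.columns[self.matrix.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in experiment {self.id!r}: {dups}")
        missing = self.matrix.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(
                f"samples missing from metadata in experiment {self.id!r}: {missing.tolist()}"
            )
        values = self.matrix.to_numpy()
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite values in experiment {self.id!r}")
        if self.technology == RNASEQ:
            if (values < 0).any():
                raise ValueError(f"negative count in rnaseq experiment {self.id!r}")
            if not np.allclose(values, np.round(values)):
                raise ValueError(f"non-integer count in rnaseq experiment {self.id!r}")

    def bio_categories(self, covariate: str) -> set:
        """Distinct categories of ``covariate`` observed in this experiment."""
        if covariate not in self.sample_meta.columns:
            return set()
        return set(self.sample_meta.loc[self.samples, covariate].dropna().unique())


@dataclass
class MetaExperiment:
    """Merged expression matrix over shared genes with batch and bio labels."""

    matrix: pd.DataFrame
    batch: pd.Series
    bio: pd.Series
    technology: str
    member_ids: tuple = ()
    strict: bool = True   # False skips the >=2-batches check (degenerate inputs)

    def __post_init__(self) -> None:
        self.batch = self.batch.reindex(self.matrix.columns)
        self.bio = self.bio.reindex(self.matrix.columns)
        self.validate()

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def samples(self) -> pd.Index:
        return self.matrix.columns

    def validate(self) -> None:
        if self.matrix.shape[0] < 1:
            raise ValueError("meta-experiment has no genes")
        if self.batch.isna().any():
            raise ValueError("every sample needs a batch label")
        counts = self.batch.value_counts()
        if self.strict and len(counts) < 2:
            raise ValueError("meta-experiment needs >= 2 batches")
        if self.strict and (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"every batch needs >= 2 samples; too small: {small}")

    def batch_codes(self) -> tuple[np.ndarray, list]:
        """Integer batch codes (sample order) and the ordered batch labels."""
        labels = sorted(self.batch.unique())
        lut = {b: i for i, b in enumerate(labels)}
        return np.array([lut[b] for b in self.batch]), labels


@dataclass
class CorrectionResult:
    """One method's corrected matrix, aligned to the source meta-experiment."""

    method: str
    matrix: pd.DataFrame
    params: dict = field(default_factory=dict)

    def check_against(self, meta: MetaExperiment) -> None:
        if not self.matrix.index.equals(meta.genes) or not self.matrix.columns.equals(
            meta.samples
        ):
            raise ValueError(
                f"corrected matrix for {self.method!r} is not aligned to the meta-experiment"
            )
        if not np.all(np.isfinite(self.matrix.to_numpy())):
            raise ValueError(f"corrected matrix for {self.method!r} has non-finite values")


def read_experiment(matrix_path, meta_path, technology: str, exp_id: str | None = None) -> Experiment:
    """Read one experiment from a TSV matrix and a TSV sample-metadata table.

    The matrix file has gene ids in the first column and sample ids in the
    header; the metadata file has a ``sample_id`` column plus one column per
    biological covariate.  Gene rows containing any missing value are
    dropped (logged).
    """
    matrix_path = Path(matrix_path)
    meta_path = Path(meta_path)
    if exp_id is None:
        exp_id = matrix_path.stem.removesuffix("_matrix")
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {matrix_path}: {dups}")
    n_missing = int(matrix.isna().any(axis=1).sum())
    if n_missing:
        logger.info("experiment %s: dropping %d gene rows with missing values", exp_id, n_missing)
        matrix = matrix.dropna(axis=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError(f"metadata file {meta_path} lacks a 'sample_id' column")
    meta = meta.set_index("sample_id")
    missing = matrix.columns.difference(meta.index)
    if len(missing):
        raise ValueError(
            f"samples in matrix absent from metadata {meta_path}: {missing.tolist()}"
        )
    if technology == RNASEQ:
        values = matrix.to_numpy()
        if (values < 0).any():
            raise ValueError(f"negative count in {matrix_path}")
        if not np.allclose(values, np.round(values)):
            raise ValueError(f"non-integer count in {matrix_path}")
        matrix = matrix.round().astype(np.int64)
    return Experiment(id=exp_id, matrix=matrix, sample_meta=meta, technology=technology)


def link_experiments(
    experiments: Sequence[Experiment], bio_covariate: str
) -> tuple[nx.Graph, list[Experiment], list[tuple[str, str]]]:
    """Link experiments sharing >= 1 category of ``bio_covariate``.

    Returns the linkage graph, the retained experiments (largest connected
    component; ties broken by total sample count, then by lexicographically
    smallest id set), and ``(experiment id, reason)`` pairs for discards.
    """
    if len(experiments) < 2:
        raise ValueError("need >= 2 experiments to link")
    ids = [e.id for e in experiments]
    if len(set(ids)) != len(ids):
        raise ValueError("experiment ids must be unique")
    by_id = {e.id: e for e in experiments}
    graph = nx.Graph()
    cats = {}
    for exp in experiments:
        graph.add_node(exp.id)
        cats[exp.id] = exp.bio_categories(bio_covariate)
    for i, a in enumerate(experiments):
        for b in experiments[i + 1 :]:
            if cats[a.id] & cats[b.id]:
                graph.add_edge(a.id, b.id)

    components = [sorted(c) for c in nx.connected_components(graph)]
    # largest component; ties -> more samples, then lexicographically first ids
    components.sort(key=lambda c: (len(c), sum(by_id[i].n_samples for i in c)), reverse=True)
    best_size = (len(components[0]), sum(by_id[i].n_samples for i in components[0]))
    tied = [c for c in components if (len(c), sum(by_id[i].n_samples for i in c)) == best_size]
    retained_ids = min(tied)  # lexicographic tie-break on sorted id lists

    if len(retained_ids) < 2:
        raise ValueError("no linkable experiments: every experiment is unlinked")
    discarded = []
    for exp in experiments:
        if exp.id in retained_ids:
            continue
        if not cats[exp.id]:
            reason = f"covariate {bio_covariate!r} absent"
        elif graph.degree(exp.id) == 0:
            reason = "unlinked: shares no category with any other experiment"
        else:
            reason = "not in the retained connected component"
        discarded.append((exp.id, reason))
        logger.info("discarding experiment %s: %s", exp.id, reason)
    retained = [by_id[i] for i in retained_ids]
    return graph, retained, discarded


def merge_experiments(experiments: Sequence[Experiment], bio_covariate: str) -> MetaExperiment:
    """Merge linked experiments into one meta-experiment.

    Genes are intersected (lexicographic order); columns are concatenated in
    experiment-id order; ``batch`` records the source experiment.  Sample ids
    colliding across experiments are disambiguated by prefixing the
    experiment id.
    """
    techs = {e.technology for e in experiments}
    if len(techs) > 1:
        raise ValueError(f"mixed technologies cannot be merged: {sorted(techs)}")
    experiments = sorted(experiments, key=lambda e: e.id)
    shared = set(experiments[0].genes)
    union = set(experiments[0].genes)
    for exp in experiments[1:]:
        shared &= set(exp.genes)
        union |= set(exp.genes)
    if not shared:
        raise ValueError("empty intersection: the experiments share no genes")
    lost = 1.0 - len(shared) / len(union)
    logger.info("merge: %d shared genes, %.1f%% of the union lost", len(shared), 100 * lost)
    genes = sorted(shared)

    seen: set[str] = set()
    blocks, batch, bio = [], {}, {}
    for exp in experiments:
        block = exp.matrix.loc[genes]
        rename = {}
        for s in block.columns:
            new = s if s not in seen else f"{exp.id}.{s}"
            rename[s] = new
            seen.add(new)
        block = block.rename(columns=rename)
        meta_col = exp.sample_meta.get(bio_covariate)
        for old, new in rename.items():
            batch[new] = exp.id
            bio[new] = meta_col.get(old) if meta_col is not None else None
        blocks.append(block)
    matrix = pd.concat(blocks, axis=1)
    return MetaExperiment(
        matrix=matrix,
        batch=pd.Series(batch, name="batch"),
        bio=pd.Series(bio, name="bio"),
        technology=experiments[0].technology,
        member_ids=tuple(e.id for e in experiments),
    )


_FLOAT_FMT = "%.12g"


def write_meta(meta: MetaExperiment, out_dir) -> Path:
    """Serialize a meta-experiment to ``{matrix.tsv, samples.tsv, manifest.json}``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if meta.technology == RNASEQ:
        meta.matrix.astype(np.int64).to_csv(out_dir / "matrix.tsv", sep="\t")
    else:
        meta.matrix.to_csv(out_dir / "matrix.tsv", sep="\t", float_format=_FLOAT_FMT)
    samples = pd.DataFrame({"batch": meta.batch, "bio": meta.bio})
    samples.index.name = "sample_id"
    samples.to_csv(out_dir / "samples.tsv", sep="\t")
    manifest = {
        "technology": meta.technology,
        "member_ids": list(meta.member_ids),
        "n_genes": int(meta.matrix.shape[0]),
        "n_samples": int(meta.matrix.shape[1]),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir


def read_meta(in_dir) -> MetaExperiment:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    matrix = pd.read_csv(in_dir / "matrix.tsv", sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    if manifest["technology"] == RNASEQ:
        matrix = matrix.astype(np.int64)
    samples = pd.read_csv(in_dir / "samples.tsv", sep="\t", index_col=0, dtype=str)
    samples.index = samples.index.astype(str)
    return MetaExperiment(
        matrix=matrix,
        batch=samples["batch"],
        bio=samples["bio"],
        technology=manifest["technology"],
        member_ids=tuple(manifest.get("member_ids", ())),
    )
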