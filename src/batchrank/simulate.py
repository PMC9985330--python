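"""Synthetic meta-experiments with known ground truth.

Two generators emulate the data the benchmark consumes:

* ``simulate_microarray_meta`` — log-intensity matrices under the additive
  location / multiplicative scale batch model: per-gene baselines are
  Normal(7, 1.5^2), a biological effect is added to a gene subset, and each
  batch perturbs an affected gene fraction with a location offset
  Normal(0, batch_loc_sd^2) and a noise-scale factor
  LogNormal(0, batch_scale_sd^2).
* ``simulate_count_meta`` — negative binomial counts with log-normal base
  means, per-gene dispersions, 2^LFC batch mean multipliers on an affected
  gene fraction and batch-specific dispersion multipliers.

Ground truth (the exact batch-free matrix, and the batch components) is
returned alongside, so tests can compare corrections against an oracle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import Experiment, MetaExperiment, CorrectionResult, merge_experiments

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "GroundTruth", "simulate_microarray_meta",
           "simulate_count_meta", "simulate_meta", "oracle_correct",
           "write_simulation"]


@dataclass
class SimConfig:
    """Parameters of a synthetic meta-experiment.

    Defaults describe a typical small multi-study bulk setting: 2000 genes,
    three studies of 10 biosamples, two biological conditions with a
    one-log2-unit effect on 10% of genes, and batch effects on every gene
    (location sd 1.0, scale sd 0.2 on the log scale for microarray; 2-fold
    mean shifts on 10% of genes for counts).
    """

    technology: str = "microarray"
    n_genes: int = 2000
    batches: list = field(default_factory=lambda: [
        {"id": "expA", "n_samples": 10},
        {"id": "expB", "n_samples": 10},
        {"id": "expC", "n_samples": 10},
    ])
    bio_levels: list = field(default_factory=lambda: ["case", "control"])
    bio_effect_size: float = 1.0
    bio_gene_fraction: float = 0.1
    # microarray batch model
    batch_loc_sd: float = 1.0
    batch_scale_sd: float = 0.2
    frac_affected: float = 1.0
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    # rnaseq batch model
    batch_lfc: float = 1.0
    count_frac_affected: float = 0.1
    base_mean_log: float = 4.0
    base_mean_sd: float = 1.0
    dispersion: float = 0.2
    dispersion_sd: float = 0.5
    batch_disp_multiplier_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.technology not in ("microarray", "rnaseq"):
            raise ValueError(f"unknown technology {self.technology!r}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.batches) < 2:
            raise ValueError("need >= 2 batches")
        for b in self.batches:
            if b["n_samples"] < 2:
                raise ValueError("every batch needs >= 2 samples")
        for frac in (self.bio_gene_fraction, self.frac_affected, self.count_frac_affected):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("gene fractions must lie in [0, 1]")
        if len(self.bio_levels) < 2:
            raise ValueError("need >= 2 biological levels")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GroundTruth:
    """Exact batch-free data and the injected batch components."""

    batch_free: pd.DataFrame            # gene x sample matrix without batch effects
    batch_offsets: pd.DataFrame         # gene x batch additive offsets (log scale)
    batch_scales: pd.DataFrame          # gene x batch scale factors (microarray) or
                                        # mean multipliers (rnaseq)
    affected_genes: list
    bio_genes: list
    config: SimConfig


def _assign_bio(levels, n, rng) -> list:
    """Balanced alternating assignment of biological levels within a batch."""
    reps = [levels[i % len(levels)] for i in range(n)]
    return reps


def simulate_microarray_meta(config: SimConfig) -> tuple[list[Experiment], GroundTruth]:
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    genes = [f"g{i:05d}" for i in range(G)]
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=G)
    bio_genes_idx = rng.choice(G, size=int(round(config.bio_gene_fraction * G)), replace=False)
    bio_effect = np.zeros((G, len(config.bio_levels)))
    for j in range(1, len(config.bio_levels)):
        signs = rng.choice([-1.0, 1.0], size=len(bio_genes_idx))
        bio_effect[bio_genes_idx, j] = signs * config.bio_effect_size

    n_affected = int(round(config.frac_affected * G))
    affected_idx = rng.choice(G, size=n_affected, replace=False)
    affected_mask = np.zeros(G, dtype=bool)
    affected_mask[affected_idx] = True

    batch_ids = [b["id"] for b in config.batches]
    offsets = np.zeros((G, len(batch_ids)))
    scales = np.ones((G, len(batch_ids)))
    for bi in range(len(batch_ids)):
        off = rng.normal(0.0, config.batch_loc_sd, size=G)
        sc = rng.lognormal(0.0, config.batch_scale_sd, size=G)
        offsets[affected_mask, bi] = off[affected_mask]
        scales[affected_mask, bi] = sc[affected_mask]

    experiments = []
    free_blocks, obs_cols = [], []
    for bi, spec in enumerate(config.batches):
        n = spec["n_samples"]
        bio = _assign_bio(config.bio_levels, n, rng)
        bio_idx = np.array([config.bio_levels.index(v) for v in bio])
        noise = rng.normal(0.0, config.noise_sd, size=(G, n))
        signal = baseline[:, None] + bio_effect[:, bio_idx]
        free = signal + noise
        observed = signal + offsets[:, [bi]] + scales[:, [bi]] * noise
        samples = [f"{spec['id']}_s{j:02d}" for j in range(n)]
        matrix = pd.DataFrame(observed, index=genes, columns=samples)
        meta = pd.DataFrame({"disease": bio}, index=pd.Index(samples, name="sample_id"))
        experiments.append(Experiment(id=spec["id"], matrix=matrix,
                                      sample_meta=meta, technology="microarray"))
        free_blocks.append(pd.DataFrame(free, index=genes, columns=samples))
    order = np.argsort(batch_ids)
    batch_free = pd.concat([free_blocks[i] for i in order], axis=1)
    gt = GroundTruth(
        batch_free=batch_free,
        batch_offsets=pd.DataFrame(offsets, index=genes, columns=batch_ids),
        batch_scales=pd.DataFrame(scales, index=genes, columns=batch_ids),
        affected_genes=[genes[i] for i in sorted(affected_idx)],
        bio_genes=[genes[i] for i in sorted(bio_genes_idx)],
        config=config,
    )
    return experiments, gt


def simulate_count_meta(config: SimConfig) -> tuple[list[Experiment], GroundTruth]:
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    genes = [f"g{i:05d}" for i in range(G)]
    base_mean = rng.lognormal(config.base_mean_log, config.base_mean_sd, size=G)
    phi = rng.lognormal(np.log(config.dispersion), config.dispersion_sd, size=G)

    bio_genes_idx = rng.choice(G, size=int(round(config.bio_gene_fraction * G)), replace=False)
    bio_lfc = np.zeros((G, len(config.bio_levels)))
    for j in range(1, len(config.bio_levels)):
        signs = rng.choice([-1.0, 1.0], size=len(bio_genes_idx))
        bio_lfc[bio_genes_idx, j] = signs * config.bio_effect_size

    n_affected = int(round(config.count_frac_affected * G))
    affected_idx = rng.choice(G, size=n_affected, replace=False)
    affected_mask = np.zeros(G, dtype=bool)
    affected_mask[affected_idx] = True

    batch_ids = [b["id"] for b in config.batches]
    lfc = np.zeros((G, len(batch_ids)))
    disp_mult = np.ones(len(batch_ids))
    for bi in range(1, len(batch_ids)):       # first batch is the reference
        signs = rng.choice([-1.0, 1.0], size=G)
        lfc[affected_mask, bi] = (signs * config.batch_lfc)[affected_mask]
        disp_mult[bi] = rng.lognormal(0.0, config.batch_disp_multiplier_sd)

    experiments, free_blocks = [], []
    for bi, spec in enumerate(config.batches):
        n = spec["n_samples"]
        bio = _assign_bio(config.bio_levels, n, rng)
        bio_idx = np.array([config.bio_levels.index(v) for v in bio])
        mu_free = base_mean[:, None] * 2.0 ** bio_lfc[:, bio_idx]
        mu = mu_free * 2.0 ** lfc[:, [bi]]
        phi_b = np.maximum(phi * disp_mult[bi], 1e-8)
        r = 1.0 / phi_b
        counts = rng.negative_binomial(r[:, None], (r / (r + mu.T)).T, size=(G, n))
        samples = [f"{spec['id']}_s{j:02d}" for j in range(n)]
        matrix = pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples)
        meta = pd.DataFrame({"stimulant": bio}, index=pd.Index(samples, name="sample_id"))
        experiments.append(Experiment(id=spec["id"], matrix=matrix,
                                      sample_meta=meta, technology="rnaseq"))
        free_blocks.append(pd.DataFrame(mu_free, index=genes, columns=samples))
    order = np.argsort(batch_ids)
    batch_free = pd.concat([free_blocks[i] for i in order], axis=1)
    gt = GroundTruth(
        batch_free=batch_free,
        batch_offsets=pd.DataFrame(lfc, index=genes, columns=batch_ids),
        batch_scales=pd.DataFrame(2.0**lfc, index=genes, columns=batch_ids),
        affected_genes=[genes[i] for i in sorted(affected_idx)],
        bio_genes=[genes[i] for i in sorted(bio_genes_idx)],
        config=config,
    )
    return experiments, gt


def simulate_meta(config: SimConfig) -> tuple[list[Experiment], GroundTruth]:
    if config.technology == "rnaseq":
        return simulate_count_meta(config)
    return simulate_microarray_meta(config)


def oracle_correct(meta: MetaExperiment, gt: GroundTruth) -> CorrectionResult:
    """Ground-truth correction: the exact batch-free matrix.

    Since observed = signal + offset + scale * noise and the generator stores
    batch_free = signal + noise, subtracting the true batch components from
    the observed data recovers batch_free exactly; for counts, batch_free
    holds the batch-free expected counts.
    """
    corrected = gt.batch_free.loc[meta.genes, meta.samples]
    return CorrectionResult("oracle", corrected.copy(), {"kind": "ground_truth"})


def write_simulation(experiments: list[Experiment], gt: GroundTruth, out_dir) -> Path:
    """Write experiment TSV pairs plus a plain-text ground-truth bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for exp in experiments:
        if exp.technology == "rnaseq":
            exp.matrix.to_csv(out_dir / f"{exp.id}_matrix.tsv", sep="\t")
        else:
            exp.matrix.to_csv(out_dir / f"{exp.id}_matrix.tsv", sep="\t", float_format="%.12g")
        meta = exp.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(out_dir / f"{exp.id}_samples.tsv", sep="\t")
    gt_dir = out_dir / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    gt.batch_free.to_csv(gt_dir / "batch_free.tsv", sep="\t", float_format="%.12g")
    gt.batch_offsets.to_csv(gt_dir / "batch_offsets.tsv", sep="\t", float_format="%.12g")
    gt.batch_scales.to_csv(gt_dir / "batch_scales.tsv", sep="\t", float_format="%.12g")
    (gt_dir / "config.json").write_text(json.dumps(asdict(gt.config), indent=1))
    (gt_dir / "affected_genes.txt").write_text("\n".join(gt.affected_genes))
    return out_dir
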