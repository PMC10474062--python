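"""Synthetic factorial RNA-seq generator.

Emulates the study design the analysis expects: a 2x2 factorial of
leukemic status (non-CML vs CML) by genotype (wt vs KO), giving four
conditions — wt, KO, CP (= CML/wt) and BC (= CML/KO) — with
``n_per_group`` samples each.  Counts are negative binomial with a
lognormal baseline expression profile, sample-specific lognormal library
sizes, a dominant leukemic axis of variation, a secondary genotype axis,
and a planted "metabolism-like" informative gene set whose responsive
members shift on both axes with random sign — informative about the
condition without being uniformly up- or down-regulated.

The NB is parameterized by (mean mu, dispersion phi) with
var = mu + phi * mu^2; a single global phi is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GeneSetCollection,
    write_annotation_tsv,
    write_counts_mtx,
    write_counts_tsv,
    write_gmt,
)

PLANTED_SET_NAME = "planted_metabolism"

#: condition label -> (leukemic, genotype)
CONDITIONS = {
    "wt": ("non-CML", "wt"),
    "KO": ("non-CML", "KO"),
    "CP": ("CML", "wt"),
    "BC": ("CML", "KO"),
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic factorial design.

    Defaults mirror the emulated study: 4 conditions x 5 samples,
    a 655-gene planted informative set in a 2000-gene universe, and
    |log2 fold-change| 1.5 on responsive genes.
    """

    n_genes: int = 2000
    n_per_group: int = 5
    baseline_log_mean_mu: float = 2.0  # natural-log scale of relative abundance
    baseline_log_mean_sd: float = 1.0
    dispersion: float = 0.1  # NB phi: var = mu + phi mu^2
    library_size_mean: int = 1_000_000
    library_size_cv: float = 0.1
    leukemic_lfc: float = 1.5  # log2 FC on leukemic-responsive genes (CML samples)
    genotype_lfc: float = 1.5  # log2 FC on genotype-responsive genes (KO samples)
    n_leukemic_responsive: int = 400
    n_genotype_responsive: int = 150
    planted_set_size: int = 655
    planted_set_responsive_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_per_group", "planted_set_size", "library_size_mean"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        for name in ("n_leukemic_responsive", "n_genotype_responsive"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigError(f"{name} must be a nonnegative integer, got {v!r}")
        for name in ("baseline_log_mean_sd", "dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.library_size_cv < 0:
            raise ConfigError("library_size_cv must be nonnegative")
        if not 0.0 <= self.planted_set_responsive_frac <= 1.0:
            raise ConfigError("planted_set_responsive_frac must lie in [0, 1]")
        if self.planted_set_size > self.n_genes:
            raise ConfigError("planted_set_size cannot exceed n_genes")
        n_free = self.n_genes - self.planted_set_size
        if self.n_leukemic_responsive > n_free or self.n_genotype_responsive > n_free:
            raise ConfigError(
                "background responsive gene counts cannot exceed the number of "
                f"genes outside the planted set ({n_free})"
            )


@dataclass
class SimulatedDataset:
    counts: pd.DataFrame  # genes x samples, raw integers
    annotation: pd.DataFrame  # sample_id index; leukemic, genotype, condition
    gene_sets: GeneSetCollection
    truth: pd.DataFrame  # per-gene flags and planted log2 FCs
    config: SimulationConfig
    metadata: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path, mtx: bool = False) -> None:
        """Write counts / annotation / gene sets / truth as plain text."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_counts_tsv(self.counts, out / "counts.tsv")
        if mtx:
            write_counts_mtx(
                self.counts, out / "counts.mtx", out / "genes.txt", out / "samples.txt"
            )
        write_annotation_tsv(self.annotation, out / "annotation.tsv")
        write_gmt(self.gene_sets, out / "gene_sets.gmt")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index_label="gene_id")


def _make_annotation(n_per_group: int) -> pd.DataFrame:
    rows = []
    for cond, (leuk, geno) in CONDITIONS.items():
        for i in range(1, n_per_group + 1):
            rows.append((f"{cond}_{i}", leuk, geno, cond))
    ann = pd.DataFrame(rows, columns=["sample_id", "leukemic", "genotype", "condition"])
    return ann.set_index("sample_id")


def generate_counts(config: SimulationConfig) -> SimulatedDataset:
    """Draw one synthetic dataset; identical config + seed is bit-identical.

    Responsive genes outside the planted set carry the signed configured
    log2 fold-change on one axis; the responsive fraction of the planted
    set shifts on *both* axes with signs drawn +/-1 equiprobably.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"g{i:05d}" for i in range(cfg.n_genes)])
    annotation = _make_annotation(cfg.n_per_group)
    n_samples = len(annotation)

    # baseline relative abundances
    base = rng.lognormal(cfg.baseline_log_mean_mu, cfg.baseline_log_mean_sd, cfg.n_genes)

    # gene role assignment
    planted_idx = rng.choice(cfg.n_genes, cfg.planted_set_size, replace=False)
    planted_mask = np.zeros(cfg.n_genes, dtype=bool)
    planted_mask[planted_idx] = True
    free_idx = np.flatnonzero(~planted_mask)
    leuk_bg = rng.choice(free_idx, cfg.n_leukemic_responsive, replace=False)
    geno_bg = rng.choice(free_idx, cfg.n_genotype_responsive, replace=False)
    n_resp = int(round(cfg.planted_set_responsive_frac * cfg.planted_set_size))
    planted_resp = rng.choice(planted_idx, n_resp, replace=False)

    lfc_leuk = np.zeros(cfg.n_genes)
    lfc_geno = np.zeros(cfg.n_genes)
    lfc_leuk[leuk_bg] = cfg.leukemic_lfc
    lfc_geno[geno_bg] = cfg.genotype_lfc
    lfc_leuk[planted_resp] = cfg.leukemic_lfc * rng.choice([-1.0, 1.0], n_resp)
    lfc_geno[planted_resp] = cfg.genotype_lfc * rng.choice([-1.0, 1.0], n_resp)

    # per-sample library sizes (lognormal with the configured mean and CV)
    if cfg.library_size_cv > 0:
        sigma2 = np.log1p(cfg.library_size_cv**2)
        lib = rng.lognormal(
            np.log(cfg.library_size_mean) - sigma2 / 2.0, np.sqrt(sigma2), n_samples
        )
    else:
        lib = np.full(n_samples, float(cfg.library_size_mean))

    is_leuk = (annotation["leukemic"] == "CML").to_numpy()
    is_ko = (annotation["genotype"] == "KO").to_numpy()
    effect = np.exp2(
        np.outer(lfc_leuk, is_leuk.astype(float)) + np.outer(lfc_geno, is_ko.astype(float))
    )
    rel = base / base.sum()
    mu = rel[:, None] * lib[None, :] * effect

    shape = 1.0 / cfg.dispersion  # NB size parameter
    p = shape / (shape + mu)
    counts = rng.negative_binomial(shape, p)

    samples = annotation.index
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    counts_df.index.name = "gene_id"

    truth = pd.DataFrame(
        {
            "leukemic_responsive": lfc_leuk != 0,
            "genotype_responsive": lfc_geno != 0,
            "in_planted_set": planted_mask,
            "lfc_leukemic": lfc_leuk,
            "lfc_genotype": lfc_geno,
        },
        index=genes,
    )
    gene_sets = GeneSetCollection(
        sets={PLANTED_SET_NAME: list(genes[np.sort(planted_idx)])},
        descriptions={PLANTED_SET_NAME: "planted informative gene set"},
    )
    return SimulatedDataset(
        counts=counts_df,
        annotation=annotation,
        gene_sets=gene_sets,
        truth=truth,
        config=cfg,
        metadata={"seed": cfg.seed, "n_samples": n_samples},
    )


def generate_gene_sets(
    dataset: SimulatedDataset, n_decoys: int, decoy_size: int, seed: int
) -> GeneSetCollection:
    """Planted set plus ``n_decoys`` uniform random decoy sets.

    Each decoy is sampled without replacement from the full gene universe,
    independently of the planted set and of other decoys.
    """
    genes = dataset.counts.index.to_numpy()
    if decoy_size > len(genes):
        raise ValueError("decoy_size cannot exceed the number of genes")
    rng = np.random.default_rng(seed)
    sets = dict(dataset.gene_sets.sets)
    descriptions = dict(dataset.gene_sets.descriptions)
    for d in range(1, n_decoys + 1):
        name = f"decoy_{d:03d}"
        sets[name] = list(rng.choice(genes, decoy_size, replace=False))
        descriptions[name] = "uniform random decoy set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)
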