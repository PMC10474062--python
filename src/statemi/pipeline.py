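"""End-to-end orchestration: normalize -> state-space -> MI -> DEG balance.

`analyze_dataset` runs the whole analysis on in-memory objects and
returns a machine-readable report; `run_pipeline` is the file-based
wrapper that reads counts / annotation / GMT inputs, writes TSV and JSON
artifacts, and logs stage boundaries.  Reports are deterministic given
the same inputs and seed (no timestamps).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import call_degs_standin, degs_from_flags, hypergeom_test
from .io import (
    GeneSetCollection,
    read_annotation_tsv,
    read_counts_tsv,
    read_gmt,
    write_json,
)
from .mutual_info import (
    CONTRASTS,
    compare_mi_density,
    compute_mi_profile,
    contrast_samples,
    fit_max_entropy_bins,
)
from .preprocess import NormalizedMatrix, mean_center, normalize_log
from .state_space import (
    StateSpaceModel,
    compare_state_spaces,
    fit_state_space,
    rotate_plane,
    score_axis_separation,
    select_axes,
)

logger = logging.getLogger("statemi")

PLANE_AXES = ("axis_disease", "axis_genotype")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31) from a global seed."""
    key = sum(ord(c) * (i + 1) for i, c in enumerate(stage))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PipelineConfig:
    counts: str
    annotation: str
    gene_sets: str
    out_dir: str
    contrasts: list[str] = field(default_factory=lambda: list(CONTRASTS))
    binning_mode: str = "refit"  # "refit" | "reuse_condition4"
    rotation_mode: str | float = "auto"  # "auto" | fixed angle in degrees
    alpha: float = 0.05
    pseudocount: float = 1.0
    seed: int = 0
    deg_mode: str = "standin"  # "standin" | path to external DEG-flags TSV
    deg_groups: tuple[str, str] = ("CP", "BC")

    def __post_init__(self) -> None:
        unknown = set(self.contrasts) - set(CONTRASTS)
        if unknown:
            raise ValueError(f"unsupported contrast(s): {sorted(unknown)}")
        if self.binning_mode not in ("refit", "reuse_condition4"):
            raise ValueError("binning_mode must be 'refit' or 'reuse_condition4'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "deg_groups" in raw:
            raw["deg_groups"] = tuple(raw["deg_groups"])
        return cls(**raw)


def _fit_rotated_space(
    matrix: NormalizedMatrix,
    annotation: pd.DataFrame,
    universe: list[str] | None,
    rotation_mode: str | float,
) -> tuple[StateSpaceModel, StateSpaceModel]:
    """Fit, select axes, and rotate one state-space.

    Returns (unrotated, rotated) models sharing the same axis selection.
    """
    model = fit_state_space(matrix, universe=universe)
    select_axes(model, annotation)
    score_axis_separation(model, annotation, "condition")
    angle = None if rotation_mode == "auto" else float(rotation_mode)
    rotated = rotate_plane(model, angle_deg=angle, annotation=annotation)
    return model, rotated


def plane_coords(model: StateSpaceModel) -> pd.DataFrame:
    """Selected-plane sample coordinates as (axis_disease, axis_genotype)."""
    i, j = model.selected_axes
    out = model.sample_coords.iloc[:, [i - 1, j - 1]].copy()
    out.columns = list(PLANE_AXES)
    return out


def analyze_dataset(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    gene_sets: GeneSetCollection,
    contrasts: list[str] | None = None,
    binning_mode: str = "refit",
    rotation_mode: str | float = "auto",
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    deg_groups: tuple[str, str] = ("CP", "BC"),
    external_deg_flags: pd.Series | None = None,
    seed: int = 0,
    return_objects: bool = False,
):
    """Full analysis on in-memory inputs.

    For the whole transcriptome and each gene set: fit and rotate the
    SVD state-space, compare sub-space coordinates with the full space
    (axis-wise R^2), compute per-gene MI for each contrast, compare the
    set's MI density against the remaining transcriptome, and check
    whether the set's DEG content is hypergeometrically over-represented.

    Returns the report dict, plus a dict of intermediate objects when
    ``return_objects`` is True.
    """
    contrasts = list(CONTRASTS) if contrasts is None else list(contrasts)
    logger.info("normalize: %d genes x %d samples", *counts.shape)
    norm = mean_center(normalize_log(counts, pseudocount=pseudocount))

    logger.info("state-space: full transcriptome (%d genes)", len(norm.genes))
    full_model, full_rot = _fit_rotated_space(norm, annotation, None, rotation_mode)
    full_plane = plane_coords(full_rot)
    full_plane_pre = plane_coords(full_model)

    # MI profiles per contrast (binning refit per contrast, or reused
    # from the 4-condition pooled fit)
    shared_binning = None
    if binning_mode == "reuse_condition4":
        samples4, _ = contrast_samples(annotation.loc[norm.samples], "condition4")
        shared_binning = fit_max_entropy_bins(norm.values[samples4].to_numpy(), k=3)
    profiles = {}
    for contrast in contrasts:
        logger.info("MI profile: contrast %s", contrast)
        profiles[contrast] = compute_mi_profile(
            norm, annotation, contrast, binning=shared_binning
        )

    # DEG stage (stand-in Welch caller or externally supplied flags)
    if external_deg_flags is not None:
        deg = degs_from_flags(external_deg_flags.reindex(norm.genes, fill_value=False), alpha)
    else:
        deg = call_degs_standin(norm, annotation, deg_groups, alpha=alpha)
    deg_genes = set(deg.deg_genes())
    logger.info("DEG stage (%s): %d DEGs at q < %g", deg.method, deg.n_deg, alpha)

    universe = set(norm.genes)
    set_reports = {}
    objects = {"norm": norm, "full_model": full_rot, "profiles": profiles, "deg": deg,
               "set_models": {}}
    for name in gene_sets.names():
        members = gene_sets[name]
        present = [g for g in members if g in universe]
        logger.info("gene set %s: %d/%d ids in universe", name, len(present), len(members))
        if not present:
            raise ValueError(f"gene set {name!r} shares no ids with the count matrix")

        sub_model, sub_rot = _fit_rotated_space(norm, annotation, present, rotation_mode)
        objects["set_models"][name] = sub_rot
        comp = compare_state_spaces(full_plane, plane_coords(sub_rot), axes=PLANE_AXES)
        comp_pre = compare_state_spaces(
            full_plane_pre, plane_coords(sub_model), axes=PLANE_AXES
        )

        mi_reports = {}
        for contrast, profile in profiles.items():
            dens = compare_mi_density(profile, present)
            mi_reports[contrast] = {
                "n_set": dens.n_set,
                "n_rest": dens.n_rest,
                "rank_sum_statistic": dens.rank_sum_statistic,
                "p_one_sided": dens.p_one_sided,
                "median_set": dens.median_set,
                "median_rest": dens.median_rest,
                "method": dens.method,
            }

        k_in_set = len(deg_genes & set(present))
        enr = hypergeom_test(len(universe), deg.n_deg, len(present), k_in_set)
        set_reports[name] = {
            "n_in_universe": len(present),
            "n_missing": len(members) - len(present),
            "space_comparison": {
                "r_squared_axis_disease": comp.r_squared_axis1,
                "r_squared_axis_genotype": comp.r_squared_axis2,
                "pre_rotation_r_squared_axis_disease": comp_pre.r_squared_axis1,
                "pre_rotation_r_squared_axis_genotype": comp_pre.r_squared_axis2,
                "rotation_angle_deg": sub_rot.rotation_angle_deg,
                "selected_axes": list(sub_rot.selected_axes),
                "elbow_index": sub_rot.elbow_index,
            },
            "mi_density": mi_reports,
            "deg_balance": {
                "N_universe": enr.N_universe,
                "K_deg": enr.K_deg,
                "n_set": enr.n_set,
                "k_deg_in_set": enr.k_deg_in_set,
                "p_hypergeometric": enr.p_hypergeometric,
                "tail": enr.tail,
            },
        }

    report = {
        "software": {"name": "statemi", "version": __version__},
        "seed": seed,
        "n_genes": int(counts.shape[0]),
        "n_samples": int(counts.shape[1]),
        "normalization": norm.metadata(),
        "state_space": {
            "elbow_index": full_rot.elbow_index,
            "selected_axes": list(full_rot.selected_axes),
            "rotation_angle_deg": full_rot.rotation_angle_deg,
            "singular_values": [float(s) for s in full_rot.singular_values],
            "separation_scores": {
                f: [float(v) for v in scores]
                for f, scores in full_rot.separation_scores.items()
            },
        },
        "deg": {
            "method": deg.method,
            "groups": list(deg_groups),
            "alpha": alpha,
            "n_deg": deg.n_deg,
        },
        "gene_sets": set_reports,
    }
    if return_objects:
        return report, objects
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based pipeline: read inputs, analyze, write artifacts.

    Writes per-space coordinate TSVs, a scree TSV, per-contrast MI TSVs,
    the DEG table, and `report.json` under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    counts = read_counts_tsv(config.counts)
    annotation = read_annotation_tsv(config.annotation)
    gene_sets = read_gmt(config.gene_sets)

    external = None
    if config.deg_mode != "standin":
        flags = pd.read_csv(config.deg_mode, sep="\t", index_col=0)
        external = flags["is_deg"].astype(bool)

    report, objects = analyze_dataset(
        counts,
        annotation,
        gene_sets,
        contrasts=config.contrasts,
        binning_mode=config.binning_mode,
        rotation_mode=config.rotation_mode,
        alpha=config.alpha,
        pseudocount=config.pseudocount,
        external_deg_flags=external,
        seed=config.seed,
        return_objects=True,
    )
    report["config"] = {
        **{k: v for k, v in dataclasses.asdict(config).items()},
        "deg_groups": list(config.deg_groups),
    }

    # artifacts
    full = objects["full_model"]
    coords = plane_coords(full)
    coords["condition"] = annotation.loc[coords.index, "condition"]
    coords.to_csv(out / "state_space_full.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame(
        {"component": np.arange(1, len(full.singular_values) + 1),
         "singular_value": full.singular_values}
    ).to_csv(out / "scree.tsv", sep="\t", index=False)
    for name, model in objects["set_models"].items():
        c = plane_coords(model)
        c["condition"] = annotation.loc[c.index, "condition"]
        c.to_csv(out / f"state_space_{name}.tsv", sep="\t", index_label="sample_id")
    for contrast, profile in objects["profiles"].items():
        tab = profile.mi.to_frame()
        for name in gene_sets.names():
            tab[f"in_{name}"] = tab.index.isin(gene_sets[name])
        tab.to_csv(out / f"mi_{contrast}.tsv", sep="\t", index_label="gene_id")
    objects["deg"].table.to_csv(out / "deg.tsv", sep="\t", index_label="gene_id")
    write_json(report, out / "report.json")
    logger.info("report written to %s", out / "report.json")
    return report
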