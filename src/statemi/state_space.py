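"""SVD state-spaces of transcriptomes and gene-set sub-spaces.

A state-space is the low-dimensional embedding of samples obtained from a
thin SVD of the mean-centered log-normalized gene-by-sample matrix: the
right singular vectors scaled by their singular values are the per-sample
coordinates ("sample scores"), the left singular vectors are the gene
loadings.  The two components that best separate the disease and genotype
factors define a 2-D plane which is then rotated so the disease axis of
variation lies along +x, making the embedding directly interpretable.
Sub-spaces built from a gene set alone are compared with the full-space
embedding axis-by-axis via squared Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from .preprocess import NormalizedMatrix

_FACTORS = ("leukemic", "genotype", "condition")


@dataclass
class StateSpaceModel:
    singular_values: np.ndarray
    sample_coords: pd.DataFrame  # samples x components, scaled by sigma
    gene_loadings: pd.DataFrame  # genes x components, orthonormal columns
    elbow_index: int  # 1-based scree elbow
    universe: list[str]
    selected_axes: tuple[int, int] | None = None  # 1-based (disease, genotype)
    rotation_angle_deg: float | None = None
    separation_scores: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(self.singular_values)


@dataclass
class SpaceComparison:
    """Axis-wise agreement between two embeddings of the same samples."""

    r_squared_axis1: float
    r_squared_axis2: float
    n_samples: int
    axes_compared: tuple[str, str]
    degenerate_axes: list[str] = field(default_factory=list)


def fit_state_space(
    matrix: NormalizedMatrix, universe: list[str] | None = None
) -> StateSpaceModel:
    """Thin SVD of the centered matrix, optionally restricted to a gene set.

    Components are ordered by descending singular value.  Each singular
    vector's sign is fixed so that its largest-magnitude gene loading is
    positive, removing the SVD sign ambiguity.

    Raises
    ------
    ValueError
        If the matrix is not centered, has fewer than 3 samples, or the
        universe is disjoint from the matrix genes.
    """
    if not matrix.centered:
        raise ValueError("state-space requires a mean-centered matrix")
    values = matrix.values
    if universe is not None:
        present = [g for g in universe if g in values.index]
        if not present:
            raise ValueError("gene universe is disjoint from the matrix genes")
        missing = sorted(set(universe) - set(present))
        if missing:
            warnings.warn(
                f"{len(missing)} universe gene(s) absent from matrix "
                f"(first few: {missing[:5]})"
            )
        values = values.loc[present]
    if values.shape[1] < 3:
        raise ValueError("state-space needs at least 3 samples")

    m = values.to_numpy()
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    # sign convention: largest-|loading| entry of each left vector positive
    for k in range(len(s)):
        j = np.argmax(np.abs(u[:, k]))
        if u[j, k] < 0:
            u[:, k] = -u[:, k]
            vt[k, :] = -vt[k, :]
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    coords = pd.DataFrame(vt.T * s, index=values.columns, columns=comp_names)
    loadings = pd.DataFrame(u, index=values.index, columns=comp_names)
    elbow = find_scree_elbow(s) if len(s) >= 3 else 1
    return StateSpaceModel(
        singular_values=s,
        sample_coords=coords,
        gene_loadings=loadings,
        elbow_index=elbow,
        universe=list(values.index),
    )


def find_scree_elbow(singular_values: np.ndarray) -> int:
    """Scree elbow: interior index with maximal perpendicular distance to
    the chord joining the first and last scree points (1-based).

    Ties go to the smallest interior index.
    """
    s = np.asarray(singular_values, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 singular values")
    if np.any(np.diff(s) > 1e-12 * max(1.0, np.abs(s).max())):
        raise ValueError("singular values must be nonincreasing")
    n = len(s)
    x = np.arange(1, n + 1, dtype=float)
    # distance from (x_i, s_i) to the line through (1, s_0) and (n, s_{n-1})
    dx, dy = n - 1.0, s[-1] - s[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dx * (s - s[0]) - dy * (x - 1.0)) / norm
    interior = dist[1 : n - 1]
    best = int(np.argmax(interior > interior.max() - 1e-12))
    return best + 2  # offset for the excluded first point, 1-based


def _separation_score(coords: np.ndarray, labels: np.ndarray) -> float:
    """Between-group sum of squares over total sum of squares, in [0, 1]."""
    grand = coords.mean()
    tss = np.sum((coords - grand) ** 2)
    if tss == 0:
        return 0.0
    bss = 0.0
    for lev in np.unique(labels):
        grp = coords[labels == lev]
        bss += len(grp) * (grp.mean() - grand) ** 2
    return float(bss / tss)


def score_axis_separation(
    model: StateSpaceModel, annotation: pd.DataFrame, factor: str
) -> np.ndarray:
    """Per-component separation of a sample factor along that component.

    ``factor`` is one of ``leukemic``, ``genotype`` or ``condition``
    (the 4-level cross).  Scores are stored on the model and returned.
    """
    if factor not in _FACTORS:
        raise ValueError(f"factor must be one of {_FACTORS}")
    samples = model.sample_coords.index
    if not set(samples).issubset(annotation.index):
        raise ValueError("annotation does not cover all samples")
    labels = annotation.loc[samples, factor].to_numpy()
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    small = levels[counts < 2]
    if len(small) > 0:
        warnings.warn(f"factor {factor!r} level(s) with <2 samples: {list(small)}")
    scores = np.array(
        [
            _separation_score(model.sample_coords.iloc[:, k].to_numpy(), labels)
            for k in range(model.n_components)
        ]
    )
    model.separation_scores[factor] = scores
    return scores


def select_axes(model: StateSpaceModel, annotation: pd.DataFrame) -> tuple[int, int]:
    """Pick the disease axis (top leukemic separation) and the genotype axis
    (top genotype separation among the remaining components); 1-based."""
    leuk = score_axis_separation(model, annotation, "leukemic")
    geno = score_axis_separation(model, annotation, "genotype")
    axis_disease = int(np.argmax(leuk))
    geno_masked = geno.copy()
    geno_masked[axis_disease] = -np.inf
    axis_genotype = int(np.argmax(geno_masked))
    model.selected_axes = (axis_disease + 1, axis_genotype + 1)
    return model.selected_axes


def rotate_plane(
    model: StateSpaceModel,
    angle_deg: float | None = None,
    annotation: pd.DataFrame | None = None,
    factor: str = "leukemic",
    positive_level: str = "CML",
) -> StateSpaceModel:
    """Rotate the selected (disease, genotype) plane by ``angle_deg``
    (counterclockwise, degrees), or in auto mode (``angle_deg=None``)
    by the angle that puts the vector from the non-``positive_level``
    centroid to the ``positive_level`` centroid along +x.

    All components outside the selected plane are untouched; the rotation
    is an isometry of the plane.
    """
    if model.selected_axes is None:
        raise ValueError("selected_axes must be set before rotation")
    i, j = (a - 1 for a in model.selected_axes)
    coords = model.sample_coords.to_numpy().copy()
    xy = coords[:, [i, j]]

    if angle_deg is None:
        if annotation is None:
            raise ValueError("auto rotation needs a sample annotation")
        labels = annotation.loc[model.sample_coords.index, factor].to_numpy()
        levels = np.unique(labels)
        if len(levels) != 2:
            raise ValueError("auto rotation requires a 2-level factor")
        pos = xy[labels == positive_level].mean(axis=0)
        neg = xy[labels != positive_level].mean(axis=0)
        d = pos - neg
        if np.hypot(*d) < 1e-12:
            raise ValueError("coincident centroids: rotation angle undefined")
        angle_deg = -float(np.degrees(np.arctan2(d[1], d[0])))

    theta = np.radians(angle_deg)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    coords[:, [i, j]] = xy @ rot.T
    new_coords = pd.DataFrame(
        coords, index=model.sample_coords.index, columns=model.sample_coords.columns
    )
    return replace(model, sample_coords=new_coords, rotation_angle_deg=float(angle_deg))


def compare_state_spaces(
    coords_full: pd.DataFrame,
    coords_subset: pd.DataFrame,
    axes: tuple[str, str] = ("PC1", "PC2"),
) -> SpaceComparison:
    """Axis-wise R^2 (squared Pearson correlation) between two embeddings.

    Both coordinate frames must contain the same samples in the same
    order, each already rotated per its own angle.  R^2 is invariant to
    sign flips and common scaling of either axis; a zero-variance axis is
    reported as NaN and flagged.
    """
    if list(coords_full.index) != list(coords_subset.index):
        raise ValueError("coordinate frames must cover the same samples in order")
    r2 = []
    degenerate = []
    for ax in axes:
        a = coords_full[ax].to_numpy()
        b = coords_subset[ax].to_numpy()
        if np.std(a) == 0 or np.std(b) == 0:
            r2.append(float("nan"))
            degenerate.append(ax)
            continue
        r, _ = scipy.stats.pearsonr(a, b)
        r2.append(float(r**2))
    return SpaceComparison(
        r_squared_axis1=r2[0],
        r_squared_axis2=r2[1],
        n_samples=len(coords_full),
        axes_compared=axes,
        degenerate_axes=degenerate,
    )
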