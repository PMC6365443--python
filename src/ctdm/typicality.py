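"""Axis-projection typicality scores and distance-based alternatives.

Given superimposed shapes from two groups, the cross-group
typicality/distinctiveness score of a specimen is its signed
orthogonal projection onto the unit vector running from one group
mean shape to the other (a two-group between-group principal
component). The score origin is the midpoint of the two means, so the
means themselves score exactly -PDM/2 and +PDM/2, where PDM is the
distance between the means. Distance-from-outgroup-mean (DfOM) and
distance-from-ingroup-mean (DfIM) are the unsigned alternatives.

All scores are computed on tangent-space coordinates, where the
Euclidean metric agrees with the Procrustes metric to high order; the
true partial Procrustes distance is available as an option for the
distance scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GroupError, ShapeMismatchError, SingularKernelError, UndefinedAxisError
from .superimposition import GPAResult, bending_energy_matrix, _tps_kernel, procrustes_distance

__all__ = [
    "TypicalityScores",
    "group_means",
    "ctdm_scores",
    "dfom_scores",
    "dfim_scores",
    "select_composite_anchors",
    "composite_shape",
    "tps_deformation_grid",
    "ANCHOR_ORDER",
]


def _labels_array(labels) -> np.ndarray:
    return np.asarray(labels, dtype=object)


def group_means(result: GPAResult, labels) -> dict:
    """Arithmetic mean of aligned tangent coordinates per group."""
    labels = _labels_array(labels)
    if labels.shape[0] != result.n_specimens:
        raise ValueError("labels length does not match the number of specimens")
    out = {}
    for g in pd.unique(labels):
        mask = labels == g
        if not mask.any():
            raise GroupError(f"group {g!r} is empty")
        out[g] = result.aligned[mask].mean(axis=0)
    return out


@dataclass
class TypicalityScores:
    """Per-specimen typicality scores along the between-group axis.

    ``ctdm`` is signed, in Procrustes units along the inter-mean axis,
    positive toward ``group_b``. ``dfom``/``dfim`` are each specimen's
    distance from the other/own group mean.
    """

    specimen_ids: list[str]
    group: np.ndarray
    ctdm: np.ndarray
    dfom: np.ndarray
    dfim: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    direction: np.ndarray  # unit vector (2k,) from mean_a toward mean_b
    origin: np.ndarray  # (k, 2) midpoint (or pooled-mean) shape scoring zero
    group_a: str
    group_b: str

    @property
    def pdm(self) -> float:
        """Distance between the two group means in tangent space."""
        return float(np.linalg.norm((self.mean_b - self.mean_a).ravel()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "specimen_id": self.specimen_ids,
                "group": self.group,
                "ctdm": self.ctdm,
                "dfom": self.dfom,
                "dfim": self.dfim,
            }
        )


def ctdm_scores(
    result: GPAResult,
    labels,
    group_a: str,
    group_b: str,
    origin: str = "midpoint",
    metric: str = "tangent-euclidean",
) -> TypicalityScores:
    """Project every specimen onto the axis between two group mean shapes.

    Scores are ``(x - origin) . direction`` on flattened tangent
    coordinates, with ``direction`` the unit vector from the mean of
    ``group_a`` toward the mean of ``group_b``; positive scores lie
    toward ``group_b``. The origin is the midpoint of the two means by
    default (``origin="pooled"`` uses the pooled specimen mean
    instead). DfOM/DfIM are filled in relative to each specimen's own
    group membership.
    """
    labels = _labels_array(labels)
    means = group_means(result, labels)
    for g in (group_a, group_b):
        if g not in means:
            raise GroupError(f"group {g!r} not present")
    mean_a, mean_b = means[group_a], means[group_b]
    axis = (mean_b - mean_a).ravel()
    pdm = np.linalg.norm(axis)
    if pdm <= 0.0:
        raise UndefinedAxisError("group means coincide; projection axis undefined")
    direction = axis / pdm
    if origin == "midpoint":
        origin_shape = (mean_a + mean_b) / 2.0
    elif origin == "pooled":
        origin_shape = result.aligned.mean(axis=0)
    else:
        raise ValueError("origin must be 'midpoint' or 'pooled'")
    flat = result.flat
    scores = (flat - origin_shape.ravel()) @ direction

    dfom = np.empty(result.n_specimens)
    dfim = np.empty(result.n_specimens)
    mask_a = labels == group_a
    mask_b = labels == group_b
    dfom[mask_a] = _distances(result.aligned[mask_a], mean_b, metric)
    dfom[mask_b] = _distances(result.aligned[mask_b], mean_a, metric)
    dfim[mask_a] = _distances(result.aligned[mask_a], mean_a, metric)
    dfim[mask_b] = _distances(result.aligned[mask_b], mean_b, metric)
    other = ~(mask_a | mask_b)
    dfom[other] = np.nan
    dfim[other] = np.nan

    ids = result.specimen_ids or [f"specimen_{i}" for i in range(result.n_specimens)]
    return TypicalityScores(
        specimen_ids=list(ids),
        group=labels,
        ctdm=scores,
        dfom=dfom,
        dfim=dfim,
        mean_a=mean_a,
        mean_b=mean_b,
        direction=direction,
        origin=origin_shape,
        group_a=group_a,
        group_b=group_b,
    )


def _distances(configs: np.ndarray, reference: np.ndarray, metric: str) -> np.ndarray:
    if metric == "tangent-euclidean":
        return np.linalg.norm(configs.reshape(len(configs), -1) - reference.ravel(), axis=1)
    if metric == "procrustes":
        return np.array([procrustes_distance(c, reference) for c in configs])
    raise ValueError("metric must be 'tangent-euclidean' or 'procrustes'")


def dfom_scores(result: GPAResult, labels, outgroup: str, metric: str = "tangent-euclidean") -> np.ndarray:
    """Distance of every specimen (all groups) from one outgroup's mean shape.

    The shorter the distance, the more typical the specimen is of the
    reference (outgroup) population.
    """
    labels = _labels_array(labels)
    means = group_means(result, labels)
    if outgroup not in means:
        raise GroupError(f"outgroup {outgroup!r} not present")
    return _distances(result.aligned, means[outgroup], metric)


def dfim_scores(result: GPAResult, labels, metric: str = "tangent-euclidean") -> np.ndarray:
    """Distance of every specimen from its own group's mean shape."""
    labels = _labels_array(labels)
    means = group_means(result, labels)
    out = np.empty(result.n_specimens)
    for g, m in means.items():
        mask = labels == g
        out[mask] = _distances(result.aligned[mask], m, metric)
    return out


# ---------------------------------------------------------------------------
# Composite anchor selection
# ---------------------------------------------------------------------------

ANCHOR_ORDER = (
    "a_farthest_from_b",
    "a_average",
    "a_closest_to_b",
    "b_closest_to_a",
    "b_average",
    "b_farthest_from_a",
)


def select_composite_anchors(scores: TypicalityScores, k: int = 6) -> dict[str, list[int]]:
    """Pick the k specimens nearest each of six score anchors.

    Within each group the anchors are the minimum, mean and maximum of
    that group's signed scores, yielding the six categories ordered
    along the axis: group A farthest from B, average A, A closest to B,
    B closest to A, average B, B farthest from A. For each anchor the k
    group members with smallest |score - anchor| are selected;
    ties break lexicographically on specimen id. Returns specimen
    indices into the underlying result.
    """
    anchors: dict[str, tuple[str, float]] = {}
    for key, grp, stat in (
        ("a_farthest_from_b", scores.group_a, "min"),
        ("a_average", scores.group_a, "mean"),
        ("a_closest_to_b", scores.group_a, "max"),
        ("b_closest_to_a", scores.group_b, "min"),
        ("b_average", scores.group_b, "mean"),
        ("b_farthest_from_a", scores.group_b, "max"),
    ):
        mask = scores.group == grp
        vals = scores.ctdm[mask]
        if mask.sum() < k:
            raise GroupError(f"group {grp!r} has fewer than k={k} members")
        anchor = {"min": vals.min(), "mean": vals.mean(), "max": vals.max()}[stat]
        anchors[key] = (grp, float(anchor))

    out: dict[str, list[int]] = {}
    for key, (grp, anchor) in anchors.items():
        members = [
            (abs(scores.ctdm[i] - anchor), scores.specimen_ids[i], i)
            for i in np.flatnonzero(scores.group == grp)
        ]
        members.sort(key=lambda t: (t[0], t[1]))
        out[key] = [i for _, _, i in members[:k]]
    return out


def composite_shape(result: GPAResult, indices) -> np.ndarray:
    """Mean of the selected aligned configurations."""
    indices = list(indices)
    if not indices:
        raise ValueError("empty index set")
    return result.aligned[indices].mean(axis=0)


# ---------------------------------------------------------------------------
# Thin-plate-spline deformation grids
# ---------------------------------------------------------------------------

def tps_deformation_grid(
    reference: np.ndarray,
    target: np.ndarray,
    magnification: float = 3.0,
    grid: tuple[int, int] = (24, 24),
    padding: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Warp a regular grid by the TPS interpolant between two mean shapes.

    The spline maps the reference landmarks to
    ``reference + magnification * (target - reference)``; the default
    three-fold magnification makes small mean-shape differences legible.
    Returns ``(grid_points, warped_points)``, each (rows*cols, 2), with
    the grid spanning the reference bounding box plus fractional
    padding.
    """
    ref = np.asarray(reference, float)
    tgt = np.asarray(target, float)
    if ref.shape != tgt.shape:
        raise ShapeMismatchError(f"shape mismatch: {ref.shape} vs {tgt.shape}")
    amplified = ref + magnification * (tgt - ref)

    k = ref.shape[0]
    d2 = np.sum((ref[:, None, :] - ref[None, :, :]) ** 2, axis=-1)
    off = d2[~np.eye(k, dtype=bool)]
    if off.size and off.min() <= 1e-24 * max(1.0, d2.max()):
        raise SingularKernelError("coincident reference landmarks")
    kmat = _tps_kernel(d2)
    q = np.column_stack([np.ones(k), ref])
    lmat = np.zeros((k + 3, k + 3))
    lmat[:k, :k] = kmat
    lmat[:k, k:] = q
    lmat[k:, :k] = q.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = amplified
    try:
        coefs = np.linalg.solve(lmat, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularKernelError("TPS system is singular") from exc
    w, aff = coefs[:k], coefs[k:]

    lo = ref.min(axis=0)
    hi = ref.max(axis=0)
    span = hi - lo
    lo = lo - padding * span
    hi = hi + padding * span
    gx = np.linspace(lo[0], hi[0], grid[0])
    gy = np.linspace(lo[1], hi[1], grid[1])
    xx, yy = np.meshgrid(gx, gy)
    pts = np.column_stack([xx.ravel(), yy.ravel()])

    d2p = np.sum((pts[:, None, :] - ref[None, :, :]) ** 2, axis=-1)
    u = _tps_kernel(d2p)
    warped = u @ w + np.column_stack([np.ones(len(pts)), pts]) @ aff
    return pts, warped
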