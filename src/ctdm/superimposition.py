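"""Procrustes superimposition for 2D landmark configurations.

Implements the standard geometric-morphometric toolchain: bilateral
symmetrization by reflected relabelling, full Generalized Procrustes
Analysis (unit centroid-size scaling, iterative rotation to the
consensus, orthogonal tangent-space projection) and semilandmark
sliding along curve tangents under the minimum bending-energy
criterion of the thin-plate spline.

Shapes are (k, 2) arrays throughout. After GPA all coordinates are
dimensionless Procrustes units: every specimen is scaled to unit
centroid size, so Euclidean distances between aligned specimens
approximate Procrustes distances to high order for small variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateShapeError,
    SchemaError,
    ShapeMismatchError,
    SingularKernelError,
)
from .landmark_io import LandmarkConfiguration, LandmarkSchema, ShapeSample

__all__ = [
    "GPAResult",
    "centroid_size",
    "center",
    "preshape",
    "optimal_rotation",
    "align_pair",
    "procrustes_distance",
    "gpa",
    "symmetrize",
    "symmetrize_sample",
    "reflect_relabel",
    "bending_energy_matrix",
    "bending_energy",
    "slide_to_reference",
    "slide_semilandmarks",
]


def centroid_size(config: np.ndarray | LandmarkConfiguration) -> float:
    """Square root of summed squared deviations of landmarks from their centroid.

    The standard size measure of geometric morphometrics; homogeneous of
    degree one under scaling.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if coords.shape[0] < 2:
        raise DegenerateShapeError("need at least two landmarks")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs <= 0.0:
        raise DegenerateShapeError("all landmarks coincide; centroid size is zero")
    return cs


def center(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, float)
    return coords - coords.mean(axis=0)


def preshape(coords: np.ndarray) -> np.ndarray:
    """Center and scale to unit centroid size."""
    c = center(coords)
    return c / centroid_size(c)


def optimal_rotation(
    config: np.ndarray, reference: np.ndarray, allow_reflection: bool = False
) -> np.ndarray:
    """2x2 rotation R minimizing ||config @ R - reference||_F.

    Closed form from the SVD of the cross-covariance matrix. With
    ``allow_reflection=False`` the determinant is constrained to +1.
    A vanishing cross-covariance leaves the optimum undetermined; the
    identity (the optimum closest to no rotation) is returned with a
    warning.
    """
    a = np.asarray(config, float)
    b = np.asarray(reference, float)
    h = a.T @ b
    norm = np.linalg.norm(h)
    if norm < 1e-15 * max(1.0, np.linalg.norm(a) * np.linalg.norm(b)):
        warnings.warn("cross-covariance is rank deficient; rotation undetermined, using identity")
        return np.eye(2)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    if allow_reflection:
        d = 1.0
    return u @ np.diag([1.0, d]) @ vt


def align_pair(
    config: np.ndarray, reference: np.ndarray, allow_reflection: bool = False
) -> np.ndarray:
    """Rotate a centered, unit-size configuration onto a reference pre-shape."""
    return np.asarray(config, float) @ optimal_rotation(config, reference, allow_reflection)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Root of the minimized summed squared differences after centering,
    unit-size scaling and optimal rotation. Symmetric; zero iff the
    shapes are identical up to a similarity transform.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    pa, pb = preshape(a), preshape(b)
    return float(np.linalg.norm(align_pair(pa, pb) - pb))


@dataclass
class GPAResult:
    """Superimposed, tangent-projected coordinates and the consensus shape.

    ``aligned`` holds one (k, 2) configuration per specimen in the
    tangent space at the consensus; ``consensus`` has unit centroid
    size and equals the mean of the aligned coordinates to within the
    convergence tolerance.
    """

    aligned: np.ndarray  # (n, k, 2)
    consensus: np.ndarray  # (k, 2)
    centroid_sizes: np.ndarray  # (n,)
    iterations: int
    converged: bool
    slid: bool = False
    specimen_ids: list[str] | None = None
    groups: np.ndarray | None = None
    energy_trace: list[float] = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def flat(self) -> np.ndarray:
        """(n, 2k) view of the aligned coordinates."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)


def _tangent_project(flat: np.ndarray, consensus_flat: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the tangent plane {y : y . c = |c|^2} at c."""
    c = consensus_flat / np.linalg.norm(consensus_flat)
    excess = flat @ c - np.linalg.norm(consensus_flat)
    return flat - np.outer(excess, c)


def gpa(
    sample: ShapeSample | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
    project: bool = True,
) -> GPAResult:
    """Generalized Procrustes Analysis.

    All configurations are centered and scaled to unit centroid size,
    iteratively rotated to the current consensus, and the consensus
    (mean shape, re-normalized to unit size) re-estimated until its
    root-mean-square change drops below ``tol``. The final coordinates
    are orthogonally projected onto the tangent plane at the consensus
    unless ``project=False``.
    """
    ids: list[str] | None = None
    groups = None
    if isinstance(sample, ShapeSample):
        coords = sample.coords_array()
        ids = sample.specimen_ids
        groups = sample.groups
    else:
        coords = np.asarray(sample, float)
    n, k, _ = coords.shape
    if n < 2:
        raise ValueError("GPA needs at least two specimens")
    sizes = np.empty(n)
    shapes = np.empty_like(coords)
    for i in range(n):
        c = center(coords[i])
        sizes[i] = centroid_size(coords[i])
        shapes[i] = c / sizes[i]

    consensus = shapes[0].copy()
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            shapes[i] = align_pair(shapes[i], consensus)
        new_consensus = shapes.mean(axis=0)
        new_consensus = center(new_consensus)
        new_consensus /= centroid_size(new_consensus)
        change = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"GPA did not converge in {max_iter} iterations")

    aligned = shapes
    if project:
        flat = shapes.reshape(n, -1)
        flat = _tangent_project(flat, consensus.reshape(-1))
        aligned = flat.reshape(n, k, 2)
    return GPAResult(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
        specimen_ids=ids,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# Symmetrization
# ---------------------------------------------------------------------------

def reflect_relabel(coords: np.ndarray, schema: LandmarkSchema) -> np.ndarray:
    """Mirror a configuration across the vertical axis and swap bilateral pairs."""
    if not schema.supports_symmetrization:
        raise SchemaError(
            "schema pairs + midline do not cover all landmarks; cannot symmetrize"
        )
    out = np.asarray(coords, float) * np.array([-1.0, 1.0])
    out = out.copy()
    for i, j in schema.pairs:
        out[[i, j]] = out[[j, i]]
    return out


def symmetrize(
    config: LandmarkConfiguration | np.ndarray, schema: LandmarkSchema
) -> LandmarkConfiguration | np.ndarray:
    """Remove bilateral asymmetry by reflected relabelling.

    The configuration is mirrored, its left/right homologues swapped,
    the relabelled reflection rigidly aligned (rotation + translation,
    no reflection) to the original, and the two averaged. The output is
    exactly symmetric under the same reflect-relabel operation, which
    makes the procedure idempotent.
    """
    is_config = isinstance(config, LandmarkConfiguration)
    coords = config.coords if is_config else np.asarray(config, float)
    centroid = coords.mean(axis=0)
    x = coords - centroid
    y = reflect_relabel(x, schema)
    y = y - y.mean(axis=0)
    y = align_pair(y, x)
    sym = (x + y) / 2.0 + centroid
    if is_config:
        return config.copy_with(sym)
    return sym


def symmetrize_sample(sample: ShapeSample, schema: LandmarkSchema | None = None) -> ShapeSample:
    schema = schema or sample.schema
    if schema is None:
        raise SchemaError("symmetrization requires a schema")
    return ShapeSample(
        configurations=[symmetrize(c, schema) for c in sample],
        schema=schema,
        provenance=sample.provenance,
    )


# ---------------------------------------------------------------------------
# Thin-plate spline bending energy
# ---------------------------------------------------------------------------

def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2 with U(0) = 0, evaluated from squared distances."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    return np.where(r2 > 0.0, out, 0.0)


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Bending-energy matrix of the thin-plate spline at a reference shape.

    The k x k upper-left block of the inverse of the bordered TPS system
    ``[[K, Q], [Q^T, 0]]`` with K the kernel matrix and Q = [1 | x | y].
    Positive semi-definite with the affine configurations in its null
    space.
    """
    ref = np.asarray(reference, float)
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
    try:
        linv = np.linalg.inv(lmat)
    except np.linalg.LinAlgError as exc:
        raise SingularKernelError("TPS system is singular") from exc
    be = linv[:k, :k]
    return (be + be.T) / 2.0  # symmetrize away round-off


def bending_energy(reference: np.ndarray, target: np.ndarray, be_matrix: np.ndarray | None = None) -> float:
    """Thin-plate-spline bending energy of the deformation reference -> target.

    Quadratic form of the target coordinates in the bending-energy
    matrix of the reference, summed over the x and y dimensions. Zero
    for any affine image of the reference.
    """
    ref = np.asarray(reference, float)
    tgt = np.asarray(target, float)
    if ref.shape != tgt.shape:
        raise ShapeMismatchError(f"shape mismatch: {ref.shape} vs {tgt.shape}")
    if be_matrix is None:
        be_matrix = bending_energy_matrix(ref)
    e = float(np.einsum("id,ij,jd->", tgt, be_matrix, tgt))
    return max(e, 0.0)


# ---------------------------------------------------------------------------
# Semilandmark sliding
# ---------------------------------------------------------------------------

def _curve_tangents(coords: np.ndarray, schema: LandmarkSchema) -> tuple[list[int], np.ndarray]:
    """Unit tangent (chord through flanking curve neighbours) per semilandmark.

    Returns the sliding landmark indices and their tangent directions;
    semilandmarks with coincident neighbours are frozen with a warning.
    """
    idx: list[int] = []
    tangents: list[np.ndarray] = []
    for curve in schema.curves:
        for pos in range(1, len(curve) - 1):
            j = curve[pos]
            t = coords[curve[pos + 1]] - coords[curve[pos - 1]]
            norm = np.linalg.norm(t)
            if norm < 1e-12:
                warnings.warn(f"semilandmark {j}: coincident neighbours, frozen")
                continue
            idx.append(j)
            tangents.append(t / norm)
    return idx, np.array(tangents) if tangents else np.empty((0, 2))


def slide_to_reference(
    coords: np.ndarray,
    reference: np.ndarray,
    schema: LandmarkSchema,
    be_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Slide one specimen's semilandmarks to minimize bending energy.

    Each semilandmark moves only along its local tangent (the chord
    through its flanking curve neighbours); the vector of slide offsets
    solves the linear system of the resulting convex quadratic in
    closed form.
    """
    coords = np.asarray(coords, float)
    if be_matrix is None:
        be_matrix = bending_energy_matrix(reference)
    idx, tangents = _curve_tangents(coords, schema)
    if not idx:
        return coords.copy()
    b_ss = be_matrix[np.ix_(idx, idx)]
    gram = tangents @ tangents.T
    a = b_ss * gram
    bp = be_matrix @ coords  # (k, 2)
    rhs = -np.einsum("md,md->m", tangents, bp[idx])
    d, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    out = coords.copy()
    out[idx] += d[:, None] * tangents
    return out


def slide_semilandmarks(
    result: GPAResult,
    schema: LandmarkSchema,
    max_cycles: int = 5,
    tol: float = 1e-10,
    gpa_tol: float = 1e-10,
) -> GPAResult:
    """Iteratively slide semilandmarks against the consensus and re-run GPA.

    Each cycle slides every specimen (closed-form minimum of the
    linearized bending-energy problem, tangents from the specimen's own
    current curve geometry), re-superimposes, and re-evaluates the total
    bending energy against the updated consensus. A cycle that fails to
    decrease the total energy is rolled back, so the returned total is
    never above the input's; the per-cycle totals are recorded in
    ``energy_trace``.
    """
    if not schema.curves:
        raise SchemaError("schema has no curves; nothing to slide")
    aligned = result.aligned.copy()
    consensus = result.consensus.copy()

    def total_energy(coords: np.ndarray, cons: np.ndarray) -> float:
        bem = bending_energy_matrix(cons)
        return float(sum(bending_energy(cons, c, bem) for c in coords))

    energy = total_energy(aligned, consensus)
    trace = [energy]
    for _ in range(max_cycles):
        bem = bending_energy_matrix(consensus)
        slid = np.stack(
            [slide_to_reference(c, consensus, schema, bem) for c in aligned]
        )
        res = gpa(slid, tol=gpa_tol)
        new_energy = total_energy(res.aligned, res.consensus)
        if new_energy > energy + tol:
            break  # linearization overstepped; keep the previous state
        improved = energy - new_energy
        aligned, consensus, energy = res.aligned, res.consensus, new_energy
        trace.append(energy)
        if improved < tol:
            break
    return GPAResult(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=result.centroid_sizes,
        iterations=result.iterations,
        converged=result.converged,
        slid=True,
        specimen_ids=result.specimen_ids,
        groups=result.groups,
        energy_trace=trace,
    )
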