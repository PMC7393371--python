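"""Landmark-based geometric morphometrics of the stylet.

The stylet (the male copulatory organ) of each specimen is described by 60
ordered 2-D landmarks: two fixed landmarks each on the tip and base
(ordinals 1, 30, 31, 60) and 28 sliding semilandmarks along each of the two
curved sides (ordinals 2-29 on the side further from the seminal vesicle,
32-59 on the nearer side).  Semilandmarks have no point-to-point homology
along their curve and are allowed to slide along the local tangent during
superimposition.

The analysis chain is:

1. **generalized Procrustes analysis (GPA)** — centre each configuration,
   scale to unit centroid size, and rotate (reflections disallowed; chirality
   is handled upstream by explicit mirroring) to minimise summed squared
   distance to an iteratively updated consensus;
2. **semilandmark sliding** — move each semilandmark along its tangent
   (the chord between its curve neighbours) to minimise either the
   thin-plate-spline bending energy against the consensus (default) or the
   Procrustes distance; re-superimpose and iterate;
3. **relative warps** — with weighting exponent alpha = 0, a principal
   component decomposition of the aligned coordinates about the consensus;
   the first score (RWS1) is the dominant axis of shape variation;
4. **thin-plate-spline grids** for visualising the consensus-to-target
   deformation.

Centroid size (the square root of the summed squared landmark distances
from their centroid) is the associated size measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

from . import traits as _traits

logger = logging.getLogger(__name__)

N_LANDMARKS = 60
#: 1-based ordinals of the fixed landmarks: tip and base of each curve.
FIXED_ORDINALS = (1, 30, 31, 60)
#: 0-based index ranges of the two semilandmark curves.
CURVES = (tuple(range(0, 30)), tuple(range(30, 60)))

GPA_TOL = 1e-10
GPA_MAX_ITER = 100
SLIDE_TOL = 1e-8
SLIDE_MAX_ITER = 20


def default_fixed_mask(n: int = N_LANDMARKS) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for ordinal in FIXED_ORDINALS:
        mask[ordinal - 1] = True
    return mask


@dataclass
class LandmarkConfiguration:
    """One specimen's 60 ordered stylet landmarks in image units."""

    specimen_id: str
    group: str
    points: np.ndarray
    fixed_mask: np.ndarray = field(default_factory=default_fixed_mask)
    curves: tuple = CURVES
    mirrored: bool = False
    scale: Optional[float] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
        if self.points.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"{self.specimen_id}: expected {N_LANDMARKS} 2-D landmarks, "
                f"got shape {self.points.shape}"
            )
        if self.fixed_mask.shape != (N_LANDMARKS,) or self.fixed_mask.sum() != 4:
            raise ValueError(
                f"{self.specimen_id}: fixed mask must flag exactly 4 of "
                f"{N_LANDMARKS} landmarks"
            )
        for curve in self.curves:
            pts = self.points[list(curve)]
            if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
                raise ValueError(
                    f"{self.specimen_id}: duplicate consecutive landmarks "
                    "on a curve"
                )

    @property
    def centroid_size(self) -> float:
        return centroid_size(self.points)


def centroid_size(points: np.ndarray | LandmarkConfiguration) -> float:
    """sqrt of summed squared landmark distances from their centroid."""
    pts = points.points if isinstance(points, LandmarkConfiguration) else (
        np.asarray(points, dtype=float)
    )
    if len(pts) < 2:
        raise ValueError("centroid size needs at least 2 landmarks")
    centred = pts - pts.mean(axis=0)
    cs = float(np.sqrt(np.sum(centred**2)))
    if cs == 0:
        raise ValueError("all landmarks coincide; centroid size undefined")
    return cs


def mirror_configuration(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Negate x coordinates (landmark order preserved), toggle the flag.

    Used to bring specimens imaged from the dorsal side into the ventral
    orientation before alignment, since reflections are disallowed in GPA.
    """
    pts = config.points.copy()
    pts[:, 0] = -pts[:, 0]
    return replace(config, points=pts, mirrored=not config.mirrored)


# --------------------------------------------------------------------------
# superimposition


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation matrix (det +1, no reflection) minimising ||source R - target||."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Both shapes are centred and scaled to unit centroid size, b is rotated
    onto a (no reflection), and the root summed squared difference returned.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = (a - a.mean(axis=0)) / centroid_size(a)
    b = (b - b.mean(axis=0)) / centroid_size(b)
    r = _optimal_rotation(b, a)
    return float(np.linalg.norm(b @ r - a))


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Deterministic orientation for a consensus shape.

    Rotates the principal axis of the landmark scatter onto x; the residual
    180-degree ambiguity is fixed by the sign of the third moment of the
    x coordinates (falling back to y if degenerate).  Makes GPA output
    reproducible regardless of how the inputs happened to be oriented.
    """
    cov = consensus.T @ consensus
    evals, evecs = np.linalg.eigh(cov)
    r = evecs[:, ::-1]  # columns: major, minor axis
    if np.linalg.det(r) < 0:
        r[:, 1] = -r[:, 1]
    rotated = consensus @ r
    m3 = float(np.sum(rotated[:, 0] ** 3))
    if abs(m3) < 1e-12:
        m3 = float(np.sum(rotated[:, 1] ** 3))
    if m3 < 0:
        r = -r  # 180-degree rotation, det stays +1
    return r


@dataclass
class ShapeDecomposition:
    """GPA consensus, aligned shapes, and (optionally) relative warps."""

    specimen_ids: list
    groups: list
    consensus: np.ndarray  # (k, 2), unit centroid size
    aligned: np.ndarray  # (n, k, 2)
    centroid_sizes: np.ndarray  # (n,)
    scores: Optional[np.ndarray] = None  # (n, n_warps)
    variance_explained: Optional[np.ndarray] = None  # percent, sums to 100
    eigenvectors: Optional[np.ndarray] = None  # (n_warps, 2k)
    n_iterations: int = 0

    @property
    def n_warps(self) -> int:
        return 0 if self.scores is None else self.scores.shape[1]

    def rws(self, i: int = 1) -> np.ndarray:
        """The i-th relative warp score per specimen (1-based)."""
        if self.scores is None:
            raise ValueError("relative warps not computed yet")
        return self.scores[:, i - 1]


def _as_point_arrays(
    configs: Sequence[LandmarkConfiguration] | Sequence[np.ndarray],
) -> tuple[np.ndarray, list, list]:
    pts, ids, groups = [], [], []
    for i, c in enumerate(configs):
        if isinstance(c, LandmarkConfiguration):
            pts.append(c.points)
            ids.append(c.specimen_id)
            groups.append(c.group)
        else:
            pts.append(np.asarray(c, dtype=float))
            ids.append(str(i))
            groups.append("")
    k = {p.shape for p in pts}
    if len(k) != 1:
        raise ValueError(f"configurations disagree in landmark count: {k}")
    return np.stack(pts), ids, groups


def gpa_align(
    configs: Sequence[LandmarkConfiguration] | Sequence[np.ndarray],
    tol: float = GPA_TOL,
    max_iter: int = GPA_MAX_ITER,
) -> ShapeDecomposition:
    """Generalized Procrustes superimposition (no reflections).

    Each configuration is centred, scaled to unit centroid size, and rotated
    to the consensus; the consensus (the aligned mean, rescaled to unit
    size) is iterated until it changes by less than ``tol``.  The result is
    brought into a canonical orientation so output does not depend on input
    order or on similarity transforms applied to any input.
    """
    raw, ids, groups = _as_point_arrays(configs)
    n = raw.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least two configurations")
    sizes = np.array([centroid_size(p) for p in raw])
    shapes = np.stack(
        [(p - p.mean(axis=0)) / s for p, s in zip(raw, sizes)]
    )

    consensus = shapes.mean(axis=0)
    cs = np.linalg.norm(consensus)
    if cs < 1e-12:
        # degenerate init (inputs in opposing orientations): seed from one shape
        consensus = shapes[0].copy()
    else:
        consensus = consensus / cs

    aligned = shapes.copy()
    for iteration in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.linalg.norm(new_consensus)
        change = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus change {change:.3e})"
        )

    r = _canonical_rotation(consensus)
    consensus = consensus @ r
    for i in range(n):
        aligned[i] = aligned[i] @ r

    return ShapeDecomposition(
        specimen_ids=ids,
        groups=groups,
        consensus=consensus,
        aligned=aligned,
        centroid_sizes=sizes,
        n_iterations=iteration,
    )


# --------------------------------------------------------------------------
# thin-plate spline and bending energy


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2 with U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


def _tps_system(source: np.ndarray) -> np.ndarray:
    """The (k+3) x (k+3) thin-plate-spline system matrix L for 2-D points."""
    k = len(source)
    d2 = np.sum((source[:, None, :] - source[None, :, :]) ** 2, axis=-1)
    kmat = _tps_kernel(d2)
    p = np.column_stack([np.ones(k), source])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = kmat
    L[:k, k:] = p
    L[k:, :k] = p.T
    return L


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Bending-energy matrix of a reference configuration.

    The upper-left k x k block of L^-1; the bending energy of a deformation
    sending the reference to target y is y_x' B y_x + y_y' B y_y.  Symmetric
    positive semidefinite with the affine maps in its null space.
    """
    k = len(reference)
    L = _tps_system(np.asarray(reference, float))
    try:
        linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular TPS system: reference landmarks degenerate (collinear "
            "or coincident)"
        ) from exc
    b = linv[:k, :k]
    return (b + b.T) / 2.0


@dataclass
class TpsGrid:
    """A deformation grid mapping the reference square lattice to the target."""

    reference_grid: np.ndarray  # (ny, nx, 2)
    deformed_grid: np.ndarray  # (ny, nx, 2)
    bending_energy: float
    source: np.ndarray
    target: np.ndarray


def tps_fit(source: np.ndarray, target: np.ndarray):
    """Fit a 2-D thin-plate spline interpolant source -> target.

    Returns ``(evaluate, bending_energy)`` where ``evaluate(points)`` maps
    arbitrary (m, 2) points and the interpolation is exact at the source
    landmarks.  Raises on a singular (degenerate) landmark system.
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 2:
        raise ValueError("source and target must be matching (k, 2) arrays")
    k = len(source)
    L = _tps_system(source)
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = target
    try:
        coefs = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular TPS system: source landmarks degenerate"
        ) from exc
    w, a = coefs[:k], coefs[k:]
    kmat = _tps_kernel(
        np.sum((source[:, None, :] - source[None, :, :]) ** 2, axis=-1)
    )
    be = float(np.trace(w.T @ kmat @ w))

    def evaluate(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        d2 = np.sum((pts[:, None, :] - source[None, :, :]) ** 2, axis=-1)
        u = _tps_kernel(d2)
        p = np.column_stack([np.ones(len(pts)), pts])
        return u @ w + p @ a

    return evaluate, be


def tps_grid(
    consensus: np.ndarray,
    target: np.ndarray,
    grid_density: int = 24,
    margin: float = 0.1,
) -> TpsGrid:
    """Deformation grid for visualising the consensus-to-target TPS.

    A ``grid_density`` x ``grid_density`` lattice spanning the consensus
    bounding box (plus ``margin``) is mapped through the interpolant.
    """
    consensus = np.asarray(consensus, float)
    target = np.asarray(target, float)
    evaluate, be = tps_fit(consensus, target)
    lo = consensus.min(axis=0)
    hi = consensus.max(axis=0)
    span = hi - lo
    lo = lo - margin * span
    hi = hi + margin * span
    xs = np.linspace(lo[0], hi[0], grid_density)
    ys = np.linspace(lo[1], hi[1], grid_density)
    gx, gy = np.meshgrid(xs, ys)
    ref = np.stack([gx, gy], axis=-1)
    deformed = evaluate(ref.reshape(-1, 2)).reshape(ref.shape)
    return TpsGrid(
        reference_grid=ref,
        deformed_grid=deformed,
        bending_energy=be,
        source=consensus,
        target=target,
    )


# --------------------------------------------------------------------------
# semilandmark sliding


def _tangent_directions(
    points: np.ndarray, curves: Sequence[Sequence[int]], sliding: np.ndarray
) -> np.ndarray:
    """Unit tangent per sliding landmark: chord between its curve neighbours."""
    tangents = np.zeros_like(points)
    for curve in curves:
        curve = list(curve)
        for pos in range(1, len(curve) - 1):
            i = curve[pos]
            if not sliding[i]:
                continue
            chord = points[curve[pos + 1]] - points[curve[pos - 1]]
            norm = np.linalg.norm(chord)
            if norm < 1e-12:
                raise ValueError(
                    f"degenerate tangent at landmark {i + 1}: curve "
                    "neighbours coincide"
                )
            tangents[i] = chord / norm
    return tangents


def _slide_caps(
    points: np.ndarray, curves: Sequence[Sequence[int]], sliding_idx: np.ndarray
) -> np.ndarray:
    """Max slide distance per sliding landmark: half the nearer-neighbour gap.

    Keeps the tangent linearisation valid (semilandmarks stay near their
    stretch of curve) and makes the bending-energy iteration stable.
    """
    caps = np.full(len(points), np.inf)
    for curve in curves:
        curve = list(curve)
        for pos in range(1, len(curve) - 1):
            i = curve[pos]
            d_prev = np.linalg.norm(points[i] - points[curve[pos - 1]])
            d_next = np.linalg.norm(points[i] - points[curve[pos + 1]])
            caps[i] = 0.5 * min(d_prev, d_next)
    return caps[sliding_idx]


def _slide_one(
    shape: np.ndarray,
    consensus: np.ndarray,
    tangents: np.ndarray,
    sliding_idx: np.ndarray,
    be_matrix: Optional[np.ndarray],
    caps: np.ndarray,
) -> np.ndarray:
    """One sliding update of a single aligned shape against the consensus."""
    resid = shape - consensus
    if be_matrix is None:
        # chord (Procrustes distance) criterion: independent projections
        t = -np.einsum("ij,ij->i", resid[sliding_idx], tangents[sliding_idx])
    else:
        u = tangents[sliding_idx]  # (m, 2)
        b_ss = be_matrix[np.ix_(sliding_idx, sliding_idx)]
        # A[j,l] = u_j . u_l * B[j,l]; rhs_j = -u_j . (B @ resid)_j
        a = (u @ u.T) * b_ss
        rhs = -np.einsum(
            "ij,ij->i", u, (be_matrix @ resid)[sliding_idx]
        )
        t = np.linalg.lstsq(a, rhs, rcond=None)[0]
    # scale the whole step so every slide respects its cap; for a convex
    # quadratic any fraction of the Newton step still decreases the objective
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = caps / np.abs(t)
    scale = min(1.0, float(np.nanmin(ratios))) if len(t) else 1.0
    out = shape.copy()
    out[sliding_idx] += (scale * t)[:, None] * tangents[sliding_idx]
    return out


def slide_semilandmarks(
    decomp: ShapeDecomposition,
    fixed_mask: Optional[np.ndarray] = None,
    curves: Sequence[Sequence[int]] = CURVES,
    criterion: Literal["bending", "chord"] = "bending",
    tol: float = SLIDE_TOL,
    max_iter: int = SLIDE_MAX_ITER,
    realign: bool = True,
) -> ShapeDecomposition:
    """Slide semilandmarks along their tangents and re-superimpose.

    Every non-fixed landmark interior to a curve slides along the chord
    between its curve neighbours so as to minimise, per specimen, either the
    thin-plate-spline bending energy of the consensus-to-specimen deformation
    (``criterion="bending"``, the default) or the Procrustes distance to the
    consensus (``"chord"``).  Fixed landmarks never move.  After each pass
    the set is re-aligned by GPA and the consensus updated; iteration stops
    when the summed objective decreases by less than ``tol``.
    ``realign=False`` performs a single sliding pass against the current
    consensus without re-superimposing (fixed landmarks then keep their
    exact coordinates).

    The objective trace is attached to the returned decomposition as
    ``slide_trace`` (one value per outer iteration, evaluated before each
    sliding pass).
    """
    if fixed_mask is None:
        fixed_mask = default_fixed_mask(decomp.consensus.shape[0])
    sliding = ~np.asarray(fixed_mask, bool)
    sliding_idx = np.flatnonzero(sliding)
    aligned = decomp.aligned.copy()
    consensus = decomp.consensus.copy()
    n = aligned.shape[0]

    def objective(shapes: np.ndarray, cons: np.ndarray) -> float:
        if criterion == "chord":
            return float(np.sum((shapes - cons) ** 2))
        b = bending_energy_matrix(cons)
        resid = shapes - cons
        return float(
            sum(np.trace(r.T @ b @ r) for r in resid)
        )

    trace = [objective(aligned, consensus)]
    for _ in range(1 if not realign else max_iter):
        prev_aligned, prev_consensus = aligned.copy(), consensus.copy()
        be = bending_energy_matrix(consensus) if criterion == "bending" else None
        for i in range(n):
            tangents = _tangent_directions(aligned[i], curves, sliding)
            caps = _slide_caps(aligned[i], curves, sliding_idx)
            aligned[i] = _slide_one(
                aligned[i], consensus, tangents, sliding_idx, be, caps
            )
        if not realign:
            trace.append(objective(aligned, consensus))
            break
        re = gpa_align(list(aligned))
        aligned, consensus = re.aligned, re.consensus
        new_obj = objective(aligned, consensus)
        if new_obj > trace[-1]:
            # consensus re-estimation stopped helping; keep the best state
            aligned, consensus = prev_aligned, prev_consensus
            break
        improved = trace[-1] - new_obj
        trace.append(new_obj)
        if improved < tol * max(1.0, abs(trace[-1])):
            break

    out = ShapeDecomposition(
        specimen_ids=decomp.specimen_ids,
        groups=decomp.groups,
        consensus=consensus,
        aligned=aligned,
        centroid_sizes=decomp.centroid_sizes,
        n_iterations=len(trace) - 1,
    )
    out.slide_trace = trace  # type: ignore[attr-defined]
    # fixed landmarks are re-rotated with the whole shape but never slide
    return out


# --------------------------------------------------------------------------
# relative warps


def relative_warps(
    decomp: ShapeDecomposition,
    alpha: float = 0.0,
    variance_tol: float = 1e-8,
) -> ShapeDecomposition:
    """Relative-warp decomposition of aligned shapes about the consensus.

    With ``alpha = 0`` (the default, and the only setting under which RWS1
    is a plain principal component) this is the singular value decomposition
    of the centred, flattened aligned coordinates.  ``alpha != 0`` reweights
    the non-affine shape space by bending energy: eigendirections of the
    consensus bending-energy matrix are scaled by lambda^(-alpha/2), so
    positive alpha emphasises large-scale (low bending energy) deformation.

    Warps with singular value below ``variance_tol`` times the largest are
    treated as numerically zero and dropped; ``variance_explained`` sums to
    100% over the retained warps.
    """
    n, k, _ = decomp.aligned.shape
    if n < 3:
        raise ValueError("relative warps need at least 3 specimens")
    flat = decomp.aligned.reshape(n, 2 * k)
    centred = flat - flat.mean(axis=0)

    if alpha != 0.0:
        b = bending_energy_matrix(decomp.consensus)
        evals, evecs = np.linalg.eigh(b)
        evals = np.clip(evals, 0, None)
        nonaffine = evals > evals.max() * 1e-10
        w = np.ones_like(evals)
        w[nonaffine] = evals[nonaffine] ** (-alpha / 2.0)
        # weight x and y coordinate blocks identically
        basis = np.kron(evecs, np.eye(2))
        weights = np.repeat(w, 2)
        centred = (centred @ basis) * weights @ basis.T

    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    keep = s > s[0] * variance_tol if s[0] > 0 else np.zeros_like(s, bool)
    s = s[keep]
    scores = u[:, keep] * s
    var = s**2
    return ShapeDecomposition(
        specimen_ids=decomp.specimen_ids,
        groups=decomp.groups,
        consensus=decomp.consensus,
        aligned=decomp.aligned,
        centroid_sizes=decomp.centroid_sizes,
        scores=scores,
        variance_explained=100.0 * var / var.sum(),
        eigenvectors=vt[keep],
        n_iterations=decomp.n_iterations,
    )


def shape_along_warp(decomp: ShapeDecomposition, warp: int, score: float
                     ) -> np.ndarray:
    """Model shape at a given score along one relative warp (1-based)."""
    if decomp.eigenvectors is None:
        raise ValueError("relative warps not computed yet")
    k = decomp.consensus.shape[0]
    mean_flat = decomp.aligned.reshape(len(decomp.aligned), -1).mean(axis=0)
    flat = mean_flat + score * decomp.eigenvectors[warp - 1]
    return flat.reshape(k, 2)


def compare_shape_groups(
    decomp: ShapeDecomposition, alpha: float = 0.05
) -> dict:
    """ANOVA + Tukey HSD on centroid size and RWS1 across specimen groups.

    Returns ``{"centroid_size": GroupComparison, "rws1": GroupComparison}``
    with letter groupings at the chosen alpha.
    """
    import pandas as pd

    if decomp.scores is None:
        decomp = relative_warps(decomp)
    table = pd.DataFrame(
        {
            "group": decomp.groups,
            "centroid_size": decomp.centroid_sizes,
            "rws1": decomp.rws(1),
        }
    )
    out = {}
    for var in ("centroid_size", "rws1"):
        out[var] = _traits.compare_groups(
            var, table, family="parametric", alpha=alpha,
            group_col="group", log_transform=False,
        )
    return out
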