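"""Systematic blind rigid-body docking over the whole receptor surface.

Starting points are placed on an offset surface at twice the peptide
radius from the receptor surface, roughly 10 A apart; at each start a
deterministic set of 260 peptide orientations is tried and each
(start, orientation) pair is relaxed by quasi-Newton minimization of
the coarse-grained interaction energy over the six rigid-body degrees
of freedom.  Minimized poses are ranked by energy.  Starts are
independent, so the loop parallelizes; the output is identical for any
worker count.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from concurrent.futures import ProcessPoolExecutor

import numpy as np
from scipy.optimize import fmin_l_bfgs_b
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .coarse_grain import ReducedModel
from .confgen import Conformer
from .energy import EnergyBreakdown, InteractionEvaluator
from .geometry import RigidPose, fibonacci_sphere, right_jacobian, \
    rotation_to_axis

logger = logging.getLogger(__name__)

__all__ = ["DockSettings", "StartPoint", "DockedPose", "peptide_radius",
           "generate_start_points", "generate_orientations", "minimize_pose",
           "dock_conformer", "merge_and_rank"]


@dataclasses.dataclass
class DockSettings:
    """Tunable docking parameters (defaults follow the published protocol
    where it states values: 10 A start spacing, 260 orientations)."""

    spacing: float = 10.0
    n_orientations: int = 260
    cutoff: float = 20.0
    gtol: float = 0.05          # kcal/mol/A, inf-norm convergence
    maxiter: int = 500
    maxfun: int = 2000          # energy-evaluation budget per start
    workers: int = 1


@dataclasses.dataclass(frozen=True)
class StartPoint:
    """A docking start: offset-surface position and its surface anchor."""

    position: np.ndarray
    surface_anchor: np.ndarray


@dataclasses.dataclass(frozen=True)
class DockedPose:
    """A minimized rigid pose with its energy and provenance."""

    pose: RigidPose
    energy: EnergyBreakdown
    conformer_id: int
    start_id: int
    orientation_id: int

    @property
    def sort_key(self):
        return (self.energy.total, self.conformer_id, self.start_id,
                self.orientation_id)


def peptide_radius(peptide) -> float:
    """Radius of a conformer: maximum bead distance from its centroid."""
    model = peptide.reduced if isinstance(peptide, Conformer) else peptide
    pos = model.positions
    if len(pos) == 0:
        raise ValueError("empty peptide model")
    c = pos.mean(axis=0)
    return float(np.linalg.norm(pos - c, axis=1).max())


def _surface_distance(point: np.ndarray, tree: cKDTree,
                      bead_radius: float) -> float:
    d, _ = tree.query(point)
    return float(d) - bead_radius


def _project_to_offset(center: np.ndarray, direction: np.ndarray,
                       tree: cKDTree, bead_radius: float, offset: float,
                       t_max: float) -> np.ndarray | None:
    """Outermost point along ``center + t*direction`` at surface distance
    ``offset``, by inward march and bisection."""
    step = 1.0
    t_hi = t_max
    f_hi = _surface_distance(center + t_hi * direction, tree,
                             bead_radius) - offset
    if f_hi < 0:  # already inside the offset surface at t_max
        return None
    t = t_hi - step
    while t > 0:
        f = _surface_distance(center + t * direction, tree,
                              bead_radius) - offset
        if f < 0:
            break
        t_hi, f_hi = t, f
        t -= step
    else:
        return None
    t_lo = max(t, 0.0)
    for _ in range(50):
        mid = 0.5 * (t_lo + t_hi)
        f = _surface_distance(center + mid * direction, tree,
                              bead_radius) - offset
        if f < 0:
            t_lo = mid
        else:
            t_hi = mid
        if t_hi - t_lo < 1e-4:
            break
    return center + t_hi * direction


def generate_start_points(receptor: ReducedModel, radius: float,
                          spacing: float = 10.0) -> list[StartPoint]:
    """Place starts on the offset surface 2x peptide radius out, ~``spacing``
    apart.

    The receptor surface is the set of bead centers offset by the
    parameter file's ``surface_bead_radius`` (0 by default, i.e. the
    bead centers themselves).  Directions from the receptor centroid are
    sampled on a golden-angle spiral, projected onto the offset surface,
    then thinned so no two starts are closer than 0.7x spacing.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if receptor.n_beads < 4:
        raise ValueError("degenerate receptor: fewer than 4 beads")
    bead_radius = receptor.params.surface_bead_radius
    offset = 2.0 * radius
    center = receptor.positions.mean(axis=0)
    tree = cKDTree(receptor.positions)
    max_ext = float(np.linalg.norm(receptor.positions - center,
                                   axis=1).max())
    t_max = max_ext + bead_radius + offset + 5.0

    def project_all(n_dir: int) -> np.ndarray:
        pts = []
        for u in fibonacci_sphere(n_dir):
            p = _project_to_offset(center, u, tree, bead_radius, offset,
                                   t_max)
            if p is not None:
                pts.append(p)
        return np.array(pts)

    probe = project_all(128)
    if len(probe) == 0:
        raise ValueError("could not project any start point")
    r_mean = float(np.linalg.norm(probe - probe.mean(axis=0),
                                  axis=1).mean())
    # hex-packing estimate: n points on a sphere of radius r at spacing s
    n_dir = max(12, int(round(14.5 * (r_mean / spacing) ** 2)))
    pts = project_all(n_dir)

    kept: list[np.ndarray] = []
    min_sep = 0.7 * spacing
    for p in pts:
        if all(np.linalg.norm(p - q) >= min_sep for q in kept):
            kept.append(p)
    starts = []
    for p in kept:
        _, j = tree.query(p)
        starts.append(StartPoint(position=p,
                                 surface_anchor=receptor.positions[j]))
    logger.info("placed %d start points (spacing %.1f A, offset %.1f A)",
                len(starts), spacing, offset)
    return starts


def generate_orientations(n: int = 260) -> np.ndarray:
    """``n`` deterministic near-uniform rotations as unit quaternions.

    Constructed as axis directions (golden-angle spiral over the sphere)
    crossed with evenly spaced roll angles about each axis; the default
    260 = 13 axes x 20 rolls.  The first orientation is the identity.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n_rolls = min(20, n)
    n_axes = math.ceil(n / n_rolls)
    axes = fibonacci_sphere(n_axes)
    axes[0] = (0.0, 0.0, 1.0)  # guarantees an identity orientation
    quats = []
    for axis in axes:
        base = rotation_to_axis(axis)
        for k in range(n_rolls):
            roll = Rotation.from_rotvec(axis * (2.0 * np.pi * k / n_rolls))
            quats.append((roll * base).as_quat())
            if len(quats) == n:
                q = np.array(quats)
                return q / np.linalg.norm(q, axis=1, keepdims=True)
    q = np.array(quats)
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def _rodrigues(w: np.ndarray) -> np.ndarray:
    """Rotation matrix exp([w]x) (cheaper than a Rotation object here)."""
    theta2 = w @ w
    K = np.array([[0.0, -w[2], w[1]],
                  [w[2], 0.0, -w[0]],
                  [-w[1], w[0], 0.0]])
    if theta2 < 1e-24:
        return np.eye(3) + K
    theta = np.sqrt(theta2)
    return (np.eye(3) + np.sin(theta) / theta * K
            + (1.0 - np.cos(theta)) / theta2 * (K @ K))


def minimize_pose(receptor: ReducedModel, peptide: ReducedModel,
                  start: RigidPose, settings: DockSettings | None = None,
                  evaluator: InteractionEvaluator | None = None,
                  conformer_id: int = 0, start_id: int = 0,
                  orientation_id: int = 0) -> DockedPose | None:
    """Quasi-Newton rigid-body relaxation of ``start``.

    Minimizes the interaction energy over (rotation-tangent, translation)
    with analytic gradients; converged when the projected gradient
    inf-norm drops below ``gtol`` or after ``maxiter`` iterations.  The
    returned energy never exceeds the start energy.  Returns None (pose
    discarded) if the start energy is non-finite even after softening.
    """
    settings = settings or DockSettings()
    ev = evaluator or InteractionEvaluator(receptor, peptide,
                                           settings.cutoff)
    c0 = peptide.positions.mean(axis=0)
    body = peptide.positions - c0
    r0 = start.rotation
    rb = r0.apply(body)  # start-rotated body coordinates, fixed
    t0 = np.asarray(start.translation, dtype=float)

    def fun(u):
        # u = (incremental rotation vector, absolute translation)
        w, t = u[:3], u[3:]
        R = _rodrigues(w)
        coords = rb @ R.T + (c0 + t)
        bd, g = ev.energy_grad(coords)
        de_dt = g.sum(axis=0)
        # dE/dw via the right Jacobian of SO(3) at w
        de_dw = right_jacobian(w).T @ np.cross(rb, g @ R).sum(axis=0)
        return bd.total, np.concatenate([de_dw, de_dt])

    e_start = ev.energy(r0.apply(body) + c0 + t0).total
    if not np.isfinite(e_start):
        logger.debug("start %d/%d discarded: non-finite energy",
                     start_id, orientation_id)
        return None

    u0 = np.concatenate([np.zeros(3), t0])
    x, _, _ = fmin_l_bfgs_b(fun, u0, pgtol=settings.gtol,
                            maxiter=settings.maxiter,
                            maxfun=settings.maxfun)
    w, t = x[:3], x[3:]
    final_quat = (Rotation.from_rotvec(w) * r0).as_quat()
    pose = RigidPose(tuple(final_quat), tuple(t), anchor=tuple(c0))
    bd = ev.energy(pose.apply(peptide.positions))
    if not np.isfinite(bd.total) or bd.total > e_start:
        pose = RigidPose(start.quat, start.translation, anchor=tuple(c0))
        bd = ev.energy(pose.apply(peptide.positions))
    return DockedPose(pose=pose, energy=bd, conformer_id=conformer_id,
                      start_id=start_id, orientation_id=orientation_id)


def _dock_start_range(args):
    (receptor, peptide, conformer_id, starts, quats, settings,
     start_lo, start_hi) = args
    ev = InteractionEvaluator(receptor, peptide, settings.cutoff)
    c0 = peptide.positions.mean(axis=0)
    out = []
    for s in range(start_lo, start_hi):
        t = np.asarray(starts[s].position) - c0
        for o, q in enumerate(quats):
            start_pose = RigidPose(tuple(q), tuple(t), anchor=tuple(c0))
            dp = minimize_pose(receptor, peptide, start_pose, settings,
                               evaluator=ev, conformer_id=conformer_id,
                               start_id=s, orientation_id=o)
            if dp is not None:
                out.append(dp)
    return out


def dock_conformer(receptor: ReducedModel, conformer: Conformer,
                   settings: DockSettings | None = None,
                   conformer_id: int = 0) -> list[DockedPose]:
    """Blind systematic docking of one conformer: every (start,
    orientation) pair is minimized; results are returned sorted by
    ascending energy.  Identical output for any worker count."""
    settings = settings or DockSettings()
    peptide = conformer.reduced
    radius = peptide_radius(conformer)
    starts = generate_start_points(receptor, radius, settings.spacing)
    quats = generate_orientations(settings.n_orientations)
    n_starts = len(starts)
    if settings.workers > 1:
        chunks = np.array_split(np.arange(n_starts),
                                min(settings.workers * 4, n_starts))
        jobs = [(receptor, peptide, conformer_id, starts, quats, settings,
                 int(c[0]), int(c[-1]) + 1) for c in chunks if len(c)]
        with ProcessPoolExecutor(max_workers=settings.workers) as ex:
            results = list(ex.map(_dock_start_range, jobs))
        poses = [dp for chunk in results for dp in chunk]
    else:
        poses = _dock_start_range((receptor, peptide, conformer_id, starts,
                                   quats, settings, 0, n_starts))
    poses.sort(key=lambda dp: dp.sort_key)
    logger.info("conformer %d: %d poses from %d starts x %d orientations",
                conformer_id, len(poses), n_starts, len(quats))
    return poses


def merge_and_rank(per_conformer: list[list[DockedPose]]) -> list[DockedPose]:
    """Aggregate per-conformer solutions and rank globally by energy.

    Ties are broken by (conformer_id, start_id, orientation_id)."""
    merged = [dp for lst in per_conformer for dp in lst]
    if not merged:
        raise ValueError("no docked poses to merge")
    merged.sort(key=lambda dp: dp.sort_key)
    return merged
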