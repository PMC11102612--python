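"""Midline frontal-curvature profiles and the CURV statistic.

The area of interest runs along the midsagittal intersection of the vault
from the glabella (section 0) to the most anterior point of the anterior
fontanelle (section 90).  The path is cut into equal arc-length bands
orthogonal to its tangent; each band averages the principal curvature k1 (or
mean curvature) of nearby vertices, giving a 91-value profile per subject.
Group profiles are compared section-wise with bootstrap confidence intervals
of the mean difference, and CURV is the average of sections 2..31.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .mesh import CurvatureField, TriangleMesh, closest_point_on_mesh

log = logging.getLogger(__name__)

N_SECTIONS = 91  # sections numbered 0 (glabella) .. 90 (anterior fontanelle)
DEFAULT_CURV_RANGE = (2, 31)


@dataclass
class MidlinePath:
    """Arc-length parameterised polyline on the midsagittal intersection."""

    points: np.ndarray          # (m, 3), ordered glabella -> fontanelle
    arclength: np.ndarray       # (m,), cumulative, starts at 0

    @property
    def length(self) -> float:
        return float(self.arclength[-1])


@dataclass
class CurvatureProfile:
    """Per-section mean curvature (mm^-1), glabella (0) to fontanelle (90).

    Empty sections are NaN and flagged in ``counts`` (never interpolated).
    """

    subject_id: str
    values: np.ndarray
    counts: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_SECTIONS,):
            raise ValueError(f"profile must have {N_SECTIONS} sections")
        if self.counts is None:
            self.counts = np.where(np.isfinite(self.values), 1, 0)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_SECTIONS,):
            raise ValueError("counts length mismatch")

    @property
    def missing_sections(self) -> np.ndarray:
        return np.flatnonzero(~np.isfinite(self.values))


@dataclass
class ProfileComparison:
    """Section-wise group mean difference with bootstrap confidence band."""

    diff: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    level: float
    significant_sections: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        sig = ((self.ci_low > 0) | (self.ci_high < 0)) & np.isfinite(self.diff)
        self.significant_sections = np.flatnonzero(sig)


def _chain_segments(segments: np.ndarray, tol: float = 1e-8) -> list[np.ndarray]:
    """Chain an unordered (s, 2, 3) segment soup into polylines."""
    pts = segments.reshape(-1, 3)
    # weld endpoints
    order = np.lexsort(pts.T)
    uniq: list[np.ndarray] = []
    idx_of = np.empty(len(pts), dtype=int)
    for i in order:
        if uniq and np.linalg.norm(pts[i] - uniq[-1]) < tol:
            idx_of[i] = len(uniq) - 1
        else:
            idx_of[i] = len(uniq)
            uniq.append(pts[i])
    uniq = np.asarray(uniq)
    edges = idx_of.reshape(-1, 2)
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        if a == b:
            continue
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    visited = set()
    loops = []
    for start in adj:
        if start in visited:
            continue
        chain = [start]
        visited.add(start)
        prev = None
        node = start
        while True:
            nxt = [n for n in adj[node] if n != prev]
            nxt = [n for n in nxt if n not in visited or (n == start and len(chain) > 2)]
            if not nxt:
                break
            node, prev = nxt[0], node
            if node == start:
                chain.append(start)
                break
            chain.append(node)
            visited.add(node)
        loops.append(uniq[chain])
    return loops


def midline_path(mesh: TriangleMesh, glabella: np.ndarray, fontanelle: np.ndarray,
                 plane_origin=(0.0, 0.0, 0.0), plane_normal=(1.0, 0.0, 0.0),
                 surface_tol: float = 5.0, resample_step: float = 0.5) -> MidlinePath:
    """Midsagittal intersection curve trimmed between glabella and fontanelle.

    The mesh (assumed in the anatomical frame, midsagittal plane x = 0 by
    default) is cut by the plane; the resulting curve is trimmed to the
    shorter arc between the two points and arc-length parameterised from
    glabella to fontanelle.
    """
    glabella = np.asarray(glabella, dtype=float)
    fontanelle = np.asarray(fontanelle, dtype=float)
    if np.linalg.norm(glabella - fontanelle) < 1e-9:
        raise ValueError("glabella and fontanelle coincide (zero-length path)")
    tm = mesh.to_trimesh()
    _, dists = closest_point_on_mesh(mesh, np.stack([glabella, fontanelle]))
    for name, d in zip(("glabella", "fontanelle"), dists):
        if d > surface_tol:
            raise ValueError(f"{name} is {d:.2f} mm from the surface "
                             f"(> {surface_tol} mm)")
    segments = trimesh.intersections.mesh_plane(
        tm, plane_normal=np.asarray(plane_normal, float),
        plane_origin=np.asarray(plane_origin, float))
    if len(segments) == 0:
        raise ValueError("midsagittal plane does not intersect the mesh")
    loops = _chain_segments(np.asarray(segments))
    # pick the loop passing nearest both endpoints
    best, best_d = None, np.inf
    for loop in loops:
        d = (np.linalg.norm(loop - glabella, axis=1).min()
             + np.linalg.norm(loop - fontanelle, axis=1).min())
        if d < best_d:
            best, best_d = loop, d
    loop = best
    closed = np.linalg.norm(loop[0] - loop[-1]) < 1e-8
    if closed:
        loop = loop[:-1]
    ig = int(np.argmin(np.linalg.norm(loop - glabella, axis=1)))
    if np.linalg.norm(loop[ig] - glabella) > surface_tol + 1e-6:
        raise ValueError("glabella not connectable to the midsagittal intersection")
    n = len(loop)
    # two candidate arcs between the endpoints; take the shorter one
    i_f = int(np.argmin(np.linalg.norm(loop - fontanelle, axis=1)))
    if closed:
        fwd_idx = np.arange(ig, ig + (i_f - ig) % n + 1) % n   # ig -> i_f forward
        bwd_idx = np.arange(ig, ig - (ig - i_f) % n - 1, -1) % n  # ig -> i_f backward
        arc_fwd, arc_bwd = loop[fwd_idx], loop[bwd_idx]

        def arclen(p):
            return np.linalg.norm(np.diff(p, axis=0), axis=1).sum()
        path = arc_fwd if arclen(arc_fwd) <= arclen(arc_bwd) else arc_bwd
    else:
        lo, hi = sorted((ig, i_f))
        path = loop[lo:hi + 1]
        if ig > i_f:
            path = path[::-1]
    if len(path) < 2:
        raise ValueError("degenerate midline path")
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    # drop duplicate stations
    keep = np.concatenate([[True], np.diff(s) > 1e-12])
    path, s = path[keep], s[keep]
    # resample to a fine uniform arc-length grid
    n_samp = max(int(np.ceil(s[-1] / resample_step)), 2)
    s_new = np.linspace(0.0, s[-1], n_samp + 1)
    pts = np.column_stack([np.interp(s_new, s, path[:, i]) for i in range(3)])
    return MidlinePath(points=pts, arclength=s_new)


def _densify_strip(vertices: np.ndarray, faces: np.ndarray, values: np.ndarray,
                   target_edge: float, max_levels: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint-subdivide a surface strip until edges fall under target_edge.

    The scalar field is carried along by linear (barycentric) interpolation on
    the surface.  Returns (sample points, sample values).
    """
    V, F, S = vertices, faces, values
    for _ in range(max_levels):
        e = V[F[:, [1, 2, 0]]] - V[F]
        if np.linalg.norm(e, axis=2).max() <= target_edge:
            break
        edges = np.sort(F[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        uniq, inv = np.unique(edges, axis=0, return_inverse=True)
        mid = 0.5 * (V[uniq[:, 0]] + V[uniq[:, 1]])
        mid_s = 0.5 * (S[uniq[:, 0]] + S[uniq[:, 1]])
        mid_idx = len(V) + np.arange(len(uniq))
        m = mid_idx[inv].reshape(-1, 3)  # midpoints of edges 01, 12, 20 per face
        V = np.vstack([V, mid])
        S = np.concatenate([S, mid_s])
        F = np.vstack([
            np.column_stack([F[:, 0], m[:, 0], m[:, 2]]),
            np.column_stack([F[:, 1], m[:, 1], m[:, 0]]),
            np.column_stack([F[:, 2], m[:, 2], m[:, 1]]),
            m,
        ])
    return V, S


def section_profile(mesh: TriangleMesh, curvature: CurvatureField, path: MidlinePath,
                    n_slices: int = 90, half_width: float = 10.0,
                    measure: str = "k1", tube_factor: float = 1.5,
                    densify: bool = True, subject_id: str = "") -> CurvatureProfile:
    """Per-section mean curvature along the midline path.

    ``n_slices + 1`` equally spaced arc-length stations (numbered 0..n_slices)
    define bands orthogonal to the path tangent; a band collects surface
    samples whose arc-length projection falls inside it, whose distance to
    the midsagittal plane is <= ``half_width`` and whose distance to the path
    is <= ``tube_factor * half_width`` (keeps skull-base vertices out of the
    glabellar band).

    With ``densify`` (default) the strip around the path is barycentrically
    resampled until the sampling is finer than the band width, so band
    occupancy does not depend on mesh resolution; the curvature field is
    interpolated linearly *on the surface* (sections with no surface in them
    are still reported missing, never filled in).  With ``densify=False``
    only raw mesh vertices enter the bands.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    vals = {"k1": curvature.k1, "k2": curvature.k2,
            "mean": curvature.mean_curvature}.get(measure)
    if vals is None:
        raise ValueError(f"unknown curvature measure {measure!r}")
    if len(vals) != mesh.n_vertices:
        raise ValueError("curvature field does not match mesh")
    v = mesh.vertices
    if densify:
        band_width = path.length / n_slices
        # faces touching a loose bounding tube around the path
        tube_r = 2.0 * tube_factor * half_width
        tree0 = cKDTree(path.points)
        d0, _ = tree0.query(v)
        near_v = (np.abs(v[:, 0]) <= 2.0 * half_width) & (d0 <= tube_r)
        fmask = near_v[mesh.faces].any(axis=1)
        if fmask.any():
            sub_f = mesh.faces[fmask]
            used = np.unique(sub_f)
            remap = np.full(mesh.n_vertices, -1)
            remap[used] = np.arange(len(used))
            v_sub, s_sub = _densify_strip(v[used], remap[sub_f], vals[used],
                                          target_edge=max(band_width, 0.25))
            v, vals = v_sub, s_sub
    near_plane = np.abs(v[:, 0]) <= half_width
    tree = cKDTree(path.points)
    dist, idx = tree.query(v[near_plane])
    in_tube = dist <= tube_factor * half_width
    sel = np.flatnonzero(near_plane)[in_tube]
    s_proj = path.arclength[idx[in_tube]]
    vv = vals[sel]
    if n_slices == 1:  # degenerate slicing: one section spanning the whole AOI
        band = np.zeros(len(sel), dtype=int)
        n_out = 1
    else:
        width = path.length / n_slices
        band = np.clip(np.round(s_proj / width).astype(int), 0, n_slices)
        n_out = n_slices + 1
    if n_out > N_SECTIONS:
        raise ValueError(f"n_slices must be <= {N_SECTIONS - 1}")
    values = np.full(N_SECTIONS, np.nan)
    counts = np.zeros(N_SECTIONS, dtype=int)
    for i in range(n_out):
        m = band == i
        counts[i] = int(m.sum())
        if counts[i]:
            values[i] = vv[m].mean()
    empty = int((counts[:n_out] == 0).sum())
    if empty:
        warnings.warn(f"{empty}/{n_out} sections are empty", RuntimeWarning, stacklevel=2)
    return CurvatureProfile(subject_id, values, counts)


def profile_group_difference(profiles_a: list[CurvatureProfile],
                             profiles_b: list[CurvatureProfile],
                             level: float = 0.95, n_boot: int = 2000,
                             seed: int | None = 0) -> ProfileComparison:
    """Section-wise mean difference (a - b) with bootstrap percentile CIs.

    A section is significant when its CI excludes 0.
    """
    if len(profiles_a) < 3 or len(profiles_b) < 3:
        raise ValueError("need >= 3 subjects per group")
    A = np.stack([p.values for p in profiles_a])
    B = np.stack([p.values for p in profiles_b])
    if A.shape[1] != B.shape[1]:
        raise ValueError("mismatched section counts")
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        diff = np.nanmean(A, axis=0) - np.nanmean(B, axis=0)
        ia = rng.integers(0, len(A), size=(n_boot, len(A)))
        ib = rng.integers(0, len(B), size=(n_boot, len(B)))
        boots = np.nanmean(A[ia], axis=1) - np.nanmean(B[ib], axis=1)
        alpha = (1.0 - level) / 2.0
        lo = np.nanquantile(boots, alpha, axis=0)
        hi = np.nanquantile(boots, 1.0 - alpha, axis=0)
    return ProfileComparison(diff=diff, ci_low=lo, ci_high=hi, level=level)


def compute_curv(profile: CurvatureProfile,
                 section_range: tuple[int, int] = DEFAULT_CURV_RANGE) -> float:
    """CURV: mean curvature over the inclusive section range (default 2..31).

    Missing sections inside the range are skipped (logged); an all-missing
    range is an error.
    """
    lo, hi = section_range
    if not (0 <= lo <= hi <= N_SECTIONS - 1):
        raise ValueError(f"section range {section_range} outside 0..{N_SECTIONS - 1}")
    window = profile.values[lo:hi + 1]
    ok = np.isfinite(window)
    if not ok.any():
        raise ValueError(f"all sections in {section_range} are missing")
    n_missing = int((~ok).sum())
    if n_missing:
        log.info("CURV for %s skipped %d missing sections", profile.subject_id, n_missing)
    return float(window[ok].mean())


def curv_from_significant_sections(profile: CurvatureProfile,
                                   comparison: ProfileComparison) -> float:
    """CURV over the sections found significant in a group comparison."""
    sections = comparison.significant_sections
    if len(sections) == 0:
        raise ValueError("no significant sections to average")
    vals = profile.values[sections]
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError("all significant sections missing for this subject")
    return float(vals[ok].mean())
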