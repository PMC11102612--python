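"""Landmark-based rigid alignment and non-rigid ICP template morphing.

Subjects are first rigidly aligned to a template with the 8 standard cranial
landmarks (left/right supra-orbital notch, left/right infra-orbital foramen,
left/right porion, opisthion, lambda); dense vertex correspondence is then
established by deforming the template with a stiffness-regularised non-rigid
ICP (per-vertex affine transforms, Amberg-style), so every registered subject
shares the template topology.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .mesh import TriangleMesh

log = logging.getLogger(__name__)

#: the 8 landmarks used for rigid alignment, in canonical order
ALIGNMENT_LANDMARKS = (
    "supraorbital_notch_L", "supraorbital_notch_R",
    "infraorbital_foramen_L", "infraorbital_foramen_R",
    "porion_L", "porion_R",
    "opisthion", "lambda",
)

#: optional derived points used by downstream measurements
DERIVED_LANDMARKS = ("glabella", "anterior_fontanelle", "most_anterior_point")


class LandmarkError(ValueError):
    pass


class DegenerateConfigurationError(ValueError):
    pass


@dataclass
class CranialLandmarkSet:
    """Named craniofacial landmarks in mm.

    The 8 alignment landmarks must all be present and finite; derived points
    (glabella, anterior fontanelle, ...) are optional.
    """

    points: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}
        missing = [n for n in ALIGNMENT_LANDMARKS if n not in self.points]
        if missing:
            raise LandmarkError(f"missing alignment landmarks: {missing}")
        for name, p in self.points.items():
            if not np.isfinite(p).all():
                raise LandmarkError(f"landmark {name!r} has non-finite coordinates")

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.points:
            raise LandmarkError(f"landmark {name!r} not present")
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def as_array(self, names=ALIGNMENT_LANDMARKS) -> np.ndarray:
        return np.stack([self[n] for n in names])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CranialLandmarkSet":
        R = np.asarray(rotation)
        t = np.asarray(translation)
        return CranialLandmarkSet({k: R @ v + t for k, v in self.points.items()})

    def to_json(self, path) -> None:
        with open(str(path), "w") as fh:
            json.dump({k: list(map(float, v)) for k, v in self.points.items()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CranialLandmarkSet":
        with open(str(path)) as fh:
            return cls(json.load(fh))


@dataclass
class RigidTransform:
    """Rotation (proper, det +1), translation, optional uniform scale."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0
    residual_rms: float = np.nan

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(points, dtype=float) @ self.rotation.T) + self.translation

    def apply_mesh(self, mesh: TriangleMesh) -> TriangleMesh:
        return TriangleMesh(self.apply(mesh.vertices), mesh.faces.copy())

    def apply_landmarks(self, lms: CranialLandmarkSet) -> CranialLandmarkSet:
        return CranialLandmarkSet({k: self.apply(v[None])[0] for k, v in lms.points.items()})


def rigid_landmark_align(source: CranialLandmarkSet, target: CranialLandmarkSet,
                         allow_scale: bool = False,
                         landmark_names=ALIGNMENT_LANDMARKS) -> RigidTransform:
    """Least-squares (Kabsch/Umeyama) transform mapping source onto target landmarks."""
    names = [n for n in landmark_names if n in source and n in target]
    if len(names) < 3:
        raise DegenerateConfigurationError(
            f"need >= 3 common landmarks, have {len(names)}")
    X = source.as_array(names)
    Y = target.as_array(names)
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    # collinearity check: second singular value of the centred cloud
    sv = np.linalg.svd(Xc, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateConfigurationError("landmarks are collinear or coincident")
    H = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if allow_scale:
        scale = float((S @ np.diag(D)).sum() / (Xc ** 2).sum())
    else:
        scale = 1.0
    t = my - scale * R @ mx
    resid = scale * Xc @ R.T - Yc
    rms = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    return RigidTransform(R, t, scale, residual_rms=rms)


def _edge_incidence(mesh: TriangleMesh) -> sparse.csr_matrix:
    e = np.unique(np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1), axis=0)
    m = len(e)
    rows = np.repeat(np.arange(m), 2)
    cols = e.ravel()
    vals = np.tile([-1.0, 1.0], m)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(m, mesh.n_vertices)).tocsr()


def nicp_register(template: TriangleMesh, target: TriangleMesh,
                  stiffness_schedule=(50.0, 20.0, 5.0, 2.0),
                  max_iter_per_step: int = 10,
                  gamma: float = 1.0,
                  normal_angle_deg: float = 60.0,
                  tol: float = 1e-4) -> tuple[TriangleMesh, dict]:
    """Deform the template onto the target with stiffness-regularised NICP.

    Each template vertex carries a 3x4 affine transform X_i; the objective
    trades closest-point data terms against an edge-wise stiffness penalty
    ``||alpha (X_i - X_j) G||_F^2`` that is relaxed along the (strictly
    decreasing) stiffness schedule.  Correspondences are nearest target
    vertices, gated by normal compatibility (< ``normal_angle_deg``).

    Returns the deformed template (identical topology) and a diagnostics dict
    with per-step mean closest-point distances.
    """
    sched = [float(s) for s in stiffness_schedule]
    if len(sched) == 0 or any(s <= 0 for s in sched):
        raise ValueError("stiffness schedule must contain positive values")
    if any(b >= a for a, b in zip(sched, sched[1:])):
        raise ValueError("stiffness schedule must be strictly decreasing")
    if target.n_vertices == 0:
        raise ValueError("empty target mesh")

    n = template.n_vertices
    M = _edge_incidence(template)
    G = sparse.diags([1.0, 1.0, 1.0, gamma])
    MG = sparse.kron(M, G).tocsr()

    from .mesh import _vertex_normals, closest_point_on_mesh
    target_tm = target.to_trimesh()
    if target_tm.is_watertight and target_tm.volume < 0:
        target_tm.invert()
    target_face_normals = np.asarray(target_tm.face_normals, dtype=float)
    cos_gate = np.cos(np.radians(normal_angle_deg))

    # unknowns X: (4n, 3); start from identity transforms
    X = np.tile(np.vstack([np.eye(3), np.zeros(3)]), (n, 1))
    V = template.vertices

    def build_D(verts: np.ndarray) -> sparse.csr_matrix:
        rows = np.repeat(np.arange(n), 4)
        cols = (np.arange(n)[:, None] * 4 + np.arange(4)[None, :]).ravel()
        vals = np.column_stack([verts, np.ones(n)]).ravel()
        return sparse.coo_matrix((vals, (rows, cols)), shape=(n, 4 * n)).tocsr()

    D0 = build_D(V)
    info = {"steps": []}
    for alpha in sched:
        for _ in range(max_iter_per_step):
            deformed = (D0 @ X)
            work_mesh = TriangleMesh(deformed, template.faces)
            cur_normals = _vertex_normals(work_mesh)
            U, dist, fidx = closest_point_on_mesh(target, deformed, return_faces=True)
            compat = np.einsum("ij,ij->i", cur_normals,
                               target_face_normals[fidx]) > cos_gate
            w = compat.astype(float)
            Wd = sparse.diags(w)
            A = sparse.vstack([alpha * MG, Wd @ D0]).tocsr()
            B = sparse.vstack([sparse.csr_matrix((MG.shape[0], 3)),
                               sparse.csr_matrix(w[:, None] * U)])
            AtA = (A.T @ A).tocsc()
            AtB = np.asarray((A.T @ B).todense())
            X_new = spsolve(AtA, AtB)
            X_new = np.asarray(X_new).reshape(4 * n, 3)
            change = np.abs(X_new - X).max()
            X = X_new
            if change < tol:
                break
        deformed = D0 @ X
        _, dist = closest_point_on_mesh(target, deformed)
        info["steps"].append({"stiffness": alpha, "mean_distance": float(dist.mean())})
        if change >= tol:
            log.warning("NICP step (stiffness %.3g) stopped at max_iter with "
                        "max transform change %.3g", alpha, change)
    info["mean_distance"] = info["steps"][-1]["mean_distance"]
    return TriangleMesh(D0 @ X, template.faces.copy()), info
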