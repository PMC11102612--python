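"""Univariate craniofacial descriptors and orbital semi-landmark processing.

Linear measures follow the orbital landmark scheme LM1..LM8:
(1, 2) fronto-maxillary junction, (3, 4) middle of the supraorbital bar,
(5, 6) ectoconchion, (7, 8) zygo-orbitale.  DIST is the LM1-LM2 inter-orbital
distance, RATIO the mean orbital height/width ratio, CI the maximal skull
width over length in the Frankfurt-aligned anatomical frame, IFA the angle at
the projected most-anterior skull point subtended by the supra-orbital
notches, and ICV the intracranial-mesh volume.

Semi-landmark machinery: a 3D thin-plate spline carries template contour
points onto each subject (then snapped to the surface), and sliding relaxes
them along their contour tangents by minimising thin-plate bending energy
against a reference configuration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .mesh import TriangleMesh, closest_point_on_mesh
from .registration import CranialLandmarkSet, DegenerateConfigurationError, LandmarkError

log = logging.getLogger(__name__)

ANATOMICAL_NAMES = tuple(f"LM{i}" for i in range(1, 9))
N_SEMILANDMARKS = 50


@dataclass
class OrbitalLandmarkSet:
    """8 anatomical orbital landmarks plus 50 ordered contour semi-landmarks.

    ``semilandmarks`` holds the left contour first, then the right; each
    contour is an ordered open curve with the anatomical landmarks as fixed
    endpoints conceptually bracketing it.
    """

    anatomical: dict = field(default_factory=dict)
    semilandmarks: np.ndarray = None
    n_left: int = 25

    def __post_init__(self) -> None:
        self.anatomical = {k: np.asarray(v, dtype=float).reshape(3)
                           for k, v in self.anatomical.items()}
        missing = [n for n in ANATOMICAL_NAMES if n not in self.anatomical]
        if missing:
            raise LandmarkError(f"missing orbital landmarks: {missing}")
        self.semilandmarks = np.asarray(self.semilandmarks, dtype=float)
        if self.semilandmarks.shape != (N_SEMILANDMARKS, 3):
            raise LandmarkError(
                f"expected {N_SEMILANDMARKS} semi-landmarks, got {self.semilandmarks.shape}")
        allpts = np.vstack([self.as_array(), self.semilandmarks])
        if not np.isfinite(allpts).all():
            raise LandmarkError("non-finite orbital landmark coordinates")

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.anatomical:
            raise LandmarkError(f"orbital landmark {name!r} not present")
        return self.anatomical[name]

    def as_array(self, names=ANATOMICAL_NAMES) -> np.ndarray:
        return np.stack([self[n] for n in names])

    @property
    def contours(self) -> tuple[np.ndarray, np.ndarray]:
        return self.semilandmarks[: self.n_left], self.semilandmarks[self.n_left:]

    def full_configuration(self) -> np.ndarray:
        """Anatomical landmarks followed by semi-landmarks (58 x 3)."""
        return np.vstack([self.as_array(), self.semilandmarks])


@dataclass
class MeasureRecord:
    """Per-subject univariate descriptor row."""

    subject_id: str
    group: str
    age_days: float
    sex: str
    CURV: float
    IFA: float
    CI: float
    DIST: float
    RATIO: float
    ICV: float

    def __post_init__(self) -> None:
        if not (0.0 < self.IFA <= 180.0):
            raise ValueError(f"IFA must be in (0, 180], got {self.IFA}")
        for name in ("CI", "DIST", "RATIO", "ICV"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    FIELDS = ("subject_id", "group", "age_days", "sex",
              "CURV", "IFA", "CI", "DIST", "RATIO", "ICV")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.FIELDS}


# ---------------------------------------------------------------------------
# linear measures


def interorbital_distance(orbits: OrbitalLandmarkSet) -> float:
    """Euclidean LM1-LM2 distance (mm)."""
    d = float(np.linalg.norm(orbits["LM1"] - orbits["LM2"]))
    if d == 0.0:
        warnings.warn("inter-orbital distance is exactly 0 (coincident LM1/LM2)",
                      RuntimeWarning, stacklevel=2)
    return d


def orbital_ratio(orbits: OrbitalLandmarkSet) -> float:
    """Mean orbital height / mean orbital width.

    height = mean(|LM3-LM7|, |LM4-LM8|); width = mean(|LM1-LM5|, |LM2-LM6|).
    """
    height = 0.5 * (np.linalg.norm(orbits["LM3"] - orbits["LM7"])
                    + np.linalg.norm(orbits["LM4"] - orbits["LM8"]))
    width = 0.5 * (np.linalg.norm(orbits["LM1"] - orbits["LM5"])
                   + np.linalg.norm(orbits["LM2"] - orbits["LM6"]))
    if width == 0:
        raise ValueError("zero orbital width")
    return float(height / width)


def frankfurt_plane(landmarks: CranialLandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit Frankfurt plane (point, unit normal oriented superiorly).

    Fitted through both porions and the available infra-orbital foramina
    (least squares when four points are given).
    """
    names = ["porion_L", "porion_R"]
    for n in ("infraorbital_foramen_L", "infraorbital_foramen_R"):
        if n in landmarks:
            names.append(n)
    if len(names) < 3:
        raise LandmarkError("need both porions and at least one infra-orbital foramen")
    pts = landmarks.as_array(names)
    centroid = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - centroid)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateConfigurationError("Frankfurt landmarks are collinear")
    normal = vt[2]
    # orient superiorly: towards lambda if available, else +z
    up_ref = landmarks["lambda"] - centroid if "lambda" in landmarks else np.array([0.0, 0.0, 1.0])
    if normal @ up_ref < 0:
        normal = -normal
    return centroid, normal


def anatomical_frame(landmarks: CranialLandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    """Frankfurt-aligned frame: x = left->right porion, z = plane normal, y anterior.

    Returns (origin, R) with R rows the frame axes; world points map to frame
    coordinates via ``(p - origin) @ R.T``.
    """
    origin = 0.5 * (landmarks["porion_L"] + landmarks["porion_R"])
    xhat = landmarks["porion_R"] - landmarks["porion_L"]
    nx = np.linalg.norm(xhat)
    if nx < 1e-9:
        raise DegenerateConfigurationError("coincident porions")
    xhat = xhat / nx
    _, n = frankfurt_plane(landmarks)
    zhat = n - (n @ xhat) * xhat
    nz = np.linalg.norm(zhat)
    if nz < 1e-9:
        raise DegenerateConfigurationError("Frankfurt normal parallel to inter-porion axis")
    zhat = zhat / nz
    yhat = np.cross(zhat, xhat)
    return origin, np.stack([xhat, yhat, zhat])


def to_frame(points: np.ndarray, frame: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    origin, R = frame
    return (np.asarray(points, dtype=float) - origin) @ R.T


def interfrontal_angle(mesh: TriangleMesh, landmarks: CranialLandmarkSet) -> float:
    """Interfrontal angle (degrees) at the projected most-anterior skull point.

    A plane parallel to the Frankfurt plane is passed through the midpoint of
    the two supra-orbital notches; the mesh's most anterior point (max y in
    the anatomical frame, ties broken by larger z) is projected onto that
    plane and the angle it subtends to the notches is returned.
    """
    frame = anatomical_frame(landmarks)
    notch_l = to_frame(landmarks["supraorbital_notch_L"], frame)
    notch_r = to_frame(landmarks["supraorbital_notch_R"], frame)
    v = to_frame(mesh.vertices, frame)
    order = np.lexsort((v[:, 2], v[:, 1]))  # primary y, tie-break z
    apex = v[order[-1]]
    mid_z = 0.5 * (notch_l[2] + notch_r[2])
    apex_proj = np.array([apex[0], apex[1], mid_z])
    a = notch_l - apex_proj
    b = notch_r - apex_proj
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-9 or nb < 1e-9:
        raise DegenerateConfigurationError("projected apex coincides with a notch")
    cosang = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def cephalic_index(mesh: TriangleMesh, frame=None) -> float:
    """Maximum skull width / maximum length, in the anatomical frame.

    If ``frame`` (origin, R) is given the mesh is first expressed in it;
    otherwise the mesh is assumed already Frankfurt-aligned (x right,
    y anterior, z superior).
    """
    v = mesh.vertices if frame is None else to_frame(mesh.vertices, frame)
    width = float(v[:, 0].max() - v[:, 0].min())
    length = float(v[:, 1].max() - v[:, 1].min())
    if length <= 0:
        raise ValueError("zero skull length extent")
    return width / length


# ---------------------------------------------------------------------------
# thin-plate splines and sliding


class ThinPlateSpline3D:
    """3D thin-plate spline interpolant (biharmonic kernel U(r) = r).

    Interpolates control points exactly; the affine part makes uniform
    scaling/rotation of the targets an exact special case.
    """

    def __init__(self, source: np.ndarray, target: np.ndarray, reg: float = 0.0):
        X = np.asarray(source, dtype=float)
        Y = np.asarray(target, dtype=float)
        if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("source/target must be matching (k, 3) arrays")
        k = len(X)
        if k < 4:
            raise DegenerateConfigurationError("TPS needs >= 4 control points")
        sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
        if sv[2] < 1e-9 * max(sv[0], 1.0):
            raise DegenerateConfigurationError("TPS control points are coplanar")
        K = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        if reg:
            K = K + reg * np.eye(k)
        P = np.column_stack([np.ones(k), X])
        L = np.zeros((k + 4, k + 4))
        L[:k, :k] = K
        L[:k, k:] = P
        L[k:, :k] = P.T
        rhs = np.zeros((k + 4, 3))
        rhs[:k] = Y
        sol = np.linalg.solve(L, rhs)
        self.source = X
        self.weights = sol[:k]
        self.affine = sol[k:]

    def transform(self, points: np.ndarray) -> np.ndarray:
        P = np.asarray(points, dtype=float)
        U = np.linalg.norm(P[:, None] - self.source[None, :], axis=2)
        return U @ self.weights + np.column_stack([np.ones(len(P)), P]) @ self.affine


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Bending-energy matrix B of a TPS anchored on the reference configuration.

    For a deformation with targets Y the bending energy is tr(Y^T B Y) >= 0.
    The 3D distance kernel U(r) = r is conditionally *negative* definite, so
    the energy form is the negated upper-left block of L^-1 (the opposite
    sign convention from the planar r^2 log r spline).
    """
    X = np.asarray(reference, dtype=float)
    k = len(X)
    K = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    P = np.column_stack([np.ones(k), X])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    Linv = np.linalg.pinv(L)
    B = -Linv[:k, :k]
    return 0.5 * (B + B.T)


def tps_project_semilandmarks(template_semis: OrbitalLandmarkSet,
                              template_anat: np.ndarray,
                              subject_anat: np.ndarray,
                              subject_mesh: TriangleMesh | None = None) -> OrbitalLandmarkSet:
    """Warp template semi-landmarks onto a subject via TPS, then snap to surface.

    The spline interpolates template->subject anatomical landmarks exactly;
    warped contour points are projected to the nearest point of the subject
    mesh when one is provided.
    """
    tps = ThinPlateSpline3D(template_anat, subject_anat)
    warped = tps.transform(template_semis.semilandmarks)
    if subject_mesh is not None:
        warped, _ = closest_point_on_mesh(subject_mesh, warped)
    anat = {n: subject_anat[i] for i, n in enumerate(ANATOMICAL_NAMES)}
    return OrbitalLandmarkSet(anat, warped, n_left=template_semis.n_left)


def _contour_tangents(config: np.ndarray, n_anat: int, n_left: int) -> np.ndarray:
    """Unit tangents of the semi-landmark contours by central differences.

    ``config`` is the full configuration (anatomical first); tangent rows are
    returned only for the semi-landmarks, zeros for anatomical points.
    """
    k = len(config)
    tangents = np.zeros((k, 3))
    semis = config[n_anat:]
    for start, stop in ((0, n_left), (n_left, len(semis))):
        c = semis[start:stop]
        t = np.empty_like(c)
        t[1:-1] = c[2:] - c[:-2]
        t[0] = c[1] - c[0]
        t[-1] = c[-1] - c[-2]
        norms = np.linalg.norm(t, axis=1)
        norms[norms < 1e-12] = 1.0
        tangents[n_anat + start:n_anat + stop] = t / norms[:, None]
    return tangents


def slide_semilandmarks(contours: list[OrbitalLandmarkSet],
                        reference: np.ndarray | None = None,
                        iterations: int = 3) -> tuple[list[OrbitalLandmarkSet], dict]:
    """Relax semi-landmarks along their contour tangents (bending-energy sliding).

    Each semi-landmark of each subject slides along its local contour tangent
    to minimise the thin-plate bending energy of the reference->subject
    deformation; anatomical landmarks never move.  The reference (mean
    configuration) is recomputed between iterations unless supplied.  A
    sliding update that would increase a subject's energy is rejected, and
    iteration stops early if the cohort total stops decreasing, so the
    reported per-iteration energy trace is non-increasing.
    """
    if not contours:
        raise ValueError("no subjects to slide")
    n_anat = len(ANATOMICAL_NAMES)
    n_left = contours[0].n_left
    configs = [c.full_configuration() for c in contours]
    fixed_reference = reference is not None
    energies = []
    current = [c.copy() for c in configs]

    def ref_mean(cfgs):
        from .stats import generalized_procrustes
        aligned, mean, _ = generalized_procrustes(cfgs)
        # rescale consensus to the mean centroid size of the raw data so the
        # bending-energy kernel lives on a physical scale
        sizes = [np.linalg.norm(c - c.mean(axis=0)) for c in cfgs]
        return mean / np.linalg.norm(mean - mean.mean(axis=0)) * np.mean(sizes)

    prev_total = np.inf
    for it in range(iterations):
        ref = np.asarray(reference, dtype=float) if fixed_reference else ref_mean(current)
        B = bending_energy_matrix(ref)

        def energy(cfg):
            return float(np.einsum("ic,ij,jc->", cfg, B, cfg))

        new_state = []
        total = 0.0
        for cfg in current:
            e0 = energy(cfg)
            tangents = _contour_tangents(cfg, n_anat, n_left)
            slide_idx = np.arange(n_anat, len(cfg))
            # minimise (cfg + T t)^T B (cfg + T t) over per-point amounts t
            BT = B[:, slide_idx]
            # gradient terms: for coordinate c, d/dt_j = 2 tau_j . (B cfg)_j + ...
            tau = tangents[slide_idx]
            Bc = B @ cfg
            g = np.einsum("jc,jc->j", tau, Bc[slide_idx])
            H = (B[np.ix_(slide_idx, slide_idx)]
                 * (tau @ tau.T))
            try:
                t = np.linalg.solve(H + 1e-9 * np.trace(H) / len(H) * np.eye(len(H)), -g)
            except np.linalg.LinAlgError:
                t = np.zeros(len(slide_idx))
            cand = cfg.copy()
            cand[slide_idx] += t[:, None] * tau
            e1 = energy(cand)
            if e1 <= e0:
                new_state.append(cand)
                total += e1
            else:  # reject an uphill step (keeps the trace monotone)
                new_state.append(cfg)
                total += e0
        if total > prev_total + 1e-12 * max(abs(prev_total), 1.0):
            log.warning("sliding stopped at iteration %d: energy would increase", it)
            break
        current = new_state
        energies.append(total)
        if prev_total - total <= 1e-10 * max(abs(prev_total), 1.0) and it > 0:
            break
        prev_total = total

    out = []
    for orig, cfg in zip(contours, current):
        out.append(OrbitalLandmarkSet(dict(orig.anatomical), cfg[n_anat:], n_left=n_left))
    if len(energies) == iterations and energies[0] - energies[-1] < 0:
        warnings.warn("sliding did not reduce bending energy", RuntimeWarning, stacklevel=2)
    return out, {"energy": energies}
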