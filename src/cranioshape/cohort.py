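"""Parametric synthetic skull cohort: controls, metopic ridge, trigonocephaly.

Each subject is a deformed ellipsoidal vault built on a fixed icosphere
parameterisation (so every subject shares vertex directions), with
interpretable deformation knobs that encode the three phenotypes:

* a broad *frontal boss* (all groups) giving infants' forehead prominence;
* a *midline crease* — a radial ridge with an ``exp(-|azimuth|/sigma)``
  profile whose non-smooth apex runs up the metopic line.  A narrow,
  glabella-limited crease is the metopic-ridge (MR) phenotype; a wide,
  tall-amplitude crease is part of trigonocephaly (TG);
* a *frontal wedge narrowing* (TG only) compressing the anterior third
  laterally, producing the triangular forehead and an acute interfrontal
  angle;
* a *hypotelorism offset* narrowing the inter-orbital landmark distance
  (strong in TG, mild in MR);
* an isotropic growth law ``(age / 220 days)^0.1`` scaling all lengths, so
  intracranial volume rises monotonically with age.

Cranial landmarks are evaluated analytically through the same deformation
chain and snapped to the (noisy) vault surface; orbital landmarks are
constructed geometrically around the orbits.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh

from .anthropometry import ANATOMICAL_NAMES, OrbitalLandmarkSet
from .mesh import TriangleMesh, closest_point_on_mesh, mesh_volume, write_stl
from .registration import CranialLandmarkSet

log = logging.getLogger(__name__)

REFERENCE_AGE_DAYS = 220.0
GROWTH_EXPONENT = 0.1

#: landmark directions (azimuth from anterior, elevation from the equator), radians
_LANDMARK_ANGLES = {
    "supraorbital_notch_L": (-0.35, -0.06),
    "supraorbital_notch_R": (+0.35, -0.06),
    "infraorbital_foramen_L": (-0.31, -0.30),
    "infraorbital_foramen_R": (+0.31, -0.30),
    "porion_L": (-1.50, -0.30),
    "porion_R": (+1.50, -0.30),
    "opisthion": (np.pi, -0.55),
    "lambda": (np.pi, 0.55),
    "glabella": (0.0, 0.0),
    "anterior_fontanelle": (0.0, 1.25),
}
FONTANELLE_ELEVATION = 1.25


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class PhenotypePreset:
    """Generator knobs for one phenotype group.

    Lengths are mm at the reference age (220 days); ``*_sd`` entries are
    between-subject standard deviations.  The three stock presets differ
    only in the crease, wedge, hypotelorism, orbital-ratio, vault-thickness
    and age-distribution parameters.
    """

    label: str
    half_axes: tuple = (65.0, 78.0, 58.0)       # x (half-width), y, z
    axis_noise_sd: float = 0.02                 # relative, per axis
    boss_amplitude: float = 0.055               # frontal boss (relative radius)
    boss_amplitude_sd: float = 0.005
    boss_azimuth_sigma: float = 0.55            # rad
    boss_elevation_center: float = 0.25         # rad
    boss_elevation_sigma: float = 0.70
    crease_amplitude: float = 0.0               # midline metopic crease
    crease_amplitude_sd: float = 0.0
    crease_amplitude_floor: float = 0.0
    crease_azimuth_sigma: float = 0.20          # rad; small = sharp ridge
    crease_elevation_sigma: float = 0.30        # rad; extent glabella -> vertex
    wedge_narrowing: float = 0.0                # TG frontal lateral compression
    wedge_narrowing_sd: float = 0.0
    hypotelorism_offset: float = 0.0            # mm per side
    hypotelorism_sd: float = 0.2
    notch_azimuth_sd: float = 0.12              # rad; supra-orbital notch placement
    interorbital_base: float = 17.0             # mm, LM1-LM2 in controls
    interorbital_sd: float = 1.0
    orbital_width: float = 25.0
    orbital_width_sd: float = 0.6
    orbital_ratio: float = 0.886
    orbital_ratio_sd: float = 0.028
    vault_thickness: float = 4.5                # mm, vault to intracranial surface
    vertex_noise_sd: float = 0.25               # mm, radial
    landmark_noise_sd: float = 0.20             # mm, before surface snapping
    age_mean: float = 218.7                     # days
    age_sd: float = 107.8
    age_range: tuple = (30.0, 900.0)
    girls_fraction: float = 0.511
    subdivisions: int = 4

    def __post_init__(self) -> None:
        if not (0.0 <= self.crease_amplitude <= 0.3):
            raise ValueError("crease amplitude outside [0, 0.3]")
        if not (0.0 <= self.wedge_narrowing <= 0.6):
            raise ValueError("wedge narrowing outside [0, 0.6]")
        if not (0.0 <= self.boss_amplitude <= 0.3):
            raise ValueError("boss amplitude outside [0, 0.3]")
        for name in ("axis_noise_sd", "boss_amplitude_sd", "crease_amplitude_sd",
                     "wedge_narrowing_sd", "hypotelorism_sd", "interorbital_sd",
                     "orbital_width_sd", "orbital_ratio_sd", "vertex_noise_sd",
                     "landmark_noise_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.vault_thickness <= 0 or self.age_range[0] >= self.age_range[1]:
            raise ValueError("invalid thickness or age range")


#: stock presets; MR is the control vault plus an isolated glabella-proximal
#: crease (and the mild orbital differences the clinic reports), TG adds the
#: wedge, a wide strong crease and marked hypotelorism.
DEFAULT_PRESETS = {
    "C": PhenotypePreset(label="C"),
    "MR": replace(
        PhenotypePreset(label="C"), label="MR",
        crease_amplitude=0.045, crease_amplitude_sd=0.007,
        crease_amplitude_floor=0.015,
        crease_azimuth_sigma=0.18, crease_elevation_sigma=0.25,
        hypotelorism_offset=0.75,
        orbital_ratio=0.920,
        age_mean=379.25, age_sd=224.7, girls_fraction=0.407,
    ),
    "TG": replace(
        PhenotypePreset(label="C"), label="TG",
        half_axes=(67.5, 77.0, 58.0),
        crease_amplitude=0.060, crease_amplitude_sd=0.008,
        crease_amplitude_floor=0.040,
        crease_azimuth_sigma=0.25, crease_elevation_sigma=0.80,
        wedge_narrowing=0.18, wedge_narrowing_sd=0.025,
        hypotelorism_offset=1.55,
        orbital_ratio=0.866,
        vault_thickness=3.2,
        age_mean=219.3, age_sd=81.4, girls_fraction=0.30,
    ),
}


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    age_days: float
    sex: str
    vault: TriangleMesh
    intracranial: TriangleMesh
    landmarks: CranialLandmarkSet
    orbits: OrbitalLandmarkSet
    ground_truth: dict = field(default_factory=dict)


_UNIT_SPHERES: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _unit_sphere(subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    if subdivisions not in _UNIT_SPHERES:
        s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        _UNIT_SPHERES[subdivisions] = (np.asarray(s.vertices, float), np.asarray(s.faces))
    return _UNIT_SPHERES[subdivisions]


def growth_scale(age_days: float) -> float:
    """Monotone isotropic growth factor, 1.0 at the reference age."""
    return float((age_days / REFERENCE_AGE_DAYS) ** GROWTH_EXPONENT)


def _deform(points: np.ndarray, params: dict) -> np.ndarray:
    """Apply boss + crease (radial) then wedge narrowing to ellipsoid points."""
    p = points.copy()
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    az = np.arctan2(x, y)
    el = np.arctan2(z, np.hypot(x, y))
    boss = params["boss"] * np.exp(-(az / params["boss_az_sigma"]) ** 2) \
        * np.exp(-((el - params["boss_el_center"]) / params["boss_el_sigma"]) ** 2)
    up = np.maximum(el, 0.0) / params["crease_el_sigma"]
    down = np.minimum(el, 0.0) / 0.15  # quick decay below the glabella
    crease = params["crease"] * np.exp(-np.abs(az) / params["crease_az_sigma"]) \
        * np.exp(-(up ** 2) - (down ** 2))
    factor = 1.0 + boss + crease
    if (factor <= 0).any():
        raise GeometryError("radial factors collapse the surface "
                            f"(boss={params['boss']:.3g}, crease={params['crease']:.3g})")
    p = p * factor[:, None]
    w = np.clip(y / params["ay"], 0.0, 1.0) ** 2
    shrink = 1.0 - params["wedge"] * w
    if (shrink <= 0).any():
        raise GeometryError(f"wedge narrowing {params['wedge']:.3g} self-intersects")
    p[:, 0] = p[:, 0] * shrink
    return p


def _angles_to_direction(azimuth: float, elevation: float) -> np.ndarray:
    return np.array([np.cos(elevation) * np.sin(azimuth),
                     np.cos(elevation) * np.cos(azimuth),
                     np.sin(elevation)])


def make_skull(preset: PhenotypePreset, age: float, seed,
               subject_id: str = "subj", sex: str | None = None) -> SyntheticSubject:
    """Generate one synthetic subject (vault, intracranial mesh, landmarks).

    Deterministic given (preset, age, seed).  ``seed`` may be an int or a
    ``numpy`` SeedSequence-compatible value.
    """
    lo, hi = preset.age_range
    if not (lo <= age <= hi):
        raise ValueError(f"age {age} outside preset range {preset.age_range}")
    rng = np.random.default_rng(seed)
    g = growth_scale(age)
    axes = np.asarray(preset.half_axes) * g \
        * (1.0 + rng.normal(0.0, preset.axis_noise_sd, 3))
    boss = max(0.0, rng.normal(preset.boss_amplitude, preset.boss_amplitude_sd))
    crease = rng.normal(preset.crease_amplitude, preset.crease_amplitude_sd)
    crease = max(crease, preset.crease_amplitude_floor)
    wedge = float(np.clip(rng.normal(preset.wedge_narrowing, preset.wedge_narrowing_sd),
                          0.0, 0.6)) if preset.wedge_narrowing > 0 else 0.0
    params = {
        "boss": boss, "boss_az_sigma": preset.boss_azimuth_sigma,
        "boss_el_center": preset.boss_elevation_center,
        "boss_el_sigma": preset.boss_elevation_sigma,
        "crease": crease, "crease_az_sigma": preset.crease_azimuth_sigma,
        "crease_el_sigma": preset.crease_elevation_sigma,
        "wedge": wedge, "ay": axes[1],
    }
    dirs, faces = _unit_sphere(preset.subdivisions)
    base = dirs * axes
    clean = _deform(base, params)
    noise = rng.normal(0.0, preset.vertex_noise_sd, len(clean))
    radii = np.linalg.norm(clean, axis=1)
    vault = TriangleMesh(clean * (1.0 + noise / radii)[:, None], faces.copy())

    # intracranial surface: clean vault offset inward by the vault thickness
    th = preset.vault_thickness
    inner = clean * ((radii - th) / radii)[:, None]
    intracranial = TriangleMesh(inner, faces.copy())

    # cranial landmarks through the same chain, then snapped to the vault
    lm_pts = {}
    for name, (azim, elev) in _LANDMARK_ANGLES.items():
        if name.startswith("supraorbital_notch"):
            # clamp away from the midline so the notch can never approach the
            # apex (which would degenerate the interfrontal angle)
            jit = rng.normal(0.0, preset.notch_azimuth_sd)
            azim = np.sign(azim) * float(np.clip(abs(azim) + jit, 0.15, 0.60))
        d = _angles_to_direction(azim, elev)
        lm_pts[name] = _deform((d * axes)[None], params)[0]
    names = list(lm_pts)
    pts = np.stack([lm_pts[n] for n in names])
    pts = pts + rng.normal(0.0, preset.landmark_noise_sd, pts.shape)
    snapped, _ = closest_point_on_mesh(vault, pts)
    landmarks = CranialLandmarkSet({n: p for n, p in zip(names, snapped)})

    # orbital landmarks: constructed around the orbits in the build frame
    D = g * (preset.interorbital_base - 2.0 * preset.hypotelorism_offset
             - 2.0 * rng.normal(0.0, preset.hypotelorism_sd)) \
        + rng.normal(0.0, preset.interorbital_sd)
    if D <= 2.0:
        raise GeometryError("inter-orbital distance collapsed; "
                            "check hypotelorism offset")
    W = g * preset.orbital_width * (1.0 + rng.normal(0.0, preset.orbital_width_sd
                                                     / preset.orbital_width))
    H = W * rng.normal(preset.orbital_ratio, preset.orbital_ratio_sd)
    y1 = axes[1] * 0.90
    z_m = -0.22 * axes[2]
    anat = {}
    for side, s in (("L", -1.0), ("R", +1.0)):
        anat["LM1" if s < 0 else "LM2"] = np.array([s * D / 2, y1, z_m + 0.15 * H])
        anat["LM3" if s < 0 else "LM4"] = np.array([s * (D / 2 + 0.5 * W), y1 - 3.0,
                                                    z_m + 0.5 * H])
        anat["LM5" if s < 0 else "LM6"] = np.array([s * (D / 2 + W), y1 - 8.0, z_m])
        anat["LM7" if s < 0 else "LM8"] = np.array([s * (D / 2 + 0.55 * W), y1 - 4.0,
                                                    z_m - 0.5 * H])
    semis = []
    for s in (-1.0, +1.0):
        center = np.array([s * (D / 2 + 0.5 * W), y1 - 3.5, z_m])
        t = np.linspace(0.0, 2.0 * np.pi, 25, endpoint=False)
        ring = np.stack([center[0] + s * 0.5 * W * np.cos(t),
                         np.full_like(t, center[1]),
                         center[2] + 0.5 * H * np.sin(t)], axis=1)
        semis.append(ring + rng.normal(0.0, 0.3, ring.shape))
    orbits = OrbitalLandmarkSet(anat, np.vstack(semis), n_left=25)

    truth = {"boss": boss, "crease": crease, "wedge": wedge,
             "hypotelorism": preset.hypotelorism_offset, "growth": g,
             "axes": axes.tolist(), "thickness": th}
    if sex is None:
        sex = "f" if rng.random() < preset.girls_fraction else "m"
    return SyntheticSubject(subject_id=subject_id, group=preset.label,
                            age_days=float(age), sex=sex, vault=vault,
                            intracranial=intracranial, landmarks=landmarks,
                            orbits=orbits, ground_truth=truth)


def _draw_age(preset: PhenotypePreset, rng: np.random.Generator) -> float:
    lo, hi = preset.age_range
    for _ in range(1000):
        a = rng.normal(preset.age_mean, preset.age_sd)
        if lo <= a <= hi:
            return float(a)
    return float(np.clip(preset.age_mean, lo, hi))


def sample_cohort(n_per_group=(90, 27, 90), presets=None, seed: int = 0,
                  out_dir=None) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Draw a cohort (default sizes 90 TG / 27 MR / 90 C as in the study design).

    ``n_per_group`` maps group order (TG, MR, C) when given as a tuple, or is
    a dict label -> n.  With ``out_dir`` the meshes (STL), landmark JSON and
    metadata CSV are written out.
    """
    presets = dict(presets) if presets else dict(DEFAULT_PRESETS)
    if isinstance(n_per_group, dict):
        sizes = dict(n_per_group)
    else:
        order = ("TG", "MR", "C")
        sizes = dict(zip(order, n_per_group))
    for lbl, n in sizes.items():
        if n < 3:
            raise ValueError(f"need n >= 3 per group (got {n} for {lbl!r})")
        if lbl not in presets:
            raise ValueError(f"no preset for group {lbl!r}")
    root = np.random.SeedSequence(seed)
    subjects: list[SyntheticSubject] = []
    rows = []
    streams = root.spawn(sum(sizes.values()) + 1)
    age_rng = np.random.default_rng(streams[0])
    i = 0
    for lbl, n in sizes.items():
        preset = presets[lbl]
        for j in range(n):
            i += 1
            sid = f"{lbl}{j + 1:03d}"
            age = _draw_age(preset, age_rng)
            subj = make_skull(preset, age, streams[i], subject_id=sid)
            subjects.append(subj)
            rows.append({"subject_id": sid, "group": lbl,
                         "age_days": subj.age_days, "sex": subj.sex,
                         **{f"gt_{k}": v for k, v in subj.ground_truth.items()
                            if np.isscalar(v)}})
    meta = pd.DataFrame(rows)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s in subjects:
            write_stl(s.vault, out / f"{s.subject_id}_vault.stl")
            write_stl(s.intracranial, out / f"{s.subject_id}_endo.stl")
            s.landmarks.to_json(out / f"{s.subject_id}_landmarks.json")
            cols = {}
            for k, v in s.orbits.anatomical.items():
                cols[k] = v
            orb = pd.DataFrame(
                np.vstack([s.orbits.as_array(), s.orbits.semilandmarks]),
                columns=["x", "y", "z"],
                index=list(ANATOMICAL_NAMES) + [f"semi{i}" for i in range(50)])
            orb.to_csv(out / f"{s.subject_id}_orbits.csv")
        meta.to_csv(out / "metadata.csv", index=False)
    return subjects, meta


def intracranial_volume(subject: SyntheticSubject) -> float:
    return mesh_volume(subject.intracranial)
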