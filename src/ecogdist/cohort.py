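"""Synthetic cohort generator.

Real intraoperative cohorts of this kind are not publicly deposited, so the
package ships a generator that emulates the full data set the pipeline
consumes: a cortical surface per patient, a binary lesion abutting it,
electrode grids/strips marched across the surface (with a hidden tail of
electrodes whose positions must be re-derived by extrapolation), and
per-channel event logs whose rate-versus-distance structure matches the
study conditions — per-pathology distance-rate slopes, rate scales, lesion
volumes, patient counts and channel counts of a 33-patient surgical cohort.

Rates are generated *conditionally on distance* (the causal direction) and
later analysed in the reverse orientation (distance regressed on rate).
For a configured slope ``b`` (mm per event/min), rate-vs-distance
coefficient is chosen as ``gamma = b * sd_rate^2 / sd_distance^2`` so that
the reverse regression recovers ``b`` in expectation; event counts are
gamma-mixed Poisson over the epoch, with the mixing variance set so the
marginal rate SD matches the configured scale.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from . import io as edio
from .events import EVENT_TYPES, PATHOLOGIES, montage_midpoints
from .geometry import (
    CorticalSurface,
    ElectrodeArray,
    LesionVolume,
    euclidean_com_distance,
    euclidean_edge_distance,
    geodesic_distances,
    lesion_volume_cm3,
)

__all__ = [
    "CohortSpec",
    "SyntheticPatient",
    "Cohort",
    "make_surface",
    "make_lesion",
    "make_rates",
    "make_cohort",
    "DEFAULT_N_PATIENTS",
    "DEFAULT_SLOPES",
    "DEFAULT_RATE_SCALES",
    "DEFAULT_VOLUMES",
    "DEFAULT_CHANNEL_COUNTS",
]

# -- study conditions -------------------------------------------------------
# Patients per pathology and per-pathology lesion volume mean/SD (cm^3) of
# the emulated 33-patient cohort.
DEFAULT_N_PATIENTS: dict[str, int] = {
    "FCD": 12,
    "ganglioglioma": 9,
    "DNET": 5,
    "low_grade_glioma": 3,
    "PXA": 2,
    "cavernoma": 2,
}

DEFAULT_VOLUMES: dict[str, tuple[float, float]] = {
    "FCD": (2.5, 3.0),
    "ganglioglioma": (10.6, 9.7),
    "DNET": (12.6, 9.4),
    "low_grade_glioma": (20.8, 28.6),
    "PXA": (7.0, 8.2),
    "cavernoma": (2.1, 0.01),
}

# Distance-on-rate slopes (mm per event/min) per event type and pathology.
DEFAULT_SLOPES: dict[str, dict[str, float]] = {
    "spike": {
        "cavernoma": -1.37,
        "FCD": -0.25,
        "PXA": -0.18,
        "low_grade_glioma": 0.65,
        "DNET": 0.0,
        "ganglioglioma": 0.0,
    },
    "ripple": {
        "FCD": -0.35,
        "low_grade_glioma": 2.67,
        "cavernoma": 0.0,
        "PXA": 0.0,
        "DNET": 0.0,
        "ganglioglioma": 0.0,
    },
    "fast_ripple": {
        "ganglioglioma": -2.22,
        "FCD": 0.0,
        "PXA": 0.0,
        # absent for these pathologies (None = no events generated)
    },
}

# Marginal rate scale (mean, SD) in events/min per pathology and type.
# ``None`` marks biomarkers never recorded for a pathology.
DEFAULT_RATE_SCALES: dict[str, dict[str, tuple[float, float] | None]] = {
    "spike": {
        "FCD": (9.4, 12.8),
        "ganglioglioma": (8.7, 10.1),
        "DNET": (3.7, 3.3),
        "low_grade_glioma": (10.0, 11.9),
        "PXA": (13.9, 15.3),
        "cavernoma": (4.1, 4.9),
    },
    "ripple": {
        "FCD": (6.0, 7.8),
        "ganglioglioma": (6.6, 7.3),
        "DNET": (3.7, 4.7),
        "low_grade_glioma": (3.9, 3.8),
        "PXA": (4.2, 4.4),
        "cavernoma": (2.3, 1.7),
    },
    "fast_ripple": {
        "FCD": (4.4, 8.2),
        "ganglioglioma": (2.0, 1.7),
        "PXA": (1.0, 0.5),
        "DNET": None,
        "low_grade_glioma": None,
        "cavernoma": None,
    },
}

# Included bipolar channel counts per pathology (used by recovery checks).
DEFAULT_CHANNEL_COUNTS: dict[str, int] = {
    "FCD": 572,
    "ganglioglioma": 368,
    "DNET": 245,
    "low_grade_glioma": 77,
    "PXA": 68,
    "cavernoma": 66,
}

DEFAULT_GRID_SPECS: tuple[tuple[int, int], ...] = ((4, 5), (4, 4), (1, 8))


@dataclass
class CohortSpec:
    """Full parameterization of a synthetic cohort.

    The defaults are the study conditions the analysis was designed for;
    ``seed`` fixes the entire output stream.
    """

    n_patients: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PATIENTS)
    )
    pathology_slopes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SLOPES.items()}
    )
    rate_scales: dict[str, dict[str, tuple[float, float] | None]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_RATE_SCALES.items()
        }
    )
    lesion_volume_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VOLUMES)
    )
    grid_specs: tuple[tuple[int, int], ...] = DEFAULT_GRID_SPECS
    hidden_fraction: float = 0.3
    artifact_fraction: float = 0.1
    epoch_length_s: float = 60.0
    nominal_spacing: float = 10.0
    surface_radius: float = 65.0
    surface_min_vertices: int = 2500
    surface_bump_amp: float = 0.03
    voxel_size_mm: float = 1.0
    max_recordings: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_patients.values()):
            raise ValueError("patient counts must be >= 0")
        for t, scales in self.rate_scales.items():
            for p, ms in scales.items():
                if ms is not None and ms[1] < 0:
                    raise ValueError(f"rate SD for {p}/{t} must be >= 0")
        if not 0 <= self.hidden_fraction < 1:
            raise ValueError("hidden_fraction must be in [0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortSpec":
        kwargs = {}
        for key, val in raw.items():
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown cohort spec field {key!r}")
            if key == "grid_specs":
                val = tuple(tuple(g) for g in val)
            if key in ("rate_scales", "lesion_volume_mean_sd"):
                val = {
                    k: (
                        {p: (None if v is None else tuple(v)) for p, v in k2.items()}
                        if isinstance(k2 := val[k], dict)
                        else k2
                    )
                    for k in val
                }
            kwargs[key] = val
        return cls(**kwargs)


@dataclass
class SyntheticPatient:
    patient_id: str
    pathology: str
    surface: CorticalSurface
    lesion: LesionVolume
    lesion_volume_cm3: float
    arrays: dict[tuple, ElectrodeArray]  # (patient, recording, array_id)
    true_arrays: dict[tuple, ElectrodeArray]  # with hidden coordinates filled
    channels: pd.DataFrame  # ground-truth channel table


@dataclass
class Cohort:
    spec: CohortSpec
    patients: list[SyntheticPatient]
    channels: pd.DataFrame
    events: pd.DataFrame
    artifacts: pd.DataFrame
    patient_table: pd.DataFrame


# --------------------------------------------------------------------------
# surfaces
# --------------------------------------------------------------------------


def _plane_surface(extent: float, spacing: float) -> CorticalSurface:
    n = max(2, int(round(extent / spacing)) + 1)
    xs = np.linspace(-extent / 2, extent / 2, n)
    xv, yv = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xv.ravel(), yv.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + 1
            c = a + n
            d = c + 1
            faces.append([a, b, c])
            faces.append([b, d, c])
    return CorticalSurface(vertices=verts, faces=np.array(faces))


def _icosphere(min_vertices: int, radius: float) -> trimesh.Trimesh:
    sub = 0
    while 10 * 4**sub + 2 < min_vertices:
        sub += 1
    return trimesh.creation.icosphere(subdivisions=sub, radius=radius)


def make_surface(
    kind: str,
    min_vertices: int = 2500,
    seed: int = 0,
    radius: float = 65.0,
    extent: float = 200.0,
    spacing: float = 5.0,
    bump_amp: float = 0.03,
) -> CorticalSurface:
    """Build a synthetic cortical surface.

    ``plane`` is a flat triangulated sheet at z=0 (``extent`` x ``extent``
    mm), ``sphere`` an icosphere with at least ``min_vertices`` vertices
    and known analytic geodesics, and ``bumpy_sphere`` a seeded smooth
    radial perturbation of the sphere that emulates gentle cortical
    curvature without folding.
    """
    if kind == "plane":
        return _plane_surface(extent, spacing)
    if kind == "sphere":
        mesh = _icosphere(min_vertices, radius)
        return CorticalSurface(
            vertices=np.asarray(mesh.vertices, float),
            faces=np.asarray(mesh.faces, np.int64),
        )
    if kind == "bumpy_sphere":
        mesh = _icosphere(min_vertices, radius)
        rng = np.random.default_rng(seed)
        v = np.asarray(mesh.vertices, float)
        u = v / np.linalg.norm(v, axis=1, keepdims=True)
        bump = np.zeros(len(v))
        n_modes = 6
        dirs = rng.normal(size=(n_modes, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        freqs = rng.uniform(1.5, 4.0, size=n_modes)
        phases = rng.uniform(0, 2 * np.pi, size=n_modes)
        for d, f, ph in zip(dirs, freqs, phases):
            bump += np.cos(f * np.pi * (u @ d) + ph)
        bump /= n_modes
        v = v * (1.0 + bump_amp * bump)[:, None]
        return CorticalSurface(vertices=v, faces=np.asarray(mesh.faces, np.int64))
    raise ValueError(f"invalid surface kind {kind!r}")


# --------------------------------------------------------------------------
# lesions
# --------------------------------------------------------------------------


def _vertex_outward_normal(surface: CorticalSurface, vidx: int) -> np.ndarray:
    proj = surface.projector()
    fids = proj._incident[vidx]
    normals = np.array([proj.face_normal(f) for f in fids])
    n = normals.mean(axis=0)
    n /= np.linalg.norm(n)
    centroid = surface.vertices.mean(axis=0)
    if np.dot(n, surface.vertices[vidx] - centroid) < 0:
        n = -n
    return n


def make_lesion(
    surface: CorticalSurface,
    volume_target_cm3: float,
    seed: int = 0,
    voxel_size_mm: float = 1.0,
    anchor_vertex: int | None = None,
    jitter: float = 0.35,
) -> LesionVolume:
    """Grow a connected lesion blob abutting the cortical surface.

    The blob is grown voxel-by-voxel from a seed just beneath a surface
    anchor vertex, ordered by jittered distance to the seed, which yields a
    connected, roughly ellipsoidal mask.  The realized volume equals the
    voxel-quantized target (within 10% for any target of a few voxels or
    more).
    """
    if volume_target_cm3 <= 0:
        raise ValueError("volume target must be positive")
    vox_vol = voxel_size_mm**3
    target_n = int(round(volume_target_cm3 * 1000.0 / vox_vol))
    if target_n < 1:
        raise ValueError(
            f"volume target {volume_target_cm3} cm^3 is smaller than one "
            f"voxel ({vox_vol / 1000.0} cm^3)"
        )
    rng = np.random.default_rng(seed)
    if anchor_vertex is None:
        anchor_vertex = int(rng.integers(0, len(surface.vertices)))
    anchor = surface.vertices[anchor_vertex]
    normal = _vertex_outward_normal(surface, anchor_vertex)
    r_blob = (3.0 * volume_target_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    center = anchor - normal * (0.6 * r_blob)

    half = r_blob * 1.6 + 4.0 * voxel_size_mm
    n_side = int(np.ceil(2 * half / voxel_size_mm)) + 1
    origin = center - half
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size_mm
    affine[:3, 3] = origin

    jit = rng.uniform(0.0, 1.0, size=(n_side, n_side, n_side))
    mask = np.zeros((n_side, n_side, n_side), dtype=bool)
    seed_ijk = tuple(np.clip(np.rint((center - origin) / voxel_size_mm), 0, n_side - 1).astype(int))

    def key(ijk: tuple[int, int, int]) -> float:
        world = origin + np.array(ijk) * voxel_size_mm
        d = np.linalg.norm(world - center)
        return d * (1.0 + jitter * jit[ijk])

    heap: list[tuple[float, tuple[int, int, int]]] = [(key(seed_ijk), seed_ijk)]
    seen = {seed_ijk}
    count = 0
    while heap and count < target_n:
        _, ijk = heapq.heappop(heap)
        mask[ijk] = True
        count += 1
        i, j, k = ijk
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nb = (i + di, j + dj, k + dk)
            if min(nb) < 0 or max(nb) >= n_side or nb in seen:
                continue
            seen.add(nb)
            heapq.heappush(heap, (key(nb), nb))
    if count < target_n:
        raise ValueError("lesion growth exhausted the voxel box")
    return LesionVolume(mask=mask, affine=affine)


# --------------------------------------------------------------------------
# rates
# --------------------------------------------------------------------------


def make_rates(
    d_edge,
    pathology: str,
    spec: CohortSpec | None = None,
    seed: int | np.random.Generator = 0,
    epoch_minutes: float = 1.0,
    require_recoverable: bool = False,
) -> dict[str, np.ndarray]:
    """Draw event counts per channel per biomarker type, given distances.

    Expected rate declines (or rises) linearly with lesion-edge distance at
    ``gamma = slope * sd_rate^2 / var(d)`` and is clipped at zero; counts
    are gamma-mixed Poisson over the epoch so the marginal rate variance
    matches the configured rate SD.  Zero-slope pathologies get
    distance-independent rates; biomarkers configured as absent yield
    all-zero counts.
    """
    spec = spec or CohortSpec()
    d = np.asarray(d_edge, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    n = len(d)
    var_d = d.var() if n > 1 else 0.0
    out: dict[str, np.ndarray] = {}
    for etype in EVENT_TYPES:
        scale = spec.rate_scales[etype].get(pathology)
        if scale is None:
            out[etype] = np.zeros(n, dtype=int)
            continue
        lam0, sd_r = scale
        slope = spec.pathology_slopes[etype].get(pathology, 0.0)
        if slope == 0.0:
            if require_recoverable:
                raise ValueError(
                    f"zero slope configured for {pathology}/{etype}: slope "
                    "recovery is not testable"
                )
            gamma = 0.0
        else:
            if var_d <= 0:
                raise ValueError(
                    "cannot inject a distance-rate slope with constant distances"
                )
            # A slope b with rate SD s_r over distances of variance v_d
            # implies a squared correlation (b*s_r)^2/v_d.  When the
            # requested slope asks for more correlation than the channel
            # geometry can carry, the realized slope saturates at the
            # attainable strength (max_r2) with the requested sign.
            max_r2 = 0.8
            implied_r2 = (slope * sd_r) ** 2 / var_d
            eff_slope = slope
            if implied_r2 > max_r2:
                eff_slope = np.sign(slope) * np.sqrt(max_r2 * var_d) / sd_r
            gamma = eff_slope * sd_r**2 / var_d
        lam = np.clip(lam0 + gamma * (d - d.mean()), 0.0, None)
        v_extra = max(0.0, sd_r**2 - gamma**2 * var_d - lam.mean() / epoch_minutes)
        if v_extra > 0:
            pos = lam > 0
            lam_mixed = np.zeros(n)
            shape = np.where(pos, lam**2 / v_extra, 1.0)
            theta = np.where(pos, v_extra / np.where(pos, lam, 1.0), 0.0)
            lam_mixed[pos] = rng.gamma(shape[pos], theta[pos])
        else:
            lam_mixed = lam
        out[etype] = rng.poisson(lam_mixed * epoch_minutes).astype(int)
    return out


# --------------------------------------------------------------------------
# electrode array construction on a surface
# --------------------------------------------------------------------------


from .geometry import _corner_point, _march_point  # placement primitives


def _step_from(proj, x0: np.ndarray, direction: np.ndarray, spacing: float,
               max_iter: int = 120, tol: float = 1e-10) -> np.ndarray:
    d = direction / np.linalg.norm(direction)
    y = x0 + spacing * d
    for _ in range(max_iter):
        ys, _ = proj.project(y)
        v = ys - x0
        n = np.linalg.norm(v)
        if n == 0:
            y = y + 1e-9
            continue
        y_new = x0 + spacing * v / n
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def construct_array_on_surface(
    surface: CorticalSurface,
    p0_hint: np.ndarray,
    direction_hint: np.ndarray,
    n_rows: int,
    n_cols: int,
    spacing: float = 10.0,
    array_id: str = "G",
) -> ElectrodeArray:
    """March a full rows x cols lattice across the surface.

    Row 0 is marched from the seed point along the (projected) direction
    hint; each further row starts perpendicular to row 0 and is completed
    column-by-column with the same in-line/corner rules the extrapolation
    operation uses, so a partially hidden copy of the result is exactly
    re-derivable.
    """
    proj = surface.projector()
    x = np.full((n_rows, n_cols, 3), np.nan)
    p0, _, f0 = proj.project_face(p0_hint)
    x[0, 0] = p0
    if n_cols > 1:
        nrm = proj.face_normal(f0)
        t1 = direction_hint - np.dot(direction_hint, nrm) * nrm
        if np.linalg.norm(t1) < 1e-9:
            raise ValueError("direction hint is normal to the surface")
        x[0, 1] = _step_from(proj, p0, t1, spacing)
    for c in range(2, n_cols):
        x[0, c] = _march_point(proj, x[0, c - 2], x[0, c - 1], spacing)
    if n_rows > 1:
        nrm = proj.face_normal(f0)
        t2 = np.cross(nrm, x[0, 1] - x[0, 0] if n_cols > 1 else direction_hint)
        x[1, 0] = _step_from(proj, p0, t2, spacing)
        if n_cols > 1:
            x[1, 1] = _corner_point(proj, x[1, 0], x[0, 1], x[0, 0], spacing)
        for r in range(2, n_rows):
            x[r, 0] = _march_point(proj, x[r - 2, 0], x[r - 1, 0], spacing)
            if n_cols > 1:
                x[r, 1] = _corner_point(proj, x[r, 0], x[r - 1, 1], x[r - 1, 0], spacing)
        for r in range(1, n_rows):
            for c in range(2, n_cols):
                x[r, c] = _corner_point(
                    proj, x[r, c - 1], x[r - 1, c], x[r - 1, c - 1], spacing
                )
    coords = x.reshape(n_rows * n_cols, 3)
    return ElectrodeArray(
        array_id=array_id,
        n_rows=n_rows,
        n_cols=n_cols,
        coordinates=coords,
        visible=np.ones(n_rows * n_cols, dtype=bool),
        nominal_spacing=spacing,
    )


def hide_trailing_columns(array: ElectrodeArray, fraction: float) -> ElectrodeArray:
    """Mark the trailing columns (the part slipped under the skull) hidden.

    At least two leading columns stay visible so extrapolation has an
    adjacent seed pair in every row.
    """
    n_hidden = min(int(round(fraction * array.n_cols)), array.n_cols - 2)
    n_hidden = max(n_hidden, 0)
    coords = array.coordinates.copy()
    visible = np.ones(array.n_electrodes, dtype=bool)
    for c in range(array.n_cols - n_hidden, array.n_cols):
        for r in range(array.n_rows):
            i = array.index(r, c)
            coords[i] = np.nan
            visible[i] = False
    return ElectrodeArray(
        array_id=array.array_id,
        n_rows=array.n_rows,
        n_cols=array.n_cols,
        coordinates=coords,
        visible=visible,
        nominal_spacing=array.nominal_spacing,
    )


# --------------------------------------------------------------------------
# full cohort
# --------------------------------------------------------------------------


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sd = max(sd, 1e-6)
    s2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _random_tangent(rng: np.random.Generator, normal: np.ndarray) -> np.ndarray:
    v = rng.normal(size=3)
    v -= np.dot(v, normal) * normal
    n = np.linalg.norm(v)
    while n < 1e-9:
        v = rng.normal(size=3)
        v -= np.dot(v, normal) * normal
        n = np.linalg.norm(v)
    return v / n


def _make_patient(
    pid: str,
    pathology: str,
    spec: CohortSpec,
    ss: np.random.SeedSequence,
) -> SyntheticPatient:
    seeds = ss.spawn(5)
    rng = np.random.default_rng(seeds[0])
    surface = make_surface(
        "bumpy_sphere",
        min_vertices=spec.surface_min_vertices,
        seed=int(seeds[1].generate_state(1)[0] % (2**31)),
        radius=spec.surface_radius,
        bump_amp=spec.surface_bump_amp,
    )
    mu, sd = spec.lesion_volume_mean_sd[pathology]
    m_ln, s_ln = _lognormal_params(mu, sd)
    volume_target = float(np.exp(rng.normal(m_ln, s_ln)))
    volume_target = max(volume_target, 0.05)
    anchor = int(rng.integers(0, len(surface.vertices)))
    lesion = make_lesion(
        surface,
        volume_target,
        seed=int(seeds[2].generate_state(1)[0] % (2**31)),
        voxel_size_mm=spec.voxel_size_mm,
        anchor_vertex=anchor,
    )
    vol = lesion_volume_cm3(lesion)

    anchor_pt = surface.vertices[anchor]
    normal = _vertex_outward_normal(surface, anchor)
    n_rec = int(rng.integers(1, spec.max_recordings + 1))
    arrays: dict[tuple, ElectrodeArray] = {}
    true_arrays: dict[tuple, ElectrodeArray] = {}
    chan_rows = []
    for rec in range(n_rec):
        rid = f"R{rec + 1}"
        rows, cols = spec.grid_specs[int(rng.integers(0, len(spec.grid_specs)))]
        aid = f"{pid}_{rid}_A1"
        offset_dir = _random_tangent(rng, normal)
        offset = offset_dir * rng.uniform(0.0, 15.0)
        march_dir = _random_tangent(rng, normal)
        arr = construct_array_on_surface(
            surface,
            anchor_pt + offset,
            march_dir,
            rows,
            cols,
            spacing=spec.nominal_spacing,
            array_id=aid,
        )
        key = (pid, rid, aid)
        true_arrays[key] = arr
        arrays[key] = hide_trailing_columns(arr, spec.hidden_fraction)
        mids = montage_midpoints(arr, direction="row")
        mids.insert(0, "patient_id", pid)
        mids.insert(1, "recording_id", rid)
        chan_rows.append(mids)

    channels = pd.concat(chan_rows, ignore_index=True)
    pts = channels[["mid_x", "mid_y", "mid_z"]].to_numpy(float)
    channels["d_edge_mm"] = [euclidean_edge_distance(p, lesion) for p in pts]
    channels["d_com_mm"] = [euclidean_com_distance(p, lesion) for p in pts]
    channels["d_geo_mm"] = geodesic_distances(
        pts, lesion, surface, labels=channels["channel_id"].tolist()
    )
    channels["pathology"] = pathology
    channels["lesion_volume_cm3"] = vol
    art_rng = np.random.default_rng(seeds[3])
    channels["artifact"] = art_rng.random(len(channels)) < spec.artifact_fraction
    return SyntheticPatient(
        patient_id=pid,
        pathology=pathology,
        surface=surface,
        lesion=lesion,
        lesion_volume_cm3=vol,
        arrays=arrays,
        true_arrays=true_arrays,
        channels=channels,
    )


def make_cohort(spec: CohortSpec | None = None, out_dir: str | Path | None = None) -> Cohort:
    """Generate a complete synthetic cohort; optionally write it to disk.

    The on-disk layout (one directory per patient with lesion NIfTI,
    surface PLY and electrode TSV, plus cohort-level event/artifact/patient
    CSVs) is exactly what the pipeline stages consume.  Rates are drawn
    per pathology over the pooled non-artifact channels so the injected
    slope refers to the same pooled regression the analysis runs.
    """
    spec = spec or CohortSpec()
    root = np.random.SeedSequence(spec.seed)
    patients: list[SyntheticPatient] = []
    order = [p for p in PATHOLOGIES for _ in range(spec.n_patients.get(p, 0))]
    seeds = root.spawn(len(order) + 1)
    for i, pathology in enumerate(order):
        pid = f"P{i + 1:02d}"
        patients.append(_make_patient(pid, pathology, spec, seeds[i]))

    channels = pd.concat([p.channels for p in patients], ignore_index=True)
    epoch_min = spec.epoch_length_s / 60.0

    # event counts per pathology over pooled included channels
    rate_rng = np.random.default_rng(seeds[-1])
    for t in EVENT_TYPES:
        channels[f"{t}_count"] = 0
    for pathology in PATHOLOGIES:
        sel = (channels["pathology"] == pathology) & (~channels["artifact"])
        if not sel.any():
            continue
        d = channels.loc[sel, "d_edge_mm"].to_numpy(float)
        counts = make_rates(
            d, pathology, spec, seed=rate_rng, epoch_minutes=epoch_min
        )
        for t in EVENT_TYPES:
            channels.loc[sel, f"{t}_count"] = counts[t]
    for t in EVENT_TYPES:
        channels[f"{t}_rate"] = channels[f"{t}_count"] / epoch_min

    # event logs with uniform times within the epoch
    ev_rows = []
    for _, row in channels.iterrows():
        for t in EVENT_TYPES:
            k = int(row[f"{t}_count"])
            if k == 0:
                continue
            times = np.sort(rate_rng.uniform(0.0, spec.epoch_length_s, size=k))
            for tt in times:
                ev_rows.append(
                    {
                        "patient_id": row["patient_id"],
                        "recording_id": row["recording_id"],
                        "channel_id": row["channel_id"],
                        "event_type": t,
                        "time_s": round(float(tt), 4),
                        "epoch_length_s": spec.epoch_length_s,
                    }
                )
    events = pd.DataFrame(ev_rows, columns=edio.EVENT_COLUMNS)
    artifacts = channels.loc[
        channels["artifact"], ["patient_id", "recording_id", "channel_id"]
    ].reset_index(drop=True)
    patient_table = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "pathology": [p.pathology for p in patients],
            "lesion_volume_cm3": [p.lesion_volume_cm3 for p in patients],
        }
    )
    cohort = Cohort(
        spec=spec,
        patients=patients,
        channels=channels,
        events=events,
        artifacts=artifacts,
        patient_table=patient_table,
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write the cohort in the formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in cohort.patients:
        pdir = out / p.patient_id
        pdir.mkdir(exist_ok=True)
        edio.save_lesion(p.lesion, pdir / "lesion.nii")
        edio.save_surface(p.surface, pdir / "surface.ply")
        edio.save_electrodes(
            edio.arrays_to_electrode_table(p.arrays), pdir / "electrodes.tsv"
        )
    cohort.events.to_csv(out / "events.csv", index=False, float_format=edio.FLOAT_FMT)
    cohort.artifacts.to_csv(out / "artifacts.csv", index=False)
    cohort.patient_table.to_csv(
        out / "patients.csv", index=False, float_format=edio.FLOAT_FMT
    )
    truth_cols = [
        "patient_id",
        "recording_id",
        "channel_id",
        "pathology",
        "lesion_volume_cm3",
        "mid_x",
        "mid_y",
        "mid_z",
        "d_edge_mm",
        "d_com_mm",
        "d_geo_mm",
        "artifact",
    ] + [f"{t}_rate" for t in EVENT_TYPES]
    cohort.channels[truth_cols].to_csv(
        out / "channels_truth.csv", index=False, float_format=edio.FLOAT_FMT
    )
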