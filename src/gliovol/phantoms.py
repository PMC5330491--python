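"""Synthetic longitudinal glioblastoma cohorts with known ground truth.

Two levels of fidelity are provided:

* :func:`simulate_cohort_table` draws per-patient volume *trajectories*
  (contrast-enhancing volume CV and FLAIR-hyperintense volume FV, in ml),
  0–5 consensus ratings, rater pairs, histopathology / tumor-board labels
  and binary progression ground truth — the tabular shape of a clinical
  volumetry dataset.
* :func:`render_phantom_images` voxelises each scan of such a cohort into
  MPRage-like and FLAIR-like 3D images plus truth masks, on the scan's own
  rigidly displaced native grid, so that segmentation, registration and
  mask subtraction can be exercised against known truth.

The generator's defaults emulate a typical single-centre glioblastoma
follow-up cohort: ~30 patients with 3–12 high-resolution scans each,
median CV around 2.8 ml and median FV around 50 ml across all scans, a
progression rate of roughly 55% among follow-ups, and progression driven
chiefly by multiplicative growth of the contrast-enhancing compartment.

Tumor geometry is a union of 2–5 overlapping, randomly oriented ellipsoids
with a smooth lobulated boundary perturbation; necrotic cavities with rim
enhancement can optionally be placed adjacent to (but outside) the tumor
as segmentation confounders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .grids import BinaryMask, ImageVolume

__all__ = [
    "PhantomSpec",
    "ScanTruth",
    "PatientTruth",
    "GroundTruth",
    "RenderedScan",
    "GenerationError",
    "simulate_cohort_table",
    "render_patient",
    "render_scan",
    "render_phantom_images",
    "true_pair_transform",
]

# Empirical scans-per-patient histogram of a 30-patient GB follow-up cohort
# (3 scans: 6 patients, 4: 3, 5: 7, 6: 7, 7: 4, 8: 1, 10: 1, 12: 1).
_SCANS_HIST: dict[int, int] = {3: 6, 4: 3, 5: 7, 6: 7, 7: 4, 8: 1, 10: 1, 12: 1}

# Sphere isoperimetric constant: surface = _SPHERE_A * volume**(2/3).
_SPHERE_A = (36.0 * math.pi) ** (1.0 / 3.0)


class GenerationError(RuntimeError):
    """Raised when a phantom cannot be generated (e.g. tumor exceeds grid)."""


@dataclass
class PhantomSpec:
    """Configuration of a synthetic longitudinal cohort.

    Volume units are ml, lengths mm, angles degrees.  ``growth_effect`` is
    the multiplicative CV change applied on a true progression event
    (``growth_effect=1`` produces a null cohort whose progression labels
    are independent of the volume trajectories).
    """

    n_patients: int = 30
    scans_per_patient: tuple[int, int] = (3, 12)
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # log-normal CV at cohort entry; median ml and log-scale sigma
    cv_baseline_median_ml: float = 1.5
    cv_baseline_sigma: float = 0.8
    # FV/CV ratio at cohort entry
    fv_to_cv_ratio_median: float = 30.0
    fv_to_cv_ratio_sigma: float = 0.5
    # follow-up event model
    progression_prob: float = 0.55
    regression_prob: float = 0.12
    growth_effect: float = 1.9
    growth_noise_sd: float = 0.20
    regression_effect: float = 0.55
    stable_sd: float = 0.12
    pseudo_progression_prob: float = 0.15
    pseudo_progression_growth: tuple[float, float] = (1.1, 1.5)
    # a true progression may look equivocal at rating time (category 4)
    uncertain_progression_prob: float = 0.15
    # FV dynamics: weakly coupled to CV events, with its own fluctuation and
    # a slight negative drift (therapy-related edema regression)
    fv_coupling: float = 0.3
    fv_fluct_sd: float = 0.22
    fv_drift: float = -0.04
    # diagnosis/postoperative prologue
    start_at_diagnosis_prob: float = 0.2
    postop_cv_residual: tuple[float, float] = (0.05, 0.35)
    postop_fv_residual: tuple[float, float] = (0.40, 0.80)
    # rating / consensus noise
    rating_noise: float = 0.06
    rc_noise: float = 0.06
    histology_prob: float = 0.164
    board_prob: float = 0.42
    # volumetry measurement noise: sigma = LSC / 2.77 (LSC convention for
    # the difference of two measurements at 95% confidence)
    meas_sigma_cv: float = 0.352 / 2.77
    meas_sigma_fv: float = 0.144 / 2.77
    # regional-subtraction surface-shell model: effective misalignment (mm)
    # combining residual registration error and boundary redraw jitter
    scv_shell_mm: float = 1.5
    sfv_shell_mm: float = 3.0
    # imaging
    noise_sd: float = 0.08
    misregistration_sd: float = 2.0
    include_confounders: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.scans_per_patient
        if lo < 3:
            raise ValueError(
                "scans_per_patient minimum must be >= 3 (cohort inclusion "
                "requires at least three follow-up MRIs)"
            )
        if hi < lo:
            raise ValueError("scans_per_patient range must satisfy min <= max")
        if any(n < 8 or n > 256 for n in self.grid_shape):
            raise ValueError("grid_shape axes must be within [8, 256]")
        for name in (
            "cv_baseline_median_ml",
            "cv_baseline_sigma",
            "fv_to_cv_ratio_median",
            "fv_to_cv_ratio_sigma",
            "growth_effect",
            "meas_sigma_cv",
            "meas_sigma_fv",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("progression_prob", "regression_prob", "rating_noise", "rc_noise",
                     "histology_prob", "board_prob", "start_at_diagnosis_prob",
                     "pseudo_progression_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.progression_prob + self.regression_prob > 1.0:
            raise ValueError("progression_prob + regression_prob must be <= 1")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if self.noise_sd < 0 or self.misregistration_sd < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class ScanTruth:
    """Ground truth of a single scan (native-grid pose and true volumes)."""

    scan_index: int
    true_cv_ml: float
    true_fv_ml: float
    category: int  # true 0-5 disease state
    progression: bool | None  # None for the first scan (no preceding scan)
    pose_angles_deg: np.ndarray  # rigid pose of the native grid vs anatomy
    pose_translation_mm: np.ndarray


@dataclass
class PatientTruth:
    patient_id: int
    scans: list[ScanTruth]
    shape: dict = field(default_factory=dict)  # rendering geometry parameters


@dataclass
class GroundTruth:
    spec: PhantomSpec
    patients: list[PatientTruth]

    def patient(self, patient_id: int) -> PatientTruth:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(f"no patient {patient_id}")


@dataclass
class RenderedScan:
    """One rendered timepoint: image pair plus truth masks, native grid."""

    patient_id: int
    scan_index: int
    mprage: ImageVolume
    flair: ImageVolume
    cv_mask: BinaryMask
    fv_mask: BinaryMask
    pose_angles_deg: np.ndarray
    pose_translation_mm: np.ndarray


def _rng_for(spec: PhantomSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec.seed, *key)))


def _confuse_rating(cat: int, p: float, rng: np.random.Generator) -> int:
    """Rater confusion: adjacent-category errors on the 2-5 follow-up scale."""
    if cat in (0, 1) or rng.random() >= p:
        return cat
    neighbours = {2: (3,), 3: (2, 4), 4: (3, 5), 5: (4,)}[cat]
    return int(rng.choice(neighbours))


def _shell_ml(volume_ml: float, shell_mm: float, rng: np.random.Generator) -> float:
    """Non-overlap volume of two same-size masks misaligned by a random offset.

    Approximated as half the surface shell swept by an absolute-normal
    misalignment; surface area uses the sphere relation inflated by 30% for
    lobulated shapes.
    """
    mis = abs(rng.normal(0.0, shell_mm))
    area_mm2 = 1.3 * _SPHERE_A * (max(volume_ml, 1e-6) * 1000.0) ** (2.0 / 3.0)
    return 0.5 * area_mm2 * mis / 1000.0


def _patient_shape(rng: np.random.Generator) -> dict:
    """Random lobulated multi-ellipsoid tumor geometry (unit scale)."""
    n_lobes = int(rng.integers(2, 6))
    centers = rng.uniform(-0.35, 0.35, size=(n_lobes, 3))
    centers[0] = 0.0
    axes = rng.uniform(0.6, 1.4, size=(n_lobes, 3))
    axes /= np.cbrt(np.prod(axes, axis=1))[:, None]
    # random rotation matrices via QR of Gaussian matrices
    rots = []
    for _ in range(n_lobes):
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        rots.append(q)
    return {
        "n_lobes": n_lobes,
        "centers": centers,
        "axes": axes,
        "rotations": np.stack(rots),
        "lobulation_amp": float(rng.uniform(0.08, 0.20)),
        "lobulation_phase": rng.uniform(0.0, 2.0 * np.pi, size=2),
        "grid_offset_mm": rng.uniform(-5.0, 5.0, size=3),
        "cavity_direction": rng.normal(size=3),
    }


def simulate_cohort_table(spec: PhantomSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a longitudinal cohort as a per-scan table plus ground truth.

    Returns a DataFrame with one row per scan and columns

    ``patient_id, scan_index, cv_ml, fv_ml, rating, rater_a, rater_b,
    histology, board, scv_ml, sfv_ml, progression``

    where ``cv_ml``/``fv_ml`` are measured (noisy) volumes, ``rating`` is
    the radiologic consensus category (0–5), ``rater_a``/``rater_b`` are
    the two independent pre-consensus ratings, ``histology``/``board`` are
    the optional higher-tier labels (NaN when unavailable), ``scv_ml``/
    ``sfv_ml`` are regional mask-subtraction volumes versus the preceding
    scan (NaN for the first scan), and ``progression`` is the generating
    ground-truth label (1 iff the growth effect was applied; NaN for first
    scans).
    """
    rng = _rng_for(spec, 0)
    lo, hi = spec.scans_per_patient
    counts = np.array([k for k in _SCANS_HIST if lo <= k <= hi])
    if counts.size == 0:
        counts = np.arange(lo, hi + 1)
        weights = np.ones_like(counts, dtype=float)
    else:
        weights = np.array([_SCANS_HIST[k] for k in counts], dtype=float)
    weights /= weights.sum()

    rows: list[dict] = []
    patients: list[PatientTruth] = []
    for pid in range(1, spec.n_patients + 1):
        n_scans = int(rng.choice(counts, p=weights))
        at_diagnosis = rng.random() < spec.start_at_diagnosis_prob
        cv = spec.cv_baseline_median_ml * math.exp(rng.normal(0.0, spec.cv_baseline_sigma))
        if at_diagnosis:
            # diagnostic scans show the untreated tumor: larger enhancing part
            cv *= spec.fv_to_cv_ratio_median / 16.0
        ratio = spec.fv_to_cv_ratio_median * math.exp(
            rng.normal(0.0, spec.fv_to_cv_ratio_sigma)
        )
        fv = max(cv * ratio, 1.05 * cv)

        scans: list[ScanTruth] = []
        for t in range(n_scans):
            progression: bool | None = None
            if t == 0:
                cat = 0 if at_diagnosis else 3
            elif t == 1 and at_diagnosis:
                cat = 1
                cv *= rng.uniform(*spec.postop_cv_residual)
                fv *= rng.uniform(*spec.postop_fv_residual)
                fv = max(fv, 1.05 * cv)
                progression = False
            else:
                u = rng.random()
                if u < spec.progression_prob:
                    cat = 4 if rng.random() < spec.uncertain_progression_prob else 5
                    mult = spec.growth_effect * math.exp(rng.normal(0.0, spec.growth_noise_sd))
                    progression = True
                elif u < spec.progression_prob + spec.regression_prob:
                    cat = 2
                    mult = spec.regression_effect * math.exp(rng.normal(0.0, spec.growth_noise_sd))
                    progression = False
                else:
                    progression = False
                    if rng.random() < spec.pseudo_progression_prob:
                        # treatment-related enhancement increase without
                        # true progression ("uncertain progression")
                        cat = 4
                        mult = rng.uniform(*spec.pseudo_progression_growth)
                    else:
                        cat = 3
                        mult = math.exp(rng.normal(0.0, spec.stable_sd))
                cv *= mult
                fv *= mult**spec.fv_coupling * math.exp(
                    spec.fv_drift + rng.normal(0.0, spec.fv_fluct_sd)
                )
                fv = max(fv, 1.05 * cv)

            pose = (
                rng.normal(0.0, spec.misregistration_sd, size=3),
                rng.normal(0.0, spec.misregistration_sd, size=3),
            )
            scans.append(
                ScanTruth(
                    scan_index=t,
                    true_cv_ml=cv,
                    true_fv_ml=fv,
                    category=cat,
                    progression=progression,
                    pose_angles_deg=pose[0],
                    pose_translation_mm=pose[1],
                )
            )

        # measured volumes + ratings + subtraction volumes
        prev_cv_meas = prev_fv_meas = None
        for s in scans:
            cv_meas = s.true_cv_ml * math.exp(rng.normal(0.0, spec.meas_sigma_cv))
            fv_meas = s.true_fv_ml * math.exp(rng.normal(0.0, spec.meas_sigma_fv))
            fv_meas = max(fv_meas, cv_meas)
            rc = _confuse_rating(s.category, spec.rc_noise, rng)
            row = {
                "patient_id": pid,
                "scan_index": s.scan_index,
                "cv_ml": cv_meas,
                "fv_ml": fv_meas,
                "rating": rc,
                "rater_a": _confuse_rating(s.category, spec.rating_noise, rng),
                "rater_b": _confuse_rating(s.category, spec.rating_noise, rng),
                "histology": np.nan,
                "board": np.nan,
                "scv_ml": np.nan,
                "sfv_ml": np.nan,
                "progression": np.nan if s.progression is None else float(s.progression),
            }
            if s.scan_index > 0 and s.category >= 2:
                if rng.random() < spec.histology_prob:
                    row["histology"] = float(5 if s.progression else int(rng.choice((2, 3))))
                elif rng.random() < spec.board_prob:
                    row["board"] = float(_confuse_rating(s.category, 0.05, rng))
            if prev_cv_meas is not None:
                row["scv_ml"] = max(cv_meas - prev_cv_meas, 0.0) + _shell_ml(
                    min(cv_meas, prev_cv_meas), spec.scv_shell_mm, rng
                )
                row["sfv_ml"] = max(fv_meas - prev_fv_meas, 0.0) + _shell_ml(
                    min(fv_meas, prev_fv_meas), spec.sfv_shell_mm, rng
                )
            prev_cv_meas, prev_fv_meas = cv_meas, fv_meas
            rows.append(row)

        patients.append(PatientTruth(pid, scans, _patient_shape(rng)))

    table = pd.DataFrame(rows)
    return table, GroundTruth(spec=spec, patients=patients)


# ---------------------------------------------------------------------------
# 3D rendering


def _pose_matrix(angles_deg: np.ndarray, translation_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix (ZYX Euler, degrees) and translation vector."""
    ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx, np.asarray(translation_mm, dtype=float)


def _shape_field(shape: dict, coords: np.ndarray, axis_scale: float, lob_scale: float) -> np.ndarray:
    """Min-over-lobes ellipsoid quadratic with lobulated modulation.

    ``coords`` is (N, 3) in tumor-local mm; the tumor boundary is the level
    set ``field <= s**2`` for an overall size parameter ``s`` (mm-ish), so
    size calibration reduces to choosing a threshold on this field.
    """
    amp = shape["lobulation_amp"] * lob_scale
    p1, p2 = shape["lobulation_phase"]
    best = np.full(coords.shape[0], np.inf)
    for c, a, r in zip(shape["centers"], shape["axes"], shape["rotations"]):
        u = (coords - 25.0 * c) @ r  # lobe centers spread on a 25 mm scale
        q = (
            (u[:, 0] / (a[0] * axis_scale)) ** 2
            + (u[:, 1] / (a[1] * axis_scale)) ** 2
            + (u[:, 2] / (a[2] * axis_scale)) ** 2
        )
        theta = np.arctan2(u[:, 1], u[:, 0])
        rho = np.linalg.norm(u, axis=1) + 1e-9
        phi = np.arccos(np.clip(u[:, 2] / rho, -1.0, 1.0))
        q = q * (1.0 + amp * np.cos(3.0 * theta + p1) * np.cos(2.0 * phi + p2))
        np.minimum(best, q, out=best)
    return best


def _threshold_for_volume(field: np.ndarray, target_voxels: int) -> float:
    if target_voxels < 1:
        target_voxels = 1
    if target_voxels > field.size:
        raise GenerationError("tumor volume exceeds the phantom grid")
    return float(np.partition(field, target_voxels - 1)[target_voxels - 1])


def render_scan(
    spec: PhantomSpec, patient: PatientTruth, scan: ScanTruth
) -> RenderedScan:
    """Voxelise one scan on its rigidly displaced native grid.

    The tumor lives in a fixed anatomical frame; the scan's native grid is
    related to that frame by the stored rigid pose, so consecutive scans of
    the same patient are mutually misregistered by known transforms.  True
    volumes on ``scan`` are updated to the voxelised mask volumes so that
    mask-derived and stored volumes agree exactly.
    """
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.voxel_size
    vox_mm3 = sx * sy * sz

    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij", copy=False
    )
    coords = np.stack(
        [ii.ravel() * sx, jj.ravel() * sy, kk.ravel() * sz], axis=1
    ).astype(np.float64)
    center = np.array([(nx - 1) * sx, (ny - 1) * sy, (nz - 1) * sz]) / 2.0

    # native grid -> anatomy: rotate about the grid centre, then translate
    rot, trans = _pose_matrix(scan.pose_angles_deg, scan.pose_translation_mm)
    anat = (coords - center) @ rot.T + center + trans
    local = anat - center - patient.shape["grid_offset_mm"]

    q_cv = _shape_field(patient.shape, local, axis_scale=1.0, lob_scale=1.0)
    q_fv = _shape_field(patient.shape, local, axis_scale=2.0, lob_scale=0.6)

    k_cv = max(int(round(scan.true_cv_ml * 1000.0 / vox_mm3)), 1)
    k_fv = max(int(round(scan.true_fv_ml * 1000.0 / vox_mm3)), k_cv)
    t_cv = _threshold_for_volume(q_cv, k_cv)
    cv = q_cv <= t_cv
    # FV = CV plus the k_fv - |CV| best FV-field voxels outside CV
    extra = k_fv - int(cv.sum())
    if extra > 0:
        q_out = np.where(cv, np.inf, q_fv)
        t_fv = _threshold_for_volume(q_out, extra)
        fv = cv | (q_out <= t_fv)
    else:
        fv = cv.copy()

    cv3 = cv.reshape(nx, ny, nz)
    fv3 = fv.reshape(nx, ny, nz)
    for m in (cv3, fv3):
        if (
            m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any()
            or m[:, :, 0].any() or m[:, :, -1].any()
        ):
            raise GenerationError("tumor touches the grid boundary; enlarge the grid")

    mpr = np.full((nx, ny, nz), 0.2)
    mpr[fv3] = 0.35
    mpr[cv3] = 1.0
    flair = np.full((nx, ny, nz), 0.2)
    flair[fv3] = 1.0

    if spec.include_confounders:
        _add_cavity(mpr, flair, cv3, fv3, patient.shape, spec)

    if spec.noise_sd > 0:
        nrng = _rng_for(spec, 1, patient.patient_id, scan.scan_index)
        mpr = mpr + nrng.normal(0.0, spec.noise_sd, mpr.shape)
        flair = flair + nrng.normal(0.0, spec.noise_sd, flair.shape)

    scan.true_cv_ml = int(cv3.sum()) * vox_mm3 / 1000.0
    scan.true_fv_ml = int(fv3.sum()) * vox_mm3 / 1000.0

    spacing = tuple(spec.voxel_size)
    return RenderedScan(
        patient_id=patient.patient_id,
        scan_index=scan.scan_index,
        mprage=ImageVolume(mpr, spacing),
        flair=ImageVolume(flair, spacing),
        cv_mask=BinaryMask(cv3, spacing, compartment="CV"),
        fv_mask=BinaryMask(fv3, spacing, compartment="FV"),
        pose_angles_deg=scan.pose_angles_deg,
        pose_translation_mm=scan.pose_translation_mm,
    )


def _add_cavity(mpr, flair, cv3, fv3, shape: dict, spec: PhantomSpec) -> None:
    """Dark resection cavity with a bright enhancing rim, adjacent to the
    tumor but disjoint from (and non-adjacent to) both truth masks."""
    nx, ny, nz = mpr.shape
    sx, sy, sz = spec.voxel_size
    idx = np.argwhere(fv3)
    if idx.size == 0:
        return
    centroid = idx.mean(axis=0) * np.array([sx, sy, sz])
    d = shape["cavity_direction"]
    d = d / (np.linalg.norm(d) + 1e-12)
    # tumor extent along d plus a gap
    ext = ((idx * np.array([sx, sy, sz]) - centroid) @ d).max()
    r_cav = 6.0
    c = centroid + d * (ext + r_cav + 4.0)
    ii, jj, kk = np.meshgrid(
        np.arange(nx) * sx, np.arange(ny) * sy, np.arange(nz) * sz, indexing="ij", copy=False
    )
    dist = np.sqrt((ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2)
    interior = (dist <= r_cav) & ~fv3 & ~cv3
    rim = (dist > r_cav) & (dist <= r_cav + 1.5) & ~fv3 & ~cv3
    mpr[interior] = 0.05
    mpr[rim] = 1.0
    flair[interior] = 0.05


def true_pair_transform(spec: PhantomSpec, fixed: ScanTruth, moving: ScanTruth):
    """Ground-truth rigid transform (fixed-scan points -> moving-scan points,
    the resampling convention) between two scans of the same patient."""
    from .registration import rigid_from_matrix

    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.voxel_size
    center = np.array([(nx - 1) * sx, (ny - 1) * sy, (nz - 1) * sz]) / 2.0
    rf, tf = _pose_matrix(fixed.pose_angles_deg, fixed.pose_translation_mm)
    rm, tm = _pose_matrix(moving.pose_angles_deg, moving.pose_translation_mm)
    # native_f -> anatomy -> native_m
    rot = rm.T @ rf
    trans = rm.T @ (tf - tm)
    return rigid_from_matrix(rot, trans, center)


def render_patient(spec: PhantomSpec, truth: GroundTruth, patient_id: int) -> Iterator[RenderedScan]:
    patient = truth.patient(patient_id)
    for scan in patient.scans:
        yield render_scan(spec, patient, scan)


def render_phantom_images(spec: PhantomSpec, truth: GroundTruth) -> Iterator[RenderedScan]:
    """Render every scan of the cohort, patient by patient (a generator, to
    keep at most one 3D volume set in memory at a time)."""
    for patient in truth.patients:
        yield from render_patient(spec, truth, patient.patient_id)
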