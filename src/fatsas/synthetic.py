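"""Seeded synthetic thoracic CT phantom cohorts with full ground truth.

Each subject is an elliptical-cylinder body with z-varying radii holding,
from the skin inward: a subcutaneous fat ring (SAT), a muscle layer, a
rib-cage ring of bone, the thoracic cavity bounded by the rib-cage inner
surface (the SAT/VAT interface), a visceral fat ring (VAT) lining the
cavity, and two lung ellipsoids.  A hemispherical diaphragm caps the
cavity inferiorly; fat planted under the dome is abdominal and must be
excluded by interface clipping downstream.  A configurable fraction of
rib-interior voxels carries fat-window HU (marrow pseudo-fat).

Per-slice compartment areas are drawn analytically first (smooth profile x
subject amplitude x level noise); at the configured standardized coupling
level the area is set exactly to ``c * V * (1 + eps)`` with a
cohort-constant ``c`` and ``eps ~ N(0, coupling_noise)``, planting a
known best slice.  Masks are rasterized to match the analytic areas, and
the analytic values are stored as ground truth.

Fat HU values are drawn from normal distributions truncated to the fat
window, so closed-form truncated-normal moments serve as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import BinaryMask, ImageVolume
from .sas import (
    DEFAULT_LANDMARK_LABELS,
    LandmarkSet,
    StandardSpaceModel,
    calibrate,
    half_level_grid,
    nearest_slice,
    sas_to_z,
    to_sas,
)
from .segmentation import FatWindow

# normalized elliptical radii of the concentric tissue layers
FRAC_RIB_OUTER = 0.80
FRAC_RIB_INNER = 0.66     # = SAT/VAT interface (inner surface of rib cage)
FRAC_SAT_INNER_FLOOR = 0.86
# lungs occupy the upper half of the cavity; VAT is a solid mediastinal
# ellipse in the lower half (convex, so it survives morphological opening)
LUNG_CX, LUNG_CY, LUNG_A, LUNG_B = 0.26, 0.18, 0.13, 0.20
VAT_CY, VAT_AX, VAT_AY = -0.30, 0.42, 0.20
VAT_G_MAX = 1.2           # max scale of the VAT ellipse
FRAC_ABD = 0.62           # dome radius at full depth
AIR_HU = -1000.0
DOME_HEIGHT_MM = 30.0


class PhantomParamError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomParams:
    """Generator configuration; see module docstring for the geometry."""

    n_subjects: int = 40
    grid_shape: tuple[int, int, int] = (64, 64, 52)
    spacing: tuple[float, float, float] = (1.5, 1.5, 5.0)
    landmark_labels: tuple[str, ...] = DEFAULT_LANDMARK_LABELS
    landmark_jitter: float = 0.15      # fraction of the inter-landmark gap
    warp_strength: float = 0.6        # magnitude of the monotone cubic warp
    sat_hu_mean: float = -90.0
    sat_hu_sd: float = 10.0
    vat_hu_mean: float = -70.0
    vat_hu_sd: float = 8.0
    soft_tissue_hu_mean: float = 40.0
    soft_tissue_hu_sd: float = 12.0
    bone_hu: float = 700.0
    lung_hu: float = -800.0
    coupling_level: str = "T8"         # standardized half-level label
    coupling_noise: float = 0.02       # relative SD of the planted coupling
    level_noise: float = 0.10          # relative SD at non-coupled slices
    group_hu_shift: float = -7.0       # VAT HU mean offset for group B
    subject_hu_sd: float = 3.0         # SD of per-subject HU mean offsets
    size_spread: float = 0.05          # relative body-size variation
    marrow_fat_fraction: float = 0.02  # rib-interior voxels given fat HU
    sat_area_base_mm2: float = 600.0
    vat_area_base_mm2: float = 300.0
    body_radii_mm: tuple[float, float] = (42.0, 34.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise PhantomParamError("n_subjects must be >= 2")
        if any(s <= 0 for s in self.spacing):
            raise PhantomParamError("spacing components must be > 0")
        for name in ("sat_hu_sd", "vat_hu_sd", "soft_tissue_hu_sd",
                     "coupling_noise", "level_noise", "landmark_jitter"):
            if getattr(self, name) < 0:
                raise PhantomParamError(f"{name} must be >= 0")
        if self.landmark_jitter > 0.4:
            raise PhantomParamError("landmark_jitter must be <= 0.4 to keep order")
        if not 0 <= self.warp_strength <= 1.2:
            raise PhantomParamError("warp_strength must be in [0, 1.2]")
        if len(self.landmark_labels) < 2:
            raise PhantomParamError("landmark_labels needs >= 2 labels")
        if self.coupling_level not in _half_labels(self.landmark_labels):
            raise PhantomParamError(
                f"coupling_level '{self.coupling_level}' is not within the "
                f"span of landmark_labels"
            )
        if not 0 <= self.marrow_fat_fraction < 1:
            raise PhantomParamError("marrow_fat_fraction must be in [0, 1)")


def _half_labels(labels: tuple[str, ...]) -> list[str]:
    out = []
    for i, lab in enumerate(labels):
        out.append(lab)
        if i + 1 < len(labels):
            out.append(f"{lab}-{labels[i + 1]}")
    return out


@dataclass
class SubjectTruth:
    group: str
    L_mm: float
    level_labels: list[str]
    level_slices: np.ndarray
    sat_area_mm2: np.ndarray
    vat_area_mm2: np.ndarray
    sat_volume_mm3: float
    vat_volume_mm3: float
    coupled_slice: int
    thoracic_slices: tuple[int, int] = (0, 0)  # inclusive trimmed z-index range
    sat_mask: BinaryMask | None = None
    vat_mask: BinaryMask | None = None
    # fat planted under the diaphragm dome: in the fat window and inside the
    # body, but abdominal -- excluded from VAT by the clipped interface
    abd_fat_mask: BinaryMask | None = None
    # rib-interior voxels carrying fat-window HU (pseudo-fat to correct)
    marrow_mask: BinaryMask | None = None


@dataclass
class SyntheticSubject:
    subject_id: str
    landmarks: LandmarkSet
    truth: SubjectTruth
    bmi: float
    volume: ImageVolume | None = None
    body_mask: BinaryMask | None = None
    lung_mask: BinaryMask | None = None
    bone_mask: BinaryMask | None = None
    interface_mask: BinaryMask | None = None


@dataclass
class _SubjectPlan:
    """Analytic description of one subject, fixed before rasterization."""

    size: float
    lung_base_z: float
    lung_apex_z: float
    landmarks: LandmarkSet
    group: str
    amp_sat: float
    amp_vat: float
    sat_hu_offset: float = 0.0
    vat_hu_offset: float = 0.0


def _shape_sat(s: np.ndarray) -> np.ndarray:
    u = np.clip(s, 0.0, 1.0)
    return 0.85 + 0.30 * np.sin(np.pi * u)


def _shape_vat(s: np.ndarray) -> np.ndarray:
    u = np.clip(s, 0.0, 1.0)
    return 0.90 + 0.25 * np.sin(np.pi * (0.2 + 0.8 * u))


def _draw_plan(params: PhantomParams, i: int, rng: np.random.Generator) -> _SubjectPlan:
    size = 1.0 + params.size_spread * rng.uniform(-1, 1)
    offset = rng.uniform(0.0, 15.0)
    lung_base = 40.0 * size + offset
    lung_apex = lung_base + 160.0 * size
    # landmarks: warped, jittered positions from apex-side T2 to base-side T10
    n = len(params.landmark_labels)
    z_top = lung_apex - 0.05 * (lung_apex - lung_base)
    z_bot = lung_base + 0.18 * (lung_apex - lung_base)
    p = np.linspace(0.0, 1.0, n)
    alpha = rng.uniform(-1, 1)
    beta = rng.uniform(0.25, 0.75)
    w = p + params.warp_strength * alpha * p * (1 - p) * (p - beta)
    z = z_top - w * (z_top - z_bot)          # strictly decreasing (cranial first)
    if n > 2 and params.landmark_jitter > 0:
        gaps = np.abs(np.diff(z))
        local = np.minimum(gaps[:-1], gaps[1:])
        z[1:-1] += params.landmark_jitter * local * rng.uniform(-1, 1, size=n - 2)
    lm = LandmarkSet(labels=params.landmark_labels, z=z, subject_id=f"S{i:03d}")
    group = "A" if i < (params.n_subjects + 1) // 2 else "B"
    amp_sat = float(np.exp(rng.normal(0.0, 0.25))) * size**2
    amp_vat = float(np.exp(rng.normal(0.0, 0.25))) * size**2
    d_sat, d_vat = rng.normal(0.0, params.subject_hu_sd, size=2)
    return _SubjectPlan(size, lung_base, lung_apex, lm, group, amp_sat, amp_vat,
                        float(d_sat), float(d_vat))


def _thoracic_slices(params: PhantomParams, plan: _SubjectPlan) -> np.ndarray:
    """Slice indices of the standardized thoracic extent (base-5 .. apex+15)."""
    dz = params.spacing[2]
    nz = params.grid_shape[2]
    k_lo = max(0, int(np.ceil((plan.lung_base_z - 5.0) / dz)))
    k_hi = min(nz - 1, int(np.floor((plan.lung_apex_z + 15.0) / dz)))
    return np.arange(k_lo, k_hi + 1)


def _body_radii(params: PhantomParams, plan: _SubjectPlan, z: np.ndarray):
    a0, b0 = params.body_radii_mm
    zc = 0.5 * (plan.lung_base_z + plan.lung_apex_z)
    half = 0.5 * params.grid_shape[2] * params.spacing[2]
    taper = 1.0 - 0.05 * ((z - zc) / half) ** 2
    return plan.size * a0 * taper, plan.size * b0 * taper


def _reference_coupling_constants(params: PhantomParams):
    """Cohort-constant area-to-volume ratios c from a noiseless unit subject."""
    lung_base_z, lung_apex_z = 47.5, 207.5
    n = len(params.landmark_labels)
    z_top = lung_apex_z - 0.05 * (lung_apex_z - lung_base_z)
    z_bot = lung_base_z + 0.18 * (lung_apex_z - lung_base_z)
    lm = LandmarkSet(params.landmark_labels, np.linspace(z_top, z_bot, n))
    model = StandardSpaceModel(params.landmark_labels, np.linspace(0, 1, n), 1)
    dz = params.spacing[2]
    plan = _SubjectPlan(1.0, lung_base_z, lung_apex_z, lm, "A", 1.0, 1.0)
    ks = _thoracic_slices(params, plan)
    z = ks * dz
    s = to_sas(lm, model, z)
    a_sat = params.sat_area_base_mm2 * _shape_sat(s)
    dome_top = lung_base_z + 8.0
    a_vat = params.vat_area_base_mm2 * _shape_vat(s) * (z >= dome_top)
    labels, s_grid = half_level_grid(model)
    s_star = s_grid[labels.index(params.coupling_level)]
    z_star = sas_to_z(lm, model, float(s_star))
    k_star = nearest_slice(z_star, z, check_range=False)
    c_sat = a_sat[k_star] / float(np.sum(a_sat) * dz)
    c_vat = a_vat[k_star] / float(np.sum(a_vat) * dz)
    return float(c_sat), float(c_vat)


def _truncnorm(rng, mean, sd, window: FatWindow, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, window.lower, window.upper)))
    a = (window.lower - mean) / sd
    b = (window.upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _analytic_profiles(params, plan, model, c_sat, c_vat, rng):
    """Per-slice analytic SAT/VAT areas with the planted coupling."""
    dz = params.spacing[2]
    ks = _thoracic_slices(params, plan)
    z = ks * dz
    s = to_sas(plan.landmarks, model, z)
    a_mm, b_mm = _body_radii(params, plan, z)
    ellipse = np.pi * a_mm * b_mm
    cap_sat = 0.95 * (1.0 - FRAC_SAT_INNER_FLOOR**2) * ellipse
    cap_vat = 0.95 * np.pi * VAT_G_MAX**2 * VAT_AX * VAT_AY * a_mm * b_mm

    a_sat = params.sat_area_base_mm2 * plan.amp_sat * _shape_sat(s)
    dome_top = plan.lung_base_z + 8.0
    a_vat = params.vat_area_base_mm2 * plan.amp_vat * _shape_vat(s) * (z >= dome_top)
    a_sat = a_sat * (1.0 + rng.normal(0.0, params.level_noise, size=len(ks)))
    a_vat = a_vat * (1.0 + rng.normal(0.0, params.level_noise, size=len(ks)))
    a_sat = np.clip(a_sat, 0.0, cap_sat)
    a_vat = np.clip(a_vat, 0.0, cap_vat)

    labels, s_grid = half_level_grid(model)
    s_star = s_grid[labels.index(params.coupling_level)]
    z_star = sas_to_z(plan.landmarks, model, float(s_star))
    k_star = nearest_slice(z_star, z, check_range=False)

    for arr, c in ((a_sat, c_sat), (a_vat, c_vat)):
        eps = rng.normal(0.0, params.coupling_noise)
        v_rest = float(np.sum(arr) * dz) - arr[k_star] * dz
        ce = c * (1.0 + eps)
        arr[k_star] = ce * v_rest / (1.0 - ce * dz)
    a_sat = np.clip(a_sat, 0.0, cap_sat)
    a_vat = np.clip(a_vat, 0.0, cap_vat)

    level_slices = np.array([
        nearest_slice(sas_to_z(plan.landmarks, model, float(sv)), z, check_range=False)
        for sv in s_grid
    ])
    return {
        "slices": ks, "z": z, "sat": a_sat, "vat": a_vat,
        "level_labels": labels, "level_slices": ks[level_slices],
        "coupled_slice": int(ks[k_star]),
        "sat_volume": float(np.sum(a_sat) * dz),
        "vat_volume": float(np.sum(a_vat) * dz),
        "dome_top": dome_top,
    }


def _analytic_L(params: PhantomParams, plan: _SubjectPlan, prof) -> float:
    z = prof["z"]
    a_mm, b_mm = _body_radii(params, plan, z)
    ex = 2.0 * FRAC_RIB_OUTER * float(np.max(a_mm))
    ey = 2.0 * FRAC_RIB_OUTER * float(np.max(b_mm))
    ez = float(z[-1] - z[0]) + params.spacing[2]
    return float(np.sqrt(ex * ex + ey * ey + ez * ez))


def _rasterize(params, plan, prof, rng, window: FatWindow):
    """Voxelize one subject: HU volume plus body/lung/bone/interface and
    truth SAT/VAT masks."""
    nx, ny, nz = params.grid_shape
    dx, dy, dz = params.spacing
    cx, cy = nx * dx / 2.0, ny * dy / 2.0
    x = (np.arange(nx) + 0.5) * dx - cx
    y = (np.arange(ny) + 0.5) * dy - cy
    zc = np.arange(nz) * dz

    ks = prof["slices"]
    a_full = np.full(nz, np.nan)
    b_full = np.full(nz, np.nan)
    a_th, b_th = _body_radii(params, plan, prof["z"])
    a_full[ks], b_full[ks] = a_th, b_th
    # body continues beyond the thoracic span with the end radii
    a_full[: ks[0]], b_full[: ks[0]] = a_th[0], b_th[0]
    a_full[ks[-1] + 1 :], b_full[ks[-1] + 1 :] = a_th[-1], b_th[-1]

    X = x[:, None, None]
    Y = y[None, :, None]
    A = a_full[None, None, :]
    B = b_full[None, None, :]
    r2 = (X / A) ** 2 + (Y / B) ** 2

    body = r2 <= 1.0

    # lungs: two ellipsoids in the upper cavity spanning the lung z range
    z_mid = 0.5 * (plan.lung_base_z + plan.lung_apex_z)
    z_rad = 0.5 * (plan.lung_apex_z - plan.lung_base_z)
    Z = zc[None, None, :]
    lung = np.zeros((nx, ny, nz), dtype=bool)
    for sgn in (-1.0, 1.0):
        q = (
            ((X - sgn * LUNG_CX * A) / (LUNG_A * A)) ** 2
            + ((Y - LUNG_CY * B) / (LUNG_B * B)) ** 2
            + ((Z - z_mid) / z_rad) ** 2
        )
        lung |= q <= 1.0

    thor = np.zeros(nz, dtype=bool)
    thor[ks] = True
    in_thorax = thor[None, None, :]

    rib = (r2 <= FRAC_RIB_OUTER**2) & (r2 > FRAC_RIB_INNER**2) & in_thorax

    # diaphragm dome: below dome_top a central abdominal region widens caudally
    dome_top = prof["dome_top"]
    depth = np.clip((dome_top - zc) / DOME_HEIGHT_MM, 0.0, 1.0)
    r_abd = FRAC_ABD * np.sqrt(depth)
    abdomen = r2 < (r_abd[None, None, :]) ** 2

    interface = (r2 <= FRAC_RIB_INNER**2) & ~abdomen & in_thorax

    # SAT ring inner radius and VAT ellipse scale from the analytic areas
    f_sat = np.ones(nz)
    g_vat = np.zeros(nz)
    ellipse = np.pi * a_th * b_th
    f_sat[ks] = np.sqrt(np.clip(1.0 - prof["sat"] / ellipse, 0.0, 1.0))
    g_vat[ks] = np.sqrt(prof["vat"] / (np.pi * VAT_AX * VAT_AY * a_th * b_th))
    sat = (r2 <= 1.0) & (r2 > f_sat[None, None, :] ** 2) & in_thorax
    G = g_vat[None, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        q_vat = (X / (VAT_AX * A * G)) ** 2 + ((Y - VAT_CY * B) / (VAT_AY * B * G)) ** 2
    vat = (G > 0) & (q_vat <= 1.0) & interface & ~lung

    # marrow pseudo-fat: random voxels strictly interior to the rib ring
    # (all 4 in-slice neighbours are bone), so a small closing recovers them
    marrow = np.zeros_like(rib)
    if params.marrow_fat_fraction > 0:
        interior = (
            rib
            & np.roll(rib, 1, axis=0) & np.roll(rib, -1, axis=0)
            & np.roll(rib, 1, axis=1) & np.roll(rib, -1, axis=1)
        )
        cand = np.flatnonzero(interior.ravel())
        n_pick = int(round(params.marrow_fat_fraction * len(cand)))
        if n_pick:
            pick = rng.choice(cand, size=n_pick, replace=False)
            marrow.ravel()[pick] = True
    bone = rib & ~marrow

    hu = np.full((nx, ny, nz), AIR_HU)
    soft = body & ~(lung | bone | marrow | sat | vat | abdomen)
    n_soft = int(soft.sum())
    hu[soft] = rng.normal(params.soft_tissue_hu_mean, params.soft_tissue_hu_sd, n_soft)
    hu[lung & body] = params.lung_hu
    hu[bone] = params.bone_hu
    sat_mean = params.sat_hu_mean + plan.sat_hu_offset
    vat_mean = (params.vat_hu_mean + plan.vat_hu_offset
                + (params.group_hu_shift if plan.group == "B" else 0.0))
    hu[sat] = _truncnorm(rng, sat_mean, params.sat_hu_sd, window, int(sat.sum()))
    hu[vat] = _truncnorm(rng, vat_mean, params.vat_hu_sd, window, int(vat.sum()))
    abd = abdomen & body & ~lung
    hu[abd] = _truncnorm(rng, vat_mean, params.vat_hu_sd, window, int(abd.sum()))
    hu[marrow] = _truncnorm(rng, sat_mean, params.sat_hu_sd, window, int(marrow.sum()))

    spacing = params.spacing
    vol = ImageVolume(hu, spacing)
    mk = lambda v: BinaryMask(v, spacing)
    return (vol, mk(body), mk(lung & body), mk(bone), mk(interface),
            mk(sat), mk(vat), mk(abd), mk(marrow))


def generate_cohort(
    params: PhantomParams,
    voxelize: bool = True,
    fat_window: FatWindow = FatWindow(),
) -> list[SyntheticSubject]:
    """Generate a seeded cohort of thoracic phantoms.

    Identical ``params`` (including seed) reproduce bit-identical cohorts.
    With ``voxelize=False`` only landmarks and the analytic ground-truth
    tables are produced (volumes and masks are ``None``); the analytic
    draws are unchanged, so truth tables match the voxelized cohort.
    """
    ss = np.random.SeedSequence(params.seed)
    subject_seeds = ss.spawn(params.n_subjects)

    streams = [s.spawn(3) for s in subject_seeds]
    plan_rngs = [np.random.default_rng(st[0]) for st in streams]
    prof_rngs = [np.random.default_rng(st[1]) for st in streams]
    voxel_rngs = [np.random.default_rng(st[2]) for st in streams]

    plans = [_draw_plan(params, i, plan_rngs[i]) for i in range(params.n_subjects)]
    model = calibrate([p.landmarks for p in plans])
    c_sat, c_vat = _reference_coupling_constants(params)

    subjects: list[SyntheticSubject] = []
    for i, plan in enumerate(plans):
        prof = _analytic_profiles(params, plan, model, c_sat, c_vat, prof_rngs[i])
        L = _analytic_L(params, plan, prof)
        truth = SubjectTruth(
            group=plan.group,
            L_mm=L,
            level_labels=prof["level_labels"],
            level_slices=prof["level_slices"],
            sat_area_mm2=prof["sat"][prof["level_slices"] - prof["slices"][0]],
            vat_area_mm2=prof["vat"][prof["level_slices"] - prof["slices"][0]],
            sat_volume_mm3=prof["sat_volume"],
            vat_volume_mm3=prof["vat_volume"],
            coupled_slice=prof["coupled_slice"],
            thoracic_slices=(int(prof["slices"][0]), int(prof["slices"][-1])),
        )
        bmi = 18.0 + 600.0 * truth.sat_volume_mm3 / L**3 + prof_rngs[i].normal(0.0, 1.0)
        subj = SyntheticSubject(
            subject_id=plan.landmarks.subject_id or f"S{i:03d}",
            landmarks=plan.landmarks,
            truth=truth,
            bmi=float(bmi),
        )
        if voxelize:
            vol, body, lung, bone, iface, sat, vat, abd, marrow = _rasterize(
                params, plan, prof, voxel_rngs[i], fat_window
            )
            subj.volume = vol
            subj.body_mask = body
            subj.lung_mask = lung
            subj.bone_mask = bone
            subj.interface_mask = iface
            truth.sat_mask = sat
            truth.vat_mask = vat
            truth.abd_fat_mask = abd
            truth.marrow_mask = marrow
        subjects.append(subj)
    return subjects


# ---------------------------------------------------------------------------
# single-slice phantoms (abdomen at L5, mid-thigh)

@dataclass
class SingleSlicePhantom:
    region: str
    volume: ImageVolume            # shape (nx, ny, 1)
    body_mask: BinaryMask
    interface_mask: BinaryMask
    bone_mask: BinaryMask
    truth_sat: BinaryMask
    truth_vat: BinaryMask
    sat_area_true_mm2: float       # analytic ring area
    vat_area_true_mm2: float


def generate_single_slice_phantom(
    region: str,
    params: PhantomParams,
    rng: np.random.Generator,
    vat_fraction: float = 0.12,
    sat_area_mm2: float | None = None,
    fat_window: FatWindow = FatWindow(),
) -> SingleSlicePhantom:
    """One 2D phantom slice (as a 1-slice volume so 3D operators apply).

    abdomen: interface is the abdominal-wall musculature interior; VAT is
    a central blob.  thigh: interface is the fascial boundary; the femur
    cross-section carries fatty marrow; VAT is intermuscular fat.
    """
    if region not in ("abdomen", "thigh"):
        raise ValueError(f"unknown region '{region}' (expected abdomen or thigh)")
    nx, ny = params.grid_shape[:2]
    dx, dy, dz = params.spacing
    x = (np.arange(nx) + 0.5) * dx - nx * dx / 2
    y = (np.arange(ny) + 0.5) * dy - ny * dy / 2
    X, Y = x[:, None], y[None, :]

    if region == "abdomen":
        a, b = params.body_radii_mm
        f_if = 0.72
    else:
        a = 0.55 * params.body_radii_mm[0]
        b = 0.55 * params.body_radii_mm[1]
        f_if = 0.70
    r2 = (X / a) ** 2 + (Y / b) ** 2
    body = r2 <= 1.0
    ellipse = np.pi * a * b

    if sat_area_mm2 is None:
        sat_area_mm2 = 0.22 * ellipse
    sat_area_mm2 = float(np.clip(sat_area_mm2, 0.0, 0.95 * (1 - f_if**2) * ellipse))
    f_sat = np.sqrt(1.0 - sat_area_mm2 / ellipse)
    sat = (r2 <= 1.0) & (r2 > f_sat**2)
    interface = r2 <= f_if**2

    vat_area = float(vat_fraction) * f_if**2 * ellipse
    if region == "abdomen":
        rv = np.sqrt(vat_area / np.pi) if vat_area > 0 else 0.0
        vat = (X**2 + (Y - 0.1 * b) ** 2) <= rv**2
        bone = ((X / (0.10 * a)) ** 2 + ((Y + 0.55 * b) / (0.14 * b)) ** 2) <= 1.0
    else:
        # intermuscular fat: a solid disc beside the femur
        rv = np.sqrt(vat_area / np.pi) if vat_area > 0 else 0.0
        vat = ((X - 0.33 * a) ** 2 + (Y - 0.2 * b) ** 2) <= rv**2
        bone = ((X / (0.12 * a)) ** 2 + (Y / (0.12 * b)) ** 2) <= 1.0
    vat = vat & interface & ~bone
    sat = sat & ~bone

    hu = np.full((nx, ny), AIR_HU)
    soft = body & ~(sat | vat | bone)
    hu[soft] = rng.normal(params.soft_tissue_hu_mean, params.soft_tissue_hu_sd, int(soft.sum()))
    hu[bone] = params.bone_hu
    if params.marrow_fat_fraction > 0 and region == "thigh":
        # fatty femoral medulla: central portion of the bone cross-section
        med = ((X / (0.06 * a)) ** 2 + (Y / (0.06 * b)) ** 2) <= 1.0
        hu[med & bone] = _truncnorm(
            rng, params.sat_hu_mean, params.sat_hu_sd, fat_window, int((med & bone).sum())
        )
        bone = bone & ~med
    hu[sat] = _truncnorm(rng, params.sat_hu_mean, params.sat_hu_sd, fat_window, int(sat.sum()))
    hu[vat] = _truncnorm(rng, params.vat_hu_mean, params.vat_hu_sd, fat_window, int(vat.sum()))

    to3d = lambda m: m[:, :, None]
    spacing = (dx, dy, dz)
    vol = ImageVolume(to3d(hu), spacing)
    mk = lambda m: BinaryMask(to3d(m), spacing)
    return SingleSlicePhantom(
        region=region,
        volume=vol,
        body_mask=mk(body),
        interface_mask=mk(interface),
        bone_mask=mk(bone),
        truth_sat=mk(sat),
        truth_vat=mk(vat),
        sat_area_true_mm2=sat_area_mm2,
        vat_area_true_mm2=float(vat.sum()) * dx * dy,
    )
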