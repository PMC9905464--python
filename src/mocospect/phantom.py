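"""4D digital thorax/abdomen phantom with parametric breathing motion.

The phantom holds a liver (ellipsoid), two lungs (ellipsoids clipped to
their lower half plane), spherical tumors inside the liver, and a soft
tissue body cylinder.  Breathing rigidly translates the liver+tumor complex
(caudally on inhale) while the lungs stay fixed; the vacated space is body
(soft tissue).  All shifts are integer-voxel nearest-neighbor moves so that
total activity is conserved exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from mocospect.grid import Grid

# organ codes in the label map
LABEL_AIR = 0
LABEL_BODY = 1
LABEL_LIVER = 2
LABEL_LUNG = 3
LABEL_TUMOR = 4


class GeometryError(ValueError):
    pass


@dataclass
class TumorSpec:
    center_mm: tuple[float, float, float]
    radius_mm: float
    uptake: float = 4.0  # activity concentration multiplier vs healthy liver

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise GeometryError("tumor radius must be positive")
        if self.uptake <= 0:
            raise GeometryError("tumor uptake must be positive")


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (4.418, 4.418, 4.418)
    # geometry, mm, coordinates relative to grid center (axis 2 = CC)
    liver_center_mm: tuple[float, float, float] = (-12.0, 0.0, -32.0)
    liver_axes_mm: tuple[float, float, float] = (58.0, 44.0, 40.0)
    lung_centers_mm: tuple = ((-38.0, 0.0, 52.0), (38.0, 0.0, 52.0))
    lung_axes_mm: tuple[float, float, float] = (26.0, 32.0, 40.0)
    body_axes_mm: tuple[float, float] = (110.0, 90.0)  # LR/AP half-axes of body cylinder
    tumors: list = field(default_factory=list)
    # activity concentrations, arbitrary count-rate units per voxel
    background_activity: float = 0.0
    liver_activity: float = 1.0
    lung_shunt_fraction_true: float = 0.05
    # attenuation at 140.5 keV, 1/mm
    mu_soft: float = 0.0145
    mu_liver: float = 0.0155
    mu_lung: float = 0.004
    mu_air: float = 0.0
    # breathing: peak-to-peak amplitude per axis (LR, AP, CC), mm; inhale
    # displaces the liver caudally (negative CC) by amplitude at mid-cycle
    motion_amplitude_mm: tuple[float, float, float] = (0.0, 2.0, 9.5)
    breathing_period_s: float = 4.0
    seed: int = 0

    def __post_init__(self):
        self.tumors = [
            t if isinstance(t, TumorSpec) else TumorSpec(**t) for t in self.tumors
        ]
        self.validate()

    def validate(self):
        if any(d <= 0 for d in self.spacing_mm):
            raise GeometryError("spacing must be positive")
        if any(a <= 0 for a in self.liver_axes_mm):
            raise GeometryError("liver axes must be positive")
        if any(a < 0 for a in self.motion_amplitude_mm):
            raise GeometryError("motion amplitudes must be non-negative")
        if not (0.0 <= self.lung_shunt_fraction_true <= 0.5):
            raise GeometryError("lung_shunt_fraction_true must be in [0, 0.5]")
        if self.breathing_period_s <= 0:
            raise GeometryError("breathing period must be positive")

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_shape, self.spacing_mm)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class StaticPhantom:
    activity: np.ndarray
    attenuation: np.ndarray
    labels: np.ndarray
    grid: Grid
    spec: PhantomSpec


@dataclass
class Phantom4D:
    """Per-phase activity/attenuation/label maps plus ground-truth motion."""

    phases: list  # of StaticPhantom
    true_liver_translation_mm: np.ndarray  # (n_phases, 3), quantized to voxels
    spec: PhantomSpec

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def grid(self) -> Grid:
        return self.phases[0].grid

    def phase_of_time(self, t) -> np.ndarray:
        """Phase index for time(s) t under the cyclic breathing schedule."""
        frac = np.mod(np.asarray(t, dtype=float) / self.spec.breathing_period_s, 1.0)
        return np.minimum((frac * self.n_phases).astype(int), self.n_phases - 1)


def _ellipsoid_mask(grid: Grid, center, axes) -> np.ndarray:
    x, y, z = grid.coords()
    cx, cy, cz = center
    ax, ay, az = axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def build_static_phantom(spec: PhantomSpec) -> StaticPhantom:
    """Rasterize the end-exhale phantom: activity, attenuation and label maps.

    Lung activity is set so that lung counts are exactly
    ``lung_shunt_fraction_true`` of total liver+lung counts.  Tumors must lie
    strictly inside the liver, otherwise a :class:`GeometryError` is raised.
    """
    grid = spec.grid
    x, y, z = grid.coords()

    body = ((x / spec.body_axes_mm[0]) ** 2 + (y / spec.body_axes_mm[1]) ** 2) <= 1.0
    liver = _ellipsoid_mask(grid, spec.liver_center_mm, spec.liver_axes_mm)
    lungs = np.zeros(grid.shape, bool)
    for c in spec.lung_centers_mm:
        m = _ellipsoid_mask(grid, c, spec.lung_axes_mm)
        lungs |= m & (z >= c[2] - spec.lung_axes_mm[2])  # ellipsoids, kept whole
    lungs &= body
    liver &= body
    lungs &= ~liver  # liver wins any raster overlap

    tumor = np.zeros(grid.shape, bool)
    for t in spec.tumors:
        tm = (
            (x - t.center_mm[0]) ** 2
            + (y - t.center_mm[1]) ** 2
            + (z - t.center_mm[2]) ** 2
        ) <= t.radius_mm**2
        if tm.sum() == 0:
            raise GeometryError(f"tumor at {t.center_mm} rasterizes to zero voxels")
        if not np.all(liver[tm]):
            raise GeometryError(f"tumor at {t.center_mm} is not inside the liver")
        tumor |= tm

    labels = np.full(grid.shape, LABEL_AIR, dtype=np.int8)
    labels[body] = LABEL_BODY
    labels[lungs] = LABEL_LUNG
    labels[liver] = LABEL_LIVER
    labels[tumor] = LABEL_TUMOR

    attenuation = np.full(grid.shape, spec.mu_air, dtype=np.float64)
    attenuation[body] = spec.mu_soft
    attenuation[lungs] = spec.mu_lung
    attenuation[liver | tumor] = spec.mu_liver

    activity = np.zeros(grid.shape, dtype=np.float64)
    activity[body] = spec.background_activity
    activity[lungs] = 0.0
    activity[liver] = spec.liver_activity
    for t in spec.tumors:
        tm = (
            (x - t.center_mm[0]) ** 2
            + (y - t.center_mm[1]) ** 2
            + (z - t.center_mm[2]) ** 2
        ) <= t.radius_mm**2
        activity[tm] = spec.liver_activity * t.uptake

    liver_total = activity[liver].sum()
    n_lung = int(lungs.sum())
    s = spec.lung_shunt_fraction_true
    if s > 0 and n_lung > 0:
        # lung / (lung + liver) == s  =>  lung_total = s/(1-s) * liver_total
        activity[lungs] = s / (1.0 - s) * liver_total / n_lung

    return StaticPhantom(activity, attenuation, labels, grid, spec)


def _quantize_shift(disp_mm, spacing) -> np.ndarray:
    """Round a mm displacement to whole voxels, ties broken toward lower index."""
    frac = np.asarray(disp_mm, dtype=float) / np.asarray(spacing, dtype=float)
    return np.ceil(frac - 0.5).astype(int)


def _shift_int(values: np.ndarray, offset, fill=0) -> np.ndarray:
    """Integer-voxel shift with zero (``fill``) boundary, no wraparound."""
    out = np.full_like(values, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for a, o in enumerate(offset):
        n = values.shape[a]
        if abs(o) >= n:
            return out
        if o >= 0:
            src[a] = slice(0, n - o)
            dst[a] = slice(o, n)
        else:
            src[a] = slice(-o, n)
            dst[a] = slice(0, n + o)
    out[tuple(dst)] = values[tuple(src)]
    return out


def phase_displacement_mm(spec: PhantomSpec, phase: int, n_phases: int) -> np.ndarray:
    """Requested (unquantized) displacement of phase p: end-exhale dwell cosine.

    Phase 0 is end-exhale (zero displacement); phase n/2 is end-inhale with
    the full peak-to-peak amplitude, CC component directed caudally.
    """
    w = (1.0 - np.cos(2.0 * np.pi * phase / n_phases)) / 2.0
    amp = np.asarray(spec.motion_amplitude_mm, dtype=float)
    direction = np.array([1.0, 1.0, -1.0])  # inhale pushes the liver caudally
    return w * amp * direction


def generate_phase_set(spec: PhantomSpec, n_phases: int = 8) -> Phantom4D:
    """Build the per-phase phantom by rigid translation of the liver complex."""
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    base = build_static_phantom(spec)
    complex_mask = (base.labels == LABEL_LIVER) | (base.labels == LABEL_TUMOR)
    body_possible = np.zeros(base.grid.shape, bool)
    x, y = base.grid.coords()[:2]
    body_possible[
        ((x / spec.body_axes_mm[0]) ** 2 + (y / spec.body_axes_mm[1]) ** 2) <= 1.0
    ] = True

    phases = []
    true_shifts = np.zeros((n_phases, 3))
    for p in range(n_phases):
        disp = phase_displacement_mm(spec, p, n_phases)
        off = _quantize_shift(disp, spec.spacing_mm)
        true_shifts[p] = off * np.asarray(spec.spacing_mm)

        shifted_mask = _shift_int(complex_mask.astype(np.int8), off).astype(bool)
        if shifted_mask.sum() != complex_mask.sum():
            raise GeometryError(f"liver complex leaves the grid at phase {p}")
        if np.any(base.labels[shifted_mask] == LABEL_LUNG) or not np.all(
            body_possible[shifted_mask]
        ):
            raise GeometryError(
                f"liver complex collides with lungs or leaves the body at phase {p}"
            )

        act = base.activity.copy()
        act[complex_mask] = spec.background_activity
        act_shifted = _shift_int(np.where(complex_mask, base.activity, 0.0), off)
        act[shifted_mask] = act_shifted[shifted_mask]

        mu = base.attenuation.copy()
        mu[complex_mask] = spec.mu_soft
        mu[shifted_mask] = spec.mu_liver

        lab = base.labels.copy()
        lab[complex_mask] = LABEL_BODY
        lab_shifted = _shift_int(base.labels, off, fill=LABEL_AIR)
        lab[shifted_mask] = lab_shifted[shifted_mask]

        phases.append(StaticPhantom(act, mu, lab, base.grid, spec))

    return Phantom4D(phases, true_shifts, spec)


# ---------------------------------------------------------------------------
# cohort sampling

#: observed liver motion range used to truncate the amplitude distribution, mm
AMPLITUDE_RANGE_MM = (3.4, 16.8)


@dataclass
class CohortConfig:
    amplitude_mean_mm: float = 9.5
    amplitude_sd_mm: float = 2.7
    amplitude_range_mm: tuple[float, float] = AMPLITUDE_RANGE_MM
    tumor_volume_range_ml: tuple[float, float] = (2.0, 200.0)
    tumor_uptake_range: tuple[float, float] = (2.0, 8.0)
    lung_shunt_range: tuple[float, float] = (0.02, 0.10)
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (4.418, 4.418, 4.418)
    liver_activity: float = 1.0


def dome_cohort(
    n_patients: int,
    seed: int,
    grid_shape=(32, 32, 32),
    spacing_mm=(6.0, 6.0, 6.0),
    amplitude_range_mm=(8.0, 14.0),
    radius_range_mm=(5.0, 20.0),
    uptake_range=(6.0, 12.0),
    shunt_range=(0.006, 0.016),
) -> list[PhantomSpec]:
    """Cohort of phantoms with a hot lesion at the hepatic dome, directly
    under the costophrenic lung recess, and CC-dominant motion.

    This construction concentrates the motion-sensitive configuration (lesion
    at the liver/lung interface, low shunt) for studying the direction of the
    lung dose change under motion compensation.
    """
    rng = np.random.default_rng(seed)
    lungs = dict(
        lung_centers_mm=((-38.0, 0.0, 44.0), (38.0, 0.0, 44.0)),
        lung_axes_mm=(28.0, 34.0, 56.0),
    )
    proto = PhantomSpec(grid_shape=grid_shape, spacing_mm=spacing_mm)
    lc = np.asarray(proto.liver_center_mm)
    la = np.asarray(proto.liver_axes_mm)
    grid = proto.grid
    x, y, z = grid.coords()
    liver_vox = (
        ((x - lc[0]) / la[0]) ** 2 + ((y - lc[1]) / la[1]) ** 2 + ((z - lc[2]) / la[2]) ** 2
    ) <= 1.0

    def fits(center, r):
        tm = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= r**2
        return tm.sum() >= 4 and bool(np.all(liver_vox[tm]))

    specs = []
    for i in range(n_patients):
        radius = float(rng.uniform(*radius_range_mm))
        cx = float(rng.choice([-44.0, -38.0]))
        # lesion top hugs the dome apex of its column; sink it until the
        # raster fits inside the liver
        z_top = lc[2] + la[2] * np.sqrt(max(1 - ((cx - lc[0]) / la[0]) ** 2, 0.0))
        cz = z_top - 1.0 - radius
        while not fits((cx, 0.0, cz), radius) and cz > lc[2]:
            cz -= 2.0
        specs.append(
            PhantomSpec(
                grid_shape=grid_shape,
                spacing_mm=spacing_mm,
                tumors=[TumorSpec((cx, 0.0, cz), radius, float(rng.uniform(*uptake_range)))],
                lung_shunt_fraction_true=float(rng.uniform(*shunt_range)),
                motion_amplitude_mm=(0.0, 0.0, float(rng.uniform(*amplitude_range_mm))),
                seed=int(rng.integers(0, 2**31 - 1)),
                **lungs,
            )
        )
    return specs


def sample_cohort(
    n_patients: int, seed: int, config: CohortConfig | None = None
) -> list[PhantomSpec]:
    """Draw seeded patient phantoms: truncated-normal amplitudes, log-uniform
    tumor volumes, one tumor per patient placed inside the liver."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    lo, hi = cfg.amplitude_range_mm
    a = (lo - cfg.amplitude_mean_mm) / cfg.amplitude_sd_mm
    b = (hi - cfg.amplitude_mean_mm) / cfg.amplitude_sd_mm
    amps = stats.truncnorm.rvs(
        a, b, loc=cfg.amplitude_mean_mm, scale=cfg.amplitude_sd_mm,
        size=n_patients, random_state=rng,
    )

    specs = []
    for i in range(n_patients):
        vol_ml = np.exp(
            rng.uniform(*np.log(np.asarray(cfg.tumor_volume_range_ml)))
        )
        radius = (3.0 * vol_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        spec_proto = PhantomSpec(
            grid_shape=cfg.grid_shape, spacing_mm=cfg.spacing_mm
        )
        # tumor center: uniform inside the liver ellipsoid shrunk by the
        # tumor radius so the lesion stays inside the liver
        axes = np.asarray(spec_proto.liver_axes_mm) - radius - max(cfg.spacing_mm)
        axes = np.maximum(axes, 1.0)
        while True:
            u = rng.uniform(-1.0, 1.0, size=3)
            if (u**2).sum() <= 1.0:
                break
        center = np.asarray(spec_proto.liver_center_mm) + u * axes
        specs.append(
            PhantomSpec(
                grid_shape=cfg.grid_shape,
                spacing_mm=cfg.spacing_mm,
                tumors=[
                    TumorSpec(
                        tuple(center), radius, float(rng.uniform(*cfg.tumor_uptake_range))
                    )
                ],
                liver_activity=cfg.liver_activity,
                lung_shunt_fraction_true=float(rng.uniform(*cfg.lung_shunt_range)),
                motion_amplitude_mm=(0.0, 0.0, float(amps[i])),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs
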