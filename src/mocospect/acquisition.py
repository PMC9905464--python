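"""SPECT camera simulator: step-and-shoot list-mode acquisition.

Two energy windows are modeled.  The primary window holds the attenuated,
PSF-blurred geometric projection plus a configurable scatter contamination;
the scatter window holds a kernel-surrogate scatter term (broad Gaussian of
the unattenuated projection).  The surrogate exists to exercise the
dual-energy-window correction pathway, not to model photon transport.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mocospect.grid import Grid, require_same_geometry
from mocospect.phantom import Phantom4D, StaticPhantom
from mocospect.projector import Projector, PSFModel, angle_set
from scipy.ndimage import gaussian_filter

WINDOW_PRIMARY = 0
WINDOW_SCATTER = 1


@dataclass(frozen=True)
class EnergyWindow:
    center_kev: float
    fractional_width: float  # total width as a fraction of center

    @property
    def width_kev(self) -> float:
        return self.center_kev * self.fractional_width


@dataclass
class AcquisitionSpec:
    n_projections: int = 60
    arc_deg: float = 360.0
    time_per_projection_s: float = 25.0
    detector_bin_mm: float = 4.418
    primary_window: EnergyWindow = field(
        default_factory=lambda: EnergyWindow(140.5, 0.20)
    )
    scatter_window: EnergyWindow = field(
        default_factory=lambda: EnergyWindow(120.0, 0.10)
    )
    psf: PSFModel | None = field(default_factory=PSFModel)
    detector_radius_mm: float | None = None
    # scatter surrogate parameters
    scatter_fraction: float = 0.3  # of geometric counts, into the scatter window
    primary_scatter_fraction: float = 0.35  # contamination of the primary window
    scatter_kernel_fwhm_mm: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if self.n_projections < 1:
            raise ValueError("n_projections must be >= 1")
        if self.primary_window.fractional_width <= 0 or self.scatter_window.fractional_width <= 0:
            raise ValueError("window widths must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        return angle_set(self.n_projections, self.arc_deg)

    @property
    def scan_duration_s(self) -> float:
        return self.n_projections * self.time_per_projection_s

    def projector(self, grid: Grid) -> Projector:
        return Projector(grid, self.angles_deg, self.psf, self.detector_radius_mm)


@dataclass
class ProjectionSet:
    """Per-angle detector count arrays, one per energy window."""

    primary: np.ndarray  # (n_projections, nu, nv)
    scatter: np.ndarray
    angles_deg: np.ndarray
    spec: AcquisitionSpec

    def __post_init__(self):
        if np.any(self.primary < 0) or np.any(self.scatter < 0):
            raise ValueError("projection counts must be non-negative")
        if not (np.all(np.isfinite(self.primary)) and np.all(np.isfinite(self.scatter))):
            raise ValueError("projection counts must be finite")


@dataclass
class ListModeData:
    """Timestamped detection events from a step-and-shoot acquisition."""

    t_s: np.ndarray
    projection: np.ndarray
    u: np.ndarray  # detector bin, in-plane axis
    v: np.ndarray  # detector bin, CC axis
    window: np.ndarray  # WINDOW_PRIMARY / WINDOW_SCATTER
    true_phase: np.ndarray  # simulation ground truth
    detector_shape: tuple[int, int]
    spec: AcquisitionSpec
    n_phases_true: int

    def __post_init__(self):
        if np.any(np.diff(self.t_s) < 0):
            raise ValueError("event times must be nondecreasing")

    def __len__(self) -> int:
        return len(self.t_s)


def forward_project(
    activity: np.ndarray,
    attenuation: np.ndarray,
    grid: Grid,
    acq: AcquisitionSpec,
    angle_deg: float,
    projector: Projector | None = None,
) -> np.ndarray:
    """Expected primary-window geometric projection at one angle."""
    if activity.shape != attenuation.shape:
        raise ValueError("activity and attenuation maps must share geometry")
    proj = projector or Projector(
        grid, np.array([angle_deg]), acq.psf, acq.detector_radius_mm
    )
    idx = int(np.argmin(np.abs(proj.angles_deg - angle_deg)))
    att = proj.attenuation_factors(attenuation, idx)
    return proj.forward(activity, idx, att)


def _broad_scatter(
    geometric_unattenuated: np.ndarray, acq: AcquisitionSpec, bin_mm: tuple[float, float]
) -> np.ndarray:
    sig = acq.scatter_kernel_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return gaussian_filter(
        geometric_unattenuated, (sig / bin_mm[0], sig / bin_mm[1]), mode="constant"
    )


def simulate_scatter_window(
    activity: np.ndarray,
    attenuation: np.ndarray,
    grid: Grid,
    acq: AcquisitionSpec,
    angle_deg: float,
    projector: Projector | None = None,
) -> np.ndarray:
    """Expected scatter-window projection (broad-kernel surrogate)."""
    angles = projector.angles_deg if projector is not None else np.array([angle_deg])
    proj = Projector(grid, angles, None, acq.detector_radius_mm)
    idx = int(np.argmin(np.abs(proj.angles_deg - angle_deg)))
    geo = proj.forward(activity, idx, None)
    return acq.scatter_fraction * _broad_scatter(geo, acq, proj.detector_spacing)


def expected_phase_projections(
    phantom: Phantom4D, acq: AcquisitionSpec, projector: Projector | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless expected count *rates* per phase, angle and window.

    Returns (primary, scatter) arrays of shape (n_phases, n_projections, nu, nv)
    in counts per second of dwell time.
    """
    proj = projector or acq.projector(phantom.grid)
    proj_nopsf = Projector(phantom.grid, acq.angles_deg, None, acq.detector_radius_mm)
    n_ph = phantom.n_phases
    n_ang = acq.n_projections
    nu, nv = proj.detector_shape
    primary = np.zeros((n_ph, n_ang, nu, nv))
    scatter = np.zeros((n_ph, n_ang, nu, nv))
    for p, ph in enumerate(phantom.phases):
        for a in range(n_ang):
            att = proj.attenuation_factors(ph.attenuation, a)
            geo = proj.forward(ph.activity, a, att)
            unatt = proj_nopsf.forward(ph.activity, a, None)
            broad = _broad_scatter(unatt, acq, proj.detector_spacing)
            primary[p, a] = geo + acq.primary_scatter_fraction * broad
            scatter[p, a] = acq.scatter_fraction * broad
    return primary, scatter


def _phase_dwell_bins(
    phantom: Phantom4D, acq: AcquisitionSpec, fine_dt: float = 0.01
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fine time grid over the scan with projection index and true phase."""
    t = np.arange(0.0, acq.scan_duration_s, fine_dt) + fine_dt / 2.0
    proj_idx = np.minimum(
        (t / acq.time_per_projection_s).astype(int), acq.n_projections - 1
    )
    phase = phantom.phase_of_time(t)
    return t, proj_idx, phase


def acquire_listmode(
    phantom: Phantom4D,
    acq: AcquisitionSpec,
    seed: int | None = None,
    projector: Projector | None = None,
    expected: tuple[np.ndarray, np.ndarray] | None = None,
) -> ListModeData:
    """Poisson-sample timestamped events for the full step-and-shoot scan.

    For each projection the 25 s (configurable) dwell is partitioned among
    respiratory phases by the breathing schedule; expected projections per
    phase are scaled by the dwell time, Poisson-sampled, and expanded into
    events with timestamps uniform within their phase's dwell intervals.
    """
    total_activity = phantom.phases[0].activity.sum()
    if total_activity <= 0:
        raise ValueError("phantom has no activity")
    rng = np.random.default_rng(acq.seed if seed is None else seed)
    prim_rate, scat_rate = (
        expected
        if expected is not None
        else expected_phase_projections(phantom, acq, projector)
    )
    fine_dt = min(0.01, phantom.spec.breathing_period_s / (8 * phantom.n_phases))
    t_fine, proj_fine, phase_fine = _phase_dwell_bins(phantom, acq, fine_dt)

    ev_t, ev_p, ev_u, ev_v, ev_w, ev_ph = [], [], [], [], [], []
    for a in range(acq.n_projections):
        in_proj = proj_fine == a
        for p in range(phantom.n_phases):
            sel = in_proj & (phase_fine == p)
            n_bins = int(sel.sum())
            if n_bins == 0:
                continue
            dwell = n_bins * fine_dt
            times_pool = t_fine[sel]
            for w, rate in ((WINDOW_PRIMARY, prim_rate), (WINDOW_SCATTER, scat_rate)):
                lam = rate[p, a] * dwell
                counts = rng.poisson(lam)
                n = int(counts.sum())
                if n == 0:
                    continue
                uu, vv = np.nonzero(counts)
                reps = counts[uu, vv]
                ev_u.append(np.repeat(uu, reps))
                ev_v.append(np.repeat(vv, reps))
                ts = times_pool[rng.integers(0, n_bins, size=n)] + rng.uniform(
                    -fine_dt / 2, fine_dt / 2, size=n
                )
                ev_t.append(ts)
                ev_p.append(np.full(n, a, dtype=np.int16))
                ev_w.append(np.full(n, w, dtype=np.int8))
                ev_ph.append(np.full(n, p, dtype=np.int16))

    t = np.concatenate(ev_t) if ev_t else np.empty(0)
    order = np.argsort(t, kind="stable")
    cat = lambda parts, dt: (
        np.concatenate(parts)[order] if parts else np.empty(0, dtype=dt)
    )
    nu, nv = prim_rate.shape[2:]
    return ListModeData(
        t_s=t[order],
        projection=cat(ev_p, np.int16),
        u=cat(ev_u, np.int64).astype(np.int16),
        v=cat(ev_v, np.int64).astype(np.int16),
        window=cat(ev_w, np.int8),
        true_phase=cat(ev_ph, np.int16),
        detector_shape=(nu, nv),
        spec=acq,
        n_phases_true=phantom.n_phases,
    )


def bin_listmode(
    lm: ListModeData, phase_labels: np.ndarray, n_phases: int
) -> list[ProjectionSet]:
    """Sort events into gated projection sets; count-exact partition."""
    phase_labels = np.asarray(phase_labels)
    if len(phase_labels) != len(lm):
        raise ValueError("phase assignment must cover all events")
    if len(lm) and (phase_labels.min() < 0 or phase_labels.max() >= n_phases):
        raise ValueError("phase label out of range")
    nu, nv = lm.detector_shape
    n_ang = lm.spec.n_projections
    out = []
    for p in range(n_phases):
        sel = phase_labels == p
        sets = {}
        for w, name in ((WINDOW_PRIMARY, "primary"), (WINDOW_SCATTER, "scatter")):
            sw = sel & (lm.window == w)
            flat = (
                lm.projection[sw].astype(np.int64) * (nu * nv)
                + lm.u[sw].astype(np.int64) * nv
                + lm.v[sw].astype(np.int64)
            )
            sets[name] = np.bincount(flat, minlength=n_ang * nu * nv).reshape(
                n_ang, nu, nv
            ).astype(float)
        out.append(
            ProjectionSet(sets["primary"], sets["scatter"], lm.spec.angles_deg, lm.spec)
        )
    return out


def bin_all(lm: ListModeData) -> ProjectionSet:
    """Ungated projections from all events."""
    return bin_listmode(lm, np.zeros(len(lm), dtype=int), 1)[0]
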