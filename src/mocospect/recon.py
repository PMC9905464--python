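"""OSEM reconstruction, dual-energy-window scatter correction, gated 4D
reconstruction and motion-compensated reconstruction from corrected events.

The motion-compensated arm ("3Dcomp") estimates a per-phase, per-angle 2D
affine transform between gated projections and a reference phase, maps each
event's detector coordinate through its phase's transform, splats the
corrected events into a single projection set and reconstructs it with OSEM
using all counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from mocospect.acquisition import (
    ListModeData,
    ProjectionSet,
    WINDOW_PRIMARY,
    WINDOW_SCATTER,
    bin_listmode,
)
from mocospect.grid import Grid
from mocospect.projector import Projector


@dataclass
class ReconConfig:
    n_subsets: int = 15
    n_iterations: int = 15
    epsilon: float = 1e-10
    dew_k: float | None = None  # None -> (primary width / scatter width) / 2

    def __post_init__(self):
        if self.n_iterations < 1 or self.n_subsets < 1:
            raise ValueError("subsets and iterations must be >= 1")


@dataclass
class ReconImage:
    values: np.ndarray
    grid: Grid
    method: str  # "3D" | "4Dgated" | "3Dcomp"
    phase: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("reconstruction must be non-negative and finite")


def dew_scatter_estimate(
    scatter_counts: np.ndarray,
    primary_width_kev: float,
    scatter_width_kev: float,
    k: float | None = None,
    primary_counts: np.ndarray | None = None,
) -> np.ndarray:
    """Dual-energy-window scatter term for the primary window.

    estimate = k * scatter-window counts, k defaulting to
    (primary width / scatter width) / 2; clipped at the observed primary
    counts when those are supplied.
    """
    if primary_width_kev <= 0 or scatter_width_kev <= 0:
        raise ValueError("window widths must be positive")
    if k is None:
        k = (primary_width_kev / scatter_width_kev) / 2.0
    est = k * np.asarray(scatter_counts, dtype=float)
    if primary_counts is not None:
        est = np.minimum(est, np.asarray(primary_counts, dtype=float))
    return est


def _subset_indices(n_projections: int, n_subsets: int) -> list[np.ndarray]:
    # round-robin assignment spreads each subset's angles over the arc
    return [np.arange(s, n_projections, n_subsets) for s in range(n_subsets)]


def osem(
    projections: ProjectionSet,
    attenuation: np.ndarray,
    projector: Projector,
    config: ReconConfig,
    scatter_estimate: np.ndarray | None = None,
    method: str = "3D",
    phase: int | None = None,
) -> ReconImage:
    """Ordered-subset EM with attenuated PSF projector and additive scatter.

    The scatter estimate (projection domain, same shape as the primary
    counts) enters the forward model denominator.  No post-reconstruction
    filtering is applied.
    """
    counts = np.asarray(projections.primary, dtype=float)
    if np.any(counts < 0):
        raise ValueError("projection counts must be non-negative")
    n_ang = counts.shape[0]
    if scatter_estimate is None:
        scatter_estimate = np.zeros_like(counts)
    n_subsets = min(config.n_subsets, n_ang)
    subsets = _subset_indices(n_ang, n_subsets)
    grid = projector.grid
    eps = config.epsilon

    att = {a: projector.attenuation_factors(attenuation, a) for a in range(n_ang)}
    sens = []
    ones = np.ones(projector.detector_shape)
    for sub in subsets:
        s = np.zeros(grid.shape)
        for a in sub:
            s += projector.adjoint(ones, a, att[a])
        sens.append(s)

    if counts.sum() == 0:
        return ReconImage(np.zeros(grid.shape), grid, method, phase,
                          {"iterations": 0, "note": "all-zero projections"})

    x = np.ones(grid.shape)
    zero_sens_flagged = False
    for _ in range(config.n_iterations):
        for sub, s in zip(subsets, sens):
            ratio_back = np.zeros(grid.shape)
            for a in sub:
                fwd = projector.forward(x, a, att[a]) + scatter_estimate[a]
                ratio_back += projector.adjoint(counts[a] / np.maximum(fwd, eps), a, att[a])
            ok = s > eps
            if not zero_sens_flagged and not ok.all():
                zero_sens_flagged = True
            upd = np.ones_like(x)
            np.divide(ratio_back, s, out=upd, where=ok)
            x = np.where(ok, x * upd, x)
    x = np.maximum(x, 0.0)
    return ReconImage(
        x, grid, method, phase,
        {
            "iterations": config.n_iterations,
            "subsets": n_subsets,
            "zero_sensitivity_voxels": bool(zero_sens_flagged),
        },
    )


def poisson_log_likelihood(
    image: np.ndarray,
    projections: ProjectionSet,
    attenuation: np.ndarray,
    projector: Projector,
    scatter_estimate: np.ndarray | None = None,
) -> float:
    """Poisson log-likelihood of the data under the forward model (up to the
    data-only log-factorial constant); used as an independent convergence oracle."""
    counts = projections.primary
    n_ang = counts.shape[0]
    if scatter_estimate is None:
        scatter_estimate = np.zeros_like(counts)
    ll = 0.0
    for a in range(n_ang):
        att = projector.attenuation_factors(attenuation, a)
        lam = np.maximum(projector.forward(image, a, att) + scatter_estimate[a], 1e-12)
        ll += float(np.sum(counts[a] * np.log(lam) - lam))
    return ll


def reconstruct_3d(
    lm_or_projections,
    attenuation: np.ndarray,
    projector: Projector,
    config: ReconConfig,
) -> ReconImage:
    """Conventional reconstruction from all counts with DEW scatter correction."""
    from mocospect.acquisition import bin_all

    projs = (
        lm_or_projections
        if isinstance(lm_or_projections, ProjectionSet)
        else bin_all(lm_or_projections)
    )
    acq = projs.spec
    scat = dew_scatter_estimate(
        projs.scatter,
        acq.primary_window.width_kev,
        acq.scatter_window.width_kev,
        k=config.dew_k,
        primary_counts=projs.primary,
    )
    return osem(projs, attenuation, projector, config, scat, method="3D")


def reconstruct_gated_4d(
    lm: ListModeData,
    phase_labels: np.ndarray,
    attenuation: np.ndarray,
    projector: Projector,
    config: ReconConfig,
) -> list[ReconImage]:
    """Per-phase OSEM on gated projections, single attenuation map."""
    n_phases = int(np.max(phase_labels)) + 1 if len(phase_labels) else 1
    gated = bin_listmode(lm, phase_labels, n_phases)
    out = []
    for p, projs in enumerate(gated):
        if projs.primary.sum() == 0:
            warnings.warn(f"phase {p} has no events; zero image")
            out.append(
                ReconImage(np.zeros(projector.grid.shape), projector.grid, "4Dgated", p)
            )
            continue
        scat = dew_scatter_estimate(
            projs.scatter,
            lm.spec.primary_window.width_kev,
            lm.spec.scatter_window.width_kev,
            k=config.dew_k,
            primary_counts=projs.primary,
        )
        out.append(osem(projs, attenuation, projector, config, scat, "4Dgated", p))
    return out


# ---------------------------------------------------------------------------
# inter-phase 2D affine registration and event correction

def _affine_warp(img: np.ndarray, params: np.ndarray) -> np.ndarray:
    M = params[:4].reshape(2, 2)
    t = params[4:]
    return ndimage.affine_transform(img, M, offset=t, order=1, mode="constant")


IDENTITY_AFFINE = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])


def register_projection_pair(
    moving: np.ndarray,
    reference: np.ndarray,
    affine: bool = True,
    smooth_bins: float = 1.0,
    maxiter: int = 60,
) -> np.ndarray:
    """2D registration of ``moving`` onto ``reference``: returns params p such
    that warp(moving, p) ~= reference (MSE on count-normalized projections)."""
    def prep(im):
        im = np.asarray(im, dtype=float)
        s = im.sum()
        im = im / s if s > 0 else im
        return ndimage.gaussian_filter(im, smooth_bins) if smooth_bins > 0 else im

    mv, ref = prep(moving), prep(reference)
    if mv.sum() == 0 or ref.sum() == 0:
        warnings.warn("empty projection in registration; identity returned")
        return IDENTITY_AFFINE.copy()
    try:
        shift, _, _ = phase_cross_correlation(ref, mv, upsample_factor=10)
    except Exception:
        shift = np.zeros(2)
    p0 = IDENTITY_AFFINE.copy()
    p0[4:] = -np.asarray(shift)  # affine_transform offset convention

    def cost(p):
        return float(np.mean((_affine_warp(mv, p) - ref) ** 2))

    if not affine:
        def cost_t(t):
            return cost(np.concatenate((IDENTITY_AFFINE[:4], t)))
        res = optimize.minimize(cost_t, p0[4:], method="Powell",
                                options={"maxiter": maxiter, "xtol": 1e-3})
        p = np.concatenate((IDENTITY_AFFINE[:4], res.x))
        ok = res.success or cost(p) <= cost(p0)
    else:
        res = optimize.minimize(cost, p0, method="Powell",
                                options={"maxiter": maxiter, "xtol": 1e-3})
        p = res.x
        ok = res.success or cost(p) <= cost(p0)
    if not ok:
        warnings.warn("projection registration failed; identity returned")
        return IDENTITY_AFFINE.copy()
    return np.asarray(p, dtype=float)


def register_phases_2d_affine(
    gated: list[ProjectionSet],
    reference: int,
    affine: bool = True,
    per_angle: bool = True,
) -> np.ndarray:
    """Per-phase, per-angle affine transforms onto the reference phase.

    Returns an array (n_phases, n_angles, 6); the reference phase rows are
    identity.  With ``per_angle=False`` one transform per phase is estimated
    from the angle-summed projections and broadcast over angles.
    """
    n_phases = len(gated)
    if not (0 <= reference < n_phases):
        raise ValueError("reference phase out of range")
    n_ang = gated[0].primary.shape[0]
    out = np.tile(IDENTITY_AFFINE, (n_phases, n_ang, 1))
    for p in range(n_phases):
        if p == reference:
            continue
        if per_angle:
            for a in range(n_ang):
                out[p, a] = register_projection_pair(
                    gated[p].primary[a], gated[reference].primary[a], affine
                )
        else:
            tr = register_projection_pair(
                gated[p].primary.sum(axis=0), gated[reference].primary.sum(axis=0), affine
            )
            out[p, :] = tr
    return out


def correct_listmode(
    lm: ListModeData, phase_labels: np.ndarray, transforms: np.ndarray
) -> tuple[ProjectionSet, int]:
    """Map each event's detector coordinate through its phase/angle affine
    and splat bilinearly into a corrected projection set.

    The registration maps the reference frame into the moving (phase) frame
    (scipy ``affine_transform`` convention: warped(x) = moving(Mx + t)), so
    events at moving-frame position x are corrected to M^-1 (x - t).
    Event weight falling off the detector is dropped and counted.
    """
    nu, nv = lm.detector_shape
    n_ang = lm.spec.n_projections
    out = {
        WINDOW_PRIMARY: np.zeros((n_ang, nu, nv)),
        WINDOW_SCATTER: np.zeros((n_ang, nu, nv)),
    }
    phase_labels = np.asarray(phase_labels)
    dropped = 0.0
    for p in np.unique(phase_labels):
        for a in range(n_ang):
            sel = (phase_labels == p) & (lm.projection == a)
            if not sel.any():
                continue
            params = transforms[p, a]
            M = params[:4].reshape(2, 2)
            t = params[4:]
            Minv = np.linalg.inv(M)
            xy = np.stack([lm.u[sel], lm.v[sel]]).astype(float)
            corr = Minv @ (xy - t[:, None])
            for w in (WINDOW_PRIMARY, WINDOW_SCATTER):
                wsel = lm.window[sel] == w
                if not wsel.any():
                    continue
                cu, cv = corr[0][wsel], corr[1][wsel]
                u0 = np.floor(cu).astype(int)
                v0 = np.floor(cv).astype(int)
                fu, fv = cu - u0, cv - v0
                total_before = float(wsel.sum())
                placed = 0.0
                for du, wu in ((0, 1 - fu), (1, fu)):
                    for dv, wv in ((0, 1 - fv), (1, fv)):
                        ui, vi = u0 + du, v0 + dv
                        wgt = wu * wv
                        ok = (ui >= 0) & (ui < nu) & (vi >= 0) & (vi < nv) & (wgt > 0)
                        if ok.any():
                            np.add.at(out[w][a], (ui[ok], vi[ok]), wgt[ok])
                            placed += float(wgt[ok].sum())
                dropped += total_before - placed
    projs = ProjectionSet(
        out[WINDOW_PRIMARY], out[WINDOW_SCATTER], lm.spec.angles_deg, lm.spec
    )
    return projs, dropped


def reconstruct_3dcomp(
    lm: ListModeData,
    phase_labels: np.ndarray,
    reference: int,
    attenuation: np.ndarray,
    projector: Projector,
    config: ReconConfig,
    transforms: np.ndarray | None = None,
    affine: bool = True,
) -> ReconImage:
    """Motion-compensated reconstruction using all corrected counts."""
    n_phases = int(np.max(phase_labels)) + 1 if len(phase_labels) else 1
    if transforms is None:
        gated = bin_listmode(lm, phase_labels, n_phases)
        transforms = register_phases_2d_affine(gated, reference, affine)
    projs, dropped = correct_listmode(lm, phase_labels, transforms)
    acq = lm.spec
    scat = dew_scatter_estimate(
        projs.scatter,
        acq.primary_window.width_kev,
        acq.scatter_window.width_kev,
        k=config.dew_k,
        primary_counts=projs.primary,
    )
    img = osem(projs, attenuation, projector, config, scat, method="3Dcomp",
               phase=reference)
    img.meta["dropped_event_weight"] = float(dropped)
    img.meta["reference_phase"] = int(reference)
    return img
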