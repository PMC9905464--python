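"""Data-driven respiratory signal extraction from list-mode data.

Events are rebinned into short time frames, each frame histogrammed on a
coarse detector grid.  A Laplacian eigenmap of the frame features (Gaussian
kernel on a k-NN graph, features centered per projection to remove the
view dependence) yields a 1D surrogate breathing signal; cycles are split
into equal-time phase bins which the events inherit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter1d
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from sklearn.neighbors import kneighbors_graph

from mocospect.acquisition import ListModeData


@dataclass
class RespSignal:
    t_s: np.ndarray  # time-bin centers
    amplitude: np.ndarray  # arbitrary units, one per time bin
    dt_s: float
    degenerate: bool = False
    phase_of_bin: np.ndarray | None = None
    quantile_fallback: bool = False


@dataclass
class FrameFeatures:
    matrix: np.ndarray  # (n_bins, n_features)
    t_s: np.ndarray
    dt_s: float
    projection_of_bin: np.ndarray
    bin_of_event: np.ndarray
    cranial_surrogate: np.ndarray  # per-bin mean CC detector coordinate


def rebin_listmode_features(
    lm: ListModeData, dt_s: float = 0.5, coarse_shape: tuple[int, int] = (16, 16)
) -> FrameFeatures:
    """Histogram events per time bin on a coarse detector grid."""
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    duration = lm.spec.scan_duration_s
    if duration < dt_s:
        raise ValueError("scan shorter than one time bin")
    n_bins = int(np.ceil(duration / dt_s))
    nu, nv = lm.detector_shape
    cu, cv = coarse_shape
    bin_of_event = np.minimum((lm.t_s / dt_s).astype(int), n_bins - 1)
    fu = np.minimum((lm.u * cu) // nu, cu - 1).astype(np.int64)
    fv = np.minimum((lm.v * cv) // nv, cv - 1).astype(np.int64)
    flat = bin_of_event * (cu * cv) + fu * cv + fv
    matrix = np.bincount(flat, minlength=n_bins * cu * cv).reshape(
        n_bins, cu * cv
    ).astype(float)

    t_centers = (np.arange(n_bins) + 0.5) * dt_s
    proj_of_bin = np.minimum(
        (t_centers / lm.spec.time_per_projection_s).astype(int),
        lm.spec.n_projections - 1,
    )
    # per-bin mean CC coordinate of events (cranial-count surrogate)
    sums = np.bincount(bin_of_event, weights=lm.v.astype(float), minlength=n_bins)
    cnts = np.bincount(bin_of_event, minlength=n_bins)
    surr = np.divide(sums, cnts, out=np.zeros(n_bins), where=cnts > 0)
    return FrameFeatures(matrix, t_centers, dt_s, proj_of_bin, bin_of_event, surr)


def _normalize_per_projection(features: FrameFeatures) -> np.ndarray:
    X = features.matrix.astype(float).copy()
    for a in np.unique(features.projection_of_bin):
        sel = features.projection_of_bin == a
        X[sel] -= X[sel].mean(axis=0, keepdims=True)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    np.divide(X, norms, out=X, where=norms > 0)
    return X


def laplacian_eigenmap_signal(
    features: FrameFeatures, k_neighbors: int = 20, max_k: int | None = None
) -> RespSignal:
    """First nontrivial eigenvector of the normalized graph Laplacian.

    The k-NN graph uses a Gaussian kernel with the median-distance bandwidth
    heuristic.  If the graph is disconnected, k is doubled (with a warning)
    until connected or ``max_k`` is reached.  Sign is fixed so that the
    correlation with the per-frame cranial-coordinate surrogate is positive.
    """
    X = _normalize_per_projection(features)
    n = X.shape[0]
    if n < k_neighbors + 1:
        raise ValueError("need at least k_neighbors + 1 time bins")
    if np.allclose(X - X.mean(axis=0, keepdims=True), 0.0):
        warnings.warn("identical feature rows: degenerate eigenmap, flat signal")
        return RespSignal(features.t_s, np.zeros(n), features.dt_s, degenerate=True)

    max_k = max_k or max(64, 4 * k_neighbors)
    k = k_neighbors
    while True:
        G = kneighbors_graph(X, k, mode="distance", include_self=False)
        G = G.maximum(G.T)
        n_comp, _ = connected_components(G, directed=False)
        if n_comp == 1:
            break
        if k >= max_k:
            raise ValueError("k-NN graph disconnected even at k=%d" % k)
        k = min(2 * k, max_k)
        warnings.warn(f"k-NN graph disconnected, increasing k to {k}")

    d = G.data
    eps = np.median(d[d > 0])
    W = G.copy()
    W.data = np.exp(-(W.data**2) / (2.0 * eps**2))
    W = W.maximum(W.T)
    deg = np.asarray(W.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    Dinv = sparse.diags(dinv)
    L = sparse.identity(n) - Dinv @ W @ Dinv
    vals, vecs = eigsh(L.tocsc(), k=2, sigma=-1e-6, which="LM")
    order = np.argsort(vals)
    signal = dinv * vecs[:, order[1]]  # random-walk eigenvector
    signal = signal - np.median(signal)

    surr = features.cranial_surrogate.copy()
    for a in np.unique(features.projection_of_bin):
        sel = features.projection_of_bin == a
        surr[sel] -= surr[sel].mean()
    if np.std(surr) > 0 and np.corrcoef(signal, surr)[0, 1] < 0:
        signal = -signal
    return RespSignal(features.t_s, signal, features.dt_s)


def assign_phases(
    signal: RespSignal,
    features: FrameFeatures,
    n_phases: int = 8,
    smooth_s: float = 0.75,
) -> tuple[np.ndarray, RespSignal]:
    """Split detected breathing cycles into equal-time phase bins.

    Cycle boundaries are upward zero crossings of the smoothed,
    median-centered signal; each cycle is divided into ``n_phases``
    equal-time bins.  Events inherit their time bin's label.  If fewer than
    two crossings are found, amplitude quantiles are used instead (with a
    warning).
    """
    if not np.all(np.isfinite(signal.amplitude)):
        raise ValueError("signal must be finite")
    n = len(signal.amplitude)
    if n_phases == 1:
        signal.phase_of_bin = np.zeros(n, dtype=int)
        return np.zeros(len(features.bin_of_event), dtype=int), signal

    s = gaussian_filter1d(signal.amplitude, max(smooth_s / signal.dt_s, 1e-6))
    s = s - np.median(s)
    up = np.nonzero((s[:-1] <= 0) & (s[1:] > 0))[0] + 1
    if len(up) >= 2 and not signal.degenerate:
        bounds = up.astype(float)
        # individual crossings jitter with noise; for (near-)periodic
        # breathing a regular cycle grid fitted through all crossings is far
        # more stable, so regress crossing time on cycle index
        med_len = float(np.median(np.diff(bounds)))
        k = np.round((bounds - bounds[0]) / med_len)
        if len(np.unique(k)) >= 2:
            period, t0 = np.polyfit(k, bounds, 1)
        else:
            period, t0 = med_len, bounds[0]
        if period <= 0:
            period = med_len
        pos = np.mod((np.arange(n) - t0) / period, 1.0)
        # align the cycle origin onto a phase boundary: the underlying gated
        # signal is piecewise-constant per phase, so the correct fractional
        # origin minimizes the pooled within-phase variance; the remaining
        # integer-phase offset is irrelevant (labels are defined up to a
        # cyclic shift)
        raw = signal.amplitude
        best_delta, best_cost = 0.0, np.inf
        for delta in np.linspace(0.0, 1.0 / n_phases, 16, endpoint=False):
            lab = np.minimum(
                (np.mod(pos - delta, 1.0) * n_phases).astype(int), n_phases - 1
            )
            cost = 0.0
            for q in range(n_phases):
                sel = lab == q
                if sel.sum() > 1:
                    cost += float(np.var(raw[sel]) * sel.sum())
            if cost < best_cost:
                best_cost, best_delta = cost, float(delta)
        pos = np.mod(pos - best_delta, 1.0)
        phase = np.minimum((pos * n_phases).astype(int), n_phases - 1)
        signal.phase_of_bin = phase
    else:
        warnings.warn("no breathing cycles detected, falling back to quantile binning")
        q = np.quantile(signal.amplitude, np.linspace(0, 1, n_phases + 1)[1:-1])
        signal.phase_of_bin = np.searchsorted(q, signal.amplitude).astype(int)
        signal.quantile_fallback = True
    return signal.phase_of_bin[features.bin_of_event], signal


def select_reference_phase(
    gated_recons: list[np.ndarray], attenuation: np.ndarray, mu_threshold: float = 0.015
) -> tuple[int, np.ndarray]:
    """Automated surrogate for visual reference-phase selection.

    Returns the phase whose gated reconstruction maximizes the normalized
    cross-correlation with the attenuation map's dense-tissue (liver)
    footprint; ties resolve to the lowest index.  Scale-invariant by
    construction.
    """
    if len(gated_recons) == 0:
        raise ValueError("need at least one gated reconstruction")
    mask = (attenuation >= mu_threshold).astype(float)
    mask_c = mask - mask.mean()
    denom_mask = np.linalg.norm(mask_c)
    if denom_mask == 0:
        raise ValueError("attenuation mask is constant; cannot score phases")
    scores = np.full(len(gated_recons), -np.inf)
    for i, rec in enumerate(gated_recons):
        r = rec - rec.mean()
        nr = np.linalg.norm(r)
        if nr == 0:
            continue
        scores[i] = float(np.dot(r.ravel(), mask_c.ravel()) / (nr * denom_mask))
    if not np.any(np.isfinite(scores)):
        raise ValueError("all gated reconstructions are zero")
    best = float(np.nanmax(scores))
    return int(np.argmax(scores >= best - 1e-12)), scores


def cyclic_label_accuracy(pred: np.ndarray, truth: np.ndarray, n_phases: int) -> float:
    """Best agreement between label sequences over all cyclic shifts."""
    best = 0.0
    for s in range(n_phases):
        best = max(best, float(np.mean((pred + s) % n_phases == truth)))
    return best
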