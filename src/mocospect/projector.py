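"""Attenuated parallel-beam projector with depth-dependent Gaussian PSF.

The camera rotates about the CC axis (grid axis 2).  For each angle the
volume is resampled into the detector frame by an exact sparse bilinear
*splat* rotation (mass-conserving, with an exact transpose), attenuated by
the line integral of mu from each voxel to the detector, blurred in the
detector plane by a Gaussian whose FWHM grows linearly with
source-detector distance, and summed along the depth axis.  The adjoint is
the exact algebraic transpose (blur kernels are symmetric, attenuation is
diagonal, rotation transposes the sparse matrix), which OSEM relies on.

Detector coordinates: u = in-plane axis (nu = nx bins of spacing_x),
v = CC axis (nv = nz bins of spacing_z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter

from mocospect.grid import Grid

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PSFModel:
    """Linear depth-dependent resolution model: fwhm(d) = fwhm_ref + slope*(d - d_ref)."""

    fwhm_ref_mm: float = 7.4
    ref_distance_mm: float = 100.0
    slope: float = 0.025  # mm FWHM per mm of distance

    def __post_init__(self):
        if self.fwhm_ref_mm <= 0:
            raise ValueError("PSF FWHM must be positive")

    def fwhm_at(self, distance_mm):
        return np.maximum(
            self.fwhm_ref_mm + self.slope * (np.asarray(distance_mm) - self.ref_distance_mm),
            1e-6,
        )


def _rotation_splat_matrix(nx: int, ny: int, angle_deg: float) -> sparse.csr_matrix:
    """Sparse matrix R: rotated_plane = R @ plane.ravel().

    Each input pixel's center is rotated by ``angle_deg`` about the plane
    center and splatted bilinearly onto the output grid; weights falling
    outside the grid are dropped.  Columns therefore sum to 1 for interior
    pixels: the rotation conserves mass for supports away from the edge.
    """
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x = ix - cx
    y = iy - cy
    xr = c * x - s * y + cx
    yr = s * x + c * y + cy

    x0 = np.floor(xr).astype(int)
    y0 = np.floor(yr).astype(int)
    fx = xr - x0
    fy = yr - y0

    cols, rows, data = [], [], []
    col_idx = (ix * ny + iy).ravel()
    for dx, wx in ((0, 1.0 - fx), (1, fx)):
        for dy, wy in ((0, 1.0 - fy), (1, fy)):
            xi = x0 + dx
            yi = y0 + dy
            w = (wx * wy).ravel()
            valid = ((xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny)).ravel() & (w > 0)
            rows.append((xi * ny + yi).ravel()[valid])
            cols.append(col_idx[valid])
            data.append(w[valid])
    P = nx * ny
    return sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(P, P),
    )


class Projector:
    """Matched forward/adjoint projector for a fixed grid and angle set."""

    def __init__(
        self,
        grid: Grid,
        angles_deg: np.ndarray,
        psf: PSFModel | None = PSFModel(),
        detector_radius_mm: float | None = None,
    ):
        self.grid = grid
        self.angles_deg = np.asarray(angles_deg, dtype=float)
        self.psf = psf
        nx, ny, nz = grid.shape
        if detector_radius_mm is None:
            half = max(nx * grid.spacing[0], ny * grid.spacing[1]) / 2.0
            detector_radius_mm = float(np.hypot(half, half)) + 1.0
        self.detector_radius_mm = float(detector_radius_mm)
        self._rot: dict[int, sparse.csr_matrix] = {}
        self._rot_t: dict[int, sparse.csr_matrix] = {}
        # depth (axis 1) voxel-center distance to the detector at +y
        y_mm = (np.arange(ny) - (ny - 1) / 2.0) * grid.spacing[1]
        self.depth_distance_mm = self.detector_radius_mm - y_mm
        if np.any(self.depth_distance_mm <= 0):
            raise ValueError("detector radius must exceed the grid half-extent")

    @property
    def detector_shape(self) -> tuple[int, int]:
        return (self.grid.shape[0], self.grid.shape[2])

    @property
    def detector_spacing(self) -> tuple[float, float]:
        return (self.grid.spacing[0], self.grid.spacing[2])

    def _rotmat(self, angle_idx: int) -> sparse.csr_matrix:
        if angle_idx not in self._rot:
            nx, ny, _ = self.grid.shape
            self._rot[angle_idx] = _rotation_splat_matrix(
                nx, ny, self.angles_deg[angle_idx]
            )
        return self._rot[angle_idx]

    def _rotmat_t(self, angle_idx: int) -> sparse.csr_matrix:
        if angle_idx not in self._rot_t:
            self._rot_t[angle_idx] = self._rotmat(angle_idx).T.tocsr()
        return self._rot_t[angle_idx]

    def rotate(self, vol: np.ndarray, angle_idx: int) -> np.ndarray:
        nx, ny, nz = self.grid.shape
        return (self._rotmat(angle_idx) @ vol.reshape(nx * ny, nz)).reshape(nx, ny, nz)

    def rotate_adjoint(self, vol: np.ndarray, angle_idx: int) -> np.ndarray:
        nx, ny, nz = self.grid.shape
        return (self._rotmat_t(angle_idx) @ vol.reshape(nx * ny, nz)).reshape(
            nx, ny, nz
        )

    def rotate_field(self, vol: np.ndarray, angle_idx: int) -> np.ndarray:
        """Normalized splat rotation for non-conserved fields (attenuation)."""
        num = self.rotate(vol, angle_idx)
        den = self.rotate(np.ones_like(vol), angle_idx)
        out = np.zeros_like(num)
        np.divide(num, den, out=out, where=den > 1e-8)
        return out

    def attenuation_factors(self, mu: np.ndarray, angle_idx: int) -> np.ndarray:
        """exp(-integral of mu from each voxel center to the detector), in the
        rotated frame.  The detector sits at the +y (axis 1, high index) side."""
        mu_rot = self.rotate_field(mu, angle_idx)
        dy = self.grid.spacing[1]
        tail = np.cumsum(mu_rot[:, ::-1, :], axis=1)[:, ::-1, :]
        return np.exp(-dy * (tail - 0.5 * mu_rot))

    def _sigma_bins(self, depth_idx: int) -> tuple[float, float]:
        if self.psf is None:
            return (0.0, 0.0)
        fwhm = float(self.psf.fwhm_at(self.depth_distance_mm[depth_idx]))
        sig = fwhm * _FWHM_TO_SIGMA
        su, sv = self.detector_spacing
        return (sig / su, sig / sv)

    def forward(
        self, activity: np.ndarray, angle_idx: int, att: np.ndarray | None = None
    ) -> np.ndarray:
        """Expected detector counts at one angle; ``att`` are precomputed
        attenuation factors (pass None for an unattenuated projection)."""
        rot = self.rotate(activity, angle_idx)
        if att is not None:
            rot = rot * att
        ny = self.grid.shape[1]
        proj = np.zeros(self.detector_shape)
        for j in range(ny):
            plane = rot[:, j, :]
            if not plane.any():
                continue
            s = self._sigma_bins(j)
            if s[0] > 0:
                proj += gaussian_filter(plane, s, mode="constant")
            else:
                proj += plane
        return proj

    def adjoint(
        self, proj: np.ndarray, angle_idx: int, att: np.ndarray | None = None
    ) -> np.ndarray:
        """Exact transpose of :meth:`forward` for fixed attenuation factors."""
        nx, ny, nz = self.grid.shape
        back = np.empty((nx, ny, nz))
        for j in range(ny):
            s = self._sigma_bins(j)
            if s[0] > 0:
                back[:, j, :] = gaussian_filter(proj, s, mode="constant")
            else:
                back[:, j, :] = proj
        if att is not None:
            back *= att
        return self.rotate_adjoint(back, angle_idx)


def angle_set(n_projections: int, arc_deg: float = 360.0) -> np.ndarray:
    return np.arange(n_projections) * (arc_deg / n_projections)
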