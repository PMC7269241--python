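"""Shared image operators: Gaussian smoothing, affine registration,
resampling and masking.

These replicate the preprocessing applied before automated scoring of a
brain FDG-PET image: spatial normalization of the image to a common PET
template (approximated here by a 12-parameter affine transform), smoothing
with a 12 mm FWHM Gaussian filter, and brain masking.  Conventions are
pinned for reproducibility: world coordinates are RAS+ mm, interpolation is
trilinear, smoothing uses nearest-edge replication at the boundary, and
out-of-field voxels resample to a caller-chosen fill value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import minimize

from .volume import VolumeGrid

__all__ = [
    "FWHM_PER_SIGMA",
    "fwhm_to_sigma",
    "gaussian_smooth",
    "AffineTransform",
    "RegistrationResult",
    "affine_register",
    "resample",
    "apply_mask",
]

log = logging.getLogger(__name__)

#: FWHM of a Gaussian divided by its standard deviation, 2*sqrt(2*ln 2).
FWHM_PER_SIGMA: float = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Convert a Gaussian full width at half maximum to a standard deviation.

    sigma = FWHM / (2*sqrt(2*ln 2)) ~= FWHM / 2.35482.
    """
    if fwhm_mm <= 0:
        raise ValueError(f"FWHM must be positive, got {fwhm_mm}")
    return float(fwhm_mm) / FWHM_PER_SIGMA


def gaussian_smooth(volume: VolumeGrid, fwhm_mm) -> VolumeGrid:
    """Separable Gaussian smoothing with FWHM given in millimetres.

    ``fwhm_mm`` may be a scalar (isotropic in world space, e.g. the 12 mm
    filter of the scoring pipeline) or a 3-sequence of per-axis values.
    Per-axis sigmas in voxel units are ``sigma_mm / voxel_size_mm``, so an
    isotropic world-space filter stays isotropic on anisotropic lattices.
    ``fwhm_mm = 0`` is the identity.  Boundary handling is nearest-edge
    replication.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    if np.any(fwhm < 0):
        raise ValueError(f"FWHM must be non-negative, got {fwhm_mm}")
    if np.all(fwhm == 0):
        return volume.with_data(volume.data.copy())
    sigma_vox = np.array(
        [fwhm_to_sigma(f) / v if f > 0 else 0.0 for f, v in zip(fwhm, volume.voxel_size_mm)]
    )
    smoothed = ndi.gaussian_filter(
        volume.data.astype(float), sigma=sigma_vox, mode="nearest"
    )
    return volume.with_data(smoothed)


# ---------------------------------------------------------------------------
# Affine transforms
# ---------------------------------------------------------------------------


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rot_z @ rot_y @ rot_x


@dataclass
class AffineTransform:
    """A 12-parameter affine map between world coordinates.

    The matrix maps points in the *fixed* (template) world frame to points
    in the *moving* image's world frame -- the pull-back convention used by
    :func:`resample`.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1]):
            raise ValueError("transform last row must be [0, 0, 0, 1]")
        det = np.linalg.det(self.matrix[:3, :3])
        if not np.isfinite(det) or abs(det) < 1e-12:
            raise ValueError("transform is singular")
        if det <= 0:
            raise ValueError("transform must preserve orientation (det > 0)")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_params(
        cls,
        translation=(0.0, 0.0, 0.0),
        rotation=(0.0, 0.0, 0.0),
        scale=(1.0, 1.0, 1.0),
        shear=(0.0, 0.0, 0.0),
        center=(0.0, 0.0, 0.0),
    ) -> "AffineTransform":
        """Build a transform from 3 translations (mm), 3 rotations (rad),
        3 scales and 3 shears, applied about ``center`` (world mm)."""
        shear_m = np.array(
            [[1.0, shear[0], shear[1]], [0.0, 1.0, shear[2]], [0.0, 0.0, 1.0]]
        )
        lin = _rotation_matrix(*rotation) @ shear_m @ np.diag(scale)
        center = np.asarray(center, dtype=float)
        mat = np.eye(4)
        mat[:3, :3] = lin
        mat[:3, 3] = np.asarray(translation, dtype=float) + center - lin @ center
        return cls(mat)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self o other (apply ``other`` first)."""
        return AffineTransform(self.matrix @ other.matrix)

    def apply_to_points(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of world points through the transform."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]


def resample(
    volume: VolumeGrid,
    transform: AffineTransform,
    target: VolumeGrid,
    order: int = 1,
    fill: float = 0.0,
) -> VolumeGrid:
    """Resample ``volume`` onto ``target``'s lattice through ``transform``.

    For each target voxel index ``i`` the value is interpolated from the
    moving volume at index ``A_m^-1 T A_t i`` (trilinear by default);
    voxels mapping outside the moving field of view take ``fill``.
    """
    a_target = target.affine
    a_moving = volume.affine
    full = np.linalg.inv(a_moving) @ transform.matrix @ a_target
    out = ndi.affine_transform(
        volume.data.astype(float),
        matrix=full[:3, :3],
        offset=full[:3, 3],
        output_shape=target.shape,
        order=order,
        mode="constant",
        cval=fill,
    )
    return target.with_data(out)


def apply_mask(volume: VolumeGrid, mask: VolumeGrid, fill: float = 0.0) -> VolumeGrid:
    """Set voxels outside a binary mask to ``fill``.

    Use ``fill=1.0`` for multiplicative error fields and ``fill=0.0`` for
    PET images.
    """
    volume.require_same_grid(mask, "apply_mask")
    m = mask.mask_array()
    return volume.with_data(np.where(m, volume.data, fill))


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------


@dataclass
class RegistrationResult:
    transform: AffineTransform
    converged: bool
    final_cost: float
    n_evaluations: int


# internal parameter scaling so that one optimizer step is comparable across
# translations (mm), rotations (rad) and unit-free scale/shear terms
_PARAM_SCALES = np.array([10.0] * 3 + [0.1] * 3 + [0.05] * 3 + [0.05] * 3)


def _params_to_transform(p: np.ndarray, center: np.ndarray) -> AffineTransform:
    return AffineTransform.from_params(
        translation=p[0:3],
        rotation=p[3:6],
        scale=1.0 + p[6:9],
        shear=p[9:12],
        center=center,
    )


def affine_register(
    moving: VolumeGrid,
    fixed: VolumeGrid,
    init: AffineTransform | None = None,
    dof: int = 12,
    pyramid: tuple[tuple[float, int], ...] = ((8.0, 2), (0.0, 1)),
    maxiter: int = 400,
) -> RegistrationResult:
    """Estimate the affine transform aligning ``moving`` to ``fixed``.

    Minimizes the mean squared intensity difference of the moving image
    resampled into the fixed lattice, over up to 12 parameters (3
    translations, 3 rotations, 3 scales, 3 shears; ``dof`` of 6 or 9
    freezes scales/shears), with a coarse-to-fine pyramid (each level a
    ``(smoothing FWHM mm, subsampling step)`` pair) and a gradient-free
    (Powell) optimizer at each level.  Mono-modal MSE is appropriate here
    because both images are PET-like phantoms.

    Non-convergence (including zero overlap between the volumes) is
    reported through ``converged=False``, not raised.
    """
    if dof not in (6, 9, 12):
        raise ValueError("dof must be 6, 9 or 12")
    # world-space centre of the fixed volume, the rotation/scale pivot
    center_idx = (np.asarray(fixed.shape, dtype=float) - 1.0) / 2.0
    center = fixed.affine[:3, :3] @ center_idx + fixed.affine[:3, 3]

    p0 = np.zeros(12)
    if init is not None:
        # only the translational part of an initial guess is carried over;
        # callers needing more should pre-apply the initialization
        p0[0:3] = init.matrix[:3, 3]

    n_eval = 0
    active = np.zeros(12, dtype=bool)
    active[:dof] = True

    def _subsample(vol: VolumeGrid, step: int) -> VolumeGrid:
        if step == 1:
            return vol
        scale_m = np.diag([float(step)] * 3 + [1.0])
        return VolumeGrid(vol.data[::step, ::step, ::step], vol.affine @ scale_m)

    z = (p0 / _PARAM_SCALES)[active]
    cost_value = np.inf
    for fwhm, step in pyramid:
        mov = gaussian_smooth(moving, fwhm) if fwhm > 0 else moving
        fix = gaussian_smooth(fixed, fwhm) if fwhm > 0 else fixed
        mov = _subsample(mov, step)
        fix = _subsample(fix, step)
        fix_data = fix.data.astype(float)

        def cost(z_active: np.ndarray) -> float:
            nonlocal n_eval
            n_eval += 1
            p = np.zeros(12)
            p[active] = z_active * _PARAM_SCALES[active]
            try:
                t = _params_to_transform(p, center)
            except ValueError:
                return 1e12  # singular/reflecting candidate
            res = resample(mov, t, fix, order=1, fill=0.0)
            return float(np.mean((res.data - fix_data) ** 2))

        opt = minimize(
            cost,
            z,
            method="Powell",
            options={"maxiter": maxiter, "xtol": 1e-4, "ftol": 1e-9},
        )
        z = opt.x
        cost_value = float(opt.fun)

    p_final = np.zeros(12)
    p_final[active] = np.atleast_1d(z) * _PARAM_SCALES[active]
    transform = _params_to_transform(p_final, center)

    # overlap sanity check: a registration that never saw the moving image
    # inside the fixed field of view cannot have converged
    res = resample(moving, transform, fixed, order=1, fill=0.0)
    overlap = int(np.count_nonzero((np.abs(res.data) > 1e-12) & (np.abs(fixed.data) > 1e-12)))
    converged = bool(overlap > 0)
    if not converged:
        log.warning("affine_register: no overlap between volumes; flagged")
    return RegistrationResult(
        transform=transform,
        converged=converged,
        final_cost=cost_value,
        n_evaluations=n_eval,
    )
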