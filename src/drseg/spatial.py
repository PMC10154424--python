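"""Random spatial augmentation: affine transforms and diffeomorphic warps.

Each generated training example deforms its source label map with a random
affine (rotations, scalings, shearings, translations drawn from uniform
priors) composed with a diffeomorphic non-linear warp. The warp is built by
sampling a coarse 10x10x10x3 Gaussian velocity field, trilinearly upsampling
it to the image grid (a stationary velocity field, SVF), and integrating it
by scaling-and-squaring so the resulting deformation has positive Jacobian
determinant everywhere — it cannot tear or fold the anatomy.

Conventions: rotations are specified in degrees and applied about the volume
centre; translations are in voxels at the high-resolution grid; the sampling
map is ``x -> A @ (x + d(x))`` so labels are pulled back through the affine
applied to the nonlinearly-warped coordinates, with a single nearest-neighbour
interpolation pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume

try:  # fused trilinear warp of a vector field; scipy fallback below
    import numba

    @numba.njit(cache=True)
    def _warp_field_kernel(field, disp, out):  # pragma: no cover - jitted
        nx, ny, nz = field.shape[0], field.shape[1], field.shape[2]
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    px = x + disp[x, y, z, 0]
                    py = y + disp[x, y, z, 1]
                    pz = z + disp[x, y, z, 2]
                    if px < 0.0:
                        px = 0.0
                    elif px > nx - 1:
                        px = nx - 1.0
                    if py < 0.0:
                        py = 0.0
                    elif py > ny - 1:
                        py = ny - 1.0
                    if pz < 0.0:
                        pz = 0.0
                    elif pz > nz - 1:
                        pz = nz - 1.0
                    x0 = int(px)
                    y0 = int(py)
                    z0 = int(pz)
                    x1 = min(x0 + 1, nx - 1)
                    y1 = min(y0 + 1, ny - 1)
                    z1 = min(z0 + 1, nz - 1)
                    fx = px - x0
                    fy = py - y0
                    fz = pz - z0
                    for c in range(3):
                        c00 = field[x0, y0, z0, c] * (1 - fx) + field[x1, y0, z0, c] * fx
                        c01 = field[x0, y0, z1, c] * (1 - fx) + field[x1, y0, z1, c] * fx
                        c10 = field[x0, y1, z0, c] * (1 - fx) + field[x1, y1, z0, c] * fx
                        c11 = field[x0, y1, z1, c] * (1 - fx) + field[x1, y1, z1, c] * fx
                        c0 = c00 * (1 - fy) + c10 * fy
                        c1 = c01 * (1 - fy) + c11 * fy
                        out[x, y, z, c] = c0 * (1 - fz) + c1 * fz

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "AffineParams",
    "VelocityField",
    "DeformationField",
    "sample_affine",
    "affine_matrix",
    "sample_svf",
    "integrate_svf",
    "apply_transform_labels",
    "jacobian_determinant",
    "save_deformation",
    "load_deformation",
]

COARSE_SVF_SHAPE = (10, 10, 10)


@dataclass
class AffineParams:
    """Twelve affine parameters: degrees, dimensionless scales/shears, voxel shifts."""

    rotations: np.ndarray  # (3,) degrees about x, y, z
    scalings: np.ndarray   # (3,) strictly positive
    shearings: np.ndarray  # (3,)
    translations: np.ndarray  # (3,) voxels

    def __post_init__(self):
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.scalings = np.asarray(self.scalings, dtype=float)
        self.shearings = np.asarray(self.shearings, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        if np.any(self.scalings <= 0):
            raise ValueError("scalings must be strictly positive")

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls(np.zeros(3), np.ones(3), np.zeros(3), np.zeros(3))


@dataclass
class VelocityField:
    """Dense stationary velocity field (voxel displacements per unit time)."""

    data: np.ndarray  # (X, Y, Z, 3)
    control_shape: tuple = COARSE_SVF_SHAPE
    sigma_svf: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError("velocity field must have shape (X, Y, Z, 3)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("velocity field must be finite")


@dataclass
class DeformationField:
    """Dense displacement field of a diffeomorphism ``x -> x + data[x]``."""

    data: np.ndarray  # (X, Y, Z, 3)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError("deformation field must have shape (X, Y, Z, 3)")


def _check_bounds(a, b, name):
    if a > b:
        raise ValueError(f"inverted bounds for {name}: [{a}, {b}]")


def sample_affine(config, rng: np.random.Generator) -> AffineParams:
    """Draw the 12 affine parameters independently from their uniform priors."""
    _check_bounds(config.a_rot, config.b_rot, "rotation")
    _check_bounds(config.a_sc, config.b_sc, "scaling")
    _check_bounds(config.a_sh, config.b_sh, "shearing")
    _check_bounds(config.a_tr, config.b_tr, "translation")
    return AffineParams(
        rotations=rng.uniform(config.a_rot, config.b_rot, 3),
        scalings=rng.uniform(config.a_sc, config.b_sc, 3),
        shearings=rng.uniform(config.a_sh, config.b_sh, 3),
        translations=rng.uniform(config.a_tr, config.b_tr, 3),
    )


def affine_matrix(p: AffineParams, center) -> np.ndarray:
    """Homogeneous 4x4 voxel-space matrix T(c).T(t).Rz.Ry.Rx.Shear.Scale.T(-c)."""
    cx, cy, cz = np.asarray(center, dtype=float)
    rx, ry, rz = np.deg2rad(p.rotations)

    def trans(t):
        m = np.eye(4)
        m[:3, 3] = t
        return m

    def rot_x(a):
        m = np.eye(4)
        m[1, 1], m[1, 2] = np.cos(a), -np.sin(a)
        m[2, 1], m[2, 2] = np.sin(a), np.cos(a)
        return m

    def rot_y(a):
        m = np.eye(4)
        m[0, 0], m[0, 2] = np.cos(a), np.sin(a)
        m[2, 0], m[2, 2] = -np.sin(a), np.cos(a)
        return m

    def rot_z(a):
        m = np.eye(4)
        m[0, 0], m[0, 1] = np.cos(a), -np.sin(a)
        m[1, 0], m[1, 1] = np.sin(a), np.cos(a)
        return m

    shear = np.eye(4)
    shear[0, 1], shear[0, 2], shear[1, 2] = p.shearings
    scale = np.diag([*p.scalings, 1.0])
    return (
        trans([cx, cy, cz])
        @ trans(p.translations)
        @ rot_z(rz)
        @ rot_y(ry)
        @ rot_x(rx)
        @ shear
        @ scale
        @ trans([-cx, -cy, -cz])
    )


def _upsample_trilinear(coarse: np.ndarray, target_shape) -> np.ndarray:
    """Centre-aligned trilinear upsampling of a coarse grid to ``target_shape``.

    Coarse cell centres are spread uniformly over the target extent; edge
    values are clamped (replicated) beyond the outermost cell centres, so the
    dense field is always a convex combination of coarse values.
    """
    target_shape = tuple(int(s) for s in target_shape)
    coords = np.meshgrid(
        *[
            (np.arange(n) + 0.5) * (c / n) - 0.5
            for n, c in zip(target_shape, coarse.shape[:3])
        ],
        indexing="ij",
    )
    coords = np.stack(coords)
    if coarse.ndim == 3:
        return ndimage.map_coordinates(coarse, coords, order=1, mode="nearest")
    out = np.empty(target_shape + (coarse.shape[-1],))
    for c in range(coarse.shape[-1]):
        out[..., c] = ndimage.map_coordinates(coarse[..., c], coords, order=1, mode="nearest")
    return out


def sample_svf(config, image_shape, rng: np.random.Generator) -> VelocityField:
    """Sample sigma_SVF ~ U(0, b_nonlin), a coarse N(0, sigma) field, upsample."""
    if config.b_nonlin < 0:
        raise ValueError("b_nonlin must be non-negative")
    sigma = float(rng.uniform(0.0, config.b_nonlin))
    coarse = rng.normal(0.0, sigma, COARSE_SVF_SHAPE + (3,)) if sigma > 0 else np.zeros(
        COARSE_SVF_SHAPE + (3,)
    )
    dense = _upsample_trilinear(coarse, image_shape)
    return VelocityField(dense, COARSE_SVF_SHAPE, sigma)


def _warp_field(field: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Sample ``field`` (vector-valued) at ``x + disp(x)`` with linear interp.

    Out-of-grid positions are clamped to the border (edge replication).
    """
    if _HAVE_NUMBA:
        out = np.empty_like(field)
        _warp_field_kernel(np.ascontiguousarray(field),
                           np.ascontiguousarray(disp), out)
        return out
    shape = field.shape[:3]
    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    )
    coords = grid + np.moveaxis(disp, -1, 0)
    out = np.empty_like(field)
    for c in range(field.shape[-1]):
        out[..., c] = ndimage.map_coordinates(field[..., c], coords, order=1, mode="nearest")
    return out


def integrate_svf(v: VelocityField, n_steps: int = 7) -> DeformationField:
    """Exponentiate a stationary velocity field by scaling-and-squaring.

    The field is scaled by 2**-n_steps (so each step is a near-identity flow)
    and the resulting small deformation is composed with itself n_steps times:
    phi_{2t} = phi_t o phi_t.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    disp = v.data / (2.0 ** n_steps)
    for _ in range(n_steps):
        disp = disp + _warp_field(disp, disp)
    return DeformationField(disp)


def apply_transform_labels(
    vol: LabelVolume, aff: np.ndarray, nonlin: DeformationField | None = None
) -> LabelVolume:
    """Pull the label map back through affine-of-warped coordinates.

    Output voxel x receives the label at ``A @ (x + d(x))``, sampled with
    nearest-neighbour interpolation; samples outside the field of view are
    background (0). A single interpolation pass avoids double aliasing.
    """
    shape = vol.shape
    if nonlin is not None and nonlin.data.shape[:3] != shape:
        raise ValueError("deformation field shape does not match the label volume")
    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    )
    coords = grid
    if nonlin is not None:
        coords = coords + np.moveaxis(nonlin.data, -1, 0)
    aff = np.asarray(aff, dtype=float)
    lin = aff[:3, :3]
    off = aff[:3, 3]
    coords = np.einsum("ij,jxyz->ixyz", lin, coords) + off[:, None, None, None]
    warped = ndimage.map_coordinates(vol.data, coords, order=0, mode="constant", cval=0)
    return LabelVolume(warped, vol.spacing.copy(), vol.affine.copy())


def save_deformation(d: DeformationField, path) -> None:
    """Write a displacement field as a 4D NIfTI (3 components, 4th dim)."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(d.data.astype(np.float32), np.eye(4)), str(path))


def load_deformation(path) -> DeformationField:
    """Read a displacement field written by :func:`save_deformation`."""
    import nibabel as nib

    data = np.asanyarray(nib.load(str(path)).dataobj)
    return DeformationField(data)


def jacobian_determinant(d: DeformationField) -> np.ndarray:
    """Central-difference Jacobian determinant of ``x -> x + d(x)``.

    Returned on the full grid (one-sided differences at the border); the
    diffeomorphism check reads the interior, where central differences apply.
    """
    disp = d.data
    jac = np.empty(disp.shape[:3] + (3, 3))
    for comp in range(3):
        grads = np.gradient(disp[..., comp], axis=(0, 1, 2))
        for ax in range(3):
            jac[..., comp, ax] = grads[ax]
    jac += np.eye(3)
    return np.linalg.det(jac)
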