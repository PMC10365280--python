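"""Synchronized spatial normalization of CT and dose volumes.

Pipeline: crop -> rigid -> affine -> iterative nonlinear warp, all driven by
a sum-of-squared-differences objective, with the identical transform chain
applied to the CT and its dose volume in a single interpolation pass.

Transforms map template (fixed) world coordinates to subject (moving) world
coordinates, which is the pull-back direction used for resampling.  A chain
is applied as ``rigid(affine(x + d(x)))`` with every element optional.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from doseatlas.volume_io import (
    AIR_HU,
    GridSpec,
    MaskVolume,
    Volume,
    make_brain_mask,
    write_volume,
    read_volume,
)

__all__ = [
    "RigidTransform",
    "AffineTransform",
    "DeformationField",
    "TransformChain",
    "ssd",
    "crop_head",
    "register_rigid",
    "register_affine",
    "register_nonlinear",
    "apply_chain",
    "normalize_subject",
    "NormalizationResult",
    "invert_displacement",
    "save_chain",
    "load_chain",
]


# --------------------------------------------------------------------------
# transform types
# --------------------------------------------------------------------------

def _rotation_matrix(angles) -> np.ndarray:
    """Rotation about x, then y, then z (radians)."""
    rx, ry, rz = angles
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass
class RigidTransform:
    """6-parameter rotation + translation about a world-space centre."""

    rotation: np.ndarray  # 3 angles, radians
    translation: np.ndarray  # mm
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    converged: bool = True

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.center = np.asarray(self.center, dtype=float)

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4: ``x -> R (x - c) + c + t``."""
        R = _rotation_matrix(self.rotation)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = self.center + self.translation - R @ self.center
        return M

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        M = self.matrix
        return pts @ M[:3, :3].T + M[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(matrix=np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.zeros(3), translation=np.zeros(3))


@dataclass
class AffineTransform:
    """General invertible 4x4 world map (rotation/translation/scale/shear)."""

    matrix: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine transform is singular")

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(matrix=np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(matrix=np.eye(4))

    @classmethod
    def from_params(cls, params, center) -> "AffineTransform":
        """12 parameters: t (mm), angles (rad), scales, shears -- about centre."""
        t = np.asarray(params[0:3], dtype=float)
        R = _rotation_matrix(params[3:6])
        S = np.diag(params[6:9])
        h1, h2, h3 = params[9:12]
        Sh = np.array([[1, h1, h2], [0, 1, h3], [0, 0, 1]], dtype=float)
        L = R @ Sh @ S
        center = np.asarray(center, dtype=float)
        M = np.eye(4)
        M[:3, :3] = L
        M[:3, 3] = center + t - L @ center
        return cls(matrix=M)


@dataclass
class DeformationField:
    """Dense per-voxel displacement (mm) on the fixed/template grid.

    The zero field is the identity.  ``disp[..., a]`` shifts world axis a.
    """

    disp: np.ndarray  # (nx, ny, nz, 3) mm
    affine: np.ndarray  # grid of definition
    smoothing_mm: float = 0.0

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.disp.ndim != 4 or self.disp.shape[-1] != 3:
            raise ValueError("displacement must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def rms_mm(self) -> float:
        return float(np.sqrt(np.mean(np.sum(self.disp ** 2, axis=-1))))

    @property
    def max_mm(self) -> float:
        return float(np.sqrt(np.sum(self.disp ** 2, axis=-1)).max())

    def sample(self, pts: np.ndarray) -> np.ndarray:
        """Displacement vectors at arbitrary world points (linear interp)."""
        inv = np.linalg.inv(self.affine)
        vox = (pts @ inv[:3, :3].T + inv[:3, 3]).T  # (3, N)
        out = np.empty((pts.shape[0], 3))
        for a in range(3):
            out[:, a] = ndimage.map_coordinates(
                self.disp[..., a], vox, order=1, mode="nearest")
        return out

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        return pts + self.sample(pts)

    @classmethod
    def zero(cls, grid: GridSpec | Volume) -> "DeformationField":
        shape = tuple(grid.shape) + (3,)
        return cls(disp=np.zeros(shape), affine=np.asarray(grid.affine))


@dataclass
class TransformChain:
    """Ordered [rigid, affine, deformation]; each element optional.

    Maps fixed/template world points to moving/subject world points as
    ``rigid(affine(x + d(x)))``; an empty chain is the identity.  The same
    chain moves the CT and its dose -- the synchronization contract.
    """

    rigid: RigidTransform | None = None
    affine: AffineTransform | None = None
    deformation: DeformationField | None = None

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        if self.deformation is not None:
            pts = self.deformation.map_points(pts)
        if self.affine is not None:
            pts = self.affine.map_points(pts)
        if self.rigid is not None:
            pts = self.rigid.map_points(pts)
        return pts

    @property
    def is_identity(self) -> bool:
        return (self.rigid is None and self.affine is None
                and self.deformation is None)


# --------------------------------------------------------------------------
# objective
# --------------------------------------------------------------------------

def ssd(a: Volume | np.ndarray, b: Volume | np.ndarray,
        mask: MaskVolume | np.ndarray | None = None) -> float:
    """Sum of squared differences -- the registration objective."""
    da = a.data if isinstance(a, Volume) else np.asarray(a)
    db = b.data if isinstance(b, Volume) else np.asarray(b)
    if da.shape != db.shape:
        raise ValueError(f"grid mismatch: {da.shape} vs {db.shape}")
    diff = da.astype(float) - db.astype(float)
    if mask is not None:
        dm = mask.data if isinstance(mask, Volume) else np.asarray(mask)
        if dm.shape != da.shape:
            raise ValueError("mask grid mismatch")
        diff = diff[dm.astype(bool)]
    return float(np.sum(diff * diff))


def _zscore(data: np.ndarray) -> np.ndarray:
    sd = data.std()
    if sd == 0:
        return np.zeros_like(data, dtype=float)
    return (data - data.mean()) / sd


# --------------------------------------------------------------------------
# cropping
# --------------------------------------------------------------------------

def crop_head(ct: Volume, dose: Volume, hu_threshold: float = -500.0,
              pad_mm: float = 10.0) -> tuple[Volume, Volume]:
    """Crop CT and dose to the head bounding box, world coords preserved.

    The box is the largest connected supra-threshold component on CT padded
    by ``pad_mm`` laterally/superiorly; no padding below the component's
    inferior extent (removes neck slices).  Dose is resampled to the CT grid
    first if the grids differ.
    """
    if not dose.same_grid(ct):
        from doseatlas.volume_io import resample_to
        dose = resample_to(dose, ct, interpolation="linear", cval=0.0)
    support = ct.data > hu_threshold
    if not support.any():
        raise ValueError(f"no voxels above {hu_threshold} HU; cannot crop")
    labels, n = ndimage.label(support, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        support = labels == counts.argmax()
    idx = np.argwhere(support)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    pad_vox = np.ceil(pad_mm / ct.spacing).astype(int)
    lo_p = np.maximum(lo - pad_vox, 0)
    hi_p = np.minimum(hi + pad_vox, np.asarray(ct.shape) - 1)
    # inferior (smallest world z) edge: no padding -> truncate below the head
    zcol = np.argmax(np.abs(ct.affine[2, :3]))  # data axis mapping to world z
    if ct.affine[2, zcol] > 0:
        lo_p[zcol] = lo[zcol]
    else:
        hi_p[zcol] = hi[zcol]
    sl = tuple(slice(int(a), int(b) + 1) for a, b in zip(lo_p, hi_p))
    new_affine = ct.affine.copy()
    new_affine[:3, 3] = ct.affine[:3, :3] @ lo_p + ct.affine[:3, 3]
    ct_out = Volume(data=ct.data[sl].copy(), affine=new_affine, space=ct.space)
    dose_out = Volume(data=dose.data[sl].copy(), affine=new_affine.copy(),
                      space=dose.space)
    return ct_out, dose_out


# --------------------------------------------------------------------------
# linear registration
# --------------------------------------------------------------------------

def _resample_world_linear(mdata: np.ndarray, m_affine: np.ndarray,
                           world_map: np.ndarray, f_affine: np.ndarray,
                           f_shape, cval: float) -> np.ndarray:
    """Resample moving data onto fixed grid through a 4x4 world map."""
    M = np.linalg.inv(m_affine) @ world_map @ f_affine
    return ndimage.affine_transform(mdata, M[:3, :3], offset=M[:3, 3],
                                    output_shape=tuple(f_shape), order=1,
                                    mode="constant", cval=cval, prefilter=False)


_DEG = np.pi / 180.0
_JITTER_SEED = 12345  # fixed: jitter is part of the deterministic objective

#: CT soft-tissue window applied before intensity normalization at every
#: registration stage; boosts the relative contrast of parenchymal texture
#: over the dominant air/bone transitions.
SOFT_TISSUE_WINDOW = (-100.0, 100.0)


class _SsdSampler:
    """SSD objective over jittered fixed-grid sample points.

    Sampling at sub-voxel jittered points (a fixed, seeded perturbation of
    the fixed-grid voxel centres) removes the spurious SSD minima that
    linear interpolation creates at grid-aligned transforms.  Both images
    are Gaussian-smoothed and z-scored; out-of-field values are filled with
    the background (minimum) intensity.
    """

    def __init__(self, moving: Volume, fixed: Volume, sigma_mm: float,
                 sub: int = 1, window: tuple[float, float] | None = None) -> None:
        sig_m = sigma_mm / moving.spacing
        sig_f = sigma_mm / fixed.spacing

        def clip(d):
            d = np.asarray(d, float)
            return np.clip(d, *window) if window is not None else d

        # both images share the fixed image's intensity normalization: CT
        # units are comparable, and per-image z-scoring would bias the
        # optimum when the field-of-view (air fraction) differs
        fsm = ndimage.gaussian_filter(clip(fixed.data), sig_f)
        mu, sd = fsm.mean(), fsm.std() or 1.0
        self.mdata = (ndimage.gaussian_filter(clip(moving.data), sig_m)
                      - mu) / sd
        fdata = (fsm - mu) / sd
        self.cval = float(self.mdata.min())
        rng = np.random.default_rng(_JITTER_SEED)
        grids = np.mgrid[[slice(0, s, sub) for s in fixed.shape]]
        vox = np.stack(grids, axis=-1).reshape(-1, 3).astype(float)
        vox += rng.uniform(-0.5, 0.5, vox.shape)
        A = np.asarray(fixed.affine)
        self.pts = vox @ A[:3, :3].T + A[:3, 3]
        self.fvals = ndimage.map_coordinates(fdata, vox.T, order=1,
                                             mode="constant",
                                             cval=float(fdata.min()))
        self.m_inv = np.linalg.inv(np.asarray(moving.affine))

    def __call__(self, world_map: np.ndarray) -> float:
        mp = self.pts @ world_map[:3, :3].T + world_map[:3, 3]
        mv = (mp @ self.m_inv[:3, :3].T + self.m_inv[:3, 3]).T
        vals = ndimage.map_coordinates(self.mdata, mv, order=1,
                                       mode="constant", cval=self.cval)
        d = vals - self.fvals
        return float(d @ d)


def _center_of_mass_world(vol: Volume) -> np.ndarray:
    w = np.asarray(vol.data, float)
    w = w - w.min()
    idx = np.asarray(ndimage.center_of_mass(w))
    return vol.affine[:3, :3] @ idx + vol.affine[:3, 3]


def _powell_stages(moving: Volume, fixed: Volume, matrix_fn, x0,
                   scales_mm=(4.0, 2.0), window=SOFT_TISSUE_WINDOW):
    """Powell refinement over a smoothing schedule; returns (x, converged)."""
    x = np.asarray(x0, dtype=float)
    converged = True
    for i, sigma in enumerate(scales_mm):
        sub = 2 if i == 0 else 1
        sampler = _SsdSampler(moving, fixed, sigma, sub=sub, window=window)

        def fun(p):
            return sampler(matrix_fn(p))

        before = fun(x)
        res = optimize.minimize(fun, x, method="Powell",
                                options={"xtol": 1e-4, "ftol": 1e-10,
                                         "maxiter": 120})
        if res.fun <= before:
            x = np.asarray(res.x)
        elif i == len(scales_mm) - 1:  # divergence at the final scale
            converged = False
    return x, converged


def register_rigid(moving: Volume, fixed: Volume,
                   scales_mm=(4.0, 2.0),
                   search_deg=(-8.0, -4.0, 0.0, 4.0, 8.0),
                   window=SOFT_TISSUE_WINDOW) -> RigidTransform:
    """6-parameter SSD rigid registration (deterministic, multi-stage).

    Translation is initialized by centre-of-mass alignment; rotation by an
    exhaustive coarse grid search over ``search_deg`` per axis on a
    subsampled smoothed level; both are refined by Powell descent over the
    ``scales_mm`` smoothing schedule.  If the objective increases at the
    final scale the best-so-far transform is returned with
    ``converged=False``.
    """
    center = _volume_center(fixed)

    def matrix_fn(x):
        return RigidTransform(rotation=np.asarray(x[3:6]) * _DEG,
                              translation=np.asarray(x[0:3]),
                              center=center).matrix

    t_init = _center_of_mass_world(moving) - _center_of_mass_world(fixed)
    x = np.concatenate([t_init, np.zeros(3)])
    coarse = _SsdSampler(moving, fixed, scales_mm[0], sub=2, window=window)
    best_x, best_f = x.copy(), coarse(matrix_fn(x))
    for angles in itertools.product(search_deg, repeat=3):
        cand = x.copy()
        cand[3:6] = angles
        f = coarse(matrix_fn(cand))
        if f < best_f:
            best_x, best_f = cand, f
    x, ok = _powell_stages(moving, fixed, matrix_fn, best_x, scales_mm,
                           window=window)
    return RigidTransform(rotation=x[3:6] * _DEG, translation=x[0:3],
                          center=center, converged=ok)


def register_affine(moving: Volume, fixed: Volume,
                    init: RigidTransform | None = None,
                    scales_mm=(4.0, 2.0),
                    window=SOFT_TISSUE_WINDOW) -> AffineTransform:
    """12-parameter SSD affine registration initialized at ``init``.

    The result matrix includes the rigid initialization (it is a full
    template->subject world map, not an increment).
    """
    center = _volume_center(fixed)
    x0 = np.zeros(12)
    x0[6:9] = 100.0  # scales stored as percent for comparable step sizes
    if init is not None:
        x0[0:3] = init.translation
        x0[3:6] = init.rotation / _DEG
        center = init.center

    def matrix_fn(x):
        params = np.concatenate([x[0:3], np.asarray(x[3:6]) * _DEG,
                                 np.asarray(x[6:9]) / 100.0,
                                 np.asarray(x[9:12]) / 100.0])
        return AffineTransform.from_params(params, center).matrix

    x, ok = _powell_stages(moving, fixed, matrix_fn, x0, scales_mm,
                           window=window)
    out = AffineTransform(matrix=matrix_fn(x))
    out.converged = ok
    return out


def _volume_center(vol: Volume) -> np.ndarray:
    idx = (np.asarray(vol.shape, dtype=float) - 1) / 2.0
    return vol.affine[:3, :3] @ idx + vol.affine[:3, 3]


# --------------------------------------------------------------------------
# nonlinear registration (demons-style greedy SSD descent)
# --------------------------------------------------------------------------

def _warp_with_field(mdata: np.ndarray, disp_vox: np.ndarray,
                     base_coords: np.ndarray, cval: float) -> np.ndarray:
    coords = base_coords + np.moveaxis(disp_vox, -1, 0)
    return ndimage.map_coordinates(mdata, coords, order=1, mode="constant",
                                   cval=cval)


def register_nonlinear(moving: Volume, fixed: Volume,
                       init: AffineTransform | None = None,
                       iters: int = 200, smoothing_mm: float = 8.0,
                       elastic_mm: float = 3.0,
                       mask: MaskVolume | None = None,
                       step_mm: float = 1.0,
                       window: tuple[float, float] | None = SOFT_TISSUE_WINDOW,
                       tol: float = 0.0) -> DeformationField:
    """Greedy demons-style deformable registration minimizing SSD.

    Each iteration computes a per-voxel demons force
    ``-diff * grad / (|grad|^2 + diff^2 / K^2)`` (K = mean voxel size),
    Gaussian-smooths it (``smoothing_mm``, fluid-like), adds it to the
    accumulated field and re-smooths the field (``elastic_mm``).  Steps that
    would increase the SSD are halved and, failing that, rejected, so the
    SSD sequence is strictly non-increasing.  Intensities are clipped to
    ``window`` (CT soft-tissue window; pass None to disable) and z-scored
    so the objective is scale-free.

    Returns the displacement field (mm) on the fixed grid; the full
    fixed->moving map is ``init(x + d(x))``.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")

    def clip(data):
        d = np.asarray(data, dtype=float)
        if window is not None:
            d = np.clip(d, window[0], window[1])
        return d

    f_w = clip(fixed.data)
    mu, sd = f_w.mean(), f_w.std() or 1.0

    def prep(data):
        # common intensity scale anchored on the fixed image (see _SsdSampler)
        return (clip(data) - mu) / sd

    f = prep(fixed.data)
    # pre-resample moving through the affine init once; the production path
    # (apply_chain) still composes to a single interpolation of the raw data
    init_mat = np.eye(4) if init is None else init.matrix
    m = _resample_world_linear(prep(moving.data), moving.affine, init_mat,
                               fixed.affine, fixed.shape, cval=float(f.min()))
    spacing = fixed.spacing
    sp4 = spacing.reshape(1, 1, 1, 3)
    mdat = np.asarray(mask.data, dtype=bool) if mask is not None else None
    base = np.mgrid[[slice(0, s) for s in fixed.shape]].astype(float)
    cap_mm = float(spacing.mean())

    def sq_err(d_mm):
        w = _warp_with_field(m, d_mm / sp4, base, cval=float(m.min()))
        diff = w - f
        if mdat is not None:
            diff = diff[mdat]
        return float(np.sum(diff * diff)), w

    disp = np.zeros(tuple(fixed.shape) + (3,))
    cur, warped = sq_err(disp)
    sig_fluid = smoothing_mm / spacing
    sig_elastic = elastic_mm / spacing
    for it in range(iters):
        diff = warped - f
        if mdat is not None:
            diff = np.where(mdat, diff, 0.0)
        grads = np.gradient(warped, *spacing)
        gmag2 = sum(g * g for g in grads)
        denom = gmag2 + diff * diff / (cap_mm * cap_mm) + 1e-12
        upd = np.stack([-diff * g / denom for g in grads], axis=-1)
        if not np.all(np.isfinite(upd)):
            raise FloatingPointError(f"non-finite demons update at "
                                     f"iteration {it}")
        norm = np.sqrt(np.sum(upd ** 2, axis=-1, keepdims=True))
        upd *= np.minimum(1.0, cap_mm / np.maximum(norm, 1e-12))
        for a in range(3):
            upd[..., a] = ndimage.gaussian_filter(upd[..., a], sig_fluid)
        step = step_mm
        accepted = False
        for _try in range(5):
            cand = disp + step * upd
            if elastic_mm > 0:
                for a in range(3):
                    cand[..., a] = ndimage.gaussian_filter(cand[..., a],
                                                           sig_elastic)
            val, w = sq_err(cand)
            if val < cur:
                improved = cur - val
                disp, warped, cur = cand, w, val
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        if tol > 0 and improved <= tol * max(cur, 1.0):
            break
    if not np.all(np.isfinite(disp)):
        raise FloatingPointError("non-finite displacement after optimization")
    return DeformationField(disp=disp, affine=fixed.affine.copy(),
                            smoothing_mm=smoothing_mm)


# --------------------------------------------------------------------------
# chain application
# --------------------------------------------------------------------------

def apply_chain(chain: TransformChain, vol: Volume,
                reference: Volume | GridSpec, interpolation: str = "linear",
                cval: float = 0.0) -> Volume:
    """Warp ``vol`` onto the reference grid through ``chain``.

    The mappings are composed in world space and the data is interpolated
    exactly once (no cascaded resampling).
    """
    if reference is None:
        raise ValueError("reference grid is required")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation mode {interpolation!r}")
    ref_affine = np.asarray(reference.affine)
    ref_shape = tuple(reference.shape)
    xs, ys, zs = np.mgrid[[slice(0, s) for s in ref_shape]]
    vox = np.stack([xs, ys, zs], axis=-1).reshape(-1, 3).astype(float)
    world = vox @ ref_affine[:3, :3].T + ref_affine[:3, 3]
    mapped = chain.map_points(world)
    inv = np.linalg.inv(vol.affine)
    mvox = (mapped @ inv[:3, :3].T + inv[:3, 3]).T
    order = 1 if interpolation == "linear" else 0
    out = ndimage.map_coordinates(np.asarray(vol.data, dtype=float), mvox,
                                  order=order, mode="constant", cval=cval)
    out = out.reshape(ref_shape)
    space = reference.space if isinstance(reference, Volume) else "template"
    if isinstance(vol, MaskVolume):
        return MaskVolume(data=(out > 0.5).astype(np.uint8),
                          affine=ref_affine.copy(), space=space)
    return Volume(data=out, affine=ref_affine.copy(), space=space)


def invert_displacement(chain_map, grid: GridSpec | Volume,
                        iters: int = 20, tol_mm: float = 1e-3) -> DeformationField:
    """Fixed-point inverse of a smooth world map as a displacement field.

    Solves ``v(x) = chain_map(x + v(x)) ... = x`` i.e. iterates
    ``v <- -(chain_map(x + v) - (x + v)) - (x + v - x)`` reorganized as the
    standard displacement-inversion recursion.  Adequate for small smooth
    deformations (used by the phantom generator to store exact inverses).
    """
    ref_affine = np.asarray(grid.affine)
    shape = tuple(grid.shape)
    xs, ys, zs = np.mgrid[[slice(0, s) for s in shape]]
    vox = np.stack([xs, ys, zs], axis=-1).reshape(-1, 3).astype(float)
    x = vox @ ref_affine[:3, :3].T + ref_affine[:3, 3]
    v = np.zeros_like(x)
    for _ in range(iters):
        fwd = chain_map(x + v)  # should approach x
        err = fwd - x
        v = v - err
        if np.abs(err).max() < tol_mm:
            break
    return DeformationField(disp=v.reshape(shape + (3,)), affine=ref_affine)


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------

@dataclass
class NormalizationResult:
    ct_mni: Volume
    dose_mni: Volume
    chain: TransformChain
    qc: dict


def normalize_subject(ct: Volume, dose: Volume, template: Volume,
                      mask: MaskVolume | None = None,
                      iters_nonlinear: int = 200,
                      smoothing_mm: float = 8.0,
                      scales_mm=(4.0, 2.0),
                      crop: bool = True) -> NormalizationResult:
    """Normalize a subject's CT to the template and move the dose with it.

    Runs crop -> rigid -> affine (initialized at rigid) -> nonlinear, then
    applies the single composed chain to both CT and dose onto the template
    grid.  QC scalars: SSD before/after (z-scored) and max displacement.
    """
    if crop:
        ct, dose = crop_head(ct, dose)
    lo, hi = SOFT_TISSUE_WINDOW
    f_win = np.clip(template.data, lo, hi)
    f_mu, f_sd = f_win.mean(), f_win.std() or 1.0
    f_norm = (f_win - f_mu) / f_sd

    def qc_ssd(chain: TransformChain) -> float:
        """Soft-tissue-windowed SSD on the template's intensity scale."""
        warped = apply_chain(chain, ct, template, cval=AIR_HU)
        w = (np.clip(warped.data, lo, hi) - f_mu) / f_sd
        return ssd(w, f_norm, mask.data if mask is not None else None)

    ssd_before = qc_ssd(TransformChain())
    rigid = register_rigid(ct, template, scales_mm=scales_mm)
    affine = register_affine(ct, template, init=rigid, scales_mm=scales_mm)
    ssd_affine = qc_ssd(TransformChain(affine=affine))
    deform = register_nonlinear(ct, template, init=affine,
                                iters=iters_nonlinear,
                                smoothing_mm=smoothing_mm, mask=mask)
    chain = TransformChain(affine=affine, deformation=deform)
    ct_mni = apply_chain(chain, ct, template, "linear", cval=AIR_HU)
    dose_mni = apply_chain(chain, dose, template, "linear", cval=0.0)
    ssd_after = qc_ssd(chain)
    qc = {
        "ssd_before": ssd_before,
        "ssd_affine": ssd_affine,
        "ssd_after": ssd_after,
        "max_displacement_mm": deform.max_mm,
        "rigid_converged": rigid.converged,
        "affine_converged": affine.converged,
    }
    return NormalizationResult(ct_mni=ct_mni, dose_mni=dose_mni, chain=chain,
                               qc=qc)


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

_AXES = "xyz"


def save_chain(chain: TransformChain, out_dir: str | Path,
               stem: str = "chain") -> Path:
    """Write a chain as JSON + per-axis NIfTI displacement volumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc: dict = {}
    if chain.rigid is not None:
        doc["rigid"] = {"rotation": chain.rigid.rotation.tolist(),
                        "translation": chain.rigid.translation.tolist(),
                        "center": chain.rigid.center.tolist()}
    if chain.affine is not None:
        doc["affine"] = chain.affine.matrix.tolist()
    if chain.deformation is not None:
        paths = []
        for a in range(3):
            p = out_dir / f"{stem}_disp_{_AXES[a]}.nii"
            write_volume(Volume(data=chain.deformation.disp[..., a],
                                affine=chain.deformation.affine), p)
            paths.append(p.name)
        doc["deformation"] = {"paths": paths,
                              "smoothing_mm": chain.deformation.smoothing_mm}
    out = out_dir / f"{stem}.json"
    out.write_text(json.dumps(doc, indent=2))
    return out


def load_chain(path: str | Path) -> TransformChain:
    path = Path(path)
    doc = json.loads(path.read_text())
    rigid = affine = deform = None
    if "rigid" in doc:
        rigid = RigidTransform(rotation=doc["rigid"]["rotation"],
                               translation=doc["rigid"]["translation"],
                               center=doc["rigid"]["center"])
    if "affine" in doc:
        affine = AffineTransform(matrix=np.asarray(doc["affine"]))
    if "deformation" in doc:
        vols = [read_volume(path.parent / p) for p in doc["deformation"]["paths"]]
        disp = np.stack([v.data for v in vols], axis=-1)
        deform = DeformationField(disp=disp, affine=vols[0].affine,
                                  smoothing_mm=doc["deformation"]["smoothing_mm"])
    return TransformChain(rigid=rigid, affine=affine, deformation=deform)
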