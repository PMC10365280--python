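"""Voxel-wise two-group GLM, TFCE, and permutation FWE inference.

The statistical model is an ordinary-least-squares GLM per voxel with an
intercept, a group indicator and optional nuisance covariates (age,
gender).  Inference on the group contrast uses threshold-free cluster
enhancement of each tail of the t map and a Freedman-Lane residual
permutation scheme: the image-wide maximum TFCE value of each permuted
dataset forms the null distribution, so the resulting p values are
family-wise-error corrected.

TFCE is computed by an incremental union-find sweep over descending
thresholds (numba-compiled), with a scipy connected-components fallback
that produces bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from doseatlas.volume_io import MaskVolume, Volume, voxel_to_world

__all__ = [
    "DesignMatrix",
    "TfceParams",
    "StatResult",
    "make_design",
    "fit_glm_tmap",
    "tfce_transform",
    "permutation_fwe",
    "summarize_result",
]

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f
        return wrap(a[0]) if a and callable(a[0]) else wrap


# --------------------------------------------------------------------------
# design matrix
# --------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """GLM design: rows = subjects in stacked-data order.

    ``contrast`` selects the column under test (the group indicator).
    """

    X: np.ndarray
    columns: list[str]
    contrast: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("X shape does not match column names")
        if self.contrast.shape != (self.X.shape[1],):
            raise ValueError("contrast length does not match design columns")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def group_indicator(self) -> np.ndarray:
        col = int(np.flatnonzero(self.contrast)[0])
        return self.X[:, col]

    def nuisance(self) -> np.ndarray:
        """Columns not touched by the contrast (intercept + covariates)."""
        keep = self.contrast == 0
        return self.X[:, keep]


def make_design(table: pd.DataFrame, group_col: str = "technique",
                group_positive: str = "IMRT",
                covariates: tuple[str, ...] = ("age", "gender"),
                ) -> DesignMatrix:
    """Build the two-sample design from a cohort table.

    Columns: intercept, group indicator (``group_positive`` = 1), then each
    covariate; ``age`` is mean-centred and ``gender`` coded male = 1.
    A positive t therefore means ``group_positive`` > other.
    """
    n = len(table)
    cols = [np.ones(n), (table[group_col] == group_positive).to_numpy(float)]
    names = ["intercept", f"{group_col}[{group_positive}]"]
    for cov in covariates:
        v = table[cov]
        if cov == "gender" or v.dtype == object:
            x = (v == "male").to_numpy(float)
        else:
            x = v.to_numpy(float)
            x = x - x.mean()
        cols.append(x)
        names.append(cov)
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return DesignMatrix(X=X, columns=names, contrast=contrast)


# --------------------------------------------------------------------------
# GLM t map
# --------------------------------------------------------------------------

def _stack(data, mask: MaskVolume) -> np.ndarray:
    """Stack subject volumes into an (n, V) matrix over mask voxels."""
    m = mask.data.astype(bool)
    if isinstance(data, np.ndarray):
        if data.ndim != 4:
            raise ValueError("stacked data must be (n, nx, ny, nz)")
        return data[:, m].astype(float)
    rows = []
    for vol in data:
        if not vol.same_grid(mask):
            raise ValueError("data volume grid does not match the mask")
        rows.append(vol.data[m])
    return np.asarray(rows, dtype=float)


def _t_from_fit(Y: np.ndarray, X: np.ndarray, pinvX: np.ndarray,
                c: np.ndarray, c_var: float, df: int) -> np.ndarray:
    beta = pinvX @ Y
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    den = np.sqrt(np.maximum(sigma2 * c_var, 0.0))
    num = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    return t


def fit_glm_tmap(data, design: DesignMatrix, mask: MaskVolume) -> Volume:
    """Per-voxel OLS t map for the design's contrast.

    ``t = c'b / sqrt(s2 * c'(X'X)^-1 c)`` with ``df = n - rank(X)``; voxels
    whose data have zero variance across subjects get t = 0.
    """
    Y = _stack(data, mask)
    X = design.X
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"{Y.shape[0]} data rows but {n} design rows")
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} subjects for {p} columns")
    df = n - p
    pinvX = np.linalg.pinv(X)
    c = design.contrast
    c_var = float(c @ np.linalg.inv(X.T @ X) @ c)
    t = _t_from_fit(Y, X, pinvX, c, c_var, df)
    t[Y.var(axis=0) <= 0] = 0.0  # constant voxels carry no evidence
    out = np.zeros(mask.shape)
    out[mask.data.astype(bool)] = t
    return Volume(data=out, affine=mask.affine.copy(), space=mask.space)


# --------------------------------------------------------------------------
# TFCE
# --------------------------------------------------------------------------

@dataclass
class TfceParams:
    """TFCE exponents and integration rule (canonical volumetric defaults)."""

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None  # None -> h_max / n_steps per map
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


def _connectivity_offsets(connectivity: int) -> np.ndarray:
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if di == dj == dk == 0:
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((di, dj, dk))
    return np.asarray(offs, dtype=np.int64)


def _structure(connectivity: int) -> np.ndarray:
    st = np.zeros((3, 3, 3), dtype=bool)
    st[1, 1, 1] = True
    for di, dj, dk in _connectivity_offsets(connectivity):
        st[1 + di, 1 + dj, 1 + dk] = True
    return st


def _tfce_thresholds(h_max: float, params: TfceParams
                     ) -> tuple[np.ndarray, float]:
    dh = params.dh if params.dh is not None else h_max / params.n_steps
    n = max(1, int(np.floor(h_max / dh + 1e-9)))
    return dh * np.arange(1, n + 1), dh


@njit(cache=True)
def _uf_find(parent, v):  # pragma: no cover - compiled
    root = v
    while parent[root] != root:
        root = parent[root]
    while parent[v] != root:
        parent[v], v = root, parent[v]
    return root


@njit(cache=True)
def _tfce_kernel(stat, order_desc, thresholds, step_w, size_pow,
                 offsets, nx, ny, nz):  # pragma: no cover - compiled
    """Union-find TFCE sweep over descending thresholds.

    Contributions are accumulated in descending-threshold order; the scipy
    fallback and the test oracle use the same order so results match
    bitwise.
    """
    V = nx * ny * nz
    parent = np.full(V, -1, dtype=np.int64)
    size = np.zeros(V, dtype=np.int64)
    out = np.zeros(V, dtype=np.float64)
    n_off = offsets.shape[0]
    ptr = 0
    n_sorted = order_desc.shape[0]
    for t in range(thresholds.shape[0] - 1, -1, -1):
        h = thresholds[t]
        while ptr < n_sorted and stat[order_desc[ptr]] >= h:
            v = order_desc[ptr]
            parent[v] = v
            size[v] = 1
            i = v // (ny * nz)
            j = (v // nz) % ny
            k = v % nz
            for o in range(n_off):
                ii = i + offsets[o, 0]
                jj = j + offsets[o, 1]
                kk = k + offsets[o, 2]
                if ii < 0 or ii >= nx or jj < 0 or jj >= ny \
                        or kk < 0 or kk >= nz:
                    continue
                w = (ii * ny + jj) * nz + kk
                if parent[w] >= 0:
                    rv = _uf_find(parent, v)
                    rw = _uf_find(parent, w)
                    if rv != rw:
                        if size[rv] < size[rw]:
                            rv, rw = rw, rv
                        parent[rw] = rv
                        size[rv] += size[rw]
            ptr += 1
        w_t = step_w[t]
        for s in range(ptr):
            v = order_desc[s]
            out[v] += size_pow[size[_uf_find(parent, v)]] * w_t
    return out


def _tfce_ndimage(stat: np.ndarray, thresholds: np.ndarray,
                  step_w: np.ndarray, size_pow: np.ndarray,
                  structure: np.ndarray) -> np.ndarray:
    """scipy fallback: explicit per-threshold component labeling."""
    out = np.zeros_like(stat, dtype=float)
    for t in range(len(thresholds) - 1, -1, -1):
        sup = stat >= thresholds[t]
        if not sup.any():
            continue
        labels, _ = ndimage.label(sup, structure=structure)
        sizes = np.bincount(labels.ravel())
        out[sup] += size_pow[sizes[labels[sup]]] * step_w[t]
    return out


def tfce_transform(stat: Volume | np.ndarray,
                   mask: MaskVolume | np.ndarray | None = None,
                   params: TfceParams | None = None,
                   engine: str = "auto") -> Volume | np.ndarray:
    """Threshold-free cluster enhancement of a non-negative statistic map.

    ``TFCE(v) = sum_h e_v(h)^E * h^H * dh`` over thresholds
    ``h = dh, 2dh, ...`` up to the map maximum, where ``e_v(h)`` is the size
    of the connected suprathreshold component containing v.  Cluster extents
    count only in-mask voxels.
    """
    params = params or TfceParams()
    is_vol = isinstance(stat, Volume)
    arr = np.asarray(stat.data if is_vol else stat, dtype=float)
    if mask is not None:
        m = np.asarray(mask.data if isinstance(mask, Volume) else mask,
                       dtype=bool)
        arr = np.where(m, arr, 0.0)
    if (arr < 0).any():
        raise ValueError("TFCE input must be non-negative; clip the tail "
                         "first (e.g. max(t, 0))")
    h_max = float(arr.max())
    if h_max <= 0:
        out = np.zeros_like(arr)
        return stat.copy(data=out) if is_vol else out
    thresholds, dh = _tfce_thresholds(h_max, params)
    step_w = np.power(thresholds, params.H) * dh
    max_size = int((arr >= thresholds[0]).sum())
    size_pow = np.power(np.arange(max_size + 1, dtype=float), params.E)

    if engine == "auto":
        engine = "numba" if _HAVE_NUMBA else "ndimage"
    if engine == "numba":
        flat = arr.ravel()
        active = np.flatnonzero(flat >= thresholds[0])
        order = active[np.argsort(-flat[active], kind="stable")]
        out = _tfce_kernel(flat, order.astype(np.int64), thresholds, step_w,
                           size_pow, _connectivity_offsets(params.connectivity),
                           *arr.shape).reshape(arr.shape)
    elif engine == "ndimage":
        out = _tfce_ndimage(arr, thresholds, step_w, size_pow,
                            _structure(params.connectivity))
    else:
        raise ValueError(f"unknown TFCE engine {engine!r}")
    return stat.copy(data=out) if is_vol else out


# --------------------------------------------------------------------------
# permutation FWE
# --------------------------------------------------------------------------

@dataclass
class StatResult:
    """Output of the permutation TFCE test (both tails)."""

    t_map: Volume
    tfce_pos: Volume
    tfce_neg: Volume
    fwe_p_pos: Volume
    fwe_p_neg: Volume
    sig_pos: MaskVolume
    sig_neg: MaskVolume
    null_max_pos: np.ndarray
    null_max_neg: np.ndarray
    n_perm: int
    seed: int
    alpha: float
    analysis_mask: MaskVolume | None = None
    zero_variance_mask: MaskVolume | None = None


def _fwe_p(observed: np.ndarray, null_max: np.ndarray,
           n_perm: int) -> np.ndarray:
    """(1 + #{null >= obs}) / (1 + n_perm), vectorized by sorting the null."""
    srt = np.sort(null_max)
    count = n_perm - np.searchsorted(srt, observed, side="left")
    return (1.0 + count) / (1.0 + n_perm)


def permutation_fwe(data, design: DesignMatrix, mask: MaskVolume,
                    params: TfceParams | None = None, n_perm: int = 5000,
                    seed: int = 0, alpha: float = 0.05,
                    tails: str = "two-sided") -> StatResult:
    """Two-tailed permutation max-TFCE test with FWE-corrected p values.

    The null is built by Freedman-Lane residual permutation: the reduced
    (nuisance-only) model is fitted once, its residuals are permuted with a
    seeded RNG, the full model is refitted, and the image-wide maximum TFCE
    is recorded.  The observed data acts as permutation 0, hence the ``+1``
    in the p-value formula and the attainable minimum p of
    ``1 / (1 + n_perm)``.

    ``tails`` selects the null convention:

    - ``"two-sided"`` (default): one null distribution of the maximum TFCE
      over *both* tails; the chance of any voxel reaching significance in
      either tail is controlled at ``alpha`` overall.
    - ``"per-tail"``: separate positive/negative null maxima, each tail
      thresholded at ``alpha`` on its own — a liberal convention whose
      any-tail error rate can approach ``2 * alpha``.

    Voxels whose data are constant across subjects are excluded from the
    analysis mask (and from the null maxima).
    """
    params = params or TfceParams()
    if tails not in ("two-sided", "per-tail"):
        raise ValueError(f"unknown tails convention {tails!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null")
    grp = design.group_indicator
    sizes = [int((grp == v).sum()) for v in np.unique(grp)]
    if len(sizes) != 2 or min(sizes) < 3:
        raise ValueError(f"need two groups with >= 3 subjects each; "
                         f"got sizes {sizes}")
    Y = _stack(data, mask)
    n, p = design.X.shape
    df = n - p
    m3 = mask.data.astype(bool)

    zero_var = Y.var(axis=0) <= 0
    ana3 = m3.copy()
    ana3[m3] = ~zero_var
    Y = Y[:, ~zero_var]
    affine = mask.affine

    X = design.X
    c = design.contrast
    pinvX = np.linalg.pinv(X)
    c_var = float(c @ np.linalg.inv(X.T @ X) @ c)
    Z = design.nuisance()
    Hz = Z @ np.linalg.pinv(Z)
    Y_res = Y - Hz @ Y
    Y_fit = Y - Y_res

    def embed(vals: np.ndarray) -> np.ndarray:
        out = np.zeros(mask.shape)
        out[ana3] = vals
        return out

    def tfce_tails(tvals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t3 = embed(tvals)
        pos = tfce_transform(np.maximum(t3, 0.0), ana3, params)
        neg = tfce_transform(np.maximum(-t3, 0.0), ana3, params)
        return pos, neg

    t_obs = _t_from_fit(Y, X, pinvX, c, c_var, df)
    tfce_pos3, tfce_neg3 = tfce_tails(t_obs)

    rng = np.random.default_rng(seed)
    null_pos = np.empty(n_perm)
    null_neg = np.empty(n_perm)
    for j in range(n_perm):
        perm = rng.permutation(n)
        t_j = _t_from_fit(Y_fit + Y_res[perm], X, pinvX, c, c_var, df)
        pos_j, neg_j = tfce_tails(t_j)
        null_pos[j] = pos_j.max()
        null_neg[j] = neg_j.max()
    if tails == "two-sided":
        combined = np.maximum(null_pos, null_neg)
        null_pos = null_neg = combined

    p_pos = np.ones(mask.shape)
    p_neg = np.ones(mask.shape)
    p_pos[ana3] = _fwe_p(tfce_pos3[ana3], null_pos, n_perm)
    p_neg[ana3] = _fwe_p(tfce_neg3[ana3], null_neg, n_perm)
    sig_pos = (p_pos <= alpha) & ana3
    sig_neg = (p_neg <= alpha) & ana3

    def vol(a) -> Volume:
        return Volume(data=a, affine=affine.copy(), space=mask.space)

    return StatResult(
        t_map=vol(embed(t_obs)),
        tfce_pos=vol(tfce_pos3), tfce_neg=vol(tfce_neg3),
        fwe_p_pos=vol(p_pos), fwe_p_neg=vol(p_neg),
        sig_pos=MaskVolume(data=sig_pos.astype(np.uint8),
                           affine=affine.copy(), space=mask.space),
        sig_neg=MaskVolume(data=sig_neg.astype(np.uint8),
                           affine=affine.copy(), space=mask.space),
        null_max_pos=null_pos, null_max_neg=null_neg,
        n_perm=n_perm, seed=seed, alpha=alpha,
        analysis_mask=MaskVolume(data=ana3.astype(np.uint8),
                                 affine=affine.copy(), space=mask.space),
        zero_variance_mask=MaskVolume(
            data=(m3 & ~ana3).astype(np.uint8), affine=affine.copy(),
            space=mask.space),
    )


def summarize_result(res: StatResult) -> dict:
    """Tail-wise significant-voxel counts, peak |t| and peak world coordinate."""
    out = {}
    for tail, sig in (("pos", res.sig_pos), ("neg", res.sig_neg)):
        sel = sig.data.astype(bool)
        count = int(sel.sum())
        entry = {"n_sig_voxels": count, "peak_t": None, "peak_mni": None}
        if count:
            t = res.t_map.data
            absmax = np.abs(np.where(sel, t, 0.0))
            idx = np.unravel_index(int(absmax.argmax()), t.shape)
            entry["peak_t"] = float(t[idx])
            entry["peak_mni"] = [float(v) for v in
                                 voxel_to_world(idx, res.t_map.affine)]
        out[tail] = entry
    return out
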