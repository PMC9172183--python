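"""Lung water density quantification.

The three-step inline procedure, run after lung segmentation:

1. a circular reference region of interest (ROI, default 12.5 cm²) is placed
   automatically in the liver, 8.75 mm below the bottom of the right lung in
   the coronal slice and column of the right-lung centroid;
2. surface-coil shading is removed by dividing the image by a smooth
   normalization map, fitted slice-by-slice to the body signal by Tikhonov-
   regularized least squares with the smoothing parameter chosen by the
   L-curve criterion;
3. the pixel-wise lung water density map is the ratio of normalized lung
   signal to the mean normalized liver-ROI signal, scaled by an assumed 70%
   hepatic water density, and is summarised globally, per lung, and over
   anterior/mid/posterior slice groups.

The Tikhonov fit minimises, per coronal slice and over the full slice grid,

    sum_{x in body} (M(x) - S(x))^2  +  lambda^2 * ||Delta M||^2

with Delta the discrete 2D Laplacian under Neumann boundary conditions. The
slice data are divided by the mean body intensity before fitting (and the
map rescaled back afterwards), which makes the selected lambda — and hence
every LWD output — exactly invariant to a global rescaling of the input
image. The fit runs on a block-averaged coarse grid (default 8x, ~28 mm blocks)
and is interpolated back bilinearly. Coil sensitivity varies on the scale of
the coil elements (>= 80 mm), so the coarse grid is still Nyquist-ample for
the field being estimated, while organ-scale anatomy (liver, bowel) becomes
unfittable at any lambda — which is exactly what a shading map should not
fit — and the sparse systems stay tiny.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage
from scipy import sparse
from scipy.sparse.linalg import splu

from .synthetic import partition_slices
from .volumes import LungSegmentation, Volume

__all__ = [
    "LiverROI",
    "NormalizationMap",
    "LWDMap",
    "RegionalLWD",
    "PipelineConfig",
    "PipelineResult",
    "compute_body_mask",
    "fit_normalization_map",
    "select_lambda_lcurve",
    "normalize_volume",
    "place_liver_roi",
    "compute_lwd_map",
    "summarize_lwd",
    "run_pipeline",
]

#: fraction of the body-median map value used as the division floor
MAP_FLOOR_FRACTION = 1e-3

#: L-curve corner detection: Savitzky-Golay stencil width for the curvature
#: of the (log residual, log seminorm) curve, and the fraction of the peak
#: curvature defining the near-corner plateau
LCURVE_SAVGOL_WINDOW = 13
LCURVE_PLATEAU_FRACTION = 0.75


# ---------------------------------------------------------------------------
# body mask
# ---------------------------------------------------------------------------

def compute_body_mask(volume: Volume, lungs: LungSegmentation) -> np.ndarray:
    """Voxels brighter than the global mean, minus lung voxels.

    Keeps the largest connected component. This is the support on which the
    normalization map is fitted.
    """
    if volume.shape != lungs.right_mask.shape:
        raise ValueError("volume and lung masks must share a grid")
    mask = volume.data > volume.data.mean()
    mask &= ~lungs.both
    if not mask.any():
        raise ValueError("body mask is empty after thresholding")
    lab, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


# ---------------------------------------------------------------------------
# normalization map
# ---------------------------------------------------------------------------

@dataclass
class NormalizationMap:
    """Smooth positive field dividing out coil shading."""

    field: np.ndarray
    lam: float
    slice_residuals: np.ndarray  # per-coronal-slice weighted residual norm
    floor: float

    @property
    def shape(self):
        return self.field.shape


def _laplacian_2d(h: int, w: int) -> sparse.csr_matrix:
    """5-point Laplacian on an h x w grid, Neumann boundaries, row-major."""
    def lap1(n):
        d = np.full(n, -2.0)
        d[0] = d[-1] = -1.0
        off = np.ones(n - 1)
        return sparse.diags([off, d, off], [-1, 0, 1])

    return (sparse.kron(sparse.eye(h), lap1(w))
            + sparse.kron(lap1(h), sparse.eye(w))).tocsr()


def _coarse_slices(volume, body_mask, downsample):
    """Block-average each coronal slice and its body support.

    Returns (weights, data, var0, (hc, wc)): weights are the body fraction
    per coarse pixel, data the mean body signal there (0 where no body), and
    var0 the per-slice within-block variance term. The fine-grid residual of
    a map that is constant within each block decomposes as

        sum_body (M - S)^2 = d^2 * [ sum w (m - s)^2 ] + sum_blocks (q - n s^2)

    so ``var0`` (scaled like the coarse data term) is the irreducible part of
    the residual that block-averaging would otherwise hide; the L-curve needs
    it, else the residual can vanish at small lambda and the curve loses its
    true corner.
    """
    S, H, W = volume.data.shape
    d = downsample
    hp, wp = (-H) % d, (-W) % d
    sig = np.pad(volume.data, ((0, 0), (0, hp), (0, wp)))
    bod = np.pad(body_mask.astype(np.float64), ((0, 0), (0, hp), (0, wp)))
    hc, wc = sig.shape[1] // d, sig.shape[2] // d
    bsum = bod.reshape(S, hc, d, wc, d).sum(axis=(2, 4))
    ssum = (sig * bod).reshape(S, hc, d, wc, d).sum(axis=(2, 4))
    qsum = (sig * sig * bod).reshape(S, hc, d, wc, d).sum(axis=(2, 4))
    weights = bsum / (d * d)
    data = np.divide(ssum, bsum, out=np.zeros_like(ssum), where=bsum > 0)
    var0 = (qsum - bsum * data ** 2).sum(axis=(1, 2)) / (d * d)
    return weights, data, var0, (hc, wc)


def _upsample_slice(coarse: np.ndarray, fine_shape, downsample) -> np.ndarray:
    """Bilinear interpolation from coarse block centers back to the fine grid."""
    d = downsample
    h, w = fine_shape
    rows = (np.arange(h) - (d - 1) / 2.0) / d
    cols = (np.arange(w) - (d - 1) / 2.0) / d
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(coarse, [rr, cc], order=1, mode="nearest")


def _solve_slices(weights, data, lam, ltl, var0=None):
    """Solve the per-slice Tikhonov systems; returns (maps, residuals, seminorms)."""
    S = weights.shape[0]
    hc, wc = weights.shape[1:]
    maps = np.full((S, hc, wc), np.nan)
    res = np.zeros(S)
    semi = np.zeros(S)
    for s in range(S):
        wvec = weights[s].ravel()
        if not wvec.any():
            continue
        svec = data[s].ravel()
        A = sparse.diags(wvec) + (lam ** 2) * ltl
        m = splu(A.tocsc()).solve(wvec * svec)
        maps[s] = m.reshape(hc, wc)
        res[s] = float(np.sum(wvec * (m - svec) ** 2))
        if var0 is not None:
            res[s] += float(var0[s])
        lm = _laplacian_apply(m, hc, wc)
        semi[s] = float(np.sum(lm ** 2))
    return maps, res, semi


_LAP_CACHE: dict = {}


def _get_ltl(hc, wc):
    key = (hc, wc)
    if key not in _LAP_CACHE:
        L = _laplacian_2d(hc, wc)
        _LAP_CACHE[key] = (L, (L.T @ L).tocsr())
    return _LAP_CACHE[key]


def _laplacian_apply(mvec, hc, wc):
    L, _ = _get_ltl(hc, wc)
    return L @ mvec


def fit_normalization_map(
    volume: Volume,
    body_mask: np.ndarray,
    lam: float,
    downsample: int = 8,
) -> NormalizationMap:
    """Fit the coil-shading normalization map at a given smoothing ``lam``.

    Coronal slices with no body voxels copy the nearest fitted slice. The
    returned field is floored at ``MAP_FLOOR_FRACTION`` of its median over
    the body so subsequent division is safe, and is strictly positive.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    scale = float(volume.data[body_mask].mean())
    unit = Volume(volume.data / scale, volume.spacing)
    weights, data, var0, (hc, wc) = _coarse_slices(unit, body_mask, downsample)
    _, ltl = _get_ltl(hc, wc)
    maps, res, _ = _solve_slices(weights, data, lam, ltl, var0)

    fitted = np.nonzero(~np.isnan(maps[:, 0, 0]))[0]
    if len(fitted) == 0:
        raise ValueError("no slice contains body voxels")
    all_idx = np.arange(maps.shape[0])
    nearest = fitted[np.argmin(np.abs(all_idx[:, None] - fitted[None, :]), axis=1)]
    maps = maps[nearest]

    S, H, W = volume.data.shape
    field = np.empty((S, H, W))
    for s in range(S):
        field[s] = _upsample_slice(maps[s], (H, W), downsample)
    field *= scale

    floor = MAP_FLOOR_FRACTION * float(np.median(field[body_mask]))
    field = np.maximum(field, floor)
    return NormalizationMap(field, float(lam), res, floor)


@dataclass
class LCurveResult:
    lambda_star: float
    grid: np.ndarray
    residual_norms: np.ndarray
    seminorms: np.ndarray
    curvature: np.ndarray
    boundary_warning: bool


def default_lambda_grid(volume: Volume, downsample: int = 8,
                        n: int = 30, decades: float = 6.0) -> np.ndarray:
    """Log-spaced lambda grid centered on the coarse slice dimension.

    With unit-mean body data (see module docstring) the natural lambda scale
    is set by the slice size alone; the grid spans ``decades`` decades around
    the geometric mean of the coarse grid sides.
    """
    H, W = volume.data.shape[1:]
    hc, wc = -(-H // downsample), -(-W // downsample)
    center = float(np.sqrt(hc * wc))
    return center * np.logspace(-decades / 2, decades / 2, n)


def select_lambda_lcurve(
    volume: Volume,
    body_mask: np.ndarray,
    grid: np.ndarray | None = None,
    downsample: int = 8,
) -> LCurveResult:
    """Choose the Tikhonov smoothing parameter by the L-curve criterion.

    For each lambda on the grid the weighted residual norm over body voxels
    and the Laplacian seminorm of the fitted map are accumulated over all
    slices; the corner is the point of maximum signed curvature of the
    (log residual, log seminorm) curve, computed by centered finite
    differences in log lambda. A flag is set when the corner lies on the
    grid boundary.
    """
    if grid is None:
        grid = default_lambda_grid(volume, downsample)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 3:
        raise ValueError("lambda grid must contain at least 3 values")
    if np.any(grid <= 0):
        raise ValueError("lambda values must be positive")
    grid = np.sort(grid)

    scale = float(volume.data[body_mask].mean())
    unit = Volume(volume.data / scale, volume.spacing)
    weights, data, var0, (hc, wc) = _coarse_slices(unit, body_mask, downsample)
    _, ltl = _get_ltl(hc, wc)

    rho = np.empty(grid.size)
    eta = np.empty(grid.size)
    for i, lam in enumerate(grid):
        _, res, semi = _solve_slices(weights, data, lam, ltl, var0)
        rho[i] = np.sqrt(res.sum())
        eta[i] = np.sqrt(semi.sum())

    t = np.log(grid)
    x = np.log(np.maximum(rho, 1e-300))
    y = np.log(np.maximum(eta, 1e-300))
    # derivatives from a local quadratic over a wide stencil: the discrete
    # curve's curvature plateau is broad and a 3-point estimate picks its
    # corner from sampling noise
    dt = t[1] - t[0]
    win = min(LCURVE_SAVGOL_WINDOW,
              grid.size if grid.size % 2 else grid.size - 1)
    if win >= 5:
        from scipy.signal import savgol_filter
        dx = savgol_filter(x, win, 2, deriv=1, delta=dt, mode="interp")
        dy = savgol_filter(y, win, 2, deriv=1, delta=dt, mode="interp")
        ddx = savgol_filter(x, win, 2, deriv=2, delta=dt, mode="interp")
        ddy = savgol_filter(y, win, 2, deriv=2, delta=dt, mode="interp")
    else:
        dx, dy = np.gradient(x, t), np.gradient(y, t)
        ddx, ddy = np.gradient(dx, t), np.gradient(dy, t)
    # orientation: residual grows and seminorm falls with lambda, so the
    # L-shaped corner has positive curvature under this sign convention
    kappa = (dy * ddx - dx * ddy) / np.power(dx * dx + dy * dy, 1.5)
    # the maximum often sits on a near-flat plateau; among near-maximal
    # candidates prefer the smoothest map — extra smoothing is free there by
    # definition, and smoothness is the safer prior for a coil field
    near = np.nonzero(kappa >= LCURVE_PLATEAU_FRACTION * kappa.max())[0]
    best = int(near.max())
    return LCurveResult(
        lambda_star=float(grid[best]),
        grid=grid,
        residual_norms=rho,
        seminorms=eta,
        curvature=kappa,
        boundary_warning=best in (0, grid.size - 1),
    )


def normalize_volume(volume: Volume, nmap: NormalizationMap) -> Volume:
    """Divide the image by the (floored) normalization map."""
    if volume.shape != nmap.shape:
        raise ValueError("volume and normalization map must share a grid")
    return Volume(volume.data / nmap.field, volume.spacing)


# ---------------------------------------------------------------------------
# liver ROI
# ---------------------------------------------------------------------------

@dataclass
class LiverROI:
    """Automatically placed circular hepatic reference region.

    ``center`` is in continuous voxel coordinates (row, col) within
    ``slice_index``; lung-labeled voxels are excluded from the member set so
    the reference stays purely hepatic even though the disc abuts the lung
    base.
    """

    slice_index: int
    center: tuple[float, float]
    radius_mm: float
    members: np.ndarray            # boolean in-plane mask after lung exclusion
    pre_exclusion_count: int
    spacing: tuple[float, float, float]
    offset_mm: float
    column_fallback: bool = False

    @property
    def member_count(self) -> int:
        return int(self.members.sum())

    @property
    def pre_exclusion_area_cm2(self) -> float:
        return self.pre_exclusion_count * self.spacing[1] * self.spacing[2] / 100.0

    def mean_in(self, volume: Volume) -> float:
        vals = volume.data[self.slice_index][self.members]
        return float(vals.mean())


def place_liver_roi(
    lungs: LungSegmentation,
    spacing=None,
    area_cm2: float = 12.5,
    offset_mm: float = 8.75,
) -> LiverROI:
    """Place the hepatic reference ROI under the right lung.

    The ROI lives in the coronal slice nearest the right-lung 3D centroid,
    in the centroid column; its center sits ``offset_mm`` below the
    bottom-most right-lung voxel of that slice/column (continuous
    coordinates, voxel centers at integers). Membership is the pixelized
    disc of the prescribed area: the ``N = round(area / voxel area)``
    in-plane voxels nearest the center (equivalently, all voxel centers
    within an effective radius), minus lung voxels. Selecting by quantized
    count rather than by the nominal radius keeps the pre-exclusion ROI
    area within half a voxel of ``area_cm2`` for every center position;
    with the nominal radius the lattice count can deviate by two to six
    voxels depending on the sub-voxel center offset.
    """
    spacing = spacing or lungs.spacing
    right = lungs.right_mask
    if not right.any():
        raise ValueError("right lung mask is empty")
    idx = np.nonzero(right)
    centroid = [float(np.mean(a)) for a in idx]
    s = int(round(centroid[0]))
    center_col = centroid[2]
    col = int(round(center_col))  # voxel column used to find the lung bottom

    column_fallback = False
    rows_here = np.nonzero(right[s, :, col])[0]
    if rows_here.size == 0:
        cols_with_lung = np.nonzero(right[s].any(axis=0))[0]
        if cols_with_lung.size == 0:
            raise ValueError("centroid slice contains no right-lung voxels")
        col = int(cols_with_lung[np.argmin(np.abs(cols_with_lung - col))])
        center_col = float(col)
        rows_here = np.nonzero(right[s, :, col])[0]
        column_fallback = True
    bottom_row = int(rows_here.max())

    center_row = bottom_row + offset_mm / spacing[1]
    radius_mm = float(np.sqrt(area_cm2 / np.pi) * 10.0)

    nrow, ncol = right.shape[1:]
    if (center_row - radius_mm / spacing[1] < 0
            or center_row + radius_mm / spacing[1] > nrow - 1
            or center_col - radius_mm / spacing[2] < 0
            or center_col + radius_mm / spacing[2] > ncol - 1):
        raise ValueError("liver ROI disc exceeds volume bounds")

    rr = (np.arange(nrow) - center_row) * spacing[1]
    cc = (np.arange(ncol) - center_col) * spacing[2]
    d2 = rr[:, None] ** 2 + cc[None, :] ** 2
    n_target = int(round(area_cm2 * 100.0 / (spacing[1] * spacing[2])))
    flat = np.argsort(d2.ravel(), kind="stable")[:n_target]
    disc = np.zeros(d2.shape, dtype=bool)
    disc.ravel()[flat] = True
    pre_count = int(disc.sum())
    members = disc & ~lungs.both[s]
    return LiverROI(
        slice_index=s,
        center=(float(center_row), float(center_col)),
        radius_mm=radius_mm,
        members=members,
        pre_exclusion_count=pre_count,
        spacing=tuple(spacing),
        offset_mm=float(offset_mm),
        column_fallback=column_fallback,
    )


# ---------------------------------------------------------------------------
# LWD map and summaries
# ---------------------------------------------------------------------------

@dataclass
class LWDMap:
    """Percent water density per lung voxel (NaN outside the lungs).

    No clipping is applied: values above 100% are reported as computed, so
    means stay unbiased. Any lung voxel whose normalized signal equals the
    liver reference mean maps to exactly ``hepatic_wd``.
    """

    values: np.ndarray
    liver_mean: float
    hepatic_wd: float
    spacing: tuple[float, float, float]


def compute_lwd_map(
    norm_volume: Volume,
    lungs: LungSegmentation,
    roi: LiverROI,
    hepatic_wd: float = 70.0,
) -> LWDMap:
    """LWD(x) = hepatic_wd * S(x) / mean liver signal, on lung voxels."""
    liver_mean = roi.mean_in(norm_volume)
    if liver_mean <= 0:
        raise ValueError("liver ROI mean must be positive")
    values = np.full(norm_volume.shape, np.nan)
    both = lungs.both
    values[both] = hepatic_wd * norm_volume.data[both] / liver_mean
    return LWDMap(values, liver_mean, float(hepatic_wd), norm_volume.spacing)


@dataclass
class RegionalLWD:
    """Global, regional (anterior/mid/posterior) and per-lung mean LWD."""

    global_mean: float
    anterior: float
    mid: float
    posterior: float
    left: float
    right: float
    lung_volume_l: float
    slice_ranges: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def as_dict(self) -> dict:
        return {
            "global_lwd_percent": self.global_mean,
            "anterior_lwd_percent": self.anterior,
            "mid_lwd_percent": self.mid,
            "posterior_lwd_percent": self.posterior,
            "left_lwd_percent": self.left,
            "right_lwd_percent": self.right,
            "lung_volume_l": self.lung_volume_l,
            "slice_ranges": [list(r) for r in self.slice_ranges],
        }


def summarize_lwd(lwd: LWDMap, lungs: LungSegmentation) -> RegionalLWD:
    """Mean LWD globally, per lung, and over three coronal slice groups.

    Lung-containing coronal slices are listed anterior -> posterior and split
    into three contiguous groups whose sizes differ by at most one (extras to
    mid, then posterior).
    """
    both = lungs.both
    if not both.any():
        raise ValueError("lung segmentation is empty")
    lung_slices = np.nonzero(both.any(axis=(1, 2)))[0]
    parts = partition_slices(len(lung_slices))

    def seg_mean(p):
        sl = lung_slices[p]
        return float(np.nanmean(lwd.values[sl][both[sl]]))

    ranges = tuple(
        (int(lung_slices[p][0]), int(lung_slices[p][-1])) for p in parts
    )
    return RegionalLWD(
        global_mean=float(np.nanmean(lwd.values[both])),
        anterior=seg_mean(parts[0]),
        mid=seg_mean(parts[1]),
        posterior=seg_mean(parts[2]),
        left=float(np.nanmean(lwd.values[lungs.left_mask]))
        if lungs.left_mask.any() else float("nan"),
        right=float(np.nanmean(lwd.values[lungs.right_mask]))
        if lungs.right_mask.any() else float("nan"),
        lung_volume_l=lungs.volume_liters,
        slice_ranges=ranges,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Resolved configuration echoed into every report."""

    segmentation_mode: str = "classical"   # classical | unet | provided
    lambda_mode: str = "lcurve"            # "lcurve" or a fixed float
    lambda_value: float | None = None
    roi_area_cm2: float = 12.5
    roi_offset_mm: float = 8.75
    hepatic_wd: float = 70.0
    lambda_grid_size: int = 30
    lambda_grid_decades: float = 6.0
    downsample: int = 8
    seed: int = 0

    def validate(self):
        if self.roi_area_cm2 <= 0:
            raise ValueError("ROI area must be positive")
        if self.roi_offset_mm < 0:
            raise ValueError("ROI offset must be non-negative")
        if not 0 < self.hepatic_wd <= 100:
            raise ValueError("hepatic water density must lie in (0, 100]")
        if self.lambda_mode != "lcurve":
            lam = float(self.lambda_mode)
            if lam <= 0:
                raise ValueError("fixed lambda must be positive")


@dataclass
class PipelineResult:
    lwd_map: LWDMap
    regional: RegionalLWD
    roi: LiverROI
    norm_map: NormalizationMap
    lungs: LungSegmentation
    report: dict

    def overlay_array(self, sentinel: float = -1.0) -> np.ndarray:
        """LWD% array with non-lung voxels set to ``sentinel``."""
        return np.where(np.isnan(self.lwd_map.values), sentinel,
                        self.lwd_map.values)


def run_pipeline(
    volume: Volume,
    segmentation_mode: str = "classical",
    config: PipelineConfig | None = None,
    lungs: LungSegmentation | None = None,
    model=None,
) -> PipelineResult:
    """Run segmentation -> liver ROI -> normalization -> LWD map -> summaries.

    ROI placement uses the raw-geometry lung masks; the ROI mean is taken on
    the normalized image. With ``lambda_mode="lcurve"`` the smoothing
    parameter is optimized per image on a fixed grid, so repeated runs on the
    same input are bit-identical.
    """
    from . import __version__
    from .segmentation import predict_lungs_unet, segment_lungs_classical

    config = config or PipelineConfig(segmentation_mode=segmentation_mode)
    config.segmentation_mode = segmentation_mode
    config.validate()
    report: dict = {"config": asdict(config), "version": __version__,
                    "stages": {}}
    t_all = time.perf_counter()

    def stage(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        report["stages"][name] = round(time.perf_counter() - t0, 4)
        return out

    if segmentation_mode == "classical":
        lungs = stage("segmentation", segment_lungs_classical, volume)
    elif segmentation_mode == "unet":
        if model is None:
            raise ValueError("segmentation_mode='unet' needs a trained model")
        lungs = stage("segmentation", predict_lungs_unet, model, volume)
    elif segmentation_mode == "provided":
        if lungs is None:
            raise ValueError("segmentation_mode='provided' needs lung masks")
    else:
        raise ValueError(f"unknown segmentation mode {segmentation_mode!r}")

    roi = stage("liver_roi", place_liver_roi, lungs, volume.spacing,
                config.roi_area_cm2, config.roi_offset_mm)
    body = stage("body_mask", compute_body_mask, volume, lungs)

    if config.lambda_mode == "lcurve":
        grid = default_lambda_grid(volume, config.downsample,
                                   config.lambda_grid_size,
                                   config.lambda_grid_decades)
        lcurve = stage("lambda_selection", select_lambda_lcurve, volume, body,
                       grid, config.downsample)
        lam = lcurve.lambda_star
        report["lambda_warning"] = lcurve.boundary_warning
    else:
        lam = float(config.lambda_mode)
    config.lambda_value = lam
    report["lambda"] = lam
    report["lambda_mode"] = ("lcurve" if config.lambda_mode == "lcurve"
                             else "fixed")

    nmap = stage("normalization_fit", fit_normalization_map, volume, body,
                 lam, config.downsample)
    norm = stage("normalization", normalize_volume, volume, nmap)
    lwd = stage("lwd_map", compute_lwd_map, norm, lungs, roi,
                config.hepatic_wd)
    regional = stage("summary", summarize_lwd, lwd, lungs)

    report["config"]["lambda_value"] = lam
    report["roi"] = {
        "slice_index": roi.slice_index,
        "center_row": roi.center[0],
        "center_col": roi.center[1],
        "radius_mm": roi.radius_mm,
        "pre_exclusion_area_cm2": roi.pre_exclusion_area_cm2,
        "member_count": roi.member_count,
        "column_fallback": roi.column_fallback,
        "offset_mm": roi.offset_mm,
        "liver_mean": lwd.liver_mean,
    }
    report["lwd"] = regional.as_dict()
    report["total_seconds"] = round(time.perf_counter() - t_all, 4)
    return PipelineResult(lwd, regional, roi, nmap, lungs, report)
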