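"""Digital phantoms with known ground truth.

Two families of phantoms make every stage of the quantification pipeline
testable without any acquired data:

* a vial dilution phantom — cylinders of known water concentration (10–100%
  in 10% steps) immersed in a water bath, mirroring the D2O dilution series
  used to validate proton-density-weighted water quantification;
* a thorax phantom — ellipsoidal body and lungs, a liver block directly under
  the right lung, an optional central airway, and a lung water density (LWD)
  field that varies along the anterior–posterior axis through prescribed
  anterior/mid/posterior regional means (gravity gradient; supine or prone).

Both share one signal model::

    S(x) = C(x) * WD(x)/100 * S0 + eps,   eps ~ N(0, (noise_sd*S0)^2), clipped at 0

where ``C`` is a smooth positive coil-shading field and ``WD`` the true water
density in percent. Clipping at zero stands in for magnitude-image behaviour;
at the noise levels simulated here the difference from a Rician model is
negligible for mean-based read-outs.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .volumes import LABELS, LabelMask, Volume

__all__ = [
    "ShadingParams",
    "Vial",
    "VialLayout",
    "ThoraxTruth",
    "coil_shading_field",
    "default_vial_layout",
    "load_vial_layout",
    "generate_vial_phantom",
    "generate_thorax_phantom",
    "generate_training_slices",
    "partition_slices",
]


# ---------------------------------------------------------------------------
# coil shading
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShadingParams:
    """Sum-of-Gaussians coil sensitivity model.

    ``gaussians`` is a tuple of ``(amplitude, center_mm, sigma_mm)`` with
    centers and widths in physical mm on the package frame. ``offset`` is the
    constant floor (> 0) and ``cap`` bounds the max/min ratio of the field
    (amplitudes are scaled down if the cap would be exceeded).
    """

    offset: float = 1.0
    gaussians: tuple = ()
    cap: float = 3.0


def coil_shading_field(grid_shape, spacing, params: ShadingParams) -> np.ndarray:
    """Evaluate a smooth positive shading field on a voxel grid."""
    if params.offset <= 0:
        raise ValueError("shading offset must be positive")
    coords = [np.arange(n) * d for n, d in zip(grid_shape, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    bump = np.zeros(grid_shape, dtype=np.float64)
    for amp, center, sigma in params.gaussians:
        q = ((zz - center[0]) / sigma[0]) ** 2
        q += ((yy - center[1]) / sigma[1]) ** 2
        q += ((xx - center[2]) / sigma[2]) ** 2
        bump += amp * np.exp(-0.5 * q)
    fld = params.offset + bump
    ratio = fld.max() / fld.min()
    if ratio > params.cap:
        # rescale the bump so (offset + a*max)/(offset + a*min) == cap
        bmax, bmin = bump.max(), bump.min()
        a = params.offset * (params.cap - 1.0) / (bmax - params.cap * bmin)
        fld = params.offset + a * bump
    return fld


# ---------------------------------------------------------------------------
# vial phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Vial:
    """One cylinder: in-plane center (row, col) in mm, radius in mm,
    water concentration in %, and whether it is the 100% reference."""

    center_mm: tuple[float, float]
    radius_mm: float
    concentration: float
    is_reference: bool = False


@dataclass(frozen=True)
class VialLayout:
    shape: tuple[int, int, int] = (16, 64, 64)
    spacing: tuple[float, float, float] = (3.5, 3.5, 3.5)
    vials: tuple[Vial, ...] = ()
    background_concentration: float = 100.0
    slice_range: tuple[int, int] = (4, 12)  # vial extent along axis 0

    @property
    def central_slice(self) -> int:
        return (self.slice_range[0] + self.slice_range[1]) // 2

    def validate(self) -> None:
        if not self.vials:
            raise ValueError("layout has no vials")
        for v in self.vials:
            if not 0 < v.concentration <= 100:
                raise ValueError(f"concentration {v.concentration} outside (0, 100]")
        if sum(v.is_reference for v in self.vials) != 1:
            raise ValueError("exactly one vial must be flagged as the 100% reference")
        for i, a in enumerate(self.vials):
            for b in self.vials[i + 1:]:
                d = math.dist(a.center_mm, b.center_mm)
                if d < a.radius_mm + b.radius_mm:
                    raise ValueError("vials overlap")


def load_vial_layout(path) -> VialLayout:
    """Read a vial layout from a JSON config file.

    Expected structure::

        {"shape": [16, 64, 64], "spacing": [3.5, 3.5, 3.5],
         "background_concentration": 100.0, "slice_range": [4, 12],
         "vials": [{"center_mm": [77.0, 35.0], "radius_mm": 12.0,
                    "concentration": 10.0, "is_reference": false}, ...]}

    Omitted top-level keys fall back to the defaults.
    """
    import json

    with open(path) as fh:
        cfg = json.load(fh)
    vials = tuple(
        Vial(tuple(v["center_mm"]), float(v["radius_mm"]),
             float(v["concentration"]), bool(v.get("is_reference", False)))
        for v in cfg["vials"]
    )
    kwargs = {"vials": vials}
    for key in ("shape", "spacing", "slice_range"):
        if key in cfg:
            kwargs[key] = tuple(cfg[key])
    if "background_concentration" in cfg:
        kwargs["background_concentration"] = float(cfg["background_concentration"])
    layout = VialLayout(**kwargs)
    layout.validate()
    return layout


def default_vial_layout() -> VialLayout:
    """Ten 12 mm-radius vials, 10–100% water in 10% steps, in two rows of
    five inside a water bath; the 100% vial is the quantification reference."""
    concentrations = [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
    rows_mm = (77.0, 147.0)
    cols_mm = (35.0, 73.5, 112.0, 150.5, 189.0)
    vials = []
    for i, conc in enumerate(concentrations):
        r = rows_mm[i // 5]
        c = cols_mm[i % 5]
        vials.append(
            Vial((r, c), 12.0, float(conc), is_reference=(conc == 100))
        )
    return VialLayout(vials=tuple(vials))


def generate_vial_phantom(
    layout: VialLayout | None = None,
    shading: ShadingParams | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    s0: float = 100.0,
) -> tuple[Volume, VialLayout]:
    """Simulate the vial dilution phantom.

    ``noise_sd`` is the additive Gaussian noise SD as a fraction of the
    reference signal ``s0``. With ``shading=None`` the coil field is unity.
    """
    layout = layout or default_vial_layout()
    layout.validate()
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    shape, spacing = layout.shape, layout.spacing

    wd = np.full(shape, layout.background_concentration, dtype=np.float64)
    rr = (np.arange(shape[1]) * spacing[1])[:, None]
    cc = (np.arange(shape[2]) * spacing[2])[None, :]
    lo, hi = layout.slice_range
    for v in layout.vials:
        disc = (rr - v.center_mm[0]) ** 2 + (cc - v.center_mm[1]) ** 2 <= v.radius_mm ** 2
        wd[lo:hi, disc] = v.concentration

    cfield = (
        coil_shading_field(shape, spacing, shading)
        if shading is not None
        else np.ones(shape)
    )
    rng = np.random.default_rng(seed)
    sig = cfield * wd / 100.0 * s0
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd * s0, size=shape)
    np.clip(sig, 0.0, None, out=sig)
    return Volume(sig, spacing), layout


# ---------------------------------------------------------------------------
# thorax phantom
# ---------------------------------------------------------------------------

def partition_slices(n: int) -> tuple[slice, slice, slice]:
    """Split ``n`` ordered slices into anterior/mid/posterior groups.

    Groups are contiguous and their sizes differ by at most one; when
    ``n % 3 != 0`` the extra slices go to the mid group first, then posterior,
    keeping the anterior/posterior extremes balanced.
    """
    if n < 3:
        raise ValueError("need at least 3 lung-containing slices")
    q, r = divmod(n, 3)
    sizes = [q, q + (1 if r >= 1 else 0), q + (1 if r >= 2 else 0)]
    a = sizes[0]
    m = a + sizes[1]
    return slice(0, a), slice(a, m), slice(m, n)


def _default_thorax_shading(shape, spacing) -> ShadingParams:
    # one broad posterior Gaussian: a spine-array-like brightening toward the
    # posterior face, mild enough that a global mean threshold still separates
    # body from lung
    extent = [n * d for n, d in zip(shape, spacing)]
    return ShadingParams(
        offset=1.0,
        gaussians=(
            (0.3, (extent[0], extent[1] / 2, extent[2] / 2), (150.0, 250.0, 250.0)),
        ),
        cap=3.0,
    )


@dataclass
class ThoraxTruth:
    """Ground-truth description of a synthetic thorax.

    Regional means are the target mean LWD (%) of the anterior, mid and
    posterior thirds of the lung-containing coronal slices. ``posture``
    controls the gravity gradient: supine puts the highest LWD posteriorly,
    prone reverses it. After generation the instance also carries the realised
    fields (``wd_field``, ``coil_field``, ``lung_profile``).
    """

    shape: tuple[int, int, int] = (72, 112, 112)
    spacing: tuple[float, float, float] = (3.5, 3.5, 3.5)
    regional_means: tuple[float, float, float] = (21.2, 23.5, 28.1)
    posture: str = "supine"
    liver_wd: float = 70.0
    soft_tissue_wd: float = 85.0
    #: relative SD of smooth soft-tissue heterogeneity (muscle/fat texture,
    #: correlation length ~25 mm). Applied to body tissue only — the liver,
    #: being the quantification reference, stays homogeneous.
    soft_tissue_texture_sd: float = 0.06
    #: rib cage + vertebral column. Marrow-containing bone carries roughly
    #: two thirds of soft-tissue proton density; being thin and below the
    #: normalization fit's resolvable scale it gives the body signal the
    #: irreducible structure real thoraces have.
    include_bones: bool = True
    bone_wd: float = 55.0
    airway_wd: float = 1.0
    include_airway: bool = True
    shading: ShadingParams | None = None
    noise_sd: float = 0.0
    s0: float = 100.0
    seed: int = 0
    # geometry jitter in voxels, used by the training-slice generator
    body_semiaxes: tuple[float, float, float] | None = None
    right_lung_semiaxes: tuple[float, float, float] | None = None
    left_lung_semiaxes: tuple[float, float, float] | None = None

    # filled in by generate_thorax_phantom
    wd_field: np.ndarray | None = field(default=None, repr=False)
    coil_field: np.ndarray | None = field(default=None, repr=False)
    lung_profile: dict | None = field(default=None, repr=False)

    def validate(self) -> None:
        if self.posture not in ("supine", "prone"):
            raise ValueError(f"unknown posture {self.posture!r}")
        for m in self.regional_means:
            if not 0 <= m <= 100:
                raise ValueError("regional means must lie in [0, 100]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.indices(shape, dtype=np.float64)
    q = np.zeros(shape)
    for g, c, a in zip(grids, center, semiaxes):
        q += ((g - c) / a) ** 2
    return q <= 1.0


def _solve_profile_knots(slices, weights, targets):
    """Knot values of a piecewise-linear A->P profile such that the
    lung-voxel-weighted mean over each slice group equals its target."""
    n = len(slices)
    part = partition_slices(n)
    knots = np.array([np.mean(slices[p]) for p in part])

    def basis(s):
        # hat-function weights of the three knots at slice s (constant
        # extrapolation beyond the outer knots)
        if s <= knots[0]:
            return np.array([1.0, 0.0, 0.0])
        if s >= knots[2]:
            return np.array([0.0, 0.0, 1.0])
        if s <= knots[1]:
            t = (s - knots[0]) / (knots[1] - knots[0])
            return np.array([1.0 - t, t, 0.0])
        t = (s - knots[1]) / (knots[2] - knots[1])
        return np.array([0.0, 1.0 - t, t])

    B = np.stack([basis(s) for s in slices])  # (n, 3)
    w = np.asarray(weights, dtype=np.float64)
    M = np.zeros((3, 3))
    for k, p in enumerate(part):
        M[k] = (w[p, None] * B[p]).sum(axis=0) / w[p].sum()
    v = np.linalg.solve(M, np.asarray(targets, dtype=np.float64))
    profile = B @ v
    return knots, v, profile, part


def generate_thorax_phantom(truth: ThoraxTruth) -> tuple[Volume, LabelMask, ThoraxTruth]:
    """Build the thorax phantom: signal volume, tissue labels, realised truth.

    The lung LWD profile is piecewise linear in coronal slice index through
    three knots placed at the centers of the anterior/mid/posterior slice
    groups; knot values are solved so that each group's lung-voxel-weighted
    mean equals the requested regional mean exactly.
    """
    truth.validate()
    shape, spacing = truth.shape, truth.spacing
    S, R, C = shape

    body_ax = truth.body_semiaxes or (0.46 * S, 0.48 * R, 0.48 * C)
    rl_ax = truth.right_lung_semiaxes or (0.31 * S, 0.20 * R, 0.125 * C)
    ll_ax = truth.left_lung_semiaxes or (0.31 * S, 0.19 * R, 0.11 * C)

    body_c = ((S - 1) / 2, 0.52 * R, (C - 1) / 2)
    rl_c = ((S - 1) / 2, 0.39 * R, 0.33 * C)   # subject right = low columns
    ll_c = ((S - 1) / 2, 0.37 * R, 0.67 * C)

    body = _ellipsoid(shape, body_c, body_ax)
    right = _ellipsoid(shape, rl_c, rl_ax) & body
    left = _ellipsoid(shape, ll_c, ll_ax) & body
    if np.any(right & left):
        raise ValueError("lung ellipsoids overlap; adjust geometry")

    labels = np.zeros(shape, dtype=np.int16)
    labels[body] = LABELS["body"]

    # liver: fill directly under the right lung's bottom face, ~45 mm deep
    liver_depth = max(1, int(round(45.0 / spacing[1])))
    liver = np.zeros(shape, dtype=bool)
    sl, rw, cl = np.nonzero(right)
    for s, c in set(zip(sl.tolist(), cl.tolist())):
        bottom = rw[(sl == s) & (cl == c)].max()
        liver[s, bottom + 1: bottom + 1 + liver_depth, c] = True
    liver &= body & ~right & ~left
    labels[liver] = LABELS["liver"]

    airway = np.zeros(shape, dtype=bool)
    if truth.include_airway:
        # central tube from the superior volume face down between the lungs
        rad_mm = 6.0
        col_mid, sl_mid = (C - 1) / 2, (S - 1) / 2
        ss, cc = np.meshgrid(np.arange(S), np.arange(C), indexing="ij")
        tube = (((cc - col_mid) * spacing[2]) ** 2
                + ((ss - sl_mid) * spacing[0]) ** 2) <= rad_mm ** 2  # (S, C)
        top_of_lungs = int(min(rl_c[1] - rl_ax[1], ll_c[1] - ll_ax[1]))
        airway[:, : max(1, top_of_lungs + int(0.25 * R)), :] = tube[:, None, :]
        airway &= ~right & ~left & ~liver
    labels[right] = LABELS["right_lung"]
    labels[left] = LABELS["left_lung"]
    labels[airway] = LABELS["airway"]

    # water density field; body tissue carries smooth heterogeneity (muscle/
    # fat texture) while the liver — the quantification reference — stays
    # homogeneous at liver_wd
    rng = np.random.default_rng(truth.seed)
    wd = np.zeros(shape, dtype=np.float64)
    body_wd = np.full(shape, truth.soft_tissue_wd)
    if truth.soft_tissue_texture_sd > 0:
        from scipy import ndimage as _ndi

        corr_vox = [25.0 / d for d in spacing]
        tex = _ndi.gaussian_filter(rng.standard_normal(shape), corr_vox)
        tex /= tex.std()
        body_wd *= np.clip(1.0 + truth.soft_tissue_texture_sd * tex, 0.6, 1.4)
        np.clip(body_wd, 0.0, 100.0, out=body_wd)
    wd[labels == LABELS["body"]] = body_wd[labels == LABELS["body"]]
    if truth.include_bones:
        from scipy import ndimage as _ndi

        lung_any = right | left
        shell = (_ndi.binary_dilation(lung_any, iterations=6)
                 & ~_ndi.binary_dilation(lung_any, iterations=2)
                 & (labels == LABELS["body"]))
        rib_rows = np.zeros(R, dtype=bool)
        pitch = max(3, int(round(25.0 / spacing[1])))
        thick = max(1, int(round(7.0 / spacing[1])))
        for r0 in range(0, R, pitch):
            rib_rows[r0: r0 + thick] = True
        ribs = shell & rib_rows[None, :, None]
        spine_half = 12.0
        cols_mm = (np.arange(C) - (C - 1) / 2) * spacing[2]
        spine_cols = np.abs(cols_mm) <= spine_half
        spine = np.zeros(shape, dtype=bool)
        spine[int(0.72 * S):, :, spine_cols] = True
        spine &= (labels == LABELS["body"])
        wd[ribs | spine] = truth.bone_wd
    wd[labels == LABELS["liver"]] = truth.liver_wd
    wd[labels == LABELS["airway"]] = truth.airway_wd

    lung = right | left
    lung_slices = np.nonzero(lung.any(axis=(1, 2)))[0]
    weights = lung[lung_slices].sum(axis=(1, 2))
    targets = truth.regional_means
    if truth.posture == "prone":
        targets = targets[::-1]
    knots, knot_vals, profile, part = _solve_profile_knots(
        lung_slices, weights, targets
    )
    if profile.min() < 0 or profile.max() > 100:
        raise ValueError("regional means produce an LWD profile outside [0, 100]")
    for s, p in zip(lung_slices, profile):
        sl_mask = lung[s]
        wd[s][sl_mask] = p

    shading = truth.shading
    if shading is None:
        shading = _default_thorax_shading(shape, spacing)
    cfield = coil_shading_field(shape, spacing, shading)

    sig = cfield * wd / 100.0 * truth.s0
    if truth.noise_sd > 0:
        sig = sig + rng.normal(0.0, truth.noise_sd * truth.s0, size=shape)
    np.clip(sig, 0.0, None, out=sig)

    out = replace(truth)
    out.shading = shading
    out.wd_field = wd
    out.coil_field = cfield
    out.lung_profile = {
        "slices": lung_slices,
        "values": profile,
        "knots": knots,
        "knot_values": knot_vals,
        "partition": part,
    }
    return Volume(sig, spacing), LabelMask(labels, spacing), out


# ---------------------------------------------------------------------------
# 2D training slices for the segmentation network
# ---------------------------------------------------------------------------

#: in-plane upsampling factor taking the 3.5 mm grid to 1.3125 mm
TRAIN_ZOOM = 8.0 / 3.0
TRAIN_RESOLUTION_MM = 3.5 / TRAIN_ZOOM


def generate_training_slices(
    n_slices: int = 200,
    size: int = 96,
    seed: int = 0,
    lung_free_fraction: float = 0.2,
    noise_sd: float = 0.01,
):
    """Image/mask slice pairs for training the lung segmentation network.

    Coronal slices are drawn from randomized thorax phantoms, upsampled
    in-plane from 3.5 mm to ~1.31 mm (bilinear for the image, nearest for the
    mask) and cropped to ``size`` x ``size`` around a jittered lung-centred
    window. A ``lung_free_fraction`` of the pairs are body-only slices with
    empty masks so the model learns to emit nothing where there is no lung.

    Returns ``(images, masks, resolution_mm)`` with ``images`` of shape
    ``(n, size, size)`` and boolean ``masks``.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    images, masks = [], []
    n_lung_free = int(round(lung_free_fraction * n_slices))
    while len(images) < n_slices:
        jitter = rng.uniform(0.85, 1.15, size=6)
        truth = ThoraxTruth(
            shape=(48, 96, 96),
            regional_means=tuple(rng.uniform(14.0, 32.0, size=3)),
            posture=rng.choice(["supine", "prone"]),
            include_bones=False,  # easy geometry: ribs at 1.3 mm are nearly
            # isointense with lung and make the desk-scale task much harder
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            body_semiaxes=(0.46 * 48 * jitter[0], 0.48 * 96 * jitter[1],
                           0.48 * 96 * jitter[2]),
            right_lung_semiaxes=(0.31 * 48 * jitter[3], 0.20 * 96 * jitter[4],
                                 0.125 * 96 * jitter[5]),
        )
        vol, lab, _ = generate_thorax_phantom(truth)
        lung = lab.mask("right_lung") | lab.mask("left_lung")
        lung_slices = np.nonzero(lung.any(axis=(1, 2)))[0]
        body = lab.mask("body")
        body_only = [
            s for s in np.nonzero(body.any(axis=(1, 2)))[0]
            if s not in set(lung_slices) and body[s].mean() >= 0.2
        ]  # lung-free negatives come from anatomy-rich (abdomen-like) slices
        picks = rng.choice(lung_slices, size=min(28, len(lung_slices)), replace=False)
        want_free = max(0, n_lung_free - sum(1 for m in masks if not m.any()))
        free_picks = rng.choice(body_only, size=min(3, want_free, len(body_only)),
                                replace=False) if body_only else []
        for s in list(picks) + list(free_picks):
            img = ndimage.zoom(vol.data[s], TRAIN_ZOOM, order=1)
            msk = ndimage.zoom(lung[s].astype(np.uint8), TRAIN_ZOOM, order=0) > 0
            H, W = img.shape
            if msk.any():
                r0, c0 = (int(v.mean()) for v in np.nonzero(msk))
            else:
                r0, c0 = H // 2, W // 2
            r0 += int(rng.integers(-12, 13))
            c0 += int(rng.integers(-12, 13))
            r0 = np.clip(r0 - size // 2, 0, H - size)
            c0 = np.clip(c0 - size // 2, 0, W - size)
            images.append(img[r0: r0 + size, c0: c0 + size].astype(np.float64))
            masks.append(msk[r0: r0 + size, c0: c0 + size])
            if len(images) >= n_slices:
                break
    return np.stack(images), np.stack(masks), TRAIN_RESOLUTION_MM
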