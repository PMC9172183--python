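"""Vial-phantom validation: relative water density, agreement statistics.

Proton-density-weighted signal is proportional to mobile water content, so a
dilution series of water/heavy-water vials has known relative densities.
The analysis mirrors the standard validation protocol: mean signal in a disc
ROI per vial in a central slice (shrunk to avoid partial-volume effects),
relative density against the 100% vial, then ordinary least squares,
Bland–Altman bias and limits of agreement, and the two-way mixed-effects
absolute-agreement single-measure intraclass correlation ICC(A,1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic import VialLayout, default_vial_layout, generate_vial_phantom
from .volumes import Volume

__all__ = [
    "VialMeasurement",
    "AgreementStats",
    "extract_vial_means",
    "linear_agreement",
    "bland_altman",
    "icc_absolute_agreement",
    "run_phantom_experiment",
]


@dataclass(frozen=True)
class VialMeasurement:
    known_concentration: float
    mean_signal: float
    relative_density: float  # % of the 100%-water reference vial
    is_reference: bool


@dataclass
class AgreementStats:
    """Agreement between measured and known water densities."""

    bias: float                 # mean(measured - known), %
    sd: float                   # sample SD of differences, %
    loa_low: float              # bias - 1.96 sd
    loa_high: float             # bias + 1.96 sd
    icc: float
    slope: float
    intercept: float
    r_squared: float


def extract_vial_means(volume: Volume, layout: VialLayout,
                       roi_shrink: float = 0.8) -> list[VialMeasurement]:
    """Per-vial mean signal in the central slice and relative densities.

    ROIs are discs of ``roi_shrink`` times the vial radius, keeping clear of
    the vial wall (partial-volume margin). Relative density is
    ``100 * mean / mean(reference vial)``.
    """
    layout.validate()
    sl = layout.central_slice
    if not 0 <= sl < volume.shape[0]:
        raise ValueError("central slice outside the volume")
    nrow, ncol = volume.shape[1:]
    rr = (np.arange(nrow) * volume.spacing[1])[:, None]
    cc = (np.arange(ncol) * volume.spacing[2])[None, :]
    means = []
    for v in layout.vials:
        r = roi_shrink * v.radius_mm
        if (v.center_mm[0] - r < -volume.spacing[1] / 2
                or v.center_mm[0] + r > (nrow - 0.5) * volume.spacing[1]
                or v.center_mm[1] - r < -volume.spacing[2] / 2
                or v.center_mm[1] + r > (ncol - 0.5) * volume.spacing[2]):
            raise ValueError(f"ROI for vial at {v.center_mm} leaves the volume")
        disc = (rr - v.center_mm[0]) ** 2 + (cc - v.center_mm[1]) ** 2 <= r ** 2
        if not disc.any():
            raise ValueError(f"ROI for vial at {v.center_mm} contains no voxel")
        means.append(float(volume.data[sl][disc].mean()))
    ref = [m for m, v in zip(means, layout.vials) if v.is_reference]
    if not ref or ref[0] <= 0:
        raise ValueError("reference vial missing or has non-positive signal")
    out = []
    for m, v in zip(means, layout.vials):
        out.append(VialMeasurement(v.concentration, m, 100.0 * m / ref[0],
                                   v.is_reference))
    return out


def linear_agreement(known, measured) -> tuple[float, float, float]:
    """OLS of measured on known: (slope, intercept, Pearson r^2)."""
    known = np.asarray(known, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if known.shape != measured.shape or known.size < 3:
        raise ValueError("need equal-length lists of at least 3 points")
    if np.ptp(known) == 0:
        raise ValueError("known values have zero variance")
    fit = stats.linregress(known, measured)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


def bland_altman(a, b) -> tuple[float, float]:
    """Bias (mean of a-b) and sample SD of the differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length lists of at least 2 points")
    d = a - b
    return float(d.mean()), float(d.std(ddof=1))


def icc_absolute_agreement(x, y) -> float:
    """ICC(A,1): two-way mixed effects, absolute agreement, single measures.

    Computed from the ANOVA mean squares of the n x 2 table with rows =
    subjects (vials) and columns = raters (known, measured):

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))

    with MSR the row (subject), MSC the column (rater) and MSE the error
    mean square.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least 3 paired measurements")
    table = np.column_stack([x, y])
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0:
        raise ValueError("zero total variance; ICC undefined")
    return float((msr - mse) / denom)


def run_phantom_experiment(
    n_repeats: int = 3,
    layout: VialLayout | None = None,
    noise_sd: float = 0.02,
    seeds=(1, 2, 3),
    roi_shrink: float = 0.8,
) -> tuple[AgreementStats, list[float]]:
    """Simulate repeated phantom scans and compute agreement statistics.

    Generates ``n_repeats`` phantoms (one seed each), extracts relative
    densities, pools known-vs-measured pairs across repeats for the overall
    statistics, and reports per-repeat ICCs alongside. Returns
    ``(pooled AgreementStats, per-repeat ICC list)``.
    """
    if n_repeats < 1:
        raise ValueError("need at least one repeat")
    if len(seeds) < n_repeats:
        raise ValueError("need one seed per repeat")
    layout = layout or default_vial_layout()
    known_all, meas_all, per_repeat = [], [], []
    for rep in range(n_repeats):
        vol, _ = generate_vial_phantom(layout, noise_sd=noise_sd,
                                       seed=int(seeds[rep]))
        ms = extract_vial_means(vol, layout, roi_shrink)
        known = [m.known_concentration for m in ms]
        meas = [m.relative_density for m in ms]
        per_repeat.append(icc_absolute_agreement(known, meas))
        known_all += known
        meas_all += meas
    slope, intercept, r2 = linear_agreement(known_all, meas_all)
    bias, sd = bland_altman(meas_all, known_all)
    icc = icc_absolute_agreement(known_all, meas_all)
    stats_out = AgreementStats(
        bias=bias, sd=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        icc=icc, slope=slope, intercept=intercept, r_squared=r2,
    )
    return stats_out, per_repeat
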