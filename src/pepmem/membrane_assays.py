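"""Laurdan generalized polarization and FRET lipid-mixing / leakage assays.

The Laurdan probe emits near 440 nm in ordered (gel-like) bilayers and near
490 nm in disordered (fluid) bilayers; the generalized polarization

    GP = (I440 - I490) / (I440 + I490)

summarizes bilayer order on [-1, 1] (higher = more ordered / less fluid).

Lipid mixing is quantified against two anchors: F0, the initial residual
donor (NBD) fluorescence of the intact FRET-labelled vesicles, and F100, the
fluorescence after Triton X-100 solubilization (complete probe dilution):

    % mixing = 100 * (F - F0) / (F100 - F0)

The same normalization serves three assay variants: total lipid mixing,
inner-monolayer mixing (after dithionite reduction of outer-leaflet NBD;
F0/F100 must come from the dithionite-treated population) and ANTS/DPX
content leakage.  Percentages are not clamped -- values outside [0, 100] are
returned and flagged, since dequenching artifacts are diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import AnalysisConfig, Spectrum, TitrationSeries
from .errors import DegenerateInputError, FitError, WavelengthRangeError

__all__ = [
    "GPResult",
    "MixingResult",
    "SaturationFit",
    "laurdan_gp",
    "gp_from_spectrum",
    "mixing_percent",
    "mixing_curve",
    "saturation_estimate",
]

ASSAY_KINDS = ("total", "inner_monolayer", "leakage")


@dataclass(frozen=True)
class GPResult:
    """Band intensities and the generalized polarization computed from them."""

    i440: float
    i490: float
    gp: float


@dataclass(frozen=True)
class MixingResult:
    """Per-point mixing percentages for one assay variant.

    ``out_of_range`` flags points whose percentage falls outside [0, 100].
    """

    f0: float
    f100: float
    p_over_l: np.ndarray
    percent: np.ndarray
    assay: str
    out_of_range: np.ndarray


@dataclass(frozen=True)
class SaturationFit:
    """Monotone saturating (Hill) fit of a mixing curve.

    ``saturation_pl`` is the smallest P/L at which the fitted curve reaches
    95% of its plateau.  ``flat`` marks curves with no measurable extent
    (e.g. a leakage-free peptide), for which no saturation point exists.
    """

    plateau_percent: float
    saturation_pl: float
    hill_k: float
    hill_n: float
    flat: bool = False


def laurdan_gp(i440: float, i490: float) -> float:
    """Generalized polarization (I440 - I490)/(I440 + I490).

    Both intensities must be nonnegative and must not sum to zero.
    """
    i440, i490 = float(i440), float(i490)
    if i440 < 0 or i490 < 0:
        raise ValueError("band intensities must be nonnegative")
    denom = i440 + i490
    if denom == 0:
        raise DegenerateInputError("I440 + I490 is zero; GP is undefined")
    return (i440 - i490) / denom


def gp_from_spectrum(
    spectrum: Spectrum, config: AnalysisConfig | None = None
) -> GPResult:
    """Read the 440/490 nm band intensities off an emission spectrum and
    compute GP.

    The band rule is taken from ``config``: "interp" (default) interpolates
    at exactly the band centres; "window_max" takes the maximum within
    +/- ``band_window_nm`` of each centre.
    """
    cfg = config or AnalysisConfig()
    w_ord, w_dis = cfg.gp_band_ordered_nm, cfg.gp_band_disordered_nm
    if cfg.band_rule == "interp":
        i440 = spectrum.value_at(w_ord)
        i490 = spectrum.value_at(w_dis)
    else:
        half = cfg.band_window_nm
        if not spectrum.covers(w_ord - half, w_dis + half):
            raise WavelengthRangeError(
                "spectrum does not cover both band windows "
                f"[{w_ord - half}, {w_ord + half}] and [{w_dis - half}, {w_dis + half}] nm"
            )
        wl = spectrum.wavelengths_nm
        i440 = float(spectrum.values[np.abs(wl - w_ord) <= half].max())
        i490 = float(spectrum.values[np.abs(wl - w_dis) <= half].max())
    return GPResult(i440=i440, i490=i490, gp=laurdan_gp(i440, i490))


def mixing_percent(f: float, f0: float, f100: float) -> float:
    """Percent mixing 100*(F - F0)/(F100 - F0); not clamped to [0, 100]."""
    f, f0, f100 = float(f), float(f0), float(f100)
    if f100 == f0:
        raise DegenerateInputError("F100 equals F0; the 0-100% scale is degenerate")
    return 100.0 * (f - f0) / (f100 - f0)


def mixing_curve(
    series: TitrationSeries, f0: float, f100: float, assay: str = "total"
) -> MixingResult:
    """Normalize a fluorescence-vs-P/L series to per-point mixing percentages.

    For the inner-monolayer assay, ``f0``/``f100`` must be measured on the
    dithionite-treated vesicle population; for leakage, the identical 0-100%
    normalization is applied to ANTS dequenching.
    """
    if assay not in ASSAY_KINDS:
        raise ValueError(f"assay must be one of {ASSAY_KINDS}, got {assay!r}")
    if series.x_kind != "peptide_lipid_ratio":
        raise ValueError(
            f"mixing curves require x_kind='peptide_lipid_ratio', got {series.x_kind!r}"
        )
    percent = np.array([mixing_percent(f, f0, f100) for f in series.y])
    flags = (percent < 0.0) | (percent > 100.0)
    if np.any(flags):
        warnings.warn(
            f"{int(flags.sum())} mixing percentage(s) outside [0, 100]; "
            "possible dequenching artifact",
            stacklevel=2,
        )
    return MixingResult(
        f0=float(f0),
        f100=float(f100),
        p_over_l=series.x.copy(),
        percent=percent,
        assay=assay,
        out_of_range=flags,
    )


def _hill(x: np.ndarray, plateau: float, k: float, n: float) -> np.ndarray:
    xn = np.power(np.maximum(x, 0.0), n)
    return plateau * xn / (xn + k**n)


def saturation_estimate(
    result: MixingResult, *, plateau_threshold: float = 0.95
) -> SaturationFit:
    """Fit a monotone saturating Hill curve and locate the saturation P/L.

    The saturation P/L is the smallest ratio at which the fitted curve
    reaches ``plateau_threshold`` (default 95%) of its plateau.  Curves whose
    maximum extent stays below 1 percentage point are reported as flat with
    plateau = mean percent and no saturation point.
    """
    x, y = result.p_over_l, result.percent
    if x.size < 4:
        raise FitError("saturation fit requires at least 4 curve points")
    if float(np.nanmax(y)) < 1.0:
        return SaturationFit(
            plateau_percent=float(np.mean(y)),
            saturation_pl=float("nan"),
            hill_k=float("nan"),
            hill_n=float("nan"),
            flat=True,
        )
    ymax = float(np.nanmax(y))
    xpos = x[x > 0]
    if xpos.size == 0:
        raise FitError("saturation fit requires positive P/L values")
    # half-rise initial guess for K
    above = x[y >= 0.5 * ymax]
    k0 = float(above[0]) if above.size else float(np.median(xpos))
    try:
        popt, _ = curve_fit(
            _hill,
            x,
            y,
            p0=(ymax, k0, 2.0),
            bounds=([0.0, xpos.min() / 100.0, 0.5], [2.0 * ymax + 10.0, xpos.max() * 100.0, 8.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise FitError(f"Hill fit did not converge: {exc}") from exc
    plateau, k, n = (float(p) for p in popt)
    t = plateau_threshold
    saturation = k * (t / (1.0 - t)) ** (1.0 / n)
    return SaturationFit(
        plateau_percent=plateau, saturation_pl=saturation, hill_k=k, hill_n=n
    )
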