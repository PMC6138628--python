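"""Tryptophan-fluorescence binding analysis and acrylamide quenching.

Peptide binding to lipid vesicles is treated as a surface partition
equilibrium

    X_b = K_p * C_f,

where X_b is mol bound peptide per mol total lipid, C_f the free peptide
concentration (M) and K_p the apparent partition coefficient (M^-1).
Because an externally added peptide initially sees only the outer leaflet
(~60% of the lipid in small vesicles), X_b is corrected to
X_b* = X_b / outer_fraction and the binding isotherm is X_b* vs C_f.  K_p
is the initial slope of that isotherm, extrapolated to C_f -> 0 so that
surface self-association at higher coverage does not bias the estimate.

The bound fraction comes from the tryptophan fluorescence enhancement,
f_b = (F - F0)/(F_inf - F0), with F_inf (fluorescence at complete binding)
extrapolated from a double-reciprocal plot of fluorescence against the
outer-leaflet lipid concentration.

Tryptophan accessibility to the aqueous quencher acrylamide follows the
Stern-Volmer law F0/F = 1 + K_sv [Q]; a smaller K_sv means a more deeply
buried tryptophan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import AnalysisConfig, Spectrum, TitrationSeries
from .errors import (
    DegenerateInputError,
    ExtrapolationError,
    FitError,
    InsufficientDataError,
)

__all__ = [
    "BindingIsotherm",
    "PartitionFit",
    "SternVolmerFit",
    "blue_shift",
    "dilution_correct",
    "estimate_f_inf",
    "bound_fraction",
    "inverse_bound_fraction",
    "build_isotherm",
    "partition_coefficient",
    "stern_volmer_fit",
]


@dataclass(frozen=True)
class BindingIsotherm:
    """(C_f, X_b*) points plus the quantities they were derived from.

    ``flagged`` marks points whose bound fraction fell outside [0, 1]
    (possible with noisy data); they are kept, not discarded.
    """

    c_f: np.ndarray  # M free peptide
    x_b_star: np.ndarray  # mol bound peptide / mol outer-leaflet lipid
    f_b: np.ndarray
    x_b: np.ndarray
    f0: float
    f_inf: float
    peptide_total: float
    outer_fraction: float
    flagged: np.ndarray

    def __len__(self) -> int:
        return self.c_f.size


@dataclass(frozen=True)
class PartitionFit:
    """Initial-slope partition coefficient with fit diagnostics."""

    kp: float  # M^-1
    n_points_used: int
    slope_se: float
    r_squared: float


@dataclass(frozen=True)
class SternVolmerFit:
    """Origin-constrained Stern-Volmer constant with free-intercept diagnostic.

    ``intercept`` is the intercept of the unconstrained F0/F vs [Q] line and
    should be 1 for well-behaved data.
    """

    ksv: float  # M^-1
    intercept: float
    r_squared: float


def _peak_wavelength(spectrum: Spectrum) -> float:
    """Sub-grid emission maximum via a local parabola through 3 grid points."""
    y = spectrum.values
    if np.ptp(y) == 0:
        raise DegenerateInputError(
            f"spectrum {spectrum.label!r} is flat; no unique emission maximum"
        )
    i = int(np.argmax(y))
    wl = spectrum.wavelengths_nm
    if i == 0 or i == y.size - 1:
        return float(wl[i])
    a, b, c = np.polyfit(wl[i - 1 : i + 2], y[i - 1 : i + 2], 2)
    if a == 0:
        return float(wl[i])
    return float(-b / (2.0 * a))


def blue_shift(spectrum_free: Spectrum, spectrum_bound: Spectrum) -> float:
    """Emission-maximum shift lambda_max(free) - lambda_max(bound), in nm.

    Positive values indicate a blue shift of the bound spectrum, i.e. the
    tryptophan moving into a less polar (membrane) environment.  Peak
    positions are refined to sub-grid resolution with a local parabola,
    since membrane-induced shifts can be smaller than the sampling step.
    """
    return _peak_wavelength(spectrum_free) - _peak_wavelength(spectrum_bound)


def dilution_correct(f_raw: float, v0: float, v_added: float) -> float:
    """Correct a raw intensity for titration dilution: F * (V0 + Vadd)/V0."""
    v0, v_added = float(v0), float(v_added)
    if v0 <= 0:
        raise ValueError("initial volume must be positive")
    if v_added < 0:
        raise ValueError("added volume must be nonnegative")
    return float(f_raw) * (v0 + v_added) / v0


def estimate_f_inf(
    lipid_total,
    f,
    outer_fraction: float = 0.6,
    *,
    mode: str = "total",
    f0: float | None = None,
    weights: str = "uniform",
) -> float:
    """Extrapolate F_inf, the fluorescence at complete binding.

    Least squares on the double-reciprocal plot against the outer-leaflet
    lipid concentration L' = outer_fraction * L_total:

    - ``mode="total"`` (default, literal reading): 1/F vs 1/L';
      F_inf = 1/intercept.
    - ``mode="delta"``: 1/(F - F0) vs 1/L'; F_inf = F0 + 1/intercept.
      Exactly linear when binding follows a hyperbolic saturation on top of
      a free-peptide baseline F0.

    ``weights="uniform"`` is ordinary least squares.  ``weights="response"``
    applies inverse-variance weights w = R^4 / F^2 (R the reciprocal-plot
    response), appropriate when fluorescence carries a constant *relative*
    error: reciprocal transforms otherwise hand the noisiest low-signal
    points the greatest leverage, which is the classic double-reciprocal
    pathology.  Both give identical answers on noiseless data.

    A non-positive intercept (extrapolation pointing the wrong way) raises
    :class:`ExtrapolationError`; a negative slope (fluorescence decreasing
    with lipid) only warns.
    """
    L = np.asarray(lipid_total, dtype=float)
    F = np.asarray(f, dtype=float)
    if L.shape != F.shape or L.ndim != 1:
        raise ValueError("lipid_total and f must be 1-D arrays of equal length")
    keep = L > 0
    L, F = L[keep], F[keep]
    if L.size < 3:
        raise InsufficientDataError(
            "F_inf extrapolation requires at least 3 points with lipid > 0"
        )
    if mode == "total":
        resp = F
        baseline = 0.0
    elif mode == "delta":
        if f0 is None:
            raise ValueError("mode='delta' requires f0")
        resp = F - float(f0)
        baseline = float(f0)
        if np.any(resp <= 0):
            raise ValueError("mode='delta' requires F > F0 at every lipid point")
    else:
        raise ValueError("mode must be 'total' or 'delta'")
    if np.any(resp <= 0):
        raise ValueError("fluorescence must be positive for the reciprocal plot")
    x = 1.0 / (float(outer_fraction) * L)
    y = 1.0 / resp
    if weights == "uniform":
        slope, intercept = np.polyfit(x, y, 1)
    elif weights == "response":
        w = resp**4 / F**2
        wsum = float(np.sum(w))
        xbar = float(np.sum(w * x)) / wsum
        ybar = float(np.sum(w * y)) / wsum
        slope = float(np.sum(w * (x - xbar) * (y - ybar))) / float(
            np.sum(w * (x - xbar) ** 2)
        )
        intercept = ybar - slope * xbar
    else:
        raise ValueError("weights must be 'uniform' or 'response'")
    slope_scale = float(np.max(np.abs(y))) / float(np.max(np.abs(x)))
    if slope < -1e-12 * slope_scale:
        warnings.warn(
            "fluorescence decreases with lipid (negative double-reciprocal "
            "slope); F_inf extrapolation may be unreliable",
            stacklevel=2,
        )
    if intercept <= 0:
        raise ExtrapolationError(
            f"double-reciprocal intercept {intercept:.3g} is not positive; "
            "F_inf extrapolation failed"
        )
    return baseline + 1.0 / float(intercept)


def bound_fraction(f: float, f0: float, f_inf: float) -> float:
    """Fraction of membrane-bound peptide f_b = (F - F0)/(F_inf - F0).

    Values outside [0, 1] are returned as-is (callers flag them).
    """
    f, f0, f_inf = float(f), float(f0), float(f_inf)
    if f_inf == f0:
        raise DegenerateInputError("F_inf equals F0; bound fraction is undefined")
    return (f - f0) / (f_inf - f0)


def inverse_bound_fraction(f_b: float, f0: float, f_inf: float) -> float:
    """Fluorescence corresponding to a bound fraction: F0 + f_b*(F_inf - F0)."""
    return float(f0) + float(f_b) * (float(f_inf) - float(f0))


def build_isotherm(
    series: TitrationSeries,
    peptide_total: float,
    f0: float,
    f_inf: float,
    outer_fraction: float = 0.6,
) -> BindingIsotherm:
    """Convert a lipid titration into a binding isotherm (C_f, X_b*).

    Per point: f_b from the fluorescence enhancement; bound peptide
    f_b * P_total; C_f = (1 - f_b) * P_total; X_b = bound / L_total;
    X_b* = X_b / outer_fraction.  Points at zero lipid are skipped (X_b is
    undefined there).
    """
    if series.x_kind != "lipid_conc":
        raise ValueError(
            f"isotherms require x_kind='lipid_conc', got {series.x_kind!r}"
        )
    P = float(peptide_total)
    if P <= 0:
        raise ValueError("peptide_total must be positive")
    if not (0.0 < outer_fraction <= 1.0):
        raise ValueError("outer_fraction must be in (0, 1]")
    keep = series.x > 0
    L = series.x[keep]
    F = series.y[keep]
    if L.size == 0:
        raise InsufficientDataError("no points with lipid > 0")
    f_b = np.array([bound_fraction(f, f0, f_inf) for f in F])
    flagged = (f_b < 0.0) | (f_b > 1.0)
    bound = f_b * P
    c_f = (1.0 - f_b) * P
    x_b = bound / L
    x_b_star = x_b / float(outer_fraction)
    return BindingIsotherm(
        c_f=c_f,
        x_b_star=x_b_star,
        f_b=f_b,
        x_b=x_b,
        f0=float(f0),
        f_inf=float(f_inf),
        peptide_total=P,
        outer_fraction=float(outer_fraction),
        flagged=flagged,
    )


def partition_coefficient(
    isotherm: BindingIsotherm, config: AnalysisConfig | None = None
) -> PartitionFit:
    """Apparent partition coefficient K_p from the isotherm's initial slope.

    Selection rule: points with C_f <= ``initial_region_fraction`` (default
    30%) of the maximum observed C_f; if fewer than ``initial_min_points``
    qualify, the ``initial_fallback_points`` smallest-C_f points are used
    instead.  The line is constrained through the origin (X_b* = K_p * C_f
    has no intercept).
    """
    cfg = config or AnalysisConfig()
    c = np.asarray(isotherm.c_f, dtype=float)
    y = np.asarray(isotherm.x_b_star, dtype=float)
    if np.all(y == 0):
        raise FitError("isotherm is identically zero (zero-slope); no binding signal")
    if np.unique(c).size < 3:
        raise InsufficientDataError(
            "partition fit requires at least 3 isotherm points with distinct C_f"
        )
    cut = cfg.initial_region_fraction * float(np.max(c))
    sel = c <= cut
    if int(sel.sum()) < cfg.initial_min_points:
        order = np.argsort(c)
        take = min(cfg.initial_fallback_points, c.size)
        sel = np.zeros_like(sel)
        sel[order[:take]] = True
    cs, ys = c[sel], y[sel]
    sxx = float(np.sum(cs * cs))
    if sxx == 0:
        raise FitError("all selected C_f values are zero; cannot fit a slope")
    slope = float(np.sum(cs * ys)) / sxx
    if slope <= 0:
        raise FitError(
            f"initial slope {slope:.3g} is not positive (zero-slope isotherm?)"
        )
    resid = ys - slope * cs
    n = cs.size
    se = float(np.sqrt(np.sum(resid**2) / max(n - 1, 1) / sxx))
    sst = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    return PartitionFit(kp=slope, n_points_used=int(n), slope_se=se, r_squared=r2)


def stern_volmer_fit(
    series: TitrationSeries,
    f0: float | None = None,
    config: AnalysisConfig | None = None,
) -> SternVolmerFit:
    """Stern-Volmer constant K_sv from an acrylamide quenching titration.

    Primary fit: least squares of (F0/F - 1) against [Q], constrained
    through the origin (the Stern-Volmer law has intercept exactly 1).  The
    unconstrained F0/F vs [Q] line is also fitted and its intercept reported
    as a diagnostic.  If ``f0`` is not supplied, the series must include a
    [Q] = 0 point (replicates at zero are averaged).
    """
    cfg = config or AnalysisConfig()
    if series.x_kind != "quencher_conc":
        raise ValueError(
            f"Stern-Volmer fits require x_kind='quencher_conc', got {series.x_kind!r}"
        )
    q = series.x
    F = series.y
    if np.any(F <= 0):
        raise ValueError("all fluorescence values must be positive")
    series.require_points(3, "Stern-Volmer fit")
    if float(np.max(q)) > cfg.sv_max_quencher_M:
        warnings.warn(
            f"quencher concentration exceeds the configured maximum "
            f"{cfg.sv_max_quencher_M} M; inner-filter artifacts likely",
            stacklevel=2,
        )
    if f0 is None:
        zero = q == 0
        if not np.any(zero):
            raise ValueError("supply f0 or include a [Q] = 0 point")
        f0 = float(np.mean(F[zero]))
    f0 = float(f0)
    ratio = f0 / F
    y = ratio - 1.0
    sxx = float(np.sum(q * q))
    if sxx == 0:
        raise InsufficientDataError("need at least one point with [Q] > 0")
    ksv = float(np.sum(q * y)) / sxx
    free_slope, free_intercept = np.polyfit(q, ratio, 1)
    resid = y - ksv * q
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    return SternVolmerFit(ksv=ksv, intercept=float(free_intercept), r_squared=r2)
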