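"""Inside/outside-vessel fluorescence quantification of tissue images.

The quantification unit is the integrated density, the product of mean
fluorescence over a region of interest and the ROI area in um^2.  A brain
slice image with a (caller-supplied) binary vessel mask is split into an
inbound compartment (the vessels themselves) and an outbound compartment
(thresholded signal outside the vessels, i.e. peptide that crossed the
barrier into the parenchyma).  A calibration curve mapping known peptide
amounts to integrated density -- linear, or the 4-parameter logistic used
by ImageJ's "Rodbard" function -- converts densities back to amounts and
hence to percent of the administered dose delivered.

Masks are boolean arrays on a row-major, 0-based (row, col) pixel grid;
vessel segmentation itself is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, FitError, OutOfRangeError

__all__ = [
    "VesselImage",
    "IntegratedDensity",
    "CalibrationCurve",
    "threshold_nonzero",
    "integrated_density",
    "inside_outside_split",
    "fit_calibration",
    "predict_density",
    "invert_calibration",
    "percent_delivered",
]


@dataclass(frozen=True)
class VesselImage:
    """A grayscale image plus its binary vessel mask and pixel size."""

    pixels: np.ndarray  # 2-D, nonnegative, arbitrary units
    vessel_mask: np.ndarray  # 2-D boolean, same shape
    pixel_area_um2: float
    label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        mask = np.asarray(self.vessel_mask, dtype=bool)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if mask.shape != px.shape:
            raise ValueError(
                f"vessel mask shape {mask.shape} != image shape {px.shape}"
            )
        if np.any(px < 0):
            raise ValueError("pixel intensities must be nonnegative")
        if self.pixel_area_um2 <= 0:
            raise ValueError("pixel_area_um2 must be positive")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "vessel_mask", mask)


@dataclass(frozen=True)
class IntegratedDensity:
    """Mean fluorescence, ROI area (um^2) and their product."""

    mean_fluorescence: float
    area_um2: float
    integrated_density: float


@dataclass(frozen=True)
class CalibrationCurve:
    """Amount -> integrated density calibration.

    For ``model="linear"``: density = slope * amount + intercept.  For
    ``model="rodbard"`` (4-parameter logistic): density =
    d + (a - d) / (1 + (amount/c)^b), with parameters in ``params``.
    """

    amounts: np.ndarray
    densities: np.ndarray
    slope: float
    intercept: float
    r2: float
    model: str
    params: dict | None = None


def _estimate_mode(values: np.ndarray, bins: int = 256) -> float:
    hist, edges = np.histogram(values, bins=bins)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))


def threshold_nonzero(
    image: VesselImage, method: str = "positive", floor: float | str = 0.0
) -> np.ndarray:
    """Boolean mask of signal pixels ("non-zero thresholding").

    ``method="positive"`` keeps pixels strictly above ``floor`` (a number,
    or ``"mode"`` to use the image's histogram mode as the background
    level).  ``method="otsu"`` keeps pixels above the Otsu threshold.  An
    image with no signal yields an empty mask with a warning, not an error.
    """
    px = image.pixels
    if method == "positive":
        level = _estimate_mode(px) if floor == "mode" else float(floor)
        mask = px > level
    elif method == "otsu":
        if np.ptp(px) == 0:
            mask = np.zeros_like(px, dtype=bool)
        else:
            mask = px > threshold_otsu(px)
    else:
        raise ValueError(f"method must be 'positive' or 'otsu', got {method!r}")
    if not mask.any():
        warnings.warn("thresholding produced an empty mask", stacklevel=2)
    return mask


def integrated_density(image: VesselImage, roi: np.ndarray) -> IntegratedDensity:
    """Integrated density over an ROI: mean fluorescence x ROI area (um^2)."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.pixels.shape:
        raise ValueError("ROI shape must match the image")
    n = int(roi.sum())
    if n == 0:
        raise DegenerateInputError("ROI is empty; integrated density undefined")
    mean = float(image.pixels[roi].mean())
    area = n * float(image.pixel_area_um2)
    return IntegratedDensity(
        mean_fluorescence=mean, area_um2=area, integrated_density=mean * area
    )


def inside_outside_split(
    image: VesselImage,
    threshold_method: str = "positive",
    floor: float | str = 0.0,
) -> tuple[IntegratedDensity, IntegratedDensity]:
    """Split image fluorescence into inbound (vessel) and outbound parts.

    Inside = integrated density over the vessel mask.  Outside = integrated
    density over thresholded signal pixels outside the vessels, i.e. with
    both vessels and background excluded.  An outside compartment with no
    signal pixels yields a zero density.
    """
    vm = image.vessel_mask
    n_vessel = int(vm.sum())
    if n_vessel == 0 or n_vessel == vm.size:
        raise DegenerateInputError(
            "vessel mask must be nonempty and must not cover the whole frame"
        )
    inside = integrated_density(image, vm)
    tmask = threshold_nonzero(image, method=threshold_method, floor=floor)
    outside_roi = tmask & ~vm
    if not outside_roi.any():
        outside = IntegratedDensity(0.0, 0.0, 0.0)
    else:
        outside = integrated_density(image, outside_roi)
    return inside, outside


def _rodbard(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    # errstate: the optimizer may probe negative b/c, where 0^b overflows
    with np.errstate(invalid="ignore", divide="ignore"):
        return d + (a - d) / (1.0 + np.power(np.maximum(x, 0.0) / c, b))


def fit_calibration(amounts, densities, model: str = "linear") -> CalibrationCurve:
    """Fit an amount -> integrated density calibration curve.

    ``model``: "linear" (>= 3 points), "rodbard" (4PL, >= 5 points), or
    "auto" (linear if its r^2 >= 0.99, matching the expectation that
    slide-spot calibrations are linear; otherwise rodbard).
    """
    x = np.asarray(amounts, dtype=float)
    y = np.asarray(densities, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("amounts and densities must be 1-D arrays of equal length")
    if np.unique(x).size < 2:
        raise ValueError("calibration amounts are degenerate (all equal)")

    def _linear() -> CalibrationCurve:
        if x.size < 3:
            raise ValueError("linear calibration requires at least 3 points")
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
        return CalibrationCurve(
            amounts=x.copy(),
            densities=y.copy(),
            slope=float(slope),
            intercept=float(intercept),
            r2=float(r2),
            model="linear",
        )

    if model == "linear":
        return _linear()
    if model == "auto":
        lin = _linear()
        if lin.r2 >= 0.99 or x.size < 5:
            return lin
        model = "rodbard"
    if model != "rodbard":
        raise ValueError(f"model must be 'linear', 'rodbard' or 'auto', got {model!r}")
    if x.size < 5:
        raise ValueError("rodbard calibration requires at least 5 points")
    # init: a = response near zero amount, d = response at large amount,
    # c = mid-range amount, b = 1 (documented initialization)
    order = np.argsort(x)
    a0, d0 = float(y[order[0]]), float(y[order[-1]])
    xpos = x[x > 0]
    c0 = float(np.median(xpos)) if xpos.size else 1.0
    try:
        popt, _ = curve_fit(
            _rodbard,
            x,
            y,
            p0=(a0, 1.0, c0, d0),
            maxfev=50000,
        )
    except RuntimeError as exc:
        raise FitError(
            f"rodbard (4PL) calibration did not converge: {exc}"
        ) from exc
    a, b, c, d = (float(p) for p in popt)
    resid = y - _rodbard(x, a, b, c, d)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    return CalibrationCurve(
        amounts=x.copy(),
        densities=y.copy(),
        slope=float("nan"),
        intercept=float("nan"),
        r2=float(r2),
        model="rodbard",
        params={"a": a, "b": b, "c": c, "d": d},
    )


def predict_density(calibration: CalibrationCurve, amount: float) -> float:
    """Predicted integrated density at a given amount."""
    if calibration.model == "linear":
        return calibration.slope * float(amount) + calibration.intercept
    p = calibration.params or {}
    return float(_rodbard(np.asarray([amount], float), **p)[0])


def invert_calibration(calibration: CalibrationCurve, density: float) -> float:
    """Amount corresponding to an integrated density."""
    yv = float(density)
    if calibration.model == "linear":
        if calibration.slope == 0:
            raise DegenerateInputError("zero calibration slope is not invertible")
        return (yv - calibration.intercept) / calibration.slope
    p = calibration.params or {}
    a, b, c, d = p["a"], p["b"], p["c"], p["d"]
    lo, hi = (a, d) if a < d else (d, a)
    if not (lo < yv < hi):
        raise OutOfRangeError(
            f"density {yv:.4g} outside the invertible range ({lo:.4g}, {hi:.4g}) "
            "of the rodbard calibration"
        )
    return float(c * ((a - d) / (yv - d) - 1.0) ** (1.0 / b))


def percent_delivered(
    density: IntegratedDensity | float,
    calibration: CalibrationCurve,
    administered_amount: float,
) -> float:
    """Percent of the administered amount recovered in an image.

    The measured integrated density is inverse-calibrated to an amount and
    expressed as a percentage of ``administered_amount`` (which must be in
    the calibration's amount units).
    """
    if administered_amount <= 0:
        raise ValueError("administered_amount must be positive")
    val = getattr(density, "integrated_density", density)
    amount = invert_calibration(calibration, float(val))
    return 100.0 * amount / float(administered_amount)
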