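"""End-to-end synthetic round trips: generate -> analyze -> recover.

These helpers wire the generators to the analysis stages exactly the way a
real experiment would be processed, and are what the recovery tests and the
acceptance script run.  Two conventions used throughout (see the methods
note): the free-peptide / quencher-free reference intensity F0 is treated
as known (it is a separate, precisely measured reference, not one noisy
titration point), and F_inf is extrapolated with the delta double-reciprocal
(1/(F - F0) vs 1/L'), which is exactly linear for a hyperbolic binding curve
on top of a baseline.
"""

from __future__ import annotations

import warnings

import numpy as np

from .binding import build_isotherm, estimate_f_inf, partition_coefficient, stern_volmer_fit
from .cd_analysis import HelixEstimate, analyze_cd
from .imaging_quant import (
    fit_calibration,
    inside_outside_split,
    integrated_density,
    percent_delivered,
    threshold_nonzero,
)
from .membrane_assays import SaturationFit, gp_from_spectrum, mixing_curve, saturation_estimate
from .synthetic_data import (
    NO_NOISE,
    ConditionPreset,
    NoiseModel,
    gen_brain_image,
    gen_cd_spectrum,
    gen_laurdan_spectrum,
    gen_mixing_series,
    gen_quenching_series,
    gen_trp_titration,
    get_preset,
)

__all__ = [
    "recover_gp",
    "recover_kp",
    "recover_ksv",
    "recover_helix",
    "recover_mixing",
    "recover_leakage_max",
    "recover_split_percent",
    "recover_dose_series",
    "run_condition",
]


def recover_gp(gp_true: float, noise: NoiseModel = NO_NOISE, seed: int = 0) -> float:
    """Generate a Laurdan spectrum at a true GP and read the GP back."""
    spec, _ = gen_laurdan_spectrum(gp_true, noise=noise, seed=seed)
    return gp_from_spectrum(spec).gp


def recover_kp(
    kp_true: float,
    noise: NoiseModel = NO_NOISE,
    seed: int = 0,
    *,
    peptide_total: float = 4e-6,
    f0: float = 100.0,
    f_inf_true: float = 300.0,
    outer_fraction: float = 0.6,
) -> float:
    """Full partition pipeline: titration -> F_inf -> isotherm -> K_p."""
    series, _ = gen_trp_titration(
        kp_true,
        peptide_total=peptide_total,
        f0=f0,
        f_inf_true=f_inf_true,
        outer_fraction=outer_fraction,
        noise=noise,
        seed=seed,
    )
    f_inf = estimate_f_inf(
        series.x, series.y, outer_fraction, mode="delta", f0=f0, weights="response"
    )
    isotherm = build_isotherm(series, peptide_total, f0, f_inf, outer_fraction)
    return partition_coefficient(isotherm).kp


def recover_ksv(
    ksv_true: float, noise: NoiseModel = NO_NOISE, seed: int = 0, *, f0: float = 100.0
) -> float:
    """Quenching pipeline: Stern-Volmer series -> origin-constrained K_sv."""
    series, _ = gen_quenching_series(ksv_true, f0=f0, noise=noise, seed=seed)
    return stern_volmer_fit(series, f0=f0).ksv


def recover_helix(
    fH_true: float,
    ratio_target: float,
    noise: NoiseModel = NO_NOISE,
    seed: int = 0,
    *,
    n_res: int = 20,
    convention: str = "unscaled",
    conc_M: float = 8e-6,
    path_cm: float = 0.1,
) -> HelixEstimate:
    """CD pipeline: raw mdeg spectrum -> MRE -> helicity and oligomer state."""
    spec, _ = gen_cd_spectrum(
        fH_true,
        ratio_target=ratio_target,
        n_res=n_res,
        convention=convention,
        conc_M=conc_M,
        path_cm=path_cm,
        noise=noise,
        seed=seed,
    )
    return analyze_cd(spec, path_cm, conc_M, n_res, convention)


def recover_mixing(
    saturation_pl: float,
    plateau_percent: float,
    noise: NoiseModel = NO_NOISE,
    seed: int = 0,
    *,
    assay: str = "total",
    f0: float = 10.0,
    f100: float = 110.0,
) -> SaturationFit:
    """Mixing pipeline: F-vs-P/L series -> percent curve -> saturation fit."""
    series, _ = gen_mixing_series(
        saturation_pl, plateau_percent, f0=f0, f100=f100, noise=noise, seed=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # noise excursions past 0/100
        result = mixing_curve(series, f0, f100, assay=assay)
    return saturation_estimate(result)


def recover_leakage_max(
    noise: NoiseModel = NO_NOISE,
    seed: int = 0,
    *,
    saturation_pl: float = 0.05,
    f0: float = 10.0,
    f100: float = 110.0,
) -> float:
    """Largest absolute leakage percentage seen for a leakage-free peptide."""
    series, _ = gen_mixing_series(
        saturation_pl, 0.0, f0=f0, f100=f100, noise=noise, seed=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # noise excursions past 0
        result = mixing_curve(series, f0, f100, assay="leakage")
    return float(np.max(np.abs(result.percent)))


def recover_split_percent(
    inside_amount: float = 7.0,
    outside_amount: float = 3.0,
    seed: int = 0,
    *,
    background_sigma: float = 0.02,
    calibration_slope: float = 1000.0,
) -> float:
    """Imaging pipeline: render a field of view, return % fluorescence inside.

    The signal floor is set to 5x the background noise level so background
    pixels do not accumulate into the outside compartment.
    """
    image, _ = gen_brain_image(
        inside_amount=inside_amount,
        outside_amount=outside_amount,
        calibration_slope=calibration_slope,
        background_sigma=background_sigma,
        seed=seed,
    )
    inside, outside = inside_outside_split(
        image, threshold_method="positive", floor=5.0 * background_sigma
    )
    total = inside.integrated_density + outside.integrated_density
    return 100.0 * inside.integrated_density / total


def recover_dose_series(
    doses=(10.0, 20.0, 40.0),
    efficiencies=(0.30, 0.20, 0.10),
    seed: int = 0,
    *,
    calibration_slope: float = 1000.0,
    background_sigma: float = 0.02,
) -> list[float]:
    """Percent delivered for a dose series with dose-dependent efficiency.

    Each dose is imaged with total delivered amount efficiency*dose; the
    total thresholded-image density is inverse-calibrated against a linear
    spotted-slide calibration to a recovered amount and expressed as a
    percentage of the dose.  Emulates the finding that lower doses deliver
    a higher fraction of the administered peptide.
    """
    amounts = np.linspace(0.0, 30.0, 7)
    cal = fit_calibration(amounts, calibration_slope * amounts, model="linear")
    out = []
    for i, (dose, eff) in enumerate(zip(doses, efficiencies)):
        delivered = eff * dose
        image, _ = gen_brain_image(
            inside_amount=0.7 * delivered,
            outside_amount=0.3 * delivered,
            calibration_slope=calibration_slope,
            background_sigma=background_sigma,
            seed=seed + i,
        )
        tmask = threshold_nonzero(image, floor=5.0 * background_sigma)
        dens = integrated_density(image, tmask)
        out.append(percent_delivered(dens, cal, dose))
    return out


def run_condition(
    label: str, noise: NoiseModel = NO_NOISE, seed: int = 0
) -> dict:
    """Run every applicable stage for one condition preset.

    Returns a dict with whichever of gp (a dict per sub-condition), kp,
    ksv, helix_fraction, ratio_222_208, state, saturation_pl,
    inner_plateau and leakage_max the preset defines.
    """
    preset: ConditionPreset = get_preset(label)
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(2**31))  # noqa: E731
    out: dict = {"label": label}
    if preset.gp is not None:
        out["gp"] = {
            k: recover_gp(v, noise=noise, seed=sub()) for k, v in preset.gp.items()
        }
    if preset.kp is not None:
        out["kp"] = recover_kp(preset.kp, noise=noise, seed=sub())
    if preset.ksv is not None:
        out["ksv"] = recover_ksv(preset.ksv, noise=noise, seed=sub())
    if preset.helix_fraction is not None:
        est = recover_helix(
            preset.helix_fraction, preset.ratio_222_208, noise=noise, seed=sub()
        )
        out["helix_fraction"] = est.helix_fraction
        out["ratio_222_208"] = est.ratio_222_208
        out["state"] = est.state
    if preset.saturation_pl is not None:
        fit = recover_mixing(
            preset.saturation_pl, preset.total_plateau, noise=noise, seed=sub()
        )
        out["saturation_pl"] = fit.saturation_pl
        inner = recover_mixing(
            preset.saturation_pl,
            preset.inner_plateau,
            noise=noise,
            seed=sub(),
            assay="inner_monolayer",
        )
        out["inner_plateau"] = inner.plateau_percent
        out["leakage_max"] = recover_leakage_max(
            noise=noise, seed=sub(), saturation_pl=preset.saturation_pl
        )
    return out
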