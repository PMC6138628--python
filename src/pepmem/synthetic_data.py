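"""Ground-truth synthetic data generators for every analysis stage.

Each generator is a pure function of its parameters and a seed, returning a
data object in the exact form the analysis modules consume plus a
:class:`GeneratorTruth` sidecar carrying the true parameters.  Truth never
leaks into the data itself, so round-trip tests exercise the real analysis
path.

Condition presets ("BBB", "liver", "buffer") bundle stage truths for
the experimental conditions the package models: membrane-order GP values, partition
coefficients of 4.24e4 / 1.55e3 M^-1, Stern-Volmer constants of
10.21 / 2.05 / 3.04 M^-1 (buffer / BBB / liver), helicities of 58% / 40%
with theta222/theta208 ratios 0.68 / 0.45, fusion saturating at P/L 0.05 /
0.7 with inner-monolayer plateaus of 20% / 100%, and zero content leakage.

Default noise is multiplicative Gaussian (sigma = 2%) on fluorescence and
additive Gaussian on images, emulating photodetector-style noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from scipy.optimize import brentq
from skimage.morphology import disk

from .core import Spectrum, TitrationSeries
from .errors import GeneratorError
from .imaging_quant import VesselImage

__all__ = [
    "NoiseModel",
    "NO_NOISE",
    "multiplicative_noise",
    "additive_noise",
    "GeneratorTruth",
    "ConditionPreset",
    "PRESETS",
    "get_preset",
    "gen_laurdan_spectrum",
    "gen_mixing_series",
    "gen_trp_titration",
    "default_lipid_grid",
    "gen_quenching_series",
    "gen_cd_spectrum",
    "gen_brain_image",
]


@dataclass(frozen=True)
class NoiseModel:
    """Noise applied to generated signals.

    ``kind`` is one of ``none``, ``multiplicative-gaussian`` (each value
    scaled by 1 + N(0, sigma)) or ``additive-gaussian`` (N(0, sigma) added).
    """

    kind: str = "none"
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "multiplicative-gaussian", "additive-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def apply(self, rng: np.random.Generator, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "none" or self.sigma == 0.0:
            return values.copy()
        if self.kind == "multiplicative-gaussian":
            return values * (1.0 + rng.normal(0.0, self.sigma, values.shape))
        return values + rng.normal(0.0, self.sigma, values.shape)


NO_NOISE = NoiseModel()


def multiplicative_noise(sigma: float = 0.02) -> NoiseModel:
    return NoiseModel(kind="multiplicative-gaussian", sigma=sigma)


def additive_noise(sigma: float) -> NoiseModel:
    return NoiseModel(kind="additive-gaussian", sigma=sigma)


@dataclass(frozen=True)
class GeneratorTruth:
    """Sidecar record of the true parameters behind a synthetic dataset."""

    stage: str
    params: dict
    seed: int
    noise: NoiseModel = NO_NOISE


@dataclass(frozen=True)
class ConditionPreset:
    """Bundle of per-stage truths for one experimental condition.

    ``gp`` maps a condition label (e.g. "no_peptide_25C") to the true GP;
    fields are None where a stage does not apply (e.g. no partition
    coefficient in plain buffer).
    """

    label: str
    ksv: float | None = None  # M^-1
    kp: float | None = None  # M^-1
    gp: dict | None = None
    helix_fraction: float | None = None
    ratio_222_208: float | None = None
    saturation_pl: float | None = None
    total_plateau: float | None = None
    inner_plateau: float | None = None
    leakage_plateau: float | None = None


PRESETS: dict[str, ConditionPreset] = {
    "buffer": ConditionPreset(label="buffer", ksv=10.21),
    "BBB": ConditionPreset(
        label="BBB",
        ksv=2.05,
        kp=4.24e4,
        gp={"no_peptide_25C": 0.20, "no_peptide_37C": 0.19, "peptide_37C": 0.15},
        helix_fraction=0.58,
        ratio_222_208=0.68,
        saturation_pl=0.05,
        total_plateau=100.0,
        inner_plateau=20.0,
        leakage_plateau=0.0,
    ),
    "liver": ConditionPreset(
        label="liver",
        ksv=3.04,
        kp=1.55e3,
        gp={"no_peptide_25C": 0.44, "no_peptide_37C": 0.40, "peptide_37C": 0.49},
        helix_fraction=0.40,
        ratio_222_208=0.45,
        saturation_pl=0.7,
        total_plateau=100.0,
        inner_plateau=100.0,
        leakage_plateau=0.0,
    ),
}


def get_preset(label: str) -> ConditionPreset:
    try:
        return PRESETS[label]
    except KeyError:
        valid = ", ".join(sorted(PRESETS))
        raise LookupError(f"unknown preset {label!r}; valid labels: {valid}") from None


# ---------------------------------------------------------------------------
# Laurdan emission


def gen_laurdan_spectrum(
    gp_true: float,
    n_points: int = 151,
    noise: NoiseModel = NO_NOISE,
    seed: int = 0,
    *,
    wl_range: tuple[float, float] = (400.0, 550.0),
    band_sigma_nm: float = 18.0,
    total_amplitude: float = 200.0,
) -> tuple[Spectrum, GeneratorTruth]:
    """Two-band Laurdan emission spectrum with an exact target GP.

    The spectrum is the sum of Gaussian bands at 440 nm (ordered phase) and
    490 nm (disordered phase), sigma 18 nm.  Band amplitudes are solved so
    that the intensities read at exactly 440/490 nm -- including each
    band's tail under the other -- give ``gp_true`` at zero noise.  Because
    the tails overlap, only |GP| <= (1-t)/(1+t) with
    t = exp(-50^2 / (2 sigma^2)) is achievable; requests beyond that raise
    :class:`GeneratorError`.
    """
    gp = float(gp_true)
    sigma = float(band_sigma_nm)
    t = float(np.exp(-(50.0**2) / (2.0 * sigma**2)))  # cross-band tail weight
    gp_max = (1.0 - t) / (1.0 + t)
    if not (-gp_max < gp < gp_max):
        raise GeneratorError(
            f"gp_true={gp} infeasible under band overlap; |GP| must be < {gp_max:.4f}"
        )
    # I440 = A1 + A2 t, I490 = A1 t + A2  =>  GP = (A1-A2)(1-t) / ((A1+A2)(1+t))
    s = total_amplitude
    d = gp * (1.0 + t) / (1.0 - t) * s
    a1, a2 = (s + d) / 2.0, (s - d) / 2.0
    wl = np.linspace(wl_range[0], wl_range[1], int(n_points))
    values = a1 * np.exp(-((wl - 440.0) ** 2) / (2 * sigma**2)) + a2 * np.exp(
        -((wl - 490.0) ** 2) / (2 * sigma**2)
    )
    rng = np.random.default_rng(seed)
    values = noise.apply(rng, values)
    spec = Spectrum(
        wavelengths_nm=wl,
        values=values,
        kind="emission",
        excitation_nm=365.0,
        label=f"laurdan_gp_{gp:+.3f}",
    )
    truth = GeneratorTruth(
        stage="laurdan",
        params={"gp_true": gp, "a440": a1, "a490": a2, "band_sigma_nm": sigma},
        seed=int(seed),
        noise=noise,
    )
    return spec, truth


# ---------------------------------------------------------------------------
# Lipid mixing


def gen_mixing_series(
    saturation_pl: float,
    plateau_percent: float,
    f0: float = 10.0,
    f100: float = 110.0,
    pl_grid=None,
    hill_n: float = 2.0,
    noise: NoiseModel = NO_NOISE,
    seed: int = 0,
) -> tuple[TitrationSeries, GeneratorTruth]:
    """Fluorescence-vs-P/L series from a monotone saturating extent curve.

    The extent follows a Hill form (default exponent 2) whose half constant
    is chosen so the curve reaches 95% of ``plateau_percent`` at
    ``saturation_pl``; fluorescence is F = F0 + extent/100 * (F100 - F0)
    plus noise.  ``plateau_percent = 0`` yields a flat series at F0 (a
    leakage-free peptide).
    """
    if f100 == f0:
        raise ValueError("f100 must differ from f0")
    if not (0.0 <= plateau_percent <= 100.0):
        raise ValueError("plateau_percent must be in [0, 100]")
    sat = float(saturation_pl)
    if sat <= 0:
        raise ValueError("saturation_pl must be positive")
    if pl_grid is None:
        pl_grid = np.concatenate([[0.0], np.geomspace(sat / 20.0, 3.0 * sat, 12)])
    pl = np.asarray(pl_grid, dtype=float)
    if pl.size == 0:
        raise ValueError("P/L grid must be nonempty")
    n = float(hill_n)
    k = sat / 19.0 ** (1.0 / n)  # extent(sat) = 0.95 * plateau
    xn = np.power(np.maximum(pl, 0.0), n)
    extent = plateau_percent * xn / (xn + k**n)
    F = f0 + extent / 100.0 * (f100 - f0)
    rng = np.random.default_rng(seed)
    F = noise.apply(rng, F)
    series = TitrationSeries(x=pl, y=F, x_kind="peptide_lipid_ratio")
    truth = GeneratorTruth(
        stage="mixing",
        params={
            "saturation_pl": sat,
            "plateau_percent": float(plateau_percent),
            "f0": float(f0),
            "f100": float(f100),
            "hill_n": n,
            "hill_k": k,
            "extent_true": extent,
        },
        seed=int(seed),
        noise=noise,
    )
    return series, truth


# ---------------------------------------------------------------------------
# Tryptophan titration (partition equilibrium)


def default_lipid_grid(
    kp: float, outer_fraction: float = 0.6, n: int = 12,
    fb_lo: float = 0.10, fb_hi: float = 0.85,
) -> np.ndarray:
    """Lipid grid spanning bound fractions ``fb_lo``..``fb_hi`` for a given K_p.

    Under the simple partition balance the bound fraction at total lipid L
    is f_b = K_p L' / (1 + K_p L') with L' = outer_fraction * L; the grid
    inverts that map on an even f_b spacing, mimicking how a titration is
    planned to cover the binding transition.
    """
    fb = np.linspace(fb_lo, fb_hi, n)
    return fb / (float(kp) * float(outer_fraction) * (1.0 - fb))


def gen_trp_titration(
    kp_true: float,
    peptide_total: float = 4e-6,
    lipid_grid=None,
    f0: float = 100.0,
    f_inf_true: float = 300.0,
    outer_fraction: float = 0.6,
    cooperativity: float = 0.0,
    critical_cf: float | None = None,
    noise: NoiseModel = NO_NOISE,
    seed: int = 0,
) -> tuple[TitrationSeries, GeneratorTruth]:
    """Tryptophan-fluorescence lipid titration under a partition equilibrium.

    At each lipid point the bound fraction solves the mass balance implied
    by X_b* = K_p C_f; fluorescence is F = F0 + f_b (F_inf - F0) plus
    noise.  ``cooperativity > 0`` adds surface self-association -- an
    upward-curving quadratic term in X_b*(C_f) above ``critical_cf``
    (default half the total peptide) -- emulating peptides that aggregate
    on the membrane beyond a critical free concentration.
    """
    kp = float(kp_true)
    if kp <= 0:
        raise GeneratorError("kp_true must be positive")
    P = float(peptide_total)
    if P <= 0:
        raise ValueError("peptide_total must be positive")
    if lipid_grid is None:
        lipid_grid = default_lipid_grid(kp, outer_fraction)
    L = np.asarray(lipid_grid, dtype=float)
    if np.any(L < 0):
        raise ValueError("lipid concentrations must be nonnegative")
    coop = float(cooperativity)
    c_crit = 0.5 * P if critical_cf is None else float(critical_cf)

    def xstar_model(c_f: float) -> float:
        extra = coop * kp * max(0.0, c_f - c_crit) ** 2 / P
        return kp * c_f + extra

    f_b = np.empty_like(L)
    for i, lip in enumerate(L):
        if lip == 0:
            f_b[i] = 0.0
            continue
        lp = float(outer_fraction) * lip

        def balance(fb: float, lp=lp) -> float:
            return fb * P / lp - xstar_model((1.0 - fb) * P)

        lo, hi = 0.0, 1.0
        if balance(lo) > 0 or balance(hi) < 0:
            raise GeneratorError(
                f"no bound-fraction solution in [0, 1] at lipid {lip:.3g} M"
            )
        f_b[i] = brentq(balance, lo, hi, xtol=1e-15)
    F = f0 + f_b * (f_inf_true - f0)
    rng = np.random.default_rng(seed)
    F = noise.apply(rng, F)
    series = TitrationSeries(x=L, y=F, x_kind="lipid_conc")
    truth = GeneratorTruth(
        stage="trp_titration",
        params={
            "kp_true": kp,
            "peptide_total": P,
            "f0": float(f0),
            "f_inf_true": float(f_inf_true),
            "outer_fraction": float(outer_fraction),
            "cooperativity": coop,
            "critical_cf": c_crit,
            "f_b_true": f_b,
        },
        seed=int(seed),
        noise=noise,
    )
    return series, truth


# ---------------------------------------------------------------------------
# Acrylamide quenching


def gen_quenching_series(
    ksv_true: float,
    f0: float = 100.0,
    q_grid=None,
    noise: NoiseModel = NO_NOISE,
    seed: int = 0,
) -> tuple[TitrationSeries, GeneratorTruth]:
    """Acrylamide quenching series from the Stern-Volmer law.

    F = F0 / (1 + K_sv [Q]) plus noise, on a quencher grid bounded by the
    0.2 M maximum acrylamide concentration used experimentally.
    """
    ksv = float(ksv_true)
    if ksv < 0:
        raise ValueError("ksv_true must be nonnegative")
    if q_grid is None:
        q_grid = np.linspace(0.0, 0.2, 9)
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("quencher concentrations must be nonnegative")
    F = float(f0) / (1.0 + ksv * q)
    rng = np.random.default_rng(seed)
    F = noise.apply(rng, F)
    series = TitrationSeries(x=q, y=F, x_kind="quencher_conc")
    truth = GeneratorTruth(
        stage="quenching",
        params={"ksv_true": ksv, "f0": float(f0)},
        seed=int(seed),
        noise=noise,
    )
    return series, truth


# ---------------------------------------------------------------------------
# Circular dichroism

# Fixed analytic basis shapes (Gaussian mixtures), not experimental
# reference sets: a helix basis with negative bands at 208/222 nm and a
# positive band near 193 nm, and a coil basis with a single negative band
# near 198 nm.  Centers/widths in nm.


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-((wl - center) ** 2) / (2.0 * sigma**2))


def _helix_basis(wl: np.ndarray) -> np.ndarray:
    return (
        -_gauss(wl, 222.0, 6.5)
        - _gauss(wl, 208.0, 5.5)
        + 1.6 * _gauss(wl, 193.0, 6.0)
    )


def _coil_basis(wl: np.ndarray) -> np.ndarray:
    return -1.3 * _gauss(wl, 198.0, 7.0)


def gen_cd_spectrum(
    fH_true: float,
    ratio_target: float = 0.68,
    n_res: int = 20,
    convention: str = "unscaled",
    conc_M: float = 8e-6,
    path_cm: float = 0.1,
    noise: NoiseModel = NO_NOISE,
    seed: int = 0,
    *,
    wl_range: tuple[float, float] = (190.0, 260.0),
    step_nm: float = 0.5,
) -> tuple[Spectrum, GeneratorTruth]:
    """Raw CD spectrum (mdeg) with target helicity and 222/208 ratio.

    A linear combination of the helix and coil bases is solved so that, in
    the requested MRE convention, MRE(222) = fH_true * (-40000(1 - 2.5/n))
    and MRE(222)/MRE(208) = ratio_target at zero noise; the MRE trace is
    then converted back to observed millidegrees for the given path length
    and concentration, so the analysis pipeline exercises its own
    normalization.  ``fH_true = 0`` emits a pure coil spectrum (the ratio
    target does not apply).  Combinations requiring a negative basis weight
    raise :class:`GeneratorError`.
    """
    from .cd_analysis import helix_reference_mre, mre as _mre_of

    fH = float(fH_true)
    if not (0.0 <= fH <= 1.0):
        raise ValueError("fH_true must be in [0, 1]")
    wl = np.arange(wl_range[0], wl_range[1] + step_nm / 2, step_nm)
    H = _helix_basis(wl)
    C = _coil_basis(wl)

    def basis_at(basis: np.ndarray, w: float) -> float:
        return float(np.interp(w, wl, basis))

    m222_target = fH * helix_reference_mre(n_res)
    if fH < 1e-12:
        a = 0.0
        b = 15000.0 / 1.3  # coil scaled to ~-15000 deg cm^2/dmol at 198 nm
    else:
        ratio = float(ratio_target)
        if ratio <= 0:
            raise GeneratorError("ratio_target must be positive for helical spectra")
        m208_target = m222_target / ratio
        mat = np.array(
            [
                [basis_at(H, 222.0), basis_at(C, 222.0)],
                [basis_at(H, 208.0), basis_at(C, 208.0)],
            ]
        )
        if abs(np.linalg.det(mat)) < 1e-12:
            raise GeneratorError("CD basis shapes are degenerate at 222/208 nm")
        a, b = np.linalg.solve(mat, np.array([m222_target, m208_target]))
        if a < -1e-9 or b < -1e-9:
            raise GeneratorError(
                f"(fH={fH}, ratio={ratio_target}) infeasible under the basis "
                f"shapes (weights a={a:.3g}, b={b:.3g})"
            )
    mre_trace = a * H + b * C
    # convert MRE back to observed millidegrees: invert the analyzer's scaling
    scale = _mre_of(1.0, path_cm, conc_M, n_res, convention)  # MRE per mdeg
    obsd = mre_trace / scale
    rng = np.random.default_rng(seed)
    obsd = noise.apply(rng, obsd)
    spec = Spectrum(
        wavelengths_nm=wl, values=obsd, kind="cd", label=f"cd_fH_{fH:.2f}"
    )
    truth = GeneratorTruth(
        stage="cd",
        params={
            "fH_true": fH,
            "ratio_target": float(ratio_target) if fH >= 1e-12 else None,
            "n_res": int(n_res),
            "convention": convention,
            "conc_M": float(conc_M),
            "path_cm": float(path_cm),
            "mre222_target": m222_target,
            "helix_weight": float(a),
            "coil_weight": float(b),
        },
        seed=int(seed),
        noise=noise,
    )
    return spec, truth


# ---------------------------------------------------------------------------
# Brain-slice images


def gen_brain_image(
    shape: tuple[int, int] = (192, 192),
    inside_amount: float = 7.0,
    outside_amount: float = 3.0,
    calibration_slope: float = 1000.0,
    background_sigma: float = 0.02,
    pixel_area_um2: float = 1.0,
    seed: int = 0,
    *,
    vessel_radius: int = 5,
    n_puncta: int = 30,
    puncta_sigma: float = 1.5,
) -> tuple[VesselImage, GeneratorTruth]:
    """Synthetic brain-slice field of view with a ground-truth vessel mask.

    A blood vessel is rendered as a thick smoothed random-walk tube
    carrying total fluorescence ``calibration_slope * inside_amount``;
    parenchymal puncta outside the vessel carry
    ``calibration_slope * outside_amount``.  Additive Gaussian background
    noise (sigma ``background_sigma``) is applied everywhere and the image
    clipped at zero.  The emitted mask is the true vessel footprint.
    """
    if inside_amount < 0 or outside_amount < 0:
        raise ValueError("amounts must be nonnegative")
    h, w = int(shape[0]), int(shape[1])
    if h < 16 or w < 16:
        raise GeneratorError("image too small to render a vessel")
    rng = np.random.default_rng(seed)

    # vessel: horizontal random walk, dilated to a tube
    margin = vessel_radius + 2
    rows = np.clip(
        np.round(h / 2 + np.cumsum(rng.normal(0.0, 1.2, w))).astype(int),
        margin,
        h - margin - 1,
    )
    mask = np.zeros((h, w), dtype=bool)
    mask[rows, np.arange(w)] = True
    mask = binary_dilation(mask, structure=disk(vessel_radius))
    frac = mask.mean()
    if frac == 0 or frac > 0.5:
        raise GeneratorError(f"degenerate vessel geometry (mask fraction {frac:.2f})")

    # inside field: smooth positive texture normalized to the target total
    inside = np.zeros((h, w))
    if inside_amount > 0:
        texture = 1.0 + 0.5 * gaussian_filter(rng.standard_normal((h, w)), 3.0)
        texture = np.clip(texture, 0.1, None) * mask
        inside = texture / texture.sum() * (calibration_slope * inside_amount)

    # parenchymal puncta: Gaussian blobs away from the vessel
    outside = np.zeros((h, w))
    if outside_amount > 0:
        keepout = binary_dilation(mask, structure=disk(int(np.ceil(4 * puncta_sigma))))
        free_rows, free_cols = np.nonzero(~keepout)
        if free_rows.size == 0:
            raise GeneratorError("no room for parenchymal puncta outside the vessel")
        picks = rng.choice(free_rows.size, size=n_puncta, replace=True)
        win = int(np.ceil(4 * puncta_sigma))
        offs = np.arange(-win, win + 1)
        blob = np.exp(-(offs[:, None] ** 2 + offs[None, :] ** 2) / (2 * puncta_sigma**2))
        for p in picks:
            r, c = int(free_rows[p]), int(free_cols[p])
            r0, r1 = max(0, r - win), min(h, r + win + 1)
            c0, c1 = max(0, c - win), min(w, c + win + 1)
            outside[r0:r1, c0:c1] += blob[
                r0 - (r - win) : r1 - (r - win), c0 - (c - win) : c1 - (c - win)
            ]
        outside[mask] = 0.0
        total = outside.sum()
        if total == 0:
            raise GeneratorError("puncta rendering produced no outside signal")
        outside *= calibration_slope * outside_amount / total

    pixels = inside + outside + rng.normal(0.0, background_sigma, (h, w))
    pixels = np.clip(pixels, 0.0, None)
    image = VesselImage(
        pixels=pixels,
        vessel_mask=mask,
        pixel_area_um2=float(pixel_area_um2),
        label=f"brain_{inside_amount:g}_{outside_amount:g}",
    )
    truth = GeneratorTruth(
        stage="brain_image",
        params={
            "inside_amount": float(inside_amount),
            "outside_amount": float(outside_amount),
            "calibration_slope": float(calibration_slope),
            "background_sigma": float(background_sigma),
            "inside_total_fluorescence": float(inside.sum()),
            "outside_total_fluorescence": float(outside.sum()),
            "pixel_area_um2": float(pixel_area_um2),
        },
        seed=int(seed),
        noise=additive_noise(background_sigma),
    )
    return image, truth
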