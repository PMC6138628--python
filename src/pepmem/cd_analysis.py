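"""Circular dichroism: mean residue ellipticity, helicity, oligomer state.

Observed ellipticity (mdeg) is normalized to mean residue ellipticity

    MRE = Obsd / (l * c * n)        ("unscaled" convention)
    MRE = Obsd / (10 * l * c * n)   ("factor10" convention)

with l the path length (cm), c the peptide concentration (M) and n the
number of residues.  The widely used definition includes the factor of 10;
both conventions are supported and the one used is recorded in every
result, because the helix-fraction scale is only meaningful when data and
reference share a convention.

Helix fraction is MRE at 222 nm against the reference limits 0 (coil) and
-40000*(1 - 2.5/n) deg cm^2 dmol^-1 per residue (full helix).  The ratio
[theta]222/[theta]208 classifies the helix association state: < 0.8
monomeric, > 1.0 oligomeric, in between indeterminate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Spectrum
from .errors import DegenerateInputError, WavelengthRangeError

__all__ = [
    "MRESpectrum",
    "HelixEstimate",
    "mre",
    "mre_spectrum",
    "helix_reference_mre",
    "helix_fraction",
    "oligomer_state",
    "analyze_cd",
]

MRE_CONVENTIONS = ("unscaled", "factor10")
FULL_HELIX_MRE = -40000.0  # deg cm^2 dmol^-1 per residue, infinite-chain limit


@dataclass(frozen=True)
class MRESpectrum:
    """A CD spectrum normalized to per-residue mean residue ellipticity."""

    wavelengths_nm: np.ndarray
    mre: np.ndarray  # deg cm^2 dmol^-1 per residue
    path_cm: float
    conc_M: float
    n_res: int
    convention: str = "unscaled"

    def __post_init__(self) -> None:
        if self.n_res < 2:
            raise ValueError("n_res must be at least 2")
        if self.path_cm <= 0 or self.conc_M <= 0:
            raise ValueError("path length and concentration must be positive")

    def value_at(self, wavelength_nm: float) -> float:
        w = float(wavelength_nm)
        wl = self.wavelengths_nm
        if w < wl[0] or w > wl[-1]:
            raise WavelengthRangeError(
                f"wavelength {w} nm outside MRE spectrum range [{wl[0]}, {wl[-1]}]"
            )
        return float(np.interp(w, wl, self.mre))


@dataclass(frozen=True)
class HelixEstimate:
    """Helicity and association-state summary of one CD spectrum."""

    mre222: float
    mre208: float
    helix_fraction: float  # clamped to [0, 1]
    ratio_222_208: float
    state: str  # monomeric | oligomeric | indeterminate
    clamped: bool
    convention: str


def _check_convention(convention: str) -> None:
    if convention not in MRE_CONVENTIONS:
        raise ValueError(
            f"convention must be one of {MRE_CONVENTIONS}, got {convention!r}"
        )


def mre(
    obsd_mdeg: float,
    path_cm: float,
    conc_M: float,
    n_res: int,
    convention: str = "unscaled",
) -> float:
    """Mean residue ellipticity from observed ellipticity in millidegrees."""
    _check_convention(convention)
    path_cm, conc_M = float(path_cm), float(conc_M)
    if path_cm <= 0 or conc_M <= 0:
        raise ValueError("path length and concentration must be positive")
    if n_res < 2:
        raise ValueError("n_res must be at least 2")
    denom = path_cm * conc_M * n_res
    if convention == "factor10":
        denom *= 10.0
    return float(obsd_mdeg) / denom


def mre_spectrum(
    raw: Spectrum,
    path_cm: float,
    conc_M: float,
    n_res: int,
    convention: str = "unscaled",
) -> MRESpectrum:
    """Normalize a blank-corrected CD spectrum (mdeg) to MRE per residue."""
    if raw.kind != "cd":
        raise ValueError(f"expected a CD spectrum, got kind={raw.kind!r}")
    values = np.array(
        [mre(v, path_cm, conc_M, n_res, convention) for v in raw.values]
    )
    return MRESpectrum(
        wavelengths_nm=raw.wavelengths_nm.copy(),
        mre=values,
        path_cm=float(path_cm),
        conc_M=float(conc_M),
        n_res=int(n_res),
        convention=convention,
    )


def helix_reference_mre(n_res: int) -> float:
    """Chain-length-corrected 100%-helix reference, -40000*(1 - 2.5/n).

    Approaches -40000 as n -> infinity; requires n > 2.5 so the reference
    stays negative.
    """
    n = int(n_res)
    if n <= 2:
        raise ValueError("n_res must exceed 2 for a negative helix reference")
    return FULL_HELIX_MRE * (1.0 - 2.5 / n)


def helix_fraction(mre222: float, n_res: int) -> float:
    """Helix fraction from MRE at 222 nm, clamped to [0, 1]."""
    raw = float(mre222) / helix_reference_mre(n_res)
    return float(min(max(raw, 0.0), 1.0))


def oligomer_state(ratio_222_208: float) -> str:
    """Classify helix association from the theta222/theta208 ratio.

    < 0.8 -> monomeric; > 1.0 -> oligomeric; boundary band [0.8, 1.0] ->
    indeterminate.
    """
    r = float(ratio_222_208)
    if not math.isfinite(r):
        raise ValueError("ratio must be finite")
    if r < 0.8:
        return "monomeric"
    if r > 1.0:
        return "oligomeric"
    return "indeterminate"


def analyze_cd(
    raw: Spectrum,
    path_cm: float,
    conc_M: float,
    n_res: int,
    convention: str = "unscaled",
) -> HelixEstimate:
    """Full CD analysis of a blank-corrected spectrum.

    Computes the MRE spectrum, interpolates MRE at exactly 222 and 208 nm,
    and derives the helix fraction and the monomer/oligomer classification.
    The spectrum must cover both 208 and 222 nm.
    """
    spec = mre_spectrum(raw, path_cm, conc_M, n_res, convention)
    wl = spec.wavelengths_nm
    if not (wl[0] <= 208.0 and wl[-1] >= 222.0):
        raise WavelengthRangeError(
            f"CD spectrum [{wl[0]}, {wl[-1]}] nm must cover 208 and 222 nm"
        )
    m222 = spec.value_at(222.0)
    m208 = spec.value_at(208.0)
    if m208 == 0:
        raise DegenerateInputError("MRE at 208 nm is zero; ratio undefined")
    ratio = m222 / m208
    raw_fraction = m222 / helix_reference_mre(n_res)
    clamped = not (0.0 <= raw_fraction <= 1.0)
    return HelixEstimate(
        mre222=m222,
        mre208=m208,
        helix_fraction=float(min(max(raw_fraction, 0.0), 1.0)),
        ratio_222_208=ratio,
        state=oligomer_state(ratio),
        clamped=clamped,
        convention=convention,
    )
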