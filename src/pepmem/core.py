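"""Shared domain containers, file I/O and configuration.

The containers here are deliberately thin: a :class:`Spectrum` is a
wavelength-indexed trace (fluorescence emission in arbitrary units, or CD
ellipticity in millidegrees), a :class:`TitrationSeries` pairs an independent
variable (lipid concentration, quencher concentration, or peptide/lipid mole
ratio) with fluorescence responses, and a :class:`LipidComposition` records a
liposome recipe in mole fractions.  CSV is the canonical tabular format
(comma-separated, '.' decimal, optional single header row); wavelengths are
stored in nm, concentrations in molar, P/L ratios as dimensionless mol/mol.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import (
    InsufficientDataError,
    SpectrumParseError,
    WavelengthRangeError,
)

__all__ = [
    "Spectrum",
    "TitrationSeries",
    "LipidComposition",
    "AnalysisConfig",
    "load_spectrum",
    "write_spectrum",
    "load_titration",
    "preset_composition",
    "COMPOSITION_PRESETS",
]

SPECTRUM_KINDS = ("emission", "cd")
TITRATION_KINDS = ("lipid_conc", "quencher_conc", "peptide_lipid_ratio")


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed trace.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nanometres.
    values
        Trace values, same length as ``wavelengths_nm``.  Intensity (a.u.)
        for ``kind="emission"``, observed ellipticity (mdeg) for
        ``kind="cd"``.
    kind
        Either ``"emission"`` or ``"cd"``.
    excitation_nm, temperature_C, label
        Acquisition metadata.  Temperature is carried as metadata only; no
        operation uses it computationally.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "emission"
    excitation_nm: float | None = None
    temperature_C: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if wl.size != vals.size:
            raise ValueError(
                f"wavelengths ({wl.size}) and values ({vals.size}) differ in length"
            )
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"kind must be one of {SPECTRUM_KINDS}, got {self.kind!r}")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def wl_min(self) -> float:
        return float(self.wavelengths_nm[0])

    @property
    def wl_max(self) -> float:
        return float(self.wavelengths_nm[-1])

    @property
    def has_negative_emission(self) -> bool:
        """True if this is an emission spectrum containing negative values.

        Negative emission is physically suspicious (over-subtracted baseline)
        and is flagged rather than rejected.
        """
        return self.kind == "emission" and bool(np.any(self.values < 0))

    def value_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated value at ``wavelength_nm``.

        An exact grid point returns the stored value; a wavelength outside
        the grid raises :class:`WavelengthRangeError`.
        """
        w = float(wavelength_nm)
        if w < self.wl_min or w > self.wl_max:
            raise WavelengthRangeError(
                f"wavelength {w} nm outside spectrum range "
                f"[{self.wl_min}, {self.wl_max}] nm"
            )
        return float(np.interp(w, self.wavelengths_nm, self.values))

    def covers(self, *wavelengths_nm: float) -> bool:
        return all(self.wl_min <= w <= self.wl_max for w in wavelengths_nm)


def value_at(spectrum: Spectrum, wavelength_nm: float) -> float:
    """Functional alias for :meth:`Spectrum.value_at`."""
    return spectrum.value_at(wavelength_nm)


@dataclass(frozen=True)
class TitrationSeries:
    """An (x, fluorescence) series with declared x units.

    ``x_kind`` is one of ``lipid_conc`` (M), ``quencher_conc`` (M) or
    ``peptide_lipid_ratio`` (mol/mol).  Points are sorted ascending in x on
    construction; duplicate x values are rejected unless ``replicates=True``.
    """

    x: np.ndarray
    y: np.ndarray
    x_kind: str
    replicates: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if np.any(x < 0):
            raise ValueError("x values must be nonnegative")
        if self.x_kind not in TITRATION_KINDS:
            raise ValueError(
                f"x_kind must be one of {TITRATION_KINDS}, got {self.x_kind!r}"
            )
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        if not self.replicates and np.any(np.diff(x) == 0):
            raise ValueError("duplicate x values require replicates=True")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.x.size

    def require_points(self, n: int, what: str = "fit") -> None:
        if len(self) < n:
            raise InsufficientDataError(
                f"{what} requires at least {n} points, got {len(self)}"
            )


@dataclass(frozen=True)
class LipidComposition:
    """A liposome recipe as (lipid name, mole fraction) pairs."""

    components: tuple[tuple[str, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        comps = tuple((str(n), float(f)) for n, f in self.components)
        if any(f < 0 for _, f in comps):
            raise ValueError("mole fractions must be nonnegative")
        total = sum(f for _, f in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1 (got {total!r})")
        object.__setattr__(self, "components", comps)

    def fraction(self, name: str) -> float:
        for n, f in self.components:
            if n == name:
                return f
        raise KeyError(name)


# Liposome recipes mimicking the lipid composition of brain capillary
# endothelium ("BBB") and of liver membranes, in mole fractions.
COMPOSITION_PRESETS: dict[str, LipidComposition] = {
    "BBB": LipidComposition(
        components=(
            ("PI", 0.04),
            ("DOPE", 0.23),
            ("DPPC", 0.30),
            ("PS", 0.08),
            ("Chol", 0.20),
            ("SM", 0.15),
        ),
        label="BBB",
    ),
    "liver": LipidComposition(
        components=(
            ("DSPC", 0.37),
            ("POPE", 0.21),
            ("PI", 0.07),
            ("PS", 0.09),
            ("lysoPC", 0.03),
            ("SM", 0.18),
            ("DOPG", 0.05),
        ),
        label="liver",
    ),
}


def preset_composition(label: str) -> LipidComposition:
    """Return one of the built-in liposome compositions ("BBB" or "liver")."""
    try:
        return COMPOSITION_PRESETS[label]
    except KeyError:
        valid = ", ".join(sorted(COMPOSITION_PRESETS))
        raise LookupError(
            f"unknown composition preset {label!r}; valid labels: {valid}"
        ) from None


@dataclass
class AnalysisConfig:
    """Tunable analysis constants with the defaults used throughout.

    ``outer_leaflet_fraction`` is the fraction of total lipid in the outer
    leaflet accessible to an externally added peptide (0.6 for small
    vesicles); ``band_rule`` selects how the Laurdan band intensities are
    read ("interp" = interpolated value at exactly 440/490 nm,
    "window_max" = maximum within +/- ``band_window_nm``).
    """

    gp_band_ordered_nm: float = 440.0
    gp_band_disordered_nm: float = 490.0
    band_rule: str = "interp"  # interp | window_max
    band_window_nm: float = 5.0
    outer_leaflet_fraction: float = 0.6
    initial_region_fraction: float = 0.3  # C_f cut for the initial-slope fit
    initial_min_points: int = 3
    initial_fallback_points: int = 4
    sv_max_quencher_M: float = 0.2
    threshold_method: str = "positive"  # positive | otsu
    mre_convention: str = "unscaled"  # unscaled | factor10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.outer_leaflet_fraction <= 1.0):
            raise ValueError("outer_leaflet_fraction must be in (0, 1]")
        if int(self.seed) != self.seed or self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")
        self.seed = int(self.seed)
        if self.band_rule not in ("interp", "window_max"):
            raise ValueError("band_rule must be 'interp' or 'window_max'")
        if self.mre_convention not in ("unscaled", "factor10"):
            raise ValueError("mre_convention must be 'unscaled' or 'factor10'")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Read a flat ``key = value`` text file ('#' starts a comment)."""
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected 'key = value', got {raw!r}"
                )
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise KeyError(f"{path}: line {lineno}: unknown config key {key!r}")
            ftype = types[key]
            if ftype in ("int", int):
                kwargs[key] = int(val)
            elif ftype in ("float", float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)  # type: ignore[arg-type]

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tabular I/O


def _read_two_column_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Parse a two-numeric-column CSV, tolerating one header row.

    Errors name the offending 1-based file line so instrument exports with a
    stray text cell are easy to fix.
    """
    xs: list[float] = []
    ys: list[float] = []
    lines = Path(path).read_text().splitlines()
    first_data_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 2:
            raise SpectrumParseError(
                f"{path}: row {lineno}: expected two comma-separated columns"
            )
        try:
            x, y = float(parts[0]), float(parts[1])
        except ValueError:
            if not first_data_seen:
                # single optional header row
                first_data_seen = True
                continue
            raise SpectrumParseError(
                f"{path}: row {lineno}: non-numeric value in {raw!r}"
            ) from None
        first_data_seen = True
        xs.append(x)
        ys.append(y)
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


def load_spectrum(
    path: str | Path,
    kind: str = "emission",
    *,
    excitation_nm: float | None = None,
    temperature_C: float | None = None,
    label: str = "",
) -> Spectrum:
    """Load a two-column (wavelength nm, value) CSV as a :class:`Spectrum`.

    Rows are re-sorted ascending in wavelength.  Fewer than 3 points raises
    :class:`InsufficientDataError`; a non-numeric cell raises
    :class:`SpectrumParseError` naming the row.
    """
    wl, vals = _read_two_column_csv(path)
    if wl.size < 3:
        raise InsufficientDataError(
            f"{path}: a spectrum needs at least 3 points, got {wl.size}"
        )
    order = np.argsort(wl, kind="stable")
    spec = Spectrum(
        wavelengths_nm=wl[order],
        values=vals[order],
        kind=kind,
        excitation_nm=excitation_nm,
        temperature_C=temperature_C,
        label=label or Path(path).stem,
    )
    if spec.has_negative_emission:
        warnings.warn(
            f"{path}: emission spectrum contains negative intensities",
            stacklevel=2,
        )
    return spec


def write_spectrum(path: str | Path, spectrum: Spectrum) -> None:
    """Write a spectrum as two-column CSV at full float precision."""
    header = "wavelength_nm,value\n"
    rows = "\n".join(
        f"{w:.17g},{v:.17g}"
        for w, v in zip(spectrum.wavelengths_nm, spectrum.values)
    )
    Path(path).write_text(header + rows + "\n")


def load_titration(
    path: str | Path, x_kind: str, *, replicates: bool = False, label: str = ""
) -> TitrationSeries:
    """Load a two-column (x, fluorescence) CSV as a :class:`TitrationSeries`."""
    x, y = _read_two_column_csv(path)
    if x.size == 0:
        raise InsufficientDataError(f"{path}: empty titration table")
    return TitrationSeries(
        x=x, y=y, x_kind=x_kind, replicates=replicates, label=label or Path(path).stem
    )
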