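"""Vesicle fusion assays: lipid mixing, inner-monolayer mixing, leakage.

Generates FRET-dequenching fluorescence curves against the peptide/lipid
mole ratio for the two membrane compositions, normalizes them to percent
mixing between the F0 (intact vesicles) and F100 (Triton-solubilized)
anchors, and fits the saturation point of each curve.
"""

from pepmem import mixing_curve, saturation_estimate
from pepmem.synthetic_data import PRESETS, gen_mixing_series, multiplicative_noise

noise = multiplicative_noise(0.02)
F0, F100 = 10.0, 110.0

for label in ("BBB", "liver"):
    p = PRESETS[label]
    print(f"{label}-mimicking liposomes")
    for assay, plateau in (
        ("total", p.total_plateau),
        ("inner_monolayer", p.inner_plateau),
        ("leakage", p.leakage_plateau),
    ):
        series, _ = gen_mixing_series(
            p.saturation_pl, plateau, f0=F0, f100=F100, noise=noise, seed=7
        )
        result = mixing_curve(series, F0, F100, assay=assay)
        fit = saturation_estimate(result)
        if fit.flat:
            print(f"  {assay:16s} flat curve, plateau {fit.plateau_percent:5.1f}%")
        else:
            print(
                f"  {assay:16s} plateau {fit.plateau_percent:5.1f}%  "
                f"saturation P/L {fit.saturation_pl:.3f}"
            )
    print()

print(
    "The BBB-like membrane fuses at a ~10x lower peptide load (saturation\n"
    "P/L 0.05 vs 0.7) but only its outer leaflet mixes (inner-monolayer\n"
    "plateau ~20% vs ~100%): hemifusion for BBB, full fusion for liver.\n"
    "Zero leakage in both distinguishes the peptide from pore-forming\n"
    "antimicrobials."
)
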