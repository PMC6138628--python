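"""Secondary structure from circular dichroism.

Generates raw CD spectra (millidegrees) for the peptide in the two vesicle
environments and in water, normalizes to mean residue ellipticity, and
reports helicity and the 222/208 association-state diagnostic.
"""

from pepmem import analyze_cd
from pepmem.synthetic_data import PRESETS, gen_cd_spectrum, multiplicative_noise

PATH_CM, CONC_M, N_RES = 0.1, 8e-6, 20
noise = multiplicative_noise(0.02)

cases = [
    ("BBB vesicles", PRESETS["BBB"].helix_fraction, PRESETS["BBB"].ratio_222_208),
    ("liver vesicles", PRESETS["liver"].helix_fraction, PRESETS["liver"].ratio_222_208),
    ("water (coil)", 0.0, None),
]

for name, fh, ratio in cases:
    spec, _ = gen_cd_spectrum(
        fh, ratio_target=ratio if ratio else 0.68, noise=noise, seed=21
    )
    est = analyze_cd(spec, PATH_CM, CONC_M, N_RES)
    print(
        f"{name:14s} [theta]222 = {est.mre222:9.0f}  helix = {100*est.helix_fraction:5.1f}%  "
        f"222/208 = {est.ratio_222_208:5.2f}  -> {est.state}"
    )

print(
    "\nThe peptide is random coil in water but folds helical in membranes --\n"
    "more so in the BBB mimic (58% vs 40%) -- and the 222/208 ratio below\n"
    "0.8 shows it stays monomeric in both, so the structural change, not\n"
    "oligomerization, drives the membrane interaction."
)
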