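"""Partition coefficients and tryptophan accessibility.

Runs the full tryptophan-fluorescence pipeline -- lipid titration, F_inf
extrapolation, binding isotherm, initial-slope K_p -- and the acrylamide
Stern-Volmer analysis, for both membrane mimics.
"""

from pepmem import (
    build_isotherm,
    estimate_f_inf,
    partition_coefficient,
    stern_volmer_fit,
)
from pepmem.synthetic_data import (
    PRESETS,
    gen_quenching_series,
    gen_trp_titration,
    multiplicative_noise,
)

noise = multiplicative_noise(0.02)
P_TOTAL, F0 = 4e-6, 100.0  # 4 uM peptide, free-peptide fluorescence

print("Surface partition coefficients (X_b* = K_p C_f):")
for label in ("BBB", "liver"):
    kp_true = PRESETS[label].kp
    series, _ = gen_trp_titration(kp_true, noise=noise, seed=11)
    f_inf = estimate_f_inf(series.x, series.y, 0.6, mode="delta", f0=F0, weights="response")
    iso = build_isotherm(series, P_TOTAL, F0, f_inf, outer_fraction=0.6)
    fit = partition_coefficient(iso)
    print(
        f"  {label:6s} K_p = {fit.kp:10.3g} M^-1  (truth {kp_true:.3g}; "
        f"F_inf {f_inf:6.1f}, {fit.n_points_used} initial-slope points)"
    )

print("\nStern-Volmer quenching constants (F0/F = 1 + K_sv [Q]):")
for label in ("buffer", "BBB", "liver"):
    ksv_true = PRESETS[label].ksv
    series, _ = gen_quenching_series(ksv_true, f0=F0, noise=noise, seed=13)
    fit = stern_volmer_fit(series, f0=F0)
    print(
        f"  {label:6s} K_sv = {fit.ksv:6.2f} M^-1  (truth {ksv_true}; "
        f"free intercept {fit.intercept:.3f})"
    )

print(
    "\nK_p is ~27x higher for the BBB mimic (stronger membrane partitioning)\n"
    "and K_sv is lowest there (tryptophan most shielded from the aqueous\n"
    "quencher), i.e. the peptide binds more strongly and buries deeper in\n"
    "the BBB-like bilayer."
)
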