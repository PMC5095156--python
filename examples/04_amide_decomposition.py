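"""Decompose a synthetic amide region into helix and sheet/coil components.

Keratin's amide carbon signal partially splits into a ~175 ppm (alpha-helix)
and a ~172.5 ppm (beta-sheet/random coil) component.  Here a 60:40
sheet:helix profile is synthesized with 1% noise and decomposed back.
"""

from kerassign import fit_two_components, synthesize_amide_profile

profile = synthesize_amide_profile(fractions=(0.6, 0.4), noise_sd_frac=0.01, seed=11)
fit = fit_two_components(profile)

print("two-component fit of the 165-185 ppm amide region:")
print(f"  sheet/coil component: center {fit.centers[0]:7.2f} ppm, "
      f"FWHM {fit.widths[0]:.2f} ppm, area fraction {fit.fractions[0]:.3f}")
print(f"  helix component:      center {fit.centers[1]:7.2f} ppm, "
      f"FWHM {fit.widths[1]:.2f} ppm, area fraction {fit.fractions[1]:.3f}")
print(f"  residual norm: {fit.residual_norm:.4g}")
print("\nThe recovered centers and 0.6/0.4 area split match the generating")
print("recipe, validating the decomposition on data of known composition.")
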