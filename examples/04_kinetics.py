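"""Single-timepoint Michaelis-Menten analysis of a phosphatase plate.

Simulates a noise-free assay plate (1.5-fold dilution series from
1 mM), converts absorbances through the standard curve, fits the
single-timepoint MM model and compares two enzymes' efficiencies.
"""

import holophos as hp

curve = hp.StandardCurve(slope=0.01, intercept=0.05)
plate = hp.gen_assay_plate(kcat_over_km=0.5, km=30.0, curve=curve, seed=4)
product, n_clamped = hp.absorbance_to_phosphate(plate["a620"], curve)
fit = hp.fit_single_timepoint_mm(plate["substrate_conc_uM"], product,
                                 t=15.0, enzyme=1.0)
print(f"kcat/KM = {fit.kcat_over_km:.4f} /min/U per uM substrate "
      f"(true 0.5), KM = {fit.km:.2f} uM (true 30), "
      f"KM reliable: {fit.km_reliable}")

# a poor substrate assayed far below its KM: only kcat/KM is defined
weak = hp.gen_assay_plate(kcat_over_km=0.005, km=5000.0, curve=curve, seed=4)
wp, _ = hp.absorbance_to_phosphate(weak["a620"], curve)
weak_fit = hp.fit_single_timepoint_mm(weak["substrate_conc_uM"], wp,
                                      t=15.0, enzyme=1.0)
print(f"weak substrate: kcat/KM = {weak_fit.kcat_over_km:.4f}, "
      f"KM reliable: {weak_fit.km_reliable} (KM >> max assayed C)")
print(f"catalytic-efficiency fold: "
      f"{hp.efficiency_fold(fit, weak_fit):.1f}x")

# the enzyme unit definition: 1 U releases 15 uM phosphate in 15 min
# from 125 uM standard substrate
p15 = float(hp.mm_product(125.0, 15.0, 1.0, fit.kcat_over_km, fit.km))
print(f"this prep in the standard assay: {p15:.2f} uM phosphate "
      f"-> activity {hp.calibrate_activity(p15):.3f} U")
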