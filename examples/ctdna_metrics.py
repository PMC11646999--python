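"""Compute the liquid-biopsy metrics for one patient by hand.

A plasma sample's ctDNA concentration in haploid genome equivalents per mL
is maxVAF x cfDNA[pg/mL] / 3.3; ΔctDNA divides the on-treatment by the
baseline concentration and calls a molecular response at or below 0.2
(an 80% drop).
"""

from ctdx import (
    MetricsConfig, PlasmaSample, VariantCall,
    classify_dynamics, classify_molecular_response, compute_btmb,
    ctdna_concentration, delta_ctdna, normalized_btmb,
)

baseline = PlasmaSample(
    sample_id="P1_T0", timepoint="baseline", cfdna_ng_per_ml=10.0,
    variants=[VariantCall("TP53", 0.10), VariantCall("KRAS", 0.04),
              VariantCall("LRP1B", 0.02, functional_class="synonymous")],
)
on_treatment = PlasmaSample(
    sample_id="P1_T1", timepoint="on_treatment", cfdna_ng_per_ml=8.0,
    variants=[VariantCall("TP53", 0.015), VariantCall("KRAS", 0.006)],
    day_from_start=26,
)

cfg = MetricsConfig()
c0 = ctdna_concentration(baseline, cfg)
c1 = ctdna_concentration(on_treatment, cfg)
delta, lod_used, _ = delta_ctdna(c0, baseline.detected, c1, on_treatment.detected, cfg)
btmb = compute_btmb(baseline.variants, cfg)

print(f"baseline ctDNA: {c0:.1f} hGE/mL   (0.10 x 10000 / 3.3)")
print(f"on-treatment ctDNA: {c1:.1f} hGE/mL")
print(f"delta ctDNA: {delta:.3f}  -> molecular responder: "
      f"{classify_molecular_response(delta, cfg)}")
print(f"dynamics: {classify_dynamics(True, True, delta, cfg)}")
print(f"bTMB: {btmb:.2f} mut/Mb (2 nonsynonymous / 1.5 Mb panel)")
print(f"normalized bTMB: {normalized_btmb(btmb, c0, cfg):.5f} (mut/Mb per hGE/mL)")
# delta 0.036 means the tumor-derived DNA burden dropped by ~96% after one
# treatment cycle - a strong molecular response.
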