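"""Model-averaged abundance and extrapolation from published per-model rows.

Runs the model-averaging and planning arithmetic on the published per-model
detection and abundance estimates: combined detection probability, total
abundance with and without the imprecise hazard-rate model, extrapolation
of the low-density stratum to unsampled polynya ice, and the extra survey
effort a 25% CV target would demand.
"""

from mrdsurvey import (
    ModelEstimate,
    combined_pa,
    effort_for_cv,
    extrapolate,
    kane_basin as kb,
    lognormal_ci,
    model_average,
)

p0_avg, p0_se = model_average(
    [ModelEstimate(l, p0, se, weight=w) for l, _, w, *_, p0, se in kb.MR_MODEL_ROWS]
)
ds_est = [ModelEstimate(l, pd, se, weight=w)
          for l, _, _, _, _, w, pd, se in kb.DS_MODEL_ROWS]
pd_avg, pd_se = model_average(ds_est)
pa, var_pa = combined_pa(p0_avg, p0_se**2, pd_avg, pd_se**2)
print(f"p0* = {p0_avg:.3f} (SE {p0_se:.3f}) x pd = {pd_avg:.3f} (SE {pd_se:.3f})"
      f" -> pa = {pa:.3f} (SE {var_pa**0.5:.3f})")

n_est = [ModelEstimate(l, n, se, weight=w) for l, w, n, se in kb.ABUNDANCE_ROWS]
for label, subset in [("all 4 models", n_est),
                      ("hazard-rate excluded", [e for e in n_est if e.label != "hazard_rate"])]:
    n, se = model_average(subset)
    cv = se / n
    lo, hi = lognormal_ci(n, cv)
    print(f"N ({label}) = {n:.0f} bears (SE {se:.0f}; CV {cv:.2f}; 95% CI {lo:.0f}-{hi:.0f})")

bears, _, (lo, hi) = extrapolate(kb.LOW_DENSITY_PER_1000KM2, kb.LOW_DENSITY_SE,
                                 kb.AREA_POLYNYA_KM2)
print(f"extrapolated to {kb.AREA_POLYNYA_KM2:.0f} km2 of unsampled polynya ice: "
      f"~{bears:.0f} bears (95% CI {lo:.0f}-{hi:.0f})")

mult = effort_for_cv(kb.CV_ACHIEVED, kb.CV_TARGET)
print(f"reaching CV {kb.CV_TARGET:.0%} from {kb.CV_ACHIEVED:.0%} needs "
      f"{mult:.1f}x the survey effort (precision improves as 1/sqrt(n)).")
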