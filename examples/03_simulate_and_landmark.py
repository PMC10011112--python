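"""Simulate a cohort with a planted post-sepsis effect and recover it.

Generates 50,000 subjects followed 12.6 years with ~2.2% sepsis incidence.
The generator multiplies the venous-thromboembolism (VTE) hazard after a
sepsis diagnosis by 80 in the first 30 days, 11.03 from day 31 to 2 years,
and 0.63 beyond 2 years.  A landmark Cox analysis per window (subjects
event-free and alive at the window start; age/sex/baseline-risk adjusted)
should recover those multipliers where events allow.
"""

from sepsisgrs import SimulationConfig, records_from_truth, simulate_cohort
from sepsisgrs.survival import landmark_window_analysis

cfg = SimulationConfig(n_subjects=50_000, seed=42, grs_exponent=0.0)
sim = simulate_cohort(cfg)
records = records_from_truth(sim.truth, "VTE", cfg.followup_years)
print(f"cohort: {len(records)} subjects, {int(records['sepsis'].sum())} with sepsis, "
      f"{int(records['event'].sum())} VTE events")

results = landmark_window_analysis(
    records, group_col="sepsis", covariates=["age", "male", "log_ascvd"]
)
print(f"\n{'window':<8}{'truth':>7} {'HR':>8}  {'95% CI':<16} {'events (sep/non)':<18} flag")
for res, truth in zip(results, cfg.sepsis_hr_windows["VTE"]):
    ci = f"({res.ci95[0]:.2f}-{res.ci95[1]:.2f})" if res.flag != "inestimable" else "-"
    hr = f"{res.hr:.2f}" if res.flag != "inestimable" else "NA"
    ev = f"{res.n_events.get(1, 0)}/{res.n_events.get(0, 0)}"
    print(f"{res.window.name:<8}{truth:>7} {hr:>8}  {ci:<16} {ev:<18} {res.flag}")

print("\nShort-window estimates rest on a handful of 30-day events, so they are")
print("wide or inestimable at this scale — mirroring how real short-term")
print("estimates are unstable even in very large cohorts.")
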