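"""Screen correlated candidate indicators before the evaluation.

Highly collinear indicators (e.g. WUE and IWUE, or the quality cluster
SP/SSC/TSS/VC with r > 0.85) would double-count information in the
entropy weighting.  'paper' mode keeps the fixed retained set
established for this trial; 'auto' mode applies a greedy |r|-threshold
rule.
"""

from wneval import screening, trial_data

candidates = trial_data.build_indicator_table(
    2022, indicators=list(trial_data.CANDIDATE_INDICATORS)
)
screened, report = screening.screen(candidates, mode="paper")
print("Pearson correlations among the candidates (2022):")
print(report.r.round(2))
print()
print(f"Retained (fixed set): {report.retained}")

_, auto_report = screening.screen(candidates, mode="auto", threshold=0.8)
print(f"Retained (greedy, |r| >= 0.8): {auto_report.retained}")
print(f"Dropped with triggering partner: {auto_report.dropped}")
print()
print(
    "The greedy rule is stricter: it also drops VC because its "
    "correlation with TSS is 0.99 on this trial."
)
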