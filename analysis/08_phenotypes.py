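"""Rosette phenotyping: growth metrics, divergence day and survival.

From the per-plant area/perimeter/convex-hull series: stockiness
(4*pi*area/perimeter^2), compactness (area/hull area), per-interval RGR,
the first day with a significant WD < WW area reduction (one-sided Welch
t-test, alpha 0.05), and percent survival (mean +- SD over replicates).
"""

from _common import run_stages

report = run_stages("simulate", "phenotype")
for sp, rec in report["stages"]["phenotype"].items():
    print(f"{sp}: first growth reduction day {rec['first_growth_reduction_day']}, "
          f"survival {rec['survival_mean_percent']:.1f} "
          f"+- {rec['survival_sd_percent']:.1f}%, "
          f"median stockiness {rec['median_stockiness']:.3f}, "
          f"median compactness {rec['median_compactness']:.3f}")
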