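"""Call drought-regulated genes and classify cross-species response timing.

Per species and timepoint, genes are called up/down at |log2FC| >= 1 on
WD/WW replicate means (pseudocount 1).  Each EMO's per-species induction
profile is reduced to first/highest-peak timepoints and a segment label
(common-synchronous, common-shifted, pair and species-specific codes).
"""

from _common import run_stages

report = run_stages("simulate", "expression", "orthology", "de", "timing")
print("regulated gene counts (per species, timepoint_direction):")
for sp, rec in report["stages"]["de"].items():
    counts = {k: v for k, v in rec.items() if k != "n_drought_specific"}
    print(f"  {sp}: {counts}; drought-specific genes: {rec['n_drought_specific']}")
timing = report["stages"]["timing"]
print(f"\ninduced EMOs: {timing['n_induced_emos']}")
print("timing segments:")
for seg, n in timing["segment_counts"].items():
    print(f"  {seg}: {n}")
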