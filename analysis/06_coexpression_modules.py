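"""Detect co-expression modules on the EMO matrix and associate them with
traits.

The joint EMO x 72-sample log2 matrix feeds the weighted-network chain
(Pearson correlation -> |r|^16 adjacency -> TOM dissimilarity -> average
linkage -> tree cut -> eigengene merge at 0.1).  Module eigengenes are
correlated with species, treatment and timepoint covariates with BH FDR.
"""

from _common import run_stages

report = run_stages("simulate", "expression", "orthology", "de", "timing",
                    "modules")
rec = report["stages"]["modules"]
print(f"detected {rec['n_modules']} modules "
      f"({rec['n_unassigned']} EMOs unassigned):")
for mod, n in rec["module_sizes"].items():
    print(f"  {mod}: {n} EMOs")
print(f"significant module-trait pairs (FDR < 0.05): "
      f"{rec['n_significant_module_trait']}")
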