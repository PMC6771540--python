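"""Generate the synthetic study inputs.

Emulates a comparative drought time course over three Brassicaceae
rosette species (Ath, Aly, Esa): per-species transcript TPM tables for
2 conditions (WW/WD) x 4 timepoints (T0/T5/T11/T14) x 3 replicates,
pairwise protein-similarity hits, a gene->term annotation table,
per-plant rosette growth series and survival outcomes — all with planted
ground truth recorded alongside (ground_truth.json).
"""

from _common import WORKDIR, run_stages

report = run_stages("simulate")
rec = report["stages"]["simulate"]
print(f"simulated {rec['n_gene_families']} ortholog families for "
      f"{', '.join(rec['species'])}")
print(f"inputs written under {WORKDIR / 'inputs'}")
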