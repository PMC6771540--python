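"""Build one-to-one ortholog pairs and expressed-mutual-ortholog triples.

Pairwise reciprocal best hits (E-value <= 1e-3, deterministic tie-breaks)
are intersected into three-way triangles; a triple survives only if the
three pairwise assignments agree and every member passed the expression
filter in its species.  The EMO table (results/pipeline/outputs/
emo_table.tsv) is the gene universe for all cross-species analyses.
"""

from _common import run_stages

report = run_stages("simulate", "expression", "orthology")
rec = report["stages"]["orthology"]
for pair, n in rec["n_pairs"].items():
    print(f"reciprocal best hits {pair}: {n}")
print(f"EMO triples: {rec['n_emos']} "
      f"({rec['n_inconsistent_triangles']} inconsistent triangles dropped)")
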