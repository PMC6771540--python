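"""Term enrichment of each detected module against the annotation table.

Study set = a module's EMO members (on species-A gene ids); universe =
all EMO genes; one-sided Fisher (hypergeometric upper tail) per term with
BH FDR across tested terms.  On the synthetic scenario the planted module
terms should surface as each recovered module's top term.
"""

from _common import run_stages

report = run_stages("simulate", "expression", "orthology", "de", "timing",
                    "modules", "enrich")
for mod, rec in report["stages"]["enrich"].items():
    print(f"{mod}: top term {rec['top_term']} "
          f"({rec['n_significant']} significant of {rec['n_terms_tested']} tested)")
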