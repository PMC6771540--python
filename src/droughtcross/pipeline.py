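"""End-to-end orchestration of the comparative drought-response analysis.

``run_pipeline`` drives the stages in dependency order on a single config
and seed: simulate (or load) inputs -> per-species expression filtering ->
reciprocal-best-hit orthology and EMO assembly -> fold-change and timing
classification -> permutation overlap significance -> co-expression module
detection with module-trait statistics -> term enrichment -> rosette
phenotyping.  Every intermediate is written as TSV/JSON under the working
directory and a machine-readable report summarizes all counts; a rerun
with the same config and seed reproduces the report bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression as cx
from . import enrichment as en
from . import orthology as orth
from . import phenotype as ph
from . import timing as tm
from .expression import (
    ExpressionMatrix, aggregate_transcripts_to_genes, expression_filter,
    log2_transform, read_sample_metadata, read_tpm_table,
    read_transcript_gene_map, write_tpm_table,
)
from .overlap import permutation_overlap_test
from .simulate import (
    GroundTruth, SimulationConfig, simulate_annotations, simulate_expression,
    simulate_growth, simulate_orthology, write_blast_tab,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "expression", "orthology", "de", "timing",
              "overlap", "modules", "enrich", "phenotype")


@dataclass
class PipelineConfig:
    seed: int = 0
    workdir: str = "pipeline_out"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # synthetic scenario
    n_genes: int = 5000
    # expression
    pseudocount: float = 1.0
    expression_threshold: float = 1.0
    # orthology
    max_evalue: float = 1e-3
    # differential regulation
    up_threshold: float = 1.0
    down_threshold: float = -1.0
    # permutation overlap
    n_permutations: int = 1000
    # co-expression network
    beta: float = 16.0
    network_type: str = "unsigned"
    min_module_size: int = 30
    cut_height_fraction: float = 0.99
    merge_dissimilarity: float = 0.1
    fdr_threshold: float = 0.05

    def network_params(self) -> cx.NetworkParams:
        return cx.NetworkParams(
            beta=self.beta, network_type=self.network_type,
            min_module_size=self.min_module_size,
            cut_height_fraction=self.cut_height_fraction,
            merge_dissimilarity=self.merge_dissimilarity,
        )


def validate_config(path) -> tuple[PipelineConfig | None, list[str]]:
    """Load a YAML config, returning either a typed config or every
    violation found, each naming the offending field."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except OSError as exc:
        return None, [f"config unreadable: {exc}"]
    errors = []
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    for k in sorted(unknown):
        errors.append(f"{k}: unknown field")
    cfg_kwargs = {k: v for k, v in raw.items() if k in known}
    cfg = PipelineConfig(**cfg_kwargs)
    if cfg.beta <= 0:
        errors.append("beta: must be positive")
    if not 0 < cfg.cut_height_fraction <= 1:
        errors.append("cut_height_fraction: must be in (0, 1]")
    if not 0 <= cfg.merge_dissimilarity <= 2:
        errors.append("merge_dissimilarity: must be in [0, 2]")
    if cfg.min_module_size < 1:
        errors.append("min_module_size: must be >= 1")
    if cfg.n_permutations < 1:
        errors.append("n_permutations: must be >= 1")
    if not cfg.up_threshold > cfg.down_threshold:
        errors.append("up_threshold: must exceed down_threshold")
    if cfg.expression_threshold < 0:
        errors.append("expression_threshold: must be nonnegative")
    if cfg.n_genes < 1:
        errors.append("n_genes: must be positive")
    if cfg.network_type not in ("unsigned", "signed"):
        errors.append("network_type: must be 'unsigned' or 'signed'")
    bad_stages = [s for s in cfg.stages if s not in ALL_STAGES]
    for s in bad_stages:
        errors.append(f"stages: unknown stage {s!r}")
    if errors:
        return None, errors
    return cfg, []


def _write_simulated_inputs(cfg: PipelineConfig, indir: Path) -> GroundTruth:
    sim = SimulationConfig(seed=cfg.seed, n_genes=cfg.n_genes)
    matrices, tg_maps, truth = simulate_expression(sim)
    indir.mkdir(parents=True, exist_ok=True)
    metas = []
    for sp, m in matrices.items():
        write_tpm_table(m, indir / f"{sp}_transcript_tpm.tsv")
        tg_maps[sp].to_csv(indir / f"{sp}_transcript_gene_map.tsv",
                           sep="\t", index=False)
        metas.append(m.samples)
    pd.concat(metas).to_csv(indir / "sample_metadata.tsv", sep="\t", index=False)
    hits, _ = simulate_orthology(sim, truth)
    for (a, b), hlist in hits.items():
        write_blast_tab(hlist, indir / f"{a}_vs_{b}.blast.tsv")
    simulate_annotations(sim, truth).to_csv(
        indir / "annotations.tsv", sep="\t", index=False)
    growth = simulate_growth(sim, truth)
    growth.to_csv(indir / "rosette_series.tsv", sep="\t", index=False)
    surv_rows = [
        {"species": sp, "replicate": ri + 1, "plant": pi + 1, "survived": s}
        for sp, reps in truth.survival.items()
        for ri, rep in enumerate(reps)
        for pi, s in enumerate(rep)
    ]
    pd.DataFrame(surv_rows).to_csv(indir / "survival.tsv", sep="\t", index=False)
    truth.to_json(indir / "ground_truth.json")
    return truth


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages and return the report dict (also
    written to ``workdir/report.json``)."""
    work = Path(cfg.workdir)
    indir = work / "inputs"
    outdir = work / "outputs"
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}
    species = list(SimulationConfig().species)

    if "simulate" in cfg.stages:
        _write_simulated_inputs(cfg, indir)
        report["stages"]["simulate"] = {
            "n_gene_families": cfg.n_genes, "species": species,
        }
    else:
        report["stages"]["simulate"] = "skipped"

    # --- expression -------------------------------------------------------
    gene_tpm: dict[str, ExpressionMatrix] = {}
    gene_log2: dict[str, ExpressionMatrix] = {}
    expressed: dict[str, set[str]] = {}
    if "expression" in cfg.stages:
        meta = read_sample_metadata(indir / "sample_metadata.tsv")
        exp_rep = {}
        for sp in species:
            sp_meta = meta[meta["species"] == sp]
            tx = read_tpm_table(indir / f"{sp}_transcript_tpm.tsv", sp_meta)
            tg = read_transcript_gene_map(indir / f"{sp}_transcript_gene_map.tsv")
            genes = aggregate_transcripts_to_genes(tx, tg)
            log2 = log2_transform(genes, cfg.pseudocount)
            filt = expression_filter(log2, cfg.expression_threshold)
            gene_tpm[sp] = genes
            gene_log2[sp] = filt
            expressed[sp] = set(filt.feature_ids)
            write_tpm_table(genes, outdir / f"{sp}_gene_tpm.tsv")
            exp_rep[sp] = {
                "n_transcripts": tx.n_features,
                "n_genes": genes.n_features,
                "n_expressed": len(expressed[sp]),
            }
        report["stages"]["expression"] = exp_rep
    else:
        report["stages"]["expression"] = "skipped"

    # --- orthology --------------------------------------------------------
    emo = None
    if "orthology" in cfg.stages:
        if not expressed:
            raise RuntimeError("orthology stage requires the expression stage")
        def pair_hits(a, b):
            return orth.parse_blast_tab(indir / f"{a}_vs_{b}.blast.tsv",
                                        cfg.max_evalue)
        a, b, c = species
        rbh_ab = orth.reciprocal_best_hits(pair_hits(a, b), pair_hits(b, a))
        rbh_ac = orth.reciprocal_best_hits(pair_hits(a, c), pair_hits(c, a))
        rbh_bc = orth.reciprocal_best_hits(pair_hits(b, c), pair_hits(c, b))
        emo = orth.build_emo_table(rbh_ab, rbh_ac, rbh_bc, expressed,
                                   species=tuple(species))
        emo.write_tsv(outdir / "emo_table.tsv")
        report["stages"]["orthology"] = {
            "n_pairs": {f"{a}-{b}": len(rbh_ab), f"{a}-{c}": len(rbh_ac),
                        f"{b}-{c}": len(rbh_bc)},
            "n_emos": len(emo),
            "n_inconsistent_triangles": emo.n_inconsistent_triangles,
        }
    else:
        report["stages"]["orthology"] = "skipped"

    # --- differential regulation -----------------------------------------
    fc_tables: dict[str, pd.DataFrame] = {}
    calls: dict[str, pd.DataFrame] = {}
    if "de" in cfg.stages:
        de_rep = {}
        for sp in species:
            expressed_tpm = gene_tpm[sp].subset_features(
                [g for g in gene_tpm[sp].feature_ids if g in expressed[sp]])
            fc = tm.log2_fold_change(expressed_tpm, cfg.pseudocount)
            called = tm.call_regulated(fc, cfg.up_threshold, cfg.down_threshold)
            fc_tables[sp] = fc
            calls[sp] = called
            called.to_csv(outdir / f"{sp}_fold_changes.tsv", sep="\t", index=False)
            counts = tm.de_counts(called)
            de_rep[sp] = {
                f"{r.timepoint}_{r.status}": int(r.n) for r in counts.itertuples()
            }
            specific = tm.drought_specific_genes(gene_log2[sp],
                                                 cfg.expression_threshold)
            de_rep[sp]["n_drought_specific"] = len(specific)
        report["stages"]["de"] = de_rep
    else:
        report["stages"]["de"] = "skipped"

    # --- timing classification -------------------------------------------
    emo_frame = None
    stress_tps = None
    if "timing" in cfg.stages:
        if emo is None or not fc_tables:
            raise RuntimeError("timing stage requires orthology and de stages")
        emo_frame = emo.to_frame()
        emo_frame.index = [f"EMO{i:05d}" for i in range(len(emo_frame))]
        tp_order = gene_tpm[species[0]].timepoint_order
        stress_tps = tp_order[1:]
        timing_table = tm.classify_emo_timing(
            fc_tables, emo_frame, stress_timepoints=stress_tps,
            up=cfg.up_threshold)
        timing_table.to_csv(outdir / "emo_timing.tsv", sep="\t", index=False)
        seg_counts = timing_table["segment"].value_counts().to_dict()
        report["stages"]["timing"] = {
            "segment_counts": {k: int(v) for k, v in sorted(seg_counts.items())},
            "n_induced_emos": int((timing_table["segment"] != "none").sum()),
        }
    else:
        report["stages"]["timing"] = "skipped"

    # --- overlap significance --------------------------------------------
    if "overlap" in cfg.stages:
        if emo_frame is None:
            raise RuntimeError("overlap stage requires the timing stage")
        gene_to_emo = {}
        for sp in species:
            gene_to_emo[sp] = dict(zip(emo_frame[sp], emo_frame.index))
        background = set(emo_frame.index)
        ov_rep = {}
        for tp in stress_tps:
            for direction in ("up", "down"):
                sets = {}
                for sp in species:
                    sub = calls[sp]
                    hit_genes = sub[(sub["timepoint"] == tp)
                                    & (sub["status"] == direction)]["gene_id"]
                    sets[sp] = {gene_to_emo[sp][g] for g in hit_genes
                                if g in gene_to_emo[sp]}
                regions = tm.venn_overlaps(sets)
                observed = regions["&".join(species)]
                res = permutation_overlap_test(
                    background, [len(sets[sp]) for sp in species], observed,
                    n=cfg.n_permutations, seed=cfg.seed + 10)
                ov_rep[f"{tp}_{direction}"] = {
                    "venn": regions,
                    "observed_triple": observed,
                    "p_text": res.p_text,
                    "null_mean": round(res.null_mean, 6),
                }
        report["stages"]["overlap"] = ov_rep
    else:
        report["stages"]["overlap"] = "skipped"

    # --- co-expression modules -------------------------------------------
    modules = None
    emo_log2 = None
    if "modules" in cfg.stages:
        if emo_frame is None:
            raise RuntimeError("modules stage requires the timing stage")
        blocks, col_meta = [], []
        for sp in species:
            vals = gene_log2[sp].values.loc[emo_frame[sp]].to_numpy()
            blocks.append(vals)
            col_meta.append(gene_log2[sp].samples)
        joint_meta = pd.concat(col_meta)
        emo_log2 = ExpressionMatrix(
            pd.DataFrame(np.hstack(blocks), index=emo_frame.index,
                         columns=joint_meta.index),
            joint_meta, "log2tpm")
        modules = cx.detect_modules(emo_log2, cfg.network_params())
        modules.assignments.rename_axis("emo_id").to_frame().to_csv(
            outdir / "module_assignments.tsv", sep="\t")
        modules.eigengenes.rename_axis("module").to_csv(
            outdir / "module_eigengenes.tsv", sep="\t")
        traits = cx.encode_traits(joint_meta, emo_log2.timepoint_order)
        mt = cx.module_trait_correlation(modules.eigengenes, traits,
                                         cfg.fdr_threshold)
        mt.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
        report["stages"]["modules"] = {
            "n_modules": modules.n_modules,
            "module_sizes": {k: int(v) for k, v in modules.module_sizes.items()},
            "n_unassigned": int((modules.assignments == cx.UNASSIGNED).sum()),
            "n_significant_module_trait": int(mt["significant"].sum()),
        }
    else:
        report["stages"]["modules"] = "skipped"

    # --- enrichment -------------------------------------------------------
    if "enrich" in cfg.stages:
        if modules is None:
            raise RuntimeError("enrich stage requires the modules stage")
        table = en.read_annotation_tsv(indir / "annotations.tsv")
        emo_to_gene = dict(zip(emo_frame.index, emo_frame[species[0]]))
        universe = set(emo_to_gene.values())
        enr_rep = {}
        frames = []
        for mod in modules.eigengenes.index:
            members = modules.assignments.index[modules.assignments == mod]
            study = {emo_to_gene[e] for e in members}
            results = en.fisher_enrichment(study, universe, table)
            df = en.enrichment_frame(results)
            df.insert(0, "module", mod)
            frames.append(df)
            sig = df[df["fdr"] < cfg.fdr_threshold]
            enr_rep[mod] = {
                "n_terms_tested": len(df),
                "n_significant": len(sig),
                "top_term": df.iloc[0]["term_id"] if len(df) else None,
            }
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False)
        report["stages"]["enrich"] = enr_rep
    else:
        report["stages"]["enrich"] = "skipped"

    # --- phenotyping ------------------------------------------------------
    if "phenotype" in cfg.stages:
        rosette = ph.read_rosette_table(indir / "rosette_series.tsv")
        metrics = ph.growth_metrics_table(rosette)
        metrics.to_csv(outdir / "growth_metrics.tsv", sep="\t", index=False)
        surv = pd.read_csv(indir / "survival.tsv", sep="\t")
        phe_rep = {}
        for sp in species:
            sub = rosette[rosette["species"] == sp]
            ww = sub[sub["treatment"] == "WW"]
            wd = sub[sub["treatment"] == "WD"]
            day = ph.first_growth_reduction_day(ww, wd)
            ssub = surv[surv["species"] == sp]
            ss = ph.survival_rate(ssub["survived"], ssub["replicate"])
            msub = metrics[metrics["species"] == sp]
            phe_rep[sp] = {
                "first_growth_reduction_day": day,
                "survival_mean_percent": round(ss.mean_percent, 4),
                "survival_sd_percent": round(ss.sd_percent, 4),
                "median_stockiness": round(float(msub["stockiness"].median()), 6),
                "median_compactness": round(float(msub["compactness"].median()), 6),
            }
        report["stages"]["phenotype"] = phe_rep
    else:
        report["stages"]["phenotype"] = "skipped"

    payload = json.dumps(report, sort_keys=True, indent=1, default=str)
    report["report_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    with open(work / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1, default=str)
    return report


def write_default_config(path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(PipelineConfig()), fh, sort_keys=True)
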