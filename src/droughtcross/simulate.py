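"""Seeded generators for every input the pipeline consumes.

The generators emulate a three-species drought time course: Ath, Aly and
Esa rosettes sampled under well-watered (WW) and water-deficit (WD)
conditions at four timepoints (T0, T5, T11, T14) with three biological
replicates — 24 samples per species, 72 in total.  Alongside the emitted
files (transcript TPM tables, sample metadata, transcript->gene maps,
pairwise BLAST tabular hits, a gene->term annotation table and per-plant
rosette series) a :class:`GroundTruth` record stores what was planted:
co-expression module memberships and their latent signals, per-species
response timing profiles, one-to-one ortholog triples, growth divergence
days and survival outcomes.

Design notes
------------
* Expression is generated on the log2 scale: gene base levels are normal
  on log2 (log-normal TPM means); module members share a latent module
  signal at a configured within-module correlation; residual noise is
  log-normal (sigma in log2 units).
* Planted drought induction is defined on the pseudocounted fold-change
  scale: for a responder with planted effect ``lfc`` at a timepoint, the
  WD abundance is ``(tpm_ww + 1) * 2**lfc - 1``, so that with zero noise
  the measured log2((mean_WD + 1)/(mean_WW + 1)) equals the planted value
  exactly.
* WD rosette curves are paired counterfactuals of WW curves: each WD plant
  reuses its WW twin's noise stream and diverges only through the planted
  growth-rate reduction, isolating the treatment effect from sampling
  noise.  Independent (unpaired) groups are available for null
  calibration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, DEFAULT_TIMEPOINTS
from .orthology import BlastHit

SPECIES = ("Ath", "Aly", "Esa")


@dataclass
class ModuleSpec:
    """One planted co-expression module."""

    size: int = 60
    within_correlation: float = 0.8
    trait: str | None = None  # "treatment_wd", a species name, "timepoint" or None
    trait_strength: float = 0.7  # weight of the trait vector in the latent signal


@dataclass
class ResponseClassSpec:
    """A planted timing class: per-species log2FC profiles over timepoints."""

    name: str
    n: int
    profiles: dict[str, dict[str, float]]  # species -> {timepoint -> log2fc}


@dataclass
class OrthologySpec:
    fraction_one_to_one: float = 0.9  # families detectable as orthologs at all
    decoy_rate: float = 0.2  # chance of an extra lower-scoring paralog hit
    missing_rate: float = 0.05  # chance a species pair lacks hits for a family


@dataclass
class GrowthSpec:
    n_plants_per_group: int = 25
    days: tuple = tuple(range(15))
    max_area: dict = field(default_factory=lambda: {"Ath": 1500.0, "Aly": 1200.0, "Esa": 900.0})
    growth_rate: float = 0.45  # logistic rate, day^-1
    midpoint_day: float = 7.0
    divergence_day: dict = field(default_factory=lambda: {"Ath": 5, "Aly": 3, "Esa": 8})
    rate_reduction: float = 0.5  # WD growth-increment multiplier is 1 - this
    plant_scale_sigma: float = 0.10  # per-plant size variability (log scale)
    paired: bool = True  # WD curves reuse WW noise (counterfactual pairing)
    survival_prob: dict = field(default_factory=lambda: {"Ath": 0.76, "Aly": 0.96, "Esa": 0.98})
    n_survival_replicates: int = 3
    n_plants_per_replicate: int = 27


def default_response_classes() -> list[ResponseClassSpec]:
    """Planted timing classes mirroring the qualitative species behavior:
    Aly responds earliest, Ath late but broadly, Esa moderately."""
    def prof(**kw):
        base = {"T5": 0.0, "T11": 0.0, "T14": 0.0}
        base.update(kw)
        return base

    return [
        ResponseClassSpec("common_synchronous", 120, {
            "Ath": prof(T11=3.0, T14=2.5),
            "Aly": prof(T11=3.0, T14=2.5),
            "Esa": prof(T11=3.0, T14=2.5),
        }),
        ResponseClassSpec("common_shifted", 120, {
            "Ath": prof(T14=3.0),
            "Aly": prof(T5=3.0, T11=2.5, T14=2.0),
            "Esa": prof(T11=3.0, T14=2.5),
        }),
        ResponseClassSpec("Ath_specific", 250, {
            "Ath": prof(T14=3.0),
            "Aly": prof(),
            "Esa": prof(),
        }),
        ResponseClassSpec("Aly_specific", 100, {
            "Ath": prof(),
            "Aly": prof(T11=3.0, T14=2.0),
            "Esa": prof(),
        }),
        ResponseClassSpec("Esa_specific", 60, {
            "Ath": prof(),
            "Aly": prof(),
            "Esa": prof(T11=2.5, T14=2.0),
        }),
    ]


def default_module_specs() -> list[ModuleSpec]:
    return [
        ModuleSpec(150, 0.8, "treatment_wd"),
        ModuleSpec(120, 0.8, "Esa"),
        ModuleSpec(100, 0.8, "Aly"),
        ModuleSpec(90, 0.8, None),
    ]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic scenario."""

    seed: int = 0
    species: tuple = SPECIES
    n_genes: int = 5000  # ortholog families
    max_transcripts_per_gene: int = 3
    timepoints: tuple = DEFAULT_TIMEPOINTS
    conditions: tuple = ("WW", "WD")
    n_replicates: int = 3
    modules: list[ModuleSpec] = field(default_factory=default_module_specs)
    responses: list[ResponseClassSpec] = field(default_factory=default_response_classes)
    base_mean_log2: float = 4.5
    base_sd_log2: float = 2.5
    planted_min_log2: float = 3.0  # floor for module/responder base levels
    species_offset_sd: float = 0.3
    noise_sigma: float = 0.4  # residual log2 noise
    module_amplitude: float = 1.0  # log2 amplitude of module signals
    orthology: OrthologySpec = field(default_factory=OrthologySpec)
    growth: GrowthSpec = field(default_factory=GrowthSpec)

    def validate(self) -> None:
        n_planted = sum(m.size for m in self.modules) + sum(r.n for r in self.responses)
        if n_planted > self.n_genes:
            raise ValueError(
                f"planted genes ({n_planted}) exceed n_genes ({self.n_genes})"
            )
        for m in self.modules:
            if not 0 <= m.within_correlation <= 1:
                raise ValueError("within_correlation must be in [0, 1]")
        for spec in (self.orthology.fraction_one_to_one,
                     self.orthology.decoy_rate, self.orthology.missing_rate):
            if not 0 <= spec <= 1:
                raise ValueError("orthology fractions must be in [0, 1]")
        if self.noise_sigma < 0 or self.module_amplitude < 0:
            raise ValueError("sigmas must be nonnegative")
        if self.max_transcripts_per_gene < 1:
            raise ValueError("need at least one transcript per gene")


@dataclass
class GroundTruth:
    """What the generators planted, keyed by ortholog family index."""

    module_assignments: dict[int, str] = field(default_factory=dict)
    module_latents: dict[str, list[float]] = field(default_factory=dict)
    sample_ids: list[str] = field(default_factory=list)
    response_class: dict[int, str] = field(default_factory=dict)
    response_profiles: dict[int, dict[str, dict[str, float]]] = field(default_factory=dict)
    ortholog_triples: list[tuple[str, str, str]] = field(default_factory=list)
    divergence_day: dict[str, int] = field(default_factory=dict)
    survival: dict[str, list[list[bool]]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=list)


def gene_id(species: str, family: int) -> str:
    return f"{species}G{family:05d}"


def _sample_frame(cfg: SimulationConfig, species: str) -> pd.DataFrame:
    rows = []
    for cond in cfg.conditions:
        for tp in cfg.timepoints:
            for rep in range(1, cfg.n_replicates + 1):
                sid = f"{species}_{cond}_{tp}_R{rep}"
                rows.append({"sample_id": sid, "species": species,
                             "condition": cond, "timepoint": tp, "replicate": rep})
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def _trait_vector(trait: str | None, meta: pd.DataFrame, cfg: SimulationConfig) -> np.ndarray | None:
    if trait is None:
        return None
    if trait == "treatment_wd":
        v = (meta["condition"] == "WD").to_numpy(float)
    elif trait == "timepoint":
        rank = {tp: i for i, tp in enumerate(cfg.timepoints)}
        v = meta["timepoint"].map(rank).to_numpy(float)
    elif trait in cfg.species:
        v = (meta["species"] == trait).to_numpy(float)
    else:
        raise ValueError(f"unknown trait {trait!r}")
    v = v - v.mean()
    sd = v.std()
    return v / sd if sd > 0 else v


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[dict[str, ExpressionMatrix], dict[str, pd.DataFrame], GroundTruth]:
    """Per-species transcript-level TPM matrices, transcript->gene maps and
    the planted ground truth.  Deterministic under ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()

    metas = {sp: _sample_frame(cfg, sp) for sp in cfg.species}
    all_meta = pd.concat(metas.values())
    n_all = len(all_meta)
    truth.sample_ids = list(all_meta.index)

    # allocate families: modules first, then responders, then background
    cursor = 0
    module_members: dict[str, list[int]] = {}
    for mi, mspec in enumerate(cfg.modules):
        label = f"PM{mi + 1}"
        fams = list(range(cursor, cursor + mspec.size))
        cursor += mspec.size
        module_members[label] = fams
        for f in fams:
            truth.module_assignments[f] = label
    for rspec in cfg.responses:
        fams = list(range(cursor, cursor + rspec.n))
        cursor += rspec.n
        for f in fams:
            truth.response_class[f] = rspec.name
            truth.response_profiles[f] = {
                sp: dict(prof) for sp, prof in rspec.profiles.items()
            }

    # base log2 levels per family, planted genes floored at planted_min_log2
    mu = rng.normal(cfg.base_mean_log2, cfg.base_sd_log2, size=cfg.n_genes)
    planted = np.zeros(cfg.n_genes, dtype=bool)
    planted[:cursor] = True
    mu[planted] = np.maximum(mu[planted], cfg.planted_min_log2)

    # latent module signals across the joint 72-sample axis; the
    # sqrt(1 - rho) idiosyncratic term IS the module genes' noise, so the
    # realized pairwise correlation matches within_correlation
    log2_signal = np.zeros((cfg.n_genes, n_all))
    is_module_gene = np.zeros(cfg.n_genes, dtype=bool)
    for (label, fams), mspec in zip(module_members.items(), cfg.modules):
        latent = rng.standard_normal(n_all)
        tv = _trait_vector(mspec.trait, all_meta, cfg)
        if tv is not None:
            w = mspec.trait_strength
            latent = math.sqrt(max(0.0, 1 - w * w)) * latent + w * tv
        truth.module_latents[label] = [float(x) for x in latent]
        rho = mspec.within_correlation
        for f in fams:
            eps = rng.standard_normal(n_all)
            z = math.sqrt(rho) * latent + math.sqrt(1 - rho) * eps
            log2_signal[f] = cfg.module_amplitude * z
            is_module_gene[f] = True

    # species offsets and residual noise; then to TPM
    matrices: dict[str, ExpressionMatrix] = {}
    tg_maps: dict[str, pd.DataFrame] = {}
    col_of = {sid: i for i, sid in enumerate(all_meta.index)}
    for sp in cfg.species:
        meta = metas[sp]
        offs = rng.normal(0.0, cfg.species_offset_sd, size=cfg.n_genes)
        cols = [col_of[sid] for sid in meta.index]
        log2 = mu[:, None] + offs[:, None] + log2_signal[:, cols]
        if cfg.noise_sigma > 0:
            noise = rng.normal(0.0, cfg.noise_sigma, size=log2.shape)
            noise[is_module_gene] = 0.0
            log2 = log2 + noise
        tpm = np.power(2.0, log2)
        # planted drought induction on the pseudocounted fold-change scale
        for f, profs in truth.response_profiles.items():
            prof = profs.get(sp)
            if not prof:
                continue
            for j, sid in enumerate(meta.index):
                row = meta.loc[sid]
                if row["condition"] != "WD":
                    continue
                lfc = prof.get(row["timepoint"], 0.0)
                if lfc:
                    tpm[f, j] = (tpm[f, j] + 1.0) * 2.0 ** lfc - 1.0
        genes = [gene_id(sp, f) for f in range(cfg.n_genes)]
        gene_mat = pd.DataFrame(tpm, index=pd.Index(genes, name="gene_id"),
                                columns=meta.index)
        # split each gene's TPM over 1..max transcripts by Dirichlet weights
        n_tx = rng.integers(1, cfg.max_transcripts_per_gene + 1, size=cfg.n_genes)
        tx_rows, tx_ids, map_rows = [], [], []
        for f, g in enumerate(genes):
            k = int(n_tx[f])
            w = rng.dirichlet(np.full(k, 5.0)) if k > 1 else np.ones(1)
            for t in range(k):
                tid = f"{g}.{t + 1}"
                tx_ids.append(tid)
                tx_rows.append(gene_mat.iloc[f].to_numpy() * w[t])
                map_rows.append({"transcript_id": tid, "gene_id": g})
        tx_mat = pd.DataFrame(
            np.vstack(tx_rows), index=pd.Index(tx_ids, name="feature_id"),
            columns=meta.index,
        )
        matrices[sp] = ExpressionMatrix(tx_mat, meta, "tpm")
        tg_maps[sp] = pd.DataFrame(map_rows)
    return matrices, tg_maps, truth


def simulate_orthology(
    cfg: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[dict[tuple[str, str], list[BlastHit]], list[tuple[str, ...]]]:
    """Pairwise BLAST-style hit lists and the planted one-to-one triples.

    True orthologs get mutual top hits; paralog decoys (rate
    ``decoy_rate``) get strictly lower bitscores so they can never displace
    a true reciprocal best hit; families hit by ``missing_rate`` lack hits
    for that species pair.  Uses an independent seed stream
    (``cfg.seed + 1``) so expression and orthology can be generated in any
    order.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    sp = list(cfg.species)
    pairs = [(a, b) for i, a in enumerate(sp) for b in sp[i + 1:]]
    detectable = rng.random(cfg.n_genes) < cfg.orthology.fraction_one_to_one

    hits: dict[tuple[str, str], list[BlastHit]] = {}
    for a, b in pairs:
        hits[(a, b)] = []
        hits[(b, a)] = []
    present: dict[tuple[str, str], np.ndarray] = {}
    for a, b in pairs:
        present[(a, b)] = detectable & (rng.random(cfg.n_genes) >= cfg.orthology.missing_rate)

    for a, b in pairs:
        for f in np.flatnonzero(present[(a, b)]):
            bitscore = round(float(rng.uniform(300.0, 800.0)), 1)
            pident = round(float(rng.uniform(60.0, 95.0)), 2)
            evalue = 10.0 ** (-min(bitscore / 4.0, 180.0))
            ga, gb = gene_id(a, int(f)), gene_id(b, int(f))
            hits[(a, b)].append(BlastHit(ga, gb, pident, evalue, bitscore))
            hits[(b, a)].append(BlastHit(gb, ga, pident, evalue, bitscore))
            # paralog decoys at strictly lower score
            for qdir, (q, s) in (("fwd", (a, b)), ("rev", (b, a))):
                if rng.random() < cfg.orthology.decoy_rate:
                    other = int(rng.integers(0, cfg.n_genes - 1))
                    if other >= f:
                        other += 1
                    dscore = round(bitscore * float(rng.uniform(0.4, 0.8)), 1)
                    devalue = 10.0 ** (-min(dscore / 4.0, 180.0))
                    hits[(q, s)].append(BlastHit(
                        gene_id(q, int(f)), gene_id(s, other),
                        round(pident * 0.8, 2), devalue, dscore,
                    ))

    triple_mask = np.ones(cfg.n_genes, dtype=bool)
    for key, mask in present.items():
        triple_mask &= mask
    triples = [tuple(gene_id(s, int(f)) for s in sp) for f in np.flatnonzero(triple_mask)]
    if truth is not None:
        truth.ortholog_triples = triples
    return hits, triples


def write_blast_tab(hits: list[BlastHit], path) -> None:
    """Write 12-column BLAST tabular (outfmt 6)."""
    with open(path, "w") as fh:
        for h in hits:
            length = 250
            mismatch = int(round(length * (100.0 - h.pident) / 100.0))
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pident}\t{length}\t{mismatch}\t0"
                f"\t1\t{length}\t1\t{length}\t{h.evalue:.3g}\t{h.bitscore}\n"
            )


def simulate_annotations(
    cfg: SimulationConfig, truth: GroundTruth, n_background_terms: int = 20,
    genes_per_term: int = 40, module_term_coverage: float = 0.6,
) -> pd.DataFrame:
    """Gene -> term table (on species-A gene ids) with one term enriched in
    each planted module plus uniform background terms."""
    rng = np.random.default_rng(cfg.seed + 2)
    sp = cfg.species[0]
    rows = []
    labels = sorted(set(truth.module_assignments.values()))
    for label in labels:
        term = f"TERM_{label}"
        fams = [f for f, lab in truth.module_assignments.items() if lab == label]
        take = max(1, int(round(module_term_coverage * len(fams))))
        chosen = rng.choice(fams, size=take, replace=False)
        for f in chosen:
            rows.append({"gene_id": gene_id(sp, int(f)), "term_id": term})
        extra = rng.integers(0, cfg.n_genes, size=max(1, take // 4))
        for f in extra:
            rows.append({"gene_id": gene_id(sp, int(f)), "term_id": term})
    for t in range(n_background_terms):
        fams = rng.integers(0, cfg.n_genes, size=genes_per_term)
        for f in fams:
            rows.append({"gene_id": gene_id(sp, int(f)), "term_id": f"TERM_BG{t:03d}"})
    return pd.DataFrame(rows).drop_duplicates(ignore_index=True)


def simulate_growth(
    cfg: SimulationConfig, truth: GroundTruth | None = None,
    noise_sigma: float | None = None,
) -> pd.DataFrame:
    """Per-plant rosette series with planted WD growth divergence and
    per-species survival outcomes.

    Returns a long table (plant_id, species, treatment, day, area,
    perimeter, hull_area, survived).  Uses seed stream ``cfg.seed + 3``.
    """
    g = cfg.growth
    rng = np.random.default_rng(cfg.seed + 3)
    if noise_sigma is None:
        noise_sigma = g.plant_scale_sigma
    rows = []
    days = np.asarray(g.days, dtype=float)
    for sp in cfg.species:
        K = g.max_area[sp]
        d_div = g.divergence_day[sp]
        if truth is not None:
            truth.divergence_day[sp] = d_div
        log_ww_mean = np.log(K / (1.0 + np.exp(-g.growth_rate * (days - g.midpoint_day))))
        incr = np.diff(log_ww_mean)
        incr_wd = incr * np.where(days[1:] >= d_div, 1.0 - g.rate_reduction, 1.0)
        log_wd_mean = np.concatenate([[log_ww_mean[0]], log_ww_mean[0] + np.cumsum(incr_wd)])
        for i in range(g.n_plants_per_group):
            scale = rng.normal(0.0, noise_sigma)
            wobble = rng.normal(0.0, noise_sigma / 2.0, size=len(days))
            for treatment, log_mean in (("WW", log_ww_mean), ("WD", log_wd_mean)):
                if not g.paired and treatment == "WD":
                    scale = rng.normal(0.0, noise_sigma)
                    wobble = rng.normal(0.0, noise_sigma / 2.0, size=len(days))
                areas = np.exp(log_mean + scale + wobble)
                stock = np.clip(rng.uniform(0.35, 0.75, size=len(days)), 1e-6, 1.0)
                compact = rng.uniform(0.55, 0.95, size=len(days))
                perims = np.sqrt(4.0 * math.pi * areas / stock)
                hulls = areas / compact
                pid = f"{sp}_{treatment}_P{i + 1:03d}"
                survived = True
                if treatment == "WD":
                    survived = bool(rng.random() < g.survival_prob[sp])
                for j, day in enumerate(days):
                    rows.append({
                        "plant_id": pid, "species": sp, "treatment": treatment,
                        "day": float(day), "area": areas[j],
                        "perimeter": perims[j], "hull_area": hulls[j],
                        "survived": survived,
                    })
    table = pd.DataFrame(rows)
    if truth is not None:
        for sp in cfg.species:
            p = g.survival_prob[sp]
            reps = [
                [bool(x) for x in rng.random(g.n_plants_per_replicate) < p]
                for _ in range(g.n_survival_replicates)
            ]
            truth.survival[sp] = reps
    return table
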