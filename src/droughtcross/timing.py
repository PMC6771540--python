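"""Fold-change calling and cross-species response-timing classification.

For each gene and timepoint, the drought response is summarized as
log2((mean TPM_WD + c) / (mean TPM_WW + c)) over replicate means with
pseudocount c = 1.  Genes are called up- or down-regulated at inclusive
thresholds (log2FC >= 1 / <= -1).  For expressed mutual orthologs the
per-species fold-change profiles over the stress course (T5, T11, T14) are
reduced to a timing profile — induced or not, first induced timepoint,
highest-peak timepoint — and the three species' profiles to a canonical
segment code (common-synchronous, common-shifted, pair and species-specific
patterns).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, timepoint_sort_key

logger = logging.getLogger(__name__)

UP_THRESHOLD = 1.0
DOWN_THRESHOLD = -1.0


def log2_fold_change(m: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene, per-timepoint log2 fold change WD over WW.

    Uses replicate means on the TPM scale with a pseudocount:
    log2((mean_WD + c) / (mean_WW + c)).  Timepoints missing either
    condition are skipped with a warning.

    Returns a tidy frame with columns gene_id, timepoint, log2fc.
    """
    if m.scale != "tpm":
        raise ValueError("fold changes are computed from TPM values")
    frames = []
    for tp in m.timepoint_order:
        sel = m.samples["timepoint"] == tp
        conds = set(m.samples.loc[sel.to_numpy(), "condition"])
        if not {"WW", "WD"} <= conds:
            logger.warning("timepoint %s missing a condition; skipped", tp)
            continue
        tp_samples = m.samples.loc[sel.to_numpy()]
        wd_cols = tp_samples.index[tp_samples["condition"] == "WD"]
        ww_cols = tp_samples.index[tp_samples["condition"] == "WW"]
        mean_wd = m.values[wd_cols].mean(axis=1)
        mean_ww = m.values[ww_cols].mean(axis=1)
        fc = np.log2((mean_wd + pseudocount) / (mean_ww + pseudocount))
        frames.append(pd.DataFrame({
            "gene_id": m.values.index, "timepoint": tp, "log2fc": fc.to_numpy(),
        }))
    if not frames:
        return pd.DataFrame(columns=["gene_id", "timepoint", "log2fc"])
    return pd.concat(frames, ignore_index=True)


def call_regulated(
    fc: pd.DataFrame, up: float = UP_THRESHOLD, down: float = DOWN_THRESHOLD
) -> pd.DataFrame:
    """Add a status column: 'up' iff log2fc >= up, 'down' iff log2fc <= down
    (both inclusive), else 'ns'."""
    if not up > down:
        raise ValueError("up threshold must exceed down threshold")
    out = fc.copy()
    status = np.where(
        out["log2fc"] >= up, "up", np.where(out["log2fc"] <= down, "down", "ns")
    )
    out["status"] = status
    return out


def de_counts(calls: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Count up/down calls per timepoint (and any extra grouping columns)."""
    by = ["timepoint"] + (by or [])
    sub = calls[calls["status"] != "ns"]
    counts = (
        sub.groupby(by + ["status"], sort=False).size().rename("n").reset_index()
    )
    return counts


def drought_specific_genes(
    m_log2: ExpressionMatrix, threshold: float = 1.0
) -> set[str]:
    """Genes expressed only in response to drought: log2TPM >= threshold in
    at least one WD sample after stress onset, and below threshold in every
    WW sample and every T0 sample."""
    if m_log2.scale != "log2tpm":
        raise ValueError("drought-specific calling operates on log2tpm")
    meta = m_log2.samples
    t0 = m_log2.timepoint_order[0]
    is_t0 = (meta["timepoint"] == t0).to_numpy()
    is_wd = (meta["condition"] == "WD").to_numpy()
    qualifying = m_log2.values.loc[:, is_wd & ~is_t0]
    disqualifying = m_log2.values.loc[:, ~is_wd | is_t0]
    on_in_wd = (qualifying >= threshold).any(axis=1)
    off_elsewhere = (disqualifying < threshold).all(axis=1)
    return set(m_log2.values.index[on_in_wd & off_elsewhere])


@dataclass
class TimingProfile:
    """Cross-species response timing of one expressed mutual ortholog."""

    emo_id: str
    induced: dict[str, bool]
    first_peak: dict[str, str | None]
    highest_peak: dict[str, str | None]
    segment: str


def _species_timing(fc: dict[str, float], up: float) -> tuple[bool, str | None, str | None]:
    tps = sorted(fc, key=timepoint_sort_key)
    induced_tps = [tp for tp in tps if fc[tp] >= up]
    if not induced_tps:
        return False, None, None
    first = induced_tps[0]
    highest = max(induced_tps, key=lambda tp: (fc[tp], -tps.index(tp)))
    # earliest wins ties: max() keeps the first of equals because the key's
    # second component prefers earlier indices
    return True, first, highest


def segment_code(induced_species: list[str], first_peaks: dict[str, str]) -> str:
    """Canonical segment label from which species are induced and whether
    their first induced timepoints agree."""
    if not induced_species:
        return "none"
    if len(induced_species) == 1:
        return f"{induced_species[0]}-specific"
    peaks = {first_peaks[sp] for sp in induced_species}
    sync = "synchronous" if len(peaks) == 1 else "shifted"
    if len(induced_species) == 2:
        return f"{'+'.join(induced_species)}-{sync}"
    return f"common-{sync}"


def classify_peak_timing(
    emo_id: str,
    fc_by_species: dict[str, dict[str, float]],
    up: float = UP_THRESHOLD,
) -> TimingProfile:
    """Reduce per-species fold-change profiles to a timing profile.

    ``fc_by_species`` maps species -> {timepoint -> log2fc} over the stress
    timepoints.  A species is induced iff any log2fc >= up; its first peak
    is the earliest such timepoint and its highest peak the timepoint of the
    maximal fold change among induced timepoints (earliest wins ties).
    """
    induced, first_peak, highest_peak = {}, {}, {}
    for sp, fc in fc_by_species.items():
        induced[sp], first_peak[sp], highest_peak[sp] = _species_timing(fc, up)
    induced_species = [sp for sp in fc_by_species if induced[sp]]
    seg = segment_code(induced_species, {sp: first_peak[sp] for sp in induced_species})
    return TimingProfile(emo_id, induced, first_peak, highest_peak, seg)


def classify_emo_timing(
    fc_tables: dict[str, pd.DataFrame],
    emo_frame: pd.DataFrame,
    stress_timepoints: list[str] | None = None,
    up: float = UP_THRESHOLD,
) -> pd.DataFrame:
    """Timing profiles for every EMO.

    ``fc_tables`` maps species -> tidy fold-change frame (per-species gene
    ids); ``emo_frame`` has one column per species holding the member gene
    id of each triple, indexed by EMO.  T0 is excluded by default: induction
    is relative to stress onset.
    """
    species = list(emo_frame.columns)
    lookups = {}
    for sp in species:
        t = fc_tables[sp]
        if stress_timepoints is not None:
            t = t[t["timepoint"].isin(stress_timepoints)]
        lookups[sp] = {
            g: dict(zip(sub["timepoint"], sub["log2fc"]))
            for g, sub in t.groupby("gene_id", sort=False)
        }
    rows = []
    for emo_id, row in emo_frame.iterrows():
        fc_by_species = {sp: lookups[sp].get(row[sp], {}) for sp in species}
        prof = classify_peak_timing(str(emo_id), fc_by_species, up=up)
        rec = {"emo_id": prof.emo_id, "segment": prof.segment}
        for sp in species:
            rec[f"{sp}_induced"] = prof.induced[sp]
            rec[f"{sp}_first_peak"] = prof.first_peak[sp]
            rec[f"{sp}_highest_peak"] = prof.highest_peak[sp]
        rows.append(rec)
    return pd.DataFrame(rows)


def venn_overlaps(sets: dict[str, set]) -> dict[str, int]:
    """All region counts of the Venn diagram of 2 or 3 named sets.

    Region keys join member names with '&' (e.g. 'Ath&Esa' = in Ath and Esa
    but not the others).  Counts sum to the size of the union.
    """
    names = list(sets)
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for members in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in members))
            for other in names:
                if other not in members:
                    inside = inside - sets[other]
            regions["&".join(members)] = len(inside)
    return regions
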