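"""TPM expression matrices with typed sample metadata.

The central in-memory object of the pipeline is :class:`ExpressionMatrix`:
a genes-(or transcripts-)by-samples table of TPM (transcripts per million)
values together with a sample annotation frame (species, watering condition,
timepoint, replicate).  All downstream stages — expression filtering,
fold-change calling, co-expression network construction — consume this
object, on either the raw TPM scale or the log2(TPM + pseudocount) scale.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("sample_id", "species", "condition", "timepoint", "replicate")
CONDITIONS = ("WW", "WD")
DEFAULT_TIMEPOINTS = ("T0", "T5", "T11", "T14")


def timepoint_sort_key(tp: str) -> tuple:
    """Order timepoints numerically when they look like 'T<number>'."""
    m = re.fullmatch(r"[Tt](\d+)", str(tp))
    if m:
        return (0, int(m.group(1)))
    return (1, str(tp))


def order_timepoints(timepoints) -> list[str]:
    """Total explicit order over a set of timepoint labels."""
    return sorted(set(map(str, timepoints)), key=timepoint_sort_key)


@dataclass
class ExpressionMatrix:
    """Features x samples abundance matrix.

    Parameters
    ----------
    values
        DataFrame, index = feature ids (transcripts or genes), columns =
        sample ids, nonnegative TPM when ``scale == "tpm"``.
    samples
        Sample metadata indexed by sample_id with columns
        species / condition / timepoint / replicate, one row per column
        of ``values``, in the same order.
    scale
        Either ``"tpm"`` or ``"log2tpm"``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "tpm"
    timepoint_order: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.scale not in ("tpm", "log2tpm"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample columns do not match metadata rows")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.samples.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        if self.scale == "tpm" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative TPM values")
        if not self.timepoint_order:
            self.timepoint_order = order_timepoints(self.samples["timepoint"])

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, mask) -> "ExpressionMatrix":
        """Subset by boolean mask (aligned to samples) or list of sample ids."""
        if isinstance(mask, pd.Series):
            mask = mask.to_numpy()
        sub = self.samples.loc[mask]
        return ExpressionMatrix(
            self.values.loc[:, sub.index], sub, self.scale, list(self.timepoint_order)
        )

    def subset_features(self, features) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(features)], self.samples, self.scale, list(self.timepoint_order)
        )


def read_sample_metadata(path) -> pd.DataFrame:
    """Read the sample annotation TSV (sample_id, species, condition,
    timepoint, replicate) and index it by sample_id."""
    meta = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file missing columns: {missing}")
    meta = meta.set_index("sample_id", drop=False)
    meta["replicate"] = meta["replicate"].astype(int)
    if (meta["replicate"] <= 0).any():
        raise ValueError("replicate numbers must be positive")
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    return meta


def read_tpm_table(path, metadata: pd.DataFrame) -> ExpressionMatrix:
    """Read a TSV expression table (first column feature id, one column per
    sample) and attach sample metadata.

    Every sample column must have a metadata row; a missing one raises with
    the column named.  Non-numeric cells raise with their row/column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    missing = [c for c in df.columns if c not in metadata.index]
    if missing:
        raise ValueError(f"no metadata for sample column(s): {missing}")
    try:
        values = df.astype(float)
    except ValueError:
        for col in df.columns:
            for rid, cell in df[col].items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {cell!r} at feature {rid!r}, sample {col!r}"
                    ) from None
        raise
    meta = metadata.loc[list(values.columns)]
    return ExpressionMatrix(values=values, samples=meta, scale="tpm")


def write_tpm_table(m: ExpressionMatrix, path) -> None:
    """Write the value matrix as a TSV round-trippable by read_tpm_table."""
    out = m.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.17g")  # bit-exact round trip


def read_transcript_gene_map(path) -> pd.DataFrame:
    """Two-column TSV transcript_id -> gene_id; one gene per transcript."""
    tg = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not {"transcript_id", "gene_id"} <= set(tg.columns):
        raise ValueError("map must have columns transcript_id, gene_id")
    if tg["transcript_id"].duplicated().any():
        raise ValueError("transcript maps to more than one gene")
    return tg


def aggregate_transcripts_to_genes(
    m: ExpressionMatrix, tg_map: pd.DataFrame, unmapped: str = "error"
) -> ExpressionMatrix:
    """Collapse transcript rows to gene rows by summing TPM per sample.

    Gene-level TPM is the sum of the TPM of the gene's transcripts, so when
    no transcript is dropped each sample's column total is conserved.
    ``unmapped`` controls transcripts absent from the map: ``"error"`` or
    ``"drop"``.
    """
    if m.scale != "tpm":
        raise ValueError("aggregate on the TPM scale, before log transform")
    if unmapped not in ("error", "drop"):
        raise ValueError("unmapped policy must be 'error' or 'drop'")
    lookup = dict(zip(tg_map["transcript_id"], tg_map["gene_id"]))
    missing = [t for t in m.values.index if t not in lookup]
    if missing:
        if unmapped == "error":
            raise ValueError(f"unmapped transcript(s): {missing[:5]}")
        logger.info("dropping %d unmapped transcripts", len(missing))
    keep = [t for t in m.values.index if t in lookup]
    vals = m.values.loc[keep]
    genes = pd.Index([lookup[t] for t in keep], name="gene_id")
    # groupby(sort=False) keeps first-appearance gene order
    agg = vals.groupby(genes, sort=False).sum()
    return ExpressionMatrix(agg, m.samples, "tpm", list(m.timepoint_order))


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(TPM + pseudocount); the working scale for filtering and networks."""
    if m.scale != "tpm":
        raise ValueError("input already log-transformed")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    vals = np.log2(m.values + pseudocount)
    return ExpressionMatrix(vals, m.samples, "log2tpm", list(m.timepoint_order))


def expression_filter(m: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Keep genes with at least one sample at or above ``threshold`` on the
    log2 scale (the boundary is inclusive).  With pseudocount 1 the default
    threshold of 1.0 corresponds to TPM >= 1."""
    if m.scale != "log2tpm":
        raise ValueError("expression filter operates on the log2tpm scale")
    keep = m.values.max(axis=1) >= threshold
    logger.info(
        "expression filter: retained %d / %d features (dropped %d)",
        int(keep.sum()), len(keep), int((~keep).sum()),
    )
    return ExpressionMatrix(m.values.loc[keep], m.samples, m.scale, list(m.timepoint_order))


def mean_by_group(m: ExpressionMatrix, keys: list[str]) -> ExpressionMatrix:
    """Average samples over metadata key combinations (e.g. replicates).

    Returns one column per distinct key combination, labelled by joining the
    key values with '.', with a reduced metadata frame carrying the keys.
    """
    if not keys:
        raise ValueError("keys must be nonempty")
    bad = [k for k in keys if k not in m.samples.columns]
    if bad:
        raise ValueError(f"unknown metadata field(s): {bad}")
    cols, meta_rows = {}, []
    # iterate the groupby (not .groups) to keep first-occurrence order
    for key, sub in m.samples.groupby(keys, sort=False):
        key_t = key if isinstance(key, tuple) else (key,)
        label = ".".join(str(k) for k in key_t)
        cols[label] = m.values.loc[:, sub.index].mean(axis=1)
        meta_rows.append(dict(zip(keys, key_t), sample_id=label))
    values = pd.DataFrame(cols)
    meta = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    return ExpressionMatrix(values, meta, m.scale, list(m.timepoint_order))
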