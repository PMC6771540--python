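"""Weighted co-expression network modules, from scratch.

The chain follows the classic weighted gene co-expression network recipe:

1. Pearson correlation of log2 expression across all samples jointly.
2. Soft-threshold adjacency ``a = |r|**beta`` (unsigned, default beta = 16)
   or ``((1 + r) / 2)**beta`` (signed).
3. Topological overlap measure
   ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``,
   with connectivity ``k_i = sum_j a_ij``; clustering runs on ``1 - TOM``.
4. Average-linkage hierarchical clustering of the TOM dissimilarity.
5. A deterministic tree cut: the dendrogram is cut at a fixed fraction of
   its root height and branches of at least ``min_module_size`` genes
   become modules; smaller branches stay "unassigned".
6. Module eigengenes — the first principal component of each module's
   standardized expression, sign-oriented along the module mean profile —
   and closest-first merging of modules whose eigengene dissimilarity
   (1 - Pearson r) falls below the merge threshold (default 0.1, i.e.
   r > 0.9).
7. Module-trait association: Pearson correlation of eigengenes with
   numerically encoded sample covariates, two-sided t-distribution
   p-values and Benjamini-Hochberg FDR across the whole module x trait
   family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from .enrichment import bh_fdr
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class NetworkParams:
    """Tunable knobs of the module-detection chain."""

    beta: float = 16.0
    correlation: str = "pearson"
    network_type: str = "unsigned"
    min_module_size: int = 30
    cut_height_fraction: float = 0.99
    merge_dissimilarity: float = 0.1

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError("network_type must be 'unsigned' or 'signed'")
        if self.correlation != "pearson":
            raise ValueError("only pearson correlation is supported")
        if not 0 < self.cut_height_fraction <= 1:
            raise ValueError("cut_height_fraction must be in (0, 1]")
        if not 0 <= self.merge_dissimilarity <= 2:
            raise ValueError("merge_dissimilarity must be in [0, 2]")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be positive")


@dataclass
class ModuleSet:
    """Gene -> module assignment with eigengenes and diagnostics."""

    assignments: pd.Series  # index = gene, value = module label or "unassigned"
    eigengenes: pd.DataFrame  # modules x samples, unit-norm rows
    variance_explained: dict[str, float]
    params: NetworkParams = field(default_factory=NetworkParams)

    @property
    def module_sizes(self) -> pd.Series:
        counts = self.assignments[self.assignments != UNASSIGNED].value_counts()
        return counts.sort_values(ascending=False)

    @property
    def n_modules(self) -> int:
        return int((self.assignments.unique() != UNASSIGNED).sum())


def correlation_matrix(
    m: ExpressionMatrix, gene_subset: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlation of genes across all samples jointly.

    Zero-variance genes get correlation 0 with every other gene (and 1 with
    themselves), with a warning.
    """
    vals = m.values if gene_subset is None else m.values.loc[list(gene_subset)]
    if vals.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    x = vals.to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s); their correlations set to 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.atleast_2d(r)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=vals.index, columns=vals.index)


def soft_threshold_adjacency(
    cor: pd.DataFrame, params: NetworkParams | None = None
) -> pd.DataFrame:
    """Raise correlations to the soft-thresholding power beta.

    Unsigned: a = |r| ** beta; signed: a = ((1 + r) / 2) ** beta.  The
    diagonal is zeroed (no self-edges).
    """
    params = params or NetworkParams()
    r = cor.to_numpy(dtype=float)
    if params.network_type == "unsigned":
        a = np.abs(r) ** params.beta
    else:
        a = ((1.0 + r) / 2.0) ** params.beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def topological_overlap(a: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Topological overlap similarity and its dissimilarity 1 - TOM.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj and k_i = sum_j a_ij; TOM_ii = 1.
    """
    A = a.to_numpy(dtype=float)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.diag(A).any():
        raise ValueError("adjacency diagonal must be zero")
    if A.min() < 0 or A.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = A.sum(axis=1)
    L = A @ A
    k_min = np.minimum.outer(k, k)
    denom = k_min + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)  # symmetrize roundoff
    sim = pd.DataFrame(tom, index=a.index, columns=a.columns)
    return sim, 1.0 - sim


def average_linkage_cluster(d: pd.DataFrame) -> np.ndarray:
    """Average-linkage (UPGMA) agglomeration of a dissimilarity matrix.

    Returns a scipy linkage matrix; scipy's nearest-neighbor-chain
    implementation is deterministic with index-order tie-breaking.
    """
    D = d.to_numpy(dtype=float)
    if not np.isfinite(D).all():
        raise ValueError("dissimilarity contains non-finite entries")
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return linkage(squareform(D, checks=False), method="average")


def dynamic_cut(
    Z: np.ndarray,
    d: pd.DataFrame,
    params: NetworkParams | None = None,
) -> pd.Series:
    """Cut the dendrogram into raw modules.

    The cut height is ``cut_height_fraction`` of the top merge height (the
    dendrogram root); connected branches below it with at least
    ``min_module_size`` members become modules M1, M2, ... ordered by
    decreasing size, and smaller branches are labelled "unassigned".
    Soft-thresholded TOM dissimilarities saturate near 1, so a fraction of
    the root height separates branches where a quantile of the merge
    heights would not.
    """
    params = params or NetworkParams()
    heights = Z[:, 2]
    cut_h = float(params.cut_height_fraction * heights.max())
    labels = fcluster(Z, t=cut_h, criterion="distance")
    genes = d.index
    raw = pd.Series(labels, index=genes)
    sizes = raw.value_counts()
    keep = sizes[sizes >= params.min_module_size]
    # stable rank: decreasing size, ties by first-appearance cluster id
    ordered = sorted(keep.index, key=lambda c: (-keep[c], c))
    rename = {c: f"M{i + 1}" for i, c in enumerate(ordered)}
    out = raw.map(lambda c: rename.get(c, UNASSIGNED))
    out.name = "module"
    logger.info(
        "dynamic cut at height %.4f: %d modules, %d unassigned genes",
        cut_h, len(rename), int((out == UNASSIGNED).sum()),
    )
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def module_eigengenes(
    m: ExpressionMatrix, assignments: pd.Series
) -> tuple[pd.DataFrame, dict[str, float]]:
    """First principal component of each module's standardized expression.

    Genes are z-scored across samples before the decomposition.  The
    eigengene is the leading right singular vector (unit norm over samples),
    sign-oriented to correlate positively with the module's mean
    standardized profile; variance explained is the leading eigenvalue
    fraction.
    """
    modules = [lab for lab in assignments.unique() if lab != UNASSIGNED]
    modules.sort(key=lambda s: (len(s), s))  # M1 < M2 < ... < M10
    rows, varex = {}, {}
    for mod in modules:
        genes = assignments.index[assignments == mod]
        if len(genes) == 0:
            raise ValueError(f"module {mod} is empty")
        x = _standardize(m.values.loc[genes].to_numpy(dtype=float))
        if x.shape[0] == 1:
            v = x[0]
            norm = np.linalg.norm(v)
            e = v / norm if norm > 0 else v
            varex[mod] = 1.0
        else:
            _, s, vt = np.linalg.svd(x, full_matrices=False)
            e = vt[0]
            varex[mod] = float(s[0] ** 2 / (s ** 2).sum())
            mean_profile = x.mean(axis=0)
            if np.dot(e, mean_profile) < 0:
                e = -e
        rows[mod] = e
    eig = pd.DataFrame(rows, index=m.values.columns).T
    return eig, varex


def merge_modules(
    m: ExpressionMatrix,
    assignments: pd.Series,
    params: NetworkParams | None = None,
) -> ModuleSet:
    """Closest-first merging of modules with highly correlated eigengenes.

    While the smallest eigengene dissimilarity 1 - Pearson(E_i, E_j) is
    below ``merge_dissimilarity`` (r > 0.9 at the default 0.1), the closest
    pair is merged and eigengenes are recomputed.  Idempotent on its own
    output.  Final labels are reassigned M1, M2, ... by decreasing size.
    """
    params = params or NetworkParams()
    labels = assignments.copy()
    while True:
        eig, varex = module_eigengenes(m, labels)
        mods = list(eig.index)
        if len(mods) < 2:
            break
        E = eig.to_numpy()
        r = np.corrcoef(E)
        np.fill_diagonal(r, -np.inf)
        i, j = np.unravel_index(np.argmax(r), r.shape)
        if 1.0 - r[i, j] >= params.merge_dissimilarity:
            break
        keep_lab, drop_lab = mods[min(i, j)], mods[max(i, j)]
        labels = labels.replace(drop_lab, keep_lab)
        logger.info("merged module %s into %s (r = %.3f)", drop_lab, keep_lab, r[i, j])
    # canonical relabel by decreasing size
    sizes = labels[labels != UNASSIGNED].value_counts()
    ordered = sorted(sizes.index, key=lambda lab: (-sizes[lab], lab))
    rename = {lab: f"M{i + 1}" for i, lab in enumerate(ordered)}
    labels = labels.map(lambda lab: rename.get(lab, UNASSIGNED))
    labels.name = "module"
    eig, varex = module_eigengenes(m, labels)
    return ModuleSet(labels, eig, varex, params)


def detect_modules(
    m: ExpressionMatrix,
    params: NetworkParams | None = None,
    gene_subset: list[str] | None = None,
) -> ModuleSet:
    """Run the full chain: correlation -> adjacency -> TOM -> average
    linkage -> cut -> eigengene merge."""
    params = params or NetworkParams()
    cor = correlation_matrix(m, gene_subset)
    adj = soft_threshold_adjacency(cor, params)
    _, dis = topological_overlap(adj)
    Z = average_linkage_cluster(dis)
    raw = dynamic_cut(Z, dis, params)
    sub = m if gene_subset is None else m.subset_features(gene_subset)
    return merge_modules(sub, raw, params)


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait.

    Traits are numeric sample covariates (one-hot species, WD = 1,
    timepoint rank).  Two-sided p-values come from the t distribution with
    n - 2 degrees of freedom; BH FDR is taken over the whole module x trait
    family.  Constant traits yield NaN r with p = 1 and a note.
    """
    if list(eigengenes.columns) != list(traits.index):
        raise ValueError("eigengene samples and trait rows must align")
    n = eigengenes.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    rows = []
    for mod in eigengenes.index:
        e = eigengenes.loc[mod].to_numpy(dtype=float)
        for trait in traits.columns:
            tv = traits[trait].to_numpy(dtype=float)
            if np.std(tv) == 0 or np.std(e) == 0:
                rows.append({"module": mod, "trait": trait, "r": np.nan,
                             "p": 1.0, "note": "constant"})
                continue
            r = float(np.corrcoef(e, tv)[0, 1])
            r = max(-1.0, min(1.0, r))
            if abs(r) == 1.0:
                p = 0.0
            else:
                tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = float(2.0 * t_dist.sf(abs(tstat), df=n - 2))
            rows.append({"module": mod, "trait": trait, "r": r, "p": p, "note": ""})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def encode_traits(samples: pd.DataFrame, timepoint_order: list[str]) -> pd.DataFrame:
    """Numeric trait encoding: one column per species (one-hot), treatment
    (WD = 1) and timepoint rank."""
    enc = pd.DataFrame(index=samples.index)
    for sp in sorted(samples["species"].unique()):
        enc[sp] = (samples["species"] == sp).astype(float)
    enc["treatment_wd"] = (samples["condition"] == "WD").astype(float)
    rank = {tp: i for i, tp in enumerate(timepoint_order)}
    enc["timepoint"] = samples["timepoint"].map(rank).astype(float)
    return enc
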