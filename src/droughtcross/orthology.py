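"""One-to-one orthology from pairwise protein similarity searches.

Pairwise orthologs between two species are called by reciprocal best hit
(RBH) over BLAST tabular (``-outfmt 6``) hits filtered at an E-value cutoff
of 1e-3: gene *g* of species A and gene *h* of species B are orthologs iff
*h* is *g*'s top-scoring hit in the A->B search and *g* is *h*'s top-scoring
hit in the B->A search.  "Top-scoring" uses a deterministic tie-break chain:
max bitscore, then min E-value, then max percent identity, then the
lexicographically smallest subject id.

Three-way expressed-mutual-ortholog (EMO) triples are RBH triangles
(A-B, A-C and B-C pairs that close consistently) whose three members all
pass the expression filter in their own species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MAX_EVALUE = 1e-3


class BlastHit(NamedTuple):
    query_id: str
    subject_id: str
    pident: float
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    bitscore_ab: float
    bitscore_ba: float


@dataclass
class EMOTable:
    """One-to-one-to-one ortholog triples, all members expressed."""

    species: tuple[str, str, str]
    triples: list[tuple[str, str, str]]
    n_inconsistent_triangles: int = 0
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.triples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.triples, columns=list(self.species))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def parse_blast_tab(path, max_evalue: float = DEFAULT_MAX_EVALUE) -> list[BlastHit]:
    """Parse 12-column BLAST tabular output, keeping hits with
    evalue <= max_evalue (inclusive) in file order."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if evalue <= max_evalue:
                hits.append(BlastHit(fields[0], fields[1], pident, evalue, bitscore))
    return hits


def _best_hits(hits: list[BlastHit]) -> dict[str, BlastHit]:
    """Best hit per query: max bitscore, min evalue, max pident,
    lexicographic subject id."""
    best: dict[str, BlastHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        new_key = (-h.bitscore, h.evalue, -h.pident, h.subject_id)
        cur_key = (-cur.bitscore, cur.evalue, -cur.pident, cur.subject_id)
        if new_key < cur_key:
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    ab: list[BlastHit], ba: list[BlastHit]
) -> list[OrthologPair]:
    """One-to-one pairs: (g, h) iff h is g's best A->B hit and g is h's best
    B->A hit.  Output sorted by gene_a for reproducibility."""
    best_ab = _best_hits(ab)
    best_ba = _best_hits(ba)
    pairs = []
    for g, hit in best_ab.items():
        h = hit.subject_id
        back = best_ba.get(h)
        if back is not None and back.subject_id == g:
            pairs.append(OrthologPair(g, h, hit.bitscore, back.bitscore))
    pairs.sort(key=lambda p: p.gene_a)
    return pairs


def build_emo_table(
    ab_pairs: list[OrthologPair],
    ac_pairs: list[OrthologPair],
    bc_pairs: list[OrthologPair],
    expressed: dict[str, set[str]],
    species: tuple[str, str, str] = ("Ath", "Aly", "Esa"),
    require_closure: bool = True,
) -> EMOTable:
    """Assemble expressed-mutual-ortholog triples from three pairwise RBH
    lists over species (A, B, C).

    A triple (a, b, c) is emitted iff (a, b) is an A-B pair, (a, c) an A-C
    pair, the B-C list pairs b with c (triangle closure; inconsistent
    triangles are dropped and counted, or kept when ``require_closure`` is
    False and a B-C pair for b simply does not exist), and each member is in
    its species' expressed set.
    """
    sp_a, sp_b, sp_c = species
    ab = {p.gene_a: p.gene_b for p in ab_pairs}
    ac = {p.gene_a: p.gene_b for p in ac_pairs}
    bc = {p.gene_a: p.gene_b for p in bc_pairs}
    triples = []
    n_inconsistent = 0
    for a in sorted(ab):
        if a not in ac:
            continue
        b, c = ab[a], ac[a]
        closes = bc.get(b) == c
        if not closes:
            if b in bc:
                n_inconsistent += 1
                continue
            if require_closure:
                n_inconsistent += 1
                continue
        if a in expressed[sp_a] and b in expressed[sp_b] and c in expressed[sp_c]:
            triples.append((a, b, c))
    table = EMOTable(
        species=species,
        triples=triples,
        n_inconsistent_triangles=n_inconsistent,
        provenance={"require_closure": require_closure},
    )
    logger.info(
        "EMO table: %d triples, %d inconsistent triangles dropped",
        len(triples), n_inconsistent,
    )
    return table
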