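"""Empirical significance of multi-species regulated-ortholog overlap.

The observed overlap — the number of orthologs regulated in all species at
some timepoint and direction — is compared against a permutation null: in
each permutation, a set of the same size as each species' regulated set is
drawn uniformly without replacement from the common-ortholog background,
and the size of the full intersection recorded.  The empirical p-value is
the fraction of permutations whose null overlap is at least the observed
one; when no permutation reaches it the result is reported as the floor
"< 1/N" (e.g. "< 0.001" at N = 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass
class PermutationResult:
    observed_overlap: int
    n_permutations: int
    n_ge_observed: int
    p_value: float
    p_text: str
    null_mean: float
    null_sd: float
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def permutation_overlap_test(
    background: set | list,
    set_sizes: list[int],
    observed: int,
    n: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for k-way gene-set overlap.

    Parameters
    ----------
    background
        The common-ortholog universe the regulated sets live in.
    set_sizes
        Size of each species' regulated set (any number of species >= 2).
    observed
        The observed size of the full intersection.
    n
        Number of permutations (1000 by default).
    seed
        Seed for the random generator; recorded in the result.

    Exceedance uses >= (null at least as large as observed); the p-value is
    n_ge_observed / n, reported as "< 1/n" when the count is zero.
    """
    n_bg = len(background)
    if any(s > n_bg for s in set_sizes):
        raise ValueError("a set size exceeds the background size")
    if any(s < 0 for s in set_sizes):
        raise ValueError("set sizes must be nonnegative")
    if observed > min(set_sizes, default=0):
        raise ValueError("observed overlap exceeds the smallest set")
    rng = np.random.default_rng(seed)
    null = np.empty(n, dtype=np.int64)
    for i in range(n):
        inter: np.ndarray | None = None
        for size in set_sizes:
            mask = np.zeros(n_bg, dtype=bool)
            mask[rng.choice(n_bg, size=size, replace=False)] = True
            inter = mask if inter is None else (inter & mask)
        null[i] = int(inter.sum()) if inter is not None else 0
    n_ge = int((null >= observed).sum())
    p = n_ge / n
    p_text = f"< {1 / n:g}" if n_ge == 0 else f"p = {n_ge}/{n}"
    return PermutationResult(
        observed_overlap=int(observed),
        n_permutations=int(n),
        n_ge_observed=n_ge,
        p_value=p if n_ge > 0 else 1.0 / n,  # reported floor when never reached
        p_text=p_text,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n > 1 else 0.0,
        seed=int(seed),
    )
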