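"""Statistics for rMP families: hypergeometric association test, Bonferroni
correction, sequence-shuffling null, and rank correlation.

The null model treats the assignment of motif pairs to intervening distances
as random.  For a family with motif pair P at distance d, among the n adjacent
pairs in the genome let n1 be the pairs at distance d (any motifs), n2 the
pairs with motif pair P (any distance) and n3 the pairs matching both
(the family's copy count).  Under random pairing the overlap X of a random
n2-subset with a fixed n1-subset of the n pairs is hypergeometric, and the
reported p-value is the upper tail P(X >= n3).  Small p means the motif pair
recurs at one distance more often than random assortment explains.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rmp_core import AdjacentPair, RMPFamily
from .ssr_scan import GenomeSequence


@dataclass(frozen=True)
class HypergeomCounts:
    """Counts entering the test.  Population n, successes n1, draws n2,
    observed overlap n3."""

    n: int
    n1: int
    n2: int
    n3: int

    def __post_init__(self) -> None:
        if not (0 <= self.n3 <= min(self.n1, self.n2) <= max(self.n1, self.n2) <= self.n):
            raise ValueError(f"invalid hypergeometric counts {self}")


@dataclass(frozen=True)
class AssociationResult:
    family: RMPFamily
    counts: HypergeomCounts
    p_tail: float
    p_adjusted: float
    significant: bool


def association_counts(
    family: RMPFamily, pairs: Sequence[AdjacentPair], tolerance: int = 0
) -> HypergeomCounts:
    """Count n, n1, n2, n3 for one family against the full pair list.

    n1 and n2 are inclusive of the n3 overlap.  With a grouping tolerance t,
    "same distance" means within ±t of the family distance.
    """
    n = len(pairs)
    n1 = n2 = n3 = 0
    for p in pairs:
        same_d = abs(p.distance - family.distance) <= tolerance
        same_m = p.motif_pair == family.motif_pair
        n1 += same_d
        n2 += same_m
        n3 += same_d and same_m
    return HypergeomCounts(n, n1, n2, n3)


def hypergeom_tail(c: HypergeomCounts) -> float:
    """Upper tail P(X >= n3), X ~ Hypergeometric(n, n1, n2).

    Computed in log space by scipy's survival function; stable for n up to
    at least 10^6.  n3 = 0 returns exactly 1.
    """
    if c.n3 == 0:
        return 1.0
    p = float(stats.hypergeom.sf(c.n3 - 1, c.n, c.n1, c.n2))
    return min(1.0, max(0.0, p))


def test_all_families(
    families: Sequence[RMPFamily],
    pairs: Sequence[AdjacentPair],
    alpha: float = 0.05,
    tolerance: int = 0,
) -> list[AssociationResult]:
    """Hypergeometric test for every family with Bonferroni correction.

    The Bonferroni divisor is the number of tested families.  Results are
    sorted by adjusted p-value (ties: family key).
    """
    if not families:
        raise ValueError("no families to test")
    m = len(families)
    results = []
    for fam in families:
        c = association_counts(fam, pairs, tolerance)
        p = hypergeom_tail(c)
        p_adj = min(1.0, p * m)
        results.append(AssociationResult(fam, c, p, p_adj, p_adj < alpha))
    results.sort(key=lambda r: (r.p_adjusted, r.p_tail, r.family.key))
    return results


def significant_fraction(results: Sequence[AssociationResult]) -> float:
    """Fraction of tested families significant after correction (0 if none tested)."""
    if not results:
        return 0.0
    return sum(r.significant for r in results) / len(results)


def shuffle_and_sample(
    genome: Sequence[GenomeSequence],
    n_samples: int = 1000,
    fragment: int = 1000,
    seed: int | np.random.Generator = 0,
    disjoint: bool = True,
) -> list[GenomeSequence]:
    """Per-sequence character shuffle, then uniform sampling of fragments.

    Each source sequence is permuted independently (base composition of every
    sequence is preserved exactly), then ``n_samples`` fragments of
    ``fragment`` bp are drawn uniformly; fragments never span sequence
    boundaries.  By default fragments are drawn from the disjoint tiling of
    each shuffled sequence *without replacement*, so no two samples share
    sequence -- overlapping samples would duplicate the same locus pairs and
    fabricate exactly the repeated-pair signal the null is meant to lack.
    ``disjoint=False`` draws independent uniform start positions instead.
    Reproducible for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shuffled: list[np.ndarray] = []
    eligible: list[int] = []
    for g in genome:
        arr = np.frombuffer(g.sequence.encode("ascii"), dtype=np.uint8).copy()
        rng.shuffle(arr)
        shuffled.append(arr)
        if g.length >= fragment:
            eligible.append(len(shuffled) - 1)
    if not eligible:
        raise ValueError(f"no sequence of length >= {fragment}")
    out = []
    if disjoint:
        tiles = [(i, t) for i in eligible for t in range(shuffled[i].shape[0] // fragment)]
        if n_samples > len(tiles):
            raise ValueError(
                f"{n_samples} disjoint fragments of {fragment} bp need "
                f">= {n_samples * fragment} bp of sequence"
            )
        order = rng.permutation(len(tiles))[:n_samples]
        for k, idx in enumerate(order):
            i, t = tiles[int(idx)]
            frag = shuffled[i][t * fragment : (t + 1) * fragment]
            out.append(GenomeSequence(f"frag_{k:05d}", frag.tobytes().decode("ascii")))
    else:
        weights = np.array(
            [shuffled[i].shape[0] - fragment + 1 for i in eligible], dtype=float
        )
        probs = weights / weights.sum()
        for k in range(n_samples):
            i = eligible[int(rng.choice(len(eligible), p=probs))]
            start = int(rng.integers(0, shuffled[i].shape[0] - fragment + 1))
            frag = shuffled[i][start : start + fragment]
            out.append(GenomeSequence(f"frag_{k:05d}", frag.tobytes().decode("ascii")))
    return out


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with two-tailed p (t approximation).

    Ranks use midranks for ties; equivalent to 1 - 6*sum(d^2)/(m(m^2-1)) when
    there are no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 observations")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def write_association_table(results: Sequence[AssociationResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            (
                r.family.key, r.counts.n, r.counts.n1, r.counts.n2, r.counts.n3,
                r.p_tail, r.p_adjusted, r.significant,
            )
            for r in results
        ],
        columns=["family", "n", "n1", "n2", "n3", "p", "p_adj", "significant"],
    ).to_csv(path, sep="\t", index=False)
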