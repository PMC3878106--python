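"""Adjacent SSR pairs, repetitive microsatellite pair (rMP) families, and
distance/chromosome summaries.

An *adjacent pair* joins two neighbouring SSR loci on one sequence; its
intervening distance d is the number of bases strictly between them.  When the
same ordered motif pair recurs with the same d at two or more genomic
locations, those pairs form an rMP family -- the unit that all downstream
statistics (hypergeometric testing, segmental-duplication calling, window
co-aggregation) operate on.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ssr_scan import Microsatellite

logger = logging.getLogger(__name__)

DEFAULT_BIN_EDGES = (0, 10, 100, 1000, 5000, 10000, 50000, 100000)

PAIR_TABLE_COLUMNS = [
    "seq_id",
    "up_start", "up_end", "up_motif",
    "down_start", "down_end", "down_motif",
    "distance", "midpoint",
]


@dataclass(frozen=True)
class AdjacentPair:
    """Two neighbouring SSRs on one sequence."""

    seq_id: str
    upstream: Microsatellite
    downstream: Microsatellite

    def __post_init__(self) -> None:
        if self.upstream.end >= self.downstream.start:
            raise ValueError(
                f"overlapping loci {self.upstream.end} >= {self.downstream.start} on {self.seq_id}"
            )

    @property
    def distance(self) -> int:
        """Bases strictly between the two loci (>= 0; 0 means abutting)."""
        return self.downstream.start - self.upstream.end - 1

    @property
    def motif_pair(self) -> tuple[str, str]:
        """Ordered by genomic left-to-right occurrence."""
        return (self.upstream.motif, self.downstream.motif)

    @property
    def midpoint(self) -> int:
        return (self.upstream.start + self.downstream.end) // 2


@dataclass(frozen=True)
class RMPFamily:
    """All adjacent pairs sharing one ordered motif pair and one intervening
    distance (within ±tolerance).  copy_count >= 2 by construction."""

    motif_pair: tuple[str, str]
    distance: int
    members: tuple[AdjacentPair, ...]
    tolerance: int = 0

    @property
    def copy_count(self) -> int:
        return len(self.members)

    @property
    def key(self) -> str:
        return f"{self.motif_pair[0]}|{self.motif_pair[1]}|{self.distance}"


@dataclass(frozen=True)
class DistanceBinTable:
    """Family counts per intervening-distance bin (left-closed, right-open)."""

    edges: tuple[int, ...]
    counts: tuple[int, ...]

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def labels(self) -> list[str]:
        return [f"[{a},{b})" for a, b in zip(self.edges[:-1], self.edges[1:])]


def adjacent_pairs(loci: Sequence[Microsatellite]) -> list[AdjacentPair]:
    """Build all neighbouring pairs, per sequence.

    Loci are grouped by seq_id and must be sorted by start within each group
    (scanner output already is).  Pairs whose loci overlap are skipped and
    logged; pairs never span sequences.
    """
    by_seq: dict[str, list[Microsatellite]] = defaultdict(list)
    for loc in loci:
        by_seq[loc.seq_id].append(loc)
    pairs: list[AdjacentPair] = []
    skipped = 0
    for seq_id, group in by_seq.items():
        if any(a.start > b.start for a, b in zip(group, group[1:])):
            group = sorted(group, key=lambda x: (x.start, x.end))
        for up, down in zip(group, group[1:]):
            if up.end >= down.start:
                skipped += 1
                continue
            pairs.append(AdjacentPair(seq_id, up, down))
    if skipped:
        logger.warning("skipped %d overlapping adjacent locus pairs", skipped)
    return pairs


def group_rmp_families(pairs: Sequence[AdjacentPair], tolerance: int = 0) -> list[RMPFamily]:
    """Group pairs into rMP families keyed by (ordered motif pair, distance).

    At tolerance 0 grouping is exact.  At tolerance t > 0, for each motif pair
    the modal distance is taken first (ties: smaller distance), all pairs
    within ±t of it are merged into one family at the modal distance, and the
    procedure repeats on the remainder (greedy, by descending cluster size).
    Only groups with >= 2 members are families.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    by_combo: dict[tuple[str, str], list[AdjacentPair]] = defaultdict(list)
    for p in pairs:
        by_combo[p.motif_pair].append(p)

    families: list[RMPFamily] = []
    for combo in sorted(by_combo):
        group = by_combo[combo]
        if tolerance == 0:
            by_d: dict[int, list[AdjacentPair]] = defaultdict(list)
            for p in group:
                by_d[p.distance].append(p)
            for d in sorted(by_d):
                if len(by_d[d]) >= 2:
                    families.append(RMPFamily(combo, d, tuple(by_d[d]), 0))
        else:
            remaining = Counter(p.distance for p in group)
            pool: dict[int, list[AdjacentPair]] = defaultdict(list)
            for p in group:
                pool[p.distance].append(p)
            while remaining:
                modal = max(remaining, key=lambda d: (remaining[d], -d))
                cluster_ds = [d for d in remaining if abs(d - modal) <= tolerance]
                members: list[AdjacentPair] = []
                for d in sorted(cluster_ds):
                    members.extend(pool[d])
                    del remaining[d]
                if len(members) >= 2:
                    families.append(RMPFamily(combo, modal, tuple(members), tolerance))
    families.sort(key=lambda f: (-f.copy_count, f.motif_pair, f.distance))
    return families


def distance_bin_table(
    families: Sequence[RMPFamily], edges: Sequence[int] = DEFAULT_BIN_EDGES
) -> DistanceBinTable:
    """Histogram of family distances over left-closed right-open bins."""
    edges = tuple(int(e) for e in edges)
    if any(a >= b for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    dists = np.array([f.distance for f in families], dtype=np.int64)
    if dists.size and (dists.min() < edges[0] or dists.max() >= edges[-1]):
        raise ValueError("family distance outside bin range")
    counts, _ = np.histogram(dists, bins=np.array(edges, dtype=np.int64))
    return DistanceBinTable(edges, tuple(int(c) for c in counts))


@dataclass(frozen=True)
class SharingClass:
    span: str  # "intra_chromosomal" | "inter_chromosomal"
    sex: str   # "sex_specific" | "autosome_specific" | "shared"


def chromosome_sharing(family: RMPFamily, sex_chromosomes: set[str]) -> SharingClass:
    """Classify a family by the chromosomes its members occupy."""
    seqs = {m.seq_id for m in family.members}
    span = "intra_chromosomal" if len(seqs) == 1 else "inter_chromosomal"
    on_sex = seqs & sex_chromosomes
    if not on_sex:
        sex = "autosome_specific"
    elif on_sex == seqs:
        sex = "sex_specific"
    else:
        sex = "shared"
    return SharingClass(span, sex)


# ---------------------------------------------------------------------------
# IO


def write_pair_table(pairs: Sequence[AdjacentPair], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (
                p.seq_id,
                p.upstream.start, p.upstream.end, p.upstream.motif,
                p.downstream.start, p.downstream.end, p.downstream.motif,
                p.distance, p.midpoint,
            )
            for p in pairs
        ],
        columns=PAIR_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_pair_table(path: str | Path) -> list[AdjacentPair]:
    """Rebuild pairs from a pair TSV.  Only coordinates and motifs are stored,
    so the embedded loci carry placeholder copy_number/mismatches/score."""
    df = pd.read_csv(path, sep="\t")
    pairs = []
    for _, r in df.iterrows():
        up = Microsatellite(r["seq_id"], int(r["up_start"]), int(r["up_end"]),
                            str(r["up_motif"]), 0.0, 0, 0)
        down = Microsatellite(r["seq_id"], int(r["down_start"]), int(r["down_end"]),
                              str(r["down_motif"]), 0.0, 0, 0)
        pairs.append(AdjacentPair(r["seq_id"], up, down))
    return pairs


def write_family_table(families: Sequence[RMPFamily], path: str | Path) -> None:
    rows = []
    for f in families:
        member_str = ";".join(
            f"{m.seq_id}:{m.upstream.start}-{m.upstream.end}/{m.downstream.start}-{m.downstream.end}"
            for m in f.members
        )
        rows.append((f.motif_pair[0], f.motif_pair[1], f.distance, f.copy_count, member_str))
    pd.DataFrame(
        rows, columns=["motif_up", "motif_down", "distance", "copy_count", "members"]
    ).to_csv(path, sep="\t", index=False)


def write_midpoint_bed(families: Sequence[RMPFamily], path: str | Path) -> None:
    """BED of member midpoints (1 bp intervals), name = family key."""
    with open(path, "w") as fh:
        for f in families:
            for m in f.members:
                fh.write(f"{m.seq_id}\t{m.midpoint - 1}\t{m.midpoint}\t{f.key}\t{f.copy_count}\t+\n")
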