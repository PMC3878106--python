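"""Calling microsatellite-anchored segmental duplications (mSDs).

An rMP family whose intervening distance exceeds 1 kb is a candidate
low-copy-repeat family: its members' intervening sequences are extracted and
aligned all-vs-all with a global affine-gap aligner (match +1, mismatch -1,
gap open -2, gap extend -1).  Identity is matches over alignment columns,
gap columns included in the denominator.  Members whose identity to at least
one other member exceeds 90% are linked (single linkage); a family with >= 2
linked members is an mSD family.  Both thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

try:
    import edlib
except ImportError:  # pragma: no cover
    edlib = None

from .rmp_core import AdjacentPair, RMPFamily
from .ssr_scan import GenomeSequence

#: sequences longer than this are aligned with a banded edit-distance aligner
DEFAULT_BAND_CAP = 50_000


class CoordinateError(ValueError):
    """A pair member's coordinates fall outside its sequence."""


@dataclass(frozen=True)
class InterveningSequence:
    member: AdjacentPair
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MSDFamily:
    """The mSD subset of an rMP family.

    ``member_index`` indexes the parent family's members; ``identity`` is the
    full all-vs-all matrix over the evaluated (> min_length) members.
    """

    parent: RMPFamily
    member_index: tuple[int, ...]
    evaluated_index: tuple[int, ...]
    identity: np.ndarray
    min_length: int
    min_identity: float

    @property
    def members(self) -> tuple[AdjacentPair, ...]:
        return tuple(self.parent.members[i] for i in self.member_index)

    @property
    def copy_count(self) -> int:
        return len(self.member_index)


def _as_mapping(genome) -> Mapping[str, str]:
    if isinstance(genome, Mapping):
        return genome
    return {g.seq_id: g.sequence for g in genome}


def extract_intervening(family: RMPFamily, genome) -> list[InterveningSequence]:
    """Substring strictly between each member's upstream end and downstream
    start (1-based inclusive locus coordinates); length equals the distance."""
    seqs = _as_mapping(genome)
    out = []
    for m in family.members:
        if m.seq_id not in seqs:
            raise CoordinateError(f"member on missing sequence {m.seq_id!r}")
        s = seqs[m.seq_id]
        if m.downstream.end > len(s):
            raise CoordinateError(
                f"member {m.seq_id}:{m.upstream.start}-{m.downstream.end} exceeds "
                f"sequence length {len(s)}"
            )
        out.append(InterveningSequence(m, s[m.upstream.end : m.downstream.start - 1]))
    return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def _identity_banded(a: str, b: str) -> float:
    """Identity from edlib's banded global (NW) alignment, for long sequences."""
    if edlib is None:  # pragma: no cover
        raise RuntimeError("edlib is required for sequences above the band cap")
    res = edlib.align(a, b, mode="NW", task="path")
    matches = columns = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            k = int(num)
            num = ""
            columns += k
            if ch == "=":
                matches += k
    return matches / columns


def pairwise_identity(a: str, b: str, band_cap: int = DEFAULT_BAND_CAP) -> float:
    """Global-alignment identity of two sequences, in [0, 1].

    Symmetric; identity(a, a) == 1.  Denominator counts every alignment
    column including gaps.  Above ``band_cap`` a banded edit-distance
    alignment is used instead of the full dynamic program.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if max(len(a), len(b)) > band_cap:
        return _identity_banded(a, b)
    alignment = _ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def identity_matrix(seqs: Sequence[str], band_cap: int = DEFAULT_BAND_CAP) -> np.ndarray:
    k = len(seqs)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = pairwise_identity(seqs[i], seqs[j], band_cap)
    return mat


def _single_linkage_components(adj: np.ndarray) -> list[list[int]]:
    k = adj.shape[0]
    seen = [False] * k
    comps = []
    for s in range(k):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in np.flatnonzero(adj[v]):
                if not seen[w]:
                    seen[w] = True
                    stack.append(int(w))
        comps.append(sorted(comp))
    return comps


def call_msds(
    families: Sequence[RMPFamily],
    genome,
    min_length: int = 1000,
    min_identity: float = 0.90,
    band_cap: int = DEFAULT_BAND_CAP,
) -> list[MSDFamily]:
    """Call mSD families among rMP families.

    Only families with distance > min_length are evaluated (strict).  Members
    in single-linkage clusters (edges where identity > min_identity, strict)
    of size >= 2 qualify; at most one MSDFamily is returned per rMP family,
    holding all qualifying members.
    """
    seqs = _as_mapping(genome)
    out = []
    for fam in families:
        if fam.distance <= min_length:
            continue
        ivs = extract_intervening(fam, seqs)
        evaluated = [i for i, iv in enumerate(ivs) if iv.length > min_length]
        if len(evaluated) < 2:
            continue
        mat = identity_matrix([ivs[i].sequence for i in evaluated], band_cap)
        adj = mat > min_identity
        np.fill_diagonal(adj, False)
        qualifying: list[int] = []
        for comp in _single_linkage_components(adj):
            if len(comp) >= 2:
                qualifying.extend(evaluated[i] for i in comp)
        if len(qualifying) >= 2:
            out.append(
                MSDFamily(
                    fam, tuple(sorted(qualifying)), tuple(evaluated), mat,
                    min_length, min_identity,
                )
            )
    return out


def species_summary(
    families: Sequence[RMPFamily], msd_families: Sequence[MSDFamily]
) -> tuple[int, int, float]:
    """(rMP family count, mSD family count, percentage to 2 decimals)."""
    r, s = len(families), len(msd_families)
    pct = 0.0 if r == 0 else round(100.0 * s / r, 2)
    return r, s, pct


# ---------------------------------------------------------------------------
# IO


def write_msd_bed(msds: Sequence[MSDFamily], path: str | Path) -> None:
    """BED of mSD member spans (0-based half-open, SSR termini included);
    name = motif_up|motif_down|distance."""
    with open(path, "w") as fh:
        for f in msds:
            for m in f.members:
                fh.write(
                    f"{m.seq_id}\t{m.upstream.start - 1}\t{m.downstream.end}\t"
                    f"{f.parent.key}\t{f.copy_count}\t+\n"
                )


def write_identity_matrix(msd: MSDFamily, path: str | Path) -> None:
    labels = [
        f"{m.seq_id}:{m.upstream.start}-{m.downstream.end}"
        for m in (msd.parent.members[i] for i in msd.evaluated_index)
    ]
    pd.DataFrame(msd.identity, index=labels, columns=labels).to_csv(path, sep="\t")


def write_species_summary(
    name: str, families: Sequence[RMPFamily], msds: Sequence[MSDFamily], path: str | Path
) -> None:
    r, s, pct = species_summary(families, msds)
    pd.DataFrame([(name, r, s, pct)], columns=["species", "rMP", "mSD", "percentage"]).to_csv(
        path, sep="\t", index=False
    )
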