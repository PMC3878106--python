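"""Detection of perfect and imperfect microsatellites (SSRs) in genome sequences.

A microsatellite is a tandem repeat of a short motif (1-6 bp).  The scanner
looks for *seeds* -- runs of ``min_seed_repeats`` exact motif copies -- and
extends them in both directions under a fixed mismatch penalty.  A locus is
reported when its score

    score = (matching positions) - mismatch_penalty * (mismatched positions)

reaches ``min_score``.  Extension stops at an ``N``, at the sequence end, or
once the running score has dropped ``2 * mismatch_penalty`` below its best
value (two unrecovered mismatches); the locus is then truncated back to the
best-scoring endpoint.

Motifs are reported in canonical form: the lexicographically smallest rotation
of the primitive period.  Reverse complements are *not* folded together, so
(TG)n and (CA)n name distinct motifs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")
_N = ord("N")

SSR_TABLE_COLUMNS = ["seq_id", "start", "end", "motif", "copy_number", "mismatches", "score"]


class InvalidMotifError(ValueError):
    """Raised for motifs containing characters outside {A, C, G, T}."""


class SSRTableError(ValueError):
    """Raised for malformed SSR tables; the message names the offending line."""


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome / scaffold: an identifier and its sequence over {A,C,G,T,N}."""

    seq_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Microsatellite:
    """A detected SSR locus.  Coordinates are 1-based inclusive."""

    seq_id: str
    start: int
    end: int
    motif: str
    copy_number: float
    mismatches: int
    score: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid coordinates {self.start}-{self.end} on {self.seq_id}")
        if not 1 <= len(self.motif) <= 6:
            raise ValueError(f"motif length {len(self.motif)} outside 1-6")


@dataclass(frozen=True)
class ScanParams:
    """Scanner thresholds.

    mismatch_penalty : score deduction per imperfect position (default 5).
    min_score        : minimum locus score; a perfect repeat of this length passes.
    min_seed_repeats : exact motif copies required to seed extension.
    max_motif_len    : longest motif period scanned.
    merge_gap        : same-motif loci closer than this are merged (0 = only overlaps).
    """

    mismatch_penalty: int = 5
    min_score: int = 15
    min_seed_repeats: int = 3
    max_motif_len: int = 6
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if self.mismatch_penalty < 0:
            raise ValueError("mismatch_penalty must be >= 0")
        if self.min_score <= 0:
            raise ValueError("min_score must be > 0")
        if self.min_seed_repeats < 2:
            raise ValueError("min_seed_repeats must be >= 2")
        if not 1 <= self.max_motif_len <= 6:
            raise ValueError("max_motif_len must be in 1..6")


def _primitive_period(motif: str) -> str:
    """Shortest period p such that motif is p repeated."""
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return motif[:d]
    return motif


def canonical_motif(motif: str) -> str:
    """Canonical name of a motif: smallest rotation of its primitive period.

    The reverse complement is intentionally not folded in, so e.g. ``CA`` and
    ``TG`` canonicalize to different strings (``AC`` and ``GT``).
    Idempotent and identical across all rotations of the same motif.
    """
    if not motif:
        raise InvalidMotifError("empty motif")
    motif = motif.upper()
    if not set(motif) <= _ACGT:
        raise InvalidMotifError(f"motif {motif!r} contains non-ACGT characters")
    p = _primitive_period(motif)
    return min(p[i:] + p[:i] for i in range(len(p)))


def _extend(arr: np.ndarray, seed_start: int, m: int, seed_len: int, penalty: int) -> tuple[int, int]:
    """Extend a periodic seed left/right; return best 0-based inclusive (lo, hi).

    The motif template is anchored at ``seed_start``; each position is compared
    against the template base for its phase, so one substitution costs exactly
    one mismatch and does not propagate.
    """
    n = arr.shape[0]
    motif = arr[seed_start : seed_start + m]
    stop_drop = 2 * penalty

    # right of the seed
    gain = 0
    best_gain_r = 0
    hi = seed_start + seed_len - 1
    j = seed_start + seed_len
    while j < n:
        b = arr[j]
        if b == _N:
            break
        if b == motif[(j - seed_start) % m]:
            gain += 1
            if gain > best_gain_r:
                best_gain_r = gain
                hi = j
        else:
            gain -= penalty
            if penalty > 0 and best_gain_r - gain >= stop_drop:
                break
        j += 1

    # left of the seed
    gain = 0
    best_gain_l = 0
    lo = seed_start
    j = seed_start - 1
    while j >= 0:
        b = arr[j]
        if b == _N:
            break
        if b == motif[(j - seed_start) % m]:
            gain += 1
            if gain > best_gain_l:
                best_gain_l = gain
                lo = j
        else:
            gain -= penalty
            if penalty > 0 and best_gain_l - gain >= stop_drop:
                break
        j -= 1

    return lo, hi


def _region_mismatches(arr: np.ndarray, lo: int, hi: int, anchor: int, m: int) -> int:
    idx = np.arange(lo, hi + 1)
    motif = arr[anchor : anchor + m]
    template = motif[(idx - anchor) % m]
    return int(np.count_nonzero(arr[idx] != template))


def _seed_positions(arr: np.ndarray, m: int, seed_repeats: int) -> np.ndarray:
    """Starts i where arr[i : i + seed_repeats*m] is seed_repeats exact copies."""
    n = arr.shape[0]
    win = (seed_repeats - 1) * m
    if n < seed_repeats * m:
        return np.empty(0, dtype=np.intp)
    eq = arr[m:] == arr[:-m]
    valid = arr != _N
    eq &= valid[m:] & valid[:-m]
    c = np.concatenate(([0], np.cumsum(eq, dtype=np.int64)))
    w = c[win:] - c[: c.shape[0] - win]
    return np.flatnonzero(w == win)


def find_ssrs(genome: GenomeSequence, params: ScanParams | None = None) -> list[Microsatellite]:
    """Scan one sequence for SSR loci of motif length 1..max_motif_len.

    Returns loci sorted by (start, end, motif); same-motif overlaps are merged
    (higher score wins) and identical intervals are de-duplicated keeping the
    higher score, then the shorter motif.  Deterministic for fixed input.
    """
    params = params or ScanParams()
    seq = genome.sequence.upper()
    if not seq:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    candidates: list[Microsatellite] = []

    for m in range(1, params.max_motif_len + 1):
        seed_len = params.min_seed_repeats * m
        seeds = _seed_positions(arr, m, params.min_seed_repeats)
        next_free = 0
        for i in seeds:
            i = int(i)
            if i < next_free:
                continue
            motif = seq[i : i + m]
            if _primitive_period(motif) != motif:
                continue
            lo, hi = _extend(arr, i, m, seed_len, params.mismatch_penalty)
            length = hi - lo + 1
            mism = _region_mismatches(arr, lo, hi, i, m)
            score = (length - mism) - params.mismatch_penalty * mism
            if score >= params.min_score:
                candidates.append(
                    Microsatellite(
                        seq_id=genome.seq_id,
                        start=lo + 1,
                        end=hi + 1,
                        motif=canonical_motif(motif),
                        copy_number=round(length / m, 2),
                        mismatches=mism,
                        score=int(score),
                    )
                )
                next_free = hi + 1
            else:
                next_free = i + 1

    return _merge_loci(candidates, params.merge_gap)


def _merge_loci(loci: list[Microsatellite], merge_gap: int) -> list[Microsatellite]:
    """Merge same-motif overlaps (keep higher score, then longer locus) and
    de-duplicate identical intervals across motifs (higher score, shorter motif)."""
    by_motif: dict[str, list[Microsatellite]] = {}
    for loc in loci:
        by_motif.setdefault(loc.motif, []).append(loc)

    kept: list[Microsatellite] = []
    for group in by_motif.values():
        group.sort(key=lambda x: (x.start, x.end))
        current = group[0]
        for nxt in group[1:]:
            if nxt.start <= current.end + merge_gap:
                if (nxt.score, nxt.length) > (current.score, current.length):
                    current = nxt
            else:
                kept.append(current)
                current = nxt
        kept.append(current)

    by_interval: dict[tuple[int, int], Microsatellite] = {}
    for loc in kept:
        key = (loc.start, loc.end)
        prev = by_interval.get(key)
        if prev is None or (loc.score, -len(loc.motif)) > (prev.score, -len(prev.motif)):
            by_interval[key] = loc
    out = list(by_interval.values())
    out.sort(key=lambda x: (x.start, x.end, x.motif))
    return out


def scan_genome(
    sequences: Iterable[GenomeSequence], params: ScanParams | None = None
) -> list[Microsatellite]:
    """find_ssrs over every sequence of a genome, concatenated in input order."""
    out: list[Microsatellite] = []
    for g in sequences:
        out.extend(find_ssrs(g, params))
    return out


# ---------------------------------------------------------------------------
# IO


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    return [GenomeSequence(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(sequences: Iterable[GenomeSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.seq_id, description="") for g in sequences]
    SeqIO.write(records, str(path), "fasta")


def write_ssr_table(loci: Sequence[Microsatellite], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (x.seq_id, x.start, x.end, x.motif, x.copy_number, x.mismatches, x.score)
            for x in loci
        ],
        columns=SSR_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_ssr_table(path: str | Path) -> list[Microsatellite]:
    """Read a TSV written by :func:`write_ssr_table` (or an external caller).

    Malformed rows raise :class:`SSRTableError` naming the 1-based file line.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SSRTableError(f"{path}: empty file without header") from exc
    missing = [c for c in SSR_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SSRTableError(f"{path}: missing column(s) {', '.join(missing)} (line 1)")
    loci = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            loci.append(
                Microsatellite(
                    seq_id=row["seq_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    motif=canonical_motif(row["motif"]),
                    copy_number=float(row["copy_number"]),
                    mismatches=int(row["mismatches"]),
                    score=int(row["score"]),
                )
            )
        except (ValueError, InvalidMotifError) as exc:
            raise SSRTableError(f"{path}: malformed row at line {line_no}: {exc}") from exc
    return loci


def write_ssr_bed(loci: Sequence[Microsatellite], path: str | Path) -> None:
    """BED6: 0-based half-open, name = motif, score = scan score, strand '+'."""
    with open(path, "w") as fh:
        for x in loci:
            fh.write(f"{x.seq_id}\t{x.start - 1}\t{x.end}\t{x.motif}\t{x.score}\t+\n")


def ssr_density(loci: Sequence[Microsatellite], genome_size: int) -> tuple[int, float]:
    """(total SSR count, count per Mb)."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    total = len(loci)
    return total, total / (genome_size / 1e6)
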