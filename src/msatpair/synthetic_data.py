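"""Seeded synthetic genomes with planted SSRs, rMP families and segmental
duplications, plus matching annotation fixtures and truth tables.

The generator emulates the statistical structure the analysis assumes: a
repeat-poor i.i.d. background, microsatellite arrays planted singly or as
motif pairs at controlled spacing, and > 1 kb duplicated segments with SSR
termini and controlled sequence identity.  Every planted element is validated
by running the scanner on the candidate insert and is re-drawn until the
scanner reports exactly the intended loci at the intended coordinates, so
family truth tables are exact (tolerance 0).  Spontaneous repeats elsewhere
in the background are allowed for realism and are excluded from truth-based
assertions.

All randomness flows from one :class:`numpy.random.Generator`; a fixed seed
gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from bisect import bisect_left, insort
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation_overlap import AnnotationFeature
from .ssr_scan import (
    GenomeSequence,
    Microsatellite,
    ScanParams,
    canonical_motif,
    find_ssrs,
    write_fasta,
)

#: random background flank built into every insert, long enough that planted
#: arrays can never be extended by or merged with neighbouring sequence
PAD = 25
#: minimum free gap kept between two inserts
MARGIN = 5


class PlacementError(RuntimeError):
    """No collision-free position could be found for an insert."""


@dataclass(frozen=True)
class PlantedSSR:
    seq_id: str
    start: int  # 1-based inclusive, like scanner output
    end: int
    motif: str


@dataclass(frozen=True)
class PlantedPair:
    family: str  # "motif_up|motif_down|distance"
    seq_id: str
    up_start: int
    up_end: int
    up_motif: str
    down_start: int
    down_end: int
    down_motif: str
    distance: int


@dataclass(frozen=True)
class PlantedSD:
    family: str
    seq_id: str
    up_start: int
    up_end: int
    down_start: int
    down_end: int
    distance: int
    expected_identity: float  # vs the master copy
    is_master: bool


# ---------------------------------------------------------------------------
# low-level sequence construction


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=length, p=probs).tobytes().decode("ascii")


def random_genome(
    length: int, gc_content: float, seed: int | np.random.Generator, seq_id: str = "chr1"
) -> GenomeSequence:
    """I.i.d. background sequence with P(G) = P(C) = gc_content / 2."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if not 0.0 <= gc_content < 1.0:
        raise ValueError("gc_content must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return GenomeSequence(seq_id, _random_bases(rng, length, gc_content))


def _mutate_segment(rng: np.random.Generator, segment: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate`` to one of
    the three other bases (never a silent substitution), no indels."""
    if rate == 0:
        return segment
    arr = np.frombuffer(segment.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.shape[0]) < rate)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


_VALIDATION_PARAMS = ScanParams()


def _insert_valid(insert: str, expected: list[tuple[int, int, str]]) -> bool:
    """True iff the scanner reports exactly the expected loci (0-based
    start, 0-based inclusive end, canonical motif) on the bare insert."""
    found = find_ssrs(GenomeSequence("_insert", insert), _VALIDATION_PARAMS)
    got = [(x.start - 1, x.end - 1, x.motif) for x in found]
    return got == sorted(expected)


def _default_repeats(motif: str, target_len: int = 20) -> int:
    """Copies so the array is ~20 bp (>= min score 15 as a perfect repeat)."""
    return max(-(-target_len // len(motif)), 3)


# ---------------------------------------------------------------------------
# the builder

RegionSampler = Callable[[np.random.Generator], tuple[str, int, int]]


class GenomeBuilder:
    """Mutable multi-scaffold genome accepting planted elements.

    Placement is by rejection sampling against previously placed inserts;
    every insert carries PAD bp of validated random flank so planted arrays
    are never extended by their surroundings.
    """

    def __init__(
        self,
        sequences: Sequence[GenomeSequence],
        rng: int | np.random.Generator,
        gc_content: float = 0.5,
    ):
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.gc = gc_content
        self.arrays: dict[str, bytearray] = {
            g.seq_id: bytearray(g.sequence.encode("ascii")) for g in sequences
        }
        self.placed: dict[str, list[tuple[int, int]]] = {k: [] for k in self.arrays}
        self.ssr_truth: list[PlantedSSR] = []
        self.pair_truth: list[PlantedPair] = []
        self.sd_truth: list[PlantedSD] = []

    # -- placement ----------------------------------------------------------

    def _collides(self, seq_id: str, start: int, end: int) -> bool:
        placed = self.placed[seq_id]
        i = bisect_left(placed, (start, end))
        for j in (i - 1, i):
            if 0 <= j < len(placed):
                a, b = placed[j]
                if start < b + MARGIN and a < end + MARGIN:
                    return True
        return False

    def _place(self, insert: str, sampler: RegionSampler | None, max_tries: int = 500) -> tuple[str, int]:
        n = len(insert)
        for _ in range(max_tries):
            if sampler is None:
                seq_id = self._weighted_seq(n)
                lo, hi = 0, len(self.arrays[seq_id])
            else:
                seq_id, lo, hi = sampler(self.rng)
            if hi - lo < n:
                continue
            start = int(self.rng.integers(lo, hi - n + 1))
            if not self._collides(seq_id, start, start + n):
                self.arrays[seq_id][start : start + n] = insert.encode("ascii")
                insort(self.placed[seq_id], (start, start + n))
                return seq_id, start
        raise PlacementError(f"could not place insert of {n} bp after {max_tries} tries")

    def _weighted_seq(self, n: int) -> str:
        ids = [k for k, v in self.arrays.items() if len(v) >= n]
        if not ids:
            raise PlacementError(f"no sequence can hold an insert of {n} bp")
        lens = np.array([len(self.arrays[k]) for k in ids], dtype=float)
        return ids[int(self.rng.choice(len(ids), p=lens / lens.sum()))]

    # -- planting -----------------------------------------------------------

    def plant_ssr(
        self, motif: str, copies: int | None = None, sampler: RegionSampler | None = None
    ) -> PlantedSSR:
        """Plant one isolated SSR array; truth coordinates are exact."""
        motif = canonical_motif(motif)
        k = copies or _default_repeats(motif)
        array = motif * k
        for _ in range(100):
            insert = (
                _random_bases(self.rng, PAD, self.gc) + array + _random_bases(self.rng, PAD, self.gc)
            )
            if _insert_valid(insert, [(PAD, PAD + len(array) - 1, motif)]):
                break
        else:
            raise PlacementError(f"could not build a clean insert for ({motif})x{k}")
        seq_id, pos = self._place(insert, sampler)
        rec = PlantedSSR(seq_id, pos + PAD + 1, pos + PAD + len(array), motif)
        self.ssr_truth.append(rec)
        return rec

    def _pair_insert(
        self, motif_a: str, motif_b: str, distance: int, rep_a: int, rep_b: int,
        spacer: str | None = None, max_tries: int = 100,
    ) -> tuple[str, str]:
        """Validated insert pad+A+spacer+B+pad; returns (insert, spacer)."""
        arr_a, arr_b = motif_a * rep_a, motif_b * rep_b
        la, lb = len(arr_a), len(arr_b)
        expected = [(PAD, PAD + la - 1, motif_a), (PAD + la + distance, PAD + la + distance + lb - 1, motif_b)]
        for _ in range(max_tries):
            sp = spacer if spacer is not None else _random_bases(self.rng, distance, self.gc)
            insert = (
                _random_bases(self.rng, PAD, self.gc)
                + arr_a + sp + arr_b
                + _random_bases(self.rng, PAD, self.gc)
            )
            if _insert_valid(insert, expected):
                return insert, sp
        raise PlacementError(
            f"could not build clean insert for ({motif_a},{motif_b}) at d={distance}"
        )

    def plant_family(
        self,
        motif_pair: tuple[str, str],
        distance: int,
        copies: int,
        repeats: tuple[int, int] | None = None,
        sampler: RegionSampler | None = None,
    ) -> list[PlantedPair]:
        """Plant an rMP family: ``copies`` independent inserts of
        (motif_a)_k + spacer + (motif_b)_k, all with the same intervening
        distance.  Spacers are background-like and re-drawn until the scanner
        sees exactly the two planted arrays."""
        if copies < 2:
            raise ValueError("an rMP family needs >= 2 copies")
        motif_a, motif_b = canonical_motif(motif_pair[0]), canonical_motif(motif_pair[1])
        rep_a, rep_b = repeats or (_default_repeats(motif_a), _default_repeats(motif_b))
        key = f"{motif_a}|{motif_b}|{distance}"
        la, lb = len(motif_a) * rep_a, len(motif_b) * rep_b
        records = []
        for _ in range(copies):
            insert, _sp = self._pair_insert(motif_a, motif_b, distance, rep_a, rep_b)
            seq_id, pos = self._place(insert, sampler)
            up_start = pos + PAD + 1
            rec = PlantedPair(
                key, seq_id,
                up_start, up_start + la - 1, motif_a,
                up_start + la + distance, up_start + la + distance + lb - 1, motif_b,
                distance,
            )
            self.pair_truth.append(rec)
            records.append(rec)
        return records

    def plant_sd_family(
        self,
        segment_length: int,
        termini: tuple[str, str],
        copies: int,
        substitution_rate: float,
        repeats: tuple[int, int] | None = None,
        sampler: RegionSampler | None = None,
    ) -> list[PlantedSD]:
        """Plant a segmental-duplication family: one master segment, plus
        copies mutated by i.i.d. substitutions at the given rate (no indels),
        each flanked by the same SSR termini.  Expected identity of each copy
        to the master is 1 - rate."""
        if segment_length <= 1000:
            raise ValueError("segment_length must exceed 1000 bp")
        if copies < 2:
            raise ValueError("an SD family needs >= 2 copies")
        if not 0 <= substitution_rate <= 0.3:
            raise ValueError("substitution_rate must be in [0, 0.3]")
        motif_a, motif_b = canonical_motif(termini[0]), canonical_motif(termini[1])
        rep_a, rep_b = repeats or (_default_repeats(motif_a), _default_repeats(motif_b))
        key = f"{motif_a}|{motif_b}|{segment_length}"
        la, lb = len(motif_a) * rep_a, len(motif_b) * rep_b

        # master segment, validated as part of a full insert
        master_insert, master_segment = self._pair_insert(
            motif_a, motif_b, segment_length, rep_a, rep_b
        )
        records = []
        for c in range(copies):
            if c == 0:
                insert, identity = master_insert, 1.0
            else:
                for _ in range(50):
                    mutated = _mutate_segment(self.rng, master_segment, substitution_rate)
                    try:
                        insert, _ = self._pair_insert(
                            motif_a, motif_b, segment_length, rep_a, rep_b, spacer=mutated,
                            max_tries=4,
                        )
                        break
                    except PlacementError:
                        continue
                else:
                    raise PlacementError(f"could not build clean mutated copy for {key}")
                identity = 1.0 - substitution_rate
            seq_id, pos = self._place(insert, sampler)
            up_start = pos + PAD + 1
            rec = PlantedSD(
                key, seq_id,
                up_start, up_start + la - 1,
                up_start + la + segment_length,
                up_start + la + segment_length + lb - 1,
                segment_length, identity, c == 0,
            )
            self.sd_truth.append(rec)
            self.pair_truth.append(
                PlantedPair(
                    key, seq_id, rec.up_start, rec.up_end, motif_a,
                    rec.down_start, rec.down_end, motif_b, segment_length,
                )
            )
            records.append(rec)
        return records

    def sequences(self) -> list[GenomeSequence]:
        return [GenomeSequence(k, v.decode("ascii")) for k, v in self.arrays.items()]


# ---------------------------------------------------------------------------
# functional wrappers matching the one-shot call style


def plant_family(
    genome: Sequence[GenomeSequence],
    motif_pair: tuple[str, str],
    distance: int,
    copies: int,
    seed: int | np.random.Generator,
    gc_content: float = 0.5,
) -> tuple[list[GenomeSequence], list[PlantedPair]]:
    b = GenomeBuilder(genome, seed, gc_content)
    recs = b.plant_family(motif_pair, distance, copies)
    return b.sequences(), recs


def plant_sd_family(
    genome: Sequence[GenomeSequence],
    segment_length: int,
    termini: tuple[str, str],
    copies: int,
    substitution_rate: float,
    seed: int | np.random.Generator,
    gc_content: float = 0.5,
) -> tuple[list[GenomeSequence], list[PlantedSD]]:
    b = GenomeBuilder(genome, seed, gc_content)
    recs = b.plant_sd_family(segment_length, termini, copies, substitution_rate)
    return b.sequences(), recs


# ---------------------------------------------------------------------------
# scenario specification


@dataclass(frozen=True)
class FamilySpec:
    motif_pair: tuple[str, str]
    distance: int
    copies: int
    repeats: tuple[int, int] | None = None


@dataclass(frozen=True)
class SDSpec:
    segment_length: int
    termini: tuple[str, str]
    copies: int
    substitution_rate: float


@dataclass(frozen=True)
class EnrichmentRegion:
    seq_id: str
    start: int  # 0-based half-open
    end: int
    multiplier: float


@dataclass(frozen=True)
class ScenarioSpec:
    sequences: tuple[tuple[str, int], ...]
    gc_content: float = 0.5
    planted_ssrs: tuple[tuple[str, int, int], ...] = ()  # (motif, array_copies, n_loci)
    planted_families: tuple[FamilySpec, ...] = ()
    planted_sds: tuple[SDSpec, ...] = ()
    enrichment_regions: tuple[EnrichmentRegion, ...] = ()
    seed: int = 0


@dataclass
class ScenarioResult:
    genome: list[GenomeSequence]
    ssr_truth: pd.DataFrame
    family_truth: pd.DataFrame
    sd_truth: pd.DataFrame
    genes: list[AnnotationFeature]
    tes: list[AnnotationFeature]


def _enrichment_sampler(
    spec: ScenarioSpec,
) -> RegionSampler | None:
    """Sample placement intervals weighted by length x multiplier (regions)
    or length x 1 (everything else)."""
    if not spec.enrichment_regions:
        return None
    items: list[tuple[str, int, int, float]] = []
    by_seq: dict[str, list[EnrichmentRegion]] = {}
    for r in spec.enrichment_regions:
        by_seq.setdefault(r.seq_id, []).append(r)
    for seq_id, length in spec.sequences:
        regs = sorted(by_seq.get(seq_id, []), key=lambda r: r.start)
        cursor = 0
        for r in regs:
            if r.start > cursor:
                items.append((seq_id, cursor, r.start, float(r.start - cursor)))
            items.append((seq_id, r.start, r.end, r.multiplier * (r.end - r.start)))
            cursor = r.end
        if cursor < length:
            items.append((seq_id, cursor, length, float(length - cursor)))
    weights = np.array([it[3] for it in items])
    probs = weights / weights.sum()

    def sampler(rng: np.random.Generator) -> tuple[str, int, int]:
        seq_id, lo, hi, _ = items[int(rng.choice(len(items), p=probs))]
        return seq_id, lo, hi

    return sampler


def generate_scenario(spec: ScenarioSpec, outdir: str | Path | None = None) -> ScenarioResult:
    """Build the genome and truth tables for a scenario; optionally write
    FASTA + truth TSV/BED + gene/TE annotation fixtures to ``outdir``."""
    rng = np.random.default_rng(spec.seed)
    background = [
        GenomeSequence(seq_id, _random_bases(rng, length, spec.gc_content))
        for seq_id, length in spec.sequences
    ]
    builder = GenomeBuilder(background, rng, spec.gc_content)
    sampler = _enrichment_sampler(spec)

    for motif, array_copies, n_loci in spec.planted_ssrs:
        for _ in range(n_loci):
            builder.plant_ssr(motif, array_copies, sampler)
    for f in spec.planted_families:
        builder.plant_family(f.motif_pair, f.distance, f.copies, f.repeats, sampler)
    for s in spec.planted_sds:
        builder.plant_sd_family(
            s.segment_length, s.termini, s.copies, s.substitution_rate, sampler=sampler
        )

    genome = builder.sequences()
    ssr_truth = pd.DataFrame(
        [(r.seq_id, r.start, r.end, r.motif) for r in builder.ssr_truth],
        columns=["seq_id", "start", "end", "motif"],
    )
    family_truth = pd.DataFrame(
        [
            (r.family, r.seq_id, r.up_start, r.up_end, r.up_motif,
             r.down_start, r.down_end, r.down_motif, r.distance)
            for r in builder.pair_truth
        ],
        columns=["family", "seq_id", "up_start", "up_end", "up_motif",
                 "down_start", "down_end", "down_motif", "distance"],
    )
    sd_truth = pd.DataFrame(
        [
            (r.family, r.seq_id, r.up_start, r.up_end, r.down_start, r.down_end,
             r.distance, r.expected_identity, r.is_master)
            for r in builder.sd_truth
        ],
        columns=["family", "seq_id", "up_start", "up_end", "down_start", "down_end",
                 "distance", "expected_identity", "is_master"],
    )
    genes, tes = _annotation_fixtures(builder)
    result = ScenarioResult(genome, ssr_truth, family_truth, sd_truth, genes, tes)
    if outdir is not None:
        _write_scenario(result, Path(outdir))
    return result


def _annotation_fixtures(
    builder: GenomeBuilder,
) -> tuple[list[AnnotationFeature], list[AnnotationFeature]]:
    """Gene features spanning the copies of the first planted SD family and TE
    features over the second, so overlap classification has known truth."""
    genes: list[AnnotationFeature] = []
    tes: list[AnnotationFeature] = []
    fams = sorted({r.family for r in builder.sd_truth})
    for i, rec in enumerate(builder.sd_truth):
        which = fams.index(rec.family) if rec.family in fams else -1
        span = (rec.seq_id, rec.up_start - 1 - 10, rec.down_end + 10)
        if which == 0:
            genes.append(
                AnnotationFeature(span[0], max(0, span[1]), span[2], "gene", f"gene_{i:04d}")
            )
        elif which == 1:
            tes.append(
                AnnotationFeature(span[0], max(0, span[1]), span[2], "TE", f"te_{i:04d}")
            )
    return genes, tes


def _write_scenario(result: ScenarioResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.genome, outdir / "genome.fa")
    result.ssr_truth.to_csv(outdir / "ssr_truth.tsv", sep="\t", index=False)
    result.family_truth.to_csv(outdir / "family_truth.tsv", sep="\t", index=False)
    with open(outdir / "sd_truth.bed", "w") as fh:
        for _, r in result.sd_truth.iterrows():
            fh.write(
                f"{r.seq_id}\t{r.up_start - 1}\t{r.down_end}\t{r.family}\t"
                f"{int(round(1000 * r.expected_identity))}\t+\n"
            )
    with open(outdir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for g in result.genes:
            fh.write(
                f"{g.seq_id}\tmsatpair\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\tID={g.feature_id}\n"
            )
    with open(outdir / "tes.bed", "w") as fh:
        for t in result.tes:
            fh.write(f"{t.seq_id}\t{t.start}\t{t.end}\t{t.feature_id}\t0\t+\n")


def load_scenario_yaml(path: str | Path) -> ScenarioSpec:
    """Read a ScenarioSpec from YAML (keys mirror the dataclass fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ScenarioSpec(
        sequences=tuple((s["seq_id"], int(s["length"])) for s in raw["sequences"]),
        gc_content=float(raw.get("gc_content", 0.5)),
        planted_ssrs=tuple(
            (p["motif"], int(p["array_copies"]), int(p["count"]))
            for p in raw.get("planted_ssrs", [])
        ),
        planted_families=tuple(
            FamilySpec(
                (f["motif_up"], f["motif_down"]), int(f["distance"]), int(f["copies"]),
                tuple(f["repeats"]) if f.get("repeats") else None,
            )
            for f in raw.get("planted_families", [])
        ),
        planted_sds=tuple(
            SDSpec(
                int(s["segment_length"]), (s["motif_up"], s["motif_down"]),
                int(s["copies"]), float(s["substitution_rate"]),
            )
            for s in raw.get("planted_sds", [])
        ),
        enrichment_regions=tuple(
            EnrichmentRegion(r["seq_id"], int(r["start"]), int(r["end"]), float(r["multiplier"]))
            for r in raw.get("enrichment_regions", [])
        ),
        seed=int(raw.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# canonical study scenarios (shared by the test suite and acceptance script)

#: motif vocabulary used when scenarios need varied, mutually distinct pairs
_MOTIFS = ("A", "C", "AC", "AG", "AT", "AAT", "AAG", "ACT", "AAAT", "AATT", "AACAG", "AATAGC")


def default_demo_scenario(seed: int = 0) -> ScenarioSpec:
    """The default 2 Mb demonstration scenario: four 500 kb scaffolds with 20
    planted rMP families and 8 planted SD families (five at 95% identity,
    three at 85%, bracketing the 90% calling threshold)."""
    distances = (5, 20, 60, 138, 250, 400, 700, 900, 1200, 2500,
                 35, 80, 170, 310, 520, 640, 777, 850, 460, 95)
    copies = (6, 2, 3, 4, 2, 5, 3, 2, 2, 2, 4, 3, 2, 2, 3, 2, 2, 2, 3, 2)
    fams = tuple(
        FamilySpec((_MOTIFS[i % len(_MOTIFS)], _MOTIFS[(i + 3) % len(_MOTIFS)]), d, c)
        for i, (d, c) in enumerate(zip(distances, copies))
    )
    sds = tuple(
        SDSpec(seg, (_MOTIFS[(2 * i) % len(_MOTIFS)], _MOTIFS[(2 * i + 5) % len(_MOTIFS)]),
               cp, rate)
        for i, (seg, cp, rate) in enumerate(
            [
                (1500, 3, 0.05), (1700, 2, 0.05), (2000, 3, 0.05),
                (2300, 2, 0.05), (2600, 4, 0.05),
                (1600, 2, 0.15), (2100, 3, 0.15), (2400, 2, 0.15),
            ]
        )
    )
    return ScenarioSpec(
        sequences=tuple((f"scaf_{i}", 500_000) for i in range(4)),
        gc_content=0.5,
        planted_families=fams,
        planted_sds=sds,
        seed=seed,
    )


def null_scenario(seed: int = 0) -> ScenarioSpec:
    """Fully random genomes with no planted elements: any rMP family found is
    a spontaneous coincidence of the i.i.d. background.  AT-rich background
    (GC 0.35), as is typical of insect assemblies."""
    return ScenarioSpec(
        sequences=(("null_1", 250_000), ("null_2", 250_000)),
        gc_content=0.35,
        seed=seed,
    )


def repeat_rich_genome(seed: int = 0) -> list[GenomeSequence]:
    """A six-scaffold 1.5 Mb genome emulating a draft assembly with
    repeat-dominated scaffolds: three scaffolds are ~77% mononucleotide-repeat
    arrays (so even their *shuffled* sequence is compositionally biased enough
    to contain spontaneous SSRs), three are ordinary background carrying
    planted rMP families."""
    rng = np.random.default_rng(seed)
    scaffolds: list[GenomeSequence] = []
    for i, base in enumerate("AAT"):
        # one dominant mononucleotide per scaffold, ~90% of its length, so the
        # scaffold stays compositionally extreme even after shuffling
        parts: list[str] = []
        total = 0
        while total < 250_000:
            run = int(rng.integers(80, 160))
            gap = int(rng.integers(8, 18))
            parts.append(base * run)
            parts.append(_random_bases(rng, gap, 0.4))
            total += run + gap
        scaffolds.append(GenomeSequence(f"rich_{i}", "".join(parts)[:250_000]))
    background = [
        GenomeSequence(f"plain_{i}", _random_bases(rng, 250_000, 0.4)) for i in range(3)
    ]
    builder = GenomeBuilder(background, rng, 0.4)
    for i, (d, c) in enumerate(zip((40, 138, 300, 520, 760, 900, 1400, 2200, 64, 480),
                                   (4, 6, 3, 2, 5, 2, 2, 3, 4, 2))):
        builder.plant_family(
            (_MOTIFS[i % len(_MOTIFS)], _MOTIFS[(i + 4) % len(_MOTIFS)]), d, c
        )
    return scaffolds + builder.sequences()


def coaggregation_scenario(seed: int = 0) -> ScenarioSpec:
    """One 1.2 Mb chromosome with a 200 kb region whose plant density is
    enriched 10-fold: 30 rMP families and 12 SD families of two copies each,
    placed by the enrichment sampler, for the window co-aggregation test."""
    fams = tuple(
        FamilySpec((_MOTIFS[i % len(_MOTIFS)], _MOTIFS[(i + 5) % len(_MOTIFS)]),
                   20 + 29 * i, 2)
        for i in range(30)
    )
    sds = tuple(
        SDSpec(2050 + 20 * i,
               (_MOTIFS[(i + 1) % len(_MOTIFS)], _MOTIFS[(i + 7) % len(_MOTIFS)]),
               2, 0.03)
        for i in range(12)
    )
    return ScenarioSpec(
        sequences=(("chr1", 1_200_000),),
        gc_content=0.5,
        planted_families=fams,
        planted_sds=sds,
        enrichment_regions=(EnrichmentRegion("chr1", 800_000, 1_000_000, 10.0),),
        seed=seed,
    )
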