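"""Overlap of mSD / rMP loci with gene, transposable-element and paralog
annotations.

Loci are partitioned with the precedence gene > TE: a locus overlapping any
gene by >= 1 bp is *genic*; otherwise one overlapping a TE is *TE_associated*;
the rest are *intergenic*.  Raw per-class overlap flags are also emitted, so
the partition does not hide a locus that touches both a gene and a TE.
All interval arithmetic is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .msd_call import MSDFamily

CLASSES = ("genic", "TE_associated", "intergenic")


class AnnotationParseError(ValueError):
    """Malformed annotation record; the message names the 1-based line."""


@dataclass(frozen=True)
class AnnotationFeature:
    seq_id: str
    start: int  # 0-based half-open
    end: int
    feature_class: str  # "gene" | "TE" | "other"
    feature_id: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end}) for {self.feature_id}")


@dataclass(frozen=True)
class LocusOverlap:
    seq_id: str
    start: int
    end: int
    label: str
    overlap_class: str  # one of CLASSES
    overlaps_gene: bool
    overlaps_te: bool
    gene_ids: tuple[str, ...]
    te_ids: tuple[str, ...]


@dataclass(frozen=True)
class OverlapReport:
    loci: tuple[LocusOverlap, ...]
    counts: dict[str, int]
    genic_fraction: float  # percentage
    te_fraction: float     # percentage


def load_features(
    path: str | Path,
    format: str = "GFF3",
    feature_class: str = "gene",
    gff_types: frozenset[str] = frozenset({"gene"}),
) -> list[AnnotationFeature]:
    """Read gene/TE features from GFF3 (1-based inclusive, converted) or BED
    (already 0-based half-open).  Invalid records raise
    :class:`AnnotationParseError` with the line number."""
    fmt = format.upper()
    if fmt not in {"GFF3", "BED"}:
        raise ValueError(f"unknown format {format!r}")
    features: list[AnnotationFeature] = []
    auto = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if fmt == "GFF3":
                    if len(cols) < 9:
                        raise ValueError(f"expected 9 columns, got {len(cols)}")
                    if cols[2] not in gff_types:
                        continue
                    start, end = int(cols[3]) - 1, int(cols[4])
                    fid = _gff_id(cols[8])
                else:
                    if len(cols) < 3:
                        raise ValueError(f"expected >= 3 columns, got {len(cols)}")
                    start, end = int(cols[1]), int(cols[2])
                    fid = cols[3] if len(cols) > 3 and cols[3] not in (".", "") else ""
                if not fid:
                    auto += 1
                    fid = f"{feature_class}_{auto:06d}"
                features.append(AnnotationFeature(cols[0], start, end, feature_class, fid))
            except ValueError as exc:
                raise AnnotationParseError(f"{path}: line {line_no}: {exc}") from exc
    return features


def _gff_id(attributes: str) -> str:
    for part in attributes.split(";"):
        part = part.strip()
        for key in ("ID=", "Name="):
            if part.startswith(key):
                return part[len(key):]
    return ""


def _trees(features: Iterable[AnnotationFeature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.seq_id, IntervalTree()).addi(f.start, f.end, f.feature_id)
    return trees


def _norm_loci(loci) -> list[tuple[str, int, int, str]]:
    out = []
    for i, loc in enumerate(loci):
        if isinstance(loc, tuple):
            seq_id, start, end = loc[0], int(loc[1]), int(loc[2])
            label = loc[3] if len(loc) > 3 else f"locus_{i:06d}"
        else:  # object with seq_id / start / end (0-based half-open expected)
            seq_id, start, end = loc.seq_id, int(loc.start), int(loc.end)
            label = getattr(loc, "feature_id", f"locus_{i:06d}")
        out.append((seq_id, start, end, label))
    return out


def classify_loci(
    loci,
    genes: Sequence[AnnotationFeature],
    tes: Sequence[AnnotationFeature] = (),
) -> OverlapReport:
    """Classify each locus (tuples ``(seq_id, start, end[, label])`` in
    0-based half-open coordinates) against gene and TE features."""
    gene_trees = _trees(genes)
    te_trees = _trees(tes)
    records: list[LocusOverlap] = []
    counts = {c: 0 for c in CLASSES}
    for seq_id, start, end, label in _norm_loci(loci):
        hits_g = sorted(iv.data for iv in gene_trees.get(seq_id, IntervalTree()).overlap(start, end))
        hits_t = sorted(iv.data for iv in te_trees.get(seq_id, IntervalTree()).overlap(start, end))
        if hits_g:
            cls = "genic"
        elif hits_t:
            cls = "TE_associated"
        else:
            cls = "intergenic"
        counts[cls] += 1
        records.append(
            LocusOverlap(seq_id, start, end, label, cls,
                         bool(hits_g), bool(hits_t), tuple(hits_g), tuple(hits_t))
        )
    total = len(records)
    genic = 100.0 * counts["genic"] / total if total else 0.0
    te = 100.0 * sum(r.overlaps_te for r in records) / total if total else 0.0
    return OverlapReport(tuple(records), counts, genic, te)


def msd_member_intervals(msds: Sequence[MSDFamily]) -> list[tuple[str, int, int, str]]:
    """mSD member spans as 0-based half-open tuples (SSR termini included)."""
    return [
        (m.seq_id, m.upstream.start - 1, m.downstream.end, f.parent.key)
        for f in msds
        for m in f.members
    ]


def nip_overlap(
    msds: Sequence[MSDFamily],
    paralog_pairs: pd.DataFrame,
    genes: Sequence[AnnotationFeature],
    min_identity: float = 0.90,
) -> pd.DataFrame:
    """Flag nearly identical paralog (NIP) pairs anchored by one mSD family.

    ``paralog_pairs`` needs columns gene_a, gene_b, identity.  A pair is
    flagged when identity >= min_identity and both genes overlap at least one
    member locus of the *same* mSD family.  Returns the flagged rows with a
    ``family`` column.
    """
    required = {"gene_a", "gene_b", "identity"}
    if not required <= set(paralog_pairs.columns):
        raise ValueError(f"paralog table needs columns {sorted(required)}")
    by_gene = {g.feature_id: g for g in genes}
    unknown = (set(paralog_pairs["gene_a"]) | set(paralog_pairs["gene_b"])) - set(by_gene)
    if unknown:
        raise ValueError(f"paralog table references unknown gene ids: {sorted(unknown)[:5]}")

    tree = _trees(genes)
    fam_genes: dict[str, set[str]] = {}
    for f in msds:
        hit: set[str] = set()
        for m in f.members:
            s, e = m.upstream.start - 1, m.downstream.end
            t = tree.get(m.seq_id)
            if t is not None:
                hit.update(iv.data for iv in t.overlap(s, e))
        fam_genes[f.parent.key] = hit

    rows = []
    for _, r in paralog_pairs.iterrows():
        if float(r["identity"]) < min_identity:
            continue
        for key, gset in fam_genes.items():
            if r["gene_a"] in gset and r["gene_b"] in gset:
                rows.append((r["gene_a"], r["gene_b"], float(r["identity"]), key))
                break
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "identity", "family"])


def write_overlap_table(report: OverlapReport, path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.seq_id, r.start, r.end, r.label, r.overlap_class,
             r.overlaps_gene, r.overlaps_te,
             ",".join(r.gene_ids), ",".join(r.te_ids))
            for r in report.loci
        ],
        columns=["seq_id", "start", "end", "locus", "class",
                 "overlaps_gene", "overlaps_te", "gene_ids", "te_ids"],
    ).to_csv(path, sep="\t", index=False)
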