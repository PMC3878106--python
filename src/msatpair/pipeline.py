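"""One-call convenience wrapper running scan -> pairs -> families -> tests."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .msd_call import MSDFamily, call_msds
from .rmp_core import AdjacentPair, RMPFamily, adjacent_pairs, group_rmp_families
from .rmp_stats import AssociationResult, test_all_families
from .ssr_scan import GenomeSequence, Microsatellite, ScanParams, scan_genome


@dataclass
class GenomeAnalysis:
    genome: list[GenomeSequence]
    loci: list[Microsatellite]
    pairs: list[AdjacentPair]
    families: list[RMPFamily]
    results: list[AssociationResult]
    msds: list[MSDFamily]


def analyze_genome(
    genome: Sequence[GenomeSequence],
    params: ScanParams | None = None,
    tolerance: int = 0,
    alpha: float = 0.05,
    call_duplications: bool = True,
    min_length: int = 1000,
    min_identity: float = 0.90,
) -> GenomeAnalysis:
    """Full analysis of one genome; association tests are skipped (empty
    result list) when no family exists."""
    genome = list(genome)
    loci = scan_genome(genome, params)
    pairs = adjacent_pairs(loci)
    families = group_rmp_families(pairs, tolerance)
    results = (
        test_all_families(families, pairs, alpha=alpha, tolerance=tolerance)
        if families
        else []
    )
    msds = (
        call_msds(families, genome, min_length=min_length, min_identity=min_identity)
        if call_duplications and families
        else []
    )
    return GenomeAnalysis(genome, loci, pairs, families, results, msds)
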