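"""Generator determinism, planted-element fidelity, scenario consistency."""

import numpy as np
import pandas as pd
import pytest

from msatpair import analyze_genome
from msatpair.annotation_overlap import classify_loci
from msatpair.msd_call import call_msds, pairwise_identity
from msatpair.rmp_core import adjacent_pairs, group_rmp_families
from msatpair.ssr_scan import find_ssrs, scan_genome
from msatpair.synthetic_data import (
    EnrichmentRegion,
    FamilySpec,
    GenomeBuilder,
    PlacementError,
    ScenarioSpec,
    SDSpec,
    generate_scenario,
    load_scenario_yaml,
    plant_family,
    random_genome,
)


class TestRandomGenome:
    def test_gc_concentration(self):
        g = random_genome(1_000_000, 0.5, 1)
        gc = (g.sequence.count("G") + g.sequence.count("C")) / g.length
        assert gc == pytest.approx(0.5, abs=0.003)

    def test_seed_determinism(self):
        assert random_genome(10_000, 0.4, 9).sequence == random_genome(10_000, 0.4, 9).sequence

    def test_gc_zero_is_at_only(self):
        g = random_genome(5_000, 0.0, 3)
        assert set(g.sequence) <= {"A", "T"}

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            random_genome(0, 0.5, 1)
        with pytest.raises(ValueError):
            random_genome(100, 1.5, 1)


class TestPlantFamily:
    def test_end_to_end_recovery(self):
        genome = [random_genome(300_000, 0.5, 5)]
        planted, truth = plant_family(genome, ("AC", "AAT"), 138, 6, seed=6)
        fams = group_rmp_families(adjacent_pairs(scan_genome(planted)))
        assert [(f.key, f.copy_count) for f in fams] == [("AC|AAT|138", 6)]
        # truth coordinates match scanner output exactly
        loci = {(x.seq_id, x.start, x.end, x.motif) for x in scan_genome(planted)}
        for rec in truth:
            assert (rec.seq_id, rec.up_start, rec.up_end, rec.up_motif) in loci
            assert (rec.seq_id, rec.down_start, rec.down_end, rec.down_motif) in loci

    def test_histone_like_near_distances(self):
        """Two families at 3807 and 3810 bp separate at tolerance 0 and merge
        at tolerance 3, mirroring slippage-shifted spacer lengths."""
        builder = GenomeBuilder([random_genome(600_000, 0.5, 7)], 8)
        builder.plant_family(("AAT", "C"), 3807, 2)
        builder.plant_family(("AAT", "C"), 3810, 3)
        pairs = adjacent_pairs(scan_genome(builder.sequences()))
        exact = [f for f in group_rmp_families(pairs, 0) if f.motif_pair == ("AAT", "C")]
        assert sorted((f.distance, f.copy_count) for f in exact) == [(3807, 2), (3810, 3)]
        merged = [f for f in group_rmp_families(pairs, 3) if f.motif_pair == ("AAT", "C")]
        assert [(f.distance, f.copy_count) for f in merged] == [(3810, 5)]

    def test_placements_never_overlap(self):
        builder = GenomeBuilder([random_genome(50_000, 0.5, 9)], 10)
        for d in (40, 90, 140):
            builder.plant_family(("AC", "AG"), d, 4)
        for intervals in builder.placed.values():
            for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
                assert b1 <= a2

    def test_impossible_placement_raises(self):
        builder = GenomeBuilder([random_genome(2_000, 0.5, 11)], 12)
        with pytest.raises(PlacementError):
            builder.plant_family(("AC", "AAT"), 1500, 3)


class TestPlantSDFamily:
    @pytest.mark.parametrize("rate,called", [(0.05, True), (0.15, False)])
    def test_identity_thresholding(self, rate, called):
        builder = GenomeBuilder([random_genome(300_000, 0.5, 13)], 14)
        builder.plant_sd_family(1500, ("AG", "AAAT"), 3, rate)
        seqs = builder.sequences()
        fams = group_rmp_families(adjacent_pairs(scan_genome(seqs)))
        msds = call_msds(fams, seqs)
        assert bool(msds) is called

    def test_rate_zero_identity_exactly_one(self):
        builder = GenomeBuilder([random_genome(200_000, 0.5, 15)], 16)
        builder.plant_sd_family(1200, ("AC", "AAT"), 3, 0.0)
        seqs = {g.seq_id: g.sequence for g in builder.sequences()}
        segs = [
            seqs[r.seq_id][r.up_end : r.down_start - 1] for r in builder.sd_truth
        ]
        assert segs[0] == segs[1] == segs[2]
        assert pairwise_identity(segs[0], segs[1]) == 1.0

    def test_truth_records_expected_identity(self):
        builder = GenomeBuilder([random_genome(200_000, 0.5, 17)], 18)
        recs = builder.plant_sd_family(1100, ("AC", "AAG"), 3, 0.1)
        assert [r.expected_identity for r in recs] == [1.0, 0.9, 0.9]
        assert [r.is_master for r in recs] == [True, False, False]


class TestGenerateScenario:
    SPEC = ScenarioSpec(
        sequences=(("s1", 150_000), ("s2", 150_000)),
        planted_families=(FamilySpec(("AC", "AAT"), 138, 3),
                          FamilySpec(("A", "AG"), 420, 2)),
        planted_sds=(SDSpec(1200, ("AT", "AAG"), 2, 0.04),
                     SDSpec(1400, ("C", "AAAT"), 2, 0.04)),
        seed=19,
    )

    def test_outputs_consistent_and_recovered(self):
        res = generate_scenario(self.SPEC)
        ana = analyze_genome(res.genome)
        truth = res.family_truth.groupby("family").size()
        found = {f.key: f.copy_count for f in ana.families}
        assert {k: found.get(k) for k in truth.index} == truth.to_dict()
        assert {m.parent.key for m in ana.msds} == set(res.sd_truth.family)

    def test_determinism(self):
        a = generate_scenario(self.SPEC)
        b = generate_scenario(self.SPEC)
        assert [g.sequence for g in a.genome] == [g.sequence for g in b.genome]
        assert a.family_truth.equals(b.family_truth)

    def test_gene_fixture_marks_sd_genic(self):
        res = generate_scenario(self.SPEC)
        assert res.genes and res.tes
        first_sd_fam = sorted(set(res.sd_truth.family))[0]
        rows = res.sd_truth[res.sd_truth.family == first_sd_fam]
        loci = [(r.seq_id, r.up_start - 1, r.down_end) for r in rows.itertuples()]
        rep = classify_loci(loci, res.genes, res.tes)
        assert all(x.overlap_class == "genic" for x in rep.loci)

    def test_no_plants_scenario_is_quiet(self):
        spec = ScenarioSpec(sequences=(("s", 100_000),), gc_content=0.35, seed=3)
        res = generate_scenario(spec)
        ana = analyze_genome(res.genome, call_duplications=False)
        assert len(ana.families) <= 1  # spontaneous families are rare

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "scenario.yaml"
        p.write_text(
            "sequences:\n  - {seq_id: s1, length: 50000}\n"
            "gc_content: 0.4\n"
            "planted_families:\n"
            "  - {motif_up: AC, motif_down: AAT, distance: 138, copies: 2}\n"
            "planted_sds:\n"
            "  - {segment_length: 1200, motif_up: AT, motif_down: AAG, copies: 2,"
            " substitution_rate: 0.05}\n"
            "enrichment_regions:\n"
            "  - {seq_id: s1, start: 0, end: 10000, multiplier: 5}\n"
            "seed: 4\n"
        )
        spec = load_scenario_yaml(p)
        assert spec.sequences == (("s1", 50_000),)
        assert spec.planted_families[0].distance == 138
        assert spec.enrichment_regions[0].multiplier == 5.0

    def test_scenario_files_written(self, tmp_path):
        generate_scenario(self.SPEC, tmp_path)
        for name in ("genome.fa", "family_truth.tsv", "sd_truth.bed", "genes.gff3", "tes.bed"):
            assert (tmp_path / name).exists()


def test_enrichment_sampler_concentrates_plants():
    spec = ScenarioSpec(
        sequences=(("chr", 500_000),),
        planted_families=tuple(FamilySpec(("AC", "AAT"), 100 + i, 2) for i in range(20)),
        enrichment_regions=(EnrichmentRegion("chr", 0, 50_000, 50.0),),
        seed=23,
    )
    res = generate_scenario(spec)
    inside = (res.family_truth.up_start < 50_000).mean()
    assert inside > 0.7  # region weight 50x on 10% of the chromosome
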