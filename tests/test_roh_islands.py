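"""Per-SNV in-ROH fractions, island detection, classification and profiling."""

import numpy as np
import pandas as pd
import pytest

from rohscan import (
    GeneRecord,
    PlantedIsland,
    PopulationSpec,
    RohParams,
    RohSegment,
    RohSet,
    SampleTable,
    SimConfig,
    SnvRohFraction,
    annotate_genes,
    call_roh,
    classify_islands,
    detect_islands,
    gene_fraction_profile,
    islands_frame,
    run_island_pipeline,
    simulate_cohort,
    snv_roh_fraction,
    window_matrix,
)
from rohscan.synthetic_data import MB

from reference import naive_site_coverage_fraction


def sites_frame(positions, chrom="1"):
    if isinstance(positions, dict):
        frames = [pd.DataFrame({"chrom": c, "pos": np.asarray(p, dtype=np.int64),
                                "id": ".", "ref": "A", "alt": "G"})
                  for c, p in positions.items()]
        return pd.concat(frames, ignore_index=True)
    return pd.DataFrame({"chrom": chrom, "pos": np.asarray(positions, dtype=np.int64),
                         "id": ".", "ref": "A", "alt": "G"})


def roh_set(segments, sample_ids):
    return RohSet(segments=segments, params=RohParams(), sample_ids=sample_ids)


def fraction(values, label="modern", size=10):
    return SnvRohFraction(label, size, np.asarray(values, dtype=float))


class TestSnvRohFraction:
    def test_no_segments_is_zero(self):
        rs = roh_set([], ["a", "b"])
        fr = snv_roh_fraction(rs, sites_frame([100, 200]), ["a", "b"])
        np.testing.assert_array_equal(fr.fractions, 0.0)

    def test_counting(self):
        ids = [f"s{i}" for i in range(5)]
        segs = [RohSegment(s, "1", 50, 150, 10, 10) for s in ids[:4]]
        rs = roh_set(segs, ids)
        fr = snv_roh_fraction(rs, sites_frame([100, 200]), ids)
        assert fr.fractions[0] == pytest.approx(0.8)
        assert fr.fractions[1] == 0.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            snv_roh_fraction(roh_set([], ["a"]), sites_frame([100]), [])

    def test_matches_naive_interval_scan(self):
        rng = np.random.default_rng(5)
        ids = [f"s{i}" for i in range(8)]
        sites = sites_frame({
            "1": np.sort(rng.choice(np.arange(1, 100_000), 30, replace=False)),
            "2": np.sort(rng.choice(np.arange(1, 100_000), 20, replace=False)),
        })
        segs, by_sample = [], {}
        for sid in ids:
            for _ in range(rng.integers(0, 4)):
                chrom = str(rng.integers(1, 3))
                start = int(rng.integers(1, 90_000))
                end = start + int(rng.integers(100, 20_000))
                segs.append(RohSegment(sid, chrom, start, end, 5, 5))
                by_sample.setdefault(sid, []).append((chrom, start, end))
        fr = snv_roh_fraction(roh_set(segs, ids), sites, ids)
        expected = naive_site_coverage_fraction(by_sample, sites, ids)
        np.testing.assert_allclose(fr.fractions, expected)


class TestDetectIslands:
    def test_singleton_dropped_at_min_two(self):
        sites = sites_frame([100, 200, 300, 400])
        islands = detect_islands(fraction([0.9, 0.85, 0.7, 0.9]), sites)
        assert len(islands) == 1
        assert (islands[0].start_pos, islands[0].end_pos) == (100, 200)
        assert islands[0].mean_fraction["modern"] == pytest.approx(0.875)

    def test_all_above_threshold_single_island(self):
        sites = sites_frame([10, 20, 30])
        (isl,) = detect_islands(fraction([1.0, 1.0, 1.0]), sites)
        assert (isl.start_pos, isl.end_pos, isl.n_snv) == (10, 30, 3)

    def test_islands_do_not_cross_chromosomes(self):
        sites = sites_frame({"1": [10, 20], "2": [10, 20]})
        islands = detect_islands(fraction([1.0, 1.0, 1.0, 1.0]), sites)
        assert [i.chrom for i in islands] == ["1", "2"]

    def test_threshold_nestedness(self):
        rng = np.random.default_rng(6)
        values = rng.random(200)
        sites = sites_frame(np.arange(200) * 50 + 1)
        strict = detect_islands(fraction(values), sites, threshold=0.90)
        loose = detect_islands(fraction(values), sites, threshold=0.80)
        for s in strict:
            assert any(l.start_pos <= s.start_pos and s.end_pos <= l.end_pos
                       for l in loose)

    def test_min_island_snvs_subsets(self):
        rng = np.random.default_rng(13)
        values = (rng.random(300) > 0.4).astype(float)
        sites = sites_frame(np.arange(300) * 10 + 1)
        small = {(i.start_pos, i.end_pos)
                 for i in detect_islands(fraction(values), sites, min_island_snvs=2)}
        large = {(i.start_pos, i.end_pos)
                 for i in detect_islands(fraction(values), sites, min_island_snvs=5)}
        assert large <= small

    def test_member_snvs_all_reach_threshold(self):
        rng = np.random.default_rng(21)
        values = rng.random(500)
        sites = sites_frame(np.arange(500) * 20 + 1)
        for isl in detect_islands(fraction(values), sites, threshold=0.8):
            assert np.all(values[isl.snv_indices] >= 0.8)


class TestClassifyIslands:
    def island(self, n=3):
        return detect_islands(fraction([0.9] * n), sites_frame(np.arange(n) * 100 + 1))

    def test_low_wild_fraction_flagged(self):
        # means echo a pooled-modern 86.15% / wild 42.62% island
        (isl,) = classify_islands(self.island(), fraction([0.43, 0.42, 0.43], "wild", 9))
        assert isl.domestication_related is True
        assert isl.mean_fraction["wild"] == pytest.approx(0.4267, abs=1e-4)

    def test_high_wild_fraction_not_flagged(self):
        (isl,) = classify_islands(self.island(), fraction([0.83, 0.83, 0.84], "wild", 9))
        assert isl.domestication_related is False

    def test_zero_wild_flagged(self):
        (isl,) = classify_islands(self.island(), fraction([0.0, 0.0, 0.0], "wild", 9))
        assert isl.domestication_related is True


def planted_cfg(seed, islands):
    return SimConfig(
        populations=(
            PopulationSpec("POP1", n_samples=10),
            PopulationSpec("POP2", n_samples=10),
            PopulationSpec("WILD", group="wild", n_samples=8),
        ),
        chrom_lengths={"1": 10 * MB},
        snv_density=400.0,
        target_autozygosity=0.10,
        tract_generations=25.0,
        planted_islands=islands,
        seed=seed,
    )


class TestIslandPipeline:
    def overlaps(self, islands, planted):
        return [i for i in islands
                if i.chrom == planted.chrom
                and i.start_pos <= planted.end and i.end_pos >= planted.start]

    def test_modern_island_detected_and_flagged(self):
        planted = PlantedIsland("1", 4 * MB, int(4.5 * MB), ("POP1", "POP2"))
        gm, _ = simulate_cohort(planted_cfg(3, (planted,)))
        rs = call_roh(gm, RohParams(min_snp=50))
        result = run_island_pipeline(rs, gm)
        hits = self.overlaps(result.pooled_islands, planted)
        assert hits
        assert any(i.domestication_related for i in hits)

    def test_single_population_island_absent_from_pooled_step(self):
        planted = PlantedIsland("1", 6 * MB, int(6.5 * MB), ("POP1",))
        gm, _ = simulate_cohort(planted_cfg(4, (planted,)))
        rs = call_roh(gm, RohParams(min_snp=50))
        result = run_island_pipeline(rs, gm)
        assert not self.overlaps(result.pooled_islands, planted)
        assert self.overlaps(result.per_population_islands["POP1"], planted)

    def test_single_population_cohort_pooled_equals_per_population(self):
        cfg = SimConfig(
            populations=(PopulationSpec("POP1", n_samples=12),),
            chrom_lengths={"1": 5 * MB}, snv_density=400.0,
            target_autozygosity=0.3, tract_generations=10.0, seed=9,
        )
        gm, _ = simulate_cohort(cfg)
        rs = call_roh(gm, RohParams(min_snp=50))
        result = run_island_pipeline(rs, gm)
        pooled = [(i.chrom, i.start_pos, i.end_pos) for i in result.pooled_islands]
        per_pop = [(i.chrom, i.start_pos, i.end_pos)
                   for i in result.per_population_islands["POP1"]]
        assert pooled == per_pop

    def test_pooled_fraction_is_weighted_mean_of_population_fractions(self):
        gm, _ = simulate_cohort(planted_cfg(10, ()))
        rs = call_roh(gm, RohParams(min_snp=50))
        result = run_island_pipeline(rs, gm)
        sizes = {p: len(gm.samples.samples_of(p)) for p in ("POP1", "POP2")}
        weighted = sum(
            sizes[p] * result.fractions_by_population[p].fractions
            for p in sizes
        ) / sum(sizes.values())
        np.testing.assert_allclose(result.pooled_fraction.fractions, weighted,
                                   atol=1e-12)

    def test_planted_island_recovery_over_replicates(self):
        """500-kb fixed modern regions recovered and flagged in 20/20 replicates."""
        for seed in range(20):
            planted = PlantedIsland("1", 3 * MB, int(3.5 * MB), ("POP1", "POP2"))
            cfg = planted_cfg(100 + seed, (planted,))
            from dataclasses import replace
            cfg = replace(cfg, het_error_rate=0.002, snv_density=300.0)
            gm, _ = simulate_cohort(cfg)
            rs = call_roh(gm, RohParams(min_snp=50))
            result = run_island_pipeline(rs, gm)
            hits = self.overlaps(result.pooled_islands, planted)
            assert hits and any(i.domestication_related for i in hits)


class TestGeneAnnotation:
    def test_gene_inside_island(self):
        islands = detect_islands(
            fraction([0.9, 0.9]), sites_frame([56_416_469, 56_517_376], chrom="13"))
        genes = [GeneRecord("13", 56_450_000, 56_470_000, "ZNF831"),
                 GeneRecord("14", 1, 100, "OTHER")]
        (hits,) = annotate_genes(islands, genes)
        assert [g.name for g in hits] == ["ZNF831"]

    def test_no_genes_on_chromosome(self):
        islands = detect_islands(fraction([0.9, 0.9]), sites_frame([10, 20]))
        (hits,) = annotate_genes(islands, [GeneRecord("9", 1, 100, "X")])
        assert hits == []

    def test_straddling_gene_included_and_ordered(self):
        islands = detect_islands(fraction([0.9, 0.9]), sites_frame([1000, 2000]))
        genes = [GeneRecord("1", 1500, 2500, "B"), GeneRecord("1", 500, 1001, "A")]
        (hits,) = annotate_genes(islands, genes)
        assert [g.name for g in hits] == ["A", "B"]


class TestGeneFractionProfile:
    def profile(self, frac_by_pop, gene=GeneRecord("1", 100, 300, "STC1")):
        sites = sites_frame([100, 200, 300, 400])
        fr = {pop: fraction([v] * 4, pop) for pop, v in frac_by_pop.items()}
        return gene_fraction_profile([gene], np.array([0, 1, 2]), sites, fr)

    def test_high_and_low_flags(self):
        prof = self.profile({"APZ": 0.96, "BEZ": 0.22})
        assert bool(prof.high.loc["STC1", "APZ"]) is True
        assert bool(prof.low.loc["STC1", "BEZ"]) is True
        assert bool(prof.high.loc["STC1", "BEZ"]) is False

    def test_exact_boundary_unflagged(self):
        prof = self.profile({"APZ": 0.75, "BEZ": 0.25})
        assert not prof.high.to_numpy().any()
        assert not prof.low.to_numpy().any()

    def test_all_fixed_all_high(self):
        prof = self.profile({"A": 1.0, "B": 1.0})
        assert prof.high.to_numpy().all()

    def test_gene_without_island_snvs_reported_missing(self):
        gene = GeneRecord("1", 10_000, 20_000, "EMPTY")
        prof = self.profile({"APZ": 0.9}, gene=gene)
        assert np.isnan(prof.fractions.loc["EMPTY", "APZ"])
        assert prof.n_island_snvs["EMPTY"] == 0


class TestWindowMatrix:
    def test_no_islands_empty_matrix(self):
        frame = window_matrix({"P1": [], "P2": []})
        assert frame.shape == (2, 0)

    def test_boundary_spanning_island_sets_both_windows(self):
        sites = sites_frame([900_000, 1_100_000])
        (isl,) = detect_islands(fraction([0.9, 0.9]), sites)
        frame = window_matrix({"P1": [isl]})
        assert list(frame.columns) == ["1:1000000", "1:2000000"]
        assert frame.loc["P1"].tolist() == [1, 1]

    def test_hand_computed_three_population_matrix(self):
        def isl(chrom, positions):
            s = sites_frame(positions, chrom=chrom)
            (i,) = detect_islands(fraction([1.0] * len(positions)), s)
            return i

        per_pop = {
            "A": [isl("1", [100, 500_000])],            # window 1:1
            "B": [isl("1", [1_200_000, 1_300_000])],    # window 1:2
            "C": [isl("2", [100, 200]),                 # window 2:1
                  isl("1", [400_000, 600_000])],        # window 1:1
        }
        frame = window_matrix(per_pop)
        expected = pd.DataFrame(
            [[1, 0, 0], [0, 1, 0], [1, 0, 1]],
            index=["A", "B", "C"],
            columns=["1:1000000", "1:2000000", "2:1000000"],
        )
        pd.testing.assert_frame_equal(frame, expected)


def test_islands_frame_columns():
    sites = sites_frame([100, 200])
    islands = classify_islands(
        detect_islands(fraction([0.9, 0.9]), sites),
        fraction([0.1, 0.2], "wild", 9))
    frame = islands_frame(islands, gene_lists=[[GeneRecord("1", 50, 150, "G1")]])
    row = frame.iloc[0]
    assert row["domestication_related"]
    assert row["genes"] == "G1"
    assert row["mean_fraction_wild"] == pytest.approx(0.15)
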