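"""ROH summaries, length classes, incidence profiles, islands, annotation."""
import numpy as np
import pytest

from rohscan.genotype_io import GroupAssignment
from rohscan.roh import ROHRecord
from rohscan.rohstats import (
    GeneInterval,
    IncidenceProfile,
    LengthClassConfig,
    annotate_islands,
    chromosome_summary,
    classify_lengths,
    find_islands,
    islands_to_frame,
    read_gene_intervals,
    snp_incidence,
    summarize_per_group,
    summarize_per_sample,
)

from conftest import make_map


def rec(sample, length_bp, chrom="1", start=1_000_000):
    return ROHRecord(sample, chrom, start, start + length_bp, 150)


class TestLengthClasses:
    def test_partition_and_boundaries(self):
        cfg = LengthClassConfig()
        lengths = [1, 1_999_999, 2_000_000, 3_999_999, 4_000_000, 8_000_000, 5 * 10**7]
        assert cfg.class_index(lengths).tolist() == [0, 0, 1, 1, 2, 3, 3]

    def test_exact_two_mb_in_upper_class(self):
        # half-open [2, 4): 2.000000 Mb belongs to 2-4
        assert LengthClassConfig().labels[int(LengthClassConfig().class_index(2_000_000))] == "2-4 Mb"

    def test_invalid_boundaries_rejected(self):
        with pytest.raises(ValueError):
            LengthClassConfig((1.0, 2.0))
        with pytest.raises(ValueError):
            LengthClassConfig((0.0, 4.0, 2.0))

    def test_counts_and_percentages_match_bruteforce(self, rng):
        groups = GroupAssignment({f"s{i}": ("A" if i < 5 else "B") for i in range(10)})
        records = [rec(f"s{int(rng.integers(10))}", int(rng.integers(10**5, 10**7)))
                   for _ in range(500)]
        counts, pct = classify_lengths(records, groups)
        cfg = LengthClassConfig()
        for g in ("A", "B"):
            lens = [r.length_bp for r in records if groups.mapping[r.sample_id] == g]
            brute = np.bincount([int(cfg.class_index(l)) for l in lens], minlength=4)
            assert counts.loc[g].tolist() == brute.tolist()
            assert counts.loc[g].sum() == len(lens)
            assert abs(pct.loc[g].sum() - 100) <= 1  # integer rounding

    def test_printed_percentage_bookkeeping(self):
        # 1369 short of 1809 -> 76% after integer rounding
        groups = GroupAssignment({"h": "HYB"})
        records = [rec("h", 1_500_000)] * 1369 + [rec("h", 3_000_000)] * 440
        counts, pct = classify_lengths(records, groups)
        assert counts.loc["HYB"].sum() == 1809
        assert int(pct.loc["HYB", "0-2 Mb"]) == 76


class TestSummaries:
    def test_sample_without_roh_reported_na(self):
        df = summarize_per_sample([rec("s1", 1_717_000)], ["s1", "s2"])
        assert df.loc["s2", "n_roh"] == 0
        assert np.isnan(df.loc["s2", "mean_length_mb"])
        assert df.loc["s1", "mean_length_mb"] == pytest.approx(1.717)

    def test_group_means_match_bruteforce(self, rng):
        samples = [f"s{i}" for i in range(12)]
        groups = GroupAssignment({s: ("A" if i % 2 else "B") for i, s in enumerate(samples)})
        records = [rec(samples[int(rng.integers(12))], int(rng.integers(10**6, 8 * 10**6)))
                   for _ in range(200)]
        df = summarize_per_group(records, groups, samples)
        for g in ("A", "B"):
            lens = [r.length_bp for r in records if groups.mapping[r.sample_id] == g]
            per = {s: sum(1 for r in records if r.sample_id == s)
                   for s in groups.samples_in(g)}
            assert df.loc[g, "n_roh"] == len(lens)
            assert df.loc[g, "mean_length_mb"] == pytest.approx(np.mean(lens) / 1e6)
            assert df.loc[g, "min_n_roh"] == min(per.values())
            assert df.loc[g, "max_n_roh"] == max(per.values())

    def test_chromosome_summary_zero_and_single(self):
        df = chromosome_summary([rec("s1", 2_000_000, chrom="2")], ["1", "2", "3"])
        assert df.loc["1", "n_roh"] == 0 and np.isnan(df.loc["1", "mean_length_mb"])
        assert df.loc["2", "n_roh"] == 1
        assert df.loc["2", "mean_length_mb"] == pytest.approx(2.0)


class TestIncidence:
    def make_profile(self):
        mmap = make_map({"1": [100, 200, 300, 400], "2": [100, 200]})
        groups = GroupAssignment({f"s{i}": "G" for i in range(10)})
        # 7 of 10 samples have a ROH covering markers 2-3 on chr 1
        records = [ROHRecord(f"s{i}", "1", 150, 320, 5) for i in range(7)]
        return snp_incidence(records, mmap, groups), mmap

    def test_incidence_values(self):
        profile, _ = self.make_profile()
        np.testing.assert_allclose(profile.incidence("G"),
                                   [0.0, 0.7, 0.7, 0.0, 0.0, 0.0])

    def test_matches_bruteforce_membership(self, rng):
        mmap = make_map({"1": sorted(rng.choice(10**6, 50, replace=False) + 1)})
        samples = [f"s{i}" for i in range(8)]
        groups = GroupAssignment({s: "G" for s in samples})
        records = []
        for s in samples:
            for _ in range(rng.integers(0, 4)):
                a = int(rng.integers(1, 10**6))
                records.append(ROHRecord(s, "1", a, a + int(rng.integers(10**4, 10**5)), 3))
        profile = snp_incidence(records, mmap, groups)
        for j, pos in enumerate(mmap.position_bp):
            covered = {r.sample_id for r in records if r.start_bp <= pos <= r.end_bp}
            assert profile.counts["G"][j] == len(covered)

    def test_single_sample_group_is_binary(self):
        mmap = make_map({"1": [100, 200, 300]})
        groups = GroupAssignment({"s1": "G"})
        profile = snp_incidence([ROHRecord("s1", "1", 150, 250, 2)], mmap, groups)
        assert set(np.unique(profile.incidence("G"))) <= {0.0, 1.0}


class TestIslands:
    def test_threshold_inclusive_at_exactly_070(self):
        mmap = make_map({"1": [100, 200, 300]})
        profile = IncidenceProfile(mmap, {"G": np.array([7, 7, 6])}, {"G": 10})
        isl = find_islands(profile, threshold=0.70)
        assert len(isl) == 1
        assert (isl[0].start_bp, isl[0].end_bp, isl[0].n_snps) == (100, 200, 2)
        assert isl[0].min_incidence == pytest.approx(0.7)

    def test_all_below_threshold_yields_nothing(self):
        mmap = make_map({"1": [100, 200, 300]})
        profile = IncidenceProfile(mmap, {"G": np.array([69, 69, 69])}, {"G": 100})
        assert find_islands(profile, 0.70) == []

    def test_two_plateaus_split_by_dip(self):
        mmap = make_map({"1": (100 * np.arange(1, 8)).tolist()})
        counts = np.array([8, 8, 8, 5, 9, 8, 2])
        profile = IncidenceProfile(mmap, {"G": counts}, {"G": 10})
        isl = find_islands(profile, 0.70)
        assert [(i.start_bp, i.end_bp) for i in isl] == [(100, 300), (500, 600)]
        # flanking markers are below threshold; inside all at/above
        for i in isl:
            assert i.min_incidence >= 0.70

    def test_min_snps_drops_singletons(self):
        mmap = make_map({"1": [100, 200, 300]})
        profile = IncidenceProfile(mmap, {"G": np.array([2, 9, 4])}, {"G": 10})
        assert find_islands(profile, 0.70, min_snps=2) == []
        assert len(find_islands(profile, 0.70, min_snps=1)) == 1

    def test_island_length_uses_end_minus_start(self):
        mmap = make_map({"2": [23_019_543, 23_500_000, 23_992_770]})
        profile = IncidenceProfile(mmap, {"HYB": np.array([30, 29, 28])}, {"HYB": 38})
        isl = find_islands(profile, 0.70)
        assert isl[0].length_bp == 973_227


class TestAnnotation:
    def test_overlap_and_touch_rules(self):
        islands = [
            find_islands(
                IncidenceProfile(make_map({"1": [150, 400]}),
                                 {"G": np.array([9, 9])}, {"G": 10}), 0.7)[0]
        ]
        genes = [GeneInterval("in", "1", 100, 200),
                 GeneInterval("out", "1", 100, 149),
                 GeneInterval("wrongchrom", "2", 100, 500)]
        with pytest.warns(UserWarning):
            # the chromosome-2 gene never matches; islands on chr 1 only
            hits = annotate_islands(islands, [genes[2]])
        assert hits == [[]]
        hits = annotate_islands(islands, genes[:2])
        assert [g.name for g in hits[0]] == ["in"]

    def test_matches_quadratic_all_pairs_oracle(self, rng):
        mmap = make_map({"1": sorted(rng.choice(10**6, 40, replace=False) + 1)})
        islands = []
        for _ in range(10):
            i = int(rng.integers(0, 39))
            j = int(rng.integers(i + 1, 41 - 1))
            pos = mmap.position_bp
            islands.append(
                find_islands(IncidenceProfile(mmap, {"G": np.where(
                    (np.arange(40) >= i) & (np.arange(40) <= j), 9, 0)}, {"G": 10}),
                    0.7)[0]
            )
        genes = [GeneInterval(f"g{k}", "1", int(a), int(a) + int(rng.integers(1, 10**5)))
                 for k, a in enumerate(rng.integers(1, 10**6, size=60))]
        hits = annotate_islands(islands, genes)
        for isl, got in zip(islands, hits):
            brute = sorted(
                (g for g in genes
                 if g.start_bp <= isl.end_bp and isl.start_bp <= g.end_bp),
                key=lambda g: (g.start_bp, g.name),
            )
            assert got == brute

    def test_read_bed_and_gff3(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("1\t99\t200\tgeneA\n1\t300\t400\n")
        genes = read_gene_intervals(bed)
        assert genes[0] == GeneInterval("geneA", "1", 100, 200)
        assert genes[1].start_bp == 301

        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1;Name=GENE1\n"
            "1\tsrc\texon\t100\t150\t.\t+\t.\tID=e1\n"
        )
        genes = read_gene_intervals(gff)
        assert len(genes) == 1
        assert genes[0] == GeneInterval("GENE1", "1", 100, 200)

    def test_islands_frame_includes_genes(self):
        mmap = make_map({"1": [100, 400]})
        isl = find_islands(IncidenceProfile(mmap, {"G": np.array([9, 9])}, {"G": 10}), 0.7)
        df = islands_to_frame(isl, [[GeneInterval("x", "1", 150, 250)]])
        assert df.loc[0, "genes"] == "x"
        assert df.loc[0, "length_bp"] == 300
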