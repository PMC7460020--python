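"""Consecutive-method ROH detector vs the exhaustive window oracle."""
import numpy as np
import pytest

from rohscan.genotype_io import MISSING
from rohscan.roh import ROHParams, ROHRecord, detect_roh, detect_roh_oracle

from conftest import make_gm, make_map, random_instance


def as_tuples(records):
    return sorted((r.sample_id, r.chromosome, r.start_bp, r.end_bp, r.n_snps)
                  for r in records)


class TestExamples:
    def test_all_heterozygous_yields_nothing(self):
        gm = make_gm(np.ones((1, 300), dtype=np.int8))
        mmap = make_map({"1": (10_000 * np.arange(1, 301)).tolist()})
        assert detect_roh(gm, mmap) == []

    def test_single_clean_run_spanning_chromosome(self):
        # 200 homozygous markers at 10 kb spacing: one ROH, ends pinned by
        # the chromosome boundaries
        gm = make_gm(np.full((1, 200), 2, dtype=np.int8))
        mmap = make_map({"1": (10_000 * np.arange(1, 201)).tolist()})
        recs = detect_roh(gm, mmap)
        assert len(recs) == 1
        r = recs[0]
        assert (r.start_bp, r.end_bp, r.n_snps) == (10_000, 2_000_000, 200)
        assert r.length_bp == 1_990_000

    def test_single_marker_chromosome_degenerate(self):
        gm = make_gm([[2]])
        mmap = make_map({"1": [500]})
        params = ROHParams(min_snps=1, min_length_bp=1, max_gap_bp=10**9)
        assert detect_roh(gm, mmap, params) == []
        assert detect_roh_oracle(gm, mmap, params) == []

    def test_large_gap_splits_run(self):
        pos = list(range(10_000, 10_000 * 101, 10_000))
        pos += [pos[-1] + 2_000_000 + 10_000 * k for k in range(1, 101)]
        gm = make_gm(np.zeros((1, 200), dtype=np.int8))
        mmap = make_map({"1": pos})
        params = ROHParams(min_snps=50, min_length_bp=500_000, max_gap_bp=1_000_000)
        recs = detect_roh(gm, mmap, params)
        assert len(recs) == 2
        assert recs[0].end_bp == 1_000_000
        assert recs[1].start_bp == 3_010_000

    def test_heterozygote_terminates_run_under_defaults(self):
        g = np.full(400, 2, dtype=np.int8)
        g[200] = 1
        gm = make_gm(g[None, :])
        mmap = make_map({"1": (10_000 * np.arange(1, 401)).tolist()})
        recs = detect_roh(gm, mmap)
        assert len(recs) == 2
        assert recs[0].n_snps == 200 and recs[1].n_snps == 199

    def test_unsorted_map_rejected_at_construction(self):
        with pytest.raises(ValueError):
            make_map({"1": [300, 100, 200]})


@pytest.mark.parametrize(
    "params",
    [
        ROHParams(min_snps=10, min_length_bp=50_000, max_gap_bp=30_000),
        ROHParams(min_snps=5, min_length_bp=20_000, max_gap_bp=60_000),
        ROHParams(min_snps=8, min_length_bp=40_000, max_gap_bp=30_000, max_het=1),
        ROHParams(min_snps=6, min_length_bp=30_000, max_gap_bp=50_000, max_het=2,
                  max_missing=1),
        ROHParams(min_snps=4, min_length_bp=10_000, max_gap_bp=25_000, max_missing=2),
    ],
    ids=["strict", "loose", "het1", "het2mis1", "mis2"],
)
def test_oracle_equivalence_randomized(params, rng):
    """Scan output equals exhaustive maximal-window enumeration (40 x 5 grids)."""
    for k in range(40):
        gm, mmap = random_instance(rng, n_samples=2, n_markers=120,
                                   het_rate=0.25, missing_rate=0.08,
                                   max_pos_step=35_000)
        assert as_tuples(detect_roh(gm, mmap, params)) == \
            as_tuples(detect_roh_oracle(gm, mmap, params)), f"instance {k}"


def test_oracle_equivalence_large_instance(rng):
    gm, mmap = random_instance(rng, n_samples=5, n_markers=600, n_chrom=3,
                               het_rate=0.2, missing_rate=0.0, max_pos_step=20_000)
    params = ROHParams(min_snps=10, min_length_bp=50_000, max_gap_bp=30_000)
    assert as_tuples(detect_roh(gm, mmap, params)) == \
        as_tuples(detect_roh_oracle(gm, mmap, params))


def test_oracle_refuses_large_instances(rng):
    gm, mmap = random_instance(rng, n_samples=5, n_markers=2500)
    with pytest.raises(ValueError, match="too large"):
        detect_roh_oracle(gm, mmap, ROHParams())


class TestInvariants:
    def test_every_record_satisfies_constraints(self, rng):
        params = ROHParams(min_snps=8, min_length_bp=40_000, max_gap_bp=30_000)
        for _ in range(20):
            gm, mmap = random_instance(rng, 3, 200, het_rate=0.15)
            slices = mmap.chrom_slices()
            for r in detect_roh(gm, mmap, params):
                sl = slices[r.chromosome]
                pos = mmap.position_bp[sl]
                g = gm.calls[gm.sample_index(r.sample_id), sl]
                i0 = int(np.searchsorted(pos, r.start_bp))
                i1 = int(np.searchsorted(pos, r.end_bp))
                win = g[i0:i1 + 1]
                assert r.length_bp >= params.min_length_bp
                assert r.n_snps >= params.min_snps
                assert ((win == 0) | (win == 2)).sum() == r.n_snps
                assert (win == 1).sum() <= params.max_het
                assert (win == MISSING).sum() <= params.max_missing
                assert np.diff(pos[i0:i1 + 1]).max() <= params.max_gap_bp

    def test_maximality_under_defaults(self, rng):
        params = ROHParams(min_snps=8, min_length_bp=40_000, max_gap_bp=30_000)
        for _ in range(20):
            gm, mmap = random_instance(rng, 3, 200, het_rate=0.15)
            slices = mmap.chrom_slices()
            for r in detect_roh(gm, mmap, params):
                sl = slices[r.chromosome]
                pos = mmap.position_bp[sl]
                g = gm.calls[gm.sample_index(r.sample_id), sl]
                i0 = int(np.searchsorted(pos, r.start_bp))
                i1 = int(np.searchsorted(pos, r.end_bp))
                if i0 > 0:  # left neighbour would break a constraint
                    assert g[i0 - 1] in (1, MISSING) or pos[i0] - pos[i0 - 1] > params.max_gap_bp
                if i1 < len(pos) - 1:
                    assert g[i1 + 1] in (1, MISSING) or pos[i1 + 1] - pos[i1] > params.max_gap_bp

    def test_runs_disjoint_per_sample_chromosome(self, rng):
        for _ in range(10):
            gm, mmap = random_instance(rng, 3, 200, het_rate=0.1)
            recs = detect_roh(gm, mmap, ROHParams(min_snps=5, min_length_bp=20_000,
                                                  max_gap_bp=40_000))
            by = {}
            for r in recs:
                by.setdefault((r.sample_id, r.chromosome), []).append(r)
            for rs in by.values():
                rs.sort(key=lambda r: r.start_bp)
                for a, b in zip(rs, rs[1:]):
                    assert a.end_bp < b.start_bp

    def test_monotonicity_in_thresholds(self, rng):
        gm, mmap = random_instance(rng, 4, 300, het_rate=0.1)
        base = ROHParams(min_snps=5, min_length_bp=20_000, max_gap_bp=40_000)
        n_base = len(detect_roh(gm, mmap, base))
        for stricter in (
            ROHParams(min_snps=10, min_length_bp=20_000, max_gap_bp=40_000),
            ROHParams(min_snps=5, min_length_bp=60_000, max_gap_bp=40_000),
        ):
            assert len(detect_roh(gm, mmap, stricter)) <= n_base

        def covered(params):
            return sum(r.length_bp for r in detect_roh(gm, mmap, params))

        wider = ROHParams(min_snps=5, min_length_bp=20_000, max_gap_bp=80_000)
        assert covered(wider) >= covered(base)


def test_true_tracts_recovered_with_reciprocal_overlap(rng):
    """Dense error-free data: every sufficiently long true tract is found."""
    import rohscan as r

    cfg = r.SimConfig(
        n_chromosomes=4, chrom_length_bp=20_000_000, n_markers_per_chrom=2_000,
        pop_specs=(r.PopSpec("P", 8, autozygosity_law=r.Law.constant(0.12),
                             tract_length_law=r.Law.exponential(4e6)),),
    )
    gm, mmap, groups, truth = r.simulate_cohort(cfg, seed=11)
    recs = r.detect_roh(gm, mmap)
    margin = 500_000
    checked = 0
    for sid, tracts in truth.tracts.items():
        mine = [x for x in recs if x.sample_id == sid]
        for chrom, s, e in tracts:
            if e - s + 1 < 1_500_000 + margin:
                continue
            checked += 1
            best = 0.0
            for x in mine:
                if x.chromosome != chrom:
                    continue
                ov = min(x.end_bp, e) - max(x.start_bp, s)
                if ov > 0:
                    best = max(best, min(ov / (e - s), ov / x.length_bp))
            assert best >= 0.9, (sid, chrom, s, e, best)
    assert checked > 10
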