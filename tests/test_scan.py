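import numpy as np
import pytest

from adpgen import (
    FstScan,
    GenoSimConfig,
    ScanConfig,
    SpikeRegion,
    call_candidates,
    intersect_comparisons,
    intervals_to_bed,
    prefilter,
    simulate_genotypes,
    smooth,
    wc_fst,
    wc_fst_components,
)
from adpgen.scan import CandidateInterval, _merge_intervals
from conftest import make_gm


# --- independent scalar oracle for the Weir & Cockerham estimator -----------

def wc_fst_scalar(geno_a, geno_b):
    """Textbook two-population W&C (1984) transcription, one SNP at a time.

    geno_a/geno_b: lists of dosages (-1 missing). Returns (a, a+b+c) or NaN
    pair when either population has < 2 genotyped samples.
    """
    pops = [[g for g in geno_a if g >= 0], [g for g in geno_b if g >= 0]]
    if any(len(p) < 2 for p in pops):
        return float("nan"), float("nan")
    r = 2
    n = [len(p) for p in pops]
    p_i = [sum(p) / (2 * len(p)) for p in pops]
    h_i = [sum(1 for g in p if g == 1) / len(p) for p in pops]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p_i)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p_i)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h_i)) / (r * nbar)
    a = nbar / nc * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, a + b + c


def test_wc_components_match_scalar_oracle_on_random_instances():
    rng = np.random.default_rng(123)
    for _ in range(300):
        na, nb = rng.integers(2, 7, size=2)
        ga = rng.choice([-1, 0, 1, 2], size=na, p=[0.1, 0.3, 0.3, 0.3])
        gb = rng.choice([-1, 0, 1, 2], size=nb, p=[0.1, 0.3, 0.3, 0.3])
        calls = np.concatenate([ga, gb]).reshape(-1, 1)
        gm = make_gm(calls)
        labels = ["A"] * na + ["B"] * nb
        a, d = wc_fst_components(gm, labels)
        a0, d0 = wc_fst_scalar(list(ga), list(gb))
        if np.isnan(a0):
            assert np.isnan(a[0]) and np.isnan(d[0])
        else:
            assert a[0] == pytest.approx(a0, abs=1e-12)
            assert d[0] == pytest.approx(d0, abs=1e-12)


def test_wc_fst_oppositely_fixed_is_one_and_shared_monomorphic_nan():
    gm = make_gm([[0, 2], [0, 2], [0, 2], [2, 2], [2, 2], [2, 2]])
    fst, weighted, mean = wc_fst(gm, ["A"] * 3 + ["B"] * 3)
    assert fst[0] == pytest.approx(1.0)
    assert np.isnan(fst[1])          # no variation anywhere: undefined
    assert weighted == pytest.approx(1.0)


def test_wc_fst_identical_populations_near_zero():
    rng = np.random.default_rng(7)
    calls = rng.choice([0, 1, 2], size=(200, 500))
    gm = make_gm(calls)
    fst, weighted, _ = wc_fst(gm, ["A"] * 100 + ["B"] * 100)
    assert abs(weighted) < 0.01


def test_wc_fst_requires_exactly_two_populations():
    gm = make_gm([[0], [1], [2]])
    with pytest.raises(ValueError):
        wc_fst(gm, ["A", "B", "C"])


# --- prefilter ----------------------------------------------------------------

def test_prefilter_drops_sex_chromosomes_and_pop_fixed_snps():
    calls = np.array(
        [
            # columns: snp0 variable in both pops, snp1 fixed in pop A,
            # snp2 on X, snp3 variable in both pops
            [0, 0, 2, 0],
            [1, 0, 0, 1],
            [2, 1, 1, 2],
            [1, 2, 2, 1],
        ],
        dtype=np.int8,
    )
    gm = make_gm(calls, chrom=["1", "1", "X", "2"])
    filtered, counts = prefilter(gm, ["A", "A", "B", "B"])
    assert counts["sex_chromosome"] == 1
    assert counts["fixed"] == 1
    assert filtered.snp_ids == [gm.snp_ids[0], gm.snp_ids[3]]


# --- smoothing ----------------------------------------------------------------

def smooth_oracle(chrom, pos, fst, hw):
    """Brute-force per-SNP window mean."""
    out = np.full(len(pos), np.nan)
    n = np.zeros(len(pos), dtype=int)
    for i in range(len(pos)):
        sel = [
            j
            for j in range(len(pos))
            if chrom[j] == chrom[i] and abs(pos[j] - pos[i]) <= hw
        ]
        n[i] = len(sel)
        vals = [fst[j] for j in sel if not np.isnan(fst[j])]
        if vals:
            out[i] = float(np.mean(vals))
    return out, n


def test_smooth_matches_brute_force_on_random_layouts():
    rng = np.random.default_rng(99)
    for _ in range(20):
        m = int(rng.integers(5, 60))
        chrom = rng.choice(["1", "2"], size=m)
        pos = rng.integers(1, 500_000, size=m)
        fst = rng.uniform(0, 1, size=m)
        fst[rng.random(m) < 0.15] = np.nan
        hw = int(rng.integers(10_000, 100_000))
        got, got_n = smooth(chrom, pos, fst, hw)
        want, want_n = smooth_oracle(chrom, pos, fst, hw)
        assert np.allclose(got, want, equal_nan=True, atol=1e-12)
        assert np.array_equal(got_n, want_n)


def test_isolated_snp_smoothed_value_is_its_raw_value():
    chrom = np.array(["1", "1", "2"])
    pos = np.array([100, 10_000_000, 500])
    fst = np.array([0.3, 0.8, 0.1])
    sm, n = smooth(chrom, pos, fst, 50_000)
    assert np.allclose(sm, fst)
    assert list(n) == [1, 1, 1]


def test_smooth_is_snp_order_invariant():
    rng = np.random.default_rng(4)
    m = 40
    chrom = rng.choice(["1", "2"], size=m)
    pos = rng.integers(1, 300_000, size=m)
    fst = rng.uniform(0, 1, size=m)
    sm, _ = smooth(chrom, pos, fst, 50_000)
    perm = rng.permutation(m)
    sm_p, _ = smooth(chrom[perm], pos[perm], fst[perm], 50_000)
    assert np.allclose(sm[perm], sm_p, atol=1e-12)


# --- candidate calling ---------------------------------------------------------

def test_merge_intervals_merges_overlap_and_bookends():
    assert _merge_intervals([(1, 10), (5, 20), (21, 30), (40, 50)]) == [
        (1, 30),
        (40, 50),
    ]


def test_constant_fst_vector_yields_no_candidates():
    m = 200
    pos = np.arange(1, m + 1) * 10_000
    chrom = np.array(["1"] * m)
    fst = np.full(m, 0.2)
    sm, _ = smooth(chrom, pos, fst, 50_000)
    qualifies, intervals = call_candidates(
        [f"m{i}" for i in range(m)], chrom, pos, fst, sm
    )
    assert not qualifies.any()
    assert intervals == []


def test_nearby_qualifying_snps_merge_into_one_interval():
    """Two qualifying SNPs 60 kb apart share one merged candidate interval."""
    m = 400
    pos = np.arange(1, m + 1) * 10_000
    chrom = np.array(["1"] * m)
    rng = np.random.default_rng(0)
    fst = rng.uniform(0.0, 0.05, size=m)
    peak_idx = [200, 206]            # 60 kb apart; windows [p-50k, p+50k] touch
    for k, i in enumerate(peak_idx):
        fst[i] = 0.9 - 0.05 * k
    # lift the neighbourhood so the smoothed threshold is also exceeded
    fst[195:212] += 0.3
    sm, _ = smooth(chrom, pos, fst, 50_000)
    qualifies, intervals = call_candidates(
        [f"m{i}" for i in range(m)], chrom, pos, fst, sm
    )
    assert qualifies[peak_idx].all()
    covering = [
        iv for iv in intervals if iv.start <= pos[peak_idx[0]] and iv.end >= pos[peak_idx[1]]
    ]
    assert len(covering) == 1
    assert covering[0].peak_snp == "m200"
    assert covering[0].start <= pos[peak_idx[0]] - 50_000
    assert covering[0].end >= pos[peak_idx[1]] + 50_000


def test_scan_recovers_spiked_region_on_scaled_genome():
    layout = (("1", 3_000_000, 10_000), ("2", 3_000_000, 10_000))
    spike = SpikeRegion("1", 1_500_000, 1_700_000, delta=0.3)
    recovered = clean = 0
    for seed in range(3):
        gm, meta = simulate_genotypes(
            GenoSimConfig(
                n_per_pop=100, fst_target=0.02, chrom_layout=layout,
                spike_regions=(spike,), seed=seed,
            )
        )
        scan = FstScan().fit(gm, dict(zip(gm.sample_ids, meta["population"])))
        hits = [
            iv for iv in scan.intervals_
            if iv.chrom == "1" and iv.start <= spike.end and iv.end >= spike.start
        ]
        recovered += bool(hits)
        clean += len(hits) == len(scan.intervals_)
    assert recovered == 3
    assert clean == 3


# --- intersection --------------------------------------------------------------

def covered_bases(intervals, chrom, lo, hi):
    return {
        b
        for iv in intervals
        if iv.chrom == chrom
        for b in range(max(iv.start, lo), min(iv.end, hi) + 1)
    }


def test_intersection_matches_per_base_oracle():
    rng = np.random.default_rng(21)
    for _ in range(15):
        runs = []
        for _r in range(3):
            ivs = []
            for c in ("1", "2"):
                for _k in range(int(rng.integers(0, 4))):
                    s = int(rng.integers(1, 900))
                    e = s + int(rng.integers(0, 200))
                    ivs.append(CandidateInterval(c, s, e, "m", float(rng.random()), 1))
            runs.append(ivs)
        got = intersect_comparisons(runs)
        for c in ("1", "2"):
            want = covered_bases(runs[0], c, 1, 1200)
            for run in runs[1:]:
                want &= covered_bases(run, c, 1, 1200)
            assert covered_bases(got, c, 1, 1200) == want


def test_intersection_of_identical_runs_is_the_run_coverage():
    run = [
        CandidateInterval("1", 100, 200, "a", 0.5, 2),
        CandidateInterval("1", 400, 500, "b", 0.7, 1),
    ]
    got = intersect_comparisons([run, run])
    assert [(iv.chrom, iv.start, iv.end) for iv in got] == [
        ("1", 100, 200),
        ("1", 400, 500),
    ]
    assert got[1].peak_snp == "b"


def test_intersection_of_disjoint_runs_is_empty():
    a = [CandidateInterval("1", 100, 200, "a", 0.5, 1)]
    b = [CandidateInterval("1", 300, 400, "b", 0.5, 1)]
    assert intersect_comparisons([a, b]) == []


def test_bed_export_is_zero_based_half_open():
    bed = intervals_to_bed([CandidateInterval("1", 101, 200, "m1", 0.4, 3)])
    assert bed.loc[0, "start"] == 100
    assert bed.loc[0, "end"] == 200


def test_fstscan_is_snp_order_invariant():
    gm, meta = simulate_genotypes(
        GenoSimConfig(
            n_per_pop=40, fst_target=0.05, seed=13,
            chrom_layout=(("1", 1_000_000, 10_000), ("2", 1_000_000, 10_000)),
        )
    )
    labels = dict(zip(gm.sample_ids, meta["population"]))
    scan1 = FstScan().fit(gm, labels)
    perm = np.random.default_rng(1).permutation(gm.n_snps)
    scan2 = FstScan().fit(gm.take_snps(perm), labels)
    assert scan1.fst_weighted_ == pytest.approx(scan2.fst_weighted_, abs=1e-12)
    t1 = scan1.result_.table.sort_values("snp").reset_index(drop=True)
    t2 = scan2.result_.table.sort_values("snp").reset_index(drop=True)
    assert np.allclose(t1["fst"], t2["fst"], equal_nan=True)
    assert np.allclose(t1["smoothed"], t2["smoothed"], equal_nan=True)
    assert [(iv.chrom, iv.start, iv.end) for iv in scan1.intervals_] == [
        (iv.chrom, iv.start, iv.end) for iv in scan2.intervals_
    ]
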