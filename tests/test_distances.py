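"""TN93+gamma distances checked against an independently coded closed form."""

import math

import numpy as np
import pytest

from adpgen import (
    DistanceConfig,
    SeqAlignment,
    bootstrap_se,
    group_mean,
    pairwise_matrix,
    simulate_tn93_pair,
    tn93_distance,
)


def tn93_closed_form(seq_a, seq_b, alpha=None):
    """Reference evaluation of the TN93 (gamma) distance, written directly
    from the published closed form and kept independent of the library path.
    """
    pairs = [
        (x, y)
        for x, y in zip(seq_a.upper(), seq_b.upper())
        if x in "ACGT" and y in "ACGT"
    ]
    n = len(pairs)
    s1 = sum(1 for x, y in pairs if {x, y} == {"A", "G"}) / n
    s2 = sum(1 for x, y in pairs if {x, y} == {"C", "T"}) / n
    v = sum(1 for x, y in pairs if x != y and {x, y} not in ({"A", "G"}, {"C", "T"})) / n
    f = {b: sum((x == b) + (y == b) for x, y in pairs) / (2 * n) for b in "ACGT"}
    gr, gy = f["A"] + f["G"], f["C"] + f["T"]
    k1 = 2 * f["A"] * f["G"] / gr
    k2 = 2 * f["C"] * f["T"] / gy
    k3 = 2 * (gr * gy - f["A"] * f["G"] * gy / gr - f["C"] * f["T"] * gr / gy)
    w1 = 1 - s1 / k1 - v / (2 * gr)
    w2 = 1 - s2 / k2 - v / (2 * gy)
    w3 = 1 - v / (2 * gr * gy)
    if min(w1, w2, w3) <= 0:
        return float("nan")
    if alpha is None:
        return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    return alpha * (
        k1 * (w1 ** (-1 / alpha) - 1)
        + k2 * (w2 ** (-1 / alpha) - 1)
        + k3 * (w3 ** (-1 / alpha) - 1)
    )


def constructed_pair():
    """600 bp pair with 30 A<->G, 20 C<->T and 10 A<->C differences."""
    a = "A" * 150 + "C" * 150 + "G" * 150 + "T" * 150
    b = list(a)
    for i in range(30):
        b[i] = "G"           # purine transitions
    for i in range(150, 170):
        b[i] = "T"           # pyrimidine transitions
    for i in range(40, 50):
        b[i] = "C"           # transversions
    return a, "".join(b)


@pytest.mark.parametrize("alpha", [0.33, 1.0, None])
def test_constructed_pair_matches_closed_form(alpha):
    a, b = constructed_pair()
    got = tn93_distance(a, b, DistanceConfig(gamma_shape=alpha))
    expected = tn93_closed_form(a, b, alpha)
    assert got == pytest.approx(expected, abs=1e-10)


def test_large_alpha_limit_matches_uncorrected():
    a, b = constructed_pair()
    corrected = tn93_distance(a, b, DistanceConfig(gamma_shape=1e9))
    uncorrected = tn93_distance(a, b, DistanceConfig(gamma_shape=None))
    assert corrected == pytest.approx(uncorrected, abs=1e-6)


def test_identical_sequences_give_zero():
    assert tn93_distance("ACGTACGT", "ACGTACGT") == 0.0


def test_saturation_is_flagged_not_raised():
    # complementary sequences: every site a transversion
    assert math.isnan(tn93_distance("ACGT" * 50, "CATG" * 50))


def test_pairwise_deletion_skips_ambiguity_and_gap_sites():
    d_plain = tn93_distance("ACGTAC", "ACGTAC")
    d_amb = tn93_distance("ACGTAN", "ACGTA-")
    assert d_plain == d_amb == 0.0
    with pytest.raises(ValueError):
        tn93_distance("NNN", "ACG")


@pytest.mark.parametrize("d", [0.01, 0.05, 0.1])
def test_distance_recovery_under_own_process(d):
    """Mean estimate within 10% of truth on pairs simulated at distance d."""
    cfg = DistanceConfig(gamma_shape=0.33)
    estimates = [
        tn93_distance(*simulate_tn93_pair(d, 10_000, gamma_shape=0.33, seed=s), cfg)
        for s in range(100)
    ]
    assert abs(np.nanmean(estimates) - d) / d < 0.10


def test_pairwise_matrix_consistent_and_permutation_equivariant(dloop_sim):
    aln, _ = dloop_sim
    sub = SeqAlignment(aln.ids[:6], aln.sequences[:6])
    dm = pairwise_matrix(sub)
    assert np.allclose(dm.matrix, dm.matrix.T)
    assert np.allclose(np.diag(dm.matrix), 0)
    # entries equal single-pair calls
    for i in range(3):
        for j in range(i + 1, 4):
            assert dm.matrix[i, j] == pytest.approx(
                tn93_distance(sub.sequences[i], sub.sequences[j]), abs=1e-12
            )
    # permuting input order permutes the matrix identically
    perm = [3, 0, 5, 1, 4, 2]
    dm2 = pairwise_matrix(SeqAlignment([sub.ids[i] for i in perm], [sub.sequences[i] for i in perm]))
    assert np.allclose(dm2.matrix, dm.matrix[np.ix_(perm, perm)])


def test_group_mean_equals_bruteforce_enumeration(dloop_sim):
    aln, truth = dloop_sim
    sub = SeqAlignment(aln.ids[:10], aln.sequences[:10])
    dm = pairwise_matrix(sub)
    grouping = {sid: ("g1" if k % 2 else "g2") for k, sid in enumerate(sub.ids)}
    results = {(r.group_a, r.group_b): r.mean_distance for r in group_mean(dm, grouping)}
    idx = {sid: k for k, sid in enumerate(sub.ids)}
    for ga, gb in [("g1", "g1"), ("g1", "g2"), ("g2", "g2")]:
        a_ids = [s for s in sub.ids if grouping[s] == ga]
        b_ids = [s for s in sub.ids if grouping[s] == gb]
        if ga == gb:
            vals = [
                dm.matrix[idx[x], idx[y]]
                for i, x in enumerate(a_ids)
                for y in a_ids[i + 1 :]
            ]
        else:
            vals = [dm.matrix[idx[x], idx[y]] for x in a_ids for y in b_ids]
        assert results[tuple(sorted((ga, gb)))] == pytest.approx(np.mean(vals), abs=1e-12)


def test_singleton_group_within_distance_undefined():
    aln = SeqAlignment(["a", "b", "c"], ["ACGT" * 10] * 3)
    dm = pairwise_matrix(aln)
    res = group_mean(dm, {"a": "g1", "b": "g2", "c": "g2"})
    within_g1 = next(r for r in res if r.group_a == "g1" and r.group_b == "g1")
    assert math.isnan(within_g1.mean_distance)


def test_two_blocks_between_mean_equals_representative_pair():
    a = "ACGT" * 25
    b = a[:-4] + "GCGT"  # one transition-bearing variant
    aln = SeqAlignment(["a1", "a2", "b1", "b2"], [a, a, b, b])
    dm = pairwise_matrix(aln)
    res = group_mean(dm, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    between = next(r for r in res if r.group_a != r.group_b)
    assert between.mean_distance == pytest.approx(tn93_distance(a, b), abs=1e-12)


def test_group_mean_invariant_to_all_gap_column(dloop_sim):
    aln, _ = dloop_sim
    sub = SeqAlignment(aln.ids[:6], aln.sequences[:6])
    padded = SeqAlignment(list(sub.ids), [s + "-" for s in sub.sequences])
    grouping = {sid: ("g1" if k < 3 else "g2") for k, sid in enumerate(sub.ids)}
    r1 = group_mean(pairwise_matrix(sub), grouping)
    r2 = group_mean(pairwise_matrix(padded), grouping)
    for x, y in zip(r1, r2):
        assert x.mean_distance == pytest.approx(y.mean_distance, abs=1e-15)


def test_bootstrap_se_zero_for_identical_sequences():
    aln = SeqAlignment(["a", "b", "c", "d"], ["ACGT" * 20] * 4)
    res = bootstrap_se(aln, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"},
                       DistanceConfig(bootstrap_reps=50, seed=0))
    for r in res:
        assert r.se == 0.0


def test_bootstrap_is_seed_deterministic_and_replicate_stable(dloop_sim):
    aln, truth = dloop_sim
    picked = aln.ids[:4] + aln.ids[-4:]          # spans both clades
    sub = aln.subset(picked)
    grouping = dict(zip(sub.ids, truth.table.set_index("sample").loc[sub.ids, "clade"]))
    r1 = bootstrap_se(sub, grouping, DistanceConfig(bootstrap_reps=100, seed=5))
    r2 = bootstrap_se(sub, grouping, DistanceConfig(bootstrap_reps=100, seed=5))
    assert [x.se for x in r1] == [x.se for x in r2]
    # doubling replicates moves the SE by < 20% relative (5 seeds)
    between = lambda rs: next(
        r for r in rs if r.group_a != r.group_b and not math.isnan(r.mean_distance)
    )
    for seed in range(5):
        se1 = between(bootstrap_se(sub, grouping, DistanceConfig(bootstrap_reps=100, seed=seed))).se
        se2 = between(bootstrap_se(sub, grouping, DistanceConfig(bootstrap_reps=200, seed=seed))).se
        assert abs(se2 - se1) / se1 < 0.20
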