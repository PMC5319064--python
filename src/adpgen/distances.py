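"""Tamura–Nei (1993) nucleotide distances with gamma rate correction.

The TN93 model distinguishes the two transition classes (A<->G among purines,
C<->T among pyrimidines) from transversions and allows unequal base
frequencies. Rate heterogeneity across sites is modelled by a gamma
distribution with shape ``alpha``; the gamma-corrected distance replaces each
``-k log(w)`` term of the plain TN93 distance with ``alpha * k * (w**(-1/alpha) - 1)``,
which converges to the uncorrected value as ``alpha -> inf``.

Ambiguous positions (anything outside A/C/G/T in either sequence) are removed
per pair (pairwise deletion); base frequencies are estimated empirically from
the two sequences after deletion, following the convention of the MEGA
distance engine.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import SeqAlignment

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_VALID = {"A", "C", "G", "T"}

#: Sentinel for saturated (undefined) distances.
UNDEFINED = float("nan")


@dataclass
class DistanceConfig:
    """Settings for TN93 distance estimation.

    gamma_shape: gamma shape alpha (>0); use a very large value (or ``None``)
        for the no-rate-variation limit.
    deletion: ``"pairwise"`` (ambiguous sites removed per pair) or
        ``"complete"`` (columns with any ambiguity removed once, globally).
    bootstrap_reps: site-bootstrap replicates for standard errors.
    seed: RNG seed for the bootstrap.
    """

    gamma_shape: float | None = 0.33
    deletion: str = "pairwise"
    bootstrap_reps: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if self.deletion not in ("pairwise", "complete"):
            raise ValueError("deletion must be 'pairwise' or 'complete'")


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray               # substitutions/site; NaN flags saturation
    comparable_sites: np.ndarray     # per-pair count of sites used

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


@dataclass
class GroupDistanceResult:
    group_a: str
    group_b: str                      # equal to group_a for within-group means
    mean_distance: float
    se: float | None = None
    n_pairs: int = 0
    n_undefined: int = 0


def tn93_from_counts(
    n_sites: int,
    p1: float,
    p2: float,
    q: float,
    freqs: dict[str, float],
    gamma_shape: float | None = None,
) -> float:
    """TN93 (optionally gamma-corrected) distance from class proportions.

    ``p1``: A<->G transition proportion; ``p2``: C<->T transition proportion;
    ``q``: transversion proportion; ``freqs``: base frequencies averaged over
    the pair. Returns NaN when a logarithm/power argument is non-positive
    (saturation).
    """
    ga, gc, gg, gt = freqs["A"], freqs["C"], freqs["G"], freqs["T"]
    gr, gy = ga + gg, gc + gt
    if min(ga, gc, gg, gt) <= 0:
        # degenerate composition: fall back on the proportion of differing sites
        pdist = p1 + p2 + q
        return 0.0 if pdist == 0 else UNDEFINED
    k1 = 2.0 * ga * gg / gr
    k2 = 2.0 * gc * gt / gy
    k3 = 2.0 * (gr * gy - ga * gg * gy / gr - gc * gt * gr / gy)
    w1 = 1.0 - p1 / k1 - q / (2.0 * gr)
    w2 = 1.0 - p2 / k2 - q / (2.0 * gy)
    w3 = 1.0 - q / (2.0 * gr * gy)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return UNDEFINED
    if gamma_shape is None or gamma_shape > 1e12:
        d = -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    else:
        a = gamma_shape
        d = a * (
            k1 * (w1 ** (-1.0 / a) - 1.0)
            + k2 * (w2 ** (-1.0 / a) - 1.0)
            + k3 * (w3 ** (-1.0 / a) - 1.0)
        )
    return max(d, 0.0)


def _pair_counts(a: str, b: str) -> tuple[int, float, float, float, dict[str, float]]:
    """Comparable-site count, class proportions and averaged base frequencies."""
    n = 0
    p1 = p2 = q = 0
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        n += 1
        counts[x] += 1
        counts[y] += 1
        if x != y:
            pair = {x, y}
            if pair <= _PURINES:
                p1 += 1
            elif pair <= _PYRIMIDINES:
                p2 += 1
            else:
                q += 1
    if n == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    freqs = {k: v / (2 * n) for k, v in counts.items()}
    return n, p1 / n, p2 / n, q / n, freqs


def tn93_distance(a: str, b: str, cfg: DistanceConfig | None = None) -> float:
    """Gamma-corrected TN93 distance between two aligned sequences.

    Sites where either sequence carries an ambiguity code or gap are removed
    before counting. Raises ValueError when the sequences differ in length or
    no comparable site remains; returns NaN on saturation.
    """
    cfg = cfg or DistanceConfig()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    n, p1, p2, q, freqs = _pair_counts(a.upper(), b.upper())
    return tn93_from_counts(n, p1, p2, q, freqs, cfg.gamma_shape)


_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _encode(aln: SeqAlignment) -> np.ndarray:
    """(k, L) uint8 codes: A,C,G,T -> 0..3, anything else -> 255."""
    raw = np.frombuffer("".join(aln.sequences).encode(), dtype=np.uint8)
    return _ENC[raw].reshape(len(aln), aln.length)


def _tn93_pair_encoded(xi: np.ndarray, xj: np.ndarray, gamma_shape: float | None) -> tuple[float, int]:
    valid = (xi < 4) & (xj < 4)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    a, b = xi[valid], xj[valid]
    diff = a != b
    ts1 = diff & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0)))
    ts2 = diff & (((a == 1) & (b == 3)) | ((a == 3) & (b == 1)))
    p1 = int(ts1.sum()) / n
    p2 = int(ts2.sum()) / n
    q = int((diff & ~ts1 & ~ts2).sum()) / n
    counts = np.bincount(a, minlength=4) + np.bincount(b, minlength=4)
    freqs = dict(zip("ACGT", counts / (2 * n)))
    return tn93_from_counts(n, p1, p2, q, freqs, gamma_shape), n


def _pairwise_from_encoded(
    enc: np.ndarray, gamma_shape: float | None
) -> tuple[np.ndarray, np.ndarray]:
    k = enc.shape[0]
    mat = np.zeros((k, k))
    sites = np.zeros((k, k), dtype=int)
    np.fill_diagonal(sites, enc.shape[1])
    for i in range(k):
        for j in range(i + 1, k):
            d, n = _tn93_pair_encoded(enc[i], enc[j], gamma_shape)
            mat[i, j] = mat[j, i] = d
            sites[i, j] = sites[j, i] = n
    return mat, sites


def pairwise_matrix(aln: SeqAlignment, cfg: DistanceConfig | None = None) -> DistanceMatrix:
    """All unordered pairwise TN93 distances with per-pair comparable-site counts."""
    cfg = cfg or DistanceConfig()
    if len(aln) < 2:
        raise ValueError("need at least two sequences")
    enc = _encode(aln)
    if cfg.deletion == "complete":
        enc = enc[:, (enc < 4).all(axis=0)]
    mat, sites = _pairwise_from_encoded(enc, cfg.gamma_shape)
    return DistanceMatrix(list(aln.ids), mat, sites)


def _group_pairs(ids: list[str], grouping: dict[str, str]):
    missing = [i for i in ids if i not in grouping]
    if missing:
        raise ValueError(f"ungrouped ids: {missing}")
    groups = sorted(set(grouping.values()))
    index = {sid: k for k, sid in enumerate(ids)}
    for gi, ga in enumerate(groups):
        a_idx = [index[s] for s in ids if grouping[s] == ga]
        for gb in groups[gi:]:
            if ga == gb:
                pairs = [
                    (a_idx[x], a_idx[y])
                    for x in range(len(a_idx))
                    for y in range(x + 1, len(a_idx))
                ]
            else:
                b_idx = [index[s] for s in ids if grouping[s] == gb]
                pairs = [(i, j) for i in a_idx for j in b_idx]
            yield ga, gb, pairs


def group_mean(dm: DistanceMatrix, grouping: dict[str, str]) -> list[GroupDistanceResult]:
    """Mean distance over all sequence pairs within and between groups.

    Pairs with undefined (saturated) distances are excluded from the mean and
    counted; a group with fewer than two members yields an undefined
    within-group mean (NaN).
    """
    results = []
    for ga, gb, pairs in _group_pairs(dm.ids, grouping):
        vals = [dm.matrix[i, j] for i, j in pairs]
        defined = [v for v in vals if not math.isnan(v)]
        n_undef = len(vals) - len(defined)
        if n_undef:
            warnings.warn(
                f"{n_undef} saturated pair(s) excluded from {ga}/{gb} mean", stacklevel=2
            )
        mean = float(np.mean(defined)) if defined else UNDEFINED
        results.append(
            GroupDistanceResult(ga, gb, mean, n_pairs=len(defined), n_undefined=n_undef)
        )
    return results


def bootstrap_se(
    aln: SeqAlignment, grouping: dict[str, str], cfg: DistanceConfig | None = None
) -> list[GroupDistanceResult]:
    """Group-mean distances with site-bootstrap standard errors.

    Alignment columns are resampled with replacement (same alignment length)
    ``bootstrap_reps`` times; group means are recomputed per replicate and the
    SE is the sample standard deviation (ddof=1) across replicates. Replicates
    where a mean is undefined are dropped for that group pair; if more than
    half the replicates are dropped for any pair, an error is raised.
    """
    cfg = cfg or DistanceConfig()
    rng = np.random.default_rng(cfg.seed)
    point = group_mean(pairwise_matrix(aln, cfg), grouping)
    enc = _encode(aln)
    if cfg.deletion == "complete":
        enc = enc[:, (enc < 4).all(axis=0)]
    reps: dict[tuple[str, str], list[float]] = {(r.group_a, r.group_b): [] for r in point}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(cfg.bootstrap_reps):
            cols = rng.integers(0, enc.shape[1], size=enc.shape[1])
            mat, _ = _pairwise_from_encoded(enc[:, cols], cfg.gamma_shape)
            dm = DistanceMatrix(list(aln.ids), mat, None)
            for r in group_mean(dm, grouping):
                if not math.isnan(r.mean_distance):
                    reps[(r.group_a, r.group_b)].append(r.mean_distance)
    out = []
    for r in point:
        vals = reps[(r.group_a, r.group_b)]
        if math.isnan(r.mean_distance):
            out.append(r)
            continue
        if len(vals) < cfg.bootstrap_reps / 2:
            raise RuntimeError(
                f"more than half of bootstrap replicates undefined for {r.group_a}/{r.group_b}"
            )
        se = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out.append(
            GroupDistanceResult(
                r.group_a, r.group_b, r.mean_distance, se=se,
                n_pairs=r.n_pairs, n_undefined=r.n_undefined,
            )
        )
    return out
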