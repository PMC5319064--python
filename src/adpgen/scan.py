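"""Two-population Weir–Cockerham FST selection scan.

Per-SNP FST follows the Weir & Cockerham (1984) variance-components
estimator for two populations, retaining the numerator (a) and denominator
(a+b+c) so the genome-wide value can be reported both as the weighted ratio
of sums (the usual headline figure) and as the mean of per-SNP ratios.
Raw values — including the negative estimates the method produces at
undifferentiated SNPs — are smoothed with windows centred on each SNP, and
candidate sweep regions are SNPs extreme in both the raw and the smoothed
distribution, expanded to windows and merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genotypes import SEX_CHROMS, GenotypeMatrix


@dataclass
class ScanConfig:
    """Selection-scan settings.

    window_half_width: half the smoothing window in bp (50 kb gives the
        standard 100 kb centred window).
    snp_percentile / window_percentile: empirical quantile thresholds a SNP's
        raw and smoothed FST must strictly exceed to qualify.
    """

    window_half_width: int = 50_000
    snp_percentile: float = 0.99
    window_percentile: float = 0.95
    exclude_sex_chromosomes: bool = True
    exclude_fixed: bool = True

    def __post_init__(self) -> None:
        if self.window_half_width <= 0:
            raise ValueError("window_half_width must be positive")
        for p in (self.snp_percentile, self.window_percentile):
            if not 0 < p < 1:
                raise ValueError("percentiles must be in (0, 1)")


@dataclass
class CandidateInterval:
    chrom: str
    start: int      # bp, 1-based inclusive
    end: int
    peak_snp: str
    peak_fst: float
    n_qualifying: int


@dataclass
class ScanResult:
    table: pd.DataFrame              # snp, chrom, pos, fst, smoothed, n_in_window, qualifies
    fst_weighted: float              # ratio of sums (sum a / sum a+b+c)
    fst_mean: float                  # mean of per-SNP ratios
    intervals: list[CandidateInterval] = field(default_factory=list)


def wc_fst_components(
    gm: GenotypeMatrix, pop_labels: dict[str, str] | list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Weir–Cockerham variance components (a, a+b+c) for two populations.

    Uses allele frequencies, sample sizes and observed heterozygosity per
    population. SNPs where either population has fewer than two genotyped
    samples get NaN components.
    """
    labels = _as_labels(gm, pop_labels)
    pops = sorted(set(labels))
    if len(pops) != 2:
        raise ValueError(f"exactly two populations required, got {pops}")
    masks = [np.array([l == p for l in labels]) for p in pops]

    calls = gm.calls
    obs = calls >= 0
    n_i = np.stack([ (obs & m[:, None]).sum(axis=0) for m in masks ]).astype(float)  # (2, snps)
    cnt = np.stack([ np.where(obs & m[:, None], calls, 0).sum(axis=0) for m in masks ]).astype(float)
    het = np.stack([ ((calls == 1) & m[:, None]).sum(axis=0) for m in masks ]).astype(float)

    valid = (n_i >= 2).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = cnt / (2.0 * n_i)
        h_i = het / n_i
        r = 2.0
        nbar = n_i.mean(axis=0)
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
        denom = a + b + c
    a = np.where(valid, a, np.nan)
    denom = np.where(valid, denom, np.nan)
    return a, denom


def wc_fst(
    gm: GenotypeMatrix, pop_labels: dict[str, str] | list[str]
) -> tuple[np.ndarray, float, float]:
    """Per-SNP FST plus genome summaries (weighted ratio-of-sums, mean of ratios).

    The per-SNP estimate is NaN where the denominator is zero (a SNP carrying
    no variation in the combined sample) or where a population has fewer than
    two genotyped samples.
    """
    a, denom = wc_fst_components(gm, pop_labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(np.abs(denom) > 0, a / denom, np.nan)
    ok = ~np.isnan(fst)
    weighted = float(np.nansum(a[ok]) / np.nansum(denom[ok])) if ok.any() else float("nan")
    mean = float(np.nanmean(fst)) if ok.any() else float("nan")
    return fst, weighted, mean


def _as_labels(gm: GenotypeMatrix, pop_labels) -> list[str]:
    if isinstance(pop_labels, dict):
        missing = [s for s in gm.sample_ids if s not in pop_labels]
        if missing:
            raise ValueError(f"samples without population label: {missing[:5]}")
        return [pop_labels[s] for s in gm.sample_ids]
    labels = list(pop_labels)
    if len(labels) != gm.n_samples:
        raise ValueError("one population label per sample required")
    return labels


def prefilter(
    gm: GenotypeMatrix, pop_labels, cfg: ScanConfig | None = None
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Remove sex-chromosome SNPs and SNPs fixed within either population."""
    cfg = cfg or ScanConfig()
    labels = _as_labels(gm, pop_labels)
    keep = np.ones(gm.n_snps, dtype=bool)
    counts = {"sex_chromosome": 0, "fixed": 0}
    if cfg.exclude_sex_chromosomes:
        sex = np.isin(gm.chrom.astype(str), list(SEX_CHROMS))
        counts["sex_chromosome"] = int(sex.sum())
        keep &= ~sex
    if cfg.exclude_fixed:
        fixed = np.zeros(gm.n_snps, dtype=bool)
        for p in sorted(set(labels)):
            m = np.array([l == p for l in labels])
            freq = gm.allele2_frequency(np.flatnonzero(m))
            fixed |= np.isnan(freq) | (freq <= 0.0) | (freq >= 1.0)
        counts["fixed"] = int((fixed & keep).sum())
        keep &= ~fixed
    return gm.take_snps(np.flatnonzero(keep)), counts


def smooth(
    chrom: np.ndarray, pos: np.ndarray, fst: np.ndarray, half_width: int = 50_000
) -> tuple[np.ndarray, np.ndarray]:
    """Window mean of raw FST centred on each SNP (focal SNP included).

    Returns the smoothed values and the number of SNPs contributing to each
    window. Undefined raw values are excluded from window means; an isolated
    SNP's smoothed value equals its own raw value.
    """
    chrom = np.asarray(chrom, dtype=object).astype(str)
    pos = np.asarray(pos, dtype=np.int64)
    fst = np.asarray(fst, dtype=float)
    smoothed = np.full(len(fst), np.nan)
    n_in_window = np.zeros(len(fst), dtype=int)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        order = idx[np.argsort(pos[idx], kind="stable")]
        p = pos[order]
        v = fst[order]
        ok = ~np.isnan(v)
        cs = np.concatenate([[0.0], np.cumsum(np.where(ok, v, 0.0))])
        cn = np.concatenate([[0], np.cumsum(ok.astype(int))])
        lo = np.searchsorted(p, p - half_width, side="left")
        hi = np.searchsorted(p, p + half_width, side="right")
        tot = cs[hi] - cs[lo]
        num = cn[hi] - cn[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = np.where(num > 0, tot / num, np.nan)
        smoothed[order] = sm
        n_in_window[order] = hi - lo
    return smoothed, n_in_window


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended [start, end] intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def call_candidates(
    snp_ids: list[str],
    chrom: np.ndarray,
    pos: np.ndarray,
    fst: np.ndarray,
    smoothed: np.ndarray,
    cfg: ScanConfig | None = None,
) -> tuple[np.ndarray, list[CandidateInterval]]:
    """Dual-percentile candidate calling with window expansion and merging.

    A SNP qualifies when its raw FST strictly exceeds the ``snp_percentile``
    empirical quantile of all raw values AND its smoothed FST strictly exceeds
    the ``window_percentile`` quantile of all smoothed values (quantiles use
    linear interpolation between order statistics). Each qualifying SNP
    contributes the window [pos - hw, pos + hw]; contributed windows that
    overlap or touch on a chromosome are merged, and each merged interval's
    peak is the SNP with the highest raw FST inside it.
    """
    cfg = cfg or ScanConfig()
    chrom = np.asarray(chrom, dtype=object).astype(str)
    pos = np.asarray(pos, dtype=np.int64)
    fst = np.asarray(fst, dtype=float)
    smoothed = np.asarray(smoothed, dtype=float)

    snp_thr = np.nanquantile(fst, cfg.snp_percentile)
    win_thr = np.nanquantile(smoothed, cfg.window_percentile)
    with np.errstate(invalid="ignore"):
        qualifies = (fst > snp_thr) & (smoothed > win_thr)

    hw = cfg.window_half_width
    intervals: list[CandidateInterval] = []
    for c in np.unique(chrom[qualifies]) if qualifies.any() else []:
        mask = qualifies & (chrom == c)
        contributed = [(max(1, p - hw), p + hw) for p in pos[mask]]
        for s, e in _merge_intervals(contributed):
            inside = (chrom == c) & (pos >= s) & (pos <= e) & ~np.isnan(fst)
            peak_idx = int(np.flatnonzero(inside)[np.argmax(fst[inside])])
            intervals.append(
                CandidateInterval(
                    chrom=c, start=int(s), end=int(e),
                    peak_snp=snp_ids[peak_idx], peak_fst=float(fst[peak_idx]),
                    n_qualifying=int((mask & (pos >= s) & (pos <= e)).sum()),
                )
            )
    intervals.sort(key=lambda iv: (iv.chrom, iv.start))
    return qualifies, intervals


def intersect_comparisons(runs: list[list[CandidateInterval]]) -> list[CandidateInterval]:
    """Maximal genomic regions covered by at least one interval in every run.

    The result is the set intersection of the runs' genomic coverage; each
    output interval carries the best peak (highest raw FST) among the source
    intervals overlapping it.
    """
    if not runs:
        return []
    coverage: dict[str, list[tuple[int, int]]] | None = None
    for run in runs:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in run:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        per_chrom = {c: _merge_intervals(v) for c, v in per_chrom.items()}
        if coverage is None:
            coverage = per_chrom
        else:
            coverage = {
                c: _intersect_sorted(coverage.get(c, []), per_chrom.get(c, []))
                for c in set(coverage) & set(per_chrom)
            }
    out: list[CandidateInterval] = []
    assert coverage is not None
    for c in sorted(coverage):
        for s, e in coverage[c]:
            peaks = [
                iv
                for run in runs
                for iv in run
                if iv.chrom == c and iv.start <= e and iv.end >= s
            ]
            best = max(peaks, key=lambda iv: iv.peak_fst)
            out.append(
                CandidateInterval(c, s, e, best.peak_snp, best.peak_fst,
                                  sum(iv.n_qualifying for iv in peaks))
            )
    return out


def _intersect_sorted(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


class FstScan(BaseEstimator):
    """End-to-end two-population selection scan as a fit-shaped estimator.

    ``fit(gm, pop_labels)`` prefilters, estimates per-SNP FST, smooths, and
    calls candidate intervals. Fitted attributes: ``result_`` (ScanResult),
    ``fst_weighted_``, ``fst_mean_``, ``intervals_``.
    """

    def __init__(
        self,
        window_half_width: int = 50_000,
        snp_percentile: float = 0.99,
        window_percentile: float = 0.95,
        exclude_sex_chromosomes: bool = True,
        exclude_fixed: bool = True,
    ):
        self.window_half_width = window_half_width
        self.snp_percentile = snp_percentile
        self.window_percentile = window_percentile
        self.exclude_sex_chromosomes = exclude_sex_chromosomes
        self.exclude_fixed = exclude_fixed

    def _config(self) -> ScanConfig:
        return ScanConfig(
            self.window_half_width, self.snp_percentile, self.window_percentile,
            self.exclude_sex_chromosomes, self.exclude_fixed,
        )

    def fit(self, gm: GenotypeMatrix, pop_labels):
        cfg = self._config()
        filtered, removed = prefilter(gm, pop_labels, cfg)
        if filtered.n_snps == 0:
            raise ValueError("no SNPs left after prefiltering")
        filtered = filtered.sort_by_position()
        if isinstance(pop_labels, dict):
            labels = pop_labels
        else:
            labels = dict(zip(gm.sample_ids, _as_labels(gm, pop_labels)))
        fst, weighted, mean = wc_fst(filtered, labels)
        smoothed, n_in_window = smooth(
            filtered.chrom, filtered.pos, fst, cfg.window_half_width
        )
        qualifies, intervals = call_candidates(
            filtered.snp_ids, filtered.chrom, filtered.pos, fst, smoothed, cfg
        )
        table = pd.DataFrame(
            {
                "snp": filtered.snp_ids,
                "chrom": filtered.chrom.astype(str),
                "pos": filtered.pos,
                "fst": fst,
                "smoothed": smoothed,
                "n_in_window": n_in_window,
                "qualifies": qualifies,
            }
        )
        self.removed_ = removed
        self.result_ = ScanResult(table, weighted, mean, intervals)
        self.fst_weighted_ = weighted
        self.fst_mean_ = mean
        self.intervals_ = intervals
        return self


def intervals_to_bed(intervals: list[CandidateInterval]) -> pd.DataFrame:
    """BED-style frame (0-based half-open) from 1-based inclusive intervals."""
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start - 1 for iv in intervals],
            "end": [iv.end for iv in intervals],
            "name": [iv.peak_snp for iv in intervals],
            "score": [iv.peak_fst for iv in intervals],
        }
    )
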