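"""SNP dataset quality control, merging, sex inference and PCA.

Filtering follows the usual chip-QC order: SNPs failing the per-SNP missing
rate are dropped first, then SNPs below the minor-allele-frequency floor
(computed on the remaining calls), then samples exceeding the individual
missing rate. PCA standardises dosages by the binomial SD sqrt(p(1-p))
(the smartpca/EIGENSTRAT convention) and eigendecomposes the sample
covariance, so the leading axes capture population structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genotypes import MISSING, SEX_CHROMS, GenotypeMatrix


@dataclass
class QcReport:
    snps_removed_missingness: int
    snps_removed_maf: int
    samples_removed_missingness: int
    snps_remaining: int
    samples_remaining: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def filter_genotypes(
    gm: GenotypeMatrix,
    snp_miss_max: float = 0.10,
    maf_min: float = 0.05,
    ind_miss_max: float = 0.10,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the three standard chip filters in order; see module docstring.

    A SNP is removed when its missing rate is strictly above ``snp_miss_max``
    or its MAF strictly below ``maf_min``; a sample when its missing rate over
    the surviving SNPs is strictly above ``ind_miss_max``. Raises if nothing
    survives, naming the stage that emptied the matrix.
    """
    for name, t in (("snp_miss_max", snp_miss_max), ("maf_min", maf_min), ("ind_miss_max", ind_miss_max)):
        if not 0 <= t <= 1:
            raise ValueError(f"{name} must be in [0, 1]")

    keep_snp = gm.snp_missing_rate() <= snp_miss_max
    n_miss = int((~keep_snp).sum())
    gm1 = gm.take_snps(np.flatnonzero(keep_snp))
    if gm1.n_snps == 0:
        raise ValueError("all SNPs removed at the missingness stage")

    freq = gm1.allele2_frequency()
    maf = np.minimum(freq, 1.0 - freq)
    keep_maf = ~(np.nan_to_num(maf, nan=0.0) < maf_min)
    n_maf = int((~keep_maf).sum())
    gm2 = gm1.take_snps(np.flatnonzero(keep_maf))
    if gm2.n_snps == 0:
        raise ValueError("all SNPs removed at the MAF stage")

    keep_ind = gm2.sample_missing_rate() <= ind_miss_max
    n_ind = int((~keep_ind).sum())
    gm3 = gm2.take_samples(np.flatnonzero(keep_ind))
    if gm3.n_samples == 0:
        raise ValueError("all samples removed at the individual-missingness stage")

    report = QcReport(n_miss, n_maf, n_ind, gm3.n_snps, gm3.n_samples)
    return gm3, report


def merge_datasets(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Merge two datasets on their shared SNPs, harmonising allele order.

    Sample ids must be disjoint. When a SNP's allele pair is swapped between
    the datasets, dosages from ``b`` are flipped (2 - dosage). SNPs with
    irreconcilable allele pairs are dropped and counted; strand-ambiguous
    SNPs (A/T or C/G pairs) whose allele-2 frequencies disagree by more than
    0.4 between datasets are also dropped with a warning, since a strand flip
    cannot be ruled out there.
    """
    if set(a.sample_ids) & set(b.sample_ids):
        raise ValueError("sample ids are not disjoint")
    shared = [s for s in a.snp_ids if s in set(b.snp_ids)]
    if not shared:
        raise ValueError("no shared SNPs between datasets")
    ia = {s: k for k, s in enumerate(a.snp_ids)}
    ib = {s: k for k, s in enumerate(b.snp_ids)}
    fa, fb = a.allele2_frequency(), b.allele2_frequency()

    keep: list[str] = []
    flip: list[bool] = []
    n_dropped = 0
    ambiguous_pairs = ({"A", "T"}, {"C", "G"})
    for s in shared:
        pa, pb = a.alleles[ia[s]], b.alleles[ib[s]]
        if set(pa) != set(pb) and "?" not in set(pa) | set(pb):
            n_dropped += 1
            continue
        swapped = pa != pb and set(pa) == set(pb)
        if set(pa) in ambiguous_pairs:
            qa, qb = fa[ia[s]], fb[ib[s]]
            qb_eff = 1.0 - qb if swapped else qb
            if not np.isnan(qa) and not np.isnan(qb_eff) and abs(qa - qb_eff) > 0.4:
                n_dropped += 1
                continue
        keep.append(s)
        flip.append(swapped)
    if n_dropped:
        warnings.warn(f"{n_dropped} SNP(s) dropped during merge", stacklevel=2)
    if not keep:
        raise ValueError("no reconcilable shared SNPs")

    idx_a = np.array([ia[s] for s in keep])
    idx_b = np.array([ib[s] for s in keep])
    calls_a = a.calls[:, idx_a]
    calls_b = b.calls[:, idx_b].copy()
    flip_arr = np.array(flip)
    flipped = calls_b[:, flip_arr]
    calls_b[:, flip_arr] = np.where(flipped >= 0, 2 - flipped, MISSING)
    return GenotypeMatrix(
        list(a.sample_ids) + list(b.sample_ids),
        keep,
        a.chrom[idx_a],
        a.pos[idx_a],
        [a.alleles[i] for i in idx_a],
        np.vstack([calls_a, calls_b]),
    )


def infer_sex(
    gm: GenotypeMatrix,
    recorded: dict[str, str] | None = None,
    x_het_max: float = 0.05,
    y_callrate_min: float = 0.5,
) -> pd.DataFrame:
    """Call genetic sex from X heterozygosity and Y call rate.

    Males are hemizygous on X (chip callers code them homozygous) and carry Y
    markers; females show substantial X heterozygosity and no Y calls. Samples
    matching neither pattern are "ambiguous". Returns a frame with the calls
    and, when recorded sexes are given, a concordance column.
    """
    x_idx = np.flatnonzero(np.isin(gm.chrom.astype(str), ["X", "23"]))
    y_idx = np.flatnonzero(np.isin(gm.chrom.astype(str), ["Y", "24"]))
    if len(x_idx) == 0 and len(y_idx) == 0:
        raise ValueError("no sex-chromosome markers in the dataset")

    rows = []
    for i, sample in enumerate(gm.sample_ids):
        x_calls = gm.calls[i, x_idx]
        x_obs = x_calls[x_calls >= 0]
        x_het = float((x_obs == 1).mean()) if len(x_obs) else np.nan
        y_calls = gm.calls[i, y_idx]
        y_rate = float((y_calls >= 0).mean()) if len(y_idx) else 0.0
        if not np.isnan(x_het) and x_het <= x_het_max and y_rate >= y_callrate_min:
            call = "male"
        elif not np.isnan(x_het) and x_het > x_het_max and y_rate < y_callrate_min:
            call = "female"
        else:
            call = "ambiguous"
        row = {"sample": sample, "x_het": x_het, "y_callrate": y_rate, "inferred_sex": call}
        if recorded is not None:
            rec = recorded.get(sample)
            row["recorded_sex"] = rec
            row["concordant"] = (call == rec) if rec is not None else None
        rows.append(row)
    return pd.DataFrame(rows)


def run_pca(
    gm: GenotypeMatrix, n_components: int = 10, scaling: str = "binomial"
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the genotype matrix; returns (coordinates, variance fractions).

    Missing calls are mean-imputed per SNP; zero-variance SNPs are excluded.
    ``scaling="binomial"`` divides by sqrt(p(1-p)) with p the allele frequency
    (smartpca convention); ``"sd"`` uses the sample standard deviation. Each
    component's sign is fixed so its largest-magnitude coordinate is positive.
    """
    if scaling not in ("binomial", "sd"):
        raise ValueError("scaling must be 'binomial' or 'sd'")
    X = gm.calls.astype(float)
    X[X < 0] = np.nan
    mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mean, inds[1])
    var = X.var(axis=0)
    keep = var > 0
    X = X[:, keep]
    mean = mean[keep]
    X -= mean
    if scaling == "binomial":
        p = mean / 2.0
        X /= np.sqrt(p * (1.0 - p))
    else:
        X /= np.sqrt(var[keep])

    n = X.shape[0]
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > 1e-9 * s[0]).sum()) if len(s) and s[0] > 0 else 0
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
    coords = u[:, :k] * s[:k]
    total_var = (s**2).sum()
    frac = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    for j in range(k):
        if len(coords) and coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    return coords, frac


class GenotypeQC(BaseEstimator):
    """Estimator facade over :func:`filter_genotypes`.

    Fitted attributes: ``report_`` (QcReport) and ``filtered_`` (the matrix).
    """

    def __init__(self, snp_miss_max: float = 0.10, maf_min: float = 0.05, ind_miss_max: float = 0.10):
        self.snp_miss_max = snp_miss_max
        self.maf_min = maf_min
        self.ind_miss_max = ind_miss_max

    def fit(self, gm: GenotypeMatrix, y=None):
        self.filtered_, self.report_ = filter_genotypes(
            gm, self.snp_miss_max, self.maf_min, self.ind_miss_max
        )
        return self

    def transform(self, gm: GenotypeMatrix) -> GenotypeMatrix:
        return self.fit(gm).filtered_

    def fit_transform(self, gm: GenotypeMatrix, y=None) -> GenotypeMatrix:
        return self.transform(gm)


class GenotypePCA(BaseEstimator):
    """Estimator facade over :func:`run_pca`.

    Fitted attributes: ``coordinates_`` and ``explained_variance_ratio_``.
    """

    def __init__(self, n_components: int = 10, scaling: str = "binomial"):
        self.n_components = n_components
        self.scaling = scaling

    def fit(self, gm: GenotypeMatrix, y=None):
        self.coordinates_, self.explained_variance_ratio_ = run_pca(
            gm, self.n_components, self.scaling
        )
        self.sample_ids_ = list(gm.sample_ids)
        return self

    def fit_transform(self, gm: GenotypeMatrix, y=None) -> np.ndarray:
        return self.fit(gm).coordinates_
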