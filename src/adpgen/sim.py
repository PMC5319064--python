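"""Synthetic data generators for every pipeline input.

Three generators cover the three data types the pipeline consumes:

* a two-clade mitochondrial control-region haplotype pool with gamma rate
  heterogeneity across sites and a transition-biased mutation process,
  emulating the deep European/Asian split of domestic pig maternal lineages;
* diploid SNP genotypes for two or more populations under the
  Balding–Nichols model, in which each population's allele frequency is a
  Beta draw around the ancestral frequency with variance F*p*(1-p), plus
  optional "spiked" windows of elevated differentiation for scan testing;
* MC1R allele sequences carrying the defining mutations of named
  coat-colour haplotypes.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import SeqAlignment
from .genotypes import MISSING, GenotypeMatrix
from . import mc1r as _mc1r

_BASES = np.array(list("ACGT"))
#: transition partner of each base (A<->G, C<->T)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ["C", "T"], "G": ["C", "T"], "C": ["A", "G"], "T": ["A", "G"],
}


# --------------------------------------------------------------------------
# mitochondrial control-region haplotypes
# --------------------------------------------------------------------------

@dataclass
class DloopSimConfig:
    """Two-clade haplotype pool settings.

    clade_divergence / within_clade_divergence are expected substitutions per
    site between the clade root sequences and between a haplotype and its
    clade root, respectively. gamma_shape is the shape of the gamma
    distribution of site rates (0.33 reflects the strong rate heterogeneity of
    the control region). kappa is the transition/transversion ratio of the
    mutation process.
    """

    n_samples: int = 140
    n_haplotypes_per_clade: int = 7
    clade_divergence: float = 0.05
    within_clade_divergence: float = 0.005
    seq_length: int = 573
    gamma_shape: float = 0.33
    clade_proportions: tuple[float, ...] = (0.5, 0.5)
    region_labels: tuple[str, ...] = ("UWR", "NR", "AR", "ER", "CR", "GAR")
    kappa: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_haplotypes_per_clade <= 0 or self.seq_length <= 0:
            raise ValueError("counts and lengths must be positive")
        if self.clade_divergence < 0 or self.within_clade_divergence < 0:
            raise ValueError("divergences must be non-negative")
        if abs(sum(self.clade_proportions) - 1.0) > 1e-9:
            raise ValueError("clade_proportions must sum to 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")


@dataclass
class DloopTruth:
    """Per-sample truth plus the haplotype pool and clade root sequences."""

    table: pd.DataFrame                 # sample, haplotype, clade, region
    haplotype_sequences: dict[str, str]
    haplotype_clades: dict[str, str]
    clade_roots: dict[str, str]


def _evolve(seq: str, divergence: float, rates: np.ndarray, kappa: float, rng) -> str:
    """Apply a Poisson number of mutations per site, transition-biased."""
    out = list(seq)
    n_mut = rng.poisson(divergence * rates)
    p_ts = kappa / (kappa + 2.0)
    for i in np.flatnonzero(n_mut):
        for _ in range(n_mut[i]):
            base = out[i]
            if rng.random() < p_ts:
                out[i] = _TRANSITION[base]
            else:
                out[i] = _TRANSVERSIONS[base][rng.integers(0, 2)]
    return "".join(out)


def simulate_dloop(config: DloopSimConfig) -> tuple[SeqAlignment, DloopTruth]:
    """Generate aligned control-region sequences from a two-clade pool.

    The ancestral sequence seeds two clade roots (European- and Asian-like)
    separated by ``clade_divergence``; each clade's haplotypes evolve from its
    root at ``within_clade_divergence``. When the within-clade divergence is
    positive, haplotypes are guaranteed distinct (duplicate draws are
    re-evolved, then minimally perturbed), so a downstream collapse can be
    compared against the truth table exactly. Every haplotype receives at
    least one sample when ``n_samples`` allows.
    """
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    rates = rng.gamma(config.gamma_shape, 1.0 / config.gamma_shape, size=L)
    ancestor = "".join(rng.choice(_BASES, size=L))

    clades = ["European", "Asian"]
    roots: dict[str, str] = {}
    for clade in clades:
        roots[clade] = _evolve(ancestor, config.clade_divergence / 2.0, rates, config.kappa, rng)
    if config.clade_divergence > 0 and roots["European"] == roots["Asian"]:
        # force at least one difference between the clade roots
        i = int(rng.integers(0, L))
        seq = list(roots["Asian"])
        seq[i] = _TRANSITION[seq[i]]
        roots["Asian"] = "".join(seq)

    hap_seqs: dict[str, str] = {}
    hap_clades: dict[str, str] = {}
    pool: set[str] = set()
    for clade in clades:
        for k in range(config.n_haplotypes_per_clade):
            name = f"{clade[:3]}_{k + 1}"
            seq = _evolve(roots[clade], config.within_clade_divergence, rates, config.kappa, rng)
            if config.within_clade_divergence > 0:
                tries = 0
                while seq in pool and tries < 100:
                    seq = _evolve(roots[clade], config.within_clade_divergence, rates, config.kappa, rng)
                    tries += 1
                while seq in pool:      # last resort: single-site perturbation
                    i = int(rng.integers(0, L))
                    s = list(seq)
                    s[i] = _TRANSITION[s[i]]
                    seq = "".join(s)
            hap_seqs[name] = seq
            hap_clades[name] = clade
            pool.add(seq)

    # allocate samples to clades by the configured proportions
    n_per_clade = [int(round(p * config.n_samples)) for p in config.clade_proportions[:2]]
    n_per_clade[-1] = config.n_samples - sum(n_per_clade[:-1])
    assignments: list[str] = []
    for clade, n in zip(clades, n_per_clade):
        names = [h for h, c in hap_clades.items() if c == clade]
        picks = list(names[: min(n, len(names))])         # cover each haplotype once
        if n > len(picks):
            picks += list(rng.choice(names, size=n - len(picks)))
        assignments.extend(picks)

    ids = [f"s{i + 1}" for i in range(config.n_samples)]
    regions = list(rng.choice(list(config.region_labels), size=config.n_samples))
    seqs = [hap_seqs[h] for h in assignments]
    truth = pd.DataFrame(
        {
            "sample": ids,
            "haplotype": assignments,
            "clade": [hap_clades[h] for h in assignments],
            "region": regions,
        }
    )
    return SeqAlignment(ids, seqs), DloopTruth(truth, hap_seqs, hap_clades, roots)


# --------------------------------------------------------------------------
# SNP genotypes under the Balding–Nichols model
# --------------------------------------------------------------------------

@dataclass
class SpikeRegion:
    """A genomic interval whose SNPs get differentiation F + delta."""

    chrom: str
    start: int
    end: int
    delta: float


@dataclass
class GenoSimConfig:
    """Balding–Nichols genotype simulation settings.

    fst_target is Wright's F: population allele frequencies are drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency p, which has
    mean p and variance F*p*(1-p). F = 0 means every population uses p
    exactly. chrom_layout lists (name, length_bp, snp_spacing_bp); the default
    puts SNPs every 50 kb on two 20 Mb autosomes so each 100 kb window holds
    several SNPs. n_x_snps / n_y_snps append sex-chromosome markers whose
    calls follow each sample's simulated sex.
    """

    n_pops: int = 2
    n_per_pop: int = 100
    fst_target: float = 0.15
    maf_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    chrom_layout: tuple[tuple[str, int, int], ...] = (
        ("1", 20_000_000, 50_000),
        ("2", 20_000_000, 50_000),
    )
    n_snps: int | None = None
    spike_regions: tuple[SpikeRegion, ...] = ()
    n_x_snps: int = 0
    n_y_snps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fst_target < 1:
            raise ValueError("fst_target must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_pops < 1 or self.n_per_pop < 1:
            raise ValueError("population counts must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")


def _positions(config: GenoSimConfig) -> tuple[np.ndarray, np.ndarray]:
    chroms, pos = [], []
    layout = config.chrom_layout
    if config.n_snps is not None:
        total_len = sum(l for _, l, _ in layout)
        counts = [int(round(config.n_snps * l / total_len)) for _, l, _ in layout]
        counts[-1] = config.n_snps - sum(counts[:-1])
        for (name, length, _), k in zip(layout, counts):
            step = max(1, length // (k + 1))
            p = np.arange(1, k + 1) * step
            chroms.extend([name] * k)
            pos.extend(p.tolist())
    else:
        for name, length, spacing in layout:
            p = np.arange(spacing, length + 1, spacing)
            chroms.extend([name] * len(p))
            pos.extend(p.tolist())
    return np.array(chroms, dtype=object), np.array(pos, dtype=np.int64)


def balding_nichols_freq(p: np.ndarray, F: float, rng) -> np.ndarray:
    """One population's allele frequencies around ancestral ``p`` at level F."""
    if F <= 0:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def simulate_genotypes(config: GenoSimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Diploid genotypes from >=2 populations with target differentiation F.

    Returns the genotype matrix plus a sample metadata frame (id, population,
    region, zone, breed class, sex). Populations map onto the sampling
    strata round-robin so downstream grouping code has realistic labels.
    """
    rng = np.random.default_rng(config.seed)
    chroms, pos = _positions(config)
    m = len(pos)
    n = config.n_pops * config.n_per_pop

    p_anc = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    F = np.full(m, config.fst_target)
    for spike in config.spike_regions:
        inside = (chroms == spike.chrom) & (pos >= spike.start) & (pos <= spike.end)
        F[inside] = np.minimum(config.fst_target + spike.delta, 0.999)

    calls = np.empty((n, m), dtype=np.int8)
    sample_ids: list[str] = []
    pops: list[str] = []
    for k in range(config.n_pops):
        # Beta parameters vary per SNP; vectorised draw over the SNP axis
        pk = np.where(
            F > 0,
            rng.beta(
                np.maximum(p_anc * (1.0 - F) / np.maximum(F, 1e-12), 1e-12),
                np.maximum((1.0 - p_anc) * (1.0 - F) / np.maximum(F, 1e-12), 1e-12),
            ),
            p_anc,
        )
        g = rng.binomial(2, pk, size=(config.n_per_pop, m)).astype(np.int8)
        calls[k * config.n_per_pop : (k + 1) * config.n_per_pop] = g
        sample_ids += [f"pop{k + 1}_s{i + 1}" for i in range(config.n_per_pop)]
        pops += [f"pop{k + 1}"] * config.n_per_pop

    snp_ids = [f"snp_{c}_{p}" for c, p in zip(chroms, pos)]
    alleles = [("A", "B")] * m
    sexes = ["male" if i % 2 == 0 else "female" for i in range(n)]

    if config.n_x_snps or config.n_y_snps:
        is_male = np.array([s == "male" for s in sexes])
        extra_chrom, extra_pos, extra_calls, extra_ids = [], [], [], []
        px = rng.uniform(0.2, 0.8, size=config.n_x_snps)
        for j in range(config.n_x_snps):
            col = np.empty(n, dtype=np.int8)
            col[is_male] = 2 * rng.binomial(1, px[j], size=is_male.sum())
            col[~is_male] = rng.binomial(2, px[j], size=(~is_male).sum())
            extra_calls.append(col)
            extra_chrom.append("X")
            extra_pos.append((j + 1) * 100_000)
            extra_ids.append(f"snp_X_{j + 1}")
        for j in range(config.n_y_snps):
            col = np.full(n, MISSING, dtype=np.int8)
            col[is_male] = 2 * rng.binomial(1, 0.5, size=is_male.sum())
            extra_calls.append(col)
            extra_chrom.append("Y")
            extra_pos.append((j + 1) * 100_000)
            extra_ids.append(f"snp_Y_{j + 1}")
        calls = np.hstack([calls, np.stack(extra_calls, axis=1)])
        chroms = np.concatenate([chroms, np.array(extra_chrom, dtype=object)])
        pos = np.concatenate([pos, np.array(extra_pos, dtype=np.int64)])
        snp_ids += extra_ids
        alleles = alleles + [("A", "B")] * (config.n_x_snps + config.n_y_snps)
        m = len(snp_ids)

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = np.where(mask, MISSING, calls).astype(np.int8)

    gm = GenotypeMatrix(sample_ids, snp_ids, chroms, pos, alleles, calls)
    zones = {"UWR": "Guinea Savannah", "NR": "Guinea Savannah", "AR": "Forest",
             "ER": "Forest", "CR": "Coastal", "GAR": "Coastal"}
    region_cycle = list(zones)
    regions = [region_cycle[int(p[3:]) % len(region_cycle) - 1] for p in pops]
    metadata = pd.DataFrame(
        {
            "id": sample_ids,
            "population": pops,
            "region": regions,
            "zone": [zones[r] for r in regions],
            "breed_class": ["ADP" if p == "pop1" else "exotic" for p in pops],
            "sex": sexes,
        }
    )
    return gm, metadata


# --------------------------------------------------------------------------
# MC1R allele sequences
# --------------------------------------------------------------------------

def simulate_mc1r(
    diplotypes: list[tuple[str, str]],
    reference_cds: str | None = None,
    seed: int = 0,
) -> tuple[dict[str, tuple[str, str]], str]:
    """Per-animal allele sequences carrying each allele's defining mutations.

    ``diplotypes`` is a list of allele-code pairs drawn from
    {0101, 0102, 0201, 0301, 0401, 0501}; animal ids are ``a1, a2, ...``.
    Returns the sequences and the reference coding sequence used. A wild-type
    code yields a sequence identical to the reference; unknown codes raise.
    The ``seed`` parameter is accepted for interface symmetry (the generator
    is currently fully deterministic given the reference).
    """
    ref = reference_cds or _mc1r.synthetic_reference_cds()
    out: dict[str, tuple[str, str]] = {}
    for i, (a, b) in enumerate(diplotypes):
        out[f"a{i + 1}"] = (_mc1r.apply_allele(ref, a), _mc1r.apply_allele(ref, b))
    return out, ref


# --------------------------------------------------------------------------
# sequence-pair simulation under the TN93+gamma process
# --------------------------------------------------------------------------

def tn93_rate_matrix(
    freqs: np.ndarray, kappa_r: float = 4.0, kappa_y: float = 4.0
) -> np.ndarray:
    """TN93 instantaneous rate matrix (order A, C, G, T), mean rate 1."""
    pa, pc, pg, pt = freqs
    beta = 1.0
    Q = np.array(
        [
            [0.0, beta * pc, kappa_r * beta * pg, beta * pt],
            [beta * pa, 0.0, beta * pg, kappa_y * beta * pt],
            [kappa_r * beta * pa, beta * pc, 0.0, beta * pt],
            [beta * pa, kappa_y * beta * pc, beta * pg, 0.0],
        ]
    )
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.sum(freqs * np.diag(Q))
    return Q / mean_rate


def simulate_tn93_pair(
    distance: float,
    length: int,
    gamma_shape: float | None = None,
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    kappa_r: float = 4.0,
    kappa_y: float = 4.0,
    seed: int = 0,
) -> tuple[str, str]:
    """A sequence pair whose true TN93 divergence is ``distance`` subs/site.

    Site rates are gamma distributed (or constant when ``gamma_shape`` is
    None); transition probabilities come from the exact matrix exponential of
    the TN93 rate matrix, evaluated per site via eigendecomposition.
    """
    rng = np.random.default_rng(seed)
    pi = np.asarray(freqs, dtype=float)
    Q = tn93_rate_matrix(pi, kappa_r, kappa_y)
    evals, evecs = np.linalg.eig(Q)
    inv = np.linalg.inv(evecs)

    rates = (
        rng.gamma(gamma_shape, 1.0 / gamma_shape, size=length)
        if gamma_shape is not None
        else np.ones(length)
    )
    anc_idx = rng.choice(4, size=length, p=pi)
    # P(t) per site: V diag(exp(lambda * t)) V^-1 with t = distance * rate
    exp_l = np.exp(np.outer(rates * distance, evals))          # (L, 4)
    P = np.einsum("ij,lj,jk->lik", evecs, exp_l, inv).real     # (L, 4, 4)
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=2, keepdims=True)
    u = rng.random(length)
    probs = P[np.arange(length), anc_idx]                      # (L, 4)
    desc_idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    bases = np.array(list("ACGT"))
    return "".join(bases[anc_idx]), "".join(bases[desc_idx])
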