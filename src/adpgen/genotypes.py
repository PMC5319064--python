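"""Diploid SNP genotype container with PLINK-style PED/MAP text I/O.

Genotypes are stored as the dosage of the second allele (0, 1, 2) with -1 for
missing calls, in a samples x SNPs int8 array. Chromosome labels are strings;
"X" and "Y" mark the sex chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

SEX_CHROMS = {"X", "Y", "23", "24"}


@dataclass
class GenotypeMatrix:
    sample_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray        # str per SNP
    pos: np.ndarray          # bp, 1-based, int64
    alleles: list[tuple[str, str]]   # (allele1, allele2) per SNP
    calls: np.ndarray        # (n_samples, n_snps) int8 dosage of allele2; -1 missing

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError("calls shape does not match ids")
        if len(self.chrom) != m or len(self.pos) != m or len(self.alleles) != m:
            raise ValueError("marker map length mismatch")
        for a1, a2 in self.alleles:
            if a1 == a2:
                raise ValueError("allele pair must be two distinct alleles")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.snp_ids[i] for i in idx],
            self.chrom[idx],
            self.pos[idx],
            [self.alleles[i] for i in idx],
            self.calls[:, idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.snp_ids),
            self.chrom,
            self.pos,
            list(self.alleles),
            self.calls[idx, :],
        )

    def sort_by_position(self) -> "GenotypeMatrix":
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        return self.take_snps(order)

    # --- frequencies -----------------------------------------------------
    def allele2_frequency(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Frequency of allele 2 per SNP over non-missing calls (NaN if none)."""
        calls = self.calls if sample_idx is None else self.calls[sample_idx]
        obs = calls >= 0
        n = obs.sum(axis=0)
        tot = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def snp_missing_rate(self) -> np.ndarray:
        return (self.calls < 0).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return (self.calls < 0).mean(axis=1)

    # --- PLINK text I/O --------------------------------------------------
    def to_plink(self, prefix: str | Path, metadata: pd.DataFrame | None = None) -> None:
        """Write ``<prefix>.ped`` and ``<prefix>.map``.

        Sex codes (1=male, 2=female, 0=unknown) are taken from a metadata
        frame indexed by sample id with a ``sex`` column when provided.
        """
        prefix = Path(prefix)
        with open(f"{prefix}.map", "w") as fh:
            for sid, c, p in zip(self.snp_ids, self.chrom, self.pos):
                fh.write(f"{c}\t{sid}\t0\t{p}\n")
        sex_codes = {}
        if metadata is not None and "sex" in metadata.columns:
            sex_map = {"male": "1", "female": "2", "M": "1", "F": "2", "1": "1", "2": "2"}
            sex_codes = {
                i: sex_map.get(str(metadata.loc[i, "sex"]), "0") for i in metadata.index
            }
        a = np.array([al[0] for al in self.alleles])
        b = np.array([al[1] for al in self.alleles])
        with open(f"{prefix}.ped", "w") as fh:
            for i, sample in enumerate(self.sample_ids):
                row = self.calls[i]
                first = np.where(row <= 1, a, b)
                second = np.where(row >= 1, b, a)
                first = np.where(row < 0, "0", first)
                second = np.where(row < 0, "0", second)
                genos = " ".join(f"{x} {y}" for x, y in zip(first, second))
                fh.write(f"FAM {sample} 0 0 {sex_codes.get(sample, '0')} -9 {genos}\n")

    @classmethod
    def from_plink(cls, prefix: str | Path) -> "GenotypeMatrix":
        prefix = Path(prefix)
        mp = pd.read_csv(
            f"{prefix}.map", sep=r"\s+", header=None,
            names=["chrom", "snp", "cm", "pos"], dtype={"chrom": str, "snp": str},
        )
        sample_ids: list[str] = []
        raw: list[np.ndarray] = []
        with open(f"{prefix}.ped") as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                sample_ids.append(parts[1])
                raw.append(np.array(parts[6:], dtype=object))
        n_snps = len(mp)
        allele_obs = np.stack(raw).reshape(len(sample_ids), n_snps, 2)
        alleles: list[tuple[str, str]] = []
        calls = np.full((len(sample_ids), n_snps), MISSING, dtype=np.int8)
        for j in range(n_snps):
            col = allele_obs[:, j, :]
            seen = sorted({x for x in col.ravel() if x != "0"})
            if len(seen) == 1:
                seen = seen + ["?"]          # monomorphic: placeholder second allele
            elif len(seen) == 0:
                seen = ["?", "!"]
            elif len(seen) > 2:
                raise ValueError(f"SNP {mp['snp'][j]} has >2 alleles")
            a1, a2 = seen[0], seen[1]
            miss = (col == "0").any(axis=1)
            dosage = (col == a2).sum(axis=1).astype(np.int8)
            calls[:, j] = np.where(miss, MISSING, dosage)
            alleles.append((a1, a2))
        return cls(
            sample_ids, list(mp["snp"]), mp["chrom"].to_numpy(dtype=object),
            mp["pos"].to_numpy(), alleles, calls,
        )
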