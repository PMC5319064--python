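"""MC1R coat-colour allele typing for pigs.

The melanocortin-1 receptor switches melanocytes between eumelanin (black) and
pheomelanin (red) production. Six named pig alleles are recognised here, each
defined by a small set of coding variants on the single-exon gene:

=======  =======  ========  =====================================
code     symbol   origin    defining variants
=======  =======  ========  =====================================
0101     E+       wild type (none; reference haplotype)
0102     E+       wild type (not separated from 0101 here)
0201     E^D1     Asian     Val95Met + Leu102Pro (dominant black)
0301     E^D2     European  Asp124Asn (dominant black)
0401     e        European  Ala164Val + Ala243Thr (recessive red)
0501     E^P      European  nt67insCC + Asp124Asn (black spotting)
=======  =======  ========  =====================================

The nt67insCC frameshift of 0501 destroys receptor function; black spots arise
from somatic reversion. Classification is rule-based on the called variants,
and coat colour is predicted from the diplotype by dominance: dominant black
(0201/0301) over wild type over spotting (0501) over recessive red (0401).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq
from sklearn.base import BaseEstimator

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}

#: nt-level definitions (1-based positions on the reference coding sequence)
#: of the defining substitutions: position, ref base, alt base, consequence.
SUBSTITUTIONS = {
    "Val95Met": (283, "G", "A"),
    "Leu102Pro": (305, "T", "C"),
    "Asp124Asn": (370, "G", "A"),
    "Ala164Val": (491, "C", "T"),
    "Ala243Thr": (727, "G", "A"),
}

#: The 2-base insertion after reference position 67 defining the spotting allele.
INSERTION_POS = 67
INSERTION_SEQ = "CC"

#: Allowed defining-variant sets per allele (substitution names; "insCC" for
#: the insertion). 0201 may be recorded with or without Val95Met.
ALLELE_DEFINITIONS: dict[str, list[frozenset[str]]] = {
    "0101": [frozenset()],
    "0501": [frozenset({"insCC", "Asp124Asn"})],
    "0301": [frozenset({"Asp124Asn"})],
    "0201": [frozenset({"Val95Met", "Leu102Pro"}), frozenset({"Leu102Pro"})],
    "0401": [frozenset({"Ala164Val", "Ala243Thr"})],
}

ALLELE_ORIGIN = {
    "0101": "wild-type", "0102": "wild-type",
    "0201": "Asian",
    "0301": "European", "0401": "European", "0501": "European",
    "novel": "unknown",
}

_DEFINING_SITES = sorted({pos for pos, _, _ in SUBSTITUTIONS.values()} | {INSERTION_POS, INSERTION_POS + 1})


def synthetic_reference_cds(n_codons: int = 321, seed: int = 20170203) -> str:
    """Deterministic synthetic stand-in for the pig MC1R coding sequence.

    Synthetic: this is not the GenBank MC1R sequence; it is a fixed random
    coding sequence engineered so that the reference codons at the positions
    of the defining variants carry the wild-type residues (Val95, Leu102,
    Asp124, Ala164, Ala243), which is all the typing logic depends on.
    """
    rng = np.random.default_rng(seed)
    codons = [c1 + c2 + c3 for c1 in "ACGT" for c2 in "ACGT" for c3 in "ACGT"]
    safe = [c for c in codons if c not in ("TAA", "TAG", "TGA", "ATG")]
    seq = ["ATG"]
    seq += [safe[i] for i in rng.integers(0, len(safe), size=n_codons - 2)]
    seq.append("TGA")
    cds = list("".join(seq))
    # codons 22-23 flank the nt67 insertion site; they are pinned to bases
    # other than C so an inserted CC cannot be shifted by the aligner
    fixed = {22: "GAT", 23: "TGG", 95: "GTG", 102: "CTG", 124: "GAC", 164: "GCC", 243: "GCG"}
    for codon_no, codon in fixed.items():
        cds[(codon_no - 1) * 3 : codon_no * 3] = list(codon)
    return "".join(cds)


@dataclass(frozen=True)
class Mc1rVariant:
    """A substitution or insertion relative to the reference coding sequence."""

    position: int                 # 1-based on the reference CDS
    kind: str                     # "substitution" | "insertion"
    ref: str
    alt: str
    consequence: str | None = None  # e.g. "Leu102Pro"; None when frameshifted

    def __str__(self) -> str:
        if self.kind == "insertion":
            return f"nt{self.position}ins{self.alt}"
        return self.consequence or f"nt{self.position}{self.ref}>{self.alt}"


@dataclass
class Mc1rAlleleCall:
    code: str                     # 0101..0501 or "novel"
    origin: str                   # European | Asian | wild-type | unknown
    variants: tuple[Mc1rVariant, ...] = ()
    completeness: str = "full"    # full | partial


@dataclass
class CoatColourPrediction:
    phenotype: str                # black | wild-type | spotted | red | indeterminate
    rule: str


def apply_allele(reference_cds: str, code: str) -> str:
    """Apply an allele's defining mutations to the reference coding sequence."""
    if code in ("0101", "0102"):
        return reference_cds
    defs = ALLELE_DEFINITIONS.get(code)
    if defs is None:
        raise ValueError(f"unknown MC1R allele code: {code}")
    names = defs[0]
    seq = list(reference_cds)
    for name in sorted(names - {"insCC"}, key=lambda n: SUBSTITUTIONS[n][0]):
        pos, ref, alt = SUBSTITUTIONS[name]
        if seq[pos - 1] != ref:
            raise ValueError(f"reference lacks {ref} at position {pos}")
        seq[pos - 1] = alt
    out = "".join(seq)
    if "insCC" in names:
        out = out[:INSERTION_POS] + INSERTION_SEQ + out[INSERTION_POS:]
    return out


def _build_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -8
    aligner.extend_gap_score = -2
    # fragments are allowed: end gaps on either molecule are free
    aligner.end_gap_score = 0
    return aligner


def call_variants(
    sample_seq: str, reference_cds: str, max_mismatch_density: float = 0.10
) -> tuple[list[Mc1rVariant], set[int]]:
    """Call substitutions and insertions of a sample against the reference.

    Returns the variants plus the set of covered reference positions
    (1-based); positions outside the alignment are no-calls. A mismatch
    density above ``max_mismatch_density`` over the aligned columns raises,
    since the sequence is then unlikely to be the targeted locus.
    """
    sample = sample_seq.upper()
    ref = reference_cds.upper()
    alignment = _build_aligner().align(ref, sample)[0]
    t_blocks, q_blocks = alignment.aligned
    variants: list[Mc1rVariant] = []
    covered: set[int] = set()
    n_cols = 0
    n_mismatch = 0
    for k, ((ts, te), (qs, qe)) in enumerate(zip(t_blocks, q_blocks)):
        for off in range(te - ts):
            r, s = ref[ts + off], sample[qs + off]
            covered.add(ts + off + 1)
            n_cols += 1
            if r != s and s in "ACGT":
                n_mismatch += 1
                pos = ts + off + 1
                variants.append(
                    Mc1rVariant(pos, "substitution", r, s, _consequence(ref, pos, s))
                )
        if k + 1 < len(t_blocks):
            nts, _ = t_blocks[k + 1]
            nqs, _ = q_blocks[k + 1]
            if nts == te and nqs > qe:        # insertion in the sample
                variants.append(
                    Mc1rVariant(te, "insertion", "", sample[qe:nqs], None)
                )
            # a target gap (deletion) leaves those reference positions uncovered
    if n_cols == 0:
        raise ValueError("sample does not align to the reference")
    if n_mismatch / n_cols > max_mismatch_density:
        raise ValueError(
            f"mismatch density {n_mismatch / n_cols:.2f} exceeds "
            f"{max_mismatch_density:.2f}; wrong locus?"
        )
    return variants, covered


def _consequence(ref: str, pos: int, alt: str) -> str | None:
    codon_no = (pos - 1) // 3 + 1
    start = (codon_no - 1) * 3
    codon = ref[start : start + 3]
    if len(codon) < 3:
        return None
    offset = (pos - 1) % 3
    alt_codon = codon[:offset] + alt + codon[offset + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    return f"{AA3.get(aa_ref, 'Xaa')}{codon_no}{AA3.get(aa_alt, 'Xaa')}"


def _variant_names(variants: list[Mc1rVariant]) -> set[str]:
    names: set[str] = set()
    for v in variants:
        if (
            v.kind == "insertion"
            and abs(v.position - INSERTION_POS) <= 2
            and v.alt == INSERTION_SEQ
        ):
            names.add("insCC")
        elif v.consequence in SUBSTITUTIONS:
            pos, ref, alt = SUBSTITUTIONS[v.consequence]
            if v.position == pos and v.ref == ref and v.alt == alt:
                names.add(v.consequence)
            else:
                names.add(str(v))
        else:
            names.add(str(v))
    return names


def classify_allele(
    variants: list[Mc1rVariant], covered_sites: set[int] | None = None
) -> Mc1rAlleleCall:
    """Classify one phased allele from its called variants.

    Decision order: nt67insCC -> 0501; else Asp124Asn -> 0301; else Leu102Pro
    (with or without Val95Met) -> 0201; else Ala164Val+Ala243Thr -> 0401; else
    no defining variants -> wild type (0101/0102 are not separable). Any other
    combination — including contradictions such as insCC together with the red
    allele's substitutions — is reported as "novel". A defining site outside
    ``covered_sites`` marks the call as partial.
    """
    names = _variant_names(variants)
    completeness = "full"
    if covered_sites is not None and any(p not in covered_sites for p in _DEFINING_SITES):
        completeness = "partial"

    code = "novel"
    if "insCC" in names:
        code = "0501"
    elif "Asp124Asn" in names:
        code = "0301"
    elif "Leu102Pro" in names:
        code = "0201"
    elif {"Ala164Val", "Ala243Thr"} <= names:
        code = "0401"
    elif not names:
        code = "0101"
    if code != "novel" and not any(names == d for d in ALLELE_DEFINITIONS[code]):
        warnings.warn(
            f"variant set {sorted(names)} is not a defined haplotype; calling novel",
            stacklevel=2,
        )
        code = "novel"

    origin = ALLELE_ORIGIN[code]
    if completeness == "partial":
        candidates = [
            c
            for c, defs in ALLELE_DEFINITIONS.items()
            if any(_consistent(names, d, covered_sites or set()) for d in defs)
        ]
        origins = {ALLELE_ORIGIN[c] for c in candidates}
        origin = origins.pop() if len(origins) == 1 else "unknown"
    return Mc1rAlleleCall(code, origin, tuple(variants), completeness)


def _consistent(names: set[str], definition: frozenset[str], covered: set[int]) -> bool:
    """Could this allele explain the observed variants given the covered sites?"""
    if not names <= definition:
        return False
    for missing in definition - names:
        if missing == "insCC":
            sites = {INSERTION_POS, INSERTION_POS + 1}
        else:
            sites = {SUBSTITUTIONS[missing][0]}
        if sites <= covered:
            return False                      # covered but variant absent
    return True


def predict_coat_colour(allele_a: str, allele_b: str) -> CoatColourPrediction:
    """Coat colour from a diplotype by the dominance hierarchy.

    Dominant black (0201 or 0301) masks everything; otherwise a wild-type
    allele gives the wild-type (agouti-like) coat; otherwise spotting (0501)
    is expressed; two recessive red alleles (0401) give red; any remaining
    combination involves a novel allele and is indeterminate.
    """
    pair = {allele_a, allele_b}
    wild = {"0101", "0102"}
    if pair & {"0201", "0301"}:
        return CoatColourPrediction("black", "dominant black allele present")
    if pair & wild:
        return CoatColourPrediction("wild-type", "wild-type allele present")
    if "0501" in pair:
        return CoatColourPrediction("spotted", "spotting allele expressed")
    if pair == {"0401"}:
        return CoatColourPrediction("red", "homozygous recessive red")
    return CoatColourPrediction("indeterminate", "novel allele in diplotype")


def enumerate_diplotypes(names_unphased: set[str]) -> list[tuple[str, str]]:
    """Allele pairs consistent with an unphased set of observed variants.

    Sanger-style sequencing yields per-site genotypes without phase; this
    enumerates unordered pairs of defined alleles whose combined defining
    variants equal the observed set. The unique explanation is returned when
    one exists, otherwise all consistent pairs.
    """
    codes = list(ALLELE_DEFINITIONS)
    pairs = []
    for i, a in enumerate(codes):
        for b in codes[i:]:
            for da in ALLELE_DEFINITIONS[a]:
                for db in ALLELE_DEFINITIONS[b]:
                    if da | db == names_unphased:
                        pairs.append((a, b))
                        break
                else:
                    continue
                break
    return pairs


class Mc1rTyper(BaseEstimator):
    """Classify MC1R allele sequences and predict coat colour per animal.

    Parameters
    ----------
    reference_cds : str or None
        Reference coding sequence; ``None`` uses the synthetic reference.
    max_mismatch_density : float
        Alignment mismatch density above which a sequence is rejected.
    """

    def __init__(self, reference_cds: str | None = None, max_mismatch_density: float = 0.10):
        self.reference_cds = reference_cds
        self.max_mismatch_density = max_mismatch_density

    def fit(self, X=None, y=None):
        self.reference_ = self.reference_cds or synthetic_reference_cds()
        return self

    def call(self, sequence: str) -> Mc1rAlleleCall:
        if not hasattr(self, "reference_"):
            self.fit()
        variants, covered = call_variants(
            sequence, self.reference_, self.max_mismatch_density
        )
        return classify_allele(variants, covered)

    def predict(self, diplotypes: dict[str, tuple[str, str]]) -> pd.DataFrame:
        """Type ``{animal: (allele_seq_a, allele_seq_b)}`` into a call table."""
        rows = []
        for animal, (seq_a, seq_b) in diplotypes.items():
            a, b = self.call(seq_a), self.call(seq_b)
            colour = predict_coat_colour(a.code, b.code)
            rows.append(
                {
                    "animal": animal,
                    "allele1": a.code, "allele2": b.code,
                    "origin1": a.origin, "origin2": b.origin,
                    "completeness1": a.completeness, "completeness2": b.completeness,
                    "predicted_colour": colour.phenotype,
                    "rule": colour.rule,
                }
            )
        return pd.DataFrame(rows)
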