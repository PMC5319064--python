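"""Aligned nucleotide sequence container and primer trimming.

Sequences are stored as equal-length uppercase strings over the nucleotide
alphabet plus IUPAC ambiguity codes and the gap character ``-``. FASTA I/O
goes through Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide ambiguity expansions (uppercase).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity support."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_match(primer_base: str, seq_base: str) -> bool:
    """True if an ambiguity-coded primer base is compatible with a sequence base."""
    p = IUPAC.get(primer_base.upper())
    s = IUPAC.get(seq_base.upper())
    if p is None or s is None:
        return False
    return bool(set(p) & set(s))


@dataclass
class SeqAlignment:
    """Equal-length nucleotide sequences keyed by unique sample ids."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sample ids must be unique")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences are not aligned (lengths {sorted(lengths)})")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.sequences))

    def subset(self, ids: Iterable[str]) -> "SeqAlignment":
        wanted = list(ids)
        lookup = dict(zip(self.ids, self.sequences))
        return SeqAlignment(wanted, [lookup[i] for i in wanted])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SeqAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s), id=i, description="") for i, s in zip(self.ids, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class TrimResult:
    """Trimmed sequences plus per-sample flags for missing primer matches."""

    alignment: SeqAlignment
    unmatched: list[str] = field(default_factory=list)


def _match_at(seq: str, primer: str, start: int) -> bool:
    if start < 0 or start + len(primer) > len(seq):
        return False
    return all(iupac_match(p, s) for p, s in zip(primer, seq[start : start + len(primer)]))


def _find_primer(seq: str, primer: str, from_end: bool) -> int:
    """Locate a primer near one terminus; returns start index or -1.

    Gap columns are ignored for matching by scanning over the ungapped string
    only when the sequence has no gaps; with gaps we fall back to a direct scan.
    """
    n, m = len(seq), len(primer)
    if m > n:
        return -1
    positions: Sequence[int]
    if from_end:
        positions = range(n - m, max(-1, n - m - 30) if n - m - 30 > -1 else -1, -1)
    else:
        positions = range(0, min(31, n - m + 1))
    for start in positions:
        if _match_at(seq, primer, start):
            return start
    return -1


def trim_primers(aln: SeqAlignment, fwd_primer: str, rev_primer: str) -> TrimResult:
    """Remove amplification primer sequences from both termini.

    ``fwd_primer`` is matched near the 5' end as given; ``rev_primer`` is given
    5'→3' on the opposite strand, so its reverse complement is matched near the
    3' end. IUPAC ambiguity codes in the primers match any compatible base.
    Sequences where either primer is not found (or the primer is longer than
    the sequence) are returned unmodified and listed in ``unmatched``.

    Trimming is per-sequence; if trimmed sequences end up with unequal lengths
    the result is still returned (as a ragged set re-wrapped only if equal).
    """
    fwd = fwd_primer.upper()
    rev_rc = reverse_complement(rev_primer)
    out_ids, out_seqs, unmatched = [], [], []
    for sid, seq in aln:
        f = _find_primer(seq, fwd, from_end=False)
        r = _find_primer(seq, rev_rc, from_end=True)
        if f < 0 or r < 0 or r <= f + len(fwd):
            unmatched.append(sid)
            out_ids.append(sid)
            out_seqs.append(seq)
        else:
            out_ids.append(sid)
            out_seqs.append(seq[f + len(fwd) : r])
    lengths = {len(s) for s in out_seqs}
    if len(lengths) == 1:
        return TrimResult(SeqAlignment(out_ids, out_seqs), unmatched)
    # ragged after trimming: pad right with gaps to keep the container contract
    width = max(lengths)
    padded = [s + "-" * (width - len(s)) for s in out_seqs]
    return TrimResult(SeqAlignment(out_ids, padded), unmatched)
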