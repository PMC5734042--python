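"""Nucleotide/protein sequence types, genetic code, ORF scanning and FASTA I/O.

Coordinate conventions used throughout the package:

* user-facing coordinates are 1-based and inclusive;
* internally everything is 0-based, half-open;
* positions upstream of an annotated start codon are negative, with -1 the
  base immediately 5' of the A of ATG.  There is no position 0.

Only the standard nuclear genetic code is supported (the yeast genes this
package was written for are intronless nuclear genes), start codons are ATG
by default, and the nucleotide alphabet is {A, C, G, T, N}.  Codons that
contain an N translate to 'X'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base codes: A=0 C=1 G=2 T=3, N=4
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _BASE_CODE[ord(_b)] = _i

_STANDARD_CODE = {}


def _build_code() -> None:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    _STANDARD_CODE.update(table.forward_table)
    for stop in table.stop_codons:
        _STANDARD_CODE[stop] = "*"


_build_code()

# codon value -> amino acid, codon value = 16*a + 4*b + c; 64 = "contains N"
CODON_AA = np.empty(65, dtype="<U1")
for _a, _b1 in enumerate("ACGT"):
    for _b, _b2 in enumerate("ACGT"):
        for _c, _b3 in enumerate("ACGT"):
            CODON_AA[16 * _a + 4 * _b + _c] = _STANDARD_CODE[_b1 + _b2 + _b3]
CODON_AA[64] = "X"

STOP_CODON_VALUES = frozenset(
    int(i) for i in range(64) if CODON_AA[i] == "*"
)
ATG_VALUE = 16 * 0 + 4 * 3 + 2  # A, T, G
_STOP_VALS = np.array(sorted(STOP_CODON_VALUES), dtype=np.int64)


class AlphabetError(ValueError):
    """A residue outside the supported alphabet was encountered."""


class FastaFormatError(ValueError):
    """Malformed or empty FASTA input."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An uppercase DNA sequence over {A, C, G, T, N}."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        res = self.residues.upper()
        bad = set(res) - NT_ALPHABET
        if bad:
            raise AlphabetError(
                f"{self.id!r}: non-IUPAC characters {sorted(bad)} "
                "(only A/C/G/T/N supported)"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def gc_fraction(self) -> float:
        if not self.residues:
            return 0.0
        gc = self.residues.count("G") + self.residues.count("C")
        return gc / len(self.residues)


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence; '*' marks a translated stop, 'X' unknown."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        res = self.residues.upper()
        bad = set(res) - AA_ALPHABET
        if bad:
            raise AlphabetError(f"{self.id!r}: unexpected residues {sorted(bad)}")
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_mature(self) -> bool:
        """True when no internal stop is present (a trailing '*' is allowed)."""
        return "*" not in self.residues[:-1]

    def without_stop(self) -> "ProteinSequence":
        if self.residues.endswith("*"):
            return ProteinSequence(self.id, self.residues[:-1], self.description)
        return self


@dataclass(frozen=True)
class OrfInterval:
    """Start codon through stop codon, 1-based inclusive, on one strand."""

    start: int
    end: int
    strand: str = "+"
    frame: int = 0

    def __post_init__(self) -> None:
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def n_nt(self) -> int:
        return self.end - self.start + 1

    @property
    def n_codons(self) -> int:
        return self.n_nt // 3


@dataclass(frozen=True)
class GeneLocus:
    """A candidate gene region: an annotated CDS inside a larger context.

    ``cds_start``/``cds_end`` are 1-based inclusive positions of the
    annotated ORF within ``context``.  The annotated ORF is *not* required
    to be a multiple of 3 nor to end at a stop codon -- annotations of
    pseudogenized loci are frequently broken, and repairing them is the
    point of this package.
    """

    label: str
    context: NucleotideSequence
    cds_start: int
    cds_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.cds_start <= self.cds_end <= len(self.context)):
            raise ValueError(
                f"{self.label}: CDS bounds {self.cds_start}..{self.cds_end} "
                f"outside context of length {len(self.context)}"
            )
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    def forward(self) -> "GeneLocus":
        """Return the locus normalized to CDS-forward (+) orientation."""
        if self.strand == "+":
            return self
        n = len(self.context)
        rc = reverse_complement(self.context)
        return GeneLocus(
            label=self.label,
            context=rc,
            cds_start=n - self.cds_end + 1,
            cds_end=n - self.cds_start + 1,
            strand="+",
        )

    # -- coordinate conversions (locus coordinates: +1 = A of annotated ATG,
    #    -1 = base immediately 5' of it, no 0) --

    def to_index(self, pos: int) -> int:
        """Locus coordinate -> 0-based index into the context."""
        if pos == 0:
            raise ValueError("there is no position 0")
        if pos > 0:
            return self.cds_start - 1 + pos - 1
        return self.cds_start - 1 + pos

    def to_position(self, index: int) -> int:
        """0-based context index -> locus coordinate (negative upstream)."""
        off = index - (self.cds_start - 1)
        return off + 1 if off >= 0 else off

    @property
    def cds(self) -> NucleotideSequence:
        return NucleotideSequence(
            self.label,
            self.context.residues[self.cds_start - 1 : self.cds_end],
        )


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Reverse complement; complement of N is N. Involution by construction."""
    return NucleotideSequence(
        seq.id, seq.residues.translate(_COMPLEMENT)[::-1], seq.description
    )


def translate(dna: NucleotideSequence | str, offset: int = 0) -> ProteinSequence:
    """Translate in a single frame; the trailing partial codon is dropped.

    Stops render as '*', codons containing N as 'X'.
    """
    if offset not in (0, 1, 2):
        raise ValueError("offset must be 0, 1 or 2")
    if isinstance(dna, str):
        dna = NucleotideSequence("seq", dna)
    res = dna.residues
    aa = []
    for i in range(offset, len(res) - 2, 3):
        codon = res[i : i + 3]
        aa.append("X" if "N" in codon else _STANDARD_CODE[codon])
    return ProteinSequence(dna.id, "".join(aa), dna.description)


def encode(residues: str) -> np.ndarray:
    """Encode residues as uint8 codes (A=0 C=1 G=2 T=3 N=4)."""
    arr = _BASE_CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise AlphabetError("non-IUPAC character in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def codon_values(codes: np.ndarray, frame: int) -> np.ndarray:
    """Codon values (0..63; 64 where a codon contains N) for one frame."""
    n = (len(codes) - frame) // 3
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    c = codes[frame : frame + 3 * n].reshape(n, 3).astype(np.int64)
    vals = 16 * c[:, 0] + 4 * c[:, 1] + c[:, 2]
    vals[(c >= 4).any(axis=1)] = 64
    return vals


def translate_values(vals: np.ndarray) -> str:
    return "".join(CODON_AA[vals])


def scan_orfs(
    dna: NucleotideSequence,
    min_aa: int = 1,
    require_atg: bool = True,
    both_strands: bool = True,
) -> list[OrfInterval]:
    """Scan for ORFs: an ATG paired with its next in-frame stop codon.

    Every qualifying (start, stop) pair is returned; an ORF must terminate
    at a stop codon inside the sequence.  ``min_aa`` counts residues before
    the stop.  Coordinates are 1-based inclusive on the forward strand; for
    '-' strand hits the interval still refers to forward coordinates and the
    ORF reads right-to-left on the reverse complement.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    out: list[OrfInterval] = []
    strands = [("+", dna)]
    if both_strands:
        strands.append(("-", reverse_complement(dna)))
    n = len(dna)
    for strand, seq in strands:
        codes = encode(seq.residues)
        for frame in range(3):
            vals = codon_values(codes, frame)
            stop_idx = np.flatnonzero(np.isin(vals, _STOP_VALS))
            if require_atg:
                start_idx = np.flatnonzero(vals == ATG_VALUE)
            else:
                start_idx = np.arange(len(vals))
            for a in start_idx:
                j = np.searchsorted(stop_idx, a)
                if j >= len(stop_idx):
                    continue
                s = stop_idx[j]
                if s - a < min_aa:
                    continue
                lo = frame + 3 * int(a)
                hi = frame + 3 * int(s) + 3
                if strand == "+":
                    out.append(OrfInterval(lo + 1, hi, "+", frame))
                else:
                    out.append(OrfInterval(n - hi + 1, n - lo, "-", frame))
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a multi-record FASTA; residues are normalized to uppercase.

    Duplicate ids trigger a logged warning but both records are kept.
    """
    return _read(path, NucleotideSequence)


def read_fasta_protein(path: str | Path) -> list[ProteinSequence]:
    return _read(path, ProteinSequence)


def _read(path, cls):
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FastaFormatError(f"empty or missing FASTA file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            logger.warning("duplicate FASTA id %r in %s (kept)", rec.id, path)
        seen.add(rec.id)
        out.append(cls(rec.id, str(rec.seq), rec.description[len(rec.id) :].strip()))
    return out


def write_fasta(
    seqs: Iterable[NucleotideSequence | ProteinSequence],
    path: str | Path,
    wrap: int = 60,
) -> None:
    """Write records wrapped at ``wrap`` columns (default 60)."""
    from Bio.SeqIO.FastaIO import FastaWriter

    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=wrap or None).write_file(records)


# ---------------------------------------------------------------------------
# Locus annotation sidecar (TSV: label, fasta_id, cds_start, cds_end, strand)


def read_loci(fasta_path: str | Path, annot_path: str | Path) -> list[GeneLocus]:
    """Assemble GeneLocus objects from a FASTA plus its TSV annotation sidecar."""
    import pandas as pd

    seqs = {s.id: s for s in read_fasta(fasta_path)}
    annot = pd.read_csv(annot_path, sep="\t", dtype={"label": str, "fasta_id": str})
    required = {"label", "fasta_id", "cds_start", "cds_end", "strand"}
    missing = required - set(annot.columns)
    if missing:
        raise FastaFormatError(f"annotation TSV missing columns: {sorted(missing)}")
    loci = []
    for row in annot.itertuples():
        if row.fasta_id not in seqs:
            raise FastaFormatError(f"annotation refers to unknown record {row.fasta_id!r}")
        loci.append(
            GeneLocus(
                label=row.label,
                context=seqs[row.fasta_id],
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                strand=row.strand,
            )
        )
    return loci


def write_loci(loci: Iterable[GeneLocus], fasta_path: str | Path, annot_path: str | Path) -> None:
    import pandas as pd

    loci = list(loci)
    write_fasta([l.context for l in loci], fasta_path)
    pd.DataFrame(
        {
            "label": [l.label for l in loci],
            "fasta_id": [l.context.id for l in loci],
            "cds_start": [l.cds_start for l in loci],
            "cds_end": [l.cds_end for l in loci],
            "strand": [l.strand for l in loci],
        }
    ).to_csv(annot_path, sep="\t", index=False)
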