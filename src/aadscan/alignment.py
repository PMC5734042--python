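"""Global pairwise alignment and percent identity/similarity statistics.

The dynamic programming itself is Biopython's ``PairwiseAligner`` (affine
gaps, end gaps penalized so alignments are truly end-to-end).  This module
pins the scoring conventions used throughout the package and derives the
column statistics that the pseudogene criteria and the family survey need:

* percent identity  -- identical columns / all columns (gap columns count
  in the denominator);
* percent similarity -- protein columns with a positive substitution-matrix
  score / all columns.  For nucleotides "similarity" is identity.

A gap of length k costs ``gap_open + k * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

from .seq_core import NucleotideSequence, ProteinSequence

DEFAULT_NT = dict(match=2.0, mismatch=-3.0, gap_open=5.0, gap_extend=2.0)
DEFAULT_AA = dict(matrix="BLOSUM62", gap_open=11.0, gap_extend=1.0)


@dataclass(frozen=True)
class ScoringScheme:
    """Scoring parameters for one alphabet; gap penalties are positive costs."""

    mode: str = "nucleotide"  # or "protein"
    match: float = DEFAULT_NT["match"]
    mismatch: float = DEFAULT_NT["mismatch"]
    matrix: str = DEFAULT_AA["matrix"]
    gap_open: float = DEFAULT_NT["gap_open"]
    gap_extend: float = DEFAULT_NT["gap_extend"]

    def __post_init__(self) -> None:
        if self.mode not in ("nucleotide", "protein"):
            raise ValueError("mode must be 'nucleotide' or 'protein'")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")

    @staticmethod
    def nucleotide(**kw) -> "ScoringScheme":
        params = {**DEFAULT_NT, **kw}
        return ScoringScheme(mode="nucleotide", **params)

    @staticmethod
    def protein(**kw) -> "ScoringScheme":
        params = {**DEFAULT_AA, **kw}
        return ScoringScheme(
            mode="protein",
            matrix=params["matrix"],
            gap_open=params["gap_open"],
            gap_extend=params["gap_extend"],
        )

    def describe(self) -> str:
        if self.mode == "nucleotide":
            return (
                f"nt match {self.match:+g}/mismatch {self.mismatch:+g}, "
                f"gap {self.gap_open:g}+{self.gap_extend:g}k, end gaps penalized"
            )
        return (
            f"protein {self.matrix}, gap {self.gap_open:g}+{self.gap_extend:g}k, "
            "end gaps penalized"
        )


@dataclass(frozen=True)
class Alignment:
    """A global pairwise alignment: equal-length gapped strings plus score."""

    a: str
    b: str
    score: float
    scheme: ScoringScheme

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("aligned strings must have equal length")
        if any(x == "-" and y == "-" for x, y in zip(self.a, self.b)):
            raise ValueError("gap/gap column in alignment")

    def __len__(self) -> int:
        return len(self.a)

    @property
    def ungapped_a(self) -> str:
        return self.a.replace("-", "")

    @property
    def ungapped_b(self) -> str:
        return self.b.replace("-", "")


@lru_cache(maxsize=32)
def _aligner(scheme: ScoringScheme) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "global"
    if scheme.mode == "nucleotide":
        al.match_score = scheme.match
        al.mismatch_score = scheme.mismatch
    else:
        al.substitution_matrix = substitution_matrices.load(scheme.matrix)
    # Biopython charges open_gap_score for the first gap base; the package
    # convention is open + k*extend, hence the -(open+extend) first base.
    al.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    al.extend_gap_score = -scheme.gap_extend
    return al


@lru_cache(maxsize=8)
def _matrix(name: str):
    return substitution_matrices.load(name)


def _residues(seq) -> str:
    if isinstance(seq, (NucleotideSequence, ProteinSequence)):
        return seq.residues
    return str(seq).upper()


def global_align(a, b, scheme: ScoringScheme | None = None) -> Alignment:
    """Optimal end-to-end affine-gap alignment with deterministic traceback.

    Among co-optimal alignments Biopython's first traceback is returned; it
    is deterministic for fixed inputs and scheme.
    """
    ra, rb = _residues(a), _residues(b)
    if not ra or not rb:
        raise ValueError("cannot align empty sequences")
    if scheme is None:
        is_nt = set(ra) | set(rb) <= set("ACGTN")
        scheme = ScoringScheme.nucleotide() if is_nt else ScoringScheme.protein()
    if scheme.mode == "nucleotide" and not (set(ra) | set(rb) <= set("ACGTN")):
        raise ValueError("non-nucleotide residues under a nucleotide scheme")
    aln = _aligner(scheme).align(ra, rb)
    best = aln[0]
    return Alignment(a=str(best[0]), b=str(best[1]), score=aln.score, scheme=scheme)


def percent_identity(al: Alignment) -> float:
    """100 x identical columns / aligned columns (gaps in the denominator)."""
    if len(al) == 0:
        raise ValueError("zero-length alignment")
    ident = sum(x == y and x != "-" for x, y in zip(al.a, al.b))
    return 100.0 * ident / len(al)


def percent_similarity(al: Alignment) -> float:
    """100 x columns with a positive substitution score / aligned columns.

    Protein alignments only; nucleotide "similarity" is plain identity and
    should go through :func:`percent_identity`.
    """
    if al.scheme.mode != "protein":
        raise ValueError("percent_similarity requires a protein alignment")
    if len(al) == 0:
        raise ValueError("zero-length alignment")
    mat = _matrix(al.scheme.matrix)
    similar = 0
    for x, y in zip(al.a, al.b):
        if x == "-" or y == "-":
            continue
        if mat[x, y] > 0:
            similar += 1
    return 100.0 * similar / len(al)


def consensus_fraction(
    a: NucleotideSequence | str,
    b: NucleotideSequence | str,
    scheme: ScoringScheme | None = None,
) -> float:
    """Nucleotide percent identity of the global alignment of ``a`` and ``b``."""
    if scheme is None:
        scheme = ScoringScheme.nucleotide()
    return percent_identity(global_align(a, b, scheme))


def protein_similarity(
    a: ProteinSequence | str,
    b: ProteinSequence | str,
    scheme: ScoringScheme | None = None,
) -> float:
    """Convenience: percent similarity of the global protein alignment."""
    if scheme is None:
        scheme = ScoringScheme.protein()
    return percent_similarity(global_align(a, b, scheme))
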