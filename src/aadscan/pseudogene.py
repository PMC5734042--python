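"""Pseudogene lesion inference: minimal single-base repairs of broken ORFs.

The central idea: a pseudogenized gene copy often differs from its ancestral
full-length ORF by a *single* base -- a frameshifting indel, a nonsense
substitution, or a critical missense change.  This module enumerates every
single-base edit of a locus (substitution, insertion, deletion), asks
whether the edited sequence contains an ORF that resembles a full-length
reference protein, and classifies the locus by the kind of repair that
resurrects it:

* ``intact``             -- the annotated ORF already passes;
* ``missense_catalytic`` -- full length, but a catalytic residue is wrong;
* ``frameshift_split``   -- best repair is a single-base indel;
* ``nonsense_truncated`` -- best repair removes a premature stop;
* ``partial_deletion``   -- too little of the reference aligns at all;
* ``absent``             -- essentially nothing aligns.

Acceptance of a repair follows four criteria: (i) nucleotide consensus with
the reference CDS >= 80%, (ii) exactly one edit, (iii) reconstructed length
within 10% of the reference, (iv) amino-acid similarity >= 80%.  All
thresholds are configurable through :class:`Thresholds`.

Indel coordinates are canonicalized to the rightmost equivalent position of
a homopolymer run (inserting G before or after an existing G yields the same
sequence), so reported junctions are stable and comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from . import alignment as aln
from .seq_core import (
    ATG_VALUE,
    CODON_AA,
    GeneLocus,
    NucleotideSequence,
    OrfInterval,
    ProteinSequence,
    STOP_CODON_VALUES,
    codon_values,
    encode,
    translate,
)

_STOP_VALS = np.array(sorted(STOP_CODON_VALUES), dtype=np.int64)
_BASES = "ACGT"


@dataclass(frozen=True)
class ReferenceGene:
    """The reference enzyme: its protein and (optionally) its CDS.

    The nucleotide-level consensus criterion needs the CDS; operations that
    only rank proteins accept a bare :class:`ProteinSequence` as well.
    """

    protein: ProteinSequence
    cds: Optional[NucleotideSequence] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "protein", self.protein.without_stop())


@dataclass(frozen=True)
class Thresholds:
    """Acceptance thresholds for ancestral-ORF reconstruction."""

    consensus_min: float = 80.0        # criterion (i), percent
    aa_similarity_min: float = 80.0    # criterion (iv), percent
    length_ratio_min: float = 0.9      # criterion (iii) band
    length_ratio_max: float = 1.1
    partial_fraction: float = 0.5      # below this alignable fraction: partial deletion
    absent_fraction: float = 0.2       # below this alignable fraction: absent
    consensus_floor: float = 60.0      # survey "NR" floor, percent
    conserved_similar: bool = False    # catalytic conservation: identical (False) or similar


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class RepairProposal:
    """One single-base edit and the ORF it resurrects.

    ``position`` is a locus coordinate (+1 = A of the annotated ATG, negative
    upstream, no 0).  For insertions the inserted base sits between
    ``position`` and ``position + 1``.  ``reconstructed_orf`` is an interval
    on the *edited* context (1-based inclusive).
    """

    edit_kind: str  # substitution | insertion | deletion
    position: int
    ref_base: str
    alt_base: str
    reconstructed_orf: OrfInterval
    reconstructed_protein: ProteinSequence
    aa_similarity_to_reference: float
    length_ratio_to_reference: float
    aa_identity_to_reference: float = 0.0
    extension_nt: int = 0
    extension_aa: int = 0

    def describe(self) -> str:
        if self.edit_kind == "substitution":
            ed = f"{self.ref_base}{self.position}{self.alt_base}"
        elif self.edit_kind == "insertion":
            ed = f"ins{self.alt_base}@{self.position}/{self.position + 1}"
        else:
            ed = f"del{self.ref_base}@{self.position}"
        return (
            f"{self.edit_kind} {ed} -> {len(self.reconstructed_protein)} aa, "
            f"{self.aa_similarity_to_reference:.1f}% aa similarity"
        )


@dataclass(frozen=True)
class CriterionReport:
    """The four-criterion evidence record behind a classification."""

    c1_consensus_ok: bool
    c2_single_edit_ok: bool
    c3_length_ok: bool
    c4_protein_similarity_ok: bool
    consensus_percent: float
    edit_count: int
    length_ratio: float
    aa_similarity_percent: float

    @property
    def all_ok(self) -> bool:
        return (
            self.c1_consensus_ok
            and self.c2_single_edit_ok
            and self.c3_length_ok
            and self.c4_protein_similarity_ok
        )


@dataclass(frozen=True)
class CatalyticSite:
    reference_position: int
    reference_residue: str
    target_position: Optional[int]
    target_residue: Optional[str]
    conserved: bool


@dataclass(frozen=True)
class CatalyticSiteMap:
    sites: tuple[CatalyticSite, ...]

    @property
    def all_conserved(self) -> bool:
        return all(s.conserved for s in self.sites)

    def missing(self) -> list[CatalyticSite]:
        return [s for s in self.sites if s.target_position is None]


@dataclass
class PseudogeneReport:
    label: str
    status: str
    best_proposal: Optional[RepairProposal] = None
    criteria: Optional[CriterionReport] = None
    catalytic: Optional[CatalyticSiteMap] = None
    upstream_repairs: list[RepairProposal] = field(default_factory=list)
    catalytic_repairs: list[RepairProposal] = field(default_factory=list)
    alignable_fraction: float = float("nan")
    annotated_aa_similarity: float = float("nan")
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def prop(p: Optional[RepairProposal]):
            if p is None:
                return None
            return {
                "edit_kind": p.edit_kind,
                "position": p.position,
                "ref_base": p.ref_base,
                "alt_base": p.alt_base,
                "orf_start": p.reconstructed_orf.start,
                "orf_end": p.reconstructed_orf.end,
                "protein_length": len(p.reconstructed_protein),
                "aa_similarity": p.aa_similarity_to_reference,
                "length_ratio": p.length_ratio_to_reference,
                "extension_nt": p.extension_nt,
                "extension_aa": p.extension_aa,
            }

        d = {
            "label": self.label,
            "status": self.status,
            "best_proposal": prop(self.best_proposal),
            "upstream_repairs": [prop(p) for p in self.upstream_repairs],
            "catalytic_repairs": [prop(p) for p in self.catalytic_repairs],
            "alignable_fraction": self.alignable_fraction,
            "annotated_aa_similarity": self.annotated_aa_similarity,
            "notes": list(self.notes),
        }
        if self.criteria is not None:
            c = self.criteria
            d["criteria"] = {
                "c1_consensus_ok": c.c1_consensus_ok,
                "c2_single_edit_ok": c.c2_single_edit_ok,
                "c3_length_ok": c.c3_length_ok,
                "c4_protein_similarity_ok": c.c4_protein_similarity_ok,
                "consensus_percent": c.consensus_percent,
                "edit_count": c.edit_count,
                "length_ratio": c.length_ratio,
                "aa_similarity_percent": c.aa_similarity_percent,
            }
        else:
            d["criteria"] = None
        if self.catalytic is not None:
            d["catalytic_sites"] = [
                {
                    "reference_position": s.reference_position,
                    "reference_residue": s.reference_residue,
                    "target_position": s.target_position,
                    "target_residue": s.target_residue,
                    "conserved": s.conserved,
                }
                for s in self.catalytic.sites
            ]
        else:
            d["catalytic_sites"] = None
        return d


# ---------------------------------------------------------------------------
# low-level helpers


def _ref_protein(reference) -> ProteinSequence:
    if isinstance(reference, ReferenceGene):
        return reference.protein
    if isinstance(reference, ProteinSequence):
        return reference.without_stop()
    raise TypeError("reference must be a ProteinSequence or ReferenceGene")


def apply_edit(residues: str, kind: str, index: int, alt: str) -> str:
    """Apply one edit to a residue string.

    substitution: replace base at ``index``; deletion: remove base at
    ``index``; insertion: insert ``alt`` *before* ``index``.
    """
    if kind == "substitution":
        return residues[:index] + alt + residues[index + 1 :]
    if kind == "deletion":
        return residues[:index] + residues[index + 1 :]
    if kind == "insertion":
        return residues[:index] + alt + residues[index:]
    raise ValueError(f"unknown edit kind {kind!r}")


def _candidate_orfs(
    codes: np.ndarray,
    overlap: tuple[int, int],
    min_codons: int,
    max_codons: int,
) -> list[tuple[int, int, int]]:
    """(start0, end0_exclusive, aa_len) of forward ORFs overlapping a window.

    ORFs run from an ATG to its next in-frame stop (stop included in the
    interval, excluded from aa_len).  For each stop, every ATG whose ORF
    length lies in [min_codons, max_codons] is reported.
    """
    lo, hi = overlap
    out = []
    for frame in range(3):
        vals = codon_values(codes, frame)
        stop_idx = np.flatnonzero(np.isin(vals, _STOP_VALS))
        atg_idx = np.flatnonzero(vals == ATG_VALUE)
        if len(stop_idx) == 0 or len(atg_idx) == 0:
            continue
        j = np.searchsorted(stop_idx, atg_idx)
        ok = j < len(stop_idx)
        for a, jj in zip(atg_idx[ok], j[ok]):
            s = stop_idx[jj]
            aa_len = int(s - a)
            if not (min_codons <= aa_len <= max_codons):
                continue
            start0 = frame + 3 * int(a)
            end0 = frame + 3 * int(s) + 3
            if start0 < hi and end0 > lo:
                out.append((start0, end0, aa_len))
    return out


def _orf_protein(codes: np.ndarray, start0: int, end0: int) -> str:
    vals = codon_values(codes[start0:end0], 0)
    return "".join(CODON_AA[vals[:-1]])  # drop the stop


_protein_scheme = aln.ScoringScheme.protein()


def _aa_scores(protein: str, ref: str) -> tuple[float, float]:
    """(percent similarity, percent identity) of the global protein alignment."""
    al = aln.global_align(protein, ref, _protein_scheme)
    return aln.percent_similarity(al), aln.percent_identity(al)


def _aa_similarity(protein: str, ref: str) -> float:
    return _aa_scores(protein, ref)[0]


def _best_qualifying(
    codes: np.ndarray,
    overlap: tuple[int, int],
    ref: str,
    thr: Thresholds,
) -> Optional[tuple[int, int, str, float, float]]:
    """Best ORF meeting length band + aa similarity; None when there is none.

    Returns (start0, end0, protein, aa_similarity, aa_identity, length_ratio).
    """
    n_ref = len(ref)
    min_c = max(1, math.ceil(thr.length_ratio_min * n_ref))
    max_c = math.floor(thr.length_ratio_max * n_ref)
    best = None
    for start0, end0, aa_len in _candidate_orfs(codes, overlap, min_c, max_c):
        protein = _orf_protein(codes, start0, end0)
        if "X" in protein:
            continue
        sim, ident = _aa_scores(protein, ref)
        if sim < thr.aa_similarity_min:
            continue
        key = (sim, ident, aa_len, -start0)
        if best is None or key > best[0]:
            best = (key, (start0, end0, protein, sim, ident, aa_len / n_ref))
    return None if best is None else best[1]


def _eval_annotated_orf(codes, s0: int, ref: str, thr: Thresholds):
    """Evaluate the ORF launched at the annotated start codon.

    Returns (start0, end0, protein, sim, ident, ratio, qualifies) or None
    when the annotated start is not an ATG or never reaches a stop.
    """
    n = len(codes)
    if s0 + 3 > n:
        return None
    tri = codes[s0 : s0 + 3]
    if (tri >= 4).any() or 16 * int(tri[0]) + 4 * int(tri[1]) + int(tri[2]) != ATG_VALUE:
        return None
    vals = codon_values(codes[s0:], 0)
    stop_rel = np.flatnonzero(np.isin(vals, _STOP_VALS))
    if len(stop_rel) == 0:
        return None
    end0 = s0 + 3 * (int(stop_rel[0]) + 1)
    protein = _orf_protein(codes, s0, end0)
    if not protein or "X" in protein:
        return None
    sim, ident = _aa_scores(protein, ref)
    ratio = len(protein) / len(ref)
    qualifies = (
        thr.length_ratio_min <= ratio <= thr.length_ratio_max
        and sim >= thr.aa_similarity_min
    )
    return s0, end0, protein, sim, ident, ratio, qualifies


_KIND_ORDER = {"substitution": 0, "insertion": 1, "deletion": 2}


def _rank_key(p: RepairProposal):
    return (
        -p.aa_similarity_to_reference,
        -p.aa_identity_to_reference,
        -p.reconstructed_orf.n_nt,
        abs(p.position),
        _KIND_ORDER[p.edit_kind],
        p.alt_base,
    )


# ---------------------------------------------------------------------------
# operations


def scan_single_edit_repairs(
    locus: GeneLocus,
    reference,
    window: Optional[tuple[int, int]] = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    max_window_flank: int = 1000,
) -> list[RepairProposal]:
    """Enumerate all single-base edits that resurrect a reference-like ORF.

    ``window`` is a pair of locus coordinates (inclusive, negative allowed)
    bounding the edit positions; by default the annotated CDS plus up to
    ``max_window_flank`` nt of flank on each side.  If the unedited locus
    already contains a qualifying ORF the scan returns an empty list --
    there is nothing to repair.

    Substitutions are pruned to those that can matter: ones that create or
    destroy a stop/ATG codon in some frame, or that fall inside an existing
    length-qualifying ORF (only there can similarity move).  Indels always
    shift frame and are always evaluated; their coordinates are
    canonicalized to the rightmost equivalent position.
    """
    locus = locus.forward()
    ref = _ref_protein(reference).residues
    if not ref:
        raise ValueError("reference protein is empty")
    context = locus.context.residues
    n = len(context)
    s0, e0 = locus.cds_start - 1, locus.cds_end  # 0-based half-open
    if window is None:
        w0 = max(0, s0 - max_window_flank)
        w1 = min(n, e0 + max_window_flank)
    else:
        lo, hi = window
        w0 = max(0, locus.to_index(lo))
        w1 = min(n, locus.to_index(hi) + 1)
    if w0 >= w1:
        raise ValueError("empty scan window")

    codes = encode(context)
    thr = thresholds

    # nothing to repair when the annotated ORF itself already qualifies
    ann = _eval_annotated_orf(codes, s0, ref, thr)
    if ann is not None and ann[-1]:
        return []

    # a proposal must strictly improve on the best ORF already present in
    # the unedited context (some other qualifying ORF -- e.g. a large 3'
    # fragment reading through into flank -- may exist without any edit)
    base = _best_qualifying(codes, (s0, e0), ref, thr)
    baseline_key = None if base is None else (base[3], base[4], len(base[2]))

    # length-qualifying unedited ORF intervals,
    # needed for the exactness of the substitution filter
    min_c = max(1, math.ceil(thr.length_ratio_min * len(ref)))
    max_c = math.floor(thr.length_ratio_max * len(ref))
    long_orfs = _candidate_orfs(codes, (s0, e0), min_c, max_c)

    def inside_long_orf(i: int) -> bool:
        return any(a <= i < b for a, b, _ in long_orfs)

    def touches_signal(i: int, new_base: int) -> bool:
        for frame in range(3):
            c = i - ((i - frame) % 3)
            if c < 0 or c + 3 > n:
                continue
            tri = codes[c : c + 3]
            if (tri >= 4).any():
                continue
            old = 16 * int(tri[0]) + 4 * int(tri[1]) + int(tri[2])
            pos_in = i - c
            mult = (16, 4, 1)[pos_in]
            new = old + mult * (new_base - int(tri[pos_in]))
            if (
                old in STOP_CODON_VALUES
                or new in STOP_CODON_VALUES
                or old == ATG_VALUE
                or new == ATG_VALUE
            ):
                return True
        return False

    proposals: list[RepairProposal] = []

    def evaluate(kind: str, index: int, alt: str, edited_codes, overlap):
        best = _best_qualifying(edited_codes, overlap, ref, thr)
        if best is None:
            return
        start0, end0, protein, sim, ident, ratio = best
        if baseline_key is not None and (sim, ident, len(protein)) <= baseline_key:
            return
        if kind == "substitution":
            pos = locus.to_position(index)
            ref_base = context[index]
        elif kind == "deletion":
            pos = locus.to_position(index)
            ref_base, alt = context[index], ""
        else:  # insertion before `index`: 5' neighbour is index-1
            pos = locus.to_position(index - 1) if index > 0 else locus.to_position(0) - 1
            ref_base = ""
        proposals.append(
            RepairProposal(
                edit_kind=kind,
                position=pos,
                ref_base=ref_base,
                alt_base=alt,
                reconstructed_orf=OrfInterval(start0 + 1, end0, "+", start0 % 3),
                reconstructed_protein=ProteinSequence(
                    f"{locus.label}|repaired", protein
                ),
                aa_similarity_to_reference=sim,
                length_ratio_to_reference=ratio,
                aa_identity_to_reference=ident,
            )
        )

    # substitutions
    for i in range(w0, w1):
        cur = int(codes[i])
        if cur >= 4:
            continue
        relevant = inside_long_orf(i)
        for nb in range(4):
            if nb == cur:
                continue
            if not relevant and not touches_signal(i, nb):
                continue
            edited = codes.copy()
            edited[i] = nb
            evaluate("substitution", i, _BASES[nb], edited, (s0, e0))

    # deletions (canonical: skip when the next base is identical and in range)
    for i in range(w0, w1):
        if i + 1 < min(n, w1) and codes[i + 1] == codes[i]:
            continue
        edited = np.delete(codes, i)
        ds = s0 - (1 if i < s0 else 0)
        de = e0 - (1 if i < e0 else 0)
        evaluate("deletion", i, "", edited, (ds, de))

    # insertions before index j, j in [w0, w1]; canonical rightmost
    for j in range(w0, w1 + 1):
        for nb in range(4):
            if j < n and j + 1 <= w1 and codes[j] == nb:
                continue
            edited = np.insert(codes, j, nb)
            is_ = s0 + (1 if j <= s0 else 0)
            ie = e0 + (1 if j < e0 else 0)
            evaluate("insertion", j, _BASES[nb], edited, (is_, ie))

    proposals.sort(key=_rank_key)

    # Protein-level scores can tie exactly (wobble degeneracy lets several
    # distinct edits encode the same protein).  When the reference CDS is
    # known, break ties in the leading group by nucleotide consensus of the
    # reconstructed CDS -- the criterion-(i) measure -- which singles out
    # the edit that restores the ancestral bases.
    ref_cds = reference.cds if isinstance(reference, ReferenceGene) else None
    if ref_cds is not None and len(proposals) > 1:
        p0 = proposals[0]
        head = (
            p0.aa_similarity_to_reference,
            p0.aa_identity_to_reference,
            p0.reconstructed_orf.n_nt,
        )
        k = 1
        while k < len(proposals) and (
            proposals[k].aa_similarity_to_reference,
            proposals[k].aa_identity_to_reference,
            proposals[k].reconstructed_orf.n_nt,
        ) == head:
            k += 1
        if k > 1:
            group = proposals[:k]
            nt_id = {
                id(p): aln.consensus_fraction(apply_repair(locus, p)[0], ref_cds)
                for p in group
            }
            group.sort(
                key=lambda p: (
                    -nt_id[id(p)],
                    abs(p.position),
                    _KIND_ORDER[p.edit_kind],
                    p.alt_base,
                )
            )
            proposals[:k] = group
    return proposals


def scan_upstream_stop_repairs(
    locus: GeneLocus,
    reference,
    max_extension_nt: Optional[int] = None,
) -> list[RepairProposal]:
    """Substitutions in the 5' flank that abolish an in-frame premature stop.

    Looks at codons in frame with the annotated ATG, upstream of it.  A
    returned proposal removes the nearest in-frame stop and extends the ORF
    to an upstream in-frame ATG; positions are negative locus coordinates
    and the extension is reported in nt and aa.
    """
    locus = locus.forward()
    ref = _ref_protein(reference).residues
    context = locus.context.residues
    s0 = locus.cds_start - 1
    if s0 < 3:
        raise ValueError("no 5' flank available")
    if max_extension_nt is None:
        max_extension_nt = s0
    if max_extension_nt < 3:
        raise ValueError("max_extension_nt must be >= 3")
    max_ext = min(max_extension_nt, s0)
    M = max_ext // 3  # upstream in-frame codons within reach

    codes = encode(context)
    # upstream codon m (m = 1 nearest): indices [s0-3m, s0-3m+3)
    cods = [
        16 * int(codes[s0 - 3 * m]) + 4 * int(codes[s0 - 3 * m + 1]) + int(codes[s0 - 3 * m + 2])
        if (codes[s0 - 3 * m : s0 - 3 * m + 3] < 4).all()
        else 64
        for m in range(1, M + 1)
    ]
    stops = [m for m, v in enumerate(cods, start=1) if v in STOP_CODON_VALUES]
    if not stops:
        return []
    m1 = stops[0]
    m2 = stops[1] if len(stops) > 1 else M + 1
    atgs = [m for m, v in enumerate(cods, start=1) if v == ATG_VALUE and m1 < m < m2]

    proposals = []
    c0 = s0 - 3 * m1  # index of the stop codon's first base
    for k in range(3):
        i = c0 + k
        cur = int(codes[i])
        for nb in range(4):
            if nb == cur:
                continue
            tri = [int(codes[c0]), int(codes[c0 + 1]), int(codes[c0 + 2])]
            tri[k] = nb
            newval = 16 * tri[0] + 4 * tri[1] + tri[2]
            if newval in STOP_CODON_VALUES:
                continue
            starts = list(atgs)
            if newval == ATG_VALUE:
                starts.append(m1)
            if not starts:
                continue
            edited = codes.copy()
            edited[i] = nb
            best = None
            for j in starts:
                start0 = s0 - 3 * j
                vals = codon_values(edited[start0:], 0)
                stop_rel = np.flatnonzero(np.isin(vals, _STOP_VALS))
                if len(stop_rel) == 0:
                    continue
                end0 = start0 + 3 * (int(stop_rel[0]) + 1)
                if end0 <= s0:  # never reaches the annotated CDS
                    continue
                protein = _orf_protein(edited, start0, end0)
                sim, ident = _aa_scores(protein, ref)
                key = (sim, ident, len(protein))
                if best is None or key > best[0]:
                    best = (key, (start0, end0, protein, sim, ident, j))
            if best is None:
                continue
            start0, end0, protein, sim, ident, j = best[1]
            proposals.append(
                RepairProposal(
                    edit_kind="substitution",
                    position=locus.to_position(i),
                    ref_base=context[i],
                    alt_base=_BASES[nb],
                    reconstructed_orf=OrfInterval(start0 + 1, end0, "+", start0 % 3),
                    reconstructed_protein=ProteinSequence(
                        f"{locus.label}|extended", protein
                    ),
                    aa_similarity_to_reference=sim,
                    length_ratio_to_reference=len(protein) / len(ref),
                    aa_identity_to_reference=ident,
                    extension_nt=3 * j,
                    extension_aa=j,
                )
            )
    proposals.sort(key=_rank_key)
    return proposals


def map_catalytic_sites(
    reference,
    site_positions: Sequence[int],
    target: ProteinSequence,
    conserved_similar: bool = False,
) -> CatalyticSiteMap:
    """Transfer catalytic-site positions through a global protein alignment.

    A site aligned to a gap in the target maps to MISSING.  Conservation is
    residue identity by default; with ``conserved_similar`` a positive
    substitution-matrix score also counts.
    """
    refp = _ref_protein(reference)
    target = target.without_stop()
    if len(target) == 0:
        raise ValueError("empty target protein")
    for p in site_positions:
        if not (1 <= p <= len(refp)):
            raise ValueError(f"site position {p} outside reference (1..{len(refp)})")
    al = aln.global_align(refp.residues, target.residues, _protein_scheme)
    mat = substitution_matrices.load(_protein_scheme.matrix)
    wanted = sorted(site_positions)
    sites = []
    rpos = tpos = 0
    by_ref: dict[int, tuple[Optional[int], Optional[str]]] = {}
    for x, y in zip(al.a, al.b):
        if x != "-":
            rpos += 1
        if y != "-":
            tpos += 1
        if x != "-" and rpos in wanted:
            by_ref[rpos] = (tpos, y) if y != "-" else (None, None)
    for p in wanted:
        tp, tr = by_ref.get(p, (None, None))
        rres = refp.residues[p - 1]
        if tp is None:
            conserved = False
        elif conserved_similar:
            conserved = tr == rres or mat[rres, tr] > 0
        else:
            conserved = tr == rres
        sites.append(CatalyticSite(p, rres, tp, tr, conserved))
    return CatalyticSiteMap(tuple(sites))


def check_ancestral_criteria(
    locus: GeneLocus,
    proposal: Optional[RepairProposal],
    reference: ReferenceGene,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> CriterionReport:
    """Evaluate the four reconstruction-acceptance criteria for a locus.

    With ``proposal=None`` the annotated ORF itself is judged (edit count 0).
    """
    if not isinstance(reference, ReferenceGene):
        reference = ReferenceGene(protein=_ref_protein(reference))
    thr = thresholds
    if proposal is not None:
        cds, protein = apply_repair(locus, proposal)
        edit_count = 1
    else:
        cds = locus.forward().cds
        protein = translate(cds).without_stop()
        edit_count = 0
    ref = reference.protein.residues
    if reference.cds is not None:
        consensus = aln.consensus_fraction(cds, reference.cds)
    else:
        consensus = float("nan")
    ratio = len(protein) / len(ref)
    if len(protein.residues.replace("*", "")) == 0:
        sim = 0.0
    else:
        sim = _aa_similarity(protein.residues.replace("*", ""), ref)
    return CriterionReport(
        c1_consensus_ok=bool(consensus >= thr.consensus_min),
        c2_single_edit_ok=edit_count <= 1,
        c3_length_ok=thr.length_ratio_min <= ratio <= thr.length_ratio_max,
        c4_protein_similarity_ok=sim >= thr.aa_similarity_min,
        consensus_percent=consensus,
        edit_count=edit_count,
        length_ratio=ratio,
        aa_similarity_percent=sim,
    )


def alignable_fraction(reference, context: NucleotideSequence) -> float:
    """Fraction of reference residues recovered by the best-frame translation.

    An overlap-style protein alignment (end gaps free on both sides) of the
    reference against each forward-frame translation of the context; the
    score is identical residue pairs / reference length, maximized over
    frames.  Near 1 for an intact locus, about the retained fraction for a
    partially deleted one, and close to 0 for unrelated sequence.
    """
    ref = _ref_protein(reference).residues
    best = 0.0
    al = PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load(_protein_scheme.matrix)
    al.open_gap_score = -(_protein_scheme.gap_open + _protein_scheme.gap_extend)
    al.extend_gap_score = -_protein_scheme.gap_extend
    try:  # Biopython >= 1.88 naming
        al.end_insertion_score = 0.0
        al.end_deletion_score = 0.0
    except AttributeError:  # pragma: no cover
        al.target_end_gap_score = 0.0
        al.query_end_gap_score = 0.0
    for frame in range(3):
        t = translate(context, frame).residues
        if not t:
            continue
        res = al.align(ref, t)
        a0, a1 = str(res[0][0]), str(res[0][1])
        ident = sum(x == y and x != "-" for x, y in zip(a0, a1))
        best = max(best, ident / len(ref))
    return best


def propose_catalytic_repairs(
    locus: GeneLocus,
    reference,
    site_positions: Sequence[int],
    orf: OrfInterval,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[RepairProposal]:
    """Single-base substitutions that restore non-conserved catalytic residues.

    For each catalytic site whose target residue differs from the reference,
    every substitution inside the target codon that re-creates the reference
    residue is proposed.  Positions are locus coordinates within the ORF.
    """
    locus = locus.forward()
    refp = _ref_protein(reference)
    context = locus.context.residues
    codes = encode(context)
    start0 = orf.start - 1
    protein = ProteinSequence("t", _orf_protein(codes, start0, orf.end))
    site_map = map_catalytic_sites(refp, site_positions, protein)
    out = []
    for site in site_map.sites:
        if site.conserved or site.target_position is None:
            continue
        c0 = start0 + 3 * (site.target_position - 1)
        for k in range(3):
            i = c0 + k
            cur = int(codes[i])
            for nb in range(4):
                if nb == cur:
                    continue
                tri = [int(codes[c0]), int(codes[c0 + 1]), int(codes[c0 + 2])]
                tri[k] = nb
                val = 16 * tri[0] + 4 * tri[1] + tri[2]
                if val >= 64 or CODON_AA[val] != site.reference_residue:
                    continue
                edited = codes.copy()
                edited[i] = nb
                prot = _orf_protein(edited, start0, orf.end)
                sim, ident = _aa_scores(prot, refp.residues)
                out.append(
                    RepairProposal(
                        edit_kind="substitution",
                        position=locus.to_position(i),
                        ref_base=context[i],
                        alt_base=_BASES[nb],
                        reconstructed_orf=orf,
                        reconstructed_protein=ProteinSequence(
                            f"{locus.label}|catalytic-repair", prot
                        ),
                        aa_similarity_to_reference=sim,
                        length_ratio_to_reference=len(prot) / len(refp),
                        aa_identity_to_reference=ident,
                    )
                )
    out.sort(key=_rank_key)
    return out


def classify_locus(
    locus: GeneLocus,
    reference: ReferenceGene,
    site_positions: Sequence[int] = (),
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> PseudogeneReport:
    """Classify a locus by the decision ladder described in the module docs."""
    if not isinstance(reference, ReferenceGene):
        reference = ReferenceGene(protein=_ref_protein(reference))
    thr = thresholds
    locus = locus.forward()
    ref = reference.protein.residues
    codes = encode(locus.context.residues)
    s0, e0 = locus.cds_start - 1, locus.cds_end
    report = PseudogeneReport(label=locus.label, status="absent")

    # upstream extension evidence is reported regardless of status (the
    # annotated ORF of a locus may be functional even when an upstream
    # lesion hides a longer ancestral form)
    if s0 >= 3:
        try:
            report.upstream_repairs = scan_upstream_stop_repairs(locus, reference)
        except ValueError:
            pass

    ann = _eval_annotated_orf(codes, s0, ref, thr)
    if ann is not None and ann[-1]:
        start0, end0, protein, sim, ident, ratio, _ = ann
        orf = OrfInterval(start0 + 1, end0, "+", start0 % 3)
        report.annotated_aa_similarity = sim
        report.criteria = check_ancestral_criteria(locus, None, reference, thr)
        if site_positions:
            report.catalytic = map_catalytic_sites(
                reference, site_positions, ProteinSequence("t", protein),
                conserved_similar=thr.conserved_similar,
            )
        if report.catalytic is None or report.catalytic.all_conserved:
            report.status = "intact"
        else:
            report.status = "missense_catalytic"
            report.catalytic_repairs = propose_catalytic_repairs(
                locus, reference, site_positions, orf, thr
            )
        report.alignable_fraction = alignable_fraction(reference, locus.context)
        return report

    proposals = scan_single_edit_repairs(locus, reference, thresholds=thr)
    if proposals:
        best = proposals[0]
        report.best_proposal = best
        report.criteria = check_ancestral_criteria(locus, best, reference, thr)
        report.status = (
            "frameshift_split"
            if best.edit_kind in ("insertion", "deletion")
            else "nonsense_truncated"
        )
        _, protein = apply_repair(locus, best)
        if site_positions:
            report.catalytic = map_catalytic_sites(
                reference, site_positions, protein,
                conserved_similar=thr.conserved_similar,
            )
        report.alignable_fraction = alignable_fraction(reference, locus.context)
        return report

    af = alignable_fraction(reference, locus.context)
    report.alignable_fraction = af
    if af < thr.absent_fraction:
        report.status = "absent"
    elif af < thr.partial_fraction:
        report.status = "partial_deletion"
    else:
        report.status = "absent"
        report.notes.append(
            "reference largely alignable but no single-base repair found; "
            "possibly multiple lesions"
        )
    return report


def apply_repair(
    locus: GeneLocus, proposal: RepairProposal
) -> tuple[NucleotideSequence, ProteinSequence]:
    """Apply a proposal to its locus; returns the reconstructed CDS + protein.

    The CDS carries an edit-trail description suitable for FASTA headers.
    """
    locus = locus.forward()
    context = locus.context.residues
    kind = proposal.edit_kind
    if kind == "insertion":
        # inserted between `position` and `position+1`; positions skip 0, so
        # the index right after locus position p is always to_index(p)+1
        # (clamped to the context start for junctions at the very edge)
        pos = proposal.position
        base_idx = locus.cds_start - 1 + (pos - 1 if pos > 0 else pos)
        index = max(0, base_idx + 1)
    else:
        index = locus.to_index(proposal.position)
        if context[index] != proposal.ref_base:
            raise ValueError(
                f"proposal/locus mismatch: expected {proposal.ref_base!r} at "
                f"position {proposal.position}, found {context[index]!r}"
            )
    edited = apply_edit(context, kind, index, proposal.alt_base)
    orf = proposal.reconstructed_orf
    cds_str = edited[orf.start - 1 : orf.end]
    protein = translate(cds_str)
    if protein.residues[:-1].count("*") or not protein.residues.endswith("*"):
        raise ValueError("reconstructed ORF does not translate cleanly")
    protein = ProteinSequence(f"{locus.label}|repaired", protein.residues[:-1])
    if protein.residues != proposal.reconstructed_protein.residues:
        raise ValueError("proposal protein does not match re-derived translation")
    cds = NucleotideSequence(
        f"{locus.label}|repaired",
        cds_str,
        description=f"edit={proposal.describe()}",
    )
    return cds, protein
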