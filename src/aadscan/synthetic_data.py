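"""Synthetic gene families and kinetics datasets with known ground truth.

Every pipeline stage in this package can be exercised without downloads:
this module builds a gene family from a single simulated ancestor CDS by
duplication, neutral divergence and *planted* lesions of the kinds seen in
degenerating subtelomeric families -- single-base frameshifts that split an
ORF, nonsense substitutions (including upstream ones that hide an
N-terminal extension), catalytic-site missense changes and 5' partial
deletions -- and records exactly what it planted, so classifier output can
be scored against truth.  It also simulates noisy Michaelis-Menten
initial-rate datasets from stated (Km, Vmax).

Design notes: neutral divergence is uniform random substitution with
rejection of in-frame stop creation (background indels would confound the
single-edit ground truth, so there are none); catalytic-site codons and the
planted-lesion codon are protected from neutral substitutions so lesions
stay unambiguous; flanks are i.i.d. uniform nucleotides.  All outputs are
bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import RateDataset
from .pseudogene import ReferenceGene
from .seq_core import (
    GeneLocus,
    NucleotideSequence,
    ProteinSequence,
    translate,
)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

LESION_KINDS = (
    "none",
    "frameshift_del",
    "frameshift_ins",
    "nonsense_sub",
    "catalytic_missense",
    "five_prime_deletion",
)

_EXPECTED_STATUS = {
    "none": "intact",
    "frameshift_del": "frameshift_split",
    "frameshift_ins": "frameshift_split",
    "nonsense_sub": "nonsense_truncated",
    "catalytic_missense": "missense_catalytic",
    "five_prime_deletion": "partial_deletion",
}


@dataclass(frozen=True)
class LesionSpec:
    """One planted lesion for one gene copy.

    ``position`` is a locus coordinate of the lesioned base (negative =
    upstream of the annotated ATG); when None a viable position is drawn at
    random.  ``upstream_ext_codons`` > 0 builds an in-frame 5' extension:
    for ``nonsense_sub`` the annotated start is moved that many codons into
    the ancestor (the extension is ancestral sequence, as for a gene whose
    N-terminus was lost to a premature stop); for ``none`` the extension is
    extra non-ancestral sense codons carrying a planted stop while the
    annotated ORF itself stays intact (an upstream lesion over a still-
    functional gene).
    """

    kind: str = "none"
    position: Optional[int] = None
    alt: Optional[str] = None
    five_prime_fraction: float = 0.6
    upstream_ext_codons: int = 0

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if not (0.0 < self.five_prime_fraction < 1.0):
            raise ValueError("five_prime_fraction must be in (0, 1)")


@dataclass(frozen=True)
class LocusTruth:
    """What was planted in one locus and what the classifier should say."""

    label: str
    kind: str
    lesion_position: Optional[int]
    lesion_ref: str
    lesion_alt: str
    expected_status: str
    repair_kind: Optional[str]
    repair_position: Optional[int]
    ancestral_cds: str


@dataclass(frozen=True)
class FamilyTruth:
    rows: tuple[LocusTruth, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def by_label(self, label: str) -> LocusTruth:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


@dataclass(frozen=True)
class MMDesign:
    """A Michaelis-Menten simulation design.

    Default concentration grid: 8 log-spaced points from 0.1xKm to 10xKm,
    in triplicate; noise is multiplicative Gaussian with coefficient of
    variation ``cv`` (or additive with standard deviation ``sd``).
    """

    km: float
    vmax: float
    concentrations_uM: Optional[tuple[float, ...]] = None
    replicates: int = 3
    noise_model: str = "multiplicative_gaussian"
    cv: float = 0.05
    sd: float = 0.0
    seed: int = 0
    substrate: str = "substrate"

    def __post_init__(self) -> None:
        if self.km <= 0 or self.vmax <= 0:
            raise ValueError("Km and Vmax must be > 0")
        if self.cv < 0 or self.sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.noise_model not in ("multiplicative_gaussian", "additive_gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.concentrations_uM is None:
            grid = tuple(
                float(x) for x in np.geomspace(0.1 * self.km, 10.0 * self.km, 8)
            )
            object.__setattr__(self, "concentrations_uM", grid)
        if any(c <= 0 for c in self.concentrations_uM):
            raise ValueError("concentration grid must be positive")


# ---------------------------------------------------------------------------
# ancestor generation


def generate_ancestor(
    n_codons: int,
    gc_target: float = 0.40,
    seed: int = 0,
    forced_codons: Optional[dict[int, str]] = None,
    max_tries: int = 200,
) -> NucleotideSequence:
    """A valid CDS (ATG ... stop, no internal stop) near a GC target.

    ``forced_codons`` pins specific codons (1-based codon index, e.g. a
    catalytic tetrad); realized GC is within +-0.04 of the target or the
    request is rejected as infeasible.  Deterministic per seed.
    """
    if n_codons < 50:
        raise ValueError("n_codons must be >= 50")
    if not (0.0 < gc_target < 1.0):
        raise ValueError("gc_target must be in (0, 1)")
    forced = dict(forced_codons or {})
    for idx, codon in forced.items():
        if not (2 <= idx <= n_codons - 1):
            raise ValueError(f"forced codon index {idx} out of range")
        if len(codon) != 3 or set(codon) - set(_BASES) or codon in _STOPS:
            raise ValueError(f"invalid forced codon {codon!r}")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    )
    for _ in range(max_tries):
        codons = ["ATG"]
        for i in range(2, n_codons):
            if i in forced:
                codons.append(forced[i])
                continue
            while True:
                c = "".join(_BASES[b] for b in rng.choice(4, size=3, p=p))
                if c not in _STOPS:
                    break
            codons.append(c)
        codons.append("TAA" if gc_target < 0.5 else "TGA")
        seq = "".join(codons)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        if abs(gc - gc_target) <= 0.04:
            return NucleotideSequence(f"ancestor_{seed}", seq)
    raise ValueError(f"could not reach GC target {gc_target} (infeasible?)")


# ---------------------------------------------------------------------------
# helpers


def _random_flank(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[b] for b in rng.integers(0, 4, size=n))


def _sense_codons(rng: np.random.Generator, k: int) -> str:
    out = []
    while len(out) < k:
        c = "".join(_BASES[b] for b in rng.integers(0, 4, size=3))
        if c not in _STOPS and c != "ATG":
            out.append(c)
    return "".join(out)


def _diverge(
    cds: str, rate: float, rng: np.random.Generator, protected: set[int]
) -> str:
    """Neutral substitutions at the given per-base rate.

    Protected indices are skipped; substitutions that would create an
    in-frame stop (or touch the start/stop codon) are rejected.
    """
    if rate == 0:
        return cds
    if not (0.0 <= rate <= 0.2):
        raise ValueError("divergence rate must be in [0, 0.2]")
    n = len(cds)
    seq = list(cds)
    always = set(range(3)) | set(range(n - 3, n))
    n_sub = rng.binomial(n, rate)
    sites = rng.choice(n, size=min(n_sub, n), replace=False)
    for i in sites:
        i = int(i)
        if i in protected or i in always:
            continue
        cur = seq[i]
        alts = [b for b in _BASES if b != cur]
        rng.shuffle(alts)
        c0 = 3 * (i // 3)
        for alt in alts:
            codon = seq[c0 : c0 + 3]
            codon[i - c0] = alt
            if "".join(codon) not in _STOPS:
                seq[i] = alt
                break
    return "".join(seq)


def _first_inframe_stop_end(seq: str, start0: int) -> Optional[int]:
    """End index (exclusive) of the first in-frame stop codon from start0."""
    for c in range(start0, len(seq) - 2, 3):
        if seq[c : c + 3] in _STOPS:
            return c + 3
    return None


def _canonical_insertion_junction(edited: str, index: int, base: str) -> int:
    """Rightmost junction equivalent to inserting ``base`` before ``index``."""
    j = index
    while j < len(edited) and edited[j] == base:
        j += 1
    return j


def _canonical_deletion_index(seq: str, index: int) -> int:
    """Rightmost index equivalent to deleting ``seq[index]`` (run shift)."""
    i = index
    while i + 1 < len(seq) and seq[i + 1] == seq[i]:
        i += 1
    return i


def _stop_making_subs(codon: str) -> list[tuple[int, str]]:
    """(offset, alt) single-base substitutions that turn a codon into a stop."""
    out = []
    for k in range(3):
        for alt in _BASES:
            if alt == codon[k]:
                continue
            new = codon[:k] + alt + codon[k + 1 :]
            if new in _STOPS:
                out.append((k, alt))
    return out


# ---------------------------------------------------------------------------
# family generation


def generate_family(
    ancestor: NucleotideSequence,
    n_copies: Optional[int] = None,
    divergence_sub_rate: float = 0.02,
    lesions: Optional[Sequence[LesionSpec]] = None,
    flank_nt: int = 1000,
    seed: int = 0,
    catalytic_site_codons: Sequence[int] = (),
    labels: Optional[Sequence[str]] = None,
) -> tuple[list[GeneLocus], FamilyTruth]:
    """Duplicate an ancestor, diverge each copy neutrally, plant one lesion
    per copy, embed in random flanks, and return loci plus the truth table.

    ``catalytic_site_codons`` are 1-based codon indices of the ancestor
    protein; those codons are protected from neutral divergence so that a
    planted catalytic missense is the only change at such a site.
    """
    if lesions is None:
        lesions = [LesionSpec()] * (n_copies or 1)
    lesions = list(lesions)
    if n_copies is None:
        n_copies = len(lesions)
    if n_copies < len(lesions):
        raise ValueError("more lesions than copies")
    lesions += [LesionSpec()] * (n_copies - len(lesions))
    anc = ancestor.residues
    n_codons = len(anc) // 3
    if len(anc) % 3 or anc[:3] != "ATG" or anc[-3:] not in _STOPS:
        raise ValueError("ancestor must be a valid CDS (ATG ... stop)")
    if labels is None:
        labels = [f"copy{i + 1}" for i in range(n_copies)]

    master = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in master.spawn(n_copies)]

    site_protect = set()
    for codon_idx in catalytic_site_codons:
        site_protect.update(range(3 * (codon_idx - 1), 3 * codon_idx))

    loci: list[GeneLocus] = []
    rows: list[LocusTruth] = []

    for label, spec, rng in zip(labels, lesions, streams):
        locus, truth = _build_copy(
            label, anc, n_codons, spec, divergence_sub_rate, flank_nt,
            site_protect, rng,
        )
        loci.append(locus)
        rows.append(truth)
    return loci, FamilyTruth(tuple(rows))


def _annotated_would_qualify(locus: GeneLocus, anc: str) -> bool:
    """Would the annotated ORF of this lesioned locus still pass the
    default length/similarity acceptance (with a safety margin)?

    Used to reject random lesion placements whose truncated ORF remains so
    close to full length that the locus would honestly classify as intact
    -- the generator's truth table must be unambiguous by construction.
    """
    from .pseudogene import Thresholds, _eval_annotated_orf
    from .seq_core import encode

    ref = translate(anc).residues[:-1]
    thr = Thresholds(
        aa_similarity_min=77.0, length_ratio_min=0.88, length_ratio_max=1.12
    )
    ann = _eval_annotated_orf(
        encode(locus.context.residues), locus.cds_start - 1, ref, thr
    )
    return ann is not None and ann[-1]


def _build_copy(
    label: str,
    anc: str,
    n_codons: int,
    spec: LesionSpec,
    rate: float,
    flank_nt: int,
    site_protect: set[int],
    rng: np.random.Generator,
    max_attempts: int = 20,
) -> tuple[GeneLocus, LocusTruth]:
    # randomly placed truncating lesions get re-drawn (jointly with the
    # divergence realization) until the annotated ORF clearly fails the
    # acceptance band; fixed positions are honored as given
    risky = (
        spec.position is None
        and spec.kind in ("frameshift_del", "frameshift_ins", "nonsense_sub")
        and spec.upstream_ext_codons == 0
    )
    attempts = max_attempts if risky else 1
    result = None
    for _ in range(attempts):
        result = _build_copy_once(
            label, anc, n_codons, spec, rate, flank_nt, site_protect, rng
        )
        if not risky or not _annotated_would_qualify(result[0], anc):
            break
    return result


def _build_copy_once(
    label: str,
    anc: str,
    n_codons: int,
    spec: LesionSpec,
    rate: float,
    flank_nt: int,
    site_protect: set[int],
    rng: np.random.Generator,
) -> tuple[GeneLocus, LocusTruth]:
    L = len(anc)

    # -- resolve the lesion target before divergence so it can be protected
    kind = spec.kind
    lesion_index: Optional[int] = None  # 0-based within the (un-relocated) CDS
    lesion_alt = spec.alt
    protect = set(site_protect)

    def protect_codon(i: int, pad_codons: int = 0) -> None:
        # protect the lesion codon (and optionally its codon neighborhood,
        # so that frame-shifted re-readings near a planted indel cannot
        # beat the true repair through divergence coincidences)
        c0 = 3 * (i // 3)
        protect.update(range(max(0, c0 - 3 * pad_codons), min(L, c0 + 3 + 3 * pad_codons)))

    if kind in ("frameshift_del", "frameshift_ins", "nonsense_sub", "catalytic_missense"):
        if spec.position is not None:
            if kind == "nonsense_sub" and spec.position < 0:
                # upstream lesion: position is relative to the *relocated*
                # annotated start at codon upstream_ext_codons + 1
                if spec.upstream_ext_codons <= 0:
                    raise ValueError("negative lesion position needs upstream_ext_codons")
                lesion_index = 3 * spec.upstream_ext_codons + spec.position
            else:
                lesion_index = spec.position - 1
            if not (0 <= lesion_index < L):
                raise ValueError(f"lesion coordinate outside CDS for {label}")

    if kind == "nonsense_sub":
        if lesion_index is None:
            lo, hi = max(4, int(0.1 * n_codons)), int(0.8 * n_codons)
            if spec.upstream_ext_codons:
                lo, hi = 2, spec.upstream_ext_codons - 1
            order = rng.permutation(np.arange(lo, hi))
            for ci in order:
                cands = _stop_making_subs(anc[3 * ci : 3 * ci + 3])
                if cands:
                    k_off, alt = cands[int(rng.integers(len(cands)))]
                    lesion_index = 3 * int(ci) + k_off
                    lesion_alt = alt
                    break
            else:
                raise ValueError("no nonsense-capable codon found")
        elif lesion_alt is None:
            ci, off = lesion_index // 3, lesion_index % 3
            for k_off, alt in _stop_making_subs(anc[3 * ci : 3 * ci + 3]):
                if k_off == off:
                    lesion_alt = alt
                    break
            if lesion_alt is None:
                raise ValueError(f"no stop-creating substitution at position {spec.position}")
        protect_codon(lesion_index, pad_codons=3)
    elif kind == "catalytic_missense":
        if lesion_index is None:
            if not site_protect:
                raise ValueError("catalytic_missense needs catalytic_site_codons")
            codons = sorted({i // 3 for i in site_protect})
            ci = int(codons[int(rng.integers(len(codons)))])
            codon = anc[3 * ci : 3 * ci + 3]
            aa0 = translate(codon).residues
            cands = []
            for k in range(3):
                for alt in _BASES:
                    if alt == codon[k]:
                        continue
                    new = codon[:k] + alt + codon[k + 1 :]
                    if new not in _STOPS and translate(new).residues != aa0:
                        cands.append((3 * ci + k, alt))
            lesion_index, lesion_alt = cands[int(rng.integers(len(cands)))]
        elif lesion_alt is None:
            raise ValueError("catalytic_missense with a fixed position needs alt")
        protect_codon(lesion_index)
    elif kind in ("frameshift_del", "frameshift_ins"):
        if lesion_index is None:
            # keep both resulting ORF fragments clearly shorter than the
            # acceptance length band (0.9x reference), so a split locus can
            # never read as an intact near-full-length gene
            lesion_index = int(rng.integers(int(0.15 * L), int(0.8 * L)))
        protect_codon(lesion_index, pad_codons=3)
        if kind == "frameshift_ins" and lesion_alt is None:
            lesion_alt = _BASES[int(rng.integers(4))]
    elif kind == "none" and spec.upstream_ext_codons:
        if spec.position is None:
            raise ValueError("an upstream lesion over an intact ORF needs a position")

    # -- for an upstream nonsense lesion the annotated start moves into the
    #    ancestor; that start codon must be ATG, so pin it before divergence
    ext = spec.upstream_ext_codons
    if kind == "nonsense_sub" and ext:
        if ext < 2 or 3 * ext >= L - 6:
            raise ValueError("upstream_ext_codons out of range")
        if (n_codons - ext) / n_codons > 0.88:
            raise ValueError(
                "upstream_ext_codons too small: the truncated ORF would "
                "remain near reference length and could classify intact"
            )
        anc = anc[: 3 * ext] + "ATG" + anc[3 * ext + 3 :]
        protect.update(range(3 * ext, 3 * ext + 3))

    cds = _diverge(anc, rate, rng, protect)

    # -- plant the lesion and lay out the context
    left = _random_flank(rng, flank_nt)
    right = _random_flank(rng, flank_nt)
    lesion_ref = ""
    lesion_pos: Optional[int] = None
    repair_kind: Optional[str] = None
    repair_pos: Optional[int] = None

    if kind == "none" and not ext:
        context = left + cds + right
        s0 = len(left)
        e0 = s0 + len(cds)
    elif kind == "none":
        # intact ORF plus an in-frame upstream extension of non-ancestral
        # sense codons with a planted stop (the gene works; its longer
        # ancestral form does not, unless the stop is repaired)
        i_ext = 3 * ext + spec.position  # 0-based index inside the extension
        if not (3 <= i_ext < 3 * ext):
            raise ValueError("upstream position outside the extension (or in its ATG)")
        ext_seq = list("ATG" + _sense_codons(rng, ext - 1))
        c0 = 3 * (i_ext // 3)  # planted codon start within the extension
        off = i_ext % 3        # base offset inside that codon
        # ancestral sense codon one substitution away from TAG at each offset
        anc_codons = {0: "CAG", 1: "TCG", 2: "TAT"}
        stop_alts = {0: "T", 1: "A", 2: "G"}
        ext_seq[c0 : c0 + 3] = list(anc_codons[off])
        lesion_ref = anc_codons[off][off]
        lesion_alt = stop_alts[off]
        ext_seq[c0 + off] = lesion_alt
        ext_str = "".join(ext_seq)
        pad = left[: max(0, flank_nt - len(ext_str))]
        context = pad + ext_str + cds + right
        s0 = len(pad) + len(ext_str)
        e0 = s0 + len(cds)
        lesion_pos = spec.position
        repair_kind, repair_pos = "substitution", spec.position
    elif kind == "nonsense_sub" and ext:
        seq = list(cds)
        lesion_ref = seq[lesion_index]
        seq[lesion_index] = lesion_alt
        seq = "".join(seq)
        upstream, annotated = seq[: 3 * ext], seq[3 * ext :]
        pad = left[: max(0, flank_nt - len(upstream))]
        context = pad + upstream + annotated + right
        s0 = len(pad) + len(upstream)
        e0 = s0 + len(annotated)
        lesion_pos = lesion_index - 3 * ext  # negative locus coordinate
        repair_kind, repair_pos = "substitution", lesion_pos
    elif kind == "nonsense_sub":
        seq = list(cds)
        lesion_ref = seq[lesion_index]
        seq[lesion_index] = lesion_alt
        seq = "".join(seq)
        context = left + seq + right
        s0 = len(left)
        stop_end = _first_inframe_stop_end(context, s0)
        e0 = stop_end if stop_end is not None else s0 + 3 * (len(seq) // 3)
        lesion_pos = lesion_index + 1
        repair_kind, repair_pos = "substitution", lesion_pos
    elif kind == "catalytic_missense":
        seq = list(cds)
        lesion_ref = seq[lesion_index]
        seq[lesion_index] = lesion_alt
        seq = "".join(seq)
        context = left + seq + right
        s0 = len(left)
        e0 = s0 + len(seq)
        lesion_pos = lesion_index + 1
        repair_kind, repair_pos = "substitution", lesion_pos
    elif kind == "frameshift_del":
        del_idx = _canonical_deletion_index(cds, lesion_index)
        lesion_ref = cds[del_idx]
        seq = cds[:del_idx] + cds[del_idx + 1 :]
        context = left + seq + right
        s0 = len(left)
        stop_end = _first_inframe_stop_end(context, s0)
        e0 = stop_end if stop_end is not None else s0 + 3 * (len(seq) // 3)
        lesion_pos = del_idx + 1
        # the repair re-inserts the deleted base at its canonical junction
        j = _canonical_insertion_junction(seq, del_idx, lesion_ref)
        repair_kind, repair_pos = "insertion", j  # base j is 5' of the junction
        lesion_alt = ""
    elif kind == "frameshift_ins":
        # place the inserted base at its canonical (rightmost-equivalent)
        # junction so lesion and repair coordinates are stable
        j_star = _canonical_insertion_junction(cds, lesion_index, lesion_alt)
        seq = cds[:j_star] + lesion_alt + cds[j_star:]
        lesion_ref = ""
        context = left + seq + right
        s0 = len(left)
        stop_end = _first_inframe_stop_end(context, s0)
        e0 = stop_end if stop_end is not None else s0 + 3 * (len(seq) // 3)
        lesion_pos = j_star + 1  # 1-based position of the inserted base
        repair_kind = "deletion"
        repair_pos = j_star + 1
    elif kind == "five_prime_deletion":
        k_nt = 3 * int(round(spec.five_prime_fraction * len(cds) / 3))
        seq = cds[k_nt:]
        context = left + seq + right
        s0 = len(left)
        e0 = s0 + len(seq)
        lesion_pos = None
        lesion_ref = ""
        lesion_alt = f"deleted_5prime_{k_nt}nt"
    else:  # pragma: no cover
        raise AssertionError(kind)

    locus = GeneLocus(
        label=label,
        context=NucleotideSequence(label, context),
        cds_start=s0 + 1,
        cds_end=e0,
        strand="+",
    )
    truth = LocusTruth(
        label=label,
        kind=kind,
        lesion_position=lesion_pos,
        lesion_ref=lesion_ref,
        lesion_alt=lesion_alt or "",
        expected_status=_EXPECTED_STATUS[kind],
        repair_kind=repair_kind,
        repair_position=repair_pos,
        ancestral_cds=cds,
    )
    return locus, truth


# ---------------------------------------------------------------------------
# kinetics simulation


def generate_mm_dataset(design: MMDesign) -> RateDataset:
    """Simulate a noisy initial-rate dataset from a Michaelis-Menten truth.

    Multiplicative mode: v = model * (1 + eps), eps ~ N(0, cv); additive
    mode: v = model + eps, eps ~ N(0, sd).  Rates that come out negative
    are resampled (and the resampling logged).  Deterministic per seed.
    """
    import logging

    rng = np.random.default_rng(design.seed)
    conc = np.repeat(np.asarray(design.concentrations_uM, float), design.replicates)
    replicate = np.tile(
        np.arange(1, design.replicates + 1), len(design.concentrations_uM)
    )
    model = design.vmax * conc / (design.km + conc)
    rates = np.empty_like(model)
    n_resampled = 0
    for i, mu in enumerate(model):
        while True:
            if design.noise_model == "multiplicative_gaussian":
                v = mu * (1.0 + rng.normal(0.0, design.cv)) if design.cv else mu
            else:
                v = mu + (rng.normal(0.0, design.sd) if design.sd else 0.0)
            if v >= 0:
                rates[i] = v
                break
            n_resampled += 1
    if n_resampled:
        logging.getLogger(__name__).info(
            "resampled %d negative simulated rates", n_resampled
        )
    return RateDataset(
        substrate=design.substrate,
        concentrations_uM=conc,
        rates=rates,
        replicate=replicate,
    )


# ---------------------------------------------------------------------------
# the study-style seven-locus family (synthetic stand-in with the published
# lesion coordinates)


#: catalytic tetrad positions on the reference protein (Asp, Tyr, Lys, His)
REFERENCE_TETRAD = (71, 76, 103, 152)

#: the same sites as codon indices of the family ancestor, which is three
#: codons shorter at its N terminus than the reference
ANCESTOR_TETRAD_CODONS = (68, 73, 100, 149)


def generate_canonical_family(
    seed: int = 0,
    flank_nt: int = 1000,
    divergence_sub_rate: float = 0.02,
    n_codons: int = 332,
) -> tuple[ReferenceGene, list[GeneLocus], tuple[int, ...], FamilyTruth]:
    """A synthetic seven-locus family reproducing the published lesion catalog.

    This is a stand-in for the real subtelomeric loci (which require a
    database fetch): one simulated ancestor carries the catalytic tetrad at
    codons 68/73/100/149 and is duplicated into seven copies with the
    canonical lesion spectrum --

    * two intact copies (the two active family members);
    * one intact copy with an upstream lesion at -136 (active gene, longer
      defunct ancestral form);
    * a catalytic missense at CDS position 218 (codon 73 TAC -> TGC), i.e.
      reference Tyr76 replaced by Cys at target position 73;
    * a single-base deletion leaving an insertion repair at the CDS
      junction 517/518 that fuses the two halves of a split ORF;
    * an upstream nonsense stop whose repair at -35 restores a 264-nt
      (88-codon) N-terminal extension;
    * a 5' partial deletion (60 % of the CDS removed).

    The reference enzyme is the ancestor with three extra N-terminal
    codons, so its tetrad sits at 71/76/103/152 and target positions are
    offset by -3, as for the real reference protein.

    Returns (reference, loci, reference_site_positions, truth).
    """
    master = np.random.SeedSequence([seed, 1504])
    anc_seed, fam_seed = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(2)]
    forced = {
        68: "GAT",   # Asp
        73: "TAC",   # Tyr (catalytic; lesioned to TGC in the aad3 analog)
        77: "TCG",   # Ser; becomes the -35 stop codon of the aad10 analog
        89: "ATG",   # internal Met = relocated annotated start (aad10 analog)
        100: "AAA",  # Lys
        149: "CAT",  # His
        173: "GGC",  # bases 517-519 G,G,C: deletion of 518 leaves the
                     # G-insertion repair at junction 517/518
    }
    ancestor = generate_ancestor(
        n_codons=n_codons, gc_target=0.40, seed=anc_seed, forced_codons=forced
    )

    # reference: ancestor plus three extra N-terminal codons, tetrad at
    # 71/76/103/152
    ref_cds = NucleotideSequence(
        "reference", "ATG" + "GCTGCAGCC" + ancestor.residues[3:]
    )
    ref_protein = translate(ref_cds).without_stop()
    reference = ReferenceGene(protein=ref_protein, cds=ref_cds)

    lesions = [
        LesionSpec(kind="none"),
        LesionSpec(kind="none", position=-136, upstream_ext_codons=60),
        LesionSpec(kind="catalytic_missense", position=218, alt="G"),
        LesionSpec(kind="frameshift_del", position=518),
        LesionSpec(kind="nonsense_sub", position=-35, upstream_ext_codons=88),
        LesionSpec(kind="five_prime_deletion", five_prime_fraction=0.6),
        LesionSpec(kind="none"),
    ]
    labels = ["aad14x", "aad4x", "aad3x", "aad6_16x", "aad10x", "aad15x", "aad7x"]
    loci, truth = generate_family(
        ancestor,
        lesions=lesions,
        divergence_sub_rate=divergence_sub_rate,
        flank_nt=flank_nt,
        seed=fam_seed,
        catalytic_site_codons=ANCESTOR_TETRAD_CODONS,
        labels=labels,
    )
    return reference, loci, REFERENCE_TETRAD, truth
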