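# Methods

This note records the models, conventions, numerical choices and known
limitations behind `aadscan`, in the order a user meets them.

## Coordinates and sequence conventions

User-facing coordinates are 1-based inclusive; internal code is 0-based
half-open. Positions upstream of an annotated start codon are negative,
with −1 the base immediately 5′ of the A of ATG and **no position 0**.
Note the consequence: an in-frame upstream codon occupies positions such
as (−36, −35, −34), and a codon spanning the start junction is
(−3, −2, −1)(+1, ...). Reverse-strand loci are normalized to CDS-forward
orientation on ingest; all reported coordinates are CDS-forward.

Only the standard nuclear genetic code is implemented (the target genes
are intronless fungal nuclear genes); start codons are ATG; codons
containing N translate to X, and k-mers containing N are skipped. An ORF
is an ATG paired with *its next in-frame stop* — every such pair is
reported by `scan_orfs`, so a run containing two ATGs before one stop
yields two (nested) ORFs.

## Alignment and the two percentages

Global end-to-end alignment with affine gaps (a gap of length k costs
open + k·extend), computed by Biopython's `PairwiseAligner`. Defaults:
nucleotide match +2 / mismatch −3, gap 5+2k; protein BLOSUM62, gap 11+1k.
End gaps are penalized, because the survey compares annotated full ORFs
end to end; every report records the scheme used. Among co-optimal
alignments the aligner's first traceback is returned, which is
deterministic for fixed inputs.

* **percent identity** = identical columns / all columns (gap columns in
  the denominator).
* **percent similarity** (protein) = columns with a positive BLOSUM62
  score / all columns. For nucleotides "similarity" is identity. This is
  the auditable operationalization of the two-number (nt/aa) survey
  format; whether end gaps were counted in the original surveys is
  unknowable, so the similarity-matrix output states the convention in a
  header comment.

## The single-edit repair scan

For a locus (annotated CDS inside up to 1 kb of flank on each side) the
scan enumerates every single-base substitution (3 per position),
insertion (4 per junction) and deletion (1 per position) within the
window and keeps edits whose edited context contains an ORF that overlaps
the annotated CDS, lies within the length band (default 0.9–1.1× the
reference length), and reaches the amino-acid similarity threshold
(default ≥ 80 %).

Decisions that make the scan exact, deterministic and fast:

* **Nothing to repair:** if the ORF launched at the annotated start
  already passes length + similarity, the scan returns empty.
* **Strict improvement:** a proposal must beat the best qualifying ORF
  already present in the unedited context (similarity, then identity,
  then length). Without this rule, a large 3′ fragment that happens to
  qualify would make every irrelevant edit "succeed".
* **Substitution pruning:** a substitution is evaluated only if it
  creates or destroys a stop or ATG codon in some frame, or falls inside
  an existing length-qualifying ORF. This is provably equivalent to full
  enumeration — any other substitution leaves the ORF interval structure
  unchanged and cannot move similarity of a qualifying ORF — and is
  verified against an exhaustive oracle in the tests. Indels always shift
  frame and are always evaluated.
* **Canonical indel coordinates:** inserting a base before or after an
  identical base yields the same sequence; insertions and deletions are
  canonicalized to the rightmost equivalent position of a homopolymer
  run, so reported junctions are stable (the split-ORF fusion reports
  insertion at junction 517/518, not 516/517).
* **Ranking:** amino-acid similarity desc, then amino-acid identity desc,
  then ORF length desc, then |position| asc, then edit kind and base.
  When the reference CDS is available, exact ties in the leading group
  (wobble degeneracy lets distinct edits encode identical proteins) are
  broken by nucleotide consensus of the reconstructed CDS — the measure
  criterion (i) uses — which singles out the edit restoring the
  ancestral bases.

`scan_upstream_stop_repairs` is the specialized view for 5′ lesions: it
finds the nearest in-frame stop upstream of the annotated ATG, proposes
every substitution that abolishes it, and extends the ORF to the best
upstream in-frame ATG, reporting the extension in nt and aa.

## Acceptance criteria and classification

A reconstruction is accepted when (i) nucleotide consensus with the
reference CDS ≥ 80 %, (ii) at most one edit was applied, (iii) the length
ratio lies in [0.9, 1.1], and (iv) amino-acid similarity ≥ 80 %. All four
thresholds are configurable (`Thresholds`) and echoed in reports.

The classifier ladder:

1. **intact** — the annotated ORF passes (iii)+(iv) and all catalytic
   sites are conserved. Upstream-stop repairs are still scanned and
   reported as evidence: an active gene may hide a longer defunct
   ancestral form, and the classifier reports both rather than forcing
   one interpretation.
2. **missense_catalytic** — annotated ORF passes but a catalytic residue
   differs; single-base substitutions restoring the reference residue are
   proposed.
3. **frameshift_split** / **nonsense_truncated** — the best single-edit
   repair is an indel / a substitution.
4. **partial_deletion** — no repair, and less than 50 % (configurable) of
   the reference is alignable to the locus.
5. **absent** — less than 20 % alignable (or a no-repair locus that fits
   none of the above; such multi-lesion cases get an explanatory note,
   as the status set has no better bucket).

"Alignable fraction" is measured by an overlap-style protein alignment
(end gaps free on both sides) of the reference against each forward-frame
translation of the context, scoring identical residue pairs / reference
length and maximizing over frames: ≈ 1 for intact loci, ≈ the retained
fraction for partial deletions, ≈ 0 for unrelated sequence. Catalytic
sites are transferred through the global protein alignment; a site
aligned to a gap is MISSING; conservation is residue identity by default
(identical-or-similar optional).

## Kinetics

Initial-rate data are converted to specific activities as
slope / (ε · path · [enzyme]), with NAD(P)H extinction coefficients
ε₃₄₀ = 6.2 and ε₃₅₅ = 5.12 mM⁻¹·cm⁻¹ as defaults and cofactor consumption
reported positive. The Michaelis–Menten model v = Vmax·S/(Km+S) is fitted
by iterative nonlinear least squares (not a linearization), initialized
at Vmax₀ = max(v) and Km₀ = S at the rate closest to Vmax₀/2, with
parameters bounded positive. Standard errors are asymptotic, from the
curvature of the least-squares surface at the optimum — matching a
"mean ± SE" presentation without replicate-level bookkeeping. A fit that
fails to converge is flagged but still reported. At least 4 distinct
concentrations are required. kcat = Vmax · M/1000 (per-minute turnover)
takes the molar mass as an explicit input, since the mass that applies
(tagged fusion vs native) is assay-specific. The blank comparison is a
two-sample two-tailed t test, equal-variance by default with a Welch
option; degenerate-variance inputs at n < 3 are flagged.

Simulated designs default to 8 log-spaced concentrations from 0.1×Km to
10×Km in triplicate with 5 % multiplicative Gaussian noise — a realistic
bench design that brackets Km symmetrically on the log scale; negative
simulated rates are resampled.

## k-mer distance and neighbor joining

Sequences are reduced to their sets of distinct forward-strand k-mers
(k = 15 default; inputs are orientation-normalized CDSs, a canonical-kmer
option would be needed for raw contigs). The distance is the
fractional-common-k-mer form d = 1 − |A∩B|/min(|A|,|B|) — parameter-free
and standard for alignment-free phylogenies; a Jaccard alternative is
selectable and the formula used is recorded in run metadata. d is a
pseudometric (symmetric, zero on identity); the triangle inequality is
not guaranteed and not asserted.

Neighbor joining is the canonical agglomeration with the standard
Q-criterion and branch-length updates, authored in-package so its
behavior is pinned: Q ties are broken by lowest (row, column) index, and
negative branch lengths are clamped to zero with a logged warning. Trees
are unrooted (trifurcating root node) `skbio.TreeNode` objects; Newick
round-trips preserve topology and branch lengths to 6 decimals. Tests
cross-check the implementation against both a path-length oracle on
random additive matrices and scikit-bio's independent NJ.

The ortholog hit filter keeps, per species, the top-ranked hit with
score ≥ 60 and length strictly > 150 bp (both configurable); running the
homology search itself is out of scope — the filter consumes a tabular
hit list.

## The synthetic-data generator

`generate_family` models duplication of one simulated ancestor CDS
followed by neutral divergence and one planted lesion per copy:

* **Ancestor:** i.i.d. codons at a GC target (default 0.40, realized
  within ±0.04 by rejection), ATG-initiated, stop-free internally,
  330-codon scale (the ~34-kDa reductase size); specific codons (e.g. a
  catalytic tetrad) can be pinned.
* **Neutral divergence:** uniform random substitutions at a per-base rate
  (default 0.02), rejecting in-frame stop creation. There is no indel
  background — background indels would confound single-edit ground
  truth. Catalytic-site codons and a ±3-codon window around the planted
  lesion are protected, so the planted edit is unambiguously the best
  repair (near-lesion divergence can otherwise be "fixed" coincidentally
  by a frame-shifted re-reading).
* **Lesions:** frameshift deletion/insertion, nonsense substitution
  (mid-CDS, or upstream with the annotated start relocated to an internal
  ATG), catalytic missense, 5′ partial deletion (default 60 % removed),
  or none (optionally with an upstream in-frame extension carrying a
  planted stop — an upstream lesion over a still-functional gene).
  Randomly placed truncating lesions are re-drawn until the truncated
  annotated ORF clearly fails the acceptance band; a late frameshift in
  a short gene would otherwise honestly classify as intact, which would
  make the truth table wrong rather than the classifier.
* **Flanks:** i.i.d. uniform nucleotides, default 1 kb per side.

The generator emulates point-mutation pseudogenization with independent
flanks; it does **not** model subtelomeric recombination, codon-usage
bias, transition/transversion bias, or indel background — so passing
tests demonstrate correctness of the inference machinery under the
stated mutation model, not robustness to every feature of real
subtelomeric DNA. All outputs are bit-reproducible given (parameters,
seed).

`generate_canonical_family` builds the canonical seven-locus spectrum with
the published lesion coordinates planted exactly (insertion repair at
CDS junction 517/518 via a pinned G-G-C codon; upstream stop whose −35
repair yields a 264-nt/88-aa extension; catalytic missense at CDS 218
with the reference protein three codons longer at the N terminus, so
reference Tyr76 maps to target position 73). It is a synthetic stand-in:
the real loci would require a sequence-database fetch, and the stand-in
makes the coordinate checks runnable offline.

## Problem sizes used in the tests

The unit and acceptance tests scale the study design down to desk scale
as the package's own choice of test size: oracle-equivalence fixtures use
60-codon genes in ~230-nt contexts (where exhaustive single-edit
enumeration is feasible); the 20-seed classifier-recovery property uses
100-codon genes with 60-nt flanks; the canonical seven-locus family runs
at full gene length (332 codons) with 300-nt flanks. Generator defaults
(1-kb flanks, divergence 0.02, the kinetics design above) are unchanged
by the tests. Monte-Carlo recoveries use 100 datasets per parameter set.

## Known limitations

* Single-base repairs only; multi-edit reconstruction is out of scope by
  design (and sequence-level repair does not imply a functional enzyme —
  the catalytic-missense case may stay dead for reasons invisible to
  sequence analysis).
* The four criteria judge protein-coding plausibility, not expression or
  regulation.
* The similarity survey compares loci to one reference; all-vs-all family
  consensus is derivable but not built in.
* NJ emits no bootstrap support; divergence dating is out of scope.
* `fit_mm` assumes simple one-substrate saturation — no substrate
  inhibition, no bi-substrate kinetics.
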