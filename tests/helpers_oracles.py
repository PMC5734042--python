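"""Independent brute-force oracles used by the test suite.

These are deliberately naive pure-Python re-derivations of the package's
contracts (string slicing, explicit enumeration, textbook DP) so that the
optimized implementations can be checked against them on small inputs.
The repair-scan oracle shares only the protein similarity scorer with the
package (that scorer is itself validated against the alignment DP oracle).
"""

from __future__ import annotations

import functools

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# six-frame ORF enumeration


def orf_oracle(seq: str, min_aa: int, require_atg: bool = True, both_strands: bool = True):
    """Every (ATG, next in-frame stop) pair, as (start, end, strand, frame)."""
    comp = str.maketrans("ACGTN", "TGCAN")
    out = []
    n = len(seq)
    strands = [("+", seq)]
    if both_strands:
        strands.append(("-", seq.translate(comp)[::-1]))
    for strand, s in strands:
        for start in range(len(s) - 2):
            if require_atg and s[start : start + 3] != "ATG":
                continue
            j = start
            while j + 3 <= len(s):
                codon = s[j : j + 3]
                if codon in _STOPS:
                    if (j - start) // 3 >= min_aa:
                        lo, hi = start, j + 3
                        if strand == "+":
                            out.append((lo + 1, hi, "+", start % 3))
                        else:
                            out.append((n - hi + 1, n - lo, "-", start % 3))
                    break
                j += 3
    out.sort()
    return out


# ---------------------------------------------------------------------------
# affine-gap global alignment score (textbook Gotoh, three matrices)


def affine_score_oracle(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Optimal end-to-end score with gap cost open + k*extend.

    ``sub(x, y)`` gives the substitution score.
    """
    NEG = float("-inf")
    n, m = len(a), len(b)
    first = gap_open + gap_extend

    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = sub(a[i - 1], b[j - 1])
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            if i > 0 and (i, j) != (i, 0):
                X[i][j] = max(
                    X[i][j],
                    max(M[i - 1][j], Y[i - 1][j]) - first,
                    X[i - 1][j] - gap_extend,
                )
            if j > 0:
                Y[i][j] = max(
                    Y[i][j],
                    max(M[i][j - 1], X[i][j - 1]) - first,
                    Y[i][j - 1] - gap_extend,
                )
    return max(M[n][m], X[n][m], Y[n][m])


def nt_sub(match: float, mismatch: float):
    return lambda x, y: match if x == y else mismatch


# ---------------------------------------------------------------------------
# exhaustive single-edit repair enumeration


def _translate(seq: str) -> str:
    from aadscan.seq_core import translate

    return translate(seq).residues


def _qualifying_orfs(seq: str, overlap, ref: str, thr):
    """All qualifying ORFs of a sequence: in the length band, above the
    similarity threshold, overlapping the window.  Plain string version."""
    import math

    from aadscan.pseudogene import _aa_scores

    lo, hi = overlap
    n_ref = len(ref)
    min_c = max(1, math.ceil(thr.length_ratio_min * n_ref))
    max_c = math.floor(thr.length_ratio_max * n_ref)
    found = []
    for frame in range(3):
        stops = [
            c for c in range(frame, len(seq) - 2, 3) if seq[c : c + 3] in _STOPS
        ]
        atgs = [c for c in range(frame, len(seq) - 2, 3) if seq[c : c + 3] == "ATG"]
        for a in atgs:
            nxt = [s for s in stops if s >= a]
            if not nxt:
                continue
            s = nxt[0]
            aa_len = (s - a) // 3
            if not (min_c <= aa_len <= max_c):
                continue
            start0, end0 = a, s + 3
            if not (start0 < hi and end0 > lo):
                continue
            protein = _translate(seq[start0 : end0 - 3])
            if "X" in protein:
                continue
            sim, ident = _aa_scores(protein, ref)
            found.append((start0, end0, protein, sim, ident))
    return found


def _best(found, thr):
    best = None
    for start0, end0, protein, sim, ident in found:
        if sim < thr.aa_similarity_min:
            continue
        key = (sim, ident, len(protein), -start0)
        if best is None or key > best[0]:
            best = (key, (start0, end0, protein, sim, ident))
    return best


def repair_scan_oracle(locus, ref_protein: str, thr):
    """Exhaustive enumeration of all canonical single-base edits.

    Returns the set of (kind, position, ref_base, alt_base, protein) tuples
    that the scan contract admits: the edited context must contain a
    qualifying ORF strictly better than the best one already present.
    """
    locus = locus.forward()
    seq = locus.context.residues
    n = len(seq)
    s0, e0 = locus.cds_start - 1, locus.cds_end
    w0, w1 = 0, n

    ann = None
    if seq[s0 : s0 + 3] == "ATG":
        stops = [c for c in range(s0, n - 2, 3) if seq[c : c + 3] in _STOPS]
        if stops:
            from aadscan.pseudogene import _aa_scores

            protein = _translate(seq[s0 : stops[0]])
            if protein and "X" not in protein:
                sim, _ = _aa_scores(protein, ref_protein)
                ratio = len(protein) / len(ref_protein)
                if (
                    thr.length_ratio_min <= ratio <= thr.length_ratio_max
                    and sim >= thr.aa_similarity_min
                ):
                    return set()  # annotated ORF already fine

    base = _best(_qualifying_orfs(seq, (s0, e0), ref_protein, thr), thr)
    base_key = None if base is None else (base[1][3], base[1][4], len(base[1][2]))

    def to_pos(i):
        off = i - s0
        return off + 1 if off >= 0 else off

    out = set()

    def consider(kind, i, alt, edited, overlap):
        best = _best(_qualifying_orfs(edited, overlap, ref_protein, thr), thr)
        if best is None:
            return
        _, (_, _, protein, sim, ident) = best
        if base_key is not None and (sim, ident, len(protein)) <= base_key:
            return
        if kind == "substitution":
            out.add((kind, to_pos(i), seq[i], alt, protein))
        elif kind == "deletion":
            out.add((kind, to_pos(i), seq[i], "", protein))
        else:
            pos = to_pos(i - 1) if i > 0 else to_pos(0) - 1
            out.add((kind, pos, "", alt, protein))

    for i in range(w0, w1):
        for alt in _BASES:
            if alt == seq[i]:
                continue
            consider("substitution", i, alt, seq[:i] + alt + seq[i + 1 :], (s0, e0))
    for i in range(w0, w1):
        if i + 1 < min(n, w1) and seq[i + 1] == seq[i]:
            continue  # canonical rightmost deletion
        ds = s0 - (1 if i < s0 else 0)
        de = e0 - (1 if i < e0 else 0)
        consider("deletion", i, "", seq[:i] + seq[i + 1 :], (ds, de))
    for j in range(w0, w1 + 1):
        for alt in _BASES:
            if j < n and j + 1 <= w1 and seq[j] == alt:
                continue  # canonical rightmost insertion
            is_ = s0 + (1 if j <= s0 else 0)
            ie = e0 + (1 if j < e0 else 0)
            consider("insertion", j, alt, seq[:j] + alt + seq[j:], (is_, ie))
    return out


# ---------------------------------------------------------------------------
# random additive trees for neighbor joining


def random_additive_matrix(rng, n_leaves: int):
    """A random tree topology with positive branch lengths; returns
    (labels, matrix of exact leaf-to-leaf path lengths)."""
    import itertools

    import numpy as np

    nodes = {i: None for i in range(n_leaves)}  # node id -> parent (id, length)
    next_id = n_leaves
    active = list(range(n_leaves))
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent = next_id
        next_id += 1
        nodes[a] = (parent, float(rng.uniform(0.1, 1.0)))
        nodes[b] = (parent, float(rng.uniform(0.1, 1.0)))
        nodes[parent] = None
        active = [x for x in active if x not in (a, b)] + [parent]
    a, b = active
    root = next_id
    nodes[a] = (root, float(rng.uniform(0.1, 1.0)))
    nodes[b] = (root, float(rng.uniform(0.1, 1.0)))
    nodes[root] = None

    def path_to_root(x):
        out = {}
        dist = 0.0
        while nodes[x] is not None:
            parent, length = nodes[x]
            dist += length
            out[parent] = dist
            x = parent
        return out

    labels = [f"L{i}" for i in range(n_leaves)]
    mat = np.zeros((n_leaves, n_leaves))
    for i, j in itertools.combinations(range(n_leaves), 2):
        pi, pj = path_to_root(i), path_to_root(j)
        shared = set(pi) & set(pj)
        d = min(pi[x] + pj[x] for x in shared)
        mat[i, j] = mat[j, i] = d
    return labels, mat
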