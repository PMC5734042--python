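"""Alignment-free k-mer distances, neighbor joining, and hit filtering.

The ortholog survey machinery: each CDS is reduced to its set of distinct
k-mers (k = 15 by default), pairwise dissimilarity is the fractional-
common-k-mer distance

    d(A, B) = 1 - |A intersect B| / min(|A|, |B|)

(a Jaccard alternative is available), and the distance matrix is resolved
into an unrooted tree by canonical Saitou-Nei neighbor joining.  Ties in
the NJ Q-criterion are broken by lowest (row, column) index so that runs
are bit-for-bit reproducible; negative branch lengths are clamped to zero
with a logged warning.  Trees are scikit-bio ``TreeNode`` objects, so
Newick I/O and tree comparisons come for free.

A small helper implements the ortholog hit-filtering rule used upstream of
the tree: per species keep only the top-ranked hit with score >= 60 and
length strictly > 150 bp (both configurable).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode

from .seq_core import NucleotideSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KmerProfile:
    """The set of distinct k-mers of one sequence (N-containing ones dropped)."""

    label: str
    k: int
    kmers: frozenset[str]

    def __len__(self) -> int:
        return len(self.kmers)


def kmer_profile(seq: NucleotideSequence | str, k: int = 15) -> KmerProfile:
    """Distinct forward-strand k-mers; any k-mer containing N is skipped."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(seq, NucleotideSequence):
        label, res = seq.id, seq.residues
    else:
        label, res = "seq", str(seq).upper()
    kmers = {
        res[i : i + k]
        for i in range(len(res) - k + 1)
        if "N" not in res[i : i + k]
    }
    return KmerProfile(label=label, k=k, kmers=frozenset(kmers))


def kmer_distance(a: KmerProfile, b: KmerProfile, method: str = "fractional") -> float:
    """Distance in [0, 1] between two k-mer profiles.

    ``fractional``: 1 - |A&B| / min(|A|, |B|)  (default);
    ``jaccard``:    1 - |A&B| / |A|B|.
    Symmetric, zero on identical profiles; the triangle inequality is not
    guaranteed by either formula.
    """
    if a.k != b.k:
        raise ValueError(f"profiles have different k ({a.k} vs {b.k})")
    if len(a) == 0 and len(b) == 0:
        raise ValueError("distance undefined: both profiles are empty")
    if len(a) == 0 or len(b) == 0:
        return 1.0
    shared = len(a.kmers & b.kmers)
    if method == "fractional":
        return 1.0 - shared / min(len(a), len(b))
    if method == "jaccard":
        return 1.0 - shared / len(a.kmers | b.kmers)
    raise ValueError(f"unknown k-mer distance method {method!r}")


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal, entries >= 0."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(vals) != 0).any():
            raise ValueError("distance matrix must have a zero diagonal")
        if (vals < 0).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", index_label=""
        )

    @staticmethod
    def from_tsv(path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return DistanceMatrix(tuple(str(c) for c in df.columns), df.to_numpy(float))

    def to_skbio(self) -> _SkbioDM:
        return _SkbioDM(self.values, ids=list(self.labels))


def kmer_distance_matrix(
    seqs: list[NucleotideSequence],
    k: int = 15,
    method: str = "fractional",
) -> DistanceMatrix:
    """All-pairs k-mer distance matrix over a list of sequences."""
    profiles = [kmer_profile(s, k) for s in seqs]
    labels = tuple(s.id for s in seqs)
    if len(set(labels)) != len(labels):
        raise ValueError("sequence ids must be unique for a distance matrix")
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kmer_distance(profiles[i], profiles[j], method)
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical Saitou-Nei neighbor joining.

    Standard Q-criterion and branch-length updates; joins the lowest
    (row, column) pair on Q ties; clamps negative branch lengths to zero
    with a warning.  For n = 2 returns the trivial two-leaf tree.  The
    result is unrooted in the usual NJ sense (trifurcating root for n >= 3).
    """
    n = len(dm)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning("negative NJ branch length %.6g clamped to 0", x)
            return 0.0
        return x

    if n == 2:
        half = d[0, 1] / 2.0
        for nd in nodes:
            nd.length = clamp(half)
        return TreeNode(children=nodes)

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (m - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, column) on ties: argmin of C-ordered flattened array
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        a, b = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[a].length = clamp(li)
        nodes[b].length = clamp(lj)
        parent = TreeNode(children=[nodes[a], nodes[b]])
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0])
        for t in active:
            if t in (a, b):
                continue
            new_row[t] = 0.5 * (d[a, t] + d[b, t] - dij)
        d[a, :] = new_row
        d[:, a] = new_row
        d[a, a] = 0.0
        nodes[a] = parent
        active.remove(b)

    # final three taxa: closed-form branch lengths, trifurcating root
    x, y, z = active
    lx = 0.5 * (d[x, y] + d[x, z] - d[y, z])
    ly = 0.5 * (d[x, y] + d[y, z] - d[x, z])
    lz = 0.5 * (d[x, z] + d[y, z] - d[x, y])
    nodes[x].length = clamp(lx)
    nodes[y].length = clamp(ly)
    nodes[z].length = clamp(lz)
    return TreeNode(children=[nodes[x], nodes[y], nodes[z]])


@dataclass(frozen=True)
class HitFilter:
    """The ortholog hit-acceptance rule: score, length, one hit per species."""

    min_score: float = 60.0
    min_length_nt: int = 150  # strictly greater than
    one_per_species: bool = True

    def __post_init__(self) -> None:
        if self.min_score < 0 or self.min_length_nt < 0:
            raise ValueError("thresholds must be >= 0")


def filter_hits(hit_table: pd.DataFrame, f: HitFilter = HitFilter()) -> pd.DataFrame:
    """Apply the hit filter: per species the top-ranked hit with
    score >= min_score and length > min_length_nt; species with no passing
    hit are dropped.
    """
    required = {"species", "score", "length", "rank"}
    missing = required - set(hit_table.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    passing = hit_table[
        (hit_table["score"] >= f.min_score)
        & (hit_table["length"] > f.min_length_nt)
    ]
    if not f.one_per_species:
        return passing.reset_index(drop=True)
    out = (
        passing.sort_values(["species", "rank"], kind="stable")
        .groupby("species", sort=False)
        .head(1)
    )
    return out.reset_index(drop=True)


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(newick: str) -> TreeNode:
    """Parse a Newick string; unlabeled internal nodes are tolerated."""
    try:
        return TreeNode.read(io.StringIO(newick), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise ValueError(f"malformed Newick string: {exc}") from exc
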