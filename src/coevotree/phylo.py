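"""Distance matrices, neighbor-joining trees and patristic distances.

This module provides the tree-building backbone of the co-evolution
pipeline: uncorrected (p-distance) matrices from multiple sequence
alignments with pairwise gap deletion, a native Saitou–Nei
neighbor-joining implementation with deterministic tie-breaking, and
patristic (path-length) distance matrices computed from trees.  Trees are
represented as :class:`dendropy.Tree` objects; Newick and PHYLIP-square
readers/writers round-trip the on-disk formats.

The distance convention follows the classic mirrortree protocol: gaps are
excluded pairwise from the distance calculation, and inter-ortholog
distances are obtained from the NJ tree by summing branch lengths along
the connecting path (not read directly from the sequence distances).
"""

from __future__ import annotations

import io
import math
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

from .errors import DegeneratePairError, FormatError

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "read_alignment_fasta",
    "pdistance_matrix",
    "neighbor_joining",
    "patristic_distances",
    "read_newick",
    "write_newick",
    "read_phylip_square",
    "write_phylip_square",
]

_SYMMETRY_ATOL = 1e-12


class Alignment:
    """A multiple sequence alignment: ordered (organism, sequence) records.

    All sequences must have equal length; organism identifiers must be
    unique.  Gaps are encoded as ``-``.
    """

    def __init__(self, records: Iterable[tuple[str, str]]):
        self.records: list[tuple[str, str]] = [(str(i), str(s).upper()) for i, s in records]
        if not self.records:
            raise ValueError("alignment is empty")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise FormatError(f"unequal sequence lengths: {sorted(lengths)}")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate organism identifiers in alignment")
        self.length = lengths.pop()

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [i for i, _ in self.records]


def read_alignment_fasta(path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return Alignment(records)


def write_alignment_fasta(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for name, seq in alignment.records:
            fh.write(f">{name}\n{seq}\n")


class DistanceMatrix:
    """A symmetric, zero-diagonal, organism-labeled distance matrix.

    Labels are held in canonical (lexicographic) order; the values array is
    reordered accordingly on construction.  Entries must be non-negative
    and symmetric to within 1e-12.
    """

    __slots__ = ("_labels", "_values")

    def __init__(self, labels: Sequence[str], values):
        labels = [str(x) for x in labels]
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(labels) != values.shape[0]:
            raise ValueError("label count does not match matrix size")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate organism labels")
        scale = max(1.0, float(np.max(np.abs(values))) if values.size else 1.0)
        if not np.allclose(values, values.T, rtol=0.0, atol=_SYMMETRY_ATOL * scale):
            raise ValueError("distance matrix is not symmetric")
        if values.size and not np.allclose(np.diag(values), 0.0, atol=_SYMMETRY_ATOL * scale):
            raise ValueError("distance matrix diagonal is not zero")
        if values.size and np.min(values) < -_SYMMETRY_ATOL * scale:
            raise ValueError("distances must be non-negative")
        order = sorted(range(len(labels)), key=lambda i: labels[i])
        self._labels = tuple(labels[i] for i in order)
        values = values[np.ix_(order, order)]
        # exact symmetry and clean diagonal after reordering
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
        np.clip(values, 0.0, None, out=values)
        self._values = values

    @property
    def labels(self) -> tuple[str, ...]:
        return self._labels

    @property
    def values(self) -> np.ndarray:
        """The (n, n) float array in canonical label order (do not mutate)."""
        return self._values

    @property
    def n(self) -> int:
        return len(self._labels)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DistanceMatrix(n={self.n})"

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        ia = self._labels.index(a)
        ib = self._labels.index(b)
        return float(self._values[ia, ib])

    def restrict(self, labels: Iterable[str]) -> "DistanceMatrix":
        """Sub-matrix over the intersection with ``labels`` (canonical order)."""
        keep = [i for i, lab in enumerate(self._labels) if lab in set(labels)]
        return DistanceMatrix(
            [self._labels[i] for i in keep], self._values[np.ix_(keep, keep)]
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in canonical pair order (i < j, row-major)."""
        iu = np.triu_indices(self.n, k=1)
        return self._values[iu]


# ---------------------------------------------------------------------------
# sequence distances
# ---------------------------------------------------------------------------

def pdistance_matrix(alignment: Alignment, correction: str | None = None) -> DistanceMatrix:
    """Pairwise sequence distances with pairwise gap deletion.

    For each pair of sequences only columns where *neither* sequence has a
    gap are compared; the distance is the mismatch fraction over those
    columns (uncorrected p-distance).  With ``correction="kimura"`` the
    ClustalW-style correction ``d = -ln(1 - p - p^2/5)`` is applied.

    Raises
    ------
    DegeneratePairError
        If some pair of sequences has no comparable column.
    """
    if len(alignment) < 3:
        raise ValueError("pdistance_matrix requires at least 3 sequences")
    if correction not in (None, "kimura"):
        raise ValueError(f"unknown correction: {correction!r}")
    ids = alignment.ids()
    arr = np.array([list(s) for _, s in alignment.records])
    gap = arr == "-"
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            if m == 0:
                raise DegeneratePairError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            p = float(np.sum(arr[i, ok] != arr[j, ok])) / m
            if correction == "kimura":
                x = 1.0 - p - 0.2 * p * p
                if x <= 0.0:
                    raise DegeneratePairError(
                        f"Kimura correction undefined for p={p:.3f} "
                        f"({ids[i]!r} vs {ids[j]!r})"
                    )
                p = -math.log(x)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Produces an unrooted tree (trifurcating root node) over all input taxa.
    On an exactly additive input matrix the tree's path metric reproduces
    the input.  Negative branch-length estimates are clamped to zero.
    Ties on the Q criterion are broken deterministically by the smallest
    (lexicographic) pair of cluster keys, where a cluster's key is its
    smallest leaf label.
    """
    if not isinstance(dm, DistanceMatrix):
        raise ValueError("neighbor_joining expects a DistanceMatrix")
    n0 = dm.n
    if n0 < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    size = 2 * n0
    M = np.zeros((size, size))
    M[:n0, :n0] = dm.values
    keys: dict[int, str] = {i: lab for i, lab in enumerate(dm.labels)}
    newick: dict[int, str] = {i: _quote_label(lab) for i, lab in enumerate(dm.labels)}
    active = list(range(n0))
    nxt = n0

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = M[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        # r_i + r_j first: keeps Q exactly symmetric in floating point
        Q = (m - 2) * sub - (r[:, None] + r[None, :])
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q == qmin)
        best = None
        for a, b in ties:
            if a >= b:
                continue
            key = tuple(sorted((keys[idx[a]], keys[idx[b]])))
            if best is None or key < best[0]:
                best = (key, int(a), int(b))
        _, ai, bi = best
        i, j = int(idx[ai]), int(idx[bi])
        dij = M[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        newick[nxt] = f"({newick[i]}:{li:.17g},{newick[j]}:{lj:.17g})"
        keys[nxt] = min(keys[i], keys[j])
        for k in active:
            if k in (i, j):
                continue
            M[nxt, k] = M[k, nxt] = 0.5 * (M[i, k] + M[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    a, b, c = sorted(active, key=lambda k: keys[k])
    dab, dac, dbc = M[a, b], M[a, c], M[b, c]
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    s = (
        f"({newick[a]}:{la:.17g},{newick[b]}:{lb:.17g},{newick[c]}:{lc:.17g});"
    )
    return read_newick(io.StringIO(s))


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "(),:;[]' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# patristic distances
# ---------------------------------------------------------------------------

def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distance matrix.

    Entry (i, j) is the sum of branch lengths along the unique path between
    leaves i and j; the root placement is irrelevant to the result.
    Computed by a single post-order sweep that merges per-subtree
    leaf-distance maps.

    Raises
    ------
    FormatError
        If any non-root edge lacks a branch length.
    """
    entries: dict[tuple[str, str], float] = {}
    labels: list[str] = []
    submaps: dict[int, dict[str, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            if node.taxon is None or node.taxon.label is None:
                raise FormatError("unlabeled leaf in tree")
            lab = node.taxon.label
            labels.append(lab)
            submaps[id(node)] = {lab: 0.0}
            continue
        maps = []
        for ch in node.child_nodes():
            if ch.edge.length is None:
                raise FormatError("missing branch length in tree")
            cm = submaps.pop(id(ch))
            maps.append({k: v + ch.edge.length for k, v in cm.items()})
        for ia in range(len(maps)):
            for ib in range(ia + 1, len(maps)):
                for la, da in maps[ia].items():
                    for lb, db in maps[ib].items():
                        entries[(la, lb)] = da + db
        merged: dict[str, float] = {}
        for mp in maps:
            merged.update(mp)
        submaps[id(node)] = merged
    labels.sort()
    n = len(labels)
    pos = {lab: i for i, lab in enumerate(labels)}
    d = np.zeros((n, n))
    for (la, lb), v in entries.items():
        ia, ib = pos[la], pos[lb]
        d[ia, ib] = d[ib, ia] = v
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Newick / PHYLIP IO
# ---------------------------------------------------------------------------

def read_newick(source) -> dendropy.Tree:
    """Read a Newick tree from a path, string or file-like object."""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and ("(" in source or ";" in source):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    depth = 0
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError("unbalanced parentheses in Newick input")
    if depth != 0:
        raise FormatError("unbalanced parentheses in Newick input")
    try:
        return dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        raise FormatError(f"could not parse Newick input: {exc}") from exc


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize ``tree`` as Newick; write to ``path`` if given."""
    s = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Independent deep copy of a tree (fresh taxon namespace)."""
    return read_newick(write_newick(tree))


def write_phylip_square(dm: DistanceMatrix, path) -> None:
    """Write a square PHYLIP distance matrix (taxon name then full row)."""
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for i, lab in enumerate(dm.labels):
            row = " ".join(f"{x:.10f}" for x in dm.values[i])
            fh.write(f"{lab} {row}\n")


def read_phylip_square(path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix written by :func:`write_phylip_square`."""
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise FormatError("empty PHYLIP matrix file")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise FormatError("first line of PHYLIP matrix must be the taxon count") from exc
    if len(lines) - 1 != n:
        raise FormatError(f"expected {n} rows, found {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise FormatError(f"malformed PHYLIP row: {ln!r}")
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(labels, np.array(rows))


def genome_fasta_lengths(path) -> dict[str, int]:
    """Sequence lengths from a FASTA file (for coverage filtering)."""
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
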