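"""Kimura-1980 distances and neighbor-joining trees with bootstrap.

The Kimura two-parameter (K2P) distance between two aligned sequences is

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))

with P the transition (A<->G, C<->T) and Q the transversion proportion
over gap-free compared sites.  Trees are built by canonical
neighbor-joining over the distance matrix, with bootstrap supports from
column-resampled pseudoreplicates of a star alignment (all taxa aligned
to the first).  The pipeline's "near-whole-genome" mode truncates every
genome at the start of its control region, mirroring the fact that the
control region cannot be recovered from transcriptome data.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import AnnotatedGenome, MitomineError, ValidationError
from .mining import MiningParams

__all__ = [
    "AlignScoring",
    "PairCounts",
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "pairwise_align",
    "count_substitutions",
    "k2p_distance",
    "k2p_from_pq",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
]

logger = logging.getLogger(__name__)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class AlignScoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = 2
    gap_extend: int = 1

    def to_params(self) -> MiningParams:
        return MiningParams(
            match=self.match, mismatch=self.mismatch,
            gap_open=self.gap_open, gap_extend=self.gap_extend,
        )


def pairwise_align(a: str, b: str, scoring: AlignScoring = AlignScoring()):
    """Optimal global alignment with affine gaps; returns the two aligned
    strings.  Deterministic: the aligner's canonical first traceback."""
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    aligner = scoring.to_params().global_aligner()
    best = aligner.align(a.upper(), b.upper())[0]
    return str(best[0]), str(best[1])


@dataclass(frozen=True)
class PairCounts:
    """Substitution counts over the gap-free compared sites of a pair."""

    n: int
    s: int  # transitions
    v: int  # transversions

    def __post_init__(self) -> None:
        if self.s + self.v > self.n:
            raise ValidationError("s + v cannot exceed n")

    @property
    def P(self) -> float:
        return self.s / self.n

    @property
    def Q(self) -> float:
        return self.v / self.n


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _pair_counts(a: np.ndarray, b: np.ndarray) -> PairCounts:
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    if n == 0:
        raise ValidationError("no comparable (gap-free) columns")
    diff = valid & (a != b)
    ts = diff & ((a ^ b) == 2)  # A<->G and C<->T differ in code bit 1
    s = int(ts.sum())
    v = int(diff.sum()) - s
    return PairCounts(n=n, s=s, v=v)


def count_substitutions(a_aln: str, b_aln: str) -> PairCounts:
    """Transitions/transversions under pairwise deletion: columns with a
    gap or ambiguity character in either sequence are excluded."""
    if len(a_aln) != len(b_aln):
        raise ValidationError("aligned sequences must have equal length")
    return _pair_counts(_encode(a_aln.upper()), _encode(b_aln.upper()))


def k2p_from_pq(P: float, Q: float) -> float:
    """K2P distance from transition/transversion proportions; NaN when
    the log arguments leave the estimable domain."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        warnings.warn(
            f"K2P distance undefined (1-2P-Q={w1:.4g}, 1-2Q={w2:.4g})",
            stacklevel=2,
        )
        return math.nan
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return d + 0.0  # normalize -0.0


def k2p_distance(counts: PairCounts) -> float:
    return k2p_from_pq(counts.P, counts.Q)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances; NaN marks undefined entries."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T)):
            raise ValidationError("matrix is not symmetric")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(
            self.values[self.labels.index(a), self.labels.index(b)]
        )

    def undefined_pairs(self) -> list:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out


def _truncate_at_control(genome: AnnotatedGenome) -> str:
    ctl = [f for f in genome.features if f.cls == "control"]
    if not ctl:
        raise ValidationError(
            f"genome {genome.name!r} has no control-region feature to "
            "truncate at"
        )
    return genome.seq[: ctl[0].start - 1]


def _extract_sequences(genomes, mode: str, gene):
    labels, seqs = [], []
    for g in genomes:
        labels.append(g.name)
        if mode in ("whole", "whole-genome-85"):
            seqs.append(_truncate_at_control(g))
        elif mode in ("gene", "per-gene"):
            if gene is None:
                raise ValidationError("per-gene mode requires a gene name")
            try:
                f = g.feature(gene)
            except KeyError:
                seqs.append(None)
                continue
            seqs.append(None if f.unrecovered else g.feature_seq(gene))
        else:
            raise ValidationError(f"unknown mode {mode!r}")
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate genome names")
    return labels, seqs


def distance_matrix(
    genomes,
    mode: str = "whole",
    gene=None,
    deletion: str = "pairwise",
    scoring: AlignScoring = AlignScoring(),
    align: str = "auto",
) -> DistanceMatrix:
    """All-pairs K2P distances over annotated genomes.

    ``mode='whole'`` truncates each genome at its control-region start
    (the near-whole-genome comparison); ``mode='gene'`` compares one named
    gene, with NaN entries for taxa missing it.  With ``align='auto'``,
    equal-length sequence pairs are compared position-by-position (exact
    for the substitution-only pipeline) and unequal pairs are globally
    aligned first.  ``deletion='complete'`` drops columns that are
    gapped/ambiguous in *any* taxon and requires equal lengths.
    """
    labels, seqs = _extract_sequences(genomes, mode, gene)
    n = len(labels)
    if deletion not in ("pairwise", "complete"):
        raise ValidationError(f"unknown deletion rule {deletion!r}")
    codes = [None if s is None else _encode(s.upper()) for s in seqs]
    mask = None
    if deletion == "complete":
        present = [c for c in codes if c is not None]
        if len({len(c) for c in present}) != 1:
            raise ValidationError(
                "complete deletion requires equal-length sequences"
            )
        mask = np.ones(len(present[0]), dtype=bool)
        for c in present:
            mask &= c < 4
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            if seqs[i] is None or seqs[j] is None:
                values[i, j] = values[j, i] = math.nan
                continue
            a, b = codes[i], codes[j]
            if len(a) != len(b) or align == "always":
                if deletion == "complete":
                    raise ValidationError(
                        "complete deletion is incompatible with per-pair "
                        "alignment"
                    )
                aa, bb = pairwise_align(seqs[i], seqs[j], scoring)
                a, b = _encode(aa), _encode(bb)
            if mask is not None:
                a, b = a[mask], b[mask]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = k2p_distance(_pair_counts(a, b))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


# --------------------------------------------------------------------------
# neighbor joining


@dataclass
class TreeNode:
    label: str = None
    children: list = field(default_factory=list)  # (TreeNode, branch length)
    support: float = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree (root is a trifurcation for >= 3 taxa)."""

    root: TreeNode

    def leaves(self) -> list:
        return sorted(self.root.leaves())

    def bipartitions(self) -> set:
        """Nontrivial splits as frozensets of the side not containing the
        lexicographically first taxon."""
        taxa = self.leaves()
        ref = taxa[0]
        n = len(taxa)
        splits = set()

        def visit(node):
            for child, _ in node.children:
                if not child.is_leaf:
                    side = frozenset(child.leaves())
                    if ref in side:
                        side = frozenset(taxa) - side
                    if 2 <= len(side) <= n - 2:
                        splits.add(side)
                    visit(child)

        visit(self.root)
        return splits

    def _edge_nodes(self):
        """Internal non-root nodes (each owns one internal edge)."""
        out = []

        def visit(node):
            for child, _ in node.children:
                if not child.is_leaf:
                    out.append(child)
                    visit(child)

        visit(self.root)
        return out

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node, length):
            if node.is_leaf:
                body = node.label
            else:
                inner = ",".join(fmt(c, bl) for c, bl in node.children)
                label = ""
                if include_support and node.support is not None:
                    label = f"{node.support:g}"
                body = f"({inner}){label}"
            if length is None:
                return body
            return f"{body}:{length:.9f}"

        return fmt(self.root, None) + ";"

    def siblings(self, a: str, b: str) -> bool:
        """True if leaves a and b form a cherry."""

        def visit(node):
            leaf_children = {
                c.label for c, _ in node.children if c.is_leaf
            }
            if a in leaf_children and b in leaf_children:
                return True
            return any(visit(c) for c, _ in node.children if not c.is_leaf)

        return visit(self.root)


def nj_tree(matrix: DistanceMatrix) -> Tree:
    """Canonical neighbor joining (Saitou-Nei Q criterion).

    Ties in Q are broken by the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest leaf).
    Negative branch lengths are clamped to 0 with a warning.
    """
    bad = matrix.undefined_pairs()
    if bad:
        raise ValidationError(f"undefined distance entries: {bad}")
    n = len(matrix.labels)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")

    nodes = {i: TreeNode(label=lab) for i, lab in enumerate(matrix.labels)}
    tag = {i: lab for i, lab in enumerate(matrix.labels)}  # smallest leaf
    D = {
        (i, j): float(matrix.values[i, j])
        for i in range(n)
        for j in range(n)
        if i != j
    }
    active = set(range(n))
    next_id = n

    def dist(i, j):
        return D[(i, j)] if i != j else 0.0

    def clamp(x, what):
        if x < 0:
            logger.warning("negative branch length %.4g for %s clamped to 0",
                           x, what)
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        R = {i: sum(dist(i, m) for m in active if m != i) for i in active}
        best = None
        for i in active:
            for j in active:
                if i >= j:
                    continue
                q = (r - 2) * dist(i, j) - R[i] - R[j]
                key = (q, tuple(sorted((tag[i], tag[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = dij - li
        li = clamp(li, tag[i])
        lj = clamp(lj, tag[j])
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        k = next_id
        next_id += 1
        nodes[k] = new
        tag[k] = min(tag[i], tag[j])
        for m in active:
            if m in (i, j):
                continue
            dkm = 0.5 * (dist(i, m) + dist(j, m) - dij)
            D[(k, m)] = D[(m, k)] = dkm
        active.discard(i)
        active.discard(j)
        active.add(k)

    i, j, k = sorted(active, key=lambda x: tag[x])
    dij, dik, djk = dist(i, j), dist(i, k), dist(j, k)
    li = clamp(0.5 * (dij + dik - djk), tag[i])
    lj = clamp(0.5 * (dij + djk - dik), tag[j])
    lk = clamp(0.5 * (dik + djk - dij), tag[k])
    root = TreeNode(
        children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)]
    )
    return Tree(root=root)


# --------------------------------------------------------------------------
# bootstrap


def star_alignment(seqs, scoring: AlignScoring = AlignScoring()) -> np.ndarray:
    """Stack all taxa on the coordinate frame of the first sequence.

    Each other taxon is globally aligned to the first; its bases at the
    first taxon's ungapped columns form its row (255 where the taxon has
    a gap).  Equal-length inputs stack directly.
    """
    if not seqs:
        raise ValidationError("no sequences")
    ref = seqs[0].upper()
    rows = [_encode(ref)]
    for s in seqs[1:]:
        s = s.upper()
        if len(s) == len(ref):
            rows.append(_encode(s))
            continue
        a_aln, b_aln = pairwise_align(ref, s, scoring)
        a = np.frombuffer(a_aln.encode(), dtype=np.uint8)
        b = np.frombuffer(b_aln.encode(), dtype=np.uint8)
        keep = a != ord("-")
        rows.append(_CODE[b[keep]])
    return np.vstack(rows)


def _matrix_from_columns(columns: np.ndarray, labels) -> DistanceMatrix:
    n = columns.shape[0]
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = k2p_distance(_pair_counts(columns[i], columns[j]))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=list(labels), values=values)


def bootstrap_support(
    seqs,
    labels,
    b: int = 1000,
    seed: int = 0,
    scoring: AlignScoring = AlignScoring(),
    resample: bool = True,
) -> Tree:
    """NJ tree with bootstrap supports on internal edges.

    ``b`` column-resampled pseudoreplicates of the star alignment each
    yield a K2P matrix and NJ tree; an internal edge's support is the
    percentage of replicate trees containing the same bipartition.
    Deterministic under a fixed seed.  ``resample=False`` scores identity
    replicates (every support becomes 100), useful as a self-check.
    """
    if b < 1:
        raise ValidationError("bootstrap replicate count must be >= 1")
    if len(seqs) != len(labels):
        raise ValidationError("seqs and labels differ in length")
    columns = star_alignment(seqs, scoring)
    main = nj_tree(_matrix_from_columns(columns, labels))
    rng = np.random.default_rng(seed)
    ncol = columns.shape[1]
    counts: dict = {}
    ok = 0
    for _ in range(b):
        idx = rng.integers(0, ncol, ncol) if resample else np.arange(ncol)
        sub = columns[:, idx]
        try:
            rep = nj_tree(_matrix_from_columns(sub, labels))
        except ValidationError:
            continue  # saturated replicate: no tree, counts unchanged
        ok += 1
        for split in rep.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    denom = max(ok, 1)
    taxa = main.leaves()
    ref = taxa[0]
    for node in main._edge_nodes():
        side = frozenset(node.leaves())
        if ref in side:
            side = frozenset(taxa) - side
        node.support = 100.0 * counts.get(side, 0) / denom
    return main
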