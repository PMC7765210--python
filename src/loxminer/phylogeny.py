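"""Distance-based phylogenetics: Poisson-corrected distances, neighbor
joining with deterministic tie-breaking, column-resampling bootstrap, and a
simple progressive multiple aligner.

This is a desk-scale toolchain for displaying subfamily/clade structure. The
contract is topology-level (which sequences form a clade), not branch-length
agreement with likelihood methods; full ML inference is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import SequenceRecord


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances over named taxa."""

    ids: list[str]
    values: np.ndarray
    model: str = "p-distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match taxon count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("distances must be finite and non-negative")


def distances_from_alignment(msa: list[SequenceRecord],
                             model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances from an alignment, with pairwise gap deletion.

    p = mismatches / compared columns (columns gapped in either sequence are
    skipped per pair). ``model='poisson'`` applies the Poisson correction
    d = -ln(1 - p); ``model='p-distance'`` returns p itself. p = 1 under the
    Poisson correction is undefined and raises, naming the pair.
    """
    if model not in ("poisson", "p-distance"):
        raise ValueError(f"unknown distance model {model!r}")
    if len(msa) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(r.sequence) for r in msa}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    n = len(msa)
    arrs = [np.frombuffer(r.sequence.encode(), dtype="S1") for r in msa]
    gap = np.bytes_(b"-")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keep = (arrs[i] != gap) & (arrs[j] != gap)
            compared = int(keep.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable columns between {msa[i].id} and {msa[j].id}"
                )
            p = float((arrs[i][keep] != arrs[j][keep]).sum()) / compared
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"p-distance of 1 between {msa[i].id} and {msa[j].id}: "
                        "Poisson correction undefined"
                    )
                dij = -np.log(1.0 - p)
            else:
                dij = p
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids=[r.id for r in msa], values=d, model=model)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class Node:
    """A tree node; leaves carry a taxon name."""

    __slots__ = ("name", "children")

    def __init__(self, name: str | None = None,
                 children: list[tuple["Node", float]] | None = None):
        self.name = name
        self.children = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    """An unrooted tree stored with an arbitrary internal root of degree 3.

    ``supports`` maps canonical bipartitions (frozensets of taxa) to
    bootstrap percentages. ``clamped`` records that at least one negative NJ
    branch-length estimate was set to zero; ``degenerate`` flags an all-zero
    input matrix (star-like tree, supports not meaningful).
    """

    root: Node
    taxa: list[str]
    clamped: bool = False
    degenerate: bool = False
    supports: dict[frozenset, float] | None = None

    def leaf_order(self) -> list[str]:
        return self.root.leaves()

    def n_edges(self) -> int:
        def count(node):
            return sum(1 + count(child) for child, _ in node.children)
        return count(self.root)

    def bipartitions(self) -> set[frozenset]:
        """Canonical internal-edge bipartitions.

        Each internal edge splits the taxa in two; the side not containing
        the lexicographically first taxon is the canonical representative.
        """
        full = set(self.taxa)
        ref = min(full)
        out: set[frozenset] = set()

        def walk(node):
            for child, _ in node.children:
                below = set(child.leaves())
                if 1 < len(below) < len(full) - 1:
                    side = below if ref not in below else full - below
                    out.add(frozenset(side))
                walk(child)

        walk(self.root)
        return out

    def leaf_distances(self) -> DistanceMatrix:
        """Pairwise path-length distances between leaves."""
        dists: dict[str, dict[str, float]] = {}

        def below(node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            sides = []
            for child, blen in node.children:
                sub = {k: v + blen for k, v in below(child).items()}
                sides.append(sub)
            merged: dict[str, float] = {}
            for i, si in enumerate(sides):
                for j in range(i + 1, len(sides)):
                    for a, da in si.items():
                        for b, db in sides[j].items():
                            dists.setdefault(a, {})[b] = da + db
                            dists.setdefault(b, {})[a] = da + db
                merged.update(si)
            return merged

        below(self.root)
        ids = sorted(self.taxa)
        n = len(ids)
        mat = np.zeros((n, n))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i != j:
                    mat[i, j] = dists[a][b]
        return DistanceMatrix(ids=ids, values=mat, model="path-length")

    def to_newick(self, with_supports: bool = False) -> str:
        full = set(self.taxa)
        ref = min(full)

        def label(node) -> str:
            if not with_supports or self.supports is None or node.is_leaf:
                return ""
            below = set(node.leaves())
            if not 1 < len(below) < len(full) - 1:
                return ""
            side = below if ref not in below else full - below
            sup = self.supports.get(frozenset(side))
            return "" if sup is None else f"{sup:.0f}"

        def fmt(node, blen=None) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, b) for c, b in node.children)
                body = f"({inner}){label(node)}"
            return body if blen is None else f"{body}:{blen:.6f}"

        return fmt(self.root) + ";"


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The minimum-Q pair with the lowest (row, column) index is always joined
    first, so identical inputs give identical trees. Negative branch-length
    estimates are clamped to zero and flagged on the tree. Any additive
    matrix is recovered exactly (topology and branch lengths).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.values.astype(float).copy()
    nodes: list[Node] = [Node(name=t) for t in dm.ids]
    clamped = False

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))          # row-major: lowest-index tie-break
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        new = Node(children=[(nodes[i], li), (nodes[j], lj)])
        dk = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.zeros((m - 1, m - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = D_new[:-1, -1] = dk[keep]
        D = D_new
        nodes = [nodes[k] for k in keep] + [new]

    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    if min(la, lb, lc) < 0:
        clamped = True
    root = Node(children=[(nodes[0], max(la, 0.0)),
                          (nodes[1], max(lb, 0.0)),
                          (nodes[2], max(lc, 0.0))])
    return Tree(root=root, taxa=list(dm.ids), clamped=clamped,
                degenerate=bool(np.allclose(dm.values, 0.0)))


def bootstrap_support(msa: list[SequenceRecord], model: str = "poisson",
                      replicates: int = 1000,
                      seed: int | None = None) -> Tree:
    """NJ tree with bootstrap supports from column resampling.

    Alignment columns are resampled with replacement *replicates* times; the
    support of each internal bipartition of the full-data tree is the
    percentage of replicate trees containing it. Seeded and reproducible;
    supports are invariant to taxon input order because bipartitions are
    compared as sets.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    tree = neighbor_joining(distances_from_alignment(msa, model))
    rng = np.random.default_rng(seed)
    length = len(msa[0].sequence)
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = [
            SequenceRecord(r.id, "".join(r.sequence[c] for c in cols),
                           r.alphabet)
            for r in msa
        ]
        try:
            rep_tree = neighbor_joining(distances_from_alignment(resampled, model))
        except ValueError:
            continue  # e.g. saturated replicate under Poisson correction
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    tree.supports = {bp: 100.0 * c / replicates for bp, c in counts.items()}
    return tree


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile_consensus(rows: list[str]) -> str:
    """Majority non-gap character per column (first alphabetically on ties);
    all-gap columns yield 'X' so the scanner treats them neutrally."""
    out = []
    for col in zip(*rows):
        residues = [c for c in col if c != "-"]
        if not residues:
            out.append("X")
            continue
        best = max(sorted(set(residues)), key=residues.count)
        out.append(best)
    return "".join(out)


def align_progressive(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Greedy progressive multiple alignment.

    Sequences are added in guide-tree order (neighbor joining on k-mer
    distances); each new sequence is globally aligned against the running
    profile's consensus with the pairwise engine, and any insertions open
    gap columns across the whole profile. De-gapping the output always
    restores the input sequences exactly.
    """
    from .comparative_genomics import AlignmentParams, _make_aligner

    if len(records) < 2:
        raise ValueError("need at least two sequences")
    alphabet = records[0].alphabet
    if any(r.alphabet != alphabet for r in records):
        raise ValueError("mixed alphabets")

    if len(records) > 2:
        n = len(records)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = _kmer_distance(records[i].sequence,
                                                   records[j].sequence)
        guide = neighbor_joining(DistanceMatrix(
            ids=[str(i) for i in range(n)], values=d, model="kmer"))
        order = [int(name) for name in guide.leaf_order()]
    else:
        order = [0, 1]

    params = (AlignmentParams.protein_default() if alphabet == "protein"
              else AlignmentParams.nucleotide_default())
    aligner = _make_aligner(params)

    ordered = [records[i] for i in order]
    profile = [ordered[0].sequence]
    names = [ordered[0].id]
    for rec in ordered[1:]:
        consensus = _profile_consensus(profile)
        alignment = aligner.align(consensus, rec.sequence)[0]
        cons_row, seq_row = str(alignment[0]), str(alignment[1])
        new_profile = ["" for _ in profile]
        new_row = ""
        ci = 0  # index into existing profile columns
        for cc, sc in zip(cons_row, seq_row):
            if cc == "-":
                for k in range(len(new_profile)):
                    new_profile[k] += "-"
                new_row += sc
            else:
                for k in range(len(new_profile)):
                    new_profile[k] += profile[k][ci]
                ci += 1
                new_row += sc
        profile = new_profile + [new_row]
        names.append(rec.id)

    by_name = dict(zip(names, profile))
    return [SequenceRecord(r.id, by_name[r.id], alphabet) for r in records]
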