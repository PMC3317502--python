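"""Distance-based phylogenetics: p-distance, neighbour-joining, bootstrap.

The engine follows the classic published recipes exactly:

* amino-acid p-distance with *pairwise deletion* — for each sequence pair
  only the columns where neither member is a gap (``-``) or missing (``X``)
  are compared, and the distance is the fraction of those that differ;
* neighbour-joining on the resulting matrix, with the standard Q criterion
  ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``, two-term branch lengths, and the
  usual reduction ``d(u,k) = (d(i,k) + d(j,k) - d(i,j)) / 2``.  Ties in Q
  are broken by the lexicographically smallest cluster-label pair and
  negative branch lengths are clamped to zero;
* non-parametric bootstrap: alignment columns are resampled with
  replacement, a replicate NJ tree is built per resample, and each internal
  edge of the original tree is annotated with the percentage of replicates
  containing the same leaf bipartition;
* majority-rule consensus over a set of trees on one leaf set.

Family assignment is distance-based rather than tree-reading: each query
domain gets the family whose reference set it is closest to on mean
pairwise-deletion p-distance, provided the runner-up is at least
``ambiguity_margin`` further away; a receptor is called by majority vote
over its domains and flagged chimeric when its assigned domains span more
than one family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import needleman_wunsch
from .discovery import DomainProfile

GAPLIKE = {"-", "X"}


# ---------------------------------------------------------------------------
# alignment container and star alignment


@dataclass(frozen=True)
class DomainAlignment:
    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        if self.rows and any(len(r) != len(self.rows[0]) for r in self.rows):
            raise ValueError("alignment rows must be equal length")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def subsample_columns(self, idx: np.ndarray) -> "DomainAlignment":
        rows = tuple("".join(r[i] for i in idx) for r in self.rows)
        return DomainAlignment(self.labels, rows)


def build_domain_alignment(
    domain_seqs: dict[str, str], anchor: DomainProfile
) -> tuple[DomainAlignment, int]:
    """Star-align sequences into the anchor consensus coordinate frame.

    Each sequence is globally aligned to the anchor consensus; residues
    aligned to anchor positions are stacked, residues inserted relative to
    the anchor are dropped.  Returns the alignment and the number of
    dropped insertion residues.
    """
    if len(domain_seqs) < 2:
        raise ValueError("need at least two sequences to build an alignment")
    labels = tuple(domain_seqs)
    rows = []
    dropped = 0
    for label in labels:
        seq = domain_seqs[label]
        if not seq:
            raise ValueError(f"empty sequence: {label}")
        a_seq, a_anchor, _ = needleman_wunsch(seq, anchor.consensus)
        row = []
        for s, c in zip(a_seq, a_anchor):
            if c == "-":  # insertion relative to anchor
                if s != "-":
                    dropped += 1
            else:
                row.append(s if s != "-" else "-")
        rows.append("".join(row))
    return DomainAlignment(labels, tuple(rows)), dropped


# ---------------------------------------------------------------------------
# distances


def p_distance(row_a: str, row_b: str) -> tuple[float, int]:
    """Pairwise-deletion amino-acid p-distance.

    Columns where either row is ``-`` or ``X`` are skipped.  Returns
    ``(distance, compared_sites)``; with zero comparable sites the distance
    is NaN (flagged undefined, not an exception).
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    compared = 0
    diff = 0
    for a, b in zip(row_a, row_b):
        if a in GAPLIKE or b in GAPLIKE:
            continue
        compared += 1
        if a != b:
            diff += 1
    if compared == 0:
        return float("nan"), 0
    return diff / compared, compared


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # (n, n) float, NaN where undefined
    sites: np.ndarray  # (n, n) int compared-site counts

    @property
    def has_undefined(self) -> bool:
        n = len(self.labels)
        off = ~np.eye(n, dtype=bool)
        return bool(np.isnan(self.d[off]).any())


def _encode_rows(rows: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.array([np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in rows])
    valid = (arr != ord("-")) & (arr != ord("X"))
    return arr, valid


def distance_matrix(aln: DomainAlignment) -> DistanceMatrix:
    """All-vs-all pairwise-deletion p-distances (symmetric, zero diagonal)."""
    n = len(aln.labels)
    if n < 2:
        raise ValueError("need at least two rows")
    arr, valid = _encode_rows(aln.rows)
    d = np.zeros((n, n), dtype=float)
    sites = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(sites, valid.sum(axis=1))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        comp = both.sum(axis=1)
        diff = ((arr[i] != arr[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(comp > 0, diff / np.maximum(comp, 1), np.nan)
        d[i, i + 1 :] = dist
        d[i + 1 :, i] = dist
        sites[i, i + 1 :] = comp
        sites[i + 1 :, i] = comp
    return DistanceMatrix(aln.labels, d, sites)


# ---------------------------------------------------------------------------
# trees


@dataclass
class PhyloTree:
    """Unrooted tree: leaves are labelled strings, internal nodes integers."""

    leaf_labels: tuple[str, ...]
    edges: list[tuple[object, object, float]]  # (node, node, length)
    supports: dict[frozenset, float] = field(default_factory=dict)

    def adjacency(self) -> dict:
        adj: dict = {}
        for a, b, w in self.edges:
            adj.setdefault(a, []).append((b, w))
            adj.setdefault(b, []).append((a, w))
        return adj

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, one canonical frozenset per edge.

        Each internal edge is represented by the leaf set on the side NOT
        containing the lexicographically smallest leaf.
        """
        leaves = set(self.leaf_labels)
        if len(leaves) < 4:
            return set()
        smallest = min(leaves)
        adj = self.adjacency()
        out = set()
        for a, b, _ in self.edges:
            side = self._leafset_beyond(adj, a, b)
            if 1 < len(side) < len(leaves) - 1:
                if smallest in side:
                    side = leaves - side
                out.add(frozenset(side))
        return out

    def _leafset_beyond(self, adj, src, dst) -> set:
        """Leaves reachable from dst without crossing back through src."""
        seen = {src, dst}
        stack = [dst]
        leaves = set()
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                leaves.add(node)
            for nxt, _ in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return leaves

    def path_length(self, a: str, b: str) -> float:
        adj = self.adjacency()
        stack = [(a, 0.0)]
        seen = {a}
        while stack:
            node, dist = stack.pop()
            if node == b:
                return dist
            for nxt, w in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, dist + w))
        raise KeyError(f"no path {a}..{b}")

    def to_newick(self, decimals: int = 6) -> str:
        adj = self.adjacency()
        if len(self.leaf_labels) == 1:
            return f"{self.leaf_labels[0]};"
        # root at an internal node if any, else first leaf
        internal = [n for n in adj if not isinstance(n, str)]
        root = internal[0] if internal else self.leaf_labels[0]
        sup_by_edge: dict[frozenset, float] = self.supports
        leaves = set(self.leaf_labels)
        smallest = min(leaves) if leaves else None

        def fmt(node, parent, length):
            if isinstance(node, str):
                body = node
            else:
                parts = [
                    fmt(nxt, node, w) for nxt, w in adj[node] if nxt != parent
                ]
                label = ""
                if parent is not None and sup_by_edge:
                    side = self._leafset_beyond(adj, parent, node)
                    if 1 < len(side) < len(leaves) - 1:
                        key = frozenset(leaves - side if smallest in side else side)
                        if key in sup_by_edge:
                            label = str(int(round(sup_by_edge[key])))
                body = f"({','.join(parts)}){label}"
            if length is None:
                return body
            return f"{body}:{length:.{decimals}f}"

        return fmt(root, None, None) + ";"


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbour-joining on a complete distance matrix.

    Deterministic: Q ties are broken by the lexicographically smallest
    (cluster label, cluster label) sorted pair, where a cluster's label is
    its smallest member leaf.  Negative branch lengths are clamped to 0.
    """
    n0 = len(dm.labels)
    if n0 < 2:
        raise ValueError("need at least two taxa")
    if dm.has_undefined:
        raise ValueError("distance matrix contains undefined entries")
    labels = list(dm.labels)
    D = dm.d.astype(float).copy()
    nodes: list[object] = list(labels)  # leaf label strings
    cluster_label = list(labels)  # smallest-leaf label per active cluster
    edges: list[tuple[object, object, float]] = []
    next_internal = 0

    if n0 == 2:
        mid = 0
        half = float(D[0, 1]) / 2.0
        edges.append((nodes[0], mid, half))
        edges.append((nodes[1], mid, half))
        return PhyloTree(tuple(labels), edges)

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # Q is only symmetric up to floating-point summation order, so
        # canonicalise each tie to (min, max) rather than assuming both
        # orientations appear
        ties = np.argwhere(Q == qmin)
        best = None
        for a, b in ties:
            i, j = (int(a), int(b)) if a < b else (int(b), int(a))
            key = tuple(sorted((cluster_label[i], cluster_label[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = next_internal
        next_internal += 1
        edges.append((nodes[i], u, float(li)))
        edges.append((nodes[j], u, float(lj)))
        du = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        newD = np.empty((n - 1, n - 1), dtype=float)
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = du[keep]
        newD[:-1, -1] = du[keep]
        newD[-1, -1] = 0.0
        D = newD
        new_label = min(cluster_label[i], cluster_label[j])
        nodes = [nodes[k] for k in keep] + [u]
        cluster_label = [cluster_label[k] for k in keep] + [new_label]

    # final three-way join with closed-form lengths
    u = next_internal
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max(0.0, (d01 + d02 - d12) / 2.0)
    l1 = max(0.0, (d01 + d12 - d02) / 2.0)
    l2 = max(0.0, (d02 + d12 - d01) / 2.0)
    edges.append((nodes[0], u, float(l0)))
    edges.append((nodes[1], u, float(l1)))
    edges.append((nodes[2], u, float(l2)))
    return PhyloTree(tuple(labels), edges)


def bootstrap_supports(
    aln: DomainAlignment,
    n_replicates: int,
    seed: int,
    max_redraw: int = 1000,
) -> tuple[PhyloTree, int]:
    """NJ tree on the full alignment with bootstrap supports on internal edges.

    Column indices are resampled with replacement per replicate; replicates
    whose distance matrix has an undefined pair are redrawn.  Returns the
    tree and the number of redraws.  With fewer than four leaves there are
    no internal edges and supports stay empty.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    dm = distance_matrix(aln)
    tree = nj_tree(dm)
    if len(aln.labels) < 4:
        return tree, 0
    base_splits = tree.bipartitions()
    counts = {s: 0 for s in base_splits}
    rng = np.random.default_rng(seed)
    C = aln.column_count
    redraws = 0
    done = 0
    while done < n_replicates:
        idx = rng.integers(0, C, size=C)
        rep = aln.subsample_columns(idx)
        rdm = distance_matrix(rep)
        if rdm.has_undefined:
            redraws += 1
            if redraws > max_redraw:
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        rep_splits = nj_tree(rdm).bipartitions()
        for s in base_splits:
            if s in rep_splits:
                counts[s] += 1
        done += 1
    tree.supports = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    return tree, redraws


def majority_consensus(trees: list[PhyloTree], threshold: float = 50.0) -> PhyloTree:
    """Majority-rule consensus: keep bipartitions in > threshold% of trees.

    ``threshold`` must be >= 50 so retained splits are mutually compatible.
    Edge lengths are not defined on a consensus; supports carry the split
    frequencies.
    """
    if threshold < 50.0:
        raise ValueError("threshold must be >= 50")
    if not trees:
        raise ValueError("no trees given")
    leafset = set(trees[0].leaf_labels)
    for t in trees[1:]:
        if set(t.leaf_labels) != leafset:
            raise ValueError("trees must share one leaf set")
    counts: dict[frozenset, int] = {}
    for t in trees:
        for s in t.bipartitions():
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    kept = {s: 100.0 * c / n for s, c in counts.items() if 100.0 * c / n > threshold}
    leaves = sorted(leafset)
    # build rooted representation from compatible splits, then emit unrooted
    # star + refinement: children sets under a virtual root
    edges: list[tuple[object, object, float]] = []
    next_id = 0
    root = f"__root{next_id}"
    next_id += 1
    parent_groups: dict[object, list] = {root: []}
    node_leafset: dict[object, set] = {}
    for x in leaves:
        parent_groups[root].append(x)
        node_leafset[x] = {x}
    # insert splits largest-first so parents precede children
    for split in sorted(kept, key=lambda s: -len(s)):
        s = set(split)
        # find current parent: the node whose child-group covers s minimally
        parent = root
        changed = True
        while changed:
            changed = False
            for child in parent_groups.get(parent, []):
                if child in parent_groups and s < node_leafset[child]:
                    parent = child
                    changed = True
                    break
        group = parent_groups[parent]
        inside = [c for c in group if node_leafset[c] <= s]
        covered = set().union(*(node_leafset[c] for c in inside)) if inside else set()
        if covered != s:
            continue  # incompatible split (cannot happen at threshold >= 50)
        new = f"__n{next_id}"
        next_id += 1
        parent_groups[new] = inside
        node_leafset[new] = s
        parent_groups[parent] = [c for c in group if c not in inside] + [new]
    # flatten to edges; internal nodes become ints for PhyloTree convention
    rename: dict[object, object] = {}
    k = 0
    for node in parent_groups:
        rename[node] = k
        k += 1
    def walk(node):
        for child in parent_groups[node]:
            if child in parent_groups:
                edges.append((rename[node], rename[child], 0.0))
                walk(child)
            else:
                edges.append((rename[node], child, 0.0))

    walk(root)
    tree = PhyloTree(tuple(leaves), edges)
    # keep only splits actually representable as bipartitions of the built tree
    built = tree.bipartitions()
    tree.supports = {s: f for s, f in kept.items() if s in built}
    return tree


# ---------------------------------------------------------------------------
# family assignment


@dataclass(frozen=True)
class DomainCall:
    domain_id: str
    best_family: str  # family label or "unassigned"
    margin: float
    mean_distances: dict[str, float]


@dataclass(frozen=True)
class ReceptorCall:
    receptor_id: str
    family: str  # majority family or "unassigned"
    vote_fraction: float
    chimeric: bool
    domain_calls: tuple[DomainCall, ...]


@dataclass(frozen=True)
class FamilyAssignment:
    domains: tuple[DomainCall, ...]
    receptors: tuple[ReceptorCall, ...]


def assign_family(
    query_rows: dict[str, str],
    reference_rows: dict[str, tuple[str, str]],
    receptor_of: dict[str, str],
    ambiguity_margin: float = 0.05,
) -> FamilyAssignment:
    """Assign each query domain, then each receptor, to a reference family.

    ``query_rows`` maps domain id to an aligned row; ``reference_rows`` maps
    reference id to ``(family, aligned row)``; all rows share one coordinate
    frame.  A domain is assigned to its nearest family by mean
    pairwise-deletion p-distance when the runner-up family is at least
    ``ambiguity_margin`` further away, otherwise "unassigned".  Receptors
    take the majority family over their domains (ties and all-unassigned
    yield "unassigned") and are flagged chimeric when their assigned
    domains span two or more families.
    """
    families = sorted({fam for fam, _ in reference_rows.values()})
    if not families:
        raise ValueError("empty reference set")
    by_family: dict[str, list[str]] = {f: [] for f in families}
    for _, (fam, row) in reference_rows.items():
        by_family[fam].append(row)
    domain_calls = []
    for did, row in query_rows.items():
        means: dict[str, float] = {}
        for fam in families:
            ds = [
                d
                for d, s in (p_distance(row, ref) for ref in by_family[fam])
                if s > 0
            ]
            means[fam] = float(np.mean(ds)) if ds else float("nan")
        defined = {f: m for f, m in means.items() if not np.isnan(m)}
        if not defined:
            domain_calls.append(DomainCall(did, "unassigned", float("nan"), means))
            continue
        ranked = sorted(defined.items(), key=lambda kv: (kv[1], kv[0]))
        best_fam, best_d = ranked[0]
        margin = (ranked[1][1] - best_d) if len(ranked) > 1 else float("inf")
        call = best_fam if margin >= ambiguity_margin else "unassigned"
        domain_calls.append(DomainCall(did, call, margin, means))
    calls_by_receptor: dict[str, list[DomainCall]] = {}
    for dc in domain_calls:
        rid = receptor_of[dc.domain_id]
        calls_by_receptor.setdefault(rid, []).append(dc)
    receptors = []
    for rid, dcs in calls_by_receptor.items():
        assigned = [dc.best_family for dc in dcs if dc.best_family != "unassigned"]
        if not assigned:
            fam, frac = "unassigned", 0.0
        else:
            tally: dict[str, int] = {}
            for f in assigned:
                tally[f] = tally.get(f, 0) + 1
            top = max(tally.values())
            winners = sorted(f for f, c in tally.items() if c == top)
            if len(winners) > 1:
                fam, frac = "unassigned", top / len(dcs)
            else:
                fam, frac = winners[0], top / len(dcs)
        chimeric = len(set(assigned)) >= 2
        receptors.append(
            ReceptorCall(rid, fam, frac, chimeric, tuple(dcs))
        )
    return FamilyAssignment(tuple(domain_calls), tuple(receptors))
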