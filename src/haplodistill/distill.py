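"""Split block haplotypes into two deep clades and characterise them.

The haplotypes inside the LD block fall into two deeply diverged clades.
This module builds pairwise Hamming distances, reconstructs a
neighbor-joining tree, roots it on an outgroup to obtain the two-clade
split, measures bootstrap bipartition support, derives the per-clade core
(consensus) haplotypes, and computes spatial (per-population) and temporal
(ancient-sample) clade frequencies.

Clade numbering follows the common/rare convention: clade 1 is the larger
clade, clade 2 the smaller one (ties broken by the first haplotype label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import MISSING, AncientSampleTable, DataError, HaplotypeMatrix

# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise difference counts with compared-site counts."""

    labels: list[str]
    d: np.ndarray
    n_compared: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.d, self.d.T):
            raise DataError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise DataError("distance matrix diagonal must be zero")

    def index(self, label: str) -> int:
        return self.labels.index(label)


def hamming_distances(
    matrix: HaplotypeMatrix,
    extra_sequences: Mapping[str, np.ndarray] | None = None,
) -> DistanceMatrix:
    """Pairwise difference counts between haplotypes (pairwise deletion).

    ``extra_sequences`` maps extra labels (outgroup, archaic pseudo-haplotypes)
    to allele vectors aligned to ``matrix.variants``; entries may be 0, 1,
    0.5 (heterozygous archaic site, counted as half a difference) or NaN
    (missing).
    """
    cols = [matrix.alleles[:, j].astype(float) for j in range(matrix.n_haplotypes)]
    labels = matrix.haplotype_ids
    for c in cols:
        c[c == MISSING] = np.nan
    if extra_sequences:
        for name, seq in extra_sequences.items():
            seq = np.asarray(seq, dtype=float)
            if seq.shape[0] != matrix.n_variants:
                raise DataError(
                    f"extra sequence {name!r}: {seq.shape[0]} sites, "
                    f"expected {matrix.n_variants}"
                )
            labels = labels + [name]
            cols.append(seq)
    if len(cols) < 2:
        raise DataError("need at least 2 haplotypes for distances")
    X = np.column_stack(cols)
    valid = ~np.isnan(X)
    n = X.shape[1]
    d = np.zeros((n, n))
    nc = np.zeros((n, n), dtype=np.int64)
    if valid.all():
        # no missing data: X @ X^T trick on 0/1 (0.5 entries handled below)
        diff = np.abs(X[:, :, None] - X[:, None, :]) if n <= 64 else None
        if diff is not None:
            d = diff.sum(axis=0)
        else:
            for i in range(n):
                d[i] = np.abs(X - X[:, [i]]).sum(axis=0)
        nc[:] = X.shape[0]
    else:
        for i in range(n):
            both = valid & valid[:, [i]]
            delta = np.abs(X - X[:, [i]])
            delta[~both] = 0.0
            d[i] = delta.sum(axis=0)
            nc[i] = both.sum(axis=0)
        if np.any((nc == 0) & ~np.eye(n, dtype=bool)):
            raise DataError("a haplotype pair shares zero comparable sites")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d, nc)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


class Tree:
    """Unrooted tree as an adjacency map; leaves carry string names."""

    def __init__(self) -> None:
        self.adj: dict[int, list[tuple[int, float]]] = {}
        self.name: dict[int, str] = {}
        self._next = 0

    def new_node(self, name: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = []
        if name is not None:
            self.name[nid] = name
        return nid

    def connect(self, a: int, b: int, length: float) -> None:
        self.adj[a].append((b, length))
        self.adj[b].append((a, length))

    @property
    def leaves(self) -> list[int]:
        return [n for n in self.adj if len(self.adj[n]) == 1 and n in self.name]

    def leaf_by_name(self, name: str) -> int:
        for n, nm in self.name.items():
            if nm == name:
                return n
        raise KeyError(name)

    def component_leaves(self, start: int, blocked: int) -> set[str]:
        """Leaf names reachable from ``start`` without crossing ``blocked``."""
        seen = {blocked, start}
        stack = [start]
        out: set[str] = set()
        while stack:
            u = stack.pop()
            if u in self.name and len(self.adj[u]) == 1:
                out.add(self.name[u])
            for v, _ in self.adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if start in self.name and len(self.adj[start]) == 1:
            out.add(self.name[start])
        return out

    def bipartitions(self) -> list[frozenset[str]]:
        """For every internal edge, the leaf-name set on one side."""
        out = []
        for u in self.adj:
            for v, _ in self.adj[u]:
                if u < v:
                    out.append(frozenset(self.component_leaves(v, u)))
        return out

    def has_bipartition(self, side: frozenset[str]) -> bool:
        """Whether some edge splits the leaves into ``side`` vs the rest.

        Uses integer bitmasks over leaf indices for speed (this runs inside
        the bootstrap loop).
        """
        leaves = self.leaves
        bit = {self.name[l]: i for i, l in enumerate(leaves)}
        if not side <= bit.keys():
            return False
        target = 0
        for nm in side:
            target |= 1 << bit[nm]
        full = (1 << len(leaves)) - 1
        root = leaves[0]
        # iterative post-order computing subtree leaf masks below each edge
        masks: dict[int, int] = {}
        stack: list[tuple[int, int, bool]] = [(root, -1, False)]
        found = False
        while stack:
            u, parent, done = stack.pop()
            if not done:
                stack.append((u, parent, True))
                for v, _ in self.adj[u]:
                    if v != parent:
                        stack.append((v, u, False))
            else:
                m = 1 << bit[self.name[u]] if u in self.name and len(self.adj[u]) == 1 else 0
                for v, _ in self.adj[u]:
                    if v != parent:
                        m |= masks[v]
                masks[u] = m
                if m == target or m == full ^ target:
                    found = True
        return found

    def newick(self, root_name: str | None = None) -> str:
        """Serialise to newick.

        With ``root_name`` the tree is written from the named leaf's
        attachment node, so that leaf (e.g. the outgroup) appears as a
        terminal child of the root.
        """
        if root_name is not None:
            leaf = self.leaf_by_name(root_name)
            (root, _), = self.adj[leaf]
        else:
            root = next(iter(self.adj))

        def sub(u: int, parent: int) -> str:
            children = [(v, ln) for v, ln in self.adj[u] if v != parent]
            if not children:
                return f"{self.name.get(u, '')}"
            inner = ",".join(f"{sub(v, u)}:{ln:.6g}" for v, ln in children)
            return f"({inner}){self.name.get(u, '')}"

        return sub(root, -1) + ";"


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor-joining (Saitou & Nei) with deterministic tie-breaking.

    On equal Q values the pair with the lowest (row, column) index is
    joined, so the result depends only on input order.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise DataError("neighbor joining needs at least 3 taxa")
    tree = Tree()
    nodes = [tree.new_node(lbl) for lbl in dm.labels]
    D = dm.d.astype(float).copy()
    active = list(range(n0))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie-break: argmin on flattened row-major array
        flat = np.argmin(Q)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # guard against negative branch lengths (standard NJ practice)
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = tree.new_node()
        tree.connect(parent, nodes[active[i]], li)
        tree.connect(parent, nodes[active[j]], lj)
        # distances from new node to the rest
        new_row = 0.5 * (sub[i, :] + sub[j, :] - dij)
        gi, gj = active[i], active[j]
        D = np.pad(D, ((0, 1), (0, 1)))
        new_idx = D.shape[0] - 1
        for k_local, k_global in enumerate(active):
            D[new_idx, k_global] = D[k_global, new_idx] = new_row[k_local]
        nodes.append(parent)
        active = [a for a in active if a not in (gi, gj)] + [new_idx]
    # connect the last two
    a, b = active
    tree.connect(nodes[a], nodes[b], max(D[a, b], 0.0))
    return tree


# ---------------------------------------------------------------------------
# Clade assignment
# ---------------------------------------------------------------------------


@dataclass
class CladeAssignment:
    """Haplotype id -> clade {1, 2}, with ambiguity bookkeeping."""

    assignment: dict[str, int]
    method: str
    #: haplotypes whose distances to the two clade medoids differ by <10%
    ambiguous: list[str] = field(default_factory=list)
    #: haplotypes that could not be assigned (e.g. missing tag allele)
    unassigned: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = self.clade_sizes()
        if sizes[1] == 0 or sizes[2] == 0:
            raise DataError("clade assignment must yield two non-empty clades")

    def clade_sizes(self) -> dict[int, int]:
        out = {1: 0, 2: 0}
        for c in self.assignment.values():
            out[c] += 1
        return out

    def members(self, clade: int) -> list[str]:
        return [h for h, c in self.assignment.items() if c == clade]


def _canonical_numbering(
    groups: tuple[set[str], set[str]], order: Sequence[str]
) -> dict[str, int]:
    """Larger group becomes clade 1; ties go to the group holding the first
    haplotype in column order."""
    g1, g2 = groups
    if len(g2) > len(g1) or (len(g2) == len(g1) and order[0] in g2):
        g1, g2 = g2, g1
    out = {h: 1 for h in g1}
    out.update({h: 2 for h in g2})
    return out


def _medoid_ambiguity(
    dm: DistanceMatrix, assignment: dict[str, int], rel_tol: float = 0.10
) -> list[str]:
    """Haplotypes nearly equidistant from the two clade medoids."""
    idx = {l: i for i, l in enumerate(dm.labels)}
    med = {}
    for clade in (1, 2):
        members = [idx[h] for h, c in assignment.items() if c == clade and h in idx]
        if not members:
            return []
        sub = dm.d[np.ix_(members, members)]
        med[clade] = members[int(np.argmin(sub.sum(axis=1)))]
    out = []
    for h in assignment:
        if h not in idx:
            continue
        d1, d2 = dm.d[idx[h], med[1]], dm.d[idx[h], med[2]]
        mean = 0.5 * (d1 + d2)
        if mean > 0 and abs(d1 - d2) < rel_tol * mean:
            out.append(h)
    return out


def assign_clades(
    matrix: HaplotypeMatrix,
    method: str = "nj_root_split",
    outgroup_label: str | None = None,
    outgroup_sequence: np.ndarray | None = None,
    tag_vid: str | None = None,
) -> CladeAssignment:
    """Partition block haplotypes into the two deep clades.

    Methods
    -------
    ``nj_root_split``
        Build an NJ tree including the outgroup, root on the outgroup's
        attachment edge, and take the two subtrees on the ingroup side.
        Requires ``outgroup_sequence`` (aligned 0/1 vector) or an
        ``outgroup_label`` already present as a matrix column.
    ``kmeans2``
        Deterministic 2-medoids on Hamming distances, seeded with the most
        distant haplotype pair.
    ``tag_allele``
        Split by the carried allele at ``tag_vid``; haplotypes missing the
        tag are left unassigned.
    """
    hap_ids = matrix.haplotype_ids
    if method == "tag_allele":
        if tag_vid is None:
            raise DataError("tag_allele method requires tag_vid")
        row = matrix.alleles[matrix.vid_index(tag_vid)]
        carriers0 = {h for h, a in zip(hap_ids, row) if a == 0}
        carriers1 = {h for h, a in zip(hap_ids, row) if a == 1}
        unassigned = [h for h, a in zip(hap_ids, row) if a == MISSING]
        if not carriers0 or not carriers1:
            raise DataError(f"tag variant {tag_vid} is monomorphic")
        assignment = _canonical_numbering((carriers0, carriers1), hap_ids)
        dm = hamming_distances(matrix)
        return CladeAssignment(
            assignment, method, _medoid_ambiguity(dm, assignment), unassigned
        )

    if method == "kmeans2":
        dm = hamming_distances(matrix)
        assignment = _two_medoids(dm)
        return CladeAssignment(assignment, method, _medoid_ambiguity(dm, assignment))

    if method == "nj_root_split":
        og_name = outgroup_label or "outgroup"
        extra = None
        if outgroup_sequence is not None:
            extra = {og_name: np.asarray(outgroup_sequence, dtype=float)}
        elif outgroup_label is None or outgroup_label not in hap_ids:
            raise DataError("nj_root_split requires an outgroup")
        dm = hamming_distances(matrix, extra_sequences=extra)
        tree = nj_tree(dm)
        og_leaf = tree.leaf_by_name(og_name)
        (attach, _), = tree.adj[og_leaf]
        parts = [
            tree.component_leaves(v, attach)
            for v, _ in tree.adj[attach]
            if v != og_leaf
        ]
        if len(parts) != 2:
            raise DataError("outgroup attachment does not split ingroup in two")
        g1 = set(parts[0]) - {og_name}
        g2 = set(parts[1]) - {og_name}
        assignment = _canonical_numbering((g1, g2), hap_ids)
        dm_in = hamming_distances(matrix)
        return CladeAssignment(assignment, method, _medoid_ambiguity(dm_in, assignment))

    raise DataError(f"unknown clade assignment method {method!r}")


def _two_medoids(dm: DistanceMatrix, max_iter: int = 100) -> dict[str, int]:
    D = dm.d
    n = len(dm.labels)
    # deterministic init: the most distant pair, lowest index on ties
    flat = np.argmax(D)
    m1, m2 = divmod(flat, n)
    if m1 > m2:
        m1, m2 = m2, m1
    for _ in range(max_iter):
        lab = np.where(D[:, m1] <= D[:, m2], 0, 1)
        new = []
        for k in (0, 1):
            members = np.where(lab == k)[0]
            sub = D[np.ix_(members, members)]
            new.append(int(members[int(np.argmin(sub.sum(axis=1)))]))
        if (new[0], new[1]) == (m1, m2):
            break
        m1, m2 = new
    g1 = {dm.labels[i] for i in np.where(lab == 0)[0]}
    g2 = {dm.labels[i] for i in np.where(lab == 1)[0]}
    return _canonical_numbering((g1, g2), dm.labels)


# ---------------------------------------------------------------------------
# Bootstrap support
# ---------------------------------------------------------------------------


@dataclass
class BootstrapSupport:
    support: int
    n_reps: int

    def __post_init__(self) -> None:
        if not 0 <= self.support <= self.n_reps:
            raise DataError("support out of range")


def bootstrap_bipartition(
    matrix: HaplotypeMatrix,
    assignment: CladeAssignment,
    outgroup_sequence: np.ndarray | None = None,
    outgroup_label: str = "outgroup",
    n_reps: int = 100,
    seed: int = 0,
) -> BootstrapSupport:
    """Bootstrap support for the two-clade split.

    Block variants are resampled with replacement ``n_reps`` times; on each
    replicate the NJ tree is rebuilt and checked for an edge separating the
    clade-1 haplotypes from everything else (the outgroup, when included,
    simply falls on clade 2's side of the complement).
    """
    if matrix.n_variants < 2:
        raise DataError("bootstrap needs at least 2 variants")
    rng = np.random.Generator(np.random.Philox(seed))
    clade1 = frozenset(assignment.members(1))
    hits = 0
    for _ in range(n_reps):
        rows = rng.integers(0, matrix.n_variants, size=matrix.n_variants)
        res_alleles = matrix.alleles[rows]
        cols = [res_alleles[:, j].astype(float) for j in range(matrix.n_haplotypes)]
        labels = matrix.haplotype_ids
        for c in cols:
            c[c == MISSING] = np.nan
        if outgroup_sequence is not None:
            labels = labels + [outgroup_label]
            cols.append(np.asarray(outgroup_sequence, dtype=float)[rows])
        X = np.column_stack(cols)
        n = X.shape[1]
        d = np.zeros((n, n))
        valid = ~np.isnan(X)
        for i in range(n):
            both = valid & valid[:, [i]]
            delta = np.abs(X - X[:, [i]])
            delta[~both] = 0.0
            d[i] = delta.sum(axis=0)
        np.fill_diagonal(d, 0.0)
        tree = nj_tree(DistanceMatrix(labels, d, np.full((n, n), X.shape[0])))
        if tree.has_bipartition(clade1):
            hits += 1
    return BootstrapSupport(hits, n_reps)


# ---------------------------------------------------------------------------
# Core haplotypes
# ---------------------------------------------------------------------------


def core_haplotypes(matrix: HaplotypeMatrix, assignment: CladeAssignment) -> pd.DataFrame:
    """Per-variant consensus alleles of each clade inside the block.

    Returns a DataFrame with columns vid, pos, ref_allele, alt_allele,
    clade1_allele, clade2_allele, clade1_fraction, clade2_fraction,
    resolved.  Consensus fractions are the majority-allele share among
    non-missing haplotypes of the clade; exact 50/50 ties are flagged
    ``resolved=False`` (and excluded from concordance scoring downstream).
    """
    hap_ids = matrix.haplotype_ids
    cols = {1: [], 2: []}
    for j, h in enumerate(hap_ids):
        c = assignment.assignment.get(h)
        if c in (1, 2):
            cols[c].append(j)
    rows = []
    for i, v in enumerate(matrix.variants):
        rec = {"vid": v.vid, "pos": v.pos, "ref_allele": v.ref_allele,
               "alt_allele": v.alt_allele, "resolved": True}
        for clade in (1, 2):
            a = matrix.alleles[i, cols[clade]]
            a = a[a != MISSING]
            if a.size == 0:
                rec[f"clade{clade}_allele"] = MISSING
                rec[f"clade{clade}_fraction"] = np.nan
                rec["resolved"] = False
                continue
            n1 = int(a.sum())
            n0 = a.size - n1
            if n1 == n0:
                rec[f"clade{clade}_allele"] = MISSING
                rec[f"clade{clade}_fraction"] = 0.5
                rec["resolved"] = False
            else:
                maj = 1 if n1 > n0 else 0
                rec[f"clade{clade}_allele"] = maj
                rec[f"clade{clade}_fraction"] = max(n1, n0) / a.size
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spatial and temporal frequencies
# ---------------------------------------------------------------------------


@dataclass
class CladeFrequencies:
    per_population: pd.DataFrame
    per_superpopulation: pd.DataFrame
    overall_pct: float  # unweighted mean of population clade-2 frequencies
    overall_weighted_pct: float  # haplotype-weighted


def clade_frequencies(
    matrix: HaplotypeMatrix, assignment: CladeAssignment
) -> CladeFrequencies:
    """Clade-2 frequency per population, per superpopulation and overall.

    The overall figure is the unweighted mean across populations; a
    haplotype-weighted alternative is also reported.
    """
    hap_ids = matrix.haplotype_ids
    recs = []
    for h, s in zip(hap_ids, matrix.sample_ids):
        c = assignment.assignment.get(h)
        if c is None:
            continue
        pop = matrix.population.get(s)
        if not pop:
            continue
        recs.append((pop, c))
    if not recs:
        raise DataError("no haplotype has a population assignment")
    df = pd.DataFrame(recs, columns=["population", "clade"])
    per_pop = (
        df.groupby("population")["clade"]
        .agg(n_haplotypes="size", clade2_freq_pct=lambda s: 100.0 * (s == 2).mean())
        .reset_index()
    )
    sp_map = matrix.superpopulation
    df["superpop"] = df["population"].map(lambda p: sp_map.get(p, "ALL"))
    pop_sp = per_pop["population"].map(lambda p: sp_map.get(p, "ALL"))
    per_sp = (
        per_pop.assign(superpop=pop_sp)
        .groupby("superpop")["clade2_freq_pct"]
        .mean()
        .reset_index()
    )
    overall = float(per_pop["clade2_freq_pct"].mean())
    weighted = float(100.0 * (df["clade"] == 2).mean())
    return CladeFrequencies(per_pop, per_sp, overall, weighted)


def temporal_trajectory(
    ancient: AncientSampleTable,
    core: pd.DataFrame,
    tag_vids: Sequence[str],
    bin_width_years: float = 2000.0,
    max_age_years: float = 45000.0,
) -> pd.DataFrame:
    """Clade-2 frequency through time from dated ancient samples.

    Per age bin, the frequency is the mean across tag SNPs of the clade-2
    allele frequency among non-missing diploid calls.  Tag genotypes are
    stored as derived(ALT)-allele counts; the core table orients each tag
    to its clade-2 allele.  Empty bins are reported with NaN frequency,
    never zero.
    """
    core_idx = core.set_index("vid")
    orient: dict[str, int] = {}
    for vid in tag_vids:
        if vid not in core_idx.index:
            raise DataError(f"tag variant {vid} absent from core haplotype table")
        a2 = core_idx.loc[vid, "clade2_allele"]
        if a2 not in (0, 1):
            raise DataError(f"tag variant {vid} has unresolved clade-2 allele")
        orient[vid] = int(a2)
    edges = np.arange(0.0, max_age_years + bin_width_years, bin_width_years)
    rows = []
    ages = np.asarray(ancient.ages_years_bp, dtype=float)
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = [
            i for i, a in enumerate(ages) if (lo <= a < hi) or (hi == edges[-1] and a == hi)
        ]
        tag_freqs = []
        samples_used: set[int] = set()
        for vid, a2 in orient.items():
            num = den = 0
            for i in in_bin:
                g = ancient.genotypes[i].get(vid)
                if g is None:
                    continue
                derived2 = g if a2 == 1 else 2 - g
                num += derived2
                den += 2
                samples_used.add(i)
            if den > 0:
                tag_freqs.append(num / den)
        rows.append(
            {
                "age_lo": lo,
                "age_hi": hi,
                "n_samples": len(samples_used),
                "clade2_freq_pct": 100.0 * float(np.mean(tag_freqs))
                if tag_freqs
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
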