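"""Subfamily discovery from co-segregating diagnostic mutations, iterative
consensus refinement, and median-joining placement of consensuses.

The discovery step follows the COSEG idea: align every element to a
template consensus, look for pairs of (column, state) assertions whose
co-occurrence across elements is far beyond what independence allows
(two-sided Fisher exact test, Bonferroni corrected), split the carriers of
a significant pair into a child subfamily, rebuild both consensuses,
reassign every element to its nearest consensus, and recurse. Only
substitution states can be diagnostic by default (deletions are weak
evidence); CpG columns can be excluded since they are hypermutable and
co-occur by chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.stats import fisher_exact

from ._seq import cpg_sites
from .divergence import AlignmentScoring, align_to_consensus

_STATES = "ACGT-N"
_STATE_CODE = {s: i for i, s in enumerate(_STATES)}
# deterministic tie-break order for consensus calls
_TIE_ORDER = "ACGT-"


# ---------------------------------------------------------------------------
# mutation matrix
# ---------------------------------------------------------------------------

@dataclass
class MutationMatrix:
    """Elements x template-columns observation matrix.

    Rows are elements re-expressed in template coordinates: insertions
    relative to the template are dropped, deletions recorded as '-'.
    """

    ids: list
    matrix: np.ndarray            # uint8 codes into _STATES
    template: str
    cpg: np.ndarray               # per-column CpG flag (template-driven)
    excluded: list = field(default_factory=list)

    @property
    def n_elements(self) -> int:
        return self.matrix.shape[0]

    def row_string(self, i: int) -> str:
        return "".join(_STATES[c] for c in self.matrix[i])


def build_mutation_matrix(elements, template_consensus: str,
                          min_template_fraction: float = 0.5,
                          scoring: AlignmentScoring | None = None
                          ) -> MutationMatrix:
    """Globally align each element to the template and project it onto
    template columns. Elements covering fewer than half the template
    columns (truncated or heavily deleted copies) are excluded, with their
    ids reported in ``excluded``.

    ``elements`` is a list of (id, sequence) pairs or a dict id -> sequence.
    """
    if not template_consensus:
        raise ValueError("template must be non-empty")
    if isinstance(elements, dict):
        elements = list(elements.items())
    ncol = len(template_consensus)
    cpg = cpg_sites(template_consensus.upper())
    rows, ids, excluded = [], [], []
    for elem_id, seq in elements:
        aln = align_to_consensus(seq, template_consensus, scoring,
                                 element_id=elem_id)
        row = np.full(ncol, _STATE_CODE["-"], dtype=np.uint8)
        ci = 0
        covered = 0
        for e, c in zip(aln.aligned_element, aln.aligned_consensus):
            if c == "-":
                continue          # insertion in the element: dropped
            if e != "-":
                row[ci] = _STATE_CODE.get(e, _STATE_CODE["N"])
                covered += 1
            ci += 1
        if covered < min_template_fraction * ncol:
            excluded.append(elem_id)
            continue
        rows.append(row)
        ids.append(elem_id)
    matrix = (np.vstack(rows) if rows
              else np.empty((0, ncol), dtype=np.uint8))
    return MutationMatrix(ids, matrix, template_consensus.upper(), cpg,
                          excluded)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _consensus_row(matrix: np.ndarray) -> np.ndarray:
    """Per-column majority state, ignoring N; ties broken A<C<G<T<-."""
    ncol = matrix.shape[1]
    out = np.empty(ncol, dtype=np.uint8)
    for j in range(ncol):
        col = matrix[:, j]
        counts = np.bincount(col, minlength=6)
        counts[_STATE_CODE["N"]] = 0
        best, best_n = _STATE_CODE["N"], 0
        for s in _TIE_ORDER:
            c = counts[_STATE_CODE[s]]
            if c > best_n:
                best, best_n = _STATE_CODE[s], c
        out[j] = best
    return out


def refine_consensus(member_rows: np.ndarray) -> str:
    """Majority-rule consensus of member rows; a '-' majority yields a
    deletion (the returned DNA string omits that column)."""
    if member_rows.shape[0] < 1:
        raise ValueError("need at least one member")
    row = _consensus_row(member_rows)
    return "".join(_STATES[c] for c in row if _STATES[c] not in "-N")


# ---------------------------------------------------------------------------
# subfamily detection
# ---------------------------------------------------------------------------

@dataclass
class Subfamily:
    members: list
    diagnostics: list[tuple[int, str]]     # (column, state) vs parent consensus
    consensus: str                         # ungapped DNA
    consensus_row: np.ndarray              # aligned, template coordinates
    size: int = 0

    def __post_init__(self) -> None:
        self.size = len(self.members)


def _candidate_assertions(rows: np.ndarray, consensus: np.ndarray,
                          cpg: np.ndarray, min_size: int, exclude_cpg: bool,
                          allow_gap_states: bool) -> list[tuple[int, int]]:
    """(column, state) assertions whose carrier count could seed a split."""
    out = []
    diag_states = [_STATE_CODE[s] for s in ("ACGT-" if allow_gap_states else "ACGT")]
    for j in range(rows.shape[1]):
        if exclude_cpg and cpg[j]:
            continue
        counts = np.bincount(rows[:, j], minlength=6)
        for s in diag_states:
            if s == consensus[j]:
                continue
            if counts[s] >= min_size:
                out.append((j, s))
    return out


def _best_pair(rows: np.ndarray, assertions: list[tuple[int, int]],
               min_size: int, alpha: float):
    """Most significant co-segregating assertion pair under Fisher exact with
    Bonferroni over all tested pairs; None when nothing passes."""
    n = rows.shape[0]
    if len(assertions) < 2:
        return None
    ind = np.stack([rows[:, j] == s for j, s in assertions])  # A x n
    co = ind.astype(np.int32) @ ind.T.astype(np.int32)
    pairs = [(i, j) for i, j in combinations(range(len(assertions)), 2)
             if assertions[i][0] != assertions[j][0]]
    n_tests = len(pairs)
    if n_tests == 0:
        return None
    best = None
    for i, j in pairs:
        a = int(co[i, j])
        if a < min_size:
            continue
        b = int(co[i, i]) - a
        c = int(co[j, j]) - a
        d = n - a - b - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        key = (p, assertions[i], assertions[j])
        if best is None or key < best[0]:
            best = (key, i, j)
    if best is None:
        return None
    (p, *_), i, j = best
    if p * n_tests >= alpha:
        return None
    carriers = ind[i] & ind[j]
    return assertions[i], assertions[j], carriers


def _hamming_to(rows: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    return (rows != consensus[None, :]).sum(axis=1)


def detect_subfamilies(matrix: MutationMatrix, min_size: int = 10,
                       exclude_cpg: bool = True, alpha: float = 1e-3,
                       allow_gap_states: bool = False) -> list[Subfamily]:
    """Recursive co-segregation splitting.

    At each node the most significant co-occurring assertion pair (if its
    Bonferroni-corrected two-sided Fisher p is below ``alpha``) seeds a
    child subfamily; both consensuses are rebuilt and every element is
    reassigned to the nearest consensus (Hamming distance, ties to the
    larger side, then to the lexicographically smaller consensus), iterated
    to a fixed point. A split whose reassigned sides fall below
    ``min_size`` is rejected. Output order and membership are invariant
    under row permutation of the matrix.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    rows = matrix.matrix
    n = rows.shape[0]
    all_idx = np.arange(n)
    if n < min_size:
        cons = _consensus_row(rows) if n else np.array(
            [_STATE_CODE[c] for c in matrix.template], dtype=np.uint8)
        return [_make_subfamily(matrix, all_idx, cons, cons)]

    results: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []

    def work(idx: np.ndarray, parent_cons: np.ndarray) -> None:
        sub = rows[idx]
        cons = _consensus_row(sub)
        assertions = _candidate_assertions(sub, cons, matrix.cpg, min_size,
                                           exclude_cpg, allow_gap_states)
        found = _best_pair(sub, assertions, min_size, alpha)
        if found is None:
            results.append((idx, cons, parent_cons))
            return
        _, _, carriers = found
        child_mask = carriers.copy()
        for _ in range(10):
            child_cons = _consensus_row(sub[child_mask])
            rest_cons = _consensus_row(sub[~child_mask])
            d_child = _hamming_to(sub, child_cons)
            d_rest = _hamming_to(sub, rest_cons)
            new_mask = d_child < d_rest
            ties = d_child == d_rest
            if ties.any():
                child_larger = child_mask.sum() > (~child_mask).sum()
                if child_mask.sum() == (~child_mask).sum():
                    child_larger = (_row_key(child_cons) < _row_key(rest_cons))
                new_mask[ties] = child_larger
            if (new_mask == child_mask).all():
                break
            child_mask = new_mask
        if child_mask.sum() < min_size or (~child_mask).sum() < min_size:
            results.append((idx, cons, parent_cons))
            return
        work(idx[~child_mask], cons)
        work(idx[child_mask], cons)

    template_row = np.array([_STATE_CODE[c] for c in matrix.template],
                            dtype=np.uint8)
    work(all_idx, template_row)

    subfams = [_make_subfamily(matrix, idx, cons, parent)
               for idx, cons, parent in results]
    subfams.sort(key=lambda s: (-s.size, s.consensus))
    return subfams


def _row_key(row: np.ndarray) -> str:
    return "".join(_STATES[c] for c in row)


def _make_subfamily(matrix: MutationMatrix, idx: np.ndarray,
                    cons: np.ndarray, parent_cons: np.ndarray) -> Subfamily:
    diagnostics = [(int(j), _STATES[cons[j]])
                   for j in np.flatnonzero(cons != parent_cons)
                   if _STATES[cons[j]] in "ACGT-"]
    members = sorted((matrix.ids[i] for i in idx), key=str)
    consensus = "".join(_STATES[c] for c in cons if _STATES[c] in "ACGT")
    return Subfamily(members, diagnostics, consensus, cons)


# ---------------------------------------------------------------------------
# median-joining network
# ---------------------------------------------------------------------------

@dataclass
class ConsensusNetwork:
    graph: nx.Graph               # nodes: sequence strings; attrs: names,
                                  # multiplicity, inferred
    columns: np.ndarray           # analysed column indices
    epsilon: int = 0

    @property
    def total_weight(self) -> int:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def write_graphml(self, path) -> None:
        g = nx.Graph()
        for node, data in self.graph.nodes(data=True):
            g.add_node(node, names=",".join(data["names"]),
                       multiplicity=data["multiplicity"],
                       inferred=data["inferred"])
        g.add_edges_from(self.graph.edges(data=True))
        nx.write_graphml(g, path)

    def write_rdf(self, path) -> None:
        """Minimal .rdf-style haplotype export (Network-program flavour)."""
        nodes = [n for n, d in self.graph.nodes(data=True) if not d["inferred"]]
        with open(path, "w") as fh:
            fh.write("  ;1.0\n")
            for n in nodes:
                names = self.graph.nodes[n]["names"]
                mult = self.graph.nodes[n]["multiplicity"]
                fh.write(f">{'/'.join(names)};{mult};;;;;;\n{n}\n")


def _hamming_matrix(seqs: np.ndarray) -> np.ndarray:
    return (seqs[:, None, :] != seqs[None, :, :]).sum(axis=2)


def _mst_weight(dist: np.ndarray) -> int:
    """Prim's algorithm; small n, dense distances."""
    n = dist.shape[0]
    if n <= 1:
        return 0
    in_tree = np.zeros(n, dtype=bool)
    best = dist[0].astype(float).copy()
    in_tree[0] = True
    best[0] = np.inf
    total = 0
    for _ in range(n - 1):
        j = int(np.argmin(best))
        total += int(best[j])
        in_tree[j] = True
        best = np.minimum(best, dist[j])
        best[in_tree] = np.inf
    return total


def _union_msts(dist: np.ndarray, epsilon: int = 0) -> list[tuple[int, int, int]]:
    """Edges belonging to the epsilon-relaxed union of all minimum spanning
    trees: an edge of weight w is kept iff its endpoints are not connected
    using only edges of weight < w - epsilon."""
    n = dist.shape[0]
    edges = sorted((int(dist[i, j]), i, j)
                   for i in range(n) for j in range(i + 1, n))
    kept = []
    for w, i, j in edges:
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        # build connectivity from strictly smaller (minus epsilon) edges
        for w2, a, b in edges:
            if w2 < w - epsilon:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
        if find(i) != find(j):
            kept.append((i, j, w))
    return kept


def _quasi_medians(triplet: np.ndarray) -> list[np.ndarray]:
    """Median vectors of three sequences: per-column majority; columns where
    all three states differ branch into each observed state (quasi-median)."""
    ncol = triplet.shape[1]
    choices: list[list[int]] = []
    for j in range(ncol):
        a, b, c = triplet[:, j]
        if a == b or a == c:
            choices.append([int(a)])
        elif b == c:
            choices.append([int(b)])
        else:
            choices.append(sorted({int(a), int(b), int(c)}))
    out: list[np.ndarray] = [np.array([], dtype=triplet.dtype)]
    for j, opts in enumerate(choices):
        out = [np.append(m, o) for m in out for o in opts]
        if len(out) > 256:        # fully heterozygous columns are rare;
            return []             # give up rather than explode
    return [m.astype(triplet.dtype) for m in out]


def median_joining_network(consensuses: dict[str, str] | list[str],
                           epsilon: int = 0, exclude_cpg: bool = False,
                           cpg_reference: str | None = None
                           ) -> ConsensusNetwork:
    """Median-joining network of aligned consensus sequences.

    Distances are Hamming distances over pairwise-complete columns (every
    sequence has A/C/G/T there), optionally excluding CpG columns of
    ``cpg_reference``. Duplicate sequences are merged into one node with a
    multiplicity. Median (Steiner) candidates are quasi-medians of node
    triplets, added greedily by largest reduction of the minimum-spanning
    weight (ties broken lexicographically); medians that stop reducing the
    total weight are pruned; the final network is the epsilon-relaxed union
    of all minimum spanning trees over the remaining nodes.
    """
    if isinstance(consensuses, list):
        consensuses = {f"seq{i}": s for i, s in enumerate(consensuses)}
    names = sorted(consensuses)
    if not names:
        raise ValueError("no sequences supplied")
    seq_strs = [consensuses[n].upper() for n in names]
    length = len(seq_strs[0])
    if any(len(s) != length for s in seq_strs):
        raise ValueError("sequences must be aligned to a common length")

    keep = np.ones(length, dtype=bool)
    for s in seq_strs:
        keep &= np.frombuffer(s.encode(), dtype=np.uint8) != ord("-")
        keep &= np.frombuffer(s.encode(), dtype=np.uint8) != ord("N")
    if exclude_cpg:
        ref = cpg_reference or seq_strs[0]
        keep &= ~cpg_sites(ref.replace("-", "A").replace("N", "A"))[:length]
    columns = np.flatnonzero(keep)

    arr = np.stack([np.frombuffer(s.encode(), dtype=np.uint8)[columns]
                    for s in seq_strs])

    # condense duplicates
    node_seqs: list[np.ndarray] = []
    node_names: list[list[str]] = []
    seen: dict[bytes, int] = {}
    for name, row in zip(names, arr):
        key = row.tobytes()
        if key in seen:
            node_names[seen[key]].append(name)
        else:
            seen[key] = len(node_seqs)
            node_seqs.append(row)
            node_names.append([name])
    n_observed = len(node_seqs)

    if n_observed >= 3:
        nodes = list(node_seqs)
        while True:
            dist = _hamming_matrix(np.stack(nodes))
            base = _mst_weight(dist)
            best = None   # (weight, seq_string, row)
            cand_seen = set(r.tobytes() for r in nodes)
            for i, j, k in combinations(range(len(nodes)), 3):
                for med in _quasi_medians(np.stack([nodes[i], nodes[j], nodes[k]])):
                    key = med.tobytes()
                    if key in cand_seen:
                        continue
                    d_new = (np.stack(nodes) != med[None, :]).sum(axis=1)
                    ext = np.zeros((len(nodes) + 1, len(nodes) + 1), dtype=int)
                    ext[:-1, :-1] = dist
                    ext[-1, :-1] = d_new
                    ext[:-1, -1] = d_new
                    w = _mst_weight(ext)
                    cand_key = (w, med.tobytes())
                    if w < base and (best is None or cand_key < best[:2]):
                        best = (w, med.tobytes(), med)
            if best is None:
                break
            nodes.append(best[2])

        # prune medians that no longer reduce the spanning weight
        changed = True
        while changed:
            changed = False
            full = _mst_weight(_hamming_matrix(np.stack(nodes)))
            for m in range(len(nodes) - 1, n_observed - 1, -1):
                rest = nodes[:m] + nodes[m + 1:]
                if _mst_weight(_hamming_matrix(np.stack(rest))) <= full:
                    nodes.pop(m)
                    changed = True
                    break
    else:
        nodes = list(node_seqs)

    dist = _hamming_matrix(np.stack(nodes))
    graph = nx.Graph()
    node_strings = []
    for i, row in enumerate(nodes):
        s = row.tobytes().decode("ascii")
        node_strings.append(s)
        if i < n_observed:
            graph.add_node(s, names=node_names[i],
                           multiplicity=len(node_names[i]), inferred=False)
        else:
            graph.add_node(s, names=[f"median{i - n_observed + 1}"],
                           multiplicity=0, inferred=True)
    if len(nodes) > 1:
        for i, j, w in _union_msts(dist, epsilon):
            graph.add_edge(node_strings[i], node_strings[j], weight=int(w))
    return ConsensusNetwork(graph, columns, epsilon)
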