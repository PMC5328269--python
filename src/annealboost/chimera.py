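"""Chimera hardware graphs and one-spin-per-qubit greedy embedding.

The chimera graph is an m x n lattice of complete-bipartite K_{k,k} cells
(default k = 4, eight qubits per cell).  One partition of each cell links
vertically to the neighboring cells above/below, the other horizontally.
Defective (inoperable) qubits are removed with their edges.  A fully
connected Ising problem is embedded one spin per qubit by a greedy
heuristic that places each spin on the free qubit retaining the most
coupling weight to already-placed spins; couplings on non-retained pairs
are truncated and the survivors rescaled by a factor alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .ising import IsingProblem

__all__ = [
    "ChimeraGraph",
    "Embedding",
    "chimera_graph",
    "random_defects",
    "average_viable_degree",
    "greedy_embed",
    "renormalize",
    "decoupled_spins",
]


@dataclass
class ChimeraGraph:
    """A defect-bearing chimera graph.

    Vertices are numbered cell-major (row-major over cells), partition-major
    within a cell: cell (r, c) holds qubits  (r*n + c)*2k .. +2k-1 , the
    first k in the "vertical" partition, the last k "horizontal".
    """

    m: int
    n: int
    k: int
    defects: frozenset[int]
    graph: nx.Graph

    @property
    def n_qubits(self) -> int:
        """Functioning qubit count."""
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def chimera_graph(
    m: int, n: int, k: int = 4, defects=()
) -> ChimeraGraph:
    """Build C(m, n, k) with the given inoperable qubits removed.

    The defect-free edge count is  m n k^2 + k (n (m-1) + m (n-1)).
    """
    if m < 1 or n < 1 or k < 1:
        raise ValueError("m, n, k must be >= 1")
    G = nx.Graph()
    total = m * n * 2 * k

    def base(r: int, c: int) -> int:
        return (r * n + c) * 2 * k

    G.add_nodes_from(range(total))
    for r in range(m):
        for c in range(n):
            b = base(r, c)
            # intra-cell complete bipartite
            for a in range(k):
                for bb in range(k):
                    G.add_edge(b + a, b + k + bb)
            # vertical links: partition 0 to the cell below
            if r + 1 < m:
                b2 = base(r + 1, c)
                for a in range(k):
                    G.add_edge(b + a, b2 + a)
            # horizontal links: partition 1 to the cell at right
            if c + 1 < n:
                b2 = base(r, c + 1)
                for a in range(k):
                    G.add_edge(b + k + a, b2 + k + a)

    defect_list = list(defects)
    dset = set()
    for d in defect_list:
        d = int(d)
        if not 0 <= d < total:
            raise ValueError(f"defect qubit {d} out of range")
        if d in dset:
            warnings.warn(f"duplicate defect qubit {d} ignored")
        dset.add(d)
    G.remove_nodes_from(dset)
    return ChimeraGraph(m=m, n=n, k=k, defects=frozenset(dset), graph=G)


def random_defects(m: int, n: int, k: int, count: int, seed: int) -> list[int]:
    """Draw ``count`` distinct inoperable qubits uniformly at random."""
    total = m * n * 2 * k
    rng = np.random.default_rng(seed)
    return sorted(int(q) for q in rng.choice(total, size=count, replace=False))


def average_viable_degree(graph: ChimeraGraph) -> float:
    """Mean number of functioning couplings per functioning qubit."""
    degrees = [d for _, d in graph.graph.degree()]
    return float(np.mean(degrees)) if degrees else 0.0


# ---------------------------------------------------------------------------
# embedding


@dataclass
class Embedding:
    """An injective spin -> qubit assignment with its retained couplings.

    ``spin_to_qubit[i]`` is the hardware qubit carrying spin i;
    ``retained_edges`` are the problem pairs (i, j) whose qubits are
    adjacent in the hardware graph; ``retained_fraction`` is the retained
    share of total |J| weight; ``alpha`` the coupling rescale factor.
    """

    spin_to_qubit: np.ndarray
    retained_edges: np.ndarray  # (E_emb, 2) spin pairs, i < j
    retained_fraction: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        q = np.asarray(self.spin_to_qubit, dtype=int)
        if len(np.unique(q)) != len(q):
            raise ValueError("embedding not injective")
        self.spin_to_qubit = q
        self.retained_edges = np.asarray(self.retained_edges, dtype=int).reshape(-1, 2)
        if not 0 < self.retained_fraction <= 1.0 + 1e-12:
            raise ValueError("retained fraction outside (0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    @property
    def n_spins(self) -> int:
        return len(self.spin_to_qubit)

    def couplings_per_qubit(self) -> float:
        """Average retained couplings per mapped qubit."""
        return 2.0 * len(self.retained_edges) / self.n_spins


def greedy_embed(
    problem: IsingProblem, graph: ChimeraGraph | nx.Graph, seed: int | None = None
) -> Embedding:
    """One-spin-per-qubit greedy embedding maximizing retained |J| weight.

    Spins are processed in descending total coupling weight sum_j |J_ij|
    (ties by spin index).  The first spin goes to the highest-degree
    functioning qubit (ties by lowest index); each later spin goes to the
    free qubit maximizing the summed |J| to already-placed neighbors (ties
    by lowest qubit index).  Deterministic; ``seed`` is accepted for
    interface symmetry but the tie rules leave nothing to chance.
    """
    G = graph.graph if isinstance(graph, ChimeraGraph) else graph
    N = problem.n
    if N > G.number_of_nodes():
        raise ValueError(
            f"{N} spins exceed {G.number_of_nodes()} functioning qubits; "
            "train iteratively or reduce the number of input features"
        )
    Jabs = np.zeros((N, N))
    if len(problem.edges):
        Jabs[problem.edges[:, 0], problem.edges[:, 1]] = np.abs(problem.couplings)
        Jabs[problem.edges[:, 1], problem.edges[:, 0]] = np.abs(problem.couplings)
    order = np.lexsort((np.arange(N), -Jabs.sum(axis=1)))

    nodes = sorted(G.nodes())
    spin_to_qubit = np.full(N, -1, dtype=int)
    qubit_of = {}  # qubit -> spin
    for step, spin in enumerate(order):
        if step == 0:
            best = max(nodes, key=lambda q: (G.degree(q), -q))
        else:
            best, best_w = None, -1.0
            for q in nodes:
                if q in qubit_of:
                    continue
                w = 0.0
                for nb in G.neighbors(q):
                    placed = qubit_of.get(nb)
                    if placed is not None:
                        w += Jabs[spin, placed]
                if w > best_w or (w == best_w and (best is None or q < best)):
                    best, best_w = q, w
        spin_to_qubit[spin] = best
        qubit_of[best] = spin

    retained = []
    for i, j in problem.edges:
        if G.has_edge(int(spin_to_qubit[i]), int(spin_to_qubit[j])):
            retained.append((i, j))
    retained = np.array(retained, dtype=int).reshape(-1, 2)
    total_w = float(np.abs(problem.couplings).sum())
    if total_w == 0:
        frac = 1.0
    else:
        keep = np.zeros(len(problem.edges), dtype=bool)
        keyset = {(int(i), int(j)) for i, j in retained}
        for idx, (i, j) in enumerate(problem.edges):
            keep[idx] = (int(i), int(j)) in keyset
        frac = float(np.abs(problem.couplings[keep]).sum() / total_w)
    return Embedding(spin_to_qubit=spin_to_qubit, retained_edges=retained, retained_fraction=frac)


def renormalize(problem: IsingProblem, embedding: Embedding, alpha: float) -> IsingProblem:
    """Truncate couplings to the embedded edges and rescale them by alpha.

    Fields h are untouched; the returned problem is flagged "embedded" and
    the input problem is not mutated.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    keyset = {(int(i), int(j)) for i, j in embedding.retained_edges}
    keep = np.array(
        [(int(i), int(j)) in keyset for i, j in problem.edges], dtype=bool
    )
    out = IsingProblem(
        n=problem.n,
        h=problem.h.copy(),
        edges=problem.edges[keep].copy(),
        couplings=problem.couplings[keep] * alpha,
        offset=problem.offset,
        lam=problem.lam,
        f=problem.f,
        provenance="embedded",
    )
    return out


def decoupled_spins(problem: IsingProblem) -> dict[int, int]:
    """Spins whose field dominates their summed retained couplings.

    Returns {spin: forced sign(h)} for every vertex a with
    |h_a| > sum_{edges at a} |J_aj| (strict); in any ground state such a
    spin takes the sign of its field.
    """
    coupling_sum = np.zeros(problem.n)
    if len(problem.edges):
        np.add.at(coupling_sum, problem.edges[:, 0], np.abs(problem.couplings))
        np.add.at(coupling_sum, problem.edges[:, 1], np.abs(problem.couplings))
    forced = {}
    for a in range(problem.n):
        if abs(problem.h[a]) > coupling_sum[a]:
            forced[a] = 1 if problem.h[a] > 0 else (-1 if problem.h[a] < 0 else 1)
    return forced
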