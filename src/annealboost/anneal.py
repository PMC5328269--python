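"""Ising optimizers: simulated annealing, exhaustive search, solution pools.

Simulated annealing follows a fixed protocol: random +/-1 start, starting
temperature equal to the largest single-flip |dE| from the initial
configuration, a linear schedule down to zero over at most ``max_steps``
temperature steps with N single-spin Metropolis proposals per step, and an
early stop once the running energy is unchanged at three consecutive
temperatures (the system has frozen).  Exhaustive enumeration provides the exact ground state(s)
for small instances, and a pooling layer aggregates many independent reads
with per-read seeds derived reproducibly from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .ising import IsingProblem, ising_energy

__all__ = [
    "SolutionPool",
    "simulated_anneal",
    "brute_force",
    "sample_pool",
]

BRUTE_FORCE_LIMIT = 24


@njit(cache=False)
def _sa_kernel(h, Jm, max_steps, seed, record):
    """One annealing read.  Returns (best_spins, best_energy, energy_trace).

    Maintains local fields f_i = sum_j J_ij s_j so each proposal costs O(1)
    to evaluate and O(N) to commit; flipping spin i changes the energy by
    dE = 2 s_i (h_i + f_i).
    """
    np.random.seed(seed)
    n = h.shape[0]
    s = np.empty(n)
    for i in range(n):
        s[i] = 1.0 if np.random.random() < 0.5 else -1.0
    f = Jm @ s
    energy = -np.dot(h, s) - 0.5 * np.dot(s, f)

    t0 = 0.0
    for i in range(n):
        de = 2.0 * s[i] * (h[i] + f[i])
        if abs(de) > t0:
            t0 = abs(de)
    if t0 == 0.0:
        t0 = 1.0

    best = s.copy()
    best_energy = energy
    stall = 0
    trace = np.empty(max_steps if record else 0)
    steps_done = 0
    for step in range(max_steps):
        # linear schedule from t0 down to exactly 0 at the final step
        temp = t0 * (max_steps - 1 - step) / (max_steps - 1) if max_steps > 1 else 0.0
        prev_energy = energy
        for _ in range(n):
            i = np.random.randint(0, n)
            de = 2.0 * s[i] * (h[i] + f[i])
            if de <= 0.0 or (temp > 0.0 and np.random.random() < np.exp(-de / temp)):
                old = s[i]
                s[i] = -old
                energy += de
                for j in range(n):
                    f[j] -= 2.0 * old * Jm[j, i]  # J_ii = 0, so f[i] is untouched
                if energy < best_energy:
                    best_energy = energy
                    best[:] = s
        if record:
            trace[step] = energy
        steps_done = step + 1
        # "no change in energy at three distinct temperatures": the system
        # is frozen once the running energy stops moving across three
        # consecutive temperature steps
        if energy == prev_energy:
            stall += 1
            if stall >= 3:
                break
        else:
            stall = 0
    return best, best_energy, trace[:steps_done] if record else trace


def simulated_anneal(
    problem: IsingProblem,
    seed: int,
    max_steps: int = 2000,
    record_trace: bool = False,
):
    """One simulated-annealing read; returns (spins, energy[, trace])."""
    if problem.n < 1:
        raise ValueError("empty problem")
    Jm = problem.coupling_matrix()
    best, energy, trace = _sa_kernel(
        problem.h.astype(np.float64),
        Jm,
        int(max_steps),
        int(seed) % (2**31),
        record_trace,
    )
    spins = best.astype(np.int8)
    energy = ising_energy(problem, spins)  # exact recompute, not drifted dE sums
    if record_trace:
        return spins, energy, trace
    return spins, energy


def _config_energies(problem: IsingProblem, S: np.ndarray) -> np.ndarray:
    """Energies of a batch of +/-1 rows."""
    Jm = problem.coupling_matrix()
    return -(S @ problem.h) - 0.5 * np.einsum("ij,ij->i", S @ Jm, S)


def brute_force(problem: IsingProblem) -> tuple[list[np.ndarray], float]:
    """Every minimal-energy configuration (lexicographic order) + its energy."""
    n = problem.n
    if n > BRUTE_FORCE_LIMIT:
        raise ValueError(f"brute force limited to N <= {BRUTE_FORCE_LIMIT}")
    best_energy = np.inf
    best: list[np.ndarray] = []
    chunk = 1 << min(n, 18)
    bits = np.arange(n)
    for start in range(0, 1 << n, chunk):
        idx = np.arange(start, min(start + chunk, 1 << n), dtype=np.int64)
        # bit 0 -> spin 0; 0 bit encodes spin -1 (so index order is
        # lexicographic over (-1, +1) vectors read left to right)
        S = (((idx[:, None] >> bits) & 1) * 2 - 1).astype(float)
        E = _config_energies(problem, S)
        emin = E.min()
        if emin < best_energy - 1e-12:
            best_energy = emin
            best = []
        mask = E <= best_energy + 1e-12
        if emin <= best_energy + 1e-12:
            best.extend(S[mask].astype(np.int8))
    # exact re-evaluation to drop float-tolerance stragglers deterministically
    energies = [ising_energy(problem, s) for s in best]
    e0 = min(energies)
    best = [s for s, e in zip(best, energies) if e <= e0 + 1e-12]
    best.sort(key=lambda s: tuple(s))
    return best, float(e0)


@dataclass
class SolutionPool:
    """Deduplicated multi-read solver output.

    ``configs`` is a (K, N) +/-1 array of distinct configurations with
    aligned ``energies`` and ``multiplicities`` (summing to ``n_reads``).
    Sorted by ascending energy, ties lexicographically.
    """

    configs: np.ndarray
    energies: np.ndarray
    multiplicities: np.ndarray
    n_reads: int
    method: str
    seed: int

    def __post_init__(self) -> None:
        if self.multiplicities.sum() != self.n_reads:
            raise ValueError("multiplicities do not sum to the read count")

    @property
    def best_energy(self) -> float:
        return float(self.energies[0])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("energy,multiplicity,spins\n")
            for e, m, s in zip(self.energies, self.multiplicities, self.configs):
                spin_str = "".join("+" if x > 0 else "-" for x in s)
                fh.write(f"{e!r},{m},{spin_str}\n")


def sample_pool(
    problem: IsingProblem,
    n_reads: int,
    solver: str = "sa",
    seed: int = 0,
    max_steps: int = 2000,
) -> SolutionPool:
    """Aggregate ``n_reads`` independent solver reads into a pool.

    Per-read seeds derive from the master seed via numpy's SeedSequence, so
    a pool is bit-reproducible given (problem, n_reads, solver, seed).  The
    "exact" solver enumerates once and returns all tied optima with the
    read count split evenly (remainder to the lexicographically first).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if solver == "exact":
        optima, energy = brute_force(problem)
        K = len(optima)
        mult = np.full(K, n_reads // K, dtype=int)
        mult[0] += n_reads - mult.sum()
        configs = np.vstack(optima)
        return SolutionPool(
            configs=configs,
            energies=np.full(K, energy),
            multiplicities=mult,
            n_reads=n_reads,
            method="exact",
            seed=seed,
        )
    if solver != "sa":
        raise ValueError(f"unknown solver {solver!r}")
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n_reads)
    ]
    seen: dict[tuple, int] = {}
    rows: list[np.ndarray] = []
    energies: list[float] = []
    counts: list[int] = []
    for rs in child_seeds:
        spins, energy = simulated_anneal(problem, seed=rs, max_steps=max_steps)
        key = tuple(int(x) for x in spins)
        if key in seen:
            counts[seen[key]] += 1
        else:
            seen[key] = len(rows)
            rows.append(spins)
            energies.append(energy)
            counts.append(1)
    order = sorted(range(len(rows)), key=lambda r: (energies[r], tuple(rows[r])))
    return SolutionPool(
        configs=np.vstack([rows[r] for r in order]),
        energies=np.array([energies[r] for r in order]),
        multiplicities=np.array([counts[r] for r in order]),
        n_reads=n_reads,
        method="sa",
        seed=seed,
    )
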