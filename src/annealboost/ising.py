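"""Regulated QBoost objective and its exact Ising form.

The training problem selects a binary-weight subset of N weak classifiers
by minimizing the regulated quadratic loss

    L(w) = sum_t (sum_i w_i c_i(t) - y(t))^2 + lambda sum_i w_i ,

with c_i(t) in {-1/N, +1/N} and the regulator parameterized as
lambda = 2 f |T| / N.  Substituting s_i = 2 w_i - 1 and using w_i^2 = w_i
gives an Ising energy  H = -sum_i h_i s_i - sum_{i<j} J_ij s_i s_j  with

    h_i  = -lambda/2 + sum_t c_i(t) y(t) - (1/2) sum_{j, t} c_i(t) c_j(t)
    J_ij = -(1/2) sum_t c_i(t) c_j(t)

(the j-sum in h_i runs over *all* j, including j = i).  The constant offset
is kept so that L(w) = H(s(w)) + offset holds exactly for every w.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .stumps import WeakEnsemble

__all__ = [
    "IsingProblem",
    "qboost_loss",
    "build_ising",
    "ising_energy",
    "spins_to_weights",
    "weights_to_spins",
]


@dataclass
class IsingProblem:
    """Fields, couplings and bookkeeping of one Ising instance.

    ``edges`` is an (E, 2) integer array of unordered pairs (i < j) and
    ``couplings`` the aligned J values.  ``provenance`` is "full" for the
    complete-graph problem straight from the loss, "embedded" after
    truncation to an embedding's retained edges (couplings then already
    include the alpha rescale).
    """

    n: int
    h: np.ndarray
    edges: np.ndarray
    couplings: np.ndarray
    offset: float = 0.0
    lam: float = 0.0
    f: float = 0.0
    provenance: str = "full"

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.couplings = np.asarray(self.couplings, dtype=float)
        if len(self.h) != self.n:
            raise ValueError("field vector length != n")
        if len(self.couplings) != len(self.edges):
            raise ValueError("couplings misaligned with edges")
        if len(self.edges) and (self.edges[:, 0] == self.edges[:, 1]).any():
            raise ValueError("self-loop edge")
        if not np.isfinite(self.offset):
            raise ValueError("non-finite offset")
        # canonical i < j, each unordered pair once
        lo = self.edges.min(axis=1)
        hi = self.edges.max(axis=1)
        self.edges = np.column_stack([lo, hi])
        if len(self.edges):
            keys = self.edges[:, 0] * self.n + self.edges[:, 1]
            if len(np.unique(keys)) != len(keys):
                raise ValueError("duplicate edges")

    def coupling_matrix(self) -> np.ndarray:
        """Dense symmetric J matrix with zero diagonal."""
        M = np.zeros((self.n, self.n))
        if len(self.edges):
            M[self.edges[:, 0], self.edges[:, 1]] = self.couplings
            M[self.edges[:, 1], self.edges[:, 0]] = self.couplings
        return M

    def to_json(self, path=None) -> str:
        payload = {
            "n": self.n,
            "h": self.h.tolist(),
            "edges": [
                [int(i), int(j), float(J)]
                for (i, j), J in zip(self.edges, self.couplings)
            ],
            "lambda": self.lam,
            "f": self.f,
            "offset": self.offset,
            "provenance": self.provenance,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "IsingProblem":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        edges = np.array([[e[0], e[1]] for e in payload["edges"]], dtype=int).reshape(-1, 2)
        J = np.array([e[2] for e in payload["edges"]], dtype=float)
        return cls(
            n=payload["n"],
            h=np.array(payload["h"], dtype=float),
            edges=edges,
            couplings=J,
            offset=payload.get("offset", 0.0),
            lam=payload.get("lambda", 0.0),
            f=payload.get("f", 0.0),
            provenance=payload.get("provenance", "full"),
        )

    def to_edge_list(self, path) -> None:
        """Flat text export: one `i j J` line per coupling."""
        with open(path, "w") as fh:
            for (i, j), J in zip(self.edges, self.couplings):
                fh.write(f"{i} {j} {J!r}\n")


# ---------------------------------------------------------------------------


def _normalized_outputs(ensemble: WeakEnsemble, normalization: str) -> np.ndarray:
    """Stump outputs under the chosen convention: +/-1/N (default, keeps
    every vote-sum margin in [-1, 1]) or +/-1/sqrt(N) (suppresses the
    couplings by 1/N relative to the fields, easing the regulator tuning
    of fully connected problems)."""
    if normalization == "count":
        return ensemble.outputs
    if normalization == "sqrt":
        return ensemble.signs.astype(float) / np.sqrt(ensemble.n)
    raise ValueError(f"unknown normalization {normalization!r}")


def qboost_loss(
    weights: np.ndarray,
    ensemble: WeakEnsemble,
    labels: np.ndarray,
    lam: float,
    normalization: str = "count",
) -> float:
    """Regulated quadratic training loss of a binary weight vector."""
    w = np.asarray(weights)
    if len(w) != ensemble.n:
        raise ValueError("weight vector length != ensemble size")
    if not np.isin(w, (0, 1)).all():
        raise ValueError("weights must be binary")
    y = np.asarray(labels, dtype=float)
    if len(y) != ensemble.n_samples:
        raise ValueError("labels misaligned with ensemble outputs")
    margins = w.astype(float) @ _normalized_outputs(ensemble, normalization)
    return float(((margins - y) ** 2).sum() + lam * w.sum())


def build_ising(
    ensemble: WeakEnsemble,
    labels: np.ndarray,
    f: float,
    normalization: str = "count",
) -> IsingProblem:
    """Exact Ising form of the regulated loss, on the complete graph.

    lambda = 2 f |T| / N; the offset makes  L(w) = H(s(w)) + offset  an
    identity over all binary w.
    """
    if f < 0:
        raise ValueError("regulator fraction f must be >= 0")
    N, T = ensemble.n, ensemble.n_samples
    y = np.asarray(labels, dtype=float)
    if len(y) != T:
        raise ValueError("labels misaligned with ensemble outputs")
    lam = 2.0 * f * T / N
    c = _normalized_outputs(ensemble, normalization)
    C = c @ c.T  # C_ij = sum_t c_i c_j
    A = c @ y  # A_i = sum_t c_i y
    h = -lam / 2.0 + A - 0.5 * C.sum(axis=1)  # j-sum includes j = i
    iu, ju = np.triu_indices(N, k=1)
    edges = np.column_stack([iu, ju])
    J = -0.5 * C[iu, ju]
    offset = (
        T
        + 0.25 * C.sum()
        + 0.25 * np.trace(C)
        + N * lam / 2.0
        - A.sum()
    )
    return IsingProblem(
        n=N, h=h, edges=edges, couplings=J, offset=float(offset), lam=lam, f=f
    )


def ising_energy(problem: IsingProblem, spins: np.ndarray) -> float:
    """H = -sum_i h_i s_i - sum_{i<j} J_ij s_i s_j for a +/-1 configuration."""
    s = np.asarray(spins, dtype=float)
    if len(s) != problem.n:
        raise ValueError("spin vector does not cover all vertices")
    if not np.isin(s, (-1, 1)).all():
        raise ValueError("spins must be +/-1")
    e = -float(problem.h @ s)
    if len(problem.edges):
        e -= float(
            (problem.couplings * s[problem.edges[:, 0]] * s[problem.edges[:, 1]]).sum()
        )
    return e


def spins_to_weights(spins: np.ndarray) -> np.ndarray:
    """w = (s + 1) / 2; positive spin means the stump's vote is retained."""
    s = np.asarray(spins, dtype=int)
    if not np.isin(s, (-1, 1)).all():
        raise ValueError("spins must be +/-1")
    return ((s + 1) // 2).astype(np.int8)


def weights_to_spins(weights: np.ndarray) -> np.ndarray:
    """s = 2 w - 1, the inverse of :func:`spins_to_weights`."""
    w = np.asarray(weights, dtype=int)
    if not np.isin(w, (0, 1)).all():
        raise ValueError("weights must be binary")
    return (2 * w - 1).astype(np.int8)
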