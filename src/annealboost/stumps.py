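"""Decision-stump weak classifiers and their ensembles.

A linear stump thresholds one raw feature, a quadratic stump thresholds the
product of two features; each comes in two orientations (+ predicts positive
when the signed feature exceeds the threshold).  Stump outputs are
normalized to +/-1/N over an ensemble of N stumps, so that the vote sum of
any binary-weight subset lies in [-1, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .features import FeatureTable

__all__ = [
    "Stump",
    "WeakEnsemble",
    "train_linear_stump",
    "train_quadratic_stump",
    "enumerate_stumps",
    "filter_random_guessers",
    "label_correlation",
    "correlation_matrix",
    "select_features_for_expansion",
]


@dataclass(frozen=True)
class Stump:
    """A single-threshold weak classifier.

    ``orientation`` '+' predicts +1 when v - threshold >= 0 and
    '-' when -v - threshold >= 0, with v the feature value (linear) or the
    product of the two features (quadratic, i <= j canonically).
    """

    kind: str  # "linear" | "quadratic"
    i: int
    j: int | None
    orientation: str  # "+" | "-"
    threshold: float
    error: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "quadratic"):
            raise ValueError(f"bad stump kind {self.kind!r}")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if not 0.0 <= self.error <= 1.0:
            raise ValueError("error rate outside [0, 1]")
        if self.kind == "quadratic":
            if self.j is None:
                raise ValueError("quadratic stump needs two feature indices")
            if self.i > self.j:
                lo, hi = self.j, self.i
                object.__setattr__(self, "i", lo)
                object.__setattr__(self, "j", hi)

    def raw_column(self, X: np.ndarray) -> np.ndarray:
        if self.kind == "linear":
            return X[:, self.i]
        return X[:, self.i] * X[:, self.j]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Unnormalized +/-1 predictions on a feature matrix."""
        v = self.raw_column(X)
        if self.orientation == "-":
            v = -v
        return np.where(v - self.threshold >= 0, 1, -1).astype(np.int8)

    def sort_key(self) -> tuple:
        return (
            self.error,
            self.i,
            -1 if self.j is None else self.j,
            0 if self.orientation == "+" else 1,
        )


@dataclass
class WeakEnsemble:
    """N stumps plus their +/-1/N output matrix over the training samples.

    ``signs`` is the (N, |T|) matrix of raw +/-1 predictions; the normalized
    outputs are c_i(t) = signs[i, t] / N.
    """

    stumps: list[Stump]
    signs: np.ndarray  # int8 (N, |T|)

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs, dtype=np.int8)
        if self.signs.ndim != 2 or self.signs.shape[0] != len(self.stumps):
            raise ValueError("output matrix shape does not match stump list")
        if not np.isin(self.signs, (-1, 1)).all():
            raise ValueError("output matrix entries must be +/-1 (before /N)")

    @property
    def n(self) -> int:
        return len(self.stumps)

    @property
    def n_samples(self) -> int:
        return self.signs.shape[1]

    @property
    def outputs(self) -> np.ndarray:
        """The normalized output matrix c_i(t) in {-1/N, +1/N}."""
        return self.signs.astype(float) / self.n

    def to_json(self, path=None) -> str:
        payload = {
            "n": self.n,
            "stumps": [
                {
                    "kind": s.kind,
                    "i": s.i,
                    "j": s.j,
                    "orientation": s.orientation,
                    "threshold": s.threshold,
                    "error": s.error,
                    "degenerate": s.degenerate,
                }
                for s in self.stumps
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_stumps(cls, stumps: Sequence[Stump], X: np.ndarray) -> "WeakEnsemble":
        """Regenerate the output matrix for a stump list on a feature matrix."""
        signs = np.vstack([s.predict(X) for s in stumps])
        return cls(list(stumps), signs)


# ---------------------------------------------------------------------------
# training


def _best_threshold(v: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact 0-1-error-minimizing threshold for 'predict +1 iff v >= b'.

    Candidates are midpoints between consecutive distinct sorted values plus
    -inf/+inf sentinels; among equal-error candidates the smallest threshold
    wins.  One sort and one cumulative pass: O(|T| log |T|).
    """
    order = np.argsort(v, kind="stable")
    vs, ys = v[order], y[order]
    n = len(vs)
    # cut after position p (0..n): first p samples predicted -1, rest +1
    pos_prefix = np.concatenate(([0], np.cumsum(ys == 1)))
    neg_total = int((ys == -1).sum())
    neg_suffix = neg_total - np.concatenate(([0], np.cumsum(ys == -1)))
    errors = pos_prefix + neg_suffix  # length n+1
    # only cuts between distinct values (or at the ends) are realizable
    valid = np.ones(n + 1, dtype=bool)
    valid[1:n] = vs[1:] != vs[:-1]
    errors = np.where(valid, errors, n + 1)
    p = int(np.argmin(errors))  # argmin takes the first, i.e. smallest b
    if p == 0:
        b = -np.inf
    elif p == n:
        b = np.inf
    else:
        b = 0.5 * (vs[p - 1] + vs[p])
    return float(b), errors[p] / n


def _train_on_column(
    v: np.ndarray, y: np.ndarray, orientation: str
) -> tuple[float, float, bool]:
    v = np.asarray(v, dtype=float)
    y = np.asarray(y)
    if len(v) < 2:
        raise ValueError("need at least two samples")
    degenerate = bool(np.all(v == v[0])) or len(np.unique(y)) < 2
    if orientation == "-":
        v = -v
    b, err = _best_threshold(v, y)
    return b, err, degenerate


def train_linear_stump(
    column: np.ndarray, labels: np.ndarray, i: int = 0, orientation: str = "+"
) -> Stump:
    """Train one linear stump on a feature column (exact 0-1 minimizer)."""
    b, err, degen = _train_on_column(column, labels, orientation)
    return Stump("linear", i, None, orientation, b, err, degen)


def train_quadratic_stump(
    col_i: np.ndarray,
    col_j: np.ndarray,
    labels: np.ndarray,
    i: int = 0,
    j: int = 1,
    orientation: str = "+",
) -> Stump:
    """Train one quadratic stump: a linear stump on the product column."""
    ii, jj = min(i, j), max(i, j)
    b, err, degen = _train_on_column(
        np.asarray(col_i, dtype=float) * np.asarray(col_j, dtype=float),
        labels,
        orientation,
    )
    return Stump("quadratic", ii, jj, orientation, b, err, degen)


def enumerate_stumps(table: FeatureTable, include_quadratic: bool = False) -> list[Stump]:
    """Train every candidate stump: both orientations per feature (2F linear)
    and, if requested, per unordered feature pair (2(F + F(F-1)/2) total)."""
    if table.labels is None:
        raise ValueError("labeled table required")
    X, y = table.matrix(), table.labels
    F = X.shape[1]
    if F < 1:
        raise ValueError("at least one feature required")
    out: list[Stump] = []
    for i in range(F):
        for orient in ("+", "-"):
            out.append(train_linear_stump(X[:, i], y, i=i, orientation=orient))
    if include_quadratic:
        for i in range(F):
            for j in range(i + 1, F):
                prod = X[:, i] * X[:, j]
                for orient in ("+", "-"):
                    b, err, degen = _train_on_column(prod, y, orient)
                    out.append(Stump("quadratic", i, j, orient, b, err, degen))
    return out


def filter_random_guessers(
    candidates: Sequence[Stump],
    table: FeatureTable,
    max_error: float = 0.5,
) -> WeakEnsemble:
    """Discard stumps no better than random guessing and build the ensemble.

    Survivors (training error strictly below ``max_error``, degenerate
    stumps included only on the same condition) are ordered by ascending
    training error, ties by (feature indices, orientation); their outputs
    are renormalized to +/-1/N with N the survivor count.
    """
    survivors = [s for s in candidates if s.error < max_error]
    if not survivors:
        raise ValueError("no stumps beat random guessing")
    survivors.sort(key=Stump.sort_key)
    return WeakEnsemble.from_stumps(survivors, table.matrix())


# ---------------------------------------------------------------------------
# ensemble diagnostics


def label_correlation(ensemble: WeakEnsemble, labels: np.ndarray) -> np.ndarray:
    """Per-stump signed agreement with the labels: sum_t c_i(t) y(t).

    A stump with training error e contributes (1-2e)|T|/N; e.g. 25% error
    gives 0.5 |T|/N.
    """
    y = np.asarray(labels, dtype=float)
    if len(y) != ensemble.n_samples:
        raise ValueError("labels misaligned with output matrix")
    return (ensemble.signs @ y) / ensemble.n


def correlation_matrix(ensemble: WeakEnsemble) -> np.ndarray:
    """Pairwise stump correlation Corr(i,j) = (N^2/|T|) sum_t c_i(t) c_j(t),
    normalized so Corr(i,i) = 1."""
    S = ensemble.signs.astype(float)
    return (S @ S.T) / ensemble.n_samples


def select_features_for_expansion(table: FeatureTable, n: int = 30) -> list[int]:
    """Pick the feature subset feeding the quadratic expansion.

    Per-feature score = lowest training error among its surviving quadratic
    stumps (error < 0.5).  Three pools are merged deterministically: the
    n//3 lowest-score features, the n//3 highest-score surviving features,
    and the remainder chosen greedily to minimize the maximum pairwise
    output correlation against the already-selected set (each feature
    represented by its best stump's output vector).
    """
    if table.labels is None:
        raise ValueError("labeled table required")
    X, y = table.matrix(), table.labels
    F = X.shape[1]
    if n > F:
        raise ValueError(f"cannot select {n} of {F} features")
    best_err = np.full(F, np.inf)
    best_signs = np.zeros((F, len(y)), dtype=np.int8)
    for i in range(F):
        for j in range(i, F):
            prod = X[:, i] * X[:, j]
            for orient in ("+", "-"):
                b, err, _ = _train_on_column(prod, y, orient)
                if err >= 0.5:
                    continue
                for fidx in {i, j}:
                    if err < best_err[fidx]:
                        best_err[fidx] = err
                        v = prod if orient == "+" else -prod
                        best_signs[fidx] = np.where(v - b >= 0, 1, -1)
    surviving = np.flatnonzero(np.isfinite(best_err))
    if n > len(surviving):
        raise ValueError(
            f"only {len(surviving)} features have non-random stumps; need {n}"
        )
    by_err = surviving[np.lexsort((surviving, best_err[surviving]))]
    pool = max(1, n // 3)  # the lowest-error pool is never empty
    selected: list[int] = [int(f) for f in by_err[:pool]]
    for f in by_err[::-1][:pool]:  # highest surviving errors
        if f not in selected:
            selected.append(int(f))
    # greedy low-correlation fill
    T = len(y)
    corr = (best_signs.astype(float) @ best_signs.astype(float).T) / T
    remaining = [int(f) for f in by_err if f not in selected]
    while len(selected) < n:
        scores = [
            (max(abs(corr[f, s]) for s in selected), f) for f in remaining
        ]
        scores.sort()
        pick = scores[0][1]
        selected.append(pick)
        remaining.remove(pick)
    return selected[:n]
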