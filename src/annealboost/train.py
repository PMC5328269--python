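"""Strong-classifier training: metaparameter scans, decoding, bias, maps.

A strong classifier is a binary-weight voting subset of the weak ensemble,
C(t) = sign(sum_i w_i c_i(t) - B).  Training builds the regulated Ising
problem for a regulator fraction f, truncates/rescales it through a fixed
embedding with factor alpha, samples an annealer pool, decodes each
distinct configuration to candidate classifiers and keeps the one of
minimal validation error; the bias B is set in post-processing on a
class-balanced set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .anneal import SolutionPool, sample_pool
from .chimera import ChimeraGraph, Embedding, greedy_embed, renormalize
from .features import FeatureTable, RasterScene, extract_feature_table
from .ising import build_ising, spins_to_weights
from .stumps import Stump, WeakEnsemble

__all__ = [
    "StrongClassifier",
    "TrainConfig",
    "split_table",
    "decode_solutions",
    "validation_select",
    "metaparameter_scan",
    "set_bias",
    "predict",
    "evaluate",
    "classify_raster",
    "parse_alpha",
]


@dataclass
class StrongClassifier:
    """A voting subset of weak classifiers with a decision bias.

    ``weights`` is the binary inclusion vector over the ensemble's stumps;
    predictions are sign(sum_i w_i c_i(t) - B) with sign(0) := +1.
    """

    weights: np.ndarray
    stumps: list[Stump]
    bias: float = 0.0
    alpha: float | None = None
    f: float | None = None
    energy: float | None = None
    validation_error: float | None = None
    solver: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.int8)
        if not np.isin(self.weights, (0, 1)).all():
            raise ValueError("weights must be binary")
        if len(self.weights) != len(self.stumps):
            raise ValueError("weight/stump length mismatch")
        if abs(self.bias) > 1.0 + 1e-12:
            raise ValueError("|B| must be <= 1")

    @property
    def cardinality(self) -> int:
        return int(self.weights.sum())

    @property
    def is_empty(self) -> bool:
        return self.cardinality == 0

    def margins(self, X: np.ndarray) -> np.ndarray:
        """Vote sums sum_i w_i c_i(t) in [-1, 1] (before the bias)."""
        N = len(self.stumps)
        out = np.zeros(X.shape[0])
        for w, s in zip(self.weights, self.stumps):
            if w:
                out += s.predict(X).astype(float) / N
        return out

    def to_json(self, path=None) -> str:
        payload = {
            "n": len(self.stumps),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "alpha": self.alpha,
            "f": self.f,
            "energy": self.energy,
            "validation_error": self.validation_error,
            "solver": self.solver,
            "seed": self.seed,
            "stumps": [
                {
                    "kind": s.kind,
                    "i": s.i,
                    "j": s.j,
                    "orientation": s.orientation,
                    "threshold": s.threshold,
                    "error": s.error,
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
    def from_json(cls, source) -> "StrongClassifier":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        stumps = [
            Stump(
                d["kind"], d["i"], d["j"], d["orientation"], d["threshold"], d["error"]
            )
            for d in payload["stumps"]
        ]
        return cls(
            weights=np.array(payload["weights"], dtype=np.int8),
            stumps=stumps,
            bias=payload["bias"],
            alpha=payload.get("alpha"),
            f=payload.get("f"),
            energy=payload.get("energy"),
            validation_error=payload.get("validation_error"),
            solver=payload.get("solver"),
            seed=payload.get("seed"),
        )


@dataclass
class TrainConfig:
    """Metaparameter grids and run sizes for a training scan.

    Alpha grid entries may be expressions in N ("N/4", "N*0.2", "1.5");
    the default grid steps alpha by factors of 2 from N/64 to N and
    f coarsely from 0.1 to 1.0.
    """

    alpha_grid: tuple = ("N/64", "N/32", "N/16", "N/8", "N/4", "N/2", "N")
    f_grid: tuple = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
    n_reads: int = 200
    solver: str = "sa"
    seed: int = 0
    sa_steps: int = 2000
    #: train/validation/bias split; scaled proportionally when a dataset is
    #: smaller than the nominal 24000/3000/3000
    split_sizes: tuple = (24000, 3000, 3000)

    def __post_init__(self) -> None:
        if not self.alpha_grid or not len(self.f_grid):
            raise ValueError("metaparameter grids must be non-empty")
        if len(self.split_sizes) != 3 or any(s <= 0 for s in self.split_sizes):
            raise ValueError("split sizes must be three positive counts")


def split_table(
    table: FeatureTable,
    sizes: tuple = (24000, 3000, 3000),
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Random train/validation/bias split of a labeled table.

    If the table holds fewer samples than sum(sizes), the split is scaled
    proportionally (each part keeps at least one sample).
    """
    if table.labels is None:
        raise ValueError("labeled table required")
    n = len(table)
    total = sum(sizes)
    if n < total:
        sizes = tuple(max(1, int(round(s * n / total))) for s in sizes)
        while sum(sizes) > n:
            sizes = (sizes[0] - 1, sizes[1], sizes[2])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    bounds = np.cumsum(sizes)
    parts = []
    for lo, hi in zip((0, bounds[0], bounds[1]), bounds):
        idx = np.sort(perm[lo:hi])
        parts.append(
            FeatureTable(
                features=table.features.iloc[idx].reset_index(drop=True),
                labels=table.labels[idx],
                block_coords=None
                if table.block_coords is None
                else table.block_coords[idx],
            )
        )
    return tuple(parts)


def parse_alpha(expr, n: int) -> float:
    """Evaluate an alpha grid entry: a number or an expression in N."""
    if isinstance(expr, (int, float)):
        return float(expr)
    allowed = {"N": float(n), "n": float(n)}
    try:
        val = eval(expr, {"__builtins__": {}}, allowed)  # noqa: S307 - tiny arithmetic DSL
    except Exception as exc:
        raise ValueError(f"cannot parse alpha expression {expr!r}") from exc
    val = float(val)
    if val <= 0:
        raise ValueError(f"alpha expression {expr!r} must be positive")
    return val


# ---------------------------------------------------------------------------


def decode_solutions(pool: SolutionPool, ensemble: WeakEnsemble) -> list[StrongClassifier]:
    """One unbiased candidate classifier per distinct pool configuration."""
    if pool.configs.shape[1] != ensemble.n:
        raise ValueError("pool spin length does not match ensemble size")
    out = []
    for spins, energy in zip(pool.configs, pool.energies):
        out.append(
            StrongClassifier(
                weights=spins_to_weights(spins),
                stumps=ensemble.stumps,
                energy=float(energy),
                solver=pool.method,
                seed=pool.seed,
            )
        )
    return out


def validation_select(
    candidates: list[StrongClassifier], validation: FeatureTable
) -> StrongClassifier:
    """Candidate of minimal validation error.

    Ties break by lower energy, then smaller cardinality, then
    lexicographic weight vector.  Each candidate's validation error is
    recorded in place, so the full (energy, error) scatter can be read off
    the candidate list afterwards.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    if validation.labels is None:
        raise ValueError("validation labels required")
    for c in candidates:
        c.validation_error = evaluate(c, validation)["error"]
    def key(c: StrongClassifier):
        e = np.inf if c.energy is None else c.energy
        return (c.validation_error, e, c.cardinality, tuple(c.weights))
    return min(candidates, key=key)


def train_once(
    ensemble: WeakEnsemble,
    train_labels: np.ndarray,
    validation: FeatureTable,
    f: float,
    alpha: float,
    embedding: Embedding | None,
    n_reads: int,
    solver: str,
    seed: int,
    sa_steps: int = 2000,
) -> StrongClassifier:
    """One (alpha, f) training cell: build, renormalize, solve, select."""
    problem = build_ising(ensemble, train_labels, f=f)
    if embedding is not None:
        problem = renormalize(problem, embedding, alpha)
    pool = sample_pool(problem, n_reads=n_reads, solver=solver, seed=seed, max_steps=sa_steps)
    candidates = decode_solutions(pool, ensemble)
    best = validation_select(candidates, validation)
    best.alpha = alpha
    best.f = f
    return best


def metaparameter_scan(
    ensemble: WeakEnsemble,
    train_labels: np.ndarray,
    validation: FeatureTable,
    config: TrainConfig,
    graph: ChimeraGraph | None = None,
):
    """Scan the (alpha, f) grid and return the best cell.

    One embedding is computed from the f-independent couplings and reused
    across the whole scan.  Returns (best classifier, scan surface
    DataFrame with columns alpha,f,val_error,cardinality,energy).
    """
    embedding = None
    if graph is not None:
        base = build_ising(ensemble, train_labels, f=float(config.f_grid[0]))
        embedding = greedy_embed(base, graph)
    rows = []
    best: StrongClassifier | None = None
    master = np.random.SeedSequence(config.seed)
    cells = [(a_expr, f) for a_expr in config.alpha_grid for f in config.f_grid]
    for child, (a_expr, f) in zip(master.spawn(len(cells)), cells):
        alpha = parse_alpha(a_expr, ensemble.n)
        cell_seed = int(child.generate_state(1)[0] % (2**31))
        clf = train_once(
            ensemble,
            train_labels,
            validation,
            f=float(f),
            alpha=alpha,
            embedding=embedding,
            n_reads=config.n_reads,
            solver=config.solver,
            seed=cell_seed,
            sa_steps=config.sa_steps,
        )
        rows.append(
            {
                "alpha": alpha,
                "f": float(f),
                "val_error": clf.validation_error,
                "cardinality": clf.cardinality,
                "energy": clf.energy,
            }
        )
        if best is None or (
            (clf.validation_error, clf.energy) < (best.validation_error, best.energy)
        ):
            best = clf
    surface = pd.DataFrame(rows)
    return best, surface, embedding


def set_bias(
    classifier: StrongClassifier,
    bias_table: FeatureTable,
    seed: int = 0,
    mode: str = "sign",
) -> StrongClassifier:
    """Set B as the average unbiased output on a class-balanced set.

    The majority class is subsampled (seeded) to enforce balance.  ``mode``
    "sign" averages the +/-1 outputs (default); "margin" averages the raw
    vote sums.
    """
    import warnings

    if classifier.is_empty:
        warnings.warn("empty classifier; bias set to 0")
        return replace(classifier, bias=0.0)
    if bias_table.labels is None:
        raise ValueError("bias table must be labeled")
    y = bias_table.labels
    X = bias_table.matrix()
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == -1)
    m = min(len(pos), len(neg))
    if m == 0:
        raise ValueError("bias table must contain both classes")
    rng = np.random.default_rng(seed)
    if len(pos) > m:
        pos = rng.choice(pos, size=m, replace=False)
    if len(neg) > m:
        neg = rng.choice(neg, size=m, replace=False)
    sel = np.sort(np.concatenate([pos, neg]))
    margins = classifier.margins(X[sel])
    if mode == "sign":
        out = np.where(margins >= 0, 1.0, -1.0)
        B = float(out.mean())
    elif mode == "margin":
        B = float(margins.mean())
    else:
        raise ValueError(f"unknown bias mode {mode!r}")
    return replace(classifier, bias=B)


def predict(classifier: StrongClassifier, table: FeatureTable) -> np.ndarray:
    """+/-1 labels: sign(sum_i w_i c_i(t) - B), with sign(0) := +1."""
    margins = classifier.margins(table.matrix())
    return np.where(margins - classifier.bias >= 0, 1, -1).astype(np.int8)


def evaluate(classifier: StrongClassifier, table: FeatureTable) -> dict:
    """Error rate and confusion accounting on a labeled table."""
    if table.labels is None:
        raise ValueError("labeled table required")
    pred = predict(classifier, table)
    y = table.labels
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == -1) & (y == -1)).sum())
    fp = int(((pred == 1) & (y == -1)).sum())
    fn = int(((pred == -1) & (y == 1)).sum())
    n = len(y)
    npos, nneg = tp + fn, tn + fp
    return {
        "error": (fp + fn) / n,
        "false_positive_rate": fp / nneg if nneg else 0.0,
        "false_negative_rate": fn / npos if npos else 0.0,
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }


def classify_raster(
    classifier: StrongClassifier,
    scene: RasterScene,
    catalog=None,
    block_size: int = 8,
) -> np.ndarray:
    """Block-resolution +/-1 label map of a scene."""
    table = extract_feature_table(scene, catalog=catalog, block_size=block_size)
    labels = predict(classifier, table)
    nrows = scene.shape[0] // block_size
    ncols = scene.shape[1] // block_size
    out = np.zeros((nrows, ncols), dtype=np.int8)
    for (br, bc), lab in zip(table.block_coords, labels):
        out[br, bc] = lab
    return out
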