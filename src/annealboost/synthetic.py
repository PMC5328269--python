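"""Synthetic scenes and planted weak-classifier ensembles.

Two generators make every pipeline stage testable without real imagery:

* :func:`generate_scene` draws NAIP-like 4-band scenes — blobby
  high-NIR, textured tree canopy against smooth grass, bare soil and
  built surfaces, with optional shadows — together with a pixel label
  mask.  Texture is Gaussian-filtered white noise with class-specific
  correlation lengths; only the induced stump-error regime matters, not
  radiometric realism.

* :func:`generate_planted_ensemble` draws abstract +/-1/N weak-classifier
  output matrices with controlled per-stump accuracies and block-correlated
  errors, and certifies by exhaustive enumeration (N <= 16) that a chosen
  "planted" subset is the exact minimizer of the unregulated quadratic
  loss at its cardinality, returning a regulator fraction f at which it is
  the *global* optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .features import RasterScene
from .ising import build_ising
from .stumps import WeakEnsemble, Stump

__all__ = [
    "SceneSpec",
    "PlantedEnsembleSpec",
    "generate_scene",
    "generate_planted_ensemble",
    "scaling_report",
]


# ---------------------------------------------------------------------------
# scenes

#: per-class band means (R, G, B, NIR): trees are dark green with high NIR,
#: grass bright green with moderate NIR, soil warm and NIR-poor, built
#: surfaces gray and NIR-poor.
CLASS_MEANS = {
    "tree": (0.26, 0.36, 0.22, 0.56),
    "grass": (0.32, 0.42, 0.25, 0.47),
    "soil": (0.48, 0.42, 0.34, 0.38),
    "urban": (0.44, 0.44, 0.43, 0.32),
}

#: spatial correlation length (pixels) of each class's texture field; trees
#: carry short-wavelength canopy texture, the rest are smooth.
CLASS_TEXTURE_SIGMA = {"tree": 1.0, "grass": 4.0, "soil": 6.0, "urban": 5.0}


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene draw."""

    height: int = 256
    width: int = 256
    tree_fraction: float = 0.4
    texture_amplitude: float = 0.18
    noise_level: float = 0.10
    #: amplitude of the per-band low-frequency illumination/moisture field;
    #: this is what blurs class separability at block scale (pixel noise
    #: averages out over an 8x8 block, broad brightness gradients do not)
    illumination_amplitude: float = 0.12
    illumination_sigma: float = 24.0
    shadow_fraction: float = 0.10
    blob_sigma: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tree_fraction <= 1.0:
            raise ValueError("tree_fraction outside [0, 1]")
        if not 0.0 <= self.shadow_fraction <= 1.0:
            raise ValueError("shadow_fraction outside [0, 1]")
        if self.noise_level < 0 or self.texture_amplitude < 0:
            raise ValueError("noise/texture amplitudes must be >= 0")


def _blob_mask(rng, shape, fraction, sigma) -> np.ndarray:
    """Smoothed-thresholded noise: a blobby mask hitting ``fraction`` cover."""
    if fraction <= 0.0:
        return np.zeros(shape, dtype=bool)
    if fraction >= 1.0:
        return np.ones(shape, dtype=bool)
    field_ = gaussian_filter(rng.standard_normal(shape), sigma)
    cut = np.quantile(field_, 1.0 - fraction)
    return field_ > cut


def generate_scene(spec: SceneSpec) -> RasterScene:
    """Draw one labeled 4-band scene; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    tree = _blob_mask(rng, shape, spec.tree_fraction, spec.blob_sigma)

    achieved = float(tree.mean())
    if abs(achieved - spec.tree_fraction) > 0.05:
        warnings.warn(
            f"achieved tree fraction {achieved:.3f} misses target "
            f"{spec.tree_fraction:.3f} by more than 0.05"
        )

    # split the non-tree background into grass / soil / urban regions
    bg_field = gaussian_filter(rng.standard_normal(shape), 1.5 * spec.blob_sigma)
    q1, q2 = np.quantile(bg_field, [1 / 3, 2 / 3])
    class_map = np.full(shape, "urban", dtype=object)
    class_map[bg_field <= q1] = "grass"
    class_map[(bg_field > q1) & (bg_field <= q2)] = "soil"
    class_map[tree] = "tree"

    bands = []
    textures = {
        cls: gaussian_filter(rng.standard_normal(shape), sig)
        for cls, sig in CLASS_TEXTURE_SIGMA.items()
    }
    # re-amplify: gaussian filtering shrinks the variance
    for cls in textures:
        sd = textures[cls].std()
        if sd > 0:
            textures[cls] /= sd
    shadow = _blob_mask(rng, shape, spec.shadow_fraction, spec.blob_sigma / 2)
    for b in range(4):
        band = np.zeros(shape)
        for cls, means in CLASS_MEANS.items():
            sel = class_map == cls
            band[sel] = means[b] + spec.texture_amplitude * textures[cls][sel]
        illum = gaussian_filter(rng.standard_normal(shape), spec.illumination_sigma)
        sd = illum.std()
        if sd > 0:
            illum /= sd
        band += spec.illumination_amplitude * illum
        band += spec.noise_level * rng.standard_normal(shape)
        band[shadow] *= 0.45
        bands.append(np.clip(band, 0.0, 1.0))

    return RasterScene(*bands, labels=tree.astype(np.int8))


# ---------------------------------------------------------------------------
# planted ensembles


@dataclass
class PlantedEnsembleSpec:
    """Parameters of one abstract weak-classifier ensemble draw.

    ``accuracies`` gives the per-stump probability of agreeing with the
    label (in (0.5, 1] for informative stumps).  ``correlation_blocks``
    lists groups of stump indices that share one error source with mixing
    weight ``block_strength`` (1.0 -> identical outputs within a block).
    ``planted`` is the target optimal subset; generation certifies it.
    """

    n_stumps: int = 12
    n_samples: int = 256
    accuracies: tuple = ()
    correlation_blocks: tuple = ()
    block_strength: float = 0.9
    planted: tuple = (0, 1, 2, 3)
    seed: int = 0
    certify: bool = True
    max_attempts: int = 40

    def __post_init__(self) -> None:
        if not set(self.planted) <= set(range(self.n_stumps)):
            raise ValueError("planted subset outside 1..N")
        if not self.accuracies:
            acc = np.full(self.n_stumps, 0.65)
            acc[list(self.planted)] = 0.8
            self.accuracies = tuple(acc)
        if len(self.accuracies) != self.n_stumps:
            raise ValueError("one accuracy per stump required")
        for a in self.accuracies:
            if not 0.0 < a <= 1.0:
                raise ValueError("accuracies must lie in (0, 1]")
        if not set(self.planted) <= set(range(self.n_stumps)):
            raise ValueError("planted subset outside 1..N")
        if not 0.0 <= self.block_strength <= 1.0:
            raise ValueError("block_strength outside [0, 1]")


@dataclass
class PlantedEnsemble:
    """A generated ensemble plus its certificate."""

    ensemble: WeakEnsemble
    labels: np.ndarray
    planted: np.ndarray
    f_star: float | None  # regulator fraction at which planted = global optimum
    certified: bool


def _abstract_stumps(n: int) -> list[Stump]:
    """Placeholder stump records for ensembles not backed by features."""
    return [Stump("linear", i, None, "+", 0.0, 0.5) for i in range(n)]


def _all_losses(signs: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unregulated loss and cardinality for all 2^N weight vectors."""
    N = signs.shape[0]
    ens = WeakEnsemble(_abstract_stumps(N), signs)
    prob = build_ising(ens, y, f=0.0)
    idx = np.arange(1 << N, dtype=np.int64)
    S = (((idx[:, None] >> np.arange(N)) & 1) * 2 - 1).astype(float)
    Jm = prob.coupling_matrix()
    E = -(S @ prob.h) - 0.5 * np.einsum("ij,ij->i", S @ Jm, S)
    losses = E + prob.offset
    cards = ((S + 1) // 2).sum(axis=1).astype(int)
    return losses, cards


def _certify(signs: np.ndarray, y: np.ndarray, planted: np.ndarray):
    """Exact certificate that ``planted`` minimizes the unregulated loss at
    its cardinality, plus the open lambda window making it global optimum.

    Returns (ok, f_star) with f_star = lambda* N / (2|T|) for a lambda* in
    the interior of the feasible window, or (False, None).
    """
    N, T = signs.shape
    losses, cards = _all_losses(signs, y)
    k = len(planted)
    w_idx = int(np.sum(1 << planted))
    L_star = losses[w_idx]
    same_k = cards == k
    if losses[same_k].min() < L_star - 1e-9 or (
        np.isclose(losses[same_k], L_star, atol=1e-9).sum() > 1
    ):
        return False, None
    hi_mask = cards > k
    lo_mask = cards < k
    lam_lo = 0.0
    if hi_mask.any():
        lam_lo = max(
            0.0, float(((L_star - losses[hi_mask]) / (cards[hi_mask] - k)).max())
        )
    lam_hi = np.inf
    if lo_mask.any():
        lam_hi = float(((losses[lo_mask] - L_star) / (k - cards[lo_mask])).min())
    if not lam_lo < lam_hi:
        return False, None
    lam = lam_lo + 0.5 * (min(lam_hi, lam_lo + 2.0) - lam_lo)
    if lam <= lam_lo:
        return False, None
    return True, float(lam * N / (2.0 * T))


def generate_planted_ensemble(spec: PlantedEnsembleSpec) -> PlantedEnsemble:
    """Draw a +/-1/N output matrix with planted optimal subset.

    Labels are balanced +/-1; each stump copies the label and flips it with
    probability 1 - accuracy; blocks share an error source.  For N <= 16
    with ``certify`` the draw is repeated until the planted subset is the
    certified exact minimizer (raises after ``max_attempts`` failures).
    """
    N, T = spec.n_stumps, spec.n_samples
    planted = np.array(sorted(spec.planted), dtype=int)
    can_certify = spec.certify and N <= 16
    master = np.random.SeedSequence(spec.seed)
    attempts = spec.max_attempts if can_certify else 1
    for child in master.spawn(attempts):
        rng = np.random.default_rng(child)
        y = np.ones(T, dtype=int)
        y[T // 2 :] = -1
        rng.shuffle(y)
        correct = np.ones((N, T), dtype=np.int8)
        for i in range(N):
            flips = rng.random(T) < (1.0 - spec.accuracies[i])
            correct[i, flips] = -1
        for block in spec.correlation_blocks:
            block = list(block)
            shared = correct[block[0]].copy()
            for i in block[1:]:
                use_shared = rng.random(T) < spec.block_strength
                correct[i, use_shared] = shared[use_shared]
        signs = (correct * y[None, :]).astype(np.int8)
        if not can_certify:
            ens = WeakEnsemble(_abstract_stumps(N), signs)
            return PlantedEnsemble(ens, y, planted, None, False)
        ok, f_star = _certify(signs, y, planted)
        if ok:
            ens = WeakEnsemble(_abstract_stumps(N), signs)
            return PlantedEnsemble(ens, y, planted, f_star, True)
    raise RuntimeError(
        f"could not certify the planted subset in {attempts} draws; "
        "adjust accuracies/correlations"
    )


# ---------------------------------------------------------------------------
# scaling diagnostics


def scaling_report(
    ensemble: WeakEnsemble,
    labels: np.ndarray,
    k: int,
    f: float = 0.0,
    alpha: float = 1.0,
) -> dict:
    """Field-vs-coupling scaling diagnostics under degree-k truncation.

    Builds the full Ising problem, truncates each edge unless it ranks in
    the top-k |J| of *both* endpoints (a symmetric proxy for a degree-k
    hardware graph; k = N-1 keeps everything), rescales survivors by
    ``alpha``, and reports per-spin |h_a| against the summed retained
    coupling magnitudes, plus the fraction of spins decoupled in the sense
    |h_a| > alpha * sum |J_aj|.
    """
    from .chimera import decoupled_spins

    prob = build_ising(ensemble, labels, f=f)
    N = prob.n
    Jm = np.abs(prob.coupling_matrix())
    if k >= N - 1:
        keep = np.ones(len(prob.edges), dtype=bool)
    else:
        # rank of each edge within each endpoint's sorted |J| row
        thresholds = np.sort(Jm, axis=1)[:, -(k):][:, 0]  # k-th largest per row
        keep = np.array(
            [
                Jm[i, j] >= thresholds[i] and Jm[i, j] >= thresholds[j]
                for i, j in prob.edges
            ]
        )
    from .ising import IsingProblem

    truncated = IsingProblem(
        n=N,
        h=prob.h.copy(),
        edges=prob.edges[keep],
        couplings=prob.couplings[keep] * alpha,
        offset=prob.offset,
        lam=prob.lam,
        f=prob.f,
        provenance="embedded",
    )
    coupling_sum = np.zeros(N)
    if len(truncated.edges):
        np.add.at(coupling_sum, truncated.edges[:, 0], np.abs(truncated.couplings))
        np.add.at(coupling_sum, truncated.edges[:, 1], np.abs(truncated.couplings))
    forced = decoupled_spins(truncated)
    return {
        "n": N,
        "k": k,
        "alpha": alpha,
        "median_abs_h": float(np.median(np.abs(truncated.h))),
        "median_coupling_sum": float(np.median(coupling_sum)),
        "decoupled_fraction": len(forced) / N,
        "abs_h": np.abs(truncated.h),
        "coupling_sums": coupling_sum,
    }
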