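"""Binary grey-wolf-optimizer (GWO) wrapper feature selection.

Candidate feature subsets are wolves with continuous per-feature positions.
Each iteration every wolf moves toward the three best wolves (alpha, beta,
delta) under a decaying exploration coefficient ``a``:

    A = 2*a*r1 - a,   C = 2*r2,   D_L = |C*X_L - X|,   X_L' = X_L - A*D_L

and the new position is the mean of the three leader-guided candidates.
Two decay schedules are supported: the classical linear ``a0*(1 - t/T)``
("gwo1") and a quadratic ``a0*(1 - t^2/T^2)`` ("gwo2") that stays high
longer to extend exploration.  Positions are binarized through a logistic
transfer with a strict threshold theta = 1 - exploitation_rate; a higher
threshold (gwo2) yields a more aggressive reduction in selected features.

Fitness is a nearest-centroid class-separation margin evaluated on a
held-out validation split: the mean over validation samples of (distance to
the nearest wrong-class centroid minus distance to the own-class centroid),
computed on the selected columns after per-feature standardization fitted
on the training split.  The fitness is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted, validate_data

from .tables import LabeledFeatureTable

__all__ = [
    "GWOConfig",
    "GWOFeatureSelector",
    "SelectionResult",
    "DegenerateThresholdError",
    "InfeasibleMaskError",
    "binarize",
    "decay_coefficient",
    "fitness_margin",
    "select_features",
    "update_wolf",
    "write_mask",
    "read_mask",
]

#: Control-parameter presets for the two optimizer variants.  The
#: exploration rate is the initial value a0 of the decay coefficient; the
#: exploitation rate rho maps to the selection threshold theta = 1 - rho.
VARIANT_PRESETS: dict[str, dict] = {
    "gwo1": dict(
        decay_variant="linear",
        exploration_rate=2.0,
        exploitation_rate=0.5,
        convergence_threshold=1e-6,
    ),
    "gwo2": dict(
        decay_variant="quadratic",
        exploration_rate=1.5,
        exploitation_rate=0.3,
        convergence_threshold=4e-7,
    ),
}

#: Iterations without meaningful best-fitness improvement before stopping.
CONVERGENCE_WINDOW = 10


class DegenerateThresholdError(RuntimeError):
    """Every wolf in the population binarized to an empty feature mask."""


class InfeasibleMaskError(ValueError):
    """A candidate mask selects no features, so fitness is undefined."""


@dataclass
class GWOConfig:
    """Optimizer control parameters (study defaults: population 10, T=100)."""

    population_size: int = 10
    max_iterations: int = 100
    decay_variant: Literal["linear", "quadratic"] = "linear"
    exploration_rate: float = 2.0
    exploitation_rate: float = 0.5
    convergence_threshold: float = 1e-6
    seed: int = 0

    @classmethod
    def for_variant(cls, variant: str, **overrides) -> "GWOConfig":
        """Preset configuration for ``"gwo1"`` (classical) or ``"gwo2"``."""
        if variant not in VARIANT_PRESETS:
            raise ValueError(f"unknown GWO variant {variant!r}")
        params = {**VARIANT_PRESETS[variant], **overrides}
        return cls(**params)

    @property
    def threshold(self) -> float:
        """Selection threshold theta = 1 - exploitation_rate."""
        return 1.0 - self.exploitation_rate

    def validate(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4 (alpha, beta, delta + omega)")
        if not 0.0 < self.exploitation_rate < 1.0:
            raise ValueError("exploitation_rate must lie in (0, 1)")
        if self.exploration_rate <= 0:
            raise ValueError("exploration_rate (a0) must be positive")
        if self.convergence_threshold <= 0:
            raise ValueError("convergence_threshold must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.decay_variant not in ("linear", "quadratic"):
            raise ValueError(f"unknown decay variant {self.decay_variant!r}")


@dataclass
class SelectionResult:
    """Outcome of one optimizer run."""

    mask: np.ndarray
    fitness: float
    fitness_trace: np.ndarray
    iterations_run: int
    converged: bool

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.mask))


def decay_coefficient(
    t: int, T: int, variant: str = "linear", a0: float = 2.0
) -> float:
    """Exploration coefficient ``a`` at iteration ``t`` of ``T``.

    Linear: ``a0*(1 - t/T)``; quadratic: ``a0*(1 - t**2/T**2)``.  Both equal
    ``a0`` at t=0 and 0 at t=T; the quadratic schedule dominates the linear
    one in between, extending exploration.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, T={T}]")
    if variant == "linear":
        frac = t / T
    elif variant == "quadratic":
        frac = (t * t) / (T * T)
    else:
        raise ValueError(f"unknown decay variant {variant!r}")
    return a0 * (1.0 - frac)


def update_wolf(
    position: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    delta: np.ndarray,
    a: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One position update toward the three leaders.

    For each leader X_L in (alpha, beta, delta), in that order, two uniform
    vectors r1, r2 are drawn per dimension (two ``rng.random(d)`` calls per
    leader), giving A = 2*a*r1 - a and C = 2*r2; the leader-guided candidate
    is X_L - A*|C*X_L - X| and the new position is the mean of the three
    candidates.
    """
    position = np.asarray(position, dtype=float)
    if a < 0:
        raise ValueError("coefficient a must be non-negative")
    candidates = []
    for leader in (alpha, beta, delta):
        leader = np.asarray(leader, dtype=float)
        if leader.shape != position.shape:
            raise ValueError("leader and wolf positions must have the same length")
        r1 = rng.random(position.shape[0])
        r2 = rng.random(position.shape[0])
        A = 2.0 * a * r1 - a
        C = 2.0 * r2
        D = np.abs(C * leader - position)
        candidates.append(leader - A * D)
    return (candidates[0] + candidates[1] + candidates[2]) / 3.0


def binarize(position: np.ndarray, threshold: float) -> np.ndarray:
    """Map continuous positions to a feature mask via the logistic transfer.

    ``mask[i] = s(position[i]) > threshold`` with ``s(x) = 1/(1+exp(-x))``;
    the inequality is strict, so values exactly at the threshold are
    excluded (tie rule).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    s = expit(np.asarray(position, dtype=float))
    return s > threshold


@dataclass
class _StandardizedCentroids:
    """Train-split statistics reused across fitness evaluations."""

    mean: np.ndarray
    sd: np.ndarray
    train_values: np.ndarray
    train_labels: np.ndarray
    val_values: np.ndarray
    val_labels: np.ndarray
    classes: np.ndarray


def _margin_context(
    train_values: np.ndarray,
    train_labels: np.ndarray,
    val_values: np.ndarray,
    val_labels: np.ndarray,
) -> _StandardizedCentroids:
    mean = train_values.mean(axis=0)
    sd = train_values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return _StandardizedCentroids(
        mean=mean,
        sd=sd,
        train_values=train_values,
        train_labels=np.asarray(train_labels),
        val_values=val_values,
        val_labels=np.asarray(val_labels),
        classes=np.unique(train_labels),
    )


def _margin_from_context(ctx: _StandardizedCentroids, mask: np.ndarray) -> float:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InfeasibleMaskError("mask selects no features")
    tr = (ctx.train_values[:, mask] - ctx.mean[mask]) / ctx.sd[mask]
    va = (ctx.val_values[:, mask] - ctx.mean[mask]) / ctx.sd[mask]
    centroids = np.stack(
        [tr[ctx.train_labels == c].mean(axis=0) for c in ctx.classes]
    )
    # (n_val, n_classes) distances to each class centroid
    dists = np.linalg.norm(va[:, None, :] - centroids[None, :, :], axis=2)
    own_col = np.searchsorted(ctx.classes, ctx.val_labels)
    own = dists[np.arange(va.shape[0]), own_col]
    masked = dists.copy()
    masked[np.arange(va.shape[0]), own_col] = np.inf
    other = masked.min(axis=1)
    return float(np.mean(other - own))


def fitness_margin(
    train: LabeledFeatureTable,
    validation: LabeledFeatureTable,
    mask: np.ndarray,
) -> float:
    """Nearest-centroid separation margin of the masked feature subset.

    Mean over validation samples of (distance to the nearest wrong-class
    centroid minus distance to the own-class centroid), on columns selected
    by ``mask`` after per-feature standardization fitted on ``train``.
    Higher is better; zero for indistinguishable classes.

    Raises
    ------
    InfeasibleMaskError
        If the mask selects no features.  The optimizer catches this and
        assigns worst fitness instead of aborting.
    """
    if train.feature_ids != validation.feature_ids:
        raise ValueError("train and validation tables must share feature_ids")
    ctx = _margin_context(train.values, train.labels, validation.values, validation.labels)
    return _margin_from_context(ctx, mask)


def _run_gwo(
    n_features: int,
    fitness_of_mask: Callable[[np.ndarray], float],
    config: GWOConfig,
) -> SelectionResult:
    """Core optimizer loop over continuous positions in [-1, 1]^d."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    theta = config.threshold
    pop = config.population_size
    T = config.max_iterations

    positions = rng.uniform(-1.0, 1.0, size=(pop, n_features))

    def evaluate(pos_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        masks = np.stack([binarize(p, theta) for p in pos_matrix])
        if not masks.any():
            raise DegenerateThresholdError(
                "every wolf binarized to an empty mask; threshold too high "
                f"(theta={theta:.3f})"
            )
        fits = np.empty(pop)
        for i, m in enumerate(masks):
            try:
                fits[i] = fitness_of_mask(m)
            except InfeasibleMaskError:
                fits[i] = -np.inf
        return masks, fits

    masks, fits = evaluate(positions)
    best_i = int(np.argmax(fits))
    best_mask = masks[best_i].copy()
    best_fit = float(fits[best_i])
    trace = [best_fit]
    stall = 0
    converged = False
    iterations = 0

    for t in range(1, T + 1):
        a = decay_coefficient(t, T, config.decay_variant, config.exploration_rate)
        order = np.argsort(-fits, kind="stable")
        x_alpha, x_beta, x_delta = (positions[order[k]].copy() for k in range(3))
        for i in range(pop):
            positions[i] = update_wolf(positions[i], x_alpha, x_beta, x_delta, a, rng)
        masks, fits = evaluate(positions)
        iter_best = int(np.argmax(fits))
        improvement = float(fits[iter_best]) - best_fit
        if improvement > 0:
            best_fit = float(fits[iter_best])
            best_mask = masks[iter_best].copy()
        trace.append(best_fit)
        iterations = t
        if improvement < config.convergence_threshold:
            stall += 1
            if stall >= CONVERGENCE_WINDOW:
                converged = True
                break
        else:
            stall = 0

    return SelectionResult(
        mask=best_mask,
        fitness=best_fit,
        fitness_trace=np.asarray(trace),
        iterations_run=iterations,
        converged=converged,
    )


def select_features(
    train: LabeledFeatureTable,
    validation: LabeledFeatureTable,
    config: GWOConfig | None = None,
    fitness: Callable[[LabeledFeatureTable, LabeledFeatureTable, np.ndarray], float] | None = None,
) -> SelectionResult:
    """Run binary GWO feature selection on a train/validation table pair.

    Wolves are initialized uniformly on [-1, 1] per feature (unbiased initial
    selection probability around 0.5 under the logistic transfer at
    theta=0.5); each iteration updates every wolf toward the current three
    best and re-evaluates fitness; stops at ``max_iterations`` or once the
    best fitness improves by less than the convergence threshold over 10
    consecutive iterations.
    """
    config = config or GWOConfig()
    if train.n_samples == 0 or validation.n_samples == 0:
        raise ValueError("train and validation tables must be non-empty")
    if train.feature_ids != validation.feature_ids:
        raise ValueError("train and validation tables must share feature_ids")
    if fitness is None:
        ctx = _margin_context(
            train.values, train.labels, validation.values, validation.labels
        )
        fitness_of_mask = lambda m: _margin_from_context(ctx, m)  # noqa: E731
    else:
        fitness_of_mask = lambda m: fitness(train, validation, m)  # noqa: E731
    return _run_gwo(train.n_features, fitness_of_mask, config)


class GWOFeatureSelector(SelectorMixin, BaseEstimator):
    """Grey-wolf wrapper feature selection as a scikit-learn transformer.

    ``fit(X, y)`` holds out a stratified validation fraction of the provided
    training data for the margin fitness, runs the optimizer and stores the
    selected-feature mask; ``transform`` keeps the selected columns.

    Parameters
    ----------
    variant : {"gwo1", "gwo2"}
        Control-parameter preset: classical linear decay ("gwo1") or the
        modified quadratic decay with a higher selection threshold ("gwo2").
    population_size, max_iterations : int
        Wolf count and iteration budget T.
    exploration_rate, exploitation_rate, convergence_threshold : float, optional
        Override the preset a0, rho (theta = 1 - rho) and stopping epsilon.
    validation_fraction : float
        Stratified share of ``fit`` data held out for the fitness margin.
    random_state : int
        Seed for initialization, position updates and the internal split.

    Attributes
    ----------
    support_mask_ : ndarray of bool, shape (n_features_in_,)
        Selected-feature indicator.
    result_ : SelectionResult
        Full optimizer outcome including the best-so-far fitness trace.
    """

    def __init__(
        self,
        variant: str = "gwo1",
        population_size: int = 10,
        max_iterations: int = 100,
        exploration_rate: float | None = None,
        exploitation_rate: float | None = None,
        convergence_threshold: float | None = None,
        validation_fraction: float = 0.2,
        random_state: int = 0,
    ):
        self.variant = variant
        self.population_size = population_size
        self.max_iterations = max_iterations
        self.exploration_rate = exploration_rate
        self.exploitation_rate = exploitation_rate
        self.convergence_threshold = convergence_threshold
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _config(self) -> GWOConfig:
        overrides = dict(
            population_size=self.population_size,
            max_iterations=self.max_iterations,
            seed=self.random_state,
        )
        for name in ("exploration_rate", "exploitation_rate", "convergence_threshold"):
            value = getattr(self, name)
            if value is not None:
                overrides[name] = value
        return GWOConfig.for_variant(self.variant, **overrides)

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        config = self._config()
        X_tr, X_val, y_tr, y_val = train_test_split(
            X,
            y,
            test_size=self.validation_fraction,
            stratify=y,
            random_state=self.random_state,
        )
        ctx = _margin_context(X_tr, y_tr, X_val, y_val)
        self.result_ = _run_gwo(
            X.shape[1], lambda m: _margin_from_context(ctx, m), config
        )
        self.support_mask_ = self.result_.mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_mask_


def write_mask(mask: np.ndarray, feature_ids: list[str], path) -> None:
    """Write a selection mask as delimited text: feature_id, selected(0/1)."""
    pd.DataFrame(
        {"feature_id": feature_ids, "selected": np.asarray(mask, dtype=int)}
    ).to_csv(path, index=False)


def read_mask(path) -> tuple[np.ndarray, list[str]]:
    """Read a selection mask written by :func:`write_mask`."""
    df = pd.read_csv(path)
    return df["selected"].to_numpy(dtype=bool), df["feature_id"].astype(str).tolist()
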