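"""Multicriteria model selection: CRITIC weighting and RAPS ranking.

A decision matrix holds n alternatives (models) scored on m criteria
(evaluation metrics), each marked benefit (maximize) or cost (minimize).

RAPS — ranking alternatives by perimeter similarity — proceeds in stages:

1. ratio normalization: benefit r_ij = x_ij / max_i x_ij, cost
   r_ij = min_i x_ij / x_ij (an explicit ideal row may override the column
   extremes);
2. weighting: u_ij = w_j * r_ij;
3. ideal decomposition: the ideal vector q (columnwise maxima of u, or the
   weights themselves when an explicit ideal row is used, since the ideal
   normalizes to 1) is split into its benefit part (Euclidean magnitude Qk)
   and cost part (Qh), the legs of a right triangle with perimeter
   P = Qk + Qh + sqrt(Qk^2 + Qh^2);
4. perimeter similarity: each alternative's row decomposes the same way
   into magnitudes Uik/Uih with perimeter Pi, and its score is
   PS_i = Pi / P — 1 for an alternative attaining every ideal value.
   Alternatives are ranked by descending PS (dense ranks, ties broken by
   input order).

CRITIC — criteria importance through intercriteria correlation — derives
objective weights from the matrix itself: columns are min-max normalized
(one orientation for all criteria), each criterion's information index is
c_j = sigma_j * sum_k (1 - rho_jk) with sigma the population standard
deviation and rho the Pearson correlation between normalized columns, and
weights are w_j = c_j / sum(c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CriterionSpec",
    "CriticWeights",
    "DecisionMatrix",
    "RapsResult",
    "apply_weights",
    "critic_weights",
    "ideal_decomposition",
    "normalize_ratio",
    "perimeter_similarity",
    "rank_models",
]

BENEFIT = "benefit"
COST = "cost"


@dataclass
class CriterionSpec:
    """One criterion: its name, optimization direction, optional weight."""

    name: str
    direction: str = BENEFIT
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in (BENEFIT, COST):
            raise ValueError(
                f"criterion {self.name!r}: direction must be "
                f"'{BENEFIT}' or '{COST}', got {self.direction!r}"
            )


@dataclass
class DecisionMatrix:
    """n alternatives x m criteria of raw performance values."""

    values: np.ndarray
    alternative_ids: list[str]
    criteria: list[CriterionSpec]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("decision matrix must have >= 1 alternative and criterion")
        if len(self.alternative_ids) != n:
            raise ValueError("alternative_ids length mismatch")
        if len(self.criteria) != m:
            raise ValueError("criteria length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("decision matrix values must be finite")
        cost_cols = [j for j, c in enumerate(self.criteria) if c.direction == COST]
        if cost_cols and (self.values[:, cost_cols] <= 0).any():
            raise ValueError("cost-criterion values must be positive (ratio normalization)")

    @property
    def directions(self) -> list[str]:
        return [c.direction for c in self.criteria]

    @property
    def criterion_names(self) -> list[str]:
        return [c.name for c in self.criteria]

    @property
    def weights(self) -> np.ndarray | None:
        ws = [c.weight for c in self.criteria]
        if any(w is None for w in ws):
            return None
        w = np.asarray(ws, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("criterion weights must be non-negative and sum to 1")
        return w

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.alternative_ids, columns=self.criterion_names
        )


@dataclass
class CriticWeights:
    """CRITIC outcome: dispersions, information indices, normalized weights."""

    sigma: np.ndarray
    c: np.ndarray
    w: np.ndarray


@dataclass
class RapsResult:
    """All RAPS stages, kept for audit."""

    alternative_ids: list[str]
    criterion_names: list[str]
    directions: list[str]
    weights: np.ndarray
    r: np.ndarray
    u: np.ndarray
    q: np.ndarray
    Qk: float
    Qh: float
    P: float
    Uik: np.ndarray
    Uih: np.ndarray
    Pi: np.ndarray
    PS: np.ndarray
    ranks: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alternative": self.alternative_ids,
                "Uik": self.Uik,
                "Uih": self.Uih,
                "Pi": self.Pi,
                "PS": self.PS,
                "rank": self.ranks,
            }
        )

    def top(self) -> str:
        return self.alternative_ids[int(np.argmin(self.ranks))]


def normalize_ratio(
    matrix: DecisionMatrix, ideal_row: np.ndarray | None = None
) -> np.ndarray:
    """Ratio normalization: benefit x/max, cost min/x.

    ``ideal_row`` (one value per criterion, in raw units) overrides the
    column extremes when given.
    """
    x = matrix.values
    r = np.empty_like(x)
    for j, crit in enumerate(matrix.criteria):
        ideal = ideal_row[j] if ideal_row is not None else None
        col = x[:, j]
        if crit.direction == BENEFIT:
            denom = float(ideal) if ideal is not None else float(col.max())
            if denom == 0:
                raise ValueError(f"criterion {crit.name!r}: zero benefit ideal/maximum")
            r[:, j] = col / denom
        else:
            numer = float(ideal) if ideal is not None else float(col.min())
            if (col == 0).any():
                raise ValueError(f"criterion {crit.name!r}: zero cost entry")
            r[:, j] = numer / col
    return r


def apply_weights(r: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted normalized matrix u_ij = w_j * r_ij."""
    r = np.asarray(r, dtype=float)
    w = np.asarray(w, dtype=float)
    if r.shape[1] != w.shape[0]:
        raise ValueError("weight count must equal criterion count")
    return r * w[None, :]


def ideal_decomposition(
    u: np.ndarray,
    directions: list[str],
    q: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float, float]:
    """Ideal vector and its benefit/cost magnitudes and triangle perimeter.

    ``q`` defaults to the columnwise maxima of ``u``; pass the weight vector
    when an explicit ideal row was used in normalization (the ideal then
    normalizes to 1 in every column, so its weighted value is the weight).
    Returns ``(q, Qk, Qh, P)`` with Qk/Qh the Euclidean norms of q's benefit
    and cost entries and P = Qk + Qh + sqrt(Qk^2 + Qh^2).
    """
    u = np.asarray(u, dtype=float)
    if q is None:
        q = u.max(axis=0)
    q = np.asarray(q, dtype=float)
    benefit = np.asarray([d == BENEFIT for d in directions])
    Qk = float(np.linalg.norm(q[benefit]))
    Qh = float(np.linalg.norm(q[~benefit]))
    P = Qk + Qh + float(np.hypot(Qk, Qh))
    return q, Qk, Qh, P


def perimeter_similarity(
    u: np.ndarray,
    directions: list[str],
    q: np.ndarray,
    Qk: float,
    Qh: float,
    P: float,
    alternative_ids: list[str],
    criterion_names: list[str],
    weights: np.ndarray,
    r: np.ndarray,
) -> RapsResult:
    """Score alternatives by the perimeter of their benefit/cost triangle.

    PS_i = Pi / P where Pi is built from the row's benefit and cost
    magnitudes exactly as P is from the ideal's.  Dense ranks by descending
    PS; ties keep input order.
    """
    if P == 0:
        raise ValueError("degenerate decision matrix: ideal perimeter is zero")
    benefit = np.asarray([d == BENEFIT for d in directions])
    Uik = np.linalg.norm(u[:, benefit], axis=1)
    Uih = np.linalg.norm(u[:, ~benefit], axis=1)
    Pi = Uik + Uih + np.hypot(Uik, Uih)
    PS = Pi / P
    # Ties broken by input order (stable sort), so ranks are a permutation.
    order = np.argsort(-PS, kind="stable")
    ranks = np.empty(len(PS), dtype=int)
    ranks[order] = np.arange(1, len(PS) + 1)
    return RapsResult(
        alternative_ids=list(alternative_ids),
        criterion_names=list(criterion_names),
        directions=list(directions),
        weights=np.asarray(weights, dtype=float),
        r=r,
        u=u,
        q=q,
        Qk=Qk,
        Qh=Qh,
        P=P,
        Uik=Uik,
        Uih=Uih,
        Pi=Pi,
        PS=PS,
        ranks=ranks,
    )


def critic_weights(matrix: DecisionMatrix) -> CriticWeights:
    """Objective criterion weights from dispersion and intercriteria correlation.

    Columns are min-max normalized with one orientation for all criteria;
    sigma_j is the population standard deviation of the normalized column;
    c_j = sigma_j * sum_k (1 - rho_jk) with rho the Pearson correlation
    between normalized columns; w = c / sum(c).
    """
    x = matrix.values
    if x.shape[0] < 2:
        raise ValueError("CRITIC needs at least 2 alternatives")
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = hi - lo
    if (span == 0).any():
        bad = [matrix.criteria[j].name for j in np.flatnonzero(span == 0)]
        raise ValueError(f"zero-range criterion column(s): {bad}")
    norm = (x - lo) / span
    sigma = norm.std(axis=0)  # population sd
    rho = np.corrcoef(norm, rowvar=False)
    c = sigma * (1.0 - rho).sum(axis=1)
    total = c.sum()
    if total <= 1e-15:
        # All criteria perfectly correlated: no information contrast; fall
        # back to equal weights by symmetry.
        m = x.shape[1]
        return CriticWeights(sigma=sigma, c=c, w=np.full(m, 1.0 / m))
    return CriticWeights(sigma=sigma, c=c, w=c / total)


def rank_models(
    matrix: DecisionMatrix,
    weights: np.ndarray | None = None,
    ideal_row: np.ndarray | None = None,
) -> RapsResult:
    """Full RAPS ranking: normalize, weight, decompose the ideal, score.

    Weights default to the matrix's own (if every criterion carries one)
    and otherwise to CRITIC weights computed from the matrix.  With an
    explicit ``ideal_row`` the ideal vector q is the weight vector itself.
    """
    if weights is None:
        weights = matrix.weights
    if weights is None:
        weights = critic_weights(matrix).w
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != len(matrix.criteria):
        raise ValueError("weight count must equal criterion count")
    r = normalize_ratio(matrix, ideal_row)
    u = apply_weights(r, weights)
    q_override = weights if ideal_row is not None else None
    q, Qk, Qh, P = ideal_decomposition(u, matrix.directions, q=q_override)
    return perimeter_similarity(
        u,
        matrix.directions,
        q,
        Qk,
        Qh,
        P,
        matrix.alternative_ids,
        matrix.criterion_names,
        weights,
        r,
    )
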