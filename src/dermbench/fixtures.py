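"""Packaged reference data from the published 51-model dermoscopy benchmark.

These small delimited-text tables are verbatim transcriptions of the
study's printed results: the 51 x 9 decision matrix of model metrics, the
CRITIC information indices and weights, the explicit ideal (best-value)
row, the published final ranking, and the selected-feature counts of the
two optimizer variants.  They serve as desk-scale inputs for reproducing
the ranking stage and as regression oracles in the test suite.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .metrics import METRIC_NAMES
from .mcdm import CriterionSpec, DecisionMatrix

__all__ = [
    "load_criteria",
    "load_decision_matrix",
    "load_feature_counts",
    "load_ideal_row",
    "load_reference_critic",
    "load_reference_ranking",
]


def _path(name: str):
    return resources.files("dermbench.data").joinpath(name)


def load_criteria(path=None) -> list[CriterionSpec]:
    """Benefit/cost orientation of the nine metrics (NPV as cost, as published)."""
    source = path if path is not None else _path("criteria.yaml")
    with open(source) if isinstance(source, str) else source.open() as fh:
        raw = yaml.safe_load(fh)
    return [
        CriterionSpec(name=c["name"], direction=c["direction"], weight=c.get("weight"))
        for c in raw["criteria"]
    ]


def load_decision_matrix() -> DecisionMatrix:
    """The 51-model x 9-metric benchmark decision matrix."""
    df = pd.read_csv(_path("model_metrics.csv"))
    return DecisionMatrix(
        values=df[list(METRIC_NAMES)].to_numpy(dtype=float),
        alternative_ids=df["id"].tolist(),
        criteria=load_criteria(),
    )


def load_reference_critic() -> tuple[np.ndarray, np.ndarray]:
    """Published CRITIC information indices c and normalized weights w."""
    df = pd.read_csv(_path("critic_reference.csv")).set_index("quantity")
    c = df.loc["c", list(METRIC_NAMES)].to_numpy(dtype=float)
    w = df.loc["weight", list(METRIC_NAMES)].to_numpy(dtype=float)
    return c, w


def load_ideal_row() -> np.ndarray:
    """Published best-value (ideal) row per metric, in raw metric units."""
    df = pd.read_csv(_path("ideal_row.csv"))
    return df[list(METRIC_NAMES)].iloc[0].to_numpy(dtype=float)


def load_reference_ranking() -> pd.DataFrame:
    """Published final ranking (id, PS, rank) of the 51 models."""
    return pd.read_csv(_path("reference_ranking.csv"))


def load_feature_counts() -> pd.DataFrame:
    """Published original and selected feature counts per extractor/variant."""
    return pd.read_csv(_path("feature_counts.csv"))
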