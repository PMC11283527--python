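"""Benchmark orchestration: the full extractor x feature-map x classifier grid.

The study grid crosses four extractor profiles with three feature maps
(original features, GWO1-selected, GWO2-selected) and a per-extractor
classifier set (CSVM/WNN/QSVM/MNN for the alexnet-, inception- and
resnet-like profiles; CSVM/WNN/QSVM/LSVM/ESD for the mobilenet-like one),
giving 3 x (4+4+5+4) = 51 models.  Selection runs once per (profile,
variant) and is shared by that profile's classifiers.  Each model's test
confusion matrix yields the nine metrics; the assembled decision matrix is
CRITIC-weighted and RAPS-ranked.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .classifiers import ClassifierSpec, train_and_evaluate
from .gwo import GWOConfig, SelectionResult, select_features
from .mcdm import CriterionSpec, DecisionMatrix, RapsResult, critic_weights, rank_models
from .metrics import METRIC_NAMES, metrics_from_confusion
from .synthetic import (
    ConfigurationError,
    EmbeddingProfile,
    SplitSpec,
    default_profiles,
    generate_embeddings,
    stratified_split,
)

__all__ = [
    "BenchmarkReport",
    "GridSpec",
    "ModelSlot",
    "enumerate_grid",
    "rank_from_table",
    "reduction_summary",
    "run_benchmark",
]

FEATURE_MAPS = ("gwo1", "gwo2", "original")

#: Classifier families per extractor profile, as in the study.
DEFAULT_CLASSIFIERS: dict[str, tuple[str, ...]] = {
    "alexnet-like": ("CSVM", "WNN", "QSVM", "MNN"),
    "inception-like": ("CSVM", "WNN", "QSVM", "MNN"),
    "mobilenet-like": ("CSVM", "WNN", "QSVM", "LSVM", "ESD"),
    "resnet-like": ("CSVM", "WNN", "QSVM", "MNN"),
}


@dataclass
class ModelSlot:
    """One enumerated model of the grid."""

    id: str
    profile: str
    feature_map: str
    family: str

    @property
    def label(self) -> str:
        return f"{self.feature_map}-{self.profile}-{self.family}"


@dataclass
class GridSpec:
    """The benchmark grid and its seeds."""

    profiles: list[EmbeddingProfile] = field(default_factory=default_profiles)
    feature_maps: tuple[str, ...] = FEATURE_MAPS
    classifier_families: dict[str, tuple[str, ...]] | None = None
    split: SplitSpec = field(default_factory=SplitSpec)
    gwo_overrides: dict = field(default_factory=dict)
    seed: int = 0

    def families_for(self, profile_name: str) -> tuple[str, ...]:
        table = self.classifier_families or DEFAULT_CLASSIFIERS
        if profile_name not in table:
            raise ConfigurationError(f"no classifier list for profile {profile_name!r}")
        families = tuple(table[profile_name])
        if not families:
            raise ConfigurationError(f"empty classifier list for {profile_name!r}")
        return families

    def validate(self) -> None:
        if not self.profiles:
            raise ConfigurationError("grid needs at least one profile")
        for fm in self.feature_maps:
            if fm not in FEATURE_MAPS:
                raise ConfigurationError(f"unknown feature map {fm!r}")
        for p in self.profiles:
            self.families_for(p.name)


@dataclass
class BenchmarkReport:
    """Everything a benchmark run produces."""

    decision_matrix: DecisionMatrix
    selection_summary: pd.DataFrame
    raps: RapsResult
    provenance: dict

    def decision_frame(self) -> pd.DataFrame:
        df = self.decision_matrix.to_dataframe().reset_index(names="id")
        return df

    def ranking_frame(self) -> pd.DataFrame:
        return self.raps.to_dataframe()


def enumerate_grid(spec: GridSpec) -> list[ModelSlot]:
    """Deterministic model order: profile outer, feature map middle,
    classifier inner — the layout of the published 51-model table."""
    spec.validate()
    slots: list[ModelSlot] = []
    i = 0
    for profile in spec.profiles:
        for fm in spec.feature_maps:
            for family in spec.families_for(profile.name):
                i += 1
                slots.append(
                    ModelSlot(id=f"A{i}", profile=profile.name, feature_map=fm, family=family)
                )
    return slots


def reduction_summary(
    original_counts: dict[str, int], selected_counts: dict[tuple[str, str], int]
) -> pd.DataFrame:
    """Integer-rounded reduction percentages 100*(1 - selected/original)."""
    rows = []
    for (profile, variant), selected in selected_counts.items():
        original = original_counts[profile]
        if selected > original:
            raise ValueError(
                f"{profile}/{variant}: selected count {selected} exceeds original {original}"
            )
        if original <= 0 or selected < 0:
            raise ValueError("counts must be positive")
        rows.append(
            {
                "profile": profile,
                "variant": variant,
                "original": original,
                "selected": selected,
                "reduction_pct": round(100.0 * (1.0 - selected / original)),
            }
        )
    return pd.DataFrame(rows)


def _gwo_config(variant: str, spec: GridSpec, profile_index: int) -> GWOConfig:
    # Per-(profile, variant) seed derived from the global seed.
    offset = {"gwo1": 1, "gwo2": 2}[variant]
    seed = (spec.seed * 1009 + profile_index * 31 + offset) % (2**31)
    return GWOConfig.for_variant(variant, seed=seed, **spec.gwo_overrides)


def run_benchmark(spec: GridSpec | None = None) -> BenchmarkReport:
    """Run the full grid on synthetic embeddings and rank the models.

    For each profile the synthetic table is generated and split 70/15/15;
    each requested optimizer variant selects features once on the
    train/validation pair; every (feature map, classifier) pair is then
    trained on the train split and evaluated on the test split.  The
    resulting decision matrix is CRITIC-weighted and RAPS-ranked.  Fully
    reproducible from (spec, seed).
    """
    spec = spec or GridSpec()
    spec.validate()
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    slots = enumerate_grid(spec)

    masks: dict[tuple[str, str], np.ndarray] = {}
    selections: dict[tuple[str, str], SelectionResult] = {}
    splits: dict[str, tuple] = {}
    original_counts: dict[str, int] = {}

    for p_idx, profile in enumerate(spec.profiles):
        table = generate_embeddings(
            replace(profile, seed=(profile.seed + spec.seed) % (2**31))
        )
        split = replace(spec.split, seed=(spec.split.seed + spec.seed + p_idx) % (2**31))
        train, validation, test = stratified_split(table, split)
        splits[profile.name] = (train, validation, test)
        original_counts[profile.name] = table.n_features
        for variant in ("gwo1", "gwo2"):
            if variant in spec.feature_maps:
                result = select_features(
                    train, validation, _gwo_config(variant, spec, p_idx)
                )
                selections[(profile.name, variant)] = result
                masks[(profile.name, variant)] = result.mask

    rows = []
    for slot_index, slot in enumerate(slots):
        train, validation, test = splits[slot.profile]
        if slot.feature_map == "original":
            tr, te = train, test
        else:
            mask = masks[(slot.profile, slot.feature_map)]
            tr, te = train.subset_columns(mask), test.subset_columns(mask)
        model_seed = (spec.seed * 7919 + slot_index) % (2**31)
        cls_spec = ClassifierSpec(family=slot.family, seed=model_seed)
        _, cm = train_and_evaluate(cls_spec, tr, te)
        rows.append(metrics_from_confusion(cm).as_dict())

    values = pd.DataFrame(rows)[list(METRIC_NAMES)].to_numpy()
    from .fixtures import load_criteria  # local import: avoids cycle at module load

    criteria = load_criteria()
    # Ratio normalization divides by cost values; a model with a zero error
    # or false rate (possible on strongly separated synthetic data) gets a
    # tiny floor instead, keeping it best-ranked on that criterion.
    cost_cols = [j for j, c in enumerate(criteria) if c.direction == "cost"]
    values[:, cost_cols] = np.maximum(values[:, cost_cols], 1e-6)
    matrix = DecisionMatrix(
        values=values,
        alternative_ids=[s.id for s in slots],
        criteria=criteria,
    )
    weights = critic_weights(matrix).w
    raps = rank_models(matrix, weights=weights)

    summary = reduction_summary(
        original_counts,
        {key: result.n_selected for key, result in selections.items()},
    )
    provenance = {
        "package_version": __version__,
        "seed": spec.seed,
        "n_models": len(slots),
        "feature_maps": list(spec.feature_maps),
        "profiles": [
            {"name": p.name, "dimension": p.dimension, "n_informative": p.n_informative}
            for p in spec.profiles
        ],
        "started": started,
        "slot_labels": {s.id: s.label for s in slots},
    }
    return BenchmarkReport(
        decision_matrix=matrix,
        selection_summary=summary,
        raps=raps,
        provenance=provenance,
    )


def read_decision_matrix(path, criteria: list[CriterionSpec]) -> DecisionMatrix:
    """Read a decision matrix CSV: first column alternative id, header names
    matching the criteria list."""
    df = pd.read_csv(path)
    id_col = df.columns[0]
    names = [c.name for c in criteria]
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise ValueError(f"{path!s}: missing criterion column(s) {missing}")
    return DecisionMatrix(
        values=df[names].to_numpy(dtype=float),
        alternative_ids=df[id_col].astype(str).tolist(),
        criteria=criteria,
    )


def rank_from_table(
    matrix_path,
    criteria: list[CriterionSpec],
    weights: np.ndarray | None = None,
    ideal_row: np.ndarray | None = None,
    out_path=None,
) -> RapsResult:
    """Rank a decision-matrix file and optionally write (id, PS, rank)."""
    matrix = read_decision_matrix(matrix_path, criteria)
    result = rank_models(matrix, weights=weights, ideal_row=ideal_row)
    if out_path is not None:
        result.to_dataframe()[["alternative", "PS", "rank"]].to_csv(
            out_path, index=False
        )
    return result


def write_report(report: BenchmarkReport, out_dir) -> None:
    """Persist a benchmark report as delimited text plus a JSON manifest."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.decision_frame().to_csv(out / "decision_matrix.csv", index=False)
    report.selection_summary.to_csv(out / "selection_summary.csv", index=False)
    report.ranking_frame().to_csv(out / "ranking.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2)
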