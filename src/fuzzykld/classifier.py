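"""Per-class fuzzy parametric models and smallest-divergence classification.

Training pools each class's feature values into one sample, selects the
best-fitting family by smallest extended KL divergence, builds the grid
posterior of its parameters, and fuzzifies each parameter through its
mode-adjusted marginal posterior.  The class's (min, max) envelope of
sorted feature vectors is kept alongside as a diagnostic profile.

A query image is classified by treating its feature vector as a sample
of values: its empirical partition is built, the fuzzy extended KL
divergence between every class model and that partition is computed,
each fuzzy divergence is defuzzified (mean of δ-cut midpoints by
default), and the smallest score wins.  Ties break by the δ=1 cut
midpoint, then by label order.

By default the decision statistic weights terms by the *empirical*
interval probabilities, Σ p_emp log(p_emp / p_f), which ranks class
models by the multinomial likelihood they assign to the query and is
therefore a proper nearest-distribution rule even when the fitted
family is misspecified.  The model-weighted direction (the form used
for family selection) is available via ``ClassifierConfig.direction``
but is degenerate as a decision statistic: it rewards models that park
probability mass away from the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes_fitting import DEFAULT_CANDIDATES, fit_fuzzy_distribution
from .divergence import (
    FuzzyDivergence,
    FuzzyParametricDistribution,
    build_partition,
    fuzzy_extended_kld,
)
from .features import FeatureVector, FuzzyProfile, fuzzy_interval_profile

__all__ = ["ClassifierConfig", "ClassModel", "train", "classify", "evaluate"]


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable knobs of the training and decision procedure."""

    candidates: tuple = DEFAULT_CANDIDATES
    delta_levels: int = 20          # δ-grid 1/L, 2/L, ..., 1
    posterior_grid_res: int = 201   # points per parameter in the posterior
    divergence_grid_res: int = 11   # points per parameter in the KLD search
    refine: bool = False            # Nelder-Mead polish of cut endpoints
    defuzzify: str = "midpoint"     # or "pessimistic"
    normalize_partition_mass: bool = False
    direction: str = "empirical"    # weighting slot of the decision statistic

    def delta_grid(self) -> np.ndarray:
        L = self.delta_levels
        return np.round(np.arange(1, L + 1) / L, 10)


@dataclass
class ClassModel:
    """A trained class: its fuzzy distribution, profile and sample count."""

    label: str
    dist: FuzzyParametricDistribution
    profile: FuzzyProfile
    n_train: int

    def to_dict(self) -> dict:
        return {"label": self.label, "dist": self.dist.to_dict(),
                "profile": self.profile.to_dict(), "n_train": self.n_train}

    @classmethod
    def from_dict(cls, d: dict) -> "ClassModel":
        return cls(d["label"], FuzzyParametricDistribution.from_dict(d["dist"]),
                   FuzzyProfile.from_dict(d["profile"]), d["n_train"])


def _values(v) -> np.ndarray:
    return v.values if isinstance(v, FeatureVector) else np.asarray(v, float)


def train(class_features: dict, config: ClassifierConfig | None = None) -> list:
    """Fit one ClassModel per label from lists of feature vectors.

    ``class_features`` maps label -> list of FeatureVector (or arrays).
    All of a class's feature values are pooled into a single 1-D sample
    for distribution fitting.
    """
    config = config or ClassifierConfig()
    if len(class_features) < 2:
        raise ValueError("training needs at least two classes")
    models = []
    for label in sorted(class_features):
        vectors = class_features[label]
        if len(vectors) < 3:
            raise ValueError(f"class {label!r} has fewer than 3 samples")
        pooled = np.concatenate([_values(v) for v in vectors])
        if np.var(pooled) == 0:
            raise ValueError(f"class {label!r} has constant feature values")
        dist = fit_fuzzy_distribution(
            pooled, candidates=config.candidates,
            delta_grid=config.delta_grid(),
            grid_res=config.posterior_grid_res)
        profile = fuzzy_interval_profile(vectors)
        models.append(ClassModel(str(label), dist, profile, len(vectors)))
    return models


def classify(query, models: list, config: ClassifierConfig | None = None):
    """Label a query feature vector by smallest defuzzified fuzzy divergence.

    Returns (label, per-class FuzzyDivergence dict, defuzzified scores).
    """
    config = config or ClassifierConfig()
    if len(models) == 0:
        raise ValueError("need at least one class model")
    values = _values(query)
    if len(values) < 2:
        raise ValueError("query must contain at least 2 feature values")
    part = build_partition(values)
    divergences: dict[str, FuzzyDivergence] = {}
    scores: dict[str, float] = {}
    for m in models:
        fd = fuzzy_extended_kld(
            m.dist, part, grid_res=config.divergence_grid_res,
            refine=config.refine,
            normalize_partition_mass=config.normalize_partition_mass,
            direction=config.direction)
        divergences[m.label] = fd
        scores[m.label] = fd.defuzzify(config.defuzzify)

    def _key(label: str):
        fd = divergences[label]
        top_mid = 0.5 * (fd.lowers[-1] + fd.uppers[-1])  # δ=1 midpoint
        return (scores[label], top_mid, label)

    winner = min(divergences, key=_key)
    return winner, divergences, scores


def evaluate(test_set, models: list, config: ClassifierConfig | None = None):
    """Accuracy and confusion table over labeled (features, label) pairs."""
    labels = [m.label for m in models]
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    correct = 0
    total = 0
    for features, true_label in test_set:
        if str(true_label) not in labels:
            raise ValueError(f"unseen label {true_label!r} in test set")
        pred, _, _ = classify(features, models, config)
        confusion.loc[str(true_label), pred] += 1
        correct += int(pred == str(true_label))
        total += 1
    accuracy = correct / total if total else float("nan")
    return accuracy, confusion


def save_models(models: list, path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in models], fh)


def load_models(path) -> list:
    with open(path) as fh:
        return [ClassModel.from_dict(d) for d in json.load(fh)]
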