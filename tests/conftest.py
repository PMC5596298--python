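import numpy as np
import pandas as pd
import pytest

from clinautoml.evaluation import TabularDataset
from clinautoml.search_space import (
    AlgorithmSpec, Condition, Configuration, FeatureSelectionSpec,
    HyperParameterSpec, Registry, default_registry,
)
from clinautoml.synthetic import make_tabular


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def tiny_enumerable_registry() -> Registry:
    """Two algorithms with finite hyper-parameter spaces (6 configurations in
    total with the single 'none' technique) — exhaustively searchable."""
    reg = Registry()
    reg.add_algorithm(AlgorithmSpec("decision_tree", "both", (
        HyperParameterSpec("max_depth", "categorical", (1, 3, 6), 3),)))
    reg.add_algorithm(AlgorithmSpec("knn", "both", (
        HyperParameterSpec("n_neighbors", "categorical", (1, 9, 25), 9),)))
    reg.add_feature_selection(FeatureSelectionSpec("none", "none", "none"))
    return reg


def fast_registry() -> Registry:
    """Small continuous spaces over quick learners, for multi-stage tests."""
    reg = Registry()
    reg.add_algorithm(AlgorithmSpec("logistic", "classification", (
        HyperParameterSpec("C", "continuous", (1e-3, 1e3), 1.0, scale="log"),)))
    reg.add_algorithm(AlgorithmSpec("decision_tree", "both", (
        HyperParameterSpec("max_depth", "integer", (1, 20), 6),)))
    reg.add_algorithm(AlgorithmSpec("knn", "both", (
        HyperParameterSpec("n_neighbors", "integer", (1, 50), 5),)))
    reg.add_feature_selection(FeatureSelectionSpec("none", "none", "none"))
    reg.add_feature_selection(FeatureSelectionSpec(
        "univariate_rank", "anova_f", "rank_top",
        (HyperParameterSpec("keep_fraction", "continuous", (0.1, 1.0), 0.5),)))
    return reg


@pytest.fixture(scope="session")
def linear_dataset():
    """Separable-ish planted-linear classification problem."""
    df, info = make_tabular(n=600, p=12, n_informative=4, target_auc=0.92, seed=11)
    return TabularDataset.from_dataframe(df, "y", "classification"), info


@pytest.fixture(scope="session")
def conditional_algorithm():
    """Algorithm with a conditional hyper-parameter deactivated by the
    parent's default value."""
    return AlgorithmSpec("cond", "classification", (
        HyperParameterSpec("kernel", "categorical", ("rbf", "poly"), "rbf"),
        HyperParameterSpec("degree", "integer", (2, 5), 3,
                           condition=Condition("kernel", ("poly",))),
        HyperParameterSpec("C", "continuous", (1e-3, 1e3), 1.0, scale="log"),
    ))
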