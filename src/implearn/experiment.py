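"""End-to-end selection experiments on planted synthetic tables.

One experiment: generate a feature table with a planted informative
subset, run bee-colony selection with cross-validated accuracy as
fitness, then evaluate the selected subset and the all-features
baseline with repeated cross-validation and compare them with a paired
t-test.  This is the with/without-selection contrast the package
exists to measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import compare_abc, evaluate_full, make_cv_fitness
from .features import mask_features
from .select import ABCConfig, run_abc
from .simulate import gen_feature_table, informative_bits


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard similarity between two 0/1 selection vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0


@dataclass
class SelectionExperiment:
    """Result of one with/without-selection contrast."""

    seed: int
    classifier: str
    best_bits: np.ndarray
    best_fitness: float
    jaccard_informative: float
    with_accuracies: np.ndarray
    without_accuracies: np.ndarray
    t: float
    df: int
    p: float

    @property
    def with_median(self) -> float:
        return float(np.median(self.with_accuracies))

    @property
    def without_median(self) -> float:
        return float(np.median(self.without_accuracies))


def planted_subset_experiment(
    seed: int,
    classifier: str = "knn-coarse",
    n_per_class: int = 175,
    n_sources: int = 8,
    limit: int = 5,
    max_iter: int = 15,
    k: int = 5,
    repeats: int = 5,
) -> SelectionExperiment:
    """Run one full selection-vs-baseline experiment from a seed."""
    table = gen_feature_table(n_per_class=n_per_class, seed=seed)
    fitness = make_cv_fitness(classifier, k=k, seed=seed)
    cfg = ABCConfig(n_sources=n_sources, limit=limit, max_iter=max_iter,
                    seed=seed)
    trace = run_abc(table, cfg, fitness)
    eval_seed = (seed + 1_000_003) % (2**31 - 1)
    with_res = evaluate_full(mask_features(table, trace.best_bits), classifier,
                             k=k, repeats=repeats, seed=eval_seed)
    without_res = evaluate_full(table, classifier, k=k, repeats=repeats,
                                seed=eval_seed)
    tt = compare_abc(with_res.accuracies, without_res.accuracies, mode="paired")
    return SelectionExperiment(
        seed=seed, classifier=classifier, best_bits=trace.best_bits,
        best_fitness=trace.best_fitness,
        jaccard_informative=jaccard(trace.best_bits,
                                    informative_bits(_default_informative())),
        with_accuracies=with_res.accuracies,
        without_accuracies=without_res.accuracies,
        t=tt.t, df=tt.df, p=tt.p)


def _default_informative():
    from .simulate import SynthConfig

    return SynthConfig().informative_set
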