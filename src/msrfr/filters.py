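"""Biological-relevance filters for regulatory modules.

Two computational filters are applied to fitted modules: (1) patients
are split into two groups by 2-means clustering on the expression of a
module's selected mRNAs and the groups' survival curves are compared
with the log-rank test — a tissue-scope module must be significant in
every cohort of the tissue, a cohort-scope module in its own cohort;
(2) the transcription-factor content of selected mRNA sets is compared
against a permutation null of equally sized uniform random gene draws.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats
from sklearn.cluster import KMeans

from .modules import TISSUE_SCOPE, RegulatoryModule
from .preprocessing import ClinicalTable, MultitaskDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalFilterResult",
    "PermutationTestResult",
    "cluster_patients",
    "logrank_test",
    "survival_filter",
    "tf_permutation_test",
]


def cluster_patients(expr: np.ndarray, seed: int = 0, n_restarts: int = 20) -> np.ndarray:
    """Best-of-``n_restarts`` 2-means partition of patients.

    ``expr`` is patients x selected-mRNAs.  Label 0 is assigned to the
    cluster with the lower mean expression over the selected mRNAs, so
    labels are reproducible across runs and machines.
    """
    expr = np.atleast_2d(np.asarray(expr, dtype=float))
    if expr.shape[0] < 4:
        raise ValueError("need at least 4 patients to cluster")
    if np.allclose(expr, expr[0]):
        raise ValueError("all patients identical; no two-group partition exists")
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(expr)
    means = [expr[labels == c].mean() for c in (0, 1)]
    if means[0] > means[1]:
        labels = 1 - labels
    return labels


def logrank_test(labels: np.ndarray, time: np.ndarray, event: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    The statistic is the standard observed-minus-expected sum over event
    times with the hypergeometric variance, one degree of freedom.
    """
    labels = np.asarray(labels)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (len(labels) == len(time) == len(event)):
        raise ValueError("labels, time and event must have equal length")
    a, b = labels == 0, labels == 1
    if not a.any() or not b.any():
        raise ValueError("both groups must be non-empty")
    res = _lifelines_logrank(time[a], time[b], event_observed_A=event[a], event_observed_B=event[b])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SurvivalFilterResult:
    """Log-rank outcome of one (module, cohort) pair.

    ``significant`` is the cohort-level verdict (p < alpha);
    ``module_significant`` applies the module-level rule — for a
    tissue-scope module, significance in *every* cohort of the tissue.
    """

    scope: str
    rank_index: int
    cohort: str
    cluster_labels: np.ndarray = field(repr=False)
    logrank_statistic: float = float("nan")
    p_value: float = float("nan")
    significant: bool = False
    module_significant: bool = False


def survival_filter(
    modules: list[RegulatoryModule],
    dataset: MultitaskDataset,
    clinical: dict[str, ClinicalTable],
    alpha: float = 0.05,
    seed: int = 0,
    n_restarts: int = 20,
) -> list[SurvivalFilterResult]:
    """Survival-stratification filter over a list of modules.

    Each module's patients are clustered on the (per-cohort
    re-standardized) expression of its selected mRNAs and the two groups
    compared by the log-rank test.  Cohort-scope modules are tested in
    their own cohort only; tissue-scope modules are tested in each
    cohort and flagged significant only when p < alpha in all of them.
    Modules with no selected mRNAs are skipped with a warning.
    """
    results: list[SurvivalFilterResult] = []
    mrna_index = {g: j for j, g in enumerate(dataset.mrna_ids)}
    for module in modules:
        if not module.selected_mrnas:
            warnings.warn(
                f"module ({module.scope}, rank {module.rank_index}) selected no mRNAs; skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        cols = [mrna_index[g] for g in module.selected_mrnas]
        cohorts = (
            dataset.cohort_names if module.scope == TISSUE_SCOPE else [module.scope]
        )
        per_cohort: list[SurvivalFilterResult] = []
        for cohort in cohorts:
            k = dataset.cohort_names.index(cohort)
            Y = dataset.Y[k]
            expr = Y.to_numpy()[:, cols]
            # re-standardize the selected columns within this cohort
            sd = expr.std(axis=0, ddof=1)
            expr = (expr - expr.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
            labels = cluster_patients(expr, seed=seed, n_restarts=n_restarts)
            clin = clinical[cohort].lookup(Y.sample_ids)
            stat, p = logrank_test(labels, clin["time_days"], clin["event"])
            per_cohort.append(
                SurvivalFilterResult(
                    scope=module.scope,
                    rank_index=module.rank_index,
                    cohort=cohort,
                    cluster_labels=labels,
                    logrank_statistic=stat,
                    p_value=p,
                    significant=bool(p < alpha),
                )
            )
        module_sig = all(r.significant for r in per_cohort)
        for r in per_cohort:
            r.module_significant = module_sig
        results.extend(per_cohort)
    return results


def survival_results_frame(results: list[SurvivalFilterResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scope": r.scope,
                "rank_index": r.rank_index,
                "cohort": r.cohort,
                "logrank_statistic": r.logrank_statistic,
                "p_value": r.p_value,
                "significant": r.significant,
                "module_significant": r.module_significant,
            }
            for r in results
        ]
    )


@dataclass
class PermutationTestResult:
    """TF enrichment of selected mRNA sets against a uniform-draw null."""

    observed_tf_count: int
    observed_tf_percent: float
    observed_percents: list[float]
    null_percents: np.ndarray = field(repr=False)
    empirical_p: float = float("nan")
    mannwhitney_p: float = float("nan")

    @property
    def null_mean_percent(self) -> float:
        return float(np.mean(self.null_percents))

    @property
    def null_max_percent(self) -> float:
        return float(np.max(self.null_percents))


def tf_permutation_test(
    selected_mrnas,
    universe,
    tf_list,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationTestResult:
    """Compare TF content of selected mRNAs with uniform random gene draws.

    ``selected_mrnas`` may be one identifier collection or a list of
    collections (one per module).  The null draws ``n_perm`` gene sets
    of the (mean) selection size uniformly without replacement from
    ``universe`` and records the TF percentage of each.  The empirical
    p-value uses the add-one estimator (never exactly zero); with
    multiple modules a one-sided Mann-Whitney test asks whether the
    observed per-module percentages are shifted above the null.
    """
    universe = list(dict.fromkeys(universe))
    tf_set = set(tf_list) & set(universe)
    if isinstance(selected_mrnas, (set, frozenset)) or (
        selected_mrnas and isinstance(next(iter(selected_mrnas)), str)
    ):
        groups = [list(selected_mrnas)]
    else:
        groups = [list(g) for g in selected_mrnas]
    if not groups or any(len(g) == 0 for g in groups):
        raise ValueError("every selected mRNA set must be non-empty")
    sizes = [len(g) for g in groups]
    draw_size = int(round(float(np.mean(sizes))))
    if draw_size > len(universe):
        raise ValueError("selection larger than the gene universe")

    observed_counts = [len(set(g) & tf_set) for g in groups]
    observed_percents = [100.0 * c / len(g) for c, g in zip(observed_counts, groups)]
    observed_percent = float(np.mean(observed_percents))

    rng = np.random.default_rng(seed)
    is_tf = np.array([g in tf_set for g in universe])
    null_counts = np.empty(n_perm, dtype=int)
    n_universe = len(universe)
    for i in range(n_perm):
        draw = rng.choice(n_universe, size=draw_size, replace=False)
        null_counts[i] = int(is_tf[draw].sum())
    null_percents = 100.0 * null_counts / draw_size

    empirical_p = (1.0 + float(np.sum(null_percents >= observed_percent))) / (n_perm + 1.0)
    if len(groups) > 1:
        mw = stats.mannwhitneyu(observed_percents, null_percents, alternative="greater")
        mannwhitney_p = float(mw.pvalue)
    else:
        mannwhitney_p = float("nan")

    return PermutationTestResult(
        observed_tf_count=int(sum(observed_counts)),
        observed_tf_percent=observed_percent,
        observed_percents=observed_percents,
        null_percents=null_percents,
        empirical_p=float(empirical_p),
        mannwhitney_p=mannwhitney_p,
    )
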