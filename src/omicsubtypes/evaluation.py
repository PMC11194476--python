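"""Evaluation statistics for subtype labelings.

Covers the differential-survival log-rank test (reported as -log10 p),
clinical-parameter enrichment counting (chi-square for discrete
parameters, Kruskal-Wallis for continuous ones, Benjamini-Hochberg
adjustment across parameters, enriched when adjusted p < 0.05), the
adjusted Rand index, and the subsampling stability protocol (repeated
80% subsamples re-clustered and compared to the base labeling).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2_contingency, kruskal
from statsmodels.stats.multitest import multipletests

from .datamodel import ClinicalTable, OmicsMatrix

__all__ = [
    "ParameterTest",
    "EvaluationReport",
    "logrank_neglog10_p",
    "count_enriched_clinical",
    "adjusted_rand_index",
    "stability_analysis",
]

_P_FLOOR = 1e-300  # avoid -log10(0) for astronomically small p-values


@dataclasses.dataclass
class ParameterTest:
    """Result of one clinical parameter's association test."""

    test: str  # "chi2" | "kruskal-wallis" | "skipped"
    p: float
    p_adjusted: float
    enriched: bool


@dataclasses.dataclass
class EvaluationReport:
    """Summary statistics for one subtype labeling."""

    neglog10_p: float | None
    n_enriched: int
    per_parameter: dict[str, ParameterTest]
    stability_aris: list[float] | None = None


def logrank_neglog10_p(times, events, labels) -> float:
    """Multi-group log-rank test; returns -log10 of its p-value."""
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events).astype(int)
    labels = np.asarray(labels)
    if times.shape != events.shape or times.shape != labels.shape:
        raise ValueError("times, events and labels must have equal length")
    if np.any(times < 0):
        raise ValueError("survival times must be nonnegative")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")
    result = multivariate_logrank_test(times, labels, events)
    p = max(float(result.p_value), _P_FLOOR)
    return float(-np.log10(p))


def count_enriched_clinical(
    clinical: ClinicalTable,
    labels,
    alpha: float = 0.05,
) -> tuple[int, dict[str, ParameterTest]]:
    """Count clinical parameters significantly associated with the clusters.

    Discrete parameters are tested with the chi-square independence test
    on the parameter x cluster contingency table (no Yates correction);
    continuous parameters with the Kruskal-Wallis test across clusters.
    P-values are Benjamini-Hochberg adjusted across the parameters;
    a parameter is enriched when its adjusted p < `alpha`. Parameters
    with a single observed level are skipped with a warning.
    """
    labels = np.asarray(labels)
    if len(labels) != len(clinical.sample_ids):
        raise ValueError("labels must align with the clinical sample_ids")
    results: dict[str, ParameterTest] = {}
    tested: list[str] = []
    raw_p: list[float] = []
    for col in clinical.parameters.columns:
        values = clinical.parameters[col]
        kind = clinical.types[col]
        if values.nunique(dropna=True) < 2 or len(np.unique(labels)) < 2:
            warnings.warn(
                f"clinical parameter {col!r} has a single observed level; skipped"
            )
            results[col] = ParameterTest("skipped", np.nan, np.nan, False)
            continue
        if kind == "discrete":
            table = pd.crosstab(values, pd.Series(labels, index=values.index))
            expected = np.outer(table.sum(1), table.sum(0)) / table.to_numpy().sum()
            if (expected < 1).any():
                warnings.warn(
                    f"contingency table for {col!r} has expected counts < 1"
                )
            stat, p, _, _ = chi2_contingency(table.to_numpy(), correction=False)
            test_name = "chi2"
        else:
            groups = [
                pd.to_numeric(values[labels == g]).to_numpy()
                for g in np.unique(labels)
            ]
            groups = [g for g in groups if len(g) > 0]
            stat, p = kruskal(*groups)
            test_name = "kruskal-wallis"
        tested.append(col)
        raw_p.append(float(p))
        results[col] = ParameterTest(test_name, float(p), np.nan, False)
    if tested:
        _, p_adj, _, _ = multipletests(raw_p, alpha=alpha, method="fdr_bh")
        for col, pa in zip(tested, p_adj):
            r = results[col]
            results[col] = ParameterTest(r.test, r.p, float(pa), bool(pa < alpha))
    n_enriched = sum(r.enriched for r in results.values())
    return n_enriched, results


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected Rand index from the pair-counting contingency table.

    1 means identical partitions (up to label names), ~0 independence,
    negative values worse-than-chance agreement.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be equal-length 1-D arrays")
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def stability_analysis(
    P,
    k: int,
    base_labels,
    rounds: int = 10,
    fraction: float = 0.8,
    config=None,
    seed: int = 0,
) -> list[float]:
    """Subsampling stability of the deep subspace clustering labels.

    Per round, a fraction of the samples is drawn without replacement,
    the clustering module is re-run on the subsample, and the subsample's
    labels are compared (ARI) with `base_labels` restricted to the same
    samples. Round seeds derive deterministically from `seed`.
    """
    from .subspace import DsccConfig, cluster_coefficients, train_dscc

    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    values = P.values if isinstance(P, OmicsMatrix) else np.asarray(P, dtype=np.float64)
    base_labels = np.asarray(base_labels)
    N = values.shape[0]
    if base_labels.shape != (N,):
        raise ValueError("base_labels must have one entry per sample")
    m = int(np.floor(fraction * N))
    if m < k:
        raise ValueError(f"subsample size {m} is smaller than k={k}")
    config = config or DsccConfig()
    round_seeds = np.random.SeedSequence(seed).generate_state(2 * rounds) % (2**31)
    aris: list[float] = []
    for r in range(rounds):
        rng = np.random.default_rng(round_seeds[2 * r])
        idx = np.sort(rng.choice(N, size=m, replace=False))
        model = train_dscc(values[idx], config=config, seed=int(round_seeds[2 * r + 1]))
        result = cluster_coefficients(
            model, k, seed=int(round_seeds[2 * r + 1]),
            kmeans_restarts=config.kmeans_restarts,
        )
        aris.append(adjusted_rand_index(result.labels, base_labels[idx]))
    return aris


def write_report(report: EvaluationReport, metrics_path, parameters_path=None) -> None:
    """Write the report as (metric, value) TSV plus a per-parameter TSV."""
    with open(metrics_path, "w") as fh:
        fh.write("metric\tvalue\n")
        if report.neglog10_p is not None:
            fh.write(f"neglog10_logrank_p\t{report.neglog10_p:.10g}\n")
        fh.write(f"n_enriched_clinical\t{report.n_enriched}\n")
        if report.stability_aris is not None:
            fh.write(f"mean_stability_ari\t{np.mean(report.stability_aris):.10g}\n")
    if parameters_path is not None:
        with open(parameters_path, "w") as fh:
            fh.write("parameter\ttest\tp\tp_adj\tenriched\n")
            for name, r in report.per_parameter.items():
                fh.write(f"{name}\t{r.test}\t{r.p:.10g}\t{r.p_adjusted:.10g}\t"
                         f"{int(r.enriched)}\n")
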