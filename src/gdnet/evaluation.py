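"""Risk-group survival evaluation and the cross-dataset Dscore.

Each cohort is split at the risk-score median into equal halves, the two
groups are compared with the two-sample log-rank test, and the hazard ratio
comes from a proportional-hazards fit on the group indicator. Discrimination
across several cohorts is summarized by

    Dscore = sum_i -log10(max(p_i, 1e-17))

over the per-cohort log-rank p-values (the floor guards numerical
precision). Fisher's combined probability statistic is the same quantity on
the natural-log scale — X = 2 ln(10) * Dscore — referred to chi-square with
2n degrees of freedom, which is how signature significance against random
same-size signatures is assessed analytically; an empirical p against a
simulated random-signature null is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from ._cox import cox_fit_matrix
from .io import ClinicalTable, ExpressionMatrix, GeneSet
from .signature import Signature, SignatureGene, score_samples

__all__ = [
    "RiskPartition",
    "LogRankResult",
    "DscoreParams",
    "split_groups",
    "logrank_test",
    "dscore",
    "fisher_combined",
    "evaluate_signature",
    "evaluate_family",
    "random_signature_null",
    "empirical_pvalue",
    "write_report",
]


@dataclass
class RiskPartition:
    """Median split of samples by risk score.

    ``group`` holds ``'low'``/``'high'`` per sample; the low-risk group gets
    ``ceil(n/2)`` members (ties and the odd middle sample resolved by stable
    input order).
    """

    sample_ids: list[str]
    risk: np.ndarray
    group: np.ndarray

    def ids(self, which: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.group) if g == which]


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    hazard_ratio: float
    hr_ci_low: float
    hr_ci_high: float


@dataclass
class DscoreParams:
    p_floor: float = 1.00e-17
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.p_floor < 1:
            raise ValueError("p_floor must be in (0, 1)")


def split_groups(risks: pd.Series) -> RiskPartition:
    """Stable ascending sort by risk; the first ceil(n/2) samples are low risk."""
    r = np.asarray(risks.values, dtype=float)
    n = r.size
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    order = np.argsort(r, kind="stable")
    n_low = int(np.ceil(n / 2))
    group = np.empty(n, dtype=object)
    group[order[:n_low]] = "low"
    group[order[n_low:]] = "high"
    return RiskPartition(list(risks.index), r, group)


def logrank_test(part: RiskPartition, clin: ClinicalTable) -> LogRankResult:
    """Two-group log-rank chi-square (1 df) plus the group hazard ratio.

    The HR and its 95% Wald CI come from a one-covariate proportional-hazards
    fit on the high-risk indicator, so HR > 1 means the high-risk group fares
    worse.
    """
    low_ids = part.ids("low")
    high_ids = part.ids("high")
    if not low_ids or not high_ids:
        raise ValueError("both risk groups must be nonempty")
    low = clin.subset(low_ids)
    high = clin.subset(high_ids)
    if low.event.sum() + high.event.sum() < 1:
        raise ValueError("no events in either group")
    res = _ll_logrank(
        low.time, high.time, event_observed_A=low.event, event_observed_B=high.event
    )
    indicator = np.concatenate([np.zeros(low.n_samples), np.ones(high.n_samples)])
    time = np.concatenate([low.time, high.time])
    event = np.concatenate([low.event, high.event])
    beta, se, _p = cox_fit_matrix(indicator[None, :], time, event)
    if np.isfinite(beta[0]):
        hr = float(np.exp(beta[0]))
        # clamp the Wald bounds' exponent so a near-degenerate fit yields inf, not overflow
        lo = float(np.exp(min(beta[0] - 1.959963984540054 * se[0], 709.0)))
        hi = float(np.exp(min(beta[0] + 1.959963984540054 * se[0], 709.0)))
    else:  # complete separation of events between groups
        hr = lo = hi = float("nan")
    return LogRankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        hazard_ratio=hr,
        hr_ci_low=lo,
        hr_ci_high=hi,
    )


def dscore(p_values, params: DscoreParams = DscoreParams()) -> float:
    """Sum of -log10 of the (floored) per-dataset p-values; larger is better."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size and ((p <= 0).any() or (p > 1).any()):
        raise ValueError("p-values must be in (0, 1]")
    if p.size == 0:
        return 0.0
    return float(np.sum(-np.log10(np.maximum(p, params.p_floor))))


def fisher_combined(p_values, params: DscoreParams = DscoreParams()) -> float:
    """Fisher's combined probability over the (floored) p-values.

    X = -2 sum ln p ~ chi-square with 2n df under the global null; note the
    identity X = 2 ln(10) * Dscore of the same p-values.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    x = -2.0 * np.sum(np.log(np.maximum(p, params.p_floor)))
    return float(stats.chi2.sf(x, 2 * p.size))


def evaluate_signature(
    sig: Signature, expr: ExpressionMatrix, clin: ClinicalTable
) -> LogRankResult:
    """Score -> median split -> log-rank on one cohort."""
    shared = [s for s in expr.sample_ids if s in set(clin.sample_ids)]
    if len(shared) < 2:
        raise ValueError("expression and clinical tables share fewer than 2 samples")
    scores = score_samples(sig, expr.subset_samples(shared))
    part = split_groups(scores)
    return logrank_test(part, clin.subset(shared))


def evaluate_family(
    sig: Signature,
    datasets: list[tuple[ExpressionMatrix, ClinicalTable]],
    names: list[str] | None = None,
    params: DscoreParams = DscoreParams(),
) -> tuple[pd.DataFrame, float]:
    """Per-dataset evaluation rows plus the family Dscore."""
    if names is None:
        names = [f"dataset_{i + 1}" for i in range(len(datasets))]
    rows = []
    for name, (expr, clin) in zip(names, datasets):
        r = evaluate_signature(sig, expr, clin)
        rows.append(
            {
                "dataset": name,
                "HR": r.hazard_ratio,
                "HR_CI_low": r.hr_ci_low,
                "HR_CI_high": r.hr_ci_high,
                "logrank_p": r.p_value,
            }
        )
    report = pd.DataFrame(rows)
    return report, dscore(report["logrank_p"], params)


def random_signature_null(
    datasets: list[tuple[ExpressionMatrix, ClinicalTable]],
    training: tuple[ExpressionMatrix, ClinicalTable],
    k: int,
    n_reps: int,
    pool: GeneSet | None = None,
    mode: str = "whole_genome",
    seed: int = 0,
    params: DscoreParams = DscoreParams(),
) -> list[float]:
    """Dscore null distribution of random same-size signatures.

    Each replicate draws ``k`` genes without replacement — from the whole
    gene complement of the training matrix (``mode='whole_genome'``) or from
    an explicit candidate ``pool`` (``mode='candidate_pool'``) — estimates
    each drawn gene's coefficient sign by a univariate Cox fit on the
    training cohort, then scores, splits and log-rank-tests every evaluation
    dataset and records the Dscore. Genes whose training fit is not
    estimable enter with a positive sign.
    """
    train_expr, train_clin = training
    if mode == "whole_genome":
        pool_ids = sorted(train_expr.gene_ids)
    elif mode == "candidate_pool":
        if pool is None:
            raise ValueError("candidate_pool mode requires an explicit pool")
        pool_ids = sorted(pool.members)
    else:
        raise ValueError("mode must be 'whole_genome' or 'candidate_pool'")
    if k > len(pool_ids):
        raise ValueError(f"k={k} exceeds pool size {len(pool_ids)}")
    if n_reps == 0:
        return []

    shared = sorted(set(train_expr.sample_ids) & set(train_clin.sample_ids))
    tr_expr = train_expr.subset_samples(shared)
    tr_clin = train_clin.subset(shared)
    gene_pos = {g: i for i, g in enumerate(tr_expr.gene_ids)}

    rng = np.random.default_rng(seed)
    scores: list[float] = []
    for _ in range(n_reps):
        drawn = [pool_ids[i] for i in rng.choice(len(pool_ids), size=k, replace=False)]
        rows = [gene_pos[g] for g in drawn]
        beta, _se, _p = cox_fit_matrix(tr_expr.values[rows], tr_clin.time, tr_clin.event)
        beta = np.where(np.isfinite(beta), beta, 0.0)
        sig = Signature(
            [SignatureGene(g, float(b), float("nan"), float("nan"))
             for g, b in zip(drawn, beta)]
        )
        _report, d = evaluate_family(sig, datasets, params=params)
        scores.append(d)
    return scores


def empirical_pvalue(observed: float, null: list[float]) -> float:
    """Fraction of null Dscores at least as large as the observed one."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    return float(np.mean(null >= observed))


def write_report(report: pd.DataFrame, d: float, path) -> None:
    """Tab-delimited per-dataset rows plus a trailing Dscore summary line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("dataset\tHR\tHR_CI_low\tHR_CI_high\tlogrank_p\n")
        for _, row in report.iterrows():
            fh.write(
                f"{row['dataset']}\t{row['HR']:.6g}\t{row['HR_CI_low']:.6g}\t"
                f"{row['HR_CI_high']:.6g}\t{row['logrank_p']:.6g}\n"
            )
        fh.write(f"# Dscore\t{d:.6g}\n")
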