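"""Seed-reproducible synthetic datasets with known ground truth.

Two generators cover the pipeline end to end without any external download:

* :func:`generate_dependency_dataset` emulates the structure the dependency
  screen assumes — a balanced binary phenotype, background genes of i.i.d.
  noise, and planted modulator triples in which the median-binarized target
  equals the phenotype with probability ``gate_strength`` inside one extreme
  stratum of the modulator and is independent of it everywhere else;
* :func:`generate_survival_family` emulates several cohorts sharing one set
  of hazard genes whose expression acts log-linearly on an exponential
  event-time hazard, with independent exponential censoring.

The planted gate is built directly on the binarized scale, so the effect
size is exactly what the stratified-MI statistic measures; the continuous
target values are then laid out so that the median split reproduces the
planted binary vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CandidatePairs, ClinicalTable, ExpressionMatrix, PhenotypeVector

__all__ = ["GeneratorConfig", "GroundTruth", "generate_dependency_dataset", "generate_survival_family"]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generators.

    The gate applies to the ``stratum_fraction`` extreme of the modulator —
    the same fraction the screen uses (0.35) — on the ``active_side``.
    ``hazard_beta`` is the log hazard ratio per unit expression; baseline
    hazard is 0.1 events/year so median event time is ~7 years, matching a
    distant-metastasis follow-up scale with a 5-year horizon.
    """

    n_samples: int = 300
    n_genes: int = 200
    n_modulated_pairs: int = 10
    n_null_pairs: int | None = None  # None -> match n_modulated_pairs
    gate_strength: float = 1.0
    active_side: str = "low"
    stratum_fraction: float = 0.35
    n_hazard_genes: int = 5
    hazard_beta: float = 0.8
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.3
    n_datasets: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gate_strength <= 1:
            raise ValueError("gate_strength must be in [0, 1]")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if not 0 < self.stratum_fraction <= 0.5:
            raise ValueError("stratum_fraction must be in (0, 0.5]")
        if self.active_side not in ("low", "high"):
            raise ValueError("active_side must be 'low' or 'high'")
        if self.n_hazard_genes > self.n_genes:
            raise ValueError("more hazard genes than genes")


@dataclass
class GroundTruth:
    modulated_pairs: list[tuple[str, str, str]] = field(default_factory=list)  # (modulator, target, side)
    hazard_genes: list[tuple[str, float]] = field(default_factory=list)  # (gene, true beta)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _sample_names(n: int, prefix: str = "S") -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def generate_dependency_dataset(
    cfg: GeneratorConfig,
) -> tuple[ExpressionMatrix, PhenotypeVector, CandidatePairs, GroundTruth]:
    """Planted modulator-gated triples among background noise genes.

    Each planted pair consumes two dedicated genes (a modulator of pure
    noise and a constructed target); null candidate pairs are drawn from the
    remaining background genes. The phenotype is an exactly balanced random
    binary vector. Targets carry exactly ``n/2`` ones, so median
    binarization of the written continuous values reproduces the planted
    binary vector (values below the median sit in [0, 0.5), values above in
    [1, 1.5)).
    """
    n = cfg.n_samples
    n_null = cfg.n_modulated_pairs if cfg.n_null_pairs is None else cfg.n_null_pairs
    needed = 2 * cfg.n_modulated_pairs + 2 * n_null
    if cfg.n_genes < needed:
        raise ValueError(
            f"n_genes={cfg.n_genes} cannot host {cfg.n_modulated_pairs} planted "
            f"and {n_null} null pairs (need >= {needed})"
        )
    if n < 8 or n % 2:
        raise ValueError("n_samples must be even and >= 8")
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    samples = _sample_names(n)

    values = rng.normal(size=(cfg.n_genes, n))
    phen = np.zeros(n, dtype=int)
    phen[rng.choice(n, size=n // 2, replace=False)] = 1

    k = int(np.floor(cfg.stratum_fraction * n))
    truth = GroundTruth()
    pairs: set[frozenset] = set()
    for t in range(cfg.n_modulated_pairs):
        mod_g = genes[2 * t]
        tgt_g = genes[2 * t + 1]
        b = values[2 * t]  # pure-noise modulator, already in the matrix
        order = np.argsort(b, kind="stable")
        active = order[:k] if cfg.active_side == "low" else order[-k:]
        a_bin = np.full(n, -1, dtype=int)
        gated = rng.random(k) < cfg.gate_strength
        a_bin[active] = np.where(gated, phen[active], rng.integers(0, 2, size=k))
        # fill the inactive samples so the target carries exactly n/2 ones
        inactive = np.setdiff1d(np.arange(n), active)
        ones_needed = n // 2 - int(a_bin[active].sum())
        ones_needed = min(max(ones_needed, 0), inactive.size)
        fill = np.zeros(inactive.size, dtype=int)
        fill[rng.choice(inactive.size, size=ones_needed, replace=False)] = 1
        a_bin[inactive] = fill
        # continuous layout whose median split returns a_bin exactly
        values[2 * t + 1] = a_bin + rng.uniform(0.0, 0.5, size=n)
        pairs.add(frozenset((mod_g, tgt_g)))
        truth.modulated_pairs.append((mod_g, tgt_g, cfg.active_side))

    background = genes[2 * cfg.n_modulated_pairs:]
    for j in range(n_null):
        pairs.add(frozenset((background[2 * j], background[2 * j + 1])))

    expr = ExpressionMatrix(genes, samples, values)
    phen_vec = PhenotypeVector(samples, phen, abandoned=[])
    return expr, phen_vec, CandidatePairs(pairs), truth


def generate_survival_family(
    cfg: GeneratorConfig,
) -> tuple[list[tuple[ExpressionMatrix, ClinicalTable]], GroundTruth]:
    """Cohorts sharing planted hazard genes.

    Per cohort, expression is i.i.d. standard normal; sample i's event time
    is exponential with rate ``baseline_hazard * exp(sum_g beta_g x_gi)``
    over the hazard genes; censoring is an independent exponential whose
    rate is tuned so that roughly ``censoring_rate`` of patients are
    censored (``censoring_rate=0`` disables censoring entirely).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    hazard_idx = np.arange(cfg.n_hazard_genes)
    truth = GroundTruth(
        hazard_genes=[(genes[i], float(cfg.hazard_beta)) for i in hazard_idx]
    )
    datasets: list[tuple[ExpressionMatrix, ClinicalTable]] = []
    for d in range(cfg.n_datasets):
        n = cfg.n_samples
        samples = _sample_names(n, prefix=f"D{d + 1}S")
        X = rng.normal(size=(cfg.n_genes, n))
        eta = cfg.hazard_beta * X[hazard_idx].sum(axis=0)
        rate = cfg.baseline_hazard * np.exp(eta)
        t_event = rng.exponential(1.0 / rate)
        if cfg.censoring_rate > 0:
            # competing exponential: P(censor first) = c / (c + rate_i); tune c
            # against the mean event rate for an approximate overall fraction
            c = cfg.censoring_rate / (1 - cfg.censoring_rate) * float(np.mean(rate))
            t_cens = rng.exponential(1.0 / c, size=n)
            time = np.minimum(t_event, t_cens)
            event = (t_event <= t_cens).astype(int)
        else:
            time = t_event
            event = np.ones(n, dtype=int)
        datasets.append(
            (ExpressionMatrix(genes, samples, X), ClinicalTable(samples, time, event))
        )
    return datasets, truth
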