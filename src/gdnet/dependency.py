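"""Modulator-dependent gene-phenotype association screen.

For a candidate directed pair B -> A (B the modulator, A the target) the
dependency score contrasts the mutual information between the binarized
target A and the binary phenotype P in the two extreme strata of the
modulator's *continuous* expression: samples are sorted by B, the bottom
``stratum_fraction`` of them give I_low = I(A; P | B low) and the top
fraction give I_high, and the score is

    CMI = | I_high - I_low |   (bits)

A large score means the A-P association switches on or off with the level
of B. Significance comes from a permutation null that jointly shuffles the
(A, P) sample pairs against B — the A-P marginal association is preserved
while the link to B is broken, so the null hypothesis is exactly "the A-P
relation does not depend on B".

Binarization of A and of the phenotype is global (done once on all retained
samples, before stratification); only the ordering of B's raw values is used,
so the score is invariant to any strictly monotone transform of B.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import CandidatePairs, ExpressionMatrix, PhenotypeVector, binarize_expression

logger = logging.getLogger(__name__)

__all__ = [
    "CMIParams",
    "CMIResult",
    "DependencyPair",
    "mutual_information",
    "stratified_mi",
    "cmi_score",
    "permutation_pvalue",
    "screen_pairs",
    "write_pair_table",
]


@dataclass
class CMIParams:
    """Knobs of the dependency screen.

    stratum_fraction
        Fraction of samples in each modulator stratum (bottom and top);
        the stratum size is ``floor(fraction * n)``.
    n_permutations
        Size of the permutation null per direction.
    alpha
        Significance level on the permutation p-value.
    seed
        Base seed; the screen derives one independent stream per direction.
    """

    stratum_fraction: float = 0.35
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.stratum_fraction <= 0.5:
            raise ValueError("stratum_fraction must be in (0, 0.5]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class CMIResult:
    mi_low: float
    mi_high: float
    cmi: float
    n_stratum: int


@dataclass
class DependencyPair:
    """Directed dependency record: ``modulator`` gates the target-phenotype link."""

    modulator: str
    target: str
    cmi: float
    p_value: float

    def __post_init__(self) -> None:
        if self.modulator == self.target:
            raise ValueError("self-dependency is not a valid pair")


def _validate_binary(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return v.astype(np.int8)


def mutual_information(x, y) -> float:
    """Plug-in mutual information of two binary vectors, in bits.

    Empirical 2x2 joint, base-2 logarithm, with 0*log(0) terms contributing 0.
    """
    x = _validate_binary(x, "x")
    y = _validate_binary(y, "y")
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = x.size - n11 - n10 - n01
    return float(_mi_from_counts(
        np.array(n11), np.array(n10), np.array(n01), np.array(n00)
    ))


def _mi_from_counts(n11, n10, n01, n00):
    """Vectorized plug-in MI (bits) from 2x2 cell counts (broadcastable arrays)."""
    n11 = np.asarray(n11, dtype=float)
    n10 = np.asarray(n10, dtype=float)
    n01 = np.asarray(n01, dtype=float)
    n00 = np.asarray(n00, dtype=float)
    n = n11 + n10 + n01 + n00
    mi = np.zeros(np.broadcast(n11, n10, n01, n00).shape, dtype=float)
    # row marginals: x=1 -> n1., x=0 -> n0.; column marginals: y=1 -> n.1
    r1 = n11 + n10
    r0 = n01 + n00
    c1 = n11 + n01
    c0 = n10 + n00
    for cell, r, c in ((n11, r1, c1), (n10, r1, c0), (n01, r0, c1), (n00, r0, c0)):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = cell / n * np.log2(cell * n / (r * c))
        mi += np.where(cell > 0, term, 0.0)
    return np.maximum(mi, 0.0)  # clip -0.0 / rounding noise


def _stratum_order(b_values: np.ndarray) -> np.ndarray:
    """Ascending stable order of the modulator values (ties keep input order)."""
    return np.argsort(np.asarray(b_values, dtype=float), kind="stable")


def _stratum_size(n: int, fraction: float) -> int:
    return int(np.floor(fraction * n))


def stratified_mi(a_binary, phen, b_values, params: CMIParams, side: str) -> float:
    """MI of (target, phenotype) within one modulator stratum.

    Samples are sorted ascending by ``b_values`` (stable); ``side='low'``
    takes the bottom ``floor(stratum_fraction * n)`` samples, ``side='high'``
    the top ones. The target is the globally binarized value — binarization
    is not redone inside the stratum.
    """
    a_binary = _validate_binary(a_binary, "a_binary")
    phen = _validate_binary(phen, "phen")
    b_values = np.asarray(b_values, dtype=float)
    if not (a_binary.size == phen.size == b_values.size):
        raise ValueError("a_binary, phen and b_values must be aligned")
    if side not in ("low", "high"):
        raise ValueError("side must be 'low' or 'high'")
    k = _stratum_size(a_binary.size, params.stratum_fraction)
    if k < 2:
        raise ValueError(f"stratum size {k} < 2 (n={a_binary.size})")
    order = _stratum_order(b_values)
    idx = order[:k] if side == "low" else order[-k:]
    return mutual_information(a_binary[idx], phen[idx])


def cmi_score(a_binary, phen, b_values, params: CMIParams) -> CMIResult:
    """Dependency score |I_high - I_low| with its two stratum MIs."""
    mi_low = stratified_mi(a_binary, phen, b_values, params, "low")
    mi_high = stratified_mi(a_binary, phen, b_values, params, "high")
    k = _stratum_size(np.asarray(a_binary).size, params.stratum_fraction)
    return CMIResult(mi_low=mi_low, mi_high=mi_high, cmi=abs(mi_high - mi_low), n_stratum=k)


def _null_cmis(
    a_binary: np.ndarray,
    phen: np.ndarray,
    low_idx: np.ndarray,
    high_idx: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation null: jointly shuffle (A, P) pairs against the fixed strata.

    Because the strata are index sets determined solely by B's order, a joint
    permutation of the (A, P) pairs is equivalent to re-drawing which samples
    land in each stratum, so the null CMIs can be computed fully vectorized.
    """
    n = a_binary.size
    perms = np.argsort(rng.random((n_permutations, n)), axis=1)
    a_p = a_binary[perms]
    p_p = phen[perms]
    out = []
    for idx in (low_idx, high_idx):
        a_s = a_p[:, idx]
        p_s = p_p[:, idx]
        n11 = np.sum(a_s & p_s, axis=1)
        n10 = np.sum(a_s & (1 - p_s), axis=1)
        n01 = np.sum((1 - a_s) & p_s, axis=1)
        n00 = idx.size - n11 - n10 - n01
        out.append(_mi_from_counts(n11, n10, n01, n00))
    return np.abs(out[1] - out[0])


def permutation_pvalue(
    a_binary, phen, b_values, params: CMIParams,
    rng: np.random.Generator | None = None,
) -> tuple[float, CMIResult]:
    """Permutation p-value of the dependency score.

    The real score is ranked (descending) within ``n_permutations`` null
    scores obtained by jointly shuffling the (A, P) pairs across samples
    relative to B; with ``c`` null scores >= the real one,
    ``p = min(1, (1 + c) / n_permutations)`` — a top-ranked real score gives
    ``1 / n_permutations`` and p is never 0.
    """
    a_binary = _validate_binary(a_binary, "a_binary")
    phen = _validate_binary(phen, "phen")
    b_values = np.asarray(b_values, dtype=float)
    real = cmi_score(a_binary, phen, b_values, params)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    k = real.n_stratum
    order = _stratum_order(b_values)
    null = _null_cmis(a_binary, phen, order[:k], order[-k:], params.n_permutations, rng)
    c = int(np.sum(null >= real.cmi))
    p = min(1.0, (1 + c) / params.n_permutations)
    return p, real


def screen_pairs(
    expr: ExpressionMatrix,
    phen: PhenotypeVector,
    candidates: CandidatePairs,
    params: CMIParams,
) -> list[DependencyPair]:
    """Test every candidate pair in both directions; keep p <= alpha.

    For each unordered candidate pair {A, B} both ``B -> A`` (B modulating A)
    and ``A -> B`` are screened. Genes absent from the matrix are skipped with
    a logged count; a direction whose target binarizes to a constant vector is
    skipped with a warning (its MI is identically zero). Deterministic for a
    fixed ``params.seed``: each direction draws from an independent stream
    spawned from the base seed in lexicographic pair order.
    """
    if len(candidates) == 0:
        return []
    expr_sub = expr.subset_samples(phen.sample_ids)
    binary = binarize_expression(expr_sub)
    gene_pos = {g: i for i, g in enumerate(expr_sub.gene_ids)}
    status = np.asarray(phen.status, dtype=np.int8)

    n_absent = 0
    results: list[DependencyPair] = []
    ss = np.random.SeedSequence(params.seed)
    pairs = candidates.sorted_pairs()
    streams = ss.spawn(2 * len(pairs))
    for i, (g1, g2) in enumerate(pairs):
        if g1 not in gene_pos or g2 not in gene_pos:
            n_absent += 1
            continue
        for j, (modulator, target) in enumerate(((g2, g1), (g1, g2))):
            tgt_bin = binary[gene_pos[target]]
            if tgt_bin.min() == tgt_bin.max():
                warnings.warn(
                    f"target {target!r} is constant after binarization; "
                    f"direction {modulator}->{target} skipped",
                    stacklevel=2,
                )
                continue
            b_vals = expr_sub.values[gene_pos[modulator]]
            rng = np.random.default_rng(streams[2 * i + j])
            p, real = permutation_pvalue(tgt_bin, status, b_vals, params, rng=rng)
            if p <= params.alpha:
                results.append(DependencyPair(modulator, target, real.cmi, p))
    if n_absent:
        logger.info("skipped %d candidate pair(s) with gene(s) absent from matrix", n_absent)
    return results


def write_pair_table(pairs: list[DependencyPair], path) -> None:
    """Tab-delimited edge table: modulator, target, cmi, p_value."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("modulator\ttarget\tcmi\tp_value\n")
        for p in pairs:
            fh.write(f"{p.modulator}\t{p.target}\t{p.cmi:.6g}\t{p.p_value:.6g}\n")
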