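"""Readers, writers and the two discretization steps.

All on-disk formats are UTF-8 tab-delimited text; lines starting with ``#``
are comments. Expression files carry a ``gene_id`` header column followed by
sample ids; clinical files carry ``sample_id``, ``time_years`` (time to
distant metastasis or censoring) and ``event`` (1 = metastasis observed).

Two discretizations feed the dependency screen:

* the clinical outcome is dichotomized at a follow-up horizon (default
  5 years): metastasis within the horizon is phenotype 1, follow-up past the
  horizon is phenotype 0, and patients censored before the horizon carry no
  usable label and are set aside;
* each gene is median-binarized across samples (strictly below the gene's
  median -> 0, otherwise 1), while the continuous values are kept for
  modulator stratification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "PhenotypeVector",
    "CandidatePairs",
    "GeneSet",
    "LoadError",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_edge_list",
    "write_edge_list",
    "read_gene_set",
    "write_gene_set",
    "dichotomize_phenotype",
    "binarize_expression",
]


class LoadError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Continuous genes x samples expression table.

    ``values`` is a float array of shape ``(len(gene_ids), len(sample_ids))``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(self.sample_ids) < 2:
            raise ValueError("expression matrix needs at least 2 samples")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        """Column subset in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])

    def gene_row(self, gene_id: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None
        return self.values[i]


@dataclass
class ClinicalTable:
    """Per-sample follow-up: time in years and event indicator (1 = distant metastasis)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (len(self.sample_ids) == len(self.time) == len(self.event)):
            raise ValueError("clinical columns have unequal lengths")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in clinical table")
        if (self.time < 0).any():
            raise ValueError("negative follow-up time")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: list[str]) -> "ClinicalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in clinical table: {missing}")
        idx = [pos[s] for s in sample_ids]
        return ClinicalTable(list(sample_ids), self.time[idx], self.event[idx])


@dataclass
class PhenotypeVector:
    """Binary phenotype after horizon dichotomization.

    ``status[i]`` is 1 when sample ``sample_ids[i]`` had a distant metastasis
    within the horizon, 0 when it is a confirmed non-case; ``abandoned`` lists
    samples censored before the horizon, which carry no label.
    """

    sample_ids: list[str]
    status: np.ndarray
    abandoned: list[str]
    horizon: float = 5.0

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=int)
        if len(self.status) != len(self.sample_ids):
            raise ValueError("status length mismatch")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("phenotype status must be 0 or 1")
        if set(self.sample_ids) & set(self.abandoned):
            raise ValueError("a sample cannot be both retained and abandoned")


@dataclass
class CandidatePairs:
    """Unordered candidate gene pairs (typically PPI partners)."""

    pairs: set[frozenset]

    def __post_init__(self) -> None:
        for p in self.pairs:
            if len(p) != 2:
                raise ValueError(f"not a pair of two distinct genes: {set(p)}")

    def __len__(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list[tuple[str, str]]:
        """Deterministic (lexicographic) listing of the unordered pairs."""
        return sorted(tuple(sorted(p)) for p in self.pairs)


@dataclass
class GeneSet:
    name: str
    members: set = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.members)


def _data_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_expression(path) -> ExpressionMatrix:
    """Read a tab-delimited expression file (header ``gene_id\\t<samples...>``).

    Duplicate gene rows are collapsed by their mean. Any non-numeric value in
    the data block raises :class:`LoadError` naming the offending line.
    """
    rows: dict[str, list[np.ndarray]] = {}
    order: list[str] = []
    header: list[str] | None = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            if len(fields) < 3:
                raise LoadError(
                    f"{path}:{lineno}: header must list a gene_id column and >=2 samples"
                )
            header = fields[1:]
            continue
        if len(fields) != len(header) + 1:
            raise LoadError(
                f"{path}:{lineno}: expected {len(header) + 1} columns, got {len(fields)}"
            )
        gene = fields[0]
        try:
            vals = np.array([float(v) for v in fields[1:]], dtype=float)
        except ValueError:
            bad = next(
                j for j, v in enumerate(fields[1:], start=2)
                if not _is_number(v)
            )
            raise LoadError(
                f"{path}:{lineno}: non-numeric value in column {bad} (gene {gene!r})"
            ) from None
        if np.isnan(vals).any():
            raise LoadError(f"{path}:{lineno}: missing value for gene {gene!r}")
        if gene not in rows:
            order.append(gene)
        rows.setdefault(gene, []).append(vals)
    if header is None:
        raise LoadError(f"{path}: empty expression file")
    if not order:
        raise LoadError(f"{path}: no gene rows")
    n_dup = sum(len(v) - 1 for v in rows.values())
    if n_dup:
        logger.info("collapsed %d duplicate gene rows by mean", n_dup)
    values = np.vstack([np.mean(rows[g], axis=0) for g in order])
    return ExpressionMatrix(order, header, values)


def _is_number(s: str) -> bool:
    try:
        v = float(s)
    except ValueError:
        return False
    return not np.isnan(v)


def write_expression(expr: ExpressionMatrix, path, fmt: str = "%.17g") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(expr.sample_ids) + "\n")
        for gene, row in zip(expr.gene_ids, expr.values):
            fh.write(gene + "\t" + "\t".join(fmt % v for v in row) + "\n")


def read_clinical(path) -> ClinicalTable:
    """Read ``sample_id\\ttime_years\\tevent`` rows (header optional)."""
    ids, times, events = [], [], []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "sample_id":
            continue
        if len(fields) != 3:
            raise LoadError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
        sid, t_s, e_s = fields
        try:
            t = float(t_s)
            e = int(e_s)
        except ValueError:
            raise LoadError(f"{path}:{lineno}: non-numeric time or event") from None
        if t < 0:
            raise LoadError(f"{path}:{lineno}: negative time {t} for sample {sid!r}")
        if e not in (0, 1):
            raise LoadError(f"{path}:{lineno}: event must be 0 or 1, got {e}")
        ids.append(sid)
        times.append(t)
        events.append(e)
    if not ids:
        raise LoadError(f"{path}: empty clinical table")
    return ClinicalTable(ids, np.array(times), np.array(events))


def write_clinical(clin: ClinicalTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\ttime_years\tevent\n")
        for sid, t, e in zip(clin.sample_ids, clin.time, clin.event):
            fh.write(f"{sid}\t{t:.10g}\t{int(e)}\n")


def read_edge_list(path) -> CandidatePairs:
    """Read two gene ids per line; self-pairs and duplicate unordered pairs are dropped."""
    pairs: set[frozenset] = set()
    n_self = n_dup = 0
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) != 2:
            raise LoadError(f"{path}:{lineno}: expected 2 gene ids, got {len(fields)}")
        a, b = fields
        if a == b:
            n_self += 1
            continue
        key = frozenset((a, b))
        if key in pairs:
            n_dup += 1
        pairs.add(key)
    if n_self:
        warnings.warn(f"dropped {n_self} self-pair line(s) from {path}", stacklevel=2)
    if n_dup:
        logger.info("dropped %d duplicate unordered pair(s)", n_dup)
    return CandidatePairs(pairs)


def write_edge_list(pairs: CandidatePairs, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in pairs.sorted_pairs():
            fh.write(f"{a}\t{b}\n")


def read_gene_set(path, name: str | None = None) -> GeneSet:
    members = set()
    for _lineno, line in _data_lines(path):
        members.add(line.split()[0])
    return GeneSet(name=name or str(path), members=members)


def write_gene_set(gs: GeneSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(gs.members):
            fh.write(g + "\n")


def dichotomize_phenotype(clin: ClinicalTable, horizon: float = 5.0) -> PhenotypeVector:
    """Dichotomize follow-up at ``horizon`` years.

    A metastasis at or before the horizon is phenotype 1; follow-up beyond the
    horizon (with or without a later event) is phenotype 0; samples censored
    event-free at or before the horizon are unlabelable and go to ``abandoned``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    kept_ids: list[str] = []
    status: list[int] = []
    abandoned: list[str] = []
    for sid, t, e in zip(clin.sample_ids, clin.time, clin.event):
        if e == 1 and t <= horizon:
            kept_ids.append(sid)
            status.append(1)
        elif t > horizon:
            kept_ids.append(sid)
            status.append(0)
        else:  # event-free and follow-up ended within the horizon
            abandoned.append(sid)
    if not kept_ids:
        raise ValueError("no samples retained after dichotomization")
    return PhenotypeVector(kept_ids, np.array(status), abandoned, horizon=horizon)


def binarize_expression(expr: ExpressionMatrix) -> np.ndarray:
    """Median-binarize each gene across samples: value < median -> 0, else 1.

    Ties at the median become 1 (the rule is a strict "below"). A constant
    gene therefore yields an all-1 row, which is flagged because it carries
    no information for the dependency screen.
    """
    med = np.median(expr.values, axis=1, keepdims=True)
    binary = (expr.values >= med).astype(np.int8)
    constant = np.ptp(expr.values, axis=1) == 0
    if constant.any():
        names = [g for g, c in zip(expr.gene_ids, constant) if c]
        warnings.warn(
            f"{constant.sum()} constant gene(s) binarize to all-1: {names[:5]}",
            stacklevel=2,
        )
    return binary
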