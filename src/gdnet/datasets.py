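"""Packaged reference tables from the breast-cancer distant-metastasis study.

Three small fixtures ship with the package:

* the 43-gene hub-based signature (candidates that are also network hubs),
* the 43-gene pseudo signature (the most risk-correlated candidates, the
  comparison control),
* the pseudo signature's per-cohort performance (hazard ratios and log-rank
  p-values on the training cohort and six independent cohorts).

All are tab-delimited; signature tables parse into :class:`~gdnet.signature.Signature`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .signature import Signature, SignatureGene

__all__ = [
    "load_hub_signature",
    "load_pseudo_signature",
    "load_pseudo_performance",
]


def _read_tsv(name: str) -> pd.DataFrame:
    ref = resources.files("gdnet.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype={"gene_id": str})


def _to_signature(frame: pd.DataFrame) -> Signature:
    return Signature(
        [
            SignatureGene(
                gene_id=str(r.gene_id),
                cox_beta=float(r.cox_beta),
                cox_p=float(r.cox_p),
                stability=float(r.stability),
            )
            for r in frame.itertuples()
        ]
    )


def load_hub_signature(as_frame: bool = False):
    """The 43-gene hub-based signature (Entrez ids, averaged Cox stats, stability)."""
    frame = _read_tsv("table1_hub_signature.tsv")
    return frame if as_frame else _to_signature(frame)


def load_pseudo_signature(as_frame: bool = False):
    """The 43-gene pseudo signature of most risk-correlated candidates."""
    frame = _read_tsv("table2_pseudo_signature.tsv")
    return frame if as_frame else _to_signature(frame)


def load_pseudo_performance() -> pd.DataFrame:
    """Per-cohort HR / CI / log-rank p of the pseudo signature.

    The ``role`` column distinguishes the training cohort from the six
    independent cohorts the cross-dataset Dscore is computed over.
    """
    return _read_tsv("table3_pseudo_performance.tsv")
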