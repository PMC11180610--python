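"""Housekeeping-normalized expression fold changes and the IFN score.

Target-gene abundance is first normalized to the HPRT housekeeping gene
within each sample, then expressed as a fold change over the untreated
baseline; multiple baseline replicates are combined by geometric mean
(ratio data).  The type-I interferon response score is the sum of the
IRF7, OAS1 and DDX58 fold changes, so an untreated sample scores 3.
"""

from __future__ import annotations

from collections.abc import Sequence
from typing import Union

import numpy as np
import pandas as pd

__all__ = ["expression_fold_change", "ifn_score", "ifn_score_from_table",
           "IFN_GENES", "HOUSEKEEPING_GENE"]

IFN_GENES = ("IRF7", "OAS1", "DDX58")
HOUSEKEEPING_GENE = "HPRT"


def _abundance(table: pd.DataFrame, sample: str, gene: str) -> float:
    sel = table[(table["sample"] == sample) & (table["gene"] == gene)]
    if not len(sel):
        raise KeyError(f"no abundance for gene {gene!r} in sample {sample!r}")
    return float(sel["abundance"].mean())


def _normalized(table: pd.DataFrame, sample: str, gene: str,
                housekeeping: str) -> float:
    hk = _abundance(table, sample, housekeeping)
    if hk <= 0:
        raise ValueError(f"housekeeping abundance is not positive in "
                         f"sample {sample!r}")
    return _abundance(table, sample, gene) / hk


def expression_fold_change(table: pd.DataFrame, gene: str, sample: str,
                           baseline_samples: Union[str, Sequence[str]],
                           housekeeping: str = HOUSEKEEPING_GENE) -> float:
    """Fold change of ``gene`` in ``sample`` over the untreated baseline.

    ``table`` has columns ``sample, gene, abundance`` (any abundance unit —
    the ratio is unit-free).  FC = (target/housekeeping)_sample ÷
    (target/housekeeping)_baseline, with multiple baselines combined by
    geometric mean.
    """
    if isinstance(baseline_samples, str):
        baseline_samples = [baseline_samples]
    if not baseline_samples:
        raise ValueError("at least one baseline sample is required")
    num = _normalized(table, sample, gene, housekeeping)
    ratios = [_normalized(table, b, gene, housekeeping)
              for b in baseline_samples]
    denom = float(np.exp(np.mean(np.log(ratios))))
    if denom <= 0:
        raise ValueError("baseline normalized expression is not positive")
    return num / denom


def ifn_score(fc_irf7: float, fc_oas1: float, fc_ddx58: float) -> float:
    """Interferon score: sum of the IRF7, OAS1 and DDX58 fold changes."""
    for fc in (fc_irf7, fc_oas1, fc_ddx58):
        if fc < 0:
            raise ValueError("fold changes must be ≥ 0")
    return fc_irf7 + fc_oas1 + fc_ddx58


def ifn_score_from_table(table: pd.DataFrame, sample: str,
                         baseline_samples: Union[str, Sequence[str]],
                         housekeeping: str = HOUSEKEEPING_GENE) -> float:
    """IFN score computed from an expression table in one call."""
    fcs = [expression_fold_change(table, g, sample, baseline_samples,
                                  housekeeping) for g in IFN_GENES]
    return ifn_score(*fcs)
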