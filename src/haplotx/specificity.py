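"""Tissue-specificity scoring with the Tau index.

Tau summarizes how concentrated a transcript's expression is across n
conditions: with x_hat_i = x_i / max(x),

    tau = sum_i (1 - x_hat_i) / (n - 1)

Tau is 0 for uniform expression, 1 for single-condition expression, and is
invariant to positive rescaling of the vector.  Expression is stabilized
before scoring with log2(normalized count + 1), a monotone transform of
size-factor-normalized counts.  The per-condition components
1 - x_i / max(x) form the matrix used for clustering displays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transcripts import ExpressionMatrix


@dataclass
class TauResult:
    tau: float
    max_condition: str
    components: pd.Series  # 1 - x/max per condition; 0 at max_condition


def transform_expression(expr: ExpressionMatrix) -> pd.DataFrame:
    """Variance-stabilizing-style transform: log2(normalized count + 1)."""
    norm = expr.counts.div(expr.size_factors, axis=1)
    if (norm < 0).any().any():
        raise ValueError("expression values must be non-negative")
    return np.log2(norm + 1)


def tau(x: pd.Series) -> TauResult:
    """Tau of one per-condition expression vector (length >= 2, max > 0)."""
    x = pd.Series(x, dtype=float)
    if len(x) < 2:
        raise ValueError("tau needs at least 2 conditions")
    if (x < 0).any():
        raise ValueError("tau requires non-negative expression")
    m = x.max()
    if m == 0:
        raise ValueError("tau undefined for an all-zero expression vector")
    x_hat = x / m
    components = 1.0 - x_hat
    t = float(components.sum() / (len(x) - 1))
    return TauResult(t, str(x.idxmax()), components)


def tau_table(transformed: pd.DataFrame) -> pd.DataFrame:
    """Tau, max condition, and components for every row of a transformed
    expression matrix.  All-zero rows get tau = NaN (flagged, not scored)."""
    maxes = transformed.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        x_hat = transformed.div(maxes, axis=0)
    comps = 1.0 - x_hat
    taus = comps.sum(axis=1) / (transformed.shape[1] - 1)
    taus[maxes == 0] = np.nan
    out = pd.DataFrame(
        {
            "tau": taus,
            "max_condition": transformed.idxmax(axis=1),
        }
    )
    out.loc[maxes == 0, "max_condition"] = pd.NA
    return out


def tau_components(transformed: pd.DataFrame) -> pd.DataFrame:
    """The 1 - x/max component matrix (rows with zero max are dropped)."""
    maxes = transformed.max(axis=1)
    keep = transformed[maxes > 0]
    return 1.0 - keep.div(keep.max(axis=1), axis=0)


def specific_set(taus: pd.Series, threshold: float = 0.8) -> tuple[pd.Index, float]:
    """Transcripts with tau strictly above the threshold, and their fraction.

    The fraction is over transcripts with a defined tau.
    """
    defined = taus.dropna()
    subset = defined[defined > threshold].index
    frac = float(len(subset) / len(defined)) if len(defined) else 0.0
    return subset, frac
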