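"""Evaluation statistics: Dice overlap, median absolute error, Gwet AC1.

Gwet's AC1 is a chance-corrected inter-rater agreement coefficient that
stays stable under prevalence imbalance (unlike kappa): chance agreement is
estimated from category prevalences as pe = 1/(K-1) * sum_k pi_k (1-pi_k),
and AC1 = (pa - pe) / (1 - pe).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class AgreementResult:
    pa: float            # observed agreement (mean per-item pairwise)
    pe: float            # chance agreement from prevalences
    ac1: float
    n_items: int
    categories: tuple

    def to_dict(self) -> dict:
        return {
            "pa": self.pa,
            "pe": self.pe,
            "ac1": self.ac1,
            "n_items": self.n_items,
            "categories": list(self.categories),
        }


def dice(a, b) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); two empty masks agree perfectly (1.0)."""
    a = np.asarray(getattr(a, "data", a)).astype(bool)
    b = np.asarray(getattr(b, "data", b)).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        log.info("dice: both masks empty, returning 1.0 (agreement on absence)")
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def median_abs_error(pred, truth) -> float:
    """Median of |pred - truth| over paired observations.

    This is the robust 'MAE' used throughout the evaluation: a median, not a
    mean, so it is unaffected by corrupting fewer than half the pairs.  Even
    counts use the mean-of-middle-two convention.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must be paired (equal length)")
    if pred.size == 0:
        raise ValueError("empty inputs")
    return float(np.median(np.abs(pred - truth)))


def ratings_from_long(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long (item_id, rater_id, label) table to items x raters."""
    return df.pivot(index="item_id", columns="rater_id", values="label")


def gwet_ac1(ratings) -> AgreementResult:
    """Gwet AC1 over an items x raters table of categorical labels.

    pa is the mean over items of the fraction of agreeing rater pairs;
    pi_k averages each rater's usage of category k over items; missing
    ratings (NaN) are allowed as long as >=2 raters scored each item.
    For 2 raters and binary labels this reduces to pe = 2*pi*(1-pi).
    """
    table = pd.DataFrame(ratings)
    if table.shape[1] < 2:
        raise ValueError("need >= 2 raters")
    if table.shape[0] < 1:
        raise ValueError("need >= 1 item")
    values = table.to_numpy(dtype=object)
    cats = sorted({v for row in values for v in row if not _is_missing(v)}, key=str)
    if len(cats) == 0:
        raise ValueError("no ratings present")
    cat_index = {c: k for k, c in enumerate(cats)}
    n_items, n_raters = values.shape

    # r_ik: number of raters assigning item i to category k
    r = np.zeros((n_items, len(cats)))
    for i in range(n_items):
        for j in range(n_raters):
            v = values[i, j]
            if not _is_missing(v):
                r[i, cat_index[v]] += 1
    ri = r.sum(axis=1)
    if (ri < 2).any():
        raise ValueError("every item needs >= 2 ratings")

    pa = float(np.mean((r * (r - 1)).sum(axis=1) / (ri * (ri - 1))))
    pi_k = (r / ri[:, None]).mean(axis=0)
    K = max(len(cats), 2)  # a single observed category still implies a binary scheme
    pe = float((pi_k * (1.0 - pi_k)).sum() / (K - 1))
    if pe >= 1.0:
        ac1 = 1.0 if pa == 1.0 else float("nan")
    else:
        ac1 = (pa - pe) / (1.0 - pe)
    return AgreementResult(pa=pa, pe=pe, ac1=float(ac1), n_items=n_items, categories=tuple(cats))


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))
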