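"""Differential-expression filter on normalised log2 matrices.

A gene is called responsive when it clears three hurdles simultaneously:
linear fold change >= 1.5 (computed from the difference of log2 group
means, i.e. a geometric-mean ratio), two-sided t-test p < 0.05, and
signal above a background floor in at least one array.  Direction labels
(up/down in KO vs WT) follow the sign of the log2 fold change.

The default location test is the pooled-variance two-sample t-test,
which at three replicates per group holds its nominal level exactly
under equal group variances and loses no degrees of freedom to the
Satterthwaite approximation; Welch's unequal-variance test is available
via ``welch=True``.  No multiple-testing adjustment is applied by
default (the filter operates on raw p-values); an optional
Benjamini-Hochberg mode is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: p-value assigned when both groups are exactly constant but differ;
#: keeps noiseless fixtures classifying deterministically.
DEGENERATE_P = 1e-12


@dataclass
class DEConfig:
    fc_cutoff: float = 1.5
    alpha: float = 0.05
    background_floor: float = 0.0
    min_above_background_arrays: int = 1
    welch: bool = False
    fdr: bool = False

    def __post_init__(self) -> None:
        if self.fc_cutoff <= 1:
            raise ValueError("fc_cutoff must exceed 1 (linear scale)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def above_background(values: pd.DataFrame, config: DEConfig) -> pd.Series:
    """True where >= ``min_above_background_arrays`` samples exceed the
    background floor."""
    n_above = (values > config.background_floor).sum(axis=1)
    return n_above >= config.min_above_background_arrays


def differential_genes(wt: pd.DataFrame, ko: pd.DataFrame,
                       config: DEConfig | None = None) -> pd.DataFrame:
    """Per-gene DE table for KO vs WT log2 matrices (rows = genes).

    Returns a DataFrame indexed by gene with columns log2fc, linear_fc,
    p_value, above_background, status (up/down/ns).  linear_fc is the
    unsigned fold magnitude 2**|log2fc|; the sign lives in log2fc/status.
    """
    config = config or DEConfig()
    if wt.shape[1] < 2 or ko.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    if not wt.index.equals(ko.index):
        raise ValueError("WT and KO matrices index different genes")

    wt_v = wt.to_numpy(dtype=float)
    ko_v = ko.to_numpy(dtype=float)
    log2fc = ko_v.mean(axis=1) - wt_v.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(ko_v, wt_v, axis=1,
                               equal_var=not config.welch)
    degenerate = (wt_v.std(axis=1) == 0) & (ko_v.std(axis=1) == 0)
    p = np.where(degenerate & (log2fc != 0), DEGENERATE_P, p)
    p = np.where(degenerate & (log2fc == 0), 1.0, p)
    p = np.nan_to_num(p, nan=1.0)

    p_eval = p
    if config.fdr:
        p_eval = _benjamini_hochberg(p)

    both = pd.concat([wt, ko], axis=1)
    ab = above_background(both, config).to_numpy()

    linear_fc = 2.0 ** np.abs(log2fc)
    passes = (linear_fc >= config.fc_cutoff) & (p_eval < config.alpha) & ab
    status = np.where(~passes, "ns", np.where(log2fc > 0, "up", "down"))

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "linear_fc": linear_fc,
            "p_value": p,
            "above_background": ab,
            "status": status,
        },
        index=wt.index,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def responsive_genes(de: pd.DataFrame) -> set[str]:
    return set(de.index[de["status"] != "ns"])


def direction_split(de: pd.DataFrame) -> dict[str, float]:
    """Fractions up / down among responsive genes (sum to 1)."""
    resp = de[de["status"] != "ns"]
    if resp.empty:
        raise ValueError("no responsive genes")
    n_up = int((resp["status"] == "up").sum())
    n_down = int((resp["status"] == "down").sum())
    total = n_up + n_down
    return {
        "n_up": n_up,
        "n_down": n_down,
        "fraction_up": n_up / total,
        "fraction_down": n_down / total,
    }
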