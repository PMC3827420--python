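"""Minimal local-Poisson peak caller.

Sliding windows of treatment tag counts are tested against a dynamic
local rate estimated from a control library: lambda is the maximum of
the genome-wide control rate and the control rate in several window
sizes centred on the test window, so local background biases raise the
bar locally.  The larger library is scaled down to the smaller one
before comparison.  Significant windows are merged into peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from tflink.core import GenomicInterval, Peak, TagLibrary


@dataclass
class PeakCallerConfig:
    window: int = 300
    step: int = 100
    local_lambda_windows: Sequence[int] = field(
        default_factory=lambda: (1000, 5000, 10000))
    pvalue_threshold: float = 1e-5
    merge_gap: int = 100

    def __post_init__(self) -> None:
        if self.window <= 0 or self.step <= 0:
            raise ValueError("window and step must be positive")
        if not (0 < self.pvalue_threshold < 1):
            raise ValueError("pvalue_threshold must lie in (0, 1)")


@dataclass
class CalledPeak:
    peak: Peak
    p_value: float
    lambda_local: float


def scale_libraries(treatment: TagLibrary, control: TagLibrary) -> float:
    """Scale factor min(totals)/max(totals), applied to the larger library.

    Returns 1.0 when totals are equal; raises on an empty library.
    """
    t, c = treatment.total_count, control.total_count
    if t == 0 or c == 0:
        raise ValueError("cannot scale an empty tag library")
    return min(t, c) / max(t, c)


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def _window_counts(positions: np.ndarray, starts: np.ndarray,
                   width: int) -> np.ndarray:
    """Tag counts in [start, start + width) for each start (vectorised)."""
    lo = np.searchsorted(positions, starts, side="left")
    hi = np.searchsorted(positions, starts + width, side="left")
    return hi - lo


def call_peaks(treatment: TagLibrary, control: TagLibrary,
               config: PeakCallerConfig | None = None,
               chrom_sizes: dict[str, int] | None = None,
               sample: str | None = None) -> list[CalledPeak]:
    """Call enriched regions of ``treatment`` over ``control``.

    Per window, lambda_local is the scale-adjusted maximum of the
    genome-wide control rate and the control rates in each configured
    local window centred on the test window; windows at p <= threshold
    are merged when separated by <= merge_gap.  The summit is placed at
    the densest treatment position within the peak.
    """
    config = config or PeakCallerConfig()
    chrom_sizes = chrom_sizes or treatment.chrom_sizes or control.chrom_sizes
    if chrom_sizes is None:
        raise ValueError("chromosome sizes required (none on either library)")
    scale_libraries(treatment, control)  # validates non-empty libraries
    t_total, c_total = treatment.total_count, control.total_count
    # put the control rate onto the treatment count scale
    control_to_treatment = min(1.0, t_total / c_total)
    treatment_scale = min(1.0, c_total / t_total)  # applied to observed k

    genome_len = sum(chrom_sizes.values())
    lambda_bg = (c_total / genome_len) * config.window * control_to_treatment

    called: list[CalledPeak] = []
    for chrom, size in sorted(chrom_sizes.items()):
        t_pos = treatment.positions.get(chrom, np.empty(0, dtype=np.int64))
        c_pos = control.positions.get(chrom, np.empty(0, dtype=np.int64))
        starts = np.arange(0, max(size - config.window, 0) + 1, config.step)
        if not len(starts):
            continue
        k = _window_counts(t_pos, starts, config.window)
        lam = np.full(len(starts), lambda_bg)
        centers = starts + config.window // 2
        for w in config.local_lambda_windows:
            local_starts = np.maximum(centers - w // 2, 0)
            c_counts = _window_counts(c_pos, local_starts, w)
            local_rate = (c_counts / w) * config.window * control_to_treatment
            lam = np.maximum(lam, local_rate)
        k_eff = np.floor(k * treatment_scale).astype(int)
        p = stats.poisson.sf(k_eff - 1, lam)
        p[k_eff == 0] = 1.0
        sig = np.flatnonzero(p <= config.pvalue_threshold)
        if not len(sig):
            continue
        # merge significant windows whose spans are within merge_gap
        runs: list[list[int]] = [[sig[0]]]
        for idx in sig[1:]:
            prev = runs[-1][-1]
            gap = starts[idx] - (starts[prev] + config.window)
            if gap <= config.merge_gap:
                runs[-1].append(idx)
            else:
                runs.append([idx])
        for run in runs:
            pk_start = int(starts[run[0]])
            pk_end = int(min(starts[run[-1]] + config.window, size))
            best = min(run, key=lambda i: p[i])
            inside = t_pos[(t_pos >= pk_start) & (t_pos < pk_end)]
            if len(inside):
                # densest position: mode of tag positions in 50 bp bins
                bins = np.arange(pk_start, pk_end + 50, 50)
                hist, edges = np.histogram(inside, bins=bins)
                summit = int(edges[int(np.argmax(hist))] + 25)
                summit = min(max(summit, pk_start), pk_end - 1)
            else:
                summit = (pk_start + pk_end) // 2
            score = -math.log10(max(p[best], 1e-300))
            peak = Peak(
                GenomicInterval(chrom, pk_start, pk_end),
                summit_offset=summit - pk_start,
                score=score,
                sample=sample,
            )
            called.append(CalledPeak(peak, float(p[best]),
                                     float(lam[best])))
    return called
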