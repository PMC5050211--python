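"""Event-level flow-cytometry analysis: background subtraction, biexponential
display scaling, ON/OFF gating and per-fraction summaries.

Event tables are plain DataFrames: one row per event, one column per channel,
plus optional ``fraction`` (pellicle / supernatant / surface), ``time_h`` and
``truth_label`` columns.  Values are signed — background subtraction leaves
negative values for dim events and they are deliberately retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import DegenerateHistogramError, otsu_thresholds

__all__ = [
    "GateResult",
    "subtract_background",
    "biex_transform",
    "biex_inverse",
    "gate_on_off",
    "summarize",
    "normalize_cv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GateResult:
    """An ON/OFF split of an event table on one channel.

    ``threshold`` lives on the transformed (biexponential) scale;
    ``fraction_on`` and ``fraction_off`` are percentages summing to exactly
    100.
    """

    threshold: float
    fraction_on: float
    fraction_off: float
    n_events: int


def subtract_background(
    events: pd.DataFrame, control: pd.DataFrame, channel: str
) -> pd.DataFrame:
    """Subtract the control population's median channel value from every event.

    The control is a non-fluorescent (or pre-induction) sample measured on
    the same channel; the median is robust to the control's own outliers.
    Negative results are retained, not clipped.
    """
    if channel not in events.columns or channel not in control.columns:
        raise KeyError(f"channel {channel!r} missing from events or control")
    if control.empty:
        raise ValueError("control table is empty")
    background = float(control[channel].median())
    out = events.copy()
    out[channel] = events[channel] - background
    return out


def biex_transform(values, cofactor: float = 150.0):
    """Biexponential display scaling: ``asinh(x / cofactor) / ln(10)``.

    Linear near zero (so negative background-subtracted values stay
    meaningful) and base-10 logarithmic at large magnitude; strictly
    increasing, odd, and invertible via :func:`biex_inverse`.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return np.arcsinh(np.asarray(values, dtype=np.float64) / cofactor) / np.log(10.0)


def biex_inverse(values, cofactor: float = 150.0):
    """Inverse of :func:`biex_transform`."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return np.sinh(np.asarray(values, dtype=np.float64) * np.log(10.0)) * cofactor


def gate_on_off(
    events: pd.DataFrame,
    channel: str,
    threshold: float | None = None,
    cofactor: float = 150.0,
    n_bins: int = 256,
) -> GateResult:
    """Split events into ON/OFF on the biexponential scale.

    ``threshold`` is given on the transformed scale; if omitted it is chosen
    automatically by 2-class Otsu on the transformed values.  Events exactly
    at the threshold count as OFF (conservative ON calls).
    """
    if events.empty:
        raise ValueError("empty event table")
    if channel not in events.columns:
        raise KeyError(f"channel {channel!r} missing from events")
    t = biex_transform(events[channel].to_numpy(), cofactor=cofactor)
    if threshold is None:
        counts, edges = np.histogram(t, bins=n_bins)
        try:
            threshold = otsu_thresholds(counts, edges, classes=2)
        except DegenerateHistogramError as exc:
            raise ValueError(
                "cannot auto-threshold a (near-)constant channel"
            ) from exc
    n = len(t)
    n_on = int((t > threshold).sum())
    frac_on = 100.0 * n_on / n
    return GateResult(
        threshold=float(threshold),
        fraction_on=frac_on,
        fraction_off=100.0 - frac_on,
        n_events=n,
    )


def summarize(
    events: pd.DataFrame,
    channel: str,
    by: list[str] | tuple[str, ...] = ("fraction", "time_h"),
) -> pd.DataFrame:
    """Per-group mean, SD and n of a channel on the untransformed scale.

    Group means are computed on raw (background-subtracted) values, never on
    the biexponential scale: the transform is concave at large values, so
    transforming first would bias skewed samples downward (Jensen).  Groups
    with no events are dropped with a logged warning.
    """
    if channel not in events.columns:
        raise KeyError(f"channel {channel!r} missing from events")
    by = [c for c in by if c in events.columns]
    if not by:
        return pd.DataFrame(
            {
                "mean": [events[channel].mean()],
                "sd": [events[channel].std(ddof=1)],
                "n": [len(events)],
            }
        )
    grouped = events.groupby(by, observed=True)[channel]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    empty = out["n"] == 0
    if empty.any():
        logger.warning("dropping %d empty groups from summary", int(empty.sum()))
        out = out[~empty]
    return out


def normalize_cv(od595: float, od600: float) -> float:
    """Crystal-violet biomass signal normalized by culture density (AU)."""
    if od600 <= 0:
        raise ValueError("OD600 must be positive")
    return od595 / od600
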