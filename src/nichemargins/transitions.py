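"""Classification of range pixels into marginality-change categories.

Each pixel of a species' current range is classified from its current
and future NMI, computed against the *frozen* current niche margin:

* currently marginal (NMI below the threshold) pixels become trailing
  (NMI decreases), leading (NMI increases) or stable edges;
* currently core pixels whose future NMI drops below the threshold are
  newly marginal;
* pixels whose future NMI falls to or below zero leave the niche
  entirely — a loss, which takes precedence over edge labels.

The default threshold is the absolute rule NMI < 0.25; a quantile rule
(the 25% most marginal pixels of the species' global current range) is
provided as an alternative.  In quantile mode the cut value is frozen
from the current period when classifying the future.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .nmi import NMIMap


class Category(IntEnum):
    """Per-pixel marginality-transition category (raster code table)."""

    CORE_STABLE = 1
    MARGINAL_TRAILING = 2
    MARGINAL_LEADING = 3
    MARGINAL_STABLE = 4
    NEWLY_MARGINAL = 5
    LOSS_FROM_MARGINAL = 6
    LOSS_FROM_CORE = 7


#: categories that indicate marginal conditions in the future period
FUTURE_MARGINAL = (Category.MARGINAL_TRAILING, Category.NEWLY_MARGINAL,
                   Category.MARGINAL_STABLE, Category.MARGINAL_LEADING)
LOSS = (Category.LOSS_FROM_MARGINAL, Category.LOSS_FROM_CORE)


@dataclass(frozen=True)
class ThresholdRule:
    """How the marginal/core cut is drawn on current-range NMI values."""

    mode: str = "absolute"  # "absolute" | "quantile"
    value: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.value < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.mode not in ("absolute", "quantile"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")

    def cut(self, current_nmi: np.ndarray) -> float:
        """The NMI value below which a pixel counts as marginal.

        In quantile mode the cut is the ``value``-quantile of the
        species' global current-range NMI, so exactly the most marginal
        fraction falls below it.
        """
        if self.mode == "absolute":
            return self.value
        finite = current_nmi[np.isfinite(current_nmi)]
        return float(np.quantile(finite, self.value))


@dataclass
class TransitionMap:
    """Per-pixel category and NMI change for one species and scenario."""

    species_id: str
    scenario_id: str
    pixel_ids: np.ndarray
    categories: np.ndarray  # Category codes, aligned with pixel_ids
    delta_nmi: np.ndarray
    cut_value: float

    def pixels_in(self, *categories: Category) -> np.ndarray:
        mask = np.isin(self.categories, [int(c) for c in categories])
        return self.pixel_ids[mask]

    def summary(self) -> pd.Series:
        names = {c.value: c.name.lower() for c in Category}
        counts = pd.Series(self.categories).map(names).value_counts()
        return counts.reindex([c.name.lower() for c in Category], fill_value=0)


def classify_marginality(nmi: NMIMap, rule: ThresholdRule) -> np.ndarray:
    """Boolean mask (aligned with nmi.pixel_ids): True = marginal.

    A pixel is marginal when its NMI lies below the rule's cut (pixels
    at or below zero — outside the margin — are included).  Warns when
    the classification is degenerate (all or none marginal).
    """
    cut = rule.cut(nmi.nmi)
    finite = np.isfinite(nmi.nmi)
    marginal = finite & (nmi.nmi < cut)
    frac = marginal.sum() / max(finite.sum(), 1)
    if frac in (0.0, 1.0):
        warnings.warn(
            f"species {nmi.species_id}: degenerate marginality "
            f"classification (marginal fraction {frac:.0%})", RuntimeWarning)
    return marginal


def classify_transitions(
    nmi_now: NMIMap,
    nmi_future: NMIMap,
    rule: ThresholdRule = ThresholdRule(),
) -> TransitionMap:
    """Assign every current-range pixel one transition category.

    Both maps must cover the same pixels; the future NMI must have been
    computed against the current-period niche model (frozen margins).
    """
    if (len(nmi_now.pixel_ids) != len(nmi_future.pixel_ids)
            or not np.array_equal(nmi_now.pixel_ids, nmi_future.pixel_ids)):
        now_only = np.setdiff1d(nmi_now.pixel_ids, nmi_future.pixel_ids)
        fut_only = np.setdiff1d(nmi_future.pixel_ids, nmi_now.pixel_ids)
        raise ValueError(
            "pixel sets differ between periods: "
            f"{len(now_only)} current-only, {len(fut_only)} future-only")

    now = nmi_now.nmi
    fut = nmi_future.nmi
    delta = fut - now
    cut = rule.cut(now)

    cats = np.zeros(len(now), dtype=int)
    finite = np.isfinite(now) & np.isfinite(fut)
    marg_now = now < cut
    lost = fut <= 0.0

    cats[finite & lost & marg_now] = Category.LOSS_FROM_MARGINAL
    cats[finite & lost & ~marg_now] = Category.LOSS_FROM_CORE
    alive = finite & ~lost
    cats[alive & marg_now & (delta < 0)] = Category.MARGINAL_TRAILING
    cats[alive & marg_now & (delta > 0)] = Category.MARGINAL_LEADING
    cats[alive & marg_now & (delta == 0)] = Category.MARGINAL_STABLE
    newly = alive & ~marg_now & (fut < cut)
    cats[newly] = Category.NEWLY_MARGINAL
    cats[alive & ~marg_now & ~(fut < cut)] = Category.CORE_STABLE

    return TransitionMap(
        species_id=nmi_now.species_id,
        scenario_id=nmi_future.period,
        pixel_ids=nmi_now.pixel_ids,
        categories=cats,
        delta_nmi=delta,
        cut_value=cut,
    )
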