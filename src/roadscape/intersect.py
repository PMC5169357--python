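"""Bivariate benefit-cost intersection and sensitivity machinery.

The planning overlay classifies each cell jointly on the benefit and
cost axes (a dual-colour / bivariate choropleth scheme). Quadrant labels
at the 0.5 median split are a summary convenience over the continuous
two-axis gradient, not a claim about published category boundaries.

Sensitivity analyses swap one layer or rule at a time; the effect is the
per-cell difference (new - original) of the affected aggregate surface,
bounded in [-1, 1], and summarised by the fraction of cells whose score
changed by more than a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .grid import Grid, Surface, check_rescaled, check_same_grid

QUADRANTS = ("high-benefit/low-cost", "low-benefit/low-cost",
             "low-benefit/high-cost", "high-benefit/high-cost")


@dataclass
class BivariateClassified:
    """Joint benefit/cost classification of a grid.

    ``benefit_bin`` / ``cost_bin`` hold integer bins 0..n_bins-1
    (-1 at NoData cells); ``quadrant`` holds indices into
    :data:`QUADRANTS` (-1 at NoData), using a 0.5/0.5 split.
    """

    grid: Grid
    benefit_bin: np.ndarray
    cost_bin: np.ndarray
    n_bins: int
    quadrant: np.ndarray

    def quadrant_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.quadrant == i))
                for i, name in enumerate(QUADRANTS)}

    def bin_counts(self) -> np.ndarray:
        """(n_bins, n_bins) matrix of cell counts, benefit x cost."""
        counts = np.zeros((self.n_bins, self.n_bins), dtype=int)
        ok = self.benefit_bin >= 0
        np.add.at(counts, (self.benefit_bin[ok], self.cost_bin[ok]), 1)
        return counts


@dataclass
class DifferenceMap:
    """Per-cell (new - original) score change for one sensitivity test."""

    grid: Grid
    delta: np.ndarray
    label: str


def bivariate_classify(benefit: Surface, cost: Surface,
                       n_bins: int = 10) -> BivariateClassified:
    """Classify cells jointly on the two 0-1 surfaces.

    Bin = floor(value * n_bins), clamped so a value of exactly 1.0 falls
    in the top bin. Quadrants split both axes at 0.5 (>= 0.5 is "high").
    """
    grid = check_same_grid(benefit, cost)
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    check_rescaled(benefit, "benefit")
    check_rescaled(cost, "cost")

    def _bins(surface: Surface) -> np.ndarray:
        b = np.full(grid.shape, -1, dtype=int)
        m = surface.defined_mask
        b[m] = np.minimum((surface.values[m] * n_bins).astype(int), n_bins - 1)
        return b

    bbin, cbin = _bins(benefit), _bins(cost)
    quad = np.full(grid.shape, -1, dtype=int)
    m = benefit.defined_mask & cost.defined_mask
    hb = benefit.values >= 0.5
    hc = cost.values >= 0.5
    quad[m & hb & ~hc] = 0
    quad[m & ~hb & ~hc] = 1
    quad[m & ~hb & hc] = 2
    quad[m & hb & hc] = 3
    return BivariateClassified(grid, bbin, cbin, n_bins, quad)


def difference_map(new: Surface, original: Surface, label: str = "") -> DifferenceMap:
    """Sensitivity difference: new minus original aggregate score.

    Both inputs are on the 0-1 scale, so deltas lie in [-1, 1] by
    construction.
    """
    grid = check_same_grid(new, original)
    check_rescaled(new, "new surface")
    check_rescaled(original, "original surface")
    return DifferenceMap(grid, new.values - original.values, label)


def changed_fraction(diff: DifferenceMap, threshold: float = 0.2) -> float:
    """Fraction of defined cells whose score changed by more than the
    threshold (strictly: |delta| > threshold)."""
    if not 0 < threshold < 1:
        raise ValidationError("threshold must be in (0, 1)")
    defined = np.isfinite(diff.delta) & diff.grid.valid_mask
    n = int(defined.sum())
    if n == 0:
        raise ValidationError("difference map has no defined cells")
    return float(np.sum(np.abs(diff.delta[defined]) > threshold) / n)
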