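"""Minimal plotting helpers: a default bivariate palette and map plots.

The bivariate palette blends a benefit hue (blue) against a cost hue
(red): dark cells are high on both axes (potential conflict), light
cells low on both. matplotlib is imported lazily so headless pipeline
runs never touch a display backend.
"""

from __future__ import annotations

import numpy as np

from .intersect import BivariateClassified


def bivariate_palette(n_bins: int = 10) -> np.ndarray:
    """(n_bins, n_bins, 3) RGB palette indexed [benefit_bin, cost_bin]."""
    b = (np.arange(n_bins) + 0.5) / n_bins
    c = (np.arange(n_bins) + 0.5) / n_bins
    bb, cc = np.meshgrid(b, c, indexing="ij")
    rgb = np.empty((n_bins, n_bins, 3))
    rgb[..., 0] = 1 - bb          # red channel falls with benefit
    rgb[..., 2] = 1 - cc          # blue channel falls with cost
    rgb[..., 1] = 1 - 0.5 * (bb + cc)
    return np.clip(rgb, 0, 1)


def plot_bivariate(classified: BivariateClassified, ax=None):
    """Render the dual-axis classification as an RGB image."""
    import matplotlib.pyplot as plt

    pal = bivariate_palette(classified.n_bins)
    img = np.ones(classified.grid.shape + (3,))
    ok = classified.benefit_bin >= 0
    img[ok] = pal[classified.benefit_bin[ok], classified.cost_bin[ok]]
    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(img, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def plot_surface(surface, ax=None, cmap="viridis"):
    """Quicklook map of one surface."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(surface.values, interpolation="nearest", cmap=cmap)
    plt.colorbar(im, ax=ax, label=surface.units)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
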