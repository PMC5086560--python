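"""Kernel-density mode/valley detection shared by the read-count noise
cutoff and the log2 fold-change essentiality cutoff."""

from __future__ import annotations

import numpy as np
from scipy.stats import gaussian_kde


def kde_profile(values, weights=None, gridsize: int = 512, pad: float = 0.5):
    """Gaussian KDE (Silverman bandwidth) evaluated on a regular grid.

    Returns (grid, density, maxima_idx, minima_idx).  Grid endpoints count as
    modes/valleys when the density is monotone into them, so boundary modes
    are not lost.
    """
    values = np.asarray(values, dtype=float)
    kde = gaussian_kde(values, bw_method="silverman", weights=weights)
    grid = np.linspace(values.min() - pad, values.max() + pad, gridsize)
    dens = kde(grid)
    sign = np.sign(np.diff(dens))
    # collapse exact plateaus so sign changes are detectable
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    maxima, minima = [], []
    if sign[0] < 0:
        maxima.append(0)
    for i in range(1, len(sign)):
        if sign[i - 1] > 0 and sign[i] < 0:
            maxima.append(i)
        elif sign[i - 1] < 0 and sign[i] > 0:
            minima.append(i)
    if sign[-1] > 0:
        maxima.append(len(grid) - 1)
    return grid, dens, np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def first_valley_between(grid, minima, left_idx, right_idx):
    """Index of the first local density minimum strictly between two modes,
    or None."""
    between = minima[(minima > left_idx) & (minima < right_idx)]
    return int(between[0]) if len(between) else None
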