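"""Octave-band bookkeeping for granularity-spectrum analysis.

Spatial frequency is measured radially in cycles/pixel.  The spectrum is
partitioned into ``n_bands`` octave-spaced bands indexed coarse-to-fine:
band ``n_bands-1`` (finest) covers (0.25, Nyquist] and everything above the
nominal Nyquist radius at the grid corners; each coarser band halves the
upper edge; band 0 (coarsest) additionally absorbs all remaining low
frequencies down to (but excluding) DC.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft

NYQUIST = 0.5


def octave_band_edges(n_bands: int) -> np.ndarray:
    """Interior upper edges separating the ``n_bands`` octave bands.

    Returns ``n_bands - 1`` increasing thresholds; a radial frequency f is in
    band b iff ``edges[b-1] < f <= edges[b]`` (with open ends at 0 and inf).
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    return NYQUIST / 2.0 ** np.arange(n_bands - 1, 0, -1)


def radial_frequency_grid(shape: tuple[int, int]) -> np.ndarray:
    """Radial frequency (cycles/pixel) of each cell of a 2-D FFT grid."""
    fy = sp_fft.fftfreq(shape[0])[:, None]
    fx = sp_fft.fftfreq(shape[1])[None, :]
    return np.hypot(fy, fx)


def band_index_grid(shape: tuple[int, int], n_bands: int) -> np.ndarray:
    """Octave-band index (0 = coarsest) of each FFT cell; DC marked -1."""
    f = radial_frequency_grid(shape)
    bands = np.digitize(f, octave_band_edges(n_bands))
    bands[f == 0.0] = -1
    return bands


def band_energy_fractions(power: np.ndarray, bands: np.ndarray, n_bands: int) -> np.ndarray:
    """Fraction of total spectral power in each octave band (DC excluded)."""
    mask = bands >= 0
    totals = np.bincount(bands[mask].ravel(), weights=power[mask].ravel(), minlength=n_bands)
    s = totals.sum()
    if s <= 0:
        raise ZeroDivisionError("zero total spectral energy")
    return totals / s
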