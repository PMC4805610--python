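"""Named BOLD frequency bands and DFT-bin selection for the ideal band-pass.

The BOLD spectrum up to 0.25 Hz (the Nyquist frequency at TR = 2 s) is
partitioned into the conventional slow bands:

====== ================
name   interval (Hz)
====== ================
slow-6 0      - 0.01
slow-5 0.01   - 0.027
slow-4 0.027  - 0.073
slow-3 0.073  - 0.198
slow-2 0.198  - 0.25
====== ================

Adjacent bands share only the printed edge. The shared DFT bin, when one falls
exactly on an edge, is assigned to the *lower* band (a bin is kept iff
``f_low < f <= f_high``), so the named bands tile (0, Nyquist] without overlap
and a band-limited decomposition conserves variance bin-by-bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: absolute tolerance (Hz) used when comparing DFT bin frequencies to band edges
EDGE_TOL_HZ = 1e-9


@dataclass(frozen=True)
class BandSpec:
    """A named frequency interval controlling the ideal band-pass filter."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 <= f_low < f_high, got ({self.f_low}, {self.f_high})"
            )

    @property
    def width_hz(self) -> float:
        return self.f_high - self.f_low


NAMED_BANDS = {
    "slow-6": BandSpec("slow-6", 0.0, 0.01),
    "slow-5": BandSpec("slow-5", 0.01, 0.027),
    "slow-4": BandSpec("slow-4", 0.027, 0.073),
    "slow-3": BandSpec("slow-3", 0.073, 0.198),
    "slow-2": BandSpec("slow-2", 0.198, 0.25),
}

#: bands analyzed by default; slow-6 mostly reflects very-low-frequency drift
#: and is excluded unless requested explicitly.
DEFAULT_ANALYSIS_BANDS = ("slow-5", "slow-4", "slow-3", "slow-2")


def get_band(band) -> BandSpec:
    """Resolve a band name or pass a BandSpec through."""
    if isinstance(band, BandSpec):
        return band
    try:
        return NAMED_BANDS[band]
    except KeyError:
        raise KeyError(f"unknown band {band!r}; known: {sorted(NAMED_BANDS)}") from None


def band_bin_keep(n_volumes: int, tr_s: float, band: BandSpec) -> np.ndarray:
    """Boolean keep-mask over the rfft bins of an ``n_volumes``-point series.

    A bin at frequency f is kept iff ``f_low < f <= f_high`` (within
    :data:`EDGE_TOL_HZ`); the DC bin is never kept.
    """
    freqs = np.fft.rfftfreq(n_volumes, d=tr_s)
    return (freqs > band.f_low + EDGE_TOL_HZ) & (freqs <= band.f_high + EDGE_TOL_HZ)
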