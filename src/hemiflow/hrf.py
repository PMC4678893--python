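"""Hemodynamic response function (HRF) kernels.

The canonical double-gamma form: a positive gamma density peaking at
``peak_delay_s`` minus a scaled gamma density modelling the late
undershoot.  Regional HRF latency differences, which confound
lag-based causality on raw BOLD, are expressed by shifting the peak
delay (see :meth:`HRFSpec.with_latency_offset`).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HRFSpec:
    """Parameters of a double-gamma HRF kernel (all times in seconds)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_duration_s: float = 32.0

    def __post_init__(self):
        if self.peak_delay_s <= 0 or self.kernel_duration_s <= 0:
            raise ValueError("peak delay and kernel duration must be positive")
        if not 0 <= self.undershoot_ratio < 1:
            raise ValueError("undershoot ratio must lie in [0, 1)")

    def sample(self, dt_s: float, normalize: str = "peak") -> np.ndarray:
        """Sample the kernel on a grid of spacing ``dt_s``.

        normalize: ``"peak"`` scales the maximum to 1, ``"none"`` leaves
        the raw gamma-difference values.
        """
        if dt_s <= 0:
            raise ValueError("dt must be positive")
        t = np.arange(0.0, self.kernel_duration_s, dt_s)
        h = self._eval(t)
        if normalize == "peak":
            m = np.max(np.abs(h))
            if m > 0:
                h = h / m
        elif normalize != "none":
            raise ValueError(f"unknown normalize mode {normalize!r}")
        return h

    def _eval(self, t: np.ndarray) -> np.ndarray:
        # shape a = delay/dispersion + 1 puts the gamma mode at `delay`
        a1 = self.peak_delay_s / self.peak_dispersion_s + 1.0
        a2 = self.undershoot_delay_s / self.undershoot_dispersion_s + 1.0
        g1 = stats.gamma.pdf(t, a1, scale=self.peak_dispersion_s)
        g2 = stats.gamma.pdf(t, a2, scale=self.undershoot_dispersion_s)
        return g1 - self.undershoot_ratio * g2

    @property
    def time_to_peak_s(self) -> float:
        """Latency of the kernel maximum, from a fine (10 ms) grid."""
        t = np.arange(0.0, self.kernel_duration_s, 0.01)
        return float(t[np.argmax(self._eval(t))])

    def with_latency_offset(self, offset_s: float) -> "HRFSpec":
        """Return a copy whose response is delayed by ``offset_s`` seconds."""
        return replace(
            self,
            peak_delay_s=self.peak_delay_s + offset_s,
            undershoot_delay_s=self.undershoot_delay_s + offset_s,
        )


CANONICAL = HRFSpec()
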