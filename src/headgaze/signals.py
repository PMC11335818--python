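"""Timestamped scalar signals with validity flags."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SampledSignal"]


@dataclass
class SampledSignal:
    """A possibly irregularly sampled scalar channel.

    ``timestamps`` must be strictly increasing; ``values`` may contain NaN
    only where ``valid`` is False.
    """

    timestamps: np.ndarray
    values: np.ndarray
    valid: np.ndarray = None

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.timestamps.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.timestamps) == len(self.values) == len(self.valid)):
            raise ValueError("timestamps, values and valid must have equal length")
        if len(self.timestamps) >= 2 and np.any(np.diff(self.timestamps) <= 0):
            bad = int(np.flatnonzero(np.diff(self.timestamps) <= 0)[0]) + 1
            raise ValueError(f"timestamps not strictly increasing at index {bad}")
        if np.any(~np.isfinite(self.values[self.valid])):
            raise ValueError("non-finite value among valid samples")

    def __len__(self) -> int:
        return len(self.timestamps)

    def shifted(self, offset: float) -> "SampledSignal":
        """Return a copy with ``offset`` subtracted from every timestamp."""
        return SampledSignal(self.timestamps - offset, self.values.copy(),
                             self.valid.copy())

    def slice_time(self, t0: float, t1: float) -> "SampledSignal":
        m = (self.timestamps >= t0) & (self.timestamps <= t1)
        return SampledSignal(self.timestamps[m], self.values[m], self.valid[m])
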