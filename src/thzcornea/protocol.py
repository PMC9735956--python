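"""Intraocular-pressure protocol for a scan session.

Default schedule: 1 h acclimation at 15 mmHg, 4 h at an elevated IOP
(25, 35 or 45 mmHg), then 4 h back at 15 mmHg, with one 9x9 scan every
4 min (136 frames over 540 min, including t = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ProtocolSpec"]


@dataclass(frozen=True)
class ProtocolSpec:
    acclimation_min: float = 60.0
    elevated_min: float = 240.0
    recovery_min: float = 240.0
    baseline_iop_mmhg: float = 15.0
    elevated_iop_mmhg: float = 35.0
    frame_interval_min: float = 4.0

    def __post_init__(self) -> None:
        for name in ("acclimation_min", "elevated_min", "recovery_min", "frame_interval_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        rem = self.total_min % self.frame_interval_min
        if min(rem, self.frame_interval_min - rem) > 1e-9:
            raise ValueError("frame interval must divide the total duration evenly")

    @property
    def total_min(self) -> float:
        return self.acclimation_min + self.elevated_min + self.recovery_min

    @property
    def n_frames(self) -> int:
        return int(round(self.total_min / self.frame_interval_min)) + 1

    def frame_times(self) -> np.ndarray:
        """Scan times in minutes, t = 0 through the end of recovery."""
        return np.arange(self.n_frames) * self.frame_interval_min

    def iop_at(self, t_min: float) -> float:
        """IOP in mmHg at time t.

        The pressure step at the end of a period takes effect after the
        scan scheduled at that instant, so frames at exact period
        boundaries belong to the period they conclude.
        """
        if t_min < 0 or t_min > self.total_min:
            raise ValueError(f"time {t_min} outside the protocol")
        if t_min <= self.acclimation_min:
            return self.baseline_iop_mmhg
        if t_min <= self.acclimation_min + self.elevated_min:
            return self.elevated_iop_mmhg
        return self.baseline_iop_mmhg

    def with_elevated_iop(self, iop_mmhg: float) -> "ProtocolSpec":
        return replace(self, elevated_iop_mmhg=iop_mmhg)
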