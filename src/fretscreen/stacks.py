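"""Time-lapse stacks and the imaging timebase.

A well is imaged as a short multi-channel time-lapse: a far-red nuclear
channel (DRAQ5-like), a FRET donor channel (CFP-like) and a FRET acceptor
channel (YFP-like).  The agonist is injected by a dispensing unit part-way
through the sequence; frames before the dispense define the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical channel order used throughout the package.
CHANNELS = ("nuclear", "donor", "acceptor")


@dataclass(frozen=True)
class Timebase:
    """Frame times (seconds) and the agonist dispense position.

    ``times`` must be strictly increasing; ``dispense_index`` is the index
    of the first post-dispense frame, so frames ``0 .. dispense_index-1``
    are the pre-agonist baseline.
    """

    times: np.ndarray
    dispense_index: int

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1 or len(times) < 2:
            raise ValueError("timebase needs at least two frame times")
        if not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not (1 <= self.dispense_index < len(times)):
            raise ValueError(
                f"dispense_index {self.dispense_index} outside 1..{len(times) - 1}"
            )

    @property
    def n_pre(self) -> int:
        """Number of pre-dispense (baseline) frames."""
        return self.dispense_index

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def dispense_time(self) -> float:
        """Moment of agonist injection: midway between the last baseline
        frame and the first post-dispense frame."""
        return 0.5 * (
            float(self.times[self.dispense_index - 1])
            + float(self.times[self.dispense_index])
        )


def default_timebase() -> Timebase:
    """The canonical 13-frame protocol.

    Baseline is sampled for 5 s at 2.5 s resolution (t = 0, 2.5, 5 s); the
    agonist is dispensed immediately afterwards; the evoked transient is
    then followed for 5 s at 1 s resolution and for a further 12.5 s at
    2.5 s resolution, giving a 23.5 s protocol per well.
    """
    times = np.concatenate(
        [
            np.array([0.0, 2.5, 5.0]),
            5.0 + np.arange(1, 6) * 1.0,          # 6..10 s
            10.0 + np.arange(1, 6) * 2.5,         # 12.5..22.5 s
        ]
    )
    return Timebase(times=times, dispense_index=3)


@dataclass
class TimeLapseStack:
    """Per-well image sequence, axis order time x channel x y x x."""

    frames: np.ndarray
    timebase: Timebase
    well_id: str = ""
    channels: tuple = field(default=CHANNELS)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 4:
            raise ValueError("frames must be 4-D (time, channel, y, x)")
        if frames.shape[0] != self.timebase.n_frames:
            raise ValueError(
                f"frame count {frames.shape[0]} != timebase length "
                f"{self.timebase.n_frames}"
            )
        if frames.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        if np.any(frames < 0):
            raise ValueError("intensities must be non-negative")
        self.frames = frames

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"stack has no channel named {name!r}") from None

    def channel(self, name: str) -> np.ndarray:
        """All frames of one named channel, shape (time, y, x)."""
        return self.frames[:, self.channel_index(name)]

    @property
    def field_shape(self) -> tuple:
        return self.frames.shape[2:]
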