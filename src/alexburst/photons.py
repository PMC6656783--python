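"""Photon-stream container for microsecond alternating-laser-excitation (us-ALEX)
confocal measurements.

A measurement is a time-ordered sequence of detected photons. Each photon
carries an integer timestamp (microseconds), a detection channel (donor or
acceptor emission), and an excitation label derived from the timestamp: the
two lasers alternate every ``alternation_period_us`` microseconds, so the
excitation phase is a pure function of ``timestamp mod 2*period``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: channel codes
DONOR = 0
ACCEPTOR = 1
#: excitation codes
DEX = 0
AEX = 1

CHANNEL_LABELS = {DONOR: "D", ACCEPTOR: "A"}
EXCITATION_LABELS = {DEX: "Dex", AEX: "Aex"}


@dataclass
class PhotonStream:
    """Time-ordered photon records from a us-ALEX measurement.

    Parameters
    ----------
    timestamps_us : array of int64
        Photon arrival times in microseconds, non-decreasing.
    channel : array of uint8
        Detection channel per photon, ``DONOR`` (0) or ``ACCEPTOR`` (1).
    alternation_period_us : int
        Duration of one excitation half-period. Timestamps with
        ``t mod 2*period < period`` fall in the donor-excitation (Dex)
        phase, the rest in the acceptor-excitation (Aex) phase.
    """

    timestamps_us: np.ndarray
    channel: np.ndarray
    alternation_period_us: int = 50
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.timestamps_us = np.ascontiguousarray(self.timestamps_us, dtype=np.int64)
        self.channel = np.ascontiguousarray(self.channel, dtype=np.uint8)
        if self.timestamps_us.shape != self.channel.shape:
            raise ValueError("timestamps and channel must have the same length")
        if self.alternation_period_us <= 0:
            raise ValueError("alternation_period_us must be positive")
        if self.timestamps_us.size and np.any(np.diff(self.timestamps_us) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if self.channel.size and self.channel.max() > ACCEPTOR:
            raise ValueError("channel codes must be 0 (donor) or 1 (acceptor)")

    def __len__(self) -> int:
        return int(self.timestamps_us.size)

    @property
    def excitation(self) -> np.ndarray:
        """Excitation phase per photon (0 = Dex, 1 = Aex), derived from time."""
        full = 2 * self.alternation_period_us
        return (
            (self.timestamps_us % full) >= self.alternation_period_us
        ).astype(np.uint8)

    @property
    def duration_us(self) -> int:
        if len(self) == 0:
            return 0
        return int(self.timestamps_us[-1] - self.timestamps_us[0])

    def shifted(self, offset_us: int) -> "PhotonStream":
        """Return a copy translated in time by a multiple of the full
        alternation cycle (preserves excitation labels)."""
        return PhotonStream(
            self.timestamps_us + np.int64(offset_us),
            self.channel.copy(),
            self.alternation_period_us,
            dict(self.meta),
        )


def merge_streams(a: PhotonStream, b: PhotonStream) -> PhotonStream:
    """Merge two streams with identical alternation period, re-sorting by time."""
    if a.alternation_period_us != b.alternation_period_us:
        raise ValueError("alternation periods differ")
    ts = np.concatenate([a.timestamps_us, b.timestamps_us])
    ch = np.concatenate([a.channel, b.channel])
    order = np.argsort(ts, kind="stable")
    return PhotonStream(ts[order], ch[order], a.alternation_period_us, dict(a.meta))
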