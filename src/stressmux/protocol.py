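"""Trial protocol: ordered epochs tiling a fixed-duration session.

The default protocol is a 195-s trial split into four contiguous epochs:
baseline (40 s), prep (25 s), immersion (90 s) and recovery (40 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ProtocolDefinition:
    """Contiguous, non-overlapping epochs covering ``[0, total_duration)``.

    Parameters
    ----------
    epochs
        Ordered mapping of epoch name to half-open ``(start, stop)`` interval
        in seconds.
    """

    epochs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "baseline": (0.0, 40.0),
            "prep": (40.0, 65.0),
            "immersion": (65.0, 155.0),
            "recovery": (155.0, 195.0),
        }
    )

    def __post_init__(self) -> None:
        prev_stop = 0.0
        for name, (start, stop) in self.epochs.items():
            if start != prev_stop:
                raise ValueError(
                    f"epoch {name!r} starts at {start}, expected {prev_stop} "
                    "(epochs must be contiguous from 0)"
                )
            if stop <= start:
                raise ValueError(f"epoch {name!r} has non-positive duration")
            prev_stop = stop

    @property
    def total_duration(self) -> float:
        return max(stop for _, stop in self.epochs.values())

    @property
    def n_seconds(self) -> int:
        """Number of 1-Hz grid points (integer seconds 0 .. duration-1)."""
        return int(round(self.total_duration))

    def epoch_interval(self, name: str) -> tuple[float, float]:
        return self.epochs[name]

    def epoch_slice(self, name: str) -> slice:
        """Integer-second slice of the 1-Hz grid covered by an epoch."""
        start, stop = self.epochs[name]
        return slice(int(round(start)), int(round(stop)))

    def epoch_of(self, t: float) -> str:
        for name, (start, stop) in self.epochs.items():
            if start <= t < stop:
                return name
        raise ValueError(f"time {t} outside protocol [0, {self.total_duration})")


def make_default_protocol() -> ProtocolDefinition:
    """Return the standard four-epoch 195-s trial protocol."""
    return ProtocolDefinition()


def make_protocol(durations: dict[str, float]) -> ProtocolDefinition:
    """Build a protocol from ordered epoch durations."""
    epochs: dict[str, tuple[float, float]] = {}
    t = 0.0
    for name, dur in durations.items():
        epochs[name] = (t, t + dur)
        t += dur
    return ProtocolDefinition(epochs=epochs)
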