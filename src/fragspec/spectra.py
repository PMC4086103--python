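"""Core spectrum containers shared by prediction, annotation and scoring."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Collision-energy levels and their nominal voltages.
ENERGY_LEVELS: tuple[str, ...] = ("low", "medium", "high")
ENERGY_VOLTS: dict[str, int] = {"low": 10, "medium": 20, "high": 40}
#: Peak-list block headers, in energy order.
ENERGY_HEADERS: dict[str, str] = {"low": "energy0", "medium": "energy1", "high": "energy2"}
HEADER_TO_ENERGY: dict[str, str] = {v: k for k, v in ENERGY_HEADERS.items()}


@dataclass
class Peak:
    """One peak: m/z (Da), relative intensity (base peak = 100) and an
    ordered list of (fragment id, explained-intensity score) annotations."""

    mz: float
    intensity: float
    annotations: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class Spectrum:
    """A peak list at one collision energy, sorted by ascending m/z."""

    energy_level: str
    peaks: list[Peak]

    def __post_init__(self) -> None:
        if self.energy_level not in ENERGY_LEVELS:
            raise ValueError(f"unknown energy level {self.energy_level!r}")
        self.peaks.sort(key=lambda p: p.mz)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    def base_normalized(self) -> "Spectrum":
        """Copy rescaled so the largest peak has intensity 100."""
        top = max((p.intensity for p in self.peaks), default=0.0)
        scale = 100.0 / top if top > 0 else 1.0
        return Spectrum(
            self.energy_level,
            [Peak(p.mz, p.intensity * scale, list(p.annotations)) for p in self.peaks],
        )
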