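"""Mass-tolerance arithmetic used by peak matching everywhere.

A match requires ``|dm| <= max(abs_da, ppm * mz * 1e-6)``: the absolute
floor dominates at low mass, the relative term at high mass, mirroring
Q-TOF-like accuracy. Defaults are 0.01 Da and 10 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_ABS_DA = 0.01
DEFAULT_PPM = 10.0


@dataclass(frozen=True)
class MassTolerance:
    abs_da: float = DEFAULT_ABS_DA
    ppm: float = DEFAULT_PPM

    def __post_init__(self) -> None:
        if self.abs_da < 0 or self.ppm < 0:
            raise ValueError("tolerances must be non-negative")
        if self.abs_da == 0 and self.ppm == 0:
            raise ValueError("at least one of abs_da / ppm must be positive")

    def window(self, mz: float) -> float:
        """Half-width of the acceptance window at a given m/z."""
        return max(self.abs_da, self.ppm * mz * 1e-6)

    def matches(self, observed_mz: float, reference_mz: float) -> bool:
        return abs(observed_mz - reference_mz) <= self.window(reference_mz)
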