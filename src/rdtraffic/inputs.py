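"""Ligand input programs Q_L(t) for the extracellular medium.

Three modes:

* ``bolus`` — a single instantaneous dose applied as an initial condition;
  the source term is identically zero for t > 0.
* ``constant`` — ligand enters at a fixed volumetric rate (nM/s).
* ``pulses`` — a train of rectangular inputs, each with a start time and a
  duration, all at the same rate; e.g. two 10 s inputs at 1 nM/s separated
  by a 40 s recovery phase.

The rate is volumetrically uniform over the extracellular domain.  Pulse
edges are reported as breakpoints so the stiff integrator can be restarted
there instead of smearing the discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["LigandInputProgram", "input_rate", "cumulative_input"]

_MODES = ("bolus", "constant", "pulses")


@dataclass(frozen=True)
class LigandInputProgram:
    """A piecewise-constant ligand source definition."""

    mode: str = "bolus"
    bolus_conc: float = 0.0                     # nM, mode="bolus"
    rate: float = 0.0                           # nM/s, modes "constant"/"pulses"
    pulses: tuple[tuple[float, float], ...] = ()  # (start s, duration s)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.bolus_conc < 0:
            raise ValueError("bolus_conc must be >= 0")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        pulses = tuple((float(s), float(d)) for s, d in self.pulses)
        object.__setattr__(self, "pulses", pulses)
        prev_end = -np.inf
        for start, duration in pulses:
            if start < 0 or duration <= 0:
                raise ValueError(
                    f"pulse windows need start >= 0 and duration > 0, "
                    f"got ({start}, {duration})"
                )
            if start < prev_end:
                raise ValueError("pulse windows must be sorted and disjoint")
            prev_end = start + duration

    @classmethod
    def bolus(cls, conc: float) -> "LigandInputProgram":
        return cls(mode="bolus", bolus_conc=conc)

    @classmethod
    def constant(cls, rate: float) -> "LigandInputProgram":
        return cls(mode="constant", rate=rate)

    @classmethod
    def pulse_train(
        cls, rate: float, pulses: Sequence[tuple[float, float]]
    ) -> "LigandInputProgram":
        return cls(mode="pulses", rate=rate, pulses=tuple(pulses))

    def breakpoints(self) -> np.ndarray:
        """Times where the source rate is discontinuous (sorted, unique)."""
        if self.mode != "pulses":
            return np.array([])
        edges = []
        for start, duration in self.pulses:
            edges.extend((start, start + duration))
        return np.unique(edges)


def input_rate(program: LigandInputProgram, t: float) -> float:
    """Source rate Q_L(t) in nM/s at time ``t`` (s)."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if program.mode == "bolus":
        return 0.0
    if program.mode == "constant":
        return program.rate
    for start, duration in program.pulses:
        if start <= t < start + duration:
            return program.rate
    return 0.0


def cumulative_input(program: LigandInputProgram, t: float) -> float:
    """Time integral of the source rate up to ``t`` (nM); exact for
    piecewise-constant programs.  A bolus contributes nothing: it is an
    initial condition, not a source."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if program.mode == "bolus":
        return 0.0
    if program.mode == "constant":
        return program.rate * t
    total = 0.0
    for start, duration in program.pulses:
        total += program.rate * max(0.0, min(t, start + duration) - start)
    return total
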