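"""Physical constants and unit conventions.

Units used throughout the package:

* gradients in mT/m, RF envelopes in μT, time in seconds;
* excitation k-space in rad/m, with the gyromagnetic ratio γ in
  rad·s⁻¹·T⁻¹ — so phase terms are literally ``exp(i k·r)`` with
  positions in metres and a single γ convention everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Gyromagnetic ratio of ¹H in rad·s⁻¹·T⁻¹.
GAMMA_1H = 2.675221e8

#: Default waveform sample interval (dwell time) in seconds.
DEFAULT_DWELL = 6.4e-6


@dataclass(frozen=True)
class PhysicsConstants:
    """Nucleus-dependent constants entering the excitation equations."""

    gamma: float = GAMMA_1H

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
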