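"""Time-varying drug action on β-TrCP.

A drug can act on β-TrCP's abundance or on its IκB-binding efficiency.
Because β-TrCP enters the model only as the multiplicative factor
(β-TrCP / 1 nM) on the two IKK-dependent IκB degradation reactions, both
modes with the same kinetic profile produce the identical effective
scaling and hence bit-identical model inputs — the abundance/binding-rate
equivalence holds by construction and is verified by simulation in the
test suite. The pharmacokinetic shapes (step, exponential decay back to
baseline, finite pulse) are representative profiles, not mechanistic
absorption/clearance models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import DomainError, ParameterSet, Stimulus
from .measures import MeasureReport, MeasureWindow, measure_report
from .simulate import Trajectory, stimulated_response

__all__ = ["DrugProfile", "effective_btrcp_factor", "simulate_with_drug"]

_MODES = ("abundance", "binding-rate")
_SHAPES = ("step", "exponential-decay", "pulse")


@dataclass(frozen=True)
class DrugProfile:
    """A multiplicative modulation of the β-TrCP-dependent degradation.

    ``magnitude`` is the dimensionless multiplier reached at drug onset
    (< 1 inhibits, 0 silences reactions 8/10, 1 is no drug). ``step``
    holds the magnitude forever; ``exponential-decay`` relaxes the effect
    back to 1 with rate ``decay_per_min``; ``pulse`` holds it for
    ``pulse_width_min`` and then releases. Before ``onset_min`` the factor
    is exactly 1.
    """

    mode: str = "abundance"
    shape: str = "step"
    onset_min: float = 0.0
    magnitude: float = 1.0
    decay_per_min: float = 0.0
    pulse_width_min: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise DomainError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.shape not in _SHAPES:
            raise DomainError(f"shape must be one of {_SHAPES}, got {self.shape!r}")
        if self.magnitude < 0:
            raise DomainError("drug magnitude must be >= 0")
        if self.onset_min < 0:
            raise DomainError("drug onset must be >= 0 min")
        if self.decay_per_min < 0:
            raise DomainError("decay constant must be >= 0 /min")
        if self.shape == "pulse":
            if self.pulse_width_min is None or self.pulse_width_min <= 0:
                raise DomainError("pulse shape requires pulse_width_min > 0")

    def factor(self, t_min: float) -> float:
        """Dimensionless scaling of the baseline β-TrCP level at time t."""
        if t_min < self.onset_min:
            return 1.0
        dt = t_min - self.onset_min
        if self.shape == "step":
            return self.magnitude
        if self.shape == "exponential-decay":
            return 1.0 + (self.magnitude - 1.0) * math.exp(-self.decay_per_min * dt)
        # pulse
        return self.magnitude if dt < self.pulse_width_min else 1.0

    def breakpoints(self) -> tuple[float, ...]:
        """Discontinuity times of the factor (integration is split there)."""
        if self.shape == "pulse":
            return (self.onset_min, self.onset_min + self.pulse_width_min)
        return (self.onset_min,)


def effective_btrcp_factor(profile: DrugProfile, baseline_nM: float,
                           t_min: float, params: ParameterSet | None = None,
                           ) -> float:
    """The dimensionless scaling applied to reactions 8 and 10 at time t.

    Equals (baseline β-TrCP / reference) × drug factor; identical for
    abundance- and binding-rate-mode profiles by construction.
    """
    if baseline_nM < 0:
        raise DomainError("baseline β-TrCP must be >= 0 nM")
    ref_nM = params.btrcp_ref * 1.0e3 if params is not None else 1.0
    return (baseline_nM / ref_nM) * profile.factor(t_min)


def simulate_with_drug(
    params: ParameterSet,
    stimulus: Stimulus,
    profile: DrugProfile,
    t_final_min: float = 630.0,
    window: MeasureWindow | None = None,
) -> tuple[Trajectory, MeasureReport]:
    """Stimulated response under a drug profile, plus its measure report.

    The initial condition is the drug-free resting state at the stimulus's
    baseline β-TrCP (profiles are 1 before onset, so a pre-onset history is
    consistent). Deterministic.
    """
    drugged = Stimulus(tnf=stimulus.tnf, btrcp_nM=stimulus.btrcp_nM, drug=profile)
    traj = stimulated_response(params, drugged, t_final_min=t_final_min)
    return traj, measure_report(traj, window)
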