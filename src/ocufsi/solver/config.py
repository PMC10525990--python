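"""Run configuration for the coupled explicit solve."""

from __future__ import annotations

from dataclasses import dataclass, asdict

from ..constitutive import MMHG_TO_PA


@dataclass
class SolverConfig:
    """Parameters of the explicit FSI run.

    The reference protocol ramps the inlet pressure from 0 to
    ``target_pressure_mmHg`` linearly over ``ramp_duration_s`` and emits
    ``n_output_steps`` output snapshots; the internal time step is always
    CFL-limited.  ``sound_speed_scaling`` reduces the effective fluid sound
    speed (the flow stays far subsonic, so the incompressible limit is
    preserved) and ``mass_damping`` adds mass-proportional damping so the
    shortened desk-scale ramp behaves quasi-statically.  The solver is
    deterministic; there is no random state.
    """

    ramp_duration_s: float = 0.5
    n_output_steps: int = 500
    target_pressure_mmHg: float = 7.0
    penalty_factor: float = 0.1
    CFL_factor: float = 0.9
    sound_speed_scaling: float = 20.0 / 1480.0
    mass_damping: float = 2.0e5            # [1/s] mass-proportional damping
    hourglass_coefficient: float = 0.1
    contact_stiffness_scale: float = 0.1
    contact_thickness_um: float = 0.2
    hold_fraction: float = 0.3             # extra settle time past the ramp
    bulk_viscosity_linear: float = 0.15    # fluid linear artificial viscosity
    mass_scaling: bool = True              # selective solid mass scaling
    outlet_relax_time_s: float = 2e-5      # running-mean window of the outlet
    store_every_state: bool = True
    inlet_mode: str = "pressure"           # "pressure" | "velocity"
    inlet_velocity_m_s: float = 0.0        # ramp target for velocity mode

    def __post_init__(self) -> None:
        if self.ramp_duration_s <= 0:
            raise ValueError("ramp_duration_s must be positive")
        if not (0.0 < self.penalty_factor <= 1.0):
            raise ValueError("penalty_factor must be in (0, 1]")
        if not (0.0 < self.CFL_factor < 1.0):
            raise ValueError("CFL_factor must be in (0, 1)")
        if self.n_output_steps < 1:
            raise ValueError("n_output_steps must be >= 1")
        if self.inlet_mode not in ("pressure", "velocity"):
            raise ValueError("inlet_mode must be 'pressure' or 'velocity'")

    @property
    def target_pressure_pa(self) -> float:
        return self.target_pressure_mmHg * MMHG_TO_PA

    def to_dict(self) -> dict:
        return asdict(self)


def pressure_ramp(t: float, config: SolverConfig) -> float:
    """Linear inlet pressure ramp [Pa]: 0 at t=0, target at t >= ramp time."""
    if t < 0:
        raise ValueError("time must be non-negative")
    frac = min(t / config.ramp_duration_s, 1.0)
    return frac * config.target_pressure_pa


def standard_desk_config(**overrides) -> SolverConfig:
    """Desk-scale configuration of the standard fixture run.

    A 0.2 ms ramp plus 30% hold with mass damping is the quasi-static
    interpretation of the reference 0.5 s / 500-step protocol; 60 output
    snapshots bound memory.  Overrides are applied on top.
    """
    base = dict(ramp_duration_s=2.0e-4, n_output_steps=60)
    base.update(overrides)
    return SolverConfig(**base)
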