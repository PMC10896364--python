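"""Synthetic bulk-velocity data with the statistical structure the calibration assumes.

The generator emulates the pulse-stimulation experiment the model was built
for: square epithelial monolayers stimulated with a reference-strength DC
field for a fixed window, with the spatially averaged bulk velocity sampled
every 10 minutes and recording continuing through at least 2.5 h of
field-off decay.  Observations are the deterministic model solution (clamp
on) plus iid Gaussian noise, which is exactly the error model the Gaussian
likelihood assumes — so parameter-recovery studies test the inference
machinery, not the noise model.  Real PIV-derived bulk velocities would be
temporally autocorrelated; that mismatch is deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import VelocityTrace
from .model import (
    DEFAULT_HORIZON,
    InvalidInputError,
    ModelParameters,
    StimulusProtocol,
)

__all__ = ["ExperimentDesign", "generate_traces", "generate_decay_segment"]


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of a synthetic pulse-stimulation experiment.

    Defaults follow the reference experiment: a 3 V/cm pulse (``s = 1``
    normalised) for 3 h, recording to 5.5 h at 10-minute cadence, nine
    replicate monolayers, and a noise scale of 3 μm/h chosen to match the
    visual spread of experimental bulk-velocity traces.
    """

    protocol: StimulusProtocol = field(
        default_factory=lambda: StimulusProtocol.pulse(1.0, DEFAULT_HORIZON))
    t_total: float = 5.5
    dt_sample: float = 1.0 / 6.0
    n_replicates: int = 9
    sigma_noise: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt_sample <= 0:
            raise InvalidInputError("dt_sample must be positive")
        if self.n_replicates < 1:
            raise InvalidInputError("need at least one replicate")
        if self.sigma_noise < 0:
            raise InvalidInputError("sigma_noise must be non-negative")
        if self.t_total <= self.dt_sample:
            raise InvalidInputError("t_total must exceed dt_sample")

    @property
    def sample_times(self) -> np.ndarray:
        """Observation grid: multiples of ``dt_sample`` in (0, t_total].

        No observation at t = 0, where the velocity is identically zero.
        """
        n = int(np.floor(self.t_total / self.dt_sample + 1e-9))
        return self.dt_sample * np.arange(1, n + 1)

    def to_dict(self) -> dict:
        return {
            "protocol_breakpoints_h": self.protocol.breakpoints.tolist(),
            "protocol_values_normalized": self.protocol.values.tolist(),
            "reference_field_V_per_cm": self.protocol.reference_field,
            "t_total_h": self.t_total,
            "dt_sample_h": self.dt_sample,
            "n_replicates": self.n_replicates,
            "sigma_noise_um_per_h": self.sigma_noise,
            "seed": self.seed,
        }


def generate_traces(params: ModelParameters,
                    design: ExperimentDesign) -> list[VelocityTrace]:
    """Simulate noisy replicate velocity traces under the design's protocol.

    Every replicate shares the deterministic model solution; replicates
    differ only in their iid Gaussian noise draws.  Bit-reproducible for a
    fixed ``design.seed``.
    """
    from .calibration import model_velocity

    t = design.sample_times
    v_model = model_velocity(params, design.protocol, t)
    rng = np.random.default_rng(design.seed)
    noise = rng.normal(0.0, design.sigma_noise,
                       size=(design.n_replicates, len(t)))
    return [
        VelocityTrace(t, v_model + noise[k], replicate_id=f"rep{k}",
                      protocol=design.protocol)
        for k in range(design.n_replicates)
    ]


def generate_decay_segment(gamma: float, C: float, t_end: float,
                           window: float = 2.5, dt_sample: float = 1.0 / 6.0,
                           sigma_noise: float = 0.0,
                           seed: int | None = None) -> VelocityTrace:
    """Exponential decay fixture ``C·e^{−γ(t−t_end)}`` plus noise.

    Produces the observation at ``t_end`` itself (value ``C``) followed by
    samples at ``dt_sample`` spacing through ``t_end + window`` — the
    field-off segment that identifies the friction rate γ.
    """
    if C <= 0:
        raise InvalidInputError("decay amplitude C must be positive")
    if gamma < 0:
        raise InvalidInputError("gamma must be non-negative")
    n = int(np.floor(window / dt_sample + 1e-9))
    t = t_end + dt_sample * np.arange(0, n + 1)
    v = C * np.exp(-gamma * (t - t_end))
    if sigma_noise > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, sigma_noise, size=len(t))
    return VelocityTrace(t, v, replicate_id="decay", protocol=None)
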