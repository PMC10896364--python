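"""Excitation-adaptation model of collective electrotaxis.

The bulk of an epithelial monolayer responds to a uniaxial DC electric field
through a fast *excitation* / slow *adaptation* signalling cascade: the applied
signal ``s`` (field strength, normalised by a reference field) produces an
internal *effective signal* ``s_eff`` that drives active force, while a slowly
accumulating *inhibitor* ``I`` shuts the response off again.  Coupled to linear
substrate friction this gives a three-variable linear ODE system for the bulk
velocity ``v`` (μm/h)::

    dv/dt     = -gamma * v + alpha * max(s_eff, 0)
    ds_eff/dt = (s - s_eff - I) / tau_e
    dI/dt     = (s - I) / tau_a

with ``tau_e << tau_a``.  A constant field therefore yields a transient
velocity peak followed by full adaptation back to rest: the only steady state
is ``(v, s_eff, I) = (0, 0, s)``.

All computation is carried out in normalised signal units (``s = 1`` is the
reference field, 3 V/cm by default), hours and μm/h; conversion to physical
field strengths happens only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InvalidInputError",
    "DegenerateParametersError",
    "InsufficientDataError",
    "NumericalError",
    "REFERENCE_FIELD",
    "POSTERIOR_MEANS",
    "DEFAULT_HORIZON",
    "S_BUDGET_PHYSICAL",
    "ModelParameters",
    "StimulusProtocol",
    "Trajectory",
    "rhs",
    "simulate",
    "step_response",
    "velocity_step_closed_form",
    "pulse_response",
    "steady_state",
    "system_eigenvalues",
    "tau_max",
]


# --------------------------------------------------------------------------
# errors
# --------------------------------------------------------------------------

class InvalidInputError(ValueError):
    """Raised when inputs are non-finite or violate a documented contract."""


class DegenerateParametersError(ValueError):
    """Raised when a closed form is singular (coincident decay rates)."""


class InsufficientDataError(ValueError):
    """Raised when a fit is requested on fewer points than it needs."""


class NumericalError(RuntimeError):
    """Raised when an ODE/BVP solver fails to converge."""


# --------------------------------------------------------------------------
# constants: units convention and calibrated defaults
# --------------------------------------------------------------------------

#: Reference field strength, V/cm; ``s = 1`` in normalised units.
REFERENCE_FIELD = 3.0

#: Default stimulation horizon, h.  A constant reference field over this
#: horizon delivers the canonical charge budget below.
DEFAULT_HORIZON = 3.0

#: Canonical squared-field ("charge") budget, V^2 h / cm^2.  In normalised
#: units this is ``S_BUDGET_PHYSICAL / REFERENCE_FIELD**2`` = 3 h.
S_BUDGET_PHYSICAL = 27.0

_RATE_COLLISION_RTOL = 1e-9


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Kinetic constants of the excitation-adaptation velocity model.

    Parameters
    ----------
    gamma : float
        Friction (velocity decay) rate, 1/h.
    alpha : float
        Field responsiveness: active force per unit normalised effective
        signal, μm/h².
    tau_e : float
        Excitation timescale, h.
    tau_a : float
        Adaptation timescale, h.  Must exceed ``tau_e``.
    """

    gamma: float
    alpha: float
    tau_e: float
    tau_a: float

    def __post_init__(self) -> None:
        vals = (self.gamma, self.alpha, self.tau_e, self.tau_a)
        if not all(np.isfinite(vals)):
            raise InvalidInputError(f"non-finite model parameters: {vals}")
        if min(vals) <= 0:
            raise InvalidInputError(f"model parameters must be positive: {vals}")
        if self.tau_e >= self.tau_a:
            raise InvalidInputError(
                f"excitation must be faster than adaptation: "
                f"tau_e={self.tau_e} >= tau_a={self.tau_a}"
            )

    @property
    def epsilon(self) -> float:
        """Timescale ratio ``tau_e / tau_a``, in (0, 1)."""
        return self.tau_e / self.tau_a

    @property
    def rates(self) -> tuple[float, float, float]:
        """The three relaxation rates ``(gamma, 1/tau_e, 1/tau_a)``."""
        return (self.gamma, 1.0 / self.tau_e, 1.0 / self.tau_a)

    def require_distinct_rates(self) -> None:
        """Raise if any two relaxation rates coincide.

        The closed forms used throughout (step response, adjoints) are
        singular at rate collisions; confluent limits are deliberately not
        implemented.
        """
        g, ke, ka = self.rates
        for x, y in ((g, ke), (g, ka), (ke, ka)):
            if math.isclose(x, y, rel_tol=_RATE_COLLISION_RTOL):
                raise DegenerateParametersError(
                    f"coincident relaxation rates {x} and {y}; "
                    "closed forms are singular here"
                )


#: Posterior-mean parameter estimates calibrated to pulse-stimulation data,
#: shipped as package defaults.
POSTERIOR_MEANS = ModelParameters(gamma=1.765, alpha=149.92, tau_e=0.260, tau_a=2.038)


# --------------------------------------------------------------------------
# stimulation protocols
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant applied signal ``s(t)`` on ``[0, T]``.

    ``breakpoints`` has length ``n + 1`` with ``breakpoints[0] == 0`` and
    ``breakpoints[-1] == T``; ``values[i]`` is the normalised field strength
    on ``[breakpoints[i], breakpoints[i+1])``.  Beyond ``T`` the signal is
    zero, so post-stimulation decay can be simulated directly.  Sampled
    protocols are converted by zero-order hold (:meth:`from_samples`).
    """

    breakpoints: np.ndarray
    values: np.ndarray
    reference_field: float = REFERENCE_FIELD

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if bp.ndim != 1 or vals.ndim != 1 or len(bp) != len(vals) + 1:
            raise InvalidInputError("need n+1 breakpoints for n segment values")
        if not np.all(np.diff(bp) > 0):
            raise InvalidInputError("breakpoints must be strictly increasing")
        if bp[0] != 0.0:
            raise InvalidInputError("protocol must start at t = 0")
        if bp[-1] <= 0.0:
            raise InvalidInputError("protocol duration must be positive")
        if not (np.all(np.isfinite(bp)) and np.all(np.isfinite(vals))):
            raise InvalidInputError("non-finite protocol specification")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", vals)

    @property
    def duration(self) -> float:
        return float(self.breakpoints[-1])

    def __call__(self, t):
        """Evaluate ``s(t)``; zero for ``t > T`` (and ``t < 0``)."""
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.breakpoints, t, side="right") - 1,
                      0, len(self.values) - 1)
        out = self.values[idx]
        out = np.where((t < 0) | (t > self.duration), 0.0, out)
        # t == T belongs to the last segment by convention
        return out if out.ndim else float(out)

    @classmethod
    def constant(cls, value: float, duration: float,
                 reference_field: float = REFERENCE_FIELD) -> "StimulusProtocol":
        return cls(np.array([0.0, duration]), np.array([float(value)]),
                   reference_field)

    @classmethod
    def pulse(cls, amplitude: float = 1.0, duration: float = DEFAULT_HORIZON,
              reference_field: float = REFERENCE_FIELD) -> "StimulusProtocol":
        """Single constant pulse from ``t = 0`` to ``t = duration``."""
        return cls.constant(amplitude, duration, reference_field)

    @classmethod
    def from_samples(cls, t: Sequence[float], values: Sequence[float],
                     duration: float | None = None,
                     reference_field: float = REFERENCE_FIELD) -> "StimulusProtocol":
        """Zero-order hold through sample points ``(t_i, s_i)``.

        The last sample extends to ``duration`` (default: last sample time
        plus the final inter-sample spacing, or the last time itself for a
        single sample).
        """
        t = np.asarray(t, dtype=float)
        values = np.asarray(values, dtype=float)
        if duration is None:
            dt = t[-1] - t[-2] if len(t) > 1 else 1.0
            duration = float(t[-1] + dt)
        if t[0] != 0.0:
            t = np.concatenate([[0.0], t])
            values = np.concatenate([[0.0], values])
        bp = np.concatenate([t, [duration]])
        return cls(bp, values, reference_field)

    @property
    def is_single_pulse(self) -> bool:
        """True when the protocol is one constant segment starting at 0."""
        return len(self.values) == 1

    def to_physical(self) -> np.ndarray:
        """Segment values in V/cm."""
        return self.values * self.reference_field

    def scaled(self, factor: float) -> "StimulusProtocol":
        return replace(self, values=self.values * factor)

    def to_csv(self, path) -> None:
        """Write breakpoint rows ``time_h, field_V_per_cm`` (zero-order hold)."""
        df = pd.DataFrame({
            "time_h": self.breakpoints,
            "field_V_per_cm": np.concatenate([self.to_physical(), [0.0]]),
        })
        with open(path, "w") as fh:
            fh.write(f"# reference_field_V_per_cm = {self.reference_field:.9g}\n")
            df.to_csv(fh, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path) -> "StimulusProtocol":
        reference = REFERENCE_FIELD
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#") and "reference_field" in first:
                reference = float(first.split("=")[1])
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, comment="#")
        t = df["time_h"].to_numpy(float)
        s_phys = df["field_V_per_cm"].to_numpy(float)
        return cls(t, s_phys[:-1] / reference, reference)


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-gridded solution of the state system.

    Attributes
    ----------
    t : ndarray
        Strictly increasing times, h.
    v : ndarray
        Bulk velocity, μm/h.
    s_eff : ndarray
        Effective (transduced) signal, unitless.
    I : ndarray
        Inhibitor, unitless.
    s : ndarray
        Applied signal, unitless.
    x : ndarray
        Accumulated displacement ``∫ v dt``, μm.
    z : ndarray
        Accumulated squared signal ``∫ s² dt``, h (normalised units).
    """

    t: np.ndarray
    v: np.ndarray
    s_eff: np.ndarray
    I: np.ndarray
    s: np.ndarray
    x: np.ndarray = field(default=None)  # type: ignore[assignment]
    z: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def distance(self) -> float:
        """Total displacement over the grid, μm."""
        if self.x is not None:
            return float(self.x[-1] - self.x[0])
        return float(np.trapezoid(self.v, self.t))

    @property
    def terminal_velocity(self) -> float:
        return float(self.v[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.t,
            "velocity_um_per_h": self.v,
            "s_eff": self.s_eff,
            "inhibitor": self.I,
            "field_normalized": self.s,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


# --------------------------------------------------------------------------
# right-hand side and simulation
# --------------------------------------------------------------------------

def rhs(state, s_value: float, params: ModelParameters, clamp: bool = True):
    """Time derivative ``(dv/dt, ds_eff/dt, dI/dt)`` of the state system.

    With ``clamp`` on, a negative effective signal produces no active force
    (``s_eff`` is replaced by ``max(s_eff, 0)`` in the velocity equation
    only); the signalling variables themselves are never clamped.
    """
    state = np.asarray(state, dtype=float)
    if not (np.all(np.isfinite(state)) and np.isfinite(s_value)):
        raise InvalidInputError(f"non-finite state {state} or signal {s_value}")
    v, s_eff, inh = state
    drive = max(s_eff, 0.0) if clamp else s_eff
    dv = -params.gamma * v + params.alpha * drive
    ds = (s_value - s_eff - inh) / params.tau_e
    dI = (s_value - inh) / params.tau_a
    return (dv, ds, dI)


def _integrate(params: ModelParameters, s_of_t: Callable, t_grid: np.ndarray,
               y0: np.ndarray, clamp: bool, rtol: float, atol: float) -> np.ndarray:
    from scipy.integrate import solve_ivp

    ga, al, te, ta = params.gamma, params.alpha, params.tau_e, params.tau_a

    def f(t, y):
        v, s_eff, inh, _, _ = y
        s = s_of_t(t)
        drive = max(s_eff, 0.0) if clamp else s_eff
        return (-ga * v + al * drive, (s - s_eff - inh) / te, (s - inh) / ta,
                v, s * s)

    sol = solve_ivp(f, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
                    method="RK45", rtol=rtol, atol=atol, dense_output=False)
    if not sol.success:
        raise NumericalError(f"ODE solver failed: {sol.message}")
    return sol.y


def simulate(params: ModelParameters,
             protocol: StimulusProtocol | Callable,
             t_grid: Sequence[float],
             clamp: bool = True,
             initial_state: Sequence[float] = (0.0, 0.0, 0.0),
             rtol: float = 1e-8,
             atol: float = 1e-10) -> Trajectory:
    """Integrate the state system under an applied signal.

    ``protocol`` may be a :class:`StimulusProtocol` (integrated exactly
    segment by segment, so discontinuities never cross an integration step)
    or any callable ``s(t)`` for smooth control inputs.  The returned
    trajectory carries the accumulated displacement ``x = ∫v dt`` and squared
    signal ``z = ∫s² dt`` as extra quadrature states.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or not np.all(np.diff(t_grid) > 0):
        raise InvalidInputError("t_grid must be strictly increasing, length >= 2")
    if t_grid[0] < 0:
        raise InvalidInputError("t_grid must start at or after t = 0")
    y0 = np.concatenate([np.asarray(initial_state, dtype=float), [0.0, 0.0]])
    if len(y0) != 5 or not np.all(np.isfinite(y0)):
        raise InvalidInputError(f"bad initial state {initial_state}")

    if isinstance(protocol, StimulusProtocol):
        # split the integration at protocol breakpoints (and at T)
        cuts = np.asarray(protocol.breakpoints)
        cuts = cuts[(cuts > t_grid[0]) & (cuts < t_grid[-1])]
        edges = np.unique(np.concatenate([[t_grid[0]], cuts, [t_grid[-1]]]))
        ys = np.empty((5, len(t_grid)))
        filled = np.zeros(len(t_grid), dtype=bool)
        y = y0
        for a, b in zip(edges[:-1], edges[1:]):
            s_const = float(protocol(0.5 * (a + b)))
            mask = (t_grid >= a) & (t_grid <= b) & ~filled
            seg_t = np.unique(np.concatenate([[a], t_grid[mask], [b]]))
            yy = _integrate(params, lambda t, s=s_const: s, seg_t, y, clamp,
                            rtol, atol)
            sel = np.isin(seg_t, t_grid[mask])
            ys[:, mask] = yy[:, sel]
            filled |= mask
            y = yy[:, -1]
        s_vals = np.asarray(protocol(t_grid), dtype=float)
    else:
        ys = _integrate(params, protocol, t_grid, y0, clamp, rtol, atol)
        s_vals = np.asarray([float(protocol(t)) for t in t_grid])

    return Trajectory(t=t_grid, v=ys[0], s_eff=ys[1], I=ys[2], s=s_vals,
                      x=ys[3], z=ys[4])


# --------------------------------------------------------------------------
# closed forms
# --------------------------------------------------------------------------

def step_response(params: ModelParameters, t):
    """Signalling response ``(s_eff, I)`` to a unit step at ``t = 0``.

    ``s_eff(t) = τa/(τa−τe) · (e^{−t/τa} − e^{−t/τe})`` and
    ``I(t) = 1 − e^{−t/τa}``: the effective signal rises on the excitation
    timescale, peaks, and adapts away while the inhibitor saturates at the
    applied signal.
    """
    te, ta = params.tau_e, params.tau_a
    if math.isclose(te, ta, rel_tol=_RATE_COLLISION_RTOL):
        raise DegenerateParametersError("step response singular at tau_e == tau_a")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("step response defined for t >= 0")
    s_eff = ta / (ta - te) * (np.exp(-t / ta) - np.exp(-t / te))
    inh = 1.0 - np.exp(-t / ta)
    return s_eff, inh


def velocity_step_closed_form(params: ModelParameters, t):
    """Exact velocity under a unit step signal (zero initial condition).

    Convolution of the friction kernel ``e^{−γt}`` with α times the step
    response of :func:`step_response`; serves as the oracle for
    :func:`simulate`.  Requires γ, 1/τe, 1/τa pairwise distinct.
    """
    params.require_distinct_rates()
    ga, te, ta = params.gamma, params.tau_e, params.tau_a
    t = np.asarray(t, dtype=float)
    pref = params.alpha * ta / (ta - te)
    term_a = (np.exp(-t / ta) - np.exp(-ga * t)) / (ga - 1.0 / ta)
    term_e = (np.exp(-t / te) - np.exp(-ga * t)) / (ga - 1.0 / te)
    return pref * (term_a - term_e)


def pulse_response(params: ModelParameters, amplitude: float, t_end: float, t,
                   clamp: bool = True):
    """Exact ``(v, s_eff, I)`` under a single pulse ``s = amplitude`` on
    ``[0, t_end]``, zero afterwards.

    During the pulse all three variables are ``amplitude`` times the unit
    step response.  After field-off the signalling pair relaxes as a sum of
    two exponentials; the effective signal crosses zero at a computable time
    ``t_c``, beyond which (with the clamp on) the velocity decays exactly as
    ``v(t_c)·e^{−γ(t−t_c)}``.  This closed form is what makes the
    calibration likelihood cheap.
    """
    params.require_distinct_rates()
    if amplitude < 0 and clamp:
        raise InvalidInputError("clamped pulse response requires amplitude >= 0")
    ga, al, te, ta = params.gamma, params.alpha, params.tau_e, params.tau_a
    t = np.asarray(t, dtype=float)

    v = np.empty_like(t)
    s_eff = np.empty_like(t)
    inh = np.empty_like(t)

    on = t <= t_end
    se_on, i_on = step_response(params, np.where(on, t, t_end))
    s_eff[on] = amplitude * se_on[on]
    inh[on] = amplitude * i_on[on]
    v[on] = amplitude * velocity_step_closed_form(params, t[on])

    if np.any(~on):
        # state at field-off
        se_T, i_T = (amplitude * u for u in step_response(params, t_end))
        v_T = amplitude * velocity_step_closed_form(params, t_end)
        x = t[~on] - t_end
        B = -i_T * ta / (ta - te)
        A = se_T - B
        inh[~on] = i_T * np.exp(-x / ta)
        s_eff[~on] = A * np.exp(-x / te) + B * np.exp(-x / ta)
        # unclamped velocity: response to the two decaying exponentials
        v_free = (v_T * np.exp(-ga * x)
                  + al * A * (np.exp(-x / te) - np.exp(-ga * x)) / (ga - 1 / te)
                  + al * B * (np.exp(-x / ta) - np.exp(-ga * x)) / (ga - 1 / ta))
        if clamp and amplitude > 0:
            # s_eff crosses zero at x_c; afterwards v decays freely
            if A > 0 and B < 0 and se_T > 0:
                x_c = math.log(A / (-B)) / (1.0 / te - 1.0 / ta)
            else:
                x_c = 0.0
            v_c = (v_T * math.exp(-ga * x_c)
                   + al * A * (math.exp(-x_c / te) - math.exp(-ga * x_c)) / (ga - 1 / te)
                   + al * B * (math.exp(-x_c / ta) - math.exp(-ga * x_c)) / (ga - 1 / ta))
            v[~on] = np.where(x <= x_c, v_free, v_c * np.exp(-ga * (x - x_c)))
        else:
            v[~on] = v_free

    if t.ndim == 0:
        return float(v), float(s_eff), float(inh)
    return v, s_eff, inh


def steady_state(params: ModelParameters, s: float):
    """Fixed point ``(v*, s_eff*, I*) = (0, 0, s)`` under a constant signal.

    The fully adapted tissue is at rest with the inhibitor balancing the
    applied signal; see :func:`system_eigenvalues` for its (strict) stability.
    """
    return (0.0, 0.0, float(s))


def system_eigenvalues(params: ModelParameters) -> np.ndarray:
    """Eigenvalues ``(−γ, −1/τe, −1/τa)`` of the homogeneous system matrix."""
    return np.array([-params.gamma, -1.0 / params.tau_e, -1.0 / params.tau_a])


def tau_max(params: ModelParameters) -> float:
    """Time at which the step response of ``s_eff`` (hence the velocity
    drive) peaks: ``ln(τa/τe) / (1/τe − 1/τa)``."""
    te, ta = params.tau_e, params.tau_a
    if te >= ta:
        raise InvalidInputError("tau_max requires tau_e < tau_a")
    return math.log(ta / te) / (1.0 / te - 1.0 / ta)
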