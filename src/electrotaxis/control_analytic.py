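"""Closed-form Pontryagin controls for the excitation-adaptation model.

Two stimulation-design problems admit fully analytic costates because the
state system is linear and the objectives depend linearly on the state:

* **maximum distance** — maximise ``∫₀ᵀ v dt`` subject to the isoperimetric
  charge budget ``∫₀ᵀ s² dt = s_budget``;
* **maximum terminal velocity** — maximise ``v(T)`` under the same budget.

For both, the Hamiltonian is quadratic in the control through the budget
multiplier μ, so the optimal field is proportional to the switching profile

    g(t) = τe⁻¹ λ_seff(t) + τa⁻¹ λ_I(t),

with ``S*(t) = g(t) / (2μ*)`` and μ* fixed by the budget.  Every costate is a
finite sum of exponentials ``c·e^{r(t−T)}``, which this module manipulates
exactly (evaluation, the λ_I convolution integral, and ``∫ g² dt`` are all
closed-form), so μ* needs no root-finding and the budget holds to round-off.

Dropping the budget in favour of a simple bound ``0 ≤ s ≤ s_max`` makes the
Hamiltonian linear in the control; since g(t) > 0 for all t < T under the
distance objective, the bang-bang policy is the constant pulse at ``s_max`` —
the stimulation protocol experimentalists converged on by iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import (
    DEFAULT_HORIZON,
    REFERENCE_FIELD,
    S_BUDGET_PHYSICAL,
    DegenerateParametersError,
    InvalidInputError,
    ModelParameters,
    StimulusProtocol,
    Trajectory,
    simulate,
)

__all__ = [
    "ExpSum",
    "IsoperimetricSpec",
    "AdjointTrajectory",
    "ClosedFormAdjoints",
    "ControlSolution",
    "adjoints_max_distance",
    "adjoints_terminal_velocity",
    "optimal_field_max_distance",
    "optimal_field_max_terminal_velocity",
    "constant_field_solution",
    "posterior_control_ensemble",
    "switching_function",
    "bang_bang_policy",
]

logger = logging.getLogger(__name__)

_COLLISION_RTOL = 1e-9


# --------------------------------------------------------------------------
# exponential sums: the closed-form algebra behind the adjoints
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpSum:
    """Finite exponential sum ``f(t) = Σ_j c_j · e^{r_j (t − T)}`` on [0, T]."""

    coeffs: np.ndarray
    rates: np.ndarray
    T: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", np.atleast_1d(np.asarray(self.coeffs, float)))
        object.__setattr__(self, "rates", np.atleast_1d(np.asarray(self.rates, float)))
        if self.coeffs.shape != self.rates.shape:
            raise InvalidInputError("coeffs and rates must have equal length")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.einsum("j,...j->...",
                        self.coeffs,
                        np.exp(np.multiply.outer(t - self.T, self.rates)))
        return out if out.ndim else float(out)

    def __mul__(self, k: float) -> "ExpSum":
        return ExpSum(self.coeffs * k, self.rates, self.T)

    __rmul__ = __mul__

    def __add__(self, other: "ExpSum") -> "ExpSum":
        if other.T != self.T:
            raise InvalidInputError("cannot add ExpSums on different horizons")
        return ExpSum(np.concatenate([self.coeffs, other.coeffs]),
                      np.concatenate([self.rates, other.rates]), self.T)

    def integral_sq(self) -> float:
        """``∫₀ᵀ f(t)² dt``, exactly.

        Uses ``∫₀ᵀ e^{r(t−T)} dt = (1 − e^{−rT})/r`` (→ T as r → 0) on every
        pairwise product of terms.
        """
        r = np.add.outer(self.rates, self.rates)
        with np.errstate(divide="ignore", invalid="ignore"):
            kern = np.where(np.abs(r) * self.T > 1e-12,
                            (1.0 - np.exp(-r * self.T)) / np.where(r == 0, 1.0, r),
                            self.T)
        return float(np.einsum("i,j,ij->", self.coeffs, self.coeffs, kern))

    def solve_linear(self, a: float) -> "ExpSum":
        """Solve ``λ' = a·λ + f(t)`` with terminal condition ``λ(T) = 0``.

        Each source term ``k·e^{r(t−T)}`` contributes the particular solution
        ``k/(r−a)·e^{r(t−T)}``; the homogeneous coefficient is fixed by the
        terminal condition.  Raises when a source rate collides with ``a``.
        """
        if np.any(np.isclose(self.rates, a, rtol=_COLLISION_RTOL, atol=0.0)):
            raise DegenerateParametersError(
                f"rate collision: source contains rate {a}")
        part = self.coeffs / (self.rates - a)
        return ExpSum(np.concatenate([part, [-part.sum()]]),
                      np.concatenate([self.rates, [a]]), self.T)


# --------------------------------------------------------------------------
# problem specification and solution containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IsoperimetricSpec:
    """Charge-budgeted stimulation-design problem on a fixed horizon.

    ``s_budget`` is in normalised units (h): the physical budget in
    V²h/cm² divided by ``reference_field²``.  The default matches constant
    stimulation at the reference field over the default horizon.
    """

    T: float = DEFAULT_HORIZON
    s_budget: float = S_BUDGET_PHYSICAL / REFERENCE_FIELD**2
    objective: str = "distance"
    reference_field: float = REFERENCE_FIELD

    def __post_init__(self) -> None:
        if self.T <= 0 or self.s_budget <= 0:
            raise InvalidInputError("horizon and budget must be positive")
        if self.objective not in ("distance", "terminal_velocity"):
            raise InvalidInputError(f"unknown objective {self.objective!r}")


@dataclass
class AdjointTrajectory:
    """Costates sampled on a time grid, plus the isoperimetric multiplier."""

    t: np.ndarray
    lambda_v: np.ndarray
    lambda_seff: np.ndarray
    lambda_I: np.ndarray
    mu_star: float | None = None


@dataclass(frozen=True)
class ClosedFormAdjoints:
    """Exact costates of a budgeted control problem, up to the 1/(2μ*) scale.

    ``switching`` is ``g = τe⁻¹λ_seff + τa⁻¹λ_I``, the unscaled optimal
    field profile.
    """

    lambda_v: ExpSum
    lambda_seff: ExpSum
    lambda_I: ExpSum
    switching: ExpSum
    T: float

    def sample(self, t_grid, mu_star: float | None = None) -> AdjointTrajectory:
        t_grid = np.asarray(t_grid, dtype=float)
        return AdjointTrajectory(t_grid, np.asarray(self.lambda_v(t_grid)),
                                 np.asarray(self.lambda_seff(t_grid)),
                                 np.asarray(self.lambda_I(t_grid)), mu_star)


@dataclass
class ControlSolution:
    """An optimal stimulation protocol with its induced dynamics."""

    t: np.ndarray
    S_star: np.ndarray
    trajectory: Trajectory
    adjoints: AdjointTrajectory | None
    mu_star: float | None
    objective: str
    objective_value: float
    budget_used: float
    params: ModelParameters
    #: re-simulation with the physical s_eff clamp on (the derivation itself
    #: uses the linear, unclamped system)
    clamped_trajectory: Trajectory | None = None

    @property
    def S_star_physical(self) -> np.ndarray:
        return self.S_star * REFERENCE_FIELD

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "time_h": self.t,
            "field_normalized": self.S_star,
            "field_V_per_cm": self.S_star_physical,
            "velocity_um_per_h": self.trajectory.v,
        })

    def summary(self) -> dict:
        return {
            "objective": self.objective,
            "objective_value": self.objective_value,
            "mu_star": self.mu_star,
            "budget_used": self.budget_used,
            "parameters": {
                "gamma": self.params.gamma, "alpha": self.params.alpha,
                "tau_e": self.params.tau_e, "tau_a": self.params.tau_a,
            },
        }


# --------------------------------------------------------------------------
# costates
# --------------------------------------------------------------------------

def adjoints_max_distance(params: ModelParameters, T: float) -> ClosedFormAdjoints:
    """Costates of the maximum-distance problem (up to the 1/(2μ*) scale).

    From ``dλv/dt = −1 + γλv`` with ``λv(T) = 0``:
    ``λv(t) = (1 − e^{γ(t−T)})/γ`` (positive before the horizon — lingering
    velocity still accrues distance).  ``λ_seff`` and ``λ_I`` follow by
    solving their linear costate ODEs backwards from zero, exactly.
    """
    params.require_distinct_rates()
    if T <= 0:
        raise InvalidInputError("horizon must be positive")
    ga, te, ta = params.gamma, params.tau_e, params.tau_a
    lam_v = ExpSum([1.0 / ga, -1.0 / ga], [0.0, ga], T)
    # dλs/dt = −α λv + τe⁻¹ λs
    lam_s = ((-params.alpha) * lam_v).solve_linear(1.0 / te)
    # dλI/dt = τe⁻¹ λs + τa⁻¹ λI
    lam_i = ((1.0 / te) * lam_s).solve_linear(1.0 / ta)
    g = (1.0 / te) * lam_s + (1.0 / ta) * lam_i
    return ClosedFormAdjoints(lam_v, lam_s, lam_i, g, T)


def adjoints_terminal_velocity(params: ModelParameters, T: float) -> ClosedFormAdjoints:
    """Costates of the maximum-terminal-velocity problem (up to scale).

    The objective ``v(T) = ∫(−γv + αs_eff)dt`` enters the Hamiltonian with
    weight ``(1 + λv)``, giving ``dλv/dt = γ(1 + λv)``, hence
    ``λv = e^{γ(t−T)} − 1``, and ``dλ_seff/dt = −α(1+λv) + τe⁻¹λ_seff``
    whose solution is ``α/(γ − τe⁻¹)·(e^{τe⁻¹(t−T)} − e^{γ(t−T)})``.
    """
    params.require_distinct_rates()
    if T <= 0:
        raise InvalidInputError("horizon must be positive")
    ga, te, ta = params.gamma, params.tau_e, params.tau_a
    lam_v = ExpSum([-1.0, 1.0], [0.0, ga], T)
    # −α(1 + λv) = −α e^{γ(t−T)}
    lam_s = ExpSum([-params.alpha], [ga], T).solve_linear(1.0 / te)
    lam_i = ((1.0 / te) * lam_s).solve_linear(1.0 / ta)
    g = (1.0 / te) * lam_s + (1.0 / ta) * lam_i
    return ClosedFormAdjoints(lam_v, lam_s, lam_i, g, T)


# --------------------------------------------------------------------------
# budget-normalised optimal fields
# --------------------------------------------------------------------------

def _solve_isoperimetric(params: ModelParameters, spec: IsoperimetricSpec,
                         adj: ClosedFormAdjoints, n_grid: int,
                         rtol: float) -> ControlSolution:
    Q = adj.switching.integral_sq()
    if Q <= 1e-300:
        raise InvalidInputError("identically-zero adjoint profile; no solution")
    scale = np.sqrt(spec.s_budget / Q)
    mu_star = 0.5 * np.sqrt(Q / spec.s_budget)
    s_star = scale * adj.switching

    t_grid = np.linspace(0.0, spec.T, n_grid)
    traj = simulate(params, s_star, t_grid, clamp=False, rtol=rtol, atol=rtol * 1e-2)
    traj_clamped = simulate(params, s_star, t_grid, clamp=True, rtol=rtol,
                            atol=rtol * 1e-2)
    value = traj.distance if spec.objective == "distance" else traj.terminal_velocity
    return ControlSolution(
        t=t_grid, S_star=np.asarray(s_star(t_grid)), trajectory=traj,
        adjoints=adj.sample(t_grid, mu_star), mu_star=float(mu_star),
        objective=spec.objective, objective_value=float(value),
        budget_used=float(traj.z[-1]), params=params,
        clamped_trajectory=traj_clamped,
    )


def optimal_field_max_distance(params: ModelParameters, spec: IsoperimetricSpec,
                               n_grid: int = 601,
                               rtol: float = 1e-8) -> ControlSolution:
    """Charge-budgeted field maximising the total distance travelled."""
    if spec.objective != "distance":
        raise InvalidInputError("spec.objective must be 'distance'")
    return _solve_isoperimetric(params, spec,
                                adjoints_max_distance(params, spec.T),
                                n_grid, rtol)


def optimal_field_max_terminal_velocity(params: ModelParameters,
                                        spec: IsoperimetricSpec,
                                        n_grid: int = 601,
                                        rtol: float = 1e-8) -> ControlSolution:
    """Charge-budgeted field maximising the velocity at the horizon."""
    if spec.objective != "terminal_velocity":
        raise InvalidInputError("spec.objective must be 'terminal_velocity'")
    return _solve_isoperimetric(params, spec,
                                adjoints_terminal_velocity(params, spec.T),
                                n_grid, rtol)


def constant_field_solution(params: ModelParameters, spec: IsoperimetricSpec,
                            n_grid: int = 601,
                            rtol: float = 1e-8) -> ControlSolution:
    """Baseline: constant field spending the same charge budget.

    Amplitude ``√(s_budget/T)`` — equal to 1 (the reference field) for the
    canonical budget and horizon.
    """
    amp = np.sqrt(spec.s_budget / spec.T)
    proto = StimulusProtocol.constant(amp, spec.T)
    t_grid = np.linspace(0.0, spec.T, n_grid)
    traj = simulate(params, proto, t_grid, clamp=False, rtol=rtol, atol=rtol * 1e-2)
    traj_clamped = simulate(params, proto, t_grid, clamp=True, rtol=rtol,
                            atol=rtol * 1e-2)
    value = traj.distance if spec.objective == "distance" else traj.terminal_velocity
    return ControlSolution(
        t=t_grid, S_star=np.asarray(proto(t_grid)), trajectory=traj,
        adjoints=None, mu_star=None, objective=spec.objective,
        objective_value=float(value), budget_used=float(traj.z[-1]),
        params=params, clamped_trajectory=traj_clamped,
    )


# --------------------------------------------------------------------------
# posterior ensembles of optimal controls
# --------------------------------------------------------------------------

def posterior_control_ensemble(samples, spec: IsoperimetricSpec,
                               n: int = 2000, seed: int | None = None,
                               quantiles: tuple[float, float] = (0.05, 0.95),
                               n_grid: int = 201, rtol: float = 1e-6) -> dict:
    """Per-time quantile envelopes of ``S*`` and its induced velocity.

    Draws ``n`` parameter sets from the posterior, rebuilds the optimal
    field — including its own budget multiplier μ* — for each draw, and
    returns empirical envelopes across the ensemble.  Draws violating the
    parameter invariants are skipped with a warning.
    """
    arr = samples.to_array()  # (n_draws, 4): alpha, tau_e, tau_a, sigma
    if len(arr) == 0:
        raise InvalidInputError("empty posterior sample set")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(arr), size=min(n, len(arr)),
                     replace=len(arr) < n)
    t_grid = np.linspace(0.0, spec.T, n_grid)
    builder = (adjoints_max_distance if spec.objective == "distance"
               else adjoints_terminal_velocity)
    s_curves, v_curves = [], []
    for alpha, tau_e, tau_a, _sigma in arr[idx]:
        try:
            p = ModelParameters(samples.gamma, alpha, tau_e, tau_a)
            adj = builder(p, spec.T)
            Q = adj.switching.integral_sq()
            s_star = np.sqrt(spec.s_budget / Q) * adj.switching
            traj = simulate(p, s_star, t_grid, clamp=False, rtol=rtol,
                            atol=rtol * 1e-2)
        except (InvalidInputError, DegenerateParametersError) as err:
            logger.warning("skipping posterior draw %s: %s",
                           (alpha, tau_e, tau_a), err)
            continue
        s_curves.append(np.asarray(s_star(t_grid)))
        v_curves.append(traj.v)
    s_curves = np.asarray(s_curves)
    v_curves = np.asarray(v_curves)
    lo, hi = quantiles
    return {
        "t": t_grid,
        "s_lower": np.quantile(s_curves, lo, axis=0),
        "s_upper": np.quantile(s_curves, hi, axis=0),
        "v_lower": np.quantile(v_curves, lo, axis=0),
        "v_upper": np.quantile(v_curves, hi, axis=0),
        "n_used": len(s_curves),
    }


# --------------------------------------------------------------------------
# bang-bang limit
# --------------------------------------------------------------------------

def switching_function(params: ModelParameters, adjoints: ClosedFormAdjoints, t):
    """``∂H/∂s = τe⁻¹ λ_seff(t) + τa⁻¹ λ_I(t)`` of the relaxed
    (bounded-control, budget-free) problem."""
    return adjoints.switching(t)


def bang_bang_policy(params: ModelParameters, T: float = DEFAULT_HORIZON,
                     s_max: float = 1.0, n_grid: int = 1001) -> StimulusProtocol:
    """Optimal bounded control without a charge budget.

    With the Hamiltonian linear in ``s``, the control sits at ``s_max``
    wherever the switching function is positive and at 0 elsewhere.  For the
    distance objective the switching function is positive on all of
    ``[0, T)``, so the policy is the constant pulse — naive stimulation is
    optimal once the budget is replaced by a field-strength bound.
    """
    if s_max < 0:
        raise InvalidInputError("s_max must be non-negative")
    if s_max == 0:
        return StimulusProtocol.constant(0.0, T)
    adj = adjoints_max_distance(params, T)
    tt = np.linspace(0.0, T, n_grid)
    sign = adj.switching(tt[:-1]) > 0  # t = T excluded: costates vanish there
    # build maximal constant segments
    edges = [0.0]
    vals = [s_max if sign[0] else 0.0]
    for k in range(1, len(sign)):
        want = s_max if sign[k] else 0.0
        if want != vals[-1]:
            edges.append(tt[k])
            vals.append(want)
    edges.append(T)
    return StimulusProtocol(np.asarray(edges), np.asarray(vals))
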