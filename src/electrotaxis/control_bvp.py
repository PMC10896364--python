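"""Two-point boundary-value problems for velocity-tracking stimulation design.

The closed-form controls in :mod:`electrotaxis.control_analytic` maximise
linear functionals of the state; keeping the monolayer at a *constant*
velocity instead leads to quadratic objectives and hence to nonlinear
two-point boundary value problems coupling states and costates:

* **constant velocity** — minimise the integrated squared acceleration
  ``∫₀ᵀ v̇² dt`` subject to the state dynamics and the terminal condition
  ``v(T) = v*``;
* **windowed constant velocity** — minimise ``∫₀ᵀ Φ(t)·(v − v*)² dt`` with a
  smooth bump ``Φ`` localising the tracking requirement to ``[t1, t2]``, and
  no terminal condition.

Because neither objective depends on the control directly, the stationarity
condition alone cannot determine the field; the control enters through a
quadratic regularisation ``ρ∫s² dt`` (weight ``control_weight`` in
:class:`SolverConfig`), giving ``S = −(τe⁻¹λ_seff + τa⁻¹λ_I)/(2ρ)``.  With
the default ρ = 1/2 the regularisation is already negligible against the
tracking terms (velocities are tens of μm/h while the normalised field is
order one), so the solutions sit close to the unpenalised limit; only the
magnitude of the onset field spike is ρ-sensitive.

Solved with SciPy's fourth-order collocation scheme (``solve_bvp``, the
bvp4c algorithm: residual control plus a damped Newton iteration), with the
working tolerances of the reference analysis: relative tolerance 1e-3,
boundary tolerance 1e-6, and a large node cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import (
    DEFAULT_HORIZON,
    REFERENCE_FIELD,
    InvalidInputError,
    ModelParameters,
    NumericalError,
    simulate,
    tau_max,
)

__all__ = [
    "SolverConfig",
    "ConstantVelocityProblem",
    "WindowProblem",
    "BVPSolution",
    "solve_constant_velocity",
    "clamp_control",
    "solve_constant_velocity_capped",
    "grid_search_v_star",
    "bump",
    "solve_window_problem",
    "admissible_t1_interval",
]


# --------------------------------------------------------------------------
# configuration and problem definitions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SolverConfig:
    """Collocation solver settings.

    ``control_weight`` is the quadratic control-regularisation weight ρ
    (normalised-field units): the tracking objectives do not involve the
    field directly, so ρ > 0 is what makes the stationarity condition
    solvable for S.  At the default ρ = 1/2 the penalty is still negligible
    against the tracking terms, so solutions approximate the unpenalised
    problem.
    """

    tol: float = 1e-3
    bc_tol: float = 1e-6
    max_nodes: int = 1_000_000
    n_mesh: int = 400
    control_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.bc_tol <= 0 or self.control_weight <= 0:
            raise InvalidInputError("tolerances and control weight must be positive")


DEFAULT_SOLVER = SolverConfig()


@dataclass(frozen=True)
class ConstantVelocityProblem:
    """Hold the bulk at velocity ``v*`` (μm/h) over the whole horizon.

    ``objective`` selects the tracking functional:

    * ``"acceleration"`` — minimise ``∫v̇² dt`` with the terminal pin
      ``v(T) = v*``; its exact minimiser is the linear velocity ramp
      ``v ≈ v*·t/T`` (plus an onset boundary layer whose field spike is the
      unphysically strong initial stimulus).
    * ``"tracking"`` — minimise ``∫(v − v*)² dt``; the velocity jumps to the
      target quasi-instantly and plateaus there, at the cost of an even
      larger onset spike.  This is the cruise-control reading.
    """

    v_star: float
    T: float = DEFAULT_HORIZON
    s_max: float | None = None     # normalised field cap, if any
    terminal_condition: bool = True
    objective: str = "acceleration"

    def __post_init__(self) -> None:
        if self.v_star < 0:
            raise InvalidInputError("v_star must be non-negative")
        if self.T <= 0:
            raise InvalidInputError("horizon must be positive")
        if self.s_max is not None and self.s_max <= 0:
            raise InvalidInputError("s_max must be positive when given")
        if self.objective not in ("acceleration", "tracking"):
            raise InvalidInputError(f"unknown objective {self.objective!r}")
        if self.objective == "acceleration" and not self.terminal_condition:
            raise InvalidInputError(
                "the acceleration objective needs the terminal condition "
                "(otherwise the zero solution is optimal)")


@dataclass(frozen=True)
class WindowProblem:
    """Hold the bulk at ``v*`` only during ``[t1, t2]`` inside ``[0, T]``.

    ``bump_width`` is the logistic transition scale of the smooth window
    indicator (h); it must be well below ``t1`` so the window edges are
    sharp relative to the waiting time.
    """

    v_star: float
    t1: float
    t2: float | None = None        # default: T - t1 (symmetric window)
    T: float = DEFAULT_HORIZON
    bump_width: float = 1.0 / 50.0

    def __post_init__(self) -> None:
        if self.t2 is None:
            object.__setattr__(self, "t2", self.T - self.t1)
        if not (0.0 < self.t1 < self.t2 < self.T):
            raise InvalidInputError(
                f"need 0 < t1 < t2 < T, got t1={self.t1}, t2={self.t2}, T={self.T}")
        if self.bump_width <= 0:
            raise InvalidInputError("bump_width must be positive")
        if self.v_star < 0:
            raise InvalidInputError("v_star must be non-negative")


@dataclass
class BVPSolution:
    """Converged collocation solution of a tracking problem."""

    mesh: np.ndarray
    v: np.ndarray
    s_eff: np.ndarray
    I: np.ndarray
    lambda_v: np.ndarray
    lambda_seff: np.ndarray
    lambda_I: np.ndarray
    S: np.ndarray                 # normalised control on the mesh
    max_residual: float
    terminal_error: float         # |v(T) − v*| or mean window deviation, μm/h
    initial_field: float          # S(0), normalised
    mean_field: float             # time average of S over [0, T], normalised
    success: bool
    message: str
    v_star: float
    n_nodes: int
    #: mean |v − v*| over the held interval (whole horizon for the
    #: constant-velocity problem, [t1, t2] for the windowed one), μm/h
    tracking_error: float = np.nan

    @property
    def initial_field_physical(self) -> float:
        return self.initial_field * REFERENCE_FIELD

    def control_callable(self):
        """Linear interpolant of the control, zero outside the mesh."""
        mesh, S = self.mesh, self.S
        return lambda t: np.interp(t, mesh, S, left=0.0, right=0.0)


# --------------------------------------------------------------------------
# shared machinery
# --------------------------------------------------------------------------

def _control_from_costates(params: ModelParameters, ls, li, rho: float):
    """Stationarity of the regularised Hamiltonian: S = −(τe⁻¹λs + τa⁻¹λI)/(2ρ)."""
    return -(ls / params.tau_e + li / params.tau_a) / (2.0 * rho)


def _finish(params: ModelParameters, sol, problem_v_star: float,
            terminal_error: float, rho: float,
            tracking_error: float = np.nan) -> BVPSolution:
    mesh = sol.x
    v, se, inh, lv, ls, li = sol.y
    S = _control_from_costates(params, ls, li, rho)
    return BVPSolution(
        mesh=mesh, v=v, s_eff=se, I=inh, lambda_v=lv, lambda_seff=ls,
        lambda_I=li, S=S,
        max_residual=float(np.max(sol.rms_residuals)) if sol.rms_residuals.size else np.nan,
        terminal_error=float(terminal_error),
        initial_field=float(S[0]),
        mean_field=float(np.trapezoid(S, mesh) / (mesh[-1] - mesh[0])),
        success=bool(sol.success), message=str(sol.message),
        v_star=float(problem_v_star), n_nodes=len(mesh),
        tracking_error=float(tracking_error),
    )


# --------------------------------------------------------------------------
# constant-velocity problem (terminal condition, whole horizon)
# --------------------------------------------------------------------------

def solve_constant_velocity(params: ModelParameters,
                            problem: ConstantVelocityProblem,
                            config: SolverConfig = DEFAULT_SOLVER) -> BVPSolution:
    """Hold the bulk at constant velocity: collocation solve of the coupled
    state/costate system.

    For the default ``"acceleration"`` objective (``∫v̇² dt`` + ρ∫s² dt,
    terminal pin ``v(T) = v*``) the costates satisfy::

        dλv/dt  = 2γ(−γv + αs_eff) + γλv
        dλs/dt  = −2α(−γv + αs_eff) − αλv + τe⁻¹λs
        dλI/dt  = τe⁻¹λs + τa⁻¹λI

    with zero initial states and transversality on the free costates
    (``λs(T) = λI(T) = 0``; ``λv(T)`` free because ``v(T)`` is pinned).
    For the ``"tracking"`` objective the λv equation becomes
    ``dλv/dt = −2(v − v*) + γλv`` (and ``λs`` loses its acceleration term);
    without the terminal condition, ``λv(T) = 0`` replaces the pin.
    In both variants the onset field is far above the physiological scale —
    the velocity slope (or level) must jump at t = 0, which the excitation
    cascade can only deliver with a very strong transient field.
    Raises :class:`NumericalError` when collocation fails.
    """
    from scipy.integrate import solve_bvp

    ga, al, te, ta = params.gamma, params.alpha, params.tau_e, params.tau_a
    rho = config.control_weight
    v_star, T = problem.v_star, problem.T
    if v_star == 0.0:
        mesh = np.linspace(0.0, T, config.n_mesh)
        zero = np.zeros_like(mesh)
        return BVPSolution(mesh, zero, zero, zero, zero, zero, zero, zero,
                           0.0, 0.0, 0.0, 0.0, True, "trivial zero solution",
                           0.0, len(mesh), 0.0)
    accel = problem.objective == "acceleration"

    def odes(t, y):
        v, se, inh, lv, ls, li = y
        S = _control_from_costates(params, ls, li, rho)
        acc = -ga * v + al * se
        if accel:
            dlv = 2.0 * ga * acc + ga * lv
            dls = -2.0 * al * acc - al * lv + ls / te
        else:
            dlv = -2.0 * (v - v_star) + ga * lv
            dls = -al * lv + ls / te
        return np.vstack([acc, (S - se - inh) / te, (S - inh) / ta,
                          dlv, dls, ls / te + li / ta])

    def bc(ya, yb):
        terminal = (yb[0] - v_star) if problem.terminal_condition else yb[3]
        return np.array([ya[0], ya[1], ya[2], terminal, yb[4], yb[5]])

    mesh = np.linspace(0.0, T, config.n_mesh)
    guess = np.zeros((6, len(mesh)))
    guess[0] = v_star
    guess[1] = v_star * ga / al
    guess[2] = 1.0
    sol = solve_bvp(odes, bc, mesh, guess, tol=config.tol,
                    bc_tol=config.bc_tol, max_nodes=config.max_nodes)
    if not sol.success:
        raise NumericalError(
            f"constant-velocity BVP failed: {sol.message} "
            f"(max residual {np.max(sol.rms_residuals):.3g})")
    return _finish(params, sol, v_star, abs(sol.y[0, -1] - v_star), rho,
                   tracking_error=float(np.trapezoid(np.abs(sol.y[0] - v_star),
                                                     sol.x) / T))


def clamp_control(S: np.ndarray, s_max: float) -> np.ndarray:
    """Physical realisability clamp: ``min(S, s_max)`` with a floor at 0.

    The cap models the field strength tissues tolerate in vitro; the floor
    reflects that the capped stimulation hardware delivers a non-negative
    field.
    """
    if s_max <= 0:
        raise InvalidInputError("s_max must be positive")
    return np.clip(np.asarray(S, dtype=float), 0.0, s_max)


def solve_constant_velocity_capped(params: ModelParameters,
                                   problem: ConstantVelocityProblem,
                                   config: SolverConfig = DEFAULT_SOLVER) -> BVPSolution:
    """Constant-velocity solution with the control clipped to ``[0, s_max]``.

    The unconstrained BVP is solved first; the clipped control is then
    forward-simulated (clamp on) and the terminal error reported from that
    physically realisable trajectory.
    """
    from dataclasses import replace as _replace

    if problem.s_max is None:
        raise InvalidInputError("problem.s_max is required for the capped solve")
    sol = solve_constant_velocity(params, problem, config)
    S_phys = clamp_control(sol.S, problem.s_max)
    s_fun = lambda t: np.interp(t, sol.mesh, S_phys, left=0.0, right=0.0)
    traj = simulate(params, s_fun, sol.mesh, clamp=True, rtol=1e-8, atol=1e-10)
    span = sol.mesh[-1] - sol.mesh[0]
    return _replace(sol, S=S_phys, v=traj.v, s_eff=traj.s_eff, I=traj.I,
                    terminal_error=abs(traj.v[-1] - problem.v_star),
                    tracking_error=float(np.trapezoid(
                        np.abs(traj.v - problem.v_star), sol.mesh) / span),
                    initial_field=float(S_phys[0]),
                    mean_field=float(np.trapezoid(S_phys, sol.mesh) / span))


def grid_search_v_star(params: ModelParameters,
                       v_range: tuple[float, float] = (0.0, 40.0),
                       n_points: int = 9,
                       T: float = DEFAULT_HORIZON,
                       config: SolverConfig = DEFAULT_SOLVER) -> pd.DataFrame:
    """Sweep target velocities and summarise the required field strengths.

    One row per target: the field at stimulation onset, its time average,
    and the terminal tracking error.  Individual solver failures are
    recorded per row rather than aborting the sweep.
    """
    rows = []
    for v_star in np.linspace(v_range[0], v_range[1], n_points):
        row = {"v_star_um_per_h": float(v_star)}
        try:
            sol = solve_constant_velocity(
                params, ConstantVelocityProblem(v_star=float(v_star), T=T), config)
            row.update({
                "initial_field_normalized": sol.initial_field,
                "mean_field_normalized": sol.mean_field,
                "initial_field_V_per_cm": sol.initial_field * REFERENCE_FIELD,
                "mean_field_V_per_cm": sol.mean_field * REFERENCE_FIELD,
                "terminal_error_um_per_h": sol.terminal_error,
                "converged": True,
            })
        except NumericalError as err:
            row.update({
                "initial_field_normalized": np.nan,
                "mean_field_normalized": np.nan,
                "initial_field_V_per_cm": np.nan,
                "mean_field_V_per_cm": np.nan,
                "terminal_error_um_per_h": np.nan,
                "converged": False,
                "message": str(err),
            })
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# windowed constant-velocity problem
# --------------------------------------------------------------------------

def bump(t, t1: float, t2: float, bump_width: float):
    """Smooth window indicator ``Φ(t)``: product of two logistic ramps.

    ``Φ ≈ 1`` inside ``(t1, t2)``, ``≈ 0`` outside, value 1/2 at each edge,
    transition scale ``bump_width``.
    """
    if t1 >= t2:
        raise InvalidInputError("need t1 < t2")
    if bump_width <= 0:
        raise InvalidInputError("bump_width must be positive")
    t = np.asarray(t, dtype=float)
    out = expit((t - t1) / bump_width) * expit((t2 - t) / bump_width)
    return out if out.ndim else float(out)


def solve_window_problem(params: ModelParameters, problem: WindowProblem,
                         config: SolverConfig = DEFAULT_SOLVER) -> BVPSolution:
    """Minimise ``∫Φ(t)(v − v*)² dt`` (+ ρ∫s² dt), no terminal condition.

    Costates obey::

        dλv/dt = −2Φ(t)(v − v*) + γλv
        dλs/dt = −αλv + τe⁻¹λs
        dλI/dt = τe⁻¹λs + τa⁻¹λI

    with zero initial states and full transversality ``λ(T) = 0``.  The
    reported ``terminal_error`` is the mean absolute deviation of the
    velocity from ``v*`` over the window.
    """
    from scipy.integrate import solve_bvp

    ga, al, te, ta = params.gamma, params.alpha, params.tau_e, params.tau_a
    rho = config.control_weight
    v_star, T = problem.v_star, problem.T
    t1, t2, w = problem.t1, problem.t2, problem.bump_width
    if v_star == 0.0:
        mesh = np.linspace(0.0, T, config.n_mesh)
        zero = np.zeros_like(mesh)
        return BVPSolution(mesh, zero, zero, zero, zero, zero, zero, zero,
                           0.0, 0.0, 0.0, 0.0, True, "trivial zero solution",
                           0.0, len(mesh), 0.0)

    def odes(t, y):
        v, se, inh, lv, ls, li = y
        S = _control_from_costates(params, ls, li, rho)
        phi = bump(t, t1, t2, w)
        return np.vstack([
            -ga * v + al * se,
            (S - se - inh) / te,
            (S - inh) / ta,
            -2.0 * phi * (v - v_star) + ga * lv,
            -al * lv + ls / te,
            ls / te + li / ta,
        ])

    def bc(ya, yb):
        return np.array([ya[0], ya[1], ya[2], yb[3], yb[4], yb[5]])

    mesh = np.linspace(0.0, T, config.n_mesh)
    guess = np.zeros((6, len(mesh)))
    guess[0] = v_star * bump(mesh, t1, t2, max(w, 0.05))
    guess[1] = guess[0] * ga / al
    sol = solve_bvp(odes, bc, mesh, guess, tol=config.tol,
                    bc_tol=config.bc_tol, max_nodes=config.max_nodes)
    if not sol.success:
        raise NumericalError(
            f"window BVP failed: {sol.message} "
            f"(max residual {np.max(sol.rms_residuals):.3g})")
    in_win = (sol.x >= t1) & (sol.x <= t2)
    dev = float(np.mean(np.abs(sol.y[0, in_win] - v_star)))
    return _finish(params, sol, v_star, dev, rho, tracking_error=dev)


def admissible_t1_interval(params: ModelParameters,
                           T: float = DEFAULT_HORIZON) -> tuple[float, float]:
    """Waiting-time band ``((T − τa)/2, τmax)`` for well-behaved window tracking.

    Below the lower end the effective stimulation window is long relative to
    the adaptation timescale and the optimal field becomes unphysically
    strong; above ``τmax`` (the time of peak step response) the field can
    start from zero without overshoot.  An empty interval (lower ≥ upper) is
    possible for short adaptation times and is flagged by the caller
    inspecting the returned endpoints, not by an exception.
    """
    if T <= params.tau_a:
        raise InvalidInputError("admissible interval defined for T > tau_a")
    return ((T - params.tau_a) / 2.0, tau_max(params))
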