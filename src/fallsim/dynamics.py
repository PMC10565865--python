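"""Equations of motion of the counterweighted inverted-pendulum fall platform.

The participant and support platform are idealised as an inverted point-mass
pendulum of mass ``m1`` at height ``L`` above the pivot. A cable wrapped
around a pulley of radius ``r`` on the pendulum axle runs through four
pulleys (wrap angle pi each) to a counterweight of mass ``m2``; drag friction
at each wrap follows the Euler-Eytelwein (capstan) relation, so each wrap
multiplies the cable tension by ``exp(mu_F * pi)``. Summing moments about
the pivot gives a single second-order ODE with constant coefficients,

    theta_ddot = (g L sin(theta) - C1 r g rho) / (L^2 + 4 C1 r^2 rho),

where ``rho = m2 / m1`` is the counterweight ratio and ``C1`` aggregates the
friction cascade over the four wraps. Because the coefficients do not depend
on time or on theta_dot, the ODE admits an exact energy-balance first
integral, used here both as a fast predictor and as the oracle for the
numerical integrator.

Angles are radians internally; ``theta`` is measured from vertical (0 =
upright, pi/2 = horizontal) and increases as the platform falls.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParams",
    "TensionSet",
    "PendulumState",
    "SimulationConfig",
    "Trajectory",
    "UnreachableAngleError",
    "capstan_factor",
    "cable_tensions",
    "angular_acceleration",
    "balance_threshold_ratio",
    "closed_form_speed",
    "simulate_fall",
]

#: effective mass of the support platform added to the participant mass, kg
DEFAULT_PLATFORM_MASS = 14.4
#: counterweight pulley radius, m (half of the 14.76-inch sprocket diameter)
DEFAULT_PULLEY_RADIUS = 0.1875
DEFAULT_G = 9.81
#: number of cable wraps in the pulley cascade, wrap angle pi each
N_WRAPS = 4


class UnreachableAngleError(ValueError):
    """The counterweight stops the fall before the requested angle."""


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of the coupled pendulum-counterweight system.

    Parameters
    ----------
    L : float
        Pendulum length, i.e. centre-of-mass height above the pivot, m.
    r : float
        Counterweight pulley radius, m.
    mu_F : float
        Capstan drag-friction coefficient per wrap, dimensionless.
    m1 : float
        Pendulum mass (participant plus effective platform mass), kg.
    m2 : float
        Counterweight mass, kg.
    g : float
        Gravitational acceleration, m/s^2.
    """

    L: float
    r: float = DEFAULT_PULLEY_RADIUS
    mu_F: float = 0.0
    m1: float = 80.0 + DEFAULT_PLATFORM_MASS
    m2: float = 0.0
    g: float = DEFAULT_G

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError(f"pendulum length L must be positive, got {self.L}")
        if self.r < 0:
            raise ValueError(f"pulley radius r must be nonnegative, got {self.r}")
        if self.mu_F < 0:
            raise ValueError(f"friction coefficient mu_F must be nonnegative, got {self.mu_F}")
        if not self.m1 > 0:
            raise ValueError(f"pendulum mass m1 must be positive, got {self.m1}")
        if self.m2 < 0:
            raise ValueError(f"counterweight mass m2 must be nonnegative, got {self.m2}")
        if not self.g > 0:
            raise ValueError(f"g must be positive, got {self.g}")

    @property
    def rho(self) -> float:
        """Counterweight ratio m2 / m1."""
        return self.m2 / self.m1

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ModelParams":
        return cls(**{k: float(v) for k, v in mapping.items()})

    def replace(self, **changes: float) -> "ModelParams":
        d = self.to_dict()
        d.update(changes)
        return ModelParams(**d)


@dataclass(frozen=True)
class TensionSet:
    """Cable tensions through the four-pulley capstan cascade, N.

    ``F`` is the tension directly above the counterweight; ``Ff[k-1]`` the
    tension after the k-th wrap; ``F_P`` their sum, the total force the cable
    system exerts at the counterweight pulley on the pendulum axle.
    """

    F: float
    Ff: tuple[float, float, float, float]
    F_P: float


@dataclass(frozen=True)
class PendulumState:
    """Instantaneous kinematic state of the platform."""

    t: float
    theta: float
    theta_dot: float
    theta_ddot: float


@dataclass(frozen=True)
class SimulationConfig:
    """Integrator and landmark settings for :func:`simulate_fall`.

    Landmark angles are degrees; 70 deg is the model-readout angle (largest
    angle before mat contact), 85 deg the gym-mat contact, 90 deg horizontal
    (shock absorbers), where integration stops by default.
    """

    readout_deg: float = 70.0
    mat_deg: float = 85.0
    horizontal_deg: float = 90.0
    stop_deg: float = 90.0
    rtol: float = 1e-10
    atol: float = 1e-12
    max_time: float = 30.0


@dataclass
class Trajectory:
    """Integrated fall: state arrays plus interpolated landmark crossings.

    ``events`` maps landmark names (``release``, ``readout_70deg``,
    ``mat_contact_85deg``, ``horizontal_90deg``) to ``(time_s,
    theta_dot_rad_s)`` at the crossing, located by the integrator's event
    root-finding (not the nearest sample). A fall that never starts because
    the counterweight torque dominates at release is flagged ``balanced`` and
    carries no crossings.
    """

    t: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    theta_ddot: np.ndarray
    events: dict[str, tuple[float, float]]
    params: ModelParams
    theta0: float
    balanced: bool = False

    @property
    def states(self) -> list[PendulumState]:
        return [
            PendulumState(float(t), float(q), float(w), float(a))
            for t, q, w, a in zip(self.t, self.theta, self.theta_dot, self.theta_ddot)
        ]

    def event_speed(self, name: str) -> float:
        """theta_dot (rad/s) at a named landmark crossing."""
        return self.events[name][1]

    def sample_angle_deg(self, rate: float) -> tuple[np.ndarray, np.ndarray]:
        """Resample the angle onto a uniform grid, motion-capture style.

        Returns ``(times_s, angle_deg)``. Interpolation is cubic Hermite on
        the integrator's steps (which carry exact angle and angular-velocity
        pairs), so resampling error is far below measurement scale.
        """
        from scipy.interpolate import CubicHermiteSpline

        if self.balanced or len(self.t) < 2:
            raise ValueError("cannot resample a balanced (non-falling) trajectory")
        spline = CubicHermiteSpline(self.t, self.theta, self.theta_dot)
        ts = np.arange(0.0, self.t[-1], 1.0 / rate)
        return ts, np.degrees(spline(ts))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "theta_deg": np.degrees(self.theta),
                "theta_dot": self.theta_dot,
                "theta_ddot": self.theta_ddot,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def events_json(self) -> str:
        block = {
            "theta0_deg": math.degrees(self.theta0),
            "balanced": self.balanced,
            "params": self.params.to_dict(),
            "events": {
                name: {"t": t, "theta_dot": w} for name, (t, w) in self.events.items()
            },
        }
        return json.dumps(block, indent=2)


def capstan_factor(mu_F: float) -> float:
    """Friction aggregation factor of the four-wrap capstan cascade.

    C1 = e^{mu pi} + e^{2 mu pi} + e^{3 mu pi} + e^{4 mu pi}. Equals 4 for a
    frictionless cable and grows strictly with ``mu_F``.
    """
    if mu_F < 0:
        raise ValueError(f"mu_F must be nonnegative, got {mu_F}")
    x = math.exp(mu_F * math.pi)
    return x + x**2 + x**3 + x**4


def cable_tensions(params: ModelParams, theta_ddot: float) -> TensionSet:
    """Tensions through the cascade at a given angular acceleration.

    The counterweight rises four times faster than the cable attachment
    point, so its vertical acceleration is ``4 r theta_ddot`` and the tension
    above it is ``F = 4 m2 r theta_ddot + m2 g``. Each wrap multiplies the
    tension by ``exp(mu_F pi)``; the total at the counterweight pulley is the
    sum of the four wrapped tensions, ``F_P = F * C1``.
    """
    F = 4.0 * params.m2 * params.r * theta_ddot + params.m2 * params.g
    e = math.exp(params.mu_F * math.pi)
    Ff = (F * e, F * e**2, F * e**3, F * e**4)
    return TensionSet(F=F, Ff=Ff, F_P=sum(Ff))


def angular_acceleration(params: ModelParams, theta: float | np.ndarray):
    """Angular acceleration of the platform at angle ``theta`` (radians).

    With no counterweight this reduces exactly to the inverted-pendulum
    characteristic form ``g sin(theta) / L``. The result can be zero or
    negative when the counterweight torque dominates (balanced or reversed
    configuration).
    """
    C1 = capstan_factor(params.mu_F)
    rho = params.rho
    num = params.g * params.L * np.sin(theta) - C1 * params.r * params.g * rho
    den = params.L**2 + 4.0 * C1 * params.r**2 * rho
    return num / den


def balance_threshold_ratio(params: ModelParams, theta0: float) -> float:
    """Counterweight ratio rho at which a release from ``theta0`` balances.

    The fall fails to start iff ``g L sin(theta0) <= C1 r g rho``; this
    returns the critical ``rho = L sin(theta0) / (C1 r)`` (inf for r = 0).
    """
    C1 = capstan_factor(params.mu_F)
    if params.r == 0:
        return math.inf
    return params.L * math.sin(theta0) / (C1 * params.r)


def closed_form_speed(params: ModelParams, theta0: float, theta: float) -> float:
    """Exact angular velocity at ``theta`` for a release from rest at ``theta0``.

    Because the ODE's coefficients are constant, integrating
    ``theta_dot d(theta_dot) = theta_ddot d(theta)`` gives the energy balance

        (L^2 + 4 C1 r^2 rho) theta_dot^2 / 2
            = g L (cos theta0 - cos theta) - C1 r g rho (theta - theta0),

    the gravitational PE released minus the work done lifting the
    counterweight against the friction-amplified cable force. With m2 = 0
    this is the textbook ``sqrt(2 g (cos theta0 - cos theta) / L)``.

    Angles in radians, ``theta >= theta0``.

    Raises
    ------
    UnreachableAngleError
        If the counterweight stops the fall before ``theta`` (negative
        radicand).
    """
    if theta < theta0:
        raise ValueError(f"theta ({theta}) must be >= theta0 ({theta0})")
    C1 = capstan_factor(params.mu_F)
    rho = params.rho
    inertia = params.L**2 + 4.0 * C1 * params.r**2 * rho
    work = params.g * params.L * (math.cos(theta0) - math.cos(theta)) - (
        C1 * params.r * params.g * rho * (theta - theta0)
    )
    radicand = 2.0 * work / inertia
    if radicand < 0:
        if radicand > -1e-15:  # roundoff at theta == theta0
            return 0.0
        raise UnreachableAngleError(
            f"fall from theta0={math.degrees(theta0):.2f} deg never reaches "
            f"theta={math.degrees(theta):.2f} deg with rho={rho:.4f}, mu_F={params.mu_F:.4f}"
        )
    return math.sqrt(radicand)


def _landmark_names(config: SimulationConfig) -> list[tuple[str, float]]:
    marks = [
        (f"readout_{config.readout_deg:g}deg", config.readout_deg),
        (f"mat_contact_{config.mat_deg:g}deg", config.mat_deg),
        (f"horizontal_{config.horizontal_deg:g}deg", config.horizontal_deg),
    ]
    if config.stop_deg not in [d for _, d in marks]:
        marks.append((f"stop_{config.stop_deg:g}deg", config.stop_deg))
    return [(n, math.radians(d)) for n, d in marks if d <= config.stop_deg]


def simulate_fall(
    params: ModelParams,
    theta0: float,
    config: SimulationConfig | None = None,
) -> Trajectory:
    """Numerically integrate a fall released from rest at angle ``theta0`` (radians).

    Integration uses adaptive Runge-Kutta (RK45) at tight tolerances;
    landmark crossings are located by the integrator's event root-finding so
    the recorded crossing velocity matches :func:`closed_form_speed` to
    <1e-6 rad/s. If the counterweight balances or reverses the fall at
    release (``theta_ddot(theta0) <= 0``) the trajectory is returned flagged
    ``balanced`` with no crossings.
    """
    if config is None:
        config = SimulationConfig()
    stop = math.radians(config.stop_deg)
    if not 0.0 < theta0 < stop:
        raise ValueError(
            f"theta0 must lie in (0, {config.stop_deg} deg); got {math.degrees(theta0):.2f} deg"
        )

    alpha0 = angular_acceleration(params, theta0)
    if alpha0 <= 0:
        return Trajectory(
            t=np.array([0.0]),
            theta=np.array([theta0]),
            theta_dot=np.array([0.0]),
            theta_ddot=np.array([alpha0]),
            events={"release": (0.0, 0.0)},
            params=params,
            theta0=theta0,
            balanced=True,
        )

    def rhs(t, y):
        return [y[1], angular_acceleration(params, y[0])]

    landmarks = [(n, a) for n, a in _landmark_names(config) if a > theta0]

    def make_event(angle, terminal):
        def ev(t, y):
            return y[0] - angle

        ev.terminal = terminal
        ev.direction = 1.0
        return ev

    events = [make_event(a, a >= stop) for _, a in landmarks]

    sol = solve_ivp(
        rhs,
        (0.0, config.max_time),
        [theta0, 0.0],
        method="RK45",
        rtol=config.rtol,
        atol=config.atol,
        events=events,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")

    theta = sol.y[0]
    if np.any(np.diff(theta) < 0):
        raise RuntimeError("internal consistency error: pendulum angle not monotone on falling branch")

    ev_map: dict[str, tuple[float, float]] = {"release": (0.0, 0.0)}
    for (name, _angle), t_ev, y_ev in zip(landmarks, sol.t_events, sol.y_events):
        if len(t_ev):
            ev_map[name] = (float(t_ev[0]), float(y_ev[0][1]))

    return Trajectory(
        t=sol.t,
        theta=theta,
        theta_dot=sol.y[1],
        theta_ddot=np.asarray(angular_acceleration(params, theta)),
        events=ev_map,
        params=params,
        theta0=theta0,
    )
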