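"""Fit the fall model to trial data and predict impact velocity.

The estimation problem mirrors the device-validation protocol: each trial
contributes one observable, the platform's angular velocity at the 70-degree
readout angle. Experiment 1 varies the initial lean angle with no
counterweight and fits a single pendulum length ``L``; Experiment 2 holds
the lean angle fixed, varies the counterweight, and fits ``(L, mu_F)``
jointly. Parameters are chosen to maximise the variance accounted for (r^2)
between model-predicted and measured velocities — equivalently, to minimise
the residual sum of squares, which is what the optimiser works on.

The public surface follows the statsmodels convention: build a
:class:`FallVelocityModel` from a trial table, call :meth:`~FallVelocityModel.fit`,
and read estimates, diagnostics and ``summary()`` off the returned
:class:`FallFitResults`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from fallsim.dynamics import (
    DEFAULT_G,
    DEFAULT_PLATFORM_MASS,
    DEFAULT_PULLEY_RADIUS,
    ModelParams,
    UnreachableAngleError,
    balance_threshold_ratio,
    closed_form_speed,
)

__all__ = [
    "ExperimentDataset",
    "FallVelocityModel",
    "FallFitResults",
    "variance_accounted_for",
    "fit_experiment1",
    "fit_experiment2",
    "predict_impact_speed",
    "solve_counterweight",
    "params_from_anthropometrics",
    "InfeasibleTargetError",
]

TRIAL_COLUMNS = ["participant_id", "mass_kg", "theta0_deg", "m2_kg", "omega_at_70"]

DEFAULT_L_BOUNDS = (0.5, 2.0)
DEFAULT_MU_BOUNDS = (0.0, 1.0)
L_SEEDS = (0.8, 1.0, 1.2, 1.4, 1.6, 1.8)
MU_SEEDS = (0.0, 0.1, 0.2, 0.4)


class InfeasibleTargetError(ValueError):
    """The requested impact speed cannot be reached by any counterweight."""


def variance_accounted_for(measured: Sequence[float], predicted: Sequence[float]) -> float:
    """Variance accounted for, r^2 = 1 - SS_residual / SS_total.

    SS_total is taken about the mean of the measured values; the statistic
    can be negative when the model predicts worse than that mean.
    """
    y = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("measured and predicted must be equal-length 1-D sequences of length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("measured values are all identical; r^2 undefined")
    ss_res = float(np.sum((y - p) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class ExperimentDataset:
    """Trial table plus experiment design label.

    ``trials`` columns: participant_id, mass_kg (participant body mass),
    theta0_deg (initial lean angle), m2_kg (counterweight mass),
    omega_at_70 (measured angular velocity at the readout angle, rad/s).
    ``design`` is ``"exp1"`` (lean angle varied, no counterweight) or
    ``"exp2"`` (lean angle fixed, counterweight varied).
    """

    trials: pd.DataFrame
    design: str

    def __post_init__(self):
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        if self.design not in ("exp1", "exp2"):
            raise ValueError(f"design must be 'exp1' or 'exp2', got {self.design!r}")
        if self.design == "exp1" and (self.trials["m2_kg"] != 0).any():
            raise ValueError("experiment-1 design requires all counterweights m2_kg == 0")
        if (self.trials["omega_at_70"] <= 0).any():
            raise ValueError("measured omega_at_70 must be positive")

    def __len__(self) -> int:
        return len(self.trials)

    @classmethod
    def from_csv(cls, trials_path, design: str, roster_path=None) -> "ExperimentDataset":
        """Load a trial-observables CSV, optionally joining participant mass
        from a roster CSV (participant_id, height_cm, mass_kg)."""
        trials = pd.read_csv(trials_path)
        if roster_path is not None and "mass_kg" not in trials.columns:
            roster = pd.read_csv(roster_path)
            trials = trials.merge(roster[["participant_id", "mass_kg"]], on="participant_id")
        return cls(trials=trials, design=design)


class FallVelocityModel:
    """Model of angular velocity at the readout angle as a function of lean
    angle and counterweight, fitted across trials.

    Parameters
    ----------
    data : ExperimentDataset or pandas.DataFrame
        Trial table (see :class:`ExperimentDataset` for columns). A bare
        DataFrame requires ``design``.
    design : str, optional
        ``"exp1"`` fits the pendulum length only (friction fixed at 0 since
        no cable is loaded); ``"exp2"`` fits length and friction jointly.
    platform_mass : float
        Effective platform mass added to each participant's body mass to
        form the pendulum mass m1, kg.
    r, g : float
        Counterweight pulley radius (m) and gravity (m/s^2).
    readout_deg : float
        Angle at which the velocity observable is read, degrees.
    """

    def __init__(
        self,
        data: ExperimentDataset | pd.DataFrame,
        design: Optional[str] = None,
        platform_mass: float = DEFAULT_PLATFORM_MASS,
        r: float = DEFAULT_PULLEY_RADIUS,
        g: float = DEFAULT_G,
        readout_deg: float = 70.0,
    ):
        if isinstance(data, pd.DataFrame):
            if design is None:
                raise ValueError("design required when constructing from a DataFrame")
            data = ExperimentDataset(trials=data, design=design)
        self.data = data
        self.design = data.design
        self.platform_mass = platform_mass
        self.r = r
        self.g = g
        self.readout_deg = readout_deg
        t = data.trials
        self._theta0 = np.radians(t["theta0_deg"].to_numpy(float))
        self._m1 = t["mass_kg"].to_numpy(float) + platform_mass
        self._m2 = t["m2_kg"].to_numpy(float)
        self._y = t["omega_at_70"].to_numpy(float)
        self._readout = math.radians(readout_deg)

    @classmethod
    def from_csv(cls, trials_path, design: str, roster_path=None, **kwargs) -> "FallVelocityModel":
        return cls(ExperimentDataset.from_csv(trials_path, design, roster_path), **kwargs)

    # -- forward model -----------------------------------------------------

    def predict(self, L: float, mu_F: float = 0.0) -> np.ndarray:
        """Model-predicted angular velocity at the readout angle per trial.

        Configurations that never reach the readout (balanced by the
        counterweight) predict 0 rad/s, giving the optimiser a finite,
        heavily penalised residual rather than a hole in the objective.
        """
        out = np.empty(len(self._y))
        for i in range(len(out)):
            p = ModelParams(L=L, r=self.r, mu_F=mu_F, m1=self._m1[i], m2=self._m2[i], g=self.g)
            try:
                out[i] = closed_form_speed(p, self._theta0[i], self._readout)
            except UnreachableAngleError:
                out[i] = 0.0
        return out

    def _ss_res(self, L: float, mu_F: float) -> float:
        return float(np.sum((self._y - self.predict(L, mu_F)) ** 2))

    # -- estimation --------------------------------------------------------

    def fit(
        self,
        L_bounds: tuple[float, float] = DEFAULT_L_BOUNDS,
        mu_bounds: tuple[float, float] = DEFAULT_MU_BOUNDS,
        L_seeds: Sequence[float] = L_SEEDS,
        mu_seeds: Sequence[float] = MU_SEEDS,
    ) -> "FallFitResults":
        """Constrained multi-start fit maximising the variance accounted for.

        Runs a bounded quasi-Newton optimiser (L-BFGS-B) on the residual sum
        of squares from a grid of starting points (length seeds, and for
        experiment 2 friction seeds as well) and keeps the best optimum.
        """
        ss_tot = float(np.sum((self._y - self._y.mean()) ** 2))
        if ss_tot == 0.0:
            raise ValueError("zero variance in measured omegas; r^2 undefined")

        if self.design == "exp1":
            starts = [(s,) for s in L_seeds]
            bounds = [L_bounds]

            def fun(x):
                return self._ss_res(x[0], 0.0)

        else:
            starts = [(sl, sm) for sl in L_seeds for sm in mu_seeds]
            bounds = [L_bounds, mu_bounds]

            def fun(x):
                return self._ss_res(x[0], x[1])

        best = None
        any_converged = False
        for x0 in starts:
            x0 = tuple(float(np.clip(v, lo, hi)) for v, (lo, hi) in zip(x0, bounds))
            res = optimize.minimize(fun, x0, method="L-BFGS-B", bounds=bounds)
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res

        L_hat = float(best.x[0])
        mu_hat = float(best.x[1]) if self.design == "exp2" else 0.0
        fitted = self.predict(L_hat, mu_hat)
        r2 = 1.0 - best.fun / ss_tot
        return FallFitResults(
            model=self,
            L_hat=L_hat,
            mu_F_hat=mu_hat,
            r2=float(r2),
            ss_res=float(best.fun),
            converged=any_converged and bool(best.success),
            n_trials=len(self._y),
            fittedvalues=fitted,
            resid=self._y - fitted,
        )


@dataclass
class FallFitResults:
    """Estimates and diagnostics from :meth:`FallVelocityModel.fit`."""

    model: FallVelocityModel
    L_hat: float
    mu_F_hat: float
    r2: float
    ss_res: float
    converged: bool
    n_trials: int
    fittedvalues: np.ndarray
    resid: np.ndarray

    @property
    def params(self) -> dict[str, float]:
        p = {"L": self.L_hat}
        if self.model.design == "exp2":
            p["mu_F"] = self.mu_F_hat
        return p

    def predict(self, theta0_deg: float, m2: float = 0.0, mass_kg: float = 80.0) -> float:
        """Predicted readout velocity (rad/s) for a new configuration."""
        p = ModelParams(
            L=self.L_hat,
            r=self.model.r,
            mu_F=self.mu_F_hat,
            m1=mass_kg + self.model.platform_mass,
            m2=m2,
            g=self.model.g,
        )
        return closed_form_speed(p, math.radians(theta0_deg), math.radians(self.model.readout_deg))

    def residual_frame(self) -> pd.DataFrame:
        out = self.model.data.trials.copy()
        out["omega_predicted"] = self.fittedvalues
        out["residual"] = self.resid
        return out

    def to_dict(self) -> dict:
        return {
            "design": self.model.design,
            "L_hat": self.L_hat,
            "mu_F_hat": self.mu_F_hat,
            "r2": self.r2,
            "ss_res": self.ss_res,
            "converged": self.converged,
            "n_trials": self.n_trials,
            "readout_deg": self.model.readout_deg,
            "platform_mass": self.model.platform_mass,
            "r": self.model.r,
            "g": self.model.g,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def summary(self) -> str:
        rmse = float(np.sqrt(np.mean(self.resid**2)))
        lines = [
            "          Fall Velocity Model Fit",
            "=" * 46,
            f"Design:              {self.model.design}",
            f"No. trials:          {self.n_trials}",
            f"Readout angle:       {self.model.readout_deg:g} deg",
            f"Converged:           {self.converged}",
            "-" * 46,
            f"Pendulum length L:   {self.L_hat:10.4f} m",
        ]
        if self.model.design == "exp2":
            lines.append(f"Friction mu_F:       {self.mu_F_hat:10.4f}")
        lines += [
            "-" * 46,
            f"Variance accounted:  {self.r2:10.4f}",
            f"Residual SS:         {self.ss_res:10.6f} (rad/s)^2",
            f"RMSE:                {rmse:10.4f} rad/s",
            "=" * 46,
        ]
        return "\n".join(lines)


def fit_experiment1(
    data: ExperimentDataset | pd.DataFrame,
    L_bounds: tuple[float, float] = DEFAULT_L_BOUNDS,
    **model_kwargs,
) -> FallFitResults:
    """Fit the single pendulum length to lean-angle-varied, no-counterweight trials."""
    model = FallVelocityModel(data, design="exp1" if isinstance(data, pd.DataFrame) else None, **model_kwargs)
    if model.design != "exp1":
        raise ValueError(f"fit_experiment1 requires an exp1 dataset, got {model.design}")
    return model.fit(L_bounds=L_bounds)


def fit_experiment2(
    data: ExperimentDataset | pd.DataFrame,
    L_bounds: tuple[float, float] = DEFAULT_L_BOUNDS,
    mu_bounds: tuple[float, float] = DEFAULT_MU_BOUNDS,
    **model_kwargs,
) -> FallFitResults:
    """Jointly fit pendulum length and capstan friction to counterweight-varied trials."""
    model = FallVelocityModel(data, design="exp2" if isinstance(data, pd.DataFrame) else None, **model_kwargs)
    if model.design != "exp2":
        raise ValueError(f"fit_experiment2 requires an exp2 dataset, got {model.design}")
    return model.fit(L_bounds=L_bounds, mu_bounds=mu_bounds)


def params_from_anthropometrics(
    height_cm: float,
    mass_kg: float,
    m2: float = 0.0,
    com_fraction: float = 0.55,
    platform_mass: float = DEFAULT_PLATFORM_MASS,
    r: float = DEFAULT_PULLEY_RADIUS,
    mu_F: float = 0.0,
    g: float = DEFAULT_G,
) -> ModelParams:
    """Build :class:`ModelParams` from participant height and mass.

    The pendulum length defaults to the standing centre-of-mass rule
    ``L = com_fraction * height`` (about 55% of stature); the pendulum mass
    is body mass plus the effective platform mass.
    """
    if not 0 < com_fraction < 1:
        raise ValueError(f"com_fraction must be in (0, 1), got {com_fraction}")
    return ModelParams(
        L=com_fraction * height_cm / 100.0,
        r=r,
        mu_F=mu_F,
        m1=mass_kg + platform_mass,
        m2=m2,
        g=g,
    )


def predict_impact_speed(
    params: ModelParams,
    theta0_deg: float,
    readout_deg: float = 70.0,
) -> float:
    """Angular velocity (rad/s) at ``readout_deg`` for a release from ``theta0_deg``.

    Raises :class:`~fallsim.dynamics.UnreachableAngleError` when the
    counterweight balances the fall (no impact occurs).
    """
    theta0 = math.radians(theta0_deg)
    from fallsim.dynamics import angular_acceleration

    if angular_acceleration(params, theta0) <= 0:
        raise UnreachableAngleError(
            f"configuration is balanced: fall from {theta0_deg:g} deg does not start "
            f"(rho={params.rho:.4f} >= critical {balance_threshold_ratio(params, theta0):.4f})"
        )
    return closed_form_speed(params, theta0, math.radians(readout_deg))


def solve_counterweight(
    params_without_m2: ModelParams,
    theta0_deg: float,
    target_speed: float,
    readout_deg: float = 70.0,
    tol: float = 1e-6,
) -> float:
    """Counterweight mass m2 (kg) producing ``target_speed`` at the readout.

    The readout speed is strictly decreasing in m2 up to the balance
    threshold ``m2* = m1 L sin(theta0) / (C1 r)``, at which the platform no
    longer falls, so the root is unique. A target of exactly 0 maps to the
    threshold mass itself; targets below the speed attained just under the
    threshold (the fall either happens faster than that, or not at all) are
    infeasible, as are targets above the no-counterweight speed.
    """
    if target_speed < 0:
        raise ValueError("target speed must be nonnegative")
    theta0 = math.radians(theta0_deg)
    base = params_without_m2.replace(m2=0.0)
    v_max = predict_impact_speed(base, theta0_deg, readout_deg)
    if target_speed > v_max + tol:
        raise InfeasibleTargetError(
            f"target {target_speed:.4f} rad/s exceeds the no-counterweight speed {v_max:.4f} rad/s"
        )
    m2_star = balance_threshold_ratio(base, theta0) * base.m1
    if target_speed == 0.0:
        return m2_star
    if math.isinf(m2_star):
        raise InfeasibleTargetError("pulley radius r = 0: the counterweight has no effect")

    def f(m2: float) -> float:
        return predict_impact_speed(base.replace(m2=m2), theta0_deg, readout_deg) - target_speed

    if f(0.0) <= 0.0:
        return 0.0
    hi = m2_star * (1.0 - 1e-12)
    if f(hi) > 0.0:
        v_min = f(hi) + target_speed
        raise InfeasibleTargetError(
            f"target {target_speed:.4f} rad/s is below the slowest achievable fall "
            f"({v_min:.4f} rad/s just under the balance threshold); heavier counterweights "
            "prevent the fall entirely"
        )
    return float(optimize.brentq(f, 0.0, hi, xtol=tol * 1e-3, rtol=8.9e-16))
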