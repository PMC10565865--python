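"""Synthetic cohorts and fall trials emulating the two validation experiments.

No public dataset accompanies the device, so testable inputs are produced
here: participant rosters drawn from the published cohort anthropometrics
(truncated normal heights and masses), and trial tables following the two
experiment designs —

* experiment 1: eight falls per participant, two at each of four initial
  lean angles (65, 52, 45, 39 deg, +-3 deg set-up jitter), no counterweight;
* experiment 2: eight falls per participant from a fixed 37 +- 1 deg lean,
  two at each of four counterweight levels (6.8, 12.4, 17.9, 29.1 %BW).

Counterweight percentages are converted to kilograms against the corrected
total mass (participant + 14.4 kg effective platform mass) by default; a
body-mass-only basis is available. Each trial's angular-velocity observable
comes from the exact energy-balance solution of the forward model with
additive Gaussian measurement noise; optionally a 150 Hz angle trace and a
ground-reaction-force step trace are synthesised for pipeline testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from fallsim.dynamics import (
    DEFAULT_G,
    DEFAULT_PLATFORM_MASS,
    DEFAULT_PULLEY_RADIUS,
    ModelParams,
    SimulationConfig,
    Trajectory,
    angular_acceleration,
    closed_form_speed,
    simulate_fall,
)
from fallsim.fitting import ExperimentDataset
from fallsim.processing import SampledSeries, DEFAULT_RATE

__all__ = [
    "CohortSpec",
    "ExperimentDesign",
    "EXP1_YOUNGER",
    "EXP1_OLDER",
    "EXP2_COHORT",
    "EXP1_DESIGN",
    "EXP2_DESIGN",
    "generate_cohort",
    "generate_exp1_cohort",
    "generate_trials",
    "synthesize_trial_series",
    "corrected_counterweight_pct",
]

#: GRF plateau after platform contact, N (only the >10 N rule is exercised)
GRF_STEP_N = 50.0


@dataclass(frozen=True)
class CohortSpec:
    """Anthropometric distribution of one participant group.

    Heights (cm) and masses (kg) are drawn from normal distributions
    truncated to the published ranges; the effective pendulum length is
    ``com_fraction`` of height.
    """

    n: int
    height_mean: float
    height_sd: float
    height_range: tuple[float, float]
    mass_mean: float
    mass_sd: float
    mass_range: tuple[float, float]
    com_fraction: float = 0.55
    label: str = "cohort"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.height_sd < 0 or self.mass_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not 0 < self.com_fraction < 1:
            raise ValueError("com_fraction must be in (0, 1)")


# Published cohort statistics of the two validation experiments.
EXP1_YOUNGER = CohortSpec(
    n=14,
    height_mean=173.9, height_sd=10.0, height_range=(159.0, 191.0),
    mass_mean=78.9, mass_sd=4.6, mass_range=(54.4, 103.0),
    label="exp1-younger",
)
EXP1_OLDER = CohortSpec(
    n=13,
    height_mean=175.2, height_sd=9.0, height_range=(157.0, 189.0),
    mass_mean=77.3, mass_sd=15.0, mass_range=(56.3, 104.8),
    label="exp1-older",
)
EXP2_COHORT = CohortSpec(
    n=13,
    height_mean=185.7, height_sd=6.1, height_range=(174.0, 193.0),
    mass_mean=82.4, mass_sd=5.6, mass_range=(77.4, 92.1),
    label="exp2-younger",
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Experiment layout: conditions, set-up jitter, and measurement noise.

    ``lean_angles`` maps nominal initial lean angles (deg) to their set-up
    jitter sd; ``counterweights_pct_bw`` likewise for counterweight levels in
    percent body weight (empty for experiment 1). Each condition is repeated
    ``trials_per_condition`` times in a per-participant random order.
    ``noise_sd_omega`` is the sd (rad/s) of additive Gaussian noise on the
    measured velocity observable.
    """

    design_id: str
    lean_angles: tuple[tuple[float, float], ...]
    counterweights_pct_bw: tuple[tuple[float, float], ...] = ()
    trials_per_condition: int = 2
    noise_sd_omega: float = 0.05
    pct_basis: str = "corrected"  # 'corrected' (body + platform) or 'body'

    def __post_init__(self):
        for a, _sd in self.lean_angles:
            if not 0 < a < 90:
                raise ValueError(f"lean angle {a} deg outside (0, 90)")
        if self.pct_basis not in ("corrected", "body"):
            raise ValueError("pct_basis must be 'corrected' or 'body'")

    @property
    def conditions(self) -> list[tuple[float, float, float, float]]:
        """(theta0_deg, theta0_sd, pct_bw, pct_sd) per condition."""
        if self.counterweights_pct_bw:
            (a, asd), = self.lean_angles
            return [(a, asd, p, psd) for p, psd in self.counterweights_pct_bw]
        return [(a, asd, 0.0, 0.0) for a, asd in self.lean_angles]


EXP1_DESIGN = ExperimentDesign(
    design_id="exp1",
    lean_angles=((65.0, 3.0), (52.0, 3.0), (45.0, 3.0), (39.0, 3.0)),
)
EXP2_DESIGN = ExperimentDesign(
    design_id="exp2",
    lean_angles=((37.0, 1.0),),
    counterweights_pct_bw=((6.8, 0.4), (12.4, 0.8), (17.9, 1.1), (29.1, 1.7)),
)


def _truncnorm(mean, sd, lo, hi, n, rng):
    if sd == 0:
        return np.full(n, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(
    spec: CohortSpec,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    id_offset: int = 0,
) -> pd.DataFrame:
    """Draw a participant roster from a cohort specification.

    Returns columns participant_id, group, height_cm, mass_kg, L (pendulum
    length, m). Reproducible under a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    heights = _truncnorm(spec.height_mean, spec.height_sd, *spec.height_range, spec.n, rng)
    masses = _truncnorm(spec.mass_mean, spec.mass_sd, *spec.mass_range, spec.n, rng)
    return pd.DataFrame(
        {
            "participant_id": [f"P{id_offset + i + 1:03d}" for i in range(spec.n)],
            "group": spec.label,
            "height_cm": heights,
            "mass_kg": masses,
            "L": spec.com_fraction * heights / 100.0,
        }
    )


def generate_exp1_cohort(seed: Optional[int] = None) -> pd.DataFrame:
    """Pooled experiment-1 roster: 14 younger + 13 older adults."""
    rng = np.random.default_rng(seed)
    younger = generate_cohort(EXP1_YOUNGER, rng=rng)
    older = generate_cohort(EXP1_OLDER, rng=rng, id_offset=len(younger))
    return pd.concat([younger, older], ignore_index=True)


def corrected_counterweight_pct(m2: float, participant_mass: float, platform_mass: float = DEFAULT_PLATFORM_MASS) -> float:
    """Counterweight as a percentage of the corrected total mass
    (participant body mass plus effective platform mass)."""
    if participant_mass <= 0 or platform_mass <= 0:
        raise ValueError("masses must be positive")
    return 100.0 * m2 / (participant_mass + platform_mass)


def _counterweight_kg(pct: float, mass_kg: float, platform_mass: float, basis: str) -> float:
    base = mass_kg + platform_mass if basis == "corrected" else mass_kg
    return pct / 100.0 * base


def generate_trials(
    roster: pd.DataFrame,
    design: ExperimentDesign,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    true_L: Optional[float] = None,
    true_mu_F: Optional[float] = None,
    r: float = DEFAULT_PULLEY_RADIUS,
    platform_mass: float = DEFAULT_PLATFORM_MASS,
    g: float = DEFAULT_G,
    readout_deg: float = 70.0,
    include_series: bool = False,
    rate: float = DEFAULT_RATE,
) -> tuple[ExperimentDataset, dict]:
    """Simulate an experiment: per-participant randomised condition orders,
    jittered set-ups, the forward model, and noisy velocity observables.

    ``true_L`` overrides the per-participant centre-of-mass length with one
    global generating length (as in parameter-recovery studies); ``true_mu_F``
    defaults to 0 for experiment 1 and 0.18 for experiment 2. Counterweight
    configurations that balance the platform (the fall never starts) are kept
    in the returned table flagged ``balanced`` with no velocity observable;
    :class:`~fallsim.fitting.ExperimentDataset` receives the falling trials.

    Returns ``(dataset, extras)`` where ``extras`` carries the full trial
    table (including balanced trials) and, when ``include_series`` is set,
    per-trial raw angle and GRF traces.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if true_mu_F is None:
        true_mu_F = 0.18 if design.counterweights_pct_bw else 0.0

    conditions = design.conditions
    rows = []
    series: dict[str, tuple[SampledSeries, SampledSeries]] = {}
    readout = math.radians(readout_deg)

    for _, person in roster.iterrows():
        L = true_L if true_L is not None else person["L"]
        m1 = person["mass_kg"] + platform_mass
        order = rng.permutation(np.repeat(np.arange(len(conditions)), design.trials_per_condition))
        for k, ci in enumerate(order):
            a_nom, a_sd, p_nom, p_sd = conditions[ci]
            # set-up jitter truncated below the readout: a release at or
            # above 70 deg would carry no velocity observable
            theta0_deg = float(rng.normal(a_nom, a_sd))
            while not 0.0 < theta0_deg <= readout_deg - 1.0:
                theta0_deg = float(rng.normal(a_nom, a_sd))
            pct = float(max(rng.normal(p_nom, p_sd), 0.0)) if p_nom > 0 else 0.0
            m2 = _counterweight_kg(pct, person["mass_kg"], platform_mass, design.pct_basis)
            params = ModelParams(L=L, r=r, mu_F=true_mu_F, m1=m1, m2=m2, g=g)
            theta0 = math.radians(theta0_deg)
            trial_id = f"{person['participant_id']}_T{k + 1:02d}"
            balanced = angular_acceleration(params, theta0) <= 0
            if balanced:
                omega = np.nan
            else:
                truth = closed_form_speed(params, theta0, readout)
                omega = truth + rng.normal(0.0, design.noise_sd_omega)
                while omega <= 0:  # measured speeds are positive by construction
                    omega = truth + rng.normal(0.0, design.noise_sd_omega)
                if include_series:
                    series[trial_id] = synthesize_trial_series(params, theta0, rate=rate, rng=rng)
            rows.append(
                {
                    "trial_id": trial_id,
                    "participant_id": person["participant_id"],
                    "mass_kg": person["mass_kg"],
                    "condition": ci,
                    "theta0_deg": theta0_deg,
                    "pct_bw": pct,
                    "m2_kg": m2,
                    "omega_at_70": omega,
                    "balanced": balanced,
                }
            )

    table = pd.DataFrame(rows)
    falling = table[~table["balanced"]].reset_index(drop=True)
    dataset = ExperimentDataset(trials=falling, design=design.design_id)
    extras = {"all_trials": table, "series": series, "true_L": true_L, "true_mu_F": true_mu_F}
    return dataset, extras


def synthesize_trial_series(
    params: ModelParams,
    theta0: float,
    rate: float = DEFAULT_RATE,
    rest_duration: float = 0.5,
    rng: Optional[np.random.Generator] = None,
    grf_step: float = GRF_STEP_N,
) -> tuple[SampledSeries, SampledSeries]:
    """Synthesise raw 150 Hz angle (deg) and vertical GRF (N) traces for one fall.

    The trace holds at the initial lean for ``rest_duration`` (the platform
    is held by the electromagnet until the unpredictable release), then
    follows the integrated fall. Rotation is simulated to 5 degrees below
    horizontal, where the bumpers stop the platform; post-contact mechanics
    (mat and shock-absorber deceleration from 85 deg on) are deliberately not
    modelled — the model readout lives at 70 deg, before any contact. The
    GRF trace is a minimal step: zero until the platform reaches horizontal,
    then a constant plateau.
    """
    config = SimulationConfig(stop_deg=95.0)
    traj = simulate_fall(params, theta0, config)
    ts, angle_fall = traj.sample_angle_deg(rate)

    n_rest = int(round(rest_duration * rate))
    angle = np.concatenate([np.full(n_rest, math.degrees(theta0)), angle_fall])

    t_horizontal = traj.events["horizontal_90deg"][0]
    grf = np.zeros_like(angle)
    i_impact = n_rest + int(np.ceil(t_horizontal * rate))
    grf[i_impact:] = grf_step

    return (
        SampledSeries(rate=rate, values=angle, quantity="angle-deg"),
        SampledSeries(rate=rate, values=grf, quantity="grf-N"),
    )
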