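"""Synthetic fed-batch CHO cultivation runs.

A daily difference-equation model of a 13-day (day 0-12) fed-batch
cultivation of an IgG1-producing CHO cell line in a small-scale stirred
bioreactor.  The model is deliberately coarse -- one update per day,
matching the daily offline sampling cadence of the real process -- but it
carries the response structure the downstream machine-learning analysis
assumes:

* Monod-type growth limitation by glucose, glutamine and dissolved oxygen,
  with a Gaussian pH optimum for growth near pH 7.15;
* a distinct, higher pH optimum for specific productivity (near pH 7.45),
  so growth and production trade off against each other and the final
  titer has an interior pH optimum between the two;
* glutamine availability boosting specific productivity;
* starvation-driven death once glucose is exhausted, plus an age-dependent
  death term producing the characteristic late-phase VCD decline;
* daily feed boluses (macronutrient/micronutrient feeds) from a
  configurable start day and a glucose top-up to a target concentration
  from day 5 onward;
* multiplicative lognormal measurement noise with configurable CV.

Default kinetic parameters were calibrated once against published
operating points of the real process (standard conditions: VCD_max about
23.7e6 cells/mL, final titer about 3.0 g/L, max diameter about 17.3 um,
Q_P about 22 pg/(cell*day); the best optimized condition: final titer
about 4.65 g/L at pH 7.4 with rich glutamine and early feeding; batch
without glucose feed: about 1.8 g/L) and then frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NONE_DAY",
    "ProcessCondition",
    "SimulatorParams",
    "DailySample",
    "CultivationRun",
    "SimulationError",
    "STD_CONDITION",
    "simulate_run",
    "build_design",
    "generate_dataset",
    "DESIGN_KINDS",
]

#: numeric sentinel for "no feed" / "no pH shift" in flat tables.
NONE_DAY = -1

N_DAYS = 13  # day 0 .. day 12


class SimulationError(RuntimeError):
    """Raised when the state update produces an invalid value."""


@dataclass(frozen=True)
class ProcessCondition:
    """The run-level setpoints defining one cultivation.

    ``feed_start_day`` / ``ph_shift_day`` use ``NONE_DAY`` (-1) for
    "never"; a pH shift raises the setpoint to ``ph_shift_value`` from the
    shift day onward and holds it there.
    """

    ph_setpoint: float = 7.15
    do_setpoint: float = 60.0
    vcd0: float = 0.3  # 1e6 cells/mL
    glc_start: float = 6.0  # g/L
    gln_start: float = 6.0  # mM
    glc_feed_target: float = 5.0  # g/L; 0 = no glucose top-up
    feed_start_day: int = 3  # 1..5 or NONE_DAY
    ph_shift_day: int = NONE_DAY  # 0..5 or NONE_DAY
    ph_shift_value: float = 7.3

    def validate(self) -> None:
        if not 6.6 <= self.ph_setpoint <= 7.6:
            raise ValueError(f"ph_setpoint {self.ph_setpoint} outside [6.6, 7.6]")
        if not 20.0 <= self.do_setpoint <= 100.0:
            raise ValueError(f"do_setpoint {self.do_setpoint} outside [20, 100]")
        if not self.vcd0 > 0:
            raise ValueError("vcd0 must be positive (no inoculum, no culture)")
        for name in ("glc_start", "gln_start", "glc_feed_target"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.feed_start_day != NONE_DAY and self.feed_start_day not in range(1, 6):
            raise ValueError("feed_start_day must be NONE_DAY or in 1..5")
        if self.ph_shift_day != NONE_DAY and self.ph_shift_day not in range(0, 6):
            raise ValueError("ph_shift_day must be NONE_DAY or in 0..5")

    def ph_on_day(self, day: int) -> float:
        if self.ph_shift_day != NONE_DAY and day >= self.ph_shift_day:
            return self.ph_shift_value
        return self.ph_setpoint


@dataclass(frozen=True)
class SimulatorParams:
    """Kinetic and noise parameters of the cultivation model.

    Rates are per day; concentrations in g/L (glucose, lactate, titer) or
    mM (glutamine); cell densities in 1e6 cells/mL.  Defaults are the
    frozen calibration (see module docstring).
    """

    mu_max: float = 1.054
    ph_opt: float = 7.15
    ph_width: float = 0.862
    do_halfsat: float = 9.0
    k_glc: float = 0.45
    k_gln: float = 0.152
    death_rate_base: float = 0.0401
    death_age_gain: float = 46.33  # scales the cubic age term of the death rate
    starvation_death_boost: float = 0.38
    yield_glc: float = 0.11  # g/L consumed per (1e6 cells/mL)*day
    yield_gln: float = 0.0395  # mM consumed per (1e6 cells/mL)*day
    fma_glc_bolus: float = 0.5  # g/L glucose per daily macronutrient feed
    fmb_gln_bolus: float = 0.53  # mM glutamine per daily micronutrient feed
    qp_alpha: float = 7.736  # pg/cell, growth-associated production
    qp_beta: float = 12.845  # pg/(cell*day), non-growth-associated
    qp_ph_opt: float = 7.477
    qp_ph_width: float = 0.373
    qp_gln_gain: float = 1.105
    lac_yield: float = 0.55  # g lactate per g glucose consumed
    diameter_base: float = 14.6  # um at inoculation
    diameter_age_gain: float = 1.018  # um per low-growth day
    noise_cv: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        positive = (
            "mu_max", "ph_width", "do_halfsat", "k_glc", "k_gln",
            "yield_glc", "yield_gln", "qp_ph_width", "diameter_base",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("death_rate_base", "starvation_death_boost", "death_age_gain",
                     "qp_alpha", "qp_beta", "qp_gln_gain", "lac_yield",
                     "diameter_age_gain", "fma_glc_bolus", "fmb_gln_bolus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.noise_cv <= 0.5:
            raise ValueError("noise_cv must lie in [0, 0.5]")


@dataclass(frozen=True)
class DailySample:
    """One day's offline measurements."""

    day: int
    vcd: float  # 1e6 cells/mL
    viability: float  # %
    diameter: float  # um
    glc: float  # g/L
    gln: float  # mM
    lac: float  # g/L
    titer: float  # g/L
    flags: frozenset = frozenset()


@dataclass(frozen=True)
class CultivationRun:
    """A condition plus its 13 daily samples and QC metadata."""

    run_id: str
    condition: ProcessCondition
    samples: tuple
    flags: frozenset = frozenset()
    metadata: dict = field(default_factory=dict)

    @property
    def titers(self) -> np.ndarray:
        return np.array([s.titer for s in self.samples])

    @property
    def vcds(self) -> np.ndarray:
        return np.array([s.vcd for s in self.samples])

    @property
    def vcd_max(self) -> float:
        return float(self.vcds.max())

    @property
    def final_titer(self) -> float:
        return float(self.samples[-1].titer)


STD_CONDITION = ProcessCondition()


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return math.exp(rng.normal(-0.5 * sigma * sigma, sigma))


def _check_finite(day: int, **state: float) -> None:
    for name, value in state.items():
        if not math.isfinite(value):
            raise SimulationError(f"non-finite {name} on day {day}")
        if name in ("glc", "gln", "lac") and value < 0:
            raise SimulationError(f"negative {name} on day {day}")


def simulate_run(
    condition: ProcessCondition,
    params: SimulatorParams = SimulatorParams(),
    seed: int = 0,
    run_id: str = "run",
) -> CultivationRun:
    """Simulate one cultivation from day 0 through day 12.

    Daily sampling happens before feeding (the offline sample is drawn,
    then the feed bolus and glucose top-up are applied, then the culture
    evolves to the next day).  Measurement noise is multiplicative
    lognormal with CV ``params.noise_cv``; titer noise is applied to the
    daily production increment so the measured titer stays non-decreasing.
    """
    condition.validate()
    params.validate()
    rng = np.random.default_rng(seed)
    cv = params.noise_cv
    # run-level biological variability (inoculum fitness, clone drift):
    # lognormal factors applied to growth and productivity for the whole run
    bio_mu = _lognormal_factor(rng, cv / 5 if cv else 0.0)
    bio_qp = _lognormal_factor(rng, cv)

    vcd = condition.vcd0
    glc = condition.glc_start
    gln = condition.gln_start
    lac = 0.0
    titer = 0.0
    diameter = params.diameter_base
    cum_starv = 0.0  # days spent glucose-starved, drives viability decline
    qp_sum = 0.0

    samples = []

    def record(day: int) -> None:
        viability = 100.0 / (1.0 + math.exp(1.5 * cum_starv - 4.0 + 0.15 * day))
        s = DailySample(
            day=day,
            vcd=max(vcd * _lognormal_factor(rng, cv), 0.0),
            viability=min(max(viability * _lognormal_factor(rng, cv / 2 if cv else 0.0), 0.0), 100.0),
            diameter=diameter * _lognormal_factor(rng, cv / 4 if cv else 0.0),
            glc=glc * _lognormal_factor(rng, cv),
            gln=gln * _lognormal_factor(rng, cv),
            lac=lac * _lognormal_factor(rng, cv),
            titer=titer,
        )
        samples.append(s)

    record(0)
    for day in range(N_DAYS - 1):
        # feeds applied after the day's sample
        if condition.feed_start_day != NONE_DAY and day >= condition.feed_start_day:
            glc += params.fma_glc_bolus
            gln += params.fmb_gln_bolus
        if day >= 5 and condition.glc_feed_target > 0 and glc < condition.glc_feed_target:
            glc = condition.glc_feed_target

        ph = condition.ph_on_day(day)
        ph_growth = math.exp(-(((ph - params.ph_opt) / params.ph_width) ** 2))
        do_fac = condition.do_setpoint / (params.do_halfsat + condition.do_setpoint)
        glc_fac = glc / (params.k_glc + glc)
        gln_fac = gln / (params.k_gln + gln)
        mu = params.mu_max * ph_growth * do_fac * glc_fac * gln_fac * bio_mu

        kd = params.death_rate_base * (1.0 + params.death_age_gain * (day / 12.0) ** 3)
        if glc < 0.5:
            kd += params.starvation_death_boost
        # cap the specific death rate below 1/day so the population decays
        # multiplicatively and never hits exactly zero
        kd = min(kd, 0.85)

        vcd_next = max(vcd * (1.0 + mu - kd), 0.0)
        vcd_avg = 0.5 * (vcd + vcd_next)

        ph_qp = math.exp(-(((ph - params.qp_ph_opt) / params.qp_ph_width) ** 2))
        qp = (params.qp_alpha * mu + params.qp_beta * ph_qp) * (
            1.0 + params.qp_gln_gain * gln_fac
        ) * glc_fac * bio_qp
        qp_sum += qp
        titer += qp * vcd_avg / 1000.0 * _lognormal_factor(rng, cv / 2 if cv else 0.0)

        glc_cons = min(glc, params.yield_glc * vcd_avg)
        glc -= glc_cons
        gln -= min(gln, params.yield_gln * vcd_avg)
        lac += params.lac_yield * glc_cons
        if glc < 1.0:  # lactate re-consumption once glucose runs low
            lac = max(lac - 0.25 * lac, 0.0)

        diameter += params.diameter_age_gain * (1.0 - mu / params.mu_max)
        if glc < 0.5:
            cum_starv += 1.0
        vcd = vcd_next
        _check_finite(day + 1, vcd=vcd, glc=glc, gln=gln, lac=lac, titer=titer,
                      diameter=diameter)
        record(day + 1)

    metadata = {
        "seed": int(seed),
        "noise_cv": cv,
        "mean_qp_internal": qp_sum / (N_DAYS - 1),
    }
    return CultivationRun(
        run_id=run_id,
        condition=condition,
        samples=tuple(samples),
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# experimental designs
# ---------------------------------------------------------------------------

DESIGN_KINDS = (
    "STD",
    "CCC_PH_DO",
    "PH_SHIFT",
    "FEED_MEDIA",
    "EXTREME_COMBOS",
    "FACTORIAL_3",
    "GLC_VARIATION",
    "FULL_58",
)

_DEFAULT_RANGES = {"ph": (6.8, 7.5), "do": (20.0, 100.0)}


def _std_design() -> list:
    return [STD_CONDITION] * 3


def _ccc_ph_do(ranges: dict) -> list:
    """Two-factor central composite circumscribed design over pH and DO.

    Axial points sit on the stated bounds; factorial points at
    center +- range/(2*sqrt(2)); plus the center point and two center
    replicates (9 distinct conditions, 11 runs).
    """
    ph_lo, ph_hi = ranges["ph"]
    do_lo, do_hi = ranges["do"]
    if ph_lo > ph_hi or do_lo > do_hi:
        raise ValueError("inverted factor bounds")
    ph_c, do_c = (ph_lo + ph_hi) / 2, (do_lo + do_hi) / 2
    ph_f = (ph_hi - ph_lo) / (2 * math.sqrt(2))
    do_f = (do_hi - do_lo) / (2 * math.sqrt(2))
    conds = []
    for sp in (-1, 1):
        for sd in (-1, 1):
            conds.append(replace(STD_CONDITION,
                                 ph_setpoint=round(ph_c + sp * ph_f, 3),
                                 do_setpoint=round(do_c + sd * do_f, 1)))
    conds += [
        replace(STD_CONDITION, ph_setpoint=ph_lo, do_setpoint=do_c),
        replace(STD_CONDITION, ph_setpoint=ph_hi, do_setpoint=do_c),
        replace(STD_CONDITION, ph_setpoint=ph_c, do_setpoint=do_lo),
        replace(STD_CONDITION, ph_setpoint=ph_c, do_setpoint=do_hi),
        replace(STD_CONDITION, ph_setpoint=ph_c, do_setpoint=do_c),
    ]
    # two additional center replicates (common CCC practice)
    conds += [conds[-1]] * 2
    return conds


def _ph_shift() -> list:
    conds = []
    for day in (0, 3, 4, 5):
        c = replace(STD_CONDITION, ph_setpoint=7.1, ph_shift_day=day,
                    ph_shift_value=7.3)
        conds += [c, c]  # duplicates
    return conds


def _feed_media() -> list:
    batch = replace(STD_CONDITION, feed_start_day=NONE_DAY, glc_feed_target=0.0)
    conds = [batch] * 3  # batch in triplicate
    conds.append(replace(batch, glc_start=7.5))  # batch + richer medium
    conds.append(replace(STD_CONDITION, gln_start=9.0))
    conds.append(replace(STD_CONDITION, gln_start=12.0))
    conds.append(replace(STD_CONDITION, glc_start=9.0))
    conds.append(replace(STD_CONDITION, glc_start=12.0))
    for day in (1, 2, 4, 5):
        conds.append(replace(STD_CONDITION, feed_start_day=day))
    return conds


def _extreme_combos() -> list:
    return [
        replace(STD_CONDITION, ph_setpoint=7.4, do_setpoint=90, glc_start=6.8, gln_start=1.0),
        replace(STD_CONDITION, ph_setpoint=7.3, do_setpoint=90, gln_start=1.0),
        replace(STD_CONDITION, ph_setpoint=7.35, do_setpoint=90, gln_start=1.0),
        replace(STD_CONDITION, ph_setpoint=7.35, do_setpoint=90, gln_start=2.0),
        # the two serendipitously good pH/DO combinations
        replace(STD_CONDITION, ph_setpoint=7.3, do_setpoint=40),
        replace(STD_CONDITION, ph_setpoint=7.4, do_setpoint=60),
    ]


def _factorial_3() -> list:
    conds = []
    for feed_day in (1, 5):
        for vcd0 in (0.1, 0.5):
            for gln in (6.0, 12.0):
                conds.append(replace(STD_CONDITION, feed_start_day=feed_day,
                                     vcd0=vcd0, gln_start=gln))
    center = replace(STD_CONDITION, feed_start_day=3, vcd0=0.3, gln_start=9.0)
    return conds + [center, center]


def _glc_variation() -> list:
    glc_minus = replace(STD_CONDITION, glc_feed_target=0.0)
    glc_plus = replace(STD_CONDITION, glc_feed_target=9.0)
    glc_mid = replace(STD_CONDITION, glc_feed_target=7.0)
    return [glc_minus] * 3 + [glc_plus] * 3 + [glc_mid] * 2


def build_design(kind: str, ranges: dict | None = None) -> list:
    """Return the deterministic condition list for a named design.

    ``FULL_58`` concatenates every group into the 58-run dataset layout
    (3 standard runs + 55 varied runs) used throughout the analysis.
    """
    ranges = {**_DEFAULT_RANGES, **(ranges or {})}
    for lo, hi in ranges.values():
        if lo > hi:
            raise ValueError("inverted factor bounds")
    builders = {
        "STD": _std_design,
        "CCC_PH_DO": lambda: _ccc_ph_do(ranges),
        "PH_SHIFT": _ph_shift,
        "FEED_MEDIA": _feed_media,
        "EXTREME_COMBOS": _extreme_combos,
        "FACTORIAL_3": _factorial_3,
        "GLC_VARIATION": _glc_variation,
    }
    if kind == "FULL_58":
        conds = []
        for k in ("STD", "CCC_PH_DO", "PH_SHIFT", "FEED_MEDIA",
                  "EXTREME_COMBOS", "FACTORIAL_3", "GLC_VARIATION"):
            conds += builders[k]()
        assert len(conds) == 58
        return conds
    if kind not in builders:
        raise ValueError(f"unknown design kind {kind!r}; choose from {DESIGN_KINDS}")
    return builders[kind]()


def child_seed(seed: int, index: int) -> int:
    """Stable per-run seed derived from a master seed (kept below 2^31)."""
    return int(np.random.SeedSequence((int(seed), int(index))).generate_state(1)[0] % (2**31))


def generate_dataset(
    design: list,
    params: SimulatorParams = SimulatorParams(),
    seed: int = 0,
    flag_fraction: float = 0.0,
) -> list:
    """Simulate one run per condition with deterministically derived seeds.

    ``flag_fraction`` marks that fraction of (run, day) samples with an
    ANALYTICS_FAILURE flag, to exercise downstream cleaning; the flagged
    samples keep their values.
    """
    if not design:
        raise ValueError("empty design")
    runs = []
    for i, cond in enumerate(design):
        try:
            run = simulate_run(cond, params, seed=child_seed(seed, i),
                               run_id=f"run_{i:03d}")
        except (ValueError, SimulationError) as exc:
            raise type(exc)(f"run index {i}: {exc}") from exc
        runs.append(run)
    if flag_fraction > 0:
        total = len(runs) * N_DAYS
        n_flag = int(round(flag_fraction * total))
        rng = np.random.default_rng(child_seed(seed, 10_000))
        picks = rng.choice(total, size=n_flag, replace=False)
        flagged = {(int(p) // N_DAYS, int(p) % N_DAYS) for p in picks}
        out = []
        for i, run in enumerate(runs):
            new_samples = tuple(
                replace(s, flags=frozenset({"ANALYTICS_FAILURE"}))
                if (i, s.day) in flagged else s
                for s in run.samples
            )
            out.append(replace(run, samples=new_samples))
        runs = out
    return runs
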