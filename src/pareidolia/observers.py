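"""Generative observers: equal-variance signal detection and drift diffusion.

The package ships no human data; cohorts of simulated observers stand in for
it.  Two response models are provided:

* **SDT observer** — on each trial a scalar evidence sample is drawn from
  N(-d'/2, 1) (noise) or N(+d'/2, 1) (signal) and compared against a
  hemifield- and category-specific criterion.  The symmetric placement makes
  the standard estimators d' = z(HR) - z(FAR) and c = -(z(HR) + z(FAR))/2
  exactly unbiased at the population level.
* **DDM observer** — evidence accumulates as a Wiener process with drift
  proportional to signal strength (1 - noise fraction) between absorbing
  boundaries at 0 ("absent") and a ("present"); hemifield bias enters
  through the relative start point z/a.  RT is first-passage time plus a
  non-decision time.

Trait profiles (four O-LIFE schizotypy subscales) are drawn from bounded
discrete distributions, with a configurable linear coupling between the
standardized Unusual Experiences score and the face-block criterion so the
population trait-bias correlation matches a target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import TrialSchedule, schedule_to_frame

__all__ = [
    "TraitProfile",
    "SDTObserverParams",
    "DDMObserverParams",
    "CohortSpec",
    "TRAIT_RANGES",
    "sample_cohort",
    "analytic_sdt_rates",
    "simulate_sdt_response",
    "simulate_sdt_block",
    "ddm_closed_form",
    "simulate_ddm_response",
    "simulate_ddm_block",
    "run_experiment",
]

#: Maximum attainable score per O-LIFE subscale (short form).
TRAIT_RANGES = {"UnEx": 12, "CogDis": 11, "IntAnh": 10, "ImpNon": 10}

#: Success probabilities of the binomial trait generators: chosen to give
#: undergraduate-typical subscale means (UnEx ~3.6, CogDis ~4.4, IntAnh ~2.5,
#: ImpNon ~3.5).
TRAIT_P = {"UnEx": 0.30, "CogDis": 0.40, "IntAnh": 0.25, "ImpNon": 0.35}

CATEGORIES = ("face", "flower")
FIELDS = ("LVF", "RVF")


@dataclass(frozen=True)
class TraitProfile:
    UnEx: int
    CogDis: int
    IntAnh: int
    ImpNon: int


@dataclass
class SDTObserverParams:
    """Latent SDT parameters: d' per (category, noise level) and criterion
    per (category, visual field); lognormal RT with evidence-distance
    slowing."""

    dprime_true: dict            # (category, level) -> d'
    criterion_true: dict         # (category, field) -> c
    rt_location: float = -0.65   # log-seconds, exp(-0.65) ~ 0.52 s
    rt_scale: float = 0.25
    rt_evidence_slow: float = 0.15
    lapse_rate: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_rate <= 0.05:
            raise ValueError("lapse_rate must lie in [0, 0.05]")

    def category_dprime(self, category: str) -> float:
        vals = [v for (c, _), v in self.dprime_true.items() if c == category]
        return float(np.mean(vals))


@dataclass
class DDMObserverParams:
    drift_scale: float = 0.25    # evidence units/s per unit signal strength
    boundary_a: float = 0.1
    start_bias: dict = field(default_factory=lambda: {"LVF": 0.45, "RVF": 0.5})
    nondecision_t0: float = 0.3
    diffusion_s: float = 0.1

    def __post_init__(self) -> None:
        if self.boundary_a <= 0:
            raise ValueError("boundary_a must be positive")
        for vf, zb in self.start_bias.items():
            if not 0.0 < zb < 1.0:
                raise ValueError(f"start_bias[{vf}] must lie in (0, 1)")
        if self.nondecision_t0 < 0:
            raise ValueError("nondecision_t0 must be non-negative")


@dataclass
class CohortSpec:
    """Group-level description of a simulated cohort.

    ``dprime_mean``/``dprime_sd`` map category -> between-subject
    distribution of block sensitivity; ``criterion_mean``/``criterion_sd``
    map visual field -> distribution of criterion (shared across categories
    unless ``criterion_mean`` carries (category, field) keys).
    ``trait_coupling`` couples the standardized trait (default UnEx) to the
    face criterion with population correlation ``target_r``.
    """

    n_subjects: int = 26
    observer_model: str = "sdt"
    dprime_mean: dict = field(default_factory=lambda: {"face": 0.277, "flower": 0.791})
    dprime_sd: dict = field(default_factory=lambda: {"face": 0.45, "flower": 0.49})
    criterion_mean: dict = field(default_factory=lambda: {"LVF": 0.329, "RVF": 0.09})
    criterion_sd: dict = field(default_factory=lambda: {"LVF": 0.48, "RVF": 0.45})
    trait_coupling: dict = field(
        default_factory=lambda: {"trait": "UnEx", "category": "face", "target_r": -0.559}
    )
    level_scaling: bool = True
    noise_levels: dict | None = None
    ddm_defaults: DDMObserverParams = field(default_factory=DDMObserverParams)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if self.observer_model not in ("sdt", "ddm"):
            raise ValueError("observer_model must be 'sdt' or 'ddm'")
        r = (self.trait_coupling or {}).get("target_r", 0.0)
        if abs(r) > 1.0:
            raise ValueError("|target_r| cannot exceed 1")


def _trait_moments(name: str) -> tuple[float, float]:
    n, p = TRAIT_RANGES[name], TRAIT_P[name]
    return n * p, np.sqrt(n * p * (1 - p))


def sample_traits(n: int, rng: np.random.Generator) -> list[TraitProfile]:
    draws = {
        name: rng.binomial(TRAIT_RANGES[name], TRAIT_P[name], size=n)
        for name in TRAIT_RANGES
    }
    return [
        TraitProfile(int(draws["UnEx"][i]), int(draws["CogDis"][i]),
                     int(draws["IntAnh"][i]), int(draws["ImpNon"][i]))
        for i in range(n)
    ]


def _level_dprimes(base: float, levels, scale: bool) -> dict:
    """Spread a block-level d' over noise levels, linear in signal strength
    (1 - noise fraction), preserving the across-level mean."""
    levels = tuple(levels)
    if not scale:
        return {lv: base for lv in levels}
    strengths = np.array([1.0 - lv for lv in levels])
    weights = strengths / strengths.mean()
    return {lv: base * w for lv, w in zip(levels, weights)}


def sample_cohort(spec: CohortSpec, seed=None) -> list[tuple]:
    """Draw a cohort of (observer params, trait profile) pairs.

    The trait-coupled criterion is built as mu + beta * z_trait + eps with
    beta = r * sigma_c and sd(eps) = sigma_c * sqrt(1 - r^2), so the
    population correlation between the trait and the coupled category's
    criterion equals ``target_r`` exactly.
    """
    from .stimuli import DEFAULT_NOISE_LEVELS

    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    traits = sample_traits(n, rng)
    levels = spec.noise_levels or DEFAULT_NOISE_LEVELS

    coupling = spec.trait_coupling or {}
    r = float(coupling.get("target_r", 0.0))
    c_trait = coupling.get("trait", "UnEx")
    c_cat = coupling.get("category", "face")
    mu_t, sd_t = _trait_moments(c_trait)
    z_trait = (np.array([getattr(t, c_trait) for t in traits]) - mu_t) / sd_t

    cohort = []
    for i in range(n):
        dprime_true, criterion_true = {}, {}
        for cat in CATEGORIES:
            base = rng.normal(spec.dprime_mean[cat], spec.dprime_sd[cat])
            dprime_true.update(
                {(cat, lv): d for lv, d in
                 _level_dprimes(base, levels[cat], spec.level_scaling).items()}
            )
        # coupled category: one standardized deviation shared across
        # hemifields, so corr(trait, c) equals target_r both per field and
        # for the field-averaged criterion the analysis actually correlates
        w_coupled = r * z_trait[i] + np.sqrt(1 - r**2) * rng.standard_normal()
        for vf in FIELDS:
            mu = spec.criterion_mean.get(vf, spec.criterion_mean.get((c_cat, vf)))
            sd = spec.criterion_sd.get(vf, spec.criterion_sd.get((c_cat, vf)))
            for cat in CATEGORIES:
                if cat == c_cat and r != 0.0:
                    dev = sd * w_coupled
                else:
                    dev = rng.normal(0, sd)
                criterion_true[(cat, vf)] = mu + dev
        if spec.observer_model == "sdt":
            params = SDTObserverParams(dprime_true, criterion_true)
        else:
            base = spec.ddm_defaults
            params = replace(base, start_bias=dict(base.start_bias))
        cohort.append((params, traits[i]))
    return cohort


# ---------------------------------------------------------------------------
# SDT observer


def analytic_sdt_rates(dprime: float, criterion: float) -> tuple[float, float]:
    """Population hit and false-alarm rates of the equal-variance model with
    symmetric evidence placement: HR = Phi(d'/2 - c), FAR = Phi(-d'/2 - c)."""
    if not (np.isfinite(dprime) and np.isfinite(criterion)):
        raise ValueError("dprime and criterion must be finite")
    return (
        float(norm.cdf(dprime / 2.0 - criterion)),
        float(norm.cdf(-dprime / 2.0 - criterion)),
    )


def simulate_sdt_block(
    params: SDTObserverParams, trials: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Vectorized SDT responses for a block of trials (one row per trial)."""
    n = len(trials)
    is_signal = (trials["stimulus_type"] == "signal").to_numpy()
    cat_mean = {cat: params.category_dprime(cat) for cat in set(trials["block"])}
    keys = pd.Series(list(zip(trials["block"], trials["noise_fraction"])), index=trials.index)
    d_signal = keys.map(params.dprime_true).to_numpy(dtype=float)
    d_noise = trials["block"].map(cat_mean).to_numpy(dtype=float)
    d = np.where(is_signal, np.where(np.isnan(d_signal), d_noise, d_signal), d_noise)
    ckeys = pd.Series(
        list(zip(trials["block"], trials["visual_field"])), index=trials.index
    )
    c = ckeys.map(params.criterion_true).to_numpy(dtype=float)
    x = np.where(is_signal, d / 2.0, -d / 2.0) + rng.standard_normal(n)
    present = x > c
    lapse = rng.random(n) < params.lapse_rate
    present = np.where(lapse, rng.random(n) < 0.5, present)
    mu = params.rt_location + params.rt_evidence_slow / (1.0 + np.abs(x - c))
    rt = np.exp(rng.normal(mu, params.rt_scale))
    out = trials.copy()
    out["response"] = np.where(present, "present", "absent")
    out["correct"] = present == is_signal
    out["rt_s"] = rt
    out["forced_guess"] = False
    return out


def simulate_sdt_response(params: SDTObserverParams, trial, seed=None) -> dict:
    """Single-trial convenience wrapper around :func:`simulate_sdt_block`."""
    frame = pd.DataFrame(
        [{
            "block": trial.block,
            "stimulus_type": trial.stimulus_type,
            "visual_field": trial.visual_field,
            "noise_fraction": trial.noise_fraction,
        }]
    )
    rng = np.random.default_rng(seed)
    return simulate_sdt_block(params, frame, rng).iloc[0].to_dict()


# ---------------------------------------------------------------------------
# DDM observer


def ddm_closed_form(
    drift: float, boundary: float, start: float, noise: float = 0.1
) -> tuple[float, float]:
    """First-passage results for a Wiener process between absorbing
    boundaries at 0 and ``boundary``, started at ``start``.

    Returns the probability of absorbing at the upper boundary and, for the
    unbiased start z = a/2, the mean decision time (a/(2v))·tanh(va/(2s²));
    at v = 0 these reduce to z/a and a²/(4s²).
    """
    if boundary <= 0 or not 0 < start < boundary or noise <= 0:
        raise ValueError("require a > 0, 0 < z < a, s > 0")
    v, a, z, s = drift, boundary, start, noise
    if v == 0:
        p_upper = z / a
        mean_dt = a**2 / (4.0 * s**2)
    else:
        k = 2.0 * v / s**2
        p_upper = (1.0 - np.exp(-k * z)) / (1.0 - np.exp(-k * a))
        mean_dt = (a / (2.0 * v)) * np.tanh(v * a / (2.0 * s**2))
    return float(p_upper), float(mean_dt)


def simulate_ddm_block(
    params: DDMObserverParams,
    trials: pd.DataFrame,
    rng: np.random.Generator,
    dt: float = 0.001,
    max_t: float = 5.0,
) -> pd.DataFrame:
    """Euler–Maruyama simulation of a block of diffusion decisions.

    Drift is +drift_scale * (1 - noise fraction) on signal trials and 0 on
    noise trials; walks not absorbed within ``max_t`` become forced guesses
    (flagged, RT capped).

    Discretely monitored walks under-detect boundary crossings, biasing
    choice probabilities and first-passage times; the absorbing boundaries
    are therefore pulled inward by the continuity correction
    0.5826 * s * sqrt(dt) so the simulator matches the continuous-time
    first-passage results at the default 1 ms step."""
    n = len(trials)
    is_signal = (trials["stimulus_type"] == "signal").to_numpy()
    frac = trials["noise_fraction"].to_numpy(dtype=float)
    strength = np.where(is_signal, 1.0 - np.nan_to_num(frac, nan=1.0), 0.0)
    v = params.drift_scale * strength
    a = params.boundary_a
    z0 = np.array([a * params.start_bias[vf] for vf in trials["visual_field"]])

    x = z0.copy()
    t_dec = np.full(n, np.nan)
    upper = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    sqdt = np.sqrt(dt) * params.diffusion_s
    beta = 0.5826 * sqdt  # continuity correction for discrete monitoring
    lo_bound, hi_bound = min(beta, a / 2), max(a - beta, a / 2)
    n_steps = int(round(max_t / dt))
    for step in range(1, n_steps + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        x[idx] += v[idx] * dt + sqdt * rng.standard_normal(idx.size)
        hit_up = x[idx] >= hi_bound
        hit_lo = x[idx] <= lo_bound
        done = hit_up | hit_lo
        fin = idx[done]
        t_dec[fin] = step * dt
        upper[fin] = hit_up[done]
        active[fin] = False
    forced = active.copy()
    if forced.any():
        t_dec[forced] = max_t
        upper[forced] = rng.random(forced.sum()) < 0.5

    present = upper
    out = trials.copy()
    out["response"] = np.where(present, "present", "absent")
    out["correct"] = present == is_signal
    out["rt_s"] = t_dec + params.nondecision_t0
    out["forced_guess"] = forced
    return out


def simulate_ddm_response(params: DDMObserverParams, trial, seed=None) -> dict:
    frame = pd.DataFrame(
        [{
            "block": trial.block,
            "stimulus_type": trial.stimulus_type,
            "visual_field": trial.visual_field,
            "noise_fraction": trial.noise_fraction,
        }]
    )
    rng = np.random.default_rng(seed)
    return simulate_ddm_block(params, frame, rng).iloc[0].to_dict()


# ---------------------------------------------------------------------------
# full sessions


def run_experiment(observer, schedule: TrialSchedule, seed=None) -> pd.DataFrame:
    """Run one observer through a two-block schedule; returns a trial log
    with one analyzable record per trial (practice trials flagged)."""
    params = observer[0] if isinstance(observer, tuple) else observer
    rng = np.random.default_rng(seed)
    frame = schedule_to_frame(schedule)
    if isinstance(params, SDTObserverParams):
        log = simulate_sdt_block(params, frame, rng)
    elif isinstance(params, DDMObserverParams):
        log = simulate_ddm_block(params, frame, rng)
    else:
        raise TypeError(f"unsupported observer parameters: {type(params)!r}")
    return log
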