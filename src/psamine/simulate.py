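"""Seedable synthetic ADT cohort generator.

Emulates the trajectory and outcome structure the discovery pipeline
assumes: PSA declines roughly exponentially from a lognormal pretreatment
level to a nadir (mean time to nadir ~10 months); afterwards every patient
fluctuates at visit scale (rebound rises under treatment holidays, slow
drift), and the two outcome classes differ only in whether a *repeated*
substantial re-decline occurs. Non-progressors (hormone-sensitive) always
express the configured number of month-scale declines of at least the
configured magnitude as a re-response phase late in follow-up;
progressors (castration-resistant) rise in trend with an event time set by
their PSA doubling time and show at most one transient decline. Visits are
spaced 1-6 months apart, non-progressors are right-censored, and baseline
covariates influence progression odds with configurable effect sizes.

All randomness flows from a single root seed through named substreams, so
adding a covariate does not perturb trajectory randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import Covariates, Measurement, PatientRecord

_SUBSTREAMS = ("covariates", "scaffold", "class", "trajectory", "noise")

#: Drug-order categories with realistic cohort prevalences.
_DRUG_ORDERS = ("leuprin_only", "zoladex_only", "leuprin_to_zoladex",
                "zoladex_to_leuprin", "anti_androgen_only")
_DRUG_PROBS = (0.59, 0.14, 0.03, 0.19, 0.05)
_STAGES = ("T2", "T3", "T4")
_STAGE_PROBS = (0.3, 0.5, 0.2)
_GLEASONS = (6, 7, 8, 9, 10)
_GLEASON_PROBS = (0.22, 0.28, 0.30, 0.15, 0.05)


def _default_effects() -> dict:
    # signs follow the univariate directions reported for this disease
    # setting: older age, higher gleason, bone metastasis and higher
    # pretreatment PSA raise progression odds; longer time to nadir and
    # higher nadir lower them.
    return {
        "age": 0.3,
        "gleason": 0.4,
        "bone_metastasis": 0.3,
        "pretreatment_psa": 0.3,
        "time_to_nadir": -0.3,
        "nadir_psa": -0.2,
    }


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort generator.

    Parameters mirror the study conditions: visit gaps uniform on
    ``visit_gap_range`` months, nadir time centred on ``nadir_time_mean``
    months, event (progression) fraction ``event_fraction``, and for
    non-progressors at least ``n_planted_declines`` post-nadir declines of
    per-month magnitude at least ``nonprogressor_decline_threshold``
    ng/(ml*mo).
    """

    n_patients: int = 300
    event_fraction: float = 0.36
    visit_gap_range: tuple[float, float] = (1.0, 6.0)
    nadir_time_mean: float = 10.3
    nadir_time_sd: float = 3.0
    pretreatment_psa_logmean: float = 4.2
    pretreatment_psa_logsd: float = 1.0
    nonprogressor_decline_threshold: float = 0.048
    n_planted_declines: int = 2
    progressor_doubling_time_mean: float = 16.0
    noise_sd: float = 0.02
    censoring_time_range: tuple[float, float] = (24.0, 36.0)
    covariate_effect_sizes: dict = field(default_factory=_default_effects)
    seed: int = 0
    # secondary knobs (post-nadir fluctuation amplitude is not pinned down
    # by any published cohort; exposed rather than fixed)
    rise_rate_range: tuple[float, float] = (0.3, 1.2)
    drift_rate_range: tuple[float, float] = (-0.01, 0.25)
    decline_rate_factors: tuple[float, float] = (2.0, 4.0)
    # a progressor's event time sits dt*log2(event_growth_factor) months
    # after the nadir on average (dt = drawn doubling time), i.e. when the
    # growth schedule reaches event_growth_factor times the nadir level
    event_growth_factor: float = 2.5
    # probability that a progressor shows one transient substantial decline
    # (isolated re-response); repeated substantial declines never occur
    progressor_transient_decline_prob: float = 0.75

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.event_fraction < 1.0:
            raise ValueError("event_fraction must be in (0, 1)")
        lo, hi = self.visit_gap_range
        if not (0 < lo <= hi):
            raise ValueError("visit_gap_range must satisfy 0 < min <= max")

    def asdict(self) -> dict:
        d = asdict(self)
        d["visit_gap_range"] = list(self.visit_gap_range)
        d["censoring_time_range"] = list(self.censoring_time_range)
        return d


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    return {
        name: np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
        for k, name in enumerate(_SUBSTREAMS)
    }


def _calibrate_intercept(lin: np.ndarray, target: float) -> float:
    """Intercept b such that mean(sigmoid(b + lin)) == target (bisection)."""
    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + lin)))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_cohort(config: SimConfig) -> list[PatientRecord]:
    """Generate a synthetic cohort of :class:`PatientRecord`.

    Identical configs (including seed) give identical cohorts. Raises
    ``ValueError`` if the drawn outcome labels leave either class empty.
    """
    cfg = config
    n = cfg.n_patients
    rng = _rngs(cfg.seed)

    # --- baseline covariates -------------------------------------------------
    rc = rng["covariates"]
    age = rc.normal(74, 8, n)
    alb = rc.normal(4.2, 0.4, n)
    plt_ = rc.normal(220, 50, n)
    hb = rc.normal(13.0, 1.5, n)
    ca = rc.normal(9.3, 0.5, n)
    intermittent = rc.binomial(1, 0.3, n)
    drug = rc.choice(len(_DRUG_ORDERS), size=n, p=_DRUG_PROBS)
    bone = rc.binomial(1, 0.16, n)
    stage = rc.choice(len(_STAGES), size=n, p=_STAGE_PROBS)
    gleason = rc.choice(_GLEASONS, size=n, p=_GLEASON_PROBS)
    volume = rc.lognormal(math.log(40.0), 0.4, n)
    pre_psa = rc.lognormal(cfg.pretreatment_psa_logmean, cfg.pretreatment_psa_logsd, n)

    # --- trajectory scaffold (class-independent) -----------------------------
    rs = rng["scaffold"]
    t_nadir_planted = np.clip(rs.normal(cfg.nadir_time_mean, cfg.nadir_time_sd, n), 3.0, 20.0)
    # nadir as a lognormal fraction of the pretreatment level: median ~2%,
    # heavy-tailed, so a realistic minority of patients reach nadir < 0.2
    nadir_frac = np.minimum(rs.lognormal(math.log(0.02), 1.5, n), 0.5)
    nadir_val = np.maximum(pre_psa * nadir_frac, 0.05)
    censor_draw = rs.uniform(*cfg.censoring_time_range, n)
    dt_sigma = 0.4
    doubling = rs.lognormal(
        math.log(cfg.progressor_doubling_time_mean) - 0.5 * dt_sigma**2, dt_sigma, n
    )

    # --- progression class via logistic model on covariates ------------------
    eff = dict(cfg.covariate_effect_sizes)
    cov_numeric = {
        "age": age, "alb": alb, "plt": plt_, "hb": hb, "ca": ca,
        "intermittent_treatment": intermittent.astype(float),
        "bone_metastasis": bone.astype(float),
        "gleason": gleason.astype(float),
        "mri_prostate_volume": volume,
        "pretreatment_psa": np.log(pre_psa),
        "nadir_psa": np.log(nadir_val),
        "time_to_nadir": t_nadir_planted,
    }
    lin = np.zeros(n)
    for name, beta in eff.items():
        if name not in cov_numeric:
            raise ValueError(f"unknown covariate in effect sizes: {name!r}")
        if beta:
            lin += beta * _standardize(cov_numeric[name])
    intercept = _calibrate_intercept(lin, cfg.event_fraction)
    p_event = 1.0 / (1.0 + np.exp(-(intercept + lin)))
    is_event = rng["class"].random(n) < p_event
    if is_event.all() or not is_event.any():
        raise ValueError(
            f"event_fraction={cfg.event_fraction} produced an empty outcome class at n={n}"
        )

    # --- per-patient trajectories --------------------------------------------
    rt = rng["trajectory"]
    rnoise = rng["noise"]
    gap_lo, gap_hi = cfg.visit_gap_range
    thr = cfg.nonprogressor_decline_threshold
    records: list[PatientRecord] = []

    for i in range(n):
        p0 = max(pre_psa[i], nadir_val[i] * 1.5)
        nv = nadir_val[i]

        # visit schedule up to the planted nadir; snap nadir to a visit
        times = [0.0]
        while times[-1] < t_nadir_planted[i]:
            times.append(times[-1] + rt.uniform(gap_lo, gap_hi))
        # nearest visit (excluding baseline) to the planted nadir time
        cand = np.asarray(times[1:])
        i_nadir = 1 + int(np.argmin(np.abs(cand - t_nadir_planted[i])))
        t_nadir = times[i_nadir]
        times = times[: i_nadir + 1]

        # exponential-like decline from p0 at t=0 to the nadir value
        decay = [p0 * (nv / p0) ** (t / t_nadir) if t_nadir > 0 else nv for t in times]
        values = list(decay)

        if is_event[i]:
            # progressor: the same iid visit-scale rises and drift as the
            # rebound phase of non-progressors (so state composition and
            # ordering carry no class signal), but never a repeated
            # substantial decline; the event time is drawn from the growth
            # schedule implied by the doubling time (the level reaches
            # event_growth_factor times the nadir after dt*log2(factor)
            # months on average), with multiplicative jitter
            dt = doubling[i]
            floor = nv + 0.05
            amp = max(1.0, nv / 5.0)  # fluctuation scales with the PSA level
            t_event = t_nadir + dt * math.log2(cfg.event_growth_factor) * rt.uniform(0.85, 1.15)
            decline_rate = thr * rt.uniform(*cfg.decline_rate_factors)
            decline_left = 1 if rt.random() < cfg.progressor_transient_decline_prob else 0
            # the transient decline fires once a drawn fraction of the time
            # to the event has elapsed
            decline_frac = rt.uniform(0.35, 0.75)
            level = nv
            t = t_nadir
            n_guard = 0
            while n_guard < 300:
                n_guard += 1
                g = rt.uniform(gap_lo, gap_hi)
                t += g
                if t > t_event:
                    break
                if (decline_left and n_guard >= 2
                        and t - t_nadir >= decline_frac * (t_event - t_nadir)
                        and (level - floor) >= decline_rate * g):
                    level -= decline_rate * g
                    decline_left = 0
                elif rt.random() < 0.5:
                    level += rt.uniform(*cfg.rise_rate_range) * g * amp
                else:
                    level = max(floor, level + rt.uniform(
                        cfg.drift_rate_range[0], cfg.drift_rate_range[1] * amp) * g)
                times.append(t)
                values.append(level)
            event, event_time = True, times[-1] + rt.uniform(0.1, 1.0)
        else:
            # rebound phase (treatment holidays: rises and slow drift above
            # the nadir), then a re-response phase near the end of follow-up:
            # the planted consecutive month-scale declines of magnitude >= thr
            floor = nv + 0.05
            amp = max(1.0, nv / 5.0)  # fluctuation scales with the PSA level
            level = nv
            remaining = cfg.n_planted_declines
            # decline depth is a per-patient trait: re-responses to ADT tend
            # to repeat with similar magnitude
            decline_rate = thr * rt.uniform(*cfg.decline_rate_factors)
            t = t_nadir
            censor = censor_draw[i]
            avg_gap = 0.5 * (gap_lo + gap_hi)
            n_guard = 0
            while (t < censor or remaining > 0) and n_guard < 300:
                n_guard += 1
                g = rt.uniform(gap_lo, gap_hi)
                t += g
                # switch to declining when the remaining follow-up just
                # accommodates the planted declines
                declining = remaining > 0 and (censor - t) < remaining * avg_gap
                if declining:
                    if (level - floor) >= decline_rate * g:
                        level -= decline_rate * g
                        remaining -= 1
                    else:  # build headroom first
                        level += rt.uniform(*cfg.rise_rate_range) * g * amp
                elif rt.random() < 0.5:
                    level += rt.uniform(*cfg.rise_rate_range) * g * amp
                else:
                    level = max(floor, level + rt.uniform(
                        cfg.drift_rate_range[0], cfg.drift_rate_range[1] * amp) * g)
                times.append(t)
                values.append(level)
            event, event_time = False, times[-1] + rt.uniform(0.1, 1.0)

        if cfg.noise_sd > 0:
            noise = rnoise.normal(0.0, cfg.noise_sd, len(values))
        else:
            noise = np.zeros(len(values))
        meas = [
            Measurement(time=float(tt), value=float(max(vv + ee, 0.0)))
            for tt, vv, ee in zip(times, values, noise)
        ]

        cov = Covariates(
            age=float(age[i]),
            alb=float(alb[i]),
            plt=float(plt_[i]),
            hb=float(hb[i]),
            ca=float(ca[i]),
            intermittent_treatment=int(intermittent[i]),
            drug_order=_DRUG_ORDERS[drug[i]],
            bone_metastasis=int(bone[i]),
            clinical_stage=_STAGES[stage[i]],
            gleason=int(gleason[i]),
            mri_prostate_volume=float(volume[i]),
            pretreatment_psa=float(pre_psa[i]),
            nadir_psa=float(nv),
            time_to_nadir=float(t_nadir),
        )
        records.append(
            PatientRecord(
                id=f"P{i:04d}",
                measurements=meas,
                covariates=cov,
                event=bool(event),
                event_time=float(event_time),
            )
        )
    return records
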