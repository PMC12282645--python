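"""Synthetic nocturnal-scratch studies with known ground truth.

The generator emulates the structure of an in-home validation study of
scratch-detecting digital health technologies (DHTs): a small cohort study
(healthy volunteers, mild and moderate atopic dermatitis) with roughly eight
video-recorded reference nights per participant, five human raters, and two
device-like sources.  Every downstream pipeline stage can therefore be tested
against a known truth.

Per participant-night, a total-sleep-opportunity (TSO) window is drawn, and
true scratch bouts arrive as a homogeneous Poisson process over the TSO with
log-normal participant and night random effects on the bout rate and on the
mean bout duration, so the log-scale outcome distribution is right-skewed and
its hierarchy is directly controlled.  Raters are jittered, thinned and
contaminated copies of the truth; devices additionally detect bouts with a
logistic probability in bout duration and report their own (biased, noisy,
occasionally fragmented) sleep periods.  Morning itch ratings are generated
as a monotone noisy map of the night's true scratch duration.

Cohort rate and duration defaults are calibrated so that cohort medians of
the normalized outcomes fall near 2.4/3.51/4.64 bouts per hour and
13.1/17.4/30.0 scratch-seconds per hour for the healthy/mild/moderate groups,
with the device presets reproducing the qualitative error structure of a
wrist accelerometer (high false-positive rate, hence low precision) and a
touchless radio-frequency sensor (more balanced errors).

All randomness flows through named streams derived from a single integer
seed; no global RNG state is touched.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    EventTrack,
    Interval,
    filter_min_duration,
    merge_gaps,
    normalize_track,
    total_duration,
)

__all__ = [
    "CohortSpec",
    "RaterModel",
    "DeviceModel",
    "StudyConfig",
    "SimulatedStudy",
    "simulate_study",
    "apply_rater_model",
    "apply_device_model",
    "simulate_log_outcomes",
    "analytic_icc",
    "default_config",
]

TRUTH_SOURCE = "Truth"
RATER_NAMES = ("R1", "R2", "R3", "R4", "R5")

# stream role codes for named, seeded RNG streams
_ROLE_TSO = 0
_ROLE_BOUTS = 1
_ROLE_PARTICIPANT = 7
_ROLE_DEVICE_PARTICIPANT = 8
_ROLE_RATER = 10  # + rater index
_ROLE_DEVICE = 20  # + device index
_ROLE_PRO = 30


def _rng(seed: int, *path: int) -> np.random.Generator:
    """A named RNG stream: deterministic in (seed, path), independent across paths."""
    return np.random.default_rng([int(seed)] + [int(p) for p in path])


@dataclass(frozen=True)
class CohortSpec:
    name: str
    n_participants: int
    median_freq_bouts_per_h: float
    median_dur_s_per_h: float

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError(f"cohort {self.name!r}: n_participants must be positive")
        if self.median_freq_bouts_per_h <= 0 or self.median_dur_s_per_h <= 0:
            raise ValueError(f"cohort {self.name!r}: medians must be positive")


@dataclass(frozen=True)
class RaterModel:
    """Error model for a human rater annotating scratch bouts and the TSO."""

    boundary_jitter_sd_s: float = 0.5
    miss_prob: float = 0.03
    false_bout_rate_per_h: float = 0.15
    false_dur_log_mean: float = math.log(3.0)
    false_dur_log_sd: float = 0.35
    tso_jitter_sd_s: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError(f"miss_prob must be in [0, 1], got {self.miss_prob}")
        for name in ("boundary_jitter_sd_s", "false_bout_rate_per_h", "tso_jitter_sd_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def zero(cls) -> "RaterModel":
        return cls(
            boundary_jitter_sd_s=0.0,
            miss_prob=0.0,
            false_bout_rate_per_h=0.0,
            tso_jitter_sd_s=0.0,
        )


@dataclass(frozen=True)
class DeviceModel:
    """Error model for a scratch-detecting DHT and its sleep-period output.

    Bout detection is Bernoulli with a logistic probability in bout duration;
    false bouts arrive as a Poisson process over the TSO.  Sleep periods are
    the true TSO with participant-level and night-level Gaussian endpoint
    errors, a constant endpoint bias, and an occasional mid-night split that
    exercises the <30 min sleep-period merge rule downstream.
    """

    detect_intercept: float = 0.0
    detect_slope_per_s: float = 0.25
    boundary_jitter_sd_s: float = 1.0
    false_bout_rate_per_h: float = 1.0
    false_dur_log_mean: float = math.log(3.5)
    false_dur_log_sd: float = 0.4
    tso_start_bias_s: float = 0.0
    tso_end_bias_s: float = 0.0
    tso_participant_sd_s: float = 0.0
    tso_night_sd_s: float = 0.0
    split_prob: float = 0.0
    #: sleep-report splits use gaps below the 30 min merge threshold, so the
    #: derived TSO is restored by merging and the duration calibration holds
    split_gap_min_range: tuple[float, float] = (5.0, 25.0)

    def __post_init__(self) -> None:
        for name in (
            "boundary_jitter_sd_s",
            "false_bout_rate_per_h",
            "tso_participant_sd_s",
            "tso_night_sd_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.split_prob <= 1.0:
            raise ValueError(f"split_prob must be in [0, 1], got {self.split_prob}")

    def detect_prob(self, duration_s: np.ndarray) -> np.ndarray:
        z = self.detect_intercept + self.detect_slope_per_s * np.asarray(duration_s, float)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-z))

    @classmethod
    def identity(cls) -> "DeviceModel":
        """A perfect device: detects everything, no noise, truthful TSO."""
        return cls(
            detect_intercept=1e9,
            detect_slope_per_s=0.0,
            boundary_jitter_sd_s=0.0,
            false_bout_rate_per_h=0.0,
            split_prob=0.0,
        )

    @classmethod
    def philips_like(cls) -> "DeviceModel":
        """Wrist-accelerometer preset: sensitive but imprecise (many false bouts)."""
        return cls(
            detect_intercept=-0.1,
            detect_slope_per_s=0.30,
            boundary_jitter_sd_s=1.5,
            false_bout_rate_per_h=4.5,
            tso_start_bias_s=-756.0,  # duration bias +0.42 h split across endpoints
            tso_end_bias_s=756.0,
            tso_participant_sd_s=2387.0,  # 0.663 h at each endpoint, half per level
            tso_night_sd_s=2387.0,
            split_prob=0.20,
        )

    @classmethod
    def emerald_like(cls) -> "DeviceModel":
        """Touchless RF preset: slightly less sensitive, far fewer false bouts."""
        return cls(
            detect_intercept=-0.85,
            detect_slope_per_s=0.30,
            boundary_jitter_sd_s=1.2,
            false_bout_rate_per_h=1.3,
            tso_start_bias_s=-792.0,  # duration bias +0.44 h
            tso_end_bias_s=792.0,
            tso_participant_sd_s=2102.0,  # 0.584 h per endpoint, half per level
            tso_night_sd_s=2102.0,
            split_prob=0.10,
        )


def _default_cohorts() -> tuple[CohortSpec, ...]:
    return (
        CohortSpec("HV", 5, 2.4, 13.1),
        CohortSpec("Mild AD", 9, 3.51, 17.4),
        CohortSpec("Moderate AD", 14, 4.64, 30.0),
    )


def _default_raters() -> dict:
    return {name: RaterModel() for name in RATER_NAMES}


def _default_devices() -> dict:
    return {"Philips": DeviceModel.philips_like(), "Emerald": DeviceModel.emerald_like()}


def _default_components() -> dict:
    return {
        "norm_duration": (1.0, 0.5, 0.5),
        "norm_frequency": (1.0, 0.5, 0.5),
    }


@dataclass(frozen=True)
class StudyConfig:
    """Full parameterization of a synthetic study."""

    cohorts: tuple[CohortSpec, ...] = field(default_factory=_default_cohorts)
    nights_per_participant: int = 8
    # log-scale random effects on the bout rate and mean bout duration
    sigma_participant_log_rate: float = 0.45
    sigma_night_log_rate: float = 0.35
    sigma_participant_log_dur: float = 0.20
    sigma_night_log_dur: float = 0.10
    bout_dur_log_sd: float = 0.40
    bout_min_dur_s: float = 2.0
    # TSO distribution (seconds from the noon night origin)
    tso_mean_start_s: float = 39600.0  # 23:00
    tso_start_sd_s: float = 1800.0
    tso_mean_dur_h: float = 8.0
    tso_dur_sd_h: float = 0.75
    tso_min_dur_h: float = 5.0
    raters: dict = field(default_factory=_default_raters)
    devices: dict = field(default_factory=_default_devices)
    #: log-scale (participant, night, residual) components per outcome, used
    #: by direct mixed-model simulation and the analytic ICC
    outcome_components: dict = field(default_factory=_default_components)
    # patient-reported itch coupling (AD cohorts only)
    pro_itch_intercept: float = -2.0
    pro_itch_slope: float = 2.1
    pro_itch_noise_sd: float = 1.1
    pro_invalid_time_prob: float = 0.03
    pro_duplicate_prob: float = 0.02
    start_date: str = "2024-01-01"
    night_spacing_days: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nights_per_participant <= 0:
            raise ValueError("nights_per_participant must be positive")
        for name in (
            "sigma_participant_log_rate",
            "sigma_night_log_rate",
            "sigma_participant_log_dur",
            "sigma_night_log_dur",
            "bout_dur_log_sd",
            "tso_start_sd_s",
            "tso_dur_sd_h",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for prob in ("pro_invalid_time_prob", "pro_duplicate_prob"):
            if not 0.0 <= getattr(self, prob) <= 1.0:
                raise ValueError(f"{prob} must be in [0, 1]")
        for outcome, comps in self.outcome_components.items():
            if len(comps) != 3 or any(c < 0 for c in comps):
                raise ValueError(f"outcome_components[{outcome!r}] must be 3 non-negative values")

    def zero_noise(self) -> "StudyConfig":
        """The same study with every measurement-error source switched off.

        Truth generation (TSO, bouts, random effects) is untouched; raters
        and devices become exact copies of the truth.
        """
        return dataclasses.replace(
            self,
            raters={name: RaterModel.zero() for name in self.raters},
            devices={name: DeviceModel.identity() for name in self.devices},
            pro_invalid_time_prob=0.0,
            pro_duplicate_prob=0.0,
        )


def default_config(seed: int = 0, **overrides) -> StudyConfig:
    return dataclasses.replace(StudyConfig(), seed=seed, **overrides)


@dataclass
class SimulatedStudy:
    """Event, PRO and participant tables for one simulated study."""

    events: pd.DataFrame
    pros: pd.DataFrame
    participants: pd.DataFrame
    config: StudyConfig
    seed: int


# ---------------------------------------------------------------------------
# noise models


def _jitter_bouts(
    intervals: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    if intervals.size == 0 or sd == 0.0:
        return intervals.copy()
    out = intervals.copy()
    for i in range(out.shape[0]):
        for _ in range(20):
            start = intervals[i, 0] + rng.normal(0.0, sd)
            end = intervals[i, 1] + rng.normal(0.0, sd)
            if end > start:
                out[i] = (start, end)
                break
        else:  # pathological jitter; keep the true bout
            out[i] = intervals[i]
    return out


def _false_bouts(
    rate_per_h: float,
    window: Interval,
    log_mean: float,
    log_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if rate_per_h <= 0.0:
        return np.empty((0, 2))
    n = rng.poisson(rate_per_h * window.duration_h)
    if n == 0:
        return np.empty((0, 2))
    starts = rng.uniform(window.start_s, window.end_s, size=n)
    durs = np.exp(rng.normal(log_mean, log_sd, size=n))
    ends = np.minimum(starts + durs, window.end_s)
    keep = ends > starts
    return np.column_stack([starts[keep], ends[keep]])


def apply_rater_model(
    truth: EventTrack,
    model: RaterModel,
    rng: np.random.Generator,
    window: Interval,
    source: Optional[str] = None,
) -> EventTrack:
    """Simulate one rater's annotation of a true scratch track.

    Each true bout is kept with probability ``1 - miss_prob``; kept bouts'
    endpoints receive Gaussian jitter (resampled if inverted); spurious bouts
    arrive as a Poisson process over ``window``.
    """
    arr = truth.intervals
    keep = rng.random(arr.shape[0]) >= model.miss_prob
    kept = _jitter_bouts(arr[keep], model.boundary_jitter_sd_s, rng)
    false = _false_bouts(
        model.false_bout_rate_per_h,
        window,
        model.false_dur_log_mean,
        model.false_dur_log_sd,
        rng,
    )
    combined = np.concatenate([kept, false]) if kept.size or false.size else np.empty((0, 2))
    return normalize_track(
        combined,
        participant_id=truth.participant_id,
        night_id=truth.night_id,
        source=source,
        kind="scratch",
    )


def apply_device_model(
    truth: EventTrack,
    truth_tso: Interval,
    model: DeviceModel,
    rng: np.random.Generator,
    source: Optional[str] = None,
    participant_offsets: tuple[float, float] = (0.0, 0.0),
) -> tuple[EventTrack, EventTrack]:
    """Simulate a device's scratch track and sleep-period track for one night.

    Returns ``(scratch_track, sleep_period_track)``.  ``participant_offsets``
    are the participant-level TSO start/end errors (drawn once per
    participant and device) added on top of the per-night errors.
    """
    arr = truth.intervals
    if arr.shape[0]:
        p = model.detect_prob(arr[:, 1] - arr[:, 0])
        keep = rng.random(arr.shape[0]) < p
    else:
        keep = np.zeros(0, dtype=bool)
    kept = _jitter_bouts(arr[keep], model.boundary_jitter_sd_s, rng)
    false = _false_bouts(
        model.false_bout_rate_per_h,
        truth_tso,
        model.false_dur_log_mean,
        model.false_dur_log_sd,
        rng,
    )
    combined = np.concatenate([kept, false]) if kept.size or false.size else np.empty((0, 2))
    scratch = normalize_track(
        combined,
        participant_id=truth.participant_id,
        night_id=truth.night_id,
        source=source,
        kind="scratch",
    )

    off_start, off_end = participant_offsets
    start = truth_tso.start_s + model.tso_start_bias_s + off_start
    end = truth_tso.end_s + model.tso_end_bias_s + off_end
    if model.tso_night_sd_s > 0:
        start += rng.normal(0.0, model.tso_night_sd_s)
        end += rng.normal(0.0, model.tso_night_sd_s)
    if end <= start + 600.0:  # guarantee a usable (>=10 min) sleep report
        end = start + 600.0
    periods = [(start, end)]
    if model.split_prob > 0 and rng.random() < model.split_prob:
        gap_s = 60.0 * rng.uniform(*model.split_gap_min_range)
        span = end - start
        cut = start + rng.uniform(0.3, 0.7) * span
        if cut + gap_s < end:
            periods = [(start, cut), (cut + gap_s, end)]
    sleep = normalize_track(
        np.asarray(periods),
        participant_id=truth.participant_id,
        night_id=truth.night_id,
        source=source,
        kind="sleep_period",
    )
    return scratch, sleep


# ---------------------------------------------------------------------------
# study simulation


def _cohort_dur_log_mean(cohort: CohortSpec, config: StudyConfig) -> float:
    """Log-location of the bout-duration distribution for a cohort.

    Chosen so the population mean bout duration equals the cohort's target
    scratch-seconds-per-hour divided by its target bouts-per-hour.
    """
    target_mean = cohort.median_dur_s_per_h / cohort.median_freq_bouts_per_h
    total_var = (
        config.bout_dur_log_sd**2
        + config.sigma_participant_log_dur**2
        + config.sigma_night_log_dur**2
    )
    return math.log(target_mean) - total_var / 2.0


def simulate_study(config: StudyConfig, seed: Optional[int] = None) -> SimulatedStudy:
    """Generate a full synthetic study: truth, five raters, devices, PROs.

    Deterministic given ``seed`` (falling back to ``config.seed``).
    """
    seed = config.seed if seed is None else int(seed)
    start_date = dt.date.fromisoformat(config.start_date)
    device_names = sorted(config.devices)
    rater_names = sorted(config.raters)

    event_rows: list[dict] = []
    pro_rows: list[dict] = []
    part_rows: list[dict] = []

    def add_track(track: EventTrack, source: str, kind: str) -> None:
        for s, e in track.intervals:
            event_rows.append(
                {
                    "participant_id": track.participant_id,
                    "night_id": track.night_id,
                    "source": source,
                    "kind": kind,
                    "start_s": float(s),
                    "end_s": float(e),
                }
            )

    pidx = 0
    for cohort in config.cohorts:
        dur_log_mean = _cohort_dur_log_mean(cohort, config)
        for _ in range(cohort.n_participants):
            pidx += 1
            pid = f"P{pidx:02d}"
            part_rows.append({"participant_id": pid, "cohort": cohort.name})
            rng_part = _rng(seed, pidx, _ROLE_PARTICIPANT, 0)
            a_rate = rng_part.normal(0.0, config.sigma_participant_log_rate)
            a_dur = rng_part.normal(0.0, config.sigma_participant_log_dur)
            device_offsets = {}
            for didx, dname in enumerate(device_names):
                model = config.devices[dname]
                rng_dev_part = _rng(seed, pidx, _ROLE_DEVICE_PARTICIPANT, didx)
                device_offsets[dname] = (
                    rng_dev_part.normal(0.0, model.tso_participant_sd_s)
                    if model.tso_participant_sd_s > 0
                    else 0.0,
                    rng_dev_part.normal(0.0, model.tso_participant_sd_s)
                    if model.tso_participant_sd_s > 0
                    else 0.0,
                )

            for nidx in range(config.nights_per_participant):
                night_date = start_date + dt.timedelta(days=nidx * config.night_spacing_days)
                nid = night_date.isoformat()

                rng_tso = _rng(seed, pidx, nidx, _ROLE_TSO)
                tso_start = config.tso_mean_start_s + rng_tso.normal(0.0, config.tso_start_sd_s)
                tso_dur_h = max(
                    rng_tso.normal(config.tso_mean_dur_h, config.tso_dur_sd_h),
                    config.tso_min_dur_h,
                )
                truth_tso = Interval(tso_start, tso_start + 3600.0 * tso_dur_h)

                rng_bouts = _rng(seed, pidx, nidx, _ROLE_BOUTS)
                b_rate = rng_bouts.normal(0.0, config.sigma_night_log_rate)
                b_dur = rng_bouts.normal(0.0, config.sigma_night_log_dur)
                lam = cohort.median_freq_bouts_per_h * math.exp(a_rate + b_rate)
                n_bouts = rng_bouts.poisson(lam * tso_dur_h)
                starts = rng_bouts.uniform(truth_tso.start_s, truth_tso.end_s, size=n_bouts)
                durs = np.exp(
                    rng_bouts.normal(dur_log_mean + a_dur + b_dur, config.bout_dur_log_sd, size=n_bouts)
                )
                durs = np.maximum(durs, config.bout_min_dur_s)
                ends = np.minimum(starts + durs, truth_tso.end_s)
                keep = ends > starts
                raw = np.column_stack([starts[keep], ends[keep]])
                truth = normalize_track(
                    raw, participant_id=pid, night_id=nid, source=TRUTH_SOURCE, kind="scratch"
                )
                # make the truth a fixed point of the bout post-processing
                truth = filter_min_duration(
                    merge_gaps(truth, 3.0), config.bout_min_dur_s
                )
                add_track(truth, TRUTH_SOURCE, "scratch")
                event_rows.append(
                    {
                        "participant_id": pid,
                        "night_id": nid,
                        "source": TRUTH_SOURCE,
                        "kind": "tso",
                        "start_s": truth_tso.start_s,
                        "end_s": truth_tso.end_s,
                    }
                )

                for ridx, rname in enumerate(rater_names):
                    model = config.raters[rname]
                    rng_rater = _rng(seed, pidx, nidx, _ROLE_RATER + ridx)
                    track = apply_rater_model(truth, model, rng_rater, truth_tso, source=rname)
                    add_track(track, rname, "scratch")
                    if rname in ("R1", "R2", "R3"):
                        ts = truth_tso.start_s + (
                            rng_rater.normal(0.0, model.tso_jitter_sd_s)
                            if model.tso_jitter_sd_s > 0
                            else 0.0
                        )
                        te = truth_tso.end_s + (
                            rng_rater.normal(0.0, model.tso_jitter_sd_s)
                            if model.tso_jitter_sd_s > 0
                            else 0.0
                        )
                        event_rows.append(
                            {
                                "participant_id": pid,
                                "night_id": nid,
                                "source": rname,
                                "kind": "tso",
                                "start_s": ts,
                                "end_s": max(te, ts + 60.0),
                            }
                        )

                for didx, dname in enumerate(device_names):
                    model = config.devices[dname]
                    rng_dev = _rng(seed, pidx, nidx, _ROLE_DEVICE + didx)
                    scratch, sleep = apply_device_model(
                        truth,
                        truth_tso,
                        model,
                        rng_dev,
                        source=dname,
                        participant_offsets=device_offsets[dname],
                    )
                    add_track(scratch, dname, "scratch")
                    add_track(sleep, dname, "sleep_period")

                if cohort.name != "HV":
                    rng_pro = _rng(seed, pidx, nidx, _ROLE_PRO)
                    nd = total_duration(truth) / tso_dur_h
                    latent = (
                        config.pro_itch_intercept
                        + config.pro_itch_slope * math.log1p(nd)
                        + rng_pro.normal(0.0, config.pro_itch_noise_sd)
                    )
                    itch = int(np.clip(round(latent), 0, 10))
                    pro_date = night_date + dt.timedelta(days=1)
                    if rng_pro.random() < config.pro_invalid_time_prob:
                        minutes = rng_pro.uniform(13 * 60, 15 * 60)  # outside 4AM-12PM
                    else:
                        minutes = float(np.clip(rng_pro.normal(450.0, 45.0), 4 * 60, 12 * 60))
                    n_copies = 2 if rng_pro.random() < config.pro_duplicate_prob else 1
                    for _copy in range(n_copies):
                        pro_rows.append(
                            {
                                "participant_id": pid,
                                "date": pro_date.isoformat(),
                                "administration": "morning",
                                "timestamp": f"{int(minutes // 60):02d}:{int(minutes % 60):02d}",
                                "itch_nrs": itch,
                            }
                        )
                    pro_rows.append(
                        {
                            "participant_id": pid,
                            "date": night_date.isoformat(),
                            "administration": "evening",
                            "timestamp": "20:00",
                            "itch_nrs": int(np.clip(itch + rng_pro.integers(-2, 3), 0, 10)),
                        }
                    )

    events = pd.DataFrame(
        event_rows, columns=["participant_id", "night_id", "source", "kind", "start_s", "end_s"]
    )
    pros = pd.DataFrame(
        pro_rows, columns=["participant_id", "date", "administration", "timestamp", "itch_nrs"]
    )
    participants = pd.DataFrame(part_rows, columns=["participant_id", "cohort"])
    return SimulatedStudy(events=events, pros=pros, participants=participants, config=config, seed=seed)


# ---------------------------------------------------------------------------
# direct mixed-model simulation and its closed-form twin


def simulate_log_outcomes(
    n_participants: int,
    n_nights: int,
    sources: Sequence[str],
    components: tuple[float, float, float],
    source_effects: Optional[Sequence[float]] = None,
    grand_mean: float = 0.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate a balanced long table directly from the agreement mixed model.

    ``components`` are the (participant, night, residual) variances on the
    log scale.  Returns columns ``participant``, ``night``, ``source``, ``y``.
    """
    var_p, var_n, var_e = components
    rng = np.random.default_rng(seed)
    k = len(sources)
    effects = np.zeros(k) if source_effects is None else np.asarray(source_effects, float)
    a = rng.normal(0.0, math.sqrt(var_p), size=n_participants)
    b = rng.normal(0.0, math.sqrt(var_n), size=(n_participants, n_nights))
    e = rng.normal(0.0, math.sqrt(var_e), size=(n_participants, n_nights, k))
    y = grand_mean + a[:, None, None] + b[:, :, None] + effects[None, None, :] + e
    idx = pd.MultiIndex.from_product(
        [
            [f"P{i + 1:02d}" for i in range(n_participants)],
            [f"N{j + 1:02d}" for j in range(n_nights)],
            list(sources),
        ],
        names=["participant", "night", "source"],
    )
    return pd.DataFrame({"y": y.reshape(-1)}, index=idx).reset_index()


def analytic_icc(config: StudyConfig) -> dict:
    """Closed-form adjusted ICC per outcome, straight from the config."""
    out = {}
    for outcome, (var_p, var_n, var_e) in config.outcome_components.items():
        den = var_p + var_n + var_e
        out[outcome] = (var_p + var_n) / den if den > 0 else float("nan")
    return out
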