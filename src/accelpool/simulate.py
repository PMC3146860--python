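"""Synthetic accelerometer cohorts with ground truth.

Emulates the data the pooling pipeline consumes: minute-level (or
sub-minute) count files from waist-worn uniaxial monitors deployed for
2-7 days on children, with diurnal structure (overnight removal, a
waking-hours mix of sedentary, light and short spontaneous MVPA bursts)
and, optionally, the device-artifact taxonomy: whole-hour temporal
shifts, saturation plateaus at 32767, and night traces that never return
to baseline zero.

Every file carries exact ground truth (wear mask, per-day intensity
minutes, MVPA bout lengths, injected-artifact parameters), so detector
recovery and summary correctness can be asserted exactly.  Three
identifiability guards keep clean files inside the detectors' "never
flag" regime by construction (see docs/methods.md): wear segments open
and close with three non-zero minutes, every aligned 15-minute wear
chunk contains a non-zero minute, and equal-count triples at values
>= 10 are jittered within their intensity interval.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import SATURATION_CEILING, EpochSeries
from .summarize import CUTPOINT_REGISTRY, CutpointSet
from .wear import WearMask

ARTIFACT_KINDS = ("temporal_shift", "saturation_plateau", "no_baseline_return")

#: artifact parameter presets inside the documented detectable regime
DETECTABLE_PRESETS = {
    "temporal_shift": {"shift_hours": 6},
    "saturation_plateau": {"length": 30, "value": SATURATION_CEILING},
    "no_baseline_return": {"floor": 30},
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate a 7-day deployment on children aged 3-18 wearing
    the monitor during waking hours (worn on a waist belt, removed
    overnight), at 60-s epochs; contributing studies ranged over 2-7
    deployment days and epochs of 5-60 s, both reachable here.
    """

    seed: int
    n_participants: int = 20
    study_id: str = "SYNTH"
    deployment_days: int = 7
    epoch_length: int = 60
    start_date: dt.date = dt.date(2004, 4, 5)
    age_range: tuple = (3, 18)
    female_fraction: float = 0.5
    wake_hour: int = 7
    sleep_hour: int = 22
    wake_jitter_hours: tuple = (0, 2)    # per-day on-time delay, inclusive
    sleep_jitter_hours: tuple = (-3, 0)  # per-day off-time advance, inclusive
    removal_prob: float = 0.4          # chance of one daytime removal per day
    removal_minutes: tuple = (60, 150)  # episode length range (>= rule window)
    removal_spike_prob: float = 0.3     # chance the episode gets 1-2 spike min
    overnight_wear: bool = False        # legitimate 24-h wear (flag-rule tests)
    p_mvpa_start: float = 0.015         # per waking minute
    mvpa_burst_mean: float = 3.0        # geometric burst length, minutes
    p_vigorous: float = 0.3             # vigorous share within MVPA minutes
    sedentary_fraction: float = 0.45    # sedentary share of non-MVPA minutes
    sedentary_zero_prob: float = 0.6    # zeros among sedentary minutes
    artifact_rates: dict = field(default_factory=dict)  # kind -> fraction
    cutpoints_name: str = "evenson_2008"

    def __post_init__(self):
        if not 2 <= self.deployment_days <= 7:
            raise ValueError("deployment_days must be in 2..7")
        if self.epoch_length not in (5, 10, 15, 20, 30, 60):
            raise ValueError("epoch_length must be one of 5,10,15,20,30,60")
        if not 0 <= self.wake_hour < self.sleep_hour <= 24:
            raise ValueError("need 0 <= wake < sleep <= 24")
        if self.sleep_hour - self.wake_hour >= 24:
            raise ValueError("infeasible schedule: no sleep period")
        if (self.wake_hour + self.wake_jitter_hours[1]
                >= self.sleep_hour + self.sleep_jitter_hours[0]):
            raise ValueError("jitter ranges allow wake at/after sleep")
        for k, v in self.artifact_rates.items():
            if k not in ARTIFACT_KINDS:
                raise ValueError(f"unknown artifact kind {k!r}")
            if not 0 <= v <= 1:
                raise ValueError(f"artifact rate for {k} must be in [0,1]")

    @property
    def cutpoints(self) -> CutpointSet:
        return CUTPOINT_REGISTRY[self.cutpoints_name]


@dataclass
class FileTruth:
    """Exact ground truth for one generated file (minute scale)."""

    wear: np.ndarray                  # bool, True = worn
    intensity_minutes: pd.DataFrame   # per day x category, wear minutes only
    bout_lengths: dict                # date -> list of MVPA bout lengths (min)
    artifact: dict | None = None      # kind + parameters, or None


@dataclass
class GroundTruth:
    """Per-file truth for a generated cohort, keyed by filename stem."""

    files: dict = field(default_factory=dict)

    def wear_mask(self, source_name: str) -> WearMask:
        return WearMask(self.files[source_name].wear)


# ---------------------------------------------------------------------------
# per-minute label / count drawing

SED, LIGHT, MOD, VIG = 0, 1, 2, 3
_CATEGORY_NAMES = ("sedentary", "light", "moderate", "vigorous")


def _draw_labels(rng, n: int, cfg: SimConfig) -> np.ndarray:
    """Intensity labels for one contiguous wear segment."""
    labels = np.empty(n, dtype=np.int8)
    i = 0
    while i < n:
        if rng.random() < cfg.p_mvpa_start:
            # geometric burst length, mean mvpa_burst_mean minutes
            burst = int(rng.geometric(1.0 / cfg.mvpa_burst_mean))
            burst = min(burst, n - i)
            for j in range(i, i + burst):
                labels[j] = VIG if rng.random() < cfg.p_vigorous else MOD
            i += burst
        else:
            labels[i] = SED if rng.random() < cfg.sedentary_fraction else LIGHT
            i += 1
    return labels


def _draw_counts(rng, labels: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Counts consistent with the labels under the active cutpoint set.

    Each minute's count is drawn uniformly within its category's
    counts-per-minute interval, so intensity classification recovers the
    labels exactly.
    """
    cp = cfg.cutpoints
    hi_vig = min(cp.vigorous + 2000, SATURATION_CEILING)
    counts = np.zeros(len(labels), dtype=np.int64)
    for code, lo, hi in (
        (LIGHT, cp.light, cp.moderate),
        (MOD, cp.moderate, cp.vigorous),
        (VIG, cp.vigorous, hi_vig),
    ):
        sel = labels == code
        counts[sel] = rng.integers(lo, hi, size=int(sel.sum()))
    sed = labels == SED
    n_sed = int(sed.sum())
    sed_counts = np.where(
        rng.random(n_sed) < cfg.sedentary_zero_prob,
        0,
        rng.integers(1, cfg.cutpoints.light, size=n_sed),
    )
    counts[sed] = sed_counts
    return counts


def _apply_guards(rng, counts: np.ndarray, wear: np.ndarray,
                  cfg: SimConfig) -> None:
    """In-place identifiability guards on clean wear counts.

    (1) first/last 3 minutes of each wear segment are non-zero;
    (2) each aligned 15-min wear chunk contains >= 1 non-zero minute
        (so no 60-min window inside wear can satisfy the non-wear rule);
    (3) no 3 identical consecutive counts at a value >= 10 (so the
        plateau rule never fires on a clean file).
    Replacement values stay within the sedentary interval or the original
    category interval, leaving ground-truth labels untouched.
    """
    light = cfg.cutpoints.light
    w = np.asarray(wear)
    change = np.flatnonzero(w[1:] != w[:-1]) + 1
    bounds = np.concatenate([[0], change, [len(w)]])
    for s, e in zip(bounds[:-1], bounds[1:]):
        if not w[s]:
            continue
        for idx in (*range(s, min(s + 3, e)), *range(max(e - 3, s), e)):
            if counts[idx] == 0:
                counts[idx] = rng.integers(1, light)
        for cs in range(s, e, 15):
            chunk = slice(cs, min(cs + 15, e))
            if not counts[chunk].any():
                counts[(cs + min(cs + 15, e)) // 2] = rng.integers(1, light)
    # plateau guard: break equal triples at values >= 10
    for i in range(2, len(counts)):
        if counts[i] >= 10 and counts[i] == counts[i - 1] == counts[i - 2]:
            counts[i] += -1 if _at_interval_top(int(counts[i]), cfg) else 1


def _at_interval_top(v: int, cfg: SimConfig) -> bool:
    cp = cfg.cutpoints
    return v + 1 in (cp.light, cp.moderate, cp.vigorous, SATURATION_CEILING + 1)


# ---------------------------------------------------------------------------
# file generation

def _generate_minutes(rng, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """One deployment at minute resolution: (counts, wear) arrays."""
    n = cfg.deployment_days * 1440
    counts = np.zeros(n, dtype=np.int64)
    wear = np.zeros(n, dtype=bool)

    for day in range(cfg.deployment_days):
        base = day * 1440
        if cfg.overnight_wear:
            wear[base: base + 1440] = True
            wake = sleep = None
        else:
            # day-to-day variation in on/off times spreads daily wear
            # across the valid-day criteria
            wake = cfg.wake_hour + int(rng.integers(
                cfg.wake_jitter_hours[0], cfg.wake_jitter_hours[1] + 1))
            sleep = cfg.sleep_hour + int(rng.integers(
                cfg.sleep_jitter_hours[0], cfg.sleep_jitter_hours[1] + 1))
            wear[base + wake * 60: base + sleep * 60] = True

        # at most one daytime removal, leaving >= 60 wear min on each side
        if not cfg.overnight_wear and rng.random() < cfg.removal_prob:
            length = int(rng.integers(*cfg.removal_minutes))
            lo = base + wake * 60 + 60
            hi = base + sleep * 60 - 60 - length
            if hi > lo:
                start = int(rng.integers(lo, hi))
                wear[start: start + length] = False
                if rng.random() < cfg.removal_spike_prob:
                    n_spikes = int(rng.integers(1, 3))
                    pos = rng.choice(
                        np.arange(start + 5, start + length - 5),
                        size=n_spikes, replace=False)
                    counts[pos] = rng.integers(200, 2000, size=n_spikes)

    # waking activity on wear minutes, segment by segment
    change = np.flatnonzero(wear[1:] != wear[:-1]) + 1
    bounds = np.concatenate([[0], change, [n]])
    hours = (np.arange(n) % 1440) // 60
    for s, e in zip(bounds[:-1], bounds[1:]):
        if not wear[s]:
            continue
        if cfg.overnight_wear:
            night = (hours[s:e] >= cfg.sleep_hour) | (hours[s:e] < cfg.wake_hour)
        else:
            night = np.zeros(e - s, dtype=bool)
        seg_labels = _draw_labels(rng, e - s, cfg)
        seg_counts = _draw_counts(rng, seg_labels, cfg)
        if night.any():
            # sleep movement: sparse low counts, >= 1 non-zero per 15 min,
            # zeros always present (baseline reached every night)
            seg_counts[night] = 0
            night_idx = np.flatnonzero(night)
            for cs in range(0, len(night_idx), 15):
                chunk = night_idx[cs: cs + 15]
                k = int(rng.integers(1, 4))
                pos = rng.choice(chunk, size=min(k, len(chunk)), replace=False)
                seg_counts[pos] = rng.integers(1, 60, size=len(pos))
        counts[s:e] = seg_counts

    _apply_guards(rng, counts, wear, cfg)
    return counts, wear


def _truth_tables(counts: np.ndarray, wear: np.ndarray,
                  cfg: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Recover per-day intensity minutes and MVPA bout lengths from counts.

    Counts were drawn inside category intervals, so the interval bounds
    reproduce the drawn labels exactly; this is generator bookkeeping,
    not a re-implementation of the pipeline (which additionally detects
    wear itself).
    """
    cp = cfg.cutpoints
    codes = cp.classify(counts)
    day_index = np.arange(len(counts)) // 1440
    rows = []
    bouts: dict = {}
    for d in range(int(day_index[-1]) + 1):
        day = cfg.start_date + dt.timedelta(days=d)
        sel = (day_index == d) & wear
        lab = codes[sel]
        rows.append({
            "date": day,
            **{name: int((lab == c).sum())
               for c, name in enumerate(_CATEGORY_NAMES)},
        })
        mvpa = lab >= MOD
        padded = np.concatenate([[False], mvpa, [False]])
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        bouts[day] = list((edges[1::2] - edges[0::2]).astype(int))
    return pd.DataFrame(rows).set_index("date"), bouts


def _expand_epochs(counts: np.ndarray, epoch_length: int) -> np.ndarray:
    """Split minute counts into sub-minute epochs (sum-preserving)."""
    if epoch_length == 60:
        return counts
    k = 60 // epoch_length
    sub = np.repeat(counts // k, k).reshape(-1, k)
    sub[:, 0] += counts - (counts // k) * k
    return sub.reshape(-1)


# ---------------------------------------------------------------------------
# artifact injection

def inject_artifact(
    series: EpochSeries,
    kind: str,
    params: dict | None = None,
    seed: int = 0,
) -> tuple[EpochSeries, dict]:
    """Inject a device artifact into a 60-s-epoch series.

    temporal_shift
        Rotates every complete day's counts forward by ``shift_hours``
        whole hours (activity appears that many hours late, on every day).
    saturation_plateau
        Overwrites a daytime run of ``length`` epochs with ``value``
        (default the 32767 ceiling; minimum detectable run is 3 at >= 10).
    no_baseline_return
        Adds a constant non-zero ``floor`` to the night block
        (00:00-05:00) of every complete day.

    Returns the modified series and a label recording the exact
    parameters; parameters below the detectable regime are permitted but
    the label carries ``sub_threshold=True``.
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}")
    params = {**DETECTABLE_PRESETS[kind], **(params or {})}
    rng = np.random.default_rng(seed)
    c = series.counts.copy()
    n_days = len(c) // 1440
    label = {"kind": kind, **params, "sub_threshold": False}

    if kind == "temporal_shift":
        k = int(params["shift_hours"]) * 60
        for d in range(n_days):
            block = c[d * 1440: (d + 1) * 1440]
            c[d * 1440: (d + 1) * 1440] = np.roll(block, k)
        label["sub_threshold"] = params["shift_hours"] == 0
    elif kind == "saturation_plateau":
        length, value = int(params["length"]), int(params["value"])
        if "start" in params:
            start = int(params["start"])
        else:
            day = int(rng.integers(0, max(n_days, 1)))
            start = day * 1440 + int(rng.integers(10 * 60, 16 * 60 - length))
        c[start: start + length] = value
        label["start"] = start
        label["sub_threshold"] = length < 3 or value < 10
    else:  # no_baseline_return
        floor = int(params["floor"])
        for d in range(n_days):
            night = slice(d * 1440, d * 1440 + 5 * 60)
            c[night] = c[night] + floor
        label["sub_threshold"] = floor < 1
    return series.replace(counts=c), label


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class Cohort:
    files: list
    truth: GroundTruth
    phenotypes: pd.DataFrame


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate a cohort of count files with phenotypes and ground truth.

    Deterministic given ``config.seed``.  Artifacts are injected into
    disjoint subsets of files at the configured per-kind rates, using the
    detectable presets unless overridden.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    files = []
    pheno_rows = []

    # disjoint artifact assignment
    n = config.n_participants
    order = rng.permutation(n)
    assignment: dict[int, str] = {}
    cursor = 0
    for kind in ARTIFACT_KINDS:
        k = int(round(config.artifact_rates.get(kind, 0.0) * n))
        for idx in order[cursor: cursor + k]:
            assignment[int(idx)] = kind
        cursor += k

    for i in range(n):
        pid = f"P{i + 1:04d}"
        age = float(np.round(rng.uniform(*config.age_range), 1))
        sex = "female" if rng.random() < config.female_fraction else "male"
        height = float(np.round(90 + (age - 3) * 5.5 + rng.normal(0, 5), 1))
        weight = float(np.round(13 + (age - 3) * 3.2 + rng.normal(0, 3), 1))
        pheno_rows.append({
            "participant_id": pid, "wave": 1, "age": age, "sex": sex,
            "height_cm": height, "weight_kg": weight,
        })

        counts, wear = _generate_minutes(rng, config)
        intensity, bouts = _truth_tables(counts, wear, config)

        source = f"{config.study_id}_{pid}"
        series = EpochSeries(
            serial_number=f"SYN{i + 1:05d}",
            device_model="GT1M",
            epoch_length=60,
            start_datetime=dt.datetime.combine(config.start_date, dt.time(0, 0)),
            counts=counts,
            study_id=config.study_id,
            participant_id=pid,
            wave="1",
            source_name=source,
        )

        artifact = None
        if i in assignment:
            series, artifact = inject_artifact(
                series, assignment[i],
                seed=int(rng.integers(0, 2**31 - 1)))
            if assignment[i] == "temporal_shift":
                # the rotation displaces true wear the same way
                k = int(artifact["shift_hours"]) * 60
                wear = wear.copy()
                for d in range(len(wear) // 1440):
                    wear[d * 1440:(d + 1) * 1440] = np.roll(
                        wear[d * 1440:(d + 1) * 1440], k)

        if config.epoch_length != 60:
            series = series.replace(
                counts=_expand_epochs(series.counts, config.epoch_length),
                epoch_length=config.epoch_length,
            )

        truth.files[source] = FileTruth(
            wear=wear, intensity_minutes=intensity,
            bout_lengths=bouts, artifact=artifact)
        files.append(series)

    phenotypes = pd.DataFrame(pheno_rows)
    return Cohort(files, truth, phenotypes)
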