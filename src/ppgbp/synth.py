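"""Synthetic paired PPG/ABP waveform generator.

Produces quasi-periodic photoplethysmogram (PPG) pulses — a systolic peak
plus an optional dicrotic wave — together with an arterial blood pressure
(ABP) trace that oscillates between a requested diastolic (DBP) and
systolic (SBP) level, at a configurable sampling rate (default 125 Hz).

The generator exists so that every downstream stage (filtering, screening,
the regression network, the evaluation protocol) can be exercised without
any clinical data download.  Blood pressure is deterministically coupled to
pulse *morphology*, not amplitude: segment-wise Min-Max normalisation later
in the pipeline destroys absolute amplitude, so a learner must recover BP
from shape.  Concretely:

* the systolic lobe width narrows monotonically as SBP rises
  (sharper upstroke at higher systolic pressure);
* the dicrotic lobe's relative timing and the pulse (diastolic) width grow
  monotonically with DBP.

Each cardiac cycle is a sum of two Gaussian lobes on a per-beat time axis.
Additive disturbances — low-frequency baseline drift, powerline
interference, and broadband Gaussian noise — are applied to the PPG only;
the ABP trace stays clean so it can serve as the reference-pressure ground
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

__all__ = [
    "SimConfig",
    "WaveformRecord",
    "pulse_shape_params",
    "generate_record",
    "generate_dataset",
    "uniform_bp_sampler",
    "skewed_bp_sampler",
    "get_bp_sampler",
]

#: relative position of the systolic peak within a beat (fraction of period)
SYSTOLIC_CENTER = 0.16

#: minimum plausible pulse pressure accepted by the BP samplers, mmHg
MIN_PULSE_PRESSURE = 20.0


@dataclass
class SimConfig:
    """Configuration of a single simulated subject record.

    Amplitude-like quantities (``drift_amp``, ``powerline_amp``,
    ``noise_sd``) are in the same arbitrary units as the unit-amplitude
    PPG pulse train.
    """

    duration_s: float = 10.0
    fs: float = 125.0
    hr_bpm: float = 70.0
    sbp: float = 120.0
    dbp: float = 80.0
    drift_amp: float = 0.3
    drift_freq: float = 0.1
    powerline_amp: float = 0.05
    powerline_freq: float = 50.0
    noise_sd: float = 0.02
    dicrotic_strength: float = 0.4
    jitter_frac: float = 0.03  # beat-to-beat period jitter, +-fraction
    sbp_end: float | None = None  # optional linear SBP trend endpoint
    dbp_end: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got fs={self.fs}")
        if not self.duration_s > 0:
            raise ValueError(
                f"duration_s must be positive, got duration_s={self.duration_s}"
            )
        if not 30.0 <= self.hr_bpm <= 180.0:
            raise ValueError(
                f"hr_bpm must lie in [30, 180], got hr_bpm={self.hr_bpm}"
            )
        if not self.sbp > self.dbp > 0:
            raise ValueError(
                f"require sbp > dbp > 0, got sbp={self.sbp}, dbp={self.dbp}"
            )
        if not 0.0 <= self.dicrotic_strength <= 1.0:
            raise ValueError(
                "dicrotic_strength must lie in [0, 1], got "
                f"dicrotic_strength={self.dicrotic_strength}"
            )
        for name in ("drift_amp", "powerline_amp", "noise_sd", "jitter_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def clean(self, **overrides) -> "SimConfig":
        """Copy of this config with all additive disturbances switched off."""
        d = asdict(self)
        d.update(drift_amp=0.0, powerline_amp=0.0, noise_sd=0.0)
        d.update(overrides)
        return SimConfig(**d)


@dataclass
class WaveformRecord:
    """One subject record: paired PPG (a.u.) and ABP (mmHg) series."""

    ppg: np.ndarray
    abp: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        if self.ppg.shape != self.abp.shape:
            raise ValueError("ppg and abp must have identical length")

    @property
    def duration_s(self) -> float:
        return len(self.ppg) / self.fs


def pulse_shape_params(sbp: float, dbp: float) -> tuple[float, float, float]:
    """Morphology parameters coupled to blood pressure.

    Returns ``(sigma_s, t_d, sigma_d)``: systolic lobe width, dicrotic lobe
    center, and dicrotic (pulse) width, all as fractions of the beat period.
    ``sigma_s`` is strictly decreasing in SBP; ``t_d`` and ``sigma_d`` are
    strictly increasing in DBP.  The affine ramps span the physiologic
    design range (SBP 90-180, DBP 50-90) and extrapolate linearly outside
    it, so monotonicity holds globally.
    """
    sigma_s = 0.055 + 0.045 * (180.0 - sbp) / 90.0
    t_d = 0.36 + 0.24 * (dbp - 50.0) / 40.0
    sigma_d = 0.07 + 0.07 * (dbp - 50.0) / 40.0
    return sigma_s, t_d, sigma_d


def _beat_onsets(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Beat onset times covering [0, duration); jittered period."""
    period = 60.0 / cfg.hr_bpm
    onsets = []
    t = 0.0
    while t < cfg.duration_s:
        onsets.append(t)
        jitter = rng.uniform(-cfg.jitter_frac, cfg.jitter_frac) if cfg.jitter_frac else 0.0
        t += period * (1.0 + jitter)
    return np.asarray(onsets)


def generate_record(cfg: SimConfig) -> WaveformRecord:
    """Simulate one paired PPG/ABP record.

    The ABP trace is the pulse train affinely rescaled *per beat* so that
    every beat's maximum equals that beat's SBP and its minimum equals the
    beat's DBP (exact by construction, before any float rounding).  The PPG
    shares the same pulse morphology and additionally carries drift,
    powerline interference and white noise.

    Identical configs (including ``seed``) give bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    onsets = _beat_onsets(cfg, rng)
    n_beats = len(onsets)
    # per-beat pressure targets (constant, or a linear trend over the record)
    frac = onsets / max(cfg.duration_s, 1e-12)
    sbp_end = cfg.sbp if cfg.sbp_end is None else cfg.sbp_end
    dbp_end = cfg.dbp if cfg.dbp_end is None else cfg.dbp_end
    beat_sbp = cfg.sbp + (sbp_end - cfg.sbp) * frac
    beat_dbp = cfg.dbp + (dbp_end - cfg.dbp) * frac

    # period of each beat = gap to next onset; last beat keeps the nominal gap
    nominal = 60.0 / cfg.hr_bpm
    periods = np.empty(n_beats)
    periods[:-1] = np.diff(onsets)
    periods[-1] = nominal

    pulse = np.zeros(n)
    for i in range(n_beats):
        t0, T = onsets[i], periods[i]
        sigma_s, t_d, sigma_d = pulse_shape_params(beat_sbp[i], beat_dbp[i])
        for center, width, amp in (
            (SYSTOLIC_CENTER, sigma_s, 1.0),
            (t_d, sigma_d, cfg.dicrotic_strength),
        ):
            if amp == 0.0:
                continue
            c = t0 + center * T
            w = width * T
            lo = max(0, int(math.floor((c - 5 * w) * cfg.fs)))
            hi = min(n, int(math.ceil((c + 5 * w) * cfg.fs)) + 1)
            if lo < hi:
                tt = t[lo:hi]
                pulse[lo:hi] += amp * np.exp(-0.5 * ((tt - c) / w) ** 2)

    # per-beat affine map onto [dbp_i, sbp_i]
    abp = np.empty(n)
    bounds = np.concatenate([np.searchsorted(t, onsets), [n]])
    for i in range(n_beats):
        lo, hi = bounds[i], bounds[i + 1]
        if lo >= hi:
            continue
        seg = pulse[lo:hi]
        pmin, pmax = seg.min(), seg.max()
        if pmax - pmin < 1e-12:
            abp[lo:hi] = beat_dbp[i]
        else:
            abp[lo:hi] = beat_dbp[i] + (beat_sbp[i] - beat_dbp[i]) * (
                (seg - pmin) / (pmax - pmin)
            )

    ppg = pulse.copy()
    if cfg.drift_amp:
        ppg += cfg.drift_amp * np.sin(
            2 * np.pi * cfg.drift_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if cfg.powerline_amp:
        ppg += cfg.powerline_amp * np.sin(
            2 * np.pi * cfg.powerline_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if cfg.noise_sd:
        ppg += cfg.noise_sd * rng.standard_normal(n)

    meta = {
        "beat_onsets": onsets,
        "beat_sbp": beat_sbp,
        "beat_dbp": beat_dbp,
        "config": asdict(cfg),
    }
    return WaveformRecord(ppg=ppg, abp=abp, fs=cfg.fs, meta=meta)


# ---------------------------------------------------------------------------
# blood-pressure samplers

def uniform_bp_sampler(rng: np.random.Generator) -> tuple[float, float]:
    """SBP ~ U[90, 180], DBP ~ U[50, 90]; resampled until pulse pressure >= 20."""
    for _ in range(1000):
        sbp = rng.uniform(90.0, 180.0)
        dbp = rng.uniform(50.0, 90.0)
        if sbp - dbp >= MIN_PULSE_PRESSURE:
            return sbp, dbp
    raise RuntimeError("uniform BP sampler failed to draw sbp - dbp >= 20")


def skewed_bp_sampler(rng: np.random.Generator) -> tuple[float, float]:
    """Right-skewed clinical-like BP mix: mass near 110-130/60-70 with a
    hypertensive tail, mimicking the skewed pressure histogram of ICU data."""
    for _ in range(1000):
        sbp = 95.0 + rng.gamma(shape=3.0, scale=10.0)
        dbp = 52.0 + rng.gamma(shape=3.0, scale=5.0)
        sbp = min(sbp, 195.0)
        dbp = min(dbp, 100.0)
        if sbp - dbp >= MIN_PULSE_PRESSURE:
            return sbp, dbp
    raise RuntimeError("skewed BP sampler failed to draw sbp - dbp >= 20")


_SAMPLERS = {"uniform": uniform_bp_sampler, "skewed": skewed_bp_sampler}


def get_bp_sampler(
    spec: str | Callable[[np.random.Generator], tuple[float, float]],
) -> Callable[[np.random.Generator], tuple[float, float]]:
    if callable(spec):
        return spec
    try:
        return _SAMPLERS[spec]
    except KeyError:
        raise ValueError(
            f"unknown BP sampler {spec!r}; choose from {sorted(_SAMPLERS)}"
        ) from None


def generate_dataset(
    n_records: int,
    bp_sampler: str | Callable = "uniform",
    base_cfg: SimConfig | None = None,
    seed: int = 0,
) -> list[WaveformRecord]:
    """Generate ``n_records`` independent records.

    Per-record sub-seeds are derived from ``seed`` through
    ``numpy.random.SeedSequence`` spawning, so the dataset is reproducible
    as a whole while records stay statistically independent.  Heart rate is
    drawn uniformly from 55-85 bpm per record; (SBP, DBP) come from
    ``bp_sampler``.
    """
    if n_records < 1:
        raise ValueError(f"n_records must be >= 1, got {n_records}")
    base = base_cfg if base_cfg is not None else SimConfig()
    sampler = get_bp_sampler(bp_sampler)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_records)
    records = []
    for i, child in enumerate(children):
        draw_seed, sub_seed = (int(s % (2**31)) for s in child.generate_state(2))
        rng = np.random.default_rng(draw_seed)
        sbp, dbp = sampler(rng)
        if not sbp > dbp:
            raise RuntimeError("BP sampler returned sbp <= dbp")
        d = asdict(base)
        d.update(
            sbp=float(sbp),
            dbp=float(dbp),
            hr_bpm=float(rng.uniform(55.0, 85.0)),
            seed=sub_seed,
        )
        rec = generate_record(SimConfig(**d))
        rec.meta["record_id"] = i
        records.append(rec)
    return records
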