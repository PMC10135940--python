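"""PPG conditioning and quality screening.

The conditioning chain, in fixed order:

1. band-pass filtering of the PPG (4th-order Butterworth, 0.5-8 Hz,
   zero-phase by default) — the ABP is deliberately left raw so reference
   pressures stay in mmHg;
2. fixed-length segmentation with a sliding window (3 s at 125 Hz = 375
   samples), applied at identical offsets to PPG and ABP;
3. reference SBP/DBP extraction from each raw ABP window (mean of detected
   per-beat maxima/minima);
4. quality screening: pressure-range rule (SBP <= 180 and DBP >= 50),
   non-negative skewness, and a lag-searched autocorrelation signal-quality
   index with threshold 0.6;
5. per-segment Min-Max normalisation to [0, 1] and construction of the
   velocity (VPG) and acceleration (APG) derivative channels.

Each step is exposed as a standalone function; :func:`preprocess_record`
runs the whole chain on one record and stamps a provenance trail on every
segment so the stage order is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .synth import WaveformRecord

__all__ = [
    "DegenerateSegmentError",
    "FilterSpec",
    "SegmentPair",
    "QualityReport",
    "ModelInput",
    "bandpass_filter",
    "segment",
    "extract_bp_reference",
    "skewness",
    "autocorrelation_sqi",
    "quality_filter",
    "minmax_normalize",
    "make_model_input",
    "preprocess_record",
    "preprocess_records",
    "screening_summary",
]


class DegenerateSegmentError(ValueError):
    """A segment is constant (zero variance) where variation is required."""


@dataclass
class FilterSpec:
    """Butterworth band-pass specification.

    ``mode='zero-phase'`` applies the filter forward and backward
    (``sosfiltfilt``), preserving pulse morphology at the cost of doubling
    the effective attenuation; ``'causal'`` is a single forward pass.
    """

    order: int = 4
    low_hz: float = 0.5
    high_hz: float = 8.0
    mode: str = "zero-phase"

    def validate(self, fs: float) -> None:
        if self.mode not in ("zero-phase", "causal"):
            raise ValueError(f"mode must be 'zero-phase' or 'causal', got {self.mode!r}")
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"require 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})"
            )
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high_hz={self.high_hz} must be below the Nyquist frequency {fs / 2}"
            )
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return sps.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass", fs=fs,
            output="sos",
        )


@dataclass
class SegmentPair:
    """One fixed-length window: conditioned PPG plus the raw ABP it pairs with."""

    ppg_window: np.ndarray  # filtered PPG, a.u.
    abp_window: np.ndarray  # raw ABP, mmHg
    start_index: int
    record_id: object = None
    sbp_ref: float | None = None
    dbp_ref: float | None = None
    provenance: list[str] = field(default_factory=list)


@dataclass
class QualityReport:
    """Outcome of every screening rule for one segment."""

    skewness: float
    ac_sqi: float
    bp_in_range: bool
    passed: bool
    fail_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.passed == (not self.fail_reasons)


@dataclass
class ModelInput:
    """Network-ready sample: 3 x 375 normalized channels (PPG, VPG, APG)."""

    channels: np.ndarray
    labels: tuple[float, float]  # (sbp_ref, dbp_ref), mmHg
    record_id: object = None
    start_index: int = 0
    provenance: list[str] = field(default_factory=list)


def bandpass_filter(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Band-pass a signal; same length out as in."""
    spec = spec or FilterSpec()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("bandpass_filter expects a 1-D signal")
    if len(x) <= 3 * spec.order:
        raise ValueError(
            f"signal of length {len(x)} too short for an order-{spec.order} filter"
        )
    sos = spec.sos(fs)
    if spec.mode == "zero-phase":
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def segment(
    record: WaveformRecord,
    window_s: float = 3.0,
    stride_s: float | None = None,
    ppg: np.ndarray | None = None,
) -> list[SegmentPair]:
    """Cut a record into fixed-length windows at offsets 0, stride, 2*stride, ...

    ``ppg`` optionally supplies a conditioned (filtered) PPG series to slice
    instead of the record's raw one; the ABP is always sliced raw at the
    identical offsets.  A trailing partial window is discarded; a record
    shorter than one window yields an empty list.
    """
    stride_s = window_s if stride_s is None else stride_s
    win_f = window_s * record.fs
    win = int(round(win_f))
    if abs(win_f - win) > 0.5:
        raise ValueError(f"window_s*fs={win_f} is not within 0.5 of an integer")
    stride = stride_s * record.fs
    if stride <= 0:
        raise ValueError("stride_s must be positive")
    src = record.ppg if ppg is None else np.asarray(ppg, dtype=float)
    if len(src) != len(record.abp):
        raise ValueError("ppg series and record abp must have equal length")
    n = len(src)
    out: list[SegmentPair] = []
    record_id = record.meta.get("record_id")
    k = 0
    while True:
        start = int(round(k * stride))
        if start + win > n:
            break
        out.append(
            SegmentPair(
                ppg_window=src[start : start + win].copy(),
                abp_window=record.abp[start : start + win].copy(),
                start_index=start,
                record_id=record_id,
                provenance=["segmented"],
            )
        )
        k += 1
    return out


def extract_bp_reference(
    abp_window: np.ndarray, fs: float, hr_max_bpm: float = 180.0
) -> tuple[float, float]:
    """Reference (SBP, DBP) of one raw ABP window.

    SBP is the mean of detected per-beat maxima, DBP the mean of per-beat
    minima; peak detection enforces a minimum inter-peak distance of one
    period at ``hr_max_bpm`` and a prominence of a quarter of the window
    range.  Falls back to the global max/min when fewer than two beats are
    detected.  A flat window (range < 1 mmHg) returns ``(nan, nan)`` — a
    quality failure for the screening stage, not an exception.
    """
    x = np.asarray(abp_window, dtype=float)
    rng_ = float(x.max() - x.min()) if len(x) else 0.0
    if len(x) == 0 or rng_ < 1.0:
        return (float("nan"), float("nan"))
    min_dist = max(1, int(round(fs * 60.0 / hr_max_bpm)))
    # half-range prominence keeps dicrotic peaks out of the beat count
    prom = 0.5 * rng_
    peaks, _ = sps.find_peaks(x, distance=min_dist, prominence=prom)
    troughs, _ = sps.find_peaks(-x, distance=min_dist, prominence=prom)
    if len(peaks) >= 2 and len(troughs) >= 1:
        sbp = float(x[peaks].mean())
        dbp = float(x[troughs].mean())
    else:
        sbp = float(x.max())
        dbp = float(x.min())
    if not sbp > dbp:  # pathological window; treat like the fallback
        sbp, dbp = float(x.max()), float(x.min())
    return sbp, dbp


def skewness(x: np.ndarray) -> float:
    """Third standardized moment with population (divide-by-N) statistics.

    Returns ``nan`` for a zero-variance segment, which downstream screening
    treats as an automatic failure.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError(f"skewness needs >= 3 samples, got {len(x)}")
    mu = x.mean()
    sigma = x.std()  # population (ddof=0)
    if sigma == 0:
        return float("nan")
    return float(np.mean(((x - mu) / sigma) ** 3))


def autocorrelation_sqi(
    x: np.ndarray, fs: float, hr_range_bpm: tuple[float, float] = (30.0, 150.0)
) -> float:
    """Periodicity signal-quality index.

    Maximum over physiologic beat-period lags of the mean-removed Pearson
    autocorrelation of the window.  Lags run from one period at the upper
    heart-rate bound to one period at the lower bound, capped so at least
    32 samples overlap; the result lies in [-1, 1].  Zero-variance windows
    return ``nan`` (degenerate segment).
    """
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        return float("nan")
    hr_lo, hr_hi = hr_range_bpm
    lag_min = max(1, int(np.floor(fs * 60.0 / hr_hi)))
    lag_max = min(int(np.ceil(fs * 60.0 / hr_lo)), len(x) - 32)
    if lag_max < lag_min:
        raise ValueError(
            f"window of {len(x)} samples too short for heart-rate range {hr_range_bpm}"
        )
    best = -1.0
    for lag in range(lag_min, lag_max + 1):
        a = x[:-lag]
        b = x[lag:]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
        if r > best:
            best = r
    return best


def quality_filter(
    segments: Sequence[SegmentPair],
    fs: float = 125.0,
    sbp_max: float = 180.0,
    dbp_min: float = 50.0,
    skew_min: float = 0.0,
    ac_threshold: float = 0.6,
    hr_range_bpm: tuple[float, float] = (30.0, 150.0),
) -> tuple[list[SegmentPair], list[QualityReport]]:
    """Apply every screening rule to every segment.

    A segment is kept iff its reference SBP <= ``sbp_max``, reference DBP >=
    ``dbp_min``, PPG skewness >= ``skew_min`` and autocorrelation SQI >=
    ``ac_threshold``.  Nothing is raised: every rule outcome is recorded in
    a :class:`QualityReport` (one per input segment, same order), so kept +
    per-rule failures always reconcile with the input count.
    """
    kept: list[SegmentPair] = []
    reports: list[QualityReport] = []
    for seg in segments:
        fails: list[str] = []
        sbp = seg.sbp_ref if seg.sbp_ref is not None else float("nan")
        dbp = seg.dbp_ref if seg.dbp_ref is not None else float("nan")
        bp_ok = bool(sbp <= sbp_max and dbp >= dbp_min)  # False for nan
        if not bp_ok:
            fails.append("bp_range")
        sk = skewness(seg.ppg_window)
        if not sk >= skew_min:  # nan fails
            fails.append("skewness")
        ac = autocorrelation_sqi(seg.ppg_window, fs, hr_range_bpm)
        if not ac >= ac_threshold:
            fails.append("autocorrelation")
        passed = not fails
        reports.append(
            QualityReport(
                skewness=sk, ac_sqi=ac, bp_in_range=bp_ok,
                passed=passed, fail_reasons=fails,
            )
        )
        if passed:
            seg.provenance.append("screened")
            kept.append(seg)
    return kept, reports


def screening_summary(reports: Iterable[QualityReport]) -> dict:
    """Per-rule failure counts plus kept/total bookkeeping."""
    reports = list(reports)
    counts: dict[str, int] = {"bp_range": 0, "skewness": 0, "autocorrelation": 0}
    kept = 0
    for r in reports:
        if r.passed:
            kept += 1
        for reason in r.fail_reasons:
            counts[reason] = counts.get(reason, 0) + 1
    return {
        "total": len(reports),
        "kept": kept,
        "failed": len(reports) - kept,
        "failures_per_rule": counts,
    }


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]; the minimum maps to 0 and the maximum to 1."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    # relative tolerance: a range at the rounding noise floor is constant
    if hi - lo <= 1e-9 * max(abs(lo), abs(hi), 1e-300):
        raise DegenerateSegmentError("constant segment cannot be Min-Max normalized")
    return (x - lo) / (hi - lo)


def make_model_input(seg: SegmentPair) -> ModelInput:
    """Build the 3-channel network input for a screened segment.

    Channel 0 is the Min-Max-normalized PPG window; the velocity (VPG) and
    acceleration (APG) channels are first differences of the previous
    channel, right-padded by repeating the last difference (so lengths
    match) and then independently Min-Max normalized.
    """
    if seg.sbp_ref is None or seg.dbp_ref is None:
        raise ValueError("segment is missing reference pressures")

    def _diff(x):
        d = np.diff(x)
        return np.append(d, d[-1])

    ch0 = minmax_normalize(seg.ppg_window)
    vpg = _diff(ch0)
    apg = _diff(vpg)
    try:
        ch1 = minmax_normalize(vpg)
        ch2 = minmax_normalize(apg)
    except DegenerateSegmentError as e:
        raise DegenerateSegmentError(f"degenerate derivative channel: {e}") from e
    seg.provenance.append("normalized")
    return ModelInput(
        channels=np.stack([ch0, ch1, ch2]),
        labels=(float(seg.sbp_ref), float(seg.dbp_ref)),
        record_id=seg.record_id,
        start_index=seg.start_index,
        provenance=list(seg.provenance),
    )


def preprocess_record(
    record: WaveformRecord,
    window_s: float = 3.0,
    stride_s: float | None = None,
    filter_spec: FilterSpec | None = None,
    **screen_kwargs,
) -> tuple[list[ModelInput], list[QualityReport]]:
    """Full conditioning chain for one record.

    filter -> segment -> extract references -> screen -> normalize/derive.
    Returns the network-ready inputs of the kept segments and the quality
    report of *every* segment.
    """
    filtered = bandpass_filter(record.ppg, record.fs, filter_spec)
    segs = segment(record, window_s=window_s, stride_s=stride_s, ppg=filtered)
    for s in segs:
        s.provenance.insert(0, "filtered")
        s.sbp_ref, s.dbp_ref = extract_bp_reference(s.abp_window, record.fs)
        s.provenance.append("referenced")
    kept, reports = quality_filter(segs, fs=record.fs, **screen_kwargs)
    inputs = [make_model_input(s) for s in kept]
    return inputs, reports


def preprocess_records(
    records: Iterable[WaveformRecord], **kwargs
) -> tuple[list[ModelInput], list[QualityReport]]:
    """Apply :func:`preprocess_record` to many records, concatenating results."""
    all_inputs: list[ModelInput] = []
    all_reports: list[QualityReport] = []
    for rec in records:
        inputs, reports = preprocess_record(rec, **kwargs)
        all_inputs.extend(inputs)
        all_reports.extend(reports)
    return all_inputs, all_reports
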