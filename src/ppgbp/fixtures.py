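"""Canonical, deterministic test fixtures.

Small constructed objects reused by the test suite and exportable as
plain-text files: a five-segment screening batch in which exactly one
segment is clean (the others each violate exactly one screening rule), a
hand-sized squeeze-and-excitation forward example, the reference
error-vector for the ME/SD/MAE statistics, and a 30-s noise-free record.
All of it is seeded, so regeneration is platform-independent.
"""

from __future__ import annotations

import numpy as np

from .preprocess import SegmentPair, bandpass_filter, segment, extract_bp_reference
from .synth import SimConfig, generate_record

__all__ = [
    "clean_record_30s",
    "make_quality_batch",
    "se_toy_example",
    "error_vector_example",
]


def clean_record_30s(sbp: float = 120.0, dbp: float = 80.0, seed: int = 11) -> "WaveformRecord":
    """30-s noise-free record at 125 Hz (drift/powerline/broadband all off)."""
    cfg = SimConfig(duration_s=30.0, sbp=sbp, dbp=dbp, seed=seed).clean()
    return generate_record(cfg)


def _clean_segment(sbp: float = 120.0, dbp: float = 80.0, seed: int = 11) -> SegmentPair:
    """One filtered, referenced 3-s segment from a clean record."""
    rec = clean_record_30s(sbp=sbp, dbp=dbp, seed=seed)
    filtered = bandpass_filter(rec.ppg, rec.fs)
    seg = segment(rec, ppg=filtered)[1]  # skip the edge-transient window
    seg.sbp_ref, seg.dbp_ref = extract_bp_reference(seg.abp_window, rec.fs)
    return seg


def make_quality_batch(fs: float = 125.0) -> list[SegmentPair]:
    """Five referenced segments for the screening rules, in order:

    0. hypertensive reference (SBP 190) — fails the BP-range rule only;
    1. hypotensive reference (DBP 45) — fails the BP-range rule only;
    2. amplitude-mirrored PPG — negative skewness only;
    3. PPG with its second half replaced by broadband noise (sensor
       corruption) — low autocorrelation only;
    4. clean — passes everything.
    """
    batch = [
        _clean_segment(sbp=190.0, dbp=80.0, seed=21),
        _clean_segment(sbp=120.0, dbp=45.0, seed=22),
        _clean_segment(seed=23),
        _clean_segment(seed=24),
        _clean_segment(seed=25),
    ]
    batch[2].ppg_window = -batch[2].ppg_window  # mirror: flips skewness sign
    damaged = batch[3].ppg_window.copy()
    half = len(damaged) // 2
    noise_rng = np.random.default_rng(2024)
    damaged[half:] = damaged.std() * np.abs(noise_rng.standard_normal(len(damaged) - half))
    batch[3].ppg_window = damaged
    return batch


def se_toy_example() -> dict:
    """Two-channel, three-sample squeeze-and-excitation example.

    Weights are chosen by hand so the whole forward pass is reproducible
    with scalar arithmetic; the expected output in the test suite is
    derived independently from the squeeze/excite/scale definition.
    """
    return {
        "x": [[1.0, 1.0, 1.0], [0.0, 0.0, 0.0]],  # channel means z = [1, 0]
        "fc1_w": [[1.0, -1.0]],  # 2 channels -> 1 hidden unit
        "fc1_b": [0.5],
        "fc2_w": [[2.0], [-1.0]],  # hidden -> 2 channels
        "fc2_b": [0.0, 0.0],
    }


def error_vector_example() -> dict:
    """Reference error vector [1, -1, 2, -2] and its exact statistics."""
    return {
        "errors": [1.0, -1.0, 2.0, -2.0],
        "me": 0.0,
        "sd": float(np.sqrt(10.0 / 3.0)),
        "mae": 1.5,
    }
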