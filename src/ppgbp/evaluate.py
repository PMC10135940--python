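"""Standards-based evaluation of blood-pressure predictions.

Implements the full device-grading protocol used for cuff-less BP
estimators:

* **Error statistics** — mean error (ME), standard deviation (SD) and mean
  absolute error (MAE), with the sign convention
  ``error = reference - predicted`` throughout;
* **AAMI criterion** — pass iff |ME| <= 5 mmHg and SD <= 8 mmHg
  (bounds treated as inclusive);
* **BHS grading** — cumulative percentages of absolute errors within
  5/10/15 mmHg; grade A requires 60/85/95, B 50/75/90, C 40/65/85, and
  anything below C is grade D;
* **Bland-Altman agreement** — mean difference and 95% limits of
  agreement (mean +- 1.96 SD of the differences);
* **Pearson correlation** between predictions and references.

SD is, by default, the sample standard deviation of the errors about
their mean (ddof=1), the standard device-evaluation usage; an
``sd_as_printed`` compatibility switch computes ``sqrt(sum(e^2)/(m-1))``
without mean-centering instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sstats

__all__ = [
    "ErrorStats",
    "BHSReport",
    "BlandAltman",
    "TargetReport",
    "EvalReport",
    "error_stats",
    "aami_check",
    "bhs_grade",
    "bhs_grade_from_percentages",
    "bland_altman",
    "pearson_r",
    "evaluate",
    "save_plots",
]

#: BHS cumulative-percentage thresholds (grade -> minima at 5/10/15 mmHg)
BHS_THRESHOLDS = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}

AAMI_ME_LIMIT = 5.0
AAMI_SD_LIMIT = 8.0


@dataclass
class ErrorStats:
    me: float
    sd: float
    mae: float
    n: int


@dataclass
class BHSReport:
    pct5: float
    pct10: float
    pct15: float
    grade: str

    def __post_init__(self):
        assert 0.0 <= self.pct5 <= self.pct10 <= self.pct15 <= 100.0


@dataclass
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    pct_within: float


@dataclass
class TargetReport:
    stats: ErrorStats
    aami_pass: bool
    bhs: BHSReport
    bland_altman: BlandAltman
    pearson_r: float


@dataclass
class EvalReport:
    sbp: TargetReport
    dbp: TargetReport
    n: int

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        def tr(t):
            return TargetReport(
                stats=ErrorStats(**t["stats"]),
                aami_pass=t["aami_pass"],
                bhs=BHSReport(**t["bhs"]),
                bland_altman=BlandAltman(**t["bland_altman"]),
                pearson_r=t["pearson_r"],
            )

        return cls(sbp=tr(d["sbp"]), dbp=tr(d["dbp"]), n=d["n"])

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def read_json(cls, path) -> "EvalReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _check_pair(pred, ref, min_n=2):
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.shape != ref.shape:
        raise ValueError("pred and ref lengths differ")
    if len(pred) < min_n:
        raise ValueError(f"need at least {min_n} samples, got {len(pred)}")
    return pred, ref


def error_stats(pred, ref, sd_as_printed: bool = False) -> ErrorStats:
    """ME / SD / MAE of ``error = ref - pred``; SD uses ddof=1."""
    pred, ref = _check_pair(pred, ref)
    e = ref - pred
    if sd_as_printed:
        sd = float(np.sqrt(np.sum(e**2) / (len(e) - 1)))
    else:
        sd = float(np.std(e, ddof=1))
    return ErrorStats(me=float(np.mean(e)), sd=sd, mae=float(np.mean(np.abs(e))),
                      n=len(e))


def aami_check(stats: ErrorStats) -> bool:
    """AAMI verdict: |ME| <= 5 mmHg and SD <= 8 mmHg (inclusive)."""
    return bool(abs(stats.me) <= AAMI_ME_LIMIT and stats.sd <= AAMI_SD_LIMIT)


def bhs_grade_from_percentages(pct5: float, pct10: float, pct15: float) -> str:
    """Best BHS grade whose three thresholds are all met, else 'D'."""
    for grade in ("A", "B", "C"):
        t5, t10, t15 = BHS_THRESHOLDS[grade]
        if pct5 >= t5 and pct10 >= t10 and pct15 >= t15:
            return grade
    return "D"


def bhs_grade(abs_errors) -> BHSReport:
    """Cumulative error percentages (<=5/10/15 mmHg) and the BHS grade."""
    e = np.abs(np.asarray(abs_errors, dtype=float).ravel())
    if len(e) == 0:
        raise ValueError("empty error list")
    pct5 = float(100.0 * np.mean(e <= 5.0))
    pct10 = float(100.0 * np.mean(e <= 10.0))
    pct15 = float(100.0 * np.mean(e <= 15.0))
    return BHSReport(pct5=pct5, pct10=pct10, pct15=pct15,
                     grade=bhs_grade_from_percentages(pct5, pct10, pct15))


def bland_altman(pred, ref) -> BlandAltman:
    """Mean difference (ref - pred) and 95% limits of agreement."""
    pred, ref = _check_pair(pred, ref)
    d = ref - pred
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(100.0 * np.mean((d >= lo) & (d <= hi)))
    return BlandAltman(mean_diff=mean, loa_low=lo, loa_high=hi, pct_within=within)


def pearson_r(pred, ref) -> float:
    """Pearson product-moment correlation coefficient."""
    pred, ref = _check_pair(pred, ref, min_n=3)
    if np.std(pred) == 0 or np.std(ref) == 0:
        raise ValueError("pearson_r requires nonconstant inputs")
    return float(sstats.pearsonr(pred, ref).statistic)


def _target_report(pred, ref, sd_as_printed=False) -> TargetReport:
    st = error_stats(pred, ref, sd_as_printed=sd_as_printed)
    return TargetReport(
        stats=st,
        aami_pass=aami_check(st),
        bhs=bhs_grade(np.asarray(ref, dtype=float) - np.asarray(pred, dtype=float)),
        bland_altman=bland_altman(pred, ref),
        pearson_r=pearson_r(pred, ref),
    )


def evaluate(pred: np.ndarray, ref: np.ndarray, sd_as_printed: bool = False) -> EvalReport:
    """Full evaluation of aligned ``(n, 2)`` [SBP, DBP] predictions (mmHg)."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 2 or pred.shape[1] != 2:
        raise ValueError(
            f"pred and ref must both be (n, 2) arrays, got {pred.shape} vs {ref.shape}"
        )
    return EvalReport(
        sbp=_target_report(pred[:, 0], ref[:, 0], sd_as_printed),
        dbp=_target_report(pred[:, 1], ref[:, 1], sd_as_printed),
        n=len(pred),
    )


def save_plots(pred: np.ndarray, ref: np.ndarray, out_dir) -> list[str]:
    """Bland-Altman and regression scatter plots for both targets."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    written = []
    for j, name in ((0, "sbp"), (1, "dbp")):
        ba = bland_altman(pred[:, j], ref[:, j])
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        mean_pair = 0.5 * (pred[:, j] + ref[:, j])
        diff = ref[:, j] - pred[:, j]
        axes[0].scatter(mean_pair, diff, s=4, alpha=0.5)
        for yline in (ba.mean_diff, ba.loa_low, ba.loa_high):
            axes[0].axhline(yline, ls="--", lw=0.8, color="k")
        axes[0].set_xlabel(f"mean of methods ({name.upper()}, mmHg)")
        axes[0].set_ylabel("reference - predicted (mmHg)")
        axes[1].scatter(ref[:, j], pred[:, j], s=4, alpha=0.5)
        lims = [min(ref[:, j].min(), pred[:, j].min()),
                max(ref[:, j].max(), pred[:, j].max())]
        axes[1].plot(lims, lims, "k--", lw=0.8)
        axes[1].set_xlabel(f"reference {name.upper()} (mmHg)")
        axes[1].set_ylabel(f"predicted {name.upper()} (mmHg)")
        fig.tight_layout()
        path = out_dir / f"{name}_agreement.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(str(path))
    return written
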