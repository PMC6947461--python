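"""Method-comparison statistics: NGS chimerism vs a reference method.

Paired donor-chimerism percentages from the test method (NGS) and a
reference method (conventional STR fragment analysis) are compared by

* squared Pearson correlation (least-squares r²),
* a Bland–Altman analysis of the raw differences (test - ref), with the
  agreement band at mean ± 3 SD,
* cutoff-based diagnostic agreement for the clinical call of "complete
  donor chimerism" (chimerism ≥ cutoff, inclusive), with the reference
  method defining truth: sensitivity, specificity, PPV, NPV and overall
  agreement at each cutoff.

Rates with empty denominators are reported as ``None``, never as 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BLAND_ALTMAN_SD_MULTIPLIER = 3.0


@dataclass(frozen=True)
class PairedChimerism:
    sample: str
    ref_pct: float
    test_pct: float

    def __post_init__(self) -> None:
        for name in ("ref_pct", "test_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0,100] (got {v})")


def load_pairs(path) -> list[PairedChimerism]:
    """Read paired percentages from a TSV (``sample ref_pct test_pct``).

    Pairs where either method is NA are excluded listwise with a logged
    count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "ref_pct", "test_pct"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    pairs, dropped = [], 0
    for _, row in df.iterrows():
        try:
            ref = float(row["ref_pct"])
            test = float(row["test_pct"])
        except (TypeError, ValueError):
            dropped += 1
            continue
        if math.isnan(ref) or math.isnan(test):
            dropped += 1
            continue
        pairs.append(PairedChimerism(str(row["sample"]), ref, test))
    if dropped:
        logger.info("excluded %d pair(s) with a missing value", dropped)
    return pairs


def least_squares_r2(pairs: Sequence[PairedChimerism]) -> float:
    """Squared Pearson correlation between the two methods."""
    if len(pairs) < 3:
        raise ValueError("at least 3 pairs required")
    ref = [p.ref_pct for p in pairs]
    test = [p.test_pct for p in pairs]
    if len(set(ref)) == 1 or len(set(test)) == 1:
        raise ValueError("degenerate input: zero variance in one method")
    r = stats.pearsonr(ref, test).statistic
    return float(r * r)


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    sd_diff: float
    lower: float
    upper: float
    outliers: tuple[PairedChimerism, ...]

    @property
    def n_outliers(self) -> int:
        return len(self.outliers)


def bland_altman(
    pairs: Sequence[PairedChimerism], k: float = BLAND_ALTMAN_SD_MULTIPLIER
) -> BlandAltman:
    """Bland–Altman on raw differences test - ref (percentage points),
    agreement limits at mean ± k·SD (sample SD; default k = 3)."""
    if len(pairs) < 3:
        raise ValueError("at least 3 pairs required")
    diffs = [p.test_pct - p.ref_pct for p in pairs]
    mean = sum(diffs) / len(diffs)
    var = sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1)
    sd = math.sqrt(var)
    lower, upper = mean - k * sd, mean + k * sd
    outliers = tuple(
        p for p, d in zip(pairs, diffs) if d < lower or d > upper
    )
    return BlandAltman(mean, sd, lower, upper, outliers)


def _rate(num: int, den: int) -> Optional[float]:
    return 100.0 * num / den if den else None


@dataclass(frozen=True)
class CutoffStats:
    cutoff: float
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> Optional[float]:
        return _rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return _rate(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return _rate(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return _rate(self.tn, self.tn + self.fn)

    @property
    def agreement(self) -> Optional[float]:
        return _rate(self.tp + self.tn, self.n)

    def as_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "agreement": self.agreement,
        }


def cutoff_concordance(pairs: Sequence[PairedChimerism], cutoff: float) -> CutoffStats:
    """2x2 agreement for the complete-donor-chimerism call at a cutoff.

    Positive means chimerism ≥ cutoff (inclusive); the reference method
    defines truth, the test method is evaluated against it.
    """
    if not pairs:
        raise ValueError("at least 1 pair required")
    tp = fp = fn = tn = 0
    for p in pairs:
        truth = p.ref_pct >= cutoff
        called = p.test_pct >= cutoff
        if truth and called:
            tp += 1
        elif truth:
            fn += 1
        elif called:
            fp += 1
        else:
            tn += 1
    return CutoffStats(cutoff=cutoff, tp=tp, fp=fp, fn=fn, tn=tn)


def concordance_report(
    pairs: Sequence[PairedChimerism], cutoffs: Sequence[float] = (99.0, 95.0, 90.0)
) -> dict:
    """All concordance statistics in one JSON-serialisable bundle."""
    ba = bland_altman(pairs)
    return {
        "n_pairs": len(pairs),
        "r_squared": least_squares_r2(pairs),
        "bland_altman": {
            "mean_diff": ba.mean_diff,
            "sd_diff": ba.sd_diff,
            "lower": ba.lower,
            "upper": ba.upper,
            "n_outliers": ba.n_outliers,
            "outlier_samples": [p.sample for p in ba.outliers],
        },
        "cutoffs": [cutoff_concordance(pairs, c).as_dict() for c in cutoffs],
    }
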