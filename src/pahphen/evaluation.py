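"""Diagnostic test characteristics and deployment summaries.

Sensitivity, specificity, PPV and NPV are exact confusion-table ratios;
ratios with a zero denominator are reported as NaN, never as 0.  AUC is the
rank-based (Mann–Whitney) statistic with tied scores contributing 1/2,
identical to brute-force counting of concordant score pairs.  Confidence
intervals over cross-validation resamples use the normal approximation
``mean +/- 1.96 * sd / sqrt(k)`` (a percentile alternative is provided),
clipped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from pahphen.lexicon import MEDICATION_CLASSES, Lexicon
from pahphen.records import PatientRecord

HEMO_FIELDS = ("mRA", "mPAP", "PCWP", "CO", "CI", "PVR")


@dataclass
class TestCharacteristics:
    """AUC, Se, Sp, PPV, NPV with confusion counts and optional 95% CIs."""

    n: int
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: Optional[float] = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "auc": self.auc,
        }
        if self.ci:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(predicted: Sequence, truth: Sequence) -> TestCharacteristics:
    """Exact confusion-table test characteristics (without AUC).

    ``predicted`` and ``truth`` are equal-length binary vectors (any truthy
    coding; booleans or 0/1).
    """
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} predictions vs {true.shape} labels")
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    tn = int(np.sum(~pred & ~true))
    return TestCharacteristics(
        n=len(pred),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


def auc_score(scores: Sequence[float], truth: Sequence) -> float:
    """Mann–Whitney AUC; ties contribute 1/2. Both classes must be present."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def resample_ci(
    samples: Sequence[float], level: float = 0.95, method: str = "normal"
) -> tuple[float, float, float]:
    """(mean, low, high) over metric resamples, clipped to [0, 1].

    ``method="normal"`` uses mean +/- z * sd/sqrt(k) with the population
    (ddof=0) standard deviation of the resamples; ``"percentile"`` uses the
    empirical quantiles.  Requires at least 2 samples.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("resample_ci requires at least 2 samples")
    mean = float(x.mean())
    if method == "normal":
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        half = z * float(x.std(ddof=0)) / math.sqrt(x.size)
        lo, hi = mean - half, mean + half
    elif method == "percentile":
        alpha = (1 - level) / 2
        lo, hi = (float(q) for q in np.quantile(x, [alpha, 1 - alpha]))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return mean, max(0.0, lo), min(1.0, hi)


def _mean_sd(values: list[float]) -> tuple[float, float]:
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        return float("nan"), float("nan")
    sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
    return float(a.mean()), sd


def characteristics_table(
    cases: list[PatientRecord], lexicon: Optional[Lexicon] = None
) -> dict:
    """Aggregate demographics, comorbidities, medication classes and
    hemodynamics over a set of predicted cases.

    Hemodynamic means/SDs are computed only over cases that have a
    right-heart-catheterization row; that sub-n is reported separately.
    No truth labels are consulted.
    """
    lexicon = lexicon or Lexicon()
    n = len(cases)
    out: dict = {"n": n}
    if n == 0:
        out.update(
            {
                "age_mean": float("nan"),
                "age_sd": float("nan"),
                "pct_female": float("nan"),
                "pct_ctd": float("nan"),
                "pct_chd": float("nan"),
                "medication_class_pct": {k: float("nan") for k in MEDICATION_CLASSES},
                "n_hemodynamics": 0,
                "hemodynamics": {},
            }
        )
        return out

    ages = [r.age_years for r in cases]
    out["age_mean"], out["age_sd"] = _mean_sd(ages)
    out["pct_female"] = 100.0 * sum(r.sex == "female" for r in cases) / n
    out["pct_ctd"] = 100.0 * sum("CTD" in r.comorbidity_codes for r in cases) / n
    out["pct_chd"] = 100.0 * sum("CHD" in r.comorbidity_codes for r in cases) / n

    med_class: dict[str, float] = {}
    for cls, generics in MEDICATION_CLASSES.items():
        hit = 0
        for r in cases:
            for ev in r.events:
                if ev.vocabulary == "MED":
                    g = lexicon.generic_of(ev.code)
                    if g in generics:
                        hit += 1
                        break
        med_class[cls] = 100.0 * hit / n
    out["medication_class_pct"] = med_class

    with_h = [r for r in cases if r.hemodynamics is not None]
    out["n_hemodynamics"] = len(with_h)
    hemo: dict[str, tuple[float, float]] = {}
    for f in HEMO_FIELDS:
        hemo[f] = _mean_sd([getattr(r.hemodynamics, f) for r in with_h])
    out["hemodynamics"] = {f: {"mean": m, "sd": s} for f, (m, s) in hemo.items()}
    return out


def characteristics_frame(summary: dict) -> pd.DataFrame:
    """Render a characteristics_table() dict as a two-column report frame."""
    rows: list[tuple[str, object]] = [
        ("n", summary["n"]),
        ("Age (years), mean (SD)", f"{summary['age_mean']:.1f} ({summary['age_sd']:.1f})"),
        ("Sex, % female", f"{summary['pct_female']:.1f}%"),
        ("CTD, %", f"{summary['pct_ctd']:.1f}%"),
        ("CHD, %", f"{summary['pct_chd']:.1f}%"),
    ]
    for cls, pct in summary["medication_class_pct"].items():
        rows.append((f"{cls}, %", f"{pct:.1f}%"))
    rows.append(("n with hemodynamics", summary["n_hemodynamics"]))
    for f, ms in summary["hemodynamics"].items():
        rows.append((f"{f}, mean (SD)", f"{ms['mean']:.1f} ({ms['sd']:.1f})"))
    return pd.DataFrame(rows, columns=["characteristic", "value"])
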