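"""Cohort and cell statistics: mean-z-score gene signatures, TMB median
split, quartile stratification, Pearson correlation, Kaplan-Meier
curves, the Mantel-Cox log-rank test, and the caliper tumor-volume
formula V = d^2 * D / 2.

Conventions (config-exposed where noted): median-split ties go to
"low"; quartile membership is inclusive at the boundary; quantiles use
the linear-interpolation definition; Pearson p-values use the exact
t-distribution with n-2 df.  No multiple-testing correction is applied
anywhere."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

CDC1_SIGNATURE_GENES = ("Batf3", "Irf8", "Thbd", "Clec9a", "Xcr1")
CD8_EFFECTOR_SIGNATURE_GENES = ("Cd8a", "Cd8b", "Ifng", "Prf1")


@dataclass(frozen=True)
class Signature:
    """A named gene set scored as the unweighted mean of member values."""

    name: str
    genes: Tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} has duplicate genes")


CDC1_SIGNATURE = Signature("cdc1", CDC1_SIGNATURE_GENES)
CD8_EFFECTOR_SIGNATURE = Signature("cd8eff", CD8_EFFECTOR_SIGNATURE_GENES)
BUILTIN_SIGNATURES = {s.name: s for s in (CDC1_SIGNATURE, CD8_EFFECTOR_SIGNATURE)}


@dataclass
class CohortSample:
    """One cohort member: TMB, per-gene z-scores, and survival."""

    sample_id: str
    tmb: float
    zscores: Dict[str, float]
    time: float
    event: int


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper axes in mm; minor axis d must not exceed major axis D."""

    d: float
    D: float

    def __post_init__(self):
        if not (0 < self.d <= self.D):
            raise ValidationError(f"need 0 < d <= D, got d={self.d}, D={self.D}")


def tumor_volume(m: TumorMeasurement) -> float:
    """V = d^2 * D / 2 (mm^3)."""
    return m.d ** 2 * m.D / 2.0


def signature_score(values, sig: Signature) -> pd.Series:
    """Mean of the signature genes' values per entity (sample or cell).

    ``values`` is a DataFrame (rows = entities, columns = genes) or a
    mapping entity -> {gene: value}.  Signature genes missing from the
    columns are dropped with one warning listing them; no genes present
    is an error."""
    if isinstance(values, Mapping):
        values = pd.DataFrame.from_dict(values, orient="index")
    present = [g for g in sig.genes if g in values.columns]
    missing = [g for g in sig.genes if g not in values.columns]
    if not present:
        raise DegenerateInputError(
            f"no genes of signature {sig.name!r} present in the value table"
        )
    if missing:
        logger.warning("signature %s: genes missing and dropped: %s",
                       sig.name, ", ".join(missing))
    return values[present].mean(axis=1)


def median_split(values, ties_to: str = "low") -> Dict[str, str]:
    """Label each entity 'high' (value > median) or 'low' (value <= median).

    ``ties_to='high'`` flips the boundary convention (value >= median is
    high).  All-identical values are a degenerate split."""
    series = pd.Series(dict(values), dtype=float)
    if len(series) < 2:
        raise DegenerateInputError("median split needs at least 2 values")
    if series.nunique() == 1:
        raise DegenerateInputError("median split of identical values is degenerate")
    med = float(np.median(series.to_numpy()))
    if ties_to == "low":
        return {k: ("high" if v > med else "low") for k, v in series.items()}
    if ties_to == "high":
        return {k: ("high" if v >= med else "low") for k, v in series.items()}
    raise ValueError(f"unknown ties_to {ties_to!r}")


def quartile_groups(scores, inclusive: bool = True) -> Dict[str, str]:
    """Label entities 'bottom' (<= Q1), 'top' (>= Q3) or 'middle'.

    Q1/Q3 use the linear-interpolation quantile convention.  With
    ``inclusive=False``, boundaries use strict inequalities."""
    series = pd.Series(dict(scores), dtype=float)
    if len(series) < 4:
        raise DegenerateInputError("quartile groups need at least 4 values")
    arr = series.to_numpy()
    q1, q3 = np.quantile(arr, [0.25, 0.75], method="linear")
    if q1 == q3:
        raise DegenerateInputError("degenerate quartiles (Q1 == Q3)")
    out = {}
    for k, v in series.items():
        if (v <= q1) if inclusive else (v < q1):
            out[k] = "bottom"
        elif (v >= q3) if inclusive else (v > q3):
            out[k] = "top"
        else:
            out[k] = "middle"
    return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-tailed Pearson product-moment correlation (r, p); p via the t
    transform with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise DegenerateInputError("pearson_r needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("pearson_r input has zero variance")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _as_time_event(group) -> Tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(list(group), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of (time, event) pairs")
    times, events = arr[:, 0], arr[:, 1].astype(int)
    if np.any(times < 0):
        raise ValidationError("negative survival times")
    return times, events


def logrank_test(group_a, group_b) -> Tuple[float, float]:
    """Mantel-Cox log-rank test between two right-censored samples.

    Groups are sequences of (time, event) pairs with event in {0,1}.
    Returns (chi2, p) on 1 df; ties use the standard hypergeometric
    variance."""
    t_a, e_a = _as_time_event(group_a)
    t_b, e_b = _as_time_event(group_b)
    if e_a.sum() + e_b.sum() == 0:
        raise DegenerateInputError("log-rank test needs at least one event")
    event_times = np.unique(np.concatenate([t_a[e_a == 1], t_b[e_b == 1]]))
    observed_a = 0.0
    expected_a = 0.0
    variance = 0.0
    for t in event_times:
        n1 = np.sum(t_a >= t)
        n2 = np.sum(t_b >= t)
        d1 = np.sum((t_a == t) & (e_a == 1))
        d2 = np.sum((t_b == t) & (e_b == 1))
        n, d = n1 + n2, d1 + d2
        if n == 0 or d == 0:
            continue
        observed_a += d1
        expected_a += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if variance == 0:
        chi2 = 0.0
    else:
        chi2 = (observed_a - expected_a) ** 2 / variance
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Product-limit survival estimate; step function, right-continuous."""

    times: Tuple[float, ...]      # distinct event times, ascending
    survival: Tuple[float, ...]   # S(t) just after each event time

    def __call__(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if t >= ti:
                s = si
            else:
                break
        return s


def km_curve(times: Sequence[float], events: Sequence[int]) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator honoring right censoring."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise DegenerateInputError("km_curve needs at least one subject")
    if np.any(t < 0):
        raise ValidationError("negative survival times")
    event_times = np.unique(t[e == 1])
    surv = []
    s = 1.0
    for ti in event_times:
        n_at_risk = np.sum(t >= ti)
        d = np.sum((t == ti) & (e == 1))
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return KaplanMeierCurve(tuple(float(x) for x in event_times),
                            tuple(float(x) for x in surv))
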