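"""Kaplan-Meier estimation and the two-group log-rank test.

Both are authored here rather than delegated, so that every number in the
survival comparison is auditable from the risk tables; conventions follow
the standard product-limit estimator and the observed-minus-expected
log-rank statistic with the hypergeometric (tie-corrected) variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .phenotype import PerfusionFeatures


@dataclass
class CohortRecord:
    """One patient of the analysis cohort."""

    patient_id: str
    features: PerfusionFeatures | None
    phenotype_visual: int          # 1 = isovascular, 0 = hypovascular
    survival_days: float
    event: int                     # 1 = death observed, 0 = censored
    phenotype_predicted: int | None = None

    def __post_init__(self) -> None:
        if self.survival_days < 0:
            raise ValueError("survival_days must be non-negative")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.phenotype_visual not in (0, 1):
            raise ValueError("phenotype_visual must be 0 or 1")


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Product-limit survival step function.

    ``survival[i]`` is S(t) for t in [event_times[i], event_times[i+1]);
    S = 1 before the first event time.  ``median`` is the smallest time at
    which the estimate drops to 0.5 or below, or None (``median_reached``
    False) if that never happens.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    median: float | None
    median_reached: bool
    n: int

    def survival_at(self, t) -> np.ndarray:
        """Evaluate the step function at arbitrary times."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.event_times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])


def km_estimate(times, events) -> KaplanMeierEstimate:
    """Kaplan-Meier estimate of the survival function.

    Parameters
    ----------
    times : array-like of float
        Follow-up durations (days), non-negative.
    events : array-like of {0, 1}
        1 where death was observed, 0 where the record is censored.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("need at least one record")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    if t.shape != e.shape:
        raise ValueError("times and events must have the same length")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t[e == 1])
    # censored records at an event time remain at risk for that event
    at_risk = np.array([(t >= u).sum() for u in uniq], dtype=int)
    deaths = np.array([((t == u) & (e == 1)).sum() for u in uniq], dtype=int)
    if uniq.size:
        surv = np.cumprod(1.0 - deaths / at_risk)
    else:
        surv = np.array([])
    below = np.nonzero(surv <= 0.5)[0] if uniq.size else np.array([], int)
    if below.size:
        median, reached = float(uniq[below[0]]), True
    else:
        median, reached = None, False
    return KaplanMeierEstimate(event_times=uniq, survival=surv,
                               at_risk=at_risk, deaths=deaths,
                               median=median, median_reached=reached,
                               n=int(t.size))


@dataclass(frozen=True)
class LogrankResult:
    statistic: float       # 1-df chi-square
    p_value: float
    observed_a: float      # total events in group A
    expected_a: float      # expected events in group A under H0


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group log-rank test over the pooled event times.

    At each distinct pooled event time the 2x2 risk table contributes
    ``d * n_a / n`` expected group-A events and the hypergeometric
    variance ``d (n_a/n)(n_b/n)(n-d)/(n-1)``; the squared standardized sum
    is referred to a 1-df chi-square distribution.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.any(ta < 0) or np.any(tb < 0):
        raise ValueError("negative survival times")
    pooled_events = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    if pooled_events.size == 0:
        raise ValueError("log-rank test requires at least one event")

    o_minus_e = 0.0
    var = 0.0
    obs_a = float(ea.sum())
    exp_a = 0.0
    for u in pooled_events:
        na = (ta >= u).sum()
        nb = (tb >= u).sum()
        n = na + nb
        da = ((ta == u) & (ea == 1)).sum()
        db = ((tb == u) & (eb == 1)).sum()
        d = da + db
        e_a = d * na / n
        exp_a += e_a
        o_minus_e += da - e_a
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if var == 0:
        # no information (e.g. all events in single-patient risk sets)
        return LogrankResult(0.0, 1.0, obs_a, exp_a)
    chi2 = o_minus_e ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(float(chi2), p, obs_a, exp_a)


def compare_groups(records, by: str = "phenotype_visual") -> dict:
    """KM estimates and log-rank comparison between the two phenotype
    groups of a cohort (``by`` = visual or predicted phenotype)."""
    groups = {0: [], 1: []}
    for r in records:
        label = getattr(r, by)
        if label is None:
            raise ValueError(f"record {r.patient_id} has no {by} label")
        groups[int(label)].append(r)
    if not groups[0] or not groups[1]:
        raise ValueError("both phenotype groups must be non-empty")
    out = {"by": by}
    km = {}
    for label, recs in groups.items():
        t = [r.survival_days for r in recs]
        e = [r.event for r in recs]
        km[label] = km_estimate(t, e)
    lr = logrank_test([r.survival_days for r in groups[0]],
                      [r.event for r in groups[0]],
                      [r.survival_days for r in groups[1]],
                      [r.event for r in groups[1]])
    out["km_hypovascular"] = km[0]
    out["km_isovascular"] = km[1]
    out["logrank"] = lr
    out["median_hypovascular"] = km[0].median
    out["median_isovascular"] = km[1].median
    return out
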