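"""Risk labelling, Kaplan–Meier estimation and the survival-marker screen.

The screening battery dichotomizes each continuous imaging marker by a
constrained 1-D two-cluster cut (equivalent to Ward's hierarchical clustering
into two groups in one dimension, with a minimum group size of 10), compares
overall survival between the groups with the Gehan–Breslow–Wilcoxon weighted
log-rank test, compares marker means between responders and non-responders
with Welch's t-test, and controls the family-wise error rate with the
Holm–Bonferroni step-down procedure at alpha = 0.05 — one family per outcome
type (OS tests; response tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .imaging_io import RESPONSE_CATEGORIES, CohortTable, ValidationError

logger = logging.getLogger(__name__)

#: OS cutoff (days) separating low and high risk; 548 days = 18 months
RISK_OS_CUTOFF_DAYS = 548

RESPONDER_CATEGORIES = ("CR", "PR", "SD")


def assign_risk(os_days: int, response: str) -> str:
    """Risk label: 'low' iff OS > 548 days and the patient responded to
    treatment (CR/PR/SD), else 'high'."""
    if response not in RESPONSE_CATEGORIES:
        raise ValidationError(f"unknown response category {response!r}")
    if os_days <= 0:
        raise ValidationError("os_days must be positive")
    low = os_days > RISK_OS_CUTOFF_DAYS and response in RESPONDER_CATEGORIES
    return "low" if low else "high"


# ---------------------------------------------------------------------------
# Kaplan–Meier


@dataclass
class KMCurve:
    times: np.ndarray  # event times (days), ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    median: float | None  # smallest event time with S(t) <= 0.5


def km_curve(times, event_flags) -> KMCurve:
    """Product-limit (Kaplan–Meier) estimate of the survival function.

    Deaths are events; survivors are censored at their last follow-up.  The
    median is the smallest event time at which S(t) drops to 0.5 or below,
    undefined when S never reaches 0.5.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    if t.size == 0:
        raise ValidationError("empty survival input")
    if np.any(t <= 0):
        raise ValidationError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    event_times = np.sort(np.unique(t[e]))
    if event_times.size:
        surv = (
            kmf.survival_function_at_times(event_times).to_numpy().astype(float)
        )
        # number at risk just before each event time
        at_risk = np.array([(t >= et).sum() for et in event_times], dtype=int)
    else:
        surv = np.array([])
        at_risk = np.array([], dtype=int)
    median = None
    below = np.nonzero(surv <= 0.5 + 1e-12)[0]
    if below.size:
        median = float(event_times[below[0]])
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk, median=median)


# ---------------------------------------------------------------------------
# dichotomization (1-D constrained two-cluster cut)


def dichotomize_marker(values, min_group: int = 10) -> tuple[float, np.ndarray]:
    """Split a 1-D marker into two groups maximising the between-group sum of
    squares, subject to both groups holding at least ``min_group`` patients.

    For two clusters in one dimension this exhaustive scan over cuts between
    consecutive sorted values is exactly Ward's hierarchical two-cluster
    solution under the size constraint.  Returns ``(threshold, assignment)``
    where ``assignment[i]`` is True for the upper group and the threshold is
    the midpoint of the chosen gap.  Ties favour more balanced groups.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2 * min_group:
        raise ValidationError(
            f"need at least {2 * min_group} values for dichotomization, got {n}"
        )
    order = np.argsort(x, kind="stable")
    xs = x[order]
    best = None  # (bss, -imbalance, cut_index)
    for k in range(min_group, n - min_group + 1):
        if xs[k - 1] == xs[k]:
            continue  # cannot cut inside a tie
        lo, hi = xs[:k], xs[k:]
        bss = (
            k * (lo.mean() - xs.mean()) ** 2
            + (n - k) * (hi.mean() - xs.mean()) ** 2
        )
        key = (bss, -abs(n - 2 * k))
        if best is None or key > best[0]:
            best = (key, k)
    if best is None:
        raise ValidationError("no valid cut satisfies the group-size constraint")
    k = best[1]
    threshold = float((xs[k - 1] + xs[k]) / 2.0)
    return threshold, x > threshold


# ---------------------------------------------------------------------------
# tests


def _gehan_chi2(times: np.ndarray, events: np.ndarray, in_group2: np.ndarray) -> float:
    """Gehan–Breslow–Wilcoxon chi-square statistic (weight = n at risk)."""
    event_times = np.unique(times[events])
    z = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n2 = (at_risk & in_group2).sum()
        n1 = n - n2
        dying = events & (times == t)
        d = dying.sum()
        d1 = (dying & ~in_group2).sum()
        w = n  # Breslow weight
        z += w * (d1 - n1 * d / n)
        if n > 1:
            var += w * w * (n1 * n2 * d * (n - d)) / (n * n * (n - 1))
    if var <= 0:
        return 0.0
    return float(z * z / var)


def gehan_wilcoxon_test(
    times1,
    events1,
    times2,
    events2,
    permutation: int = 0,
    seed: int | None = None,
) -> tuple[float, float]:
    """Gehan–Breslow–Wilcoxon weighted log-rank test between two arms.

    Weights each event time by the number at risk, emphasising early
    differences.  Returns ``(chi2 statistic, p)``; with ``permutation > 0`` the
    p-value is instead estimated by seeded label shuffling (assumption-free
    oracle mode).  If no events occur in either arm the test is undefined and
    ``(0.0, 1.0)`` is returned.
    """
    t1 = np.asarray(times1, float)
    t2 = np.asarray(times2, float)
    e1 = np.asarray(events1, bool)
    e2 = np.asarray(events2, bool)
    if t1.size == 0 or t2.size == 0:
        raise ValidationError("both groups must be nonempty")
    if e1.sum() + e2.sum() == 0:
        logger.warning("no events in either arm; Wilcoxon test undefined")
        return 0.0, 1.0
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    in_g2 = np.arange(t.size) >= t1.size
    stat = _gehan_chi2(t, e, in_g2)
    if permutation <= 0:
        return stat, float(stats.chi2.sf(stat, df=1))
    rng = np.random.default_rng(seed)
    n2 = t2.size
    count = 0
    for _ in range(permutation):
        perm = np.zeros(t.size, dtype=bool)
        perm[rng.choice(t.size, size=n2, replace=False)] = True
        if _gehan_chi2(t, e, perm) >= stat - 1e-12:
            count += 1
    return stat, (count + 1) / (permutation + 1)


def welch_t_test(x1, x2) -> tuple[float, float]:
    """Welch's t-test (unequal variances, Satterthwaite df), two-sided."""
    a = np.asarray(x1, float)
    b = np.asarray(x2, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("both samples need at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        logger.warning("zero variance in both samples with different means")
        return np.inf, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def holm_bonferroni(pvals, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down rejections at family-wise level alpha, in input order."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject


# ---------------------------------------------------------------------------
# marker screen


@dataclass
class MarkerTestResult:
    marker: str
    threshold: float | None  # None for dichotomous markers
    n_low: int
    n_high: int
    os_statistic: float
    os_p: float
    os_rejected: bool  # Holm decision within the OS family
    response_statistic: float | None
    response_p: float | None
    response_rejected: bool | None


#: continuous markers screened (column names of the patient-features table)
SCREEN_CONTINUOUS = [
    "tmtv_ml",
    "tlg_total",
    "n_lesions",
    "n_organ_regions",
    "dm_max",
    "sul_peak_min",
    "adc_mean_range",
    "blr",
]

#: dichotomous markers: organ-region indicators + SLR classification
SCREEN_REGIONS = [
    "lymph_nodes",
    "soft_tissue",
    "bone",
    "liver",
    "spleen",
    "lung",
    "pleura",
    "brain",
    "other_viscera",
]


def marker_screen(
    features: pd.DataFrame,
    cohort: CohortTable,
    alpha: float = 0.05,
    min_group: int = 10,
    slr_cutoff: float = 1.1,
) -> list[MarkerTestResult]:
    """Screen every imaging marker against OS and treatment response.

    ``features`` is a patient-features table keyed by ``patient_id`` (as
    produced by :func:`melrisk.quant_features.patient_features_frame`).
    Continuous markers are dichotomized by the constrained cluster cut;
    organ-region indicators and the SLR classification bypass clustering.
    Holm–Bonferroni is applied separately across the OS family and the
    response family.  Markers that are entirely missing, constant, or with a
    degenerate group (< 2 patients on one side) are skipped with a log entry.
    """
    feats = features.set_index(features["patient_id"].astype(str))
    ids = [r.patient_id for r in cohort]
    missing_ids = [i for i in ids if str(i) not in feats.index]
    if missing_ids:
        raise ValidationError(f"features missing for patients {missing_ids}")
    feats = feats.loc[[str(i) for i in ids]]
    os_days = np.array([r.os_days for r in cohort], float)
    died = np.array([r.died for r in cohort], bool)
    responder = np.array(
        [r.response in RESPONDER_CATEGORIES for r in cohort], bool
    )

    candidates: list[tuple[str, float | None, np.ndarray]] = []

    for name in SCREEN_CONTINUOUS:
        if name not in feats.columns:
            logger.info("marker %s absent from feature table; skipped", name)
            continue
        col = pd.to_numeric(feats[name], errors="coerce").to_numpy(float)
        ok = np.isfinite(col)
        if ok.sum() < col.size:
            logger.info("marker %s has missing values; skipped", name)
            continue
        try:
            threshold, upper = dichotomize_marker(col, min_group=min_group)
        except ValidationError as exc:
            logger.info("marker %s not dichotomizable: %s; skipped", name, exc)
            continue
        candidates.append((name, threshold, upper))

    for region in SCREEN_REGIONS:
        col_name = f"region_{region}"
        if col_name not in feats.columns:
            continue
        ind = feats[col_name].to_numpy(float) > 0
        if ind.sum() < 2 or (~ind).sum() < 2:
            logger.info("organ indicator %s has < 2 patients per side; skipped", region)
            continue
        candidates.append((col_name, None, ind))

    if "slr" in feats.columns:
        slr_vals = pd.to_numeric(feats["slr"], errors="coerce").to_numpy(float)
        if np.all(np.isfinite(slr_vals)):
            ind = slr_vals > slr_cutoff
            if ind.sum() >= 2 and (~ind).sum() >= 2:
                candidates.append((f"slr_gt_{slr_cutoff}", float(slr_cutoff), ind))
            else:
                logger.info("SLR classification degenerate at cutoff %.2f; skipped",
                            slr_cutoff)

    results: list[MarkerTestResult] = []
    os_p, resp_p = [], []
    for name, threshold, upper in candidates:
        stat, p = gehan_wilcoxon_test(
            os_days[~upper], died[~upper], os_days[upper], died[upper]
        )
        # response comparison: marker values (continuous) or indicator
        marker_vals = (
            pd.to_numeric(feats[name], errors="coerce").to_numpy(float)
            if name in feats.columns
            else upper.astype(float)
        )
        if responder.sum() >= 2 and (~responder).sum() >= 2:
            t_stat, t_p = welch_t_test(marker_vals[responder], marker_vals[~responder])
        else:
            t_stat, t_p = None, None
        results.append(
            MarkerTestResult(
                marker=name,
                threshold=threshold,
                n_low=int((~upper).sum()),
                n_high=int(upper.sum()),
                os_statistic=stat,
                os_p=p,
                os_rejected=False,
                response_statistic=t_stat,
                response_p=t_p,
                response_rejected=None if t_p is None else False,
            )
        )
        os_p.append(p)
        resp_p.append(t_p)

    if os_p:
        os_reject = holm_bonferroni(os_p, alpha=alpha)
        for r, rej in zip(results, os_reject):
            r.os_rejected = bool(rej)
    resp_idx = [i for i, p in enumerate(resp_p) if p is not None]
    if resp_idx:
        resp_reject = holm_bonferroni([resp_p[i] for i in resp_idx], alpha=alpha)
        for i, rej in zip(resp_idx, resp_reject):
            results[i].response_rejected = bool(rej)
    return results


def marker_screen_frame(results: list[MarkerTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker": r.marker,
                "threshold": r.threshold,
                "n_low": r.n_low,
                "n_high": r.n_high,
                "os_statistic": r.os_statistic,
                "os_p": r.os_p,
                "os_rejected": r.os_rejected,
                "response_statistic": r.response_statistic,
                "response_p": r.response_p,
                "response_rejected": r.response_rejected,
            }
            for r in results
        ]
    )
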