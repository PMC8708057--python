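"""Statistical layer: agreement, regression thresholds, group comparison,
normality, median CIs and treatment-response classification.

These are the analyses applied to the per-eye quantification output: ICC
between manual and automated fluid areas, ordinary least squares of a
tomography feature on edema volume (whose intercept is the feature value at
zero detectable fluid), Kruskal-Wallis with Conover-Iman post hoc tests
across retinopathy grades or response groups, Lilliefors-type normality
screening, and distribution-free median confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ICCResult",
    "RegressionResult",
    "ConoverResult",
    "Visit",
    "DR_GRADES",
    "RESPONSE_GROUPS",
    "icc_agreement",
    "linreg_threshold",
    "kruskal_conover",
    "ks_normality",
    "median_ci",
    "classify_response",
]

DR_GRADES = ("none", "mild NPDR", "moderate NPDR", "severe NPDR", "PDR")
RESPONSE_GROUPS = (
    "responder",
    "non-responder",
    "recurrent",
    "treatment-naive",
    "no-edema",
)

# response-rule constants: a clinically meaningful CFT change is 100 um and
# "injection free period of 2 months" is read as 60 days
CFT_RESPONSE_UM = 100.0
INJECTION_FREE_DAYS = 60


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater."""

    icc: float
    ci_low: float
    ci_high: float
    n_pairs: int


def icc_agreement(x: Sequence[float], y: Sequence[float]) -> ICCResult:
    """Absolute-agreement ICC between two raters' measurements.

    Uses the two-way random-effects single-measure model with an F-based 95%
    confidence interval.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired measurements, got {n}")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("zero variance in both raters; ICC undefined")
    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["A", "B"], n),
            "score": np.concatenate([x, y]),
        }
    )
    import warnings

    with warnings.catch_warnings():
        # perfect agreement yields infinite F ratios inside pingouin
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=df, targets="target", raters="rater", ratings="score"
        ).set_index("Type")
    # the absolute-agreement single-measure row; label varies across versions
    for label in ("ICC2", "ICC(A,1)"):
        if label in table.index:
            row = table.loc[label]
            break
    else:  # pragma: no cover - unexpected pingouin layout
        raise RuntimeError("no ICC(2,1) row in pingouin output")
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    icc = float(row["ICC"])
    ci_low, ci_high = (float(v) for v in row[ci_col])
    if not np.isfinite(ci_low) or not np.isfinite(ci_high):
        # degenerate F statistics (e.g. perfect agreement) give no interval
        ci_low = ci_high = icc
    return ICCResult(icc=icc, ci_low=ci_low, ci_high=ci_high, n_pairs=n)


@dataclass(frozen=True)
class RegressionResult:
    """OLS of a tomography feature on edema volume.

    ``intercept`` is the fitted feature value at zero edema volume — the
    detectability threshold of the feature for the scanner at hand.
    """

    slope: float
    intercept: float
    r: float
    p_value: float
    intercept_ci: tuple[float, float]
    n: int
    degenerate: bool = False


def linreg_threshold(
    feature: Sequence[float], ev: Sequence[float]
) -> RegressionResult:
    """Regress a feature on edema volume over eyes with EV > 0.

    Returns the slope, the zero-EV intercept with its 95% CI, and the Pearson
    correlation with its p-value.  A feature with zero variance yields the
    degenerate result r = 0, p = 1 (flat line at the intercept).
    """
    feature = np.asarray(feature, float)
    ev = np.asarray(ev, float)
    if feature.shape != ev.shape:
        raise ValueError("feature and ev must have equal length")
    keep = (ev > 0) & np.isfinite(ev) & np.isfinite(feature)
    feature, ev = feature[keep], ev[keep]
    n = ev.size
    if n < 3:
        raise ValueError(f"need >= 3 pairs with edema volume > 0, got {n}")
    if np.ptp(ev) == 0:
        raise ValueError("edema volume has zero variance; regression undefined")
    fit = sm.OLS(feature, sm.add_constant(ev)).fit()
    intercept, slope = fit.params
    lo, hi = fit.conf_int(alpha=0.05)[0]
    if np.ptp(feature) == 0:
        return RegressionResult(
            slope=0.0,
            intercept=float(feature[0]),
            r=0.0,
            p_value=1.0,
            intercept_ci=(float(lo), float(hi)),
            n=n,
            degenerate=True,
        )
    r, p = sps.pearsonr(feature, ev)
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        r=float(r),
        p_value=float(p),
        intercept_ci=(float(lo), float(hi)),
        n=n,
    )


@dataclass
class ConoverResult:
    """Tie-corrected Kruskal-Wallis omnibus plus Conover-Iman pairwise tests."""

    h_statistic: float
    p_value: float
    pairwise_p: pd.DataFrame
    pairwise_p_raw: pd.DataFrame = field(repr=False, default=None)
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def kruskal_conover(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> ConoverResult:
    """Kruskal-Wallis omnibus test with Conover-Iman post hoc comparisons.

    The pairwise t statistics are computed on the pooled ranks with the
    (N - 1 - H)/(N - k) variance deflation and df = N - k; two-sided p-values
    are Holm-adjusted across the k(k-1)/2 pairs.
    """
    names = list(groups)
    samples = [np.asarray(groups[g], float) for g in names]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for g, s in zip(names, samples):
        if s.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence of any difference
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)
    sizes = np.array([s.size for s in samples])
    n_total = int(sizes.sum())
    k = len(samples)

    ranks = sps.rankdata(pooled)
    edges = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[edges[i] : edges[i + 1]].mean() for i in range(k)]
    )
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4.0) / (n_total - 1)
    dfree = n_total - k
    pmat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    raw = []
    pairs = []
    if s2 > 0 and dfree > 0:
        scale = s2 * (n_total - 1 - h) / dfree
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(scale * (1.0 / sizes[i] + 1.0 / sizes[j]))
                t = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
                pr = 2.0 * sps.t.sf(abs(t), dfree)
                raw.append(min(pr, 1.0))
                pairs.append((i, j))
        adj = multipletests(raw, method="holm")[1] if raw else []
        for (i, j), pr, pa in zip(pairs, raw, adj):
            pmat.iloc[i, j] = pmat.iloc[j, i] = pa
    raw_mat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for (i, j), pr in zip(pairs, raw):
        raw_mat.iloc[i, j] = raw_mat.iloc[j, i] = pr
    return ConoverResult(
        h_statistic=float(h),
        p_value=float(p),
        pairwise_p=pmat,
        pairwise_p_raw=raw_mat,
        alpha=alpha,
    )


def _ks_statistic(z_sorted: np.ndarray) -> np.ndarray:
    """Sup distance between the ecdf of standardised sorted rows and the
    standard normal cdf (vectorised over rows)."""
    n = z_sorted.shape[-1]
    cdf = sps.norm.cdf(z_sorted)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=-1)
    d_minus = (cdf - (i - 1) / n).max(axis=-1)
    return np.maximum(d_plus, d_minus)


def ks_normality(
    values: Sequence[float], n_sim: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Composite-normality KS test with estimated mean/SD (Lilliefors form).

    The null distribution of the statistic is simulated (``n_sim`` seeded
    standard-normal samples, each standardised by its own mean/SD), so the
    p-value accounts for parameter estimation.  Returns ``(statistic, p)``.
    """
    values = np.asarray(values, float)
    n = values.size
    if n < 5:
        raise ValueError(f"need at least 5 observations, got {n}")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation; normality test undefined")
    z = np.sort((values - values.mean()) / sd)
    stat = float(_ks_statistic(z))
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_sim, n))
    sims = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=1, keepdims=True)
    null = _ks_statistic(np.sort(sims, axis=1))
    p = (1.0 + np.count_nonzero(null >= stat)) / (n_sim + 1.0)
    return stat, float(p)


def median_ci(
    values: Sequence[float], level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Sample median with a distribution-free confidence interval.

    The interval is the symmetric pair of order statistics (x_(l), x_(u))
    whose binomial(n, 1/2) coverage first reaches ``level``; conservative and
    free of distributional assumptions.
    """
    values = np.sort(np.asarray(values, float))
    n = values.size
    if n < 6:
        raise ValueError(f"need at least 6 observations, got {n}")
    med = float(np.median(values))
    # l counts from 1; shrink l until P(l <= B <= n - l) >= level
    l = n // 2
    while l >= 1:
        cover = sps.binom.cdf(n - l, n, 0.5) - sps.binom.cdf(l - 1, n, 0.5)
        if cover >= level:
            break
        l -= 1
    if l < 1:
        raise ValueError(f"cannot reach {level:.0%} coverage with n={n}")
    return med, (float(values[l - 1]), float(values[n - l]))


@dataclass(frozen=True)
class Visit:
    """One clinic visit: date, CFT (um), and whether an injection was given."""

    when: date
    cft_um: float
    injection: bool = False


def _as_date(d) -> date:
    if isinstance(d, datetime):
        return d.date()
    if isinstance(d, date):
        return d
    return pd.Timestamp(d).date()


def classify_response(visits: Sequence[Visit]) -> str:
    """Assign a treatment-response label from a time-ordered visit series.

    Rule order (first match wins):

    1. treatment-naive — no injections at any visit;
    2. responder — CFT decreases by >= 100 um from the visit at which the
       first or second injection was given to any later visit before the
       next injection;
    3. recurrent — after an injection-free period of >= 60 days following
       treatment, CFT rises by > 100 um relative to the previous visit;
    4. non-responder — everything else (persistent edema: >= 3 injections
       without a qualifying decrease, or too few injections to qualify).
    """
    if not visits:
        raise ValueError("no visits supplied")
    vs = [
        Visit(when=_as_date(v.when), cft_um=float(v.cft_um), injection=bool(v.injection))
        for v in visits
    ]
    dates = [v.when for v in vs]
    if any(b < a for a, b in zip(dates, dates[1:])):
        raise ValueError("visits must be in chronological order")
    if any(not np.isfinite(v.cft_um) for v in vs):
        raise ValueError("missing CFT value in visit series")

    inj_idx = [i for i, v in enumerate(vs) if v.injection]
    if not inj_idx:
        return "treatment-naive"

    # responder: response to the first or second injection
    for k, i in enumerate(inj_idx[:2]):
        nxt = inj_idx[k + 1] if k + 1 < len(inj_idx) else len(vs)
        baseline = vs[i].cft_um
        for j in range(i + 1, nxt):
            if baseline - vs[j].cft_um >= CFT_RESPONSE_UM:
                return "responder"

    # recurrent: rebound after a >= 60-day injection-free interval
    last_inj_date = None
    for j in range(1, len(vs)):
        if vs[j - 1].injection:
            last_inj_date = vs[j - 1].when
        elif last_inj_date is None and any(v.injection for v in vs[:j]):
            last_inj_date = max(v.when for v in vs[:j] if v.injection)
        if last_inj_date is None:
            continue
        free_days = (vs[j].when - last_inj_date).days
        if free_days >= INJECTION_FREE_DAYS and not vs[j].injection:
            if vs[j].cft_um - vs[j - 1].cft_um > CFT_RESPONSE_UM:
                return "recurrent"

    return "non-responder"
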