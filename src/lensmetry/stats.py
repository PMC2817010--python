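"""Cohort statistics: rank correlations, normality screening, paired
comparisons, repeatability tables and batch-effect logistic regression.

The statistical layer mirrors a lens-biometry study design: traits are
screened for normality (Lilliefors-corrected Kolmogorov-Smirnov, since the
normal parameters are estimated from the sample), associations are
quantified with Spearman rank correlations (valid for the skewed
post-fixation trait distributions), repeat-scan agreement is summarised
per trait, and the association of the kidney-shape artifact with
categorical batch factors (hatch, scan group) is tested by a logistic
likelihood-ratio test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

__all__ = [
    "CorrelationResult",
    "LogisticLRT",
    "spearman",
    "ks_normality",
    "paired_t",
    "logistic_lrt",
    "repeatability_table",
    "correlation_map",
    "REPEATABILITY_TRAITS",
]

REPEATABILITY_TRAITS = ["axial_thickness", "equatorial_diameter", "volume",
                        "r_anterior", "r_posterior"]


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.n >= 3:
            assert -1.0000001 <= self.rho <= 1.0000001
            assert 0.0 <= self.p <= 1.0


@dataclass
class LogisticLRT:
    deviance: float     #: likelihood-ratio statistic (deviance difference)
    df: int
    p: float
    proportions: dict   #: fitted outcome proportion per factor level
    n: int


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-sided p by exhaustive permutation of one rank vector."""
    n = len(rx)
    rx_c = rx - rx.mean()
    denom_x = np.sqrt((rx_c ** 2).sum())
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        ry_p = np.asarray(perm)
        ry_c = ry_p - ry_p.mean()
        denom = denom_x * np.sqrt((ry_c ** 2).sum())
        r = float(rx_c @ ry_c / denom)
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with midrank ties.

    Missing values are removed pairwise.  The two-sided p-value uses the
    t approximation, or exhaustive permutation enumeration for n < 10.
    Invariant under strictly monotone transforms of either variable.
    """
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero-variance ranks: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n < 10:
        p = _exact_spearman_p(rx, ry, rho)
    elif abs(rho) >= 1.0 - 1e-12:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(rho, min(p, 1.0), n)


def ks_normality(x, specified: bool = False):
    """Kolmogorov-Smirnov normality test, Lilliefors-corrected by default.

    The Lilliefors variant accounts for the mean and SD being estimated
    from the sample; ``specified=True`` instead tests against a normal
    with the sample moments plugged in as if known (the naive one-sample
    KS, provided for comparison with legacy software output).
    Returns ``(D, p)``.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    if specified:
        d, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        return float(d), float(p)
    d, p = _lilliefors(x, dist="norm", pvalmethod="table")
    return float(d), float(p)


def paired_t(x1, x2):
    """Two-sided paired t test; returns ``(t, p)``."""
    x1, x2 = _pairwise_complete(x1, x2)
    if len(x1) < 2:
        raise ValueError("need at least 2 pairs")
    diff = x1 - x2
    if np.ptp(diff) == 0 and diff.std() == 0:
        raise ValueError("zero-variance differences: t undefined")
    t, p = sps.ttest_rel(x1, x2)
    return float(t), float(p)


def _binom_loglik(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    """Binomial log-likelihood (constants dropped), safe at p in {0, 1}."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    out = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(p), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log(1.0 - p), 0.0)
    return float(np.sum(t1 + t2))


def logistic_lrt(outcome, factor) -> LogisticLRT:
    """Likelihood-ratio test of a binary outcome against a categorical
    factor (binary logistic regression, outcome ~ factor vs intercept).

    The factor model is fitted by IRLS on per-level aggregated binomial
    counts; levels with complete separation (all 0 or all 1) make the IRLS
    estimates diverge, in which case the exact limiting deviance (zero
    contribution from a saturated level) is used with a warning.  The
    statistic is asymptotically chi-squared with ``levels - 1`` degrees of
    freedom.
    """
    outcome = np.asarray(outcome)
    factor = np.asarray(factor)
    if outcome.shape != factor.shape:
        raise ValueError("outcome and factor must have equal length")
    vals = np.unique(outcome)
    if not np.all(np.isin(vals, [0, 1])):
        raise ValueError("outcome must be binary (0/1)")
    levels, inverse = np.unique(factor, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("factor must have at least 2 levels")
    if len(vals) < 2:
        raise ValueError("both outcome values must be represented")

    n_l = np.bincount(inverse)
    k_l = np.bincount(inverse, weights=outcome.astype(float))
    separated = (k_l == 0) | (k_l == n_l)

    endog = np.column_stack([k_l, n_l - k_l])
    exog0 = np.ones((len(levels), 1))
    null = sm.GLM(endog, exog0, family=sm.families.Binomial()).fit()
    dev_null = float(null.deviance)

    if separated.any():
        warnings.warn(
            f"{int(separated.sum())} factor level(s) show complete "
            "separation; using the exact limiting deviance for them",
            stacklevel=2)
        dev_factor = 0.0  # saturated per-level model: exact limit
    else:
        exog1 = np.eye(len(levels))
        fit = sm.GLM(endog, exog1, family=sm.families.Binomial()).fit()
        dev_factor = float(fit.deviance)

    lrt = max(dev_null - dev_factor, 0.0)
    df = len(levels) - 1
    # Williams' correction: the raw deviance over-rejects against
    # chi-squared when the per-level counts are small (many sparse
    # levels); the reported statistic stays uncorrected, the p-value
    # uses the corrected one
    n_tot = float(len(outcome))
    k_tot = float(k_l.sum())
    q = 1.0 + ((n_tot / k_tot + n_tot / (n_tot - k_tot) - 1.0)
               * ((n_tot / n_l).sum() - 1.0)
               / (6.0 * n_tot * df))
    p = float(sps.chi2.sf(lrt / q, df))
    props = {lv: float(k / n) for lv, k, n in zip(levels, k_l, n_l)}
    return LogisticLRT(lrt, df, p, props, int(len(outcome)))


def repeatability_table(scan1: pd.DataFrame, scan2: pd.DataFrame,
                        traits=None, id_col: str = "eye_id",
                        kidney_col: str = "kidney") -> pd.DataFrame:
    """Repeat-scan agreement per trait, overall and for non-kidney lenses.

    ``scan1`` and ``scan2`` hold one biometry row per eye; rows are matched
    on ``id_col``.  For every trait the Spearman correlation between scans
    and a paired t test are reported, in two strata: all lenses, and those
    not rated kidney-shaped in either scan.
    """
    traits = list(traits) if traits is not None else list(REPEATABILITY_TRAITS)
    merged = scan1.merge(scan2, on=id_col, suffixes=("_1", "_2"))
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} matched ids between scans (need >= 3)")
    strata = {"all": np.ones(len(merged), dtype=bool)}
    if kidney_col + "_1" in merged:
        non_kidney = ~(merged[kidney_col + "_1"].astype(bool)
                       | merged[kidney_col + "_2"].astype(bool))
        strata["non_kidney"] = non_kidney.to_numpy()
    rows = []
    for name, sel in strata.items():
        sub = merged[sel]
        for trait in traits:
            a = sub[trait + "_1"].to_numpy(dtype=float)
            b = sub[trait + "_2"].to_numpy(dtype=float)
            cr = spearman(a, b)
            try:
                t, tp = paired_t(a, b)
            except ValueError:
                t, tp = np.nan, np.nan
            rows.append({"stratum": name, "trait": trait, "r": cr.rho,
                         "p": cr.p, "n": cr.n, "t": t, "t_p": tp})
    return pd.DataFrame(rows)


def correlation_map(table: pd.DataFrame, lens_traits, other_traits,
                    strata: dict | None = None, alpha: float = 0.05):
    """All pairwise Spearman correlations among lens and non-lens traits,
    per stratum, plus the significance graph.

    ``strata`` maps stratum names to boolean row masks (default: a single
    ``all`` stratum).  Returns ``{stratum: {"table": DataFrame, "graph":
    {"nodes": [...], "edges": [...]}}}`` with one edge per pair at
    ``p < alpha``, weighted by ``|rho|``.
    """
    lens_traits = list(lens_traits)
    other_traits = list(other_traits)
    cols = lens_traits + other_traits
    if len(cols) < 2:
        raise ValueError("need at least two trait columns")
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"traits not in table: {missing}")
    if strata is None:
        strata = {"all": np.ones(len(table), dtype=bool)}
    out = {}
    for name, sel in strata.items():
        sel = np.asarray(sel, dtype=bool)
        sub = table[sel]
        if len(sub) == 0:
            raise ValueError(f"stratum {name!r} is empty")
        rows, edges = [], []
        for a, b in itertools.combinations(cols, 2):
            res = spearman(sub[a].to_numpy(dtype=float),
                           sub[b].to_numpy(dtype=float))
            rows.append({"trait_a": a, "trait_b": b, "rho": res.rho,
                         "p": res.p, "n": res.n})
            if res.p < alpha:
                edges.append({"source": a, "target": b,
                              "weight": abs(res.rho), "rho": res.rho,
                              "p": res.p})
        out[name] = {
            "table": pd.DataFrame(rows),
            "graph": {"nodes": cols, "edges": edges},
        }
    return out
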