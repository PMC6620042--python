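"""Inferential statistics: Spearman CIs, Meng's dependent-correlation test,
t-tests, repeated-measures ANOVA, BCa bootstrap mediation, and the
within-subject block-level regression.

Conventions: two-tailed p-values throughout; no multiple-comparison
correction is applied anywhere in this module. Spearman confidence
intervals use the Fisher transform with variance 1.06/(n-3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult", "CorrelationComparison", "TTestResult",
    "RMAnovaResult", "MediationResult", "WithinSubjectFit",
    "spearman_ci", "meng_compare", "one_sample_t", "paired_t", "rm_anova",
    "mediation_bootstrap", "within_subject_regression", "group_strength_test",
]


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------- results

@dataclass
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    df: int
    p: float
    n: int

    def to_dict(self) -> dict:
        return {"rho": self.rho, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "df": self.df, "p": self.p,
                "n": self.n}


@dataclass
class CorrelationComparison:
    z: float
    p: float
    diff_ci_low: float   # Fisher-z scale difference CI
    diff_ci_high: float
    n: int

    def to_dict(self) -> dict:
        return {"z": self.z, "p": self.p, "diff_ci_low": self.diff_ci_low,
                "diff_ci_high": self.diff_ci_high, "n": self.n}


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean: float

    def to_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p, "mean": self.mean}


@dataclass
class RMAnovaResult:
    f: float
    df1: int
    df2: int
    p: float

    def to_dict(self) -> dict:
        return {"F": self.f, "df1": self.df1, "df2": self.df2, "p": self.p}


@dataclass
class MediationResult:
    """Linear-model mediation with BCa bootstrap intervals.

    acme/ade/total/prop_mediated are dicts with keys
    est, ci_low, ci_high, p. Per-draw bootstrap estimates are kept so the
    linear identity total = acme + ade can be audited.
    """

    acme: dict
    ade: dict
    total: dict
    prop_mediated: dict
    n: int
    n_boot: int
    draws: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {"acme": self.acme, "ade": self.ade, "total": self.total,
                "prop_mediated": self.prop_mediated, "n": self.n,
                "n_boot": self.n_boot}

    def summary(self) -> str:
        lines = [f"Mediation (n = {self.n}, {self.n_boot} bootstrap draws)"]
        for name in ("acme", "ade", "total", "prop_mediated"):
            e = getattr(self, name)
            lines.append(
                f"  {name:14s} {e['est']: .4f} "
                f"[{e['ci_low']: .4f}, {e['ci_high']: .4f}]  p = {e['p']:.4f}")
        return "\n".join(lines)


@dataclass
class WithinSubjectFit:
    """Block-level regressions of pRT on DMN strength (18 blocks).

    simple:  pRT_i = w0 + w1 * strength_i
    full:    pRT_i = w0 + w1 * load_i + w2 * strength_i
    """

    simple_w0: float
    simple_w1: float
    full_w0: float
    full_w1: float
    full_w2: float


# ------------------------------------------------------------ correlations

def _check_vector_pair(x, y, min_n=4):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("inputs must be 1-D vectors of equal length")
    if len(x) < min_n:
        raise StatsError(f"need at least {min_n} observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise StatsError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("constant input vector")
    return x, y


def spearman_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Spearman rho with Fisher-transform CI (variance 1.06/(n-3)).

    rho is the Pearson correlation of average ranks; the p-value uses the
    t approximation with n - 2 degrees of freedom.
    """
    x, y = _check_vector_pair(x, y)
    n = len(x)
    rho = float(sps.spearmanr(x, y).statistic)
    if abs(rho) >= 1.0:
        p = 0.0
        ci = (rho, rho)
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
        p = float(2 * sps.t.sf(abs(t), n - 2))
        se = np.sqrt(1.06 / (n - 3))
        zc = sps.norm.ppf(1 - alpha / 2)
        zr = np.arctanh(rho)
        ci = (float(np.tanh(zr - zc * se)), float(np.tanh(zr + zc * se)))
    return CorrelationResult(rho=rho, ci_low=ci[0], ci_high=ci[1],
                             df=n - 2, p=p, n=n)


def meng_compare(ry1: float, ry2: float, r12: float, n: int,
                 alpha: float = 0.05) -> CorrelationComparison:
    """Meng-Rosenthal-Rubin z for two dependent, overlapping correlations.

    Compares corr(x, y1) with corr(x, y2) sharing the variable x, given
    corr(y1, y2) = r12. The CI is for the difference of the Fisher-z
    transformed correlations.
    """
    for r in (ry1, ry2, r12):
        if not -1.0 < r < 1.0:
            raise StatsError("correlations must lie strictly in (-1, 1)")
    if n <= 3:
        raise StatsError("need n > 3")
    z1, z2 = np.arctanh(ry1), np.arctanh(ry2)
    r2bar = (ry1 ** 2 + ry2 ** 2) / 2.0
    f = min((1.0 - r12) / (2.0 * (1.0 - r2bar)), 1.0)
    h = (1.0 - f * r2bar) / (1.0 - r2bar)
    se = np.sqrt(2.0 * (1.0 - r12) * h / (n - 3))
    z = float((z1 - z2) / se)
    p = float(2 * sps.norm.sf(abs(z)))
    zc = sps.norm.ppf(1 - alpha / 2)
    diff = z1 - z2
    return CorrelationComparison(z=z, p=p,
                                 diff_ci_low=float(diff - zc * se),
                                 diff_ci_high=float(diff + zc * se), n=n)


# ----------------------------------------------------------------- t-tests

def one_sample_t(x, mu0: float = 0.0) -> TTestResult:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise StatsError("need at least 2 observations")
    if np.std(x, ddof=1) == 0:
        raise StatsError("zero variance")
    res = sps.ttest_1samp(x, mu0)
    return TTestResult(t=float(res.statistic), df=len(x) - 1,
                       p=float(res.pvalue), mean=float(np.mean(x)))


def paired_t(x, y) -> TTestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatsError("paired samples must have equal length")
    return one_sample_t(x - y, 0.0)


# ---------------------------------------------------------------- rm-ANOVA

def rm_anova(matrix) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix.

    Sphericity is assumed (no correction): F = MS_condition / MS_error with
    df1 = k - 1 and df2 = (k - 1)(n - 1).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise StatsError("need a complete subjects x conditions matrix (k >= 2)")
    if np.isnan(m).any():
        raise StatsError("missing cells are not allowed")
    n, k = m.shape
    grand = m.mean()
    ss_cond = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        f = 0.0 if ms_cond == 0 else np.inf
    else:
        f = ms_cond / ms_err
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return RMAnovaResult(f=float(f), df1=df1, df2=df2, p=p)


# --------------------------------------------------------------- mediation

def _ols_paths(t, m, y):
    """Point estimates (a, b, c') from the two mediation regressions."""
    X1 = np.column_stack([np.ones_like(t), t])
    X2 = np.column_stack([np.ones_like(t), t, m])
    if np.linalg.matrix_rank(X2) < 3:
        raise StatsError("collinear predictors in the outcome model")
    a = np.linalg.lstsq(X1, m, rcond=None)[0][1]
    beta = np.linalg.lstsq(X2, y, rcond=None)[0]
    cprime, b = beta[1], beta[2]
    return float(a), float(b), float(cprime)


def _batched_paths(t, m, y, idx):
    """(a, b, c') for each row of bootstrap index matrix `idx`."""
    T, M, Y = t[idx], m[idx], y[idx]
    Tc = T - T.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    stt = np.einsum("ij,ij->i", Tc, Tc)
    smm = np.einsum("ij,ij->i", Mc, Mc)
    stm = np.einsum("ij,ij->i", Tc, Mc)
    sty = np.einsum("ij,ij->i", Tc, Yc)
    smy = np.einsum("ij,ij->i", Mc, Yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = stm / stt
        det = stt * smm - stm ** 2
        cprime = (smm * sty - stm * smy) / det
        b = (stt * smy - stm * sty) / det
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(cprime)
    return a, b, cprime, ok


def _jackknife_paths(t, m, y):
    """Leave-one-out (a, b, c') via closed-form moment subtraction, O(n)."""
    n = len(t)

    def loo_cross(u, v):
        # centred cross-moment of the sample with observation i removed
        su, sv, suv = u.sum(), v.sum(), (u * v).sum()
        mu = (su - u) / (n - 1)
        mv = (sv - v) / (n - 1)
        return suv - u * v - (n - 1) * mu * mv

    stt = loo_cross(t, t)
    smm = loo_cross(m, m)
    stm = loo_cross(t, m)
    sty = loo_cross(t, y)
    smy = loo_cross(m, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = stm / stt
        det = stt * smm - stm ** 2
        cprime = (smm * sty - stm * smy) / det
        b = (stt * smy - stm * sty) / det
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(cprime)
    return a, b, cprime, ok


def _bca_interval(draws, est, jack, alpha):
    """BCa (lower, upper) for one effect."""
    b = len(draws)
    prop = np.clip((draws < est).mean(), 1.0 / (b + 1), 1.0 - 1.0 / (b + 1))
    z0 = sps.norm.ppf(prop)
    d = jack.mean() - jack
    denom = (d ** 2).sum() ** 1.5
    acc = (d ** 3).sum() / (6.0 * denom) if denom > 0 else 0.0
    zc = sps.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = sps.norm.cdf(z0 + (z0 + zc) / (1.0 - acc * (z0 + zc)))
    lo, hi = np.quantile(draws, np.clip(adj, 0.0, 1.0))
    return float(lo), float(hi)


def _bca_p(draws, est, jack, tol=1e-6):
    """Smallest alpha at which the BCa interval excludes zero."""
    def excludes(alpha):
        lo, hi = _bca_interval(draws, est, jack, alpha)
        return lo > 0 or hi < 0

    if not excludes(1 - tol):
        return 1.0
    if excludes(tol):
        return float(tol)
    lo_a, hi_a = tol, 1 - tol
    for _ in range(40):
        mid = 0.5 * (lo_a + hi_a)
        if excludes(mid):
            hi_a = mid
        else:
            lo_a = mid
    return float(hi_a)


def mediation_bootstrap(treatment, mediator, outcome, n_boot: int = 10_000,
                        seed: int = 0, alpha: float = 0.05,
                        keep_draws: bool = True) -> MediationResult:
    """Linear-model causal mediation with a nonparametric BCa bootstrap.

    ACME = a*b (treatment -> mediator -> outcome), ADE = c' and
    total = a*b + c' from the OLS regressions
    mediator ~ treatment and outcome ~ treatment + mediator.
    Cases are resampled with replacement; intervals are bias-corrected and
    accelerated (jackknife acceleration); the p-value is the smallest alpha
    at which the BCa interval excludes zero.
    """
    t, m = _check_vector_pair(treatment, mediator, min_n=10)
    _, y = _check_vector_pair(treatment, outcome, min_n=10)
    n = len(t)
    a, b, cprime = _ols_paths(t, m, y)
    est = {"acme": a * b, "ade": cprime, "total": a * b + cprime}
    est["prop_mediated"] = (est["acme"] / est["total"]
                            if est["total"] != 0 else np.nan)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    ab, bb, cb, ok = _batched_paths(t, m, y, idx)
    draws = {
        "acme": (ab * bb)[ok],
        "ade": cb[ok],
        "total": (ab * bb + cb)[ok],
    }
    with np.errstate(divide="ignore", invalid="ignore"):
        pm = draws["acme"] / draws["total"]
    draws["prop_mediated"] = pm[np.isfinite(pm)]

    aj, bj, cj, okj = _jackknife_paths(t, m, y)
    jack = {
        "acme": (aj * bj)[okj],
        "ade": cj[okj],
        "total": (aj * bj + cj)[okj],
    }
    with np.errstate(divide="ignore", invalid="ignore"):
        pmj = jack["acme"] / jack["total"]
    jack["prop_mediated"] = pmj[np.isfinite(pmj)]

    effects = {}
    for name in ("acme", "ade", "total", "prop_mediated"):
        dr, jk = draws[name], jack[name]
        if len(dr) == 0 or len(jk) == 0 or not np.isfinite(est[name]):
            effects[name] = {"est": est[name], "ci_low": np.nan,
                             "ci_high": np.nan, "p": np.nan}
            continue
        lo, hi = _bca_interval(dr, est[name], jk, alpha)
        p = _bca_p(dr, est[name], jk)
        effects[name] = {"est": float(est[name]), "ci_low": lo,
                         "ci_high": hi, "p": p}
    return MediationResult(
        acme=effects["acme"], ade=effects["ade"], total=effects["total"],
        prop_mediated=effects["prop_mediated"], n=n, n_boot=n_boot,
        draws=draws if keep_draws else {})


# ------------------------------------------------ within-subject regression

def within_subject_regression(block_prt, block_strength,
                              block_load) -> WithinSubjectFit:
    """Fit the simple and load-adjusted block-level models for one subject."""
    prt = np.asarray(block_prt, dtype=float)
    strength = np.asarray(block_strength, dtype=float)
    load = np.asarray(block_load, dtype=float)
    if not (len(prt) == len(strength) == len(load)):
        raise StatsError("block vectors must have equal length")
    if np.isnan(prt).any() or np.isnan(strength).any():
        raise StatsError("incomplete blocks")
    X1 = np.column_stack([np.ones_like(prt), strength])
    X2 = np.column_stack([np.ones_like(prt), load, strength])
    if np.linalg.matrix_rank(X2) < 3:
        raise StatsError("rank-deficient block design")
    b1 = np.linalg.lstsq(X1, prt, rcond=None)[0]
    b2 = np.linalg.lstsq(X2, prt, rcond=None)[0]
    return WithinSubjectFit(simple_w0=float(b1[0]), simple_w1=float(b1[1]),
                            full_w0=float(b2[0]), full_w1=float(b2[1]),
                            full_w2=float(b2[2]))


def group_strength_test(fits: list[WithinSubjectFit]) -> dict:
    """One-sample t over subjects on the DMN-strength coefficients."""
    simple = np.array([f.simple_w1 for f in fits])
    adjusted = np.array([f.full_w2 for f in fits])
    load = np.array([f.full_w1 for f in fits])
    return {
        "simple_strength": one_sample_t(simple).to_dict(),
        "adjusted_strength": one_sample_t(adjusted).to_dict(),
        "load": one_sample_t(load).to_dict(),
    }
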