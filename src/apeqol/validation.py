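"""Clinical validation: SHI scoring, reliability, and the statistics suite.

Covers the questionnaire side (Speech Handicap Index scoring and
Cronbach's alpha), the generic two-sample and contingency tests used for
cohort balance and dimorphism checks, the pre-operative stage-trend
regression, two-way ANOVA, and the longitudinal pre/post mixed-effects
model with a subject random intercept.

The mixed model is fit by REML (statsmodels ``MixedLM``); fixed-effect
terms are tested with Wald F statistics against containment denominator
degrees of freedom (within-subject terms: n_obs - n_subjects - rank of the
within design; between-subject terms: n_subjects - rank of the between
design).  In the balanced single-factor complete-data case this reproduces
the paired t-test exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "SHI_DOMAINS",
    "SHIRecord",
    "ClinicalProfile",
    "score_shi",
    "shi_table",
    "cronbach_alpha",
    "pearson",
    "t_test",
    "mann_whitney",
    "fisher_exact",
    "chi_square",
    "trend_regression",
    "two_way_anova",
    "mixed_prepost",
]

# Item -> domain map: 28 of the 30 items split equally between the speech
# and psychosocial subdomains; the final two items are unassigned but count
# toward the total.  The map is configuration data.
SHI_DOMAINS: dict[str, tuple[int, ...]] = {
    "speech": tuple(range(1, 15)),
    "psychosocial": tuple(range(15, 29)),
    "unassigned": (29, 30),
}
_ITEM_SCALE = (0, 4)  # five-point 0-4 per item


@dataclass(frozen=True)
class SHIRecord:
    """Scored SHI: 30 items plus the three totals."""

    items: tuple[int, ...]
    total: int
    speech: int
    psychosocial: int


@dataclass(frozen=True)
class ClinicalProfile:
    """Clinical covariates of one participant."""

    age: float
    gender: str
    t_class: int  # 0 = healthy control
    resection: str = "none"
    reconstruction: bool = False
    flap: str = "none"

    def __post_init__(self) -> None:
        if self.t_class not in (0, 1, 2, 3, 4):
            raise ValueError("T class must be 0-4")
        if self.t_class == 0 and (self.resection != "none" or self.reconstruction):
            raise ValueError("healthy controls (T0) carry no resection/reconstruction")
        if self.flap != "none" and not self.reconstruction:
            raise ValueError("a flap type implies reconstruction")


def score_shi(items: Sequence[int], domains: Mapping[str, tuple[int, ...]] = SHI_DOMAINS) -> SHIRecord:
    """Score 30 item responses into total, speech, and psychosocial sums."""
    arr = np.asarray(items)
    if arr.shape != (30,):
        raise ValueError("SHI requires exactly 30 item scores")
    lo, hi = _ITEM_SCALE
    if arr.min() < lo or arr.max() > hi or not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"item scores must lie on the {lo}-{hi} scale")
    total = int(arr.sum())
    speech = int(arr[[i - 1 for i in domains["speech"]]].sum())
    psych = int(arr[[i - 1 for i in domains["psychosocial"]]].sum())
    return SHIRecord(items=tuple(int(v) for v in arr), total=total, speech=speech, psychosocial=psych)


def shi_table(item_matrix: pd.DataFrame) -> pd.DataFrame:
    """Score a session x 30-item frame into a session x totals frame."""
    rows = {}
    for sid, row in item_matrix.iterrows():
        rec = score_shi(row.to_numpy())
        rows[sid] = {
            "shi_total": rec.total,
            "shi_speech": rec.speech,
            "shi_psychosocial": rec.psychosocial,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis(item_matrix.index.name)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/variance(totals)).

    Sample (ddof=1) variances.  Returns NaN when the totals have zero
    variance (alpha undefined).
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("alpha needs >= 2 respondents and >= 2 items")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        import logging

        logging.getLogger(__name__).warning("zero total variance: alpha undefined")
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


# ---------------------------------------------------------------------------
# generic tests (thin, contract-enforcing wrappers over scipy)
# ---------------------------------------------------------------------------

def _result(statistic, p, n, **extra) -> dict:
    return {"statistic": float(statistic), "p": float(p), "n": int(n), **extra}


def pearson(x, y) -> dict:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.std(x) == 0 or np.std(y) == 0:
        return _result(float("nan"), float("nan"), len(x))
    r, p = stats.pearsonr(x, y)
    return _result(r, p, len(x), r=float(r))


def t_test(x, y, tails: int = 2, paired: bool = False, alternative: str = "greater") -> dict:
    """Student's t-test; one-tailed direction given by ``alternative``."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.std(x) == 0 and np.std(y) == 0:
        return _result(float("nan"), float("nan"), len(x) + len(y))
    alt = "two-sided" if tails == 2 else alternative
    if paired:
        t, p = stats.ttest_rel(x, y, alternative=alt)
    else:
        t, p = stats.ttest_ind(x, y, alternative=alt)
    return _result(t, p, len(x) + len(y))


def mann_whitney(x, y, tails: int = 2, alternative: str = "greater") -> dict:
    """Mann-Whitney U: exact enumeration for small samples (both n <= 8 and
    no ties), otherwise the normal approximation with tie correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    alt = "two-sided" if tails == 2 else alternative
    pooled = np.concatenate([x, y])
    small = max(len(x), len(y)) <= 8 and len(np.unique(pooled)) == len(pooled)
    method = "exact" if small else "asymptotic"
    u, p = stats.mannwhitneyu(x, y, alternative=alt, method=method)
    return _result(u, p, len(x) + len(y), method=method)


def fisher_exact(table) -> dict:
    """Fisher's exact test, two-sided by summing tables with probability
    less than or equal to the observed one."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("Fisher's exact test takes a 2x2 table")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return _result(odds, p, table.sum(), odds_ratio=float(odds))


def chi_square(table) -> dict:
    """Pearson chi-square on an r x c contingency table."""
    table = np.asarray(table, dtype=float)
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return _result(chi2, p, int(table.sum()), df=int(dof))


# ---------------------------------------------------------------------------
# trend regression
# ---------------------------------------------------------------------------

def trend_regression(outcome, t_class) -> dict:
    """OLS of an outcome on the numeric T code with slope CI, R², and p.

    Patients only (codes 1-4); at least three distinct classes must be
    represented for a trend to be meaningful.
    """
    y = np.asarray(outcome, float)
    t = np.asarray(t_class, float)
    if len(np.unique(t)) < 3:
        raise ValueError("trend regression needs >= 3 distinct T classes")
    X = sm.add_constant(t)
    fit = sm.OLS(y, X).fit()
    if np.allclose(y, y[0]):
        return {
            "slope": 0.0, "ci95": (0.0, 0.0), "r_squared": 0.0,
            "p": float("nan"), "n": len(y), "degenerate": True,
        }
    ci = fit.conf_int()[1]
    return {
        "slope": float(fit.params[1]),
        "ci95": (float(ci[0]), float(ci[1])),
        "r_squared": float(fit.rsquared),
        "p": float(fit.pvalues[1]),
        "n": len(y),
        "degenerate": False,
    }


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

def two_way_anova(outcome, factor_a, factor_b, names=("A", "B")) -> pd.DataFrame:
    """Two-way ANOVA with type-III sums of squares (sum-to-zero coding).

    Handles unbalanced designs; raises on an empty cell, naming it.
    """
    df = pd.DataFrame(
        {"y": np.asarray(outcome, float), "a": pd.Categorical(factor_a), "b": pd.Categorical(factor_b)}
    )
    for la in df["a"].cat.categories:
        for lb in df["b"].cat.categories:
            if not ((df["a"] == la) & (df["b"] == lb)).any():
                raise ValueError(f"empty cell: {names[0]}={la}, {names[1]}={lb}")
    model = smf.ols("y ~ C(a, Sum) * C(b, Sum)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    # zero residual variance: F = SS/0 is conventionally certain, not missing
    if np.isclose(table.loc["Residual", "sum_sq"], 0.0):
        nonres = table.index != "Residual"
        table.loc[nonres, "PR(>F)"] = np.where(
            table.loc[nonres, "sum_sq"] > 1e-12, 0.0, 1.0
        )
    rename = {
        "C(a, Sum)": names[0],
        "C(b, Sum)": names[1],
        "C(a, Sum):C(b, Sum)": f"{names[0]}x{names[1]}",
    }
    table = table.rename(index=rename)
    return table.loc[[names[0], names[1], f"{names[0]}x{names[1]}", "Residual"]]


# ---------------------------------------------------------------------------
# pre/post mixed-effects model
# ---------------------------------------------------------------------------

@dataclass
class MixedPrePostResult:
    effects: pd.DataFrame           # F, df_num, df_den, p for time / factor / interaction
    pairwise: pd.DataFrame          # pre-vs-post within each factor level
    model: object = field(repr=False, default=None)
    excluded_levels: tuple = ()


def _wald_f(params, cov, L, df_den):
    L = np.atleast_2d(L)
    est = L @ params
    mid = np.linalg.pinv(L @ cov @ L.T)
    q = np.linalg.matrix_rank(L)
    f = float(est.T @ mid @ est) / q
    p = float(stats.f.sf(f, q, df_den)) if df_den > 0 else float("nan")
    return f, q, p


def mixed_prepost(
    data: pd.DataFrame,
    outcome: str,
    factor: str,
    subject: str = "subject",
    time: str = "timepoint",
    alpha: float = 0.05,
) -> MixedPrePostResult:
    """Linear mixed model for a pre/post outcome with one between factor.

    Random intercept per subject, REML fit; Wald F tests with containment
    denominator df for the time main effect, the factor main effect, and
    their interaction; Sidak-corrected pairwise pre-vs-post contrasts
    within each factor level.  Subjects missing the post session are kept
    (the model tolerates unbalanced data); factor levels with a single
    subject are excluded with a warning.
    """
    df = data[[outcome, factor, subject, time]].dropna().copy()
    df[factor] = df[factor].astype(str)
    df[time] = pd.Categorical(df[time], categories=["pre", "post"], ordered=True)

    level_sizes = df.groupby(factor)[subject].nunique()
    excluded = tuple(level_sizes[level_sizes < 2].index)
    if excluded:
        import logging

        logging.getLogger(__name__).warning(
            "mixed_prepost: excluding single-subject level(s) %s", excluded
        )
        df = df[~df[factor].isin(excluded)]
    levels = sorted(df[factor].unique())
    if len(levels) < 1:
        raise ValueError("no usable factor levels")

    # explicit design: intercept, time(post), factor dummies, interactions
    d_time = (df[time] == "post").to_numpy(float)
    cols = {"Intercept": np.ones(len(df)), "time[post]": d_time}
    for lev in levels[1:]:
        d_lev = (df[factor] == lev).to_numpy(float)
        cols[f"{factor}[{lev}]"] = d_lev
        cols[f"time[post]:{factor}[{lev}]"] = d_time * d_lev
    X = pd.DataFrame(cols, index=df.index)

    md = sm.MixedLM(df[outcome].to_numpy(float), X, groups=df[subject])
    fit = md.fit(reml=True)
    k = X.shape[1]
    params = fit.fe_params.to_numpy()
    cov = fit.cov_params().to_numpy()[:k, :k]

    n_obs = len(df)
    n_subj = df[subject].nunique()
    names = list(X.columns)
    idx_time = [names.index("time[post]")]
    idx_fac = [names.index(f"{factor}[{lev}]") for lev in levels[1:]]
    idx_int = [names.index(f"time[post]:{factor}[{lev}]") for lev in levels[1:]]
    n_within = 1 + len(idx_int)  # columns involving time
    df_within = n_obs - n_subj - n_within
    df_between = n_subj - (1 + len(idx_fac))

    def contrast_rows(idxs):
        L = np.zeros((len(idxs), k))
        for r, i in enumerate(idxs):
            L[r, i] = 1.0
        return L

    eff_rows = []
    for name, idxs, dd in [
        ("time", idx_time, df_within),
        (factor, idx_fac, df_between),
        (f"time x {factor}", idx_int, df_within),
    ]:
        if not idxs:
            continue
        f, q, p = _wald_f(params, cov, contrast_rows(idxs), dd)
        eff_rows.append({"effect": name, "F": f, "df_num": q, "df_den": dd, "p": p})
    effects = pd.DataFrame(eff_rows)

    # pairwise pre-vs-post within each level; Sidak family correction
    m = len(levels)
    pw_rows = []
    for lev in levels:
        L = np.zeros(k)
        L[names.index("time[post]")] = 1.0
        if lev != levels[0]:
            L[names.index(f"time[post]:{factor}[{lev}]")] = 1.0
        est = float(L @ params)
        se = float(np.sqrt(L @ cov @ L))
        tval = est / se if se > 0 else float("nan")
        p_unc = 2.0 * stats.t.sf(abs(tval), df_within) if df_within > 0 else float("nan")
        p_sidak = 1.0 - (1.0 - p_unc) ** m if np.isfinite(p_unc) else float("nan")
        pw_rows.append(
            {
                "level": lev,
                "post_minus_pre": est,
                "se": se,
                "t": tval,
                "df": df_within,
                "p": p_unc,
                "p_sidak": min(p_sidak, 1.0) if np.isfinite(p_sidak) else p_sidak,
                "significant": bool(np.isfinite(p_sidak) and p_sidak < alpha),
            }
        )
    pairwise = pd.DataFrame(pw_rows)
    return MixedPrePostResult(effects=effects, pairwise=pairwise, model=fit, excluded_levels=excluded)
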