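"""Adjusted line means, the LNAE index, its ANOVA, and Scott-Knott grouping.

The analysis chain is: fit, separately per environment x N level, the
linear mixed model

    y = Xb + Zu + e,      u ~ N(0, I sigma_b^2),  e ~ N(0, I sigma^2)

with fixed intercept/replicate/genotype effects and random incomplete
blocks, and extract the genotype adjusted means (BLUEs at the average
replicate).  From the IN/LN adjusted means the low-N agronomic
efficiency index is

    LNAE = GY_LN * (GY_LN / GY_IN) = GY_LN^2 / GY_IN

i.e. absolute low-N yield weighted by the low-N : optimal-N yield ratio.
A two-way fixed-effects ANOVA (environment + line) on the per-environment
LNAE values supplies the error mean square for the Scott-Knott test,
which partitions the line means into non-overlapping groups — in the
intended application two groups contrasting in low-N tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genio import GenioError, validate_phenotypes


class PhenoError(ValueError):
    """Raised on invalid phenotype-analysis input."""


# ============================================================ adjusted means
@dataclass
class AdjustedMeans:
    """Per (line, environment, N level) adjusted grain-yield means.

    ``means`` has columns line, environment, n_level, adj_mean (NaN where
    a line is absent from a trial); ``varcomps`` holds the REML variance
    components sigma2_block / sigma2_resid per environment x N level.
    """

    means: pd.DataFrame
    varcomps: pd.DataFrame

    def pivot(self) -> pd.DataFrame:
        """lines x (environment, n_level) wide table of adjusted means."""
        return self.means.pivot_table(
            index="line", columns=["environment", "n_level"], values="adj_mean"
        )


def _reml_fit(y: np.ndarray, X: np.ndarray, Z: np.ndarray):
    """Profiled REML for y = Xb + Zu + e with one variance ratio.

    Maximizes the restricted likelihood over gamma = sigma_b^2/sigma^2 on a
    log-spaced bracket (plus the gamma = 0 boundary) and returns
    (beta_hat, sigma2, sigma2_b).
    """
    n, p = X.shape

    def neg_rll(gamma: float):
        V = np.eye(n) + gamma * (Z @ Z.T)
        L = np.linalg.cholesky(V)
        logdet_V = 2.0 * np.log(np.diag(L)).sum()
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        sign, logdet_X = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf, None, None
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        Vi_r = np.linalg.solve(V, r)
        s2 = float(r @ Vi_r) / (n - p)
        rll = -0.5 * ((n - p) * np.log(s2) + logdet_V + logdet_X + (n - p))
        return -rll, beta, s2

    best = (np.inf, 0.0, None, None)
    for g in [0.0]:
        f, beta, s2 = neg_rll(g)
        if f < best[0]:
            best = (f, g, beta, s2)
    res = optimize.minimize_scalar(
        lambda lg: neg_rll(10.0**lg)[0], bounds=(-6.0, 4.0), method="bounded",
        options={"xatol": 1e-6},
    )
    g = 10.0 ** float(res.x)
    f, beta, s2 = neg_rll(g)
    if f < best[0]:
        best = (f, g, beta, s2)
    _, g, beta, s2 = best
    return beta, s2, g * s2


def adjusted_means(
    pheno: pd.DataFrame, single_rep_policy: str = "raise"
) -> AdjustedMeans:
    """Genotype adjusted means (BLUEs) per environment x N level.

    Fits the replicate + genotype fixed / block random model separately
    for every trial.  With an estimated block variance of zero the result
    coincides with ordinary least-squares line means.  Lines absent from
    a trial get NaN (flagged missing, never fabricated).

    ``single_rep_policy``: with only one replicate the block variance is
    inestimable; ``"raise"`` (default) errors, ``"raw"`` returns raw line
    means with a warning.
    """
    pheno = validate_phenotypes(pheno)
    if single_rep_policy not in ("raise", "raw"):
        raise PhenoError(f"unknown single_rep_policy {single_rep_policy!r}")
    all_lines = sorted(pheno["line"].unique())
    rows, vcs = [], []
    for (env, nlev), sub in pheno.groupby(["environment", "n_level"], sort=True):
        reps = sorted(sub["rep"].unique())
        if len(reps) < 2:
            if single_rep_policy == "raise":
                raise PhenoError(
                    f"trial {env}/{nlev} has a single replicate; block variance "
                    "inestimable (pass single_rep_policy='raw' for raw means)"
                )
            warnings.warn(
                f"trial {env}/{nlev}: single replicate, returning raw means",
                stacklevel=2,
            )
            means = sub.groupby("line")["grain_yield"].mean()
            for lid in all_lines:
                rows.append((lid, env, nlev, means.get(lid, np.nan)))
            vcs.append((env, nlev, np.nan, np.nan))
            continue

        lines = sorted(sub["line"].unique())
        li = pd.Categorical(sub["line"], categories=lines).codes
        ri = pd.Categorical(sub["rep"]).codes
        bi = pd.Categorical(
            sub["rep"].astype(str) + ":" + sub["block"].astype(str)
        ).codes
        n = len(sub)
        g, r, b = len(lines), len(reps), bi.max() + 1
        X = np.zeros((n, g + r - 1))
        X[np.arange(n), li] = 1.0
        # sum-to-zero replicate contrasts: adjusted mean sits at the average rep
        for k in range(r - 1):
            X[:, g + k] = np.where(ri == k, 1.0, np.where(ri == r - 1, -1.0, 0.0))
        Z = np.zeros((n, b))
        Z[np.arange(n), bi] = 1.0
        y = sub["grain_yield"].to_numpy(dtype=float)
        beta, s2, s2b = _reml_fit(y, X, Z)
        est = dict(zip(lines, beta[:g]))
        for lid in all_lines:
            rows.append((lid, env, nlev, est.get(lid, np.nan)))
        vcs.append((env, nlev, s2b, s2))
    return AdjustedMeans(
        means=pd.DataFrame(rows, columns=["line", "environment", "n_level", "adj_mean"]),
        varcomps=pd.DataFrame(
            vcs, columns=["environment", "n_level", "sigma2_block", "sigma2_resid"]
        ),
    )


def raw_means(pheno: pd.DataFrame) -> pd.DataFrame:
    """Unadjusted line means per environment x N level (comparison baseline)."""
    pheno = validate_phenotypes(pheno)
    return (
        pheno.groupby(["line", "environment", "n_level"], sort=True)["grain_yield"]
        .mean()
        .rename("adj_mean")
        .reset_index()
    )


# ==================================================================== LNAE
def compute_lnae(gy_ln, gy_in):
    """Low-N agronomic efficiency: LNAE = GY_LN * (GY_LN / GY_IN).

    Combines the absolute low-N yield with the low-N : optimal-N ratio;
    scale-consistent (scaling both yields by c scales LNAE by c).
    Vectorized over array inputs; requires GY_IN > 0 and GY_LN >= 0.
    """
    gy_ln = np.asarray(gy_ln, dtype=float)
    gy_in = np.asarray(gy_in, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(gy_in[~np.isnan(gy_in)] <= 0):
            raise PhenoError("GY_IN must be strictly positive")
        if np.any(gy_ln[~np.isnan(gy_ln)] < 0):
            raise PhenoError("GY_LN must be non-negative")
    out = gy_ln * gy_ln / gy_in
    return float(out) if out.ndim == 0 else out


@dataclass
class LnaeTable:
    """Per-(line, environment) LNAE plus a combined per-line estimate.

    ``combined`` is the arithmetic mean over environments with a value;
    for balanced data it equals the least-squares line mean of the
    two-way ANOVA model (asserted in the test-suite invariants).
    """

    per_env: pd.DataFrame  # line, environment, lnae
    combined: pd.Series  # index line

    def __post_init__(self):
        if (self.per_env["lnae"].dropna() < 0).any():
            raise PhenoError("negative LNAE value")


def lnae_table(adj: AdjustedMeans) -> LnaeTable:
    """LNAE per line x environment from IN/LN adjusted means."""
    wide = adj.means.pivot_table(
        index=["line", "environment"], columns="n_level", values="adj_mean"
    )
    for col in ("IN", "LN"):
        if col not in wide.columns:
            raise PhenoError(f"adjusted means lack the {col} level")
    ok = wide["IN"].notna() & wide["LN"].notna()
    lnae = pd.Series(np.nan, index=wide.index, name="lnae")
    lnae[ok] = compute_lnae(wide.loc[ok, "LN"], wide.loc[ok, "IN"])
    per_env = lnae.reset_index()
    combined = per_env.groupby("line")["lnae"].mean()
    combined = combined[combined.notna()]
    return LnaeTable(per_env=per_env, combined=combined)


@dataclass
class AnovaResult:
    table: pd.DataFrame
    f_line: float
    p_line: float
    resid_ms: float
    resid_df: float


def lnae_anova(lnae: LnaeTable) -> AnovaResult:
    """Two-way fixed-effects ANOVA (environment + line) on LNAE values.

    Returns the line-effect F test plus the residual mean square and df,
    which feed the Scott-Knott grouping as its error term.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = lnae.per_env.dropna(subset=["lnae"]).copy()
    if df["environment"].nunique() < 2:
        raise PhenoError(
            "LNAE ANOVA needs >=2 environments: with a single environment the "
            "line effect is saturated and untestable against this model"
        )
    if np.allclose(df["lnae"].var(ddof=0), 0.0):
        # all values identical: F undefined, return a degenerate table
        tab = pd.DataFrame(
            {"sum_sq": [0.0, 0.0, 0.0], "df": [np.nan] * 3, "F": [np.nan] * 3,
             "PR(>F)": [np.nan] * 3},
            index=["C(environment)", "C(line)", "Residual"],
        )
        return AnovaResult(tab, np.nan, np.nan, 0.0, 0.0)
    fit = smf.ols("lnae ~ C(environment) + C(line)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    return AnovaResult(
        table=tab,
        f_line=float(tab.loc["C(line)", "F"]),
        p_line=float(tab.loc["C(line)", "PR(>F)"]),
        resid_ms=float(tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]),
        resid_df=float(tab.loc["Residual", "df"]),
    )


# ============================================================== Scott-Knott
_SK_COEF = np.pi / (2.0 * (np.pi - 2.0))


@dataclass
class GroupAssignment:
    """Scott-Knott partition of lines into mean-ordered groups.

    ``labels`` maps line -> group number (1 = highest mean); ``group_means``
    is indexed by group number; ``splits`` records every significant split
    (members tested, B0, lambda, nu0, critical value).
    """

    labels: pd.Series
    group_means: pd.Series
    splits: list[dict]

    @property
    def n_groups(self) -> int:
        return int(self.labels.max())

    def members(self, group: int) -> list[str]:
        return list(self.labels.index[self.labels == group])

    def root_partition(self) -> pd.Series | None:
        """Two-group partition from the first (root) split, or None.

        When the recursion subdivides further than two groups, the root
        split is still the natural high/low contrast: it is the single
        cut of the ordered means maximizing the between-group sum of
        squares.  Labels are 1 (higher-mean side) and 2.
        """
        if not self.splits:
            return None
        root = self.splits[0]
        lab = {}
        for lid in root["members"][: root["cut"]]:
            lab[lid] = 1
        for lid in root["members"][root["cut"]:]:
            lab[lid] = 2
        return pd.Series([lab[lid] for lid in self.labels.index],
                         index=self.labels.index, dtype=int, name="group")


def _best_cut(vals: np.ndarray) -> tuple[int, float]:
    """Best contiguous 2-way cut of descending-ordered means by B0.

    Returns (cut index c meaning groups vals[:c] / vals[c:], B0).  Cuts
    between exactly-equal adjacent means are disallowed so ties are never
    separated.  Returns (-1, 0) if no admissible cut exists.
    """
    g = len(vals)
    grand = vals.mean()
    best_c, best_b0 = -1, -np.inf
    csum = np.cumsum(vals)
    total = csum[-1]
    for c in range(1, g):
        if vals[c - 1] == vals[c]:
            continue
        m1 = csum[c - 1] / c
        m2 = (total - csum[c - 1]) / (g - c)
        b0 = c * (m1 - grand) ** 2 + (g - c) * (m2 - grand) ** 2
        if b0 > best_b0:
            best_c, best_b0 = c, b0
    if best_c < 0:
        return -1, 0.0
    return best_c, float(best_b0)


def scott_knott(
    values: pd.Series,
    error_ms: float,
    error_df: float,
    alpha: float = 0.05,
    n_rep: int = 1,
) -> GroupAssignment:
    """Divisive means clustering after Scott & Knott (1974).

    Means are sorted descending and recursively cut at the point
    maximizing the between-group sum of squares B0.  A cut is accepted
    when

        lambda = pi/(2(pi-2)) * B0 / sigma0^2  >  chi2(alpha; nu0)

    with sigma0^2 = (sum_i (y_i - ybar)^2 + nu * s_ybar^2) / (g + nu),
    s_ybar^2 = error_ms / n_rep, nu = error_df, and fractional degrees of
    freedom nu0 = g/(pi-2) evaluated through the continuous chi-square
    quantile.  Groups are numbered 1, 2, ... in descending mean order; a
    group of exactly-equal means is never split.

    Parameters
    ----------
    values
        Per-line mean estimates, indexed by line id.
    error_ms, error_df
        Error mean square and its degrees of freedom (typically the LNAE
        ANOVA residual).
    n_rep
        Observations averaged per mean, so the variance of one mean is
        ``error_ms / n_rep``.
    """
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise PhenoError("Scott-Knott needs at least two means")
    if not np.isfinite(values).all():
        raise PhenoError("non-finite mean values")
    if error_ms < 0 or error_df < 0:
        raise PhenoError("error_ms and error_df must be non-negative")
    if not 0.0 < alpha < 1.0:
        raise PhenoError("alpha must lie in (0, 1)")
    # descending means; ties broken by line id for a stable, deterministic order
    order = sorted(values.index, key=lambda lid: (-values[lid], str(lid)))
    vals = values.loc[order].to_numpy()
    s2_mean = error_ms / n_rep
    nu = error_df
    splits: list[dict] = []
    groups: list[list[str]] = []

    def recurse(lo: int, hi: int) -> None:
        seg = vals[lo:hi]
        g = hi - lo
        if g < 2 or np.all(seg == seg[0]):
            groups.append(order[lo:hi])
            return
        c, b0 = _best_cut(seg)
        if c < 0:
            groups.append(order[lo:hi])
            return
        sigma0_sq = (np.sum((seg - seg.mean()) ** 2) + nu * s2_mean) / (g + nu)
        if sigma0_sq <= 0:
            lam = np.inf if b0 > 0 else 0.0
        else:
            lam = _SK_COEF * b0 / sigma0_sq
        nu0 = g / (np.pi - 2.0)
        crit = stats.chi2.ppf(1.0 - alpha, nu0)
        if lam > crit:
            splits.append(
                {
                    "members": order[lo:hi],
                    "cut": c,
                    "B0": b0,
                    "lambda": float(lam),
                    "nu0": float(nu0),
                    "critical": float(crit),
                }
            )
            recurse(lo, lo + c)
            recurse(lo + c, hi)
        else:
            groups.append(order[lo:hi])

    recurse(0, len(vals))
    lab_of = {}
    gmeans = {}
    for k, members in enumerate(groups, start=1):
        for lid in members:
            lab_of[lid] = k
        gmeans[k] = float(values[members].mean())
    labels = pd.Series([lab_of[lid] for lid in values.index],
                       index=values.index, dtype=int, name="group")
    return GroupAssignment(
        labels=labels,
        group_means=pd.Series(gmeans, name="group_mean"),
        splits=splits,
    )


def sk_root_significant(
    values: pd.Series, error_ms: float, error_df: float,
    alpha: float = 0.05, n_rep: int = 1,
) -> bool:
    """Whether the Scott-Knott root split alone is significant.

    Used for size/power calibration of the procedure's first test without
    running the full recursion.
    """
    ga = _root_only(values, error_ms, error_df, alpha, n_rep)
    return ga


def _root_only(values, error_ms, error_df, alpha, n_rep) -> bool:
    values = pd.Series(values).astype(float)
    order = sorted(values.index, key=lambda lid: (-values[lid], str(lid)))
    vals = values.loc[order].to_numpy()
    g = len(vals)
    c, b0 = _best_cut(vals)
    if c < 0:
        return False
    sigma0_sq = (np.sum((vals - vals.mean()) ** 2) + error_df * error_ms / n_rep) / (
        g + error_df
    )
    if sigma0_sq <= 0:
        return b0 > 0
    lam = _SK_COEF * b0 / sigma0_sq
    return bool(lam > stats.chi2.ppf(1.0 - alpha, g / (np.pi - 2.0)))
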