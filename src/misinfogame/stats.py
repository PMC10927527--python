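"""Statistical toolkit for engagement/accuracy analyses.

Mirrors the empirical pipeline used alongside the model:

* per-site OLS of standardized log10-engagement on standardized perceived
  accuracy (the within-site slope equals the correlation coefficient);
* Fisher's combined probability test over per-site p-values;
* DerSimonian–Laird random-effects meta-analysis of the per-site slopes;
* rating-level linear regression with all variables z-scored and robust
  standard errors two-way clustered on subject and headline
  (inclusion–exclusion: V = V_subject + V_headline - V_{subject x headline}).

Tables are plain :class:`pandas.DataFrame` objects.  A *site table* has
columns (site_id, site_type, headline_id, mean_accuracy, engagement) with
site_type in {mainstream, misinformation}; a *rating table* has columns
(subject_id, headline_id, accuracy, click, share) and optionally
headline_veracity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "SITE_COLUMNS",
    "RATING_COLUMNS",
    "SlopeResult",
    "MetaResult",
    "RegressionResult",
    "SiteAnalysis",
    "validate_site_table",
    "validate_rating_table",
    "load_table",
    "site_slope",
    "fishers_combined",
    "random_effects_meta",
    "clustered_rating_regression",
    "analyze_site_table",
]

SITE_COLUMNS = ("site_id", "site_type", "headline_id", "mean_accuracy", "engagement")
RATING_COLUMNS = ("subject_id", "headline_id", "accuracy", "click", "share")
SITE_TYPES = ("mainstream", "misinformation")


@dataclass(frozen=True)
class SlopeResult:
    slope: float
    se: float
    p: float


@dataclass(frozen=True)
class MetaResult:
    """Random-effects summary: pooled mean, its SE, between-site variance, p."""

    mu: float
    se_mu: float
    tau2: float
    p: float
    method: str = "DerSimonian-Laird"


@dataclass(frozen=True)
class RegressionResult:
    beta: float
    se: float
    z: float
    p: float


@dataclass(frozen=True)
class SiteAnalysis:
    """Per-site-type pipeline output."""

    slopes: pd.DataFrame  # columns: site_id, slope, se, p, n
    fisher_statistic: float
    fisher_df: int
    fisher_p: float
    meta: MetaResult


def validate_site_table(table: pd.DataFrame) -> None:
    missing = [c for c in SITE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    bad = set(table["site_type"].unique()) - set(SITE_TYPES)
    if bad:
        raise ValueError(f"unknown site_type values: {sorted(bad)}")
    if (table["engagement"] < 0).any():
        raise ValueError("engagement counts must be non-negative")


def validate_rating_table(table: pd.DataFrame) -> None:
    missing = [c for c in RATING_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"rating table missing columns: {missing}")


def load_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a CSV table, optionally renaming columns via ``column_map``
    (mapping from the file's column names to the canonical ones)."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return df


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / s


def site_slope(site_rows: pd.DataFrame) -> SlopeResult:
    """Within-site OLS slope of z-scored log10-engagement on z-scored accuracy.

    Because both variables are standardized within the site, the slope is
    the sample correlation coefficient.  Rows with zero engagement enter as
    log10(engagement + 1) = 0.  At least 3 headlines are required; zero
    variance in either variable yields slope 0, p = 1 with a warning.
    """
    if len(site_rows) < 3:
        raise ValueError("need at least 3 headlines per site")
    acc = site_rows["mean_accuracy"].to_numpy(dtype=float)
    eng = site_rows["engagement"].to_numpy(dtype=float)
    log_eng = np.where(eng > 0, np.log10(np.where(eng > 0, eng, 1.0)), 0.0)
    if acc.std() == 0 or log_eng.std() == 0:
        warnings.warn("zero variance within site; slope set to 0", stacklevel=2)
        return SlopeResult(slope=0.0, se=float("nan"), p=1.0)
    res = sps.linregress(_zscore(acc), _zscore(log_eng))
    return SlopeResult(slope=float(res.slope), se=float(res.stderr), p=float(res.pvalue))


def fishers_combined(p_values: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's combined probability test.

    Returns (X2, df, p) with X2 = -2 sum(ln p_i) and df = 2k.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    statistic = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return statistic, df, float(sps.chi2.sf(statistic, df))


def random_effects_meta(effects: Iterable[tuple[float, float]]) -> MetaResult:
    """DerSimonian–Laird random-effects meta-analysis of (effect, se) pairs.

    The between-site variance tau^2 is the moment estimator truncated at
    zero; the pooled mean is the inverse-variance weighted mean with
    weights 1/(se_i^2 + tau^2); the p-value is a two-sided z-test of
    mu = 0.  With tau^2 = 0 this reduces to the fixed-effect
    inverse-variance mean.
    """
    pairs = list(effects)
    if len(pairs) < 2:
        raise ValueError("need at least 2 effects")
    y = np.array([e for e, _ in pairs], dtype=float)
    se = np.array([s for _, s in pairs], dtype=float)
    if (se <= 0).any() or not np.isfinite(se).all():
        raise ValueError("all standard errors must be positive and finite")
    w = 1.0 / se**2
    mu_fixed = float((w * y).sum() / w.sum())
    q = float((w * (y - mu_fixed) ** 2).sum())
    k = y.size
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom)
    w_star = 1.0 / (se**2 + tau2)
    mu = float((w_star * y).sum() / w_star.sum())
    se_mu = float(np.sqrt(1.0 / w_star.sum()))
    z = mu / se_mu
    return MetaResult(mu=mu, se_mu=se_mu, tau2=tau2, p=float(2.0 * sps.norm.sf(abs(z))))


def clustered_rating_regression(
    table: pd.DataFrame,
    outcome: str = "click",
    predictor: str = "accuracy",
    small_sample: bool = False,
) -> RegressionResult:
    """Rating-level OLS with two-way cluster-robust standard errors.

    The outcome and predictor are z-scored over the whole table; the
    regression includes an intercept; the variance is estimated by the
    inclusion–exclusion two-way clustering on subject and headline.  By
    default no small-sample adjustment is applied; ``small_sample=True``
    turns on the conventional cluster and degrees-of-freedom corrections.
    """
    validate_rating_table(table)
    if outcome not in ("click", "share", "accuracy"):
        raise ValueError("outcome must be one of click/share/accuracy")
    n_subj = table["subject_id"].nunique()
    n_head = table["headline_id"].nunique()
    if n_subj < 2 or n_head < 2:
        raise ValueError("need at least 2 subjects and 2 headlines")
    y = _zscore(table[outcome].to_numpy(dtype=float))
    x = _zscore(table[predictor].to_numpy(dtype=float))
    if x.std() == 0:
        raise ValueError("singular design: predictor has zero variance")
    X = sm.add_constant(x)
    groups = np.column_stack(
        [
            pd.factorize(table["subject_id"])[0],
            pd.factorize(table["headline_id"])[0],
        ]
    )
    fit = sm.OLS(y, X).fit(
        cov_type="cluster",
        cov_kwds={
            "groups": groups,
            "use_correction": small_sample,
            "df_correction": small_sample,
        },
        use_t=False,
    )
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    z = beta / se if se > 0 else float("inf")
    p = float(2.0 * sps.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return RegressionResult(beta=beta, se=se, z=z, p=p)


def analyze_site_table(table: pd.DataFrame) -> dict[str, SiteAnalysis]:
    """Full per-site-type pipeline: slopes, Fisher's test, random-effects meta.

    Requires at least 2 sites of each type present in the table.  Returns a
    mapping from site type to its :class:`SiteAnalysis`.
    """
    validate_site_table(table)
    out: dict[str, SiteAnalysis] = {}
    for site_type in SITE_TYPES:
        sub = table[table["site_type"] == site_type]
        site_ids = sub["site_id"].unique()
        if len(site_ids) < 2:
            raise ValueError(f"need at least 2 sites of type {site_type!r}")
        rows = []
        for site_id in site_ids:
            res = site_slope(sub[sub["site_id"] == site_id])
            rows.append(
                {
                    "site_id": site_id,
                    "slope": res.slope,
                    "se": res.se,
                    "p": res.p,
                    "n": int((sub["site_id"] == site_id).sum()),
                }
            )
        slopes = pd.DataFrame(rows)
        statistic, df, fisher_p = fishers_combined(slopes["p"].to_numpy())
        usable = slopes.dropna(subset=["se"])
        meta = random_effects_meta(list(zip(usable["slope"], usable["se"])))
        out[site_type] = SiteAnalysis(
            slopes=slopes,
            fisher_statistic=statistic,
            fisher_df=df,
            fisher_p=fisher_p,
            meta=meta,
        )
    return out
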