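"""Statistics for the access analysis.

Three pieces:

* quartile binning of continuous tract covariates (Q1..Q4, ties to the
  lower bin), so odds ratios read as quartile contrasts;
* univariate odds of losing vs maintaining access, per non-reference level
  of a categorical predictor, with Wald 95% confidence intervals
  ``exp(ln OR ± 1.96 · sqrt(Σ 1/cell))`` — for a categorical predictor this
  cross-product estimator coincides with the maximum-likelihood logistic
  coefficient, which tests verify independently;
* segmented (interrupted time series) regression of annual clinic counts
  around a policy breakpoint, parameterised as
  ``count ~ 1 + year + post + post·(year − breakpoint)`` so each segment has
  its own slope ``b`` with a Wald 95% CI.

No multiple-testing adjustment and no multivariate model: covariates are
collinear and each contrast is reported on its own, two-sided α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

Z95 = 1.959963984540054  # two-sided 95% normal quantile

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


def quartile_bin(values, labels=QUARTILE_LABELS) -> tuple[pd.Series, np.ndarray]:
    """Bin a series at its empirical 25/50/75 percentiles.

    Ties at a cut point go to the lower bin (``v <= q25`` is Q1, etc.);
    missing values stay missing.  A constant series has no quartiles and is
    an error.  Returns ``(labels_series, cut_points)``.
    """
    s = pd.Series(values).astype(float)
    ok = s.dropna()
    if len(ok) < 4:
        raise ValueError("need at least 4 non-missing values to form quartiles")
    cuts = np.percentile(ok.to_numpy(), [25.0, 50.0, 75.0])
    if ok.max() == ok.min():
        raise ValueError("constant series: quartiles are degenerate")
    out = pd.Series(pd.NA, index=s.index, dtype="object")
    v = s.to_numpy()
    with np.errstate(invalid="ignore"):
        idx = np.searchsorted(cuts, v, side="left")  # v <= cut -> lower bin
    for i, lab in enumerate(labels):
        out[np.isfinite(v) & (idx == i)] = lab
    return out.astype(pd.CategoricalDtype(list(labels), ordered=True)), cuts


def exclude_for_or_analysis(records: pd.DataFrame) -> pd.DataFrame:
    """Restrict to lost/maintained tracts: never-access and gained tracts are
    out of the lost-vs-maintained contrast by design."""
    subset = records[records["category"].isin(["lost", "maintained"])].copy()
    if subset.empty:
        raise ValueError("no lost or maintained tracts: odds-ratio analysis is empty")
    return subset


@dataclass
class OddsRatioResult:
    """One odds-ratio contrast with its Wald 95% CI and the 2x2 cells used."""

    predictor: str
    level: str
    reference: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    cells: dict = field(default_factory=dict)  # keys: lost_level, kept_level, lost_ref, kept_ref

    def __post_init__(self):
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must bracket the estimate")

    def __str__(self):
        return (
            f"{self.predictor}[{self.level} vs {self.reference}]: "
            f"OR {self.odds_ratio:.2f} (95% CI {self.ci_low:.2f}-{self.ci_high:.2f})"
        )


def odds_ratio_from_cells(
    lost_level: int,
    kept_level: int,
    lost_ref: int,
    kept_ref: int,
    predictor: str = "predictor",
    level: str = "level",
    reference: str = "reference",
) -> OddsRatioResult:
    """Cross-product OR with a Wald interval from the four cell counts."""
    cells = dict(
        lost_level=int(lost_level),
        kept_level=int(kept_level),
        lost_ref=int(lost_ref),
        kept_ref=int(kept_ref),
    )
    if any(v <= 0 for v in cells.values()):
        raise ValueError(
            f"zero cell in {cells}: odds ratio undefined (continuity corrections out of scope)"
        )
    orr = (lost_level * kept_ref) / (kept_level * lost_ref)
    se = np.sqrt(sum(1.0 / v for v in cells.values()))
    lo, hi = np.exp(np.log(orr) - Z95 * se), np.exp(np.log(orr) + Z95 * se)
    return OddsRatioResult(predictor, level, reference, float(orr), float(lo), float(hi), cells)


def univariate_or(
    records: pd.DataFrame,
    predictor: str,
    reference: str | None = None,
    outcome: str = "category",
) -> list[OddsRatioResult]:
    """Odds of lost (vs maintained) for each non-reference predictor level.

    ``records`` must already be restricted to lost/maintained; rows missing
    the predictor are dropped here (per-covariate exclusion).  The reference
    level defaults to the first category (ordered categoricals) or the first
    level in sorted order.
    """
    df = records[[predictor, outcome]].dropna()
    lost = df[outcome] == "lost"
    levels = (
        list(df[predictor].cat.categories)
        if isinstance(df[predictor].dtype, pd.CategoricalDtype)
        else sorted(df[predictor].unique(), key=str)
    )
    levels = [l for l in levels if (df[predictor] == l).any()]
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent from {predictor!r}")
    lost_ref = int((lost & (df[predictor] == reference)).sum())
    kept_ref = int((~lost & (df[predictor] == reference)).sum())
    out = []
    for lev in levels:
        if lev == reference:
            continue
        out.append(
            odds_ratio_from_cells(
                int((lost & (df[predictor] == lev)).sum()),
                int((~lost & (df[predictor] == lev)).sum()),
                lost_ref,
                kept_ref,
                predictor=predictor,
                level=str(lev),
                reference=str(reference),
            )
        )
    return out


def or_results_frame(results: list[OddsRatioResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "predictor": r.predictor,
                "level": r.level,
                "reference": r.reference,
                "or": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                **r.cells,
            }
            for r in results
        ]
    )


@dataclass
class ITSResults:
    """Per-segment slopes of an interrupted time series fit."""

    breakpoint_year: int
    pre_slope: float
    pre_ci: tuple[float, float]
    post_slope: float
    post_ci: tuple[float, float]
    level_change: float
    nobs: int
    ols_results: object = None

    def summary(self) -> str:
        return (
            f"Interrupted time series (breakpoint {self.breakpoint_year}, n={self.nobs})\n"
            f"  pre-break slope  b = {self.pre_slope:.1f} "
            f"(95% CI {self.pre_ci[0]:.1f} to {self.pre_ci[1]:.1f}) per year\n"
            f"  post-break slope b = {self.post_slope:.1f} "
            f"(95% CI {self.post_ci[0]:.1f} to {self.post_ci[1]:.1f}) per year\n"
            f"  level change at breakpoint = {self.level_change:.1f}"
        )


class SegmentedITS:
    """Segmented OLS of an annual count series around a breakpoint year.

    Design matrix: intercept, centred year, post-break indicator, and
    post-break years-since-break — a level-and-slope-change parameterisation.
    ``fit()`` returns :class:`ITSResults` with each segment's slope and its
    Wald 95% CI (the post slope is the linear combination year + interaction).
    """

    def __init__(self, annual_counts: dict[int, float] | pd.Series, breakpoint_year: int):
        s = pd.Series(dict(annual_counts)).sort_index().astype(float)
        years = s.index.to_numpy(int)
        pre = years < breakpoint_year
        post = ~pre
        if pre.sum() < 2 or post.sum() < 2:
            raise ValueError(
                f"need at least 2 annual points on each side of {breakpoint_year}; "
                f"got {int(pre.sum())} pre and {int(post.sum())}"
            )
        self.series = s
        self.breakpoint_year = int(breakpoint_year)

    def fit(self) -> ITSResults:
        years = self.series.index.to_numpy(float)
        b = float(self.breakpoint_year)
        post = (years >= b).astype(float)
        X = np.column_stack([np.ones_like(years), years - years.min(), post, post * (years - b)])
        res = sm.OLS(self.series.to_numpy(), X).fit()
        pre_slope = res.params[1]
        pre_ci = res.conf_int(alpha=0.05)[1]
        comb = res.t_test(np.array([0.0, 1.0, 0.0, 1.0]))
        post_slope = float(np.atleast_1d(comb.effect)[0])
        post_ci = tuple(np.asarray(comb.conf_int(alpha=0.05)).ravel()[:2])
        return ITSResults(
            breakpoint_year=self.breakpoint_year,
            pre_slope=float(pre_slope),
            pre_ci=(float(pre_ci[0]), float(pre_ci[1])),
            post_slope=post_slope,
            post_ci=(float(post_ci[0]), float(post_ci[1])),
            level_change=float(res.params[2]),
            nobs=int(res.nobs),
            ols_results=res,
        )


def segmented_regression(annual_counts, breakpoint_year: int) -> ITSResults:
    """Convenience wrapper: fit :class:`SegmentedITS` in one call."""
    return SegmentedITS(annual_counts, breakpoint_year).fit()
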