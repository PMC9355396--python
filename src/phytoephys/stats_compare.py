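"""Statistical comparisons across devices and Faraday-cage conditions.

Two procedures mirror the benchmark's figure captions: a common-slope test
for regressions of waveform slope on amplitude (simple linear regression
per device group, then an interaction F-test in a pooled model), and a
two-factor ANOVA (device x cage, with interaction) followed by Tukey's
multiple-comparison test on the cell means.

Unbalanced designs use Type II sums of squares (switchable to Type III) and
the Tukey-Kramer adjustment for unequal group sizes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import InvalidArgumentError

__all__ = [
    "RegressionFit",
    "SlopeComparison",
    "ComparisonResult",
    "fit_line",
    "compare_slopes",
    "two_way_anova_tukey",
]


@dataclass
class RegressionFit:
    """Ordinary-least-squares line fit for one device x cage group."""

    slope: float
    intercept: float
    slope_se: float
    n: int
    r2: float
    label: str = ""


@dataclass
class SlopeComparison:
    """Interaction F-test for equality of regression slopes across groups."""

    f: float
    df_num: int
    df_den: int
    p: float
    fits: dict = field(default_factory=dict)


@dataclass
class ComparisonResult:
    """Two-way ANOVA table plus Tukey pairwise comparisons.

    ``anova`` has rows for device, cage, their interaction and the residual
    (sum_sq, df, F, PR(>F)).  ``tukey`` lists every pair of device x cage
    cells with the Tukey-adjusted p-value.  ``within_cage`` /
    ``within_device`` are the significant pairs sharing a cage condition or
    a device, mirroring the black/red annotation scheme of the figures.
    ``no_variance`` flags a degenerate all-equal input.
    """

    anova: pd.DataFrame | None
    tukey: pd.DataFrame | None
    alpha: float
    within_cage: list = field(default_factory=list)
    within_device: list = field(default_factory=list)
    no_variance: bool = False

    def p_value(self, factor: str) -> float:
        """ANOVA p-value for 'device', 'cage' or 'interaction'."""
        if self.no_variance or self.anova is None:
            return float("nan")
        row = {"device": "C(device)", "cage": "C(cage)",
               "interaction": "C(device):C(cage)"}[factor]
        return float(self.anova.loc[row, "PR(>F)"])


# ---------------------------------------------------------------------------


def fit_line(x, y, label: str = "") -> RegressionFit:
    """OLS fit of y on x with slope standard error."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise InvalidArgumentError("x and y must have equal length")
    if x.size < 3:
        raise InvalidArgumentError("need at least 3 points")
    if np.ptp(x) == 0:
        raise InvalidArgumentError("x is constant; slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        n=int(x.size),
        r2=float(res.rsquared),
        label=label,
    )


def compare_slopes(groups: dict[str, tuple]) -> SlopeComparison:
    """Test whether regression slopes differ between groups.

    ``groups`` maps a label to its raw ``(x, y)`` data (the pooled
    interaction test needs the observations, not just fitted summaries).
    Implemented as the F-test comparing a common-slope model
    ``y ~ x + group`` against the separate-slopes model ``y ~ x * group``.
    Identical groups yield F = 0, p = 1.
    """
    if len(groups) < 2:
        raise InvalidArgumentError("need at least 2 groups")
    fits = {lbl: fit_line(x, y, lbl) for lbl, (x, y) in groups.items()}
    frames = [
        pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float), "g": lbl})
        for lbl, (x, y) in groups.items()
    ]
    df = pd.concat(frames, ignore_index=True)
    full = smf.ols("y ~ C(g) * x", data=df).fit()
    reduced = smf.ols("y ~ C(g) + x", data=df).fit()
    f, p, df_num = full.compare_f_test(reduced)
    f = float(f)
    if f < 1e-10:  # SSR round-off at the identical-groups boundary
        f, p = 0.0, 1.0
    return SlopeComparison(
        f=f, df_num=int(df_num), df_den=int(full.df_resid), p=p, fits=fits
    )


def two_way_anova_tukey(
    table: pd.DataFrame,
    alpha: float = 0.05,
    value_col: str = "value",
    ss_type: int = 2,
    include_tukey: bool = True,
) -> ComparisonResult:
    """Device x cage factorial ANOVA with Tukey multiple comparisons.

    ``table`` needs columns ``value_col``, ``device`` and ``cage``; every
    device x cage cell must contain at least two replicates.  When all
    values are identical the result carries ``no_variance=True`` and no
    significant pairs instead of dividing by a zero residual.

    ``include_tukey=False`` skips the pairwise stage (the studentized-range
    quantiles dominate the runtime), for callers that only need the ANOVA
    table, e.g. large calibration simulations.
    """
    for col in (value_col, "device", "cage"):
        if col not in table.columns:
            raise InvalidArgumentError(f"table lacks required column {col!r}")
    df = table[[value_col, "device", "cage"]].copy()
    df.columns = ["value", "device", "cage"]
    df["device"] = df["device"].astype(str)
    df["cage"] = df["cage"].astype(str)
    if df["device"].nunique() < 2 or df["cage"].nunique() < 2:
        raise InvalidArgumentError("need at least 2 levels per factor")
    counts = df.groupby(["device", "cage"]).size()
    if len(counts) < df["device"].nunique() * df["cage"].nunique():
        raise InvalidArgumentError("empty device x cage cells are not supported")
    if (counts < 2).any():
        raise InvalidArgumentError("every device x cage cell needs >= 2 replicates")
    if np.ptp(df["value"].to_numpy()) == 0:
        return ComparisonResult(anova=None, tukey=None, alpha=alpha, no_variance=True)

    model = smf.ols("value ~ C(device) * C(cage)", data=df).fit()
    anova = anova_lm(model, typ=ss_type)
    if not include_tukey:
        return ComparisonResult(anova=anova, tukey=None, alpha=alpha)

    cell = df["device"] + "|" + df["cage"]
    hsd = pairwise_tukeyhsd(df["value"].to_numpy(), cell.to_numpy(), alpha=alpha)
    tukey = pd.DataFrame(
        hsd.summary().data[1:],
        columns=[str(c) for c in hsd.summary().data[0]],
    )
    tukey[["p-adj", "meandiff"]] = tukey[["p-adj", "meandiff"]].astype(float)
    tukey["reject"] = tukey["reject"].astype(bool)

    within_cage, within_device = [], []
    for _, row in tukey.iterrows():
        d1, c1 = str(row["group1"]).split("|")
        d2, c2 = str(row["group2"]).split("|")
        if not row["reject"]:
            continue
        pair = (str(row["group1"]), str(row["group2"]), float(row["p-adj"]))
        if c1 == c2 and d1 != d2:
            within_cage.append(pair)
        elif d1 == d2 and c1 != c2:
            within_device.append(pair)
    return ComparisonResult(
        anova=anova, tukey=tukey, alpha=alpha,
        within_cage=within_cage, within_device=within_device,
    )
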