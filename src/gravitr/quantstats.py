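"""Group comparisons and genetics statistics for derived TR features.

Covers the preliminary group-level analyses (per-group regression of daily
maximum TR on maximum VPD; two-way fixed-effects ANOVA of max TR on group
and day) and the per-feature genetics statistics: broad-sense heritability
H2 = sigma2_g / (sigma2_g + sigma2_e) from the one-way random-effects model
y = 1*mu + Z_g g + e, one-way ANOVA per feature, and Tukey-HSD pairwise
genotype comparisons summarised as a compact letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Preliminary analyses
# ---------------------------------------------------------------------------

def max_tr_regression(max_tr, max_vpd, group=None) -> pd.DataFrame:
    """OLS of daily maximum TR on daily maximum VPD, per group.

    Returns one row per group with slope, intercept and the two-sided
    p-value of the slope.
    """
    df = pd.DataFrame({"y": np.asarray(max_tr, dtype=float),
                       "x": np.asarray(max_vpd, dtype=float),
                       "group": "all" if group is None else np.asarray(group)})
    rows = []
    for g, sub in df.groupby("group"):
        if len(sub) < 3:
            raise ValueError(f"group {g!r}: need at least 3 days")
        if np.ptp(sub["x"]) == 0:
            raise ValueError(f"group {g!r}: max VPD has zero variance")
        fit = sps.linregress(sub["x"], sub["y"])
        rows.append({"group": g, "slope": fit.slope,
                     "intercept": fit.intercept, "p_value": fit.pvalue,
                     "r": fit.rvalue, "n": len(sub)})
    return pd.DataFrame(rows)


def two_way_anova(y, group, day) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA y ~ group + day + group:day (type-I SS).

    Designed for the balanced tables this pipeline produces; unbalanced
    input triggers a warning (type-I sums of squares are order-dependent
    when cells are unbalanced).  Empty cells are rejected.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": np.asarray(y, dtype=float),
                       "group": np.asarray(group).astype(str),
                       "day": np.asarray(day).astype(str)})
    cells = df.groupby(["group", "day"]).size()
    full = len(df["group"].unique()) * len(df["day"].unique())
    if len(cells) < full:
        have = set(cells.index)
        missing = [(g, d) for g in df["group"].unique()
                   for d in df["day"].unique() if (g, d) not in have]
        raise ValueError(f"empty design cells: {missing}")
    if cells.nunique() > 1:
        warnings.warn("unbalanced design: type-I sums of squares are "
                      "order-dependent")
    model = smf.ols("y ~ C(day) + C(group) + C(day):C(group)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(index={
        "C(day)": "Day", "C(group)": "Group",
        "C(day):C(group)": "Day x Group", "Residual": "Residuals",
    })
    table.columns = ["df", "SS", "F", "p"] if len(table.columns) == 4 else table.columns
    # statsmodels returns df, sum_sq, F, PR(>F); add mean squares
    table = table.rename(columns={"sum_sq": "SS", "PR(>F)": "p"})
    table["MS"] = table["SS"] / table["df"]
    return table[["df", "SS", "MS", "F", "p"]]


def f_from_sums(ss_term: float, df_term: int, ss_resid: float,
                df_resid: int):
    """Recompute an ANOVA F statistic and p-value from printed SS and df."""
    ms_term = ss_term / df_term
    ms_resid = ss_resid / df_resid
    f = ms_term / ms_resid
    p = sps.f.sf(f, df_term, df_resid)
    return f, p


# ---------------------------------------------------------------------------
# Broad-sense heritability
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Genotypic and residual variance with broad-sense heritability."""

    sigma2_g: float
    sigma2_e: float
    method: str

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


def _heritability_ems(y, genotype) -> VarianceComponents:
    """Expected-mean-squares (method-of-moments) variance components.

    For unbalanced data the replicate count is replaced by the standard
    effective value n0 = (N - sum n_i^2 / N) / (a - 1).
    """
    df = pd.DataFrame({"y": y, "g": genotype}).dropna()
    groups = df.groupby("g")["y"]
    a = groups.ngroups
    N = len(df)
    ni = groups.size().to_numpy(dtype=float)
    grand = df["y"].mean()
    ss_between = float((ni * (groups.mean() - grand) ** 2).sum())
    ss_within = float(((df["y"] - groups.transform("mean")) ** 2).sum())
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a) if N > a else 0.0
    n0 = (N - (ni ** 2).sum() / N) / (a - 1)
    sigma2_g = max(0.0, (ms_between - ms_within) / n0)
    return VarianceComponents(sigma2_g=sigma2_g, sigma2_e=ms_within,
                              method="ems")


def heritability(y, genotype, method: str = "reml") -> VarianceComponents:
    """Variance components of the one-way random-effects genotype model.

    REML by default (via a mixed model with a random genotype intercept);
    ``method="ems"`` uses the expected-mean-squares estimator, which is also
    the fallback when the REML fit fails.  H2 is the per-plot ratio
    sigma2_g / (sigma2_g + sigma2_e), with negative component estimates
    truncated at zero.
    """
    y = np.asarray(y, dtype=float)
    genotype = np.asarray(genotype)
    df = pd.DataFrame({"y": y, "g": genotype}).dropna()
    counts = df.groupby("g").size()
    if len(counts) < 2:
        raise ValueError("need >= 2 genotypes")
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 replicates for >= 2 genotypes")
    if method == "ems":
        return _heritability_ems(df["y"], df["g"])
    if method != "reml":
        raise ValueError("method must be 'reml' or 'ems'")
    try:
        import statsmodels.formula.api as smf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm("y ~ 1", df, groups=df["g"])
            fit = md.fit(reml=True)
        sigma2_g = max(0.0, float(fit.cov_re.iloc[0, 0]))
        sigma2_e = max(0.0, float(fit.scale))
        if not (np.isfinite(sigma2_g) and np.isfinite(sigma2_e)):
            raise ValueError("non-finite REML estimates")
        return VarianceComponents(sigma2_g=sigma2_g, sigma2_e=sigma2_e,
                                  method="reml")
    except Exception:
        warnings.warn("REML fit failed; falling back to expected mean squares")
        return _heritability_ems(df["y"], df["g"])


def heritability_table(feature_values: pd.DataFrame, design: pd.DataFrame,
                       method: str = "reml") -> pd.DataFrame:
    """H2 per feature from per-sector feature means.

    ``feature_values`` is indexed by sector with one column per feature;
    ``design`` maps sectors to genotypes.
    """
    geno = design.set_index("sector_id")["genotype_id"]
    rows = []
    for feat in feature_values.columns:
        y = feature_values[feat]
        vc = heritability(y.to_numpy(), geno.reindex(y.index).to_numpy(),
                          method=method)
        rows.append({"feature": feat, "sigma2_g": vc.sigma2_g,
                     "sigma2_e": vc.sigma2_e, "H2": vc.h2,
                     "method": vc.method})
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# Tukey-HSD compact letter display
# ---------------------------------------------------------------------------

def compact_letter_display(levels, not_different) -> dict:
    """Insert-and-absorb letter assignment from a 'not different' relation.

    ``levels`` are ordered (conventionally by descending mean);
    ``not_different(a, b)`` says whether a pair is statistically
    indistinguishable.  Two levels share a letter iff they are not
    significantly different.
    """
    columns = [set(levels)]
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            if not_different(a, b):
                continue
            # the pair is significant: split every column containing both
            new_cols = []
            for col in columns:
                if a in col and b in col:
                    new_cols.extend([col - {a}, col - {b}])
                else:
                    new_cols.append(col)
            # absorb columns contained in another
            columns = [c for c in new_cols
                       if not any(c < d for d in new_cols)]
            # deduplicate
            uniq = []
            for c in columns:
                if c not in uniq:
                    uniq.append(c)
            columns = uniq
    letters = {lv: "" for lv in levels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for ci, col in enumerate(columns):
        tag = alphabet[ci % 26] * (1 + ci // 26)
        for lv in levels:
            if lv in col:
                letters[lv] += tag
    return letters


@dataclass
class TukeyGroups:
    """Tukey-HSD genotype comparison summarised as letter groups."""

    letters: dict
    n_groups: int
    results: pd.DataFrame


def tukey_groups(y, genotype, alpha: float = 0.05) -> TukeyGroups:
    """All-pairs Tukey honest-significant-difference genotype comparison.

    Implemented with the studentized-range critical value (Tukey-Kramer
    standard errors for unequal replication): a pair differs when
    |mean_i - mean_j| exceeds q_crit * sqrt(MSE/2 * (1/n_i + 1/n_j)).
    Using one critical value instead of per-pair p-values keeps all-pairs
    comparisons of ~50 genotypes fast.  Returns the compact letter display
    and the number of distinct letter groups (a proxy for how much genotypic
    diversity the trait resolves).
    """
    df = pd.DataFrame({"y": np.asarray(y, dtype=float),
                       "g": np.asarray(genotype).astype(str)}).dropna()
    if df["g"].nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    stats = df.groupby("g")["y"].agg(["mean", "count"])
    k = len(stats)
    df_resid = len(df) - k
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for Tukey HSD")
    mse = float(((df["y"] - df.groupby("g")["y"].transform("mean")) ** 2).sum()
                / df_resid)
    q_crit = float(sps.studentized_range.ppf(1 - alpha, k, df_resid))

    import itertools

    rows, sig = [], {}
    for a, b in itertools.combinations(stats.index, 2):
        se = np.sqrt(mse / 2 * (1 / stats.loc[a, "count"]
                                + 1 / stats.loc[b, "count"]))
        diff = stats.loc[a, "mean"] - stats.loc[b, "mean"]
        reject = bool(abs(diff) > q_crit * se) if se > 0 else abs(diff) > 0
        sig[frozenset((a, b))] = reject
        rows.append({"group1": a, "group2": b, "meandiff": diff,
                     "q_stat": abs(diff) / se if se > 0 else np.inf,
                     "reject": reject})
    table = pd.DataFrame(rows)
    means = stats["mean"].sort_values(ascending=False)
    levels = list(means.index)
    letters = compact_letter_display(
        levels, lambda a, b: not sig[frozenset((a, b))])
    distinct = len(set(letters.values()))
    return TukeyGroups(letters=letters, n_groups=distinct, results=table)
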