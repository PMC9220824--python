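"""Group statistics: ANOVA with Šidák or Tukey post tests, and the
TMT proteomics abundance screen.

Šidák adjustment over m planned comparisons: p_adj = 1 - (1 - p)^m.
Tukey adjusted p-values come from the studentized-range distribution over
all pairwise level comparisons, using the ANOVA residual mean square.
The abundance screen normalises channels to equal sums (equal loading),
scales each protein's row to sum 100 (relative abundance), tests groups by
Welch's t on log values, and corrects with Benjamini-Hochberg; hits need
fold change > 1.25 (up) or < 1/1.25 (down) at adjusted p < 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests


def sidak_adjust(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Šidák family-wise adjustment over m planned comparisons."""
    if m < 1:
        raise ValueError("m must be at least 1")
    adj = 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m
    adj = np.clip(adj, 0.0, 1.0)
    adj = np.maximum(adj, np.asarray(p, dtype=float))  # guard rounding at tiny p
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(adj)
    return adj


@dataclass
class PosthocResult:
    """ANOVA table plus the post-hoc comparison table.

    ``comparisons`` columns: the stratifying level (if any), the two groups
    compared, estimate (mean difference), test statistic, df, raw p,
    adjusted p, and the adjustment method.
    """

    anova_table: pd.DataFrame
    comparisons: pd.DataFrame
    mse: float
    df_resid: float
    method: str


def _check_cells(df: pd.DataFrame, factors: Sequence[str]) -> None:
    counts = df.groupby(list(factors), observed=True).size()
    full = pd.MultiIndex.from_product(
        [df[f].unique() for f in factors], names=list(factors)
    ) if len(factors) > 1 else pd.Index(df[factors[0]].unique(), name=factors[0])
    missing = [idx for idx in full if idx not in counts.index]
    if missing:
        raise ValueError(f"empty design cells: {missing}")


def _anova(df: pd.DataFrame, value_col: str, factors: Sequence[str]):
    terms = " * ".join(f"C(Q('{f}'))" for f in factors)
    model = smf.ols(f"Q('{value_col}') ~ {terms}", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    mse = float(model.mse_resid)
    return table, mse, float(model.df_resid)


def anova_posthoc(
    records: pd.DataFrame,
    value_col: str,
    factors: Sequence[str],
    posthoc: str = "sidak",
    group_factor: Optional[str] = None,
) -> PosthocResult:
    """Fixed-effects ANOVA with Šidák or Tukey post tests.

    One factor with ``posthoc='tukey'``: one-way ANOVA and all pairwise
    comparisons via the studentized range. One factor with ``'sidak'``: all
    pairwise t comparisons, Šidák-adjusted over the number of pairs. Two
    factors with ``'sidak'``: two-way ANOVA (with interaction) and, within
    each level of the second factor, pairwise comparisons of the first
    (``group_factor``, default ``factors[0]``); the Šidák family is the
    total number of comparisons (one per level when the group factor has
    two levels). Pooled-variance t statistics use the ANOVA residual mean
    square.
    """
    if posthoc not in {"sidak", "tukey"}:
        raise ValueError("posthoc must be 'sidak' or 'tukey'")
    factors = list(factors)
    if not 1 <= len(factors) <= 2:
        raise ValueError("one or two factors are supported")
    df = records.dropna(subset=[value_col]).copy()
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    _check_cells(df, factors)
    table, mse, df_resid = _anova(df, value_col, factors)

    rows: List[dict] = []
    if posthoc == "tukey":
        if len(factors) != 1:
            raise ValueError("Tukey post tests follow a one-way ANOVA")
        f = factors[0]
        stats_by = df.groupby(f, observed=True)[value_col].agg(["mean", "size"])
        k = len(stats_by)
        for a, b in itertools.combinations(stats_by.index, 2):
            ma, na = stats_by.loc[a, "mean"], stats_by.loc[a, "size"]
            mb, nb = stats_by.loc[b, "mean"], stats_by.loc[b, "size"]
            diff = mb - ma
            se_t = np.sqrt(mse * (1 / na + 1 / nb))
            t_stat = diff / se_t
            p_raw = 2 * sps.t.sf(abs(t_stat), df_resid)
            # Tukey-Kramer: q = |diff| / sqrt(MSE/2 * (1/na + 1/nb))
            q = abs(diff) / np.sqrt(mse / 2.0 * (1 / na + 1 / nb))
            p_adj = float(sps.studentized_range.sf(q, k, df_resid))
            rows.append({
                "level": "", "group_a": a, "group_b": b, "estimate": diff,
                "statistic": q, "df": df_resid, "p_raw": float(p_raw),
                "p_adj": min(max(p_adj, float(p_raw)), 1.0), "method": "tukey",
            })
    else:
        gf = group_factor or factors[0]
        strat = [f for f in factors if f != gf]
        sf_levels = sorted(df[strat[0]].unique()) if strat else [""]
        glevels = sorted(df[gf].unique())
        pairs = list(itertools.combinations(glevels, 2))
        m = len(sf_levels) * len(pairs)
        for level in sf_levels:
            sub = df if not strat else df[df[strat[0]] == level]
            stats_by = sub.groupby(gf, observed=True)[value_col].agg(["mean", "size"])
            for a, b in pairs:
                ma, na = stats_by.loc[a, "mean"], stats_by.loc[a, "size"]
                mb, nb = stats_by.loc[b, "mean"], stats_by.loc[b, "size"]
                diff = mb - ma
                se = np.sqrt(mse * (1 / na + 1 / nb))
                t_stat = diff / se if se > 0 else 0.0
                p_raw = float(2 * sps.t.sf(abs(t_stat), df_resid))
                rows.append({
                    "level": level, "group_a": a, "group_b": b, "estimate": diff,
                    "statistic": float(t_stat), "df": df_resid, "p_raw": p_raw,
                    "p_adj": float(sidak_adjust(p_raw, m)), "method": "sidak",
                })

    comparisons = pd.DataFrame(rows)
    return PosthocResult(anova_table=table, comparisons=comparisons,
                         mse=mse, df_resid=df_resid, method=posthoc)


# --------------------------------------------------------------------------
# Proteomics abundance screen
# --------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Normalised tables and the per-protein differential test.

    ``results`` columns: protein, mean relative abundance per group, fold
    change (group b over group a), log2 fold change, Welch t, raw p, BH
    adjusted p, and hit direction (up / down / none).
    """

    normalized: pd.DataFrame       # after column normalisation
    relative_abundance: pd.DataFrame  # rows scaled to sum 100
    results: pd.DataFrame
    up: List[str] = field(default_factory=list)
    down: List[str] = field(default_factory=list)


def column_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each channel so all channel sums equal their mean (equal loading)."""
    arr = table.to_numpy(dtype=float)
    if np.any(arr <= 0) or not np.isfinite(arr).all():
        raise ValueError("abundances must be positive and finite")
    sums = arr.sum(axis=0)
    return table * (sums.mean() / sums)


def scale_rows_to_100(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each protein so its summed signal across channels equals 100."""
    return table.div(table.sum(axis=1), axis=0) * 100.0


def abundance_screen(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    fc_threshold: float = 1.25,
    alpha: float = 0.05,
) -> ScreenResult:
    """Differential abundance screen on a protein x channel table.

    Steps: column normalisation -> per-protein row scaling to 100 ->
    Welch's t between the two groups on log relative abundances ->
    Benjamini-Hochberg correction. Hits require fold change above
    ``fc_threshold`` (up) or below its reciprocal (down) at adjusted
    p < ``alpha``. ``groups`` maps every channel to one of exactly two
    group labels.
    """
    missing = set(table.columns) - set(groups)
    if missing:
        raise ValueError(f"channels without a group: {sorted(missing)}")
    labels = sorted(set(groups[c] for c in table.columns))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups are required, got {labels}")
    ga = [c for c in table.columns if groups[c] == labels[0]]
    gb = [c for c in table.columns if groups[c] == labels[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs at least two channels")

    normalized = column_normalize(table)
    scaled = scale_rows_to_100(normalized)

    la = np.log(scaled[ga].to_numpy(dtype=float))
    lb = np.log(scaled[gb].to_numpy(dtype=float))
    t_stat, p_raw = sps.ttest_ind(lb, la, axis=1, equal_var=False)
    mean_a = scaled[ga].mean(axis=1)
    mean_b = scaled[gb].mean(axis=1)
    fc = (mean_b / mean_a).to_numpy(dtype=float)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]

    hit = np.where(
        (fc > fc_threshold) & (p_adj < alpha), "up",
        np.where((fc < 1.0 / fc_threshold) & (p_adj < alpha), "down", "none"),
    )
    results = pd.DataFrame(
        {
            "protein": table.index,
            f"mean_{labels[0]}": mean_a.to_numpy(),
            f"mean_{labels[1]}": mean_b.to_numpy(),
            "fold_change": fc,
            "log2_fold_change": np.log2(fc),
            "t": t_stat,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "hit": hit,
        }
    ).reset_index(drop=True)
    return ScreenResult(
        normalized=normalized,
        relative_abundance=scaled,
        results=results,
        up=results.loc[results.hit == "up", "protein"].tolist(),
        down=results.loc[results.hit == "down", "protein"].tolist(),
    )
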