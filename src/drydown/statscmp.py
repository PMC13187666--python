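"""Group comparisons: delta-psi between techniques, ANOVA + Tukey letters,
confidence-interval overlap tests, and Pearson trait-threshold correlations."""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import AnalysisError, ConfigError

__all__ = [
    "ComparisonResult",
    "PearsonMatrix",
    "delta_psi",
    "anova_tukey",
    "compact_letter_display",
    "ci_compare",
    "pearson_matrix",
]


@dataclass
class ComparisonResult:
    """One-way ANOVA + Tukey HSD outcome with assumption checks."""

    anova_f: float
    anova_p: float
    tukey: pd.DataFrame                 # group_a, group_b, p_adj, reject
    letters: dict[str, str]             # compact letter display
    shapiro_p: dict[str, float]
    levene_p: float
    assumption_flags: list[str] = field(default_factory=list)
    alpha: float = 0.05


@dataclass
class PearsonMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: int


def delta_psi(psi_ov50: float, psi_aemax: float) -> float:
    """Difference psi_OV50 - psi_AEmax (positive when the optical threshold
    is less negative, i.e. the optical technique reports earlier embolism)."""
    if psi_ov50 > 0 or psi_aemax > 0:
        raise ConfigError("water potentials must be <= 0 MPa")
    return psi_ov50 - psi_aemax


def compact_letter_display(groups: list[str], significant: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff their pairwise comparison is NOT in
    ``significant``.  ``groups`` fixes the display order; letters are
    assigned a, b, c, ... in that order.
    """
    sig = {frozenset(pair) for pair in significant}
    columns: list[set[str]] = [set(groups)]
    for pair in sig:
        a, b = tuple(pair)
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                columns.append(col - {a})
                columns.append(col - {b})
        # absorb columns contained in another
        columns = [c for c in columns
                   if c and not any(c < other for other in columns if other is not c)]
        # deduplicate
        uniq = []
        for c in columns:
            if c not in uniq:
                uniq.append(c)
        columns = uniq
    # stable order: by first member's position in `groups`
    columns.sort(key=lambda c: min(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for letter, col in zip(string.ascii_lowercase, columns):
        for g in col:
            letters[g] += letter
    return letters


def anova_tukey(groups: dict[str, list | np.ndarray], alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA followed by Tukey's HSD with a compact letter display.

    Shapiro-Wilk (per group) and Levene (across groups) run first; failures
    at ``alpha`` are recorded in ``assumption_flags`` and warned about but
    do not switch the analysis.
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if len(names) < 2:
        raise ConfigError("need at least 2 groups")
    for g, vals in zip(names, data):
        if len(vals) < 2:
            raise ConfigError(f"group {g!r} needs n >= 2")
    if all(np.ptp(vals) == 0 for vals in data) and len({v[0] for v in data}) == 1:
        raise AnalysisError("degenerate data: all values identical in every group")

    flags: list[str] = []
    shapiro_p = {}
    for g, vals in zip(names, data):
        if len(vals) >= 3 and np.ptp(vals) > 0:
            p = float(sps.shapiro(vals).pvalue)
        else:
            p = np.nan
        shapiro_p[g] = p
        if np.isfinite(p) and p < alpha:
            flags.append(f"shapiro:{g}")
    try:
        levene_p = float(sps.levene(*data).pvalue)
    except Exception:
        levene_p = np.nan
    if np.isfinite(levene_p) and levene_p < alpha:
        flags.append("levene")
    if flags:
        warnings.warn(f"assumption checks failed: {flags} (analysis proceeds "
                      "unchanged)", stacklevel=2)

    f_stat, f_p = sps.f_oneway(*data)
    hsd = sps.tukey_hsd(*data)
    rows = []
    significant = set()
    for i, j in itertools.combinations(range(len(names)), 2):
        p_adj = float(hsd.pvalue[i, j])
        reject = p_adj < alpha
        if reject:
            significant.add((names[i], names[j]))
        rows.append({"group_a": names[i], "group_b": names[j],
                     "mean_diff": float(np.mean(data[i]) - np.mean(data[j])),
                     "p_adj": p_adj, "reject": reject})
    letters = compact_letter_display(names, significant)
    return ComparisonResult(anova_f=float(f_stat), anova_p=float(f_p),
                            tukey=pd.DataFrame(rows), letters=letters,
                            shapiro_p=shapiro_p, levene_p=levene_p,
                            assumption_flags=flags, alpha=alpha)


def ci_compare(a: tuple[float, float], b: tuple[float, float]) -> str:
    """"different" iff the two (closed) intervals are disjoint, else "same".

    Touching endpoints count as overlap (conservative closed-interval rule).
    """
    a_lo, a_hi = sorted(a)
    b_lo, b_hi = sorted(b)
    return "different" if (a_hi < b_lo or b_hi < a_lo) else "same"


def pearson_matrix(traits: pd.DataFrame, thresholds: pd.DataFrame) -> PearsonMatrix:
    """Pearson r (and per-pair p) between every trait and threshold column.

    Rows are aligned on the shared index.  No multiple-testing correction is
    applied.  A warning fires for n < 5 (correlations on so few points are
    essentially descriptive); zero-variance columns yield NaN entries with a
    warning.
    """
    joined = traits.join(thresholds, how="inner", lsuffix="_trait")
    n = len(joined)
    if n < 3:
        raise ConfigError(f"need n >= 3 paired observations, got {n}")
    if n < 5:
        warnings.warn(f"only n={n} paired observations: correlations are "
                      "descriptive, not inferential", stacklevel=2)
    r = pd.DataFrame(index=traits.columns, columns=thresholds.columns, dtype=float)
    p = pd.DataFrame(index=traits.columns, columns=thresholds.columns, dtype=float)
    for tc in traits.columns:
        for hc in thresholds.columns:
            x = joined[tc if tc in joined else tc + "_trait"].to_numpy(dtype=float)
            y = joined[hc].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"zero variance in pair ({tc}, {hc}); r undefined",
                              stacklevel=2)
                r.loc[tc, hc] = np.nan
                p.loc[tc, hc] = np.nan
                continue
            res = sps.pearsonr(x, y)
            r.loc[tc, hc] = float(res.statistic)
            p.loc[tc, hc] = float(res.pvalue)
    return PearsonMatrix(r=r, p=p, n=n)
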