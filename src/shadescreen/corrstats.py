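"""Correlation screening against the WIS and Duncan's multiple range test.

``correlate_with_wis`` screens each isoflavone variable (12 analytes + 8
derived totals) for association with the weighted index of sensitivity at
the germplasm level, flagging 0.05 (*) and 0.01 (**) significance from the
t transform of the Pearson coefficient.  No multiplicity correction is
applied across the 20 variables; this is a screening report and the output
notes it.

``duncan_mrt`` is the classical post-ANOVA multiple range test: group means
are ordered, the range of every subset of p adjacent means is compared with
a least significant range built from the studentized-range distribution at
the protection level 1 - (1-alpha)^(p-1), and the result is summarised as a
compact letter display.  Unbalanced group sizes use the harmonic mean n.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["correlate_with_wis", "duncan_mrt"]

logger = logging.getLogger(__name__)


def _flag(p: float, alphas: tuple[float, float]) -> str:
    loose, strict = max(alphas), min(alphas)
    if p < strict:
        return "**"
    if p < loose:
        return "*"
    return "ns"


def correlate_with_wis(
    profiles: pd.DataFrame,
    wis: pd.Series,
    variables: list[str] | None = None,
    method: str = "pearson",
    alphas: tuple[float, float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Correlate per-genotype profile variables with per-genotype WIS.

    Parameters
    ----------
    profiles
        One row per genotype (index = genotype) with numeric variable
        columns, typically genotype-mean concentrations plus derived totals.
    wis
        WIS per genotype (index = genotype); keys must match ``profiles``.
    method
        "pearson" (default) or "spearman".

    Returns a frame (variable, r, p, flag) sorted by r ascending, so the
    strongest negative association (the tolerance-marker side) comes first.
    Zero-variance variables get NaN r/p and flag "ns".
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    common = profiles.index.intersection(wis.index)
    if len(common) < 3:
        raise ValueError("need at least 3 matching genotypes")
    if len(common) < len(profiles.index) or len(common) < len(wis.index):
        logger.warning("genotype keys only partially overlap; using %d genotypes",
                       len(common))
    prof = profiles.loc[common]
    w = wis.loc[common].to_numpy(dtype=float)
    if variables is None:
        variables = [c for c in prof.columns if pd.api.types.is_numeric_dtype(prof[c])]
    rows = []
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    for var in variables:
        x = prof[var].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(w) == 0:
            logger.warning("variable %r has zero variance; correlation undefined", var)
            rows.append((var, np.nan, np.nan, "ns"))
            continue
        res = corr(x, w)
        r, p = float(res.statistic), float(res.pvalue)
        rows.append((var, r, p, _flag(p, alphas)))
    out = pd.DataFrame(rows, columns=["variable", "r", "p", "flag"])
    out.attrs["note"] = "p-values are per-variable; no multiple-testing correction applied"
    return out.sort_values("r", na_position="last").reset_index(drop=True)


def _least_significant_range(p: int, df: int, alpha: float, mse: float, n_h: float) -> float:
    """Duncan least significant range for a subset of p ordered means."""
    protection = (1.0 - alpha) ** (p - 1)
    q = stats.studentized_range.ppf(protection, p, df)
    return float(q * np.sqrt(mse / n_h))


def duncan_mrt(
    values,
    groups,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Duncan's multiple range test with a one-way ANOVA gate.

    If the ANOVA F test is not significant at ``alpha`` every group shares
    the letter "a".  Otherwise ordered subsets of adjacent group means are
    tested step-down against the least significant range; a difference
    contained inside a non-significant range is itself declared
    non-significant (Duncan's containment rule).

    Returns a frame (group, n, mean, letters) sorted by mean descending,
    with the ANOVA p-value in ``attrs["anova_p"]``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    frame = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    sizes = frame.groupby("group", observed=True)["value"].size()
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 samples")
    samples = [g["value"].to_numpy() for _, g in frame.groupby("group", observed=True)]
    anova_p = float(stats.f_oneway(*samples).pvalue)

    means = frame.groupby("group", observed=True)["value"].mean().sort_values(ascending=False)
    m = len(means)
    # A NaN F statistic (no variance anywhere) counts as not significant.
    if not np.isfinite(anova_p) or anova_p >= alpha:
        out = pd.DataFrame(
            {"group": means.index, "n": sizes.loc[means.index].to_numpy(),
             "mean": means.to_numpy(), "letters": ["a"] * m}
        )
        out.attrs["anova_p"] = anova_p
        return out

    n_total = len(frame)
    df_err = n_total - m
    group_means = frame.groupby("group", observed=True)["value"].transform("mean")
    mse = float(((frame["value"] - group_means) ** 2).sum() / df_err)
    n_h = m / float((1.0 / sizes).sum())  # harmonic mean group size

    # Step-down range testing over means ordered descending.
    mu = means.to_numpy()
    nonsig = np.zeros((m, m), dtype=bool)  # pairs declared not different
    shielded = np.zeros((m, m), dtype=bool)  # inside a non-significant range
    for p in range(m, 1, -1):
        lsr = _least_significant_range(p, df_err, alpha, mse, n_h)
        for i in range(0, m - p + 1):
            j = i + p - 1
            if shielded[i, j] or (mu[i] - mu[j]) <= lsr:
                for a, b in combinations(range(i, j + 1), 2):
                    nonsig[a, b] = nonsig[b, a] = True
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        shielded[a, b] = True

    # Compact letter display: maximal runs of mutually non-significant,
    # adjacently-ordered groups (intervals, by the containment rule).
    intervals: list[tuple[int, int]] = []
    for i in range(m):
        j = i
        while j + 1 < m and nonsig[i, j + 1]:
            j += 1
        # keep only maximal intervals (drop spans nested in the previous one)
        if not intervals or j > intervals[-1][1]:
            intervals.append((i, j))
    letters = [""] * m
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, (lo, hi) in enumerate(intervals):
        ch = alphabet[idx % len(alphabet)]
        for g in range(lo, hi + 1):
            letters[g] += ch
    out = pd.DataFrame(
        {"group": means.index, "n": sizes.loc[means.index].to_numpy(),
         "mean": mu, "letters": letters}
    )
    out.attrs["anova_p"] = anova_p
    return out
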