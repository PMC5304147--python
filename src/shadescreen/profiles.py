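"""Derived isoflavone totals, percentage composition and variability summaries.

A seed or leaf sample is described by twelve analyte concentrations in mg/g
dry weight.  From these the pipeline derives eight totals: the four
conjugation-form sums (T-e aglycones, T-g beta-glucosides, T-m
malonylglucosides, T-a acetylglucosides), the three skeleton-family sums
(To-G, To-D, To-GL) and the grand total.  Both the form partition and the
type partition sum exactly to the total; this conservation is asserted by
the test suite on every generated table.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .analytes import (
    ANALYTES,
    DERIVED,
    DERIVED_GROUPS,
    FORM_PARTITION,
    TYPE_PARTITION,
)

__all__ = [
    "derive_totals",
    "add_derived_totals",
    "percentage_composition",
    "variability_summary",
]


def derive_totals(concentrations: Sequence[float] | pd.Series) -> pd.Series:
    """Compute the eight derived totals from a single 12-analyte profile.

    Parameters
    ----------
    concentrations
        Either a sequence of 12 values in the canonical analyte order
        (``analytes.ANALYTES``) or a Series indexed by analyte code.

    Returns
    -------
    pandas.Series
        Indexed by ``("T-e", "T-g", "T-m", "T-a", "To-G", "To-D", "To-GL",
        "total")``, in mg/g.

    Raises
    ------
    ValueError
        If any concentration is negative or the vector is malformed.
    """
    if isinstance(concentrations, pd.Series):
        missing = set(ANALYTES) - set(concentrations.index)
        if missing:
            raise ValueError(f"missing analyte concentrations: {sorted(missing)}")
        values = concentrations.reindex(list(ANALYTES)).astype(float)
    else:
        arr = np.asarray(concentrations, dtype=float)
        if arr.shape != (len(ANALYTES),):
            raise ValueError(
                f"expected {len(ANALYTES)} concentrations, got shape {arr.shape}"
            )
        values = pd.Series(arr, index=list(ANALYTES))
    if (values < 0).any():
        bad = values[values < 0].index.tolist()
        raise ValueError(f"negative concentrations for {bad}")

    out = {name: float(values[list(group)].sum()) for name, group in DERIVED_GROUPS.items()}
    out["total"] = float(values.sum())
    return pd.Series(out, index=list(DERIVED))


def add_derived_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Append the eight derived-total columns to a concentration table.

    The input must contain the twelve analyte columns; metadata columns are
    passed through untouched.  Vectorised over rows.
    """
    missing = [a for a in ANALYTES if a not in table.columns]
    if missing:
        raise ValueError(f"concentration table missing analyte columns: {missing}")
    conc = table[list(ANALYTES)].astype(float)
    if (conc.to_numpy() < 0).any():
        raise ValueError("negative concentrations in table")
    out = table.copy()
    for name, group in DERIVED_GROUPS.items():
        out[name] = conc[list(group)].sum(axis=1)
    out["total"] = conc.sum(axis=1)
    return out


def percentage_composition(profile: Sequence[float] | pd.Series) -> pd.DataFrame:
    """Percentage of the total held by each conjugation form and each skeleton.

    Returns a frame with columns ``partition`` (``form`` or ``type``),
    ``component`` and ``percent``.  Within each partition the percentages sum
    to 100 (to numerical precision).

    Raises
    ------
    ValueError
        If the profile total is zero (composition undefined).
    """
    derived = (
        profile.reindex(list(DERIVED))
        if isinstance(profile, pd.Series) and set(DERIVED) <= set(profile.index)
        else derive_totals(profile)
    )
    total = float(derived["total"])
    if total <= 0:
        raise ValueError("percentage composition undefined for zero total")
    rows = []
    for name in FORM_PARTITION:
        rows.append(("form", name, 100.0 * float(derived[name]) / total))
    for name in TYPE_PARTITION:
        rows.append(("type", name, 100.0 * float(derived[name]) / total))
    return pd.DataFrame(rows, columns=["partition", "component", "percent"])


def variability_summary(
    table: pd.DataFrame,
    group_key: str | None = "genotype",
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-variable mean, sample standard deviation and CV%.

    When ``group_key`` is given the table is first collapsed to group means
    (by default germplasm means, the level at which between-genotype
    variability is usually quoted) and the summary describes dispersion
    across groups; pass ``None`` to summarise across raw rows.

    CV% is ``100 * sd / mean`` with the n-1 standard deviation.  Variables
    whose mean is zero get ``NaN`` CV.
    """
    if variables is None:
        variables = [c for c in table.columns if c in set(ANALYTES) | set(DERIVED)]
    if not variables:
        raise ValueError("no analyte or derived columns found to summarise")
    data = table[list(variables)].astype(float)
    if group_key is not None:
        if group_key not in table.columns:
            raise ValueError(f"group key {group_key!r} not in table")
        data = data.groupby(table[group_key], observed=True).mean()
    if len(data) < 2:
        raise ValueError("variability summary needs at least 2 rows (or groups)")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    cv = 100.0 * sd / mean.where(mean != 0, np.nan)
    return pd.DataFrame({"mean": mean, "sd": sd, "cv_percent": cv})
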