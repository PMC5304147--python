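"""Weighted index of sensitivity (WIS) for shade-tolerance screening.

Each agronomic trait yields a per-genotype sensitivity index

    IS = [(X_r - X_s) / X_s] / [(X_ar - X_as) / X_as]

where X_r / X_s are the genotype's trait means in the intercropped (IT) and
sole-cropped (SC) systems and X_ar / X_as are the corresponding averages
over all tested genotypes.  IS = 1 means the genotype responds like the
population average, IS = 0 means no response.  Traits are then combined
into a single score

    WIS = sum_i w_i * IS_i,    w_i = r_i / sum_j r_j

where r_i is the Pearson correlation between trait i's IS column and the
genotype-wise mean IS over all traits (negative r_i are floored at zero
before normalising, so a trait anti-correlated with overall sensitivity
gets no weight).  Higher WIS = more shade-sensitive; genotypes are binned
into tolerant (< 0.6), moderate ([0.6, 1.2]) and susceptible (> 1.2).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .synthetic import TRAITS

__all__ = [
    "sensitivity_index",
    "sensitivity_matrix",
    "trait_weights",
    "compute_wis",
    "classify_tolerance",
    "wis_report",
    "DEFAULT_THRESHOLDS",
]

logger = logging.getLogger(__name__)

#: (tolerant upper edge, susceptible lower edge); the closed middle interval
#: is classified moderate.
DEFAULT_THRESHOLDS: tuple[float, float] = (0.6, 1.2)
#: Minimum population relative response for a trait to be usable.
DEFAULT_EPSILON = 1e-6


def sensitivity_index(
    x_r: float, x_s: float, x_ar: float, x_as: float, epsilon: float = DEFAULT_EPSILON
) -> float:
    """Population-normalised sensitivity index of one genotype for one trait.

    Raises
    ------
    ValueError
        If a sole-cropping reference is non-positive, or the population
        relative response is below ``epsilon`` (trait unusable: the
        normaliser is effectively zero).
    """
    if x_s <= 0 or x_as <= 0:
        raise ValueError("sole-cropping trait values must be > 0")
    pop = (x_ar - x_as) / x_as
    if abs(pop) < epsilon:
        raise ValueError(
            f"population relative change {pop:.3g} below epsilon={epsilon:g}; trait unusable"
        )
    return ((x_r - x_s) / x_s) / pop


def sensitivity_matrix(
    traits: pd.DataFrame,
    trait_columns: tuple[str, ...] = TRAITS,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Build the genotypes x traits IS matrix from a plant-level trait table.

    ``traits`` needs columns ``genotype``, ``system`` (IT/SC) and the trait
    columns.  Plant rows are first averaged to genotype x system means; the
    population references X_ar / X_as are the unweighted means of those
    genotype means.  Traits whose population relative response is below
    ``epsilon`` are dropped with a warning.
    """
    required = {"genotype", "system"} | set(trait_columns)
    missing = required - set(traits.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    systems = set(traits["system"].unique())
    if not {"IT", "SC"} <= systems:
        raise ValueError(f"trait table must contain both IT and SC rows, has {systems}")
    means = traits.groupby(["genotype", "system"], observed=True)[list(trait_columns)].mean()
    it = means.xs("IT", level="system")
    sc = means.xs("SC", level="system")
    genotypes = it.index.intersection(sc.index)
    if len(genotypes) < 3:
        raise ValueError("need at least 3 genotypes with both systems")
    it, sc = it.loc[genotypes], sc.loc[genotypes]
    if (sc <= 0).any().any():
        raise ValueError("sole-cropping trait means must be > 0")
    x_ar, x_as = it.mean(axis=0), sc.mean(axis=0)
    pop = (x_ar - x_as) / x_as
    usable = pop.abs() >= epsilon
    if not usable.all():
        logger.warning("dropping traits with negligible population response: %s",
                       list(pop.index[~usable]))
    if not usable.any():
        raise ValueError("no usable traits: all population responses below epsilon")
    rel = (it - sc) / sc
    is_matrix = rel.loc[:, usable].div(pop[usable], axis=1)
    is_matrix.index.name = "genotype"
    return is_matrix


def trait_weights(is_matrix: pd.DataFrame, mode: str = "floor") -> pd.Series:
    """Correlation-derived trait weights.

    r_i = Pearson correlation of trait i's IS column with the genotype-wise
    mean IS vector.  ``mode="floor"`` (default) floors negative r_i at zero;
    ``mode="abs"`` uses |r_i|.  Weights are normalised to sum to 1.
    Zero-variance IS columns get r_i = 0 with a warning.
    """
    if is_matrix.shape[0] < 3 or is_matrix.shape[1] < 2:
        raise ValueError("need >= 3 genotypes and >= 2 traits for weights")
    if mode not in ("floor", "abs"):
        raise ValueError("mode must be 'floor' or 'abs'")
    mean_is = is_matrix.mean(axis=1)
    r = pd.Series(0.0, index=is_matrix.columns)
    for col in is_matrix.columns:
        x = is_matrix[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(mean_is) == 0:
            logger.warning("zero-variance IS column %r; weight set to 0", col)
            continue
        r[col] = np.corrcoef(x, mean_is.to_numpy(dtype=float))[0, 1]
    r = r.abs() if mode == "abs" else r.clip(lower=0.0)
    total = r.sum()
    if total <= 0:
        raise ValueError("degenerate weights: every trait correlation <= 0")
    return r / total


def compute_wis(is_matrix: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Per-genotype WIS = weighted sum of sensitivity indices."""
    if set(weights.index) != set(is_matrix.columns):
        raise ValueError("weights and IS matrix cover different trait sets")
    if abs(float(weights.sum()) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    wis = is_matrix.mul(weights.reindex(is_matrix.columns), axis=1).sum(axis=1)
    wis.name = "wis"
    return wis


def classify_tolerance(
    wis: float | pd.Series, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> str | pd.Series:
    """Bin WIS into tolerant (< lower), susceptible (> upper), else moderate."""
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError("thresholds must be ordered (lower < upper)")

    def _one(v: float) -> str:
        if not np.isfinite(v):
            raise ValueError("WIS must be finite")
        if v < lo:
            return "tolerant"
        if v > hi:
            return "susceptible"
        return "moderate"

    if isinstance(wis, pd.Series):
        return wis.map(_one).rename("tolerance_class")
    return _one(float(wis))


def wis_report(
    traits: pd.DataFrame,
    trait_columns: tuple[str, ...] = TRAITS,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    weight_mode: str = "floor",
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """End-to-end WIS analysis of a plant-level trait table.

    Returns one row per genotype: the per-trait IS values (``IS_<trait>``),
    the shared per-trait weights (``w_<trait>``), the WIS and the tolerance
    class, sorted by WIS ascending (most tolerant first).
    """
    is_matrix = sensitivity_matrix(traits, trait_columns, epsilon)
    weights = trait_weights(is_matrix, mode=weight_mode)
    wis = compute_wis(is_matrix, weights)
    report = is_matrix.rename(columns={t: f"IS_{t}" for t in is_matrix.columns})
    for t in is_matrix.columns:
        report[f"w_{t}"] = weights[t]
    report["wis"] = wis
    report["tolerance_class"] = classify_tolerance(wis, thresholds)
    return report.sort_values("wis").reset_index()
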