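"""Synthetic seed-profile, leaf-experiment and field-trial data.

The generators emulate the three datasets the screening pipeline consumes:

* seed isoflavone profiles of nine soybean germplasms falling into three
  shade-tolerance classes, with malonylglucosides + beta-glucosides
  dominating the seed total (>85%) and the aglycone fraction elevated in
  tolerant lines;
* a two-genotype (ND12 tolerant vs C103 susceptible) x two-light-condition
  (control CK vs shade) leaf experiment in which genistein (GE) is the only
  detectable aglycone;
* a plant-level agronomic trait trial under sole cropping (SC) and
  maize-soybean intercropping (IT), calibrated so the weighted index of
  sensitivity recovers a realistic 0.5-1.8 spread across genotypes.

All noise is drawn from a truncated-at-zero normal with standard deviation
``cv * mean``, so concentrations and trait values are never negative and the
relative dispersion is controlled per preset.  Every generator takes an
explicit integer seed; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .analytes import AGLYCONES, ANALYTES, GLUCOSIDES, MALONYLGLUCOSIDES

__all__ = [
    "GenotypePreset",
    "TraitPreset",
    "TRAITS",
    "load_presets",
    "seed_presets",
    "field_presets",
    "hplc_reference",
    "generate_seed_profiles",
    "generate_leaf_experiment",
    "generate_field_trial",
]

#: The six agronomic traits scored in both cropping systems.
TRAITS: tuple[str, ...] = (
    "main_stem_length",
    "avg_internode_length",
    "hypocotyl_length",
    "node_number",
    "stem_diameter",
    "breaking_strength",
)

TOLERANCE_CLASSES = ("tolerant", "moderate", "susceptible")


@dataclass(frozen=True)
class GenotypePreset:
    """Target concentration means for one germplasm.

    ``seed_means`` maps the 12 analyte codes to seed concentrations (mg/g);
    ``leaf_means_by_condition`` optionally maps {"CK", "shade"} to 12-analyte
    leaf means.  ``cv`` is the relative standard deviation applied to every
    analyte when sampling replicates.
    """

    name: str
    tolerance_class: str
    seed_means: dict[str, float] | None = None
    leaf_means_by_condition: dict[str, dict[str, float]] | None = None
    cv: float = 0.08

    def __post_init__(self) -> None:
        if self.tolerance_class not in TOLERANCE_CLASSES:
            raise ValueError(f"unknown tolerance class {self.tolerance_class!r}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        for means in self._all_mean_maps():
            missing = set(ANALYTES) - set(means)
            if missing:
                raise ValueError(f"{self.name}: missing analyte means {sorted(missing)}")
            if any(v < 0 for v in means.values()):
                raise ValueError(f"{self.name}: negative analyte mean")

    def _all_mean_maps(self) -> list[dict[str, float]]:
        maps = []
        if self.seed_means is not None:
            maps.append(self.seed_means)
        if self.leaf_means_by_condition is not None:
            maps.extend(self.leaf_means_by_condition.values())
        return maps


@dataclass(frozen=True)
class TraitPreset:
    """Agronomic trait means for one genotype under sole cropping and
    intercropping, plus the plant-level relative noise."""

    genotype: str
    trait_means_sc: dict[str, float]
    trait_means_it: dict[str, float]
    noise_cv: float = 0.025
    tolerance_class: str | None = field(default=None)

    def __post_init__(self) -> None:
        for means in (self.trait_means_sc, self.trait_means_it):
            missing = set(TRAITS) - set(means)
            if missing:
                raise ValueError(f"{self.genotype}: missing trait means {sorted(missing)}")
            if any(v <= 0 for v in means.values()):
                raise ValueError(f"{self.genotype}: trait means must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def load_presets() -> dict:
    """Load the bundled preset configuration (YAML) shipped with the package."""
    with resources.files("shadescreen.data").joinpath("presets.yaml").open() as fh:
        return yaml.safe_load(fh)


def seed_presets(name: str = "sichuan9") -> list[GenotypePreset]:
    """Bundled seed-profile preset set ``name`` as GenotypePreset objects."""
    cfg = load_presets()["seed_presets"]
    if name not in cfg:
        raise KeyError(f"unknown seed preset set {name!r}; have {sorted(cfg)}")
    block = cfg[name]
    return [
        GenotypePreset(
            name=g["name"],
            tolerance_class=g["tolerance_class"],
            seed_means={a: float(g["means"][a]) for a in ANALYTES},
            cv=float(block.get("cv", 0.08)),
        )
        for g in block["genotypes"]
    ]


def field_presets(name: str = "sichuan9") -> list[TraitPreset]:
    """Bundled field-trial preset set ``name`` as TraitPreset objects."""
    cfg = load_presets()["field_presets"]
    if name not in cfg:
        raise KeyError(f"unknown field preset set {name!r}; have {sorted(cfg)}")
    block = cfg[name]
    return [
        TraitPreset(
            genotype=g["genotype"],
            trait_means_sc={t: float(g["sc"][t]) for t in TRAITS},
            trait_means_it={t: float(g["it"][t]) for t in TRAITS},
            noise_cv=float(block.get("noise_cv", 0.025)),
            tolerance_class=g.get("tolerance_class"),
        )
        for g in block["genotypes"]
    ]


def hplc_reference() -> dict[str, dict[str, float]]:
    """Bundled synthetic HPLC reference: per-analyte retention time (min) and
    calibration slope/intercept (area per ug/mL).  These are invented
    plumbing values for demonstrations and round-trip checks, not measured
    instrument constants."""
    return {
        a: {k: float(v) for k, v in d.items()}
        for a, d in load_presets()["hplc_reference"].items()
    }


def _truncated_normal(
    rng: np.random.Generator, means: np.ndarray, sds: np.ndarray
) -> np.ndarray:
    """Draw one value per (mean, sd) pair from a normal truncated at zero.

    The mean/sd parametrise the underlying (untruncated) normal; with the
    small CVs used here the truncation bias is negligible.  sd == 0 entries
    pass the mean through exactly.
    """
    out = np.array(means, dtype=float, copy=True)
    mask = sds > 0
    if mask.any():
        a = (0.0 - means[mask]) / sds[mask]
        out[mask] = truncnorm.rvs(
            a, np.inf, loc=means[mask], scale=sds[mask], random_state=rng
        )
    return out


def generate_seed_profiles(
    presets: list[GenotypePreset],
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a seed concentration table: ``len(presets) * n_reps`` rows of
    12 analyte columns plus sample metadata.  Deterministic given ``seed``."""
    if not presets:
        raise ValueError("presets must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    for p in presets:
        if p.seed_means is None:
            raise ValueError(f"preset {p.name} has no seed means")
    rng = np.random.default_rng(seed)
    rows = []
    for p in presets:
        means = np.array([p.seed_means[a] for a in ANALYTES])
        sds = means * p.cv
        for rep in range(1, n_reps + 1):
            values = _truncated_normal(rng, means, sds)
            rows.append(
                {
                    "sample_id": f"{p.name}_seed_r{rep}",
                    "genotype": p.name,
                    "tissue": "seed",
                    "condition": "none",
                    "replicate": rep,
                    "tolerance_class": p.tolerance_class,
                    **dict(zip(ANALYTES, values)),
                }
            )
    return pd.DataFrame(rows)


def generate_leaf_experiment(seed: int = 0, n_reps: int = 3) -> pd.DataFrame:
    """Simulate the phytotron leaf experiment: genotypes {ND12, C103} x light
    conditions {CK, shade}.

    Cell means are anchored to the leaf observations the generator emulates:
    genistein (GE) is the only aglycone present (DE and GLE columns are
    exactly zero) and the non-GE mass is spread over the conjugated forms by
    a fixed documented split favouring malonylglucosides and glucosides.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = load_presets()["leaf_experiment"]
    cv = float(cfg["cv"])
    split = {a: float(v) for a, v in cfg["conjugate_split"].items()}
    if abs(sum(split.values()) - 1.0) > 1e-9:
        raise ValueError("leaf conjugate split must sum to 1")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in ("ND12", "C103"):
        for condition in ("CK", "shade"):
            ge = float(cfg["ge_means"][genotype][condition])
            total = float(cfg["total_means"][genotype][condition])
            means = {a: 0.0 for a in ANALYTES}
            means["GE"] = ge
            for a, frac in split.items():
                means[a] = (total - ge) * frac
            mean_vec = np.array([means[a] for a in ANALYTES])
            sd_vec = mean_vec * cv
            for rep in range(1, n_reps + 1):
                values = _truncated_normal(rng, mean_vec, sd_vec)
                rows.append(
                    {
                        "sample_id": f"{genotype}_leaf_{condition}_r{rep}",
                        "genotype": genotype,
                        "tissue": "leaf",
                        "condition": condition,
                        "replicate": rep,
                        **dict(zip(ANALYTES, values)),
                    }
                )
    return pd.DataFrame(rows)


def generate_field_trial(
    trait_presets: list[TraitPreset],
    n_plants: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate plant-level agronomic measurements under SC and IT.

    Requires at least three genotypes (the sensitivity-index weights are
    cross-genotype correlations).  Rows are individual plants; ten plants per
    genotype x system is the default scoring effort.
    """
    if len(trait_presets) < 3:
        raise ValueError("need at least 3 genotypes for a field trial")
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for p in trait_presets:
        for system, means_map in (("SC", p.trait_means_sc), ("IT", p.trait_means_it)):
            means = np.array([means_map[t] for t in TRAITS])
            sds = means * p.noise_cv
            for plant in range(1, n_plants + 1):
                values = _truncated_normal(rng, means, sds)
                rows.append(
                    {
                        "genotype": p.genotype,
                        "system": system,
                        "plant_id": plant,
                        **dict(zip(TRAITS, values)),
                    }
                )
    return pd.DataFrame(rows)


def seed_fraction_check(table: pd.DataFrame) -> pd.Series:
    """Per-row (malonylglucoside + glucoside) fraction of the total, used to
    verify the dominant-conjugate structure of generated seed tables."""
    conc = table[list(ANALYTES)]
    dominant = conc[list(MALONYLGLUCOSIDES) + list(GLUCOSIDES)].sum(axis=1)
    return dominant / conc.sum(axis=1)


def aglycone_fraction(table: pd.DataFrame) -> pd.Series:
    """Per-row aglycone (T-e) fraction of the total."""
    conc = table[list(ANALYTES)]
    return conc[list(AGLYCONES)].sum(axis=1) / conc.sum(axis=1)
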