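"""Table readers/writers, run configuration, the packaged nine-germplasm
reference table, and the end-to-end screening run.

All tables travel as CSV.  Concentration tables carry sample metadata
(sample_id, genotype, tissue, condition, replicate) followed by the twelve
analyte columns; trait tables carry genotype, system (IT/SC), plant_id and
the six agronomic traits.  Every writer/reader pair round-trips without
loss, and a screening run is a pure function of (inputs, config), so reruns
are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .analytes import AGLYCONES, ANALYTES
from .opls import cross_validate, export_scores_loadings, fit_opls_da
from .profiles import add_derived_totals
from .synthetic import TRAITS
from .wis import DEFAULT_THRESHOLDS, classify_tolerance, wis_report
from .corrstats import correlate_with_wis

__all__ = [
    "read_concentration_table",
    "write_concentration_table",
    "read_trait_table",
    "write_trait_table",
    "load_reference_germplasms",
    "RunConfig",
    "load_config",
    "run_screen",
]

_CONC_META = ["sample_id", "genotype", "tissue", "condition", "replicate"]


def read_concentration_table(path: str | Path) -> pd.DataFrame:
    """Read a concentration CSV, validating the twelve analyte columns."""
    table = pd.read_csv(path)
    missing = [c for c in ANALYTES if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing analyte columns {missing}")
    if table.empty:
        raise ValueError(f"{path}: empty concentration table")
    for col in ("sample_id", "genotype"):
        if col in table.columns:
            table[col] = table[col].astype(str)
    return table


def write_concentration_table(table: pd.DataFrame, path: str | Path) -> None:
    meta = [c for c in _CONC_META if c in table.columns]
    extra = [c for c in table.columns if c not in meta and c not in ANALYTES]
    table[meta + list(ANALYTES) + extra].to_csv(path, index=False)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a plant-level trait CSV (genotype, system, plant_id, 6 traits)."""
    table = pd.read_csv(path)
    missing = [c for c in ("genotype", "system", *TRAITS) if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing trait-table columns {missing}")
    if table.empty:
        raise ValueError(f"{path}: empty trait table")
    bad = set(table["system"].unique()) - {"IT", "SC"}
    if bad:
        raise ValueError(f"{path}: unknown cropping system labels {sorted(bad)}")
    table["genotype"] = table["genotype"].astype(str)
    return table


def write_trait_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["genotype", "system"] + (["plant_id"] if "plant_id" in table.columns else [])
    table[cols + list(TRAITS)].to_csv(path, index=False)


def load_reference_germplasms() -> pd.DataFrame:
    """The packaged reference table of nine soybean germplasms: code, name,
    geographic origin, published WIS value and cultivar/wild note."""
    with resources.files("shadescreen.data").joinpath("germplasm_panel.csv").open() as fh:
        table = pd.read_csv(fh, dtype={"code": str})
    assert len(table) == 9
    return table


@dataclass
class RunConfig:
    """Settings for an end-to-end screening run."""

    seed: int = 0
    preset: str = "sichuan9"
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
    scaling: str = "uv"
    k_folds: int = 7
    n_predictive: int | None = None
    n_orthogonal: int = 1
    alphas: tuple[float, float] = (0.05, 0.01)
    out_dir: str = "screen_out"

    def __post_init__(self) -> None:
        lo, hi = self.thresholds
        if not lo < hi:
            raise ValueError("thresholds must be ordered")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not all(0 < a < 1 for a in self.alphas):
            raise ValueError("alpha levels must be in (0, 1)")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("thresholds", "alphas"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def run_screen(
    config: RunConfig,
    concentrations: pd.DataFrame,
    wis: pd.Series | None = None,
    class_col: str = "tolerance_class",
) -> dict[str, Path]:
    """Chain the full screening pipeline and write the report bundle.

    Derived profiles are computed from the concentration table; class labels
    come either from classifying a per-genotype ``wis`` series with the
    configured thresholds, or from an existing ``class_col``.  An OPLS-DA
    model is fitted on the 20-variable block, cross-validated, and exported;
    candidates are ranked by aglycone percentage of the total (genistein
    percentage breaking ties), the screening statistic for shade tolerance.
    Returns the mapping of artifact name -> written path.
    """
    if concentrations.empty:
        raise ValueError("empty concentration table")
    profiles = add_derived_totals(concentrations)
    if wis is not None:
        classes = classify_tolerance(wis, config.thresholds)
        labels = profiles["genotype"].map(classes)
        if labels.isna().any():
            missing = sorted(profiles.loc[labels.isna(), "genotype"].unique())
            raise ValueError(f"no WIS value for genotypes: {missing}")
    elif class_col in profiles.columns:
        labels = profiles[class_col]
    else:
        raise ValueError(f"need either a WIS series or a {class_col!r} column")

    variables = list(ANALYTES) + [c for c in profiles.columns
                                  if c in ("T-e", "T-g", "T-m", "T-a", "To-G", "To-D", "To-GL", "total")]
    X = profiles[variables]
    sample_ids = (profiles["sample_id"].astype(str).tolist()
                  if "sample_id" in profiles.columns else None)
    model = fit_opls_da(
        X, labels, n_predictive=config.n_predictive,
        n_orthogonal=config.n_orthogonal, scaling=config.scaling,
        sample_ids=sample_ids,
    )
    model.q2 = cross_validate(
        X, labels, n_predictive=config.n_predictive,
        n_orthogonal=config.n_orthogonal, k_folds=config.k_folds,
        scaling=config.scaling,
    )
    scores, loadings = export_scores_loadings(model)

    # Candidate ranking: aglycone share of the total, GE share as tie-break.
    geno = profiles.groupby("genotype", observed=True)[variables].mean()
    candidates = pd.DataFrame(
        {
            "genotype": geno.index,
            "aglycone_percent": 100.0 * geno[list(AGLYCONES)].sum(axis=1) / geno["total"],
            "GE_percent": 100.0 * geno["GE"] / geno["total"],
            "total_mg_g": geno["total"],
        }
    ).sort_values(
        ["aglycone_percent", "GE_percent"], ascending=False
    ).reset_index(drop=True)
    candidates["rank"] = candidates.index + 1

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, frame: pd.DataFrame) -> None:
        p = out_dir / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p

    _write("profiles", profiles)
    _write("scores", scores)
    _write("loadings", loadings)
    _write("candidates", candidates)
    if wis is not None:
        corr = correlate_with_wis(geno, wis, alphas=config.alphas)
        _write("correlation", corr)
    summary_path = out_dir / "model_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(model.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["model_summary"] = summary_path
    return paths
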