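"""Readers, writers and run configuration.

All files are plain CSV (comma separated, header row, UTF-8, ``NA`` for
missing) with documented schemas:

* map:        ``marker, chromosome, position_cM``
* genotypes:  ``individual, is_parent, <marker>...`` with dosages 0/1/2 or NA
* crosses:    ``individual, cross, parent1, parent2``
* phenotypes: ``genotype, cross, env, rep, block, check, trait``
* covariate:  ``environment, covariate, value``

``read_inputs`` cross-validates the bundle (every phenotyped entry must be
genotyped and assigned to a cross; the map must cover every marker) and
fails with a report naming the offending ids.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .envcov import EnvCovariate
from .markers import CrossTable, GeneticMap, MarkerMatrix
from .scan import QtlModel, ScanProfile
from .stage_one import PlotTable

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "InputBundle",
    "read_map",
    "read_genotypes",
    "read_crosses",
    "read_plots",
    "read_covariate",
    "read_inputs",
    "write_profile",
    "read_profile",
    "write_qtl_model",
    "write_results",
]


@dataclass
class RunConfig:
    """Paths and settings for a pipeline run (loadable from YAML)."""

    map_file: str
    geno_file: str
    cross_file: str
    pheno_file: str
    covariate_file: str | None = None
    covariate_name: str = "precipitation"
    central_parent: str = ""
    trait: str = "trait"
    method: str = "M3"
    allele_model: str = "parental"
    threshold: float = 4.0
    cofactor_dist_cM: float = 50.0
    qtl_dist_cM: float = 20.0
    merge_dist_cM: float = 10.0
    seed: int = 1
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class InputBundle:
    gmap: GeneticMap
    geno: MarkerMatrix
    crosses: CrossTable
    plots: PlotTable
    covariate: EnvCovariate | None = None


def read_map(path: str | Path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path))


def read_genotypes(path: str | Path) -> MarkerMatrix:
    df = pd.read_csv(path, na_values=["NA"])
    if "individual" not in df.columns or "is_parent" not in df.columns:
        raise ValueError("genotype file needs 'individual' and 'is_parent' columns")
    df = df.set_index("individual")
    is_parent = df.pop("is_parent").astype(bool)
    scores = df.loc[~is_parent].astype(float)
    parent_scores = df.loc[is_parent].astype(float)
    return MarkerMatrix(scores, parent_scores)


def read_crosses(path: str | Path, central_parent: str) -> CrossTable:
    df = pd.read_csv(path)
    need = {"individual", "cross", "parent1", "parent2"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"cross file missing columns: {sorted(missing)}")
    ind_cross = df.set_index("individual")["cross"].astype(str)
    parents = {
        str(r["cross"]): (str(r["parent1"]), str(r["parent2"]))
        for _, r in df.drop_duplicates("cross").iterrows()
    }
    return CrossTable(ind_cross, parents, central_parent)


def read_plots(path: str | Path, trait: str = "trait") -> PlotTable:
    df = pd.read_csv(path)
    if trait != "trait":
        if trait not in df.columns:
            raise ValueError(f"trait column {trait!r} absent from phenotype file")
        df = df.rename(columns={trait: "trait"})
    df["check"] = df["check"].astype(bool)
    dup = df.duplicated(["genotype", "env", "rep", "block"], keep=False)
    if dup.any():
        bad = df.loc[dup, ["genotype", "env", "rep", "block"]].drop_duplicates()
        raise ValueError(
            f"duplicated plots (genotype, env, rep, block): {bad.to_dict('records')[:5]}"
        )
    return PlotTable(df)


def read_covariate(
    path: str | Path, name: str, reference_environment: str | None = None
) -> EnvCovariate:
    df = pd.read_csv(path)
    need = {"environment", "covariate", "value"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"covariate file missing columns: {sorted(missing)}")
    sub = df[df["covariate"].astype(str) == name]
    if sub.empty:
        raise ValueError(f"covariate {name!r} absent from file")
    values = dict(zip(sub["environment"].astype(str), sub["value"].astype(float)))
    return EnvCovariate(values, name=name, reference_environment=reference_environment)


def read_inputs(config: RunConfig) -> InputBundle:
    """Load and cross-validate the full input bundle."""
    gmap = read_map(config.map_file)
    geno = read_genotypes(config.geno_file)
    crosses = read_crosses(config.cross_file, config.central_parent)
    plots = read_plots(config.pheno_file, config.trait)
    problems: list[str] = []
    map_markers = set(gmap.markers)
    not_mapped = [m for m in geno.markers if m not in map_markers]
    if not_mapped:
        problems.append(f"markers absent from map: {not_mapped[:10]}")
    genotyped = set(geno.individuals)
    entries = plots.entries()["genotype"].astype(str).unique()
    unknown = [g for g in entries if g not in genotyped]
    if unknown:
        problems.append(f"phenotyped entries without genotypes: {unknown[:10]}")
    in_cross = set(crosses.individual_cross.index.astype(str))
    no_cross = [g for g in entries if g not in in_cross]
    if no_cross:
        problems.append(f"phenotyped entries without a cross: {no_cross[:10]}")
    if problems:
        raise ValueError("inconsistent inputs:\n  " + "\n  ".join(problems))
    cov = None
    if config.covariate_file:
        cov = read_covariate(config.covariate_file, config.covariate_name)
    return InputBundle(gmap, geno, crosses, plots, cov)


def write_profile(profile: ScanProfile, path: str | Path) -> None:
    profile.table.to_csv(path, index=False)


def read_profile(
    path: str | Path, method: str = "", allele_model: str = ""
) -> ScanProfile:
    return ScanProfile(pd.read_csv(path), method, allele_model)


def write_qtl_model(model: QtlModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)


def write_results(
    outdir: str | Path,
    config: RunConfig | None = None,
    profiles: dict[str, ScanProfile] | None = None,
    models: dict[str, QtlModel] | None = None,
) -> None:
    """Write profiles (CSV), QTL models (JSON) and a run manifest enabling
    an exact rerun."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, profile in (profiles or {}).items():
        write_profile(profile, out / f"profile_{name}.csv")
    for name, model in (models or {}).items():
        write_qtl_model(model, out / f"qtl_model_{name}.json")
    manifest = {
        "package": "mppme",
        "version": _version(),
        "config": config.to_dict() if config else None,
        "seed": config.seed if config else None,
        "outputs": sorted(
            [f"profile_{k}.csv" for k in (profiles or {})]
            + [f"qtl_model_{k}.json" for k in (models or {})]
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("mppme")
    except Exception:  # pragma: no cover
        return "unknown"
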