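"""Stage-one analysis: genotype BLUEs from plot-level phenotype data.

Field trials are laid out per environment as augmented p-rep designs:
replicates split into incomplete blocks, a fraction of the entries
replicated, and repeated check genotypes.  The plot model is

    y_icep = mu + E_e + rep_l(e) + block_m(le) + G_ic + GE_ice + eps_icep

with environment and genotype fixed, replicate and block random (one
variance each across environments), a homogeneous genotype-by-environment
variance, and an iid plot error.  The genotype term is partitioned into
checks and entries; entry effects are the quantities of interest.  Fitting
the model jointly over environments yields best linear unbiased estimates
(BLUEs) of the genotype main effect across environments; dropping the
environment terms and fitting a single environment yields within-
environment BLUEs, the inputs of the multi-environment QTL models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed import VcovSpec, reml_fit

logger = logging.getLogger(__name__)

__all__ = ["PlotTable", "BlueTable", "fit_blues_joint", "fit_blues_within"]

_PLOT_COLUMNS = ["genotype", "cross", "env", "rep", "block", "check", "trait"]


@dataclass
class PlotTable:
    """Plot-level phenotype records.

    Columns: ``genotype``, ``cross``, ``env``, ``rep``, ``block`` (nested in
    replicate within environment), ``check`` (bool), ``trait`` (value).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_PLOT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"plot table missing columns: {sorted(missing)}")
        self.data = self.data.reset_index(drop=True)

    @property
    def environments(self) -> list[str]:
        return sorted(self.data["env"].astype(str).unique().tolist())

    def entries(self) -> pd.DataFrame:
        return self.data[~self.data["check"].astype(bool)]


@dataclass
class BlueTable:
    """Genotype BLUEs, one row per genotype (x environment when
    environment-specific).  ``environment`` is ``"ALL"`` for joint BLUEs."""

    data: pd.DataFrame  # columns: genotype, cross, environment, blue, se


def _indicator(labels: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(labels.astype(str))
    Z = np.zeros((len(codes), codes.max() + 1))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _design(df: pd.DataFrame, with_env: bool) -> tuple[pd.DataFrame, list[str]]:
    """Fixed-effect design: intercept, environment (reference drop), check
    genotype dummies, entry genotype dummies (reference drop).  Returns the
    design and the list of entry genotypes (including the reference)."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    if with_env:
        envs = sorted(df["env"].astype(str).unique())
        for e in envs[1:]:
            cols[f"env[{e}]"] = (df["env"].astype(str) == e).to_numpy(float)
    checks = sorted(df.loc[df["check"].astype(bool), "genotype"].astype(str).unique())
    for g in checks:
        cols[f"check[{g}]"] = (
            (df["genotype"].astype(str) == g) & df["check"].astype(bool)
        ).to_numpy(float)
    entries = sorted(df.loc[~df["check"].astype(bool), "genotype"].astype(str).unique())
    for g in entries[1:]:
        cols[f"geno[{g}]"] = (
            (df["genotype"].astype(str) == g) & ~df["check"].astype(bool)
        ).to_numpy(float)
    return pd.DataFrame(cols), entries


def _blues_from_fit(fit, df: pd.DataFrame, entries: list[str], env_label: str,
                    n_env_avg: list[str] | None) -> BlueTable:
    """Assemble entry BLUEs as intercept + mean environment effect +
    genotype effect (the reference environment and genotype contribute
    zero, so ``beta.get`` covers them)."""
    base = float(fit.beta.get("intercept", 0.0))
    if n_env_avg:
        env_eff = [float(fit.beta.get(f"env[{e}]", 0.0)) for e in n_env_avg]
        base += float(np.mean(env_eff))  # includes the reference's zero
    ent = df.loc[~df["check"].astype(bool)]
    cross_of = ent.groupby(ent["genotype"].astype(str))["cross"].first()
    rows = []
    for g in entries:
        eff = float(fit.beta.get(f"geno[{g}]", 0.0))
        se = 0.0
        key = f"geno[{g}]"
        if key in fit.cov_beta.index:
            se = float(np.sqrt(fit.cov_beta.loc[key, key]))
        rows.append(
            {
                "genotype": g,
                "cross": str(cross_of.get(g, "")),
                "environment": env_label,
                "blue": base + eff,
                "se": se,
            }
        )
    return BlueTable(pd.DataFrame(rows))


def fit_blues_joint(plots: PlotTable, ols: bool = False) -> BlueTable:
    """Across-environment genotype BLUEs from the joint plot model.

    Requires >= 2 environments.  ``ols=True`` forces all random variances to
    zero (ordinary least squares), mainly for validation: the BLUEs then
    reduce to least-squares cell means.
    """
    df = plots.data
    envs = plots.environments
    if len(envs) < 2:
        raise ValueError("joint BLUEs require at least two environments")
    X, entries = _design(df, with_env=True)
    y = df["trait"].to_numpy(dtype=float)
    if ols:
        spec = VcovSpec.iid(len(df))
    else:
        spec = VcovSpec.iid(len(df))
        rep = df["env"].astype(str) + ":" + df["rep"].astype(str)
        blk = rep + ":" + df["block"].astype(str)
        ge = df["genotype"].astype(str) + ":" + df["env"].astype(str)
        spec = spec.with_random("replicate", _indicator(rep))
        spec = spec.with_random("block", _indicator(blk))
        spec = spec.with_random("ge", _indicator(ge))
    fit = reml_fit(y, X, spec)
    if not fit.converged:
        logger.warning("stage-one joint fit did not converge")
    return _blues_from_fit(fit, df, entries, "ALL", envs)


def fit_blues_within(plots: PlotTable, environment: str, ols: bool = False) -> BlueTable:
    """Within-environment genotype BLUEs (environment and GxE terms
    dropped from the joint model)."""
    df = plots.data
    mask = df["env"].astype(str) == str(environment)
    if not mask.any():
        raise ValueError(f"environment {environment!r} not present in plot data")
    df = df.loc[mask].reset_index(drop=True)
    X, entries = _design(df, with_env=False)
    y = df["trait"].to_numpy(dtype=float)
    if ols:
        spec = VcovSpec.iid(len(df))
    else:
        spec = VcovSpec.iid(len(df))
        rep = df["rep"].astype(str)
        blk = rep + ":" + df["block"].astype(str)
        spec = spec.with_random("replicate", _indicator(rep))
        spec = spec.with_random("block", _indicator(blk))
    fit = reml_fit(y, X, spec)
    if not fit.converged:
        logger.warning("stage-one fit for %s did not converge", environment)
    return _blues_from_fit(fit, df, entries, str(environment), None)
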