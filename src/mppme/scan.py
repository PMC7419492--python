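"""Genome scans and multi-QTL model building for methods M1-M4.

The four detection methods share one scan machinery and differ in the data
vector and covariance structure:

* M1 — across-environment genotype BLUEs; QTL main effects only;
  cross-specific residual variances.
* M2 — within-environment BLUEs, one separate analysis per environment;
  cross-specific residual variances.
* M3 — the within-environment BLUE vectors stacked and analysed jointly;
  environment-specific QTL and cross effects; compound-symmetry genotype
  covariance with environment cross-specific errors (CS + ECSE).
* M4 — one-stage analysis of the raw plot data; as M3 plus random replicate
  and block design effects.

The detection procedure is: a simple interval mapping (SIM) scan to pick
cofactors (greedy, minimum 50 cM apart), a composite interval mapping (CIM)
scan conditioning on cofactors outside an exclusion window, greedy QTL
selection (minimum 20 cM apart), and backward elimination of the candidate
list in a joint multi-QTL model.  Significance is the Wald chi-square of
the position's allele-substitution block; the default threshold is
-log10(p) = 4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import AlleleDesign, build_design
from .ibd import AncestralClustering, IbdResult
from .markers import CrossTable, GeneticMap, MarkerMatrix
from .mixed import MixedFit, VcovSpec, WaldResult, reml_fit, wald_test
from .stage_one import BlueTable, PlotTable

logger = logging.getLogger(__name__)

__all__ = [
    "MethodData",
    "ScanProfile",
    "QtlModel",
    "designs_genomewide",
    "sim_scan",
    "cim_scan",
    "select_cofactors",
    "select_qtls",
    "backward_elimination",
    "consolidate_qtls",
]

DEFAULT_THRESHOLD = 4.0
DEFAULT_COFACTOR_DIST = 50.0
DEFAULT_QTL_DIST = 20.0
DEFAULT_MERGE_DIST = 10.0


# --------------------------------------------------------------------------
# method data assembly


@dataclass
class MethodData:
    """Response vector, structural fixed effects and covariance layout for
    one detection method.

    ``envs`` lists the environments over which QTL effects are expanded
    (empty for main-effect coding as in M1/M2); ``genotype`` and ``env``
    give each observation's genotype and environment for aligning QTL
    dosage columns.
    """

    method: str
    y: np.ndarray
    base_X: pd.DataFrame
    spec: VcovSpec
    genotype: pd.Series
    env: pd.Series
    envs: list[str]
    environment: str | None = None  # for M2: which environment this is

    def qtl_columns(self, design: AlleleDesign, prefix: str = "qtl") -> pd.DataFrame:
        """QTL dosage columns aligned with the observation rows; expanded
        per environment when the method estimates environment-specific
        effects.  Genotypes absent from the design (checks) get zeros."""
        D = design.dosages.reindex(self.genotype.to_numpy()).fillna(0.0)
        cols: dict[str, np.ndarray] = {}
        if self.envs:
            env = self.env.to_numpy()
            for a in design.allele_labels:
                xa = D[a].to_numpy()
                for e in self.envs:
                    cols[f"{prefix}[{a}]@{e}"] = xa * (env == e)
        else:
            for a in design.allele_labels:
                cols[f"{prefix}[{a}]"] = D[a].to_numpy()
        return pd.DataFrame(cols, index=self.base_X.index)


def _cross_dummies(cross: pd.Series, prefix: str = "cross") -> pd.DataFrame:
    levels = sorted(cross.astype(str).unique())
    return pd.DataFrame(
        {
            f"{prefix}[{c}]": (cross.astype(str) == c).to_numpy(float)
            for c in levels[1:]
        }
    )


def method_data_m1(blues: BlueTable) -> MethodData:
    """Across-environment BLUEs with cross fixed effects and cross-specific
    residual variances (method M1)."""
    df = blues.data.reset_index(drop=True)
    X = pd.concat(
        [pd.DataFrame({"intercept": np.ones(len(df))}), _cross_dummies(df["cross"])],
        axis=1,
    )
    spec = VcovSpec.cross_specific(df["cross"])
    return MethodData(
        "M1",
        df["blue"].to_numpy(float),
        X,
        spec,
        df["genotype"].astype(str),
        df["environment"].astype(str),
        envs=[],
    )


def method_data_m2(blues_within: BlueTable, environment: str) -> MethodData:
    """Single-environment BLUEs (method M2, one instance per environment)."""
    df = blues_within.data
    df = df[df["environment"].astype(str) == str(environment)].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no BLUEs for environment {environment!r}")
    X = pd.concat(
        [pd.DataFrame({"intercept": np.ones(len(df))}), _cross_dummies(df["cross"])],
        axis=1,
    )
    spec = VcovSpec.cross_specific(df["cross"])
    return MethodData(
        "M2",
        df["blue"].to_numpy(float),
        X,
        spec,
        df["genotype"].astype(str),
        df["environment"].astype(str),
        envs=[],
        environment=str(environment),
    )


def _env_cross_fixed(df: pd.DataFrame) -> pd.DataFrame:
    """Intercept + environment main effects + environment-specific cross
    effects (reference cross dropped within each environment)."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    envs = sorted(df["env"].astype(str).unique())
    for e in envs[1:]:
        cols[f"env[{e}]"] = (df["env"].astype(str) == e).to_numpy(float)
    crosses = sorted(df["cross"].astype(str).unique())
    for e in envs:
        in_e = (df["env"].astype(str) == e).to_numpy()
        for c in crosses[1:]:
            cols[f"cross[{c}]@{e}"] = (
                in_e & (df["cross"].astype(str) == c).to_numpy()
            ).astype(float)
    return pd.DataFrame(cols)


def method_data_m3(blue_tables: list[BlueTable]) -> MethodData:
    """Stacked within-environment BLUEs with CS + ECSE covariance
    (method M3)."""
    frames = [t.data for t in blue_tables]
    df = pd.concat(frames, axis=0, ignore_index=True)
    df = df.rename(columns={"environment": "env"})
    envs = sorted(df["env"].astype(str).unique())
    X = _env_cross_fixed(df)
    spec = VcovSpec.cs_ecse(df["genotype"], df["cross"], df["env"])
    return MethodData(
        "M3",
        df["blue"].to_numpy(float),
        X,
        spec,
        df["genotype"].astype(str),
        df["env"].astype(str),
        envs=envs,
    )


def method_data_m4(plots: PlotTable) -> MethodData:
    """One-stage plot-data model: environment-specific cross and QTL fixed
    effects, random replicate and block, CS genotype covariance and ECSE
    residuals (method M4).  Check plots keep their own fixed effects and a
    per-environment residual stratum."""
    df = plots.data.reset_index(drop=True)
    envs = sorted(df["env"].astype(str).unique())
    is_check = df["check"].astype(bool)
    ent = df.loc[~is_check]
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    for e in envs[1:]:
        cols[f"env[{e}]"] = (df["env"].astype(str) == e).to_numpy(float)
    crosses = sorted(ent["cross"].astype(str).unique())
    for e in envs:
        in_e = (df["env"].astype(str) == e).to_numpy()
        for c in crosses[1:]:
            cols[f"cross[{c}]@{e}"] = (
                in_e & (df["cross"].astype(str) == c).to_numpy() & ~is_check.to_numpy()
            ).astype(float)
    for g in sorted(df.loc[is_check, "genotype"].astype(str).unique()):
        cols[f"check[{g}]"] = (
            (df["genotype"].astype(str) == g) & is_check
        ).to_numpy(float)
    X = pd.DataFrame(cols)

    def _ind(labels: pd.Series) -> np.ndarray:
        codes, _ = pd.factorize(labels.astype(str))
        Z = np.zeros((len(codes), codes.max() + 1))
        Z[np.arange(len(codes)), codes] = 1.0
        return Z

    cross_cell = df["cross"].astype(str).where(~is_check, "CHECK")
    spec = VcovSpec.cs_ecse(df["genotype"], cross_cell, df["env"])
    rep = df["env"].astype(str) + ":" + df["rep"].astype(str)
    blk = rep + ":" + df["block"].astype(str)
    spec = spec.with_random("replicate", _ind(rep))
    spec = spec.with_random("block", _ind(blk))
    geno = df["genotype"].astype(str).where(~is_check, "")
    return MethodData(
        "M4",
        df["trait"].to_numpy(float),
        X,
        spec,
        geno,
        df["env"].astype(str),
        envs=envs,
    )


# --------------------------------------------------------------------------
# genome-wide allele designs


def designs_genomewide(
    model: str,
    gmap: GeneticMap,
    cross_table: CrossTable,
    ibd: dict[str, IbdResult] | None = None,
    clustering: AncestralClustering | None = None,
    geno: MarkerMatrix | None = None,
    positions: list[str] | None = None,
) -> dict[str, AlleleDesign]:
    """Allele design at every marker of the map (or a subset)."""
    out = {}
    for marker in positions if positions is not None else gmap.markers:
        out[marker] = build_design(
            marker, model, cross_table, ibd=ibd, clustering=clustering, geno=geno
        )
    return out


# --------------------------------------------------------------------------
# scan profiles


@dataclass
class ScanProfile:
    """Genome-wide -log10(p) profile of the QTL Wald test."""

    table: pd.DataFrame  # columns: marker, chromosome, position_cM, neglog10p
    method: str
    allele_model: str
    environment: str | None = None

    def peak(self) -> pd.Series:
        t = self.table.dropna(subset=["neglog10p"])
        return t.loc[t["neglog10p"].idxmax()]


def _scan(
    md: MethodData,
    designs: dict[str, AlleleDesign],
    gmap: GeneticMap,
    allele_model: str,
    cofactors: list[str] | None = None,
    exclusion_cM: float = DEFAULT_COFACTOR_DIST,
) -> ScanProfile:
    tab = gmap.table[gmap.table["marker"].isin(designs.keys())]
    chrom_of = dict(zip(tab["marker"], tab["chromosome"]))
    pos_of = dict(zip(tab["marker"], tab["position_cM"]))
    cof_cols = {}
    if cofactors:
        for j, cm in enumerate(cofactors):
            cof_cols[cm] = md.qtl_columns(designs[cm], prefix=f"cof{j}")
    rows = []
    warm: np.ndarray | None = None
    for marker in tab["marker"]:
        parts = [md.base_X]
        if cofactors:
            for cm in cofactors:
                same = chrom_of[cm] == chrom_of[marker]
                if same and abs(pos_of[cm] - pos_of[marker]) <= exclusion_cM:
                    continue
                parts.append(cof_cols[cm])
        qcols = md.qtl_columns(designs[marker])
        parts.append(qcols)
        X = pd.concat(parts, axis=1)
        try:
            fit = reml_fit(
                md.y, X, md.spec, start=warm, multistart=warm is None
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("position %s: fit failed (%s)", marker, exc)
            rows.append((marker, chrom_of[marker], pos_of[marker], np.nan))
            continue
        if not fit.converged:
            logger.warning("position %s: REML did not converge", marker)
            rows.append((marker, chrom_of[marker], pos_of[marker], np.nan))
            warm = None
            continue
        warm = np.array([fit.varcomps[k] for k in md.spec.param_names])
        tested = [c for c in qcols.columns if c in fit.beta.index]
        w = wald_test(fit, tested)
        rows.append((marker, chrom_of[marker], pos_of[marker], w.neglog10p))
    table = pd.DataFrame(
        rows, columns=["marker", "chromosome", "position_cM", "neglog10p"]
    )
    return ScanProfile(table, md.method, allele_model, md.environment)


def sim_scan(
    md: MethodData,
    designs: dict[str, AlleleDesign],
    gmap: GeneticMap,
    allele_model: str,
) -> ScanProfile:
    """Simple interval mapping: the method's model with a single QTL term at
    each map position."""
    return _scan(md, designs, gmap, allele_model)


def cim_scan(
    md: MethodData,
    designs: dict[str, AlleleDesign],
    gmap: GeneticMap,
    allele_model: str,
    cofactors: list[str],
    exclusion_cM: float = DEFAULT_COFACTOR_DIST,
) -> ScanProfile:
    """Composite interval mapping: as SIM but conditioning on cofactor QTL
    terms, omitting cofactors within ``exclusion_cM`` of the tested position
    on its chromosome."""
    return _scan(md, designs, gmap, allele_model, cofactors, exclusion_cM)


# --------------------------------------------------------------------------
# greedy position selection


def _greedy_select(
    profile: ScanProfile, threshold: float, min_dist_cM: float
) -> list[str]:
    t = profile.table.dropna(subset=["neglog10p"])
    t = t[t["neglog10p"] >= threshold]
    # deterministic order: best value first, ties to smallest chrom then cM
    t = t.sort_values(
        ["neglog10p", "chromosome", "position_cM"],
        ascending=[False, True, True],
        kind="stable",
    )
    chosen: list[tuple[str, int, float]] = []
    for _, row in t.iterrows():
        ok = all(
            not (row["chromosome"] == ch and abs(row["position_cM"] - pos) < min_dist_cM)
            for _, ch, pos in chosen
        )
        if ok:
            chosen.append((row["marker"], row["chromosome"], row["position_cM"]))
    chosen.sort(key=lambda x: (x[1], x[2]))
    return [m for m, _, _ in chosen]


def select_cofactors(
    profile: ScanProfile,
    threshold: float = DEFAULT_THRESHOLD,
    min_dist_cM: float = DEFAULT_COFACTOR_DIST,
) -> list[str]:
    """Greedy cofactor selection from a SIM profile: repeatedly take the
    highest remaining -log10(p) >= threshold and exclude positions within
    ``min_dist_cM`` on the same chromosome."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return _greedy_select(profile, threshold, min_dist_cM)


def select_qtls(
    profile: ScanProfile,
    threshold: float = DEFAULT_THRESHOLD,
    min_dist_cM: float = DEFAULT_QTL_DIST,
) -> list[str]:
    """Greedy candidate-QTL selection from a CIM profile (same rule as
    cofactor selection, default spacing 20 cM)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return _greedy_select(profile, threshold, min_dist_cM)


# --------------------------------------------------------------------------
# multi-QTL model


@dataclass
class QtlRecord:
    """One retained QTL with its allele (x environment) effects."""

    marker: str
    chromosome: int
    position_cM: float
    effects: pd.DataFrame  # columns: allele, environment, estimate, se
    wald: WaldResult


@dataclass
class QtlModel:
    """Final multi-QTL model after backward elimination."""

    method: str
    allele_model: str
    qtls: list[QtlRecord] = field(default_factory=list)
    fit: MixedFit | None = None
    threshold: float = DEFAULT_THRESHOLD
    environment: str | None = None

    @property
    def positions(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "marker": q.marker,
                    "chromosome": q.chromosome,
                    "position_cM": q.position_cM,
                    "neglog10p": q.wald.neglog10p,
                }
                for q in self.qtls
            ]
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "allele_model": self.allele_model,
            "environment": self.environment,
            "threshold": self.threshold,
            "qtls": [
                {
                    "marker": q.marker,
                    "chromosome": int(q.chromosome),
                    "position_cM": float(q.position_cM),
                    "wald": {
                        "W": q.wald.W,
                        "df": q.wald.df,
                        "p": q.wald.p,
                        "neglog10p": q.wald.neglog10p,
                    },
                    "effects": q.effects.to_dict(orient="records"),
                }
                for q in self.qtls
            ],
        }


def _effects_frame(
    fit: MixedFit, qcols: list[str], envs: list[str]
) -> pd.DataFrame:
    rows = []
    for c in qcols:
        inner = c[c.index("[") + 1 : c.rindex("]")]
        env = c.split("@", 1)[1] if "@" in c else "ALL"
        est = float(fit.beta[c])
        se = float(np.sqrt(fit.cov_beta.loc[c, c]))
        rows.append({"allele": inner, "environment": env, "estimate": est, "se": se})
    return pd.DataFrame(rows)


def backward_elimination(
    md: MethodData,
    designs: dict[str, AlleleDesign],
    candidates: list[str],
    gmap: GeneticMap,
    allele_model: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> QtlModel:
    """Joint multi-QTL model over the candidate positions; iteratively drop
    the least significant QTL while its Wald -log10(p) is below the
    threshold, refitting after each drop."""
    if not candidates:
        raise ValueError("candidate list is empty")
    tab = gmap.table.set_index("marker")
    current = list(candidates)
    while current:
        parts = [md.base_X]
        qcols_per: dict[str, list[str]] = {}
        for j, marker in enumerate(current):
            cols = md.qtl_columns(designs[marker], prefix=f"q{j}")
            qcols_per[marker] = list(cols.columns)
            parts.append(cols)
        X = pd.concat(parts, axis=1)
        fit = reml_fit(md.y, X, md.spec)
        walds = {
            m: wald_test(fit, [c for c in qcols_per[m] if c in fit.beta.index])
            for m in current
        }
        worst = min(current, key=lambda m: walds[m].neglog10p)
        if walds[worst].neglog10p >= threshold:
            qtls = []
            for m in current:
                kept = [c for c in qcols_per[m] if c in fit.beta.index]
                qtls.append(
                    QtlRecord(
                        m,
                        int(tab.loc[m, "chromosome"]),
                        float(tab.loc[m, "position_cM"]),
                        _effects_frame(fit, kept, md.envs),
                        walds[m],
                    )
                )
            qtls.sort(key=lambda q: (q.chromosome, q.position_cM))
            return QtlModel(md.method, allele_model, qtls, fit, threshold,
                            md.environment)
        current.remove(worst)
    logger.warning("backward elimination removed every candidate QTL")
    return QtlModel(md.method, allele_model, [], None, threshold, md.environment)


def consolidate_qtls(
    models: list[QtlModel], merge_dist_cM: float = DEFAULT_MERGE_DIST
) -> pd.DataFrame:
    """Cluster the QTL positions of several models into unique QTL regions.

    Single-linkage per chromosome: positions closer than ``merge_dist_cM``
    chain into one cluster.  Returns one row per detected position with its
    cluster id and the set of methods detecting each cluster.
    """
    rows = []
    for model in models:
        label = model.method if model.environment is None else (
            f"{model.method}-{model.environment}"
        )
        for q in model.qtls:
            rows.append(
                {
                    "model": label,
                    "allele_model": model.allele_model,
                    "marker": q.marker,
                    "chromosome": q.chromosome,
                    "position_cM": q.position_cM,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["model", "allele_model", "marker", "chromosome",
                     "position_cM", "cluster"]
        )
    df = pd.DataFrame(rows).sort_values(["chromosome", "position_cM"]).reset_index(
        drop=True
    )
    cluster = 0
    ids = []
    prev_chrom, prev_pos = None, None
    for _, row in df.iterrows():
        if (
            prev_chrom is not None
            and row["chromosome"] == prev_chrom
            and row["position_cM"] - prev_pos < merge_dist_cM
        ):
            ids.append(cluster)
        else:
            cluster += 1
            ids.append(cluster)
        prev_chrom, prev_pos = row["chromosome"], row["position_cM"]
    df["cluster"] = ids
    return df
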