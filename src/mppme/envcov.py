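"""Environmental-covariate decomposition of environment-specific QTL effects.

When a QTL shows QTL-by-environment interaction, its per-environment allele
effects can be regressed on an environmental index Z_e (precipitation,
temperature, ...):

    x_ia * beta_ae = x_ia * (beta_a + Z_e * gamma_a + delta_ae)

``beta_a`` is the allele's effect at Z = 0 (Z is centered on a reference
environment, e.g. the driest site), ``gamma_a`` its sensitivity — the change
in trait value per unit of the covariate — and ``delta_ae`` a random
residual QTL-by-environment term (only estimable with at least three
environments).  Both vectors are deviations from the reference allele.

The homozygous allele contrast translates the fit into trait units: the
extra trait value conferred by the reference allele over allele ``a`` at
covariate level Z is ``-2 (beta_a + Z gamma_a)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import AlleleDesign
from .mixed import MixedFit, reml_fit, wald_test
from .scan import MethodData

logger = logging.getLogger(__name__)

__all__ = ["EnvCovariate", "SensitivityFit", "fit_sensitivity", "allele_contrast"]


@dataclass
class EnvCovariate:
    """Environmental index values per environment, centered on a reference
    environment (which then sits at Z = 0)."""

    values: dict[str, float]
    name: str = "covariate"
    reference_environment: str | None = None

    def centered(self) -> dict[str, float]:
        ref = self.reference_environment
        offset = self.values[ref] if ref is not None else 0.0
        return {e: v - offset for e, v in self.values.items()}


@dataclass
class SensitivityFit:
    """Per-allele main effects and covariate sensitivities.

    ``table`` has one row per allele (the reference allele included, with
    zero entries) and columns ``beta``, ``se_beta``, ``wald_beta``,
    ``p_beta``, ``gamma``, ``se_gamma``, ``wald_gamma``, ``p_gamma``,
    ``carriers`` and ``flagged`` (low carrier count).  ``cov`` is the joint
    covariance of the (beta, gamma) coefficients for delta-method
    contrasts.
    """

    table: pd.DataFrame
    cov: pd.DataFrame
    reference_allele: str
    covariate: EnvCovariate
    fit: MixedFit | None
    delta_variance: float | None

    @classmethod
    def from_coefficients(
        cls,
        coefficients: pd.DataFrame,
        covariate: EnvCovariate,
        reference_allele: str,
    ) -> "SensitivityFit":
        """Build a sensitivity table from externally supplied coefficients.

        ``coefficients`` is indexed by allele with columns ``beta``,
        ``gamma`` and optionally ``se_beta``, ``se_gamma`` (assumed
        independent, so contrast SEs at Z = 0 are exact and elsewhere
        conservative).  Useful for computing contrasts from published
        estimates.
        """
        table = coefficients.copy()
        for col in ("se_beta", "se_gamma"):
            if col not in table.columns:
                table[col] = 0.0
        names, var = [], []
        for a in table.index:
            names += [f"beta[{a}]", f"gamma[{a}]"]
            var += [float(table.loc[a, "se_beta"]) ** 2,
                    float(table.loc[a, "se_gamma"]) ** 2]
        cov = pd.DataFrame(np.diag(var), index=names, columns=names)
        return cls(table, cov, reference_allele, covariate, None, None)


def fit_sensitivity(
    md: MethodData,
    design: AlleleDesign,
    covariate: EnvCovariate,
    cofactor_designs: list[AlleleDesign] | None = None,
    min_carriers: int = 10,
) -> SensitivityFit:
    """Fit the sensitivity decomposition of one QTL on M3/M4 data.

    The focal QTL's environment-specific block is replaced by main-effect
    columns ``x_ia`` and interaction columns ``x_ia * Z_e``; cofactor QTLs
    keep their saturated per-environment coding.  With >= 3 environments a
    random residual QTL-by-environment term absorbs lack of fit of the
    linear regression on Z; with 2 environments the decomposition is exact
    and the term is dropped.
    """
    if md.method not in ("M3", "M4"):
        raise ValueError("sensitivity decomposition requires M3 or M4 data")
    z = covariate.centered()
    missing = [e for e in md.envs if e not in z]
    if missing:
        raise ValueError(f"covariate missing environments: {missing}")
    zvals = np.array([z[e] for e in md.envs])
    if len(md.envs) < 2 or np.ptp(zvals) == 0:
        raise ValueError(
            "sensitivities are inestimable: need >= 2 environments with "
            "distinct covariate values"
        )
    D = design.dosages.reindex(md.genotype.to_numpy()).fillna(0.0)
    zrow = md.env.map(z).to_numpy(dtype=float)
    parts = [md.base_X]
    if cofactor_designs:
        for j, cd in enumerate(cofactor_designs):
            parts.append(md.qtl_columns(cd, prefix=f"cof{j}"))
    cols: dict[str, np.ndarray] = {}
    for a in design.allele_labels:
        xa = D[a].to_numpy()
        cols[f"beta[{a}]"] = xa
        cols[f"gamma[{a}]"] = xa * zrow
    parts.append(pd.DataFrame(cols, index=md.base_X.index))
    X = pd.concat(parts, axis=1)
    spec = md.spec
    delta_used = len(md.envs) >= 3
    if delta_used:
        env_arr = md.env.to_numpy()
        Zd = np.column_stack(
            [
                D[a].to_numpy() * (env_arr == e)
                for a in design.allele_labels
                for e in md.envs
            ]
        )
        spec = spec.with_random("qtl_by_env", Zd)
    fit = reml_fit(md.y, X, spec)
    if not fit.converged:
        logger.warning("sensitivity fit did not converge")
    carriers = (design.dosages > 1e-8).sum(axis=0)
    rows = [
        {
            "allele": design.reference_allele,
            "beta": 0.0,
            "se_beta": 0.0,
            "wald_beta": np.nan,
            "p_beta": np.nan,
            "gamma": 0.0,
            "se_gamma": 0.0,
            "wald_gamma": np.nan,
            "p_gamma": np.nan,
            "carriers": np.nan,
            "flagged": False,
        }
    ]
    for a in design.allele_labels:
        row = {"allele": a, "carriers": int(carriers[a])}
        row["flagged"] = bool(carriers[a] < min_carriers)
        if row["flagged"]:
            logger.warning(
                "allele %s has only %d carriers: estimates may be unstable",
                a,
                int(carriers[a]),
            )
        for part, key in (("beta", "beta"), ("gamma", "gamma")):
            name = f"{part}[{a}]"
            if name in fit.beta.index:
                w = wald_test(fit, [name])
                row[key] = float(fit.beta[name])
                row[f"se_{key}"] = float(np.sqrt(fit.cov_beta.loc[name, name]))
                row[f"wald_{key}"] = w.W
                row[f"p_{key}"] = w.p
            else:
                row[key] = np.nan
                row[f"se_{key}"] = np.nan
                row[f"wald_{key}"] = np.nan
                row[f"p_{key}"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("allele")
    coef = [c for c in X.columns if c.startswith(("beta[", "gamma["))]
    coef = [c for c in coef if c in fit.beta.index]
    cov = fit.cov_beta.loc[coef, coef]
    delta_var = fit.varcomps.get("qtl_by_env") if delta_used else None
    return SensitivityFit(
        table, cov, design.reference_allele, covariate, fit, delta_var
    )


def allele_contrast(
    fit: SensitivityFit, allele: str, Z: float
) -> tuple[float, float]:
    """Homozygous contrast of the reference allele versus ``allele`` at
    covariate level ``Z`` (centered scale): the extra trait value conferred
    by two copies of the reference allele, ``-2 (beta_a + Z gamma_a)``, with
    its delta-method standard error."""
    if allele not in fit.table.index:
        raise KeyError(f"allele {allele!r} not in sensitivity fit")
    row = fit.table.loc[allele]
    value = -2.0 * (float(row["beta"]) + Z * float(row["gamma"]))
    bname, gname = f"beta[{allele}]", f"gamma[{allele}]"
    if bname in fit.cov.index and gname in fit.cov.index:
        vb = float(fit.cov.loc[bname, bname])
        vg = float(fit.cov.loc[gname, gname])
        cbg = float(fit.cov.loc[bname, gname])
        se = 2.0 * float(np.sqrt(max(vb + Z * Z * vg + 2.0 * Z * cbg, 0.0)))
    else:
        se = 0.0
    return value, se
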