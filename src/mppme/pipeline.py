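"""End-to-end QTL detection: QC, allele designs, stage one and the scan.

``detect_qtls`` runs the full procedure for one method and one allele
model: marker QC, IBD/clustering/dosage design construction, stage-one
BLUEs where the method needs them, a SIM scan for cofactor selection, a
CIM scan, greedy candidate selection and backward elimination.  M2 returns
one result per environment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .design import AlleleDesign
from .ibd import cluster_ancestral, compute_ibd_all_crosses
from .markers import CrossTable, GeneticMap, MarkerMatrix, impute_biallelic
from .scan import (
    DEFAULT_COFACTOR_DIST,
    DEFAULT_QTL_DIST,
    DEFAULT_THRESHOLD,
    MethodData,
    QtlModel,
    ScanProfile,
    backward_elimination,
    cim_scan,
    designs_genomewide,
    method_data_m1,
    method_data_m2,
    method_data_m3,
    method_data_m4,
    select_cofactors,
    select_qtls,
    sim_scan,
)
from .stage_one import PlotTable, fit_blues_joint, fit_blues_within

logger = logging.getLogger(__name__)

__all__ = ["DetectionResult", "build_method_data", "build_designs", "detect_qtls"]


@dataclass
class DetectionResult:
    """Everything produced by one detection run."""

    method: str
    allele_model: str
    sim_profile: ScanProfile
    cim_profile: ScanProfile
    cofactors: list[str]
    candidates: list[str]
    model: QtlModel
    designs: dict[str, AlleleDesign] = field(repr=False, default_factory=dict)
    method_data: MethodData | None = field(repr=False, default=None)
    environment: str | None = None


def build_designs(
    allele_model: str,
    gmap: GeneticMap,
    geno: MarkerMatrix,
    crosses: CrossTable,
    window_cM: float = 2.0,
    ancestral_threshold: float = 0.9,
    seed: int = 1,
) -> dict[str, AlleleDesign]:
    """Genome-wide allele designs for one coding, including the required
    preprocessing (IBD dosages, ancestral clustering or imputation)."""
    if allele_model in ("parental", "ancestral"):
        ibd = compute_ibd_all_crosses(geno, gmap, crosses)
        clustering = None
        if allele_model == "ancestral":
            clustering = cluster_ancestral(
                geno.parent_scores, gmap, window_cM, ancestral_threshold
            )
        return designs_genomewide(
            allele_model, gmap, crosses, ibd=ibd, clustering=clustering
        )
    if allele_model == "biallelic":
        geno = impute_biallelic(geno, crosses, seed)
        return designs_genomewide("biallelic", gmap, crosses, geno=geno)
    raise ValueError(f"unknown allele model {allele_model!r}")


def build_method_data(
    method: str,
    plots: PlotTable,
    environment: str | None = None,
) -> MethodData:
    """Stage-one BLUEs plus the method's model layout (M1/M2/M3), or the
    plot data directly (M4)."""
    if method == "M1":
        return method_data_m1(fit_blues_joint(plots))
    if method == "M2":
        if environment is None:
            raise ValueError("M2 needs an environment")
        return method_data_m2(fit_blues_within(plots, environment), environment)
    if method == "M3":
        tables = [fit_blues_within(plots, e) for e in plots.environments]
        return method_data_m3(tables)
    if method == "M4":
        return method_data_m4(plots)
    raise ValueError(f"unknown method {method!r}")


def detect_qtls(
    gmap: GeneticMap,
    geno: MarkerMatrix,
    crosses: CrossTable,
    plots: PlotTable,
    method: str = "M3",
    allele_model: str = "parental",
    threshold: float = DEFAULT_THRESHOLD,
    cofactor_dist_cM: float = DEFAULT_COFACTOR_DIST,
    qtl_dist_cM: float = DEFAULT_QTL_DIST,
    exclusion_cM: float = DEFAULT_COFACTOR_DIST,
    window_cM: float = 2.0,
    ancestral_threshold: float = 0.9,
    seed: int = 1,
) -> DetectionResult | dict[str, DetectionResult]:
    """Run the full detection procedure; for M2 a dict keyed by
    environment is returned."""
    designs = build_designs(
        allele_model, gmap, geno, crosses, window_cM, ancestral_threshold, seed
    )
    if method == "M2":
        out = {}
        for env in plots.environments:
            md = build_method_data("M2", plots, env)
            out[env] = _run_one(
                md, designs, gmap, allele_model, threshold, cofactor_dist_cM,
                qtl_dist_cM, exclusion_cM,
            )
        return out
    md = build_method_data(method, plots)
    return _run_one(
        md, designs, gmap, allele_model, threshold, cofactor_dist_cM,
        qtl_dist_cM, exclusion_cM,
    )


def _run_one(
    md: MethodData,
    designs: dict[str, AlleleDesign],
    gmap: GeneticMap,
    allele_model: str,
    threshold: float,
    cofactor_dist_cM: float,
    qtl_dist_cM: float,
    exclusion_cM: float,
) -> DetectionResult:
    sim = sim_scan(md, designs, gmap, allele_model)
    cofactors = select_cofactors(sim, threshold, cofactor_dist_cM)
    if cofactors:
        cim = cim_scan(md, designs, gmap, allele_model, cofactors, exclusion_cM)
    else:
        cim = sim
    candidates = select_qtls(cim, threshold, qtl_dist_cM)
    if candidates:
        model = backward_elimination(
            md, designs, candidates, gmap, allele_model, threshold
        )
    else:
        logger.info("%s/%s: no candidate positions above threshold",
                    md.method, allele_model)
        model = QtlModel(md.method, allele_model, [], None, threshold,
                         md.environment)
    return DetectionResult(
        md.method,
        allele_model,
        sim,
        cim,
        cofactors,
        candidates,
        model,
        designs,
        md,
        md.environment,
    )
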