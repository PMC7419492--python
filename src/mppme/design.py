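"""QTL design matrices for the parental, ancestral and bi-allelic codings.

At a map position each individual carries an expected number of copies
``x_ia`` of QTL allele ``a``:

* parental  — one allele per founder parent; ``x_ia`` is the expected number
  of copies inherited from parent ``a`` (IBD posterior dosage);
* ancestral — parental alleles merged within local ancestral classes, so
  ``x_ia`` sums the parental dosages of the class members;
* biallelic — the SNP minor-allele dosage itself.

Substitution effects are deviations from a reference allele (the central
parent's allele, the ancestral class containing it, or the SNP major
allele), so the reference column is dropped from the fixed-effect design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ibd import AncestralClustering, IbdResult
from .markers import CrossTable, MarkerMatrix

logger = logging.getLogger(__name__)

__all__ = ["AlleleDesign", "build_design"]


@dataclass
class AlleleDesign:
    """Design matrix of expected allele dosages at one position.

    ``dosages`` holds one row per individual and one column per
    *non-reference* allele; all entries lie in [0, 2].  ``full_row_sum`` is
    the total expected allele count including the reference column (2 for
    parental/ancestral codings).
    """

    position_id: str
    model: str  # parental | ancestral | biallelic
    allele_labels: list[str]
    dosages: pd.DataFrame
    reference_allele: str

    def __post_init__(self) -> None:
        arr = self.dosages.to_numpy(dtype=float)
        if arr.size and (arr.min() < -1e-8 or arr.max() > 2 + 1e-8):
            raise ValueError("allele dosages must lie in [0, 2]")

    @property
    def n_alleles(self) -> int:
        """Total allele count including the reference."""
        return len(self.allele_labels) + 1

    @property
    def individuals(self) -> list[str]:
        return self.dosages.index.tolist()


def _drop_empty(cols: pd.DataFrame, position_id: str) -> pd.DataFrame:
    zero = cols.columns[(cols.abs().sum(axis=0) < 1e-12)]
    if len(zero):
        logger.warning(
            "position %s: dropping absent allele columns %s",
            position_id,
            list(zero),
        )
        cols = cols.drop(columns=zero)
    return cols


def build_design(
    position_id: str,
    model: str,
    cross_table: CrossTable,
    ibd: dict[str, IbdResult] | None = None,
    clustering: AncestralClustering | None = None,
    geno: MarkerMatrix | None = None,
) -> AlleleDesign:
    """Assemble the allele design matrix at one map position.

    ``ibd`` (per-cross IBD dosages with parent1 = central parent) drives the
    parental and ancestral models; ``clustering`` supplies the ancestral
    classes; ``geno`` supplies SNP dosages for the biallelic model.  The
    reference column (central parent / its ancestral class / major allele)
    is excluded, and allele columns absent from the data are dropped with a
    warning.
    """
    central = cross_table.central_parent
    if model in ("parental", "ancestral"):
        if ibd is None:
            raise ValueError(f"{model} model requires IBD dosages")
        rows: list[pd.Series] = []
        parents = cross_table.parents
        blocks = []
        for cross in cross_table.crosses:
            res = ibd[cross]
            if position_id not in res.p1_copies.columns:
                raise KeyError(f"position {position_id} absent from IBD result")
            x_central = res.p1_copies[position_id]
            peri = cross_table.peripheral_parent(cross)
            block = pd.DataFrame(
                0.0, index=res.individuals, columns=parents
            )
            block[central] = x_central
            block[peri] = 2.0 - x_central
            blocks.append(block)
        par_dos = pd.concat(blocks, axis=0)
        if model == "parental":
            cols = par_dos.drop(columns=[central])
            cols = _drop_empty(cols, position_id)
            return AlleleDesign(
                position_id, "parental", cols.columns.tolist(), cols, central
            )
        if clustering is None:
            raise ValueError("ancestral model requires a clustering")
        cls = clustering.classes[position_id]
        ref_class = cls[central]
        groups: dict[int, list[str]] = {}
        for p in parents:
            groups.setdefault(cls[p], []).append(p)
        cols = {}
        for cid, members in sorted(groups.items()):
            if cid == ref_class:
                continue
            label = "anc_" + "+".join(sorted(members))
            cols[label] = par_dos[members].sum(axis=1)
        frame = pd.DataFrame(cols, index=par_dos.index)
        frame = _drop_empty(frame, position_id)
        ref_label = "anc_" + "+".join(sorted(groups[ref_class]))
        return AlleleDesign(
            position_id, "ancestral", frame.columns.tolist(), frame, ref_label
        )
    if model == "biallelic":
        if geno is None:
            raise ValueError("biallelic model requires genotype dosages")
        dose = geno.scores[position_id].astype(float)
        if dose.isna().any():
            raise ValueError(
                f"position {position_id}: missing dosages; impute before "
                "building the biallelic design"
            )
        frame = pd.DataFrame({"minor": dose})
        frame = _drop_empty(frame, position_id)
        labels = frame.columns.tolist()
        return AlleleDesign(position_id, "biallelic", labels, frame, "major")
    raise ValueError(f"unknown allele model {model!r}")
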