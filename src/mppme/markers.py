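"""Genetic map, marker data and cross-structure containers, plus marker QC.

The population layout throughout the package is a NAM-type multi-parent
population: a set of biparental crosses sharing one central parent, with
doubled-haploid (DH) progeny.  Marker scores are minor-allele dosages in
{0, 1, 2}; DH lines are fully homozygous, so progeny dosages are expected in
{0, 2} and residual heterozygous calls are treated as missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticMap",
    "MarkerMatrix",
    "CrossTable",
    "qc_markers",
    "dedupe_positions",
    "impute_biallelic",
]


@dataclass
class GeneticMap:
    """Marker positions in centimorgan on numbered chromosomes.

    Parameters
    ----------
    table:
        DataFrame with columns ``marker``, ``chromosome`` (int >= 1) and
        ``position_cM`` (float >= 0).  Rows are sorted by (chromosome,
        position) on construction; marker ids must be unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chromosome", "position_cM"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"genetic map missing columns: {sorted(missing)}")
        if self.table["marker"].duplicated().any():
            dups = self.table.loc[self.table["marker"].duplicated(), "marker"]
            raise ValueError(f"duplicated marker ids in map: {list(dups)[:5]}")
        if (self.table["position_cM"] < 0).any():
            raise ValueError("map positions must be >= 0 cM")
        if (self.table["chromosome"] < 1).any():
            raise ValueError("chromosome numbers must be >= 1")
        self.table = (
            self.table.sort_values(["chromosome", "position_cM"], kind="stable")
            .reset_index(drop=True)
        )

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    def chromosomes(self) -> list[int]:
        return sorted(self.table["chromosome"].unique().tolist())

    def chromosome_of(self, marker: str) -> int:
        return int(self.table.set_index("marker").loc[marker, "chromosome"])

    def position_of(self, marker: str) -> float:
        return float(self.table.set_index("marker").loc[marker, "position_cM"])

    def subset(self, markers: list[str]) -> "GeneticMap":
        keep = self.table[self.table["marker"].isin(set(markers))]
        return GeneticMap(keep.copy())


@dataclass
class MarkerMatrix:
    """Minor-allele dosage matrix for progeny and parents.

    ``scores``: DataFrame, rows = progeny individuals, columns = markers,
    values in {0, 1, 2} or NaN.  ``parent_scores``: same layout for the
    parents.  DH progeny should be homozygous; dosage-1 calls are converted
    to missing with a warning.
    """

    scores: pd.DataFrame
    parent_scores: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.scores.columns) != list(self.parent_scores.columns):
            raise ValueError("progeny and parent matrices must share marker columns")
        het = (self.scores == 1).to_numpy().sum()
        if het:
            logger.warning(
                "%d heterozygous calls in DH progeny set to missing", int(het)
            )
            self.scores = self.scores.mask(self.scores == 1)

    @property
    def individuals(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def markers(self) -> list[str]:
        return self.scores.columns.tolist()

    def minor_allele_frequency(self) -> pd.Series:
        """Per-marker minor-allele frequency over non-missing progeny calls.

        The stored dosage is folded so the frequency is always <= 0.5.
        """
        dose = self.scores.sum(axis=0, skipna=True)
        n = self.scores.notna().sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = dose / (2.0 * n)
        return np.minimum(freq, 1.0 - freq)

    def missing_fraction(self) -> pd.Series:
        return self.scores.isna().mean(axis=0)

    def subset_markers(self, markers: list[str]) -> "MarkerMatrix":
        return MarkerMatrix(
            self.scores[markers].copy(), self.parent_scores[markers].copy()
        )

    def subset_individuals(self, individuals: list[str]) -> "MarkerMatrix":
        return MarkerMatrix(
            self.scores.loc[individuals].copy(), self.parent_scores.copy()
        )


@dataclass
class CrossTable:
    """Assignment of individuals to crosses and crosses to parent pairs.

    Every cross shares the designated central parent; the other parent is the
    cross's peripheral parent.
    """

    individual_cross: pd.Series  # index = individual id, value = cross id
    cross_parents: dict[str, tuple[str, str]]  # cross -> (parent1, parent2)
    central_parent: str

    def __post_init__(self) -> None:
        for cross, (p1, p2) in self.cross_parents.items():
            if self.central_parent not in (p1, p2):
                raise ValueError(
                    f"cross {cross!r} does not involve central parent "
                    f"{self.central_parent!r}"
                )
        unknown = set(self.individual_cross.unique()) - set(self.cross_parents)
        if unknown:
            raise ValueError(f"individuals map to unknown crosses: {sorted(unknown)}")

    @property
    def crosses(self) -> list[str]:
        return sorted(self.cross_parents)

    @property
    def parents(self) -> list[str]:
        """Central parent first, then peripheral parents in cross order."""
        out = [self.central_parent]
        for cross in self.crosses:
            p = self.peripheral_parent(cross)
            if p not in out:
                out.append(p)
        return out

    def peripheral_parent(self, cross: str) -> str:
        p1, p2 = self.cross_parents[cross]
        return p2 if p1 == self.central_parent else p1

    def individuals_of(self, cross: str) -> list[str]:
        mask = self.individual_cross == cross
        return self.individual_cross.index[mask].tolist()

    def cross_of(self, individual: str) -> str:
        return str(self.individual_cross.loc[individual])


def qc_markers(
    geno: MarkerMatrix, maf_min: float = 0.05, miss_max: float = 0.10
) -> MarkerMatrix:
    """Drop markers with minor-allele frequency below ``maf_min`` or missing
    fraction above ``miss_max``.

    Marker order is preserved.  Raises ``ValueError`` if no marker survives.
    """
    if not 0 < maf_min < 0.5:
        raise ValueError("maf_min must be in (0, 0.5)")
    if not 0 < miss_max < 1:
        raise ValueError("miss_max must be in (0, 1)")
    maf = geno.minor_allele_frequency()
    miss = geno.missing_fraction()
    keep = [
        m
        for m in geno.markers
        if np.isfinite(maf[m]) and maf[m] >= maf_min and miss[m] <= miss_max
    ]
    if not keep:
        raise ValueError("no markers survive QC")
    return geno.subset_markers(keep)


def dedupe_positions(geno: MarkerMatrix, gmap: GeneticMap) -> MarkerMatrix:
    """Among markers mapped to the same (chromosome, position), keep only the
    most polymorphic one (highest minor-allele frequency; ties broken by map
    order)."""
    present = set(geno.markers)
    missing = [m for m in geno.markers if m not in set(gmap.markers)]
    if missing:
        raise ValueError(f"map does not cover markers: {missing[:5]}")
    maf = geno.minor_allele_frequency()
    keep: list[str] = []
    tab = gmap.table[gmap.table["marker"].isin(present)]
    for (_, _), grp in tab.groupby(["chromosome", "position_cM"], sort=False):
        names = grp["marker"].tolist()
        best = max(names, key=lambda m: (maf[m], -names.index(m)))
        keep.append(best)
    keep_set = set(keep)
    ordered = [m for m in geno.markers if m in keep_set]
    return geno.subset_markers(ordered)


def impute_biallelic(geno: MarkerMatrix, cross_table: CrossTable, seed: int) -> MarkerMatrix:
    """Randomly impute missing progeny dosages from the within-cross allele
    frequency (fallback: population frequency when a marker is entirely
    missing inside a cross).

    DH dosages are drawn in {0, 2}: an imputed individual receives two copies
    of the minor allele with probability equal to the local minor-allele
    frequency.  Deterministic under ``seed``.
    """
    if not geno.scores.isna().to_numpy().any():
        return geno
    rng = np.random.default_rng(seed)
    scores = geno.scores.copy()
    arr = scores.to_numpy(dtype=float)
    inds = scores.index.to_numpy()
    cross_of = cross_table.individual_cross.reindex(scores.index).to_numpy()
    with np.errstate(invalid="ignore"):
        pop_freq = np.nanmean(arr, axis=0) / 2.0
    for cross in np.unique(cross_of):
        rows = np.flatnonzero(cross_of == cross)
        block = arr[rows]
        miss = np.isnan(block)
        if not miss.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(block, axis=0) / 2.0
        whole_cols = np.isnan(freq)
        if whole_cols.any() and miss[:, whole_cols].any():
            logger.warning(
                "cross %s: %d markers entirely missing, imputed from population "
                "frequency",
                cross,
                int(whole_cols.sum()),
            )
            freq = np.where(whole_cols, pop_freq, freq)
        draw = 2.0 * (rng.random(block.shape) < freq[None, :])
        arr[rows] = np.where(miss, draw, block)
    out = pd.DataFrame(arr, index=scores.index, columns=scores.columns)
    return MarkerMatrix(out, geno.parent_scores.copy())
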