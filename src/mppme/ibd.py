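"""Identity-by-descent dosages for DH progeny and ancestral allele clustering.

A doubled-haploid line is a single recombinant gamete, doubled, so its genome
is a mosaic of the two parental genomes.  Parental origin along a chromosome
is modelled as a two-state Markov chain whose transition probability between
positions d cM apart is the Haldane recombination fraction

    r(d) = (1 - exp(-2 d / 100)) / 2.

At markers where the two parents carry the same allele (or where any call is
missing) the observation is uninformative; elsewhere the progeny dosage
identifies the transmitting parent.  The forward-backward posterior gives the
expected number of allele copies received from each parent (0..2, summing
to 2), which is the QTL regressor for the parental allele model.

The ancestral model merges parents that are locally identical by state: at
each position, parents are compared over all markers within a +-window
(default 2 cM), and single-linkage clustering at a similarity threshold
groups them into ancestral classes.  This is a deliberately simple local-IBS
clustering, not a kernel-smoothed haplotype model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .markers import CrossTable, GeneticMap, MarkerMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "haldane",
    "compute_ibd_dh",
    "IbdResult",
    "AncestralClustering",
    "cluster_ancestral",
]


def haldane(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Haldane recombination fraction for a map distance in centimorgan."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


@dataclass
class IbdResult:
    """Expected parental allele copies per individual and map position.

    ``p1_copies`` has one row per individual and one column per marker; the
    copies from the second parent are ``2 - p1_copies``.
    """

    individuals: list[str]
    markers: list[str]
    parent1: str
    parent2: str
    p1_copies: pd.DataFrame

    def p2_copies(self) -> pd.DataFrame:
        return 2.0 - self.p1_copies


def _chrom_posteriors(
    obs: np.ndarray, p1: np.ndarray, p2: np.ndarray, pos: np.ndarray
) -> np.ndarray:
    """Forward-backward posterior P(origin = parent1) at each marker.

    obs: (n_ind, m) progeny dosages (NaN = missing); p1, p2: (m,) parental
    dosages; pos: (m,) positions in cM, non-decreasing.
    """
    n, m = obs.shape
    # emission[i, j, s]: P(obs_ij | origin s); uninformative -> 1 for both
    informative = np.isfinite(p1) & np.isfinite(p2) & (p1 != p2)
    e1 = np.ones((n, m))
    e2 = np.ones((n, m))
    seen = np.isfinite(obs) & informative[None, :]
    e1[seen] = (obs[seen] == np.broadcast_to(p1, obs.shape)[seen]).astype(float)
    e2[seen] = (obs[seen] == np.broadcast_to(p2, obs.shape)[seen]).astype(float)
    # an observation incompatible with both parents is treated as missing
    conflict = seen & (e1 == 0) & (e2 == 0)
    if conflict.any():
        logger.warning(
            "%d progeny calls match neither parent; treated as missing",
            int(conflict.sum()),
        )
        e1[conflict] = 1.0
        e2[conflict] = 1.0
    r = haldane(np.diff(pos))
    fwd = np.empty((n, m, 2))
    fwd[:, 0, 0] = 0.5 * e1[:, 0]
    fwd[:, 0, 1] = 0.5 * e2[:, 0]
    scale = np.empty((n, m))
    s0 = fwd[:, 0].sum(axis=1)
    s0[s0 == 0] = 1.0
    scale[:, 0] = s0
    fwd[:, 0] /= s0[:, None]
    for j in range(1, m):
        stay = 1.0 - r[j - 1]
        a = fwd[:, j - 1, 0] * stay + fwd[:, j - 1, 1] * r[j - 1]
        b = fwd[:, j - 1, 0] * r[j - 1] + fwd[:, j - 1, 1] * stay
        fwd[:, j, 0] = a * e1[:, j]
        fwd[:, j, 1] = b * e2[:, j]
        s = fwd[:, j].sum(axis=1)
        s[s == 0] = 1.0
        fwd[:, j] /= s[:, None]
    bwd = np.empty((n, m, 2))
    bwd[:, -1] = 1.0
    for j in range(m - 2, -1, -1):
        stay = 1.0 - r[j]
        x = bwd[:, j + 1, 0] * e1[:, j + 1]
        y = bwd[:, j + 1, 1] * e2[:, j + 1]
        bwd[:, j, 0] = stay * x + r[j] * y
        bwd[:, j, 1] = r[j] * x + stay * y
        s = bwd[:, j].sum(axis=1)
        s[s == 0] = 1.0
        bwd[:, j] /= s[:, None]
    post = fwd * bwd
    tot = post.sum(axis=2)
    tot[tot == 0] = 1.0
    return post[:, :, 0] / tot


def compute_ibd_dh(
    cross_geno: MarkerMatrix,
    gmap: GeneticMap,
    parent1: str,
    parent2: str,
) -> IbdResult:
    """Expected parental allele copies for DH progeny of one cross.

    Runs the two-state origin HMM independently per chromosome over the
    markers of ``gmap`` and returns ``2 * P(origin = parent1)`` at every
    marker position.  If the parents are identical over a whole chromosome
    the posterior is flat (one copy from each parent) and a warning is
    logged.
    """
    markers = [m for m in gmap.markers if m in set(cross_geno.markers)]
    sub = cross_geno.subset_markers(markers)
    gmap = gmap.subset(markers)
    inds = sub.individuals
    out = np.empty((len(inds), len(markers)))
    col = {m: j for j, m in enumerate(markers)}
    p1_all = sub.parent_scores.loc[parent1]
    p2_all = sub.parent_scores.loc[parent2]
    for chrom in gmap.chromosomes():
        tab = gmap.table[gmap.table["chromosome"] == chrom]
        mks = tab["marker"].tolist()
        pos = tab["position_cM"].to_numpy(dtype=float)
        p1 = p1_all[mks].to_numpy(dtype=float)
        p2 = p2_all[mks].to_numpy(dtype=float)
        if not np.any(np.isfinite(p1) & np.isfinite(p2) & (p1 != p2)):
            logger.warning(
                "parents %s/%s identical on chromosome %s: flat IBD posterior",
                parent1,
                parent2,
                chrom,
            )
        obs = sub.scores[mks].to_numpy(dtype=float)
        post1 = _chrom_posteriors(obs, p1, p2, pos)
        for k, mk in enumerate(mks):
            out[:, col[mk]] = 2.0 * post1[:, k]
    frame = pd.DataFrame(out, index=inds, columns=markers)
    return IbdResult(inds, markers, parent1, parent2, frame)


def compute_ibd_all_crosses(
    geno: MarkerMatrix, gmap: GeneticMap, crosses: CrossTable
) -> dict[str, IbdResult]:
    """Per-cross IBD dosages keyed by cross id; parent1 is always the central
    parent so ``p1_copies`` counts central-parent allele copies."""
    out = {}
    for cross in crosses.crosses:
        inds = crosses.individuals_of(cross)
        sub = geno.subset_individuals(inds)
        out[cross] = compute_ibd_dh(
            sub, gmap, crosses.central_parent, crosses.peripheral_parent(cross)
        )
    return out


@dataclass
class AncestralClustering:
    """Per-position partition of the parents into ancestral classes.

    ``classes[marker]`` maps parent id -> class id (ints, arbitrary labels);
    parents in the same class are treated as carrying the same ancestral
    allele at that position.
    """

    classes: dict[str, dict[str, int]]
    window_cM: float
    threshold: float

    def n_classes(self, marker: str) -> int:
        return len(set(self.classes[marker].values()))

    def mean_classes(self) -> float:
        return float(np.mean([self.n_classes(m) for m in self.classes]))


def cluster_ancestral(
    parent_scores: pd.DataFrame,
    gmap: GeneticMap,
    window_cM: float = 2.0,
    threshold: float = 0.9,
) -> AncestralClustering:
    """Cluster parents into ancestral classes at every marker position.

    At each position the pairwise parent similarity is the fraction of equal
    (non-missing) scores over markers within ``+-window_cM`` on the same
    chromosome; single-linkage clustering merges parents whose similarity is
    >= ``threshold``.  An empty window falls back to the focal marker alone.
    """
    if window_cM <= 0:
        raise ValueError("window_cM must be > 0")
    parents = parent_scores.index.tolist()
    n_p = len(parents)
    classes: dict[str, dict[str, int]] = {}
    for chrom in gmap.chromosomes():
        tab = gmap.table[gmap.table["chromosome"] == chrom]
        mks = [m for m in tab["marker"] if m in parent_scores.columns]
        pos = tab.set_index("marker").loc[mks, "position_cM"].to_numpy(dtype=float)
        block = parent_scores[mks].to_numpy(dtype=float)
        for j, mk in enumerate(mks):
            inside = np.abs(pos - pos[j]) <= window_cM
            if not inside.any():  # cannot happen: the focal marker is inside
                inside = np.zeros_like(inside)
                inside[j] = True
            sub = block[:, inside]
            sim = np.ones((n_p, n_p))
            for a in range(n_p):
                for b in range(a + 1, n_p):
                    ok = np.isfinite(sub[a]) & np.isfinite(sub[b])
                    if not ok.any():
                        s = 0.0
                    else:
                        s = float(np.mean(sub[a][ok] == sub[b][ok]))
                    sim[a, b] = sim[b, a] = s
            dist = squareform(1.0 - sim, checks=False)
            if n_p == 1:
                labels = np.array([1])
            else:
                link = linkage(dist, method="single")
                labels = fcluster(link, t=1.0 - threshold + 1e-12, criterion="distance")
            classes[mk] = {p: int(k) for p, k in zip(parents, labels)}
    return AncestralClustering(classes, window_cM, threshold)
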