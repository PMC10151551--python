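"""Pairwise kinship from genotype calls: the KING-robust estimator.

The estimator uses only heterozygote concordance and opposite-homozygote
counts, so it needs no population allele frequencies and is robust to
population structure — the property that matters when comparing ancient
samples against a structured modern panel:

    phi = (N_het,het - 2 * N_opp_hom) / (N_het_i + N_het_j)

IBS0 (the fraction of compared sites at which the two samples are opposite
homozygotes) is reported alongside: it is exactly zero for parent-offspring
and duplicate pairs and separates them from other first-degree relatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix

CATEGORIES = (
    "duplicate/clone",
    "parent-offspring",
    "first-degree-other",
    "second-degree",
    "third-degree",
    "unrelated",
    "undetermined",
)


@dataclass
class PairCounts:
    """Site counts for one sample pair, over sites called in both."""

    n_compared: int
    n_het_het: int
    n_opp_hom: int
    n_het_i: int
    n_het_j: int

    def __post_init__(self):
        if self.n_het_het > min(self.n_het_i, self.n_het_j):
            raise ValueError("n_het_het exceeds a sample's het count")
        if self.n_opp_hom > self.n_compared:
            raise ValueError("n_opp_hom exceeds n_compared")
        if min(self.n_compared, self.n_het_het, self.n_opp_hom,
               self.n_het_i, self.n_het_j) < 0:
            raise ValueError("negative count")


@dataclass
class KinshipThresholds:
    """Classification cut-offs on (phi, IBS0).

    Defaults are the conventional powers-of-two kinship ranges: phi above
    1/2^1.5 duplicate, (1/2^2.5, 1/2^1.5] first degree — parent-offspring
    when IBS0 <= ibs0_po_max — then second and third degree, else
    unrelated.  Pairs with fewer than min_compared overlapping calls are
    undetermined.
    """

    duplicate_min: float = 0.354
    first_min: float = 0.177
    second_min: float = 0.0884
    third_min: float = 0.0442
    ibs0_po_max: float = 0.01
    min_compared: int = 200


@dataclass
class KinshipResult:
    id1: str
    id2: str
    phi: float
    ibs0: float
    category: str
    counts: PairCounts = field(repr=False)


def pair_counts(gi: np.ndarray, gj: np.ndarray) -> PairCounts:
    """Tally comparison counts for two dosage vectors (missing = -1).

    Sites missing in either sample are excluded from every count.
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    if gi.shape != gj.shape:
        raise ValueError(f"length mismatch: {gi.shape} vs {gj.shape}")
    ok = (gi != MISSING) & (gj != MISSING)
    a, b = gi[ok], gj[ok]
    return PairCounts(
        n_compared=int(ok.sum()),
        n_het_het=int(((a == 1) & (b == 1)).sum()),
        n_opp_hom=int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum()),
        n_het_i=int((a == 1).sum()),
        n_het_j=int((b == 1).sum()),
    )


def king_robust(counts: PairCounts) -> float:
    """KING-robust kinship coefficient; NaN when the denominator is zero."""
    denom = counts.n_het_i + counts.n_het_j
    if denom == 0:
        return math.nan
    return (counts.n_het_het - 2 * counts.n_opp_hom) / denom


def ibs0(counts: PairCounts) -> float:
    return counts.n_opp_hom / counts.n_compared if counts.n_compared else math.nan


def classify(
    phi: float, ibs0_value: float, thresholds: KinshipThresholds | None = None,
    n_compared: int | None = None,
) -> str:
    """Map (phi, IBS0) to a relatedness category."""
    t = thresholds or KinshipThresholds()
    if math.isnan(phi) or (n_compared is not None and n_compared < t.min_compared):
        return "undetermined"
    if phi > t.duplicate_min:
        return "duplicate/clone"
    if phi > t.first_min:
        return "parent-offspring" if ibs0_value <= t.ibs0_po_max else "first-degree-other"
    if phi > t.second_min:
        return "second-degree"
    if phi > t.third_min:
        return "third-degree"
    return "unrelated"


def kinship_pair(
    G: GenotypeMatrix, id1: str, id2: str, thresholds: KinshipThresholds | None = None
) -> KinshipResult:
    c = pair_counts(G.dosage[G.sample_index(id1)], G.dosage[G.sample_index(id2)])
    phi = king_robust(c)
    i0 = ibs0(c)
    return KinshipResult(id1, id2, phi, i0, classify(phi, i0, thresholds, c.n_compared), c)


def kinship_matrix(
    G: GenotypeMatrix, thresholds: KinshipThresholds | None = None
) -> pd.DataFrame:
    """All-pairs kinship table (one row per unordered pair, diagonal omitted).

    Columns: id1, id2, n_compared, n_het_het, n_opp_hom, phi, ibs0, category.
    """
    if G.n_samples < 2:
        raise ValueError("kinship needs at least two samples")
    t = thresholds or KinshipThresholds()
    D = G.dosage
    called = D != MISSING
    het = (D == 1) & called
    hom_ref = (D == 0) & called
    hom_alt = (D == 2) & called
    # pairwise count matrices via boolean matmul
    f = np.float64
    n_cmp = called.astype(f) @ called.astype(f).T
    hh = het.astype(f) @ het.astype(f).T
    opp = hom_ref.astype(f) @ hom_alt.astype(f).T
    opp = opp + opp.T
    het_i = het.astype(f) @ called.astype(f).T  # het in i among sites called in both

    rows = []
    for i in range(G.n_samples):
        for j in range(i + 1, G.n_samples):
            c = PairCounts(
                n_compared=int(n_cmp[i, j]),
                n_het_het=int(hh[i, j]),
                n_opp_hom=int(opp[i, j]),
                n_het_i=int(het_i[i, j]),
                n_het_j=int(het_i[j, i]),
            )
            phi = king_robust(c)
            i0 = ibs0(c)
            rows.append(
                (
                    G.sample_ids[i], G.sample_ids[j], c.n_compared, c.n_het_het,
                    c.n_opp_hom, phi, i0, classify(phi, i0, t, c.n_compared),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["id1", "id2", "n_compared", "n_het_het", "n_opp_hom", "phi", "ibs0", "category"],
    )
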