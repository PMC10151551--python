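"""Directional descent arguments for parent-offspring and selfing lineages.

Three complementary tests for the claim "sample B descends from sample A
and from A alone":

* genotype containment — at every site, each of the putative offspring's
  allele copies must be present in the putative parent's genotype, up to a
  small sequencing-error allowance.  A selfed or outcrossed offspring can be
  homozygous where the parent is heterozygous, but never carry an allele the
  parent lacks; the reverse direction fails for a true parent, giving the
  relationship a direction.
* heterozygosity ratio — each selfing (or clone-by-clone breeding)
  generation halves expected heterozygosity, so the offspring/parent ratio
  of heterozygous-site counts estimates the number of selfing generations
  as g = round(log2(parent_het / offspring_het)).
* phased haplotype matching — each offspring haplotype should match one of
  the parent's haplotypes nearly perfectly, chromosome by chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix


@dataclass
class ContainmentResult:
    """Outcome of a one-direction genotype-containment test.

    ``n_violating_alleles`` counts offspring allele copies absent from the
    parent genotype at the same site (parent AA vs offspring Aa -> 1,
    vs aa -> 2; a heterozygous parent can never be violated).  The error
    rate normalises by the 2 * n_sites_compared allele copies examined.
    """

    parent_id: str
    offspring_id: str
    n_sites_compared: int
    n_violating_alleles: int
    allowance: int
    contained: bool

    @property
    def error_rate(self) -> float:
        if self.n_sites_compared == 0:
            return math.nan
        return self.n_violating_alleles / (2 * self.n_sites_compared)


@dataclass
class SelfingEstimate:
    """Selfing-generation estimate from the heterozygosity ratio.

    ratio = het_offspring / het_parent; g_hat = round(log2(1 / ratio)),
    floored at 0; ``compatible`` is True when the ratio lies within a
    multiplicative tolerance of (1/2)^g_hat.
    """

    het_parent: int
    het_offspring: int
    ratio: float
    g_hat: int | None
    compatible: bool
    tolerance: float = 0.25


def _violations(parent: np.ndarray, offspring: np.ndarray) -> tuple[int, int]:
    """(n_sites_compared, n_violating_alleles) for dosage vectors."""
    parent = np.asarray(parent)
    offspring = np.asarray(offspring)
    if parent.shape != offspring.shape:
        raise ValueError(f"length mismatch: {parent.shape} vs {offspring.shape}")
    ok = (parent != MISSING) & (offspring != MISSING)
    p, o = parent[ok].astype(np.int64), offspring[ok].astype(np.int64)
    # alt copies the parent cannot supply when hom-ref; ref copies when hom-alt
    v = np.where(p == 0, o, 0) + np.where(p == 2, 2 - o, 0)
    return int(ok.sum()), int(v.sum())


def containment_test(
    parent: np.ndarray,
    offspring: np.ndarray,
    allowance: float = 0.005,
    parent_id: str = "parent",
    offspring_id: str = "offspring",
) -> ContainmentResult:
    """Test whether every offspring allele is present in the parent genotype.

    ``allowance`` is either a maximum count of violating alleles (int >= 1)
    or a maximum per-allele violation rate (float < 1), converted to a count
    over the 2 * n_compared allele copies.  Sites missing in either sample
    are skipped.
    """
    n_cmp, n_viol = _violations(parent, offspring)
    if isinstance(allowance, float) and allowance < 1:
        max_viol = int(math.floor(allowance * 2 * n_cmp))
    else:
        max_viol = int(allowance)
    return ContainmentResult(
        parent_id=parent_id,
        offspring_id=offspring_id,
        n_sites_compared=n_cmp,
        n_violating_alleles=n_viol,
        allowance=max_viol,
        contained=n_viol <= max_viol,
    )


def directionality(
    a: np.ndarray, b: np.ndarray, allowance: float = 0.005,
    id_a: str = "a", id_b: str = "b",
) -> str:
    """Run containment both ways: a_contains_b, b_contains_a, mutual or neither."""
    ab = containment_test(a, b, allowance, id_a, id_b).contained
    ba = containment_test(b, a, allowance, id_b, id_a).contained
    if ab and ba:
        return "mutual"
    if ab:
        return "a_contains_b"
    if ba:
        return "b_contains_a"
    return "neither"


def selfing_generations(
    parent: np.ndarray, offspring: np.ndarray, tolerance: float = 0.25
) -> SelfingEstimate:
    """Estimate selfing generations separating offspring from parent.

    Heterozygote counts are restricted to sites called in both samples, so
    differential missingness cannot masquerade as selfing.
    """
    parent = np.asarray(parent)
    offspring = np.asarray(offspring)
    if parent.shape != offspring.shape:
        raise ValueError("length mismatch")
    ok = (parent != MISSING) & (offspring != MISSING)
    hp = int((parent[ok] == 1).sum())
    ho = int((offspring[ok] == 1).sum())
    if hp == 0 or ho == 0:
        return SelfingEstimate(hp, ho, math.nan, None, False, tolerance)
    ratio = ho / hp
    g_hat = max(0, round(math.log2(1.0 / ratio)))
    expected = 0.5 ** g_hat
    compatible = abs(ratio - expected) <= tolerance * expected
    return SelfingEstimate(hp, ho, ratio, g_hat, compatible, tolerance)


def haplotype_containment(
    G: GenotypeMatrix, parent_id: str, offspring_id: str
) -> pd.DataFrame:
    """Match each offspring haplotype to its closest parent haplotype.

    For every chromosome and each offspring haplotype, reports the parent
    haplotype with the smaller mismatch fraction over sites phased in both
    samples.  Requires phased input.

    Returns a DataFrame with columns chrom, offspring_hap, best_parent_hap,
    mismatch_fraction, n_sites.
    """
    if G.haplotypes is None:
        raise ValueError("haplotype containment requires phased genotypes")
    from .simulate import _chrom_slices

    i = G.sample_index(parent_id)
    j = G.sample_index(offspring_id)
    H = G.haplotypes
    rows = []
    for a, b in _chrom_slices(G.loci):
        chrom = str(G.loci["chrom"].iloc[a])
        ok = (H[i, a:b] != MISSING).all(axis=1) & (H[j, a:b] != MISSING).all(axis=1)
        n = int(ok.sum())
        for oh in (0, 1):
            off = H[j, a:b, oh][ok]
            if n == 0:
                rows.append((chrom, oh + 1, None, math.nan, 0))
                continue
            frac = [float((off != H[i, a:b, ph][ok]).mean()) for ph in (0, 1)]
            best = int(np.argmin(frac))
            rows.append((chrom, oh + 1, best + 1, frac[best], n))
    return pd.DataFrame(
        rows, columns=["chrom", "offspring_hap", "best_parent_hap", "mismatch_fraction", "n_sites"]
    )


def descent_report(
    G: GenotypeMatrix, id_a: str, id_b: str, allowance: float = 0.005
) -> dict:
    """Full two-sample descent report (containment both ways, het ratio,
    haplotype matching when phase is available) as a JSON-serialisable dict."""
    ga = G.dosage[G.sample_index(id_a)]
    gb = G.dosage[G.sample_index(id_b)]
    fwd = containment_test(ga, gb, allowance, id_a, id_b)
    rev = containment_test(gb, ga, allowance, id_b, id_a)
    selfing = selfing_generations(ga, gb)
    both_called = int(((ga != MISSING) & (gb != MISSING)).sum())
    report = {
        "pair": [id_a, id_b],
        "n_loci_total": G.n_loci,
        "n_sites_pairwise_complete": both_called,
        "containment": {
            f"{id_a}_contains_{id_b}": {
                "n_sites_compared": fwd.n_sites_compared,
                "n_violating_alleles": fwd.n_violating_alleles,
                "error_rate": fwd.error_rate,
                "contained": fwd.contained,
            },
            f"{id_b}_contains_{id_a}": {
                "n_sites_compared": rev.n_sites_compared,
                "n_violating_alleles": rev.n_violating_alleles,
                "error_rate": rev.error_rate,
                "contained": rev.contained,
            },
        },
        "verdict": directionality(ga, gb, allowance, id_a, id_b),
        "selfing": {
            "het_parent": selfing.het_parent,
            "het_offspring": selfing.het_offspring,
            "ratio": selfing.ratio,
            "g_hat": selfing.g_hat,
            "compatible": selfing.compatible,
        },
    }
    if G.haplotypes is not None:
        hap = haplotype_containment(G, id_a, id_b)
        report["haplotype_matches"] = hap.to_dict(orient="records")
    return report
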