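"""Polygenic berry-colour scoring.

Berry colour in grape behaves as an ordinal trait (white, gray, rose, red,
black graded 0-4) with a largely additive genetic basis at a small set of
loci.  Given a table of per-locus effect-allele weights in colour-grade
units, the polygenic score of a sample is the sum of effect-allele dosage
times effect over the loci with genotype calls.  Scores are interpreted by
placement within the score distribution of a reference panel of known
colour.

``fit_allele_effects`` is a simple per-locus least-squares estimator of
such weights from a graded panel, intended for validating the scoring
machinery on simulated data — not a full association-study replacement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class EffectTable:
    """Per-locus effect-allele weights.

    Wraps a DataFrame with columns chrom, pos, effect_allele, beta and an
    optional pvalue; loci must be unique by (chrom, pos).
    """

    COLUMNS = ("chrom", "pos", "effect_allele", "beta")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"effect table lacks columns {missing}")
        if df.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("effect loci not unique by (chrom, pos)")
        if not np.isfinite(df["beta"].to_numpy(dtype=float)).all():
            raise ValueError("effect sizes must be finite")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def read_tsv(cls, path: str) -> "EffectTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def effect_dosage(self, G: GenotypeMatrix) -> np.ndarray:
        """Per-sample dosage of the effect allele at each table locus.

        Shape (n_samples, len(table)); NaN where the call is missing.  The
        effect allele may be either ref or alt at a locus; the dosage is
        flipped to count effect-allele copies, so relabelling alleles with a
        sign-flipped beta leaves scores unchanged up to a constant.
        Raises KeyError if a table locus is absent from the matrix.
        """
        key = {(c, p): j for j, (c, p) in enumerate(zip(G.loci["chrom"], G.loci["pos"]))}
        out = np.full((G.n_samples, len(self.df)), np.nan)
        for k, row in self.df.iterrows():
            j = key.get((row["chrom"], row["pos"]))
            if j is None:
                raise KeyError(f"effect locus {row['chrom']}:{row['pos']} not in matrix")
            d = G.dosage[:, j].astype(float)
            d[G.dosage[:, j] == MISSING] = np.nan
            allele = row["effect_allele"]
            if allele == G.loci["alt"].iloc[j]:
                out[:, k] = d
            elif allele == G.loci["ref"].iloc[j]:
                out[:, k] = 2.0 - d
            else:
                raise ValueError(
                    f"effect allele {allele} matches neither allele at "
                    f"{row['chrom']}:{row['pos']}"
                )
        return out


@dataclass
class ColorScore:
    sample_id: str
    score: float
    n_loci_used: int
    defined: bool


def polygenic_scores(
    G: GenotypeMatrix, effects: EffectTable, min_loci: int = 1
) -> pd.DataFrame:
    """Score every sample: sum of effect-allele dosage x beta over called loci.

    Loci with missing calls are skipped (no imputation); a sample with fewer
    than ``min_loci`` usable loci is flagged undefined (score NaN).

    Returns a DataFrame (sample, score, n_loci_used, defined).
    """
    if len(effects) == 0:
        raise ValueError("empty effect table")
    dos = effects.effect_dosage(G)
    beta = effects.df["beta"].to_numpy(dtype=float)
    used = ~np.isnan(dos)
    n_used = used.sum(axis=1)
    score = np.nansum(dos * beta[None, :], axis=1)
    defined = n_used >= min_loci
    score = np.where(defined, score, np.nan)
    return pd.DataFrame(
        {"sample": G.sample_ids, "score": score, "n_loci_used": n_used, "defined": defined}
    )


def polygenic_score(
    G: GenotypeMatrix, sample_id: str, effects: EffectTable, min_loci: int = 1
) -> ColorScore:
    """Score a single sample (see :func:`polygenic_scores`)."""
    df = polygenic_scores(G, effects, min_loci)
    row = df.set_index("sample").loc[sample_id]
    return ColorScore(sample_id, float(row["score"]), int(row["n_loci_used"]), bool(row["defined"]))


def percentile_placement(
    score: float, reference: dict[str, np.ndarray]
) -> dict[str, float]:
    """Fraction of each reference category scoring strictly below ``score``.

    Ties contribute half weight, so the placement is order-independent and
    monotone non-decreasing in the score.
    """
    out = {}
    for cat, ref in reference.items():
        ref = np.asarray(ref, dtype=float)
        ref = ref[~np.isnan(ref)]
        if ref.size == 0:
            raise ValueError(f"empty reference category {cat!r}")
        out[cat] = float(((ref < score).sum() + 0.5 * (ref == score).sum()) / ref.size)
    return out


def fit_allele_effects(
    G: GenotypeMatrix,
    grades: np.ndarray,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> EffectTable:
    """Per-locus least-squares regression of colour grade on alt dosage.

    Retains loci whose slope p-value clears ``alpha`` after Bonferroni
    correction over ``n_tests`` (default: the number of polymorphic loci
    tested).  Monomorphic loci are skipped with a log count.  The effect
    allele is the alt allele; a negative beta means alt lightens the berry.
    """
    grades = np.asarray(grades, dtype=float)
    if grades.shape != (G.n_samples,) or np.isnan(grades).any():
        raise ValueError("grades must be present for every panel sample")
    rows = []
    n_mono = 0
    for j in range(G.n_loci):
        d = G.dosage[:, j]
        ok = d != MISSING
        x = d[ok].astype(float)
        if ok.sum() < 3 or np.ptp(x) == 0:
            n_mono += 1
            continue
        res = stats.linregress(x, grades[ok])
        rows.append(
            (G.loci["chrom"].iloc[j], G.loci["pos"].iloc[j], G.loci["alt"].iloc[j],
             res.slope, res.pvalue)
        )
    if n_mono:
        logger.info("fit_allele_effects: skipped %d monomorphic/sparse loci", n_mono)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "effect_allele", "beta", "pvalue"])
    n_tests = n_tests if n_tests is not None else max(len(df), 1)
    df = df[df["pvalue"] < alpha / n_tests].reset_index(drop=True)
    return EffectTable(df)
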