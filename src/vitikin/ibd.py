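"""Identity-by-descent segment sharing.

Consumes haplotype-level IBD segment calls (refined-IBD-style tab files),
aggregates them into per-pair summed-sharing matrices, and orders samples
for heatmap display either by hierarchical clustering or by average
closeness to a focal (e.g. archaeological) sample set.

:func:`naive_segments` is a desk-scale exact-match segment finder for
error-free phased data; probabilistic IBD detection on real data is the job
of external phasing/IBD software whose output this module parses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: column order of the segment file dialect
IBD_COLUMNS = ("id1", "hap1", "id2", "hap2", "chrom", "start", "end", "lod")


@dataclass(frozen=True)
class IbdSegment:
    """A shared haplotype segment; coordinates are 1-based, end inclusive."""

    id1: str
    hap1: int
    id2: str
    hap2: int
    chrom: str
    start: int
    end: int
    lod: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.hap1 not in (1, 2) or self.hap2 not in (1, 2):
            raise ValueError("haplotype indices must be 1 or 2")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def parse_ibd(path: str, min_lod: float = 3.0, columns=IBD_COLUMNS) -> list[IbdSegment]:
    """Read a whitespace/tab-delimited segment file, dropping weak calls.

    Rows with LOD <= ``min_lod`` are discarded; malformed rows are skipped
    with a logged count.  ``columns`` remaps the dialect if a caller's files
    order fields differently.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, names=list(columns),
                         dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return []
    segs: list[IbdSegment] = []
    n_bad = 0
    for row in df.itertuples(index=False):
        try:
            seg = IbdSegment(
                id1=str(row.id1), hap1=int(row.hap1),
                id2=str(row.id2), hap2=int(row.hap2),
                chrom=str(row.chrom), start=int(row.start), end=int(row.end),
                lod=float(row.lod),
            )
        except (TypeError, ValueError):
            n_bad += 1
            continue
        if seg.lod > min_lod:
            segs.append(seg)
    if n_bad:
        logger.warning("parse_ibd: skipped %d malformed rows in %s", n_bad, path)
    return segs


@dataclass
class SharingMatrix:
    """Per-pair total shared base pairs and segment counts.

    Symmetric with a zero diagonal; totals sum segment lengths over all
    four haplotype pairings of each sample pair.
    """

    sample_ids: list[str]
    total_bp: np.ndarray
    n_segments: np.ndarray

    def __post_init__(self):
        n = len(self.sample_ids)
        assert self.total_bp.shape == (n, n) and self.n_segments.shape == (n, n)

    def total(self, id1: str, id2: str) -> int:
        i, j = self.sample_ids.index(id1), self.sample_ids.index(id2)
        return int(self.total_bp[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.total_bp, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path: str) -> None:
        self.to_frame().rename_axis("sample").to_csv(path, sep="\t")


def sharing_matrix(segments: list[IbdSegment], sample_ids: list[str]) -> SharingMatrix:
    """Sum shared segment lengths into a per-pair relatedness matrix.

    Samples absent from the segment list get all-zero rows; segments whose
    samples are not in ``sample_ids`` are ignored with a log notice.
    """
    n = len(sample_ids)
    idx = {s: i for i, s in enumerate(sample_ids)}
    total = np.zeros((n, n), dtype=np.int64)
    count = np.zeros((n, n), dtype=np.int64)
    n_unknown = 0
    for seg in segments:
        i, j = idx.get(seg.id1), idx.get(seg.id2)
        if i is None or j is None or i == j:
            n_unknown += 1
            continue
        total[i, j] += seg.length
        total[j, i] += seg.length
        count[i, j] += 1
        count[j, i] += 1
    if n_unknown:
        logger.info("sharing_matrix: ignored %d segments outside the sample set", n_unknown)
    return SharingMatrix(list(sample_ids), total, count)


def order_samples(
    M: SharingMatrix, mode: str = "hclust", focal: list[str] | None = None
) -> list[str]:
    """Sample display order for a sharing heatmap.

    ``hclust``: average-linkage agglomerative clustering on the distance
    ``1 - shared / max(shared)``; returns the dendrogram leaf order.

    ``closeness``: the focal samples first (input order), then the rest in
    descending mean shared length with the focal set.
    """
    ids = M.sample_ids
    if mode == "hclust":
        if len(ids) < 3:
            return list(ids)
        mx = M.total_bp.max()
        dist = 1.0 - M.total_bp / mx if mx > 0 else np.ones_like(M.total_bp, dtype=float)
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        return [ids[i] for i in leaves_list(Z)]
    if mode == "closeness":
        if not focal:
            raise ValueError("closeness ordering requires a non-empty focal set")
        fidx = [ids.index(f) for f in focal]
        rest = [s for s in ids if s not in set(focal)]
        mean_share = {s: M.total_bp[ids.index(s), fidx].mean() for s in rest}
        rest.sort(key=lambda s: (-mean_share[s], s))
        return list(focal) + rest
    raise ValueError(f"unknown ordering mode {mode!r}")


def naive_segments(
    hapA: np.ndarray,
    hapB: np.ndarray,
    positions: np.ndarray,
    min_bp: int = 1,
    chrom: str = "chr1",
    id1: str = "A",
    hap1: int = 1,
    id2: str = "B",
    hap2: int = 1,
) -> list[IbdSegment]:
    """Exact-match segment finder for error-free phased haplotypes.

    Emits every maximal run of identical alleles whose spanned base pairs
    (last position - first position + 1) reach ``min_bp``.  The LOD field is
    set to +inf: these are exact matches, not statistical calls.
    """
    hapA = np.asarray(hapA)
    hapB = np.asarray(hapB)
    positions = np.asarray(positions)
    if hapA.shape != hapB.shape or hapA.shape != positions.shape:
        raise ValueError("haplotypes and positions must have equal length")
    if len(positions) > 1 and not (np.diff(positions) > 0).all():
        raise ValueError("positions must be strictly ascending")
    segs = []
    same = hapA == hapB
    from .simulate import _runs  # local import: simulate imports IbdSegment

    for s, e in _runs(same):
        start, end = int(positions[s]), int(positions[e - 1])
        if end - start + 1 >= min_bp:
            segs.append(IbdSegment(id1, hap1, id2, hap2, chrom, start, end, math.inf))
    return segs


def matrix_segments(G, min_bp: int = 1) -> list[IbdSegment]:
    """Run the naive finder over every sample pair and haplotype pairing."""
    if G.haplotypes is None:
        raise ValueError("naive segment finding requires phased haplotypes")
    from .simulate import _chrom_slices

    pos = G.loci["pos"].to_numpy()
    segs: list[IbdSegment] = []
    for a, b in _chrom_slices(G.loci):
        chrom = str(G.loci["chrom"].iloc[a])
        for i in range(G.n_samples):
            for j in range(i + 1, G.n_samples):
                for h1 in (0, 1):
                    for h2 in (0, 1):
                        segs.extend(
                            naive_segments(
                                G.haplotypes[i, a:b, h1], G.haplotypes[j, a:b, h2],
                                pos[a:b], min_bp, chrom,
                                G.sample_ids[i], h1 + 1, G.sample_ids[j], h2 + 1,
                            )
                        )
    return segs


def write_ibd(segments: list[IbdSegment], path: str) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{s.id1}\t{s.hap1}\t{s.id2}\t{s.hap2}\t{s.chrom}\t{s.start}\t{s.end}\t{s.lod}\n"
            )
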