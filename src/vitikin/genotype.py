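"""Genotype container, VCF input/output and dataset-construction filters.

The central object is :class:`GenotypeMatrix`: a samples x loci matrix of
diploid alt-allele dosages (0/1/2, ``-1`` for a missing call), with optional
per-call read depth and phased haplotypes.  Low-coverage ancient samples make
missingness a first-class citizen: every summary (call rate, allele
frequency, heterozygosity) is computed over called genotypes only.

Filtering reproduces the usual sparse-panel dataset construction: a per-call
depth mask for sequenced (non-array) samples, locus and sample call-rate
thresholds, and a minor-allele-frequency stage with its own call-rate
requirement.  :func:`build_dual_datasets` implements the two-dataset
trade-off between SNP count and ancient-sample count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

_GROUPS = ("archaeological", "cultivated", "wild")


class GenotypeError(ValueError):
    """Raised for malformed or empty genotype data."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for a panel of samples.

    Parameters
    ----------
    sample_ids
        Ordered sample names, unique.
    loci
        DataFrame with columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``;
        loci unique by (chrom, pos).
    dosage
        ``(n_samples, n_loci)`` int8 array of alt-allele dosages in
        {0, 1, 2}; ``-1`` marks a missing call.
    depth
        Optional ``(n_samples, n_loci)`` int32 array of per-call read depth.
    haplotypes
        Optional ``(n_samples, n_loci, 2)`` int8 array of phased alleles
        (0 = ref, 1 = alt, -1 = missing).  Where present and called, the two
        alleles sum to the dosage.
    ancestry
        Optional ``(n_samples, n_loci, 2)`` int32 array of founder-haplotype
        labels used by the simulator for identity-by-descent ground truth
        (label ``2*f + k`` = haplotype ``k`` of founder ``f``; -1 unknown).
    samples
        Per-sample metadata indexed by sample id, with columns ``group``
        (archaeological / cultivated / wild), ``region`` and ``color``.
    """

    sample_ids: list[str]
    loci: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray | None = None
    haplotypes: np.ndarray | None = None
    ancestry: np.ndarray | None = None
    samples: pd.DataFrame | None = None

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeError("duplicate sample ids")
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (self.n_samples, self.n_loci):
            raise GenotypeError(
                f"dosage shape {self.dosage.shape} != "
                f"({self.n_samples}, {self.n_loci})"
            )
        dup = self.loci.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise GenotypeError("loci not unique by (chrom, pos)")
        self.loci = self.loci.reset_index(drop=True)
        if self.samples is None:
            self.samples = pd.DataFrame(
                {"group": "cultivated", "region": "", "color": ""},
                index=pd.Index(self.sample_ids, name="sample"),
            )

    # -- basic shape / masks -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls, shape (n_samples, n_loci)."""
        return self.dosage != MISSING

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    # -- per-locus / per-sample summaries ------------------------------------

    def locus_call_rate(self, sample_subset: np.ndarray | None = None) -> np.ndarray:
        called = self.called if sample_subset is None else self.called[sample_subset]
        n = called.shape[0]
        return called.sum(axis=0) / n if n else np.zeros(self.n_loci)

    def sample_call_rate(self) -> np.ndarray:
        return self.called.mean(axis=1) if self.n_loci else np.zeros(self.n_samples)

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per locus over called genotypes (NaN if none)."""
        called = self.called
        n_alleles = 2 * called.sum(axis=0).astype(float)
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def het_counts(self) -> np.ndarray:
        """Number of heterozygous calls per sample."""
        return (self.dosage == 1).sum(axis=1)

    # -- subsetting ----------------------------------------------------------

    def subset(
        self,
        samples: list[str] | np.ndarray | None = None,
        locus_mask: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given samples and/or loci."""
        if samples is None:
            row_idx = np.arange(self.n_samples)
            ids = self.sample_ids
        elif np.asarray(samples).dtype == bool:
            row_idx = np.flatnonzero(samples)
            ids = [self.sample_ids[i] for i in row_idx]
        else:
            ids = list(samples)
            row_idx = np.array([self.sample_index(s) for s in ids], dtype=int)
        col_idx = (
            np.arange(self.n_loci) if locus_mask is None else np.flatnonzero(locus_mask)
        )

        def take(a):
            return None if a is None else a[np.ix_(row_idx, col_idx)]

        return GenotypeMatrix(
            sample_ids=ids,
            loci=self.loci.iloc[col_idx],
            dosage=self.dosage[np.ix_(row_idx, col_idx)],
            depth=take(self.depth),
            haplotypes=None if self.haplotypes is None else self.haplotypes[np.ix_(row_idx, col_idx)],
            ancestry=None if self.ancestry is None else self.ancestry[np.ix_(row_idx, col_idx)],
            samples=self.samples.loc[ids].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            loci=self.loci.copy(),
            dosage=self.dosage.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            haplotypes=None if self.haplotypes is None else self.haplotypes.copy(),
            ancestry=None if self.ancestry is None else self.ancestry.copy(),
            samples=self.samples.copy(),
        )

    def mask_calls(self, mask: np.ndarray) -> None:
        """Set the calls selected by a boolean (n_samples, n_loci) mask to missing."""
        self.dosage[mask] = MISSING
        if self.haplotypes is not None:
            self.haplotypes[mask] = MISSING


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> GenotypeMatrix:
    """Load biallelic SNP records from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (a count is logged).
    Missing genotypes become missing dosages; phased calls populate the
    haplotype array; FORMAT/DP, when present, populates per-call depth.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    rows, dosages, haps, depths = [], [], [], []
    n_skipped = 0
    any_phased = False
    any_depth = False
    bases = {"A", "C", "G", "T"}
    for v in vcf:
        if (
            len(v.ALT) != 1
            or v.REF not in bases
            or v.ALT[0] not in bases
        ):
            n_skipped += 1
            continue
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        gts = np.array(v.genotypes, dtype=np.int16)  # (n, 3): a0, a1, phased
        alleles = gts[:, :2].astype(np.int8)
        phased = gts[:, 2].astype(bool)
        missing = (alleles < 0).any(axis=1)
        dos = alleles.sum(axis=1).astype(np.int8)
        dos[missing] = MISSING
        dosages.append(dos)
        hap = alleles.copy()
        hap[~phased] = MISSING
        hap[missing] = MISSING
        haps.append(hap)
        any_phased = any_phased or bool((phased & ~missing).any())
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            d = dp.astype(np.int32).reshape(n)
            d[d < 0] = 0
        else:
            d = np.zeros(n, dtype=np.int32)
        any_depth = any_depth or dp is not None
        depths.append(d)
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not rows:
        raise GenotypeError(f"no biallelic SNP records in {path}")
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(
        sample_ids=sample_ids,
        loci=loci,
        dosage=np.stack(dosages, axis=1),
        depth=np.stack(depths, axis=1) if any_depth else None,
        haplotypes=np.stack(haps, axis=1) if any_phased else None,
    )


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write the matrix as an uncompressed VCF 4.2 file (GT, and DP if present).

    Calls with phased haplotypes are written ``a|b``; everything else
    unphased ``a/b`` (``./.`` when missing).
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "vitikin")
    for chrom in pd.unique(G.loci["chrom"]):
        max_pos = int(G.loci.loc[G.loci["chrom"] == chrom, "pos"].max())
        header.contigs.add(str(chrom), length=max_pos + 1000)
    header.formats.add("GT", 1, "String", "Genotype")
    if G.depth is not None:
        header.formats.add("DP", 1, "Integer", "Read depth")
    for s in G.sample_ids:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(G.n_loci):
            row = G.loci.iloc[j]
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            for i, s in enumerate(G.sample_ids):
                d = int(G.dosage[i, j])
                call = rec.samples[s]
                if d == MISSING:
                    call["GT"] = (None, None)
                elif G.haplotypes is not None and G.haplotypes[i, j, 0] != MISSING:
                    call["GT"] = (int(G.haplotypes[i, j, 0]), int(G.haplotypes[i, j, 1]))
                    call.phased = True
                else:
                    call["GT"] = (0, 1) if d == 1 else (d // 2, d // 2)
                if G.depth is not None:
                    call["DP"] = int(G.depth[i, j])
            out.write(rec)


def read_sample_metadata(path: str) -> pd.DataFrame:
    """Read a sample-metadata TSV with columns sample, group, region, color."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "sample" not in df.columns:
        raise GenotypeError("metadata must have a 'sample' column")
    bad = set(df.get("group", pd.Series(dtype=str))) - set(_GROUPS) - {""}
    if bad:
        raise GenotypeError(f"unknown sample groups: {sorted(bad)}")
    for col in ("group", "region", "color"):
        if col not in df.columns:
            df[col] = ""
    return df.set_index("sample")[["group", "region", "color"]]


def write_sample_metadata(G: GenotypeMatrix, path: str) -> None:
    G.samples.rename_axis("sample").reset_index().to_csv(path, sep="\t", index=False)


def attach_metadata(G: GenotypeMatrix, meta: pd.DataFrame) -> None:
    """Attach metadata rows (by sample id) to the matrix in place."""
    present = [s for s in G.sample_ids if s in meta.index]
    G.samples.loc[present, meta.columns] = meta.loc[present].values


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterSpec:
    """Dataset-construction thresholds.

    ``min_depth`` masks individual calls below the depth threshold in the
    samples named by ``depth_samples`` (sequenced samples; array-derived
    panel genotypes carry no meaningful depth).  ``min_maf`` with
    ``maf_callrate`` is the stricter variant-selection stage used before
    kinship estimation; set ``min_maf=0`` to skip it.
    """

    min_locus_callrate: float = 0.75
    min_sample_callrate: float = 0.60
    min_depth: int = 5
    depth_samples: tuple[str, ...] | None = None  # None = apply to all samples
    min_maf: float = 0.03
    maf_callrate: float = 0.80

    def __post_init__(self):
        for name in ("min_locus_callrate", "min_sample_callrate", "min_maf", "maf_callrate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass
class FilterReport:
    """Counts removed at each filtering stage, in order of application."""

    n_samples_in: int = 0
    n_loci_in: int = 0
    calls_masked_by_depth: int = 0
    loci_removed_callrate: int = 0
    samples_removed_callrate: int = 0
    loci_removed_maf: int = 0
    n_samples_out: int = 0
    n_loci_out: int = 0
    stages: list = field(default_factory=list)

    def to_json(self, path: str | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def apply_filters(
    G: GenotypeMatrix,
    spec: FilterSpec,
    exempt_samples: tuple[str, ...] = (),
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply dataset-construction filters in a fixed, auditable order.

    Order: per-call depth mask -> locus call rate -> sample call rate ->
    MAF (computed on calls surviving the previous stages).  Samples in
    ``exempt_samples`` are never removed by the sample-call-rate stage.

    Returns the filtered matrix and a :class:`FilterReport`.  Raises
    :class:`GenotypeError` if nothing survives.
    """
    rep = FilterReport(n_samples_in=G.n_samples, n_loci_in=G.n_loci)
    out = G.copy()

    # 1. depth mask on individual calls
    if out.depth is not None and spec.min_depth > 0:
        if spec.depth_samples is None:
            rows = np.ones(out.n_samples, dtype=bool)
        else:
            rows = np.array([s in spec.depth_samples for s in out.sample_ids])
        low = rows[:, None] & (out.depth < spec.min_depth) & out.called
        rep.calls_masked_by_depth = int(low.sum())
        out.mask_calls(low)
    rep.stages.append(("depth_mask", out.n_samples, out.n_loci))

    # 2. locus call rate
    keep_loci = out.locus_call_rate() >= spec.min_locus_callrate
    rep.loci_removed_callrate = int((~keep_loci).sum())
    out = out.subset(locus_mask=keep_loci)
    rep.stages.append(("locus_callrate", out.n_samples, out.n_loci))

    # 3. sample call rate
    keep_samples = out.sample_call_rate() >= spec.min_sample_callrate
    for s in exempt_samples:
        if s in out.sample_ids:
            keep_samples[out.sample_index(s)] = True
    rep.samples_removed_callrate = int((~keep_samples).sum())
    out = out.subset(samples=keep_samples)
    rep.stages.append(("sample_callrate", out.n_samples, out.n_loci))

    # 4. MAF (+ its own call-rate requirement), on the post-filter calls
    if spec.min_maf > 0 and out.n_loci:
        maf = out.maf()
        cr = out.locus_call_rate()
        keep = (~np.isnan(maf)) & (maf >= spec.min_maf) & (cr >= spec.maf_callrate)
        rep.loci_removed_maf = int((~keep).sum())
        out = out.subset(locus_mask=keep)
    rep.stages.append(("maf", out.n_samples, out.n_loci))

    rep.n_samples_out, rep.n_loci_out = out.n_samples, out.n_loci
    if out.n_samples == 0 or out.n_loci == 0:
        raise GenotypeError("no data survive filters")
    return out, rep


def build_dual_datasets(
    G: GenotypeMatrix,
    focal_samples: list[str],
    spec: FilterSpec,
) -> tuple[GenotypeMatrix, GenotypeMatrix, dict]:
    """Build the two complementary datasets of the sparse-panel strategy.

    ``wide`` maximises locus count: focal (ancient) samples that fail the
    sample-call-rate threshold on the locus-filtered matrix are dropped
    before filtering, so their sparsity does not drag loci down.

    ``deep`` maximises focal-sample count: only loci called in *every*
    focal sample are considered, all focal samples are retained (exempt
    from the sample-call-rate stage), and the standard filters then apply.

    Returns (wide, deep, report_dict).
    """
    missing = [s for s in focal_samples if s not in G.sample_ids]
    if missing:
        raise KeyError(f"focal samples not in matrix: {missing}")

    # which focal samples individually survive the sample-call-rate bar
    # on the locus-filtered matrix
    probe, _ = apply_filters(
        G, FilterSpec(
            min_locus_callrate=spec.min_locus_callrate,
            min_sample_callrate=0.0,
            min_depth=spec.min_depth,
            depth_samples=spec.depth_samples,
            min_maf=0.0,
        ),
    )
    cr = dict(zip(probe.sample_ids, probe.sample_call_rate()))
    wide_focal = [s for s in focal_samples if cr.get(s, 0.0) >= spec.min_sample_callrate]
    keep = [s for s in G.sample_ids if s not in set(focal_samples) - set(wide_focal)]
    wide, wide_rep = apply_filters(G.subset(samples=keep), spec)

    focal_idx = np.array([G.sample_index(s) for s in focal_samples])
    focal_called = G.called[focal_idx].all(axis=0)
    deep, deep_rep = apply_filters(
        G.subset(locus_mask=focal_called), spec, exempt_samples=tuple(focal_samples)
    )

    report = {
        "focal_samples": list(focal_samples),
        "wide_focal_retained": wide_focal,
        "wide": {"n_samples": wide.n_samples, "n_loci": wide.n_loci},
        "deep": {"n_samples": deep.n_samples, "n_loci": deep.n_loci},
        "wide_report": asdict(wide_rep),
        "deep_report": asdict(deep_rep),
    }
    logger.info(
        "dual datasets: wide %d samples x %d loci; deep %d samples x %d loci",
        wide.n_samples, wide.n_loci, deep.n_samples, deep.n_loci,
    )
    return wide, deep, report
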