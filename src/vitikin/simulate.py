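"""Pedigree and genotype-panel simulator.

Generates the statistical structure the downstream analyses assume: diploid
biallelic founders in Hardy-Weinberg equilibrium, pedigrees mixing
outcrossing, selfing and clonal propagation, phased haplotypes with
founder-haplotype ancestry labels (identity-by-descent ground truth), a
genotyping degradation step (per-allele error, per-sample missingness,
per-call read depth) mimicking sparse ancient-DNA calls, and an ordinal
berry-colour phenotype driven by additive allele effects.

Gametes are formed per chromosome as a two-state Markov walk over the
parent's two haplotypes with switch probability ``crossover_rate`` between
adjacent loci.  The default 0.5 makes every locus an independent Mendelian
draw; rates near 0 transmit long intact haplotype blocks, which is what the
IBD-segment machinery needs for exact ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix
from .ibd import IbdSegment

logger = logging.getLogger(__name__)

COLOR_NAMES = ("white", "gray", "rose", "red", "black")  # grades 0..4


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Simulation parameters.

    error_rate is the per-allele flip probability (the study's ancient-call
    arithmetic implies a floor around 0.33%, the default here).
    missing_rate may be a single probability or a sample-id -> probability
    mapping; mean_depth is the Poisson mean of per-call read depth.
    """

    n_founders: int = 20
    n_loci: int = 1000
    freq_range: tuple[float, float] = (0.05, 0.95)
    error_rate: float = 0.0033
    missing_rate: float | dict[str, float] = 0.0
    mean_depth: float = 30.0
    n_chrom: int = 19
    locus_spacing_bp: int = 1000
    crossover_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 1 or self.n_loci < 1 or self.n_chrom < 1:
            raise ConfigError("n_founders, n_loci and n_chrom must be >= 1")
        lo, hi = self.freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError(f"freq_range {self.freq_range} invalid")
        for name, v in (("error_rate", self.error_rate), ("crossover_rate", self.crossover_rate)):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        rates = (
            self.missing_rate.values()
            if isinstance(self.missing_rate, dict)
            else [self.missing_rate]
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ConfigError("missing rates must lie in [0, 1]")
        if self.mean_depth < 0:
            raise ConfigError("mean_depth must be >= 0")


@dataclass
class PedigreeEvent:
    child: str
    kind: str  # cross | self | clone
    parents: tuple[str, ...]


@dataclass
class PedigreeSpec:
    """Ordered breeding events; parents must be declared before children."""

    events: list[PedigreeEvent] = field(default_factory=list)

    def __post_init__(self):
        for ev in self.events:
            need = 2 if ev.kind == "cross" else 1
            if ev.kind not in ("cross", "self", "clone"):
                raise ConfigError(f"unknown event kind {ev.kind!r}")
            if len(ev.parents) != need:
                raise ConfigError(f"{ev.kind} event for {ev.child} needs {need} parent(s)")

    def validate_against(self, founder_ids: list[str]) -> None:
        known = set(founder_ids)
        for ev in self.events:
            unknown = [p for p in ev.parents if p not in known]
            if unknown:
                raise KeyError(f"unknown parent id(s) {unknown} for child {ev.child}")
            if ev.child in known:
                raise ConfigError(f"duplicate sample id {ev.child}")
            known.add(ev.child)

    @classmethod
    def from_tsv(cls, path: str) -> "PedigreeSpec":
        df = pd.read_csv(path, sep="\t", dtype=str)
        events = [
            PedigreeEvent(r["child"], r["kind"], tuple(str(r["parents"]).split(",")))
            for _, r in df.iterrows()
        ]
        return cls(events)

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(
            [(e.child, e.kind, ",".join(e.parents)) for e in self.events],
            columns=["child", "kind", "parents"],
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def _locus_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = config.n_loci
    chrom_of = np.arange(m) % config.n_chrom
    order = np.argsort(chrom_of, kind="stable")
    chrom_of = chrom_of[order]
    pos = np.empty(m, dtype=np.int64)
    for c in range(config.n_chrom):
        k = int((chrom_of == c).sum())
        pos[chrom_of == c] = (np.arange(k) + 1) * config.locus_spacing_bp
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, m)]
    alt = bases[(np.char.find("ACGT", ref) + rng.integers(1, 4, m)) % 4]
    return pd.DataFrame(
        {"chrom": [f"chr{c + 1}" for c in chrom_of], "pos": pos, "ref": ref, "alt": alt}
    )


def simulate_founders(
    config: SimConfig,
    freqs: np.ndarray | None = None,
    sample_prefix: str = "F",
) -> GenotypeMatrix:
    """Draw unrelated Hardy-Weinberg founders with phased haplotypes.

    Each founder haplotype allele at locus ``l`` is an independent Bernoulli
    draw with that locus's alt frequency; the two haplotypes of founder
    ``f`` carry ancestry labels ``2f`` and ``2f + 1``.
    """
    rng = np.random.default_rng(config.seed)
    loci = _locus_table(config, rng)
    n, m = config.n_founders, config.n_loci
    if freqs is None:
        lo, hi = config.freq_range
        freqs = rng.uniform(lo, hi, m)
    else:
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (m,):
            raise ConfigError("freqs must have length n_loci")
    haps = (rng.random((n, m, 2)) < freqs[None, :, None]).astype(np.int8)
    ancestry = np.empty((n, m, 2), dtype=np.int32)
    ancestry[:, :, 0] = (2 * np.arange(n))[:, None]
    ancestry[:, :, 1] = (2 * np.arange(n) + 1)[:, None]
    ids = [f"{sample_prefix}{i:03d}" for i in range(n)]
    G = GenotypeMatrix(
        sample_ids=ids,
        loci=loci,
        dosage=haps.sum(axis=2, dtype=np.int8),
        haplotypes=haps,
        ancestry=ancestry,
    )
    G.samples["group"] = "cultivated"
    return G


# ---------------------------------------------------------------------------
# breeding
# ---------------------------------------------------------------------------

def _chrom_slices(loci: pd.DataFrame):
    chroms = loci["chrom"].to_numpy()
    starts = np.flatnonzero(np.r_[True, chroms[1:] != chroms[:-1]])
    ends = np.r_[starts[1:], len(chroms)]
    return list(zip(starts, ends))


def _gamete_choice(m_slices, m, crossover_rate, rng) -> np.ndarray:
    """Haplotype index (0/1) transmitted at each locus: Markov walk per chromosome."""
    choice = np.empty(m, dtype=np.int8)
    for a, b in m_slices:
        k = b - a
        switch = rng.random(k) < crossover_rate
        switch[0] = rng.random() < 0.5  # uniform start haplotype
        # cumulative XOR: parity of switches so far
        choice[a:b] = np.bitwise_xor.accumulate(switch.astype(np.int8))
    return choice


def breed(
    founders: GenotypeMatrix,
    pedigree: PedigreeSpec,
    seed: int,
    crossover_rate: float = 0.5,
) -> GenotypeMatrix:
    """Extend a founder panel by the pedigree's breeding events.

    cross: one gamete from each parent.  self: two independent gametes from
    the one parent.  clone: an identical copy.  Haplotype ancestry labels
    propagate with the alleles, so every offspring allele traces back to a
    founder haplotype.
    """
    if founders.haplotypes is None or founders.ancestry is None:
        raise ConfigError("breed requires phased founders with ancestry labels")
    pedigree.validate_against(founders.sample_ids)
    rng = np.random.default_rng(seed)
    m = founders.n_loci
    slices = _chrom_slices(founders.loci)

    ids = list(founders.sample_ids)
    haps = [founders.haplotypes]
    anc = [founders.ancestry]
    all_haps = founders.haplotypes
    all_anc = founders.ancestry
    index = {s: i for i, s in enumerate(ids)}
    cols = np.arange(m)

    def gamete(parent_row: int):
        pick = _gamete_choice(slices, m, crossover_rate, rng)
        return all_haps[parent_row, cols, pick], all_anc[parent_row, cols, pick]

    for ev in pedigree.events:
        if ev.kind == "clone":
            p = index[ev.parents[0]]
            h = all_haps[p].copy()
            a = all_anc[p].copy()
        else:
            parents = ev.parents if ev.kind == "cross" else (ev.parents[0], ev.parents[0])
            h = np.empty((m, 2), dtype=np.int8)
            a = np.empty((m, 2), dtype=np.int32)
            for k, pid in enumerate(parents):
                h[:, k], a[:, k] = gamete(index[pid])
        all_haps = np.concatenate([all_haps, h[None]], axis=0)
        all_anc = np.concatenate([all_anc, a[None]], axis=0)
        index[ev.child] = len(ids)
        ids.append(ev.child)

    G = GenotypeMatrix(
        sample_ids=ids,
        loci=founders.loci.copy(),
        dosage=all_haps.sum(axis=2, dtype=np.int8),
        haplotypes=all_haps,
        ancestry=all_anc,
    )
    G.samples["group"] = "cultivated"
    G.samples.loc[founders.sample_ids, :] = founders.samples.values
    return G


# ---------------------------------------------------------------------------
# degradation (genotyping error, missingness, depth)
# ---------------------------------------------------------------------------

def degrade(G: GenotypeMatrix, config: SimConfig, seed: int | None = None) -> GenotypeMatrix:
    """Apply observational noise; the input matrix is left untouched.

    Each allele copy flips ref<->alt independently with ``error_rate``;
    each call is then masked missing with the sample's missing rate; depth
    is Poisson around ``mean_depth`` (0 for missing calls).  Ancestry labels
    are inheritance truth and are kept as-is.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = G.copy()
    n, m = out.n_samples, out.n_loci

    if out.haplotypes is None:
        # reconstruct allele copies from dosage (phase unknown, order arbitrary)
        h = np.zeros((n, m, 2), dtype=np.int8)
        h[:, :, 0] = (out.dosage >= 1).astype(np.int8)
        h[:, :, 1] = (out.dosage == 2).astype(np.int8)
        h[out.dosage == MISSING] = MISSING
        allele = h
        phased = False
    else:
        allele = out.haplotypes.copy()
        phased = True

    if config.error_rate > 0:
        flips = (rng.random((n, m, 2)) < config.error_rate) & (allele != MISSING)
        allele[flips] = 1 - allele[flips]

    if isinstance(config.missing_rate, dict):
        rates = np.array([config.missing_rate.get(s, 0.0) for s in out.sample_ids])
    else:
        rates = np.full(n, float(config.missing_rate))
    drop = rng.random((n, m)) < rates[:, None]

    called = (allele[:, :, 0] != MISSING) & ~drop
    allele[~called] = MISSING
    dosage = allele.sum(axis=2, dtype=np.int8)
    dosage[~called] = MISSING

    depth = rng.poisson(config.mean_depth, size=(n, m)).astype(np.int32)
    depth[~called] = 0

    out.dosage = dosage
    out.haplotypes = allele if phased else None
    out.depth = depth
    return out


# ---------------------------------------------------------------------------
# colour phenotype
# ---------------------------------------------------------------------------

def simulate_color(
    G: GenotypeMatrix,
    effects: "pd.DataFrame | object",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ordinal berry-colour grades from additive allele effects.

    latent grade = sum over effect loci of (effect-allele dosage x effect)
    + N(0, noise_sd), clipped to [0, 4]; the category is the nearest of the
    five grades (white=0 ... black=4), ties rounding half up.

    Returns a DataFrame (sample, grade, category, color) and also records
    the colour name in ``G.samples['color']``.
    """
    from .colorscore import EffectTable

    table = effects if isinstance(effects, EffectTable) else EffectTable(effects)
    rng = np.random.default_rng(seed)
    dos = table.effect_dosage(G)  # (n_samples, n_eff), NaN for missing
    if np.isnan(dos).any():
        raise ConfigError("effect loci must be called in all samples for simulation")
    latent = dos @ table.df["beta"].to_numpy()
    latent = latent + rng.normal(0.0, noise_sd, size=G.n_samples)
    grade = np.clip(latent, 0.0, 4.0)
    category = np.floor(grade + 0.5).astype(int)  # nearest, half up
    df = pd.DataFrame(
        {
            "sample": G.sample_ids,
            "grade": grade,
            "category": category,
            "color": [COLOR_NAMES[c] for c in category],
        }
    )
    G.samples["color"] = df.set_index("sample")["color"]
    return df


# ---------------------------------------------------------------------------
# IBD ground truth from ancestry labels
# ---------------------------------------------------------------------------

def shared_ancestry_segments(
    G: GenotypeMatrix, id1: str, id2: str, min_bp: int = 1
) -> list[IbdSegment]:
    """True IBD segments between two samples from the simulator's ancestry.

    For each of the four haplotype pairings, emits maximal runs of loci at
    which both haplotypes descend from the same founder haplotype, provided
    the run spans at least ``min_bp``.  Segment coordinates are the first
    and last locus positions of the run.
    """
    if G.ancestry is None:
        raise ConfigError("matrix carries no ancestry labels")
    i, j = G.sample_index(id1), G.sample_index(id2)
    pos = G.loci["pos"].to_numpy()
    segs: list[IbdSegment] = []
    for a, b in _chrom_slices(G.loci):
        chrom = G.loci["chrom"].iloc[a]
        for h1 in (0, 1):
            for h2 in (0, 1):
                same = G.ancestry[i, a:b, h1] == G.ancestry[j, a:b, h2]
                for s, e in _runs(same):
                    start, end = int(pos[a + s]), int(pos[a + e - 1])
                    if end - start + 1 >= min_bp:
                        segs.append(
                            IbdSegment(id1, h1 + 1, id2, h2 + 1, str(chrom), start, end, np.inf)
                        )
    return segs


def _runs(mask: np.ndarray):
    """Yield (start, end) half-open index ranges of True runs."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        ends = np.r_[ends, len(m)]
    yield from zip(starts.tolist(), ends.tolist())
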