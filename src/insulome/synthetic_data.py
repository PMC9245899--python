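"""Forward-in-time gene-dropping simulator with founder-ancestry tracking.

The simulator represents every haplotype as a *mosaic* of founder
haplotypes: per chromosome, a list of breakpoints (cM offsets from the
chromosome start) and the founder haplotype occupying each piece.  Meiosis
operates directly on mosaics — crossover counts are Poisson in map length
(no interference), crossover positions uniform in cM — so ancestry is
tracked exactly and ground-truth ROH/IBD segments fall out of interval
arithmetic rather than genotype heuristics.  Alleles are materialised only
when a genotype panel is requested, by reading each mosaic piece out of
the founder haplotype panel.

Founder haplotypes are mutually unrelated by construction: alleles are
drawn independently per site with frequencies from a truncated Beta,
emulating an imputed common-SNP panel (MAF >= 5%) with no LD and no
baseline inbreeding.  There is no mutation model: over the tens of
generations simulated here, new mutations at common SNPs are negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from insulome.core_io import (
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    InsulomeError,
    Segment,
    SITE_COLUMNS,
)


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, or a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# haplotypes and founder panels
# ---------------------------------------------------------------------------


@dataclass
class Haplotype:
    """A haplotype as a founder mosaic.

    ``mosaic[chrom] = (breaks, founders)`` with ``breaks`` a float array of
    length k+1 running from 0 to the chromosome map length (cM offsets) and
    ``founders`` the k founder-haplotype indices occupying the pieces.
    """

    mosaic: dict[str, tuple[np.ndarray, np.ndarray]]

    @classmethod
    def founder(cls, gmap: GeneticMap, founder_index: int) -> "Haplotype":
        mosaic = {}
        for chrom in gmap.chromosomes:
            length = gmap.length_cm(chrom)
            mosaic[chrom] = (
                np.array([0.0, length]),
                np.array([founder_index], dtype=np.int32),
            )
        return cls(mosaic)

    def founder_at(self, chrom: str, cm_offset: np.ndarray) -> np.ndarray:
        """Founder haplotype index covering each cM offset."""
        breaks, founders = self.mosaic[chrom]
        idx = np.clip(np.searchsorted(breaks, cm_offset, side="right") - 1, 0, len(founders) - 1)
        return founders[idx]

    def equals(self, other: "Haplotype") -> bool:
        if set(self.mosaic) != set(other.mosaic):
            return False
        return all(
            np.array_equal(self.mosaic[c][0], other.mosaic[c][0])
            and np.array_equal(self.mosaic[c][1], other.mosaic[c][1])
            for c in self.mosaic
        )


@dataclass
class HaplotypePanel:
    """Founder haplotypes: concrete alleles plus shared site metadata."""

    hap_ids: list[str]
    alleles: np.ndarray  # (n_haplotypes, n_sites) uint8 in {0,1}
    sites: pd.DataFrame  # SITE_COLUMNS
    founder_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.shape != (len(self.hap_ids), len(self.sites)):
            raise InsulomeError("allele array shape does not match ids x sites")
        if not np.isin(self.alleles, (0, 1)).all():
            raise InsulomeError("founder alleles must be 0/1 (no missing)")
        if not self.founder_labels:
            self.founder_labels = list(self.hap_ids)

    @property
    def n_haplotypes(self) -> int:
        return len(self.hap_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def make_founders(
    n_haplotypes: int,
    n_sites_per_chrom: int,
    gmap: GeneticMap,
    freq_beta_params: tuple[float, float] = (1.0, 1.0),
    seed=0,
    maf_floor: float = 0.05,
    sites_per_cm: float | None = None,
) -> HaplotypePanel:
    """Unrelated founder haplotypes at common biallelic SNPs.

    Site frequencies are Beta(a, b) truncated to [maf_floor, 1 - maf_floor]
    by inverse-CDF sampling, emulating a MAF-filtered imputed panel;
    alleles are drawn independently per site (founders carry no LD).
    Sites are evenly spaced in bp along each chromosome; pass
    ``sites_per_cm`` instead of ``n_sites_per_chrom`` for a uniform
    genetic-map density on maps with unequal chromosome lengths (which
    keeps ROH-caller resolution uniform across chromosomes).
    """
    if n_haplotypes < 4 or n_haplotypes % 2:
        raise InsulomeError("n_haplotypes must be even and >= 4")
    a, b = freq_beta_params
    if a <= 0 or b <= 0:
        raise InsulomeError(f"invalid Beta parameters {freq_beta_params}")
    rng = as_rng(seed)

    records = []
    for chrom in gmap.chromosomes:
        abp, acm = gmap.anchors[chrom]
        n_sites = n_sites_per_chrom
        if sites_per_cm is not None:
            n_sites = max(2, int(round(sites_per_cm * float(acm[-1] - acm[0]))))
        bp = np.unique(np.linspace(abp[0], abp[-1], n_sites).astype(np.int64))
        cm = gmap.interpolate(chrom, bp)
        for pos, c in zip(bp, cm):
            records.append((chrom, int(pos), float(c), "A", "G", 0.0))
    sites = pd.DataFrame(records, columns=SITE_COLUMNS)

    beta = stats.beta(a, b)
    lo, hi = beta.cdf(maf_floor), beta.cdf(1.0 - maf_floor)
    p = beta.ppf(rng.uniform(lo, hi, size=len(sites)))
    sites["p"] = p
    alleles = (rng.random((n_haplotypes, len(sites))) < p).astype(np.uint8)
    return HaplotypePanel(
        hap_ids=[f"F{h}" for h in range(n_haplotypes)],
        alleles=alleles,
        sites=sites,
    )


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


_NO_XS = np.empty(0)


def crossover_positions(gmap: GeneticMap, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Poisson(L Morgans) crossovers per chromosome, uniform in cM."""
    out = {}
    for chrom, (_, acm) in gmap.anchors.items():
        length = float(acm[-1] - acm[0])
        n = rng.poisson(length / 100.0) if length > 0 else 0
        if n:
            xs = rng.uniform(0.0, length, size=n)
            xs.sort()
            out[chrom] = xs
        else:
            out[chrom] = _NO_XS
    return out


def _splice(
    mos_a: tuple[np.ndarray, np.ndarray],
    mos_b: tuple[np.ndarray, np.ndarray],
    xs: np.ndarray,
    start_phase: int,
    length: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Recombinant mosaic alternating between parents at crossovers."""
    if len(xs) == 0:
        src = mos_a if start_phase == 0 else mos_b
        return src[0].copy(), src[1].copy()
    n_bounds = len(xs) + 2
    bounds = np.empty(n_bounds)
    bounds[0] = 0.0
    bounds[1:-1] = xs
    bounds[-1] = length
    end_parts: list[np.ndarray] = []
    fd_parts: list[np.ndarray] = []
    phase = start_phase
    for i in range(n_bounds - 1):
        lo = bounds[i]
        hi = bounds[i + 1]
        phase_now, phase = phase, 1 - phase
        if hi <= lo:
            continue
        breaks, fd = mos_a if phase_now == 0 else mos_b
        j0 = int(breaks.searchsorted(lo, side="right")) - 1
        if j0 < 0:
            j0 = 0
        j1 = int(breaks.searchsorted(hi, side="left"))
        if j1 > len(fd):
            j1 = len(fd)
        ends = breaks[j0 + 1 : j1 + 1].copy()
        if ends[-1] > hi:
            ends[-1] = hi
        end_parts.append(ends)
        fd_parts.append(fd[j0:j1])
    ends = np.concatenate(end_parts)
    founders = np.concatenate(fd_parts)
    # drop zero-length pieces, then merge adjacent pieces of one founder
    nz = np.empty(len(ends), dtype=bool)
    nz[0] = ends[0] > 0.0
    np.greater(ends[1:], ends[:-1], out=nz[1:])
    if not nz.all():
        ends, founders = ends[nz], founders[nz]
    if len(founders) > 1:
        keep = np.empty(len(founders), dtype=bool)
        keep[-1] = True
        np.not_equal(founders[:-1], founders[1:], out=keep[:-1])
        if not keep.all():
            ends, founders = ends[keep], founders[keep]
    ends[-1] = length  # guard against float round-off at the terminus
    breaks_out = np.empty(len(ends) + 1)
    breaks_out[0] = 0.0
    breaks_out[1:] = ends
    return breaks_out, founders.astype(np.int32, copy=False)


def meiosis(
    parent_hap_pair: tuple[Haplotype, Haplotype],
    gmap: GeneticMap,
    seed,
) -> tuple[Haplotype, dict[str, np.ndarray]]:
    """One gamete from a parental haplotype pair.

    Crossover counts are Poisson in map length (no interference), positions
    uniform on the cM axis, starting phase a fair coin per chromosome.
    Returns the gamete and the crossover positions used.
    """
    hap_a, hap_b = parent_hap_pair
    if set(hap_a.mosaic) != set(hap_b.mosaic):
        raise InsulomeError("parental haplotypes cover different chromosome sets")
    rng = as_rng(seed)
    xs = crossover_positions(gmap, rng)
    mosaic = {}
    mos_a, mos_b = hap_a.mosaic, hap_b.mosaic
    for chrom, (_, acm) in gmap.anchors.items():
        length = float(acm[-1] - acm[0])
        phase = int(rng.integers(2))
        mosaic[chrom] = _splice(mos_a[chrom], mos_b[chrom], xs[chrom], phase, length)
    return Haplotype(mosaic), xs


# ---------------------------------------------------------------------------
# allele materialisation
# ---------------------------------------------------------------------------


def _chrom_offsets(panel: HaplotypePanel, gmap: GeneticMap) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: (site index array, cM offsets from chromosome start)."""
    chrom_col = panel.sites["chrom"].to_numpy()
    cm_col = panel.sites["cM"].to_numpy()
    out = {}
    for chrom in gmap.chromosomes:
        idx = np.flatnonzero(chrom_col == chrom)
        cm0 = gmap.anchors[chrom][1][0]
        out[chrom] = (idx, cm_col[idx] - cm0)
    return out


def haplotype_alleles(
    hap: Haplotype, panel: HaplotypePanel, gmap: GeneticMap, offsets=None
) -> np.ndarray:
    """Concrete 0/1 alleles of a mosaic haplotype over the panel's sites."""
    if offsets is None:
        offsets = _chrom_offsets(panel, gmap)
    alleles = np.empty(panel.n_sites, dtype=np.uint8)
    for chrom, (idx, cm_off) in offsets.items():
        if len(idx) == 0:
            continue
        founder = hap.founder_at(chrom, cm_off)
        alleles[idx] = panel.alleles[founder, idx]
    return alleles


def diploid_genotypes(
    pairs: dict[str, tuple[Haplotype, Haplotype]],
    panel: HaplotypePanel,
    gmap: GeneticMap,
    groups: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Unphased genotype matrix for mosaic haplotype pairs.

    The sites keep the founder panel's allele frequencies (the population
    frequency), which is what downstream IBD scoring conditions on; use
    :meth:`GenotypeMatrix.recompute_frequencies` for sample frequencies.
    """
    offsets = _chrom_offsets(panel, gmap)
    geno = np.empty((len(pairs), panel.n_sites), dtype=np.int8)
    for i, (h1, h2) in enumerate(pairs.values()):
        geno[i] = haplotype_alleles(h1, panel, gmap, offsets).astype(np.int8)
        geno[i] += haplotype_alleles(h2, panel, gmap, offsets)
    return GenotypeMatrix(
        ids=list(pairs), sites=panel.sites.copy(), genotypes=geno, groups=groups
    )


# ---------------------------------------------------------------------------
# ancestry truth and true segments
# ---------------------------------------------------------------------------


@dataclass
class AncestryTruth:
    """Ground-truth founder mosaics for present-day individuals."""

    haplotypes: dict[str, tuple[Haplotype, Haplotype]]
    gmap: GeneticMap
    sites: pd.DataFrame | None = None

    def check_tiling(self) -> None:
        """Mosaics must tile each chromosome exactly (no gaps/overlaps)."""
        for ind, pair in self.haplotypes.items():
            for hap in pair:
                for chrom, (breaks, founders) in hap.mosaic.items():
                    length = self.gmap.length_cm(chrom)
                    ok = (
                        breaks[0] == 0.0
                        and np.isclose(breaks[-1], length)
                        and np.all(np.diff(breaks) > 0)
                        and len(founders) == len(breaks) - 1
                    )
                    if not ok:
                        raise InsulomeError(f"mosaic of {ind} does not tile {chrom}")


def _shared_intervals(h1: Haplotype, h2: Haplotype, chrom: str) -> list[tuple[float, float]]:
    """Maximal cM-offset intervals where the two mosaics share a founder."""
    b1, f1 = h1.mosaic[chrom]
    b2, f2 = h2.mosaic[chrom]
    bounds = np.union1d(b1, b2)
    if len(bounds) < 2:
        return []
    mids = 0.5 * (bounds[:-1] + bounds[1:])
    s1 = f1[np.clip(np.searchsorted(b1, mids, side="right") - 1, 0, len(f1) - 1)]
    s2 = f2[np.clip(np.searchsorted(b2, mids, side="right") - 1, 0, len(f2) - 1)]
    shared = s1 == s2
    out = []
    i = 0
    while i < len(shared):
        if shared[i]:
            j = i
            while j + 1 < len(shared) and shared[j + 1]:
                j += 1
            out.append((float(bounds[i]), float(bounds[j + 1])))
            i = j + 1
        i += 1
    return out


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def true_segments(
    truth: AncestryTruth, id_i: str, id_j: str, min_cm: float = 0.0
) -> list[Segment]:
    """Ground-truth ROH (i == j) or pairwise IBD (i != j) segments.

    For a pair, the union over the four inter-individual haplotype
    combinations is taken (IBD1 and IBD2 regions are not distinguished).
    """
    for ind in (id_i, id_j):
        if ind not in truth.haplotypes:
            raise InsulomeError(f"unknown individual id {ind!r}")
    if id_i == id_j:
        combos = [(truth.haplotypes[id_i][0], truth.haplotypes[id_i][1])]
        kind, ids = "ROH", (id_i,)
    else:
        hi, hj = truth.haplotypes[id_i], truth.haplotypes[id_j]
        combos = [(a, b) for a in hi for b in hj]
        kind, ids = "IBD", (id_i, id_j)

    segments = []
    for chrom in truth.gmap.chromosomes:
        cm0 = float(truth.gmap.anchors[chrom][1][0])
        intervals = _merge_intervals(
            [iv for h1, h2 in combos for iv in _shared_intervals(h1, h2, chrom)]
        )
        for lo, hi_ in intervals:
            if hi_ - lo < min_cm or hi_ <= lo:
                continue
            start_cm, end_cm = lo + cm0, hi_ + cm0
            start_bp = int(round(truth.gmap.invert(chrom, start_cm)))
            end_bp = int(round(truth.gmap.invert(chrom, end_cm)))
            n_snps = 1
            if truth.sites is not None:
                sel = truth.sites["chrom"].to_numpy() == chrom
                cm = truth.sites["cM"].to_numpy()[sel]
                n_snps = max(1, int(((cm >= start_cm) & (cm <= end_cm)).sum()))
            segments.append(
                Segment(
                    kind=kind,
                    ids=ids,
                    chrom=chrom,
                    start_bp=start_bp,
                    end_bp=max(end_bp, start_bp + 1),
                    start_cm=start_cm,
                    end_cm=end_cm,
                    n_snps=n_snps,
                )
            )
    return segments


def true_f_roh(truth: AncestryTruth, ind: str, min_cm: float = 0.0) -> float:
    """Genealogical inbreeding realised as ground-truth ROH fraction."""
    segs = true_segments(truth, ind, ind, min_cm=min_cm)
    return sum(s.length_cm for s in segs) / truth.gmap.total_length_cm


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------


@dataclass
class NeTrajectory:
    """Per-deme diploid sizes by generation (0 = present, G = oldest).

    ``sizes`` is either 1-D of length G+1 (every deme has that size) or
    2-D of shape (G+1, n_demes) for deme-specific trajectories.
    """

    sizes: np.ndarray
    n_demes: int = 1
    migration: float = 0.0

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.sizes.ndim == 2 and self.sizes.shape[1] != self.n_demes:
            raise InsulomeError("2-D sizes must have one column per deme")
        if np.any(self.sizes < 2):
            raise InsulomeError("all generation sizes must be >= 2")
        if not 0.0 <= self.migration < 1.0:
            raise InsulomeError("migration fraction must lie in [0, 1)")
        if self.n_demes < 1:
            raise InsulomeError("need at least one deme")

    @classmethod
    def constant(cls, n: int, n_generations: int, n_demes: int = 1, migration: float = 0.0):
        return cls(np.full(n_generations + 1, n), n_demes=n_demes, migration=migration)

    @classmethod
    def constant_per_deme(cls, deme_sizes, n_generations: int, migration: float = 0.0):
        sizes = np.tile(np.asarray(deme_sizes, dtype=np.int64), (n_generations + 1, 1))
        return cls(sizes, n_demes=len(deme_sizes), migration=migration)

    def size_at(self, g: int, deme: int) -> int:
        if self.sizes.ndim == 1:
            return int(self.sizes[g])
        return int(self.sizes[g, deme])

    @property
    def n_generations(self) -> int:
        return len(self.sizes) - 1


def simulate_population(
    founders: HaplotypePanel,
    traj: NeTrajectory,
    n_generations: int | None = None,
    seed=0,
    gmap: GeneticMap | None = None,
) -> tuple[GenotypeMatrix, AncestryTruth]:
    """Wright–Fisher gene dropping with ancestry tracking.

    Generation G individuals carry distinct founder haplotypes.  Each
    offspring draws two distinct random parents within its deme (random
    mating, selfing disallowed); newborn individuals then migrate by a
    random permutation of deme labels among the migrant pool (probability
    ``traj.migration`` each), which preserves deme sizes.  The final
    generation is returned as unphased genotypes plus full ancestry
    mosaics.
    """
    if gmap is None:
        gmap = _implied_uniform_map(founders)
    if n_generations is None:
        n_generations = traj.n_generations
    if n_generations > traj.n_generations:
        raise InsulomeError("trajectory does not cover the requested generations")
    rng = as_rng(seed)

    start_sizes = [traj.size_at(n_generations, d) for d in range(traj.n_demes)]
    n_start = sum(start_sizes)
    if founders.n_haplotypes < 2 * n_start:
        raise InsulomeError(
            f"need {2 * n_start} founder haplotypes for generation {n_generations}, "
            f"panel has {founders.n_haplotypes}"
        )
    pop = [
        (Haplotype.founder(gmap, 2 * i), Haplotype.founder(gmap, 2 * i + 1))
        for i in range(n_start)
    ]
    demes = np.repeat(np.arange(traj.n_demes), start_sizes)

    for g in range(n_generations - 1, -1, -1):
        gen_sizes = [traj.size_at(g, d) for d in range(traj.n_demes)]
        new_pop = []
        for d in range(traj.n_demes):
            members = np.flatnonzero(demes == d)
            if len(members) < 2:
                raise InsulomeError(f"deme {d} has fewer than 2 potential parents")
            nm = len(members)
            for _ in range(gen_sizes[d]):
                i = int(rng.integers(nm))
                j = int(rng.integers(nm - 1))
                if j >= i:
                    j += 1  # distinct parents: no selfing
                child = (
                    meiosis(pop[members[i]], gmap, rng)[0],
                    meiosis(pop[members[j]], gmap, rng)[0],
                )
                new_pop.append(child)
        pop = new_pop
        demes = np.repeat(np.arange(traj.n_demes), gen_sizes)
        if traj.migration > 0.0 and traj.n_demes > 1:
            movers = np.flatnonzero(rng.random(len(pop)) < traj.migration)
            demes[movers] = demes[movers][rng.permutation(len(movers))]

    pairs = {
        f"d{demes[i]}_i{i}": pop[i] for i in range(len(pop))
    }
    groups = {ind: f"deme{demes[i]}" for i, ind in enumerate(pairs)}
    gm = diploid_genotypes(pairs, founders, gmap, groups=groups)
    truth = AncestryTruth(haplotypes=pairs, gmap=gmap, sites=gm.sites)
    return gm, truth


def _implied_uniform_map(panel: HaplotypePanel) -> GeneticMap:
    """Reconstruct a two-anchor map from the panel's site coordinates."""
    anchors = {}
    for chrom, sub in panel.sites.groupby("chrom", sort=False):
        bp = sub["bp"].to_numpy()
        cm = sub["cM"].to_numpy()
        anchors[str(chrom)] = (np.array([bp[0], bp[-1]]), np.array([cm[0], cm[-1]]))
    return GeneticMap(anchors)


# ---------------------------------------------------------------------------
# genotype error model
# ---------------------------------------------------------------------------


def add_errors(
    gm: GenotypeMatrix,
    miscall_rate: float,
    missing_rate: float,
    seed=0,
    recompute_freq: bool = True,
) -> GenotypeMatrix:
    """Independent per-genotype dropout and per-allele miscalls.

    Each genotype is set missing with ``missing_rate``; otherwise each of
    its two alleles flips with ``miscall_rate`` (so a het can become either
    homozygote and vice versa).  Frequencies are recomputed from the noisy
    calls unless ``recompute_freq=False`` (useful when the matrix carries
    population rather than sample frequencies).
    """
    if not 0.0 <= miscall_rate <= 0.05:
        raise InsulomeError(f"miscall_rate out of supported range [0, 0.05]: {miscall_rate}")
    if not 0.0 <= missing_rate <= 1.0:
        raise InsulomeError(f"missing_rate out of [0, 1]: {missing_rate}")
    rng = as_rng(seed)
    g = gm.genotypes.copy()
    present = g != MISSING

    if missing_rate > 0:
        drop = present & (rng.random(g.shape) < missing_rate)
        g[drop] = MISSING
        present &= ~drop

    if miscall_rate > 0:
        # alt-allele count of each genotype = sum of two allele indicators
        a1 = (g == 2) | (g == 1)  # allele 1 is alt for g in {1, 2}
        a2 = g == 2  # allele 2 is alt only for g == 2
        flip1 = rng.random(g.shape) < miscall_rate
        flip2 = rng.random(g.shape) < miscall_rate
        new = (a1 ^ flip1).astype(np.int8) + (a2 ^ flip2).astype(np.int8)
        g = np.where(present, new, g).astype(np.int8)

    out = GenotypeMatrix(ids=gm.ids, sites=gm.sites.copy(), genotypes=g, groups=gm.groups)
    return out.recompute_frequencies() if recompute_freq else out
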