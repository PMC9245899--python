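"""Genotype panels, genetic maps, site filters and segment I/O.

Conventions
-----------
* Base-pair positions are stored 1-based (VCF convention); segment files
  are written 0-based half-open (BED convention).
* Genetic distance (cM) is the analysis unit throughout; physical
  positions are converted to cM by linear interpolation on a
  :class:`GeneticMap`.
* Genotypes count alternate alleles: 0, 1, 2, with -1 for missing.
* Missing genotypes never contribute to allele frequencies, kinship or
  LD r**2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

SITE_COLUMNS = ["chrom", "bp", "cM", "ref", "alt", "p"]

#: approximate sex-averaged genetic lengths (cM) of the 22 human autosomes,
#: totalling ~35.9 Morgans; used for "human-scale" simulations.
HUMAN_AUTOSOME_CM = {
    "1": 286.3, "2": 268.6, "3": 223.3, "4": 214.6, "5": 204.1,
    "6": 192.0, "7": 187.2, "8": 168.0, "9": 166.4, "10": 181.1,
    "11": 158.2, "12": 174.7, "13": 125.8, "14": 120.8, "15": 141.9,
    "16": 134.0, "17": 128.5, "18": 117.9, "19": 107.9, "20": 108.3,
    "21": 62.8, "22": 74.1,
}


class InsulomeError(RuntimeError):
    """Fatal error in input data or configuration."""


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Per-chromosome monotone bp -> cM anchor tables.

    ``anchors`` maps a chromosome label to a pair of arrays
    ``(bp, cM)``: bp strictly increasing, cM non-decreasing, at least two
    anchors per chromosome.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, dtype=np.int64)
            cm = np.asarray(cm, dtype=np.float64)
            if bp.size < 2:
                raise InsulomeError(f"chromosome {chrom}: need >=2 map anchors")
            if np.any(np.diff(bp) <= 0):
                raise InsulomeError(f"chromosome {chrom}: anchor bp not strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise InsulomeError(f"chromosome {chrom}: anchor cM decreasing")
            if np.any(bp < 0) or np.any(cm < 0):
                raise InsulomeError(f"chromosome {chrom}: negative anchor coordinate")
            clean[chrom] = (bp, cm)
        self.anchors = clean

    @property
    def chromosomes(self) -> list[str]:
        return list(self.anchors)

    def length_cm(self, chrom: str) -> float:
        """Total map length of one chromosome (last minus first anchor)."""
        bp, cm = self.anchors[chrom]
        return float(cm[-1] - cm[0])

    @property
    def total_length_cm(self) -> float:
        return float(sum(self.length_cm(c) for c in self.anchors))

    def lengths_morgans(self) -> np.ndarray:
        return np.array([self.length_cm(c) / 100.0 for c in self.anchors])

    def interpolate(self, chrom: str, bp: np.ndarray) -> np.ndarray:
        """bp -> cM, linear between anchors, clamped to terminal anchors."""
        if chrom not in self.anchors:
            raise InsulomeError(
                f"chromosome {chrom!r} absent from genetic map "
                f"(map has {sorted(self.anchors)})"
            )
        abp, acm = self.anchors[chrom]
        return np.interp(np.asarray(bp, dtype=np.float64), abp, acm)

    def invert(self, chrom: str, cm: np.ndarray) -> np.ndarray:
        """cM -> bp (linear inverse; cM plateaus map to their first bp)."""
        abp, acm = self.anchors[chrom]
        return np.interp(np.asarray(cm, dtype=np.float64), acm, abp.astype(np.float64))

    @classmethod
    def uniform(cls, lengths_cm: dict[str, float], rate_cm_per_mb: float = 1.0) -> "GeneticMap":
        """Map with a constant recombination rate (default 1 cM/Mb)."""
        anchors = {}
        for chrom, length in lengths_cm.items():
            end_bp = int(round(length / rate_cm_per_mb * 1e6))
            anchors[chrom] = (np.array([1, end_bp]), np.array([0.0, length]))
        return cls(anchors)

    @classmethod
    def human_scale(cls, rate_cm_per_mb: float = 1.0) -> "GeneticMap":
        """22 autosomes at approximately human genetic lengths (~35.9 M)."""
        return cls.uniform(HUMAN_AUTOSOME_CM, rate_cm_per_mb)


def read_genetic_map(path) -> GeneticMap:
    """Read a 4-column map table: chrom, bp, rate_cM_per_Mb, cM.

    The rate column is optional and ignored; a 3-column file is read as
    chrom, bp, cM.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
    if df.shape[1] == 4:
        df.columns = ["chrom", "bp", "rate", "cM"]
    elif df.shape[1] == 3:
        df.columns = ["chrom", "bp", "cM"]
    else:
        raise InsulomeError(f"{path}: expected 3 or 4 columns, got {df.shape[1]}")
    anchors = {
        str(chrom): (sub["bp"].to_numpy(np.int64), sub["cM"].to_numpy(np.float64))
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    return GeneticMap(anchors)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tbp\trate_cM_per_Mb\tcM\n")
        for chrom, (bp, cm) in gmap.anchors.items():
            for b, c in zip(bp, cm):
                fh.write(f"{chrom}\t{int(b)}\t.\t{float(c)!r}\n")


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic sites, unphased diploid alt-allele counts.

    ``sites`` is a DataFrame with columns chrom, bp, cM, ref, alt, p
    (alt-allele frequency among non-missing calls), sorted by
    (chromosome, bp).  ``genotypes`` is an ``(n_individuals, n_sites)``
    int8 array with entries in {0, 1, 2, -1}.
    """

    ids: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray
    groups: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.ids), len(self.sites)):
            raise InsulomeError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise InsulomeError(f"{bad.sum()} genotype entries outside {{0,1,2,missing}}")
        self.sites = self.sites.reset_index(drop=True)
        self._check_sorted()

    def _check_sorted(self) -> None:
        chrom = self.sites["chrom"].to_numpy()
        bp = self.sites["bp"].to_numpy()
        for i in range(1, len(self.sites)):
            if chrom[i] == chrom[i - 1] and bp[i] <= bp[i - 1]:
                raise InsulomeError(
                    f"sites not sorted: {chrom[i]}:{bp[i]} after {chrom[i-1]}:{bp[i-1]}"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def index_of(self, individual_id: str) -> int:
        try:
            return self.ids.index(individual_id)
        except ValueError:
            raise InsulomeError(f"unknown individual id {individual_id!r}") from None

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per site from non-missing genotypes."""
        g = self.genotypes
        present = g != MISSING
        n_called = present.sum(axis=0)
        alt = np.where(present, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = alt / (2.0 * n_called)
        return np.where(n_called > 0, p, np.nan)

    def recompute_frequencies(self) -> "GenotypeMatrix":
        sites = self.sites.copy()
        sites["p"] = self.allele_frequencies()
        return replace(self, sites=sites)

    def missingness(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return replace(
            self,
            sites=self.sites.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[:, mask],
        )

    def subset_individuals(self, keep_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.index_of(i) for i in keep_ids]
        groups = None
        if self.groups is not None:
            groups = {i: self.groups[i] for i in keep_ids if i in self.groups}
        return replace(self, ids=list(keep_ids), genotypes=self.genotypes[idx], groups=groups)

    def genotypes_of(self, individual_id: str) -> np.ndarray:
        return self.genotypes[self.index_of(individual_id)]


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


@dataclass
class SiteFilterConfig:
    """Site-level filter settings (PLINK-style defaults).

    ``max_missingness`` and ``min_maf`` mirror ``--geno 0.02 --maf 0.05``;
    the LD block mirrors ``--indep 50 2 2`` with the variance-inflation
    criterion replaced by pairwise r**2 > ``ld_r2_max`` (deterministic and,
    for the downstream statistics here, interchangeable).
    """

    max_missingness: float = 0.02
    min_maf: float = 0.05
    ld_window_snps: int = 50
    ld_step_snps: int = 2
    ld_r2_max: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_missingness <= 1.0 and 0.0 <= self.min_maf <= 1.0):
            raise InsulomeError("filter fractions must lie in [0, 1]")
        if not self.ld_window_snps >= self.ld_step_snps >= 1:
            raise InsulomeError("need ld_window_snps >= ld_step_snps >= 1")
        if not 0.0 <= self.ld_r2_max <= 1.0:
            raise InsulomeError("ld_r2_max must lie in [0, 1]")


def filter_sites(gm: GenotypeMatrix, cfg: SiteFilterConfig) -> GenotypeMatrix:
    """Drop sites by missingness, then by MAF; recompute frequencies.

    Order matters and mirrors the usual PLINK pipeline: missingness is
    assessed on all individuals first, MAF on what survives.
    """
    miss = gm.missingness()
    keep1 = miss <= cfg.max_missingness
    n_miss_removed = int((~keep1).sum())
    gm1 = gm.subset_sites(keep1).recompute_frequencies()

    p = gm1.sites["p"].to_numpy()
    maf = np.minimum(p, 1.0 - p)
    keep2 = ~np.isnan(p) & (maf >= cfg.min_maf)
    n_maf_removed = int((~keep2).sum())
    out = gm1.subset_sites(keep2)
    logger.info(
        "filter_sites: removed %d sites by missingness > %g, %d by MAF < %g; %d remain",
        n_miss_removed, cfg.max_missingness, n_maf_removed, cfg.min_maf, out.n_sites,
    )
    if out.n_sites == 0:
        raise InsulomeError("all sites removed by missingness/MAF filters")
    return out


def _pairwise_r2(gi: np.ndarray, gj: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete."""
    ok = (gi != MISSING) & (gj != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = gi[ok].astype(np.float64)
    y = gj[ok].astype(np.float64)
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_prune(gm: GenotypeMatrix, cfg: SiteFilterConfig) -> GenotypeMatrix:
    """Windowed greedy r**2 pruning, deterministic given input order.

    Within each window of ``ld_window_snps`` kept sites (advanced by
    ``ld_step_snps``), the later member of any pair with r**2 >
    ``ld_r2_max`` is dropped.  Dropping only removes pairs, so a single
    ordered sweep per window reaches the fixed point; pruned output is
    idempotent under re-pruning.
    """
    keep = np.ones(gm.n_sites, dtype=bool)
    chrom = gm.sites["chrom"].to_numpy()
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while start < len(idx):
            window = idx[start : start + cfg.ld_window_snps]
            live = [k for k in window if keep[k]]
            for a in range(len(live)):
                if not keep[live[a]]:
                    continue
                for b in range(a + 1, len(live)):
                    if not keep[live[b]]:
                        continue
                    r2 = _pairwise_r2(gm.genotypes[:, live[a]], gm.genotypes[:, live[b]])
                    if r2 > cfg.ld_r2_max:
                        keep[live[b]] = False
            if start + cfg.ld_window_snps >= len(idx):
                break
            start += cfg.ld_step_snps
    logger.info("ld_prune: removed %d of %d sites", int((~keep).sum()), gm.n_sites)
    return gm.subset_sites(keep)


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    """A maximal ROH or IBD interval with physical and genetic coordinates.

    ``ids`` holds one individual id for ROH, an ordered pair for IBD.
    bp endpoints are 1-based inclusive of the outermost contributing SNPs;
    ``lod`` is present for IBD segments only.
    """

    kind: str  # "ROH" | "IBD"
    ids: tuple[str, ...]
    chrom: str
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    n_snps: int
    lod: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("ROH", "IBD"):
            raise InsulomeError(f"segment kind must be ROH or IBD, got {self.kind!r}")
        if self.end_bp <= self.start_bp:
            raise InsulomeError(f"segment end_bp {self.end_bp} <= start_bp {self.start_bp}")
        if self.end_cm < self.start_cm:
            raise InsulomeError("segment end_cm < start_cm")
        if self.n_snps < 1:
            raise InsulomeError("segment needs n_snps >= 1")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def id_label(self) -> str:
        return "|".join(self.ids)


SEGMENT_HEADER = (
    "#chrom\tstart0\tend0\tkind\tid_or_pair\tstart_cM\tend_cM\tlength_cM\tn_snps\tlod"
)


def write_segments(segments: list[Segment], path) -> None:
    """Write segments as BED-style TSV (0-based half-open bp), sorted."""
    ordered = sorted(segments, key=lambda s: (s.chrom, s.start_bp, s.end_bp, s.id_label()))
    with open(path, "w") as fh:
        fh.write(SEGMENT_HEADER + "\n")
        for s in ordered:
            lod = "." if s.lod is None else repr(float(s.lod))
            fh.write(
                f"{s.chrom}\t{s.start_bp - 1}\t{s.end_bp}\t{s.kind}\t{s.id_label()}\t"
                f"{float(s.start_cm)!r}\t{float(s.end_cm)!r}\t{float(s.length_cm)!r}\t"
                f"{int(s.n_snps)}\t{lod}\n"
            )


def read_segments(path) -> list[Segment]:
    segments = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            segments.append(
                Segment(
                    kind=f[3],
                    ids=tuple(f[4].split("|")),
                    chrom=f[0],
                    start_bp=int(f[1]) + 1,
                    end_bp=int(f[2]),
                    start_cm=float(f[5]),
                    end_cm=float(f[6]),
                    n_snps=int(f[8]),
                    lod=None if f[9] == "." else float(f[9]),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# genotype readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read a diploid genotype panel from VCF or the TSV dialect.

    Multiallelic and non-SNP records are skipped (a count is logged);
    allele frequencies are computed from non-missing calls.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise InsulomeError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 is a standard install
        return _read_vcf_text(path)

    try:
        vcf = VCF(str(path))
    except OSError as exc:
        raise InsulomeError(f"cannot read VCF {path}: {exc}") from exc
    ids = list(vcf.samples)
    rows, records = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = var.gt_types.astype(np.int8)
        g = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING).astype(np.int8)
        rows.append(g)
        records.append((str(var.CHROM), int(var.POS), 0.0, var.REF, var.ALT[0], 0.0))
    return _assemble(ids, records, rows, n_skipped, path)


def _read_vcf_text(path) -> GenotypeMatrix:
    """Minimal GT-only fallback parser for plain-text VCF."""
    ids: list[str] = []
    rows, records = [], []
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                ids = line.rstrip("\n").split("\t")[9:]
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos, ref, alt = f[0], int(f[1]), f[3], f[4]
            if "," in alt or len(ref) != 1 or len(alt) != 1:
                n_skipped += 1
                continue
            g = np.empty(len(ids), dtype=np.int8)
            for k, sample in enumerate(f[9:]):
                gt = sample.split(":")[0].replace("|", "/")
                a = gt.split("/")
                if "." in a:
                    g[k] = MISSING
                else:
                    g[k] = int(a[0]) + int(a[1])
            rows.append(g)
            records.append((chrom, pos, 0.0, ref, alt, 0.0))
    return _assemble(ids, records, rows, n_skipped, path)


def _assemble(ids, records, rows, n_skipped, path) -> GenotypeMatrix:
    if n_skipped:
        logger.info("read_genotypes: skipped %d multiallelic/non-SNP records", n_skipped)
    if not rows:
        raise InsulomeError(f"{path}: no usable biallelic SNP records")
    sites = pd.DataFrame(records, columns=SITE_COLUMNS)
    gm = GenotypeMatrix(ids=ids, sites=sites, genotypes=np.array(rows, dtype=np.int8).T)
    return gm.recompute_frequencies()


def _read_tsv(path) -> GenotypeMatrix:
    """Genotype TSV dialect: '#id s1 s2 ...' plus '<path>.sites' table."""
    sites_path = str(path) + ".sites"
    try:
        sites = pd.read_csv(sites_path, sep="\t", dtype={"chrom": str})
    except OSError as exc:
        raise InsulomeError(f"cannot read sites table {sites_path}: {exc}") from exc
    try:
        geno = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except OSError as exc:
        raise InsulomeError(f"cannot read genotype table {path}: {exc}") from exc
    g = geno.to_numpy(dtype=np.float64)
    g = np.where(np.isnan(g), MISSING, g).astype(np.int8)
    if "p" not in sites.columns:
        sites["p"] = 0.0
    if "cM" not in sites.columns:
        sites["cM"] = 0.0
    gm = GenotypeMatrix(
        ids=[str(i) for i in geno.index],
        sites=sites[SITE_COLUMNS],
        genotypes=g,
    )
    return gm.recompute_frequencies()


def write_genotypes(gm: GenotypeMatrix, path, format: str = "vcf") -> None:
    if format == "vcf":
        _write_vcf(gm, path)
    elif format == "tsv":
        _write_tsv(gm, path)
    else:
        raise InsulomeError(f"unknown genotype format {format!r}")


def _write_vcf(gm: GenotypeMatrix, path) -> None:
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gm.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.ids) + "\n")
        for j, site in enumerate(gm.sites.itertuples(index=False)):
            calls = "\t".join(gt_str[int(g)] for g in gm.genotypes[:, j])
            fh.write(
                f"{site.chrom}\t{site.bp}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def _write_tsv(gm: GenotypeMatrix, path) -> None:
    gm.sites[SITE_COLUMNS].to_csv(str(path) + ".sites", sep="\t", index=False)
    with open(path, "w") as fh:
        names = [f"{s.chrom}:{s.bp}" for s in gm.sites.itertuples(index=False)]
        fh.write("#id\t" + "\t".join(names) + "\n")
        for i, ind in enumerate(gm.ids):
            row = "\t".join("NA" if g == MISSING else str(int(g)) for g in gm.genotypes[i])
            fh.write(f"{ind}\t{row}\n")


def read_groups(path) -> dict[str, str]:
    """Group table TSV: individual_id, group_label."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return dict(zip(df[0], df[1]))


def write_groups(groups: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for ind, grp in groups.items():
            fh.write(f"{ind}\t{grp}\n")


def attach_genetic_map(gm: GenotypeMatrix, gmap: GeneticMap) -> GenotypeMatrix:
    """Fill the sites' cM column by interpolation on the genetic map."""
    missing_chroms = sorted(set(gm.sites["chrom"]) - set(gmap.anchors))
    if missing_chroms:
        raise InsulomeError(f"chromosomes absent from genetic map: {missing_chroms}")
    sites = gm.sites.copy()
    cm = np.empty(len(sites))
    chrom = sites["chrom"].to_numpy()
    bp = sites["bp"].to_numpy()
    for c in pd.unique(chrom):
        sel = chrom == c
        cm[sel] = gmap.interpolate(c, bp[sel])
    sites["cM"] = cm
    return replace(gm, sites=sites)
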