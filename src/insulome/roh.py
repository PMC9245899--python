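"""Sliding-window ROH calling (PLINK semantics), F_ROH and length spectra.

The caller reproduces the windowed heuristic of ``plink --homozyg`` with
the parameter set ``--homozyg-window-het 0 --homozyg-snp 50 --homozyg-kb 1
--homozyg-density 5000 --homozyg-gap 5000``:

1. every window of ``window_snps`` consecutive sites is *homozygous* iff
   its het count <= ``window_het_max`` and missing count <=
   ``window_missing_max``;
2. a site is in the ROH state iff the fraction of windows overlapping it
   that are homozygous is >= ``window_hit_fraction``;
3. candidate segments are maximal runs of in-state sites, split wherever
   the bp gap between adjacent sites exceeds ``max_inter_snp_gap_kb``;
4. segments are kept if they contain >= ``min_snps`` SNPs, span >=
   ``min_length_kb`` kb, and average no more than
   ``min_density_kb_per_snp`` kb per SNP;
5. segments are reported with bp and cM endpoints; those shorter than
   ``min_report_cM`` (genetic length) are dropped.

F_ROH is the summed genetic length of reported segments divided by the
total autosomal map length, in cM by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from insulome.core_io import MISSING, GenotypeMatrix, InsulomeError, Segment

logger = logging.getLogger(__name__)


@dataclass
class RohParams:
    """ROH caller settings; defaults freeze the PLINK parameter string.

    ``window_missing_max`` and ``window_hit_fraction`` take PLINK's
    documented defaults (5 and 0.05); the rest mirror the explicit flags.
    ``min_report_cM`` post-filters reported segments by genetic length
    (0 reports everything; 4/5/10/15 are the usual re-analysis settings).
    """

    window_snps: int = 50
    window_het_max: int = 0
    window_missing_max: int = 5
    min_snps: int = 50
    min_length_kb: float = 1.0
    max_inter_snp_gap_kb: float = 5000.0
    min_density_kb_per_snp: float = 5000.0
    window_hit_fraction: float = 0.05
    min_report_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.window_snps < 1:
            raise InsulomeError("window_snps must be >= 1")
        for name in (
            "window_het_max", "window_missing_max", "min_snps", "min_length_kb",
            "max_inter_snp_gap_kb", "min_density_kb_per_snp",
            "window_hit_fraction", "min_report_cm",
        ):
            if getattr(self, name) < 0:
                raise InsulomeError(f"{name} must be non-negative")


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    cs = np.concatenate(([0], np.cumsum(x)))
    return cs[w:] - cs[:-w]


def _in_roh_state(g: np.ndarray, params: RohParams) -> np.ndarray:
    """Step (1)+(2): per-site in-ROH-state flags for one chromosome."""
    n = len(g)
    w = params.window_snps
    if n < w:
        return np.zeros(n, dtype=bool)
    het = (g == 1).astype(np.int64)
    miss = (g == MISSING).astype(np.int64)
    hom_win = (_sliding_sum(het, w) <= params.window_het_max) & (
        _sliding_sum(miss, w) <= params.window_missing_max
    )
    # window i covers sites i .. i+w-1; windows covering site j are
    # i in [max(0, j-w+1), min(j, n-w)]
    hw = np.concatenate(([0], np.cumsum(hom_win)))
    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n - w)
    n_cover = hi - lo + 1
    n_hom = hw[hi + 1] - hw[lo]
    return n_hom >= params.window_hit_fraction * n_cover


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    return list(zip(starts, ends))


def call_roh(
    gm: GenotypeMatrix, individual_id: str, params: RohParams | None = None
) -> list[Segment]:
    """ROH segments of one individual (see module docstring for semantics)."""
    return call_roh_arrays(
        gm.genotypes_of(individual_id),
        gm.sites["chrom"].to_numpy(),
        gm.sites["bp"].to_numpy(),
        gm.sites["cM"].to_numpy(),
        params or RohParams(),
        individual_id,
    )


def call_roh_arrays(
    g_all: np.ndarray,
    chrom_col: np.ndarray,
    bp_col: np.ndarray,
    cm_col: np.ndarray,
    params: RohParams,
    individual_id: str,
) -> list[Segment]:
    """Array-level ROH caller (hot path for simulation replicates)."""
    if np.all(g_all == MISSING):
        logger.warning("call_roh: %s has no called genotypes", individual_id)
        return []

    segments: list[Segment] = []
    # chromosome blocks: sites are sorted, so block boundaries are label changes
    change = np.flatnonzero(chrom_col[1:] != chrom_col[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends_ = np.concatenate((change, [len(chrom_col)]))
    max_gap_bp = params.max_inter_snp_gap_kb * 1000.0
    for s0, s1 in zip(starts, ends_):
        chrom = chrom_col[s0]
        g = g_all[s0:s1]
        bp = bp_col[s0:s1]
        cm = cm_col[s0:s1]
        state = _in_roh_state(g, params)
        for start, end in _runs(state):
            # step (3): split at large inter-SNP gaps
            big = np.flatnonzero(np.diff(bp[start : end + 1]) > max_gap_bp)
            piece_starts = np.concatenate(([start], start + big + 1))
            piece_ends = np.concatenate((start + big, [end]))
            for a, b in zip(piece_starts, piece_ends):
                n_snps = b - a + 1
                span_bp = int(bp[b] - bp[a] + 1)
                if n_snps < params.min_snps:
                    continue
                if span_bp < params.min_length_kb * 1000.0:
                    continue
                if span_bp / n_snps > params.min_density_kb_per_snp * 1000.0:
                    continue
                if cm[b] - cm[a] < params.min_report_cm:
                    continue
                segments.append(
                    Segment(
                        kind="ROH",
                        ids=(individual_id,),
                        chrom=str(chrom),
                        start_bp=int(bp[a]),
                        end_bp=int(bp[b]),
                        start_cm=float(cm[a]),
                        end_cm=float(cm[b]),
                        n_snps=n_snps,
                    )
                )
    return segments


def f_roh(
    segments: list[Segment],
    autosomal_map_length_cm: float,
    min_report_cm: float = 0.0,
) -> float:
    """Fraction of the autosomal map in ROH at least ``min_report_cm`` long."""
    if autosomal_map_length_cm <= 0:
        raise InsulomeError("autosomal map length must be positive")
    total = sum(s.length_cm for s in segments if s.length_cm >= min_report_cm)
    f = total / autosomal_map_length_cm
    if f > 1.0 + 1e-9:
        raise InsulomeError(f"F_ROH {f} exceeds 1: segments overlap or wrong denominator")
    return min(f, 1.0)


def roh_spectrum(
    segments: list[Segment], bin_edges_cm
) -> tuple[np.ndarray, int]:
    """Histogram of genetic lengths, left-closed right-open bins.

    Returns (counts per bin, remainder outside all bins); counts plus
    remainder always equal the number of segments.
    """
    edges = np.asarray(bin_edges_cm, dtype=np.float64)
    if len(edges) < 2:
        raise InsulomeError("need at least two bin edges")
    if np.any(np.diff(edges) <= 0):
        raise InsulomeError("bin edges must be strictly increasing")
    lengths = np.array([s.length_cm for s in segments])
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    remainder = 0
    if lengths.size:
        idx = np.searchsorted(edges, lengths, side="right") - 1
        in_range = (idx >= 0) & (idx < len(edges) - 1)
        np.add.at(counts, idx[in_range], 1)
        remainder = int((~in_range).sum())
    return counts, remainder


@dataclass
class RohProfile:
    """Per-individual ROH summary: class totals and F_ROH."""

    individual_id: str
    segments: list[Segment]
    autosomal_map_length_cm: float
    total_cm_by_class: dict[float, float] = field(default_factory=dict)
    f_roh: float = 0.0

    @classmethod
    def from_segments(
        cls,
        individual_id: str,
        segments: list[Segment],
        autosomal_map_length_cm: float,
        length_classes: tuple[float, ...] = (4.0, 5.0, 10.0, 15.0),
        min_report_cm: float = 0.0,
    ) -> "RohProfile":
        totals = {
            c: sum(s.length_cm for s in segments if s.length_cm > c)
            for c in length_classes
        }
        return cls(
            individual_id=individual_id,
            segments=segments,
            autosomal_map_length_cm=autosomal_map_length_cm,
            total_cm_by_class=totals,
            f_roh=f_roh(segments, autosomal_map_length_cm, min_report_cm),
        )
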