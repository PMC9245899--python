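"""IBD segment detection, kinship filtering, sharing summaries and PCA.

Detection scores each site with a log10 likelihood ratio comparing an
IBD1 model (the pair shares one allele drawn from the population, each
individual adding one independent population allele) against a non-IBD
model (independent Hardy–Weinberg genotypes), both perturbed by a
per-allele miscall rate ``errormax``.  Per chromosome, maximal-scoring
disjoint intervals of the site-score sequence are reported when their
total LOD reaches ``lod_min`` and their genetic length reaches
``min_length_cM`` (2 cM by default: shorter segments are unreliable on
unphased common-SNP data).  Sites are treated as independent given the
IBD state — appropriate after MAF filtering and LD pruning, a documented
approximation otherwise.

Relatedness is estimated with the robust within-pair kinship
``phi = (N_het,het - 2 N_opp,hom) / (N_het(i) + N_het(j))`` (the KING
estimator); pairs closer than a threshold (default 0.0442, the 3rd/4th
degree boundary) are pruned before population-level IBD summaries so that
close family does not masquerade as deme-level sharing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from insulome.core_io import MISSING, GenotypeMatrix, InsulomeError, Segment

logger = logging.getLogger(__name__)


@dataclass
class IbdParams:
    errormax: float = 0.005
    lod_min: float = 3.0
    min_length_cm: float = 2.0
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.errormax <= 0.05:
            raise InsulomeError("errormax must lie in (0, 0.05]")
        if self.lod_min <= 0 or self.min_length_cm <= 0:
            raise InsulomeError("lod_min and min_length_cm must be positive")


# ---------------------------------------------------------------------------
# site-level LOD score
# ---------------------------------------------------------------------------


def _error_matrix(eps: float) -> np.ndarray:
    """P(observed genotype | true genotype) under per-allele miscalls."""
    return np.array(
        [
            [(1 - eps) ** 2, 2 * eps * (1 - eps), eps**2],
            [eps * (1 - eps), (1 - eps) ** 2 + eps**2, eps * (1 - eps)],
            [eps**2, 2 * eps * (1 - eps), (1 - eps) ** 2],
        ]
    )


def site_lod(g1: int, g2: int, p: float, errormax: float) -> float:
    """log10 P(g1, g2 | IBD1) / P(g1, g2 | non-IBD) at one site."""
    if not 0.0 < p < 1.0:
        raise InsulomeError(f"allele frequency must lie in (0, 1), got {p}")
    if g1 == MISSING or g2 == MISSING:
        return 0.0
    table = lod_table(np.array([p]), errormax)[0]
    return float(table[g1, g2])


def lod_table(p: np.ndarray, errormax: float) -> np.ndarray:
    """(n_sites, 3, 3) per-site LOD lookup over observed genotype pairs."""
    p = np.asarray(p, dtype=np.float64)
    if np.any(p <= 0) or np.any(p >= 1):
        raise InsulomeError("allele frequencies must lie strictly in (0, 1)")
    q = 1.0 - p
    m = _error_matrix(errormax)  # (3, 3): true -> observed

    # non-IBD: independent HWE genotypes, error-perturbed
    hwe = np.stack([q * q, 2 * p * q, p * p], axis=1)  # (n, 3) true
    marg = hwe @ m  # (n, 3) observed
    p_non = marg[:, :, None] * marg[:, None, :]  # (n, 3, 3)

    # IBD1: shared allele a ~ freq; each individual = a + one population allele
    d_ref = np.stack([q, p, np.zeros_like(p)], axis=1) @ m  # obs | a = ref
    d_alt = np.stack([np.zeros_like(p), q, p], axis=1) @ m  # obs | a = alt
    # outer products computed first so the table is bit-exactly symmetric
    p_ibd = (
        q[:, None, None] * (d_ref[:, :, None] * d_ref[:, None, :])
        + p[:, None, None] * (d_alt[:, :, None] * d_alt[:, None, :])
    )
    return np.log10(p_ibd) - np.log10(p_non)


# ---------------------------------------------------------------------------
# segment detection
# ---------------------------------------------------------------------------


def _max_scoring_intervals(
    scores: np.ndarray, lod_min: float, cm: np.ndarray, min_len_cm: float
) -> list[tuple[int, int, float]]:
    """Maximal-scoring disjoint intervals (recursive max-subarray split).

    The best-scoring interval is located via the running-sum minimum; if
    its score reaches ``lod_min`` and its genetic span ``min_len_cm`` it is
    reported; the flanks are processed recursively either way (no interval
    elsewhere can outscore the best, so recursion preserves maximality).
    """
    out: list[tuple[int, int, float]] = []
    stack = [(0, len(scores))]
    prefix = np.concatenate(([0.0], np.cumsum(scores)))
    while stack:
        lo, hi = stack.pop()
        if hi <= lo:
            continue
        seg = prefix[lo : hi + 1]
        # best (i, j): maximise prefix[j+1] - prefix[i], i <= j; the
        # running-minimum index (earliest on ties) marks the start
        mins = np.minimum.accumulate(seg)
        is_new_min = np.empty(len(seg), dtype=bool)
        is_new_min[0] = True
        is_new_min[1:] = seg[1:] < mins[:-1]
        min_idx = np.maximum.accumulate(
            np.where(is_new_min, np.arange(len(seg)), 0)
        )
        gains = seg[1:] - mins[:-1]
        j_rel = int(np.argmax(gains))
        i_rel = int(min_idx[j_rel])
        score = float(gains[j_rel])
        if score < lod_min:
            continue
        i, j = lo + i_rel, lo + j_rel  # sites i..j inclusive
        if cm[j] - cm[i] >= min_len_cm:
            out.append((i, j, score))
        stack.append((lo, i))
        stack.append((j + 1, hi))
    return sorted(out)


def detect_ibd(
    gm: GenotypeMatrix,
    id_i: str,
    id_j: str,
    params: IbdParams | None = None,
    table: np.ndarray | None = None,
) -> list[Segment]:
    """IBD segments between two distinct individuals.

    ``table`` may carry a precomputed :func:`lod_table` for the panel
    (reused across pairs).  Endpoints are the outermost contributing SNPs.
    """
    params = params or IbdParams()
    if id_i == id_j:
        raise InsulomeError("detect_ibd needs two distinct individuals (use ROH within one)")
    if table is None:
        table = lod_table(gm.sites["p"].to_numpy(), params.errormax)
    g1 = gm.genotypes_of(id_i)
    g2 = gm.genotypes_of(id_j)
    ok = (g1 != MISSING) & (g2 != MISSING)
    scores = np.zeros(gm.n_sites)
    idx = np.flatnonzero(ok)
    scores[idx] = table[idx, g1[idx], g2[idx]]

    chrom_col = gm.sites["chrom"].to_numpy()
    bp_col = gm.sites["bp"].to_numpy()
    cm_col = gm.sites["cM"].to_numpy()
    segments = []
    for chrom in pd.unique(chrom_col):
        sel = np.flatnonzero(chrom_col == chrom)
        for i, j, lod in _max_scoring_intervals(
            scores[sel], params.lod_min, cm_col[sel], params.min_length_cm
        ):
            a, b = sel[i], sel[j]
            segments.append(
                Segment(
                    kind="IBD",
                    ids=(id_i, id_j),
                    chrom=str(chrom),
                    start_bp=int(bp_col[a]),
                    end_bp=int(bp_col[b]),
                    start_cm=float(cm_col[a]),
                    end_cm=float(cm_col[b]),
                    n_snps=int(b - a + 1),
                    lod=lod,
                )
            )
    return segments


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def kinship(gm: GenotypeMatrix, id_i: str, id_j: str, min_overlap: int = 100) -> float:
    """Robust pairwise kinship phi-hat (KING estimator); NaN if overlap < min."""
    g1 = gm.genotypes_of(id_i)
    g2 = gm.genotypes_of(id_j)
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < min_overlap:
        logger.warning("kinship %s/%s: only %d overlapping sites", id_i, id_j, ok.sum())
        return float("nan")
    a, b = g1[ok], g2[ok]
    n_hethet = int(((a == 1) & (b == 1)).sum())
    n_opphom = int((np.abs(a.astype(np.int16) - b) == 2).sum())
    n_het = int((a == 1).sum() + (b == 1).sum())
    if n_het == 0:
        return float("nan")
    return (n_hethet - 2.0 * n_opphom) / n_het


def kinship_matrix(gm: GenotypeMatrix, min_overlap: int = 100) -> pd.DataFrame:
    n = gm.n_individuals
    phi = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            phi[i, j] = phi[j, i] = kinship(gm, gm.ids[i], gm.ids[j], min_overlap)
    return pd.DataFrame(phi, index=gm.ids, columns=gm.ids)


def filter_relatives(
    gm: GenotypeMatrix, threshold: float = 0.0442, min_overlap: int = 100
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedily prune individuals until no pair has phi-hat > threshold.

    From the highest-kinship offending pair, the member with more missing
    genotypes is removed (ties break toward the later id).  Returns kept
    ids (input order) and a (removed, partner, phi) log.  The default
    threshold 0.0442 removes 3rd-degree and closer relatives.
    """
    phi = kinship_matrix(gm, min_overlap).to_numpy()
    n_missing = (gm.genotypes == MISSING).sum(axis=1)
    alive = np.ones(gm.n_individuals, dtype=bool)
    removed_log: list[tuple[str, str, float]] = []
    while True:
        masked = np.where(np.outer(alive, alive), phi, np.nan)
        np.fill_diagonal(masked, np.nan)
        if not np.any(masked > threshold):
            break
        i, j = np.unravel_index(np.nanargmax(masked), masked.shape)
        if n_missing[i] > n_missing[j]:
            drop = i
        elif n_missing[j] > n_missing[i]:
            drop = j
        else:
            drop = max(i, j)  # tie: later id in panel order
        alive[drop] = False
        other = j if drop == i else i
        removed_log.append((gm.ids[drop], gm.ids[other], float(phi[i, j])))
    kept = [gm.ids[k] for k in range(gm.n_individuals) if alive[k]]
    return kept, removed_log


# ---------------------------------------------------------------------------
# IBD matrix, group summaries, PCA
# ---------------------------------------------------------------------------


@dataclass
class IbdMatrix:
    """Symmetric per-pair total shared cM and segment counts (diagonal 0)."""

    ids: list[str]
    total_cm: np.ndarray
    n_segments: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        for m in (self.total_cm, self.n_segments):
            if m.shape != (n, n) or not np.allclose(m, m.T) or np.any(np.diag(m) != 0):
                raise InsulomeError("IBD matrix must be symmetric with zero diagonal")
        if np.any(self.total_cm < 0):
            raise InsulomeError("IBD totals must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.total_cm, index=self.ids, columns=self.ids)


def pairwise_ibd_matrix(
    gm: GenotypeMatrix, params: IbdParams | None = None
) -> tuple[IbdMatrix, list[Segment]]:
    """detect_ibd over all pairs; returns the matrix and all segments."""
    params = params or IbdParams()
    if gm.n_individuals < 2:
        raise InsulomeError("need at least two individuals")
    table = lod_table(gm.sites["p"].to_numpy(), params.errormax)
    n = gm.n_individuals
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=np.int64)
    all_segments: list[Segment] = []
    for i in range(n):
        for j in range(i + 1, n):
            segs = detect_ibd(gm, gm.ids[i], gm.ids[j], params, table=table)
            s = sum(seg.length_cm for seg in segs)
            total[i, j] = total[j, i] = s
            count[i, j] = count[j, i] = len(segs)
            all_segments.extend(segs)
    return IbdMatrix(ids=list(gm.ids), total_cm=total, n_segments=count), all_segments


@dataclass
class GroupSummary:
    """Mean per-pair total IBD cM within and between groups (>= 2 members)."""

    labels: list[str]
    mean_total_cm: pd.DataFrame
    pair_counts: pd.DataFrame


def group_summary(matrix: IbdMatrix, groups: dict[str, str]) -> GroupSummary:
    """Within/between-group means over pairs; singleton groups dropped."""
    if not groups:
        raise InsulomeError("empty group table")
    unknown = [i for i in matrix.ids if i not in groups]
    if unknown:
        raise InsulomeError(f"individuals without group label: {unknown[:5]}")
    members: dict[str, list[int]] = {}
    for k, ind in enumerate(matrix.ids):
        members.setdefault(groups[ind], []).append(k)
    labels = sorted(g for g, m in members.items() if len(m) >= 2)
    mean = pd.DataFrame(0.0, index=labels, columns=labels)
    counts = pd.DataFrame(0, index=labels, columns=labels)
    for a in labels:
        for b in labels:
            ia, ib = members[a], members[b]
            if a == b:
                vals = [matrix.total_cm[i, j] for x, i in enumerate(ia) for j in ia[x + 1 :]]
            else:
                vals = [matrix.total_cm[i, j] for i in ia for j in ib]
            mean.loc[a, b] = float(np.mean(vals)) if vals else 0.0
            counts.loc[a, b] = len(vals)
    return GroupSummary(labels=labels, mean_total_cm=mean, pair_counts=counts)


def ibd_pca(
    matrix: IbdMatrix, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the total-IBD matrix (rows as feature vectors).

    Columns are mean-centred and decomposed by SVD; returns per-individual
    scores for the leading components and variance-explained fractions.
    """
    n = len(matrix.ids)
    if n < 3:
        raise InsulomeError("PCA needs at least three individuals")
    x = matrix.total_cm - matrix.total_cm.mean(axis=0, keepdims=True)
    if np.allclose(x, 0):
        raise InsulomeError("constant IBD matrix: no variance to decompose")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    var_frac = (s**2 / np.sum(s**2))[:k]
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=matrix.ids, columns=cols), var_frac


def ne_eligibility(
    segments_by_group: dict[str, list[Segment]],
    min_segments: int = 90,
    min_length_cm: float = 2.0,
) -> dict[str, bool]:
    """Groups eligible for trajectory estimation: >= 90 segments >= 2 cM."""
    return {
        g: sum(1 for s in segs if s.length_cm >= min_length_cm) >= min_segments
        for g, segs in segments_by_group.items()
    }
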