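"""Independent brute-force oracles used to validate the implementations.

These are deliberately literal, slow re-statements of the operation
contracts — no code is shared with the package modules they check.
"""

from __future__ import annotations

import math

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# ROH window-semantics oracle
# ---------------------------------------------------------------------------


def brute_force_roh(g, bp, cm, params) -> list[tuple[int, int]]:
    """Literal implementation of the windowed ROH steps (1)-(5).

    Returns kept segments as (first, last) site index pairs for a single
    chromosome.
    """
    g = list(g)
    n = len(g)
    w = params.window_snps

    hom_windows = []
    for i in range(n - w + 1):
        win = g[i : i + w]
        n_het = sum(1 for x in win if x == 1)
        n_miss = sum(1 for x in win if x == MISSING)
        hom_windows.append(
            n_het <= params.window_het_max and n_miss <= params.window_missing_max
        )

    in_state = []
    for j in range(n):
        cover = [
            hom_windows[i]
            for i in range(max(0, j - w + 1), min(j, n - w) + 1)
        ]
        in_state.append(
            bool(cover) and sum(cover) / len(cover) >= params.window_hit_fraction
        )

    runs = []
    j = 0
    while j < n:
        if in_state[j]:
            k = j
            while k + 1 < n and in_state[k + 1]:
                k += 1
            runs.append((j, k))
            j = k + 1
        else:
            j += 1

    pieces = []
    for start, end in runs:
        s = start
        for k in range(start, end):
            if bp[k + 1] - bp[k] > params.max_inter_snp_gap_kb * 1000.0:
                pieces.append((s, k))
                s = k + 1
        pieces.append((s, end))

    kept = []
    for a, b in pieces:
        n_snps = b - a + 1
        span = bp[b] - bp[a] + 1
        if n_snps < params.min_snps:
            continue
        if span < params.min_length_kb * 1000.0:
            continue
        if span / n_snps > params.min_density_kb_per_snp * 1000.0:
            continue
        if cm[b] - cm[a] < params.min_report_cm:
            continue
        kept.append((a, b))
    return kept


# ---------------------------------------------------------------------------
# site-LOD enumeration oracle
# ---------------------------------------------------------------------------


def _obs_prob(alleles: tuple[int, ...], g_obs: int, eps: float) -> float:
    """P(observed alt count | true alleles) by enumerating per-allele flips."""
    total = 0.0
    a1, a2 = alleles
    for f1 in (0, 1):
        for f2 in (0, 1):
            obs = (a1 ^ f1) + (a2 ^ f2)
            if obs == g_obs:
                total += (eps if f1 else 1 - eps) * (eps if f2 else 1 - eps)
    return total


def enumerate_site_lod(g1: int, g2: int, p: float, eps: float) -> float:
    """LOD by exhaustive enumeration of true alleles and miscalls."""
    q = 1.0 - p

    def freq(a: int) -> float:
        return p if a == 1 else q

    # non-IBD: each individual's two alleles independent draws
    def p_obs_hwe(g_obs: int) -> float:
        return sum(
            freq(a1) * freq(a2) * _obs_prob((a1, a2), g_obs, eps)
            for a1 in (0, 1)
            for a2 in (0, 1)
        )

    p_non = p_obs_hwe(g1) * p_obs_hwe(g2)

    # IBD1: one shared allele plus one population allele per individual
    p_ibd = 0.0
    for shared in (0, 1):
        term = freq(shared)
        for g_obs in (g1, g2):
            term *= sum(
                freq(b) * _obs_prob((shared, b), g_obs, eps) for b in (0, 1)
            )
        p_ibd += term
    return math.log10(p_ibd) - math.log10(p_non)


# ---------------------------------------------------------------------------
# Monte-Carlo oracle for the expected ROH length spectrum
# ---------------------------------------------------------------------------


def mc_roh_spectrum(
    ne: float,
    chrom_lengths_morgans,
    bin_edges,
    n_reps: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the segment-length model directly.

    Per genome and chromosome: draw the coalescence time T from the
    geometric distribution with success probability 1/(2 Ne), drop
    Poisson(2 T G) recombination breakpoints uniformly, and tally all
    resulting piece lengths into the bins.  Returns (mean counts per
    genome, standard error) per bin.
    """
    rng = np.random.default_rng(seed)
    edges = np.asarray(bin_edges)
    counts = np.zeros((n_reps, len(edges) - 1))
    for g_len in chrom_lengths_morgans:
        t = rng.geometric(1.0 / (2.0 * ne), size=n_reps)
        n_breaks = rng.poisson(2.0 * t * g_len)
        for r in range(n_reps):
            if n_breaks[r] == 0:
                lens = np.array([g_len])
            else:
                b = np.sort(rng.uniform(0.0, g_len, size=n_breaks[r]))
                lens = np.diff(np.concatenate(([0.0], b, [g_len])))
            counts[r] += np.histogram(lens, bins=edges)[0]
    return counts.mean(axis=0), counts.std(axis=0) / np.sqrt(n_reps)


def integrate_expected_density(model, ne: float, bin_edges, n_sub: int = 50) -> np.ndarray:
    """Fine midpoint quadrature of lambda(x) over each bin."""
    edges = np.asarray(bin_edges)
    out = np.empty(len(edges) - 1)
    for k, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        xs = a + (np.arange(n_sub) + 0.5) * (b - a) / n_sub
        out[k] = float(np.mean(model.expected_density(ne, xs)) * (b - a))
    return out
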