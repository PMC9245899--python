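"""Effective population size from the ROH length spectrum.

Model
-----
For a diploid genome, the two copies of a locus coalesce ``t`` generations
back with the discrete-time geometric probability
``P(T = t) = (1/2Ne) (1 - 1/2Ne)^(t-1)``.  Conditional on ``t``,
recombination in the ``2t`` meioses separating the two copies is a Poisson
process of rate ``2t`` per Morgan, so on a chromosome of map length ``G``
Morgans the expected number of ROH segments of length ``x`` (density per
Morgan) is ``(2t)^2 (G - x) e^(-2tx)`` for interior segments plus
``2 (2t) e^(-2tx)`` for segments abutting a chromosome end.  Marginalising
over ``t`` gives the expected ROH length spectrum

    lambda(x) = sum_c sum_t P(T=t) [ 4 t^2 (G_c - x) + 4 t ] e^(-2 t x)

summed over chromosomes ``c`` (a chromosome shorter than ``x`` contributes
nothing).  Segments are treated as independent, giving a composite Poisson
likelihood over narrow length bins; the constant-Ne MLE maximises it over
``ln Ne`` and a 95% CI comes from the profile-likelihood drop of 1.92
(chi-square with one degree of freedom).

The likelihood is evaluated on segments selected to a length window
(default 4-20 cM, where the spectrum is informative about recent size and
insensitive to both very recent pedigree loops and phasing-scale noise);
bins outside the window carry no terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from insulome.core_io import GeneticMap, InsulomeError, Segment

logger = logging.getLogger(__name__)


@dataclass
class RohNeModel:
    """Configuration of the ROH-spectrum likelihood.

    ``chrom_lengths_morgans`` are the map lengths of the analysed
    autosomes; ``bin_range`` (Morgans) is discretised into ``n_bins``
    equal bins, of which only those inside [min_len, max_len] cM enter the
    likelihood; ``n_genomes`` scales expected counts.  ``t_max`` truncates
    the coalescence-time sum; the geometric tail mass beyond it must be
    negligible at the lower Ne search bound.
    """

    chrom_lengths_morgans: np.ndarray
    min_len_cm: float = 4.0
    max_len_cm: float = 20.0
    bin_range: tuple[float, float] = (0.04, 0.5)
    n_bins: int = 1000
    t_max: int = 2000
    ne_bounds: tuple[float, float] = (10.0, 1e6)
    n_genomes: int = 1

    bin_edges: np.ndarray = field(init=False)
    bin_mids: np.ndarray = field(init=False)
    bin_width: float = field(init=False)

    def __post_init__(self) -> None:
        self.chrom_lengths_morgans = np.asarray(self.chrom_lengths_morgans, dtype=np.float64)
        if not 0 < self.min_len_cm < self.max_len_cm:
            raise InsulomeError("need 0 < min_len_cm < max_len_cm")
        if self.n_genomes < 1:
            raise InsulomeError("n_genomes must be >= 1")
        lo, hi = self.bin_range
        self.bin_edges = np.linspace(lo, hi, self.n_bins + 1)
        self.bin_mids = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        self.bin_width = (hi - lo) / self.n_bins
        # geometric tail mass beyond t_max at the lower Ne search bound
        tail = (1 - 1 / (2 * self.ne_bounds[0])) ** self.t_max
        if tail > 1e-6:
            raise InsulomeError(
                f"t_max={self.t_max} leaves tail mass {tail:.2e} at Ne={self.ne_bounds[0]}"
            )
        self._t = np.arange(1, self.t_max + 1, dtype=np.float64)
        self._cache_x: np.ndarray | None = None
        self._cache_E: np.ndarray | None = None

    @classmethod
    def from_map(cls, gmap: GeneticMap, **kwargs) -> "RohNeModel":
        return cls(chrom_lengths_morgans=gmap.lengths_morgans(), **kwargs)

    @property
    def fit_mask(self) -> np.ndarray:
        """Bins whose midpoints lie inside the [min_len, max_len] window."""
        return (self.bin_mids >= self.min_len_cm / 100.0) & (
            self.bin_mids <= self.max_len_cm / 100.0
        )

    # -- model terms -------------------------------------------------------

    def _geom_weights(self, ne: float) -> np.ndarray:
        if ne < 2:
            raise InsulomeError(f"Ne must be >= 2, got {ne}")
        p = 1.0 / (2.0 * ne)
        # log-space to avoid underflow of (1-p)^(t-1) at small Ne
        return np.exp(np.log(p) + (self._t - 1) * np.log1p(-p))

    def _sum_terms(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """S1(x) = sum_c max(G_c - x, 0);  S0(x) = sum_c [x < G_c]."""
        g = self.chrom_lengths_morgans[:, None]
        xr = np.asarray(x, dtype=np.float64)[None, :]
        inside = xr < g
        s1 = np.where(inside, g - xr, 0.0).sum(axis=0)
        s0 = inside.sum(axis=0).astype(np.float64)
        return s1, s0

    def _exp_matrix(self, x: np.ndarray) -> np.ndarray:
        """e^(-2 t x), memoised for the most recent evaluation grid."""
        x = np.asarray(x, dtype=np.float64)
        if (
            self._cache_x is not None
            and x.shape == self._cache_x.shape
            and np.array_equal(x, self._cache_x)
        ):
            return self._cache_E
        E = np.exp(-2.0 * np.outer(self._t, x))
        self._cache_x, self._cache_E = x, E
        return E

    def expected_density(self, ne: float, x) -> np.ndarray:
        """lambda(x): expected ROH segments per Morgan per genome."""
        scalar = np.isscalar(x)
        x = np.atleast_1d(np.asarray(x, dtype=np.float64))
        if np.any(x <= 0):
            raise InsulomeError("segment length x must be positive (Morgans)")
        w = self._geom_weights(ne)
        E = self._exp_matrix(x)
        s1, s0 = self._sum_terms(x)
        lam = ((w * 4 * self._t**2) @ E) * s1 + ((w * 4 * self._t) @ E) * s0
        return float(lam[0]) if scalar else lam

    def expected_bin_counts(self, ne: float, fit_window_only: bool = True) -> np.ndarray:
        """mu_b = n_genomes * lambda(midpoint) * width, per bin."""
        mu = self.n_genomes * self.expected_density(ne, self.bin_mids) * self.bin_width
        if fit_window_only:
            mu = np.where(self.fit_mask, mu, 0.0)
        return mu


def expected_roh_density(ne: float, x, model: RohNeModel):
    """Functional alias for :meth:`RohNeModel.expected_density`."""
    return model.expected_density(ne, x)


def roh_loglik(bin_counts: np.ndarray, ne: float, model: RohNeModel) -> float:
    """Composite Poisson log-likelihood, up to a constant in Ne.

    Only bins inside the model's fit window contribute; counts there must
    be non-negative.
    """
    k = np.asarray(bin_counts, dtype=np.float64)
    if len(k) != model.n_bins:
        raise InsulomeError(f"expected {model.n_bins} bin counts, got {len(k)}")
    if np.any(k < 0):
        raise InsulomeError("negative bin counts")
    mask = model.fit_mask
    mu = model.n_genomes * model.expected_density(ne, model.bin_mids[mask]) * model.bin_width
    kk = k[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = kk * np.log(mu) - mu
    term = np.where((kk == 0) & (mu == 0), 0.0, term)
    return float(np.sum(term))


def segments_to_bin_counts(segments: list[Segment], model: RohNeModel) -> np.ndarray:
    """Histogram segment genetic lengths (Morgans) onto the model bins."""
    lengths = np.array([s.length_cm / 100.0 for s in segments])
    counts = np.zeros(model.n_bins, dtype=np.int64)
    if lengths.size:
        idx = np.searchsorted(model.bin_edges, lengths, side="right") - 1
        ok = (idx >= 0) & (idx < model.n_bins)
        np.add.at(counts, idx[ok], 1)
    return counts


@dataclass
class NeEstimate:
    """Constant-Ne MLE with profile-likelihood 95% CI."""

    ne_hat: float
    ci95: tuple[float, float]
    max_loglik: float
    n_segments: int
    excluded_ids: list[str]
    at_boundary: bool
    model: RohNeModel

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= self.ne_hat <= hi:
            raise InsulomeError("CI does not contain the point estimate")


def fit_ne_roh(
    segment_sets: dict[str, list[Segment]],
    model: RohNeModel,
    exclude_ids: list[str] | None = None,
) -> NeEstimate:
    """Pooled constant-Ne MLE from per-individual ROH segment sets.

    ``exclude_ids`` removes individuals (e.g. those classified as products
    of close consanguinity, whose long ROH reflect pedigree loops rather
    than population size) before pooling.  Segments are restricted to the
    model's [min_len, max_len] cM window.  The 95% CI is the profile
    likelihood drop of 1.92; estimates that hit a search bound are
    reported at the bound with ``at_boundary=True``.
    """
    exclude = set(exclude_ids or ())
    used = {k: v for k, v in segment_sets.items() if k not in exclude}
    model.n_genomes = max(len(used), 1)
    pooled = [
        s
        for segs in used.values()
        for s in segs
        if model.min_len_cm <= s.length_cm <= model.max_len_cm
    ]
    counts = segments_to_bin_counts(pooled, model)
    est = fit_ne_counts(counts, model, n_segments=len(pooled))
    est.excluded_ids = sorted(exclude)
    return est


def fit_ne_counts(
    counts: np.ndarray, model: RohNeModel, n_segments: int | None = None
) -> NeEstimate:
    """Constant-Ne MLE and profile-likelihood CI from binned counts."""
    counts = np.asarray(counts)
    if n_segments is None:
        n_segments = int(counts[model.fit_mask].sum())
    lo, hi = model.ne_bounds
    log_lo, log_hi = np.log(lo), np.log(hi)

    if n_segments == 0:
        logger.warning("fit_ne: zero usable segments; reporting upper search bound")
        ll = roh_loglik(counts, hi, model)
        return NeEstimate(hi, (lo, hi), ll, 0, [], True, model)

    def neg_ll(log_ne: float) -> float:
        return -roh_loglik(counts, float(np.exp(log_ne)), model)

    res = optimize.minimize_scalar(
        neg_ll, bounds=(log_lo, log_hi), method="bounded",
        options={"xatol": 1e-4},
    )
    log_ne_hat = float(res.x)
    ll_max = -float(res.fun)
    at_boundary = bool(log_ne_hat - log_lo < 1e-3 or log_hi - log_ne_hat < 1e-3)
    ne_hat = float(np.exp(log_ne_hat))

    def drop(log_ne: float) -> float:
        return (-neg_ll(log_ne)) - (ll_max - 1.92)

    ci_lo, ci_hi = lo, hi
    if drop(log_lo) < 0:
        ci_lo = float(np.exp(optimize.brentq(drop, log_lo, log_ne_hat, xtol=1e-6)))
    else:
        at_boundary = True
    if drop(log_hi) < 0:
        ci_hi = float(np.exp(optimize.brentq(drop, log_ne_hat, log_hi, xtol=1e-6)))
    else:
        at_boundary = True
    return NeEstimate(
        ne_hat=min(max(ne_hat, ci_lo), ci_hi),
        ci95=(ci_lo, ci_hi),
        max_loglik=ll_max,
        n_segments=n_segments,
        excluded_ids=[],
        at_boundary=at_boundary,
        model=model,
    )


def harmonic_mean_ne(trajectory, g_start: int = 5, g_end: int = 30) -> float:
    """Harmonic mean of per-generation sizes over [g_start, g_end].

    ``trajectory`` is indexable by generation (0 = present): an array
    covering at least generation ``g_end``, or a mapping generation->size.
    """
    if g_end < g_start:
        raise InsulomeError("g_end must be >= g_start")
    gens = range(g_start, g_end + 1)
    try:
        values = np.array([float(trajectory[g]) for g in gens])
    except (IndexError, KeyError) as exc:
        raise InsulomeError(f"trajectory does not cover generations {g_start}..{g_end}") from exc
    if np.any(values <= 0):
        raise InsulomeError("population sizes must be positive")
    return float(len(values) / np.sum(1.0 / values))
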