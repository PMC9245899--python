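"""Consanguinity null distributions from pedigree gene dropping.

Six explicit pedigrees produce an inbred focal offspring whose parents are
first-degree (full siblings, parent-offspring), second-degree (avuncular,
grandparent-grandchild) or third-degree (first cousins, great-avuncular)
relatives, with expected inbreeding coefficients 1/4, 1/4, 1/8, 1/8, 1/16,
1/16.  Each scenario is gene-dropped many times (default 400) from founder
haplotypes sampled without replacement; every replicate is pushed through
the ROH caller, yielding a null cloud in (number of ROH segments, F_ROH)
space.  A query genome is classified against the clouds by Mahalanobis
distance together with the empirical quantile of that distance among the
cloud's own points, turning the visual "inside / at the edge / outside the
simulated distribution" judgement into a reproducible rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from insulome.core_io import GeneticMap, GenotypeMatrix, InsulomeError
from insulome.roh import RohParams, call_roh_arrays, f_roh
from insulome.synthetic_data import (
    AncestryTruth,
    Haplotype,
    HaplotypePanel,
    _chrom_offsets,
    as_rng,
    diploid_genotypes,
    haplotype_alleles,
    meiosis,
)

FOCAL = "X"


@dataclass(frozen=True)
class PedigreeScenario:
    """One consanguinity scenario: founder slots and mating order.

    ``matings`` lists (child, parent1, parent2) in dependency order;
    parents are founder slots ("F1", ...) or previously defined children.
    The focal inbred offspring is always named "X".
    """

    label: str
    degree: int
    expected_f: float
    n_founders: int
    matings: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if abs(self.expected_f - 0.5 ** (self.degree + 1)) > 1e-12:
            raise InsulomeError(
                f"{self.label}: expected F {self.expected_f} != (1/2)^(degree+1)"
            )


def scenario_pedigrees() -> list[PedigreeScenario]:
    """The six scenarios: two each of degrees 1, 2 and 3."""
    return [
        PedigreeScenario(
            "first_degree_sib", 1, 1 / 4, 2,
            (("A", "F1", "F2"), ("B", "F1", "F2"), (FOCAL, "A", "B")),
        ),
        PedigreeScenario(
            "first_degree_parent_offspring", 1, 1 / 4, 2,
            (("A", "F1", "F2"), (FOCAL, "F1", "A")),
        ),
        PedigreeScenario(
            "second_degree_avuncular", 2, 1 / 8, 3,
            (("A", "F1", "F2"), ("B", "F1", "F2"), ("C", "B", "F3"), (FOCAL, "A", "C")),
        ),
        PedigreeScenario(
            "second_degree_grandparent", 2, 1 / 8, 3,
            (("A", "F1", "F2"), ("B", "A", "F3"), (FOCAL, "F1", "B")),
        ),
        PedigreeScenario(
            "third_degree_first_cousins", 3, 1 / 16, 4,
            (
                ("A", "F1", "F2"), ("B", "F1", "F2"),
                ("C", "A", "F3"), ("D", "B", "F4"), (FOCAL, "C", "D"),
            ),
        ),
        PedigreeScenario(
            "third_degree_great_avuncular", 3, 1 / 16, 4,
            (
                ("A", "F1", "F2"), ("B", "F1", "F2"),
                ("C", "B", "F3"), ("D", "C", "F4"), (FOCAL, "A", "D"),
            ),
        ),
    ]


def _drop_focal(
    scenario: PedigreeScenario,
    founders: HaplotypePanel,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> tuple[Haplotype, Haplotype]:
    """Gene-drop one replicate; returns the focal offspring's haplotypes."""
    need = 2 * scenario.n_founders
    if founders.n_haplotypes < need:
        raise InsulomeError(
            f"{scenario.label}: need {need} founder haplotypes, have {founders.n_haplotypes}"
        )
    picks = rng.choice(founders.n_haplotypes, size=need, replace=False)
    people: dict[str, tuple[Haplotype, Haplotype]] = {
        f"F{k + 1}": (
            Haplotype.founder(gmap, int(picks[2 * k])),
            Haplotype.founder(gmap, int(picks[2 * k + 1])),
        )
        for k in range(scenario.n_founders)
    }
    for child, p1, p2 in scenario.matings:
        people[child] = (
            meiosis(people[p1], gmap, rng)[0],
            meiosis(people[p2], gmap, rng)[0],
        )
    return people[FOCAL]


def gene_drop(
    scenario: PedigreeScenario,
    founders: HaplotypePanel,
    gmap: GeneticMap,
    seed=0,
) -> tuple[GenotypeMatrix, AncestryTruth]:
    """One replicate: focal offspring genotypes plus ancestry truth."""
    rng = as_rng(seed)
    focal = _drop_focal(scenario, founders, gmap, rng)
    gm = diploid_genotypes({FOCAL: focal}, founders, gmap)
    truth = AncestryTruth(haplotypes={FOCAL: focal}, gmap=gmap, sites=gm.sites)
    return gm, truth


# ---------------------------------------------------------------------------
# null clouds
# ---------------------------------------------------------------------------


@dataclass
class NullCloud:
    """Simulated (N_ROH, F_ROH) distribution for one scenario."""

    label: str
    degree: int
    points: np.ndarray  # (n_reps, 2): n_roh_segments, f_roh
    mean: np.ndarray = field(init=False)
    cov: np.ndarray = field(init=False)
    degenerate: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise InsulomeError("a null cloud needs >= 2 (count, F) points")
        if np.any(self.points[:, 1] < 0) or np.any(self.points[:, 1] > 1):
            raise InsulomeError("F_ROH points outside [0, 1]")
        self.mean = self.points.mean(axis=0)
        cov = np.cov(self.points, rowvar=False) + 1e-9 * np.eye(2)
        self.degenerate = np.linalg.matrix_rank(np.cov(self.points, rowvar=False)) < 2
        self.cov = cov

    @property
    def n_reps(self) -> int:
        return len(self.points)

    def mahalanobis(self, point) -> float:
        d = np.asarray(point, dtype=np.float64) - self.mean
        if self.degenerate:
            return float(np.sqrt(d @ d))  # identity fallback
        return float(np.sqrt(d @ np.linalg.solve(self.cov, d)))

    def distance_quantile(self, point) -> float:
        """Empirical quantile of the query's distance among cloud points."""
        d = self.mahalanobis(point)
        own = np.array([self.mahalanobis(p) for p in self.points])
        return float((own <= d).mean())


def simulate_null(
    scenario: PedigreeScenario,
    founders: HaplotypePanel,
    gmap: GeneticMap,
    roh_params: RohParams | None = None,
    n_reps: int = 400,
    seed=0,
) -> NullCloud:
    """Gene-drop ``n_reps`` replicates and summarise the ROH of each.

    Every replicate is genotyped, pushed through the ROH caller with
    ``roh_params`` (so the null incorporates caller behaviour, not just
    genealogy), and reduced to (segment count, F_ROH).
    """
    if n_reps < 2:
        raise InsulomeError("n_reps must be >= 2")
    roh_params = roh_params or RohParams()
    rng = as_rng(seed)
    offsets = _chrom_offsets(founders, gmap)
    chrom_col = founders.sites["chrom"].to_numpy()
    bp_col = founders.sites["bp"].to_numpy()
    cm_col = founders.sites["cM"].to_numpy()
    total_cm = gmap.total_length_cm

    points = np.empty((n_reps, 2))
    for r in range(n_reps):
        h1, h2 = _drop_focal(scenario, founders, gmap, rng)
        g = haplotype_alleles(h1, founders, gmap, offsets).astype(np.int8)
        g += haplotype_alleles(h2, founders, gmap, offsets)
        segs = call_roh_arrays(g, chrom_col, bp_col, cm_col, roh_params, FOCAL)
        points[r] = (len(segs), f_roh(segs, total_cm))
    return NullCloud(label=scenario.label, degree=scenario.degree, points=points)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass
class Classification:
    """Per-scenario distances and verdicts for one query genome."""

    query_id: str
    query_point: tuple[float, float]
    labels: list[str]
    distances: dict[str, float]
    quantiles: dict[str, float]
    verdicts: dict[str, str]  # inside | edge | outside
    nearest: str
    nearest_degree: int


def classify_inbreeding(
    query: tuple[float, float],
    clouds: list[NullCloud],
    edge_band: tuple[float, float] = (0.90, 0.99),
    query_id: str = "query",
) -> Classification:
    """Place a (N_ROH, F_ROH) point relative to each null cloud.

    Verdict per cloud: *inside* if the empirical quantile of the query's
    Mahalanobis distance is below ``edge_band[0]``, *edge* within the band,
    *outside* above.  The nearest cloud minimises the distance; ties break
    toward the lower consanguinity degree.
    """
    if not clouds:
        raise InsulomeError("need at least one null cloud")
    lo, hi = edge_band
    if not 0.0 <= lo <= hi <= 1.0:
        raise InsulomeError("edge band quantiles must satisfy 0 <= lo <= hi <= 1")
    distances, quantiles, verdicts = {}, {}, {}
    for cloud in clouds:
        d = cloud.mahalanobis(query)
        q = cloud.distance_quantile(query)
        distances[cloud.label] = d
        quantiles[cloud.label] = q
        verdicts[cloud.label] = "inside" if q < lo else ("edge" if q <= hi else "outside")
    nearest_cloud = min(clouds, key=lambda c: (distances[c.label], c.degree))
    return Classification(
        query_id=query_id,
        query_point=(float(query[0]), float(query[1])),
        labels=[c.label for c in clouds],
        distances=distances,
        quantiles=quantiles,
        verdicts=verdicts,
        nearest=nearest_cloud.label,
        nearest_degree=nearest_cloud.degree,
    )
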