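"""End-to-end analysis pipeline: filter -> relatives -> ROH -> nulls ->
classification -> Ne -> IBD matrix -> group summary / PCA.

A run is driven by one INI-style config (sections mirror module names)
naming either real inputs (genotypes + map + groups) or a synthetic
scenario block; exactly one of the two must be present.  A single global
seed fans out to per-stage child seeds through ``SeedSequence([seed,
crc32(stage)])`` so stages are individually reproducible.  Re-running a
config reproduces every output byte-for-byte (no timestamps are written).
"""

from __future__ import annotations

import configparser
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

import insulome
from insulome import ne_from_roh, pedigree_sim, roh, synthetic_data
from insulome.core_io import (
    GeneticMap,
    GenotypeMatrix,
    InsulomeError,
    SiteFilterConfig,
    attach_genetic_map,
    filter_sites,
    ld_prune,
    read_genetic_map,
    read_genotypes,
    read_groups,
    write_segments,
)
from insulome.ibd_geography import (
    IbdParams,
    filter_relatives,
    group_summary,
    ibd_pca,
    ne_eligibility,
    pairwise_ibd_matrix,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "filter", "relatives", "roh", "null", "classify", "ne", "ibd",
)


def stage_seed(global_seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([global_seed, zlib.crc32(stage.encode())])


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration; see :func:`load_config`."""

    seed: int
    out_dir: Path
    input_paths: dict[str, str] | None
    synthetic: dict[str, str] | None
    site_filter: SiteFilterConfig
    roh_params: roh.RohParams
    ibd_params: IbdParams
    null_reps: int
    edge_band: tuple[float, float]
    kinship_threshold: float
    ne_min_len_cm: float
    ne_max_len_cm: float
    run_ld_prune: bool

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.synthetic is None):
            raise InsulomeError("config must have exactly one of [input] / [synthetic]")


def load_config(path) -> PipelineConfig:
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    run = cp["run"]

    def section(name) -> dict[str, str]:
        return dict(cp[name]) if cp.has_section(name) else {}

    sf = section("site_filter")
    rp = section("roh")
    ib = section("ibd")
    ped = section("pedigree_null")
    ne = section("ne")
    return PipelineConfig(
        seed=run.getint("seed", 0),
        out_dir=Path(run.get("out_dir", "insulome_out")),
        input_paths=section("input") or None,
        synthetic=section("synthetic") or None,
        site_filter=SiteFilterConfig(
            max_missingness=float(sf.get("max_missingness", 0.02)),
            min_maf=float(sf.get("min_maf", 0.05)),
            ld_window_snps=int(sf.get("ld_window_snps", 50)),
            ld_step_snps=int(sf.get("ld_step_snps", 2)),
            ld_r2_max=float(sf.get("ld_r2_max", 0.5)),
        ),
        roh_params=roh.RohParams(
            window_snps=int(rp.get("window_snps", 50)),
            window_het_max=int(rp.get("window_het_max", 0)),
            min_snps=int(rp.get("min_snps", 50)),
            min_report_cm=float(rp.get("min_report_cm", 0.0)),
        ),
        ibd_params=IbdParams(
            errormax=float(ib.get("errormax", 0.005)),
            lod_min=float(ib.get("lod_min", 3.0)),
            min_length_cm=float(ib.get("min_length_cm", 2.0)),
        ),
        null_reps=int(ped.get("n_reps", 400)),
        edge_band=(
            float(ped.get("edge_lo", 0.90)),
            float(ped.get("edge_hi", 0.99)),
        ),
        kinship_threshold=float(ib.get("kinship_threshold", 0.0442)),
        ne_min_len_cm=float(ne.get("min_len_cm", 4.0)),
        ne_max_len_cm=float(ne.get("max_len_cm", 20.0)),
        run_ld_prune=sf.get("ld_prune", "false").lower() in ("1", "true", "yes"),
    )


# ---------------------------------------------------------------------------
# synthetic input stage
# ---------------------------------------------------------------------------


def _synthetic_panel(cfg: PipelineConfig):
    """Simulate the demo panel: structured demes plus a planted sib-mating."""
    s = cfg.synthetic
    n_demes = int(s.get("n_demes", 2))
    n_gen = int(s.get("n_generations", 30))
    migration = float(s.get("migration", 0.0))
    snps = int(s.get("snps_per_chrom", 800))
    n_chrom = int(s.get("n_chromosomes", 6))
    chrom_cm = float(s.get("chrom_length_cm", 150.0))
    deme_sizes = [int(x) for x in s.get("deme_sizes", "50,50").split(",")]
    if len(deme_sizes) != n_demes:
        raise InsulomeError("deme_sizes must list one size per deme")
    n_sample = int(s.get("n_sample_per_deme", 20))
    plant_sib = s.get("plant_sib", "true").lower() in ("1", "true", "yes")
    miscall = float(s.get("miscall_rate", 0.0))
    missing = float(s.get("missing_rate", 0.0))

    gmap = GeneticMap.uniform({f"chr{i + 1}": chrom_cm for i in range(n_chrom)})
    rng = synthetic_data.as_rng(stage_seed(cfg.seed, "simulate"))
    founders = synthetic_data.make_founders(
        2 * sum(deme_sizes), snps, gmap, seed=rng
    )
    traj = synthetic_data.NeTrajectory.constant_per_deme(deme_sizes, n_gen, migration=migration)
    gm, truth = synthetic_data.simulate_population(founders, traj, seed=rng, gmap=gmap)

    keep: list[str] = []
    for d in range(n_demes):
        ids_d = [i for i in gm.ids if gm.groups[i] == f"deme{d}"]
        take = min(n_sample, len(ids_d))
        keep.extend(list(rng.choice(ids_d, size=take, replace=False)))
    gm = gm.subset_individuals(keep)

    if plant_sib:
        parents = [truth.haplotypes[i] for i in keep[:2]]
        sib_a = tuple(synthetic_data.meiosis(p, gmap, rng)[0] for p in parents)
        sib_b = tuple(synthetic_data.meiosis(p, gmap, rng)[0] for p in parents)
        focal = (
            synthetic_data.meiosis(sib_a, gmap, rng)[0],
            synthetic_data.meiosis(sib_b, gmap, rng)[0],
        )
        gm_plant = synthetic_data.diploid_genotypes(
            {"planted_sib_offspring": focal}, founders, gmap
        )
        gm = GenotypeMatrix(
            ids=gm.ids + ["planted_sib_offspring"],
            sites=gm.sites,
            genotypes=np.vstack([gm.genotypes, gm_plant.genotypes]),
            groups={**gm.groups, "planted_sib_offspring": "deme0"},
        ).recompute_frequencies()
        truth.haplotypes["planted_sib_offspring"] = focal

    if miscall > 0 or missing > 0:
        gm = synthetic_data.add_errors(gm, miscall, missing, seed=rng)
    return gm, gmap, founders, truth


def _real_panel(cfg: PipelineConfig):
    paths = cfg.input_paths
    gm = read_genotypes(paths["genotypes"], format=paths.get("format", "vcf"))
    gmap = read_genetic_map(paths["map"])
    gm = attach_genetic_map(gm, gmap)
    if "groups" in paths:
        gm.groups = read_groups(paths["groups"])
    rng = synthetic_data.as_rng(stage_seed(cfg.seed, "simulate"))
    founders = synthetic_data.make_founders(
        64, max(gm.n_sites // len(gmap.chromosomes), 100), gmap, seed=rng
    )
    return gm, gmap, founders, None


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage, writing the report bundle into ``cfg.out_dir``."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ---- input -------------------------------------------------------
        stage = "simulate"
        if cfg.synthetic is not None:
            gm, gmap, founders, truth = _synthetic_panel(cfg)
        else:
            gm, gmap, founders, truth = _real_panel(cfg)

        # ---- site filters --------------------------------------------------
        stage = "filter"
        n_before = gm.n_sites
        gm = filter_sites(gm, cfg.site_filter)
        if cfg.run_ld_prune:
            gm = ld_prune(gm, cfg.site_filter)
        _write_json(out / "filtered_panel.json", {
            "n_individuals": gm.n_individuals,
            "n_sites_before": n_before,
            "n_sites_after": gm.n_sites,
        })

        # ---- relatives -----------------------------------------------------
        stage = "relatives"
        kept, removed = filter_relatives(gm, threshold=cfg.kinship_threshold)
        pd.DataFrame(removed, columns=["removed", "partner", "phi"]).to_csv(
            out / "removed_relatives.tsv", sep="\t", index=False
        )
        (out / "kept_individuals.txt").write_text("\n".join(kept) + "\n")
        gm_unrel = gm.subset_individuals(kept)

        # ---- ROH -----------------------------------------------------------
        stage = "roh"
        total_cm = gmap.total_length_cm
        roh_by_ind = {i: roh.call_roh(gm, i, cfg.roh_params) for i in gm.ids}
        write_segments([s for segs in roh_by_ind.values() for s in segs],
                       out / "roh_segments.tsv")
        profiles = pd.DataFrame(
            {
                "individual": list(roh_by_ind),
                "n_roh": [len(v) for v in roh_by_ind.values()],
                "f_roh": [roh.f_roh(v, total_cm) for v in roh_by_ind.values()],
                "total_cm_gt4": [
                    sum(s.length_cm for s in v if s.length_cm > 4) for v in roh_by_ind.values()
                ],
            }
        )
        profiles.to_csv(out / "roh_profiles.tsv", sep="\t", index=False, float_format="%.10g")

        # ---- pedigree nulls ------------------------------------------------
        stage = "null"
        rng_null = np.random.default_rng(stage_seed(cfg.seed, "null"))
        clouds = [
            pedigree_sim.simulate_null(
                sc, founders, gmap, cfg.roh_params, n_reps=cfg.null_reps, seed=rng_null
            )
            for sc in pedigree_sim.scenario_pedigrees()
        ]
        pd.DataFrame(
            {
                "scenario": [c.label for c in clouds],
                "degree": [c.degree for c in clouds],
                "n_reps": [c.n_reps for c in clouds],
                "mean_n_roh": [c.mean[0] for c in clouds],
                "mean_f_roh": [c.mean[1] for c in clouds],
            }
        ).to_csv(out / "null_clouds.tsv", sep="\t", index=False, float_format="%.10g")

        # ---- classification --------------------------------------------------
        stage = "classify"
        rows = []
        flagged: list[str] = []
        for _, row in profiles.iterrows():
            c = pedigree_sim.classify_inbreeding(
                (row["n_roh"], row["f_roh"]), clouds, cfg.edge_band, query_id=row["individual"]
            )
            close = any(
                c.verdicts[cl.label] in ("inside", "edge") and cl.degree <= 2 for cl in clouds
            )
            if close:
                flagged.append(c.query_id)
            rows.append({
                "individual": c.query_id,
                "n_roh": row["n_roh"],
                "f_roh": row["f_roh"],
                "nearest": c.nearest,
                "nearest_degree": c.nearest_degree,
                "consanguineous": close,
                **{f"q_{k}": v for k, v in c.quantiles.items()},
            })
        pd.DataFrame(rows).to_csv(
            out / "classification.tsv", sep="\t", index=False, float_format="%.10g"
        )

        # ---- Ne ------------------------------------------------------------
        stage = "ne"
        ne_out = {}
        groups = gm_unrel.groups or {i: "all" for i in gm_unrel.ids}
        for grp in sorted(set(groups.values())):
            members = [i for i in gm_unrel.ids if groups[i] == grp]
            model = ne_from_roh.RohNeModel.from_map(
                gmap, min_len_cm=cfg.ne_min_len_cm, max_len_cm=cfg.ne_max_len_cm
            )
            est = ne_from_roh.fit_ne_roh(
                {i: roh_by_ind[i] for i in members}, model, exclude_ids=flagged
            )
            ne_out[grp] = {
                "ne_hat": est.ne_hat,
                "ci95": list(est.ci95),
                "n_segments": est.n_segments,
                "n_genomes": est.model.n_genomes,
                "excluded": [i for i in est.excluded_ids if i in members],
                "at_boundary": est.at_boundary,
            }
        _write_json(out / "ne_estimates.json", ne_out)

        # ---- IBD -------------------------------------------------------------
        stage = "ibd"
        matrix, ibd_segments = pairwise_ibd_matrix(gm_unrel, cfg.ibd_params)
        write_segments(ibd_segments, out / "ibd_segments.tsv")
        matrix.to_frame().to_csv(out / "ibd_matrix.tsv", sep="\t", float_format="%.10g")
        summary = group_summary(matrix, groups)
        summary.mean_total_cm.to_csv(out / "group_summary.tsv", sep="\t", float_format="%.10g")
        segs_by_group = {}
        for s in ibd_segments:
            g1, g2 = groups[s.ids[0]], groups[s.ids[1]]
            if g1 == g2:
                segs_by_group.setdefault(g1, []).append(s)
        eligible = ne_eligibility(segs_by_group, min_length_cm=cfg.ibd_params.min_length_cm)
        _write_json(out / "ne_eligibility.json", eligible)
        scores, var_frac = ibd_pca(matrix)
        scores.to_csv(out / "pca.tsv", sep="\t", float_format="%.10g")
        pd.DataFrame({"component": scores.columns, "variance_fraction": var_frac}).to_csv(
            out / "pca_variance.tsv", sep="\t", index=False, float_format="%.10g"
        )

        # ---- run log ---------------------------------------------------------
        _write_json(out / "run_log.json", {
            "insulome_version": insulome.__version__,
            "numpy_version": np.__version__,
            "seed": cfg.seed,
            "stages": list(STAGES),
            "site_filter": vars(cfg.site_filter),
            "roh_params": vars(cfg.roh_params),
            "ibd_params": vars(cfg.ibd_params),
            "null_reps": cfg.null_reps,
            "edge_band": list(cfg.edge_band),
            "kinship_threshold": cfg.kinship_threshold,
        })
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise InsulomeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return {
        "out_dir": str(out),
        "flagged_consanguineous": flagged,
        "ne": ne_out,
        "eligible": eligible,
    }


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


DEMO_CONFIG = """\
[run]
seed = {seed}
out_dir = {out_dir}

[synthetic]
n_demes = 2
deme_sizes = 60,180
n_generations = 12
migration = 0.0
n_chromosomes = 6
chrom_length_cm = 150
snps_per_chrom = 900
n_sample_per_deme = 14
plant_sib = true
miscall_rate = 0.002
missing_rate = 0.002

[pedigree_null]
n_reps = 60

[ne]
min_len_cm = 4
max_len_cm = 20
"""


def write_demo_config(path, seed: int = 0, out_dir: str = "demo_out") -> None:
    Path(path).write_text(DEMO_CONFIG.format(seed=seed, out_dir=out_dir))
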