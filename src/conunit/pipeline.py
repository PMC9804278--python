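"""End-to-end orchestration of the conservation-unit analysis.

Stage order mirrors the study workflow: filter cascade -> candidate-locus
detection and neutral/candidate split -> diversity and differentiation
tables -> LD-Ne table -> gravity-model competition and flow prediction ->
AMOVA comparison of site groupings. Runs either on user inputs (VCF + site
metadata + environment + rasters) or fully synthetically from a SimConfig.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import conunit
from conunit import amova, gea, gravity, ne, popgen, synth
from conunit.genotypes import (
    FilterConfig,
    GenotypeMatrix,
    apply_filter_cascade,
    read_sites_csv,
    read_vcf,
    select_rda_loci,
)
from conunit.raster import Raster

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "cu_run"
    seed: int = 0
    # real inputs
    vcf: str | None = None
    sites_csv: str | None = None
    env_csv: str | None = None
    raster_paths: dict[str, str] = field(default_factory=dict)
    # or synthetic
    synth: synth.SimConfig | None = None
    # stage settings
    filter: FilterConfig = field(default_factory=FilterConfig)
    ne: ne.NeConfig = field(default_factory=ne.NeConfig)
    condition_pcs: int = 7
    candidate_sd: float = 3.5
    predictors: tuple[str, ...] = ("summer_precip", "autumn_precip", "winter_tmin")
    pi_locus_length: float = 90.0  # bp per RAD locus for the pi denominator
    prune_km: float | None = 50.0
    dispersal_km: float = 15.0
    flow_cutoff: float = 0.85
    hypotheses: list[gravity.GravityHypothesis] = field(default_factory=lambda: [
        gravity.GravityHypothesis("Null (distance only)"),
        gravity.GravityHypothesis("Temperature + Moisture",
                                  at_site=["hli"], between_site=["cti"]),
        gravity.GravityHypothesis("Moisture", between_site=["cti"]),
    ])
    amova_max_missing: float = 0.05

    def validate(self) -> None:
        if self.synth is None and (self.vcf is None or self.sites_csv is None):
            raise ValueError("provide either synth config or vcf + sites inputs")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; write artifacts under ``cfg.out_dir``; return the
    run manifest. Any stage error propagates with the stage name; artifacts
    written before the failure are retained."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": conunit.__version__,
        "seed": cfg.seed,
        "stages": {},
        "inputs": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    # ---- inputs ------------------------------------------------------
    rec = stage("load")
    if cfg.synth is not None:
        gm, truth = synth.simulate_genotypes(cfg.synth)
        env_table = truth.env_table.set_index("site_id")
        rasters = truth.rasters
        coords = truth.site_coords
        rec["source"] = "synthetic"
    else:
        sites = read_sites_csv(cfg.sites_csv)
        gm = read_vcf(cfg.vcf, sites=sites)
        env_table = (
            pd.read_csv(cfg.env_csv).set_index("site_id") if cfg.env_csv else None
        )
        rasters = {k: Raster.read_ascii(v) for k, v in cfg.raster_paths.items()}
        coords = pd.DataFrame(
            [dict(site_id=s.site_id, x=s.easting, y=s.northing,
                  region=s.region, mu_label=s.mu_label) for s in sites.values()]
        )
        manifest["inputs"] = {"vcf": _sha256(cfg.vcf), "sites": _sha256(cfg.sites_csv)}
        rec["source"] = "files"
    rec.update(n_ind=gm.n_ind, n_snp=gm.n_snp)

    # ---- filter ------------------------------------------------------
    rec = stage("filter")
    gm_f, report = apply_filter_cascade(gm, cfg.filter)
    report.to_json(out / "filter_report.json")
    rec.update(n_ind=gm_f.n_ind, n_snp=gm_f.n_snp, report=str(out / "filter_report.json"))

    # ---- gea: candidate detection and neutral split ------------------
    rec = stage("gea")
    candidates_path = out / "candidates.csv"
    if env_table is not None and all(p in env_table.columns for p in cfg.predictors):
        gm_rda = select_rda_loci(gm_f, cfg.filter)
        freqs, site_ids = gea.site_allele_frequencies(gm_rda)
        freqs = np.where(np.isnan(freqs), np.nanmean(freqs, axis=0), freqs)
        predictors = env_table.loc[site_ids, list(cfg.predictors)]
        try:
            gea.check_predictor_correlations(predictors)
        except ValueError as exc:
            logger.warning("predictor screen: %s (continuing)", exc)
        n_pcs = min(cfg.condition_pcs, len(site_ids) - len(cfg.predictors) - 2)
        pcs, _ = gea.pca_genotypes(freqs, n_pcs)
        model = gea.fit_rda(freqs, predictors, conditioners=pcs)
        n_axes = min(2, model.n_axes)
        cand = gea.detect_outliers_sd(model, freqs, predictors, n_axes=n_axes,
                                      threshold_sd=cfg.candidate_sd)
        cand_ids = set(gm_rda.snp_meta["snp_id"].iloc[cand.snp_indices])
        tab = cand.table.copy()
        tab.insert(0, "snp_id", gm_rda.snp_meta["snp_id"].iloc[cand.snp_indices].to_numpy())
        tab.to_csv(candidates_path, index=False)
        neutral = gm_f.take_snps(~gm_f.snp_meta["snp_id"].isin(cand_ids).to_numpy())
        rec.update(n_candidates=len(cand), candidates=str(candidates_path))
    else:
        logger.warning("gea skipped: no environment table with required predictors")
        neutral = gm_f
        rec.update(skipped=True)
    rec.update(n_neutral=neutral.n_snp)

    # ---- popgen ------------------------------------------------------
    rec = stage("popgen")
    div = popgen.site_diversity(neutral, assayed_length=neutral.n_snp * cfg.pi_locus_length)
    div.to_csv(out / "diversity.csv", index=False)
    fst = popgen.pairwise_fst_wc(neutral)
    fst.to_frame().to_csv(out / "fst.csv")
    nei = popgen.nei_distance_matrix(neutral)
    nei.to_frame().to_csv(out / "nei_d.csv")
    rec.update(diversity=str(out / "diversity.csv"), fst=str(out / "fst.csv"),
               nei_d=str(out / "nei_d.csv"))

    # ---- ne ----------------------------------------------------------
    rec = stage("ne")
    ne_tab = ne.ne_table(neutral, cfg.ne)
    ne_tab.to_csv(out / "ne.csv", index=False)
    rec.update(table=str(out / "ne.csv"), n_estimates=len(ne_tab))

    # ---- gravity -----------------------------------------------------
    rec = stage("gravity")
    nodes = coords[["site_id", "x", "y"]].rename(columns={"site_id": "node_id"}).copy()
    nodes["kind"] = "genetic"
    if rasters:
        # at-site covariates from raster values at the node
        for name, rast in rasters.items():
            nodes[name] = [rast.value_at(x, y) for x, y in nodes[["x", "y"]].to_numpy()]
        graph = gravity.build_graph(nodes, method="delaunay", prune_km=cfg.prune_km)
        graph = gravity.extract_edge_covariates(graph, rasters)
        nei_df = nei.to_frame()
        flows = np.array([
            1.0 - nei_df.loc[e.i, e.j] for e in graph.edges.itertuples()
        ])
        ok = np.isfinite(flows) & (flows > 0)
        if not ok.all():
            logger.warning("dropping %d edges with unusable flow", int((~ok).sum()))
            graph = gravity.SpatialGraph(graph.nodes, graph.edges[ok].reset_index(drop=True),
                                         graph.method, graph.prune_km)
            flows = flows[ok]
        ranking = gravity.rank_models_aicc(flows, graph, cfg.hypotheses)
        ranking.to_csv(out / "gravity_models.csv", index=False)
        conv = ranking[ranking["converged"]]
        best_name = (conv if len(conv) else ranking)["hypothesis"].iloc[0]
        best_hyp = next(h for h in cfg.hypotheses if h.name == best_name)
        fit = gravity.fit_gravity(flows, graph, best_hyp, mode="REML")
        fit.to_json(out / "gravity_best.json")
        for label, variant in (
            ("flows_15km", gravity.build_graph(nodes, "saturated", prune_km=cfg.dispersal_km)),
            ("flows_saturated", gravity.build_graph(nodes, "saturated", prune_km=None)),
        ):
            variant = gravity.extract_edge_covariates(variant, rasters)
            flow_tab = gravity.predict_flow(fit, variant, cutoff=cfg.flow_cutoff)
            flow_tab.table.to_csv(out / f"{label}.csv", index=False)
            rec[label] = str(out / f"{label}.csv")
        rec.update(models=str(out / "gravity_models.csv"),
                   best=best_name, best_fit=str(out / "gravity_best.json"))
    else:
        logger.warning("gravity skipped: no rasters")
        rec.update(skipped=True)

    # ---- amova -------------------------------------------------------
    rec = stage("amova")
    groupings = []
    for col in ("mu_label", "region"):
        if col in coords.columns and coords[col].nunique() >= 2:
            groupings.append(amova.Grouping(
                name=col, assignment=dict(zip(coords["site_id"], coords[col]))
            ))
    if len(groupings) >= 2:
        comp = amova.compare_groupings(neutral, groupings, cfg.amova_max_missing)
        comp.to_csv(out / "amova.csv", index=False)
        rec.update(table=str(out / "amova.csv"))
    elif len(groupings) == 1:
        res = amova.run_amova(neutral, groupings[0], cfg.amova_max_missing)
        pd.DataFrame([dict(grouping=res.grouping, n_groups=res.n_groups,
                           **{f"pct_{k}": v for k, v in res.percentages.items()})]
                     ).to_csv(out / "amova.csv", index=False)
        rec.update(table=str(out / "amova.csv"))
    else:
        rec.update(skipped=True)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


__all__ = ["RunConfig", "run_pipeline"]
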