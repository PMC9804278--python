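"""Synthetic landscapes, site networks, genotypes and flows with known truth.

Every downstream stage of the pipeline is testable against this module:
genotypes follow the Balding-Nichols island model (its closed-form F_ST
expectation is a free oracle), adaptive loci respond logistically to an
environmental gradient, a forward Wright-Fisher simulator provides the
drift oracle for LD-based Ne estimation, and gravity flows are generated
from the same log-linear mixed model the fitting code assumes.

All randomness flows from ``SimConfig.seed`` through deterministically
derived per-operation substreams, so identical configs give bit-identical
outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from conunit.genotypes import MISSING, GenotypeMatrix, SampleMetadata, write_vcf
from conunit.gravity import GravityHypothesis, SpatialGraph, _design
from conunit.raster import Raster

logger = logging.getLogger(__name__)

# substream labels -> integers mixed into the seed sequence
_STREAMS = {"landscape": 1, "sites": 2, "genotypes": 3, "wf": 4, "flows": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


@dataclass
class EnvGradient:
    """Spatial structure of one environmental covariate: a linear trend in
    units per metre along (x, y), i.i.d. noise smoothed to the given radius
    (cells), and the noise standard deviation."""

    trend_x: float = 0.0
    trend_y: float = 0.0
    noise_sd: float = 1.0
    smooth_cells: float = 3.0


def default_env_gradients() -> dict[str, EnvGradient]:
    # three weakly correlated climate predictors (precipitation trends at
    # right angles, winter minimum temperature noise-driven) plus two
    # topographic gravity covariates (wetness and heat-load indices)
    return {
        "summer_precip": EnvGradient(trend_x=1e-4, trend_y=0.0, noise_sd=1.0),
        "autumn_precip": EnvGradient(trend_x=0.0, trend_y=1e-4, noise_sd=1.0),
        "winter_tmin": EnvGradient(trend_x=0.0, trend_y=0.0, noise_sd=1.5),
        "cti": EnvGradient(trend_x=5e-5, trend_y=5e-5, noise_sd=1.0),
        "hli": EnvGradient(trend_x=0.0, trend_y=0.0, noise_sd=1.0),
    }


#: climate predictors used for genotype-environment association; adaptive
#: loci couple to these (cyclically), not to the topographic covariates
SELECTION_PREDICTORS = ("summer_precip", "autumn_precip", "winter_tmin")


def default_gravity_truth() -> dict[str, float]:
    return {
        "intercept": -1.2,
        "ln_dist": -0.25,
        "ln_cti": 0.3,
        "ln_hli_site": -0.3,
    }


@dataclass
class SimConfig:
    seed: int = 0
    n_sites: int = 31
    n_ind_per_site: int = 12
    n_neutral: int = 5000
    n_adaptive: int = 50
    target_fst: float = 0.2
    env_gradients: dict[str, EnvGradient] = field(default_factory=default_env_gradients)
    selection_strength: float = 1.0
    missing_rate: float = 0.05
    depth_mean: float = 30.0
    landscape_extent: float = 60_000.0
    cell_size: float = 30.0
    gravity_truth: dict[str, float] = field(default_factory=default_gravity_truth)
    wf_ne: int = 50
    n_groups: int = 1  # >1 adds a group level above demes (hierarchical model)
    group_fst: float = 0.15  # differentiation among groups when n_groups > 1

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_ind_per_site", "n_neutral", "wf_ne", "n_groups"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_adaptive < 0:
            raise ValueError("n_adaptive must be >= 0")
        if not 0 < self.target_fst < 1:
            raise ValueError("target_fst must be in (0,1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0,1)")
        if self.landscape_extent <= 0 or self.cell_size <= 0:
            raise ValueError("landscape extent and cell size must be positive")


@dataclass
class SimTruth:
    adaptive_locus_ids: set
    adaptive_predictor: dict[str, str]  # locus id -> driving predictor
    site_freqs: pd.DataFrame  # site x locus allele frequencies
    site_coords: pd.DataFrame  # site_id, x, y, region, mu_label, group
    env_table: pd.DataFrame  # site_id + standardized predictor values
    rasters: dict[str, Raster]
    gravity_truth: dict[str, float]
    true_ne: int
    target_fst: float

    def to_json(self, path: str | Path) -> None:
        payload = dict(
            adaptive_locus_ids=sorted(self.adaptive_locus_ids),
            adaptive_predictor=self.adaptive_predictor,
            gravity_truth=self.gravity_truth,
            true_ne=self.true_ne,
            target_fst=self.target_fst,
            site_coords=self.site_coords.to_dict(orient="list"),
            env_table=self.env_table.to_dict(orient="list"),
        )
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def make_landscape(config: SimConfig) -> dict[str, Raster]:
    """One spatially autocorrelated single-band raster per named covariate:
    smoothed Gaussian noise plus a linear trend, on a square grid of
    ``cell_size`` metre cells covering ``landscape_extent``."""
    n = int(np.ceil(config.landscape_extent / config.cell_size))
    rng = _rng(config.seed, "landscape")
    out = {}
    xs = (np.arange(n) + 0.5) * config.cell_size
    ys = xs[::-1]  # row 0 is north
    xx, yy = np.meshgrid(xs, ys)
    for name, grad in config.env_gradients.items():
        noise = rng.normal(size=(n, n))
        if grad.noise_sd > 0 and grad.smooth_cells > 0:
            noise = gaussian_filter(noise, grad.smooth_cells, mode="reflect")
            sd = noise.std()
            noise = noise / sd * grad.noise_sd if sd > 0 else noise
        elif grad.noise_sd == 0:
            noise = np.zeros((n, n))
        values = grad.trend_x * xx + grad.trend_y * yy + noise
        out[name] = Raster(values=values, x0=0.0, y0=0.0, cell=config.cell_size)
    return out


# ---------------------------------------------------------------------------
# Sites and environment
# ---------------------------------------------------------------------------

def simulate_sites(config: SimConfig, rasters: dict[str, Raster] | None = None):
    """Random site placement with region/management-unit labels and per-site
    standardized environmental predictor values sampled from the rasters."""
    rng = _rng(config.seed, "sites")
    if rasters is None:
        rasters = make_landscape(config)
    margin = 2 * config.cell_size
    lo, hi = margin, config.landscape_extent - margin
    xy = rng.uniform(lo, hi, size=(config.n_sites, 2))
    groups = np.arange(config.n_sites) % config.n_groups
    coords = pd.DataFrame(
        dict(
            site_id=[f"S{i:02d}" for i in range(config.n_sites)],
            x=xy[:, 0],
            y=xy[:, 1],
            region=[f"R{g}" for g in groups],
            mu_label=[f"MU{i // 3}" for i in range(config.n_sites)],
            group=groups,
        )
    )
    env = {"site_id": coords["site_id"]}
    for name, rast in rasters.items():
        vals = np.array([rast.value_at(x, y) for x, y in xy])
        sd = vals.std(ddof=1) if len(vals) > 1 else 1.0
        env[name] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    return coords, pd.DataFrame(env), rasters


# ---------------------------------------------------------------------------
# Genotypes (Balding-Nichols with environment-coupled adaptive loci)
# ---------------------------------------------------------------------------

def _bn_freqs(rng, p: np.ndarray, fst: float, n_demes: int) -> np.ndarray:
    """Deme frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F), shape (demes, loci)."""
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale, size=(n_demes, len(p)))


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Genotypes for ``n_sites`` demes under the island model.

    Neutral loci: ancestral frequency Uniform(0.1, 0.9), deme frequencies
    Balding-Nichols at F = ``target_fst`` (optionally via an intermediate
    group level when ``n_groups`` > 1). Adaptive loci: deme frequency is a
    logistic response to one standardized environmental predictor with slope
    ``selection_strength`` plus small noise. Genotypes are Binomial(2, freq),
    thinned to missing at ``missing_rate``; per-genotype depths are Poisson.
    """
    if config.n_sites < 2:
        raise ValueError("need at least two sites")
    if config.n_adaptive == 0 and config.selection_strength != 0:
        raise ValueError("selection_strength set but n_adaptive is 0")
    rng = _rng(config.seed, "genotypes")
    coords, env, rasters = simulate_sites(config)
    d = config.n_sites
    env_names = [n for n in SELECTION_PREDICTORS if n in config.env_gradients]
    if not env_names:
        env_names = list(config.env_gradients)

    # neutral deme frequencies
    p_anc = rng.uniform(0.1, 0.9, size=config.n_neutral)
    if config.n_groups > 1:
        grp = _bn_freqs(rng, p_anc, config.group_fst, config.n_groups)
        freqs_n = np.empty((d, config.n_neutral))
        within = config.target_fst
        for i, g in enumerate(coords["group"]):
            freqs_n[i] = _bn_freqs(rng, np.clip(grp[g], 1e-4, 1 - 1e-4), within, 1)[0]
    else:
        freqs_n = _bn_freqs(rng, p_anc, config.target_fst, d)

    # adaptive deme frequencies: logistic cline on one predictor each
    adaptive_predictor: dict[str, str] = {}
    freqs_a = np.empty((d, config.n_adaptive))
    for k in range(config.n_adaptive):
        pred = env_names[k % len(env_names)]
        a = logit(rng.uniform(0.25, 0.75))
        e = env[pred].to_numpy()
        f = expit(a + config.selection_strength * e)
        f = np.clip(f + rng.normal(0.0, 0.02, size=d), 0.01, 0.99)
        freqs_a[:, k] = f
        adaptive_predictor[f"adaptive_{k:04d}"] = pred

    loci = [f"neutral_{i:04d}" for i in range(config.n_neutral)] + [
        f"adaptive_{k:04d}" for k in range(config.n_adaptive)
    ]
    freqs = np.hstack([freqs_n, freqs_a])

    # diploid genotypes per site
    n_ind = config.n_ind_per_site
    blocks, ind_ids, site_ids = [], [], []
    for i, sid in enumerate(coords["site_id"]):
        blocks.append(rng.binomial(2, freqs[i], size=(n_ind, len(loci))))
        ind_ids += [f"{sid}_{j:02d}" for j in range(n_ind)]
        site_ids += [sid] * n_ind
    g = np.vstack(blocks).astype(np.int8)
    if config.missing_rate > 0:
        drop = rng.random(g.shape) < config.missing_rate
        g[drop] = MISSING
    depths = rng.poisson(config.depth_mean, size=g.shape)
    called = g != MISSING
    mean_depth = np.where(
        called.any(axis=0),
        (depths * called).sum(axis=0) / np.maximum(called.sum(axis=0), 1),
        np.nan,
    )

    snp_meta = pd.DataFrame(
        dict(snp_id=[f"{l}_snp" for l in loci], locus_id=loci,
             pos=np.full(len(loci), 50), ref="A", alt="T", mean_depth=mean_depth)
    )
    ind_meta = pd.DataFrame(dict(ind_id=ind_ids, site_id=site_ids))
    sites = {
        row.site_id: SampleMetadata(
            site_id=row.site_id, easting=row.x, northing=row.y,
            region=row.region, watershed=row.region, mu_label=row.mu_label)
        for row in coords.itertuples()
    }
    gm = GenotypeMatrix(g, snp_meta, ind_meta, sites)
    truth = SimTruth(
        adaptive_locus_ids=set(adaptive_predictor),
        adaptive_predictor=adaptive_predictor,
        site_freqs=pd.DataFrame(freqs, index=coords["site_id"], columns=loci),
        site_coords=coords,
        env_table=env,
        rasters=rasters,
        gravity_truth=dict(config.gravity_truth),
        true_ne=config.wf_ne,
        target_fst=config.target_fst,
    )
    gm.depths = depths  # carried for VCF export
    return gm, truth


# ---------------------------------------------------------------------------
# Wright-Fisher oracle for LD-Ne
# ---------------------------------------------------------------------------

def simulate_wf_sample(
    true_ne: int, n_loci: int, n_sample: int, seed: int,
    n_generations: int | None = None,
) -> GenotypeMatrix:
    """A single isolated diploid Wright-Fisher population of constant size
    ``true_ne``, run ``4 * true_ne`` generations (default) from Uniform(0.2,
    0.8) initial frequencies with free recombination between loci; a random
    sample of ``n_sample`` diploids is genotyped."""
    if n_sample > true_ne:
        warnings.warn("sample size exceeds true Ne; estimates will be unstable")
    if n_loci < 50:
        warnings.warn("fewer than 50 loci: LD-Ne estimate will be unstable")
    rng = np.random.default_rng([seed, _STREAMS["wf"]])
    gens = 4 * true_ne if n_generations is None else n_generations
    p0 = rng.uniform(0.2, 0.8, size=n_loci)
    # two haploid genome copies per diploid
    pop = (rng.random((2, true_ne, n_loci)) < p0).astype(np.int8)
    for _ in range(gens):
        parents = rng.integers(0, true_ne, size=(2, true_ne))
        # free recombination: each transmitted genome picks one of the two
        # parental copies independently per locus
        which = rng.integers(0, 2, size=(2, true_ne, n_loci))
        pop = pop[which, parents[:, :, None], np.arange(n_loci)[None, None, :]]
    take = rng.choice(true_ne, size=n_sample, replace=False)
    g = (pop[0, take] + pop[1, take]).astype(np.int8)
    snp_meta = pd.DataFrame(
        dict(snp_id=[f"wf_{i:05d}" for i in range(n_loci)],
             locus_id=[f"wf_{i:05d}" for i in range(n_loci)],
             pos=np.full(n_loci, 50), ref="A", alt="T", mean_depth=np.nan)
    )
    ind_meta = pd.DataFrame(
        dict(ind_id=[f"WF_{i:03d}" for i in range(n_sample)],
             site_id=["WF"] * n_sample)
    )
    return GenotypeMatrix(g, snp_meta, ind_meta, {"WF": SampleMetadata("WF")})


def expected_heterozygosity(pop_or_gm) -> float:
    """Mean 2p(1-p) across loci for a GenotypeMatrix (drift-decay oracle)."""
    freq = pop_or_gm.allele_freq()
    return float(np.nanmean(2 * freq * (1 - freq)))


# ---------------------------------------------------------------------------
# Gravity flows
# ---------------------------------------------------------------------------

def simulate_gravity_flows(
    graph: SpatialGraph,
    truth: dict[str, float],
    sigma_site: float,
    sigma_resid: float,
    seed: int,
) -> np.ndarray:
    """ln T_ij = b0 + sum b ln(covariate) + u_site(i) + e_ij with
    u ~ N(0, sigma_site^2), e ~ N(0, sigma_resid^2). Flows above 1 (possible
    in the tails of the noise) are capped just below 1 with a logged count so
    they remain valid (1 - Nei's D) measurements."""
    rng = np.random.default_rng([seed, _STREAMS["flows"]])
    at_site = [k[3:-5] for k in truth if k.endswith("_site")]
    between = [k[3:] for k in truth
               if k.startswith("ln_") and not k.endswith("_site") and k != "ln_dist"]
    hyp = GravityHypothesis(name="truth", at_site=at_site, between_site=between)
    x, terms, _ = _design(graph, hyp)
    lin = np.full(len(x), truth.get("intercept", 0.0))
    for t in terms:
        lin += truth[t] * x[t].to_numpy()
    origins = graph.edges["i"].to_numpy()
    site_ids = list(dict.fromkeys(origins))
    u = dict(zip(site_ids, rng.normal(0.0, sigma_site, size=len(site_ids))))
    lin += np.array([u[s] for s in origins])
    lin += rng.normal(0.0, sigma_resid, size=len(lin))
    flows = np.exp(lin)
    n_over = int((flows >= 1).sum())
    if n_over:
        logger.info("simulate_gravity_flows: capped %d flows below 1", n_over)
        flows = np.minimum(flows, 1.0 - 1e-9)
    return flows


# ---------------------------------------------------------------------------
# Export helpers
# ---------------------------------------------------------------------------

def export_simulation(gm: GenotypeMatrix, truth: SimTruth, out_dir: str | Path) -> dict:
    """Write VCF (GT + DP), site metadata CSV, environment CSV, rasters
    (ASCII grids) and truth JSON; returns the path manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = dict(
        vcf=str(out / "genotypes.vcf"),
        sites=str(out / "sites.csv"),
        env=str(out / "env.csv"),
        truth=str(out / "truth.json"),
    )
    write_vcf(gm, paths["vcf"], depths=getattr(gm, "depths", None))
    truth.site_coords.to_csv(paths["sites"], index=False)
    truth.env_table.to_csv(paths["env"], index=False)
    truth.to_json(paths["truth"])
    for name, rast in truth.rasters.items():
        p = out / f"raster_{name}.asc"
        rast.write_ascii(p)
        paths[f"raster_{name}"] = str(p)
    return paths


__all__ = [
    "EnvGradient",
    "SimConfig",
    "SimTruth",
    "default_env_gradients",
    "default_gravity_truth",
    "expected_heterozygosity",
    "export_simulation",
    "make_landscape",
    "simulate_genotypes",
    "simulate_gravity_flows",
    "simulate_sites",
    "simulate_wf_sample",
]
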