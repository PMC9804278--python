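"""Gravity-model functional connectivity on spatial site networks.

A singly constrained gravity model relates gene flow T_ij between sites to
distance (w), at-site attractiveness of the origin node (v terms) and
between-site landscape covariates (c terms):

    ln T_ij = b0 + b_w ln w_ij + sum b_v ln v_i + sum b_c ln c_ij + u_i + e_ij

with a random intercept u_i per origin site absorbing the non-independence
of rows sharing a site. Flow is measured as 1 - Nei's D. Models are fit as
linear mixed models (ML for AICc competition, REML for reported
coefficients); log-scale predictions are back-transformed with the Duan
smearing factor (mean of exponentiated residuals).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Delaunay, QhullError

from conunit.raster import Raster

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Spatial graph
# ---------------------------------------------------------------------------

@dataclass
class SpatialGraph:
    """nodes: node_id, x, y, kind plus at-site covariate columns;
    edges: i, j (node_id, i the designated origin), length_m plus
    between-site covariate columns."""

    nodes: pd.DataFrame
    edges: pd.DataFrame
    method: str = "delaunay"
    prune_km: float | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_xy(self) -> np.ndarray:
        return self.nodes[["x", "y"]].to_numpy(dtype=float)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes["node_id"])
        g.add_weighted_edges_from(
            self.edges[["i", "j", "length_m"]].itertuples(index=False, name=None)
        )
        return g


def build_graph(
    nodes: pd.DataFrame,
    method: str = "delaunay",
    prune_km: float | None = None,
) -> SpatialGraph:
    """Delaunay triangulation or saturated (all-pairs) graph over projected
    node coordinates; optional pruning of edges longer than ``prune_km``.

    Edge origin = the lower-indexed node in input order (used as the random
    effect grouping of the gravity model). Duplicate coordinates are jittered
    by <1 m deterministically; an all-collinear point set falls back to a
    nearest-neighbour chain.
    """
    nodes = nodes.reset_index(drop=True).copy()
    if "node_id" not in nodes.columns:
        nodes.insert(0, "node_id", [f"n{i}" for i in range(len(nodes))])
    xy = nodes[["x", "y"]].to_numpy(dtype=float)

    # deterministic sub-metre jitter of exact duplicates
    _, first_idx, inverse = np.unique(xy, axis=0, return_index=True, return_inverse=True)
    if len(first_idx) < len(xy):
        logger.warning("duplicate coordinates jittered by <1 m")
        seen: dict[int, int] = {}
        for row, grp in enumerate(inverse):
            k = seen.get(grp, 0)
            if k:
                ang = 2 * np.pi * (k * 0.618034 % 1.0)
                xy[row] += 0.5 * np.array([np.cos(ang), np.sin(ang)])
            seen[grp] = k + 1
        nodes[["x", "y"]] = xy

    if method == "saturated":
        pairs = [(i, j) for i in range(len(xy)) for j in range(i + 1, len(xy))]
    elif method == "delaunay":
        if len(xy) < 3:
            raise ValueError("delaunay needs >= 3 nodes")
        try:
            tri = Delaunay(xy)
            pairs = set()
            for simplex in tri.simplices:
                for a in range(3):
                    for b in range(a + 1, 3):
                        i, j = sorted((simplex[a], simplex[b]))
                        pairs.add((i, j))
            pairs = sorted(pairs)
        except QhullError:
            logger.warning("collinear nodes; falling back to nearest-neighbour chain")
            # order along the dominant axis and connect consecutive points
            span = xy.max(axis=0) - xy.min(axis=0)
            order = np.argsort(xy[:, int(span[1] > span[0])])
            pairs = [tuple(sorted((order[k], order[k + 1]))) for k in range(len(order) - 1)]
    else:
        raise ValueError(f"unknown method: {method}")

    rows = []
    ids = nodes["node_id"].to_numpy()
    for i, j in pairs:
        length = float(np.hypot(*(xy[i] - xy[j])))
        rows.append(dict(i=ids[i], j=ids[j], length_m=length))
    edges = pd.DataFrame(rows, columns=["i", "j", "length_m"])
    if prune_km is not None:
        edges = edges[edges["length_m"] <= prune_km * 1000.0].reset_index(drop=True)
    return SpatialGraph(nodes=nodes, edges=edges, method=method, prune_km=prune_km)


def node_metrics(graph: SpatialGraph, alpha_frac: float = 0.85) -> pd.DataFrame:
    """Degree, shortest-path betweenness (unweighted, unnormalized) and alpha
    centrality x = (I - alpha A^T)^{-1} e with e = 1 and
    alpha = alpha_frac / lambda_max(A)."""
    g = graph.to_networkx()
    order = list(graph.nodes["node_id"])
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    a = nx.to_numpy_array(g, nodelist=order, weight=None)
    n = len(order)
    if a.any():
        lam = float(np.max(np.abs(np.linalg.eigvals(a)).real))
        alpha = alpha_frac / lam if lam > 0 else 0.0
    else:
        alpha = 0.0
    m = np.eye(n) - alpha * a.T
    if np.linalg.cond(m) > 1e12:
        raise ValueError("alpha * lambda_max too close to 1: singular system")
    cent = np.linalg.solve(m, np.ones(n))
    return pd.DataFrame(
        dict(node_id=order,
             degree=[deg.get(v, 0) for v in order],
             betweenness=[btw.get(v, 0.0) for v in order],
             alpha_centrality=cent)
    )


def extract_edge_covariates(
    graph: SpatialGraph,
    rasters: dict[str, Raster],
    width_m: float = 30.0,
    stat: str = "median",
) -> SpatialGraph:
    """Attach per-edge landscape covariates: the named statistic (default
    median) of all raster cells intersecting each straight edge, buffered to
    ``width_m`` total width. Edges leaving the raster extent raise; edges
    crossing only NODATA get a missing covariate with a warning."""
    func = {"median": np.median, "mean": np.mean}[stat]
    xy = {row.node_id: (row.x, row.y) for row in graph.nodes.itertuples()}
    edges = graph.edges.copy()
    for name, rast in rasters.items():
        vals = []
        for e in edges.itertuples():
            x1, y1 = xy[e.i]
            x2, y2 = xy[e.j]
            try:
                cells = rast.sample_segment(x1, y1, x2, y2, width_m)
            except ValueError as exc:
                raise ValueError(f"edge {e.i}-{e.j} outside raster '{name}': {exc}") from exc
            if cells.size == 0:
                logger.warning("edge %s-%s: only NODATA under '%s'", e.i, e.j, name)
                vals.append(np.nan)
            else:
                vals.append(float(func(cells)))
        edges[name] = vals
    return SpatialGraph(graph.nodes, edges, graph.method, graph.prune_km)


# ---------------------------------------------------------------------------
# Hypotheses and fitting
# ---------------------------------------------------------------------------

@dataclass
class GravityHypothesis:
    """One candidate model: distance always enters; ``at_site`` variables are
    origin-node attributes, ``between_site`` variables are edge attributes."""

    name: str
    at_site: list[str] = field(default_factory=list)
    between_site: list[str] = field(default_factory=list)


@dataclass
class GravityFit:
    hypothesis: str
    n_edges: int
    terms: list[str]  # design column names in order (intercept first)
    coefficients: np.ndarray
    ci_half_width: np.ndarray
    sigma_site: float
    sigma_resid: float
    loglik: float
    aic: float
    aicc: float
    bic: float
    mode: str  # "ML" | "REML"
    smearing: float
    residuals: np.ndarray = field(repr=False, default=None)
    shifts: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    n_landscape_params: int = 0  # distance + v + c terms (reporting convention)

    @property
    def k(self) -> int:
        """Parameters counted for AICc: fixed effects + 2 variance terms."""
        return len(self.coefficients) + 2

    def coefficient(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def ci(self, term: str) -> tuple[float, float]:
        i = self.terms.index(term)
        return (float(self.coefficients[i] - self.ci_half_width[i]),
                float(self.coefficients[i] + self.ci_half_width[i]))

    def to_json(self, path: str | Path) -> None:
        payload = dict(
            hypothesis=self.hypothesis, n_edges=self.n_edges, terms=self.terms,
            coefficients=self.coefficients.tolist(),
            ci_half_width=self.ci_half_width.tolist(),
            sigma_site=self.sigma_site, sigma_resid=self.sigma_resid,
            loglik=self.loglik, aic=self.aic, aicc=self.aicc, bic=self.bic,
            mode=self.mode, smearing=self.smearing, shifts=self.shifts,
            converged=self.converged,
        )
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GravityFit":
        d = json.loads(Path(path).read_text())
        return cls(
            hypothesis=d["hypothesis"], n_edges=d["n_edges"], terms=d["terms"],
            coefficients=np.asarray(d["coefficients"]),
            ci_half_width=np.asarray(d["ci_half_width"]),
            sigma_site=d["sigma_site"], sigma_resid=d["sigma_resid"],
            loglik=d["loglik"], aic=d["aic"], aicc=d["aicc"], bic=d["bic"],
            mode=d["mode"], smearing=d["smearing"], shifts=d["shifts"],
            converged=d["converged"],
        )


def aicc_from_loglik(loglik: float, k: int, n: int) -> float:
    if n <= k + 1:
        raise ValueError("AICc undefined: n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _design(
    graph: SpatialGraph,
    hypothesis: GravityHypothesis,
    shifts: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, list[str], dict[str, float]]:
    """Log-scale design matrix for the gravity fit. Covariates that are not
    strictly positive are shifted by (1 - min) before the log; shifts learned
    at fit time are reused at prediction."""
    edges = graph.edges
    node_attr = graph.nodes.set_index("node_id")
    cols: dict[str, np.ndarray] = {"ln_dist": edges["length_m"].to_numpy(dtype=float)}
    for v in hypothesis.at_site:
        if v not in node_attr.columns:
            raise ValueError(f"missing at-site covariate: {v}")
        cols[f"ln_{v}_site"] = node_attr.loc[edges["i"], v].to_numpy(dtype=float)
    for c in hypothesis.between_site:
        if c not in edges.columns:
            raise ValueError(f"missing between-site covariate: {c}")
        cols[f"ln_{c}"] = edges[c].to_numpy(dtype=float)

    learned = {} if shifts is None else dict(shifts)
    out = {}
    for name, vals in cols.items():
        vals = np.asarray(vals, dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"covariate {name} has missing values on some edges")
        if name not in learned:
            mn = vals.min()
            learned[name] = float(1.0 - mn) if mn <= 0 else 0.0
        shifted = vals + learned[name]
        if (shifted <= 0).any():
            raise ValueError(f"covariate {name} non-positive after shift")
        out[name] = np.log(shifted)
    x = pd.DataFrame(out)
    return x, list(x.columns), learned


def fit_gravity(
    flows: np.ndarray,
    graph: SpatialGraph,
    hypothesis: GravityHypothesis,
    mode: str = "REML",
    corr_threshold: float = 0.70,
) -> GravityFit:
    """Fit ln(flow) ~ ln covariates with a random intercept per origin site.

    ``flows`` aligns with ``graph.edges`` rows and must lie in (0, 1].
    """
    import statsmodels.api as sm

    flows = np.asarray(flows, dtype=float)
    if len(flows) != graph.n_edges:
        raise ValueError("one flow per edge required")
    if (flows <= 0).any() or (flows > 1).any():
        raise ValueError("flows must lie in (0, 1]")
    x, terms, shifts = _design(graph, hypothesis)
    xm = x.to_numpy()
    if xm.shape[1] > 1:
        corr = np.corrcoef(xm, rowvar=False)
        iu = np.triu_indices(xm.shape[1], k=1)
        bad = np.abs(corr[iu]) >= corr_threshold
        if bad.any():
            w = np.argmax(np.abs(corr[iu]))
            logger.warning(
                "hypothesis %s: covariates %s and %s correlated at |r|=%.2f",
                hypothesis.name, terms[iu[0][w]], terms[iu[1][w]], abs(corr[iu][w]),
            )
    exog = sm.add_constant(x, prepend=True)
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ValueError(f"hypothesis {hypothesis.name}: rank-deficient design")
    endog = np.log(flows)
    groups = graph.edges["i"].to_numpy()

    model = sm.MixedLM(endog, exog, groups=groups)
    converged = True
    res = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for kwargs in ({}, {"method": "cg"}):
            try:
                res = model.fit(reml=(mode.upper() == "REML"), **kwargs)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if res is not None:
            if not getattr(res, "converged", True):
                converged = False
            if any("converge" in str(w.message).lower() or "singular" in str(w.message).lower()
                   for w in caught):
                converged = False

    if res is not None:
        bad = (not converged) or (not np.isfinite(np.asarray(res.bse_fe)).all())
        if bad:
            # boundary/non-convergent mixed fit: unusable estimates
            res = None
    if res is not None:
        fe = np.asarray(res.fe_params)
        bse = np.asarray(res.bse_fe)
        try:
            fitted = np.asarray(res.fittedvalues)  # fixed + predicted random
        except (ValueError, np.linalg.LinAlgError):
            # random-effect variance at the zero boundary: marginal fit
            fitted = exog.to_numpy() @ fe
        resid = endog - fitted
        sigma_site = float(np.sqrt(max(float(np.squeeze(res.cov_re)), 0.0)))
        sigma_resid = float(np.sqrt(res.scale))
        loglik = float(res.llf)
    else:
        # degenerate (e.g. noise-free) data: the mixed model's profiled
        # likelihood is singular; fall back to the fixed-effects solution
        logger.warning("hypothesis %s: mixed model singular, OLS fallback",
                       hypothesis.name)
        ols = sm.OLS(endog, exog).fit()
        fe = np.asarray(ols.params)
        bse = np.asarray(ols.bse)
        resid = endog - np.asarray(ols.fittedvalues)
        sigma_site = 0.0
        sigma_resid = float(np.sqrt(max(ols.scale, 0.0)))
        loglik = float(ols.llf)
    n = len(endog)
    k = len(fe) + 2
    aic = -2 * loglik + 2 * k
    aicc = aicc_from_loglik(loglik, k, n)
    bic = -2 * loglik + k * np.log(n)
    # 95% Wald-type CI with a between-within df approximation: the grouping
    # factor (origin sites) sets the effective replication, so plug-in
    # normal quantiles undercover site-level terms at few clusters
    n_groups = len(np.unique(groups))
    tq = float(stats.t.ppf(0.975, max(n_groups - 1, 2)))
    return GravityFit(
        hypothesis=hypothesis.name, n_edges=n,
        terms=["intercept"] + terms,
        coefficients=fe, ci_half_width=tq * bse,
        sigma_site=sigma_site, sigma_resid=sigma_resid,
        loglik=loglik, aic=aic, aicc=aicc, bic=bic, mode=mode.upper(),
        smearing=float(np.mean(np.exp(resid))), residuals=resid, shifts=shifts,
        converged=converged,
        n_landscape_params=1 + len(hypothesis.at_site) + len(hypothesis.between_site),
    )


def rank_models_aicc(
    flows: np.ndarray, graph: SpatialGraph, hypotheses: list[GravityHypothesis]
) -> pd.DataFrame:
    """ML fit of every hypothesis on the same edge set; AICc-ranked table.
    Non-converged fits are flagged and excluded from the 'best' baseline."""
    if len(hypotheses) < 2:
        raise ValueError("need at least two hypotheses")
    if len({h.name for h in hypotheses}) != len(hypotheses):
        raise ValueError("duplicate hypothesis names")
    rows = []
    for h in hypotheses:
        fit = fit_gravity(flows, graph, h, mode="ML")
        rows.append(
            dict(hypothesis=h.name, n_params=fit.n_landscape_params, k=fit.k,
                 aicc=fit.aicc, bic=fit.bic, loglik=fit.loglik,
                 converged=fit.converged)
        )
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    best = ok["aicc"].min() if len(ok) else table["aicc"].min()
    table["delta_aicc"] = table["aicc"] - best
    return table.sort_values("aicc", kind="stable").reset_index(drop=True)


@dataclass
class FlowTable:
    table: pd.DataFrame  # i, j, length_m, flow, flagged
    cutoff: float
    variant: str = ""

    def __len__(self) -> int:
        return len(self.table)


def predict_flow(
    fit: GravityFit,
    graph: SpatialGraph,
    cutoff: float = 0.85,
    include_smearing: bool = True,
) -> FlowTable:
    """Population-level flow prediction on a target graph (random effects at
    zero): flow = phi * exp(X beta), clipped to <= 1, flagged at the cutoff
    (flow >= cutoff, i.e. predicted Nei's D <= 1 - cutoff)."""
    hyp = GravityHypothesis(
        name=fit.hypothesis,
        at_site=[t[3:-5] for t in fit.terms if t.endswith("_site")],
        between_site=[t[3:] for t in fit.terms
                      if t.startswith("ln_") and not t.endswith("_site") and t != "ln_dist"],
    )
    x, terms, _ = _design(graph, hyp, shifts=fit.shifts)
    beta = fit.coefficients
    lin = beta[0] + x.to_numpy() @ beta[1:]
    phi = fit.smearing if include_smearing else 1.0
    flow = phi * np.exp(lin)
    n_clip = int((flow > 1).sum())
    if n_clip:
        logger.info("predict_flow: clipped %d predictions to 1", n_clip)
    flow = np.minimum(flow, 1.0)
    table = graph.edges[["i", "j", "length_m"]].copy()
    table["flow"] = flow
    table["flagged"] = flow >= cutoff
    variant = f"{graph.prune_km:g} km" if graph.prune_km else "saturated"
    return FlowTable(table=table, cutoff=cutoff, variant=variant)


__all__ = [
    "FlowTable",
    "GravityFit",
    "GravityHypothesis",
    "SpatialGraph",
    "aicc_from_loglik",
    "build_graph",
    "extract_edge_covariates",
    "fit_gravity",
    "node_metrics",
    "predict_flow",
    "rank_models_aicc",
]
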