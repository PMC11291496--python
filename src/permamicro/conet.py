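"""Co-occurrence networks: correlation, RMT thresholding, topology, modules,
relative modularity, node roles (Zi-Pi) and module eigengenes."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import CountTable, ValidationError
from . import rmt

#: node-role thresholds of the standard Zi-Pi taxonomy
ZI_HUB_THRESHOLD = 2.5
PI_CONNECTOR_THRESHOLD = 0.62


@dataclass
class CorrelationMatrix:
    feature_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, float)
        n = len(self.feature_ids)
        if self.r.shape != (n, n):
            raise ValidationError("correlation matrix shape mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValidationError("correlation matrix not symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-9):
            raise ValidationError("correlation entries outside [-1, 1]")


@dataclass
class ModulePartition:
    membership: dict[str, int]
    modularity: float
    relative_modularity: float
    null_modularities: list[float] = field(default_factory=list)


@dataclass
class NodeRole:
    node: str
    zi: float
    pi: float
    role: str  # peripheral | connector | module_hub | network_hub


def prepare_matrix(table: CountTable, treatment_samples: Sequence[str]) -> CorrelationMatrix:
    """Pearson correlation of log10 relative abundances across samples.

    Only features present (count > 0) in every retained sample are kept, so
    the log transform needs no pseudocount. Features constant across samples
    are dropped (their correlation is undefined).
    """
    if len(treatment_samples) < 4:
        raise ValidationError("need at least 4 samples for correlations")
    sub = table.subset_samples(treatment_samples)
    present = np.all(sub.counts > 0, axis=1)
    counts = sub.counts[present].astype(float)
    ids = [f for f, keep in zip(sub.feature_ids, present) if keep]
    rel = counts / counts.sum(axis=0, keepdims=True)
    logx = np.log10(rel)
    sd = logx.std(axis=1)
    varying = sd > 0
    if np.any(~varying):
        warnings.warn(f"dropping {int((~varying).sum())} constant features")
    logx = logx[varying]
    ids = [f for f, keep in zip(ids, varying) if keep]
    if len(ids) < 2:
        raise ValidationError("fewer than 2 features survive the prevalence filter")
    r = np.corrcoef(logx)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(ids, np.clip(r, -1.0, 1.0))


def rmt_threshold(
    c: CorrelationMatrix,
    s_min: float = 0.3,
    step: float = 0.01,
    s_max: float = 0.99,
    p_threshold: float = 0.05,
    n_consecutive: int = 3,
) -> float:
    """Smallest cut-off where the thresholded spectrum first conforms to
    Poisson spacing statistics and stays Poisson for ``n_consecutive`` steps.

    At each candidate s, entries with \\|r\\| < s are zeroed, fully isolated
    rows are dropped, and the nearest-neighbour spacing distribution of the
    remaining eigenvalues is tested against the exponential. A spectrum too
    small to test is treated as conforming (everything non-trivial is gone).
    """
    n = len(c.feature_ids)
    if n < rmt.MIN_EIGENVALUES:
        warnings.warn(f"only {n} features; RMT threshold is unreliable below 20")
    candidates = np.arange(s_min, s_max + step / 2, step)
    conforms = np.zeros(len(candidates), dtype=bool)
    for k, s in enumerate(candidates):
        b = np.where(np.abs(c.r) >= s, c.r, 0.0)
        np.fill_diagonal(b, 1.0)
        off = b - np.diag(np.diag(b))
        keep = np.any(off != 0, axis=1)
        if keep.sum() < rmt.MIN_EIGENVALUES:
            conforms[k] = True
            continue
        eigs = np.linalg.eigvalsh(b[np.ix_(keep, keep)])
        try:
            p = rmt.nnsd_poisson_pvalue(eigs)
        except ValueError:
            conforms[k] = True
            continue
        conforms[k] = p > p_threshold
    for k in range(len(candidates)):
        run = conforms[k : k + n_consecutive]
        if run.all() and len(run) > 0:
            return float(round(candidates[k], 10))
    raise ValidationError(
        "no threshold below {:.2f} yields Poisson spacing statistics; "
        "supply a manual threshold".format(s_max)
    )


def build_network(c: CorrelationMatrix, s_t: float) -> nx.Graph:
    """Undirected network keeping edges with |r| >= s_t; isolated nodes dropped."""
    if not 0 < s_t < 1:
        raise ValidationError("threshold must be in (0, 1)")
    g = nx.Graph(threshold=s_t)
    n = len(c.feature_ids)
    iu, ju = np.triu_indices(n, 1)
    mask = np.abs(c.r[iu, ju]) >= s_t
    for i, j in zip(iu[mask], ju[mask]):
        r = float(c.r[i, j])
        g.add_edge(c.feature_ids[i], c.feature_ids[j], r=r, sign=1 if r > 0 else -1)
    if g.number_of_edges() == 0:
        raise ValidationError(f"threshold {s_t} leaves an empty network")
    return g


def topology(g: nx.Graph) -> dict:
    """Standard summary: n, L, avgK = 2L/n, average clustering, edge signs."""
    n = g.number_of_nodes()
    L = g.number_of_edges()
    signs = [d.get("sign", 1) for _, _, d in g.edges(data=True)]
    return {
        "n_nodes": n,
        "n_links": L,
        "avgK": 2.0 * L / n,
        "avg_clustering": nx.average_clustering(g),
        "positive_links": int(sum(1 for s in signs if s > 0)),
        "negative_links": int(sum(1 for s in signs if s < 0)),
    }


def _greedy_modules(g: nx.Graph) -> list[set]:
    # deterministic: greedy modularity with node ids resolving internal ties
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes()))
    h.add_edges_from(sorted((min(u, v), max(u, v)) for u, v in g.edges()))
    return [set(c) for c in nx.community.greedy_modularity_communities(h)]


def modules_and_relative_modularity(
    g: nx.Graph, n_null: int = 100, seed: int | None = None
) -> ModulePartition:
    """Greedy modularity modules plus relative modularity against a
    degree-preserving (edge-rewiring) null ensemble.

    RM = (M - mean(M_null)) / mean(M_null), with each null produced by
    10 x L double-edge swaps and re-run module detection.
    """
    if n_null < 10:
        warnings.warn(f"n_null={n_null} gives a noisy null mean; 100 recommended")
    communities = _greedy_modules(g)
    m_obs = nx.community.modularity(g, communities)
    membership = {}
    for mid, com in enumerate(sorted(communities, key=lambda c: sorted(c)[0])):
        for node in com:
            membership[node] = mid
    rng = np.random.default_rng(seed)
    nulls = []
    L = g.number_of_edges()
    for _ in range(n_null):
        h = g.copy()
        try:
            nx.double_edge_swap(h, nswap=10 * L, max_tries=200 * L, seed=int(rng.integers(2**31)))
        except nx.NetworkXError:
            pass  # too few swappable edges; use as-is
        nulls.append(nx.community.modularity(h, _greedy_modules(h)))
    mean_null = float(np.mean(nulls))
    rm = (m_obs - mean_null) / mean_null
    return ModulePartition(membership, float(m_obs), float(rm), nulls)


def node_roles(g: nx.Graph, part: ModulePartition) -> list[NodeRole]:
    """Within-module degree z-score Zi and participation coefficient Pi.

    Zi = (k_within - module mean) / module sd (0 where sd = 0);
    Pi = 1 - sum_m (k_im / k_i)^2. Roles: Zi > 2.5 and Pi > 0.62 network hub,
    Zi > 2.5 module hub, Pi > 0.62 connector, else peripheral.
    """
    membership = part.membership
    missing = [v for v in g.nodes() if v not in membership]
    if missing:
        raise ValidationError(f"partition does not cover nodes: {missing[:5]}")
    modules: dict[int, list[str]] = {}
    for node, mid in membership.items():
        modules.setdefault(mid, []).append(node)
    k_within = {
        v: sum(1 for u in g.neighbors(v) if membership[u] == membership[v]) for v in g.nodes()
    }
    mod_stats = {}
    for mid, members in modules.items():
        vals = np.array([k_within[v] for v in members if v in g])
        mod_stats[mid] = (vals.mean(), vals.std())
    roles = []
    for v in sorted(g.nodes()):
        k = g.degree(v)
        if k == 0:
            warnings.warn(f"node {v} has degree 0; excluded from role analysis")
            continue
        mean_m, sd_m = mod_stats[membership[v]]
        zi = 0.0 if sd_m == 0 else (k_within[v] - mean_m) / sd_m
        per_module: dict[int, int] = {}
        for u in g.neighbors(v):
            per_module[membership[u]] = per_module.get(membership[u], 0) + 1
        pi = 1.0 - sum((km / k) ** 2 for km in per_module.values())
        hub = zi > ZI_HUB_THRESHOLD
        conn = pi > PI_CONNECTOR_THRESHOLD
        role = (
            "network_hub" if hub and conn else "module_hub" if hub else "connector" if conn else "peripheral"
        )
        roles.append(NodeRole(v, float(zi), float(pi), role))
    return roles


def keystone_fraction(roles: Sequence[NodeRole]) -> float:
    """Fraction of non-peripheral nodes (module hubs, connectors, network hubs)."""
    if not roles:
        return 0.0
    return sum(1 for r in roles if r.role != "peripheral") / len(roles)


def module_eigengenes(
    g: nx.Graph,
    part: ModulePartition,
    table: CountTable,
    env: pd.DataFrame,
    min_module_size: int = 3,
) -> pd.DataFrame:
    """Correlate each module eigengene with each environmental covariate.

    The eigengene is the first principal component of the standardized
    log10 member abundance submatrix (samples restricted to ``env.index``;
    a half-count pseudocount guards rarefaction zeros), sign-oriented to
    correlate positively with the mean member profile — the same log scale
    the network correlations use. Modules smaller than ``min_module_size``
    are skipped.
    """
    samples = list(env.index)
    sub = table.subset_samples(samples)
    counts = sub.counts.astype(float)
    rel = np.log10((counts + 0.5) / counts.sum(axis=0, keepdims=True))
    modules: dict[int, list[str]] = {}
    for node, mid in part.membership.items():
        modules.setdefault(mid, []).append(node)
    rows = []
    for mid in sorted(modules):
        members = [m for m in modules[mid] if m in sub.feature_ids]
        if len(members) < min_module_size:
            warnings.warn(f"module {mid} smaller than {min_module_size}; skipped")
            continue
        idx = [sub.feature_ids.index(m) for m in members]
        x = rel[idx]
        mean_ = x.mean(axis=1, keepdims=True)
        sd_ = x.std(axis=1, keepdims=True)
        sd_[sd_ == 0] = 1.0
        z = (x - mean_) / sd_
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(eig, mean_profile) < 0:
            eig = -eig
        expl = s[0] ** 2 / (s**2).sum()
        for cov in env.columns:
            vals = env[cov].to_numpy(float)
            if np.std(vals) == 0 or np.std(eig) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = sps.pearsonr(eig, vals)
            rows.append(
                {
                    "module": mid,
                    "n_members": len(members),
                    "explained_var": float(expl),
                    "covariate": cov,
                    "r": float(r),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


def write_network(g: nx.Graph, out_dir: str | Path, prefix: str) -> None:
    """Export a network as edge-list TSV and GraphML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {"source": u, "target": v, "r": d.get("r"), "sign": d.get("sign")}
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(out / f"{prefix}_edges.tsv", sep="\t", index=False)
    nx.write_graphml(g, out / f"{prefix}.graphml")
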