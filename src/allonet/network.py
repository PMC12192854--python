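"""Dynamic cross-correlation matrices and residue correlation networks.

The DCCM entry for residues i, j is the normalised scalar covariance of
their displacement vectors about the mean structure,

    C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|^2> <|Δr_j|^2>),

bounded in [−1, 1] with unit diagonal.  A residue graph keeps an edge where
|C_ij| exceeds a strict threshold (default 0.8); edge weights are |C_ij|
and the path length for betweenness is −log|C_ij| by default, so strongly
correlated pairs are dynamically "close".

Communities come from the Louvain algorithm (best of several seeded
restarts by modularity).  Each module's purity is the fraction of its
residues belonging to the module's dominant structural region; the
lowest-purity module of sufficient size is the system's *integration
module* — the most region-mixed group of concertedly moving residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .descriptors import mean_structure
from .io import DomainMap, Ensemble

__all__ = [
    "CorrelationMatrix",
    "CommunityPartition",
    "CentralityProfile",
    "dccm",
    "average_dccm",
    "dccm_similarity",
    "build_graph",
    "export_graphml",
    "detect_communities",
    "integration_module",
    "betweenness",
    "top_connectors",
    "threshold_consistency",
]


@dataclass
class CorrelationMatrix:
    values: np.ndarray          # (N, N) in [-1, 1]
    res_ids: np.ndarray
    system: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("correlation matrix has non-finite entries")
        self.values = v
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        if len(self.res_ids) != v.shape[0]:
            raise ValueError("res_ids length does not match matrix dimension")


@dataclass
class CommunityPartition:
    module_of: dict[int, int]           # selection position -> module id
    purity: dict[int, float]
    dominant_region: dict[int, str]
    sizes: dict[int, int]
    unassigned: list[int]               # isolated positions
    modularity: float
    integration_module: int | None = None

    def members(self, module_id: int) -> list[int]:
        return [p for p, m in self.module_of.items() if m == module_id]


@dataclass
class CentralityProfile:
    values: np.ndarray                  # per selection position
    res_ids: np.ndarray
    system: str = ""


# ---------------------------------------------------------------------------
# DCCM


def dccm(ensemble: Ensemble, align: bool = True) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix of Cα displacements.

    ``align=True`` superposes frames to the ensemble mean first (the right
    choice for raw trajectories); ``align=False`` takes displacements about
    the per-residue mean in the existing frame, appropriate for ensembles
    already expressed in a common reference frame (e.g. synthetic samples).
    Zero-variance residues get zero off-diagonal correlation with a warning.
    """
    if ensemble.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    if align:
        mean, fitted = mean_structure(ensemble)
        dev = fitted.coords - mean[None]
    else:
        dev = ensemble.coords - ensemble.coords.mean(axis=0, keepdims=True)
    f, n, _ = dev.shape
    x = dev.transpose(0, 2, 1).reshape(f * 3, n)     # xyz folded into samples
    cov = x.T @ x / f
    var = np.diag(cov).copy()
    dead = var <= 1e-30
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance residue(s); "
                      "their correlations are set to 0")
        var[dead] = 1.0
    denom = np.sqrt(np.outer(var, var))
    corr = cov / denom
    corr[dead, :] = 0.0
    corr[:, dead] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(corr, ensemble.res_ids.copy(), ensemble.system)


def average_dccm(matrices: list[CorrelationMatrix]) -> CorrelationMatrix:
    """Element-wise mean of replicate DCCMs (the default replicate handling)."""
    if not matrices:
        raise ValueError("no matrices to average")
    ref = matrices[0]
    for m in matrices[1:]:
        if not np.array_equal(m.res_ids, ref.res_ids):
            raise ValueError("replicate DCCMs cover different selections")
    mean = np.mean([m.values for m in matrices], axis=0)
    np.fill_diagonal(mean, 1.0)
    return CorrelationMatrix(mean, ref.res_ids.copy(), ref.system)


def dccm_similarity(a: CorrelationMatrix, b: CorrelationMatrix
                    ) -> tuple[float, float]:
    """Pearson r (and two-sided p) between two DCCMs.

    Computed over the off-diagonal upper triangle, flattened.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("matrices have different dimensions")
    iu = np.triu_indices_from(a.values, k=1)
    x, y = a.values[iu], b.values[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant matrix: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# graph construction


def build_graph(matrix: CorrelationMatrix, threshold: float = 0.8,
                length: str = "neglog") -> nx.Graph:
    """Residue graph with an edge where |C_ij| > threshold (strict).

    Nodes are 0-based selection positions carrying their residue id; every
    residue is a node even if isolated.  Edge attributes: ``corr`` (signed),
    ``weight`` = |corr|, and ``length`` for shortest-path analyses
    (``neglog``: −log|c|; ``1minus``: 1−|c|; ``unweighted``: 1).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be inside (0, 1)")
    if length not in ("neglog", "1minus", "unweighted"):
        raise ValueError(f"unknown length transform {length!r}")
    c = matrix.values
    n = len(c)
    g = nx.Graph()
    for pos in range(n):
        g.add_node(pos, res_id=int(matrix.res_ids[pos]))
    ii, jj = np.where(np.triu(np.abs(c), k=1) > threshold)
    for i, j in zip(ii.tolist(), jj.tolist()):
        cij = float(c[i, j])
        w = abs(cij)
        if length == "neglog":
            ell = float(-np.log(w))
        elif length == "1minus":
            ell = 1.0 - w
        else:
            ell = 1.0
        g.add_edge(i, j, corr=cij, weight=w, length=ell)
    g.graph["threshold"] = threshold
    g.graph["length"] = length
    return g


def export_graphml(graph: nx.Graph, path) -> None:
    """Write the residue graph as GraphML (node res_id, edge corr/weight)."""
    nx.write_graphml(graph, str(path))


# ---------------------------------------------------------------------------
# communities


def detect_communities(graph: nx.Graph, domain_map: DomainMap,
                       resolution: float = 1.0, seed: int = 0,
                       n_restarts: int = 10,
                       min_integration_size: int = 4) -> CommunityPartition:
    """Louvain communities on the |c|-weighted graph, best of ``n_restarts``.

    Isolated residues are left unassigned (they carry no dynamic coupling).
    Purity is measured against the domain map; the integration module is
    the lowest-purity module among those of size ≥ ``min_integration_size``
    (ties: larger module, then lower module id).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    connected = [v for v, d in graph.degree() if d > 0]
    if not connected:
        raise ValueError("graph has no edges: no communities to detect")
    sub = graph.subgraph(connected)
    best: tuple[float, list[set]] | None = None
    for k in range(n_restarts):
        comms = nx.community.louvain_communities(
            sub, weight="weight", resolution=resolution, seed=seed + k)
        q = nx.community.modularity(sub, comms, weight="weight",
                                    resolution=resolution)
        if best is None or q > best[0]:
            best = (q, comms)
    q, comms = best
    # stable module ids: sort by smallest member position
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    res_ids = {v: graph.nodes[v]["res_id"] for v in graph.nodes}
    module_of, purity, dominant, sizes = {}, {}, {}, {}
    for mid, members in enumerate(comms):
        labels = [None] * 0
        regions = {}
        for v in members:
            module_of[v] = mid
            lab = domain_map.region_of.get(res_ids[v])
            if lab is None:
                raise KeyError(f"residue {res_ids[v]} missing from the domain map")
            regions[lab] = regions.get(lab, 0) + 1
        dom = max(sorted(regions), key=lambda lab: regions[lab])
        purity[mid] = regions[dom] / len(members)
        dominant[mid] = dom
        sizes[mid] = len(members)
    unassigned = [v for v, d in graph.degree() if d == 0]
    part = CommunityPartition(
        module_of=module_of, purity=purity, dominant_region=dominant,
        sizes=sizes, unassigned=sorted(unassigned), modularity=float(q),
    )
    try:
        part.integration_module = integration_module(
            part, min_size=min_integration_size)
    except ValueError:
        part.integration_module = None
    return part


def integration_module(partition: CommunityPartition, min_size: int = 4) -> int:
    """Lowest-purity module of size ≥ ``min_size``.

    Ties are broken by larger size, then lower module id.
    """
    eligible = [m for m, s in partition.sizes.items() if s >= min_size]
    if not eligible:
        raise ValueError(f"no module of size >= {min_size}")
    return min(eligible, key=lambda m: (partition.purity[m],
                                        -partition.sizes[m], m))


# ---------------------------------------------------------------------------
# centrality


def betweenness(graph: nx.Graph) -> CentralityProfile:
    """Normalised shortest-path betweenness on the length-weighted graph.

    Uses the graph's ``length`` edge attribute (−log|c| by default) and the
    standard 2/((N−1)(N−2)) normalisation over the graph's node count;
    isolated residues get 0.
    """
    weight = None if graph.graph.get("length") == "unweighted" else "length"
    bc = nx.betweenness_centrality(graph, weight=weight, normalized=True)
    n = graph.number_of_nodes()
    values = np.zeros(n)
    res_ids = np.zeros(n, dtype=int)
    for v in graph.nodes:
        values[v] = bc[v]
        res_ids[v] = graph.nodes[v]["res_id"]
    return CentralityProfile(values, res_ids)


def top_connectors(profile: CentralityProfile, n: int = 25) -> np.ndarray:
    """Residue ids of the ``n`` highest-betweenness residues.

    Ties are broken by lower residue id.
    """
    order = sorted(range(len(profile.values)),
                   key=lambda i: (-profile.values[i], profile.res_ids[i]))
    return profile.res_ids[order[:n]]


def threshold_consistency(matrix: CorrelationMatrix, domain_map: DomainMap,
                          thresholds=(0.70, 0.75, 0.80, 0.85, 0.90),
                          n: int = 25, seed: int = 0) -> dict[int, float]:
    """Fraction of thresholds at which each residue is a top-``n`` connector.

    For each threshold the graph, communities and integration module are
    rebuilt and the top-``n`` betweenness residues recorded; a residue's
    consistency is the fraction of (non-degenerate) thresholds at which it
    recurs.  Thresholds yielding an edgeless graph are skipped with a
    warning; if all are skipped this is an error.
    """
    counts: dict[int, int] = {int(r): 0 for r in matrix.res_ids}
    used = 0
    for t in thresholds:
        g = build_graph(matrix, threshold=float(t))
        if g.number_of_edges() == 0:
            warnings.warn(f"threshold {t}: empty graph, skipped")
            continue
        detect_communities(g, domain_map, seed=seed)   # validates partition path
        prof = betweenness(g)
        for r in top_connectors(prof, n=n):
            counts[int(r)] += 1
        used += 1
    if used == 0:
        raise ValueError("all thresholds yielded empty graphs")
    return {r: c / used for r, c in counts.items()}
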