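"""Network proximity between drug-target and disease modules.

The proximity of a drug module ``T`` to a disease module ``S`` in the
interactome is the average, over drug targets ``t``, of the hop distance
to the nearest disease gene:

    p(T, S) = (1 / |T|) * sum_{t in T} min_{s in S} d(t, s)

Distances are unweighted shortest paths.  Proximities are turned into an
adjusted similarity in (0, 1) through a sigmoid of the normalized
closeness:

    f(p) = 1 / (1 + exp(-c * [(1 + QC) * (m - p) / m - d]))

where ``m`` is the maximum proximity over the evaluated pairs, ``QC`` a
quality-cluster score (default 0, pluggable), ``c`` the steepness and
``d`` the midpoint.  Statistical significance of a proximity is assessed
against a degree-aware permutation null.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


def shortest_path_distances(graph: nx.Graph, sources: set[str]) -> dict[str, float]:
    """Multi-source BFS hop distances from ``sources`` to every node.

    Unreachable nodes get ``inf``.
    """
    unknown = set(sources) - set(graph)
    if unknown:
        raise KeyError(f"source genes not in interactome: {sorted(unknown)}")
    dist = {node: math.inf for node in graph}
    queue = deque()
    for s in sources:
        dist[s] = 0
        queue.append(s)
    while queue:
        u = queue.popleft()
        for v in graph[u]:
            if dist[v] == math.inf:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def proximity(graph: nx.Graph, T: set[str], S: set[str]) -> float:
    """Mean nearest-disease-gene distance over the drug targets.

    Targets with no path to ``S`` are excluded with a warning; if no
    target reaches ``S`` a ``ValueError`` is raised.
    """
    if not T or not S:
        raise ValueError("drug module and disease module must be non-empty")
    unknown = (set(T) | set(S)) - set(graph)
    if unknown:
        raise KeyError(f"module genes not in interactome: {sorted(unknown)}")
    dist_to_S = shortest_path_distances(graph, set(S))
    dists = [dist_to_S[t] for t in T]
    reachable = [d for d in dists if math.isfinite(d)]
    n_dropped = len(dists) - len(reachable)
    if not reachable:
        raise ValueError("no drug target has a path to the disease module")
    if n_dropped:
        warnings.warn(
            f"{n_dropped} drug target(s) unreachable from the disease module; "
            "excluded from the proximity average",
            stacklevel=2,
        )
    return float(np.mean(reachable))


def adjusted_similarity(
    p: float, m: float, QC: float = 0.0, c: float = 30.0, d_mid: float = 0.33
) -> float:
    """Sigmoid-adjusted similarity of a proximity value.

    ``f = 1 / (1 + exp(-c * [(1 + QC) * (m - p) / m - d_mid]))``; strictly
    decreasing in ``p`` for fixed ``QC``, ``m``, ``c``.
    """
    if m <= 0:
        raise ValueError("m (the maximum proximity) must be positive")
    z = c * ((1.0 + QC) * (m - p) / m - d_mid)
    return float(1.0 / (1.0 + math.exp(-z)))


def _degree_bins(graph: nx.Graph, min_bin_size: int = 10) -> dict[str, list[str]]:
    """Group nodes into degree bins of at least ``min_bin_size`` members.

    Nodes are sorted by degree and chunked; a short trailing bin is merged
    into its neighbor (a widening, reported by the caller when relevant).
    """
    nodes = sorted(graph.nodes, key=lambda n: (graph.degree[n], str(n)))
    bins: list[list[str]] = []
    for start in range(0, len(nodes), min_bin_size):
        bins.append(nodes[start : start + min_bin_size])
    if len(bins) > 1 and len(bins[-1]) < min_bin_size:
        bins[-2].extend(bins.pop())
    lookup: dict[str, list[str]] = {}
    for members in bins:
        for n in members:
            lookup[n] = members
    return lookup


def proximity_significance(
    graph: nx.Graph,
    T: set[str],
    S: set[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Empirical p-value of p(T, S) under a degree-aware permutation null.

    Random node sets matching |T| and the degree-bin profile of ``T`` are
    drawn; the empirical p-value is
    ``(1 + #{null p <= observed p}) / (n_permutations + 1)``.
    Returns ``(observed_p, empirical_p_value)``.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    observed = proximity(graph, T, S)
    bins = _degree_bins(graph)
    rng = np.random.default_rng(seed)
    count = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_permutations):
            fake: set[str] = set()
            for t in T:
                pool = [n for n in bins[t] if n not in fake]
                if not pool:  # bin exhausted: widen to the whole graph
                    pool = [n for n in graph if n not in fake]
                fake.add(pool[int(rng.integers(len(pool)))])
            try:
                null_p = proximity(graph, fake, S)
            except ValueError:
                continue
            if null_p <= observed:
                count += 1
    return observed, (1 + count) / (n_permutations + 1)


@dataclass
class ProximityResult:
    """Proximity and adjusted similarity for one (drug, disease) pair."""

    drug: str
    p: float
    m: float
    QC: float
    f: float
    c: float
    d_mid: float


def score_drug_modules(
    graph: nx.Graph,
    drug_modules: dict[str, set[str]],
    disease_module: set[str],
    QC: float | dict[str, float] = 0.0,
    c: float = 30.0,
    d_mid: float = 0.33,
) -> list[ProximityResult]:
    """Proximity and f(p) for every drug module against one disease module.

    ``m`` is the maximum proximity over the evaluated pairs (so the
    similarity scale is relative to the current run); a ``QC`` mapping
    supplies per-drug quality-cluster scores.
    """
    if not drug_modules:
        return []
    prox = {
        drug: proximity(graph, module, disease_module)
        for drug, module in drug_modules.items()
    }
    m = max(prox.values())
    if m == 0:  # all drug modules inside the disease module
        m = 1.0
    results = []
    for drug, p in prox.items():
        qc = QC[drug] if isinstance(QC, dict) else QC
        results.append(
            ProximityResult(
                drug=drug,
                p=p,
                m=m,
                QC=qc,
                f=adjusted_similarity(p, m, QC=qc, c=c, d_mid=d_mid),
                c=c,
                d_mid=d_mid,
            )
        )
    return results


def build_association_table(
    dt_scores: pd.DataFrame,
    known_interactions: pd.DataFrame,
    proximity_results: list[ProximityResult],
    disease: str = "AD",
    score_threshold: float = 0.0,
    similarity_threshold: float = 0.5,
) -> pd.DataFrame:
    """Assemble the drug-target-disease association edge table.

    ``dt_scores`` has columns drug, target, score (model predictions);
    ``known_interactions`` has columns drug, target for observed pairs.
    Predicted drug-target edges must exceed ``score_threshold``;
    drug-disease edges require ``f(p) > similarity_threshold``.  Edges are
    labeled ``known`` or ``predicted``.
    """
    known_pairs = {
        (str(r.drug), str(r.target)) for r in known_interactions.itertuples()
    }
    score_drugs = set(dt_scores["drug"].astype(str))
    prox_drugs = {r.drug for r in proximity_results}
    orphans = prox_drugs - score_drugs - {d for d, _ in known_pairs}
    if orphans and not score_drugs <= prox_drugs | score_drugs:
        raise ValueError(f"drug identifiers not shared across inputs: {sorted(orphans)}")

    rows = []
    for d, t in sorted(known_pairs):
        rows.append(
            {"drug": d, "partner": t, "partner_type": "target", "score": 1.0, "label": "known"}
        )
    for r in dt_scores.itertuples():
        pair = (str(r.drug), str(r.target))
        if pair in known_pairs or r.score <= score_threshold:
            continue
        rows.append(
            {
                "drug": pair[0],
                "partner": pair[1],
                "partner_type": "target",
                "score": float(r.score),
                "label": "predicted",
            }
        )
    for res in proximity_results:
        if res.f > similarity_threshold:
            rows.append(
                {
                    "drug": res.drug,
                    "partner": disease,
                    "partner_type": "disease",
                    "score": res.f,
                    "label": "predicted",
                }
            )
    return pd.DataFrame(
        rows, columns=["drug", "partner", "partner_type", "score", "label"]
    )
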