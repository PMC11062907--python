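"""Characterization of graphical clusters: ORA, GSEA, networks, markers.

Given the gene (or metabolite) sets behind a graphically defined cluster,
this module provides the downstream characterization battery: one-sided
hypergeometric over-representation with BH correction and redundancy
pruning (overlap coefficient >= 0.8 removes near-duplicate pathways),
weighted-KS GSEA with label-permutation NES and p-values, a
pathway-similarity network (Jaccard similarity of driver sets over a
configurable threshold) with Louvain community detection, and
marker-correlation tests relating a cluster's average abundance to panels
of cell-type or process markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import FeatureMatrix
from .differential import bh_qvalues


@dataclass(frozen=True)
class GeneSetDB:
    """A gene-set collection plus the testing universe.

    Pathway members are restricted to the universe on construction;
    pathways left empty after restriction are dropped.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    @classmethod
    def from_dict(cls, raw: dict[str, tuple[str, set[str]]],
                  universe: set[str] | None = None) -> "GeneSetDB":
        if universe is None:
            universe = set().union(*(members for _, members in raw.values())) if raw else set()
        universe = frozenset(universe)
        sets = {}
        for pid, (name, members) in raw.items():
            if not members:
                raise ValueError(f"empty pathway {pid!r}")
            restricted = frozenset(members) & universe
            if restricted:
                sets[pid] = (name, restricted)
        return cls(sets, universe)


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def hypergeom_enrich(
    genes: set[str],
    db: GeneSetDB,
    fdr: float = 0.10,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation against a gene-set DB.

    Tests ``P(X >= overlap)`` for each pathway with between ``min_size`` and
    ``max_size`` members (after restriction to the universe), then BH across
    the tested pathways.  Drivers are the query/pathway overlap.  Returns a
    frame sorted by p with columns ``pathway, name, overlap, set_size,
    pathway_size, universe_size, p, q, significant, drivers``.
    """
    if not db.sets:
        raise ValueError("empty gene-set database")
    query = set(genes) & db.universe
    if not genes:
        raise ValueError("empty query gene set")
    if not query:
        raise ValueError("query gene set is disjoint from the universe")
    M, n = len(db.universe), len(query)
    rows = []
    for pid, (name, members) in sorted(db.sets.items()):
        K = len(members)
        if K < min_size or K > max_size:
            continue
        overlap = query & members
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append(
            {
                "pathway": pid,
                "name": name,
                "overlap": k,
                "set_size": n,
                "pathway_size": K,
                "universe_size": M,
                "p": min(max(p, np.finfo(float).tiny), 1.0),
                "drivers": frozenset(overlap),
            }
        )
    if not rows:
        raise ValueError("no pathway passed the size filter")
    out = pd.DataFrame(rows)
    out["q"] = bh_qvalues(out["p"].to_numpy())
    out["significant"] = out["q"] <= fdr
    return out.sort_values(["p", "pathway"], kind="stable").reset_index(drop=True)


def prune_redundant(records: pd.DataFrame, overlap_threshold: float = 0.8) -> pd.DataFrame:
    """Greedy redundancy pruning of enrichment records.

    Walking the records in ascending p order (ties by pathway id), a record
    is dropped when the overlap coefficient ``|A∩B| / min(|A|,|B|)`` of its
    driver set with any already-retained record reaches the threshold.
    """
    if not 0.0 < overlap_threshold <= 1.0:
        raise ValueError("overlap_threshold must lie in (0, 1]")
    ordered = records.sort_values(["p", "pathway"], kind="stable")
    retained: list[frozenset[str]] = []
    keep_index = []
    for idx, row in ordered.iterrows():
        drivers = row["drivers"]
        redundant = False
        for other in retained:
            denom = min(len(drivers), len(other))
            if denom and len(drivers & other) / denom >= overlap_threshold:
                redundant = True
                break
        if not redundant:
            retained.append(drivers)
            keep_index.append(idx)
    return records.loc[keep_index].reset_index(drop=True)


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GseaResult:
    es: float
    nes: float
    p: float
    leading_edge: tuple[str, ...]
    n_perm: int


def _running_sum_es(scores: np.ndarray, hits: np.ndarray, weight: float) -> tuple[float, int]:
    """Signed enrichment score and position of the extreme deviation."""
    abs_w = np.abs(scores) ** weight
    hit_total = abs_w[hits].sum()
    n, n_hits = scores.size, int(hits.sum())
    steps = np.where(hits, abs_w / hit_total if hit_total > 0 else 0.0,
                     -1.0 / (n - n_hits))
    walk = np.cumsum(steps)
    pos = int(np.argmax(np.abs(walk)))
    return float(walk[pos]), pos


def gsea(
    scores: pd.Series,
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> GseaResult:
    """Weighted Kolmogorov–Smirnov GSEA with label-permutation calibration.

    ``scores`` map analytes to ranking scores (e.g. -log10 training p,
    optionally signed); analytes are ranked by decreasing score.  Hits step
    the running sum up proportionally to ``|score|**weight``, misses step it
    down by ``1/(N - n)``; the enrichment score ES is the extreme deviation.
    NES divides ES by the mean |permuted ES| of the same sign, and p is the
    same-sign exceedance fraction over gene-label permutations
    (add-one smoothed).  Deterministic given the seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    ranked = scores.loc[order]
    members = set(gene_set) & set(ranked.index)
    if len(members) < 2:
        raise ValueError("gene set intersects the ranked list in fewer than 2 analytes")
    if len(members) >= len(ranked):
        raise ValueError("gene set covers the entire ranked list")

    values = ranked.to_numpy(dtype=float)
    hits = np.array([g in members for g in ranked.index])
    es, pos = _running_sum_es(values, hits, weight)
    if es >= 0:
        leading = tuple(g for g, h in zip(ranked.index[: pos + 1], hits[: pos + 1]) if h)
    else:
        leading = tuple(g for g, h in zip(ranked.index[pos:], hits[pos:]) if h)

    rng = np.random.default_rng(seed)
    n, k = values.size, int(hits.sum())
    perm_es = np.empty(n_perm)
    for b in range(n_perm):
        perm_hits = np.zeros(n, dtype=bool)
        perm_hits[rng.choice(n, size=k, replace=False)] = True
        perm_es[b], _ = _running_sum_es(values, perm_hits, weight)
    same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        nes, p = float("nan"), 1.0 / (n_perm + 1)
    else:
        denom = float(np.abs(perm_es[same_sign]).mean())
        nes = es / denom if denom > 0 else float("nan")
        p = (1 + int((np.abs(perm_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
    return GseaResult(es, float(nes), float(p), leading, n_perm)


# ---------------------------------------------------------------------------
# pathway-similarity network
# ---------------------------------------------------------------------------

def pathway_similarity_network(
    records: pd.DataFrame,
    threshold: float = 0.375,
    seed: int = 0,
    resolution: float = 1.0,
):
    """Network of pathways linked by similar driver sets, with communities.

    Nodes are the records' pathways; an edge joins two pathways when the
    Jaccard similarity of their driver gene sets is at least ``threshold``.
    Communities come from a seeded Louvain modularity partition; singleton
    pathways are allowed.  Returns ``(graph, communities)`` where communities
    is a list of node sets and each node carries a ``community`` attribute.
    """
    import networkx as nx

    if records.empty:
        raise ValueError("no enrichment records supplied")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    g = nx.Graph()
    items = list(zip(records["pathway"], records["drivers"]))
    for pid, drivers in items:
        g.add_node(pid, size=len(drivers))
    for i, (pid_a, da) in enumerate(items):
        for pid_b, db_ in items[i + 1:]:
            union = len(da | db_)
            if union == 0:
                continue
            jaccard = len(da & db_) / union
            if jaccard >= threshold:
                g.add_edge(pid_a, pid_b, similarity=jaccard)
    communities = nx.community.louvain_communities(g, resolution=resolution, seed=seed)
    communities = sorted((sorted(c) for c in communities), key=lambda c: (-len(c), c[0]))
    for cid, members in enumerate(communities):
        for node in members:
            g.nodes[node]["community"] = cid
    return g, [set(c) for c in communities]


# ---------------------------------------------------------------------------
# marker correlations
# ---------------------------------------------------------------------------

def marker_correlation_test(
    matrix: FeatureMatrix,
    feature_set,
    marker_map: dict[str, list[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Correlate a cluster's average abundance with marker panels.

    Each feature in ``feature_set`` is standardized across samples and the
    per-sample mean is the cluster signature.  For every marker feature the
    sample-level Pearson r against the signature is computed; categories
    with at least two markers get a two-sided one-sample t-test of their r
    values against zero, BH-corrected across categories.  Single-marker
    categories report r without a test; constant markers are dropped with a
    warning.
    """
    features = list(feature_set)
    if not features:
        raise ValueError("empty feature set")
    missing = [f for f in features if f not in matrix.feature_ids]
    if missing:
        raise KeyError(f"feature(s) absent from matrix: {missing[:5]}")
    X = matrix.data.loc[features].to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    if not (sd > 0).any():
        raise ValueError("all features in the set are constant")
    Z = (X[sd > 0] - X[sd > 0].mean(axis=1, keepdims=True)) / sd[sd > 0][:, None]
    signature = Z.mean(axis=0)

    rows = []
    for category, markers in marker_map.items():
        rs = []
        used = []
        for marker in markers:
            if marker not in matrix.feature_ids:
                raise KeyError(f"marker {marker!r} absent from matrix")
            mvals = matrix.data.loc[marker].to_numpy(dtype=float)
            if mvals.std() == 0:
                warnings.warn(f"constant marker {marker!r} excluded", stacklevel=2)
                continue
            rs.append(float(stats.pearsonr(mvals, signature).statistic))
            used.append(marker)
        if not rs:
            continue
        row = {
            "category": category,
            "n_markers": len(rs),
            "mean_r": float(np.mean(rs)),
            "markers": ",".join(used),
        }
        if len(rs) >= 2:
            t_res = stats.ttest_1samp(rs, 0.0)
            row["t"], row["p"] = float(t_res.statistic), float(t_res.pvalue)
        else:
            row["t"], row["p"] = float("nan"), float("nan")
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no usable markers in any category")
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = bh_qvalues(
            np.clip(out.loc[tested, "p"].to_numpy(), np.finfo(float).tiny, 1.0)
        )
    out["significant"] = out["q"] <= fdr
    return out.reset_index(drop=True)
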