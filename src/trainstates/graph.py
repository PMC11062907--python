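"""State-path graphs and trajectory summaries for clustered features.

Nodes are (time point, joint state) pairs sized by the number of features
assigned to that state at that time; edges connect consecutive time points
and carry the number of features flowing between the two states, split by
ome.  Features sharing a full four-state path form a "graphical cluster";
the largest paths summarize a tissue's dominant temporal response.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GROUPS, WEEKS, FeatureMatrix, StudyDesign
from .states import node_label, parse_node_label, parse_path_label


@dataclass
class TrainingGraph:
    """Feature flows through the per-time joint states.

    ``nodes`` maps ``"<w>w_F<f>_M<m>"`` labels to feature counts; ``edges``
    maps ``(source label, target label)`` to a dict with the total ``count``
    and per-ome sub-counts; ``paths`` maps each feature to its path label.
    """

    nodes: dict[str, int]
    edges: dict[tuple[str, str], dict]
    paths: dict[str, str]
    n_features: int

    def to_json(self) -> str:
        payload = {
            "n_features": self.n_features,
            "nodes": self.nodes,
            "edges": [
                {"source": s, "target": t, "count": e["count"],
                 "ome_counts": e["ome_counts"]}
                for (s, t), e in sorted(self.edges.items())
            ],
            "paths": self.paths,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrainingGraph":
        payload = json.loads(text)
        edges = {
            (e["source"], e["target"]): {
                "count": e["count"],
                "ome_counts": dict(e["ome_counts"]),
            }
            for e in payload["edges"]
        }
        return cls(dict(payload["nodes"]), edges, dict(payload["paths"]),
                   int(payload["n_features"]))

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph(n_features=self.n_features)
        for label, count in self.nodes.items():
            week, f, m = parse_node_label(label)
            g.add_node(label, week=week, f=f, m=m, count=count)
        for (s, t), e in self.edges.items():
            g.add_edge(s, t, count=e["count"],
                       **{f"count_{o}": c for o, c in e["ome_counts"].items()})
        return g


def build_training_graph(
    assignments: pd.DataFrame, ome_tags: dict[str, str] | pd.Series
) -> TrainingGraph:
    """Tally node and edge counts from per-feature path assignments.

    ``assignments`` is the output of :func:`trainstates.states.assign_path`;
    ``ome_tags`` maps each feature id to its ome for the edge sub-counts.
    """
    if assignments["feature"].duplicated().any():
        dups = assignments.loc[assignments["feature"].duplicated(), "feature"]
        raise ValueError(f"duplicate feature ids in assignments: {dups.tolist()[:5]}")
    tags = dict(ome_tags) if not isinstance(ome_tags, dict) else ome_tags

    nodes: dict[str, int] = {}
    edges: dict[tuple[str, str], dict] = {}
    paths: dict[str, str] = {}
    for _, row in assignments.iterrows():
        fid = row["feature"]
        states = parse_path_label(row["label"])
        ome = tags.get(fid, "unknown")
        paths[fid] = row["label"]
        labels = [node_label(w, f, m) for w, (f, m) in zip(WEEKS, states)]
        for lab in labels:
            nodes[lab] = nodes.get(lab, 0) + 1
        for s, t in zip(labels[:-1], labels[1:]):
            e = edges.setdefault((s, t), {"count": 0, "ome_counts": {}})
            e["count"] += 1
            e["ome_counts"][ome] = e["ome_counts"].get(ome, 0) + 1
    return TrainingGraph(nodes, edges, paths, n_features=len(assignments))


def top_paths(assignments: pd.DataFrame, k: int = 3) -> list[tuple[str, int, tuple[str, ...]]]:
    """The k largest full paths: (label, feature count, member feature ids).

    Ranked by count, ties broken by lexicographic label.  If fewer than k
    distinct paths exist, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    groups = assignments.groupby("label")["feature"]
    ranked = sorted(
        ((label, tuple(sorted(members))) for label, members in groups),
        key=lambda item: (-len(item[1]), item[0]),
    )
    if k > len(ranked):
        warnings.warn(
            f"requested {k} paths but only {len(ranked)} distinct paths exist",
            stacklevel=2,
        )
        k = len(ranked)
    return [(label, len(members), members) for label, members in ranked[:k]]


@dataclass(frozen=True)
class TrajectorySummary:
    """Standardized per-feature curves plus the grand average, per sex."""

    feature_curves: pd.DataFrame  # feature, sex, group, value
    average: pd.DataFrame         # sex, group, value
    excluded: tuple[str, ...]     # zero-variance features left out


def standardized_trajectories(
    matrix: FeatureMatrix, features, design: StudyDesign
) -> TrajectorySummary:
    """Mean standardized abundance per sex x group for a feature set.

    Each feature is standardized to zero mean / unit SD across all samples
    of its tissue x ome dataset (both sexes on one axis), then averaged
    within each sex x group cell; the grand average across features is the
    cluster's consensus trajectory.
    """
    features = list(features)
    missing = [f for f in features if f not in matrix.feature_ids]
    if missing:
        raise KeyError(f"features absent from matrix: {missing[:5]}")
    X = matrix.data.loc[features].to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    excluded = tuple(np.asarray(features)[~keep])
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} zero-variance feature(s) from trajectories",
            stacklevel=2,
        )
    if not keep.any():
        empty = pd.DataFrame(columns=["feature", "sex", "group", "value"])
        return TrajectorySummary(empty, pd.DataFrame(columns=["sex", "group", "value"]),
                                 excluded)
    kept = [f for f, k in zip(features, keep) if k]
    Z = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]

    meta = design.for_matrix(matrix.tissue, matrix.ome).loc[matrix.sample_ids]
    sex = meta["sex"].to_numpy()
    group = meta["group"].to_numpy()
    rows = []
    for s in sorted(set(sex)):
        for g in GROUPS:
            cols = (sex == s) & (group == g)
            if not cols.any():
                continue
            cell_means = Z[:, cols].mean(axis=1)
            rows.extend(
                {"feature": f, "sex": s, "group": g, "value": v}
                for f, v in zip(kept, cell_means)
            )
    curves = pd.DataFrame(rows)
    average = (
        curves.groupby(["sex", "group"], sort=False)["value"].mean().reset_index()
    )
    return TrajectorySummary(curves, average, excluded)


#: Categories used when summarizing states by time point.
STATE_CATEGORIES = ("up-both", "down-both", "female-only", "male-only", "opposite", "null")


def categorize_state(f: int, m: int) -> str:
    if f == m == 0:
        return "null"
    if f * m == -1:
        return "opposite"
    if m == 0:
        return "female-only"
    if f == 0:
        return "male-only"
    return "up-both" if f == 1 else "down-both"


def summarize_states_by_time(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-time feature counts in the six sex-response categories.

    Columns are the categories in ``STATE_CATEGORIES``; rows are the four
    time points; each row sums to the number of clustered features.
    """
    counts = {w: {c: 0 for c in STATE_CATEGORIES} for w in WEEKS}
    for label in assignments["label"]:
        for w, (f, m) in zip(WEEKS, parse_path_label(label)):
            counts[w][categorize_state(f, m)] += 1
    out = pd.DataFrame.from_dict(counts, orient="index")
    out.index.name = "time"
    return out
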