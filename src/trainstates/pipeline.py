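"""End-to-end pipeline: configuration, staged execution, manifest.

Stages communicate through files in the output directory, so the CLI
subcommands (simulate, diff, states, graph, enrich) compose to exactly the
outputs of a single ``run_pipeline`` call.  One global seed fans out to a
named sub-seed per stage; any stage failure aborts with the stage name and
cause while retaining partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import differential, graph as graph_mod, io, states as states_mod
from .core import WEEKS, FeatureMatrix, StudyDesign
from .enrich import (
    hypergeom_enrich,
    marker_correlation_test,
    pathway_similarity_network,
    prune_redundant,
)
from .synthgen import SynthConfig, generate_study, truth_to_frame

logger = logging.getLogger("trainstates")
if not logger.handlers:  # stderr logging, configurable via logging API
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)


def sub_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class MatrixInput:
    path: str
    tissue: str
    ome: str
    kind: str = "continuous"


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs, thresholds, seeds, output directory."""

    outdir: str = "trainstates_out"
    seed: int = 0
    synth: SynthConfig | None = None
    design_path: str | None = None
    matrices: list[MatrixInput] = field(default_factory=list)
    gene_sets_path: str | None = None
    feature_gene_map_path: str | None = None
    marker_map_path: str | None = None
    fdr_training: float = 0.05
    fdr_enrich: float = 0.10
    fdr_markers: float = 0.05
    redundancy_threshold: float = 0.8
    similarity_threshold: float = 0.375
    prior_df: float = 4.0
    em_max_iter: int = 500
    em_tol: float = 1e-8
    top_k_paths: int = 3
    min_set_size: int = 5
    max_set_size: int = 500

    def __post_init__(self) -> None:
        for name in ("fdr_training", "fdr_enrich", "fdr_markers",
                     "redundancy_threshold", "similarity_threshold"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {value}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synth", None)
        if synth is not None:
            if "path_catalogue" in synth:
                synth["path_catalogue"] = tuple(
                    (tuple(tuple(s) for s in p), w) for p, w in synth["path_catalogue"]
                )
            for key in ("omes", "tissues"):
                if key in synth:
                    synth[key] = tuple(
                        tuple(v) if isinstance(v, list) else v for v in synth[key]
                    )
            synth = SynthConfig(**synth)
        matrices = [MatrixInput(**m) for m in raw.pop("matrices", [])]
        return cls(synth=synth, matrices=matrices, **raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# stage implementations (file-based contracts within cfg.outdir)
# ---------------------------------------------------------------------------

def _out(cfg: PipelineConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _matrix_filename(tissue: str, ome: str, prefix: str) -> str:
    return f"{prefix}_{tissue}_{ome}.tsv"


def stage_simulate(cfg: PipelineConfig) -> list[str]:
    """Generate a synthetic study and write design/matrices/truth."""
    if cfg.synth is None:
        raise ValueError("no synthetic-study configuration supplied")
    out = _out(cfg)
    synth = dataclasses.replace(cfg.synth, seed=sub_seed(cfg.seed, "simulate"))
    study = generate_study(synth)
    written = []
    io.write_design(study.design, out / "design.tsv")
    written.append("design.tsv")
    for (tissue, ome), matrix in study.matrices.items():
        name = _matrix_filename(tissue, ome, "matrix")
        io.write_matrix(matrix, out / name)
        written.append(name)
    truth_to_frame(study.truth).to_csv(out / "truth.tsv", sep="\t", index=False)
    written.append("truth.tsv")
    with open(out / "synth_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(synth), fh, sort_keys=True)
    written.append("synth_config.yaml")
    logger.info("simulate: %d datasets, %d features each",
                len(study.matrices), synth.n_features)
    return written


def _load_inputs(cfg: PipelineConfig) -> tuple[StudyDesign, dict[tuple[str, str], FeatureMatrix]]:
    out = _out(cfg)
    if cfg.synth is not None:
        design = io.read_design(out / "design.tsv")
        matrices = {}
        kinds = dict(cfg.synth.omes)
        for tissue, ome in design.datasets:
            matrices[(tissue, ome)] = io.read_matrix(
                out / _matrix_filename(tissue, ome, "matrix"),
                tissue, ome, kind=kinds[ome],
            )
        return design, matrices
    if cfg.design_path is None or not cfg.matrices:
        raise ValueError("need design_path and matrices when synth is not configured")
    design = io.read_design(cfg.design_path)
    matrices = {
        (m.tissue, m.ome): io.read_matrix(m.path, m.tissue, m.ome, kind=m.kind)
        for m in cfg.matrices
    }
    return design, matrices


def stage_diff(cfg: PipelineConfig) -> list[str]:
    """Normalize, timewise stats, training p, BH selection per dataset."""
    out = _out(cfg)
    design, matrices = _load_inputs(cfg)
    timewise_frames, training_frames, excluded_rows = [], [], []
    for (tissue, ome), matrix in sorted(matrices.items()):
        norm = differential.normalize(matrix)
        io.write_matrix(norm, out / _matrix_filename(tissue, ome, "normalized"))
        tw = differential.timewise_stats(norm, design, prior_df=cfg.prior_df)
        tw.insert(1, "tissue", tissue)
        tw.insert(2, "ome", ome)
        timewise_frames.append(tw)
        p, excluded = differential.training_pvalue(norm, design, prior_df=cfg.prior_df)
        if not p.empty:
            sel = differential.select_training_regulated(p, fdr=cfg.fdr_training)
            sel.insert(1, "tissue", tissue)
            sel.insert(2, "ome", ome)
            training_frames.append(sel)
        excluded_rows.extend(
            {"feature": fid, "tissue": tissue, "ome": ome, "reason": why}
            for fid, why in sorted(excluded.items())
        )
    pd.concat(timewise_frames, ignore_index=True).to_csv(
        out / "timewise.tsv", sep="\t", index=False
    )
    training = (
        pd.concat(training_frames, ignore_index=True)
        if training_frames
        else pd.DataFrame(columns=["feature", "tissue", "ome", "p", "q", "selected"])
    )
    training.to_csv(out / "training.tsv", sep="\t", index=False)
    pd.DataFrame(excluded_rows, columns=["feature", "tissue", "ome", "reason"]).to_csv(
        out / "excluded.tsv", sep="\t", index=False
    )
    logger.info("diff: %d features selected at %.0f%% FDR",
                int(training["selected"].sum()), 100 * cfg.fdr_training)
    written = ["timewise.tsv", "training.tsv", "excluded.tsv"]
    written += [_matrix_filename(t, o, "normalized") for t, o in sorted(matrices)]
    return written


def stage_states(cfg: PipelineConfig) -> list[str]:
    """Fit per-time state mixtures on selected features; assign paths."""
    out = _out(cfg)
    timewise = pd.read_csv(out / "timewise.tsv", sep="\t")
    training = pd.read_csv(out / "training.tsv", sep="\t")
    posterior_frames, path_frames = [], []
    skipped = []
    for (tissue, ome), sel in training.groupby(["tissue", "ome"], sort=True):
        chosen = set(sel.loc[sel["selected"], "feature"])
        tw = timewise[
            (timewise["tissue"] == tissue)
            & (timewise["ome"] == ome)
            & timewise["feature"].isin(chosen)
        ]
        # only features with complete timewise statistics enter clustering
        complete = tw.groupby("feature").size()
        complete = set(complete[complete == 2 * len(WEEKS)].index)
        if len(complete) < 10:
            skipped.append((tissue, ome, len(complete)))
            continue
        tw = tw[tw["feature"].isin(complete)]
        per_time = []
        for week in WEEKS:
            zf = differential.z_wide(tw, "F", week).sort_index()
            zm = differential.z_wide(tw, "M", week).sort_index()
            params = states_mod.fit_state_model(
                zf.to_numpy(), zm.to_numpy(), time=week,
                max_iter=cfg.em_max_iter, tol=cfg.em_tol,
                seed=sub_seed(cfg.seed, f"states:{tissue}:{ome}:{week}"),
            )
            post = states_mod.posterior_states(zf.to_numpy(), zm.to_numpy(), params)
            per_time.append(states_mod.posterior_frame(zf.index, week, post))
        posteriors = pd.concat(per_time, ignore_index=True)
        assignments = states_mod.assign_path(posteriors)
        posteriors.insert(1, "tissue", tissue)
        posteriors.insert(2, "ome", ome)
        assignments.insert(1, "tissue", tissue)
        assignments.insert(2, "ome", ome)
        posterior_frames.append(posteriors)
        path_frames.append(assignments)
    post_cols = ["feature", "tissue", "ome", "time"] + [
        f"p_F{f}_M{m}" for f, m in states_mod.STATES
    ]
    (pd.concat(posterior_frames, ignore_index=True) if posterior_frames
     else pd.DataFrame(columns=post_cols)).to_csv(
        out / "posteriors.tsv", sep="\t", index=False
    )
    path_cols = ["feature", "tissue", "ome"] + [f"state_{w}w" for w in WEEKS] + [
        "label", "min_posterior", "tied"
    ]
    (pd.concat(path_frames, ignore_index=True) if path_frames
     else pd.DataFrame(columns=path_cols)).to_csv(
        out / "paths.tsv", sep="\t", index=False
    )
    for tissue, ome, n in skipped:
        logger.info("states: skipping %s/%s (only %d selected features)", tissue, ome, n)
    return ["posteriors.tsv", "paths.tsv"]


def stage_graph(cfg: PipelineConfig) -> list[str]:
    """Per-tissue state graphs, largest paths, summaries, trajectories."""
    out = _out(cfg)
    paths = pd.read_csv(out / "paths.tsv", sep="\t")
    written = []
    top_rows, summary_frames, curve_frames, avg_frames = [], [], [], []
    if paths.empty:
        logger.info("graph: no clustered features; writing empty summaries")
    design = None
    for tissue, sub in paths.groupby("tissue", sort=True):
        tgraph = graph_mod.build_training_graph(
            sub, dict(zip(sub["feature"], sub["ome"]))
        )
        (out / f"graph_{tissue}.json").write_text(tgraph.to_json())
        written.append(f"graph_{tissue}.json")
        import networkx as nx

        nx.write_graphml(tgraph.to_networkx(), out / f"graph_{tissue}.graphml")
        written.append(f"graph_{tissue}.graphml")

        ranked = graph_mod.top_paths(sub, k=min(cfg.top_k_paths, sub["label"].nunique()))
        for rank, (label, count, members) in enumerate(ranked, start=1):
            top_rows.append({"tissue": tissue, "rank": rank, "label": label,
                             "count": count})
        summary = graph_mod.summarize_states_by_time(sub).reset_index()
        summary.insert(0, "tissue", tissue)
        summary_frames.append(summary)

        if ranked:
            if design is None:
                design = io.read_design(out / "design.tsv") if cfg.synth is not None \
                    else io.read_design(cfg.design_path)
            label, _, members = ranked[0]
            member_set = set(members)
            for ome, ome_sub in sub.groupby("ome", sort=True):
                feats = [f for f in ome_sub["feature"] if f in member_set]
                if not feats:
                    continue
                norm = io.read_matrix(
                    out / _matrix_filename(tissue, ome, "normalized"), tissue, ome
                )
                traj = graph_mod.standardized_trajectories(norm, feats, design)
                if traj.feature_curves.empty:
                    continue
                curves = traj.feature_curves.copy()
                curves.insert(0, "tissue", tissue)
                curves.insert(1, "ome", ome)
                curves.insert(2, "path", label)
                curve_frames.append(curves)
                avg = traj.average.copy()
                avg.insert(0, "tissue", tissue)
                avg.insert(1, "ome", ome)
                avg.insert(2, "path", label)
                avg_frames.append(avg)

    pd.DataFrame(top_rows, columns=["tissue", "rank", "label", "count"]).to_csv(
        out / "top_paths.tsv", sep="\t", index=False
    )
    (pd.concat(summary_frames, ignore_index=True) if summary_frames
     else pd.DataFrame(columns=["tissue", "time", *graph_mod.STATE_CATEGORIES])).to_csv(
        out / "state_summary.tsv", sep="\t", index=False
    )
    curve_cols = ["tissue", "ome", "path", "feature", "sex", "group", "value"]
    (pd.concat(curve_frames, ignore_index=True) if curve_frames
     else pd.DataFrame(columns=curve_cols)).to_csv(
        out / "trajectory_curves.tsv", sep="\t", index=False
    )
    avg_cols = ["tissue", "ome", "path", "sex", "group", "value"]
    (pd.concat(avg_frames, ignore_index=True) if avg_frames
     else pd.DataFrame(columns=avg_cols)).to_csv(
        out / "trajectories.tsv", sep="\t", index=False
    )
    return written + ["top_paths.tsv", "state_summary.tsv",
                      "trajectory_curves.tsv", "trajectories.tsv"]


def stage_enrich(cfg: PipelineConfig) -> list[str]:
    """ORA + pruning + similarity network for each tissue's largest paths."""
    out = _out(cfg)
    if cfg.gene_sets_path is None:
        logger.info("enrich: no gene sets configured; stage skipped")
        return []
    db = io.read_gmt(cfg.gene_sets_path)
    if cfg.feature_gene_map_path is None:
        raise ValueError("gene sets configured but no feature->gene map supplied")
    fmap = io.read_feature_gene_map(cfg.feature_gene_map_path)
    paths = pd.read_csv(out / "paths.tsv", sep="\t")
    records_frames = []
    for tissue, sub in paths.groupby("tissue", sort=True):
        ranked = graph_mod.top_paths(sub, k=min(cfg.top_k_paths, sub["label"].nunique()))
        for label, _, members in ranked:
            genes = {fmap[f] for f in members if f in fmap}
            genes &= db.universe
            if not genes:
                continue
            try:
                rec = hypergeom_enrich(
                    genes, db, fdr=cfg.fdr_enrich,
                    min_size=cfg.min_set_size, max_size=cfg.max_set_size,
                )
            except ValueError as err:
                logger.info("enrich: %s %s skipped (%s)", tissue, label, err)
                continue
            rec = prune_redundant(rec, overlap_threshold=cfg.redundancy_threshold)
            rec.insert(0, "tissue", tissue)
            rec.insert(1, "cluster", label)
            records_frames.append(rec)
    written = []
    if records_frames:
        records = pd.concat(records_frames, ignore_index=True)
        table = records.copy()
        table["drivers"] = table["drivers"].map(lambda s: ",".join(sorted(s)))
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        written.append("enrichment.tsv")
        significant = records[records["significant"]]
        if not significant.empty:
            dedup = significant.drop_duplicates("pathway")
            net, communities = pathway_similarity_network(
                dedup, threshold=cfg.similarity_threshold,
                seed=sub_seed(cfg.seed, "enrich:network"),
            )
            import networkx as nx

            payload = nx.node_link_data(net, edges="edges")
            (out / "network.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
            nx.write_graphml(net, out / "network.graphml")
            comm_rows = [
                {"community": cid, "pathway": p}
                for cid, members in enumerate(communities)
                for p in sorted(members)
            ]
            pd.DataFrame(comm_rows).to_csv(out / "communities.tsv", sep="\t", index=False)
            written += ["network.json", "network.graphml", "communities.tsv"]
    else:
        pd.DataFrame(
            columns=["tissue", "cluster", "pathway", "name", "overlap", "set_size",
                     "pathway_size", "universe_size", "p", "drivers", "q", "significant"]
        ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        written.append("enrichment.tsv")

    if cfg.marker_map_path is not None:
        markers = io.read_marker_map(cfg.marker_map_path)
        marker_frames = []
        for (tissue, ome), sub in paths.groupby(["tissue", "ome"], sort=True):
            ranked = graph_mod.top_paths(sub, k=1)
            if not ranked:
                continue
            label, _, members = ranked[0]
            norm = io.read_matrix(
                out / _matrix_filename(tissue, ome, "normalized"), tissue, ome
            )
            usable = {
                cat: [m for m in ms if m in norm.feature_ids]
                for cat, ms in markers.items()
            }
            usable = {cat: ms for cat, ms in usable.items() if ms}
            feats = [f for f in members if f in norm.feature_ids]
            if not usable or not feats:
                continue
            res = marker_correlation_test(norm, feats, usable, fdr=cfg.fdr_markers)
            res.insert(0, "tissue", tissue)
            res.insert(1, "ome", ome)
            res.insert(2, "cluster", label)
            marker_frames.append(res)
        if marker_frames:
            pd.concat(marker_frames, ignore_index=True).to_csv(
                out / "markers.tsv", sep="\t", index=False
            )
            written.append("markers.tsv")
    return written


_STAGES = (
    ("simulate", stage_simulate),
    ("diff", stage_diff),
    ("states", stage_states),
    ("graph", stage_graph),
    ("enrich", stage_enrich),
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(cfg: PipelineConfig) -> Path:
    """Checksum every file in the output directory into manifest.json."""
    out = _out(cfg)
    files = sorted(
        p.relative_to(out).as_posix()
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": cfg.seed,
        "stage_seeds": {name: sub_seed(cfg.seed, name) for name, _ in _STAGES},
        "parameters": {
            "fdr_training": cfg.fdr_training,
            "fdr_enrich": cfg.fdr_enrich,
            "redundancy_threshold": cfg.redundancy_threshold,
            "similarity_threshold": cfg.similarity_threshold,
            "prior_df": cfg.prior_df,
        },
        "files": {name: _sha256(out / name) for name in files},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Run the staged pipeline end to end and write the output manifest.

    ``stages`` restricts execution (the CLI's subcommands); the default runs
    everything, skipping simulation when no synthetic config is present.
    """
    for name, func in _STAGES:
        if stages is not None and name not in stages:
            continue
        if name == "simulate" and cfg.synth is None:
            continue
        try:
            func(cfg)
        except Exception as err:  # abort with stage context, keep partial output
            raise PipelineStageError(name, err) from err
    manifest_path = write_manifest(cfg)
    return json.loads(manifest_path.read_text())
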