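"""Readers and writers for the pipeline's plain-text formats.

Tables are TSV with a mandatory header row; gene sets are GMT
(pathway id, description, then members, tab-separated); graphs are JSON or
GraphML.  Write-then-read round trips are identity for every format.
"""

from __future__ import annotations

import pandas as pd

from .core import FeatureMatrix, StudyDesign
from .enrich import GeneSetDB


def write_design(design: StudyDesign, path) -> None:
    design.samples.to_csv(path, sep="\t", index=False)


def read_design(path) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return StudyDesign(df)  # validates columns and tokens


def write_matrix(matrix: FeatureMatrix, path) -> None:
    out = matrix.data.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t")


def read_matrix(path, tissue: str, ome: str, kind: str = "continuous") -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    log_scale = kind == "continuous"
    return FeatureMatrix(df, tissue, ome, kind=kind, log_scale=log_scale)


def write_gmt(db: GeneSetDB, path) -> None:
    with open(path, "w") as fh:
        for pid, (name, members) in sorted(db.sets.items()):
            fh.write("\t".join([pid, name, *sorted(members)]) + "\n")


def read_gmt(path, universe: set[str] | None = None) -> GeneSetDB:
    """Parse a GMT file: each line is ``id<TAB>description<TAB>member...``.

    The universe defaults to the union of all members.  Duplicate pathway
    ids and lines with fewer than three fields are rejected.
    """
    raw: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs at least 3 tab-separated fields"
                )
            pid, name, members = fields[0], fields[1], fields[2:]
            if pid in raw:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            raw[pid] = (name, set(members))
    return GeneSetDB.from_dict(raw, universe)


def write_feature_gene_map(mapping: dict[str, str], path) -> None:
    pd.DataFrame(
        sorted(mapping.items()), columns=["feature", "gene"]
    ).to_csv(path, sep="\t", index=False)


def read_feature_gene_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"feature", "gene"} <= set(df.columns):
        raise ValueError("feature->gene map needs 'feature' and 'gene' columns")
    if df["feature"].duplicated().any():
        raise ValueError("duplicate features in feature->gene map")
    return dict(zip(df["feature"], df["gene"]))


def write_marker_map(markers: dict[str, list[str]], path) -> None:
    rows = [
        {"category": cat, "marker": m}
        for cat in sorted(markers)
        for m in markers[cat]
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"category", "marker"} <= set(df.columns):
        raise ValueError("marker map needs 'category' and 'marker' columns")
    out: dict[str, list[str]] = {}
    for cat, sub in df.groupby("category", sort=True):
        out[cat] = sub["marker"].tolist()
    return out
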