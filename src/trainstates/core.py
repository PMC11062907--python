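"""Shared domain containers for the endurance-training response pipeline.

The experimental frame is a two-sex, five-group design: sedentary controls
plus groups that trained for 1, 2, 4 or 8 weeks, profiled across multiple
tissues and molecular platforms ("omes").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEXES = ("F", "M")
GROUPS = ("control", "1w", "2w", "4w", "8w")
TRAINED_GROUPS = ("1w", "2w", "4w", "8w")
WEEKS = (1, 2, 4, 8)
GROUP_FOR_WEEK = {1: "1w", 2: "2w", 4: "4w", 8: "8w"}
WEEK_FOR_GROUP = {v: k for k, v in GROUP_FOR_WEEK.items()}

OME_KINDS = ("continuous", "counts")

DESIGN_COLUMNS = ("sample_id", "sex", "group", "tissue", "ome")


@dataclass(frozen=True)
class StudyDesign:
    """Sample-to-condition assignments for every tissue x ome dataset.

    Parameters
    ----------
    samples : pandas.DataFrame
        One row per sample with columns ``sample_id, sex, group, tissue, ome``.
        ``sex`` is ``F`` or ``M``; ``group`` is ``control`` or one of the
        trained groups ``1w/2w/4w/8w``.
    """

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.samples
        missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"design table is missing columns: {missing}")
        bad_sex = sorted(set(df["sex"]) - set(SEXES))
        if bad_sex:
            raise ValueError(f"unknown sex token(s) in design: {bad_sex}")
        bad_group = sorted(set(df["group"]) - set(GROUPS))
        if bad_group:
            raise ValueError(f"unknown group token(s) in design: {bad_group}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in design: {dups[:5]}")

    def for_matrix(self, tissue: str, ome: str) -> pd.DataFrame:
        """Design rows for one tissue x ome dataset, indexed by sample id."""
        df = self.samples
        sub = df[(df["tissue"] == tissue) & (df["ome"] == ome)]
        if sub.empty:
            raise KeyError(f"no design rows for tissue={tissue!r}, ome={ome!r}")
        return sub.set_index("sample_id")

    @property
    def datasets(self) -> list[tuple[str, str]]:
        """Distinct (tissue, ome) pairs present in the design."""
        pairs = self.samples[["tissue", "ome"]].drop_duplicates()
        return [tuple(r) for r in pairs.itertuples(index=False)]


@dataclass
class FeatureMatrix:
    """A feature-by-sample abundance matrix for one tissue x ome dataset.

    ``data`` holds features on rows and samples on columns.  ``kind`` is
    ``continuous`` (already log scale) or ``counts`` (non-negative counts
    awaiting normalization).  ``log_scale`` records whether values are on a
    log2 scale; ``zero_variance`` lists features flagged during
    normalization as untestable.
    """

    data: pd.DataFrame
    tissue: str
    ome: str
    kind: str = "continuous"
    log_scale: bool = True
    zero_variance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in OME_KINDS:
            raise ValueError(f"unknown ome kind {self.kind!r}; expected one of {OME_KINDS}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate feature ids in matrix")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample ids in matrix")
        if self.data.empty:
            raise ValueError("empty feature matrix")
        if self.log_scale and not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("non-finite values in log-scale matrix")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns
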