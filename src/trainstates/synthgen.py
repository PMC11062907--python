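"""Synthetic multi-tissue, multi-ome training studies with known ground truth.

Emulates the study design — two sexes, sedentary controls plus 1/2/4/8-week
trained groups, several tissues and molecular platforms — with a known
per-feature state path (the joint female/male differential direction at each
time point) and known effect sizes, so that every downstream stage of the
pipeline can be tested for recovery and error control without any real data.

Effect-size calibration
-----------------------
Each non-null feature draws one effect magnitude ``m`` from an exponential
distribution with mean ``effect_size_scale``; every active (sex, time) cell
of that feature gets a log2 fold change of ``±m`` with the sign dictated by
its state path.  The default scale 0.7126 solves
``1 - exp(-log2(1.5)/scale) = 0.56`` so that 56% of non-null features have
their maximum fold change inside (1/1.5, 1.5), matching the modest effect
sizes observed in endurance-training omics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    GROUPS,
    GROUP_FOR_WEEK,
    SEXES,
    WEEKS,
    FeatureMatrix,
    StudyDesign,
)

State = tuple[int, int]
Path = tuple[State, State, State, State]

NULL_STATE: State = (0, 0)
NULL_PATH: Path = (NULL_STATE,) * 4

#: Non-null trajectory patterns highlighted by the study, with sampling
#: weights. The all-null path is listed for completeness at weight zero:
#: null features are produced by ``frac_null`` so their count is exact.
DEFAULT_PATH_CATALOGUE: tuple[tuple[Path, float], ...] = (
    (((1, 1), (1, 1), (1, 1), (1, 1)), 0.25),        # consistent up, both sexes
    (((0, 1), (0, 1), (0, 1), (1, 1)), 0.15),        # male first, female joins at 8w
    (((0, 1), (0, 1), (0, 1), (0, 1)), 0.15),        # male-only up
    (((-1, -1), (-1, -1), (-1, -1), (-1, -1)), 0.15),  # consistent down
    (((1, 1), (1, 1), (0, 0), (0, 0)), 0.15),        # early transient
    (((1, -1), (1, -1), (1, -1), (1, -1)), 0.15),    # opposite-sex response
    (NULL_PATH, 0.0),
)

# mean |log2FC| solving P(m < log2 1.5) = 0.56 for m ~ Exp(scale)
DEFAULT_EFFECT_SCALE = math.log2(1.5) / -math.log(1 - 0.56)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic study.

    ``n_features`` applies per tissue x ome dataset.  ``noise_sd`` is the
    residual SD on the log2 scale; ``count_dispersion`` is the negative
    binomial dispersion (var = mu + phi mu^2) for count omes, whose library
    sizes vary log-normally with the given CV.
    """

    n_features: int = 1000
    omes: tuple[tuple[str, str], ...] = (
        ("transcriptomics", "counts"),
        ("metabolomics", "continuous"),
    )
    tissues: tuple[str, ...] = ("gastrocnemius", "liver")
    n_per_group: int = 6
    frac_null: float = 0.9
    path_catalogue: tuple[tuple[Path, float], ...] = DEFAULT_PATH_CATALOGUE
    effect_size_scale: float = DEFAULT_EFFECT_SCALE
    noise_sd: float = 0.5
    count_dispersion: float = 0.1
    libsize_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if not self.omes:
            raise ValueError("at least one ome is required")
        for name, kind in self.omes:
            if kind not in ("continuous", "counts"):
                raise ValueError(f"ome {name!r} has unknown kind {kind!r}")
        if not self.tissues:
            raise ValueError("at least one tissue is required")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if not 0.0 <= self.frac_null <= 1.0:
            raise ValueError("frac_null must lie in [0, 1]")
        weights = [w for _, w in self.path_catalogue]
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("path catalogue weights must be a distribution")
        for path, _ in self.path_catalogue:
            if len(path) != 4:
                raise ValueError("every catalogue path needs exactly 4 time points")
            for f, m in path:
                if f not in (-1, 0, 1) or m not in (-1, 0, 1):
                    raise ValueError("states must be in {-1, 0, 1}")
        if self.effect_size_scale <= 0 or self.noise_sd <= 0:
            raise ValueError("effect_size_scale and noise_sd must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one feature: its state path and true log2FC per cell."""

    feature_id: str
    tissue: str
    ome: str
    path: Path
    logfc: dict[tuple[str, int], float]  # (sex, week) -> true log2 fold change

    @property
    def is_null(self) -> bool:
        return self.path == NULL_PATH


@dataclass(frozen=True)
class SynthStudy:
    design: StudyDesign
    matrices: dict[tuple[str, str], FeatureMatrix]
    truth: list[TruthRecord]


def _make_design(config: SynthConfig) -> StudyDesign:
    rows = []
    for tissue in config.tissues:
        for ome, _ in config.omes:
            for sex in SEXES:
                for group in GROUPS:
                    for i in range(config.n_per_group):
                        rows.append(
                            {
                                "sample_id": f"{tissue}:{ome}:{sex}_{group}_r{i + 1}",
                                "sex": sex,
                                "group": group,
                                "tissue": tissue,
                                "ome": ome,
                            }
                        )
    return StudyDesign(pd.DataFrame(rows))


def _sample_truth(
    config: SynthConfig, tissue: str, ome: str, rng: np.random.Generator
) -> list[TruthRecord]:
    n = config.n_features
    n_signal = int(round(n * (1.0 - config.frac_null)))
    ids = [f"{tissue}:{ome}:feat{i:05d}" for i in range(n)]
    signal_idx = set(rng.choice(n, size=n_signal, replace=False).tolist())

    paths = [p for p, w in config.path_catalogue if w > 0]
    weights = np.array([w for _, w in config.path_catalogue if w > 0], dtype=float)
    weights = weights / weights.sum() if len(weights) else weights

    records: list[TruthRecord] = []
    for i, fid in enumerate(ids):
        if i in signal_idx and paths:
            path = paths[rng.choice(len(paths), p=weights)]
            mag = rng.exponential(config.effect_size_scale)
        else:
            path, mag = NULL_PATH, 0.0
        logfc = {}
        for (f, m), week in zip(path, WEEKS):
            logfc[("F", week)] = f * mag
            logfc[("M", week)] = m * mag
        records.append(TruthRecord(fid, tissue, ome, path, logfc))
    return records


def _effect_matrix(truth: list[TruthRecord], design: pd.DataFrame) -> np.ndarray:
    """Per-sample true log2 shift (features x samples); zero for controls."""
    eff = np.zeros((len(truth), len(design)), dtype=float)
    sex = design["sex"].to_numpy()
    group = design["group"].to_numpy()
    for j, (s, g) in enumerate(zip(sex, group)):
        if g == "control":
            continue
        week = {v: k for k, v in GROUP_FOR_WEEK.items()}[g]
        for i, rec in enumerate(truth):
            eff[i, j] = rec.logfc[(s, week)]
    return eff


def generate_study(config: SynthConfig) -> SynthStudy:
    """Simulate one full study: design, matrices and ground-truth records.

    Continuous omes are Gaussian on the log2 scale around a per-feature
    baseline plus the true effect; count omes draw negative binomial counts
    around exp-scale means with log-normal library-size factors.  The same
    seed always yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    design = _make_design(config)
    matrices: dict[tuple[str, str], FeatureMatrix] = {}
    truth: list[TruthRecord] = []

    for tissue in config.tissues:
        for ome, kind in config.omes:
            sub = design.for_matrix(tissue, ome).reset_index()
            recs = _sample_truth(config, tissue, ome, rng)
            truth.extend(recs)
            eff = _effect_matrix(recs, sub)
            n, s = len(recs), len(sub)
            ids = [r.feature_id for r in recs]
            if kind == "continuous":
                base = rng.normal(8.0, 2.0, size=n)[:, None]
                values = base + eff + rng.normal(0.0, config.noise_sd, size=(n, s))
                data = pd.DataFrame(values, index=ids, columns=sub["sample_id"])
                matrices[(tissue, ome)] = FeatureMatrix(
                    data, tissue, ome, kind="continuous", log_scale=True
                )
            else:
                base = rng.normal(5.0, 1.5, size=n)[:, None]
                sigma = math.sqrt(math.log(1.0 + config.libsize_cv**2))
                libfac = rng.lognormal(-0.5 * sigma**2, sigma, size=s)[None, :]
                # biological noise on the log scale, then NB sampling noise
                log_mu = base + eff + rng.normal(0.0, config.noise_sd, size=(n, s))
                mu = np.exp2(log_mu) * libfac
                phi = config.count_dispersion
                nb_n = 1.0 / phi
                counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
                data = pd.DataFrame(
                    counts.astype(float), index=ids, columns=sub["sample_id"]
                )
                matrices[(tissue, ome)] = FeatureMatrix(
                    data, tissue, ome, kind="counts", log_scale=False
                )
    return SynthStudy(design, matrices, truth)


def truth_fdp(selected: set[str], truth: list[TruthRecord]) -> float:
    """False-discovery proportion of a selected feature set against truth.

    Returns ``|selected ∩ null| / max(|selected|, 1)``; an empty selection
    has FDP 0 by convention.
    """
    null_ids = {r.feature_id for r in truth if r.is_null}
    all_ids = {r.feature_id for r in truth}
    unknown = set(selected) - all_ids
    if unknown:
        raise KeyError(f"unknown feature id(s): {sorted(unknown)[:5]}")
    if not selected:
        return 0.0
    return len(set(selected) & null_ids) / len(selected)


def truth_to_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    """Flatten TruthRecords to a tidy table (one row per feature)."""
    from .states import path_label  # local import to avoid a cycle

    rows = []
    for r in truth:
        row = {
            "feature": r.feature_id,
            "tissue": r.tissue,
            "ome": r.ome,
            "path": path_label(r.path),
            "is_null": r.is_null,
        }
        for (sex, week), v in r.logfc.items():
            row[f"logfc_{sex}_{week}w"] = v
        rows.append(row)
    return pd.DataFrame(rows)
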