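"""Timewise differential statistics and the combined training test.

Every feature is fit with a cell-means linear model over the observed
sex x group cells (``abundance ~ sex + sex:group``, with the sex-matched
sedentary controls as per-sex baseline).  The residual variance is pooled
across all cells and moderated towards a common prior variance estimated
from all features (empirical Bayes shrinkage with a configurable prior
degrees of freedom), exactly in the spirit of moderated t/F statistics for
omics data:

* **timewise statistics** — per (sex, time): log2 fold change of the trained
  group versus the sex-matched controls, its moderated SE, the standardized
  effect z = logFC/SE, and a two-sided p-value from a t reference with
  ``residual df + prior df`` degrees of freedom.
* **training p-value** — one p-value per feature from the moderated F-test
  that all sex x time training effects are simultaneously zero.
* **selection** — Benjamini–Hochberg q-values within each tissue x ome
  dataset; features with q below the FDR threshold are "training-regulated".
* **permutation validation** — the full pipeline re-run under permuted group
  (or sex) labels to show that the selected-feature count is driven by
  signal rather than by the machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import (
    SEXES,
    TRAINED_GROUPS,
    WEEK_FOR_GROUP,
    FeatureMatrix,
    StudyDesign,
)

_TINY = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Bring a matrix to the log2 scale and flag untestable features.

    Count omes become ``log2(counts-per-million + 0.5)`` using per-sample
    library sizes; continuous omes pass through unchanged.  Features with
    zero variance across samples are recorded in ``zero_variance`` and are
    excluded from downstream testing.
    """
    values = matrix.data.to_numpy(dtype=float)
    if matrix.kind == "counts":
        if (values < 0).any():
            raise ValueError("negative values in a counts matrix")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts matrix must contain integers")
        libsize = values.sum(axis=0)
        if (libsize == 0).any():
            bad = matrix.sample_ids[libsize == 0].tolist()
            raise ValueError(f"zero library size for sample(s): {bad[:5]}")
        logged = np.log2(values / libsize * 1e6 + 0.5)
        data = pd.DataFrame(logged, index=matrix.feature_ids, columns=matrix.sample_ids)
    else:
        data = matrix.data
        logged = values
    flagged = tuple(matrix.feature_ids[logged.std(axis=1) == 0.0])
    return FeatureMatrix(
        data,
        matrix.tissue,
        matrix.ome,
        kind="continuous",
        log_scale=True,
        zero_variance=flagged,
    )


# ---------------------------------------------------------------------------
# moderated cell-means fit (shared by timewise stats and the training test)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _CellFit:
    feature_ids: pd.Index
    cells: list[tuple[str, str]]        # (sex, group), observed order
    counts: np.ndarray                  # samples per cell
    means: np.ndarray                   # features x cells
    s2: np.ndarray                      # pooled residual variance per feature
    s2_post: np.ndarray                 # moderated variance
    df_resid: int
    df_prior: float
    s2_prior: float

    @property
    def df_total(self) -> float:
        return self.df_resid + self.df_prior


def _aligned_labels(matrix: FeatureMatrix, design: StudyDesign) -> tuple[np.ndarray, np.ndarray]:
    d = design.samples.set_index("sample_id")
    missing = [s for s in matrix.sample_ids if s not in d.index]
    if missing:
        raise ValueError(f"matrix samples absent from design: {missing[:5]}")
    sub = d.loc[matrix.sample_ids]
    return sub["sex"].to_numpy(), sub["group"].to_numpy()


def _fit_cells(matrix: FeatureMatrix, design: StudyDesign, prior_df: float) -> _CellFit:
    if prior_df < 0:
        raise ValueError("prior_df must be non-negative")
    keep = ~matrix.feature_ids.isin(matrix.zero_variance)
    X = matrix.data.to_numpy(dtype=float)[keep.nonzero()[0]]
    fids = matrix.feature_ids[keep]
    sex, group = _aligned_labels(matrix, design)

    cells = sorted(set(zip(sex, group)))
    for s in set(sex):
        if (s, "control") not in cells:
            raise ValueError(f"no sedentary control samples for sex {s!r}")
    idx = {c: i for i, c in enumerate(cells)}
    C = np.zeros((X.shape[1], len(cells)))
    for j, c in enumerate(zip(sex, group)):
        C[j, idx[c]] = 1.0
    counts = C.sum(axis=0)
    low = [c for c, n in zip(cells, counts) if n < 2]
    if low:
        raise ValueError(f"sex x group cell(s) with fewer than 2 samples: {low}")

    means = (X @ C) / counts
    rowss = (X**2).sum(axis=1)
    rss1 = np.maximum(rowss - (means**2 * counts).sum(axis=1), 0.0)
    df_resid = X.shape[1] - len(cells)
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom in the design")
    s2 = rss1 / df_resid

    if prior_df == 0:
        if (s2 == 0).any():
            bad = fids[s2 == 0].tolist()
            raise ValueError(
                "zero residual variance with moderation disabled for "
                f"feature(s): {bad[:5]}"
            )
        s2_prior, s2_post = float("nan"), s2
    else:
        positive = s2 > 0
        if not positive.any():
            raise ValueError("all features have zero residual variance")
        d = df_resid
        e = np.log(s2[positive]) - special.digamma(d / 2.0) + np.log(d / 2.0)
        s2_prior = float(
            np.exp(e.mean() + special.digamma(prior_df / 2.0) - np.log(prior_df / 2.0))
        )
        s2_post = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)

    return _CellFit(fids, cells, counts, means, s2, s2_post, df_resid, prior_df, s2_prior)


# ---------------------------------------------------------------------------
# timewise statistics
# ---------------------------------------------------------------------------

def timewise_stats(
    matrix: FeatureMatrix, design: StudyDesign, prior_df: float = 4.0
) -> pd.DataFrame:
    """Per-feature, per sex x time effects of training versus controls.

    Returns a tidy frame with columns ``feature, sex, time, logFC, SE, z, p``
    (time in weeks).  ``logFC`` is the difference of cell means against the
    sex-matched control cell, ``SE`` uses the moderated pooled variance, and
    ``p`` is two-sided from a t distribution with residual + prior df.
    """
    fit = _fit_cells(matrix, design, prior_df)
    idx = {c: i for i, c in enumerate(fit.cells)}
    frames = []
    for sex in SEXES:
        if (sex, "control") not in idx:
            continue
        ctrl = idx[(sex, "control")]
        n_ctrl = fit.counts[ctrl]
        for group in TRAINED_GROUPS:
            if (sex, group) not in idx:
                continue
            j = idx[(sex, group)]
            logfc = fit.means[:, j] - fit.means[:, ctrl]
            se = np.sqrt(fit.s2_post * (1.0 / fit.counts[j] + 1.0 / n_ctrl))
            z = np.divide(logfc, se, out=np.zeros_like(logfc), where=se > 0)
            p = np.clip(2.0 * stats.t.sf(np.abs(z), df=fit.df_total), _TINY, 1.0)
            frames.append(
                pd.DataFrame(
                    {
                        "feature": fit.feature_ids,
                        "sex": sex,
                        "time": WEEK_FOR_GROUP[group],
                        "logFC": logfc,
                        "SE": se,
                        "z": z,
                        "p": p,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["feature", "sex", "time"], kind="stable").reset_index(drop=True)


def training_pvalue(
    matrix: FeatureMatrix, design: StudyDesign, prior_df: float = 4.0
) -> tuple[pd.Series, dict[str, str]]:
    """Joint moderated F-test that all sex x time training effects are zero.

    The null model fits one mean per sex; the full model one mean per
    sex x group cell.  Returns the per-feature p-values plus a map of
    excluded features to the reason (constant features cannot be tested).
    """
    fit = _fit_cells(matrix, design, prior_df)
    X = matrix.data.loc[fit.feature_ids].to_numpy(dtype=float)
    sex, _ = _aligned_labels(matrix, design)

    rowss = (X**2).sum(axis=1)
    rss1 = fit.s2 * fit.df_resid
    rss0 = rowss.copy()
    for s in sorted(set(sex)):
        cols = sex == s
        m = X[:, cols].mean(axis=1)
        rss0 -= m**2 * cols.sum()
    rss0 = np.maximum(rss0, 0.0)

    n_trained = sum(1 for _, g in fit.cells if g != "control")
    constant = X.std(axis=1) == 0.0
    excluded = {fid: "constant across all samples" for fid in fit.feature_ids[constant]}
    excluded.update({fid: "zero variance" for fid in matrix.zero_variance})

    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = ((rss0 - rss1) / n_trained) / fit.s2_post
    p = np.clip(stats.f.sf(fstat, n_trained, fit.df_total), _TINY, 1.0)
    keep = ~constant
    return pd.Series(p[keep], index=fit.feature_ids[keep], name="p"), excluded


# ---------------------------------------------------------------------------
# FDR selection
# ---------------------------------------------------------------------------

def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return stats.false_discovery_control(p, method="bh")


def select_training_regulated(pvalues: pd.Series, fdr: float = 0.05) -> pd.DataFrame:
    """BH selection of training-regulated features at the given FDR.

    ``pvalues`` is one tissue x ome stratum (the multiple-testing universe);
    callers with several datasets apply this per stratum.  Returns a frame
    with columns ``feature, p, q, selected``.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must lie in (0, 1)")
    q = bh_qvalues(pvalues.to_numpy())
    return pd.DataFrame(
        {
            "feature": pvalues.index,
            "p": pvalues.to_numpy(),
            "q": q,
            "selected": q <= fdr,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# permutation validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    observed: int
    permuted: np.ndarray
    empirical_p: float  # fraction of permutations with count >= observed
    mode: str
    n_perm: int


def _permuted_design(design: StudyDesign, matrix: FeatureMatrix, mode: str,
                     rng: np.random.Generator) -> StudyDesign:
    df = design.samples.copy()
    in_matrix = df["sample_id"].isin(matrix.sample_ids)
    if mode == "group":
        for s in SEXES:
            sel = (in_matrix & (df["sex"] == s)).to_numpy()
            if sel.any():
                df.loc[sel, "group"] = rng.permutation(df.loc[sel, "group"].to_numpy())
    elif mode == "sex":
        for g in df.loc[in_matrix, "group"].unique():
            sel = (in_matrix & (df["group"] == g)).to_numpy()
            if sel.any():
                df.loc[sel, "sex"] = rng.permutation(df.loc[sel, "sex"].to_numpy())
    else:
        raise ValueError(f"unknown permutation mode {mode!r}; use 'group' or 'sex'")
    return StudyDesign(df)


def _selection_count(matrix: FeatureMatrix, design: StudyDesign, fdr: float,
                     prior_df: float) -> int:
    p, _ = training_pvalue(matrix, design, prior_df=prior_df)
    if p.empty:
        return 0
    return int(select_training_regulated(p, fdr=fdr)["selected"].sum())


def permutation_selection_counts(
    matrix: FeatureMatrix,
    design: StudyDesign,
    mode: str = "group",
    n_perm: int = 50,
    seed: int = 0,
    fdr: float = 0.05,
    prior_df: float = 4.0,
) -> PermutationResult:
    """Re-run selection under label permutations to validate the count.

    Group labels are permuted within each sex (mode ``group``) or sex labels
    within each group (mode ``sex``); the full training-p + BH pipeline is
    recomputed per permutation.  ``empirical_p`` is the fraction of permuted
    selection counts at least as large as the observed count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if mode not in ("group", "sex"):
        raise ValueError(f"unknown permutation mode {mode!r}; use 'group' or 'sex'")
    rng = np.random.default_rng(seed)
    observed = _selection_count(matrix, design, fdr, prior_df)
    permuted = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        permuted[b] = _selection_count(
            matrix, _permuted_design(design, matrix, mode, rng), fdr, prior_df
        )
    empirical_p = float((permuted >= observed).mean())
    return PermutationResult(observed, permuted, empirical_p, mode, n_perm)


# ---------------------------------------------------------------------------
# fold-change summaries
# ---------------------------------------------------------------------------

def fold_change_band_fraction(
    timewise: pd.DataFrame,
    selected: set[str] | list[str],
    lo: float = 1 / 1.5,
    hi: float = 1.5,
) -> float:
    """Fraction of selected features whose extreme fold change is inside (lo, hi).

    Per feature, the linear fold change is ``2**logFC`` at the (sex, time)
    cell with the largest |logFC|.  The default band (1/1.5, 1.5) captures
    "modest" training effects.
    """
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    selected = set(selected)
    if not selected:
        raise ValueError("empty selection")
    sub = timewise[timewise["feature"].isin(selected)]
    if sub.empty:
        raise ValueError("selected features absent from timewise statistics")
    extreme = sub.loc[sub.groupby("feature")["logFC"].apply(lambda s: s.abs().idxmax())]
    fc = np.exp2(extreme["logFC"].to_numpy())
    return float(((fc > lo) & (fc < hi)).mean())


def z_wide(timewise: pd.DataFrame, sex: str, time: int) -> pd.Series:
    """Feature-indexed z-scores for one (sex, time) cell (helper for states)."""
    sub = timewise[(timewise["sex"] == sex) & (timewise["time"] == time)]
    if sub.empty:
        raise KeyError(f"no timewise cell for sex={sex!r}, time={time}")
    return sub.set_index("feature")["z"]
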