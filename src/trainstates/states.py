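"""Empirical Bayes assignment of features to joint (female, male) states.

At each training time point a feature's pair of sex-specific z-scores
``(zF, zM)`` is modelled as a nine-component mixture over the joint states
``(f, m)`` with ``f, m ∈ {-1, 0, +1}``: each sex contributes a null
component fixed at N(0, 1) and free down/up Gaussian components with
sign-constrained means, and the joint density factorizes given the state:

    f(zF, zM) = sum_{(a,b)} pi_{ab} * phi_a(zF) * phi_b(zM)

The mixture weights ``pi`` and the four alternative components (per sex:
down mean/SD, up mean/SD) are fit by EM; posterior state probabilities are
the local-fdr style quantities used downstream, and the per-time argmax
states concatenate into a feature's path, written with node labels such as
``8w_F1_M1`` (up-regulated in both sexes at 8 weeks).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import WEEKS

#: The nine joint states in lexicographic order over {-1, 0, 1}^2.
STATES: tuple[tuple[int, int], ...] = tuple(
    (f, m) for f in (-1, 0, 1) for m in (-1, 0, 1)
)
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
NULL_STATE = (0, 0)

_LEVELS = (-1, 0, 1)
_LABEL_RE = re.compile(r"^(\d+)w_F(-1|0|1)_M(-1|0|1)$")


# ---------------------------------------------------------------------------
# node and path labels
# ---------------------------------------------------------------------------

def node_label(week: int, f: int, m: int) -> str:
    """Canonical node label, e.g. ``node_label(8, 1, 1) == "8w_F1_M1"``."""
    if week not in WEEKS:
        raise ValueError(f"week must be one of {WEEKS}, got {week}")
    if f not in _LEVELS or m not in _LEVELS:
        raise ValueError(f"states must be in {{-1, 0, 1}}, got ({f}, {m})")
    return f"{week}w_F{f}_M{m}"


def parse_node_label(label: str) -> tuple[int, int, int]:
    """Inverse of :func:`node_label`; raises on malformed labels."""
    match = _LABEL_RE.match(label)
    if not match:
        raise ValueError(f"malformed node label: {label!r}")
    week, f, m = (int(g) for g in match.groups())
    if week not in WEEKS:
        raise ValueError(f"malformed node label (bad week): {label!r}")
    return week, f, m


def path_label(path) -> str:
    """Join the four per-week node labels with ``->``."""
    if len(path) != len(WEEKS):
        raise ValueError(f"a path needs {len(WEEKS)} states, got {len(path)}")
    return "->".join(node_label(w, f, m) for w, (f, m) in zip(WEEKS, path))


def parse_path_label(label: str) -> tuple[tuple[int, int], ...]:
    parts = label.split("->")
    if len(parts) != len(WEEKS):
        raise ValueError(f"malformed path label: {label!r}")
    states = []
    for expected_week, part in zip(WEEKS, parts):
        week, f, m = parse_node_label(part)
        if week != expected_week:
            raise ValueError(f"path weeks out of order in {label!r}")
        states.append((f, m))
    return tuple(states)


# ---------------------------------------------------------------------------
# mixture model
# ---------------------------------------------------------------------------

@dataclass
class StateModelParams:
    """Fitted mixture for one time point.

    ``pi`` holds the nine state weights in ``STATES`` order; per sex the
    down/up alternative components are Gaussians with sign-constrained means
    (down mean < 0 < up mean); the null component is fixed at N(0, 1).
    """

    pi: np.ndarray
    f_components: dict[int, tuple[float, float]]  # state level -> (mean, sd)
    m_components: dict[int, tuple[float, float]]
    log_likelihood: float = float("nan")
    n_iter: int = 0
    time: int | None = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (9,):
            raise ValueError("pi must have 9 entries")
        if (self.pi < 0).any() or abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("pi must be a distribution over the 9 states")
        for comps in (self.f_components, self.m_components):
            if set(comps) != set(_LEVELS):
                raise ValueError("components required for levels -1, 0, 1")
            if comps[0] != (0.0, 1.0):
                raise ValueError("null component must be N(0, 1)")
            if not (comps[-1][0] < 0.0 < comps[1][0]):
                raise ValueError("need down mean < 0 < up mean")
            if comps[-1][1] <= 0 or comps[1][1] <= 0:
                raise ValueError("component SDs must be positive")


def _component_densities(z: np.ndarray, comps: dict[int, tuple[float, float]]) -> np.ndarray:
    """n x 3 Gaussian densities at z for levels (-1, 0, 1)."""
    out = np.empty((z.size, 3))
    for j, level in enumerate(_LEVELS):
        mu, sd = comps[level]
        out[:, j] = np.exp(-0.5 * ((z - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    return out


def _joint_densities(zf: np.ndarray, zm: np.ndarray,
                     params: StateModelParams) -> np.ndarray:
    """n x 9 per-state joint densities phi_a(zF) * phi_b(zM)."""
    df = _component_densities(zf, params.f_components)
    dm = _component_densities(zm, params.m_components)
    cols = [
        df[:, _LEVELS.index(a)] * dm[:, _LEVELS.index(b)] for a, b in STATES
    ]
    return np.column_stack(cols)


def _em_once(
    zf: np.ndarray,
    zm: np.ndarray,
    init: StateModelParams,
    max_iter: int,
    tol: float,
    min_mu: float,
    min_sd: float,
) -> StateModelParams:
    params = StateModelParams(
        init.pi.copy(), dict(init.f_components), dict(init.m_components)
    )
    n = zf.size
    loglik = -np.inf
    for iteration in range(1, max_iter + 1):
        dens = _joint_densities(zf, zm, params)
        weighted = dens * params.pi
        total = weighted.sum(axis=1)
        total = np.maximum(total, np.finfo(float).tiny)
        new_loglik = float(np.log(total).sum())
        resp = weighted / total[:, None]

        params.pi = resp.mean(axis=0)
        for sex_axis, comps, z in (("F", params.f_components, zf),
                                   ("M", params.m_components, zm)):
            for level in (-1, 1):
                if sex_axis == "F":
                    cols = [STATE_INDEX[(level, b)] for b in _LEVELS]
                else:
                    cols = [STATE_INDEX[(a, level)] for a in _LEVELS]
                w = resp[:, cols].sum(axis=1)
                w_sum = w.sum()
                if w_sum < 1e-10 * n:
                    continue  # empty component: keep current parameters
                mu = float((w * z).sum() / w_sum)
                # constrained M-step: clip the mean into its half-space,
                # then take the variance around the clipped mean (the exact
                # box-constrained maximizer, so the likelihood stays monotone)
                mu = max(mu, min_mu) if level == 1 else min(mu, -min_mu)
                var = float((w * (z - mu) ** 2).sum() / w_sum)
                comps[level] = (mu, max(np.sqrt(var), min_sd))

        if new_loglik - loglik <= tol * (abs(loglik) + tol) and iteration > 1:
            loglik = new_loglik
            params.n_iter = iteration
            break
        loglik = new_loglik
        params.n_iter = iteration
    params.log_likelihood = loglik
    return params


def _default_init(rng: np.random.Generator | None = None) -> StateModelParams:
    pi = np.full(9, 0.2 / 8.0)
    pi[STATE_INDEX[NULL_STATE]] = 0.8
    mu_up, mu_dn = 3.0, -3.0
    if rng is not None:  # perturbed restart
        mu_up = float(rng.uniform(1.0, 6.0))
        mu_dn = float(-rng.uniform(1.0, 6.0))
    comps = {-1: (mu_dn, 1.0), 0: (0.0, 1.0), 1: (mu_up, 1.0)}
    return StateModelParams(pi, dict(comps), dict(comps))


def fit_state_model(
    zf: np.ndarray,
    zm: np.ndarray,
    time: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_restarts: int = 3,
    seed: int = 0,
    min_mu: float = 1.0,
    min_sd: float = 1.0,
) -> StateModelParams:
    """Fit the nine-state mixture to one time point's (zF, zM) pairs by EM.

    The null component is held at N(0, 1).  The per-sex up/down components
    are Gaussians whose means are constrained at least ``min_mu`` away from
    zero on the correct side and whose SDs are at least ``min_sd``: an
    alternative z-score is true effect plus unit sampling noise, so its
    marginal SD cannot fall below 1, and bounding the means away from zero
    keeps the alternatives identifiable against the fixed null.  If a
    converged solution still violates the sign constraint, up to
    ``n_restarts`` perturbed re-initializations are tried before failing.
    Fixed inputs and seed give identical parameters.
    """
    zf = np.asarray(zf, dtype=float).ravel()
    zm = np.asarray(zm, dtype=float).ravel()
    if zf.shape != zm.shape:
        raise ValueError("zF and zM must have equal length")
    if zf.size < 10:
        raise ValueError(f"need at least 10 features to fit the mixture, got {zf.size}")
    if not (np.isfinite(zf).all() and np.isfinite(zm).all()):
        raise ValueError("z-scores must be finite")

    rng = np.random.default_rng(seed)
    attempts = [_default_init()] + [_default_init(rng) for _ in range(n_restarts)]
    last_error = None
    for init in attempts:
        fitted = _em_once(zf, zm, init, max_iter, tol, min_mu, min_sd)
        ok = all(
            comps[-1][0] < 0.0 < comps[1][0]
            for comps in (fitted.f_components, fitted.m_components)
        )
        if ok:
            fitted.time = time
            return fitted
        last_error = "sign constraint on component means violated"
    raise RuntimeError(f"EM failed after {n_restarts} restarts: {last_error}")


def posterior_states(
    zf: np.ndarray, zm: np.ndarray, params: StateModelParams
) -> np.ndarray:
    """Posterior probabilities over the nine joint states (n x 9, rows sum to 1)."""
    zf = np.asarray(zf, dtype=float).ravel()
    zm = np.asarray(zm, dtype=float).ravel()
    if not (np.isfinite(zf).all() and np.isfinite(zm).all()):
        raise ValueError("z-scores must be finite")
    weighted = _joint_densities(zf, zm, params) * params.pi
    total = np.maximum(weighted.sum(axis=1), np.finfo(float).tiny)
    return weighted / total[:, None]


def posterior_frame(
    feature_ids, time: int, posteriors: np.ndarray
) -> pd.DataFrame:
    """Tidy posterior table: feature, time, and one column per state."""
    cols = {f"p_F{f}_M{m}": posteriors[:, i] for i, (f, m) in enumerate(STATES)}
    return pd.DataFrame({"feature": list(feature_ids), "time": time, **cols})


# ---------------------------------------------------------------------------
# path assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathAssignment:
    feature_id: str
    states: tuple[tuple[int, int], ...]
    label: str
    min_posterior: float
    tied: bool


def assign_path(posteriors: pd.DataFrame) -> pd.DataFrame:
    """Assign each feature its per-time argmax state and canonical path label.

    ``posteriors`` is the concatenation of :func:`posterior_frame` outputs
    over all four time points.  Exact ties at the maximum are resolved to
    the null state and flagged.  Returns a frame with columns ``feature,
    state_1w..state_8w, label, min_posterior, tied``.
    """
    state_cols = [f"p_F{f}_M{m}" for f, m in STATES]
    missing_cols = [c for c in ("feature", "time", *state_cols) if c not in posteriors.columns]
    if missing_cols:
        raise ValueError(f"posterior table is missing columns: {missing_cols}")

    rows = []
    for fid, sub in posteriors.groupby("feature", sort=True):
        times = set(sub["time"])
        if times != set(WEEKS):
            missing = sorted(set(WEEKS) - times)
            raise ValueError(f"feature {fid!r} is missing time point(s): {missing}")
        states, min_post, tied = [], 1.0, False
        for week in WEEKS:
            probs = sub.loc[sub["time"] == week, state_cols].to_numpy(dtype=float)[0]
            top = probs.max()
            winners = np.nonzero(probs == top)[0]
            if winners.size > 1:
                states.append(NULL_STATE)
                tied = True
            else:
                states.append(STATES[int(winners[0])])
            min_post = min(min_post, float(top))
        rows.append(
            {
                "feature": fid,
                **{f"state_{w}w": node_label(w, f, m).split("_", 1)[1]
                   for w, (f, m) in zip(WEEKS, states)},
                "label": path_label(states),
                "min_posterior": min_post,
                "tied": tied,
            }
        )
    return pd.DataFrame(rows)


def assignment_states(assignment_row: pd.Series) -> tuple[tuple[int, int], ...]:
    """Recover the 4-tuple of (f, m) states from an assignment table row."""
    return parse_path_label(assignment_row["label"])
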