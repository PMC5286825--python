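"""Pathway activity inference, discretization and binary encoding.

A pathway's activity in a sample is the averaged z-score of its
condition-responsive genes (CORG): member genes are ranked by the absolute
class-contrast t statistic and greedily accumulated — each gene sign-aligned
so its class difference points the same way — for as long as the
discriminative score of the running activity
``a_S = sum_{g in S} z_g / sqrt(|S|)`` strictly improves.

Continuous activities are discretized to -1/+1 against the per-pathway
median and then encoded as a 2n-bit transaction matrix: bit ``i`` (i < n)
is set when pathway i is up-regulated (or hyper-methylated) in the sample,
bit ``n + i`` when it is down-regulated (hypo-methylated).  Exactly one of
the two bits is set per pathway and sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .enrichment import tstat_score
from .io_formats import CASE, CONTROL, GeneSetCollection, OmicsMatrix

logger = logging.getLogger(__name__)

UP_SUFFIX = ":up"
DOWN_SUFFIX = ":down"


@dataclass
class PathwayActivityProfile:
    """Continuous pathway-by-sample activities plus the CORG per pathway."""

    activities: pd.DataFrame
    corg: dict[str, list[str]] = field(default_factory=dict)
    corg_signs: dict[str, list[int]] = field(default_factory=dict)
    datatype: str = "expression"

    @property
    def pathways(self) -> list[str]:
        return list(self.activities.index)

    @property
    def samples(self) -> list[str]:
        return list(self.activities.columns)


@dataclass
class DiscretizedActivity:
    """Pathway-by-sample states in {-1, +1}."""

    states: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.states.to_numpy()
        if not np.isin(vals, (-1, 1)).all():
            raise ValueError("discretized states must be -1 or +1")


@dataclass
class BinaryTransactionMatrix:
    """2n-item binary matrix: items ``P:up`` (first n) then ``P:down``."""

    bits: pd.DataFrame
    n_pathways: int

    @property
    def pathways(self) -> list[str]:
        return [i[: -len(UP_SUFFIX)] for i in self.bits.index[: self.n_pathways]]

    @property
    def items(self) -> list[str]:
        return list(self.bits.index)

    @property
    def samples(self) -> list[str]:
        return list(self.bits.columns)


def parse_item(item: str) -> tuple[str, int]:
    """Split a signed item name into (pathway, direction in {+1,-1})."""
    if item.endswith(UP_SUFFIX):
        return item[: -len(UP_SUFFIX)], 1
    if item.endswith(DOWN_SUFFIX):
        return item[: -len(DOWN_SUFFIX)], -1
    raise ValueError(f"item {item!r} lacks an :up/:down suffix")


def make_item(pathway: str, direction: int) -> str:
    return pathway + (UP_SUFFIX if direction > 0 else DOWN_SUFFIX)


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of s2 ~ s0^2 * F(df, d0) on the log scale.

    Returns (d0, s0^2); d0 = inf means complete shrinkage to s0^2.
    """
    s2 = np.maximum(s2, 0.0)
    m = np.median(s2)
    if m == 0:
        m = 1.0
    s2 = np.maximum(s2, 1e-5 * m)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(s2.mean())
    return d0, s0_2


def _moderated(values: np.ndarray, is_case: np.ndarray,
               min_features_for_prior: int = 30,
               ) -> tuple[np.ndarray, float]:
    """(moderated t per row, total degrees of freedom d + d0)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    is_case = np.asarray(is_case, dtype=bool)
    a = values[:, is_case]
    b = values[:, ~is_case]
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each class needs >=2 samples")
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / df
    if values.shape[0] >= min_features_for_prior:
        d0, s0_2 = _fit_f_dist(s2, df)
    else:
        d0, s0_2 = 0.0, 0.0
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_2)
    else:
        s2_tilde = (d0 * s0_2 + df * s2) / (d0 + df)
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    se = np.maximum(se, 1e-300)
    # total df capped at the pooled residual df across features
    df_total = min(df + d0, values.shape[0] * df)
    return (a.mean(axis=1) - b.mean(axis=1)) / se, df_total


def moderated_t_matrix(values: np.ndarray, is_case: np.ndarray,
                       min_features_for_prior: int = 30) -> np.ndarray:
    """Empirical-Bayes moderated two-sample t for every row of ``values``.

    The pooled per-feature variance ``s^2`` (df = n1+n2-2) is shrunk toward
    a prior ``s0^2`` with weight ``d0`` estimated across features by
    method of moments on the log variances; with fewer than
    ``min_features_for_prior`` features no shrinkage is applied (d0 = 0).
    """
    return _moderated(values, is_case, min_features_for_prior)[0]


def moderated_t_test(values: np.ndarray, is_case: np.ndarray,
                     min_features_for_prior: int = 30,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t per row plus its two-sided p-value on d + d0 df."""
    from scipy import stats as _stats

    t, df_total = _moderated(values, is_case, min_features_for_prior)
    if np.isinf(df_total):
        p = 2.0 * _stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * _stats.t.sf(np.abs(t), df_total)
    return t, p


def moderated_t(values, labels: Mapping[str, str] | np.ndarray) -> float:
    """Moderated t for a single feature; with one vector there is no prior
    to borrow from, so this is the ordinary pooled-variance t."""
    if isinstance(values, pd.Series):
        is_case = np.array([labels[s] == CASE for s in values.index])
        vec = values.to_numpy(dtype=float)
    else:
        vec = np.asarray(values, dtype=float)
        is_case = np.asarray(labels, dtype=bool)
    return float(moderated_t_matrix(vec[None, :], is_case)[0])


# ---------------------------------------------------------------------------
# greedy CORG combination


def _greedy_combine(rows: np.ndarray, score_rows: np.ndarray,
                    combined_score: Callable[[np.ndarray], float],
                    ) -> tuple[list[int], list[int], list[float]]:
    """Greedy sign-aligned accumulation of rows maximizing a running score.

    ``rows`` are combined on the columns used for scoring; ``score_rows``
    gives each row's own discriminative statistic (sign + ranking).
    Returns (selected row indices, signs, accepted score trajectory).
    """
    order = np.argsort(-np.abs(score_rows), kind="stable")
    signs_all = np.where(score_rows >= 0, 1, -1)
    selected: list[int] = []
    signs: list[int] = []
    trajectory: list[float] = []
    running = np.zeros(rows.shape[1])
    best = -np.inf
    for idx in order:
        cand = running + signs_all[idx] * rows[idx]
        k = len(selected) + 1
        score = abs(combined_score(cand / np.sqrt(k)))
        if score > best:
            selected.append(int(idx))
            signs.append(int(signs_all[idx]))
            trajectory.append(score)
            running = cand
            best = score
        else:
            break
    return selected, signs, trajectory


def infer_pathway_activity(matrix: OmicsMatrix, gene_set: Sequence[str],
                           ) -> tuple[pd.Series, list[str], list[int]]:
    """CORG activity of one pathway: (activity over samples, genes, signs).

    Member genes are z-scored, ranked by |Welch t| and greedily accumulated
    while the Welch t of the running mean activity strictly improves.
    """
    present = [g for g in gene_set if g in matrix.values.index]
    if not present:
        raise ValueError("no member gene of the set is present in the matrix")
    sub = matrix.values.loc[present].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all member genes are constant across samples")
    present = [g for g, k in zip(present, keep) if k]
    sub = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    is_case = matrix.label_vector()

    def welch(v: np.ndarray) -> float:
        return tstat_score(v[is_case], v[~is_case])

    gene_t = np.array([welch(row) for row in sub])
    sel, signs, _ = _greedy_combine(sub, gene_t, welch)
    # orient the activity to the pathway's dominant response direction so
    # that a coherently down-regulated pathway has LOWER activity in cases;
    # the sign-aligned sum itself always discriminates case-upward
    orient = signs[0]
    multipliers = [orient * s for s in signs]
    activity = (sub[sel] * np.array(multipliers)[:, None]).sum(axis=0) / np.sqrt(len(sel))
    return (pd.Series(activity, index=matrix.values.columns),
            [present[i] for i in sel], multipliers)


def pathway_activity_profile(matrix: OmicsMatrix, gene_sets: GeneSetCollection,
                             pathways: Sequence[str] | None = None,
                             ) -> PathwayActivityProfile:
    """Infer CORG activities for each listed pathway (default: whole collection)."""
    if pathways is None:
        pathways = sorted(gene_sets.sets)
    rows, corg, corg_signs = {}, {}, {}
    for pid in pathways:
        try:
            act, genes, signs = infer_pathway_activity(matrix, gene_sets.sets[pid])
        except ValueError as exc:
            logger.warning("skipping pathway %s: %s", pid, exc)
            continue
        rows[pid] = act
        corg[pid] = genes
        corg_signs[pid] = signs
    if not rows:
        raise ValueError("no pathway could be scored against the matrix")
    activities = pd.DataFrame(rows).T
    activities.index.name = "pathway"
    return PathwayActivityProfile(activities, corg, corg_signs, matrix.datatype)


def pathway_set_activity(profile: PathwayActivityProfile,
                         labels: Mapping[str, str],
                         pathway_set: Sequence[str],
                         fit_samples: Sequence[str] | None = None,
                         ) -> pd.Series:
    """Combined activity of a signed pathway-set (items like ``P:up``).

    The same greedy scheme as gene-level CORG runs over the sign-aligned
    pathway activity rows, scored by the moderated t (which for a single
    combined vector reduces to the pooled two-sample t).  When
    ``fit_samples`` is given, the combination is selected on those samples
    only and then applied to every sample (used for fold-internal refits).
    """
    if not pathway_set:
        raise ValueError("empty pathway set")
    parsed = [parse_item(i) for i in pathway_set]
    missing = [p for p, _ in parsed if p not in profile.activities.index]
    if missing:
        raise KeyError(f"pathways missing from profile: {missing}")
    rows_all = np.stack([
        d * profile.activities.loc[p].to_numpy(dtype=float) for p, d in parsed
    ])
    samples = profile.samples
    if fit_samples is None:
        fit_idx = np.arange(len(samples))
    else:
        pos = {s: i for i, s in enumerate(samples)}
        fit_idx = np.array([pos[s] for s in fit_samples])
    is_case_fit = np.array([labels[samples[i]] == CASE for i in fit_idx])
    fit_rows = rows_all[:, fit_idx]

    def score(v: np.ndarray) -> float:
        return moderated_t(v, is_case_fit)

    row_t = moderated_t_matrix(fit_rows, is_case_fit)
    sel, signs, _ = _greedy_combine(fit_rows, row_t, score)
    # orient to the top-ranked row's declared direction: a singleton
    # {P:down} set yields exactly the sign-flipped activity of P
    orient = signs[0]
    multipliers = np.array([orient * s for s in signs])
    combined = (rows_all[sel] * multipliers[:, None]).sum(axis=0) / np.sqrt(len(sel))
    return pd.Series(combined, index=samples)


# ---------------------------------------------------------------------------
# discretization / binarization


def discretize_activity(profile: PathwayActivityProfile) -> DiscretizedActivity:
    """Threshold each activity row at its median: above -> +1, else -> -1."""
    vals = profile.activities
    med = vals.median(axis=1)
    states = vals.gt(med, axis=0).astype(int) * 2 - 1
    return DiscretizedActivity(states)


def binarize(states: DiscretizedActivity) -> BinaryTransactionMatrix:
    """Encode -1/+1 states as the 2n-bit up/down transaction matrix."""
    s = states.states
    up = (s == 1).astype(int)
    down = (s == -1).astype(int)
    up.index = [make_item(p, 1) for p in s.index]
    down.index = [make_item(p, -1) for p in s.index]
    bits = pd.concat([up, down])
    return BinaryTransactionMatrix(bits, n_pathways=s.shape[0])


def decode(bits: BinaryTransactionMatrix) -> DiscretizedActivity:
    """Inverse of :func:`binarize`."""
    n = bits.n_pathways
    up = bits.bits.iloc[:n]
    down = bits.bits.iloc[n:]
    if not ((up.to_numpy() + down.to_numpy()) == 1).all():
        raise ValueError("invalid encoding: up/down bits are not complementary")
    states = up.to_numpy() * 2 - 1
    return DiscretizedActivity(
        pd.DataFrame(states, index=[parse_item(i)[0] for i in up.index],
                     columns=bits.bits.columns)
    )


# ---------------------------------------------------------------------------
# expression vs methylation


def inverse_relationship_count(expr_states: DiscretizedActivity,
                               meth_states: DiscretizedActivity,
                               labels: Mapping[str, str], klass: str,
                               ) -> tuple[int, dict[str, bool]]:
    """Count pathways whose majority state in a class is opposite between
    expression and methylation.

    Majorities are taken per datatype on its own class samples (paired
    designs may profile different sample sets); a tied majority on either
    side means the pathway is not counted as inverse.
    """
    if klass not in (CASE, CONTROL):
        raise ValueError(f"class must be case or control, got {klass!r}")
    shared = [p for p in expr_states.states.index if p in meth_states.states.index]
    if not shared:
        raise ValueError("no shared pathways between the two state matrices")
    flags: dict[str, bool] = {}
    for states in (expr_states, meth_states):
        cols = [s for s in states.states.columns if labels.get(s) == klass]
        if not cols:
            raise ValueError(f"no {klass} samples in one of the state matrices")
    for p in shared:
        maj = []
        for states in (expr_states, meth_states):
            cols = [s for s in states.states.columns if labels.get(s) == klass]
            total = int(states.states.loc[p, cols].sum())
            maj.append(0 if total == 0 else (1 if total > 0 else -1))
        flags[p] = maj[0] != 0 and maj[1] != 0 and maj[0] == -maj[1]
    return sum(flags.values()), flags
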