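"""Fold-activation scoring and many-to-one significance calling.

The screening readout for a well is the TdTomato/TagBFP2 ratio; dividing
by the mean ratio of the scramble (Scr) control wells puts every condition
on a dimensionless fold-activation scale where the control mean is exactly
1. Candidate activating conditions are then called by a one-way
fixed-effects ANOVA across all conditions followed by Dunnett's
many-to-one comparison against the scramble control, which controls the
family-wise error rate over the k treatment-vs-control contrasts with a
pooled within-group variance.

Dunnett adjusted p-values are computed from the distribution of
max_i |T_i| where (T_1..T_k) follow the equicorrelated multivariate t
implied by the common control group. With equal group sizes the
correlation is exactly 1/2 and the probability is evaluated by Gaussian
quadrature (conditioning on the control mean and the pooled scale);
unequal group sizes fall back to seeded Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .plate_io import ScreenDataset, WellRecord, parse_condition_guides

__all__ = [
    "ConditionActivation",
    "AnovaResult",
    "DunnettResult",
    "well_ratio",
    "fold_activation",
    "one_way_anova",
    "dunnett_vs_control",
    "dunnett_critical_value",
    "significance_tier",
    "activation_report",
]

#: Adjusted-p bins for the conventional significance marks * .. ****.
SIGNIFICANCE_TIERS: tuple[tuple[float, str], ...] = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)


@dataclass(frozen=True)
class ConditionActivation:
    """Replicate fold-activation values for one condition."""

    condition: str
    guides: frozenset[str]
    folds: tuple[float, ...]
    mean_fold: float
    sem_fold: float

    @classmethod
    def from_folds(
        cls, condition: str, guides: frozenset[str], folds: Sequence[float]
    ) -> "ConditionActivation":
        if len(folds) < 2:
            raise ValueError(f"condition {condition!r} needs >= 2 replicate folds")
        arr = np.asarray(folds, dtype=float)
        return cls(
            condition=condition,
            guides=guides,
            folds=tuple(arr.tolist()),
            mean_fold=float(arr.mean()),
            sem_fold=float(arr.std(ddof=1) / math.sqrt(arr.size)),
        )


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class DunnettResult:
    condition: str
    raw_p: float
    adjusted_p: float
    significant: bool


def well_ratio(well: WellRecord) -> float:
    """TdTomato/TagBFP2 ratio of a single well (transfection-normalised)."""
    if well.tagbfp_au <= 0:
        raise ValueError(f"tagbfp_au must be > 0 for {well.plate_id}/{well.well_id}")
    return well.tdtomato_au / well.tagbfp_au


def fold_activation(dataset: ScreenDataset) -> list[ConditionActivation]:
    """Fold activation of every condition relative to the scramble baseline.

    The baseline is the arithmetic mean of the control wells' ratios; each
    well's fold is its ratio divided by that baseline, so the control
    condition's mean fold is exactly 1 by construction.
    """
    control_ratios = [well_ratio(w) for w in dataset.replicate_map[dataset.control_condition]]
    baseline = float(np.mean(control_ratios))
    if baseline == 0:
        raise ValueError("scramble baseline ratio is zero; folds undefined")
    out = []
    for condition, wells in dataset.replicate_map.items():
        folds = [well_ratio(w) / baseline for w in wells]
        guides = parse_condition_guides(condition, dataset.control_condition)
        out.append(ConditionActivation.from_folds(condition, guides, folds))
    return out


# ---------------------------------------------------------------------------
# One-way ANOVA

def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA over per-condition fold values."""
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs >= 2 groups")
    arrays = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        arrays[name] = arr
    allv = np.concatenate(list(arrays.values()))
    grand = allv.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_between = len(arrays) - 1
    df_within = allv.size - len(arrays)
    if ssw == 0 and ssb == 0:
        raise ValueError("all values identical within and between groups; F undefined")
    if ssw == 0:
        return AnovaResult(math.inf, df_between, df_within, 0.0)
    f = (ssb / df_between) / (ssw / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), df_between, df_within, p)


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparison

_N_NODES = 48


@lru_cache(maxsize=64)
def _dunnett_nodes(df: int, n_nodes: int = _N_NODES, tail: float = 1e-13):
    """Quadrature nodes: Gauss-Hermite for the shared control-mean component,
    Gauss-Legendre against the explicit chi density (pooled scale, truncated
    where the density mass drops below ``tail``)."""
    from scipy.special import ndtr  # noqa: F401  (imported for callers)

    x, wx = np.polynomial.hermite.hermgauss(n_nodes)
    z = x * math.sqrt(2.0)  # nodes for standard normal
    wz = wx / math.sqrt(math.pi)
    lo = math.sqrt(stats.chi2.ppf(tail, df) / df)
    hi = math.sqrt(stats.chi2.isf(tail, df) / df)
    u, wu = np.polynomial.legendre.leggauss(n_nodes)
    w = 0.5 * (hi - lo) * u + 0.5 * (hi + lo)  # pooled sd / true sd
    dens = 2.0 * df * w * stats.chi2.pdf(df * w**2, df)
    return z, wz, w, 0.5 * (hi - lo) * wu * dens


def _max_abs_t_cdf_equal(q: np.ndarray, k: int, df: int) -> np.ndarray:
    """P(max_i |T_i| <= q) for k equicorrelated (rho=1/2) Dunnett t statistics
    with pooled df, equal group sizes."""
    from scipy.special import ndtr

    z, wz, w, wu = _dunnett_nodes(df)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    # shape (nz, nw, nq)
    half = math.sqrt(2.0) * q[None, None, :] * w[None, :, None]
    zz = z[:, None, None]
    inner = ndtr(zz + half) - ndtr(zz - half)
    probs = np.einsum("i,j,ijq->q", wz, wu, inner**k)
    return np.clip(probs, 0.0, 1.0)


def _max_t_cdf_equal_greater(q: np.ndarray, k: int, df: int) -> np.ndarray:
    """P(max_i T_i <= q), one-sided-greater variant."""
    from scipy.special import ndtr

    z, wz, w, wu = _dunnett_nodes(df)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    upper = z[:, None, None] + math.sqrt(2.0) * q[None, None, :] * w[None, :, None]
    inner = ndtr(upper)
    probs = np.einsum("i,j,ijq->q", wz, wu, inner**k)
    return np.clip(probs, 0.0, 1.0)


def dunnett_critical_value(k: int, df: int, alpha: float = 0.05) -> float:
    """Two-sided Dunnett critical value q with P(max|T_i| > q) = alpha
    (equal group sizes, correlation 1/2)."""
    from scipy.optimize import brentq

    return float(
        brentq(lambda q: _max_abs_t_cdf_equal(np.array([q]), k, df)[0] - (1 - alpha), 1e-6, 50.0)
    )


def dunnett_vs_control(
    groups: Mapping[str, Sequence[float]],
    control_label: str,
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> list[DunnettResult]:
    """Dunnett's test of every non-control group mean against the control.

    Uses the pooled within-group variance across all groups. With equal
    group sizes the adjusted p-values come from the exact equicorrelated
    formulation (quadrature); otherwise from ``n_mc`` seeded Monte Carlo
    draws of the null max-|T| distribution (``seed`` then mandatory).
    Monte-Carlo adjusted p-values are floored at the raw p so the
    adjusted >= raw invariant always holds.
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    if alternative not in {"two-sided", "greater"}:
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    names = [g for g in groups if g != control_label]
    if not names:
        raise ValueError("need at least one non-control group")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in groups}
    for g, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    k = len(names)
    n_total = sum(a.size for a in arrays.values())
    df = n_total - len(arrays)
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays.values())
    if ssw == 0:
        raise ValueError("zero pooled within-group variance; t statistics undefined")
    s2 = ssw / df
    ctrl = arrays[control_label]
    tstats = np.array(
        [
            (arrays[g].mean() - ctrl.mean()) / math.sqrt(s2 * (1 / arrays[g].size + 1 / ctrl.size))
            for g in names
        ]
    )
    if alternative == "two-sided":
        raw = 2.0 * stats.t.sf(np.abs(tstats), df)
    else:
        raw = stats.t.sf(tstats, df)
    sizes = {a.size for a in arrays.values()}
    if len(sizes) == 1:
        if alternative == "two-sided":
            adj = 1.0 - _max_abs_t_cdf_equal(np.abs(tstats), k, df)
        else:
            adj = 1.0 - _max_t_cdf_equal_greater(tstats, k, df)
    else:
        if seed is None:
            raise ValueError("unequal group sizes require an explicit seed for Monte Carlo")
        adj = _dunnett_adjusted_mc(
            tstats, [arrays[g].size for g in names], ctrl.size, df, n_mc, seed, alternative
        )
    adj = np.minimum(1.0, np.maximum(adj, raw))
    return [
        DunnettResult(g, float(raw[i]), float(adj[i]), bool(adj[i] < alpha))
        for i, g in enumerate(names)
    ]


def _dunnett_adjusted_mc(
    tstats: np.ndarray,
    sizes: Sequence[int],
    n0: int,
    df: int,
    n_mc: int,
    seed: int,
    alternative: str,
) -> np.ndarray:
    if n_mc < 1000:
        raise ValueError("n_mc too small for a stable Monte Carlo adjustment")
    rng = np.random.default_rng(seed)
    k = len(sizes)
    z0 = rng.standard_normal(n_mc)
    zi = rng.standard_normal((n_mc, k))
    w = np.sqrt(rng.chisquare(df, n_mc) / df)
    inv = np.array([math.sqrt(1 / n + 1 / n0) for n in sizes])
    t_null = (zi / np.sqrt(np.array(sizes)) - z0[:, None] / math.sqrt(n0)) / (w[:, None] * inv)
    stat = np.abs(t_null).max(axis=1) if alternative == "two-sided" else t_null.max(axis=1)
    obs = np.abs(tstats) if alternative == "two-sided" else tstats
    return (stat[:, None] >= obs[None, :]).mean(axis=0)


def significance_tier(adjusted_p: float) -> str:
    """Map an adjusted p to the conventional mark: **** <= 0.0001 ... * <= 0.05,
    'ns' otherwise."""
    for cut, mark in SIGNIFICANCE_TIERS:
        if adjusted_p <= cut:
            return mark
    return "ns"


def activation_report(
    activations: Sequence[ConditionActivation],
    dunnett: Sequence[DunnettResult],
    control_condition: str,
):
    """Tabular screening report: one row per condition with fold statistics,
    Dunnett adjusted p and significance tier."""
    import pandas as pd

    dmap = {d.condition: d for d in dunnett}
    rows = []
    for act in activations:
        d = dmap.get(act.condition)
        rows.append(
            {
                "condition": act.condition,
                "guides": "+".join(sorted(act.guides)) if act.guides else "",
                "n": len(act.folds),
                "mean_fold": act.mean_fold,
                "sem_fold": act.sem_fold,
                "dunnett_adj_p": d.adjusted_p if d else float("nan"),
                "significance_tier": significance_tier(d.adjusted_p)
                if d
                else ("control" if act.condition == control_condition else "ns"),
            }
        )
    return pd.DataFrame(rows)
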