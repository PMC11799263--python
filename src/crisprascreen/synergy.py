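"""Synergy and antagonism inference for dual-sgRNA conditions.

Whether two guides interact is decided in two steps. First a 2x2
fixed-effects factorial ANOVA over the four conditions (scramble, guide A
alone, guide B alone, A+B) tests the interaction term: a significant
interaction rejects the null that the two guides act independently.
Second, a response-additivity Combination Index orients the interaction:

    E = act_A + act_B        (expected additive activation)
    CI = E / act_AB          (expected over observed combined activation)

CI < 1 with a significant interaction is synergy, CI > 1 antagonism,
and a non-significant interaction is reported as independent regardless
of CI.

Note the two additivity baselines intentionally differ: the factorial
interaction contrast is zero when act_AB = act_A + act_B − act_Scr
(with the scramble mean at 1), while CI = 1 when act_AB = act_A + act_B.
Both are applied exactly as defined; reports carry both E and CI so the
discrepancy stays visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .screening import ConditionActivation

__all__ = [
    "PairDesign",
    "InteractionTestResult",
    "PairInteraction",
    "combination_index",
    "interaction_test",
    "classify_pair",
    "synergy_matrix",
    "pair_report",
]


@dataclass(frozen=True)
class PairDesign:
    """Replicate fold activations for the four cells of one guide pair."""

    guide_a: str
    guide_b: str
    folds_scr: tuple[float, ...]
    folds_a: tuple[float, ...]
    folds_b: tuple[float, ...]
    folds_ab: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("folds_scr", "folds_a", "folds_b", "folds_ab"):
            if len(getattr(self, name)) < 2:
                raise ValueError(f"{name} needs >= 2 replicate values")


@dataclass(frozen=True)
class InteractionTestResult:
    f_stat: float
    p_value: float
    ss_interaction: float
    df_interaction: int
    df_residual: int


@dataclass(frozen=True)
class PairInteraction:
    guide_a: str
    guide_b: str
    act_a: float
    act_b: float
    act_ab: float
    interaction_p: float
    expected_additive: float
    ci: float  # NaN when undefined
    classification: str  # synergistic | antagonistic | independent | undefined


def combination_index(act_a: float, act_b: float, act_ab: float) -> tuple[float, float]:
    """Expected additive activation and Combination Index for a guide pair.

    Returns ``(E, CI)`` with ``E = act_a + act_b`` and ``CI = E / act_ab``.
    A non-positive observed combined activation leaves CI undefined (NaN)
    rather than raising, so batch processing of user tables survives
    degenerate rows.
    """
    expected = act_a + act_b
    if act_ab <= 0 or not math.isfinite(act_ab):
        return expected, float("nan")
    return expected, expected / act_ab


def interaction_test(design: PairDesign) -> InteractionTestResult:
    """Interaction term of the 2x2 factorial ANOVA over the four cells.

    Factors are presence-of-A and presence-of-B; the scramble condition is
    the (absent, absent) cell. Fitted by OLS with the type-II ANOVA table
    (identical to type I/III for the interaction in a balanced design).
    A design with zero residual variance and zero interaction contrast is
    reported as p = 1 (no evidence of interaction in noiseless additive
    data); zero residual variance with a non-zero contrast as p = 0.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    cells = {
        (0, 0): design.folds_scr,
        (1, 0): design.folds_a,
        (0, 1): design.folds_b,
        (1, 1): design.folds_ab,
    }
    rows = [
        {"fold": v, "a": a, "b": b}
        for (a, b), values in cells.items()
        for v in values
    ]
    df = pd.DataFrame(rows)
    model = smf.ols("fold ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss_int = float(table.loc["C(a):C(b)", "sum_sq"])
    df_int = int(table.loc["C(a):C(b)", "df"])
    df_res = int(table.loc["Residual", "df"])
    ss_res = float(table.loc["Residual", "sum_sq"])
    if ss_res <= 1e-30 * max(1.0, abs(df["fold"]).max() ** 2):
        if ss_int <= 1e-30 * max(1.0, abs(df["fold"]).max() ** 2):
            return InteractionTestResult(0.0, 1.0, ss_int, df_int, df_res)
        return InteractionTestResult(math.inf, 0.0, ss_int, df_int, df_res)
    f = float(table.loc["C(a):C(b)", "F"])
    p = float(table.loc["C(a):C(b)", "PR(>F)"])
    return InteractionTestResult(f, p, ss_int, df_int, df_res)


def classify_pair(interaction_p: float, ci: float, alpha: float = 0.05) -> str:
    """Two-step synergy call: interaction significance gates the CI direction."""
    if ci is None or not math.isfinite(ci):
        return "undefined"
    if interaction_p < alpha and ci < 1:
        return "synergistic"
    if interaction_p < alpha and ci > 1:
        return "antagonistic"
    return "independent"


def _holm(pvals: Sequence[float]) -> list[float]:
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(pvals, method="holm")[1])


def synergy_matrix(
    activations: Sequence[ConditionActivation],
    alpha: float = 0.05,
    holm: bool = False,
) -> tuple[list[PairInteraction], list[tuple[str, str]]]:
    """Evaluate every dual-guide condition found in a screening result.

    Pairs are the conditions whose labels reference two guides; each needs
    both single-guide conditions and the scramble (empty guide set) present,
    otherwise it is skipped with a reason. Returns ``(interactions,
    skipped)`` where ``skipped`` holds ``(condition, reason)`` tuples.
    With ``holm=True`` interaction p-values are Holm-adjusted across the
    evaluated pairs before classification (off by default).
    """
    singles: dict[str, ConditionActivation] = {}
    scramble: ConditionActivation | None = None
    for act in activations:
        if len(act.guides) == 0:
            scramble = act
        elif len(act.guides) == 1:
            (g,) = act.guides
            singles[g] = act
    pairs = [a for a in activations if len(a.guides) == 2]
    results: list[PairInteraction] = []
    skipped: list[tuple[str, str]] = []
    designs: list[tuple[ConditionActivation, str, str]] = []
    for act in sorted(pairs, key=lambda a: a.condition):
        ga, gb = sorted(act.guides)
        if scramble is None:
            skipped.append((act.condition, "no scramble condition in dataset"))
            continue
        missing = [g for g in (ga, gb) if g not in singles]
        if missing:
            skipped.append(
                (act.condition, f"missing single-guide condition(s): {', '.join(missing)}")
            )
            continue
        designs.append((act, ga, gb))
    raw_ps = []
    metas = []
    for act, ga, gb in designs:
        design = PairDesign(
            ga,
            gb,
            scramble.folds,
            singles[ga].folds,
            singles[gb].folds,
            act.folds,
        )
        test = interaction_test(design)
        expected, ci = combination_index(
            singles[ga].mean_fold, singles[gb].mean_fold, act.mean_fold
        )
        raw_ps.append(test.p_value)
        metas.append((act, ga, gb, expected, ci))
    ps = _holm(raw_ps) if (holm and raw_ps) else raw_ps
    for p, (act, ga, gb, expected, ci) in zip(ps, metas):
        results.append(
            PairInteraction(
                guide_a=ga,
                guide_b=gb,
                act_a=singles[ga].mean_fold,
                act_b=singles[gb].mean_fold,
                act_ab=act.mean_fold,
                interaction_p=float(p),
                expected_additive=expected,
                ci=ci,
                classification=classify_pair(float(p), ci, alpha),
            )
        )
    return results, skipped


def pair_report(interactions: Sequence[PairInteraction]) -> pd.DataFrame:
    """Tabular pair report mirroring the TSV interface."""
    return pd.DataFrame(
        [
            {
                "guide_a": it.guide_a,
                "guide_b": it.guide_b,
                "act_a": it.act_a,
                "act_b": it.act_b,
                "act_ab": it.act_ab,
                "expected_additive": it.expected_additive,
                "ci": it.ci,
                "interaction_p": it.interaction_p,
                "classification": it.classification,
            }
            for it in interactions
        ]
    )
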