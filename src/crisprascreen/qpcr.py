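"""Relative qPCR quantification of endogenous expression.

Implements efficiency-corrected relative quantification (Pfaffl): the
expression ratio of a sample against the control condition is

    fold = E_target^(Ct_control,target − Ct_sample,target)
           / E_ref^(Ct_control,ref − Ct_sample,ref)

with per-gene amplification efficiencies E in (1, 2] (fold of product per
cycle). With E_target = E_ref = 2 this is exactly the classical
2^(−ΔΔCt). The control anchor is the mean Ct of the control condition for
each gene. Condition-level statistics (mean fold, SEM, one-way ANOVA +
Dunnett vs control) are delegated to the screening module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import screening

__all__ = [
    "QpcrMeasurement",
    "pfaffl_ratio",
    "read_ct_table",
    "sample_folds",
    "expression_report",
]


def _check_efficiency(e: float, name: str) -> None:
    if not (1.0 < e <= 2.0):
        raise ValueError(f"{name} amplification efficiency must be in (1, 2], got {e}")


@dataclass(frozen=True)
class QpcrMeasurement:
    """Paired target/reference Ct values for one sample."""

    sample: str
    condition: str
    ct_target: float
    ct_ref: float
    e_target: float = 2.0
    e_ref: float = 2.0

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_ref", self.ct_ref)):
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError(f"{name} must be finite and positive, got {ct}")
        _check_efficiency(self.e_target, "target")
        _check_efficiency(self.e_ref, "reference")


def pfaffl_ratio(
    ct_control_target: float,
    ct_sample_target: float,
    ct_control_ref: float,
    ct_sample_ref: float,
    e_target: float = 2.0,
    e_ref: float = 2.0,
) -> float:
    """Efficiency-corrected expression ratio of a sample vs the control.

    ``fold = e_target**(ct_control_target - ct_sample_target)
    / e_ref**(ct_control_ref - ct_sample_ref)``; equal efficiencies of 2
    reduce this to ``2**(-ddCt)``.
    """
    _check_efficiency(e_target, "target")
    _check_efficiency(e_ref, "reference")
    d_target = ct_control_target - ct_sample_target
    d_ref = ct_control_ref - ct_sample_ref
    return float(e_target**d_target / e_ref**d_ref)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a long Ct CSV with columns sample, condition, gene, ct."""
    df = pd.read_csv(path, comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = {"sample", "condition", "gene", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {', '.join(sorted(missing))}")
    df["ct"] = pd.to_numeric(df["ct"])
    return df


def sample_folds(
    ct: pd.DataFrame,
    target_gene: str,
    ref_gene: str,
    control_condition: str,
    efficiencies: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-sample Pfaffl folds against the control-condition mean Ct anchor.

    ``ct`` is the long table from :func:`read_ct_table`; each sample must
    carry one Ct for the target and one for the reference gene.
    """
    eff = dict(efficiencies or {})
    e_t = eff.get(target_gene, 2.0)
    e_r = eff.get(ref_gene, 2.0)
    wide = ct.pivot_table(index=["sample", "condition"], columns="gene", values="ct")
    for gene in (target_gene, ref_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from Ct table")
    wide = wide.reset_index()
    if wide[[target_gene, ref_gene]].isna().any().any():
        bad = wide.loc[wide[[target_gene, ref_gene]].isna().any(axis=1), "sample"]
        raise ValueError(f"sample(s) with missing Ct values: {', '.join(map(str, bad))}")
    ctrl = wide[wide["condition"] == control_condition]
    if len(ctrl) < 2:
        raise ValueError(
            f"control condition {control_condition!r} needs >= 2 samples, got {len(ctrl)}"
        )
    anchor_t = float(ctrl[target_gene].mean())
    anchor_r = float(ctrl[ref_gene].mean())
    wide["fold"] = [
        pfaffl_ratio(anchor_t, row_t, anchor_r, row_r, e_t, e_r)
        for row_t, row_r in zip(wide[target_gene], wide[ref_gene])
    ]
    return wide[["sample", "condition", "fold"]]


def expression_report(
    ct: pd.DataFrame,
    target_gene: str,
    ref_gene: str,
    control_condition: str,
    efficiencies: Mapping[str, float] | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
):
    """Condition-level expression report with ANOVA and Dunnett vs control.

    Returns ``(report_df, anova_result)`` where the report has one row per
    condition (mean fold, SEM, n, Dunnett adjusted p, significance tier).
    """
    folds = sample_folds(ct, target_gene, ref_gene, control_condition, efficiencies)
    groups = {c: g["fold"].tolist() for c, g in folds.groupby("condition")}
    anova = screening.one_way_anova(groups)
    dunnett = screening.dunnett_vs_control(groups, control_condition, alpha=alpha, seed=seed)
    dmap = {d.condition: d for d in dunnett}
    rows = []
    for cond, values in groups.items():
        arr = np.asarray(values)
        d = dmap.get(cond)
        rows.append(
            {
                "condition": cond,
                "n": arr.size,
                "mean_fold": float(arr.mean()),
                "sem_fold": float(arr.std(ddof=1) / np.sqrt(arr.size)),
                "dunnett_adj_p": d.adjusted_p if d else float("nan"),
                "significance_tier": screening.significance_tier(d.adjusted_p)
                if d
                else "control",
            }
        )
    return pd.DataFrame(rows), anova
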