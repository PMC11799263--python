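"""Seeded generators for plate, TFBS and Ct tables.

The study's raw data are not deposited, so every analysis stage is
exercised against synthetic tables with the statistical structure the
assay implies:

* plates — per-well transfection efficiency is lognormal (TagBFP2
  channel); the reporter channel is TagBFP2 x baseline ratio x the
  condition's activation multiplier x mean-one lognormal noise, so the
  expected well ratio is exactly baseline x activation and the scramble
  fold scale is recovered unbiasedly;
* TFBS maps — uniform background sites plus dense clusters constructed
  so single-linkage chaining at the default parameters provably recovers
  them;
* Ct tables — reference-gene Ct around a base cycle, target-gene Ct
  shifted down by log_E(fold), so the Pfaffl round trip returns the
  configured folds in expectation.

All generators take a mandatory seed and touch no global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .plate_io import WellRecord
from .promoter_context import TFBSRecord

__all__ = [
    "PlateSimConfig",
    "default_screen_conditions",
    "simulate_plate",
    "simulate_tfbs_map",
    "simulate_qpcr_ct",
    "load_plate_config",
]

#: Printed per-condition mean fold activations of the Adam17 screen for the
#: twelve significantly activating conditions; all other conditions at the
#: scramble baseline of 1. Used as the default effect structure for a
#: realistic 28-condition + scramble plate.
_ADAM17_MEANS: dict[str, float] = {
    "1": 4.01, "2": 4.00, "5": 6.64,
    "1+2": 4.19, "1+3": 3.93, "1+5": 6.66, "1+7": 4.15,
    "2+5": 4.16, "2+6": 3.63, "3+5": 5.66, "5+7": 4.90, "6+7": 4.03,
}


def default_screen_conditions(control_condition: str = "Scr") -> dict[str, float]:
    """The default 29-condition activation map: 7 singles + 21 pairs +
    scramble, with the significant conditions at their screen means and the
    rest at baseline."""
    conditions: dict[str, float] = {control_condition: 1.0}
    singles = [str(i) for i in range(1, 8)]
    for s in singles:
        conditions[s] = _ADAM17_MEANS.get(s, 1.0)
    for i in range(7):
        for j in range(i + 1, 7):
            label = f"{singles[i]}+{singles[j]}"
            conditions[label] = _ADAM17_MEANS.get(label, 1.0)
    return conditions


@dataclass
class PlateSimConfig:
    """Generative model for one screening plate.

    ``conditions`` maps condition label -> activation multiplier on the
    scramble = 1 scale. TagBFP2 well sums are LogNormal(mu, sigma) in
    arbitrary units; the reporter channel multiplies in the baseline
    TdTomato/TagBFP2 ratio, the activation multiplier and mean-one
    lognormal measurement noise.
    """

    seed: int
    conditions: dict[str, float] = field(default_factory=default_screen_conditions)
    control_condition: str = "Scr"
    n_replicates: int = 3
    bfp_lognormal_mu: float = 9.2  # median well sum ~1e4 AU
    bfp_lognormal_sigma: float = 0.5
    reporter_noise_sigma: float = 0.2
    baseline_ratio: float = 0.1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is mandatory")
        if self.bfp_lognormal_sigma < 0 or self.reporter_noise_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if self.baseline_ratio <= 0:
            raise ValueError("baseline_ratio must be > 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        bad = {c: a for c, a in self.conditions.items() if a <= 0}
        if bad:
            raise ValueError(f"activation multipliers must be > 0: {bad}")
        if self.control_condition not in self.conditions:
            raise ValueError(f"control condition {self.control_condition!r} not in conditions")


_ROWS = "ABCDEFGH"


def _well_name(index: int) -> tuple[str, str]:
    """Map a running well index onto 96-well plates: (plate_id, well_id)."""
    plate, pos = divmod(index, 96)
    row, col = divmod(pos, 12)
    return f"plate{plate + 1}", f"{_ROWS[row]}{col + 1:02d}"


def simulate_plate(config: PlateSimConfig) -> list[WellRecord]:
    """Draw one plate of wells under the configured generative model.

    Reporter noise is lognormal with mean exactly one
    (``exp(N(-sigma^2/2, sigma))``), so E[ratio] = baseline x activation.
    """
    rng = np.random.default_rng(config.seed)
    wells: list[WellRecord] = []
    idx = 0
    for condition, activation in config.conditions.items():
        for _ in range(config.n_replicates):
            bfp = float(
                np.exp(rng.normal(config.bfp_lognormal_mu, config.bfp_lognormal_sigma))
            )
            sigma = config.reporter_noise_sigma
            noise = float(np.exp(rng.normal(-0.5 * sigma**2, sigma))) if sigma > 0 else 1.0
            td = bfp * config.baseline_ratio * activation * noise
            plate_id, well_id = _well_name(idx)
            idx += 1
            wells.append(WellRecord(plate_id, well_id, condition, td, bfp))
    return wells


def simulate_tfbs_map(
    window_length: int = 600,
    n_background: int = 50,
    clusters: Sequence[tuple[int, int, int]] = (),
    seed: int = 0,
    motif_len: int = 8,
    max_gap: int = 10,
) -> list[TFBSRecord]:
    """Synthetic TFBS interval map: uniform background plus dense clusters.

    Each ``(center, members, width)`` spec places ``members`` sites of
    ``motif_len`` bp evenly across ``width`` bp centred on ``center`` (with
    bounded jitter), guaranteeing consecutive gaps <= ``max_gap`` so the
    default single-linkage detection recovers the cluster. Raises for
    specs that cannot honour that guarantee.
    """
    rng = np.random.default_rng(seed)
    records: list[TFBSRecord] = []
    for ci, (center, members, width) in enumerate(clusters):
        if members < 1 or width < motif_len:
            raise ValueError(f"cluster spec {ci}: cannot place {members} sites in {width} bp")
        lo = center - width // 2
        if lo < 0 or lo + width > window_length:
            raise ValueError(f"cluster spec {ci} does not fit in the window")
        if members == 1:
            starts = [lo + (width - motif_len) // 2]
        else:
            step = (width - motif_len) / (members - 1)
            if step - motif_len > max_gap:
                raise ValueError(
                    f"cluster spec {ci}: {members} sites of {motif_len} bp cannot chain "
                    f"across {width} bp with gaps <= {max_gap}"
                )
            # keep worst-case gap (spacing + opposing jitter + rounding) <= max_gap
            slack = int(max(0.0, (max_gap - 1 - max(0.0, step - motif_len)) // 2))
            starts = [
                int(round(lo + i * step)) + (int(rng.integers(-slack, slack + 1)) if slack else 0)
                for i in range(members)
            ]
            starts = [min(max(s, 0), window_length - motif_len) for s in starts]
        for si, s in enumerate(starts):
            records.append(TFBSRecord(f"cluster{ci}_site{si}", s, s + motif_len))
    for bi in range(n_background):
        length = int(rng.integers(6, 13))
        start = int(rng.integers(0, max(1, window_length - length)))
        records.append(TFBSRecord(f"bg{bi}", start, start + length))
    records.sort(key=lambda t: (t.start, t.end))
    return records


def simulate_qpcr_ct(
    true_folds: Mapping[str, float],
    n_replicates: int = 4,
    ct_base: float = 22.0,
    ct_noise_sd: float = 0.15,
    efficiency: float = 2.0,
    seed: int = 0,
    target_gene: str = "target",
    ref_gene: str = "ref",
) -> pd.DataFrame:
    """Synthetic long Ct table consistent with the given expression folds.

    Reference-gene Ct ~ Normal(ct_base, sd); target-gene Ct sits
    log_E(fold) cycles below the fold-1 anchor (plus noise), so the Pfaffl
    round trip against a fold-1 control recovers ``true_folds`` in
    expectation of the Ct differences.
    """
    if any(f <= 0 for f in true_folds.values()):
        raise ValueError("all folds must be > 0")
    if not (1.0 < efficiency <= 2.0):
        raise ValueError(f"efficiency must be in (1, 2], got {efficiency}")
    rng = np.random.default_rng(seed)
    rows = []
    log_e = math.log(efficiency)
    for condition, fold in true_folds.items():
        for i in range(n_replicates):
            sample = f"{condition}_r{i + 1}"
            ct_ref = ct_base + (rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
            shift = math.log(fold) / log_e
            ct_t = ct_base - shift + (rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
            rows.append({"sample": sample, "condition": condition, "gene": ref_gene, "ct": ct_ref})
            rows.append({"sample": sample, "condition": condition, "gene": target_gene, "ct": ct_t})
    return pd.DataFrame(rows)


def load_plate_config(path: str | Path, seed: int | None = None) -> PlateSimConfig:
    """Load a :class:`PlateSimConfig` from a YAML file; an explicit ``seed``
    argument overrides the file's value."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if seed is not None:
        raw["seed"] = seed
    if "seed" not in raw:
        raise ValueError("config must provide a seed (or pass one explicitly)")
    return PlateSimConfig(**raw)
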