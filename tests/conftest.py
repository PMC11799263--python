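"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from crisprascreen.plate_io import WellRecord, build_screen_dataset
from crisprascreen.synthetic_data import PlateSimConfig, simulate_plate


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the implementation's code paths)

def anova_oracle(groups: dict[str, list[float]]):
    """One-way ANOVA F and p via scipy.stats.f_oneway, df by counting."""
    arrays = [np.asarray(v, float) for v in groups.values()]
    f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return float(f), k - 1, n - k, float(p)


def interaction_oracle(scr, a, b, ab):
    """Balanced 2x2 interaction F via the cell-mean contrast.

    For n replicates per cell, SS_int = n * (m11 - m10 - m01 + m00)^2 / 4
    and F = SS_int / MS_within.
    """
    cells = [np.asarray(v, float) for v in (scr, a, b, ab)]
    n = cells[0].size
    assert all(c.size == n for c in cells), "oracle requires a balanced design"
    m00, m10, m01, m11 = (c.mean() for c in cells)
    ss_int = n * (m11 - m10 - m01 + m00) ** 2 / 4.0
    ss_w = sum(((c - c.mean()) ** 2).sum() for c in cells)
    df_w = 4 * (n - 1)
    if ss_w == 0:
        return ss_int, np.inf if ss_int > 0 else 0.0, np.nan
    f = ss_int / (ss_w / df_w)
    return ss_int, f, float(stats.f.sf(f, 1, df_w))


def cluster_oracle(intervals: list[tuple[int, int]], min_members=10, max_gap=10):
    """Transitive-closure clustering by union-find over all interval pairs."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            gap = max(0, s1 - e2, s2 - e1)
            if gap <= max_gap:
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        if len(members) >= min_members:
            starts = [intervals[i][0] for i in members]
            ends = [intervals[i][1] for i in members]
            out.append((min(starts), max(ends), len(members)))
    return sorted(out)


def pooled_t_oracle(a, b):
    """Two-sided pooled-variance two-sample t-test p-value."""
    _, p = stats.ttest_ind(a, b, equal_var=True)
    return float(p)


# ---------------------------------------------------------------------------
# Fixtures

@pytest.fixture(scope="session")
def screen_config() -> PlateSimConfig:
    """The default 29-condition screening plate configuration."""
    return PlateSimConfig(seed=20_001)


@pytest.fixture(scope="session")
def screen_dataset(screen_config):
    wells = simulate_plate(screen_config)
    return build_screen_dataset(wells, screen_config.control_condition)


@pytest.fixture()
def small_wells() -> list[WellRecord]:
    """A four-condition miniature screen with exact round-number ratios."""
    wells = []
    ratios = {"Scr": [1.0, 1.0, 1.0], "A": [2.0, 2.0, 2.0],
              "B": [3.0, 3.0, 3.0], "A+B": [4.0, 4.0, 4.0]}
    idx = 0
    for cond, rs in ratios.items():
        for r in rs:
            wells.append(WellRecord("p1", f"A{idx + 1:02d}", cond, 100.0 * r, 100.0))
            idx += 1
    return wells
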