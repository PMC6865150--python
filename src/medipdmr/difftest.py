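"""Per-window two-group differential methylation testing.

Each 100-bp window is tested for a depth difference between two sample groups
with Welch's unequal-variance t-test on rpm values, the family-wise error is
controlled with a Bonferroni adjustment over the tested windows, and windows
with adjusted p below the significance threshold (default 0.10, strict
inequality) are selected for merging into candidate DMRs.

Windows whose summed raw count across all samples falls below ``min_total``
are marked untested and carry p = p_adj = 1 by convention; they contribute no
hypothesis to the Bonferroni family.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .windows import CountMatrix, ValidationError

DEFAULT_P_THRESHOLD = 0.10
DEFAULT_MIN_TOTAL = 10
DEFAULT_VAR_FLOOR = 1e-8   # rpm^2; keeps all-equal groups finite
LOG2_EPS = 1e-6            # rpm pseudo-offset inside the log2 ratio

HYPER_IN_A = "hyper_in_A"
HYPO_IN_A = "hypo_in_A"
NO_DIRECTION = "none"


@dataclass(frozen=True)
class WindowTestResult:
    """Welch test outcome for one window (group A vs group B)."""

    mean_a: float
    mean_b: float
    log2_ratio: float
    direction: str
    t_stat: float
    df: float
    p: float
    p_adj: float = 1.0
    tested: bool = True


def welch_arrays(
    a: np.ndarray, b: np.ndarray, var_floor: float = DEFAULT_VAR_FLOOR
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch statistic, Welch-Satterthwaite df and two-sided p.

    ``a`` and ``b`` are (n_tests, n_samples) arrays; the test runs along the
    last axis. Per-group variances are floored at ``var_floor``. Where both
    means are exactly equal the statistic is 0 and p is 1.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = a.shape[-1], b.shape[-1]
    if na < 2 or nb < 2:
        raise ValidationError(f"each group needs >= 2 samples (got {na} and {nb})")
    ma, mb = a.mean(-1), b.mean(-1)
    va = np.maximum(a.var(-1, ddof=1), var_floor)
    vb = np.maximum(b.var(-1, ddof=1), var_floor)
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, (ma - mb) / np.sqrt(se2), 0.0)
        df = np.where(se2 > 0, se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1)), 1.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, np.minimum(p, 1.0)


def test_window(
    depths_a: Sequence[float],
    depths_b: Sequence[float],
    min_total: float | None = None,
    var_floor: float = DEFAULT_VAR_FLOOR,
    raw_total: float | None = None,
) -> WindowTestResult:
    """Welch's t-test on one window's rpm values.

    ``raw_total`` (summed raw counts over all samples) is compared against
    ``min_total`` to decide whether the window is tested at all.
    """
    a = np.asarray(depths_a, dtype=np.float64)
    b = np.asarray(depths_b, dtype=np.float64)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    l2 = float(np.log2((mean_a + LOG2_EPS) / (mean_b + LOG2_EPS)))
    if min_total is not None and raw_total is not None and raw_total < min_total:
        return WindowTestResult(mean_a, mean_b, l2, NO_DIRECTION, 0.0, 1.0, 1.0, 1.0, False)
    t, df, p = welch_arrays(a[None, :], b[None, :], var_floor)
    t, df, p = float(t[0]), float(df[0]), float(p[0])
    if l2 > 0 and t != 0:
        direction = HYPER_IN_A
    elif l2 < 0 and t != 0:
        direction = HYPO_IN_A
    else:
        direction = NO_DIRECTION
    return WindowTestResult(mean_a, mean_b, l2, direction, t, df, p, p, True)


def test_windows(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    min_total: float = DEFAULT_MIN_TOTAL,
    var_floor: float = DEFAULT_VAR_FLOOR,
    adjust: bool = True,
) -> pd.DataFrame:
    """Test every window of ``matrix`` (rpm) for group_a vs group_b.

    Returns one row per window with the :class:`WindowTestResult` fields plus
    chrom/start/end, Bonferroni-adjusted over the tested windows.
    """
    if matrix.rpm is None:
        raise ValidationError("CountMatrix must be rpm-normalized before testing")
    cols_a = matrix.columns_for(group_a)
    cols_b = matrix.columns_for(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError(
            f"need >= 2 samples per group; {group_a}: {len(cols_a)}, {group_b}: {len(cols_b)}"
        )
    A = matrix.rpm[:, cols_a]
    B = matrix.rpm[:, cols_b]
    tested = matrix.raw.sum(axis=1) >= min_total
    t, df, p = welch_arrays(A, B, var_floor)
    mean_a, mean_b = A.mean(1), B.mean(1)
    l2 = np.log2((mean_a + LOG2_EPS) / (mean_b + LOG2_EPS))
    direction = np.where(
        (l2 > 0) & (t != 0), HYPER_IN_A, np.where((l2 < 0) & (t != 0), HYPO_IN_A, NO_DIRECTION)
    )
    t = np.where(tested, t, 0.0)
    df = np.where(tested, df, 1.0)
    p = np.where(tested, p, 1.0)
    direction = np.where(tested, direction, NO_DIRECTION)

    grid = matrix.grid
    out = pd.DataFrame(
        {
            "window": grid.window_ids(),
            "chrom": [grid.chrom_names[c] for c in grid.chroms],
            "start": grid.starts,
            "end": grid.ends,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_ratio": l2,
            "direction": direction,
            "t_stat": t,
            "df": df,
            "p": p,
            "tested": tested,
        }
    )
    if adjust:
        m = int(tested.sum())
        out["p_adj"] = np.where(
            tested, bonferroni_adjust(p, max(m, 1)), 1.0
        )
    else:
        out["p_adj"] = out["p"]
    return out


def bonferroni_adjust(p_values: np.ndarray, m: int) -> np.ndarray:
    """Bonferroni family-wise adjustment: p_adj = min(1, m * p)."""
    if m <= 0:
        raise ValidationError(f"number of hypotheses m must be positive, got {m}")
    p = np.asarray(p_values, dtype=np.float64)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


def select_significant(results: pd.DataFrame, threshold: float = DEFAULT_P_THRESHOLD) -> pd.DataFrame:
    """Tested windows with p_adj strictly below ``threshold``, order kept."""
    keep = results["tested"] & (results["p_adj"] < threshold)
    return results.loc[keep].copy()


def write_results_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
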