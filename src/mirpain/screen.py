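"""Replicate-consistency dysregulation screen on miRNA expression arrays.

The screen operates on quantile-normalized linear-scale intensities and
calls a miRNA dysregulated when, within a timepoint,

    |m_T - m_S| >= k * (s_T + s_S)        (replicate consistency, k = 5)

and the tumour/sham fold change ``FC = m_T / m_S`` satisfies
``FC >= fc_primary`` or ``FC <= 1/fc_primary`` (default 2.5-fold, either
direction).  A secondary, looser fold-change count (default 2.0-fold) is
reported alongside.  Both comparisons are inclusive.

Group means and SDs are taken over biological-replicate arrays.  miRNAs
with a non-positive group mean cannot be assigned a fold change; they are
flagged unevaluable and excluded from selection rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUP_SHAM = "sham"
GROUP_TUMOUR = "tumour"

#: Column contract for the design table accompanying an expression matrix.
DESIGN_COLUMNS = ("array_id", "group", "replicate", "timepoint")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the dysregulation screen.

    Parameters
    ----------
    k
        Multiplier on the sum of the two group SDs; the distance between
        group means must be at least ``k`` times that sum.
    fc_primary
        Linear fold-change bound (either direction) for selection.
    fc_secondary
        Looser fold-change bound counted in reports only.
    sd_mode
        ``"sample"`` for the n-1 denominator (default) or ``"population"``.
    """

    k: float = 5.0
    fc_primary: float = 2.5
    fc_secondary: float = 2.0
    sd_mode: str = "sample"

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if not self.fc_primary >= self.fc_secondary > 1:
            raise ValueError(
                "require fc_primary >= fc_secondary > 1, got "
                f"fc_primary={self.fc_primary}, fc_secondary={self.fc_secondary}"
            )
        if self.sd_mode not in ("sample", "population"):
            raise ValueError(f"sd_mode must be 'sample' or 'population', got {self.sd_mode!r}")

    @property
    def ddof(self) -> int:
        return 1 if self.sd_mode == "sample" else 0


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative miRNA x array intensity matrix with its design table.

    ``values`` is indexed by miRNA id with one column per array id;
    ``design`` maps each array to a group (sham/tumour), a biological
    replicate index and a timepoint label (e.g. PID-4, PID-8).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate miRNA ids: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate array ids: {dup}")
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        undesigned = set(self.values.columns) - set(self.design["array_id"])
        if undesigned:
            raise ValueError(f"arrays without design entry: {sorted(undesigned)}")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = [
                (self.values.index[i], self.values.columns[j])
                for i, j in zip(*np.nonzero(~np.isfinite(vals)))
            ]
            raise ValueError(f"non-finite intensities at {bad[:20]}")
        if (vals < 0).any():
            raise ValueError("negative intensities present")

    @property
    def mirna_ids(self) -> list:
        return list(self.values.index)

    @property
    def array_ids(self) -> list:
        return list(self.values.columns)

    def timepoints(self) -> list:
        return sorted(self.design["timepoint"].unique())

    def arrays_for(self, group: str, timepoint: str) -> list:
        d = self.design
        sel = d[(d["group"] == group) & (d["timepoint"] == timepoint)]
        return list(sel["array_id"])


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force all arrays (columns) onto one shared empirical distribution.

    Each column's sorted vector is replaced by the across-column mean of
    sorted vectors; within-column rank order is preserved.  Ties within a
    column receive the mean of the reference values their rank span covers,
    so the transform is deterministic and permutation-equivariant.
    """
    arr = values.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = [
            (values.index[i], values.columns[j])
            for i, j in zip(*np.nonzero(~np.isfinite(arr)))
        ]
        raise ValueError(f"non-finite values at {bad[:20]}")
    n_rows, n_cols = arr.shape
    if n_cols == 1:
        return values.copy()
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(n_cols):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty(n_rows)
        ranked[order] = reference
        # ties: average the reference values spanned by each tied block
        sorted_col = col[order]
        block_start = 0
        for i in range(1, n_rows + 1):
            if i == n_rows or sorted_col[i] != sorted_col[block_start]:
                if i - block_start > 1:
                    ranked[order[block_start:i]] = reference[block_start:i].mean()
                block_start = i
        out[:, j] = ranked
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def group_stats(
    matrix: ExpressionMatrix, timepoint: str, config: ScreenConfig | None = None
) -> pd.DataFrame:
    """Per-miRNA sham/tumour means and SDs over biological replicates.

    Returns a frame indexed by miRNA id with columns
    ``mean_sham, sd_sham, mean_tumour, sd_tumour, n_sham, n_tumour``.
    """
    config = config or ScreenConfig()
    sham = matrix.arrays_for(GROUP_SHAM, timepoint)
    tum = matrix.arrays_for(GROUP_TUMOUR, timepoint)
    if not sham or not tum:
        missing = [g for g, a in ((GROUP_SHAM, sham), (GROUP_TUMOUR, tum)) if not a]
        raise ValueError(f"timepoint {timepoint!r}: no arrays for group(s) {missing}")
    s = matrix.values[sham].to_numpy(dtype=float)
    t = matrix.values[tum].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "mean_sham": s.mean(axis=1),
            "sd_sham": s.std(axis=1, ddof=config.ddof),
            "mean_tumour": t.mean(axis=1),
            "sd_tumour": t.std(axis=1, ddof=config.ddof),
            "n_sham": len(sham),
            "n_tumour": len(tum),
        },
        index=matrix.values.index,
    )


def screen(stats: pd.DataFrame, config: ScreenConfig | None = None) -> pd.DataFrame:
    """Apply the consistency and fold-change criteria to group statistics.

    Returns the ScreenResult frame: per-miRNA means/SDs, ``fold_change``
    (tumour over sham; < 1 means downregulation), ``direction`` in
    {up, down, none}, boolean ``passes_consistency``, ``passes_fc_primary``,
    ``passes_fc_secondary``, ``selected`` and ``evaluable``.  miRNAs with a
    non-positive group mean are marked unevaluable and never selected.
    """
    config = config or ScreenConfig()
    m_s = stats["mean_sham"].to_numpy(dtype=float)
    m_t = stats["mean_tumour"].to_numpy(dtype=float)
    s_s = stats["sd_sham"].to_numpy(dtype=float)
    s_t = stats["sd_tumour"].to_numpy(dtype=float)

    evaluable = (m_s > 0) & (m_t > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(evaluable, m_t / np.where(m_s > 0, m_s, np.nan), np.nan)

    # inclusive ("at least") boundaries, robust to round-off so that the
    # decisions are invariant under global intensity scaling
    rtol = 1e-12
    consistency = np.abs(m_t - m_s) >= config.k * (s_t + s_s) * (1 - rtol)
    fc_primary = evaluable & (
        (fc >= config.fc_primary * (1 - rtol)) | (fc <= (1.0 / config.fc_primary) * (1 + rtol))
    )
    fc_secondary = evaluable & (
        (fc >= config.fc_secondary * (1 - rtol)) | (fc <= (1.0 / config.fc_secondary) * (1 + rtol))
    )
    selected = evaluable & consistency & fc_primary

    direction = np.full(len(stats), "none", dtype=object)
    direction[selected & (m_t > m_s)] = "up"
    direction[selected & (m_t < m_s)] = "down"

    out = stats.copy()
    out["fold_change"] = fc
    out["direction"] = direction
    out["passes_consistency"] = consistency
    out["passes_fc_primary"] = fc_primary
    out["passes_fc_secondary"] = fc_secondary
    out["selected"] = selected
    out["evaluable"] = evaluable
    return out


def implied_t_bound(k: float, n: int) -> float:
    """Worst-case two-tailed equal-variance t-test p implied by the screen.

    Over all SD configurations (s_S, s_T) >= 0 (not both zero) with the
    group-mean distance exactly at the boundary |m_T - m_S| = k (s_T + s_S),
    the pooled-variance two-sample t statistic

        t = k (s_T + s_S) / sqrt((s_S^2 + s_T^2) / n)

    is minimized (p maximized) as one SD tends to 0, where
    (s_T + s_S)/sqrt(s_S^2 + s_T^2) -> 1, giving t_min = k sqrt(n) with
    2n - 2 degrees of freedom.  Returns the corresponding two-tailed p;
    any miRNA passing the consistency criterion has p at or below it.
    """
    if not k > 0:
        raise ValueError(f"k must be positive, got {k}")
    if n < 2:
        raise ValueError(f"need n >= 2 replicates per group, got {n}")
    t_min = k * np.sqrt(n)
    df = 2 * n - 2
    return float(2.0 * sps.t.sf(t_min, df))


def screen_report(
    results: pd.DataFrame,
    normalized: pd.DataFrame | None = None,
    config: ScreenConfig | None = None,
) -> dict:
    """Summarize screen results and build a heatmap-ready matrix.

    Reports the count passing the secondary fold-change bound alone, the
    selected count (consistency + primary fold change) split by direction,
    and the unevaluable count.  If ``normalized`` intensities are given,
    a matrix of the selected miRNAs is included, rows ordered by direction
    (up first) then by decreasing |log2 fold change|.
    """
    config = config or ScreenConfig()
    selected = results[results["selected"]]
    summary = {
        "n_total": int(len(results)),
        "n_fc_secondary": int(results["passes_fc_secondary"].sum()),
        "n_selected": int(len(selected)),
        "n_up": int((selected["direction"] == "up").sum()),
        "n_down": int((selected["direction"] == "down").sum()),
        "n_unevaluable": int((~results["evaluable"]).sum()),
        "k": config.k,
        "fc_primary": config.fc_primary,
        "fc_secondary": config.fc_secondary,
    }
    heatmap = None
    if normalized is not None and len(selected):
        order = selected.assign(
            _dir=(selected["direction"] != "up").astype(int),
            _mag=-np.abs(np.log2(selected["fold_change"])),
        ).sort_values(["_dir", "_mag"]).index
        heatmap = normalized.loc[order]
    return {"summary": summary, "heatmap": heatmap}
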