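"""ddCt relative quantification from long-format Ct tables.

Fold change between a treatment and a control group is computed as
``2^(-ddCt)`` where, per sample, ``dCt = Ct_target - Ct_reference`` (the
reference being a stably expressed assay such as sno202 for miRNAs or
GAPDH for mRNAs), and ``ddCt = mean dCt(treatment) - mean dCt(control)``.
Amplification efficiency is fixed at perfect doubling; no efficiency
correction is applied.

Technical replicates (typically triplicate wells) are averaged per
(sample, assay) first; a QC flag marks replicate SD above ``max_rep_sd``
cycles without excluding anything.  Undetermined Cts (non-amplification,
encoded as NaN) are treated as missing and reported, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column contract for long-format Ct tables.
CT_COLUMNS = ("sample", "group", "assay", "role", "replicate", "ct")

DEFAULT_MAX_REP_SD = 0.5  # cycles


@dataclass(frozen=True)
class RelQuantResult:
    """ddCt outcome for one target assay and one group comparison."""

    target: str
    reference: str
    treatment: str
    control: str
    mean_dct_treatment: float
    mean_dct_control: float
    ddct: float
    fold_change: float
    n_treatment: int
    n_control: int
    qc_flags: list = field(default_factory=list)


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    return table


def aggregate_technical(
    table: pd.DataFrame, max_rep_sd: float = DEFAULT_MAX_REP_SD
) -> pd.DataFrame:
    """Mean Ct per (sample, assay) over technical replicates, with QC flag.

    Rows with undetermined Ct (NaN) are dropped from the mean and counted
    in ``n_missing``.  ``high_rep_sd`` is True when the replicate sample SD
    exceeds ``max_rep_sd`` cycles; flagged wells stay in all downstream
    computation.
    """
    _check_table(table)

    def _agg(g: pd.DataFrame) -> pd.Series:
        ct = g["ct"].to_numpy(dtype=float)
        present = ct[np.isfinite(ct)]
        if present.size == 0:
            mean = np.nan
            sd = np.nan
        else:
            mean = present.mean()
            sd = present.std(ddof=1) if present.size > 1 else 0.0
        return pd.Series(
            {
                "group": g["group"].iloc[0],
                "role": g["role"].iloc[0],
                "mean_ct": mean,
                "rep_sd": sd,
                "n_rep": int(present.size),
                "n_missing": int(ct.size - present.size),
                "high_rep_sd": bool(np.isfinite(sd) and sd > max_rep_sd),
            }
        )

    out = (
        table.groupby(["sample", "assay"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return out


def ddct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    treatment: str,
    control: str,
    max_rep_sd: float = DEFAULT_MAX_REP_SD,
) -> RelQuantResult:
    """Relative quantification of ``target`` between two groups.

    Per-sample dCt values are formed from technical-replicate mean Cts,
    then averaged within each group; missing (sample, assay) pairs raise
    with the offending pair named.
    """
    agg = aggregate_technical(table, max_rep_sd=max_rep_sd)
    qc_flags = [
        f"high replicate SD: sample={r.sample} assay={r.assay} sd={r.rep_sd:.2f}"
        for r in agg.itertuples(index=False)
        if r.high_rep_sd
    ]

    def _group_dct(group: str) -> np.ndarray:
        sub = agg[agg["group"] == group]
        tgt = sub[sub["assay"] == target].set_index("sample")["mean_ct"]
        ref = sub[sub["assay"] == reference].set_index("sample")["mean_ct"]
        if ref.empty:
            raise ValueError(f"group {group!r} lacks reference assay {reference!r}")
        if tgt.empty:
            raise ValueError(f"group {group!r} lacks target assay {target!r}")
        samples = tgt.index.intersection(ref.index)
        missing_ref = tgt.index.difference(ref.index).tolist()
        if missing_ref:
            raise ValueError(
                f"missing (sample, assay) pairs: "
                f"{[(s, reference) for s in missing_ref]}"
            )
        dct = (tgt.loc[samples] - ref.loc[samples]).to_numpy(dtype=float)
        dct = dct[np.isfinite(dct)]
        if dct.size == 0:
            raise ValueError(f"group {group!r}: no sample with both {target!r} and {reference!r} determined")
        return dct

    dct_treat = _group_dct(treatment)
    dct_ctrl = _group_dct(control)
    dd = float(dct_treat.mean() - dct_ctrl.mean())
    return RelQuantResult(
        target=target,
        reference=reference,
        treatment=treatment,
        control=control,
        mean_dct_treatment=float(dct_treat.mean()),
        mean_dct_control=float(dct_ctrl.mean()),
        ddct=dd,
        fold_change=float(2.0 ** (-dd)),
        n_treatment=int(dct_treat.size),
        n_control=int(dct_ctrl.size),
        qc_flags=qc_flags,
    )


def timecourse_fc(
    tables: dict,
    target: str,
    reference: str,
    treatment: str = "tumour",
    control: str = "sham",
    max_rep_sd: float = DEFAULT_MAX_REP_SD,
) -> pd.DataFrame:
    """Fold change of ``target`` per timepoint, each vs its own control.

    ``tables`` maps timepoint label -> Ct table containing both groups
    measured at that timepoint (the study compares each post-implantation
    day against sham controls taken at the same day).  Returns a frame
    with columns ``timepoint, fold_change, log2_fc, direction`` suitable
    for reciprocal-regulation scoring.
    """
    if not tables:
        raise ValueError("no timepoint tables given")
    rows = []
    for tp, table in tables.items():
        res = ddct(table, target, reference, treatment, control, max_rep_sd=max_rep_sd)
        log2_fc = -res.ddct
        rows.append(
            {
                "timepoint": tp,
                "fold_change": res.fold_change,
                "log2_fc": log2_fc,
                "direction": "up" if log2_fc > 0 else ("down" if log2_fc < 0 else "none"),
            }
        )
    return pd.DataFrame(rows)
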