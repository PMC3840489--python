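"""Consensus target prioritization and in-vivo expression-response filtering.

Per-algorithm miRNA->gene prediction tables are tallied into support
counts; genes predicted by at least ``min_algorithms`` distinct algorithms
(default 2, of the study's 14) form the consensus candidate set.  Candidate
expression measured on digital count data (inhibitor vs mismatch-control)
is normalized to the geometric mean of flagged housekeeping genes per
sample; genes whose inhibitor/control ratio of normalized means is at
least ``min_ratio`` (default 1.5, i.e. >= 50% up-regulation on inhibition)
are flagged responders.  Reciprocal regulation between a miRNA and a
candidate over a shared time course is scored as the fraction of
timepoints where their log fold changes have opposite sign.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

PREDICTION_COLUMNS = ("algorithm", "mirna", "gene")

DEFAULT_MIN_ALGORITHMS = 2
DEFAULT_MIN_RATIO = 1.5

CONDITION_INHIBITOR = "inhibitor"
CONDITION_CONTROL = "mismatch-control"


def tally(
    tables: list[pd.DataFrame] | pd.DataFrame,
    mirna: str,
    min_algorithms: int = DEFAULT_MIN_ALGORITHMS,
) -> pd.DataFrame:
    """Count distinct algorithms predicting each gene as a target of ``mirna``.

    Accepts one long-format table or a list of them (columns
    ``algorithm, mirna, gene``); duplicate (algorithm, miRNA, gene) triples
    are collapsed with a warning.  Returns a frame with columns
    ``gene, n_algorithms, consensus`` sorted by descending support.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    if not tables or all(len(t) == 0 for t in tables):
        warnings.warn("empty prediction input; returning empty consensus table")
        return pd.DataFrame(columns=["gene", "n_algorithms", "consensus"])
    combined = pd.concat(tables, ignore_index=True)
    missing = [c for c in PREDICTION_COLUMNS if c not in combined.columns]
    if missing:
        raise ValueError(f"prediction table missing columns: {missing}")
    sub = combined[combined["mirna"] == mirna]
    n_dup = int(sub.duplicated(subset=["algorithm", "mirna", "gene"]).sum())
    if n_dup:
        warnings.warn(f"collapsed {n_dup} duplicate (algorithm, miRNA, gene) records")
        sub = sub.drop_duplicates(subset=["algorithm", "mirna", "gene"])
    counts = (
        sub.groupby("gene")["algorithm"]
        .nunique()
        .rename("n_algorithms")
        .reset_index()
        .sort_values(["n_algorithms", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )
    counts["consensus"] = counts["n_algorithms"] >= min_algorithms
    return counts


def normalize_counts(counts: pd.DataFrame, housekeeping: pd.Series) -> pd.DataFrame:
    """Normalize each sample's counts to its housekeeping geometric mean.

    ``counts`` is genes x samples; ``housekeeping`` is a boolean Series
    indexed like the genes marking the reference set.  Each sample's
    values are divided by the geometric mean of that sample's housekeeping
    counts, making the result invariant to per-sample scaling.
    """
    hk = housekeeping.reindex(counts.index, fill_value=False).astype(bool)
    hk_genes = counts.index[hk]
    if len(hk_genes) == 0:
        raise ValueError("no housekeeping genes flagged")
    hk_counts = counts.loc[hk_genes]
    zero = hk_counts <= 0
    if zero.to_numpy().any():
        gene, sample = next(
            (g, s) for g in hk_counts.index for s in hk_counts.columns
            if hk_counts.at[g, s] <= 0
        )
        raise ValueError(
            f"non-positive housekeeping count: gene={gene!r} sample={sample!r}"
        )
    geo_mean = np.exp(np.log(hk_counts.to_numpy(dtype=float)).mean(axis=0))
    return counts / pd.Series(geo_mean, index=counts.columns)


def response_filter(
    normalized: pd.DataFrame,
    design: pd.Series | dict,
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> pd.DataFrame:
    """Flag genes up-regulated on miRNA inhibition in vivo.

    ``design`` maps sample id -> condition (``inhibitor`` or
    ``mismatch-control``).  Per gene, ``response_ratio`` is the ratio of
    mean normalized expression under inhibitor to that under control;
    ``responder`` is True when the ratio is at least ``min_ratio``
    (inclusive).  Genes with zero control mean are marked unevaluable.
    """
    design = pd.Series(design)
    inhib = design.index[design == CONDITION_INHIBITOR]
    ctrl = design.index[design == CONDITION_CONTROL]
    if len(inhib) == 0 or len(ctrl) == 0:
        raise ValueError(
            f"both conditions required; got {design.value_counts().to_dict()}"
        )
    mean_inhib = normalized[list(inhib)].mean(axis=1)
    mean_ctrl = normalized[list(ctrl)].mean(axis=1)
    evaluable = mean_ctrl > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(evaluable, mean_inhib / mean_ctrl.where(evaluable), np.nan)
    return pd.DataFrame(
        {
            "mean_inhibitor": mean_inhib,
            "mean_control": mean_ctrl,
            "response_ratio": ratio,
            # inclusive boundary, robust to round-off through the normalization
            "responder": evaluable & (ratio >= min_ratio * (1 - 1e-12)),
            "evaluable": evaluable,
        },
        index=normalized.index,
    )


def reciprocal_check(
    mirna_fc: pd.DataFrame,
    target_fc: pd.DataFrame,
    min_concordant: int | None = None,
) -> tuple[float, bool, pd.DataFrame]:
    """Score reciprocal regulation of a miRNA/target pair over time.

    Both inputs follow the ``timecourse_fc`` contract (columns
    ``timepoint, fold_change``).  A shared timepoint is concordant when
    the miRNA and target log2 fold changes are both nonzero and have
    opposite sign.  The score is concordant / shared; the flag is True
    when the concordant count reaches ``min_concordant`` (default
    ``ceil(shared / 2) + 1``, i.e. a strict majority plus one).

    Returns (score, flag, per-timepoint detail frame).
    """
    m = mirna_fc.set_index("timepoint")["fold_change"]
    t = target_fc.set_index("timepoint")["fold_change"]
    shared = m.index.intersection(t.index)
    if len(shared) == 0:
        raise ValueError("no shared timepoints between miRNA and target time courses")
    lm = np.log2(m.loc[shared].to_numpy(dtype=float))
    lt = np.log2(t.loc[shared].to_numpy(dtype=float))
    concordant = (np.sign(lm) == -np.sign(lt)) & (lm != 0) & (lt != 0)
    if min_concordant is None:
        min_concordant = int(np.ceil(len(shared) / 2)) + 1
    score = float(concordant.sum() / len(shared))
    flag = bool(concordant.sum() >= min_concordant)
    detail = pd.DataFrame(
        {
            "timepoint": shared,
            "mirna_log2_fc": lm,
            "target_log2_fc": lt,
            "concordant": concordant,
        }
    )
    return score, flag, detail
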