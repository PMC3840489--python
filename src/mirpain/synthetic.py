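"""Synthetic pipeline inputs with planted, machine-readable ground truth.

Every downstream stage of the pipeline can be exercised end to end
without animal data: these generators emulate the five input kinds —
miRNA expression arrays, qPCR Ct tables, per-algorithm target prediction
tables, digital count matrices with housekeeping flags, and von Frey
trial tables — each with known planted effects recorded in a separate
:class:`GroundTruth` object, never embedded in the data tables.

Noise models (the study reports none):

* array intensities are log-normal around a per-miRNA log2 baseline,
  with multiplicative noise of a given coefficient of variation on the
  linear scale — positive and right-skewed, as array intensities are;
* Ct values receive additive Gaussian noise in cycles;
* digital counts receive multiplicative log-normal noise ("dispersion"
  is its CV), so zero dispersion recovers planted ratios exactly;
* withdrawal counts are binomial draws from a logistic psychometric
  function of log10 force with floor and ceiling, the standard
  psychophysics form.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .behavior import DEFAULT_FILAMENTS_G, DEFAULT_N_TRIALS
from .relquant import CT_COLUMNS
from .screen import DESIGN_COLUMNS, GROUP_SHAM, GROUP_TUMOUR, ExpressionMatrix


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class ArraySimConfig:
    """Conditions of the simulated miRNA array screen.

    Defaults mirror the study's screen: 615 assayed mouse miRNAs, three
    biological replicates per group, with planted up-/down-regulated
    subsets at a linear fold change ``planted_fc``.
    """

    n_mirnas: int = 615
    n_per_group: int = 3
    n_up: int = 26
    n_down: int = 31
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 2.0
    planted_fc: float = 3.0
    noise_cv: float = 0.05
    timepoint: str = "PID-8"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1:
            raise ConfigurationError(f"n_mirnas must be >= 1, got {self.n_mirnas}")
        if self.n_per_group < 1:
            raise ConfigurationError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if self.n_up < 0 or self.n_down < 0:
            raise ConfigurationError("n_up and n_down must be nonnegative")
        if self.n_up + self.n_down > self.n_mirnas:
            raise ConfigurationError(
                f"n_up + n_down ({self.n_up + self.n_down}) exceeds n_mirnas ({self.n_mirnas})"
            )
        if not self.planted_fc > 1:
            raise ConfigurationError(f"planted_fc must be > 1, got {self.planted_fc}")
        if self.noise_cv < 0:
            raise ConfigurationError(f"noise_cv must be >= 0, got {self.noise_cv}")


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Conditions of the simulated von Frey time course.

    The tumour group's 50%-threshold trajectory declines over
    post-implantation days; sham thresholds stay at baseline.  Withdrawal
    probability at force F is
    ``floor + (ceiling - floor) * logistic(slope * (log10 F - log10 threshold))``.
    """

    filaments_g: tuple = DEFAULT_FILAMENTS_G
    n_trials: int = DEFAULT_N_TRIALS
    days: tuple = (0, 2, 4, 6, 8)
    n_mice_per_group: int = 6
    baseline_threshold_g: float = 0.6
    tumour_threshold_trajectory: dict = field(
        default_factory=lambda: {0: 0.6, 2: 0.45, 4: 0.3, 6: 0.15, 8: 0.05}
    )
    slope: float = 4.0
    floor: float = 0.0
    ceiling: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        fil = np.asarray(self.filaments_g, dtype=float)
        if fil.size < 2 or not np.all(np.diff(fil) > 0) or not np.all(fil > 0):
            raise ConfigurationError(
                f"filaments_g must be >= 2 strictly increasing positive forces, got {self.filaments_g}"
            )
        if self.n_trials < 1:
            raise ConfigurationError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.n_mice_per_group < 1:
            raise ConfigurationError(f"n_mice_per_group must be >= 1, got {self.n_mice_per_group}")
        if not 0 <= self.floor < self.ceiling <= 1:
            raise ConfigurationError(
                f"require 0 <= floor < ceiling <= 1, got floor={self.floor} ceiling={self.ceiling}"
            )
        if not self.baseline_threshold_g > 0:
            raise ConfigurationError("baseline_threshold_g must be positive")
        missing = [d for d in self.days if d not in self.tumour_threshold_trajectory]
        if missing:
            raise ConfigurationError(
                f"tumour_threshold_trajectory missing days {missing}"
            )
        if any(v <= 0 for v in self.tumour_threshold_trajectory.values()):
            raise ConfigurationError("tumour_threshold_trajectory thresholds must be positive")


@dataclass
class GroundTruth:
    """Planted effects recorded alongside each generated dataset."""

    planted_up: set = field(default_factory=set)
    planted_down: set = field(default_factory=set)
    planted_fc_map: dict = field(default_factory=dict)
    planted_targets: dict = field(default_factory=dict)
    planted_responders: set = field(default_factory=set)
    true_thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.planted_up & self.planted_down
        if overlap:
            raise ConfigurationError(f"planted_up and planted_down overlap: {sorted(overlap)}")

    def to_jsonable(self) -> dict:
        return {
            "planted_up": sorted(self.planted_up),
            "planted_down": sorted(self.planted_down),
            "planted_fc_map": {str(k): v for k, v in self.planted_fc_map.items()},
            "planted_targets": {k: sorted(v) for k, v in self.planted_targets.items()},
            "planted_responders": sorted(self.planted_responders),
            "true_thresholds": {f"{m}|{d}": v for (m, d), v in self.true_thresholds.items()},
        }


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given linear-scale CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def gen_expression(config: ArraySimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a miRNA expression array experiment with planted effects.

    Planted-up miRNAs have tumour-group expected linear mean equal to
    ``planted_fc`` times the sham mean; planted-down symmetric.  Returns
    the matrix (with its design table) and the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    ids = [f"mmu-sim-miR-{i:04d}" for i in range(config.n_mirnas)]
    baseline = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_mirnas)

    # plant within the array's dynamic range: fold changes of probes at the
    # distribution extremes are not measurable after quantile normalization
    # (no headroom in the shared reference distribution), as on real arrays
    n_planted = config.n_up + config.n_down
    order = np.argsort(baseline)
    margin = int(np.floor(0.05 * config.n_mirnas))
    eligible = order[margin : config.n_mirnas - margin] if config.n_mirnas - 2 * margin >= n_planted else order
    planted = rng.choice(eligible, size=n_planted, replace=False)
    up_idx, down_idx = planted[: config.n_up], planted[config.n_up :]
    tumour_mean = baseline.copy()
    tumour_mean[up_idx] *= config.planted_fc
    tumour_mean[down_idx] /= config.planted_fc

    n = config.n_per_group
    sham_vals = baseline[:, None] * _lognormal_noise(rng, config.noise_cv, (config.n_mirnas, n))
    tum_vals = tumour_mean[:, None] * _lognormal_noise(rng, config.noise_cv, (config.n_mirnas, n))

    sham_arrays = [f"{GROUP_SHAM}-{config.timepoint}-r{i + 1}" for i in range(n)]
    tum_arrays = [f"{GROUP_TUMOUR}-{config.timepoint}-r{i + 1}" for i in range(n)]
    values = pd.DataFrame(
        np.hstack([sham_vals, tum_vals]), index=ids, columns=sham_arrays + tum_arrays
    )
    values.index.name = "mirna_id"
    design = pd.DataFrame(
        {
            "array_id": sham_arrays + tum_arrays,
            "group": [GROUP_SHAM] * n + [GROUP_TUMOUR] * n,
            "replicate": list(range(1, n + 1)) * 2,
            "timepoint": config.timepoint,
        },
        columns=list(DESIGN_COLUMNS),
    )
    truth = GroundTruth(
        planted_up={ids[i] for i in up_idx},
        planted_down={ids[i] for i in down_idx},
        planted_fc_map={
            **{ids[i]: config.planted_fc for i in up_idx},
            **{ids[i]: 1.0 / config.planted_fc for i in down_idx},
        },
    )
    return ExpressionMatrix(values=values, design=design), truth


def gen_ct(
    targets: list[str],
    true_fc_map: dict,
    n_bio: int = 3,
    n_tech: int = 3,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    reference: str = "sno202",
    treatment: str = GROUP_TUMOUR,
    control: str = GROUP_SHAM,
    reference_ct: float = 20.0,
    baseline_dct: float = 5.0,
) -> pd.DataFrame:
    """Simulate a long-format Ct table with known fold changes.

    For each target assay the treatment-group expected ddCt equals
    ``-log2(true_fc)``; the reference assay's Ct does not depend on group.
    """
    if n_tech < 1:
        raise ConfigurationError(f"n_tech must be >= 1, got {n_tech}")
    if n_bio < 1:
        raise ConfigurationError(f"n_bio must be >= 1, got {n_bio}")
    for tgt in targets:
        fc = true_fc_map.get(tgt)
        if fc is None or not fc > 0:
            raise ConfigurationError(f"true fold change for {tgt!r} must be positive, got {fc}")
    rng = np.random.default_rng(seed)
    rows = []
    for group in (control, treatment):
        for b in range(1, n_bio + 1):
            sample = f"{group}-s{b}"
            for assay in [reference] + list(targets):
                if assay == reference:
                    expected = reference_ct
                    role = "reference"
                else:
                    dct = baseline_dct
                    if group == treatment:
                        dct = baseline_dct - np.log2(true_fc_map[assay])
                    expected = reference_ct + dct
                    role = "target"
                for rep in range(1, n_tech + 1):
                    ct = expected + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                    rows.append((sample, group, assay, role, rep, ct))
    return pd.DataFrame(rows, columns=list(CT_COLUMNS))


def gen_predictions(
    n_algorithms: int,
    genes: list[str],
    planted: dict,
    support: dict,
    background_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-algorithm target prediction tables in long format.

    ``planted`` maps miRNA -> gene set; each planted gene is predicted by
    exactly ``support[gene]`` distinct algorithms (a seeded random
    subset).  Remaining genes are predicted independently by each
    algorithm at ``background_rate``.
    """
    if n_algorithms < 1:
        raise ConfigurationError(f"n_algorithms must be >= 1, got {n_algorithms}")
    if not 0 <= background_rate <= 1:
        raise ConfigurationError(f"background_rate must be in [0, 1], got {background_rate}")
    for gene, s in support.items():
        if not 0 <= s <= n_algorithms:
            raise ConfigurationError(
                f"support for {gene!r} is {s}, outside [0, {n_algorithms}]"
            )
    rng = np.random.default_rng(seed)
    algorithms = [f"algo-{i + 1:02d}" for i in range(n_algorithms)]
    rows = []
    for mirna, gene_set in planted.items():
        for gene in sorted(gene_set):
            s = support.get(gene, 1)
            chosen = rng.choice(n_algorithms, size=s, replace=False)
            for a in sorted(chosen):
                rows.append((algorithms[a], mirna, gene))
    planted_genes = set().union(*planted.values()) if planted else set()
    for mirna in planted:
        for gene in genes:
            if gene in planted_genes:
                continue
            if background_rate > 0:
                hits = rng.random(n_algorithms) < background_rate
                for a in np.nonzero(hits)[0]:
                    rows.append((algorithms[a], mirna, gene))
    return pd.DataFrame(rows, columns=["algorithm", "mirna", "gene"])


def gen_counts(
    genes: list[str],
    housekeeping: list[str],
    responders: set,
    response_ratio: float = 1.5,
    n_per_group: int = 3,
    dispersion: float = 0.0,
    seed: int = 0,
    base_count: float = 500.0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Simulate a digital count matrix with planted inhibitor responders.

    Responder genes have expected housekeeping-normalized
    inhibitor/control ratio equal to ``response_ratio``; housekeeping
    genes are group-invariant in expectation.  Per-sample library-size
    factors are drawn so that normalization is actually exercised.
    Returns (counts genes x samples, housekeeping flags, sample design).
    """
    overlap = set(housekeeping) & set(responders)
    if overlap:
        raise ConfigurationError(f"housekeeping and responder sets overlap: {sorted(overlap)}")
    if not response_ratio > 0:
        raise ConfigurationError(f"response_ratio must be positive, got {response_ratio}")
    if dispersion < 0:
        raise ConfigurationError(f"dispersion must be >= 0, got {dispersion}")
    rng = np.random.default_rng(seed)
    all_genes = list(housekeeping) + [g for g in genes if g not in housekeeping]
    base = base_count * 2.0 ** rng.normal(0.0, 1.0, len(all_genes))
    base_s = pd.Series(base, index=all_genes)

    samples, conditions = [], []
    for cond in ("mismatch-control", "inhibitor"):
        for i in range(1, n_per_group + 1):
            samples.append(f"{cond}-s{i}")
            conditions.append(cond)
    design = pd.Series(conditions, index=samples)

    # per-sample depth factor: exercises housekeeping normalization
    depth = 2.0 ** rng.uniform(-0.5, 0.5, len(samples))
    counts = pd.DataFrame(index=all_genes, columns=samples, dtype=float)
    for j, (sample, cond) in enumerate(zip(samples, conditions)):
        mean = base_s.copy()
        if cond == "inhibitor":
            resp = [g for g in all_genes if g in responders]
            mean.loc[resp] *= response_ratio
        noise = _lognormal_noise(rng, dispersion, len(all_genes))
        counts[sample] = mean.to_numpy() * depth[j] * noise
    hk_flags = pd.Series([g in set(housekeeping) for g in all_genes], index=all_genes)
    return counts, hk_flags, design


def gen_behavior(config: BehaviorSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate trial-level von Frey data from a logistic psychometric.

    Withdrawal counts per (mouse, day, filament) are binomial with
    ``n_trials`` trials and probability
    ``floor + (ceiling - floor) * logistic(slope * (log10 F - log10 threshold))``
    where sham thresholds stay at baseline and tumour thresholds follow
    the configured trajectory.  Returns the long table and ground truth.
    """
    rng = np.random.default_rng(config.seed)
    forces = np.asarray(config.filaments_g, dtype=float)
    rows = []
    truth = GroundTruth()
    for group in (GROUP_SHAM, GROUP_TUMOUR):
        for m in range(1, config.n_mice_per_group + 1):
            mouse = f"{group}-m{m:03d}"
            for day in config.days:
                thr = (
                    config.baseline_threshold_g
                    if group == GROUP_SHAM
                    else config.tumour_threshold_trajectory[day]
                )
                truth.true_thresholds[(mouse, day)] = thr
                p = config.floor + (config.ceiling - config.floor) * expit(
                    config.slope * (np.log10(forces) - np.log10(thr))
                )
                withdrawals = rng.binomial(config.n_trials, p)
                for f, w in zip(forces, withdrawals):
                    rows.append((mouse, group, day, f, config.n_trials, int(w)))
    data = pd.DataFrame(
        rows, columns=["mouse", "group", "day", "force_g", "n_trials", "n_withdrawals"]
    )
    return data, truth
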