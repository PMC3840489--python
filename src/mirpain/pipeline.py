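"""End-to-end orchestration: simulate -> screen -> relquant -> targets -> behavior.

A run is described by a :class:`RunConfig` (usually loaded from YAML)
holding per-stage parameter blocks and a global seed.  Every tabular
output carries a metadata header of ``#``-prefixed comment lines
(package version, producing stage, parameters, seed), and a JSON
manifest lists every artifact a run wrote.  Reruns with the same config
and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .behavior import group_timecourse
from .relquant import ddct
from .screen import (
    ExpressionMatrix,
    ScreenConfig,
    group_stats,
    quantile_normalize,
    screen,
    screen_report,
)
from .synthetic import (
    ArraySimConfig,
    BehaviorSimConfig,
    gen_behavior,
    gen_counts,
    gen_ct,
    gen_expression,
    gen_predictions,
)
from .targets import normalize_counts, response_filter, tally

log = logging.getLogger("mirpain")

STAGES = ("simulate", "screen", "relquant", "targets", "behavior")

_CONFIG_BLOCKS = {"stages", "seed", "out_dir", "inputs", "array", "screen",
                  "relquant", "targets", "behavior", "log_level"}


@dataclass
class RunConfig:
    """Validated run configuration; defaults are the study's stated values."""

    stages: list = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    out_dir: str = "mirpain-out"
    inputs: dict = field(default_factory=dict)   # stage -> explicit input paths
    array: dict = field(default_factory=dict)    # ArraySimConfig overrides
    screen: dict = field(default_factory=dict)   # ScreenConfig overrides
    relquant: dict = field(default_factory=dict)
    targets: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        errors = []
        unknown = set(raw) - _CONFIG_BLOCKS
        if unknown:
            errors.append(f"unknown config keys: {sorted(unknown)}")
        stages = raw.get("stages", list(STAGES))
        bad = [s for s in stages if s not in STAGES]
        if bad:
            errors.append(f"unknown stages: {bad} (allowed: {list(STAGES)})")
        if "simulate" not in stages:
            inputs = raw.get("inputs", {})
            for s in stages:
                if s not in inputs:
                    errors.append(f"stage {s!r} selected without 'simulate' but no inputs.{s} path block")
        if errors:
            raise ValueError("invalid run config:\n  " + "\n  ".join(errors))
        return cls(
            stages=list(stages),
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "mirpain-out")),
            inputs=dict(raw.get("inputs", {})),
            array=dict(raw.get("array", {})),
            screen=dict(raw.get("screen", {})),
            relquant=dict(raw.get("relquant", {})),
            targets=dict(raw.get("targets", {})),
            behavior=dict(raw.get("behavior", {})),
            log_level=str(raw.get("log_level", "INFO")),
        )


def write_table(path: Path, frame: pd.DataFrame, stage: str, params: dict,
                seed: int, index: bool = False, sep: str = "\t") -> None:
    """Write a TSV/CSV with a ``#`` metadata header (version, stage, params, seed)."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# mirpain {__version__}\n# stage: {stage}\n# seed: {seed}\n")
        for k, v in sorted(params.items()):
            fh.write(f"# {k}: {v}\n")
        frame.to_csv(fh, sep=sep, index=index)


def read_table(path: str | Path, sep: str = "\t", **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", **kw)


def _simulate(cfg: RunConfig, out: Path, manifest: list) -> dict:
    seed = cfg.seed
    arr_cfg = ArraySimConfig(seed=seed, **cfg.array)
    # null timepoint (no planted effects) at PID-4 and planted effects at PID-8,
    # mirroring the two screened post-implantation days
    null_cfg = ArraySimConfig(
        **{**arr_cfg.__dict__, "n_up": 0, "n_down": 0,
           "timepoint": "PID-4", "seed": seed + 1},
    )
    mat8, truth = gen_expression(arr_cfg)
    mat4, _ = gen_expression(null_cfg)
    values = pd.concat([mat4.values, mat8.values], axis=1)
    design = pd.concat([mat4.design, mat8.design], ignore_index=True)

    params = {k: getattr(arr_cfg, k) for k in ("n_mirnas", "n_per_group", "n_up",
                                               "n_down", "planted_fc", "noise_cv")}
    paths = {}

    def _emit(name, frame, params, index=False, sep=","):
        p = out / name
        write_table(p, frame, "simulate", params, seed, index=index, sep=sep)
        manifest.append({"path": p.name, "stage": "simulate", "params": params, "seed": seed})
        return p

    paths["expression"] = _emit("expression.csv", values, params, index=True)
    paths["design"] = _emit("design.csv", design, params)

    planted_fc = {m: truth.planted_fc_map[m] for m in sorted(truth.planted_fc_map)}
    demo_targets = sorted(truth.planted_up)[:2] or ["mmu-sim-miR-0000"]
    fc_map = {t: planted_fc.get(t, 4.0) for t in demo_targets}
    ct = gen_ct(demo_targets, fc_map, ct_noise_sd=cfg.relquant.get("ct_noise_sd", 0.0),
                seed=seed + 2)
    paths["ct"] = _emit("ct.csv", ct, {"targets": demo_targets, "fc_map": fc_map})

    tgt_block = cfg.targets
    mirna = demo_targets[0]
    n_algo = tgt_block.get("n_algorithms", 14)
    n_consensus = tgt_block.get("n_consensus", 10)
    n_background = tgt_block.get("n_background", 60)
    n_responders = tgt_block.get("n_responders", 4)
    genes = [f"Gene{i:03d}" for i in range(n_background)]
    consensus_genes = [f"Target{i:02d}" for i in range(n_consensus)]
    support = {g: (2 + i % (n_algo - 1)) for i, g in enumerate(consensus_genes)}
    predictions = gen_predictions(
        n_algo, genes, {mirna: set(consensus_genes)}, support,
        background_rate=tgt_block.get("background_rate", 0.0), seed=seed + 3,
    )
    paths["predictions"] = _emit(
        "predictions.csv", predictions, {"mirna": mirna, "n_algorithms": n_algo}
    )

    housekeeping = ["Cltc", "Gapdh", "Gusb", "Hprt", "Tubb5"]
    responders = set(consensus_genes[:n_responders])
    counts, hk_flags, count_design = gen_counts(
        consensus_genes, housekeeping, responders,
        response_ratio=tgt_block.get("response_ratio", 1.5),
        dispersion=tgt_block.get("dispersion", 0.0), seed=seed + 4,
    )
    counts_out = counts.copy()
    counts_out.insert(0, "housekeeping", hk_flags.astype(int))
    counts_out.index.name = "gene"
    paths["counts"] = _emit("counts.csv", counts_out, {"responders": sorted(responders)},
                            index=True)
    paths["count_design"] = _emit(
        "count_design.csv",
        count_design.rename("condition").rename_axis("sample").reset_index(), {}
    )

    sim_fields = {f for f in BehaviorSimConfig.__dataclass_fields__ if f != "seed"}
    beh_cfg = BehaviorSimConfig(
        seed=seed + 5, **{k: v for k, v in cfg.behavior.items() if k in sim_fields}
    )
    beh, beh_truth = gen_behavior(beh_cfg)
    paths["behavior"] = _emit("behavior.csv", beh, {"n_trials": beh_cfg.n_trials})

    truth.planted_targets = {mirna: set(consensus_genes)}
    truth.planted_responders = responders
    truth.true_thresholds = beh_truth.true_thresholds
    gt_path = out / "ground_truth.json"
    gt_path.write_text(json.dumps(truth.to_jsonable(), indent=2, sort_keys=True) + "\n")
    manifest.append({"path": gt_path.name, "stage": "simulate", "params": {}, "seed": seed})
    paths["ground_truth"] = gt_path
    return {"paths": paths, "truth": truth, "mirna": mirna,
            "demo_targets": demo_targets, "fc_map": fc_map}


def run(config: RunConfig) -> dict:
    """Execute the selected stages; returns ``{"manifest": ..., "summary": ...}``.

    Each stage reads the documented CSV contracts (from a prior simulate
    stage or from ``config.inputs``) and writes TSV results with metadata
    headers into ``config.out_dir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list = []
    summary: dict = {"seed": config.seed}
    sim = None

    if "simulate" in config.stages:
        log.info("stage simulate -> %s", out)
        sim = _simulate(config, out, manifest)

    def _input(stage: str, key: str, default_name: str) -> Path:
        if sim is not None and key in sim["paths"]:
            return sim["paths"][key]
        block = config.inputs.get(stage, {})
        if key in block:
            return Path(block[key])
        return out / default_name

    if "screen" in config.stages:
        values = read_table(_input("screen", "expression", "expression.csv"),
                            sep=",", index_col=0)
        design = read_table(_input("screen", "design", "design.csv"), sep=",")
        matrix = ExpressionMatrix(values=values, design=design)
        scfg = ScreenConfig(**config.screen)
        normalized = quantile_normalize(matrix.values)
        norm_matrix = ExpressionMatrix(values=normalized, design=matrix.design)
        screen_summary = {}
        for tp in matrix.timepoints():
            stats = group_stats(norm_matrix, tp, scfg)
            result = screen(stats, scfg)
            report = screen_report(result, normalized, scfg)
            p = out / f"screen_{tp}.tsv"
            params = {"k": scfg.k, "fc_primary": scfg.fc_primary,
                      "fc_secondary": scfg.fc_secondary, "sd_mode": scfg.sd_mode,
                      "timepoint": tp}
            write_table(p, result.rename_axis("mirna_id"), "screen", params,
                        config.seed, index=True)
            manifest.append({"path": p.name, "stage": "screen", "params": params,
                             "seed": config.seed})
            if report["heatmap"] is not None:
                hp = out / f"screen_{tp}_heatmap.tsv"
                write_table(hp, report["heatmap"].rename_axis("mirna_id"), "screen",
                            params, config.seed, index=True)
                manifest.append({"path": hp.name, "stage": "screen", "params": params,
                                 "seed": config.seed})
            screen_summary[tp] = report["summary"]
        summary["screen"] = screen_summary

    if "relquant" in config.stages:
        ct = read_table(_input("relquant", "ct", "ct.csv"), sep=",")
        rq = config.relquant
        reference = rq.get("reference", "sno202")
        treatment = rq.get("treatment", "tumour")
        control = rq.get("control", "sham")
        targets_list = rq.get("targets") or sorted(
            ct.loc[ct["role"] == "target", "assay"].unique()
        )
        rows = []
        for tgt in targets_list:
            res = ddct(ct, tgt, reference, treatment, control,
                       max_rep_sd=rq.get("max_rep_sd", 0.5))
            rows.append({
                "target": tgt, "reference": reference,
                "ddct": res.ddct, "fold_change": res.fold_change,
                "n_treatment": res.n_treatment, "n_control": res.n_control,
                "n_qc_flags": len(res.qc_flags),
            })
        rq_frame = pd.DataFrame(rows)
        p = out / "relquant.tsv"
        params = {"reference": reference, "treatment": treatment, "control": control}
        write_table(p, rq_frame, "relquant", params, config.seed)
        manifest.append({"path": p.name, "stage": "relquant", "params": params,
                         "seed": config.seed})
        summary["relquant"] = {r["target"]: r["fold_change"] for r in rows}

    if "targets" in config.stages:
        predictions = read_table(_input("targets", "predictions", "predictions.csv"), sep=",")
        counts_raw = read_table(_input("targets", "counts", "counts.csv"), sep=",",
                                index_col=0)
        count_design = read_table(_input("targets", "count_design", "count_design.csv"),
                                  sep=",").set_index("sample")["condition"]
        tcfg = config.targets
        mirna = tcfg.get("mirna") or (sim["mirna"] if sim else predictions["mirna"].iloc[0])
        consensus = tally(predictions, mirna,
                          min_algorithms=tcfg.get("min_algorithms", 2))
        hk_flags = counts_raw["housekeeping"].astype(bool)
        counts = counts_raw.drop(columns=["housekeeping"])
        normalized = normalize_counts(counts, hk_flags)
        candidates = consensus.loc[consensus["consensus"], "gene"]
        norm_candidates = normalized.loc[normalized.index.intersection(candidates)]
        response = response_filter(norm_candidates, count_design,
                                   min_ratio=tcfg.get("min_ratio", 1.5))
        params = {"mirna": mirna, "min_algorithms": tcfg.get("min_algorithms", 2),
                  "min_ratio": tcfg.get("min_ratio", 1.5)}
        pc = out / "consensus.tsv"
        write_table(pc, consensus, "targets", params, config.seed)
        pr = out / "target_response.tsv"
        write_table(pr, response.rename_axis("gene"), "targets", params, config.seed,
                    index=True)
        manifest += [
            {"path": pc.name, "stage": "targets", "params": params, "seed": config.seed},
            {"path": pr.name, "stage": "targets", "params": params, "seed": config.seed},
        ]
        summary["targets"] = {
            "n_predicted": int(consensus["gene"].nunique()),
            "n_consensus": int(consensus["consensus"].sum()),
            "n_responders": int(response["responder"].sum()),
        }

    if "behavior" in config.stages:
        beh = read_table(_input("behavior", "behavior", "behavior.csv"), sep=",")
        bcfg = config.behavior
        q = bcfg.get("quantile", 50.0)
        auc_scale = bcfg.get("auc_scale", "log10")
        tc = group_timecourse(beh, q=q, auc_scale=auc_scale)
        params = {"quantile": q, "auc_scale": auc_scale}
        for name, frame in (("behavior_per_animal.tsv", tc["per_animal"]),
                            ("behavior_group.tsv", tc["summary"]),
                            ("behavior_frequency.tsv", tc["frequency"])):
            p = out / name
            write_table(p, frame, "behavior", params, config.seed)
            manifest.append({"path": p.name, "stage": "behavior", "params": params,
                             "seed": config.seed})
        g = tc["summary"]
        summary["behavior"] = {
            "days": sorted(g["day"].unique().tolist()),
            "tumour_final_threshold": float(
                g.loc[(g["group"] == "tumour"), "threshold_mean"].iloc[-1]
            ) if (g["group"] == "tumour").any() else None,
        }

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(
        {"version": __version__, "seed": config.seed, "artifacts": manifest,
         "summary": _jsonable(summary)},
        indent=2, sort_keys=True) + "\n")
    return {"manifest": manifest, "manifest_path": manifest_path, "summary": summary}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, set):
        return [_jsonable(v) for v in sorted(obj)]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def validate_inputs(paths: dict) -> dict:
    """Check input files against the documented CSV contracts.

    ``paths`` maps kind (expression, design, ct, predictions, counts,
    behavior) to file path.  Returns per-file reports with line-level
    diagnostics; never raises on content problems.
    """
    report = {}
    for kind, path in paths.items():
        entry = {"path": str(path), "ok": True, "problems": []}
        try:
            if kind == "expression":
                frame = read_table(path, sep=",", index_col=0)
                dup = frame.index[frame.index.duplicated()].unique().tolist()
                if dup:
                    entry["problems"].append(f"duplicated miRNA id(s): {dup}")
                if (frame.to_numpy(dtype=float) < 0).any():
                    entry["problems"].append("negative intensities present")
            elif kind == "design":
                frame = read_table(path, sep=",")
                missing = [c for c in ("array_id", "group", "replicate", "timepoint")
                           if c not in frame.columns]
                if missing:
                    entry["problems"].append(f"missing columns: {missing}")
            elif kind == "ct":
                frame = read_table(path, sep=",")
                missing = [c for c in ("sample", "group", "assay", "role", "replicate", "ct")
                           if c not in frame.columns]
                if missing:
                    entry["problems"].append(f"missing columns: {missing}")
            elif kind == "predictions":
                frame = read_table(path, sep=",")
                missing = [c for c in ("algorithm", "mirna", "gene") if c not in frame.columns]
                if missing:
                    entry["problems"].append(f"missing columns: {missing}")
            elif kind == "counts":
                frame = read_table(path, sep=",", index_col=0)
                if "housekeeping" not in frame.columns:
                    entry["problems"].append("missing housekeeping flag column")
            elif kind == "behavior":
                frame = read_table(path, sep=",")
                missing = [c for c in ("mouse", "group", "day", "force_g",
                                       "n_trials", "n_withdrawals") if c not in frame.columns]
                if missing:
                    entry["problems"].append(f"missing columns: {missing}")
                else:
                    bad = frame.index[
                        (frame["n_withdrawals"] > frame["n_trials"])
                        | (frame["n_withdrawals"] < 0)
                    ].tolist()
                    for row in bad:
                        entry["problems"].append(
                            f"row {row}: withdrawals outside [0, trials]"
                        )
            else:
                entry["problems"].append(f"unknown input kind {kind!r}")
        except Exception as exc:  # unreadable file is a report, not a crash
            entry["problems"].append(f"unreadable: {exc}")
        entry["ok"] = not entry["problems"]
        report[kind] = entry
    return report
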