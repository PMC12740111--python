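"""End-to-end orchestration: ingest/simulate -> filter -> DMS -> entropy ->
ROC -> clocks -> age deceleration, with a structured JSON + text report.

Every stage runs separately per modification channel (6mA and 5mC are never
mixed in one model); every filter logs input/output counts; every random
stage derives its seed from the single pipeline seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from . import clock as clock_mod
from . import dms as dms_mod
from . import entropy as entropy_mod
from . import roc as roc_mod
from .io import (
    MOD_CODES,
    MethylationMatrix,
    Sample,
    build_matrix,
    filter_coverage,
    global_methylation,
    read_bedmethyl,
    read_feature_bed,
    read_manifest,
)
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

MOD_LABELS = {"a": "6mA", "m": "5mC"}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Single-document configuration for one pipeline run."""

    mode: str = "simulate"                  # simulate | bedmethyl_dir
    bedmethyl_dir: str | None = None
    manifest_path: str | None = None
    feature_bed: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mod_codes: tuple[str, ...] = MOD_CODES
    min_cov: int = 10
    fdr: float = 0.05
    roc_p_threshold: float = 0.05
    roc_r2_threshold: float = roc_mod.DEFAULT_R2_THRESHOLD
    clock_types: tuple[str, ...] = (
        "elasticnet_levels", "ridge_dms", "elasticnet_entropy",
    )
    n_train: int = 10
    n_perm: int = 100
    run_permutation: bool = False
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "bedmethyl_dir"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "bedmethyl_dir" and not (self.bedmethyl_dir and self.manifest_path):
            raise ValueError("bedmethyl_dir mode requires bedmethyl_dir and manifest_path")
        if self.min_cov < 1:
            raise ValueError(f"min_cov must be >= 1, got {self.min_cov}")
        if not 0 < self.fdr < 1:
            raise ValueError(f"fdr must lie in (0, 1), got {self.fdr}")
        if not (0 < self.roc_p_threshold < 1 and 0 < self.roc_r2_threshold < 1):
            raise ValueError("ROC thresholds must lie in (0, 1)")
        unknown = set(self.clock_types) - set(clock_mod.CLOCK_MIXING)
        if unknown:
            raise ValueError(f"unknown clock types: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim = doc.pop("simulation", None)
        cfg = cls(**doc)
        if sim is not None:
            for key in ("ages_days", "baseline_beta_params", "methylated_beta_params",
                        "dynamic_beta_params", "mod_codes"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def _jsonable(obj: Any) -> Any:
    """Recursively convert report values to plain JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj, key=str) if True] if isinstance(obj, set) else [
            _jsonable(v) for v in obj
        ]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _load_inputs(config: PipelineConfig):
    if config.mode == "simulate":
        cohort = simulate_cohort(config.simulation)
        return cohort.tables, cohort.manifest, cohort.truth
    manifest = read_manifest(config.manifest_path)
    tables = {}
    base = Path(config.bedmethyl_dir)
    for s in manifest:
        path = base / f"{s.sample_id}.bedmethyl.tsv"
        if not path.exists():
            raise FileNotFoundError(f"no bedMethyl file for sample {s.sample_id}: {path}")
        tables[s.sample_id] = read_bedmethyl(path, config.mod_codes)
    return tables, manifest, None


def _channel_analysis(
    mat: MethylationMatrix,
    mod: str,
    config: PipelineConfig,
    untreated: list[Sample],
    rng_seed: int,
) -> dict[str, Any]:
    """Run every per-channel stage; returns a report section."""
    out: dict[str, Any] = {"mod_code": mod, "label": MOD_LABELS.get(mod, mod)}
    ages = sorted({s.age_days for s in untreated})
    young_group = [s.sample_id for s in untreated if s.age_days == ages[0]]
    old_group = [s.sample_id for s in untreated if s.age_days == ages[-1]]
    group_of = {s.sample_id: s.group for s in untreated}
    groups = sorted({s.group for s in untreated},
                    key=lambda g: min(s.age_days for s in untreated if s.group == g))

    # --- differential methylation ------------------------------------
    records = dms_mod.call_dms(mat, young_group, old_group, fdr=config.fdr)
    n_hypo, n_hyper = (0, 0)
    if records:
        n_hypo, n_hyper = dms_mod.direction_proportions(records)
    out["dms"] = {
        "n_sites_tested": mat.n_sites,
        "n_dms": len(records),
        "n_hypo": n_hypo,
        "n_hyper": n_hyper,
        "young_group": young_group,
        "old_group": old_group,
    }
    dms_keys = [r.key for r in records]

    # --- genomic context ---------------------------------------------
    if config.feature_bed:
        features = read_feature_bed(config.feature_bed)
        records = dms_mod.annotate_context(records, features)
        counts: dict[str, int] = {}
        for r in records:
            counts[r.context] = counts.get(r.context, 0) + 1
        out["dms"]["context_counts"] = counts
    out["_dms_records"] = records

    # --- entropy -------------------------------------------------------
    untreated_ids = [s.sample_id for s in untreated]
    ent: dict[str, Any] = {}
    for label, site_set in (("genome_wide", None), ("dms_only", dms_keys or None)):
        if label == "dms_only" and not dms_keys:
            ent[label] = {"skipped": "no DMS called"}
            continue
        prof = entropy_mod.entropy_profile(mat, site_set, label=label)
        by_group = {
            g: [prof.per_sample_mean[sid] for sid in untreated_ids if group_of[sid] == g]
            for g in groups
        }
        cmp_res = entropy_mod.compare_groups(by_group)
        ent[label] = {
            "per_group_mean": {g: float(np.mean(v)) for g, v in by_group.items()},
            "per_group_sd": {g: float(np.std(v, ddof=1)) for g, v in by_group.items()},
            "comparison": cmp_res,
        }
    out["entropy"] = ent

    # --- rate of change ------------------------------------------------
    if dms_keys:
        untreated_mat = mat.subset_samples(untreated_ids)
        rocs = roc_mod.site_roc_table(untreated_mat, dms_keys)
        summary = roc_mod.mean_roc(rocs, config.roc_p_threshold, config.roc_r2_threshold)
        alt = roc_mod.mean_roc(rocs, config.roc_p_threshold, 0.5)
        out["roc"] = {
            "mean_slope_pct_per_week": summary.mean_slope,
            "sd_slope": summary.sd_slope,
            "n_retained": summary.n_retained,
            "r2_threshold": config.roc_r2_threshold,
            "alt_r2_0.5": {
                "mean_slope_pct_per_week": alt.mean_slope,
                "n_retained": alt.n_retained,
            },
        }
        out["_roc_slopes"] = roc_mod.retained_slopes(
            rocs, config.roc_p_threshold, config.roc_r2_threshold
        )
    else:
        out["roc"] = {"skipped": "no DMS called"}
        out["_roc_slopes"] = np.array([])

    # --- clocks --------------------------------------------------------
    train_ids, test_ids = clock_mod.split_train_test(
        untreated, config.n_train, seed=rng_seed
    )
    age_of = {s.sample_id: s.age_days for s in untreated}
    clocks: dict[str, Any] = {"train_ids": train_ids, "test_ids": test_ids}
    out["_models"] = {}
    for ctype in config.clock_types:
        needs_dms = clock_mod.CLOCK_FEATURES[ctype] != "levels"
        if needs_dms and not dms_keys:
            clocks[ctype] = {"skipped": "no DMS called"}
            continue
        feats = clock_mod.assemble_features(mat, ctype, dms=dms_keys or None)
        model = clock_mod.train_clock(
            feats.loc[train_ids], [age_of[s] for s in train_ids], ctype,
        )
        pred = clock_mod.predict_age(model, feats.loc[test_ids])
        mae, mre, r = clock_mod.evaluate_predictions(
            pred, [age_of[s] for s in test_ids]
        )
        stability = clock_mod.feature_stability(model)
        section: dict[str, Any] = {
            "training": model.training_metrics,
            "test": {"mae_days": mae, "mre_percent": mre, "pearson_r": r},
            "n_selected": len(model.selected_sites),
            "chosen_lambda": model.chosen_lambda,
            "stability": stability,
            "test_predictions": {
                sid: float(p) for sid, p in zip(test_ids, pred)
            },
        }
        if config.run_permutation:
            perm = clock_mod.permutation_test(
                feats.loc[train_ids], [age_of[s] for s in train_ids], ctype,
                n_perm=config.n_perm, seed=rng_seed + 1,
            )
            section["permutation"] = {
                "p_value": perm.p_value,
                "observed_cv_mae": perm.observed,
                "n_perm": config.n_perm,
            }
        clocks[ctype] = section
        out["_models"][ctype] = (model, feats)
    out["clocks"] = clocks
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and return the report dict (also written to disk
    when ``config.out_dir`` is set)."""

    def stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, exc) from exc
                logger.info("stage %s: done", name)
        return _Ctx()

    report: dict[str, Any] = {"config": _jsonable(dataclasses.asdict(config))}

    with stage("input"):
        tables, manifest, truth = _load_inputs(config)
        report["n_samples"] = len(manifest)

    with stage("global_methylation"):
        glob = {}
        for mod in config.mod_codes:
            per_sample_read = []
            per_sample_site = []
            for s in manifest:
                recs = [r for r in tables[s.sample_id] if r.key.mod_code == mod]
                if recs:
                    per_sample_read.append(global_methylation(recs, "read"))
                    per_sample_site.append(global_methylation(recs, "site"))
            glob[mod] = {
                "read_weighted_mean_pct": float(np.mean(per_sample_read)),
                "read_weighted_sd_pct": float(np.std(per_sample_read, ddof=1)),
                "site_weighted_mean_pct": float(np.mean(per_sample_site)),
            }
        report["global_methylation"] = glob

    with stage("coverage_filter"):
        n_before = {sid: len(t) for sid, t in tables.items()}
        filtered = {sid: filter_coverage(t, config.min_cov) for sid, t in tables.items()}
        report["coverage_filter"] = {
            "min_cov": config.min_cov,
            "rows_in": int(sum(n_before.values())),
            "rows_out": int(sum(len(t) for t in filtered.values())),
        }

    with stage("matrix"):
        matrix = build_matrix(filtered, manifest, min_cov=config.min_cov)
        report["matrix"] = {"n_sites": matrix.n_sites, "n_samples": matrix.n_samples}

    untreated = [s for s in manifest if s.treatment in ("none", "control")]
    treatments = sorted({s.treatment for s in manifest} - {"none", "control"})

    channels: dict[str, Any] = {}
    for mod in config.mod_codes:
        with stage(f"channel_{mod}"):
            cmat = matrix.subset_channel(mod)
            if cmat.n_sites < 2:
                channels[mod] = {"skipped": "fewer than 2 sites in channel"}
                continue
            channels[mod] = _channel_analysis(
                cmat, mod, config, untreated, rng_seed=config.seed,
            )

    with stage("cross_channel"):
        done = [m for m in config.mod_codes
                if "dms" in channels.get(m, {}) and channels[m]["dms"]["n_dms"] > 0]
        if len(done) == 2:
            a, m = done
            res = dms_mod.compare_proportions_chisq(
                (channels[a]["dms"]["n_hypo"], channels[a]["dms"]["n_hyper"]),
                (channels[m]["dms"]["n_hypo"], channels[m]["dms"]["n_hyper"]),
            )
            report["direction_chisq"] = res
            slopes_a = channels[a].get("_roc_slopes")
            slopes_m = channels[m].get("_roc_slopes")
            if slopes_a is not None and slopes_m is not None and (
                len(slopes_a) >= 3 and len(slopes_m) >= 3
            ):
                w_p, l_p = roc_mod.compare_roc(slopes_a, slopes_m)
                report["roc_comparison"] = {"wilcoxon_p": w_p, "levene_p": l_p}

    if treatments:
        with stage("age_deceleration"):
            decel: dict[str, Any] = {}
            old_age = max(s.age_days for s in untreated)
            control_ids = [s.sample_id for s in untreated if s.age_days == old_age]
            for mod in config.mod_codes:
                ch = channels.get(mod, {})
                models = ch.get("_models", {})
                if "elasticnet_levels" not in models:
                    continue
                model, feats = models["elasticnet_levels"]
                arms = {
                    t: feats.loc[[s.sample_id for s in manifest if s.treatment == t]]
                    for t in treatments
                }
                decel[mod] = clock_mod.age_deceleration_test(
                    model, feats.loc[control_ids], arms, old_age,
                )
            report["age_deceleration"] = decel

    if truth is not None:
        report["simulation_truth_summary"] = {
            "n_clock_sites": len(truth.clock_sites),
            "n_entropy_sites": len(truth.entropy_sites),
        }

    # strip private keys, keep channel sections
    report["channels"] = {
        mod: {k: v for k, v in ch.items() if not k.startswith("_")}
        for mod, ch in channels.items()
    }

    if config.out_dir:
        with stage("write_report"):
            write_report(report, channels, config)
    return _jsonable(report)


def write_report(report: dict[str, Any], channels: dict[str, Any],
                 config: PipelineConfig) -> None:
    """Write report.json, summary.txt and per-stage TSV/JSON artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = _jsonable({k: v for k, v in report.items()})
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (out / "summary.txt").write_text(render_summary(payload))
    for mod, ch in channels.items():
        recs = ch.get("_dms_records")
        if recs:
            dms_mod.dms_to_frame(recs).to_csv(
                out / f"dms_{mod}.tsv", sep="\t", index=False
            )
        for ctype, (model, _) in ch.get("_models", {}).items():
            (out / f"clock_{mod}_{ctype}.json").write_text(model.to_json())


def render_summary(report: dict[str, Any]) -> str:
    """Human-readable summary in mean +/- SD / test-statistic style."""
    lines = [f"methclock pipeline report ({report['n_samples']} samples)", ""]
    for mod, glob in report.get("global_methylation", {}).items():
        lines.append(
            f"global {MOD_LABELS.get(mod, mod)} level: "
            f"{glob['read_weighted_mean_pct']:.2f} +/- {glob['read_weighted_sd_pct']:.2f} % "
            f"(read-weighted; site-weighted {glob['site_weighted_mean_pct']:.2f} %)"
        )
    cov = report.get("coverage_filter", {})
    if cov:
        lines.append(
            f"coverage filter >= {cov['min_cov']}X: {cov['rows_in']} -> {cov['rows_out']} rows"
        )
    for mod, ch in report.get("channels", {}).items():
        label = MOD_LABELS.get(mod, mod)
        if "skipped" in ch:
            lines.append(f"[{label}] skipped: {ch['skipped']}")
            continue
        d = ch["dms"]
        lines += ["", f"[{label}]",
                  f"  DMS (q < {report['config']['fdr']}): {d['n_dms']} of "
                  f"{d['n_sites_tested']} sites ({d['n_hypo']} hypo / {d['n_hyper']} hyper)"]
        r = ch.get("roc", {})
        if "mean_slope_pct_per_week" in r and r.get("n_retained", 0) > 0:
            sd = r["sd_slope"]
            sd_txt = f" +/- {sd:.2f}" if isinstance(sd, (int, float)) and sd is not None else ""
            lines.append(
                f"  mean ROC: {r['mean_slope_pct_per_week']:.2f}{sd_txt} %/week "
                f"[n = {r['n_retained']}] (R2 > {r['r2_threshold']})"
            )
        for label2, ent in ch.get("entropy", {}).items():
            if "skipped" in ent:
                continue
            cmpv = ent["comparison"]
            means = ", ".join(
                f"{g}: {m:.3f}" for g, m in ent["per_group_mean"].items()
            )
            lines.append(
                f"  entropy ({label2}): {means}; {cmpv['test_name']} "
                f"p = {cmpv['p_value']:.3g}"
            )
        for ctype, c in ch.get("clocks", {}).items():
            if ctype in ("train_ids", "test_ids") or "skipped" in c:
                continue
            t = c["test"]
            lines.append(
                f"  clock {ctype}: test r = {t['pearson_r']:.3f}, "
                f"MAE = {t['mae_days']:.2f} d, MRE = {t['mre_percent']:.1f} %"
                + (f", permutation p = {c['permutation']['p_value']:.4f}"
                   if "permutation" in c else "")
            )
    chi = report.get("direction_chisq")
    if chi:
        lines.append(
            f"\nhypo/hyper direction 6mA vs 5mC: chi-squared = {chi['statistic']:.3f}, "
            f"df = {chi['df']}, p = {chi['p_value']:.3g}"
        )
    for mod, dec in report.get("age_deceleration", {}).items():
        for arm in dec["arms"]:
            lines.append(
                f"age deceleration [{MOD_LABELS.get(mod, mod)}] {arm['arm']}: "
                f"predicted {arm['mean_predicted_age']:.1f} d vs control "
                f"{dec['control_mean_predicted_age']:.1f} d "
                f"(p = {arm['p_vs_control']:.4f})"
            )
    return "\n".join(lines) + "\n"
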