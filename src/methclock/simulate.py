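"""Synthetic aging-methylome generator.

Emulates the statistical structure of an insect aging cohort profiled for
6mA and 5mC by long-read sequencing: three age groups (7/21/35 days, n = 5
each), low global methylation (~2-3%), a minority of "clock" sites whose
methylation drifts linearly with age (slope prior 1.32 +/- 2.04 % per week
on the 6mA-like channel), a minority of "entropy" sites whose per-sample
methylation becomes both noisier and more intermediate with age, binomial
read counts at negative-binomial depth (mean ~30X, overdispersed to match
a reported 32.6 +/- 10.7X), and optional treatment arms whose methylome
behaves as if the animal were younger than its chronological age
(rejuvenation modelled as an effective-age offset).

Drift is applied on the logit scale so fractions stay inside (0, 1); a
site's nominal "% per week" slope is its fraction-scale derivative at the
cohort midpoint age.  Entropy sites shift their Beta mean toward 0.5 while
their Beta precision falls with age: a precision drop alone cannot raise
expected binary entropy (entropy is concave in the fraction, so spreading
mass around a fixed mean lowers its expectation), hence the mean shift is
the component that actually inflates entropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .io import (
    MOD_CODES,
    Sample,
    SiteKey,
    SiteMethylation,
    write_bedmethyl,
    write_manifest,
)


@dataclass
class SimulationConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_per_group: int = 5
    ages_days: tuple[float, ...] = (7.0, 21.0, 35.0)
    n_sites: int = 2000                 # per modification channel
    frac_clock_sites: float = 0.10
    slope_mean_pct_per_week: float = 1.32
    slope_sd_pct_per_week: float = 2.04
    frac_entropy_sites: float = 0.05
    # Beta precision at the youngest/oldest chronological age (log-linear in
    # between); lower precision = noisier per-sample fractions.
    entropy_precision_young: float = 150.0
    entropy_precision_old: float = 25.0
    # Fraction of the distance from baseline to 0.5 an entropy site's mean
    # travels by the oldest age.
    entropy_inflation_old: float = 0.35
    # Baseline fraction mixture: mostly near-zero with a minority methylated
    # component, tuned so the read-weighted global level lands near 2-3%.
    baseline_beta_params: tuple[float, float] = (1.0, 150.0)
    methylated_weight: float = 0.03
    methylated_beta_params: tuple[float, float] = (2.0, 12.0)
    # Baseline distribution of drifting (clock) and entropy sites.  Dynamic
    # sites start low, like the bulk of a 2-3%-methylated genome; on the
    # logit scale an absolute drift at a low baseline is a large fold change,
    # which is what makes age signal detectable at ~30X depth.
    dynamic_beta_params: tuple[float, float] | None = (1.2, 45.0)
    coverage_mean: float = 30.0
    coverage_dispersion: float = 13.0   # negative-binomial size parameter r
    treatment_arms: dict[str, float] = field(default_factory=dict)
    treatment_age_days: float = 35.0
    treatment_n: int | None = None      # defaults to n_per_group
    mod_codes: tuple[str, ...] = MOD_CODES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not (0 <= self.frac_clock_sites <= 1 and 0 <= self.frac_entropy_sites <= 1):
            raise ValueError("site fractions must lie in [0, 1]")
        if self.frac_clock_sites + self.frac_entropy_sites > 1:
            raise ValueError("frac_clock_sites + frac_entropy_sites must be <= 1")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort.

    ``clock_sites`` maps each drifting site to its nominal slope (% per
    week: the fraction-scale derivative of the logit drift at the cohort
    midpoint age).  ``realized_slopes`` maps the same sites to the average
    rate actually present over the observed age window,
    ``100 * (p(oldest) - p(youngest)) / weeks``, computed on the exact
    generating fractions: with a symmetric equal-n age design the OLS
    slope estimates this window rate, so it is the recovery target.
    """

    clock_sites: dict[SiteKey, float]      # nominal slope, % per week
    entropy_sites: set[SiteKey]
    effective_age_days: dict[str, float]   # sample_id -> effective age
    realized_slopes: dict[SiteKey, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "clock_sites": {str(k): v for k, v in sorted(self.clock_sites.items())},
                "realized_slopes": {
                    str(k): v for k, v in sorted(self.realized_slopes.items())
                },
                "entropy_sites": sorted(str(k) for k in self.entropy_sites),
                "effective_age_days": dict(sorted(self.effective_age_days.items())),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        return cls(
            clock_sites={SiteKey.from_string(k): v for k, v in d["clock_sites"].items()},
            entropy_sites={SiteKey.from_string(k) for k in d["entropy_sites"]},
            effective_age_days=d["effective_age_days"],
            realized_slopes={
                SiteKey.from_string(k): v
                for k, v in d.get("realized_slopes", {}).items()
            },
        )


@dataclass
class Cohort:
    """A simulated cohort: per-sample record tables, manifest and truth."""

    tables: dict[str, list[SiteMethylation]]
    manifest: list[Sample]
    truth: SimulationTruth
    config: SimulationConfig


def _dispersion_schedule(cfg: SimulationConfig, age_days: float) -> float:
    """Beta precision at an (effective) age: log-linear between the anchors."""
    a0, a1 = min(cfg.ages_days), max(cfg.ages_days)
    t = np.clip((age_days - a0) / (a1 - a0), 0.0, 1.0)
    return float(
        cfg.entropy_precision_young
        * (cfg.entropy_precision_old / cfg.entropy_precision_young) ** t
    )


def _entropy_inflation(cfg: SimulationConfig, age_days: float) -> float:
    a0, a1 = min(cfg.ages_days), max(cfg.ages_days)
    t = np.clip((age_days - a0) / (a1 - a0), 0.0, 1.0)
    return float(cfg.entropy_inflation_old * t)


def clock_site_fraction(p0: float, slope_pct_per_week: float,
                        age_weeks: float, mid_weeks: float) -> float:
    """Expected fraction of a drifting site at a given effective age.

    The logit-scale rate is chosen so the fraction-scale derivative at the
    cohort midpoint equals the nominal slope.
    """
    b = (slope_pct_per_week / 100.0) / (p0 * (1.0 - p0))
    return float(expit(logit(p0) + b * (age_weeks - mid_weeks)))


def expected_entropy_site_mean(cfg: SimulationConfig, p0: float,
                               age_days: float) -> float:
    """Generating Beta mean of an entropy site at an (effective) age."""
    infl = _entropy_inflation(cfg, age_days)
    return float(p0 + (0.5 - p0) * infl)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw one cohort.  Same config (incl. seed) -> identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- manifest -------------------------------------------------------
    manifest: list[Sample] = []
    for age in cfg.ages_days:
        group = f"W{int(round(age / 7))}"
        for r in range(cfg.n_per_group):
            manifest.append(Sample(f"{group}_r{r + 1}", age, group, "none"))
    n_treat = cfg.treatment_n if cfg.treatment_n is not None else cfg.n_per_group
    for arm in sorted(cfg.treatment_arms):
        group = f"W{int(round(cfg.treatment_age_days / 7))}"
        for r in range(n_treat):
            manifest.append(
                Sample(f"{arm}_r{r + 1}", cfg.treatment_age_days, group, arm)
            )
    effective_age = {
        s.sample_id: max(1.0, s.age_days - cfg.treatment_arms.get(s.treatment, 0.0))
        for s in manifest
    }

    mid_weeks = float(np.mean([min(cfg.ages_days), max(cfg.ages_days)])) / 7.0

    tables: dict[str, list[SiteMethylation]] = {s.sample_id: [] for s in manifest}
    clock_truth: dict[SiteKey, float] = {}
    realized_truth: dict[SiteKey, float] = {}
    entropy_truth: set[SiteKey] = set()
    n_clipped = 0

    for mod in cfg.mod_codes:
        n = cfg.n_sites
        n_clock = int(round(n * cfg.frac_clock_sites))
        n_entropy = int(round(n * cfg.frac_entropy_sites))
        keys = [SiteKey("ctg1", 10 * i, "+", mod) for i in range(n)]
        roles = np.zeros(n, dtype=int)  # 0 static, 1 clock, 2 entropy
        pick = rng.permutation(n)
        roles[pick[:n_clock]] = 1
        roles[pick[n_clock:n_clock + n_entropy]] = 2

        # Baselines: static sites from the low-level mixture; drifting and
        # entropy sites from the methylated component so their dynamics are
        # observable at ~30X depth.
        a0, b0 = cfg.baseline_beta_params
        a1, b1 = cfg.methylated_beta_params
        is_meth = rng.random(n) < cfg.methylated_weight
        baseline = np.where(
            is_meth, rng.beta(a1, b1, size=n), rng.beta(a0, b0, size=n)
        )
        dynamic = roles != 0
        ad, bd = (
            cfg.dynamic_beta_params
            if cfg.dynamic_beta_params is not None
            else cfg.methylated_beta_params
        )
        baseline[dynamic] = rng.beta(ad, bd, size=int(dynamic.sum()))
        baseline = np.clip(baseline, 1e-4, 1 - 1e-4)

        slopes = rng.normal(
            cfg.slope_mean_pct_per_week, cfg.slope_sd_pct_per_week, size=n
        )

        a_min_w, a_max_w = min(cfg.ages_days) / 7.0, max(cfg.ages_days) / 7.0
        for i, key in enumerate(keys):
            if roles[i] == 1:
                clock_truth[key] = float(slopes[i])
                p0 = float(np.clip(baseline[i], 0.02, 0.98))
                b = (slopes[i] / 100.0) / (p0 * (1.0 - p0))
                p_young = float(np.clip(
                    expit(logit(p0) + b * (a_min_w - mid_weeks)), 1e-4, 1 - 1e-4))
                p_old = float(np.clip(
                    expit(logit(p0) + b * (a_max_w - mid_weeks)), 1e-4, 1 - 1e-4))
                realized_truth[key] = 100.0 * (p_old - p_young) / (a_max_w - a_min_w)
            elif roles[i] == 2:
                entropy_truth.add(key)

        for s in manifest:
            eff_days = effective_age[s.sample_id]
            eff_weeks = eff_days / 7.0
            p = baseline.copy()
            # clock drift
            ci = np.where(roles == 1)[0]
            if ci.size:
                p0 = np.clip(baseline[ci], 0.02, 0.98)
                b = (slopes[ci] / 100.0) / (p0 * (1.0 - p0))
                raw = expit(logit(p0) + b * (eff_weeks - mid_weeks))
                n_clipped += int(np.sum((raw < 1e-4) | (raw > 1 - 1e-4)))
                p[ci] = np.clip(raw, 1e-4, 1 - 1e-4)
            # entropy inflation
            ei = np.where(roles == 2)[0]
            if ei.size:
                kappa = _dispersion_schedule(cfg, eff_days)
                infl = _entropy_inflation(cfg, eff_days)
                mean = baseline[ei] + (0.5 - baseline[ei]) * infl
                p[ei] = rng.beta(mean * kappa, (1.0 - mean) * kappa)
                p[ei] = np.clip(p[ei], 1e-6, 1 - 1e-6)

            r = cfg.coverage_dispersion
            n_valid = rng.negative_binomial(r, r / (r + cfg.coverage_mean), size=n)
            n_mod = rng.binomial(n_valid, p)
            recs = tables[s.sample_id]
            for i, key in enumerate(keys):
                if n_valid[i] > 0:
                    recs.append(SiteMethylation(key, int(n_valid[i]), int(n_mod[i])))

    if n_clipped:
        import logging

        logging.getLogger(__name__).warning(
            "simulate_cohort: %d drifted fractions clipped into (0, 1)", n_clipped
        )

    truth = SimulationTruth(clock_truth, entropy_truth, effective_age,
                            realized_slopes=realized_truth)
    return Cohort(tables=tables, manifest=manifest, truth=truth, config=cfg)


def write_fixture_set(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort as bedMethyl files + manifest.tsv + truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample in cohort.manifest:
        p = out / f"{sample.sample_id}.bedmethyl.tsv"
        write_bedmethyl(cohort.tables[sample.sample_id], p)
        paths[sample.sample_id] = p
    write_manifest(cohort.manifest, out / "manifest.tsv")
    (out / "truth.json").write_text(cohort.truth.to_json())
    paths["manifest"] = out / "manifest.tsv"
    paths["truth"] = out / "truth.json"
    return paths
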