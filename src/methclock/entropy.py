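"""Methylation entropy and gated group comparisons.

Site-level entropy is the binary Shannon entropy of the methylation
fraction, in bits (base 2), so it is already normalized to [0, 1]; the
sample-level statistic is its mean over a chosen site set (genome-wide or
DMS-restricted).  Because each site is a two-state system, the mean of
per-site base-2 entropies equals the genome-normalized entropy of the
Hannum construction.

Group comparisons run a one-way ANOVA with Tukey HSD only when every group
passes Shapiro-Wilk normality and Levene's homoscedasticity gate at
alpha = 0.05; otherwise Kruskal-Wallis with pairwise Mann-Whitney post hoc,
BH-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .io import MethylationMatrix, SiteKey


def site_entropy(fraction, base: float = 2.0):
    """Binary Shannon entropy of a methylation fraction.

    ``base=2`` (default) gives entropy in bits, normalized to [0, 1];
    ``base=np.e`` gives nats.  Accepts scalars or arrays; 0*log(0) is 0.
    """
    p = np.asarray(fraction, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(
            np.where(p > 0, p * np.log(p), 0.0)
            + np.where(p < 1, (1 - p) * np.log1p(-p), 0.0)
        ) / np.log(base)
    h = np.where((p == 0) | (p == 1), 0.0, h)
    return float(h) if np.isscalar(fraction) else h


def sample_mean_entropy(
    matrix: MethylationMatrix,
    sample_id: str,
    site_set: Sequence[SiteKey] | None = None,
    base: float = 2.0,
) -> float:
    """Mean site entropy for one sample over a site set (default: all)."""
    j = matrix.sample_index(sample_id)
    if site_set is None:
        fracs = matrix.fractions[:, j]
    else:
        site_set = list(site_set)
        if not site_set:
            raise ValueError("empty site set")
        index = matrix.site_index()
        try:
            rows = [index[k] for k in site_set]
        except KeyError as e:
            raise KeyError(f"site not in matrix: {e.args[0]}") from None
        fracs = matrix.fractions[rows, j]
    return float(np.mean(site_entropy(fracs, base=base)))


@dataclass
class EntropyProfile:
    """Per-site and per-sample entropy over one site set."""

    per_site: pd.DataFrame          # sites x samples
    per_sample_mean: pd.Series
    site_set_label: str


def entropy_profile(
    matrix: MethylationMatrix,
    site_set: Sequence[SiteKey] | None = None,
    label: str | None = None,
    base: float = 2.0,
) -> EntropyProfile:
    if site_set is None:
        rows = slice(None)
        index = [str(k) for k in matrix.sites]
        label = label or "genome_wide"
    else:
        site_set = list(site_set)
        if not site_set:
            raise ValueError("empty site set")
        site_idx = matrix.site_index()
        rows = [site_idx[k] for k in site_set]
        index = [str(k) for k in site_set]
        label = label or "dms_only"
    h = site_entropy(matrix.fractions[rows, :], base=base)
    per_site = pd.DataFrame(h, index=index, columns=matrix.sample_ids)
    return EntropyProfile(per_site, per_site.mean(axis=0), label)


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    p_adjusted: float
    mean_difference: float      # mean(b) - mean(a)


@dataclass
class GroupComparison:
    """Omnibus + post hoc comparison across groups, with the gate outcome."""

    test_name: str              # anova_tukey | kruskal_mwu
    statistic: float
    p_value: float
    shapiro_p: dict[str, float]
    levene_p: float
    pairwise: list[PairwiseResult]

    def pairwise_p(self, a: str, b: str) -> float:
        for r in self.pairwise:
            if {r.group_a, r.group_b} == {a, b}:
                return r.p_adjusted
        raise KeyError(f"no pairwise result for ({a}, {b})")


def compare_groups(
    values: Mapping[str, Sequence[float]], alpha_gate: float = 0.05
) -> GroupComparison:
    """Compare >= 2 groups of sample-level values with an assumptions gate.

    All groups normal (Shapiro) and homoscedastic (Levene) at ``alpha_gate``
    -> one-way ANOVA + Tukey HSD; otherwise Kruskal-Wallis + pairwise
    Mann-Whitney with BH adjustment.  Degenerate all-constant input skips
    the gate into the nonparametric branch.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")

    names = list(groups)
    arrays = [groups[g] for g in names]

    shapiro_p: dict[str, float] = {}
    degenerate = any(np.ptp(v) == 0 for v in arrays)
    for g, v in groups.items():
        shapiro_p[g] = float(stats.shapiro(v).pvalue) if np.ptp(v) > 0 else 0.0
    if degenerate:
        levene_p = 0.0
    else:
        levene_p = float(stats.levene(*arrays, center="mean").pvalue)

    parametric = (
        not degenerate
        and all(p > alpha_gate for p in shapiro_p.values())
        and levene_p > alpha_gate
    )

    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    pairwise: list[PairwiseResult] = []
    if parametric:
        stat, p = stats.f_oneway(*arrays)
        flat = np.concatenate(arrays)
        labels = np.concatenate([[g] * len(groups[g]) for g in names])
        tk = pairwise_tukeyhsd(flat, labels)
        # result rows follow combinations() over the sorted unique groups
        from itertools import combinations

        tukey_pairs = list(combinations(tk.groupsunique, 2))
        for (a, b), padj in zip(tukey_pairs, tk.pvalues):
            pairwise.append(
                PairwiseResult(str(a), str(b), float(padj),
                               float(np.mean(groups[str(b)]) - np.mean(groups[str(a)])))
            )
        return GroupComparison("anova_tukey", float(stat), float(p),
                               shapiro_p, levene_p, pairwise)

    stat, p = stats.kruskal(*arrays)
    raw = []
    for a, b in pairs:
        if np.ptp(groups[a]) == 0 and np.ptp(groups[b]) == 0 and np.array_equal(
            np.unique(groups[a]), np.unique(groups[b])
        ):
            raw.append(1.0)
        else:
            raw.append(float(stats.mannwhitneyu(groups[a], groups[b],
                                                alternative="two-sided").pvalue))
    adj = multipletests(raw, method="fdr_bh")[1]
    for (a, b), padj in zip(pairs, adj):
        pairwise.append(
            PairwiseResult(a, b, float(padj),
                           float(np.mean(groups[b]) - np.mean(groups[a])))
        )
    return GroupComparison("kruskal_mwu", float(stat), float(p),
                           shapiro_p, levene_p, pairwise)
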