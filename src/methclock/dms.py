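"""Differential methylation between two age groups.

The inferential test is Fisher's exact test on replicate-pooled modified /
unmodified read counts, with Benjamini-Hochberg FDR control applied within
each modification channel.  The absolute difference of beta-posterior MAP
estimates (uniform Beta(1,1) prior on each condition's methylation
fraction) is carried along as a descriptive effect-confidence score; it is
not used for inference.  A per-replicate Welch t-test on fractions is
available as a sensitivity option.

Effect sizes are oriented old minus young, so a positive effect size means
hypermethylation with age.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureInterval, MethylationMatrix, SiteKey, SiteMethylation

#: Context assignment priority when a site overlaps several feature classes.
CONTEXT_PRIORITY = ("rDNA", "ncRNA", "coding")


@dataclass(frozen=True)
class DMSRecord:
    """Per-site differential methylation result."""

    key: SiteKey
    effect_size: float          # mean fraction (old) - mean fraction (young)
    p_value: float
    q_value: float
    direction: str              # hyper | hypo | none
    context: str = "unannotated"
    map_score: float = float("nan")


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 chi-squared comparison of two count pairs."""

    table: tuple[tuple[int, int], tuple[int, int]]
    statistic: float
    df: int
    p_value: float
    continuity_corrected: bool


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for a vector of p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def pool_counts(
    per_sample_records: Mapping[str, Mapping[SiteKey, SiteMethylation]],
    group: Sequence[str],
    site: SiteKey,
) -> tuple[int, int]:
    """Sum (n_mod, n_valid) for one site across a group's samples."""
    n_mod = n_valid = 0
    for sid in group:
        try:
            rec = per_sample_records[sid][site]
        except KeyError:
            raise KeyError(f"site {site} missing in sample {sid}") from None
        n_mod += rec.n_mod
        n_valid += rec.n_valid
    return n_mod, n_valid


def beta_map(n_mod: int, n_canonical: int) -> float:
    """MAP of the Beta(1 + n_mod, 1 + n_canonical) posterior.

    With the uniform prior this is the observed fraction
    ``n_mod / (n_mod + n_canonical)``.
    """
    total = n_mod + n_canonical
    if total == 0:
        raise ValueError("MAP undefined with zero reads")
    return n_mod / total


def site_test(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> tuple[float, float, float]:
    """Test one site between two conditions on pooled counts.

    Returns ``(p_value, effect_size, map_score)`` where the p-value is a
    two-sided Fisher's exact test on the 2x2 modified/unmodified table,
    effect size is ``fraction_b - fraction_a``, and the MAP score is the
    absolute difference of the two beta-posterior MAP estimates.
    """
    mod_a, valid_a = counts_a
    mod_b, valid_b = counts_b
    if valid_a <= 0 or valid_b <= 0:
        raise ValueError("site not testable: zero valid coverage in a condition")
    table = [[mod_a, valid_a - mod_a], [mod_b, valid_b - mod_b]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    effect = mod_b / valid_b - mod_a / valid_a
    score = abs(beta_map(mod_b, valid_b - mod_b) - beta_map(mod_a, valid_a - mod_a))
    return float(p), float(effect), float(score)


def dms_table(
    matrix: MethylationMatrix,
    group_young: Sequence[str],
    group_old: Sequence[str],
    method: str = "fisher",
) -> pd.DataFrame:
    """Per-site differential test over every matrix site.

    BH q-values are computed within each modification channel.  Rows are
    indexed by site-key string; columns: effect_size, p, q, map_score,
    direction.
    """
    if not group_young or not group_old:
        raise ValueError("both groups must be non-empty")
    if matrix.n_sites < 2:
        raise ValueError("BH correction undefined with fewer than 2 tested sites")

    ji_young = [matrix.sample_index(s) for s in group_young]
    ji_old = [matrix.sample_index(s) for s in group_old]
    counts = matrix.mod_counts()
    cov = matrix.coverages

    mod_y = counts[:, ji_young].sum(axis=1)
    val_y = cov[:, ji_young].sum(axis=1)
    mod_o = counts[:, ji_old].sum(axis=1)
    val_o = cov[:, ji_old].sum(axis=1)

    frac_y_mean = matrix.fractions[:, ji_young].mean(axis=1)
    frac_o_mean = matrix.fractions[:, ji_old].mean(axis=1)
    effect = frac_o_mean - frac_y_mean

    n = matrix.n_sites
    p = np.empty(n)
    score = np.empty(n)
    if method == "fisher":
        for i in range(n):
            p[i], _, score[i] = site_test(
                (int(mod_y[i]), int(val_y[i])), (int(mod_o[i]), int(val_o[i]))
            )
    elif method == "ttest":
        fy = matrix.fractions[:, ji_young]
        fo = matrix.fractions[:, ji_old]
        res = stats.ttest_ind(fo, fy, axis=1, equal_var=False)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        score[:] = np.abs(
            mod_o / val_o - mod_y / val_y
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    q = np.empty(n)
    mods = np.array([k.mod_code for k in matrix.sites])
    for mod in np.unique(mods):
        mask = mods == mod
        q[mask] = bh_qvalues(p[mask])

    direction = np.where(effect > 0, "hyper", np.where(effect < 0, "hypo", "none"))
    return pd.DataFrame(
        {
            "effect_size": effect,
            "p": p,
            "q": q,
            "map_score": score,
            "direction": direction,
        },
        index=pd.Index([str(k) for k in matrix.sites], name="site"),
    )


def call_dms(
    matrix: MethylationMatrix,
    group_young: Sequence[str],
    group_old: Sequence[str],
    fdr: float = 0.05,
    method: str = "fisher",
) -> list[DMSRecord]:
    """Sites differentially methylated between the two groups at ``q < fdr``.

    Sites with zero effect size are never called, whatever their q-value.
    """
    if not 0 < fdr < 1:
        raise ValueError(f"fdr must lie in (0, 1), got {fdr}")
    table = dms_table(matrix, group_young, group_old, method=method)
    out: list[DMSRecord] = []
    for key, row in zip(matrix.sites, table.itertuples()):
        if row.q < fdr and row.effect_size != 0:
            out.append(
                DMSRecord(
                    key=key,
                    effect_size=float(row.effect_size),
                    p_value=float(row.p),
                    q_value=float(row.q),
                    direction=str(row.direction),
                    map_score=float(row.map_score),
                )
            )
    return out


def annotate_context(
    records: Sequence[DMSRecord], features: Sequence[FeatureInterval]
) -> list[DMSRecord]:
    """Assign each site a genomic context from overlapping feature intervals.

    Overlap ties resolve by priority rDNA > ncRNA > coding; no overlap means
    intergenic.
    """
    by_contig: dict[str, list[FeatureInterval]] = {}
    for f in features:
        by_contig.setdefault(f.contig, []).append(f)
    rank = {c: i for i, c in enumerate(CONTEXT_PRIORITY)}

    out: list[DMSRecord] = []
    for rec in records:
        hits = [
            f.feature_class
            for f in by_contig.get(rec.key.contig, [])
            if f.start <= rec.key.position < f.end
        ]
        context = min(hits, key=rank.__getitem__) if hits else "intergenic"
        out.append(
            DMSRecord(
                key=rec.key,
                effect_size=rec.effect_size,
                p_value=rec.p_value,
                q_value=rec.q_value,
                direction=rec.direction,
                context=context,
                map_score=rec.map_score,
            )
        )
    return out


def direction_proportions(records: Sequence[DMSRecord]) -> tuple[int, int]:
    """Counts of (hypo, hyper) records; direction 'none' is excluded."""
    if not records:
        raise ValueError("no records")
    n_hypo = sum(1 for r in records if r.direction == "hypo")
    n_hyper = sum(1 for r in records if r.direction == "hyper")
    return n_hypo, n_hyper


def compare_proportions_chisq(
    counts_a: tuple[int, int], counts_b: tuple[int, int], yates: bool = True
) -> ContingencyResult:
    """Pearson chi-squared on a 2x2 table of two count pairs.

    Yates continuity correction is applied by default, the convention for
    1-df tables.
    """
    table = np.array([counts_a, counts_b], dtype=np.int64)
    if (table < 0).any():
        raise ValueError("negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a zero row or column margin")
    res = stats.chi2_contingency(table, correction=yates)
    return ContingencyResult(
        table=((int(table[0, 0]), int(table[0, 1])),
               (int(table[1, 0]), int(table[1, 1]))),
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        continuity_corrected=yates,
    )


def dms_to_frame(records: Sequence[DMSRecord]) -> pd.DataFrame:
    """BED-compatible DMS table (contig, start, end, strand, mod_code, ...)."""
    rows = [
        (
            r.key.contig, r.key.position, r.key.position + 1, r.key.strand,
            r.key.mod_code, r.effect_size, r.p_value, r.q_value, r.direction,
            r.context,
        )
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "start", "end", "strand", "mod_code",
            "effect_size", "p", "q", "direction", "context",
        ],
    )
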