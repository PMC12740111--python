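"""Reading, writing and assembling per-site modified-base call tables.

The on-disk dialect is the 18-column bedMethyl variant emitted by ONT's
Modkit ``pileup`` command: one row per (contig, position, strand,
modification code), tab separated, carrying the valid-read coverage, the
modified-read count and a percent-modified column.  The percent column is
never trusted: methylation fractions are always recomputed from the two
count columns so that downstream statistics are free of printing round-off.

Coordinates are 0-based half-open (BED native) and strands are never
collapsed: N6-methyladenine is not tied to a palindromic context, so each
(contig, position, strand, mod) is its own site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Strand symbols accepted in bedMethyl input.
STRANDS = ("+", "-", ".")

#: Supported modification channels: ``a`` = 6mA, ``m`` = 5mC.
MOD_CODES = ("a", "m")

N_BEDMETHYL_COLUMNS = 18


@dataclass(frozen=True, order=True)
class SiteKey:
    """Identity of a single methylation site.

    Parameters
    ----------
    contig : str
        Reference sequence name.
    position : int
        0-based start coordinate.
    strand : str
        One of ``+``, ``-``, ``.``.
    mod_code : str
        ``a`` (6mA) or ``m`` (5mC).
    """

    contig: str
    position: int
    strand: str
    mod_code: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative position: {self.position}")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.mod_code not in MOD_CODES:
            raise ValueError(f"unsupported mod code {self.mod_code!r}")

    def __str__(self) -> str:
        return f"{self.contig}:{self.position}:{self.strand}:{self.mod_code}"

    @classmethod
    def from_string(cls, s: str) -> "SiteKey":
        contig, pos, strand, mod = s.rsplit(":", 3)
        return cls(contig, int(pos), strand, mod)


@dataclass(frozen=True)
class SiteMethylation:
    """One site x modification x strand observation in one sample."""

    key: SiteKey
    n_valid: int
    n_mod: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_mod <= self.n_valid:
            raise ValueError(
                f"invalid counts for {self.key}: n_mod={self.n_mod}, n_valid={self.n_valid}"
            )
        if self.n_valid == 0:
            raise ValueError(f"zero-coverage record for {self.key} (fraction undefined)")

    @property
    def fraction(self) -> float:
        return self.n_mod / self.n_valid


@dataclass(frozen=True)
class Sample:
    """Manifest entry for one sequenced individual."""

    sample_id: str
    age_days: float
    group: str
    treatment: str = "none"

    def __post_init__(self) -> None:
        if self.age_days <= 0:
            raise ValueError(f"age_days must be positive, got {self.age_days}")


@dataclass
class MethylationMatrix:
    """Complete-case sites x samples methylation matrix.

    ``fractions`` and ``coverages`` are aligned ``(n_sites, n_samples)``
    arrays; a cell's modified-read count is recovered exactly as
    ``round(fraction * coverage)``.
    """

    sites: list[SiteKey]
    samples: list[Sample]
    fractions: np.ndarray
    coverages: np.ndarray
    min_cov: int = 1

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.coverages = np.asarray(self.coverages)
        expected = (len(self.sites), len(self.samples))
        if self.fractions.shape != expected or self.coverages.shape != expected:
            raise ValueError(
                f"inconsistent matrix dimensions: sites x samples = {expected}, "
                f"fractions {self.fractions.shape}, coverages {self.coverages.shape}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def ages_days(self) -> np.ndarray:
        return np.array([s.age_days for s in self.samples], dtype=float)

    def sample_index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return i
        raise KeyError(sample_id)

    def site_index(self) -> dict[SiteKey, int]:
        return {k: i for i, k in enumerate(self.sites)}

    def mod_counts(self) -> np.ndarray:
        """Modified-read counts, reconstructed exactly from fractions."""
        return np.rint(self.fractions * self.coverages).astype(np.int64)

    def group_samples(self, group: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.group == group]

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        """Restrict to the given samples (order follows ``sample_ids``)."""
        idx = [self.sample_index(s) for s in sample_ids]
        return MethylationMatrix(
            sites=list(self.sites),
            samples=[self.samples[i] for i in idx],
            fractions=self.fractions[:, idx],
            coverages=self.coverages[:, idx],
            min_cov=self.min_cov,
        )

    def subset_channel(self, mod_code: str) -> "MethylationMatrix":
        """Restrict to one modification channel (``a`` or ``m``)."""
        idx = [i for i, k in enumerate(self.sites) if k.mod_code == mod_code]
        return MethylationMatrix(
            sites=[self.sites[i] for i in idx],
            samples=list(self.samples),
            fractions=self.fractions[idx],
            coverages=self.coverages[idx],
            min_cov=self.min_cov,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fractions,
            index=[str(k) for k in self.sites],
            columns=self.sample_ids,
        )


def read_bedmethyl(
    path: str | Path, mod_codes: Iterable[str] = MOD_CODES
) -> list[SiteMethylation]:
    """Parse a Modkit-pileup bedMethyl file.

    Rows whose mod code is outside ``mod_codes`` are skipped; rows with zero
    valid coverage are dropped (fraction undefined); rows with
    ``N_mod > N_valid_cov`` or the wrong field count are rejected with a
    warning.  Fractions are recomputed from counts downstream; the printed
    percent column is ignored.
    """
    path = Path(path)
    wanted = set(mod_codes)
    bad = wanted.difference(MOD_CODES)
    if bad:
        raise ValueError(f"unsupported mod codes requested: {sorted(bad)}")

    records: list[SiteMethylation] = []
    n_malformed = n_zero_cov = n_skipped_mod = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != N_BEDMETHYL_COLUMNS:
                n_malformed += 1
                logger.warning(
                    "%s:%d: expected %d tab-separated fields, got %d",
                    path, lineno, N_BEDMETHYL_COLUMNS, len(fields),
                )
                continue
            mod = fields[3]
            if mod not in wanted:
                n_skipped_mod += 1
                continue
            try:
                contig = fields[0]
                start = int(fields[1])
                strand = fields[5]
                n_valid = int(fields[9])
                n_mod = int(fields[11])
                key = SiteKey(contig, start, strand, mod)
            except ValueError:
                n_malformed += 1
                logger.warning("%s:%d: malformed row", path, lineno)
                continue
            if n_valid == 0:
                n_zero_cov += 1
                continue
            if n_mod > n_valid:
                n_malformed += 1
                logger.warning(
                    "%s:%d: N_mod (%d) exceeds N_valid_cov (%d); row rejected",
                    path, lineno, n_mod, n_valid,
                )
                continue
            records.append(SiteMethylation(key, n_valid=n_valid, n_mod=n_mod))
    if n_zero_cov:
        logger.info("%s: dropped %d zero-coverage rows", path, n_zero_cov)
    if n_malformed:
        logger.warning("%s: rejected %d malformed rows", path, n_malformed)
    logger.debug(
        "%s: %d records kept, %d rows outside requested mod codes",
        path, len(records), n_skipped_mod,
    )
    return records


def write_bedmethyl(records: Iterable[SiteMethylation], path: str | Path) -> None:
    """Write records in the 18-column Modkit pileup dialect.

    Only the fields this package retains (key, counts) are meaningful on
    re-read; the remaining count columns are written as zero, the score as
    the valid coverage, and percent modified to two decimals as Modkit does.
    """
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            k = rec.key
            n_canon = rec.n_valid - rec.n_mod
            pct = 100.0 * rec.n_mod / rec.n_valid
            fh.write(
                "\t".join(
                    [
                        k.contig,
                        str(k.position),
                        str(k.position + 1),
                        k.mod_code,
                        str(rec.n_valid),
                        k.strand,
                        str(k.position),
                        str(k.position + 1),
                        "255,0,0",
                        str(rec.n_valid),
                        f"{pct:.2f}",
                        str(rec.n_mod),
                        str(n_canon),
                        "0", "0", "0", "0", "0",
                    ]
                )
                + "\n"
            )


def filter_coverage(
    records: Sequence[SiteMethylation], min_cov: int
) -> list[SiteMethylation]:
    """Keep records with ``n_valid >= min_cov``, preserving order."""
    if min_cov < 1:
        raise ValueError(f"min_cov must be >= 1, got {min_cov}")
    return [r for r in records if r.n_valid >= min_cov]


def global_methylation(
    records: Sequence[SiteMethylation], weighting: str = "read"
) -> float:
    """Global methylation level in percent.

    ``weighting='read'`` (default) is the read-weighted level
    ``100 * sum(n_mod) / sum(n_valid)``; ``weighting='site'`` is the
    unweighted mean of per-site fractions times 100.
    """
    if not records:
        raise ValueError("global methylation undefined on an empty collection")
    if weighting == "read":
        total_valid = sum(r.n_valid for r in records)
        total_mod = sum(r.n_mod for r in records)
        return 100.0 * total_mod / total_valid
    if weighting == "site":
        return 100.0 * float(np.mean([r.fraction for r in records]))
    raise ValueError(f"unknown weighting {weighting!r}")


def build_matrix(
    per_sample_records: Mapping[str, Sequence[SiteMethylation]],
    manifest: Sequence[Sample],
    min_cov: int = 1,
) -> MethylationMatrix:
    """Assemble a complete-case matrix over the samples in ``manifest``.

    Sites missing from any sample are removed rather than imputed.  Site
    order is lexicographic by (contig, position, strand, mod_code); sample
    order follows the manifest.
    """
    ids = [s.sample_id for s in manifest]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in manifest")
    missing = [i for i in ids if i not in per_sample_records]
    if missing:
        raise ValueError(f"manifest samples without record collections: {missing}")

    per_sample: list[dict[SiteKey, SiteMethylation]] = []
    for sid in ids:
        recs = per_sample_records[sid]
        d = {r.key: r for r in recs}
        if len(d) != len(recs):
            raise ValueError(f"duplicate site keys in sample {sid}")
        per_sample.append(d)

    shared = set(per_sample[0])
    for d in per_sample[1:]:
        shared.intersection_update(d)
    if not shared:
        sizes = {sid: len(d) for sid, d in zip(ids, per_sample)}
        raise ValueError(
            f"no site is observed in every sample; per-sample site counts: {sizes}"
        )
    n_union = len(set().union(*per_sample))
    logger.info(
        "build_matrix: %d shared sites kept of %d observed across %d samples",
        len(shared), n_union, len(ids),
    )

    sites = sorted(shared)
    fractions = np.empty((len(sites), len(ids)))
    coverages = np.empty((len(sites), len(ids)), dtype=np.int64)
    for j, d in enumerate(per_sample):
        for i, key in enumerate(sites):
            rec = d[key]
            fractions[i, j] = rec.fraction
            coverages[i, j] = rec.n_valid
    return MethylationMatrix(
        sites=sites, samples=list(manifest), fractions=fractions,
        coverages=coverages, min_cov=min_cov,
    )


FEATURE_CLASSES = ("coding", "ncRNA", "rDNA")


@dataclass(frozen=True)
class FeatureInterval:
    """Half-open genomic interval carrying a feature class."""

    contig: str
    start: int
    end: int
    feature_class: str


def read_feature_bed(path: str | Path) -> list[FeatureInterval]:
    """Read a BED4 feature file whose 4th column is coding | ncRNA | rDNA."""
    path = Path(path)
    out: list[FeatureInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: BED4 requires >= 4 columns, got {len(fields)}"
                )
            cls = fields[3]
            if cls not in FEATURE_CLASSES:
                raise ValueError(
                    f"{path}:{lineno}: unknown feature class {cls!r}; "
                    f"expected one of {FEATURE_CLASSES}"
                )
            out.append(FeatureInterval(fields[0], int(fields[1]), int(fields[2]), cls))
    return out


MANIFEST_COLUMNS = ["sample_id", "age_days", "group", "treatment"]


def read_manifest(path: str | Path) -> list[Sample]:
    """Read the TSV sample manifest (sample_id, age_days, group, treatment)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return [
        Sample(row.sample_id, float(row.age_days), str(row.group), str(row.treatment))
        for row in df.itertuples()
    ]


def write_manifest(samples: Sequence[Sample], path: str | Path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.age_days, s.group, s.treatment) for s in samples],
        columns=MANIFEST_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
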