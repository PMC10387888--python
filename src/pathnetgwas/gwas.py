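"""GWAS summary-statistic preprocessing and gene-level scoring.

Pipeline order mirrors standard pathway-oriented post-GWAS practice:

1. read per-SNP association results (chromosome, position, alleles, p);
2. keep nominally significant variants (p < 0.05, strict);
3. weight p-values by a functional score FS in [0, 1]: p_w = p_gwas / 10**FS,
   so a maximally damaging variant gains one order of magnitude of evidence;
4. assign SNPs to genes by physical distance (gene interval +/- a flanking
   window);
5. aggregate SNP p-values into one gene p-value via the maximum (min-p) or the
   sum of 1-df chi-squared statistics -- deliberately without LD or gene-size
   correction, recorded in ``statistic_kind``;
6. combine gene p-values across datasets with Fisher's method, restricted to
   genes scored in every dataset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Smallest p-value kept after ingest clamping (avoids log/quantile overflow).
P_FLOOR = 1e-300

DEFAULT_COLUMNS = {
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "p": "p",
    "rsid": "rsid",
    "fs": "fs",
}

DEFAULT_GENE_WINDOW = 50_000


class ColumnSpecError(KeyError):
    """A required summary-statistic column could not be resolved."""


def normalize_chrom(label: str) -> str:
    """Strip a leading 'chr' prefix, case-insensitively ('chr1' -> '1')."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label.upper()


@dataclass
class SnpRecord:
    """One summary-statistic row with raw and functionally weighted p-values."""

    chrom: str
    pos: int  # 1-based
    effect_allele: str
    other_allele: str
    p_gwas: float
    rsid: str | None = None
    fs: float | None = None
    p_w: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_gwas <= 1.0):
            raise ValueError(f"p_gwas must be in (0,1], got {self.p_gwas!r}")
        if self.fs is not None and not (0.0 <= self.fs <= 1.0):
            raise ValueError(
                f"functional score must be in [0,1]; record at "
                f"{self.chrom}:{self.pos} ({self.rsid}) has fs={self.fs!r}"
            )
        self.chrom = normalize_chrom(self.chrom)
        self.p_w = self.p_gwas / (10.0 ** (self.fs or 0.0))


@dataclass(frozen=True)
class GeneModel:
    """A gene interval (0-based half-open, BED convention) with a flanking window."""

    gene_id: str
    chrom: str
    start: int
    end: int
    window: int = DEFAULT_GENE_WINDOW

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.window < 0:
            raise ValueError(f"{self.gene_id}: window must be >= 0")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    def contains(self, pos_1based: int) -> bool:
        pos0 = pos_1based - 1
        return (self.start - self.window) <= pos0 < (self.end + self.window)


@dataclass
class GeneScoreTable:
    """Per-gene association p-values for one dataset.

    ``entries`` maps gene_id -> (p_gene, n_snps, statistic_kind).
    """

    dataset_label: str
    entries: dict[str, tuple[float, int, str]] = field(default_factory=dict)

    def pvalues(self) -> dict[str, float]:
        return {g: v[0] for g, v in self.entries.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "p_gene": p, "n_snps": n, "statistic_kind": kind}
            for g, (p, n, kind) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "p_gene", "n_snps", "statistic_kind"])


@dataclass(frozen=True)
class CombinedScore:
    """Fisher's combined test result for one gene across datasets."""

    gene_id: str
    chi2_stat: float
    df: int
    p_combined: float


def read_summary_stats(
    path, column_spec: Mapping[str, str] | None = None
) -> list[SnpRecord]:
    """Read a TSV of summary statistics into :class:`SnpRecord` objects.

    ``column_spec`` maps canonical names (chrom, pos, effect_allele,
    other_allele, p, rsid, fs) to the file's header names. Rows whose p-value
    is unparsable or outside (0, 1] are dropped and counted in the log;
    p-values below 1e-300 (including underflowed zeros) are clamped.
    """
    spec = dict(DEFAULT_COLUMNS)
    if column_spec:
        spec.update(column_spec)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and df.columns.size == 0:
        logger.warning("summary-statistics file %s is empty", path)
        return []
    for key in ("chrom", "pos", "effect_allele", "other_allele", "p"):
        if spec[key] not in df.columns:
            raise ColumnSpecError(
                f"required column {key!r} (file column {spec[key]!r}) "
                f"not found in {path}; available: {list(df.columns)}"
            )
    has_rsid = spec["rsid"] in df.columns
    has_fs = spec["fs"] in df.columns

    records: list[SnpRecord] = []
    n_dropped = 0
    n_clamped = 0
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        try:
            p = float(row[spec["p"]])
            pos = int(row[spec["pos"]])
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        if not math.isfinite(p) or p < 0.0 or p > 1.0:
            n_dropped += 1
            continue
        if p < P_FLOOR:
            p = P_FLOOR
            n_clamped += 1
        fs = None
        if has_fs:
            raw_fs = row[spec["fs"]]
            if raw_fs is not None and str(raw_fs) not in ("", "nan", "NA"):
                fs = float(raw_fs)
        records.append(
            SnpRecord(
                chrom=row[spec["chrom"]],
                pos=pos,
                effect_allele=row[spec["effect_allele"]],
                other_allele=row[spec["other_allele"]],
                p_gwas=p,
                rsid=(str(row[spec["rsid"]]) if has_rsid else None),
                fs=fs,
            )
        )
    if n_dropped:
        logger.warning("%s: dropped %d rows with invalid p-values", path, n_dropped)
    if n_clamped:
        logger.info("%s: clamped %d p-values below %g", path, n_clamped, P_FLOOR)
    if not records:
        logger.warning("%s: no usable records", path)
    return records


def filter_by_pvalue(records: Sequence[SnpRecord], cutoff: float = 0.05) -> list[SnpRecord]:
    """Keep records with p_gwas strictly below ``cutoff`` (order preserved)."""
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff must be in (0,1], got {cutoff}")
    return [r for r in records if r.p_gwas < cutoff]


def apply_functional_weighting(
    records: Sequence[SnpRecord], fs_source: Mapping[str, float] | None = None
) -> list[SnpRecord]:
    """Return records with p_w = p_gwas / 10**fs.

    ``fs_source`` maps rsid -> functional score; when None, each record's own
    ``fs`` column is used. A missing score is treated as 0 (no weighting).
    """
    out: list[SnpRecord] = []
    for r in records:
        fs = r.fs
        if fs_source is not None and r.rsid is not None:
            fs = fs_source.get(r.rsid, fs)
        if fs is not None and not (0.0 <= fs <= 1.0):
            raise ValueError(
                f"functional score out of [0,1] for record {r.chrom}:{r.pos} "
                f"({r.rsid}): {fs}"
            )
        out.append(
            SnpRecord(
                chrom=r.chrom,
                pos=r.pos,
                effect_allele=r.effect_allele,
                other_allele=r.other_allele,
                p_gwas=r.p_gwas,
                rsid=r.rsid,
                fs=fs,
            )
        )
    return out


def map_snps_to_genes(
    records: Sequence[SnpRecord],
    genes: Sequence[GeneModel],
    use_weighted: bool = True,
) -> dict[str, list[float]]:
    """Assign each SNP to every gene whose window-extended interval contains it.

    Intervals are 0-based half-open [start-window, end+window); summary-stat
    positions are 1-based, converted internally. SNPs matching no gene are
    discarded and counted in the log. Returns gene_id -> list of p-values
    (weighted p_w by default).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    assigned: dict[str, list[float]] = {}
    n_unmapped = 0
    for r in records:
        hits = [g for g in by_chrom.get(r.chrom, ()) if g.contains(r.pos)]
        if not hits:
            n_unmapped += 1
            continue
        p = r.p_w if use_weighted else r.p_gwas
        for g in hits:
            assigned.setdefault(g.gene_id, []).append(p)
    if n_unmapped:
        logger.info("%d SNPs mapped to no gene and were discarded", n_unmapped)
    return assigned


def gene_score(snp_pvalues: Sequence[float], kind: str = "max_chi2") -> float:
    """Aggregate SNP p-values into one gene p-value.

    max_chi2: the maximum of the 1-df inverse-chi-squared transforms, whose
    p-value is exactly the minimum SNP p-value. sum_chi2: upper tail of
    sum_i chi2_1(p_i) against a chi-squared with one df per SNP. Neither
    statistic corrects for LD or gene size.
    """
    if len(snp_pvalues) == 0:
        raise ValueError("gene_score requires at least one SNP p-value")
    ps = np.clip(np.asarray(snp_pvalues, dtype=float), P_FLOOR, 1.0)
    if kind == "max_chi2":
        return float(ps.min())
    if kind == "sum_chi2":
        chi2_vals = stats.chi2.isf(ps, df=1)
        return float(stats.chi2.sf(chi2_vals.sum(), df=len(ps)))
    raise ValueError(f"unknown gene score kind: {kind!r}")


def score_genes(
    snps_by_gene: Mapping[str, Sequence[float]],
    dataset_label: str,
    kind: str = "max_chi2",
) -> GeneScoreTable:
    """Build a :class:`GeneScoreTable` from per-gene SNP p-value lists."""
    table = GeneScoreTable(dataset_label=dataset_label)
    for gene_id, ps in snps_by_gene.items():
        table.entries[gene_id] = (gene_score(ps, kind=kind), len(ps), kind)
    return table


def fisher_combine(p_by_dataset: Sequence[float], gene_id: str = "") -> CombinedScore:
    """Fisher's combined probability test: chi2 = -2 sum ln p_i, df = 2m."""
    ps = np.asarray(p_by_dataset, dtype=float)
    if ps.size == 0:
        raise ValueError("fisher_combine requires at least one p-value")
    if np.any(ps <= 0.0) or np.any(ps > 1.0):
        raise ValueError("all p-values must be in (0,1] (clamp before combining)")
    chi2_stat = float(-2.0 * np.log(ps).sum())
    df = 2 * ps.size
    return CombinedScore(
        gene_id=gene_id,
        chi2_stat=chi2_stat,
        df=df,
        p_combined=float(stats.chi2.sf(chi2_stat, df=df)),
    )


def combine_across_datasets(tables: Iterable[GeneScoreTable]) -> GeneScoreTable:
    """Fisher-combine gene p-values over genes present in *every* dataset."""
    tables = list(tables)
    if len(tables) < 1:
        raise ValueError("need at least one gene score table")
    common = set(tables[0].entries)
    for t in tables[1:]:
        common &= set(t.entries)
    out = GeneScoreTable(dataset_label="combined")
    for gene in sorted(common):
        ps = [t.entries[gene][0] for t in tables]
        ps = [max(p, P_FLOOR) for p in ps]
        combined = fisher_combine(ps, gene_id=gene)
        n_snps = sum(t.entries[gene][1] for t in tables)
        out.entries[gene] = (combined.p_combined, n_snps, "fisher_combined")
    logger.info("combined %d genes common to %d datasets", len(common), len(tables))
    return out
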