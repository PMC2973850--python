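"""Genome-wide variance-heterogeneity scan over real genotype data.

Workflow: read genotypes (VCF or a plain dosage matrix), read a phenotype
table keyed by sample ID (optionally natural-log transformed, the usual
pre-treatment for right-skewed biomarkers such as CRP), intersect samples,
and apply a variance-homogeneity test per SNP.  Levene's (Brown-Forsythe)
2-df test is the default — it is the only one of the three tests that
holds its type I error under non-normal traits.  Output is a flat
per-SNP table plus an optional QQ table for calibration checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .experiments import run_single_test
from .hettests import DegenerateGroupError, ZeroVarianceError

__all__ = [
    "GenotypeMatrix",
    "ScanRecord",
    "read_genotypes",
    "read_phenotype",
    "scan",
    "scan_to_frame",
    "qq_table",
    "SCAN_COLUMNS",
]

logger = logging.getLogger(__name__)

SCAN_COLUMNS = [
    "snp", "chrom", "pos", "n_AA", "n_AB", "n_BB",
    "var_AA", "var_AB", "var_BB", "maf", "stat", "df", "p",
    "gw_significant", "skipped_reason",
]


@dataclass
class GenotypeMatrix:
    """Allele-count matrix (SNPs x samples); NaN marks missing calls."""

    snp_ids: list
    chrom: list
    pos: np.ndarray  # 1-based
    sample_ids: list
    counts: np.ndarray  # float (n_snps, n_samples), values in {0,1,2,nan}

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class ScanRecord:
    snp_id: str
    chrom: str
    pos: int
    n0: int = 0
    n1: int = 0
    n2: int = 0
    var0: float = math.nan
    var1: float = math.nan
    var2: float = math.nan
    maf: float = math.nan
    statistic: float = math.nan
    df: int = 0
    p_value: float = math.nan
    test: str = ""
    gw_significant: bool = False
    skipped_reason: str | None = None


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError(f"duplicate sample IDs in VCF {path}")
    snp_ids, chrom, pos, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic site %s:%d", var.CHROM, var.POS)
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        row = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chrom.append(str(var.CHROM))
        pos.append(var.POS)
        rows.append(row)
    counts = np.array(rows, dtype=float) if rows else np.empty((0, len(samples)))
    return GenotypeMatrix(snp_ids, chrom, np.array(pos, dtype=int), samples, counts)


def _read_tsv_matrix(path) -> GenotypeMatrix:
    """Plain genotype matrix: columns snp, chrom, pos, then one per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["snp", "chrom", "pos"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"genotype matrix {path} lacks required columns {missing}")
    samples = [c for c in df.columns if c not in required]
    if len(set(samples)) != len(samples):
        raise ValueError(f"duplicate sample IDs in {path}")
    counts = df[samples].to_numpy(dtype=float)
    bad = ~(np.isnan(counts) | np.isin(counts, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid allele count {counts[i, j]!r} at SNP {df['snp'].iat[i]}, "
            f"sample {samples[j]} (line {i + 2})"
        )
    return GenotypeMatrix(
        df["snp"].tolist(), df["chrom"].tolist(), df["pos"].to_numpy(dtype=int),
        samples, counts,
    )


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Load genotypes as allele counts from a VCF or a TSV matrix."""
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv-matrix":
        return _read_tsv_matrix(path)
    raise ValueError(f"format must be 'vcf' or 'tsv-matrix', got {format!r}")


def read_phenotype(path, id_col: str, value_col: str, log_transform: bool = False) -> pd.Series:
    """Phenotype vector keyed by sample ID, optionally natural-log scaled.

    Non-numeric or missing values are dropped (count logged).  Under
    ``log_transform`` every value must be strictly positive.
    """
    df = pd.read_csv(path, sep="\t", dtype={id_col: str})
    for col in (id_col, value_col):
        if col not in df.columns:
            raise ValueError(f"phenotype file {path} has no column {col!r}")
    values = pd.to_numeric(df[value_col], errors="coerce")
    keep = values.notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d samples with missing/non-numeric phenotype", dropped)
    series = pd.Series(values[keep].to_numpy(), index=df[id_col][keep], name=value_col)
    if series.index.has_duplicates:
        dups = series.index[series.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in phenotype file: {dups[:5]}")
    if log_transform:
        nonpos = series.index[series <= 0].tolist()
        if nonpos:
            raise ValueError(
                f"--log-transform requires positive phenotypes; offending IDs: {nonpos[:10]}"
            )
        series = np.log(series)
    return series


def scan(
    genotypes: GenotypeMatrix,
    y: pd.Series,
    test: str = "levene",
    contrast: str = "2df",
    min_group_n: int = 30,
    alpha_gw: float = 5e-8,
) -> list[ScanRecord]:
    """Per-SNP variance-homogeneity test over the sample intersection.

    Missing genotype calls are excluded pairwise per SNP.  Genotype
    classes smaller than ``min_group_n`` are dropped from the test; a SNP
    left with fewer than two classes is reported with a skip reason rather
    than a p-value.  Records with p below ``alpha_gw`` are flagged
    genome-wide significant.
    """
    if genotypes.n_snps == 0:
        raise ValueError("no SNPs in the genotype input")
    common = [s for s in genotypes.sample_ids if s in y.index]
    if not common:
        raise ValueError("no overlap between genotype and phenotype sample IDs")
    logger.info(
        "sample intersection: %d of %d genotyped / %d phenotyped",
        len(common), len(genotypes.sample_ids), y.size,
    )
    col_idx = [genotypes.sample_ids.index(s) for s in common]
    gmat = genotypes.counts[:, col_idx]
    yvec = y.loc[common].to_numpy(dtype=float)

    records = []
    n_tested = 0
    for i in range(genotypes.n_snps):
        rec = ScanRecord(
            snp_id=genotypes.snp_ids[i], chrom=genotypes.chrom[i],
            pos=int(genotypes.pos[i]), test=test,
        )
        row = gmat[i]
        obs = ~np.isnan(row)
        g = row[obs].astype(np.int8)
        yy = yvec[obs]
        counts = np.bincount(g, minlength=3)
        rec.n0, rec.n1, rec.n2 = (int(c) for c in counts)
        n_obs = g.size
        if n_obs:
            af = float(g.sum()) / (2 * n_obs)
            rec.maf = min(af, 1.0 - af)
        for j, attr in enumerate(("var0", "var1", "var2")):
            if counts[j] >= 2:
                setattr(rec, attr, float(yy[g == j].var(ddof=1)))
        usable = counts >= min_group_n
        if usable.sum() < 2:
            rec.skipped_reason = "k<2"
            records.append(rec)
            continue
        keep = usable[g]
        try:
            res = run_single_test(yy[keep], g[keep], test, contrast)
        except (DegenerateGroupError, ZeroVarianceError, ValueError) as exc:
            rec.skipped_reason = str(exc)
            records.append(rec)
            continue
        rec.statistic = res.statistic
        rec.df = res.df1
        rec.p_value = res.p_value
        rec.gw_significant = res.p_value < alpha_gw
        n_tested += 1
        records.append(rec)
    if n_tested == 0:
        raise ValueError("zero SNPs were testable under the given filters")
    return records


def scan_to_frame(records: list[ScanRecord], with_bh: bool = True) -> pd.DataFrame:
    """Flatten scan records into the canonical output table.

    ``with_bh`` appends a Benjamini-Hochberg q-value column (q_bh) over
    the tested SNPs as a convenience beyond the fixed genome-wide
    threshold.
    """
    df = pd.DataFrame(
        dict(
            snp=[r.snp_id for r in records],
            chrom=[r.chrom for r in records],
            pos=[r.pos for r in records],
            n_AA=[r.n0 for r in records],
            n_AB=[r.n1 for r in records],
            n_BB=[r.n2 for r in records],
            var_AA=[r.var0 for r in records],
            var_AB=[r.var1 for r in records],
            var_BB=[r.var2 for r in records],
            maf=[r.maf for r in records],
            stat=[r.statistic for r in records],
            df=[r.df for r in records],
            p=[r.p_value for r in records],
            gw_significant=[r.gw_significant for r in records],
            skipped_reason=[r.skipped_reason or "" for r in records],
        )
    )
    if with_bh:
        from scipy.stats import false_discovery_control

        tested = df["p"].notna()
        q = pd.Series(np.nan, index=df.index)
        if tested.any():
            q[tested] = false_discovery_control(df.loc[tested, "p"].to_numpy(), method="bh")
        df["q_bh"] = q
    return df


def qq_table(records: list[ScanRecord]) -> pd.DataFrame:
    """Expected vs observed -log10(p) quantiles for a QQ plot.

    Observed p-values are sorted ascending; the i-th (1-based) expectation
    under the uniform null is (i - 0.5) / m for m tested SNPs.
    """
    pvals = np.sort([r.p_value for r in records if not math.isnan(r.p_value)])
    if pvals.size == 0:
        raise ValueError("no unskipped records to build a QQ table from")
    m = pvals.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.maximum(pvals, np.finfo(float).tiny))
    return pd.DataFrame({"expected_neglog10_p": expected, "observed_neglog10_p": observed})
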