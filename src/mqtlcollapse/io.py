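"""Standard-format I/O: VCF 4.2 (GT + DS), BED3 islands, TSV tables.

Writing is plain-text and deterministic (no timestamps); reading goes
through cyvcf2/htslib for VCF so fixtures are validated against a standard
parser, with MAF and Hardy-Weinberg p recomputed from the analyzed sample's
own dosages rather than trusted from file metadata.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import folded_maf, hwe_exact_pvalue
from .regions import GenomicInterval

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_bed",
    "read_bed",
    "read_probe_manifest",
    "read_matrix_tsv",
    "read_covariates",
    "read_known_mqtl",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=mqtlcollapse-simulator
##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the alternate allele">
##contig=<ID=chr1>
##contig=<ID=chr2>
"""


def write_vcf(
    path: str | Path,
    variants: pd.DataFrame,
    dosages: np.ndarray,
    sample_ids: list[str],
) -> None:
    """Write variants and per-sample dosages as an uncompressed VCF 4.2.

    GT is the hard call nearest the dosage; DS carries the dosage itself.
    Records are sorted by (chrom, pos).
    """
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    lines = [_VCF_HEADER]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids)
        + "\n"
    )
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j in order:
        row = variants.iloc[j]
        ds = dosages[:, j]
        hard = np.rint(ds).astype(int)
        fields = [
            str(row["chrom"]),
            str(int(row["pos"])),
            str(row["id"]),
            "A",
            "G",
            ".",
            "PASS",
            f"INFO={row['info_score']:.4f}" if "info_score" in row else ".",
            "GT:DS",
        ]
        fields += [f"{gt_codes[int(h)]}:{d:.4f}" for h, d in zip(hard, ds)]
        lines.append("\t".join(fields) + "\n")
    Path(path).write_text("".join(lines))


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a VCF into (variant table, dosage matrix, sample ids).

    Dosages come from DS when present, else from GT sums.  MAF (folded) and
    the HWE exact p are recomputed from the parsed genotypes.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for rec in vcf:
        try:
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            ds = None
        if ds is None:
            gts = np.asarray(rec.genotype.array())[:, :2]
            ds = np.where(gts < 0, np.nan, gts).sum(axis=1).astype(float)
        hard = np.rint(np.nan_to_num(ds, nan=np.nanmean(ds))).astype(int)
        info_score = rec.INFO.get("INFO")
        rows.append(
            {
                "id": rec.ID,
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "maf": folded_maf(ds),
                "info_score": float(info_score) if info_score is not None else np.nan,
                "hwe_p": hwe_exact_pvalue(
                    int(np.sum(hard == 1)),
                    int(np.sum(hard == 2)),
                    int(np.sum(hard == 0)),
                ),
            }
        )
        cols.append(ds)
    vcf.close()
    variants = pd.DataFrame(rows)
    dosages = np.stack(cols, axis=1) if cols else np.empty((len(samples), 0))
    return variants, dosages, samples


def write_bed(path: str | Path, islands: pd.DataFrame) -> None:
    """BED3, 0-based half-open, sorted by (chrom, start)."""
    df = islands.sort_values(["chrom", "start"])
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        out.append(GenomicInterval(chrom, int(start), int(end)))
    return out


def read_probe_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"probe manifest must have columns {sorted(required)}")
    return df


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Probes-by-samples matrix with probe_id as the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_known_mqtl(path: str | Path) -> pd.DataFrame:
    """Known single-variant mQTL list: snp_id, probe_id, chrom, pos."""
    df = pd.read_csv(path, sep="\t")
    if "pos" not in df.columns or "chrom" not in df.columns:
        raise ValueError("known-mQTL list must have chrom and pos columns")
    return df
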