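"""VCF/BED input-output and variant set operations.

Reads multi-sample VCFs with per-sample allele depths (AD), applies the
parent-heterozygosity marker filter (allele frequency within [0.25, 0.75] and
at least 20 reads, bounds inclusive), and identifies evolved-strain de-novo
variants by subtracting everything seen in the parent.

Internal coordinates are 1-based closed (VCF convention); BED files are
emitted and read as 0-based half-open.

Site tables are pandas DataFrames with columns ``chrom, pos, ref, alt,
variant_class`` plus ``<sample>.ref_depth`` / ``<sample>.alt_depth`` per
sample; sample names are listed in ``df.attrs["samples"]``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genome import GenomeSpec

__all__ = [
    "classify_variant",
    "write_vcf",
    "read_vcf",
    "call_het_sites",
    "subtract_parental_variants",
    "write_bed",
    "read_bed",
]

logger = logging.getLogger(__name__)

_KEY = ["chrom", "pos", "ref", "alt"]


def classify_variant(ref: str, alt: str) -> str:
    """SNP when the alleles have equal length, InDel otherwise."""
    return "SNP" if len(ref) == len(alt) else "InDel"


def write_vcf(
    path: str | Path,
    sites: pd.DataFrame,
    sample_counts: dict[str, pd.DataFrame],
    genome: GenomeSpec | None = None,
) -> None:
    """Write a minimal VCF 4.2 with AD/DP per sample.

    ``sites`` needs columns ``chrom, pos, ref, alt``; each value of
    ``sample_counts`` must be row-aligned to ``sites`` with columns
    ``ref_depth, alt_depth``.
    """
    samples = list(sample_counts)
    if not samples:
        raise ValueError("at least one sample required")
    for name, df in sample_counts.items():
        if len(df) != len(sites):
            raise ValueError(f"sample {name!r} counts not aligned to sites")
    lengths = genome.lengths if genome is not None else {}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in pd.unique(sites["chrom"]):
            if chrom in lengths:
                fh.write(f"##contig=<ID={chrom},length={lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        refs = sites["ref"].to_numpy()
        alts = sites["alt"].to_numpy()
        chroms = sites["chrom"].to_numpy()
        poss = sites["pos"].to_numpy()
        per_sample = [
            (sample_counts[s]["ref_depth"].to_numpy(), sample_counts[s]["alt_depth"].to_numpy())
            for s in samples
        ]
        for i in range(len(sites)):
            cells = []
            for r, a in per_sample:
                cells.append(f"{r[i]},{a[i]}:{r[i] + a[i]}")
            fh.write(
                f"{chroms[i]}\t{poss[i]}\t.\t{refs[i]}\t{alts[i]}\t.\tPASS\t.\tAD:DP\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path: str | Path, required_samples: list[str] | None = None) -> pd.DataFrame:
    """Read a multi-sample VCF into a site table with per-sample AD counts.

    Multiallelic records are skipped (count logged and stored in
    ``attrs["n_multiallelic_skipped"]``). Coordinates stay 1-based. A missing
    or absent AD field for a required sample raises, naming sample and site.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    if required_samples:
        missing = [s for s in required_samples if s not in samples]
        if missing:
            raise ValueError(f"VCF {path} lacks required sample(s): {', '.join(missing)}")
    rows: dict[str, list] = {k: [] for k in _KEY}
    depth_cols: dict[str, list] = {}
    for s in samples:
        depth_cols[f"{s}.ref_depth"] = []
        depth_cols[f"{s}.alt_depth"] = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"missing AD field at {v.CHROM}:{v.POS} in {path}")
        for j, s in enumerate(samples):
            r, a = int(ad[j, 0]), int(ad[j, 1])
            if r < 0 or a < 0:
                raise ValueError(f"missing AD for sample {s!r} at {v.CHROM}:{v.POS}")
            depth_cols[f"{s}.ref_depth"].append(r)
            depth_cols[f"{s}.alt_depth"].append(a)
        rows["chrom"].append(v.CHROM)
        rows["pos"].append(v.POS)
        rows["ref"].append(v.REF)
        rows["alt"].append(v.ALT[0])
    vcf.close()
    if n_multi:
        logger.info("skipped %d multiallelic records in %s", n_multi, path)
    df = pd.DataFrame({**rows, **depth_cols})
    if len(df):
        df["variant_class"] = [classify_variant(r, a) for r, a in zip(df["ref"], df["alt"])]
    else:
        df["variant_class"] = pd.Series(dtype=str)
    df.attrs["samples"] = samples
    df.attrs["n_multiallelic_skipped"] = n_multi
    return df


def call_het_sites(
    records: pd.DataFrame,
    parent_sample: str,
    af_min: float = 0.25,
    af_max: float = 0.75,
    min_depth: int = 20,
) -> pd.DataFrame:
    """Keep sites heterozygous in the parent: AF in [af_min, af_max], DP >= min_depth.

    Both allele-frequency bounds and the depth bound are inclusive, so the
    printed limits (0.25, 0.75, 20 reads) are themselves attainable. Retained
    SNP and InDel counts are stored in ``attrs``.
    """
    rcol, acol = f"{parent_sample}.ref_depth", f"{parent_sample}.alt_depth"
    if rcol not in records.columns:
        raise ValueError(f"parent sample {parent_sample!r} not present in records")
    ref = records[rcol].to_numpy(dtype=float)
    alt = records[acol].to_numpy(dtype=float)
    dp = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(dp > 0, alt / np.maximum(dp, 1), np.nan)
    keep = (dp >= min_depth) & (af >= af_min) & (af <= af_max)
    out = records.loc[keep].drop_duplicates(subset=["chrom", "pos"]).copy()
    order = _genome_order(out)
    out = out.iloc[order].reset_index(drop=True)
    out.attrs.update(records.attrs)
    out.attrs["filter_params"] = {"af_min": af_min, "af_max": af_max, "min_depth": min_depth}
    if "variant_class" in out.columns:
        vc = out["variant_class"].value_counts()
        out.attrs["n_snp"] = int(vc.get("SNP", 0))
        out.attrs["n_indel"] = int(vc.get("InDel", 0))
    return out


def _genome_order(df: pd.DataFrame) -> np.ndarray:
    """Stable sort order by (chromosome in first-appearance order, position)."""
    cats = pd.unique(df["chrom"])
    codes = pd.Categorical(df["chrom"], categories=cats).codes
    return np.lexsort((df["pos"].to_numpy(), codes))


def subtract_parental_variants(
    evolved_records: pd.DataFrame,
    parent_records: pd.DataFrame,
    parent_het: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """De-novo variants: in the evolved strain but absent from the parent.

    A variant is removed when its (chrom, pos, ref, alt) key is present in
    the parent call set or in the parent heterozygous set — matching requires
    the identical alternate allele, not just the position. SNP and InDel
    counts of the result are stored in ``attrs``.
    """
    def keys(df: pd.DataFrame) -> set[tuple]:
        if len(df) == 0:
            return set()
        return set(zip(df["chrom"], df["pos"], df["ref"], df["alt"]))

    drop = keys(parent_records) | (keys(parent_het) if parent_het is not None else set())
    if len(evolved_records) == 0:
        out = evolved_records.copy()
    else:
        ek = list(zip(evolved_records["chrom"], evolved_records["pos"],
                      evolved_records["ref"], evolved_records["alt"]))
        mask = np.array([k not in drop for k in ek])
        out = evolved_records.loc[mask].copy()
    out.attrs.update(evolved_records.attrs)
    if "variant_class" not in out.columns and len(out):
        out["variant_class"] = [classify_variant(r, a) for r, a in zip(out["ref"], out["alt"])]
    vc = out["variant_class"].value_counts() if len(out) else {}
    out.attrs["n_snp"] = int(vc.get("SNP", 0)) if len(out) else 0
    out.attrs["n_indel"] = int(vc.get("InDel", 0)) if len(out) else 0
    return out.reset_index(drop=True)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based closed intervals as BED (0-based half-open).

    ``intervals`` needs columns ``chrom, start, end`` and may carry a
    ``name`` column. An empty set produces a file with only a header comment.
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for _, row in intervals.iterrows():
            name = row.get("name", ".")
            fh.write(f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}\t{name}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file back to 1-based closed intervals."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("track"):
            continue
        parts = line.split("\t")
        rows.append(
            {
                "chrom": parts[0],
                "start": int(parts[1]) + 1,
                "end": int(parts[2]),
                "name": parts[3] if len(parts) > 3 else ".",
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
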