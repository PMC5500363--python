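import numpy as np
import pandas as pd
import pytest

from bsakit import GenomeSpec


@pytest.fixture
def tiny_genome() -> GenomeSpec:
    """Three small chromosomes; enough structure for allocation tests."""
    return GenomeSpec(
        chromosomes=(("chrA", 100_000), ("chrB", 300_000), ("chrC", 600_000)),
        recombination_rate=0.35,
    )


@pytest.fixture
def single_chromosome() -> GenomeSpec:
    return GenomeSpec(chromosomes=(("chr1", 1_000),), recombination_rate=0.0)


def make_records(rows, samples=("parent",)):
    """Build a variant record table in the shape read_vcf produces.

    ``rows`` is a list of (chrom, pos, ref, alt, {sample: (ref_depth, alt_depth)}).
    """
    data = {"chrom": [], "pos": [], "ref": [], "alt": []}
    for s in samples:
        data[f"{s}.ref_depth"] = []
        data[f"{s}.alt_depth"] = []
    for chrom, pos, ref, alt, depths in rows:
        data["chrom"].append(chrom)
        data["pos"].append(pos)
        data["ref"].append(ref)
        data["alt"].append(alt)
        for s in samples:
            r, a = depths[s]
            data[f"{s}.ref_depth"].append(r)
            data[f"{s}.alt_depth"].append(a)
    df = pd.DataFrame(data)
    df["variant_class"] = [
        "SNP" if len(r) == len(a) else "InDel" for r, a in zip(df["ref"], df["alt"])
    ]
    df.attrs["samples"] = list(samples)
    return df


@pytest.fixture
def toy_vcf(tmp_path):
    """A small three-site VCF written through the package's own writer."""
    from bsakit.variant_io import write_vcf

    sites = pd.DataFrame(
        {
            "chrom": ["chrA", "chrA", "chrB"],
            "pos": [100, 2000, 50],
            "ref": ["A", "C", "G"],
            "alt": ["T", "G", "GA"],
        }
    )
    counts = {
        "parent": pd.DataFrame({"ref_depth": [20, 10, 15], "alt_depth": [20, 90, 45]}),
        "pool1": pd.DataFrame({"ref_depth": [5, 5, 80], "alt_depth": [35, 5, 0]}),
    }
    path = tmp_path / "toy.vcf"
    write_vcf(path, sites, counts)
    return path, sites, counts
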