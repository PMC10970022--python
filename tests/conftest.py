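import textwrap

import numpy as np
import pandas as pd
import pytest

from fpfinder import PresenceMatrix, SampleManifest

VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=A01,length=100000>
    ##contig=<ID=A02,length=100000>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
    """)


def make_vcf(path, records, samples=("S1", "S2", "S3")):
    """Write a small VCF; records are (chrom, pos, ref, alt, qual, [gt, ...])."""
    lines = [VCF_HEADER.format(samples="\t".join(samples))]
    for chrom, pos, ref, alt, qual, gts in records:
        q = "." if qual is None else f"{qual:g}"
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{q}\t.\t.\tGT\t" + "\t".join(gts) + "\n"
        )
    path.write_text("".join(lines))
    return path


@pytest.fixture
def toy_vcf(tmp_path):
    """Five records spanning the QUAL ladder {10, 29, 30, 31, missing}."""
    return make_vcf(
        tmp_path / "toy.vcf",
        [
            ("A01", 100, "A", "G", 10, ["0/1", "0/0", "0/0"]),
            ("A01", 200, "C", "T", 29, ["0/1", "0/1", "0/0"]),
            ("A01", 300, "G", "A", 30, ["0/1", "0/0", "1/1"]),
            ("A01", 400, "T", "C", 31, ["0/0", "0/1", "0/0"]),
            ("A01", 500, "A", "C", None, ["1/1", "0/1", "0/0"]),
        ],
    )


def random_matrix(rng, n_sites=None, n_samples=None):
    """A random PresenceMatrix with (chrom, pos)-sorted unique sites."""
    n_sites = n_sites or int(rng.integers(1, 51))
    n_samples = n_samples or int(rng.integers(2, 31))
    pos = np.sort(rng.choice(100_000, size=n_sites, replace=False) + 1)
    ref = rng.choice(list("ACGT"), n_sites)
    alt = [("ACGT".replace(r, ""))[rng.integers(0, 3)] for r in ref]
    sites = pd.DataFrame({"chrom": "A01", "pos": pos, "ref": ref, "alt": alt})
    samples = [f"S{i}" for i in range(n_samples)]
    values = rng.random((n_sites, n_samples)) < rng.uniform(0.05, 0.95)
    return PresenceMatrix(sites=sites, samples=samples, values=values)


def split_manifest(samples, n_target):
    roles = {s: ("target" if i < n_target else "background")
             for i, s in enumerate(samples)}
    return SampleManifest(samples=list(samples), roles=roles)
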