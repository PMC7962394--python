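import numpy as np
import pandas as pd
import pytest

from popgrs.genotypes import GenotypeMatrix, SamplePanel


@pytest.fixture
def write_assoc_tsv(tmp_path):
    """Factory writing an association table in the minimal TSV dialect."""

    def _write(rows, name="assoc.tsv",
               header=("rsid", "chrom", "pos", "risk_allele", "ref", "alt", "odds_ratio")):
        path = tmp_path / name
        lines = ["\t".join(header)]
        for row in rows:
            lines.append("\t".join(str(x) for x in row))
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def write_vcf_text(tmp_path):
    """Factory writing a small plain-text VCF 4.2."""

    def _write(samples, variant_lines, name="test.vcf"):
        path = tmp_path / name
        header = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
        ]
        path.write_text("\n".join(header + list(variant_lines)) + "\n")
        return path

    return _write


@pytest.fixture
def tiny_panel():
    return SamplePanel(
        {
            "S1": ("POPA", "SUP1"),
            "S2": ("POPA", "SUP1"),
            "S3": ("POPB", "SUP2"),
            "S4": ("POPB", "SUP2"),
        }
    )


def make_matrix(dosage, rsids=None, samples=None, effect_ref=()):
    """Build a GenotypeMatrix from a dosage array (NaN = missing)."""
    dosage = np.asarray(dosage, dtype=float)
    n_samples, n_snps = dosage.shape
    rsids = rsids or [f"rs{900000 + j}" for j in range(n_snps)]
    samples = samples or [f"S{i + 1}" for i in range(n_samples)]
    variants = pd.DataFrame(
        {
            "rsid": rsids,
            "chrom": ["1"] * n_snps,
            "pos": [1000 * (j + 1) for j in range(n_snps)],
            "ref": ["A"] * n_snps,
            "alt": ["G"] * n_snps,
            "effect_allele": ["A" if j in effect_ref else "G" for j in range(n_snps)],
        }
    )
    return GenotypeMatrix(variants, samples, dosage)
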