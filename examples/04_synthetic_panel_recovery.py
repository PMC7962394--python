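"""Simulate a structured panel and recover its ground truth end to end.

Generates two super-groups of three populations with opposite frequency
shifts on a third of the SNPs, writes VCF + panel + association files,
then runs the real pipeline stages on those files and compares the
classification and clustering against the generator's recorded truth.
"""

import tempfile
from pathlib import Path

from popgrs import (
    SamplePanel, build_matrix, cluster_populations, compute_eaf,
    deduplicate, harmonize, parse_association_table, read_vcf_genotypes,
    scenario_two_clusters,
)

with tempfile.TemporaryDirectory() as td:
    td = Path(td)
    truth = scenario_two_clusters(td, n_snps=30, n_shifted=10,
                                  n_samples=150, seed=42)
    records, _ = deduplicate(harmonize(
        parse_association_table(td / "associations.tsv", "OAG")))
    panel = SamplePanel.from_tsv(td / "panel.tsv")
    genotypes, report = read_vcf_genotypes(td / "genotypes.vcf", records)
    table = compute_eaf(genotypes, panel, "population").concat(
        compute_eaf(genotypes, panel, "pooled"))
    matrix = build_matrix(table, genotypes.rsids,
                          panel.groups("population"), "GLOBAL")

    agree = sum(
        cell.klass == truth["expected_class"][f"{cell.rsid}:{cell.group}"]
        for cell in matrix.cells
    )
    tree = cluster_populations(matrix)

print(f"SNPs matched in VCF: {len(report.matched)}/{len(records)}")
print(f"cell-class agreement with ground truth: {agree}/{len(matrix.cells)} "
      f"({agree / len(matrix.cells):.1%})")
print(f"recovered top split: {[sorted(c) for c in tree.cut(2)]}")
print(f"designed partition:  {truth['expected_partition']}")
print("\nShifted SNPs are detected as enriched/depleted in the right")
print("populations, null SNPs stay 'similar' at close to the nominal rate,")
print("and clustering recovers the two designed super-groups.")
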