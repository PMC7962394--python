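"""Curate a small association table: harmonize risk alleles, deduplicate.

Builds a five-row catalog-style table in memory, then runs the standard
curation chain.  Note how the OR < 1 record gets its effect allele
flipped to the other member of the pair, and how the duplicate collapses.
"""

import tempfile
from pathlib import Path

from popgrs import deduplicate, harmonize, parse_association_table

TABLE = """\
rsid\tchrom\tpos\trisk_allele\tref\talt\todds_ratio
rs2024211\tchr7\t116153025\trs2024211-C\tA\tC\t1.2
rs1579050\tchr2\t153364527\trs1579050-A\tA\tG\t0.8
rs8141433\tchr22\t19854006\trs8141433-G\tA\tG\t1.1
rs8141433\tchr22\t19854006\trs8141433-G\tA\tG\t1.1
rs999999\tchr1\t1000\trs999999-?\tA\tG\t
"""

with tempfile.TemporaryDirectory() as td:
    path = Path(td) / "assoc.tsv"
    path.write_text(TABLE)
    records = parse_association_table(path, trait="IOP")
    records = harmonize(records)
    records, report = deduplicate(records)

print(f"{report.n_in} records in, {report.n_out} out ({report.n_removed} duplicates)")
for r in records:
    print(f"  {r.rsid:<10} {r.ref_allele}/{r.alt_allele} "
          f"effect={r.effect_allele} orientation={r.orientation}")
print("\nrs1579050 was reported with allele A but OR 0.8 (< 1): the risk")
print("runs through the other allele, so its effect allele is now G.")
print("rs999999 had no defined risk allele and stays flagged ambiguous.")
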