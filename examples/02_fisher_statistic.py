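"""The signed log-space Fisher statistic on allele-count tables.

Compares a population's effect-allele count against a pooled reference
and prints the two-sided P and the signed log10 P.  The last case shows
why log space matters: the P value is ~1e-219, far beyond where naive
products of factorials overflow, yet the statistic is computed exactly.
"""

from popgrs import classify, fisher_signed_log10p

cases = [
    ("same frequency      ", 100, 1000, 500, 5000),
    ("mild enrichment     ", 150, 1000, 500, 5000),
    ("strong depletion    ", 24, 3444, 1052, 5008),  # ~0.7% vs ~21%
]
for name, k_pop, n_pop, k_ref, n_ref in cases:
    res = fisher_signed_log10p(k_pop, n_pop, k_ref, n_ref)
    klass = classify(res.signed_log10p)
    print(f"{name} eaf {k_pop / n_pop:.4f} vs ref {k_ref / n_ref:.4f}  "
          f"P={res.p_two_sided:.3g}  signed log10 P={res.signed_log10p:+.3f}  "
          f"-> {klass}")

print("\nPositive signed values mean the allele is more common than in the")
print("reference (enriched), negative means less common (depleted); the")
print("|value| > 1.301 cut corresponds to P < 0.05.")
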