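"""Rank candidate variants for the packaged nine-member family.

Runs the full prioritization on the bundled worked example: five
Sanger-validated heterozygous missense variants genotyped across five
affected and four unaffected relatives of a dominant-disease family.
"""

from exomd import za253_fixtures, run_prioritize

pedigree, genotypes, variants = za253_fixtures()
ranked, decision_log = run_prioritize(variants, pedigree, genotypes)

print("rank  gene     votes  conserved  segregation  maf")
for rc in ranked:
    p = rc.profile
    print(
        f"{rc.rank:>4}  {p.gene_symbol:<7} {p.deleterious_votes:>5}  "
        f"{'yes' if p.conserved else 'no':<9}  "
        f"{'pass' if rc.verdict.passes else 'fail':<11}  "
        f"{'novel' if rc.maf is None else f'{rc.maf:.3g}'}"
    )
print()
for entry in decision_log:
    print(f"excluded: {entry['variant_id']} ({entry['rule']})")

# The top-ranked variant is the one called deleterious by all five tools at a
# conserved site; the last-ranked one failed co-segregation because three
# unaffected relatives carry it. A "novel" MAF means the variant was never
# seen in reference populations.
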