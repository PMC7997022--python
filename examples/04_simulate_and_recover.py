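"""Planted-signal recovery: simulate a family, re-identify the causal variant.

Generates a synthetic dominant family (5 affected, one of them a
phenocopy, 4 unaffected, 20 background polymorphisms) and checks that the
pipeline ranks the planted causal variant first.
"""

from exomd import FamilySimConfig, generate_family_dataset, run_prioritize

hits = 0
n = 10
for seed in range(n):
    pedigree, genotypes, variants = generate_family_dataset(FamilySimConfig(seed=seed))
    ranked, _ = run_prioritize(variants, pedigree, genotypes)
    top = ranked[0].profile.gene_symbol
    hits += top == "CAUSAL1"
    print(f"seed {seed}: top candidate = {top}")
print(f"\nplanted variant ranked first in {hits}/{n} replicates")

# Each replicate plants one novel heterozygous deleterious variant shared by
# the non-phenocopy affecteds; recovery demonstrates that the filtration
# cascade plus consensus ranking isolates it from benign background variation.
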