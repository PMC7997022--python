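"""End-to-end candidate prioritization: filter -> segregate -> consensus -> rank.

``run_prioritize`` chains the filtration cascade, the pedigree
co-segregation assessment and the consensus ranking, and records for every
excluded variant the first rule that removed it, in the order the cascade
applies them (synonymous, homozygous, common, not shared in the index
cases, then segregation).
"""

from __future__ import annotations

from .consensus import (
    ConsensusThresholds,
    DEFAULT_THRESHOLDS,
    RankedCandidate,
    consensus_profile,
    rank_candidates,
)
from .domain import AnnotatedVariant, GenotypeMatrix, Pedigree
from .segregation import (
    FilterConfig,
    assess_cosegregation,
    filter_candidates_with_log,
)

__all__ = ["run_prioritize"]


def _submatrix(genotypes: GenotypeMatrix, variant_ids: list[str]) -> GenotypeMatrix:
    sub = GenotypeMatrix(genotypes.individual_ids, variant_ids)
    for ind in genotypes.individual_ids:
        for vid in variant_ids:
            sub.set(ind, vid, genotypes.get(ind, vid))
    return sub


def run_prioritize(
    variants: list[AnnotatedVariant],
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    shared_in: list[str] | None = None,
    filter_cfg: FilterConfig | None = None,
    thresholds: ConsensusThresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[RankedCandidate], list[dict]]:
    """Run the full prioritization and return (ranked candidates, decision log).

    ``shared_in`` defaults to the pedigree's sequenced affected members
    (the index cases).  The decision log holds one dict per excluded
    variant: ``{"variant_id": ..., "rule": ...}``; variants failing
    co-segregation stay in the ranked output (after all passing ones) but
    are logged with the allowance they violated.
    """
    filter_cfg = filter_cfg or FilterConfig()
    if shared_in is None:
        shared_in = [m.id for m in pedigree.members if m.sequenced and m.id in
                     set(pedigree.affected_ids)]
        if not shared_in:
            raise ValueError("no sequenced affected members; pass shared_in explicitly")
    kept, exclusions = filter_candidates_with_log(
        variants, shared_in, genotypes, filter_cfg
    )
    log = [{"variant_id": vid, "rule": rule} for vid, rule in exclusions]
    if not kept:
        return [], log
    sub = _submatrix(genotypes, [v.variant_id for v in kept])
    verdicts = assess_cosegregation(sub, pedigree, filter_cfg)
    for w in verdicts:
        if w.passes:
            continue
        if w.affected_noncarriers > filter_cfg.max_phenocopies:
            rule = "phenocopies"
        else:
            rule = "unaffected_carriers"
        log.append({"variant_id": w.variant_id, "rule": rule})
    profiles = [consensus_profile(v, thresholds) for v in kept]
    ranked = rank_candidates(profiles, verdicts, variants=kept)
    return ranked, log
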