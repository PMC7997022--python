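"""Variant filtration cascade and pedigree co-segregation assessment.

Implements the dominant-model candidate filter used in family exome
studies: drop synonymous and homozygous calls, drop common variants
(minor allele frequency above a threshold), keep variants shared by all
index cases, then test co-segregation in the full genotyped family while
allowing a configurable number of phenocopies (affected non-carriers)
and unaffected carriers (reduced penetrance).
"""

from __future__ import annotations

from dataclasses import dataclass

from .domain import (
    AnnotatedVariant,
    Affection,
    Carrier,
    Consequence,
    GenotypeMatrix,
    Pedigree,
    Zygosity,
)

__all__ = [
    "FilterConfig",
    "SegregationVerdict",
    "compute_maf",
    "filter_candidates",
    "filter_candidates_with_log",
    "assess_cosegregation",
]


@dataclass(frozen=True)
class FilterConfig:
    """Knobs of the filtration cascade and segregation test.

    maf_threshold:
        Keep variants with minor allele frequency <= this value (inclusive;
        the conventional rare-variant cutoff is 1%).  Variants with no
        frequency record at all are "novel" and always kept.
    max_phenocopies:
        Affected individuals allowed to lack the variant.  The default of 1
        models one sporadic case inside an otherwise Mendelian family.
    max_unaffected_carriers:
        Unaffected carriers tolerated; 0 assumes full penetrance.
    require_het:
        Dominant model: drop homozygous calls in the index cases.
    exclude_synonymous:
        Drop synonymous variants.
    """

    maf_threshold: float = 0.01
    max_phenocopies: int = 1
    max_unaffected_carriers: int = 0
    require_het: bool = True
    exclude_synonymous: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_threshold <= 1.0):
            raise ValueError("maf_threshold must be in [0, 1]")
        if self.max_phenocopies < 0 or self.max_unaffected_carriers < 0:
            raise ValueError("allowance counts must be >= 0")


@dataclass(frozen=True)
class SegregationVerdict:
    """Per-variant co-segregation counts over typed family members."""

    variant_id: str
    affected_carriers: int
    affected_noncarriers: int
    unaffected_carriers: int
    passes: bool


def compute_maf(allele_count: int, allele_number: int) -> float:
    """Minor allele frequency min(f, 1 - f) with f = allele_count / allele_number."""
    if allele_number <= 0:
        raise ValueError("allele_number must be positive")
    if not (0 <= allele_count <= allele_number):
        raise ValueError("allele_count must be in [0, allele_number]")
    f = allele_count / allele_number
    return min(f, 1.0 - f)


def variant_maf(variant: AnnotatedVariant) -> float | None:
    """MAF of a variant's frequency record, or None when novel."""
    if variant.frequency is None:
        return None
    return compute_maf(variant.frequency.allele_count, variant.frequency.allele_number)


# Rules in the order the cascade applies them.
RULE_SYNONYMOUS = "synonymous"
RULE_HOMOZYGOUS = "homozygous"
RULE_COMMON = "common"
RULE_NOT_SHARED = "not_shared"


def _first_failing_rule(
    variant: AnnotatedVariant,
    shared_in: list[str],
    genotypes: GenotypeMatrix,
    cfg: FilterConfig,
) -> str | None:
    if cfg.exclude_synonymous and variant.consequence is Consequence.SYNONYMOUS:
        return RULE_SYNONYMOUS
    if cfg.require_het and variant.zygosity is Zygosity.HOM:
        return RULE_HOMOZYGOUS
    maf = variant_maf(variant)
    if maf is not None and maf > cfg.maf_threshold:
        return RULE_COMMON
    for ind in shared_in:
        if genotypes.get(ind, variant.variant_id) is not Carrier.PRESENT:
            return RULE_NOT_SHARED
    return None


def filter_candidates_with_log(
    variants: list[AnnotatedVariant],
    shared_in: list[str],
    genotypes: GenotypeMatrix,
    cfg: FilterConfig | None = None,
) -> tuple[list[AnnotatedVariant], list[tuple[str, str]]]:
    """Like :func:`filter_candidates` but also return, for every excluded
    variant, the first rule of the cascade that removed it."""
    cfg = cfg or FilterConfig()
    unknown = [i for i in shared_in if i not in genotypes.individual_ids]
    if unknown:
        raise KeyError(f"shared_in ids not in genotype matrix: {unknown}")
    kept: list[AnnotatedVariant] = []
    log: list[tuple[str, str]] = []
    for v in variants:
        rule = _first_failing_rule(v, list(shared_in), genotypes, cfg)
        if rule is None:
            kept.append(v)
        else:
            log.append((v.variant_id, rule))
    return kept, log


def filter_candidates(
    variants: list[AnnotatedVariant],
    shared_in: list[str],
    genotypes: GenotypeMatrix,
    cfg: FilterConfig | None = None,
) -> list[AnnotatedVariant]:
    """Apply the filtration cascade, preserving input order.

    Retains variants that are non-synonymous, heterozygous, rare
    (MAF <= threshold, or novel) and carried by every individual in
    ``shared_in`` (the index cases whose exomes were compared).
    """
    kept, _ = filter_candidates_with_log(variants, shared_in, genotypes, cfg)
    return kept


def assess_cosegregation(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    cfg: FilterConfig | None = None,
) -> list[SegregationVerdict]:
    """Count carriers among typed family members and apply the
    phenocopy / penetrance allowances.

    Individuals with unknown affection status contribute to no count;
    untyped genotype calls are likewise excluded.  A variant passes iff
    affected_noncarriers <= max_phenocopies and
    unaffected_carriers <= max_unaffected_carriers.
    """
    cfg = cfg or FilterConfig()
    genotypes.validate_against(pedigree)
    verdicts: list[SegregationVerdict] = []
    for vid in genotypes.variant_ids:
        affected_carriers = affected_noncarriers = unaffected_carriers = 0
        typed_affected = 0
        for ind in genotypes.individual_ids:
            status = genotypes.get(ind, vid)
            if status is Carrier.UNTYPED:
                continue
            affection = pedigree[ind].affection
            if affection is Affection.AFFECTED:
                typed_affected += 1
                if status is Carrier.PRESENT:
                    affected_carriers += 1
                else:
                    affected_noncarriers += 1
            elif affection is Affection.UNAFFECTED:
                if status is Carrier.PRESENT:
                    unaffected_carriers += 1
        if typed_affected == 0:
            raise ValueError(f"variant {vid!r} has no typed affected individual")
        verdicts.append(
            SegregationVerdict(
                variant_id=vid,
                affected_carriers=affected_carriers,
                affected_noncarriers=affected_noncarriers,
                unaffected_carriers=unaffected_carriers,
                passes=(
                    affected_noncarriers <= cfg.max_phenocopies
                    and unaffected_carriers <= cfg.max_unaffected_carriers
                ),
            )
        )
    return verdicts
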