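"""Consensus deleteriousness calls and candidate ranking.

Each prediction tool's raw score is mapped to a categorical call with a
documented cutoff; the calls are combined into a vote count, a
conservation flag (GERP++) and a lexicographic rank key.  Candidates that
fail co-segregation are always ranked after those that pass.

Default cutoffs
---------------
SIFT <= 0.05 deleterious (SIFT's published damaging cutoff, inclusive);
PolyPhen-2 HumDiv tiers (>= 0.909 probably damaging, >= 0.447 possibly
damaging, both counted as deleterious); MutationTaster >= 0.5 disease
causing; CADD phred >= 15 deleterious (midway between the "top 10%" and
"top 1%" tiers); Condel >= 0.522 deleterious (published default); GERP++
>= 2.0 flags an evolutionarily conserved site.  All cutoffs are
overridable through :class:`ConsensusThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .domain import AnnotatedVariant
from .segregation import SegregationVerdict, variant_maf

__all__ = [
    "Call",
    "PolyPhenLabel",
    "ConsensusThresholds",
    "ConsensusProfile",
    "RankedCandidate",
    "classify_tool_score",
    "consensus_profile",
    "rank_candidates",
    "VOTING_TOOLS",
]

VOTING_TOOLS = ("sift", "polyphen2", "mutationtaster", "cadd", "condel")


class Call(str, Enum):
    DELETERIOUS = "deleterious"
    BENIGN = "benign"
    ABSENT = "absent"


class PolyPhenLabel(str, Enum):
    BENIGN = "benign"
    POSSIBLY_DAMAGING = "possibly_damaging"
    PROBABLY_DAMAGING = "probably_damaging"


@dataclass(frozen=True)
class ConsensusThresholds:
    sift_deleterious_max: float = 0.05
    polyphen2_possibly: float = 0.447
    polyphen2_probably: float = 0.909
    mutationtaster_min: float = 0.5
    cadd_min: float = 15.0
    condel_min: float = 0.522
    gerp_conserved_min: float = 2.0


DEFAULT_THRESHOLDS = ConsensusThresholds()


def _check_domain(tool: str, score: float, low: float, high: float) -> None:
    if not (low <= score <= high):
        raise ValueError(f"{tool} score {score} outside [{low}, {high}]")


def classify_tool_score(
    tool: str, score: float, thresholds: ConsensusThresholds = DEFAULT_THRESHOLDS
):
    """Map one tool's raw score to its categorical call.

    Returns a :class:`Call` for the five voting tools, a
    :class:`PolyPhenLabel` for ``"polyphen2_label"``, and a bool
    (conserved) for ``"gerp"``.
    """
    if tool == "sift":
        _check_domain(tool, score, 0.0, 1.0)
        return Call.DELETERIOUS if score <= thresholds.sift_deleterious_max else Call.BENIGN
    if tool == "polyphen2":
        _check_domain(tool, score, 0.0, 1.0)
        return Call.DELETERIOUS if score >= thresholds.polyphen2_possibly else Call.BENIGN
    if tool == "polyphen2_label":
        _check_domain("polyphen2", score, 0.0, 1.0)
        if score >= thresholds.polyphen2_probably:
            return PolyPhenLabel.PROBABLY_DAMAGING
        if score >= thresholds.polyphen2_possibly:
            return PolyPhenLabel.POSSIBLY_DAMAGING
        return PolyPhenLabel.BENIGN
    if tool == "mutationtaster":
        _check_domain(tool, score, 0.0, 1.0)
        return Call.DELETERIOUS if score >= thresholds.mutationtaster_min else Call.BENIGN
    if tool == "cadd":
        if score < 0:
            raise ValueError(f"cadd score {score} is negative")
        return Call.DELETERIOUS if score >= thresholds.cadd_min else Call.BENIGN
    if tool == "condel":
        _check_domain(tool, score, 0.0, 1.0)
        return Call.DELETERIOUS if score >= thresholds.condel_min else Call.BENIGN
    if tool == "gerp":
        _check_domain(tool, score, -12.3, 6.17)
        return score >= thresholds.gerp_conserved_min
    raise ValueError(f"unknown tool {tool!r}")


@dataclass(frozen=True)
class ConsensusProfile:
    """Categorical calls plus the derived consensus summary for one variant."""

    variant_id: str
    gene_symbol: str
    protein_change: str
    calls: dict[str, Call]
    polyphen2_label: PolyPhenLabel | None
    conserved: bool
    deleterious_votes: int
    unanimous: bool
    cadd_phred: float | None

    @property
    def rank_key(self) -> tuple:
        cadd = self.cadd_phred if self.cadd_phred is not None else float("-inf")
        return (self.deleterious_votes, self.conserved, cadd)


def consensus_profile(
    v: AnnotatedVariant, thresholds: ConsensusThresholds = DEFAULT_THRESHOLDS
) -> ConsensusProfile:
    """Build the consensus profile of one variant from its raw scores.

    An absent score yields an ``absent`` call which counts as a
    non-deleterious vote but stays distinguishable from ``benign`` in the
    report.  GERP++ sets the conservation flag rather than casting a vote.
    """
    s = v.tool_scores
    if not s.any_present:
        raise ValueError(f"{v.variant_id}: all tool scores absent")
    raw = {
        "sift": s.sift,
        "polyphen2": s.polyphen2,
        "mutationtaster": s.mutationtaster,
        "cadd": s.cadd_phred,
        "condel": s.condel,
    }
    calls = {
        tool: (Call.ABSENT if score is None else classify_tool_score(tool, score, thresholds))
        for tool, score in raw.items()
    }
    votes = sum(1 for c in calls.values() if c is Call.DELETERIOUS)
    conserved = (
        bool(classify_tool_score("gerp", s.gerp, thresholds)) if s.gerp is not None else False
    )
    return ConsensusProfile(
        variant_id=v.variant_id,
        gene_symbol=v.gene_symbol,
        protein_change=v.protein_change,
        calls=calls,
        polyphen2_label=(
            classify_tool_score("polyphen2_label", s.polyphen2, thresholds)
            if s.polyphen2 is not None
            else None
        ),
        conserved=conserved,
        deleterious_votes=votes,
        unanimous=(votes == len(VOTING_TOOLS) and conserved),
        cadd_phred=s.cadd_phred,
    )


@dataclass(frozen=True)
class RankedCandidate:
    rank: int
    profile: ConsensusProfile
    verdict: SegregationVerdict
    maf: float | None


def rank_candidates(
    profiles: list[ConsensusProfile],
    verdicts: list[SegregationVerdict],
    variants: list[AnnotatedVariant] | None = None,
) -> list[RankedCandidate]:
    """Order candidates: segregation-passing variants first, then within
    each block by descending (votes, conserved, CADD), ties broken by gene
    symbol alphabetically.  Deterministic for any input permutation.

    ``variants`` (optional, same ids) supplies the frequency records used
    for the report's MAF column.
    """
    by_id = {p.variant_id: p for p in profiles}
    verdict_by_id = {w.variant_id: w for w in verdicts}
    if set(by_id) != set(verdict_by_id):
        raise ValueError(
            "profiles and verdicts must cover the same variant ids: "
            f"{sorted(set(by_id) ^ set(verdict_by_id))}"
        )
    maf_by_id: dict[str, float | None] = {}
    if variants is not None:
        for v in variants:
            maf_by_id[v.variant_id] = variant_maf(v)

    def sort_key(p: ConsensusProfile):
        passes = verdict_by_id[p.variant_id].passes
        votes, conserved, cadd = p.rank_key
        return (not passes, -votes, not conserved, -cadd, p.gene_symbol)

    ordered = sorted(profiles, key=sort_key)
    return [
        RankedCandidate(
            rank=i + 1,
            profile=p,
            verdict=verdict_by_id[p.variant_id],
            maf=maf_by_id.get(p.variant_id),
        )
        for i, p in enumerate(ordered)
    ]
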