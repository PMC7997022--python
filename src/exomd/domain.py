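"""Core domain types shared by the variant-prioritization and trajectory stages.

The variant stage works on annotated exome variants, a family pedigree and a
carrier matrix (who carries which variant).  The trajectory stage works on a
molecular topology (``Structure``) and an ordered stack of coordinate frames
(``Trajectory``).  All trajectory coordinates are stored in nanometres; file
readers convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Consequence",
    "Zygosity",
    "Affection",
    "Sex",
    "Carrier",
    "ToolScores",
    "FrequencyRecord",
    "AnnotatedVariant",
    "Individual",
    "Pedigree",
    "GenotypeMatrix",
    "Structure",
    "Trajectory",
    "GERP_MIN",
    "GERP_MAX",
]

# Published range of the GERP++ evolutionary-constraint score.
GERP_MIN = -12.3
GERP_MAX = 6.17


class Consequence(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    OTHER = "other"


class Zygosity(str, Enum):
    HET = "het"
    HOM = "hom"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Carrier(str, Enum):
    """Carrier status of one individual for one variant."""

    PRESENT = "present"
    ABSENT = "absent"
    UNTYPED = "untyped"


def _check_unit(name: str, value: float | None) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} score {value} outside [0, 1]")


@dataclass(frozen=True)
class ToolScores:
    """Raw per-tool deleteriousness scores; any score may be absent (None).

    sift, polyphen2, mutationtaster and condel live in [0, 1];
    cadd_phred is a non-negative phred-scaled rank; gerp is the GERP++
    constraint score, restricted to its published range.
    """

    sift: float | None = None
    polyphen2: float | None = None
    mutationtaster: float | None = None
    gerp: float | None = None
    cadd_phred: float | None = None
    condel: float | None = None

    def __post_init__(self) -> None:
        _check_unit("sift", self.sift)
        _check_unit("polyphen2", self.polyphen2)
        _check_unit("mutationtaster", self.mutationtaster)
        _check_unit("condel", self.condel)
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"cadd_phred {self.cadd_phred} is negative")
        if self.gerp is not None and not (GERP_MIN <= self.gerp <= GERP_MAX):
            raise ValueError(
                f"gerp {self.gerp} outside published range [{GERP_MIN}, {GERP_MAX}]"
            )

    @property
    def any_present(self) -> bool:
        return any(
            s is not None
            for s in (
                self.sift,
                self.polyphen2,
                self.mutationtaster,
                self.gerp,
                self.cadd_phred,
                self.condel,
            )
        )


@dataclass(frozen=True)
class FrequencyRecord:
    """Allele count / allele number in a reference population."""

    allele_count: int
    allele_number: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.allele_number <= 0:
            raise ValueError("allele_number must be positive")
        if not (0 <= self.allele_count <= self.allele_number):
            raise ValueError("allele_count must be in [0, allele_number]")


@dataclass(frozen=True)
class AnnotatedVariant:
    """A single annotated exonic variant.

    ``frequency`` is None for variants never observed in reference
    populations ("novel").
    """

    gene_symbol: str
    cdna_change: str
    protein_change: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    zygosity: Zygosity
    tool_scores: ToolScores = field(default_factory=ToolScores)
    frequency: FrequencyRecord | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def variant_id(self) -> str:
        return f"{self.gene_symbol}:{self.protein_change}"


@dataclass(frozen=True)
class Individual:
    id: str
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    sequenced: bool = False


@dataclass(frozen=True)
class Pedigree:
    members: tuple[Individual, ...]

    def __init__(self, members: Sequence[Individual]):
        object.__setattr__(self, "members", tuple(members))
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dupes}")

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, individual_id: str) -> Individual:
        for m in self.members:
            if m.id == individual_id:
                return m
        raise KeyError(individual_id)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    def with_affection(self, affection: Affection) -> list[Individual]:
        return [m for m in self.members if m.affection == affection]

    @property
    def affected_ids(self) -> list[str]:
        return [m.id for m in self.with_affection(Affection.AFFECTED)]

    @property
    def unaffected_ids(self) -> list[str]:
        return [m.id for m in self.with_affection(Affection.UNAFFECTED)]


class GenotypeMatrix:
    """Carrier status per (individual id x variant id).

    Any pair not explicitly set is ``Carrier.UNTYPED``.  Insertion order of
    variants and individuals is preserved for deterministic reporting.
    """

    def __init__(
        self,
        individual_ids: Sequence[str],
        variant_ids: Sequence[str],
        calls: Mapping[tuple[str, str], Carrier] | None = None,
    ):
        self.individual_ids = list(individual_ids)
        self.variant_ids = list(variant_ids)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids")
        self._calls: dict[tuple[str, str], Carrier] = {}
        for (ind, var), status in (calls or {}).items():
            self.set(ind, var, status)

    def set(self, individual_id: str, variant_id: str, status: Carrier) -> None:
        if individual_id not in self.individual_ids:
            raise KeyError(f"unknown individual id {individual_id!r}")
        if variant_id not in self.variant_ids:
            raise KeyError(f"unknown variant id {variant_id!r}")
        self._calls[(individual_id, variant_id)] = Carrier(status)

    def get(self, individual_id: str, variant_id: str) -> Carrier:
        return self._calls.get((individual_id, variant_id), Carrier.UNTYPED)

    def carriers(self, variant_id: str) -> list[str]:
        return [
            i for i in self.individual_ids if self.get(i, variant_id) is Carrier.PRESENT
        ]

    def validate_against(self, pedigree: Pedigree) -> None:
        """Every individual in the matrix must exist in the pedigree."""
        known = set(pedigree.ids)
        missing = [i for i in self.individual_ids if i not in known]
        if missing:
            raise ValueError(f"individuals not in pedigree: {missing}")


class Structure:
    """Topology plus one set of reference coordinates (nm).

    Stored column-wise for numerics: names, 1-based residue indices,
    masses (amu), radii (nm, for solvent-accessibility) and an (N, 3)
    coordinate array.
    """

    def __init__(
        self,
        names: Sequence[str],
        residue_indices: Sequence[int],
        masses: Sequence[float],
        radii: Sequence[float],
        coords: np.ndarray,
    ):
        self.names = list(names)
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.masses = np.asarray(masses, dtype=float)
        self.radii = np.asarray(radii, dtype=float)
        self.coords = np.asarray(coords, dtype=float)
        n = len(self.names)
        if n < 1:
            raise ValueError("Structure needs at least one particle")
        if not (
            len(self.residue_indices) == len(self.masses) == len(self.radii) == n
        ) or self.coords.shape != (n, 3):
            raise ValueError("inconsistent particle array lengths")
        if np.any(np.diff(self.residue_indices) < 0):
            raise ValueError("residue indices must be non-decreasing")

    @property
    def n_particles(self) -> int:
        return len(self.names)

    @property
    def residue_ids(self) -> np.ndarray:
        """Sorted unique residue indices."""
        return np.unique(self.residue_indices)


class Trajectory:
    """Ordered coordinate frames congruent with one Structure topology.

    ``coords`` has shape (n_frames, n_particles, 3) in nm; ``frame_time``
    is the time between successive frames in ns.
    """

    def __init__(self, coords: np.ndarray, frame_time: float = 1.0):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("trajectory coords must have shape (frames, atoms, 3)")
        if coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if frame_time <= 0:
            raise ValueError("frame_time must be positive")
        self.coords = coords
        self.frame_time = float(frame_time)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ns (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_time
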