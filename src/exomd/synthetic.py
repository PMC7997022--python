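"""Synthetic data generators and packaged worked-example fixtures.

``generate_family_dataset`` emulates the data-generating structure of a
dominant-disease family study: one planted heterozygous causal variant
carried by every affected member except declared phenocopies, absent from
unaffected members and from frequency databases, with deleterious-leaning
tool scores; plus background polymorphisms carried at random according to
their population frequency with benign-leaning scores.

``generate_trajectory`` produces coordinate trajectories with controlled
statistical structure: static, harmonic (independent Gaussian
fluctuations with planted per-residue amplitudes), hinge (a sub-domain
oscillating rigidly about an axis, emulating a flexing inter-domain
hinge) and two-state (switching between a compact and an extended
conformation with geometric dwell times, emulating flexed/extended
domain transitions).

``za253_fixtures`` returns, verbatim, the printed worked example shipped
with the package: a nine-member genotyped pedigree, its 5-variant carrier
matrix and the per-tool score table.  Genomic coordinates other than the
CFAP65 variant's (which is the published gnomAD site) are synthetic
placeholders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .domain import (
    Affection,
    AnnotatedVariant,
    Carrier,
    Consequence,
    FrequencyRecord,
    GenotypeMatrix,
    Individual,
    Pedigree,
    Sex,
    Structure,
    ToolScores,
    Trajectory,
    Zygosity,
    GERP_MAX,
    GERP_MIN,
)
from .io import read_genotype_matrix, read_pedigree, read_variant_table

__all__ = [
    "FamilySimConfig",
    "TrajSimConfig",
    "generate_family_dataset",
    "generate_trajectory",
    "za253_fixtures",
    "CAUSAL_SCORE_DISTRIBUTIONS",
    "BACKGROUND_SCORE_DISTRIBUTIONS",
]


# Per-tool score distributions: (kind, *params).  Causal variants draw
# deleterious-leaning scores, background variants benign-leaning ones;
# draws are clipped to each tool's documented domain.
CAUSAL_SCORE_DISTRIBUTIONS = {
    "sift": ("beta", 1.0, 20.0),
    "polyphen2": ("beta", 20.0, 1.5),
    "mutationtaster": ("beta", 20.0, 1.5),
    "gerp": ("normal", 5.0, 0.5),
    "cadd": ("normal", 28.0, 3.0),
    "condel": ("beta", 12.0, 2.0),
}
BACKGROUND_SCORE_DISTRIBUTIONS = {
    "sift": ("beta", 5.0, 2.0),
    "polyphen2": ("beta", 1.0, 8.0),
    "mutationtaster": ("beta", 1.5, 8.0),
    "gerp": ("normal", 0.0, 1.5),
    "cadd": ("normal", 3.0, 2.0),
    "condel": ("beta", 1.0, 8.0),
}


@dataclass(frozen=True)
class FamilySimConfig:
    """Family simulation mirroring a five-affected / four-unaffected
    pedigree with three exome-sequenced index cases and one phenocopy.

    Affected individuals are named A1..An, unaffected U1..Um; the first
    ``n_sequenced`` non-phenocopy affecteds carry the sequenced flag (the
    index cases whose exomes are intersected).
    """

    n_affected: int = 5
    n_unaffected: int = 4
    n_sequenced: int = 3
    n_background_variants: int = 20
    phenocopy_ids: tuple[str, ...] = ("A5",)
    causal_distributions: dict = field(
        default_factory=lambda: dict(CAUSAL_SCORE_DISTRIBUTIONS)
    )
    background_distributions: dict = field(
        default_factory=lambda: dict(BACKGROUND_SCORE_DISTRIBUTIONS)
    )
    # MAF of background polymorphisms: mixture of rare and common sites.
    maf_distribution: tuple = ("beta", 0.5, 3.0)
    background_synonymous_fraction: float = 0.3
    background_hom_fraction: float = 0.1
    allele_number: int = 281690
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_affected, self.n_unaffected, self.n_background_variants) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_sequenced < 1:
            raise ValueError("need at least one sequenced index case")


def _draw(rng: np.random.Generator, spec: tuple) -> float:
    kind = spec[0]
    if kind == "beta":
        return float(rng.beta(spec[1], spec[2]))
    if kind == "normal":
        return float(rng.normal(spec[1], spec[2]))
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    raise ValueError(f"unknown distribution kind {kind!r}")


def _draw_scores(rng: np.random.Generator, dists: dict) -> ToolScores:
    def unit(tool: str) -> float:
        return min(1.0, max(0.0, _draw(rng, dists[tool])))

    return ToolScores(
        sift=unit("sift"),
        polyphen2=unit("polyphen2"),
        mutationtaster=unit("mutationtaster"),
        gerp=min(GERP_MAX, max(GERP_MIN, _draw(rng, dists["gerp"]))),
        cadd_phred=max(0.0, _draw(rng, dists["cadd"])),
        condel=unit("condel"),
    )


_BASES = ("A", "C", "G", "T")


def generate_family_dataset(
    cfg: FamilySimConfig,
) -> tuple[Pedigree, GenotypeMatrix, list[AnnotatedVariant]]:
    """Simulate a pedigree, its carrier matrix and an annotated variant
    table containing exactly one planted causal variant.

    The planted variant is heterozygous, missense, has no frequency record
    ("novel"), is carried by every affected member except the declared
    phenocopies and by no unaffected member.  Background variants are
    carried independently with probability 1 - (1 - MAF)^2 per individual.
    Bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(cfg.seed)
    affected = [f"A{i + 1}" for i in range(cfg.n_affected)]
    unaffected = [f"U{i + 1}" for i in range(cfg.n_unaffected)]
    bad = [p for p in cfg.phenocopy_ids if p not in affected]
    if bad:
        raise ValueError(f"phenocopy ids not among affected individuals: {bad}")
    non_phenocopy = [a for a in affected if a not in cfg.phenocopy_ids]
    sequenced = set(non_phenocopy[: cfg.n_sequenced])
    members = [
        Individual(a, Sex.UNKNOWN, Affection.AFFECTED, sequenced=a in sequenced)
        for a in affected
    ] + [Individual(u, Sex.UNKNOWN, Affection.UNAFFECTED) for u in unaffected]
    pedigree = Pedigree(members)

    variants: list[AnnotatedVariant] = []
    ref, alt = "G", "A"
    causal = AnnotatedVariant(
        gene_symbol="CAUSAL1",
        cdna_change="c.G1000A",
        protein_change="p.G334D",
        chrom="1",
        pos=1_000_000,
        ref=ref,
        alt=alt,
        consequence=Consequence.MISSENSE,
        zygosity=Zygosity.HET,
        tool_scores=_draw_scores(rng, cfg.causal_distributions),
        frequency=None,
    )
    variants.append(causal)
    for b in range(cfg.n_background_variants):
        maf = min(0.5, max(0.0, _draw(rng, cfg.maf_distribution)))
        synonymous = rng.random() < cfg.background_synonymous_fraction
        hom = rng.random() < cfg.background_hom_fraction
        ref_b, alt_b = rng.choice(_BASES, size=2, replace=False)
        pos = int(rng.integers(1, 10_000_000))
        aa = int(rng.integers(1, 900))
        variants.append(
            AnnotatedVariant(
                gene_symbol=f"BG{b + 1:03d}",
                cdna_change=f"c.{ref_b}{aa * 3}{alt_b}",
                protein_change=f"p.X{aa}Y" if not synonymous else f"p.X{aa}X",
                chrom=str(1 + b % 22),
                pos=pos,
                ref=str(ref_b),
                alt=str(alt_b),
                consequence=(
                    Consequence.SYNONYMOUS if synonymous else Consequence.MISSENSE
                ),
                zygosity=Zygosity.HOM if hom else Zygosity.HET,
                tool_scores=_draw_scores(rng, cfg.background_distributions),
                frequency=FrequencyRecord(
                    allele_count=int(round(maf * cfg.allele_number)),
                    allele_number=cfg.allele_number,
                    source="synthetic_popdb",
                ),
            )
        )

    matrix = GenotypeMatrix(pedigree.ids, [v.variant_id for v in variants])
    for ind in pedigree.ids:
        carries_causal = ind in affected and ind not in cfg.phenocopy_ids
        matrix.set(ind, causal.variant_id, Carrier.PRESENT if carries_causal else Carrier.ABSENT)
    for v in variants[1:]:
        maf = (
            v.frequency.allele_count / v.frequency.allele_number
            if v.frequency is not None
            else 0.0
        )
        p_carrier = 1.0 - (1.0 - maf) ** 2
        for ind in pedigree.ids:
            status = Carrier.PRESENT if rng.random() < p_carrier else Carrier.ABSENT
            matrix.set(ind, v.variant_id, status)
    return pedigree, matrix, variants


@dataclass(frozen=True)
class TrajSimConfig:
    """Trajectory simulation settings.

    Defaults mirror a coarse (one bead per residue) 40-residue chain
    sampled every 0.1 ns for 100 ns.  ``amplitudes`` plants the target
    per-residue RMSF (nm) for harmonic mode; ``hinge_residues`` selects
    the sub-domain rotated by ``hinge_amplitude`` radians (sinusoid of
    period ``hinge_period`` frames); two-state mode switches between the
    reference and a hinge-opened conformation with geometric dwell times
    of mean ``dwell_frames``.
    """

    mode: str = "harmonic"
    n_particles: int = 40
    n_frames: int = 1000
    frame_time: float = 0.1  # ns
    amplitudes: tuple[float, ...] | None = None  # nm, per residue
    hinge_residues: tuple[int, ...] = ()  # 1-based residue indices
    hinge_amplitude: float = 1.0  # rad
    hinge_period: int = 200  # frames
    two_state_angle: float = 1.6  # rad separating the two conformations
    dwell_frames: float = 100.0
    noise: float = 0.02  # nm, isotropic per-axis jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"static", "harmonic", "hinge", "two_state"}:
            raise ValueError(f"unknown trajectory mode {self.mode!r}")
        if self.n_particles < 1 or self.n_frames < 1:
            raise ValueError("n_particles and n_frames must be >= 1")
        if self.dwell_frames <= 0:
            raise ValueError("dwell_frames must be positive")
        if self.amplitudes is not None and any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be >= 0")


def _reference_chain(cfg: TrajSimConfig, rng: np.random.Generator) -> Structure:
    """Helical reference chain, one CA bead per residue, light jitter."""
    n = cfg.n_particles
    i = np.arange(n)
    turn = np.deg2rad(100.0)
    coords = np.stack(
        [0.23 * np.cos(i * turn), 0.23 * np.sin(i * turn), 0.15 * i], axis=1
    )
    coords = coords - coords.mean(axis=0)
    coords = coords + rng.normal(scale=0.01, size=coords.shape)
    return Structure(
        names=["CA"] * n,
        residue_indices=i + 1,
        masses=[110.0] * n,  # average residue mass
        radii=[0.17] * n,
        coords=coords,
    )


def _rotate_subset(
    coords: np.ndarray, subset: np.ndarray, angle: float, pivot: np.ndarray
) -> np.ndarray:
    """Rotate the subset rigidly about the x-axis through ``pivot``."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    out = coords.copy()
    out[subset] = (coords[subset] - pivot) @ rot.T + pivot
    return out


def generate_trajectory(cfg: TrajSimConfig) -> tuple[Structure, Trajectory]:
    """Simulate a coordinate trajectory per ``cfg.mode``; seeded and
    bit-reproducible."""
    rng = np.random.default_rng(cfg.seed)
    structure = _reference_chain(cfg, rng)
    ref = structure.coords
    n, f = cfg.n_particles, cfg.n_frames

    if cfg.mode == "static":
        frames = np.tile(ref, (f, 1, 1))
    elif cfg.mode == "harmonic":
        if cfg.amplitudes is not None:
            if len(cfg.amplitudes) != n:
                raise ValueError("amplitudes length must equal n_particles")
            amp = np.asarray(cfg.amplitudes, dtype=float)
        else:
            amp = rng.uniform(0.05, 0.3, size=n)
        # per-axis sd = amplitude / sqrt(3) so the 3D RMSF equals the amplitude
        sd = amp / np.sqrt(3.0)
        frames = ref[None] + rng.normal(size=(f, n, 3)) * sd[None, :, None]
    elif cfg.mode == "hinge":
        subset = _hinge_subset(structure, cfg)
        pivot = ref[subset[0]]
        t = np.arange(f)
        theta = cfg.hinge_amplitude * np.sin(2.0 * np.pi * t / cfg.hinge_period)
        frames = np.empty((f, n, 3))
        for k in range(f):
            frames[k] = _rotate_subset(ref, subset, theta[k], pivot)
        frames += rng.normal(scale=cfg.noise, size=frames.shape)
    else:  # two_state
        subset = _hinge_subset(structure, cfg, default_fraction=0.5)
        pivot = ref[subset[0]]
        open_conf = _rotate_subset(ref, subset, cfg.two_state_angle, pivot)
        states = np.empty(f, dtype=int)
        k, state = 0, 0
        while k < f:
            dwell = int(rng.geometric(1.0 / cfg.dwell_frames))
            states[k : k + dwell] = state
            k += dwell
            state = 1 - state
        frames = np.where(states[:, None, None] == 0, ref[None], open_conf[None])
        frames = frames + rng.normal(scale=cfg.noise, size=frames.shape)
    return structure, Trajectory(frames, frame_time=cfg.frame_time)


def _hinge_subset(
    structure: Structure, cfg: TrajSimConfig, default_fraction: float = 1 / 3
) -> np.ndarray:
    if cfg.hinge_residues:
        mask = np.isin(structure.residue_indices, cfg.hinge_residues)
        if not mask.any():
            raise ValueError("hinge_residues match no particles")
        return np.where(mask)[0]
    start = int(round(structure.n_particles * (1.0 - default_fraction)))
    return np.arange(start, structure.n_particles)


def za253_fixtures() -> tuple[Pedigree, GenotypeMatrix, list[AnnotatedVariant]]:
    """The packaged worked example: nine genotyped family members (five
    affected, four unaffected), the 5-variant carrier matrix and the
    per-tool score table, exactly as printed."""
    data = resources.files("exomd.data")
    with resources.as_file(data / "za253.ped") as p:
        pedigree = read_pedigree(p)
    with resources.as_file(data / "za253_genotypes.tsv") as p:
        matrix = read_genotype_matrix(p)
    with resources.as_file(data / "za253_variants.tsv") as p:
        variants = read_variant_table(p, dialect="tsv")
    return pedigree, matrix, variants
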