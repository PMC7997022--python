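"""Readers and writers for the formats the pipeline touches.

Variant tables come in two dialects: a fixed-header TSV and VCF 4.2 with
per-tool scores carried in INFO keys (SIFT, PP2, MT, GERP, CADD, CONDEL).
Pedigrees use the standard 6-column PED layout with an optional seventh
column flagging whole-exome-sequenced members.  Trajectories come as
multi-model PDB (Angstrom, converted to nm at the boundary) or as a plain
XYZ text dialect (nm):

    line 1: particle count
    line 2: comment ``t=<ns>``
    then one line per particle: ``name resindex mass radius x y z``
    frames concatenated.

Score values in the VCF dialect are encoded as INFO strings rather than
Float fields so that a write -> read round trip preserves full double
precision.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np

from .domain import (
    AnnotatedVariant,
    Affection,
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
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for typing only
    from .consensus import RankedCandidate

__all__ = [
    "read_variant_table",
    "write_variant_table",
    "read_pedigree",
    "write_pedigree",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_trajectory",
    "write_trajectory",
    "write_candidate_report",
    "read_candidate_report",
    "DEFAULT_RADII",
    "DEFAULT_MASSES",
    "TSV_HEADER",
]

TSV_HEADER = [
    "gene",
    "cdna",
    "protein",
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
    "zygosity",
    "sift",
    "polyphen2",
    "mutationtaster",
    "gerp",
    "cadd",
    "condel",
    "ac",
    "an",
    "source",
]

# van der Waals radii (nm) by element, used for solvent accessibility.
DEFAULT_RADII = {"N": 0.155, "C": 0.170, "O": 0.152, "S": 0.180, "H": 0.120, "P": 0.180}
# Atomic masses (amu) by element.
DEFAULT_MASSES = {
    "N": 14.007,
    "C": 12.011,
    "O": 15.999,
    "S": 32.06,
    "H": 1.008,
    "P": 30.974,
}
_FALLBACK_RADIUS = 0.170
_FALLBACK_MASS = 12.011

_MISSING = "."


def _fmt(value) -> str:
    if value is None:
        return _MISSING
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_float(token: str, line_no: int, field: str) -> float | None:
    if token == _MISSING or token == "":
        return None
    try:
        return float(token)
    except ValueError as exc:
        raise ValueError(f"line {line_no}: bad {field} value {token!r}") from exc


def _variant_from_fields(fields: dict[str, str], line_no: int) -> AnnotatedVariant:
    try:
        consequence = Consequence(fields["consequence"])
        zygosity = Zygosity(fields["zygosity"])
    except ValueError as exc:
        raise ValueError(f"line {line_no}: {exc}") from exc
    try:
        pos = int(fields["pos"])
    except ValueError as exc:
        raise ValueError(f"line {line_no}: bad pos {fields['pos']!r}") from exc
    scores = ToolScores(
        sift=_parse_float(fields["sift"], line_no, "sift"),
        polyphen2=_parse_float(fields["polyphen2"], line_no, "polyphen2"),
        mutationtaster=_parse_float(fields["mutationtaster"], line_no, "mutationtaster"),
        gerp=_parse_float(fields["gerp"], line_no, "gerp"),
        cadd_phred=_parse_float(fields["cadd"], line_no, "cadd"),
        condel=_parse_float(fields["condel"], line_no, "condel"),
    )
    frequency = None
    if fields["ac"] not in (_MISSING, "") and fields["an"] not in (_MISSING, ""):
        try:
            frequency = FrequencyRecord(
                allele_count=int(fields["ac"]),
                allele_number=int(fields["an"]),
                source=fields.get("source", "") if fields.get("source") != _MISSING else "",
            )
        except ValueError as exc:
            raise ValueError(f"line {line_no}: {exc}") from exc
    try:
        return AnnotatedVariant(
            gene_symbol=fields["gene"],
            cdna_change=fields["cdna"],
            protein_change=fields["protein"],
            chrom=fields["chrom"],
            pos=pos,
            ref=fields["ref"],
            alt=fields["alt"],
            consequence=consequence,
            zygosity=zygosity,
            tool_scores=scores,
            frequency=frequency,
        )
    except ValueError as exc:
        raise ValueError(f"line {line_no}: {exc}") from exc


def _read_variant_tsv(path: Path) -> list[AnnotatedVariant]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected header") from None
        if header != TSV_HEADER:
            raise ValueError(
                f"{path}: unexpected header {header!r}; expected {TSV_HEADER!r}"
            )
        variants = []
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(TSV_HEADER):
                raise ValueError(
                    f"line {line_no}: expected {len(TSV_HEADER)} fields, got {len(row)}"
                )
            variants.append(_variant_from_fields(dict(zip(TSV_HEADER, row)), line_no))
    return variants


_VCF_INFO_KEYS = {
    "sift": "SIFT",
    "polyphen2": "PP2",
    "mutationtaster": "MT",
    "gerp": "GERP",
    "cadd": "CADD",
    "condel": "CONDEL",
}

_VCF_HEADER_LINES = (
    ["##fileformat=VCFv4.2"]
    + [
        f'##INFO=<ID={k},Number=1,Type=String,Description="{d}">'
        for k, d in [
            ("GENE", "Gene symbol"),
            ("CDNA", "cDNA change"),
            ("PROT", "Protein change"),
            ("CSQ", "Consequence class"),
            ("ZYG", "Zygosity in the index cases"),
            ("SIFT", "SIFT score"),
            ("PP2", "PolyPhen-2 score"),
            ("MT", "MutationTaster score"),
            ("GERP", "GERP++ constraint score"),
            ("CADD", "CADD phred score"),
            ("CONDEL", "Condel score"),
            ("AC", "Reference-population allele count"),
            ("AN", "Reference-population allele number"),
            ("FSRC", "Frequency source database"),
        ]
    ]
    + ["#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
)


def _read_variant_vcf(path: Path) -> list[AnnotatedVariant]:
    from cyvcf2 import VCF

    variants = []
    vcf = VCF(str(path))
    try:
        for line_no, rec in enumerate(vcf, start=1):
            info = rec.INFO

            def get(key: str) -> str:
                value = info.get(key)
                return _MISSING if value is None else str(value)

            fields = {
                "gene": get("GENE"),
                "cdna": get("CDNA"),
                "protein": get("PROT"),
                "chrom": rec.CHROM,
                "pos": str(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else "",
                "consequence": get("CSQ"),
                "zygosity": get("ZYG"),
                "sift": get("SIFT"),
                "polyphen2": get("PP2"),
                "mutationtaster": get("MT"),
                "gerp": get("GERP"),
                "cadd": get("CADD"),
                "condel": get("CONDEL"),
                "ac": get("AC"),
                "an": get("AN"),
                "source": get("FSRC"),
            }
            variants.append(_variant_from_fields(fields, line_no))
    finally:
        vcf.close()
    return variants


def read_variant_table(path, dialect: str = "tsv") -> list[AnnotatedVariant]:
    """Read an annotated variant table.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``"tsv"`` (fixed header, ``.`` for missing values) or ``"vcf"``
        (scores in INFO keys SIFT/PP2/MT/GERP/CADD/CONDEL; absent key means
        absent score).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf":
        return _read_variant_vcf(path)
    raise ValueError(f"unknown variant table dialect {dialect!r}")


def write_variant_table(
    variants: Sequence[AnnotatedVariant], path, dialect: str = "tsv"
) -> None:
    """Write variants in the dialect understood by :func:`read_variant_table`."""
    path = Path(path)
    if dialect == "tsv":
        lines = ["\t".join(TSV_HEADER)]
        for v in variants:
            s = v.tool_scores
            freq = v.frequency
            lines.append(
                "\t".join(
                    [
                        v.gene_symbol,
                        v.cdna_change,
                        v.protein_change,
                        v.chrom,
                        str(v.pos),
                        v.ref,
                        v.alt,
                        v.consequence.value,
                        v.zygosity.value,
                        _fmt(s.sift),
                        _fmt(s.polyphen2),
                        _fmt(s.mutationtaster),
                        _fmt(s.gerp),
                        _fmt(s.cadd_phred),
                        _fmt(s.condel),
                        _fmt(freq.allele_count if freq else None),
                        _fmt(freq.allele_number if freq else None),
                        (freq.source or _MISSING) if freq else _MISSING,
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "vcf":
        lines = list(_VCF_HEADER_LINES)
        for v in variants:
            s = v.tool_scores
            info = [
                f"GENE={v.gene_symbol}",
                f"CDNA={v.cdna_change}",
                f"PROT={v.protein_change}",
                f"CSQ={v.consequence.value}",
                f"ZYG={v.zygosity.value}",
            ]
            for attr, key in [
                ("sift", "SIFT"),
                ("polyphen2", "PP2"),
                ("mutationtaster", "MT"),
                ("gerp", "GERP"),
                ("cadd_phred", "CADD"),
                ("condel", "CONDEL"),
            ]:
                value = getattr(s, attr)
                if value is not None:
                    info.append(f"{key}={value!r}")
            if v.frequency is not None:
                info.append(f"AC={v.frequency.allele_count}")
                info.append(f"AN={v.frequency.allele_number}")
                if v.frequency.source:
                    info.append(f"FSRC={v.frequency.source}")
            lines.append(
                "\t".join(
                    [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", ".", ";".join(info)]
                )
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown variant table dialect {dialect!r}")


_PED_AFFECTION = {"1": Affection.UNAFFECTED, "2": Affection.AFFECTED}
_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}


def read_pedigree(path) -> Pedigree:
    """Read a 6-column PED file (optional 7th column: sequenced flag).

    Affection codes: 1 = unaffected, 2 = affected, 0 / -9 = unknown.
    """
    path = Path(path)
    members: list[Individual] = []
    seen: set[str] = set()
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"line {line_no}: PED row needs >= 6 columns")
        _, iid, _, _, sex, affection = fields[:6]
        if iid in seen:
            raise ValueError(f"line {line_no}: duplicate individual id {iid!r}")
        seen.add(iid)
        sequenced = len(fields) >= 7 and fields[6] == "1"
        members.append(
            Individual(
                id=iid,
                sex=_PED_SEX.get(sex, Sex.UNKNOWN),
                affection=_PED_AFFECTION.get(affection, Affection.UNKNOWN),
                sequenced=sequenced,
            )
        )
    return Pedigree(members)


def write_pedigree(pedigree: Pedigree, path, family_id: str = "FAM1") -> None:
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_code = {Affection.UNAFFECTED: "1", Affection.AFFECTED: "2", Affection.UNKNOWN: "0"}
    lines = [
        "\t".join(
            [
                family_id,
                m.id,
                "0",
                "0",
                sex_code[m.sex],
                aff_code[m.affection],
                "1" if m.sequenced else "0",
            ]
        )
        for m in pedigree.members
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotype_matrix(path) -> GenotypeMatrix:
    """Read a TSV carrier matrix: first column individual id, then one
    column per variant id with values present/absent/untyped."""
    with open(Path(path), newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        variant_ids = header[1:]
        rows = [row for row in reader if row]
    matrix = GenotypeMatrix([r[0] for r in rows], variant_ids)
    for row in rows:
        for vid, token in zip(variant_ids, row[1:]):
            matrix.set(row[0], vid, Carrier(token))
    return matrix


def write_genotype_matrix(matrix: GenotypeMatrix, path) -> None:
    lines = ["\t".join(["individual"] + matrix.variant_ids)]
    for ind in matrix.individual_ids:
        lines.append(
            "\t".join([ind] + [matrix.get(ind, v).value for v in matrix.variant_ids])
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --- trajectories -----------------------------------------------------------

_NM_PER_ANGSTROM = 0.1


def _element_of(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _read_trajectory_pdb(path: Path, frame_time: float) -> tuple[Structure, Trajectory]:
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:
        raise ValueError(f"{path}: inconsistent models ({exc})") from exc
    if stack.array_length() == 0:
        raise ValueError(f"{path}: no atoms")
    names = list(stack.atom_name)
    residue_indices = np.asarray(stack.res_id, dtype=int)
    elements = [
        el if el else _element_of(nm) for el, nm in zip(stack.element, names)
    ]
    masses = np.array([DEFAULT_MASSES.get(el, _FALLBACK_MASS) for el in elements])
    radii = np.array([DEFAULT_RADII.get(el, _FALLBACK_RADIUS) for el in elements])
    coords_nm = stack.coord * _NM_PER_ANGSTROM  # PDB is Angstrom
    structure = Structure(names, residue_indices, masses, radii, coords_nm[0])
    return structure, Trajectory(coords_nm, frame_time=frame_time)


def _write_trajectory_pdb(structure: Structure, traj: Trajectory, path: Path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = structure.n_particles
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord = traj.coords / _NM_PER_ANGSTROM
    stack.atom_name = np.array(structure.names, dtype="U6")
    stack.res_id = structure.residue_indices
    stack.res_name = np.array(["GLY"] * n, dtype="U5")
    stack.chain_id = np.array(["A"] * n, dtype="U4")
    stack.element = np.array([_element_of(nm) for nm in structure.names], dtype="U2")
    stack.hetero = np.zeros(n, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def _read_trajectory_xyz(path: Path) -> tuple[Structure, Trajectory]:
    lines = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    times: list[float] = []
    topo: list[tuple[str, int, float, float]] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"line {i + 1}: expected particle count") from exc
        comment = lines[i + 1].strip()
        if not comment.startswith("t="):
            raise ValueError(f"line {i + 2}: expected comment 't=<ns>'")
        times.append(float(comment[2:]))
        frame_topo: list[tuple[str, int, float, float]] = []
        xyz = np.empty((count, 3))
        for j in range(count):
            fields = lines[i + 2 + j].split()
            if len(fields) != 7:
                raise ValueError(f"line {i + 3 + j}: expected 7 fields")
            name, resindex, mass, radius = (
                fields[0],
                int(fields[1]),
                float(fields[2]),
                float(fields[3]),
            )
            frame_topo.append((name, resindex, mass, radius))
            xyz[j] = [float(fields[4]), float(fields[5]), float(fields[6])]
        if topo is None:
            topo = frame_topo
        elif frame_topo != topo:
            raise ValueError(f"frame {len(frames) + 1}: topology differs from frame 1")
        frames.append(xyz)
        i += 2 + count
    if topo is None:
        raise ValueError(f"{path}: no frames")
    frame_time = times[1] - times[0] if len(times) > 1 else (times[0] or 1.0)
    structure = Structure(
        [t[0] for t in topo],
        [t[1] for t in topo],
        [t[2] for t in topo],
        [t[3] for t in topo],
        frames[0],
    )
    return structure, Trajectory(np.array(frames), frame_time=frame_time)


def _write_trajectory_xyz(structure: Structure, traj: Trajectory, path: Path) -> None:
    out: list[str] = []
    for f in range(traj.n_frames):
        out.append(str(structure.n_particles))
        out.append(f"t={f * traj.frame_time!r}")
        for name, res, mass, radius, xyz in zip(
            structure.names,
            structure.residue_indices,
            structure.masses,
            structure.radii,
            traj.coords[f],
        ):
            out.append(
                f"{name} {int(res)} {float(mass)!r} {float(radius)!r} "
                f"{float(xyz[0])!r} {float(xyz[1])!r} {float(xyz[2])!r}"
            )
    Path(path).write_text("\n".join(out) + "\n")


def read_trajectory(
    path, dialect: str = "pdb_multimodel", frame_time: float = 1.0
) -> tuple[Structure, Trajectory]:
    """Read a trajectory.

    ``pdb_multimodel`` expects MODEL/ENDMDL records in Angstrom, converted
    to nm; ``frame_time`` (ns) is taken from the caller because PDB carries
    no time axis.  ``xyz_text`` is the documented nm dialect and carries its
    own times.  All models must share one atom count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "pdb_multimodel":
        return _read_trajectory_pdb(path, frame_time)
    if dialect == "xyz_text":
        return _read_trajectory_xyz(path)
    raise ValueError(f"unknown trajectory dialect {dialect!r}")


def write_trajectory(
    structure: Structure, traj: Trajectory, path, dialect: str = "pdb_multimodel"
) -> None:
    if traj.n_particles != structure.n_particles:
        raise ValueError("trajectory and structure particle counts differ")
    path = Path(path)
    if dialect == "pdb_multimodel":
        _write_trajectory_pdb(structure, traj, path)
    elif dialect == "xyz_text":
        _write_trajectory_xyz(structure, traj, path)
    else:
        raise ValueError(f"unknown trajectory dialect {dialect!r}")


# --- candidate report -------------------------------------------------------

REPORT_HEADER = [
    "rank",
    "gene",
    "protein_change",
    "segregation",
    "affected_carriers",
    "affected_noncarriers",
    "unaffected_carriers",
    "sift_call",
    "polyphen2_call",
    "mutationtaster_call",
    "cadd_call",
    "condel_call",
    "deleterious_votes",
    "conserved",
    "maf",
]


def write_candidate_report(ranked: "Sequence[RankedCandidate]", path) -> None:
    """Write the ranked candidate table as TSV (header always written)."""
    lines = ["\t".join(REPORT_HEADER)]
    for rc in ranked:
        p, verdict = rc.profile, rc.verdict
        lines.append(
            "\t".join(
                [
                    str(rc.rank),
                    p.gene_symbol,
                    p.protein_change,
                    "pass" if verdict.passes else "fail",
                    str(verdict.affected_carriers),
                    str(verdict.affected_noncarriers),
                    str(verdict.unaffected_carriers),
                    p.calls["sift"].value,
                    p.calls["polyphen2"].value,
                    p.calls["mutationtaster"].value,
                    p.calls["cadd"].value,
                    p.calls["condel"].value,
                    str(p.deleterious_votes),
                    "yes" if p.conserved else "no",
                    _fmt(rc.maf),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_candidate_report(path):
    """Read a candidate report back as a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(Path(path), sep="\t", na_values=[_MISSING])
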