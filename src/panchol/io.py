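"""Readers and writers for the on-disk formats used throughout the package.

Protein FASTA files carry one record per protein; a companion tab-separated
annotation table maps ``protein_id`` to a one-letter COG functional class.
Proteomes are held in :class:`StrainProteome` containers; matrices and summary
tables are serialized as TSV (strain ids as row/column headers) and JSON.

All writers are deterministic: identical in-memory objects yield byte-identical
files. Logging goes to stderr, results to files only.
"""

from __future__ import annotations

import io as _stdio
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("panchol")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

# 20 canonical amino acids plus X (unknown).
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")


class FastaFormatError(ValueError):
    """Raised for structurally malformed FASTA input (reports the line number)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence with its strain of origin and optional COG class."""

    protein_id: str
    strain_id: str
    sequence: str
    cog_class: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r}: illegal residue(s) {sorted(bad)}"
            )
        if self.cog_class is not None and (
            len(self.cog_class) != 1 or not self.cog_class.isalpha()
        ):
            raise ValueError(
                f"protein {self.protein_id!r}: COG class must be one letter, "
                f"got {self.cog_class!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class StrainProteome:
    """All proteins of one strain, in input order, with an optional group label.

    ``group_label`` carries the comparison-group membership, e.g.
    ``"hypocholesterolemic"`` for cholesterol-assimilating strains versus
    ``"general"`` for ordinary probiotic strains.
    """

    strain_id: str
    proteins: list[ProteinRecord] = field(default_factory=list)
    group_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"strain {self.strain_id!r}: proteome must be non-empty")
        seen: set[str] = set()
        for p in self.proteins:
            if p.strain_id != self.strain_id:
                raise ValueError(
                    f"protein {p.protein_id!r} carries strain {p.strain_id!r}, "
                    f"expected {self.strain_id!r}"
                )
            if p.protein_id in seen:
                raise ValueError(
                    f"strain {self.strain_id!r}: duplicate protein id {p.protein_id!r}"
                )
            seen.add(p.protein_id)

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)

    def get(self, protein_id: str) -> ProteinRecord:
        for p in self.proteins:
            if p.protein_id == protein_id:
                return p
        raise KeyError(protein_id)


@dataclass
class RunConfig:
    """Thresholds and parameters for a full comparative run.

    Percent-valued thresholds live in [0, 100]; the ANI fragment length is in
    base pairs (>= 100); ``seed`` feeds every random draw of a run.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_rbh_identity_pct: float = 30.0
    min_rbh_coverage_pct: float = 50.0
    prefilter_k: int = 4
    prefilter_min_shared: int = 1
    ani_fragment_length: int = 1000
    ani_min_fragment_identity_pct: float = 70.0
    ani_min_fragment_coverage_pct: float = 70.0
    screen_min_identity_pct: float = 85.0
    screen_min_query_coverage_pct: float = 99.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_rbh_identity_pct",
            "min_rbh_coverage_pct",
            "ani_min_fragment_identity_pct",
            "ani_min_fragment_coverage_pct",
            "screen_min_identity_pct",
            "screen_min_query_coverage_pct",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if self.ani_fragment_length < 100:
            raise ValueError("ani_fragment_length must be >= 100 bp")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dict(sorted(self.__dict__.items())), fh, sort_keys=True)


def _iter_fasta(path: str | Path):
    """Yield (header, sequence, line_number) from a FASTA file.

    Raises :class:`FastaFormatError` with the offending line number for
    sequence data before the first header or empty records.
    """
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    if not chunks:
                        raise FastaFormatError(
                            f"{path}: record {header!r} at line {header_line} has no sequence"
                        )
                    yield header, "".join(chunks), header_line
                header = line[1:].split()[0]
                if not header:
                    raise FastaFormatError(f"{path}: empty FASTA header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                chunks.append(line.upper())
    if header is not None:
        if not chunks:
            raise FastaFormatError(
                f"{path}: record {header!r} at line {header_line} has no sequence"
            )
        yield header, "".join(chunks), header_line


def read_annotation_tsv(path: str | Path) -> dict[str, str]:
    """Read a ``protein_id<TAB>cog_class`` table (header row required).

    Empty class cells mean "unannotated". If a cell lists several class letters
    the first one wins (logged), matching the single-class-per-protein model.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein_id", "cog_class"}
    if not required <= set(df.columns):
        raise ValueError(
            f"{path}: annotation TSV must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    out: dict[str, str] = {}
    for pid, cls in zip(df["protein_id"], df["cog_class"]):
        cls = cls.strip()
        if not cls:
            continue
        if len(cls) > 1:
            logger.warning(
                "annotation %s: protein %s lists classes %r; keeping first", path, pid, cls
            )
            cls = cls[0]
        out[pid] = cls
    return out


def read_proteome(
    fasta_path: str | Path,
    annotation_tsv_path: Optional[str | Path],
    strain_id: str,
    group_label: Optional[str] = None,
) -> StrainProteome:
    """Load one strain's protein FASTA plus optional COG annotation table.

    FASTA order is preserved. A trailing stop codon ``*`` is stripped; an
    internal ``*`` is an error. Annotation ids absent from the FASTA produce a
    warning, not an error; FASTA records without an annotation row get
    ``cog_class=None``.
    """
    cog_map = read_annotation_tsv(annotation_tsv_path) if annotation_tsv_path else {}
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for header, seq, lineno in _iter_fasta(fasta_path):
        if header in seen:
            raise ValueError(
                f"{fasta_path}: duplicate protein id {header!r} (line {lineno})"
            )
        seen.add(header)
        if seq.endswith("*"):
            seq = seq[:-1]
        if "*" in seq:
            raise ValueError(
                f"{fasta_path}: protein {header!r} has an internal stop codon"
            )
        records.append(
            ProteinRecord(
                protein_id=header,
                strain_id=strain_id,
                sequence=seq,
                cog_class=cog_map.get(header),
            )
        )
    missing = set(cog_map) - seen
    if missing:
        logger.warning(
            "%s: %d annotated id(s) not present in FASTA (e.g. %s)",
            fasta_path,
            len(missing),
            sorted(missing)[0],
        )
    return StrainProteome(strain_id=strain_id, proteins=records, group_label=group_label)


def write_proteome_fasta(proteome: StrainProteome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteome:
            fh.write(f">{p.protein_id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def write_annotation_tsv(proteome: StrainProteome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tcog_class\n")
        for p in proteome:
            fh.write(f"{p.protein_id}\t{p.cog_class or ''}\n")


def read_genome_fasta(path: str | Path, strain_id: str):
    """Read a nucleotide FASTA into a :class:`panchol.ani.GenomeSequence`."""
    from .ani import GenomeSequence

    contigs = []
    for header, seq, lineno in _iter_fasta(path):
        bad = set(seq) - NUCLEOTIDE_ALPHABET
        if bad:
            raise ValueError(
                f"{path}: contig {header!r} has non-ACGTN letters {sorted(bad)}"
            )
        contigs.append(seq)
    return GenomeSequence(strain_id=strain_id, contigs=contigs)


def write_genome_fasta(genome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for i, contig in enumerate(genome.contigs, start=1):
            fh.write(f">{genome.strain_id}_contig{i}\n")
            for j in range(0, len(contig), width):
                fh.write(contig[j : j + width] + "\n")


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    """Write a matrix with row/column headers as TSV (deterministic order)."""
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path: str | Path) -> None:
    """Canonical JSON writer: sorted keys, 2-space indent, trailing newline."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_summary(report, path: str | Path, format: str = "json") -> None:
    """Serialize a summary object (anything exposing ``to_dict``/``to_frame``).

    ``format`` is ``"json"`` (lossless round-trip via ``to_dict``/``from_dict``)
    or ``"tsv"`` (tabular view via ``to_frame``).
    """
    if format == "json":
        if not hasattr(report, "to_dict"):
            raise TypeError(f"{type(report).__name__} has no to_dict; cannot write JSON")
        write_json(report.to_dict(), path)
    elif format == "tsv":
        frame = report.to_frame() if hasattr(report, "to_frame") else report
        if not isinstance(frame, pd.DataFrame):
            raise TypeError(f"cannot render {type(report).__name__} as TSV")
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
    else:
        raise ValueError(f"unknown summary format {format!r}")
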