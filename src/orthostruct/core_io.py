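"""Shared sequence/gene-model data types and flat-file I/O.

All coordinates are 0-based half-open internally.  Serializers alone convert
to the 1-based inclusive convention of GFF3 and of human-facing reports.
Sequences are handled on the forward strand only; reverse-strand inputs must
be pre-oriented.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

GFF3_SOURCE = "orthostruct"


class OrthostructError(Exception):
    """Base class for all package errors."""


class FastaFormatError(OrthostructError):
    """Raised for malformed or empty FASTA input."""


class ValidationError(OrthostructError):
    """Raised when a record or model violates its invariants."""


class Group(str, Enum):
    """Taxonomic group label used throughout the pipeline."""

    MONOCOT = "monocot"
    DICOT = "dicot"
    OUTGROUP = "outgroup"
    UNKNOWN = "unknown"


@dataclass
class SequenceRecord:
    """A nucleotide or protein sequence with species and group metadata.

    Parameters
    ----------
    id : str
        Record identifier, unique within a collection.
    species : str
        Species tag (e.g. ``"Zm"``); empty when unknown.
    group : Group
        monocot / dicot / outgroup / unknown.
    alphabet : str
        ``"dna"`` or ``"protein"``.
    residues : str
        Upper-case sequence; DNA ⊆ {A,C,G,T,N}, protein ⊆ 20 aa + {X,*}.
    """

    id: str
    residues: str
    species: str = ""
    group: Group = Group.UNKNOWN
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if isinstance(self.group, str) and not isinstance(self.group, Group):
            self.group = Group(self.group)
        if self.alphabet not in ("dna", "protein"):
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        if not self.residues:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        self.residues = self.residues.upper()
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        for off, ch in enumerate(self.residues):
            if ch not in allowed:
                raise ValidationError(
                    f"record {self.id!r}: invalid {self.alphabet} residue "
                    f"{ch!r} at offset {off}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Intron:
    """A single intron with its phase and exonic splice context.

    ``flank_5prime`` is the last 3 exonic nt upstream of the donor site and
    ``flank_3prime`` the first exonic nt downstream of the acceptor; the
    protosplice class is derived from these flanks.
    """

    start: int
    end: int
    phase: int | None = None
    donor_dinuc: str = ""
    acceptor_dinuc: str = ""
    flank_5prime: str = ""
    flank_3prime: str = ""
    proto_class: str | None = None  # PROTOSPLICE / N_G / G_N / N_N / None
    canonical: bool = True
    coding: bool = True

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValidationError(
                f"intron [{self.start},{self.end}) has non-positive length"
            )
        if self.phase is not None and self.phase not in (0, 1, 2):
            raise ValidationError(f"intron phase {self.phase!r} not in {{0,1,2}}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Ordered exon coordinates on a genomic sequence plus derived introns.

    ``exons`` are 0-based half-open genomic intervals; ``cds_start`` and
    ``cds_end`` are coordinates on the spliced cDNA.  Introns are derived
    from the gaps between consecutive exons when not supplied.
    """

    seq_id: str
    exons: list[tuple[int, int]]
    cds_start: int = 0
    cds_end: int | None = None
    introns: list[Intron] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.seq_id}: model has no exons")
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        for s, e in self.exons:
            if e <= s:
                raise ValidationError(f"{self.seq_id}: empty exon [{s},{e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"{self.seq_id}: exons [{s1},{e1}) and [{s2},{e2}) "
                    "overlap or are unsorted"
                )
            if s2 == e1:
                raise ValidationError(
                    f"{self.seq_id}: zero-length intron between exons at {e1}"
                )
        if self.cds_end is None:
            self.cds_end = self.spliced_length
        if not self.introns:
            self.introns = [
                Intron(start=e1, end=s2)
                for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            ]
        if len(self.introns) != len(self.exons) - 1:
            raise ValidationError(
                f"{self.seq_id}: {len(self.introns)} introns for "
                f"{len(self.exons)} exons"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def intron_bp_total(self) -> int:
        return sum(i.length for i in self.introns)

    def junctions_cdna(self) -> list[int]:
        """cDNA coordinate of each intron (position of first nt of the
        following exon on the spliced transcript)."""
        out, acc = [], 0
        for s, e in self.exons[:-1]:
            acc += e - s
            out.append(acc)
        return out

    def validate_cds(self) -> None:
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValidationError(
                f"{self.seq_id}: CDS span {self.cds_end - self.cds_start} "
                "is not a multiple of 3"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _parse_metadata(description: str) -> tuple[str, Group]:
    """Extract ``species=...;group=...`` tokens from a FASTA description.

    Unparseable headers degrade to species '' / group unknown.
    """
    species, group = "", Group.UNKNOWN
    for chunk in description.replace(";", " ").split():
        if chunk.startswith("species="):
            species = chunk[len("species="):]
        elif chunk.startswith("group="):
            try:
                group = Group(chunk[len("group="):])
            except ValueError:
                group = Group.UNKNOWN
    return species, group


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    Species/group are parsed from a ``species=...;group=...`` token in the
    header when present.  An empty file raises :class:`FastaFormatError`;
    a residue outside the alphabet raises :class:`ValidationError` naming
    the record and offset.
    """
    path = Path(path)
    records = []
    for bio in SeqIO.parse(str(path), "fasta"):
        species, group = _parse_metadata(bio.description)
        records.append(
            SequenceRecord(
                id=bio.id,
                residues=str(bio.seq),
                species=species,
                group=group,
                alphabet=alphabet,
            )
        )
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> Path:
    """Write records as 60-column-wrapped FASTA, re-emitting metadata tokens."""
    if not records:
        raise ValidationError("write_fasta: empty record list")
    seen: set[str] = set()
    bio_records = []
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = ""
        if rec.species or rec.group is not Group.UNKNOWN:
            desc = f"species={rec.species};group={rec.group.value}"
        bio_records.append(
            _BioSeqRecord(Seq(rec.residues), id=rec.id, description=desc)
        )
    path = Path(path)
    with open(path, "w") as fh:
        SeqIO.write(bio_records, fh, "fasta")
    return path


# ---------------------------------------------------------------------------
# GFF3 (gene / mRNA / exon / intron); writer plus a reader used for the
# lossless round-trip contract of the report artifacts.
# ---------------------------------------------------------------------------

def _gff3_attrs(pairs: Iterable[tuple[str, str]]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs)


def write_gene_models_gff3(models: Sequence[GeneModel], path: str | Path) -> Path:
    """Serialize gene models to GFF3 (1-based inclusive coordinates).

    Intron features carry phase / protosplice class / canonical flags as
    attributes; CDS offsets on the spliced transcript are stored on the mRNA
    so that a parse-back reproduces the model exactly.
    """
    path = Path(path)
    lines = ["##gff-version 3"]
    for m in models:
        gene_id = f"{m.seq_id}.gene"
        mrna_id = f"{m.seq_id}.mrna"
        start1, end1 = m.exons[0][0] + 1, m.exons[-1][1]
        lines.append(
            "\t".join(
                [m.seq_id, GFF3_SOURCE, "gene", str(start1), str(end1), ".",
                 "+", ".", _gff3_attrs([("ID", gene_id)])]
            )
        )
        mrna_attrs = [("ID", mrna_id), ("Parent", gene_id),
                      ("cds_start", str(m.cds_start)),
                      ("cds_end", str(m.cds_end))]
        lines.append(
            "\t".join(
                [m.seq_id, GFF3_SOURCE, "mRNA", str(start1), str(end1), ".",
                 "+", ".", _gff3_attrs(mrna_attrs)]
            )
        )
        for i, (s, e) in enumerate(m.exons, start=1):
            lines.append(
                "\t".join(
                    [m.seq_id, GFF3_SOURCE, "exon", str(s + 1), str(e), ".",
                     "+", ".",
                     _gff3_attrs([("ID", f"{mrna_id}.exon{i}"),
                                  ("Parent", mrna_id)])]
                )
            )
        for i, intron in enumerate(m.introns, start=1):
            attrs = [("ID", f"{mrna_id}.intron{i}"), ("Parent", mrna_id)]
            if intron.phase is not None:
                attrs.append(("phase", str(intron.phase)))
            if intron.proto_class is not None:
                attrs.append(("proto_class", intron.proto_class))
            attrs.append(("canonical", str(intron.canonical).lower()))
            lines.append(
                "\t".join(
                    [m.seq_id, GFF3_SOURCE, "intron", str(intron.start + 1),
                     str(intron.end), ".", "+", ".", _gff3_attrs(attrs)]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
    return path


def read_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file written by :func:`write_gene_models_gff3`."""
    exons: dict[str, list[tuple[int, int]]] = {}
    intron_attrs: dict[str, list[tuple[int, int, dict]]] = {}
    cds: dict[str, tuple[int, int]] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        seqid, _src, ftype, start, end, _score, _strand, _frame, attrs = (
            line.split("\t")
        )
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
        s, e = int(start) - 1, int(end)  # back to 0-based half-open
        if ftype == "mRNA":
            order.append(seqid)
            cds[seqid] = (int(attr["cds_start"]), int(attr["cds_end"]))
        elif ftype == "exon":
            exons.setdefault(seqid, []).append((s, e))
        elif ftype == "intron":
            intron_attrs.setdefault(seqid, []).append((s, e, attr))
    models = []
    for seqid in order:
        introns = [
            Intron(
                start=s, end=e,
                phase=int(a["phase"]) if "phase" in a else None,
                proto_class=a.get("proto_class"),
                canonical=a.get("canonical", "true") == "true",
            )
            for s, e, a in sorted(intron_attrs.get(seqid, []))
        ]
        cs, ce = cds[seqid]
        models.append(
            GeneModel(
                seq_id=seqid, exons=sorted(exons[seqid]),
                cds_start=cs, cds_end=ce,
                introns=introns if introns else [],
            )
        )
    return models
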