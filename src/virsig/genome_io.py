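"""Genome input, segment handling and protein extraction.

Reference and query genomes enter the pipeline either as GenBank flat
files (with protein annotations) or as plain FASTA plus a taxonomy
sidecar table.  Proteins are taken from annotations when present;
otherwise they are predicted from a six-frame translation by splitting
at stop codons and reading from the first methionine of each fragment.
A conservative length filter (default 100 aa) removes the very short
hypothetical proteins that such prediction generates in abundance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

DEFAULT_MIN_PROTEIN_LEN = 100

TAXONOMY_RANKS = ("baltimore_group", "order", "family", "genus", "species")

# segment suffix used in FASTA headers of segmented genomes: ACC.seg1, ACC.seg2 ...
_SEGMENT_RE = re.compile(r"^(?P<acc>.+)\.seg\d+$")


@dataclass(frozen=True)
class Taxonomy:
    """Taxonomic labels of a genome; any rank may be empty."""

    baltimore_group: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def label(self, rank: str) -> str:
        if rank not in TAXONOMY_RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return getattr(self, rank)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its provenance (annotated or predicted)."""

    id: str
    source_accession: str
    sequence: str
    provenance: str = "annotated"  # "annotated" | "predicted"
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeRecord:
    """A virus genome: one or more nucleotide segments plus metadata."""

    accession: str
    segments: list[str]
    taxonomy: Taxonomy = field(default_factory=Taxonomy)
    topology: str = "linear"
    annotated_proteins: list[ProteinRecord] | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"genome {self.accession}: at least one segment required")
        self.segments = [s.upper() for s in self.segments]

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.segments)

    def sequence(self) -> str:
        """The single-sequence representation used by the annotators."""
        return concatenate_segments(self.segments)


def concatenate_segments(segments: Sequence[str]) -> str:
    """Concatenate genome segments from largest to smallest.

    Equal-length segments keep their input order (stable sort), so the
    result is deterministic for any input permutation up to that tie.
    """
    if not segments:
        raise ValueError("no segments")
    return "".join(sorted(segments, key=len, reverse=True))


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def canonical_orientation(seq: str) -> str:
    """The lexicographically smaller of a sequence and its reverse complement.

    Annotating the canonical orientation makes every downstream signature
    independent of the strand on which an (unsegmented) genome was
    submitted.
    """
    rc = reverse_complement(seq)
    return rc if rc < seq else seq


def six_frame_translate(seq: str, table: int = 1) -> dict[int, str]:
    """Translate ``seq`` in all six reading frames.

    Returns a mapping frame -> amino-acid string where frame is one of
    +1, +2, +3 (forward strand) or -1, -2, -3 (reverse complement).
    Stop codons appear as ``*``; ambiguous codons as ``X``; trailing
    partial codons are dropped.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    frames: dict[int, str] = {}
    fwd = Seq(seq.upper())
    rev = fwd.reverse_complement()
    for offset in range(3):
        for sign, strand in ((1, fwd), (-1, rev)):
            sub = strand[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames[sign * (offset + 1)] = str(sub.translate(table=table))
    return frames


def predict_proteins(
    seq: str,
    min_len: int = DEFAULT_MIN_PROTEIN_LEN,
    source_accession: str = "",
    table: int = 1,
) -> list[ProteinRecord]:
    """Predict hypothetical proteins from a six-frame translation.

    Each translated frame is split at every stop codon; within each
    fragment the protein runs from the first methionine to the fragment
    end.  Fragments without a methionine, and proteins shorter than
    ``min_len``, yield nothing.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    proteins: list[ProteinRecord] = []
    for frame, aa in sorted(six_frame_translate(seq, table=table).items(), key=_frame_order):
        for i, fragment in enumerate(aa.split("*")):
            m = fragment.find("M")
            if m < 0:
                continue
            candidate = fragment[m:]
            if len(candidate) < min_len:
                continue
            frame_tag = f"F{frame:+d}"
            proteins.append(
                ProteinRecord(
                    id=f"{source_accession}|{frame_tag}.{i}",
                    source_accession=source_accession,
                    sequence=candidate,
                    provenance="predicted",
                    description=f"hypothetical protein ({frame_tag} fragment {i})",
                )
            )
    return proteins


def _frame_order(item: tuple[int, str]) -> tuple[int, int]:
    frame = item[0]
    return (0 if frame > 0 else 1, abs(frame))


def extract_proteins(
    record: GenomeRecord, min_len: int = DEFAULT_MIN_PROTEIN_LEN, table: int = 1
) -> list[ProteinRecord]:
    """Proteins of a genome: annotated ones when present, predicted otherwise.

    The length filter applies in both cases.  When annotations exist the
    prediction path is never taken, so predicted ORFs are not mixed in.
    """
    if not any(record.segments):
        raise ValueError(f"genome {record.accession} has no sequence")
    if record.annotated_proteins is not None:
        return [p for p in record.annotated_proteins if len(p) >= min_len]
    return predict_proteins(
        record.sequence(), min_len=min_len, source_accession=record.accession, table=table
    )


# ---------------------------------------------------------------------------
# readers / writers


def read_taxonomy_table(path: str | Path) -> dict[str, Taxonomy]:
    """Read a TSV with columns accession, baltimore_group, order, family, genus, species."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "accession" not in df.columns:
        raise ValueError("taxonomy table must have an 'accession' column")
    out: dict[str, Taxonomy] = {}
    for row in df.itertuples(index=False):
        kwargs = {r: getattr(row, r, "") for r in TAXONOMY_RANKS if hasattr(row, r)}
        out[row.accession] = Taxonomy(**kwargs)
    return out


def read_fasta_genomes(
    path: str | Path, taxonomy: dict[str, Taxonomy] | None = None
) -> list[GenomeRecord]:
    """Read genomes from FASTA; ``ACC.segN`` headers are grouped into one record.

    Segments are stored in file order; the annotators concatenate them
    largest-to-smallest at scan time.
    """
    groups: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _SEGMENT_RE.match(rec.id)
        acc = m.group("acc") if m else rec.id
        groups.setdefault(acc, []).append(str(rec.seq))
    taxonomy = taxonomy or {}
    return [
        GenomeRecord(accession=acc, segments=segs, taxonomy=taxonomy.get(acc, Taxonomy()))
        for acc, segs in groups.items()
    ]


def read_genbank_genomes(path: str | Path) -> list[GenomeRecord]:
    """Read full GenBank records; CDS translations become annotated proteins.

    A CDS without a /translation qualifier is translated from its
    coordinates and still counts as annotated.
    """
    genomes: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        proteins: list[ProteinRecord] = []
        for i, feat in enumerate(f for f in rec.features if f.type == "CDS"):
            desc = feat.qualifiers.get("product", [""])[0]
            if "translation" in feat.qualifiers:
                aa = feat.qualifiers["translation"][0]
            else:
                aa = str(feat.extract(rec.seq).translate(to_stop=True))
            pid = feat.qualifiers.get("protein_id", [f"{rec.id}|cds{i}"])[0]
            proteins.append(
                ProteinRecord(
                    id=pid,
                    source_accession=rec.id,
                    sequence=aa,
                    provenance="annotated",
                    description=desc,
                )
            )
        taxonomy = Taxonomy(
            family=_genbank_family(rec),
            species=rec.annotations.get("organism", ""),
        )
        genomes.append(
            GenomeRecord(
                accession=rec.id,
                segments=[str(rec.seq)],
                taxonomy=taxonomy,
                topology=rec.annotations.get("topology", "linear"),
                annotated_proteins=proteins or None,
            )
        )
    return genomes


def _genbank_family(rec) -> str:
    for name in rec.annotations.get("taxonomy", []):
        if name.endswith("viridae"):
            return name
    return ""


def write_protein_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            desc = f" {p.description}" if p.description else ""
            fh.write(f">{p.id}{desc}\n{p.sequence}\n")


def with_taxonomy(record: GenomeRecord, taxonomy: Taxonomy) -> GenomeRecord:
    return replace(record, taxonomy=taxonomy)
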