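"""Paralog-aware marker reference database construction.

Marker amplicons (gyrB, its parE paralog, or 16S fragments) are extracted
from annotated genome records by degenerate-primer in-silico PCR. A gene is
retained only when both primer sites are found on it; everything else is
discarded, so the database contains exactly the sequences the primer pair
could amplify. Exact duplicates of (trimmed sequence, species, gene) are
collapsed to a single record.

Two input formats are supported: standard annotated flat files (GenBank,
parsed with Biopython) and a simple tab-separated gene table
(taxonomy, gene, sequence [, record_id]) that keeps tests and synthetic
workflows free of large downloads.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from gyrbench.insilico_pcr import IUPAC, PrimerPair, amplify

__all__ = [
    "RANKS",
    "GenomeRecord",
    "MarkerRecord",
    "RefDBError",
    "EmptyDatabaseError",
    "extract_marker_genes",
    "build_database",
    "read_genome_table",
    "read_genbank",
    "read_marker_fasta",
    "write_marker_fasta",
    "write_marker_tsv",
    "markers_as_genomes",
]

logger = logging.getLogger(__name__)

#: Taxonomy ranks, shallow to deep; an optional eighth element names the strain.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species", "strain")


class RefDBError(ValueError):
    """A genome or marker record is malformed."""


class EmptyDatabaseError(RefDBError):
    """Database construction retained zero sequences."""


def _check_sequence(seq: str, context: str) -> None:
    bad = re.search(f"[^{''.join(IUPAC)}]", seq)
    if bad:
        raise RefDBError(
            f"{context}: invalid nucleotide {bad.group()!r} at position {bad.start()}"
        )


@dataclass(frozen=True)
class GenomeRecord:
    """An annotated genome: a taxonomy path and named gene sequences."""

    record_id: str
    taxonomy: tuple[str, ...]  # domain..species (+ optional strain)
    genes: tuple[tuple[str, str], ...]  # (gene_name, nucleotide sequence)

    def __post_init__(self) -> None:
        if not 7 <= len(self.taxonomy) <= 8:
            raise RefDBError(
                f"record {self.record_id}: taxonomy must have 7 ranks "
                f"(+ optional strain), got {len(self.taxonomy)}"
            )
        for name, seq in self.genes:
            _check_sequence(seq.upper(), f"record {self.record_id}, gene {name}")


@dataclass(frozen=True)
class MarkerRecord:
    """One reference amplicon with its taxonomy and gene label."""

    marker_id: str
    taxonomy: tuple[str, ...]  # 7 ranks + strain
    gene: str  # gyrB | parE | 16S
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise RefDBError(f"marker {self.marker_id}: empty sequence")
        _check_sequence(self.sequence, f"marker {self.marker_id}")

    @property
    def species(self) -> str:
        return self.taxonomy[6]

    @property
    def strain(self) -> str:
        return self.taxonomy[7] if len(self.taxonomy) > 7 else ""

    @property
    def label(self) -> str:
        return f"{self.marker_id}|{self.gene}|{self.species}"


def extract_marker_genes(
    record: GenomeRecord, gene_names: Iterable[str]
) -> list[tuple[str, str]]:
    """Genes of ``record`` whose annotated name matches a requested name.

    Matching is case-insensitive and exact; the annotated label is preserved
    in the output. Returns an empty list when nothing matches.
    """
    wanted = {g.lower() for g in gene_names}
    if not wanted:
        raise ValueError("gene_names must be nonempty")
    return [(name, seq.upper()) for name, seq in record.genes if name.lower() in wanted]


def build_database(
    records: Sequence[GenomeRecord],
    primers: PrimerPair,
    gene_names: Iterable[str] = ("gyrB", "parE"),
    dedup: bool = True,
    keep_primers: bool = False,
) -> list[MarkerRecord]:
    """Build the marker database by in-silico PCR over annotated genomes.

    Every requested gene is amplified with ``primers``; genes on which either
    primer site is missing are discarded. Each retained record holds the
    primer-trimmed amplicon (or the site-inclusive amplicon with
    ``keep_primers``, in which case a rebuild from the database's own output
    is idempotent). With ``dedup``, exact (sequence, species, gene)
    duplicates collapse to one record.

    Raises :class:`EmptyDatabaseError` when nothing is retained.
    """
    markers: list[MarkerRecord] = []
    seen: set[tuple[str, str, str]] = set()
    n_discarded = 0
    for record in records:
        tax = record.taxonomy if len(record.taxonomy) == 8 else record.taxonomy + ("",)
        for gene_name, seq in extract_marker_genes(record, gene_names):
            insert = amplify(seq, primers, keep_primers=keep_primers)
            if insert is None or len(insert) == 0:
                n_discarded += 1
                continue
            key = (insert, tax[6], gene_name.lower())
            if dedup and key in seen:
                continue
            seen.add(key)
            marker_id = f"{record.record_id}_{gene_name}_{len(markers) + 1:05d}"
            markers.append(MarkerRecord(marker_id, tax, gene_name, insert))
    logger.info(
        "build_database: retained %d markers, discarded %d genes lacking a primer site",
        len(markers),
        n_discarded,
    )
    if not markers:
        raise EmptyDatabaseError(
            "empty database: no gene contained both primer sites"
        )
    return markers


# ---------------------------------------------------------------------------
# I/O


def _parse_taxonomy(text: str) -> tuple[str, ...]:
    parts = tuple(p.strip() for p in text.split(";"))
    if not 7 <= len(parts) <= 8:
        raise RefDBError(
            f"taxonomy {text!r}: expected 7 ranks (+ optional strain), got {len(parts)}"
        )
    return parts


def read_genome_table(path: str | Path) -> list[GenomeRecord]:
    """Read genomes from a TSV of (taxonomy, gene, sequence [, record_id]).

    Taxonomy is a semicolon-separated 7- or 8-rank path; rows sharing the same
    taxonomy (or record_id when given) are grouped into one record.
    """
    groups: dict[str, tuple[tuple[str, ...], list[tuple[str, str]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RefDBError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            tax = _parse_taxonomy(fields[0])
            rec_id = fields[3] if len(fields) > 3 else ";".join(tax)
            groups.setdefault(rec_id, (tax, []))[1].append((fields[1], fields[2].upper()))
    return [
        GenomeRecord(rec_id, tax, tuple(genes)) for rec_id, (tax, genes) in groups.items()
    ]


def read_genbank(path: str | Path, default_taxonomy: tuple[str, ...] | None = None) -> list[GenomeRecord]:
    """Read annotated genomes from a GenBank flat file.

    Gene names are taken from the ``gene`` qualifier of gene/CDS features;
    taxonomy from the record annotations (falling back to
    ``default_taxonomy``), padded or truncated to the 7-rank convention with
    the organism name as species.
    """
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        genes: list[tuple[str, str]] = []
        for feat in rec.features:
            if feat.type not in ("gene", "CDS"):
                continue
            names = feat.qualifiers.get("gene")
            if not names:
                continue
            seq = str(feat.extract(rec.seq)).upper()
            genes.append((names[0], seq))
        if default_taxonomy is not None:
            tax = default_taxonomy
        else:
            lineage = rec.annotations.get("taxonomy", [])
            organism = rec.annotations.get("organism", rec.id)
            path7 = (list(lineage) + [""] * 6)[:6] + [organism]
            tax = tuple(path7)
        # drop duplicate feature pairs (gene + CDS of the same locus)
        unique = list(dict.fromkeys(genes))
        records.append(GenomeRecord(rec.id, tax, tuple(unique)))
    return records


def write_marker_fasta(markers: Sequence[MarkerRecord], path: str | Path) -> None:
    """Write markers as FASTA, header ``marker_id|gene|dom;...;species;strain``."""
    with open(path, "w") as fh:
        for m in markers:
            tax = m.taxonomy if len(m.taxonomy) == 8 else m.taxonomy + ("",)
            fh.write(f">{m.marker_id}|{m.gene}|{';'.join(tax)}\n{m.sequence}\n")


def read_marker_fasta(path: str | Path) -> list[MarkerRecord]:
    """Read a marker FASTA written by :func:`write_marker_fasta`."""
    markers: list[MarkerRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        if len(parts) != 3:
            raise RefDBError(f"{path}: malformed marker header {rec.description!r}")
        marker_id, gene, tax_text = parts
        markers.append(
            MarkerRecord(marker_id, _parse_taxonomy(tax_text), gene, str(rec.seq).upper())
        )
    return markers


def write_marker_tsv(markers: Sequence[MarkerRecord], path: str | Path) -> None:
    """Sidecar TSV with the same fields as the FASTA headers."""
    with open(path, "w") as fh:
        fh.write("marker_id\tgene\t" + "\t".join(RANKS) + "\tsequence\n")
        for m in markers:
            tax = m.taxonomy if len(m.taxonomy) == 8 else m.taxonomy + ("",)
            fh.write(f"{m.marker_id}\t{m.gene}\t" + "\t".join(tax) + f"\t{m.sequence}\n")


def markers_as_genomes(markers: Sequence[MarkerRecord]) -> list[GenomeRecord]:
    """View marker records as single-gene genome records (for rebuild tests)."""
    return [
        GenomeRecord(m.marker_id, m.taxonomy, ((m.gene, m.sequence),)) for m in markers
    ]
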