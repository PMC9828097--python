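"""Genome, annotation and expression input handling.

Parses FASTA genomes, GenBank/GFF3 gene annotations and a two-column
expression table; extracts validated in-frame coding sequences and assigns
genes to expression groups by FPKM thresholds.  Internal coordinates are
0-based half-open; the 1-based inclusive convention of GenBank/GFF3 is
converted at the parsing boundary.
"""
from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

from .genetics import STOP_CODONS, normalize_dna, reverse_complement

#: IUPAC nucleotide codes accepted in genome sequences.
_IUPAC = set("ACGTNRYSWKMBDHV")

#: Non-native or uncharacterised plastid ORFs excluded from usage analyses.
DEFAULT_EXCLUSIONS: tuple[str, ...] = ("i-cre", "icre", "wendy", "orf528", "orf 528")


class GenomeIOError(ValueError):
    pass


@dataclass
class GenomeRecord:
    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = normalize_dna(self.sequence)
        if not self.sequence:
            raise GenomeIOError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _IUPAC
        if bad:
            raise GenomeIOError(
                f"record {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """One CDS feature; exons ordered 5'->3' on the coding strand."""

    gene: str
    strand: str
    exons: list[tuple[int, int]]
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"{self.gene}: strand must be '+' or '-'")
        if not self.exons:
            raise GenomeIOError(f"{self.gene}: CDS feature without coordinates")
        for s, e in self.exons:
            if e <= s:
                raise GenomeIOError(f"{self.gene}: empty or inverted exon ({s},{e})")
        spans = sorted(self.exons)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise GenomeIOError(f"{self.gene}: overlapping exons")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class CdsRecord:
    """An in-frame coding sequence with provenance."""

    gene: str
    nt_seq: str
    codons: list[str] = field(default_factory=list)
    fpkm: float | None = None

    def __post_init__(self) -> None:
        self.nt_seq = normalize_dna(self.nt_seq)
        if len(self.nt_seq) % 3:
            raise GenomeIOError(
                f"{self.gene}: CDS length {len(self.nt_seq)} not divisible by 3"
            )
        if not self.codons:
            self.codons = [
                self.nt_seq[i : i + 3] for i in range(0, len(self.nt_seq), 3)
            ]

    @property
    def length_codons(self) -> int:
        return len(self.codons)

    @property
    def sense_codons(self) -> list[str]:
        """Codons with the trailing stop (if any) removed."""
        if self.codons and self.codons[-1] in STOP_CODONS:
            return self.codons[:-1]
        return list(self.codons)


@dataclass
class Thresholds:
    """FPKM cut-offs separating expression groups (strict comparisons)."""

    top7_min: float = 10_000.0
    top18_min: float = 5_000.0
    low8_max: float = 500.0

    def __post_init__(self) -> None:
        if not self.top7_min > self.top18_min > self.low8_max:
            raise GenomeIOError("thresholds must satisfy top7 > top18 > low8")


@dataclass
class ExpressionGrouping:
    """Gene -> finest group label; Top7 is a subset of Top18."""

    assignments: dict[str, str]
    thresholds: Thresholds

    def group_of(self, gene: str) -> str:
        return self.assignments.get(gene, "intermediate")

    def members(self, group: str) -> list[str]:
        if group == "Top18":
            keep = {"Top7", "Top18"}
        else:
            keep = {group}
        return sorted(g for g, lab in self.assignments.items() if lab in keep)


def read_fasta(path) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects (U mapped to T)."""
    records = [
        GenomeRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise GenomeIOError(f"{path}: no FASTA records")
    return records


def _is_excluded(gene: str, exclusions) -> bool:
    g = gene.casefold()
    return any(pat.casefold() in g for pat in exclusions)


def _parse_gff3(path, exclusions) -> list[GeneAnnotation]:
    groups: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeIOError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if cols[2] != "CDS":
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise GenomeIOError(
                    f"{path}:{lineno}: CDS feature without numeric coordinates"
                ) from exc
            attrs = {}
            for item in cols[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = v.strip()
            gene = (
                attrs.get("ID")
                or attrs.get("Parent")
                or attrs.get("gene")
                or attrs.get("Name")
            )
            if not gene:
                raise GenomeIOError(f"{path}:{lineno}: CDS without an identifier")
            entry = groups.setdefault(gene, {"strand": cols[6], "exons": []})
            if gene not in order:
                order.append(gene)
            entry["exons"].append((start - 1, end))
    annotations = []
    for gene in order:
        entry = groups[gene]
        exons = sorted(entry["exons"])
        if entry["strand"] == "-":
            exons = exons[::-1]
        annotations.append(
            GeneAnnotation(
                gene,
                entry["strand"],
                exons,
                excluded=_is_excluded(gene, exclusions),
            )
        )
    return annotations


def _parse_genbank(path, exclusions) -> list[GeneAnnotation]:
    annotations = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            if feat.location is None:
                raise GenomeIOError(f"{path}: CDS feature without coordinates")
            quals = feat.qualifiers
            gene = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
            strand = "-" if feat.location.strand == -1 else "+"
            exons = [(int(p.start), int(p.end)) for p in feat.location.parts]
            exons.sort()
            if strand == "-":
                exons = exons[::-1]
            annotations.append(
                GeneAnnotation(
                    gene, strand, exons, excluded=_is_excluded(gene, exclusions)
                )
            )
    if not annotations:
        raise GenomeIOError(f"{path}: no CDS features found")
    return annotations


def read_annotations(path, format: str, exclusions=DEFAULT_EXCLUSIONS) -> list[GeneAnnotation]:
    """Read CDS annotations from GenBank or GFF3.

    Multi-line GFF3 CDS features sharing an ID become one annotation with
    ordered exons.  Genes matching the exclusion list (case-insensitive
    substring) are flagged ``excluded`` but still returned.
    """
    if format == "gff3":
        return _parse_gff3(path, exclusions)
    if format == "genbank":
        return _parse_genbank(path, exclusions)
    raise GenomeIOError(f"unknown annotation format {format!r}")


def extract_cds(
    genome: GenomeRecord,
    ann: GeneAnnotation,
    on_internal_stop: str = "warn",
    fpkm: float | None = None,
) -> CdsRecord:
    """Concatenate exons 5'->3', reverse-complementing minus-strand genes."""
    length = len(genome)
    parts = []
    for start, end in ann.exons:
        if 0 <= start < end <= length:
            seg = genome.sequence[start:end]
        elif genome.circular and 0 <= start < length < end <= 2 * length:
            seg = genome.sequence[start:] + genome.sequence[: end - length]
        else:
            raise GenomeIOError(
                f"{ann.gene}: exon ({start},{end}) outside genome of length {length}"
            )
        if ann.strand == "-":
            seg = reverse_complement(seg)
        parts.append(seg)
    nt_seq = "".join(parts)
    rec = CdsRecord(ann.gene, nt_seq, fpkm=fpkm)
    internal = [
        (i, c) for i, c in enumerate(rec.codons[:-1]) if c in STOP_CODONS
    ]
    if internal:
        msg = f"{ann.gene}: internal stop codon(s) at codon index {internal[0][0]}"
        if on_internal_stop == "error":
            raise GenomeIOError(msg)
        warnings.warn(msg, stacklevel=2)
    return rec


def read_expression_table(path) -> dict[str, float]:
    """Read a TSV with header ``gene<TAB>fpkm`` (CRLF and blank lines ok)."""
    table: dict[str, float] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if any(f.strip() for f in r)]
    if not rows:
        raise GenomeIOError(f"{path}: empty expression table")
    header = [h.strip().lower() for h in rows[0]]
    if header[:2] != ["gene", "fpkm"]:
        raise GenomeIOError(f"{path}: expected header 'gene\\tfpkm', got {rows[0]}")
    for row in rows[1:]:
        gene, value = row[0].strip(), float(row[1])
        if value < 0:
            raise GenomeIOError(f"{path}: negative FPKM for {gene}")
        table[gene] = value
    return table


def assign_groups(
    expression: dict[str, float],
    thresholds: Thresholds | None = None,
    exclusions=(),
    all_genes=None,
) -> ExpressionGrouping:
    """Assign genes to Top7/Top18/Low8/intermediate by strict FPKM cuts.

    Genes listed in ``all_genes`` but absent from the expression table fall
    into the intermediate group with a warning, so genome-wide statistics
    stay complete.
    """
    thresholds = thresholds or Thresholds()
    assignments: dict[str, str] = {}
    excluded = {g for g in (all_genes or []) if _is_excluded(g, exclusions)}
    excluded |= {g for g in expression if _is_excluded(g, exclusions)}
    for gene, fpkm in expression.items():
        if fpkm < 0:
            raise GenomeIOError(f"negative FPKM for {gene}")
        if gene in excluded:
            assignments[gene] = "excluded"
        elif fpkm > thresholds.top7_min:
            assignments[gene] = "Top7"
        elif fpkm > thresholds.top18_min:
            assignments[gene] = "Top18"
        elif fpkm < thresholds.low8_max:
            assignments[gene] = "Low8"
        else:
            assignments[gene] = "intermediate"
    for gene in all_genes or []:
        if gene not in assignments:
            if gene in excluded:
                assignments[gene] = "excluded"
            else:
                warnings.warn(
                    f"{gene}: no expression value; assigned to intermediate",
                    stacklevel=2,
                )
                assignments[gene] = "intermediate"
    return ExpressionGrouping(assignments, thresholds)
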