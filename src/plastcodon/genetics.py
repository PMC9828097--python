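"""Genetic code tables, codon-family boxes and small sequence utilities.

The package works on DNA-alphabet codons (``T``, not ``U``) throughout;
RNA-alphabet input is mapped at the I/O boundary.  Codon families are
organised into *boxes*: duet boxes split by third-base pyrimidine (NNU/C)
or purine (NNA/G) class, quartet boxes share their first two bases, the
isoleucine triplet is its own box, and methionine/tryptophan are
single-codon boxes.  The six-codon amino acids (Leu, Ser, Arg) decompose
into one duet box and one quartet box each.
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable as _CodonTable
from Bio.Seq import Seq

_STANDARD = _CodonTable.unambiguous_dna_by_id[1]

#: Map of the 61 sense codons to one-letter amino acids.
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))
#: Synonymous codons per amino acid (one to six codons).
SYNONYMOUS: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
    for aa in AMINO_ACIDS
}

#: Lys, Arg, His — the residues that interact with the ribosomal exit tunnel.
POSITIVELY_CHARGED: tuple[str, ...] = ("K", "R", "H")

SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Family-box kinds.
KIND_NNUC = "NNU/C"
KIND_NNAG = "NNA/G"
KIND_QUARTET = "quartet"
KIND_ILE = "three-codon"
KIND_SINGLE = "single"


@dataclass(frozen=True)
class FamilyBox:
    """A codon box: codons of one amino acid sharing their first two bases."""

    name: str
    amino_acid: str
    kind: str
    codons: tuple[str, ...]


def _build_boxes() -> tuple[FamilyBox, ...]:
    boxes = []
    for aa in AMINO_ACIDS:
        by_prefix: dict[str, list[str]] = {}
        for codon in SYNONYMOUS[aa]:
            by_prefix.setdefault(codon[:2], []).append(codon)
        for prefix, codons in sorted(by_prefix.items()):
            thirds = {c[2] for c in codons}
            if len(codons) == 4:
                kind = KIND_QUARTET
            elif len(codons) == 3:
                kind = KIND_ILE
            elif len(codons) == 2 and thirds == {"T", "C"}:
                kind = KIND_NNUC
            elif len(codons) == 2 and thirds == {"A", "G"}:
                kind = KIND_NNAG
            else:
                kind = KIND_SINGLE
            boxes.append(
                FamilyBox(f"{aa}_{prefix}", aa, kind, tuple(sorted(codons)))
            )
    return tuple(boxes)


FAMILY_BOXES: tuple[FamilyBox, ...] = _build_boxes()
#: Every sense codon belongs to exactly one box.
BOX_OF: dict[str, FamilyBox] = {
    c: box for box in FAMILY_BOXES for c in box.codons
}


def aa_of(codon: str) -> str:
    """One-letter amino acid for a sense codon; ``*`` for a stop codon."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA[codon]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_codons(codons) -> str:
    """Translate a codon list; stops render as ``*``."""
    return "".join(aa_of(c) for c in codons)


def normalize_dna(seq: str) -> str:
    """Upper-case a nucleotide string and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")
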