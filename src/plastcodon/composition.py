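"""Nucleotide and amino-acid composition statistics.

GC content overall and per codon position, GC3 restricted to codon-family
boxes, the expected GC3 under the neutral mutational-bias correlation, and
amino-acid usage profiles.  Cross-gene aggregation is an unweighted
per-gene mean with a population standard deviation (dispersion across
genes); codon-pooled variants are also provided for transparency.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .genetics import (
    AMINO_ACIDS,
    BOX_OF,
    CODON_TO_AA,
    KIND_ILE,
    KIND_NNAG,
    KIND_NNUC,
    KIND_QUARTET,
    KIND_SINGLE,
    POSITIVELY_CHARGED,
    aa_of,
)

FAMILY_KINDS = (KIND_NNUC, KIND_NNAG, KIND_QUARTET, KIND_ILE, KIND_SINGLE)

#: Anchors of the neutral GC3-vs-genomic-GC line: a 39.0% GC gene set is
#: expected at GC3 = 34%, a 30.9% set at 19%.
DEFAULT_GC3_ANCHORS: tuple[tuple[float, float], tuple[float, float]] = (
    (39.0, 34.0),
    (30.9, 19.0),
)


class CompositionError(ValueError):
    pass


@dataclass
class GcByPosition:
    """Per-gene GC% at codon positions 1-3 plus cross-gene mean +/- sd."""

    per_gene: list[tuple[str, float, float, float]]
    gc1: tuple[float, float]
    gc2: tuple[float, float]
    gc3: tuple[float, float]
    pooled: tuple[float, float, float]


@dataclass
class AaProfile:
    freq_per_1000: dict[str, float]
    positively_charged_fraction: float
    scope: str = "set"


def gc_content(seq: str) -> float:
    """GC percent of a sequence; N bases leave the denominator."""
    if not seq:
        raise CompositionError("empty sequence")
    seq = seq.upper()
    counted = sum(seq.count(b) for b in "ACGT")
    if counted == 0:
        raise CompositionError("sequence contains no unambiguous bases")
    return 100.0 * (seq.count("G") + seq.count("C")) / counted


def _mean_sd(values) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std())  # population sd (divisor n)


def gc_by_position(cds_set) -> GcByPosition:
    """GC% at codon positions 1/2/3 per gene, stop codon excluded."""
    per_gene = []
    pooled_gc = np.zeros(3)
    pooled_n = np.zeros(3)
    for rec in cds_set:
        codons = rec.sense_codons
        if not codons:
            warnings.warn(f"{rec.gene}: no sense codons; skipped", stacklevel=2)
            continue
        values = []
        for pos in range(3):
            bases = [c[pos] for c in codons if c[pos] in "ACGT"]
            gc = sum(b in "GC" for b in bases)
            values.append(100.0 * gc / len(bases))
            pooled_gc[pos] += gc
            pooled_n[pos] += len(bases)
        per_gene.append((rec.gene, values[0], values[1], values[2]))
    if not per_gene:
        raise CompositionError("no genes with sense codons")
    cols = list(zip(*[(g1, g2, g3) for _, g1, g2, g3 in per_gene]))
    pooled = tuple(100.0 * g / n for g, n in zip(pooled_gc, pooled_n))
    return GcByPosition(
        per_gene,
        gc1=_mean_sd(cols[0]),
        gc2=_mean_sd(cols[1]),
        gc3=_mean_sd(cols[2]),
        pooled=pooled,
    )


def gc3_by_family(cds_set, exclude_aa=()) -> dict[str, tuple[float, float]]:
    """GC3% restricted to each codon-box kind, per gene then aggregated.

    ``exclude_aa`` removes an amino acid's codons from its kind's pool
    (e.g. the cysteine-free NNU/C variant).  Genes with no codons of a
    kind are skipped for that kind.
    """
    excluded = set(exclude_aa)
    per_kind: dict[str, list[float]] = {k: [] for k in FAMILY_KINDS}
    for rec in cds_set:
        tallies: dict[str, list[int]] = {k: [0, 0] for k in FAMILY_KINDS}
        for codon in rec.sense_codons:
            if codon not in CODON_TO_AA or CODON_TO_AA[codon] in excluded:
                continue
            kind = BOX_OF[codon].kind
            tallies[kind][1] += 1
            if codon[2] in "GC":
                tallies[kind][0] += 1
        for kind, (gc, n) in tallies.items():
            if n:
                per_kind[kind].append(100.0 * gc / n)
    return {k: _mean_sd(v) for k, v in per_kind.items() if v}


def expected_gc3(
    genomic_gc: float,
    calibration: tuple[float, float] | None = None,
) -> float:
    """Expected GC3 under the neutral correlation with genomic GC.

    ``calibration`` is a (slope, intercept) line; the default is the line
    through :data:`DEFAULT_GC3_ANCHORS`.
    """
    if calibration is None:
        (x1, y1), (x2, y2) = DEFAULT_GC3_ANCHORS
        slope = (y1 - y2) / (x1 - x2)
        intercept = y1 - slope * x1
    else:
        slope, intercept = calibration
    return slope * genomic_gc + intercept


def aa_profile(cds_set, scope: str = "set") -> AaProfile:
    """Amino-acid frequency per 1000 residues (standard genetic code)."""
    counts = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for rec in cds_set:
        for codon in rec.sense_codons:
            if codon not in CODON_TO_AA:
                warnings.warn(
                    f"{rec.gene}: ambiguous codon {codon} skipped", stacklevel=2
                )
                continue
            counts[aa_of(codon)] += 1
            total += 1
    if total == 0:
        raise CompositionError("no translatable codons in scope")
    charged = sum(counts[aa] for aa in POSITIVELY_CHARGED)
    return AaProfile(
        freq_per_1000={aa: 1000.0 * n / total for aa, n in counts.items()},
        positively_charged_fraction=charged / total,
        scope=scope,
    )


def aa_fold_change(
    profile_a: AaProfile,
    profile_b: AaProfile,
    significance_fold: float = 1.4,
    cap: float = 100.0,
) -> dict[str, tuple[float, bool]]:
    """Per-amino-acid usage ratio a/b with a strict significance flag.

    A ratio is significant when it exceeds ``significance_fold`` or falls
    below its reciprocal (strict inequalities); zero denominators cap at a
    flagged sentinel.
    """
    out: dict[str, tuple[float, bool]] = {}
    for aa in AMINO_ACIDS:
        va, vb = profile_a.freq_per_1000[aa], profile_b.freq_per_1000[aa]
        if vb == 0 and va == 0:
            out[aa] = (math.nan, False)
            continue
        ratio = cap if vb == 0 else va / vb
        significant = ratio > significance_fold or ratio < 1.0 / significance_fold
        out[aa] = (ratio, significant)
    return out
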