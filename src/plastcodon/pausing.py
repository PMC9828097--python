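"""Aggregation of ribosome-profiling pausing scores by codon and site.

Consumes an externally produced table of per-position pausing scores with
the codons occupying the ribosomal E/P/A sites, averages scores by codon
identity for a chosen site selection, and contrasts translationally
favored against unfavorable codons within each codon box.  Upstream read
processing and score normalisation are out of scope; scores are assumed
normalised per gene.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass

from .genetics import (
    BOX_OF,
    FAMILY_BOXES,
    KIND_NNAG,
    KIND_NNUC,
    KIND_QUARTET,
)

_COLUMNS = ("gene", "position", "score", "e_codon", "p_codon", "a_codon")


class PausingError(ValueError):
    pass


@dataclass
class PausingRecord:
    gene: str
    codon_index: int
    score: float
    e_codon: str
    p_codon: str
    a_codon: str


@dataclass
class BoxPausing:
    box: str
    kind: str
    favored_mean: float | None
    unfavorable_mean: float | None
    pct_difference: float | None  # 100 * (unfavorable/favored - 1)
    n_favored_codons: int
    n_unfavorable_codons: int


def read_pausing_table(path) -> list[PausingRecord]:
    """Read a TSV of gene, position, score, e_codon, p_codon, a_codon."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if any(f.strip() for f in r)]
    if not rows:
        raise PausingError(f"{path}: empty pausing table")
    header = tuple(h.strip().lower() for h in rows[0])
    if header != _COLUMNS:
        raise PausingError(
            f"{path}: expected columns {_COLUMNS}, got {header}"
        )
    records = []
    for lineno, row in enumerate(rows[1:], 2):
        try:
            rec = PausingRecord(
                gene=row[0].strip(),
                codon_index=int(row[1]),
                score=float(row[2]),
                e_codon=row[3].strip().upper(),
                p_codon=row[4].strip().upper(),
                a_codon=row[5].strip().upper(),
            )
        except (ValueError, IndexError) as exc:
            raise PausingError(f"{path}:{lineno}: malformed row {row}") from exc
        if rec.score < 0:
            raise PausingError(f"{path}:{lineno}: negative score")
        records.append(rec)
    return records


def write_pausing_table(records, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for r in records:
            writer.writerow(
                [r.gene, r.codon_index, r.score, r.e_codon, r.p_codon, r.a_codon]
            )


def mean_pausing_per_codon(records, selection: str = "P") -> dict[str, float]:
    """Mean pausing score per codon for a site selection (P, EP or EPA).

    In EP/EPA mode a record contributes once per site the codon occupies.
    Codons with no contributing records are absent from the map.
    """
    sites = {"P": ("p_codon",), "EP": ("e_codon", "p_codon"),
             "EPA": ("e_codon", "p_codon", "a_codon")}.get(selection)
    if sites is None:
        raise PausingError(f"unknown site selection {selection!r}")
    if not records:
        raise PausingError("no pausing records")
    sums: dict[str, float] = {}
    ns: dict[str, int] = {}
    for rec in records:
        for attr in sites:
            codon = getattr(rec, attr)
            if codon not in BOX_OF:
                continue
            sums[codon] = sums.get(codon, 0.0) + rec.score
            ns[codon] = ns.get(codon, 0) + 1
    return {c: sums[c] / ns[c] for c in sums}


def _box_sides(box, classification):
    """(favored, unfavorable) codon lists for one comparable box."""
    if box.kind == KIND_NNAG:
        return (
            [c for c in box.codons if c.endswith("A")],
            [c for c in box.codons if c.endswith("G")],
        )
    if box.kind == KIND_NNUC:
        return (
            [c for c in box.codons if c.endswith("C")],
            [c for c in box.codons if c.endswith("T")],
        )
    if box.kind == KIND_QUARTET:
        return (
            [c for c in box.codons if c in classification.optimal],
            [c for c in box.codons if c in classification.non_optimal],
        )
    return None


def relative_pausing_by_box(
    means: dict[str, float],
    classification,
    exclude_aa=(),
) -> dict[str, BoxPausing]:
    """Percent pausing excess of unfavorable over favored codons per box.

    NNA/G duets contrast G- against A-ending codons, NNU/C duets U- (T-)
    against C-ending, quartets non-optimal against optimal per the
    supplied classification.  Codon means are averaged unweighted within
    each side; boxes with a missing side are reported undefined.
    """
    out: dict[str, BoxPausing] = {}
    excluded = set(exclude_aa)
    for box in FAMILY_BOXES:
        if box.amino_acid in excluded:
            continue
        sides = _box_sides(box, classification)
        if sides is None:
            continue
        favored, unfavorable = sides
        fav = [means[c] for c in favored if c in means]
        unf = [means[c] for c in unfavorable if c in means]
        fav_mean = sum(fav) / len(fav) if fav else None
        unf_mean = sum(unf) / len(unf) if unf else None
        pct = (
            100.0 * (unf_mean / fav_mean - 1.0)
            if fav_mean and unf_mean is not None
            else None
        )
        out[box.name] = BoxPausing(
            box.name, box.kind, fav_mean, unf_mean, pct, len(fav), len(unf)
        )
    return out


def kind_average_excess(by_box: dict[str, BoxPausing], kind: str) -> float:
    """Unweighted mean percent excess over the defined boxes of one kind."""
    values = [b.pct_difference for b in by_box.values() if b.kind == kind and b.pct_difference is not None]
    if not values:
        raise PausingError(f"no defined boxes of kind {kind!r}")
    return sum(values) / len(values)
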