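"""Codon-usage descriptors: counts, frequency/1000, RSCU, W, CAI and demand.

The descriptors follow the classic definitions.  For amino acid *i* with
:math:`n_i` synonymous codons and codon counts :math:`X_{ij}`,

.. math::

    \\mathrm{RSCU}_{ij} = \\frac{X_{ij}}{\\frac{1}{n_i}\\sum_j X_{ij}},
    \\qquad
    W_{ij} = \\frac{X_{ij}}{X_{i,\\max}}
           = \\frac{\\mathrm{RSCU}_{ij}}{\\mathrm{RSCU}_{i,\\max}},
    \\qquad
    \\mathrm{CAI} = \\Big(\\prod_{j=1}^{L} W_j\\Big)^{1/L},

with the CAI product computed in log space and the reference :math:`W`
built from a high-expression gene set.  Codons absent from the reference
receive a pseudocount (default 0.5) before :math:`W` is formed, so genes
containing them do not collapse to CAI = 0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .genetics import (
    BOX_OF,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMOUS,
    aa_of,
)


class CodonStatsError(ValueError):
    pass


@dataclass
class CodonCountTable:
    """Sense-codon counts for a gene or gene group, stops tallied apart."""

    counts: dict[str, int]
    stop_counts: dict[str, int] = field(default_factory=dict)
    scope: str = "set"

    def __post_init__(self) -> None:
        self.counts = {c: int(self.counts.get(c, 0)) for c in SENSE_CODONS}
        self.stop_counts = {c: int(self.stop_counts.get(c, 0)) for c in STOP_CODONS}

    @property
    def total_sense(self) -> int:
        return sum(self.counts.values())


@dataclass
class UsageProfile:
    freq_per_1000: dict[str, float]
    rscu: dict[str, float]
    w: dict[str, float]
    missing_amino_acids: frozenset[str]
    scope: str = "set"


@dataclass
class CaiScore:
    gene: str
    cai: float
    length_codons_used: int


@dataclass
class CodonClassification:
    """Optimal vs non-optimal sense codons at a W cut-off."""

    optimal: frozenset[str]
    non_optimal: frozenset[str]
    w_threshold: float


@dataclass
class DemandTable:
    """Expression-weighted codon counts: demand(c) = sum_g X_g(c) * FPKM_g."""

    demand: dict[str, float]
    scope: str = "set"


@dataclass
class FoldDifference:
    ratios: dict[str, float]
    capped: frozenset[str]
    cap: float
    metric: str


def count_codons(cds_set, scope: str = "set") -> CodonCountTable:
    """Tally sense codons over a gene set; stop codons go to a 3-entry report."""
    records = list(cds_set)
    if not records:
        raise CodonStatsError("empty gene set")
    counts = {c: 0 for c in SENSE_CODONS}
    stops = {c: 0 for c in STOP_CODONS}
    for rec in records:
        for codon in rec.codons:
            if codon in stops:
                stops[codon] += 1
            elif codon in counts:
                counts[codon] += 1
            # codons containing N are skipped
    return CodonCountTable(counts, stops, scope=scope)


def freq_per_1000(counts: CodonCountTable) -> dict[str, float]:
    total = counts.total_sense
    if total == 0:
        raise CodonStatsError(f"{counts.scope}: zero sense codons")
    return {c: 1000.0 * x / total for c, x in counts.counts.items()}


def rscu(counts: CodonCountTable) -> dict[str, float]:
    """RSCU per codon; codons of absent amino acids map to NaN (missing)."""
    out: dict[str, float] = {}
    for aa, codons in SYNONYMOUS.items():
        family_total = sum(counts.counts[c] for c in codons)
        if family_total == 0:
            for c in codons:
                out[c] = math.nan
        else:
            expected = family_total / len(codons)
            for c in codons:
                out[c] = counts.counts[c] / expected
    return out


def relative_adaptiveness(
    counts: CodonCountTable, pseudocount: float = 0.5
) -> dict[str, float]:
    """W per codon from a reference count table.

    Zero-count codons receive ``pseudocount`` occurrences before the
    family-wise normalisation, so every sense codon has a defined,
    non-zero W (an amino acid entirely absent from the reference yields a
    flat W of 1 across its family).
    """
    w: dict[str, float] = {}
    for aa, codons in SYNONYMOUS.items():
        x = {c: counts.counts[c] if counts.counts[c] > 0 else pseudocount for c in codons}
        x_max = max(x.values())
        for c in codons:
            w[c] = x[c] / x_max
    return w


def build_usage_profile(
    counts: CodonCountTable, pseudocount: float = 0.5
) -> UsageProfile:
    missing = frozenset(
        aa
        for aa, codons in SYNONYMOUS.items()
        if sum(counts.counts[c] for c in codons) == 0
    )
    return UsageProfile(
        freq_per_1000=freq_per_1000(counts),
        rscu=rscu(counts),
        w=relative_adaptiveness(counts, pseudocount),
        missing_amino_acids=missing,
        scope=counts.scope,
    )


#: Codons excluded from the CAI product by default: single-codon boxes have
#: no synonymous choice, so W = 1 carries no information.
CAI_DEFAULT_EXCLUDED: frozenset[str] = frozenset({"ATG", "TGG"})


def cai(
    cds,
    reference_w: dict[str, float],
    excluded_codons: frozenset[str] = CAI_DEFAULT_EXCLUDED,
) -> CaiScore:
    """Geometric mean of reference W over a gene's codons, in log space."""
    log_sum = 0.0
    used = 0
    for codon in cds.sense_codons:
        if codon in excluded_codons or codon not in reference_w:
            continue
        w = reference_w[codon]
        if not w > 0:
            raise CodonStatsError(
                f"{cds.gene}: W({codon}) = {w}; apply pseudocount handling first"
            )
        log_sum += math.log(w)
        used += 1
    if used == 0:
        raise CodonStatsError(f"{cds.gene}: no codons left after exclusions")
    return CaiScore(cds.gene, math.exp(log_sum / used), used)


def classify_codons(
    reference_w: dict[str, float], w_threshold: float = 0.5
) -> CodonClassification:
    """Split sense codons into optimal (W >= threshold) and non-optimal.

    Single-codon boxes (Met, Trp) are always optimal.
    """
    optimal, non_optimal = set(), set()
    for codon in SENSE_CODONS:
        if len(SYNONYMOUS[CODON_TO_AA[codon]]) == 1:
            optimal.add(codon)
        elif reference_w[codon] >= w_threshold:
            optimal.add(codon)
        else:
            non_optimal.add(codon)
    return CodonClassification(frozenset(optimal), frozenset(non_optimal), w_threshold)


def optimal_fraction(counts: CodonCountTable, classification: CodonClassification) -> float:
    """Percent of sense codons in scope that are classified optimal."""
    total = counts.total_sense
    if total == 0:
        raise CodonStatsError("zero sense codons")
    n_opt = sum(x for c, x in counts.counts.items() if c in classification.optimal)
    return 100.0 * n_opt / total


def codon_demand(
    per_gene_counts: dict[str, CodonCountTable],
    fpkm_map: dict[str, float],
    scope: str = "set",
) -> DemandTable:
    """Expression-weighted codon counts over a gene group."""
    missing = sorted(g for g in per_gene_counts if g not in fpkm_map)
    if missing:
        raise CodonStatsError(f"missing FPKM for genes: {missing}")
    demand = {c: 0.0 for c in SENSE_CODONS}
    for gene, counts in per_gene_counts.items():
        fpkm = fpkm_map[gene]
        for c, x in counts.counts.items():
            demand[c] += x * fpkm
    return DemandTable(demand, scope=scope)


def demand_share_fold(
    demand_top: DemandTable, demand_low: DemandTable, cap: float = 100.0
) -> FoldDifference:
    """Per-codon ratio of demand *shares* between two groups (top/low)."""
    tot_t = sum(demand_top.demand.values())
    tot_l = sum(demand_low.demand.values())
    if tot_t <= 0 or tot_l <= 0:
        raise CodonStatsError("zero total demand in a group")
    ratios, capped = {}, set()
    for c in SENSE_CODONS:
        share_t = demand_top.demand[c] / tot_t
        share_l = demand_low.demand[c] / tot_l
        if share_l == 0 or share_t == 0:
            if share_t == share_l == 0:
                ratios[c] = math.nan
            else:
                ratios[c] = cap
                capped.add(c)
        else:
            ratios[c] = share_t / share_l
    return FoldDifference(ratios, frozenset(capped), cap, metric="demand_share")


def demand_fold_by_kind(fold: FoldDifference) -> dict[str, float]:
    """Average magnitude of the demand fold bias per codon-box kind.

    The per-codon fold is folded onto the >=1 scale (max(r, 1/r)) before
    averaging, so over- and underuse both register as bias; capped and
    undefined codons are skipped.
    """
    sums: dict[str, list[float]] = {}
    for c, r in fold.ratios.items():
        if c in fold.capped or math.isnan(r) or r <= 0:
            continue
        kind = BOX_OF[c].kind
        sums.setdefault(kind, []).append(max(r, 1.0 / r))
    return {k: sum(v) / len(v) for k, v in sums.items()}


def fold_difference(
    profile_a: UsageProfile,
    profile_b: UsageProfile,
    metric: str = "rscu",
    cap: float = 100.0,
) -> FoldDifference:
    """Per-codon ratio a/b of RSCU or freq/1000; absences cap at a sentinel."""
    if metric == "rscu":
        a, b = profile_a.rscu, profile_b.rscu
    elif metric == "freq":
        a, b = profile_a.freq_per_1000, profile_b.freq_per_1000
    else:
        raise CodonStatsError(f"unknown metric {metric!r}")
    ratios, capped = {}, set()
    for c in SENSE_CODONS:
        va, vb = a[c], b[c]
        if math.isnan(va) or math.isnan(vb):
            ratios[c] = math.nan
        elif vb == 0 and va == 0:
            ratios[c] = math.nan
        elif vb == 0:
            ratios[c] = cap
            capped.add(c)
        elif va == 0:
            ratios[c] = 1.0 / cap
            capped.add(c)
        else:
            ratios[c] = va / vb
    return FoldDifference(ratios, frozenset(capped), cap, metric=metric)


def write_usage_table(counts: CodonCountTable, path) -> None:
    """Write a codon usage table (codon, aa, fraction, freq/1000, count)."""
    if counts.total_sense == 0:
        raise CodonStatsError("refusing to write an empty usage table")
    freqs = freq_per_1000(counts)
    rows = []
    for c in SENSE_CODONS:
        family = SYNONYMOUS[CODON_TO_AA[c]]
        family_total = sum(counts.counts[x] for x in family)
        fraction = counts.counts[c] / family_total if family_total else math.nan
        rows.append(
            {
                "codon": c,
                "amino_acid": CODON_TO_AA[c],
                "fraction": fraction,
                "per_1000": freqs[c],
                "count": counts.counts[c],
            }
        )
    for c in STOP_CODONS:
        rows.append(
            {
                "codon": c,
                "amino_acid": "*",
                "fraction": math.nan,
                "per_1000": math.nan,
                "count": counts.stop_counts[c],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_usage_table(path, scope: str = "set") -> CodonCountTable:
    df = pd.read_csv(path, sep="\t")
    sense, stop = set(SENSE_CODONS), set(STOP_CODONS)
    counts = {c: int(n) for c, n in zip(df["codon"], df["count"]) if c in sense}
    stops = {c: int(n) for c, n in zip(df["codon"], df["count"]) if c in stop}
    return CodonCountTable(counts, stops, scope=scope)


def descriptor_frame(profile: UsageProfile, counts: CodonCountTable) -> pd.DataFrame:
    """Long-format per-codon descriptor table (count, freq/1000, RSCU, W)."""
    return pd.DataFrame(
        {
            "codon": SENSE_CODONS,
            "amino_acid": [aa_of(c) for c in SENSE_CODONS],
            "count": [counts.counts[c] for c in SENSE_CODONS],
            "per_1000": [profile.freq_per_1000[c] for c in SENSE_CODONS],
            "rscu": [profile.rscu[c] for c in SENSE_CODONS],
            "w": [profile.w[c] for c in SENSE_CODONS],
        }
    )
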