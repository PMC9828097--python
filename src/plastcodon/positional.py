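"""Position-resolved analyses along coding sequences.

Unfavorable-codon tracks, rare-codon cluster detection in sliding codon
windows, translational ramp statistics, cumulative GC profiles over the
first codons, and Shine-Dalgarno motif scans.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetics import (
    POSITIVELY_CHARGED,
    SYNONYMOUS,
    aa_of,
)
from .genome_io import CdsRecord


class PositionalError(ValueError):
    pass


@dataclass
class CodonFlagTrack:
    gene: str
    flags: list[bool]  # per sense codon; True = unfavorable


@dataclass
class ClusterCall:
    gene: str
    start_codon: int
    end_codon: int  # inclusive index of the last flagged codon
    n_unfavorable: int


@dataclass
class RampStats:
    group: str
    ramp_len: int
    rare_density_ramp: float
    rare_density_rest: float
    rare_enrichment_pct: float
    charged_density_ramp: float
    charged_density_rest: float
    charged_enrichment_pct: float
    rare_enrichment_pct_per_gene: float
    genes_used: int
    genes_excluded_short: int


def flag_unfavorable(cds: CdsRecord, classification) -> CodonFlagTrack:
    return CodonFlagTrack(
        cds.gene, [c in classification.non_optimal for c in cds.sense_codons]
    )


def detect_clusters(
    track: CodonFlagTrack, window: int = 30, min_count: int = 3
) -> list[ClusterCall]:
    """Maximal clusters of >= min_count flagged codons within a codon window.

    Every window of ``window`` consecutive codons containing at least
    ``min_count`` flags qualifies; overlapping qualifying windows merge
    into one call spanning the first to the last flagged codon inside the
    merged region.
    """
    flags = np.asarray(track.flags, dtype=bool)
    n = len(flags)
    if n == 0:
        return []
    win = min(window, n)
    counts = np.convolve(flags, np.ones(win, dtype=int), mode="valid")
    qualifying = [s for s in range(len(counts)) if counts[s] >= min_count]
    calls: list[ClusterCall] = []
    region: list[int] | None = None
    for s in qualifying + [None]:
        if s is not None and region is not None and s < region[1]:
            region[1] = s + win  # extend merged region (end exclusive)
            continue
        if region is not None:
            lo, hi = region
            inside = np.nonzero(flags[lo:hi])[0] + lo
            calls.append(
                ClusterCall(track.gene, int(inside[0]), int(inside[-1]), len(inside))
            )
        if s is not None:
            region = [s, s + win]
        else:
            region = None
    return calls


def _densities(records, ramp_len, predicate):
    """Pooled (hits, totals) in ramp vs rest; the initiator codon is skipped."""
    ramp_hit = ramp_n = rest_hit = rest_n = 0
    per_gene = []
    for rec in records:
        sense = rec.sense_codons
        g_counts = [0, 0, 0, 0]
        for i, codon in enumerate(sense):
            if i == 0:
                continue  # forced ATG start carries no codon choice
            hit = predicate(codon)
            if i < ramp_len:
                ramp_hit += hit
                ramp_n += 1
                g_counts[0] += hit
                g_counts[1] += 1
            else:
                rest_hit += hit
                rest_n += 1
                g_counts[2] += hit
                g_counts[3] += 1
        per_gene.append(g_counts)
    return ramp_hit, ramp_n, rest_hit, rest_n, per_gene


def ramp_stats(
    cds_set_by_group: dict,
    classification,
    ramp_len: int = 30,
    min_gene_len_nt: int = 150,
) -> dict[str, RampStats]:
    """Rare-codon and charged-residue density in the ramp vs the remainder.

    Densities are pooled over codons across genes within each group (the
    per-gene mean variant is also reported); genes of ``min_gene_len_nt``
    nucleotides or shorter are excluded.
    """
    out = {}
    for group, records in cds_set_by_group.items():
        eligible = [r for r in records if len(r.nt_seq) > min_gene_len_nt]
        excluded = len(records) - len(eligible)
        if not eligible:
            raise PositionalError(f"group {group!r}: no genes above {min_gene_len_nt} nt")
        rare = lambda c: c in classification.non_optimal  # noqa: E731
        charged = lambda c: aa_of(c) in POSITIVELY_CHARGED  # noqa: E731
        r_hit, r_n, s_hit, s_n, per_gene = _densities(eligible, ramp_len, rare)
        c_hit, c_n, d_hit, d_n, _ = _densities(eligible, ramp_len, charged)
        d_ramp, d_rest = r_hit / r_n, s_hit / s_n
        ch_ramp, ch_rest = c_hit / c_n, d_hit / d_n
        gene_enr = [
            100.0 * ((a / b) / (c / d) - 1.0)
            for a, b, c, d in per_gene
            if b and d and c
        ]
        out[group] = RampStats(
            group=group,
            ramp_len=ramp_len,
            rare_density_ramp=d_ramp,
            rare_density_rest=d_rest,
            rare_enrichment_pct=100.0 * (d_ramp / d_rest - 1.0) if d_rest else float("nan"),
            charged_density_ramp=ch_ramp,
            charged_density_rest=ch_rest,
            charged_enrichment_pct=100.0 * (ch_ramp / ch_rest - 1.0)
            if ch_rest
            else float("nan"),
            rare_enrichment_pct_per_gene=float(np.mean(gene_enr)) if gene_enr else float("nan"),
            genes_used=len(eligible),
            genes_excluded_short=excluded,
        )
    return out


def cumulative_gc_profile(cds_set, n: int = 30) -> np.ndarray:
    """Mean cumulative GC fraction of codons 1..p for p = 1..n.

    Only genes with at least ``n`` codons contribute, so every position
    averages over the same gene set.
    """
    profiles = []
    for rec in cds_set:
        sense = rec.sense_codons
        if len(sense) < n:
            continue
        gc = np.array(
            [sum(b in "GC" for b in codon) / 3.0 for codon in sense[:n]]
        )
        profiles.append(np.cumsum(gc) / np.arange(1, n + 1))
    if not profiles:
        raise PositionalError(f"no genes with >= {n} codons")
    return np.mean(profiles, axis=0)


#: Shine-Dalgarno motif family derived from the anti-SD sequence.
def sd_motifs(anti_sd: str = "UCCUCC") -> dict[str, list[str]]:
    """Hexa/penta/tetra SD motifs from an anti-SD written 3'->5'.

    rRNA pairs antiparallel with the message, so complementing the 3'->5'
    anti-SD base by base yields the SD motif read 5'->3' (UCCUCC ->
    AGGAGG).
    """
    from Bio.Seq import Seq

    sd = str(Seq(anti_sd.upper().replace("U", "T")).complement())
    return {
        "hexa": [sd],
        "penta": [sd[:5], sd[1:]],
        "tetra": [sd[i : i + 4] for i in range(3)],
    }


def _count_overlapping(seq: str, motif: str) -> int:
    count = start = 0
    while True:
        pos = seq.find(motif, start)
        if pos < 0:
            return count
        count += 1
        start = pos + 1


def scan_sd_motifs(cds_set, anti_sd: str = "UCCUCC") -> dict:
    """Per-gene overlapping counts of SD hexa/penta/tetra motifs (any frame)."""
    motifs = sd_motifs(anti_sd)
    per_gene = {}
    totals = {k: 0 for k in motifs}
    for rec in cds_set:
        gene_counts = {
            k: sum(_count_overlapping(rec.nt_seq, m) for m in ms)
            for k, ms in motifs.items()
        }
        per_gene[rec.gene] = gene_counts
        for k, v in gene_counts.items():
            totals[k] += v
    return {"per_gene": per_gene, "totals": totals, "motifs": motifs}


def recode_ramp(
    cds: CdsRecord,
    classification,
    reference_w: dict[str, float] | None = None,
    ramp_len: int = 30,
) -> CdsRecord:
    """Synonymously replace unfavorable ramp codons with optimal ones.

    The replacement is the highest-W optimal synonym (first optimal codon
    alphabetically when no reference W is supplied).  The start codon and
    everything beyond the ramp are untouched; the result is meant for
    external RNA-structure analysis of the recoded ramp.
    """
    codons = list(cds.codons)
    for i in range(1, min(ramp_len, len(cds.sense_codons))):
        codon = codons[i]
        if codon not in classification.non_optimal:
            continue
        synonyms = [
            c for c in SYNONYMOUS[aa_of(codon)] if c in classification.optimal
        ]
        if not synonyms:
            continue
        if reference_w:
            synonyms.sort(key=lambda c: (-reference_w[c], c))
        codons[i] = synonyms[0]
    return CdsRecord(cds.gene, "".join(codons), fpkm=cds.fpkm)
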