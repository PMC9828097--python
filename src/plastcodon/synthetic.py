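"""Seeded generator of plastome-like inputs for the whole pipeline.

The generator emulates the statistical structure of an AT-rich plastome:
a modest number of CDSs with log-spread FPKM values, expression-dependent
codon usage (a designed "high" W vector favoring C-ending duet codons,
A-ending NNA/G codons and U/A-ending quartet codons, versus a
mutational-bias-dominated "low" vector), an optional dipeptide bias,
injectable codon-pair overrepresentation, a controllable rare-codon ramp
enrichment, and an optional GC3 target enforced by exponential tilting of
third-position choice.  Genes are placed on both strands with AT-rich
spacers, and a fraction are split into two exons, so coordinate handling
is exercised end to end.  All sampling flows through one seeded generator
and every realized parameter is recorded in a machine-readable truth
record.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import codon_pairs, codon_stats
from .genetics import (
    SENSE_CODONS,
    SYNONYMOUS,
    aa_of,
    reverse_complement,
)
from .genome_io import CdsRecord, GeneAnnotation, GenomeRecord


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Designed usage profiles (chosen once; see docs/methods.md).
# ---------------------------------------------------------------------------

def _w_by_rules(duet_uc, duet_ag, quartet, ile, leu, ser, arg, gly=None, cys=None):
    w: dict[str, float] = {}
    for aa, codons in SYNONYMOUS.items():
        if aa == "L":
            w.update(leu)
        elif aa == "S":
            w.update(ser)
        elif aa == "R":
            w.update(arg)
        elif aa == "I":
            w.update(ile)
        elif aa == "G" and gly is not None:
            w.update(gly)
        elif aa == "C" and cys is not None:
            w.update(cys)
        elif len(codons) == 1:
            w[codons[0]] = 1.0
        elif len(codons) == 2 and {c[2] for c in codons} == {"T", "C"}:
            for c in codons:
                w[c] = duet_uc[c[2]]
        elif len(codons) == 2 and {c[2] for c in codons} == {"A", "G"}:
            for c in codons:
                w[c] = duet_ag[c[2]]
        else:  # quartet
            for c in codons:
                w[c] = quartet[c[2]]
    return w


#: High-expression (translationally optimal) relative adaptiveness: C-ending
#: duet codons favored (~2:1, cysteine excepted), G-ending NNA/G codons and
#: C/G-ending quartet codons nearly absent, U-only glycine/arginine quartets.
W_HIGH: dict[str, float] = _w_by_rules(
    duet_uc={"C": 1.0, "T": 0.45},
    duet_ag={"A": 1.0, "G": 0.03},
    quartet={"T": 1.0, "A": 0.8, "C": 0.06, "G": 0.04},
    ile={"ATT": 1.0, "ATC": 0.55, "ATA": 0.02},
    leu={"TTA": 1.0, "TTG": 0.3, "CTT": 0.25, "CTA": 0.2, "CTC": 0.03, "CTG": 0.03},
    ser={"TCT": 1.0, "TCA": 0.9, "TCC": 0.1, "TCG": 0.04, "AGT": 0.15, "AGC": 0.3},
    arg={"CGT": 1.0, "CGA": 0.1, "CGC": 0.03, "CGG": 0.02, "AGA": 0.06, "AGG": 0.03},
    gly={"GGT": 1.0, "GGA": 0.2, "GGC": 0.05, "GGG": 0.03},
    cys={"TGT": 1.0, "TGC": 0.55},
)

#: Low-expression (mutational-bias-dominated) relative adaptiveness: U/A
#: third positions dominate everywhere, with a residual G/C-ending tail.
W_LOW: dict[str, float] = _w_by_rules(
    duet_uc={"T": 1.0, "C": 0.25},
    duet_ag={"A": 1.0, "G": 0.13},
    quartet={"T": 1.0, "A": 0.9, "C": 0.17, "G": 0.17},
    ile={"ATT": 1.0, "ATC": 0.25, "ATA": 0.6},
    leu={"TTA": 1.0, "TTG": 0.25, "CTT": 0.5, "CTA": 0.3, "CTC": 0.08, "CTG": 0.08},
    ser={"TCT": 1.0, "TCA": 0.8, "TCC": 0.15, "TCG": 0.08, "AGT": 0.5, "AGC": 0.12},
    arg={"CGT": 1.0, "CGA": 0.35, "CGC": 0.1, "CGG": 0.08, "AGA": 0.5, "AGG": 0.12},
)

#: AT-rich plastome-like amino-acid frequencies (per 1, sums to 1).
DEFAULT_AA_FREQS: dict[str, float] = {
    "L": 0.100, "K": 0.075, "I": 0.070, "F": 0.060, "N": 0.055,
    "S": 0.065, "T": 0.050, "A": 0.060, "G": 0.065, "V": 0.060,
    "E": 0.055, "D": 0.050, "R": 0.045, "P": 0.045, "Q": 0.040,
    "Y": 0.035, "H": 0.020, "M": 0.025, "W": 0.015, "C": 0.010,
}


def family_reversed(w: dict[str, float]) -> dict[str, float]:
    """Family-wise reversal of a W vector (best codon becomes worst)."""
    out: dict[str, float] = {}
    for codons in SYNONYMOUS.values():
        ranked = sorted(codons, key=lambda c: (w[c], c))
        values = sorted((w[c] for c in codons), reverse=True)
        for codon, value in zip(ranked, values):
            out[codon] = value
    return out


def _codon_probs(w: dict[str, float]) -> dict[str, np.ndarray]:
    probs = {}
    for aa, codons in SYNONYMOUS.items():
        arr = np.array([w[c] for c in codons], dtype=float)
        probs[aa] = arr / arr.sum()
    return probs


def chloroplast_like_codon_freqs() -> dict[str, float]:
    """Stylized total-CDS codon frequency vector (sums to 1).

    An even blend of the high- and low-expression codon choice profiles
    weighted by the amino-acid frequencies; it reproduces the qualitative
    plastome picture of a strongly biased AT-rich usage with a tail of
    genuinely rare codons.
    """
    p_high, p_low = _codon_probs(W_HIGH), _codon_probs(W_LOW)
    freqs = {}
    for aa, codons in SYNONYMOUS.items():
        mix = 0.5 * p_high[aa] + 0.5 * p_low[aa]
        for c, p in zip(codons, mix):
            freqs[c] = DEFAULT_AA_FREQS[aa] * p
    total = sum(freqs.values())
    return {c: freqs[c] / total for c in SENSE_CODONS}


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    name: str
    fpkm_range: tuple[float, float]
    w: dict[str, float]
    n_genes: int | None = None
    #: Per-group codon length range; falls back to the spec-level range.
    gene_length_codons: tuple[int, int] | None = None


def default_groups() -> tuple[GroupSpec, GroupSpec]:
    """High genes average ~340 codons, low genes ~1100 (photosystem-sized
    versus polymerase-sized CDSs), mirroring real plastome group totals."""
    return (
        GroupSpec("high", (5e3, 5e4), W_HIGH, gene_length_codons=(150, 550)),
        GroupSpec("low", (10.0, 500.0), W_LOW, gene_length_codons=(400, 1800)),
    )


@dataclass
class SyntheticSpec:
    """Full parameterization of a generated plastome."""

    n_genes: int = 40
    gene_length_codons: tuple[int, int] = (150, 350)
    groups: tuple[GroupSpec, ...] = field(default_factory=default_groups)
    aa_freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AA_FREQS))
    target_gc3: float | None = None
    dipeptide_multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    injected_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    ramp_len: int = 30
    ramp_factor: float = 1.0
    expression_coupling: bool = True
    w_threshold: float = 0.5
    intron_every: int = 5
    spacer_gc: float = 30.0
    spacer_len: tuple[int, int] = (20, 80)
    minus_strand_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.aa_freqs.values())
        if abs(total - 1.0) > 1e-6:
            raise SyntheticError(f"aa frequencies sum to {total}, not 1")
        for group in self.groups:
            for aa, codons in SYNONYMOUS.items():
                w_max = max(group.w[c] for c in codons)
                if abs(w_max - 1.0) > 1e-9:
                    raise SyntheticError(
                        f"group {group.name}: max W for {aa} is {w_max}, not 1"
                    )
        if any(f <= 0 for f in self.dipeptide_multipliers.values()):
            raise SyntheticError("dipeptide multipliers must be > 0")
        if any(f <= 0 for f in self.injected_pairs.values()):
            raise SyntheticError("injection folds must be > 0")


@dataclass
class SyntheticGenome:
    genome: GenomeRecord
    annotations: list[GeneAnnotation]
    expression: dict[str, float]
    cds: list[CdsRecord]
    truth: dict

    def to_files(self, outdir) -> dict[str, Path]:
        """Write FASTA + GFF3 + expression TSV + truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fasta",
            "gff3": outdir / "annotations.gff3",
            "expression": outdir / "expression.tsv",
            "truth": outdir / "truth.json",
        }
        with open(paths["fasta"], "w") as fh:
            fh.write(f">{self.genome.id}\n")
            seq = self.genome.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
        with open(paths["gff3"], "w") as fh:
            fh.write("##gff-version 3\n")
            for ann in self.annotations:
                for start, end in sorted(ann.exons):
                    fh.write(
                        "\t".join(
                            [
                                self.genome.id,
                                "plastcodon",
                                "CDS",
                                str(start + 1),
                                str(end),
                                ".",
                                ann.strand,
                                "0",
                                f"ID={ann.gene}",
                            ]
                        )
                        + "\n"
                    )
        with open(paths["expression"], "w") as fh:
            fh.write("gene\tfpkm\n")
            for gene, fpkm in self.expression.items():
                fh.write(f"{gene}\t{fpkm:.4f}\n")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return paths


# ---------------------------------------------------------------------------
# Sampling machinery
# ---------------------------------------------------------------------------

def _gc3_share(probs: dict[str, np.ndarray], aa_freqs, t: float) -> float:
    share = 0.0
    for aa, codons in SYNONYMOUS.items():
        p = probs[aa]
        gc_mask = np.array([c[2] in "GC" for c in codons])
        tilted = p * np.where(gc_mask, t, 1.0)
        tilted = tilted / tilted.sum()
        share += aa_freqs[aa] * tilted[gc_mask].sum()
    return share


def _tilt_to_gc3(probs, aa_freqs, target_pct: float) -> dict[str, np.ndarray]:
    """Exponentially tilt third-position choice toward a target GC3."""
    target = target_pct / 100.0
    lo_share = _gc3_share(probs, aa_freqs, 1e-9)
    hi_share = _gc3_share(probs, aa_freqs, 1e9)
    if not lo_share + 1e-4 < target < hi_share - 1e-4:
        raise SyntheticError(
            f"GC3 target {target_pct}% outside the feasible range "
            f"({100 * lo_share:.1f}%, {100 * hi_share:.1f}%)"
        )
    lo, hi = -25.0, 25.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _gc3_share(probs, aa_freqs, math.exp(mid)) < target:
            lo = mid
        else:
            hi = mid
    t = math.exp(0.5 * (lo + hi))
    out = {}
    for aa, codons in SYNONYMOUS.items():
        gc_mask = np.array([c[2] in "GC" for c in codons])
        tilted = probs[aa] * np.where(gc_mask, t, 1.0)
        out[aa] = tilted / tilted.sum()
    return out


def _boost_rare(probs, rare: set, factor: float) -> dict[str, np.ndarray]:
    """Scale the rare-codon probability mass by ``factor`` per family."""
    out = {}
    for aa, codons in SYNONYMOUS.items():
        p = probs[aa].copy()
        mask = np.array([c in rare for c in codons])
        m = p[mask].sum()
        if 0.0 < m < 1.0 and factor != 1.0:
            m2 = min(factor * m, 0.9)
            p[mask] *= m2 / m
            p[~mask] *= (1.0 - m2) / (1.0 - m)
        out[aa] = p
    return out


def _sample_aa_sequence(n, aa_freqs, multipliers, rng) -> list[str]:
    aas = sorted(aa_freqs)
    base = np.array([aa_freqs[a] for a in aas])
    base = base / base.sum()
    if not multipliers:
        idx = rng.choice(len(aas), size=n, p=base)
        return [aas[i] for i in idx]
    seq = [aas[rng.choice(len(aas), p=base)]]
    while len(seq) < n:
        weights = base.copy()
        for k, a in enumerate(aas):
            weights[k] *= multipliers.get((seq[-1], a), 1.0)
        weights /= weights.sum()
        seq.append(aas[rng.choice(len(aas), p=weights)])
    return seq


def _designed_rare(reference_w: dict[str, float], threshold: float) -> set:
    rare = set()
    for aa, codons in SYNONYMOUS.items():
        if len(codons) == 1:
            continue
        rare.update(c for c in codons if reference_w[c] < threshold)
    return rare


def _spacer(rng, spec) -> str:
    length = int(rng.integers(spec.spacer_len[0], spec.spacer_len[1] + 1))
    g = spec.spacer_gc / 200.0
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[0.5 - g, g, g, 0.5 - g])
    return "".join(bases)


def _inject_pair(gene_codons: dict[str, list[str]], ci, cj, fold, rng) -> dict:
    """Raise o(ci,cj) to fold x the mixed-model floor by local resampling.

    Eligible junctions encode the same dipeptide; both codons are swapped
    synonymously so the protein and dipeptide structure are untouched.
    """
    aa_i, aa_j = aa_of(ci), aa_of(cj)

    def analyzer_state():
        tmp = [CdsRecord(g, "".join(c)) for g, c in gene_codons.items()]
        counts = codon_stats.count_codons(tmp)
        dipb = codon_pairs.dipeptide_bias(tmp)
        pairs = codon_pairs.count_pairs(tmp)
        i, j = codon_pairs.SENSE_INDEX[ci], codon_pairs.SENSE_INDEX[cj]
        c_i = counts.counts[ci]
        f_j = counts.counts[cj] / counts.total_sense
        d = dipb.dipb[codon_pairs.AA_INDEX[aa_i], codon_pairs.AA_INDEX[aa_j]]
        e_norm = c_i * f_j * (d if np.isfinite(d) else 1.0)
        return float(e_norm), int(pairs.observed[i, j])

    candidates = []
    for gene, codons in gene_codons.items():
        for t in range(1, len(codons) - 2):
            if aa_of(codons[t]) == aa_i and aa_of(codons[t + 1]) == aa_j:
                if (codons[t], codons[t + 1]) != (ci, cj):
                    candidates.append((gene, t))
    rng.shuffle(candidates)
    used_positions: set = set()
    swapped = 0
    for _ in range(4):
        e_norm, observed = analyzer_state()
        target = math.ceil(fold * max(e_norm, 1.0))
        if observed >= target:
            break
        need = target - observed
        while need > 0 and candidates:
            gene, t = candidates.pop()
            if (gene, t) in used_positions or (gene, t + 1) in used_positions or (gene, t - 1) in used_positions:
                continue
            gene_codons[gene][t] = ci
            gene_codons[gene][t + 1] = cj
            used_positions.update({(gene, t), (gene, t + 1)})
            swapped += 1
            need -= 1
        if need > 0:
            break
    e_norm, observed = analyzer_state()
    return {
        "pair": f"{ci}-{cj}",
        "fold": fold,
        "swapped": swapped,
        "realized_o": observed,
        "e_norm": e_norm,
    }


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def generate_genome(spec: SyntheticSpec) -> SyntheticGenome:
    """Generate a plastome-like genome, annotations, expression and truth.

    Fully reproducible from ``spec.seed``: the same spec yields
    byte-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    groups = list(spec.groups)
    # genes per group
    per_group = []
    base, extra = divmod(spec.n_genes, len(groups))
    for k, group in enumerate(groups):
        per_group.append(group.n_genes if group.n_genes is not None else base + (k < extra))

    ordered = sorted(groups, key=lambda g: math.sqrt(g.fpkm_range[0] * g.fpkm_range[1]))
    p_lowest = _codon_probs(ordered[0].w)
    p_highest = _codon_probs(ordered[-1].w)
    reference_w = ordered[-1].w
    rare = _designed_rare(reference_w, spec.w_threshold)
    f_min = min(g.fpkm_range[0] for g in groups)
    f_max = max(g.fpkm_range[1] for g in groups)

    gene_codons: dict[str, list[str]] = {}
    gene_meta: dict[str, dict] = {}
    expression: dict[str, float] = {}
    for group, n in zip(groups, per_group):
        p_group = _codon_probs(group.w)
        for k in range(n):
            gene = f"{group.name}{k + 1:03d}"
            lo, hi = group.fpkm_range
            fpkm = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            if spec.expression_coupling and len(groups) > 1 and f_max > f_min:
                lam = (math.log(fpkm) - math.log(f_min)) / (
                    math.log(f_max) - math.log(f_min)
                )
                lam = min(max(lam, 0.0), 1.0)
                probs = {
                    aa: (1.0 - lam) * p_lowest[aa] + lam * p_highest[aa]
                    for aa in SYNONYMOUS
                }
            else:
                lam = None
                probs = {aa: p.copy() for aa, p in p_group.items()}
            if spec.target_gc3 is not None:
                probs = _tilt_to_gc3(probs, spec.aa_freqs, spec.target_gc3)
            ramp_probs = _boost_rare(probs, rare, spec.ramp_factor)
            len_range = group.gene_length_codons or spec.gene_length_codons
            length = int(rng.integers(len_range[0], len_range[1] + 1))
            residues = _sample_aa_sequence(
                length, spec.aa_freqs, spec.dipeptide_multipliers, rng
            )
            codons = ["ATG"]
            for i, aa in enumerate(residues):
                p = ramp_probs[aa] if (i + 1) < spec.ramp_len else probs[aa]
                codons.append(SYNONYMOUS[aa][rng.choice(len(p), p=p)])
            codons.append("TAA")
            gene_codons[gene] = codons
            gene_meta[gene] = {"group": group.name, "fpkm": fpkm, "lambda": lam}
            expression[gene] = fpkm

    injections = []
    for (ci, cj), fold in sorted(spec.injected_pairs.items()):
        injections.append(_inject_pair(gene_codons, ci, cj, fold, rng))

    # --- genome assembly -----------------------------------------------
    parts: list[str] = []
    pos = 0
    annotations: list[GeneAnnotation] = []
    for k, (gene, codons) in enumerate(gene_codons.items()):
        sp = _spacer(rng, spec)
        parts.append(sp)
        pos += len(sp)
        nt = "".join(codons)
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        split_gene = (
            spec.intron_every
            and (k % spec.intron_every == spec.intron_every - 1)
            and len(nt) > 90
        )
        if split_gene:
            s = int(rng.integers(30, len(nt) - 30))
            intron = _spacer(rng, spec)
            if strand == "+":
                parts.extend([nt[:s], intron, nt[s:]])
                exons = [(pos, pos + s), (pos + s + len(intron), pos + len(nt) + len(intron))]
            else:
                parts.extend(
                    [reverse_complement(nt[s:]), intron, reverse_complement(nt[:s])]
                )
                len2 = len(nt) - s
                exons = [
                    (pos + len2 + len(intron), pos + len2 + len(intron) + s),
                    (pos, pos + len2),
                ]
            pos += len(nt) + len(intron)
        else:
            parts.append(nt if strand == "+" else reverse_complement(nt))
            exons = [(pos, pos + len(nt))]
            pos += len(nt)
        annotations.append(GeneAnnotation(gene, strand, exons))
        gene_meta[gene]["strand"] = strand
    parts.append(_spacer(rng, spec))
    genome = GenomeRecord("synthetic_plastome", "".join(parts))

    cds = [
        CdsRecord(g, "".join(c), fpkm=gene_meta[g]["fpkm"])
        for g, c in gene_codons.items()
    ]
    truth = {
        "seed": spec.seed,
        "n_genes": spec.n_genes,
        "ramp_len": spec.ramp_len,
        "ramp_factor": spec.ramp_factor,
        "target_gc3": spec.target_gc3,
        "w_threshold": spec.w_threshold,
        "expression_coupling": spec.expression_coupling,
        "optimal_codons": sorted(set(SENSE_CODONS) - rare),
        "rare_codons": sorted(rare),
        "injections": injections,
        "genes": {
            g: {**gene_meta[g], "codons": gene_codons[g]} for g in gene_codons
        },
    }
    return SyntheticGenome(genome, annotations, expression, cds, truth)


def iid_codon_records(
    freqs: dict[str, float],
    n_codons: int,
    n_genes: int = 20,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> list[CdsRecord]:
    """A null gene set of i.i.d. sense codons drawn from a frequency vector.

    No sequence structure beyond the marginal codon frequencies: the null
    surface for codon-pair-bias calibration.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    p = np.array([freqs.get(c, 0.0) for c in SENSE_CODONS], dtype=float)
    p = p / p.sum()
    draws = rng.choice(len(SENSE_CODONS), size=n_codons, p=p)
    codons = [SENSE_CODONS[i] for i in draws]
    bounds = np.linspace(0, n_codons, n_genes + 1).astype(int)
    records = []
    for g, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
        if hi > lo:
            records.append(CdsRecord(f"null{g + 1:03d}", "".join(codons[lo:hi])))
    return records
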