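"""Codon pair bias with dipeptide correction and a mixed Poisson model.

The observed count :math:`o_{ij}` of each of the 3721 ordered sense-codon
pairs (first codon = ribosomal P-site, second = A-site; pairs never span
gene boundaries) is compared with an expectation built from individual
codon usage,

.. math::

    e_{ij} = c_i F_j, \\qquad
    e_{ij,\\mathrm{norm}} = c_i F_j \\, \\mathrm{DiPB}_{kl},

where :math:`c_i` is the codon count, :math:`F_j = c_j/N_\\mathrm{TOT}`
the codon frequency over sense codons, and :math:`\\mathrm{DiPB}_{kl} =
P_{kl}/Q_{kl}` the observed/expected ratio of the encoded dipeptide
(:math:`Q_{kl} = F_k F_l N_P` from amino-acid frequencies).  The bias is
:math:`(o - e_\\mathrm{used})/e_\\mathrm{used}`.

Pairs involving rare codons have expectations far below one occurrence,
which inflates the bias as soon as a single pair exists.  A Poisson law
classifies each codon: with :math:`\\lambda_{ij} = c_i F_j`, the mean over
all 61 second codons of :math:`P(X \\le 1) = (1+\\lambda)e^{-\\lambda}`
above 0.75 marks the codon as rare (deterministic regime).  In the mixed
model the expectation is rounded up to the nearest whole number before the
bias is formed, so a single observed pair of a rare codon can never look
overrepresented; the naive model applies no ceiling and reproduces the
artificial inflation the mixed model removes.
"""
from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import (
    AA_INDEX,
    AMINO_ACIDS,
    CODON_TO_AA,
    SENSE_CODONS,
    SENSE_INDEX,
    aa_of,
)

_N_SENSE = len(SENSE_CODONS)
#: Row index (codon) -> amino-acid index, for mapping 20x20 onto 61x61.
_AA_OF_SENSE = np.array([AA_INDEX[CODON_TO_AA[c]] for c in SENSE_CODONS])


class CodonPairError(ValueError):
    pass


@dataclass
class PairCounts:
    observed: np.ndarray  # (61, 61) int, [P-site, A-site]
    n_pairs: int
    scope: str = "set"
    codons: tuple[str, ...] = SENSE_CODONS


@dataclass
class DipeptideBias:
    observed: np.ndarray  # (20, 20) int, P_kl
    expected: np.ndarray  # (20, 20) float, Q_kl = F_k * F_l * N_P
    dipb: np.ndarray  # (20, 20) float, NaN where Q == 0
    amino_acids: tuple[str, ...] = AMINO_ACIDS


@dataclass
class RareCodonClassification:
    mean_p_le1: dict[str, float]
    deterministic: frozenset[str]
    threshold: float

    def model_of(self, codon: str) -> str:
        return "deterministic" if codon in self.deterministic else "probabilistic"


@dataclass
class PairBiasResult:
    e_raw: np.ndarray
    e_norm: np.ndarray
    e_used: np.ndarray
    bias: np.ndarray
    mode: str
    pair_counts: PairCounts
    classification: RareCodonClassification | None = None
    codons: tuple[str, ...] = SENSE_CODONS

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: codon1, codon2, o, e_raw, e_norm, e_used, bias."""
        i, j = np.meshgrid(range(_N_SENSE), range(_N_SENSE), indexing="ij")
        model = (
            [self.classification.model_of(c) for c in self.codons]
            if self.classification
            else ["-"] * _N_SENSE
        )
        return pd.DataFrame(
            {
                "codon1": np.array(self.codons)[i.ravel()],
                "codon2": np.array(self.codons)[j.ravel()],
                "o": self.pair_counts.observed.ravel(),
                "e_raw": self.e_raw.ravel(),
                "e_norm": self.e_norm.ravel(),
                "e_used": self.e_used.ravel(),
                "bias": self.bias.ravel(),
                "model_codon1": np.array(model)[i.ravel()],
            }
        )


def _sense_runs(cds_set):
    for rec in cds_set:
        yield rec.gene, [c for c in rec.codons if c in SENSE_INDEX]


def count_pairs(cds_set, scope: str = "set") -> PairCounts:
    """Count adjacent sense-codon pairs per gene (never across genes)."""
    observed = np.zeros((_N_SENSE, _N_SENSE), dtype=np.int64)
    n_pairs = 0
    for _, sense in _sense_runs(cds_set):
        idx = [SENSE_INDEX[c] for c in sense]
        for a, b in zip(idx, idx[1:]):
            observed[a, b] += 1
            n_pairs += 1
    return PairCounts(observed, n_pairs, scope=scope)


def dipeptide_bias(cds_set) -> DipeptideBias:
    """Observed/expected adjacent amino-acid pairs over the same windows."""
    p = np.zeros((len(AMINO_ACIDS), len(AMINO_ACIDS)), dtype=np.int64)
    aa_counts = np.zeros(len(AMINO_ACIDS), dtype=np.int64)
    n_pairs = 0
    for _, sense in _sense_runs(cds_set):
        residues = [AA_INDEX[aa_of(c)] for c in sense]
        for r in residues:
            aa_counts[r] += 1
        for a, b in zip(residues, residues[1:]):
            p[a, b] += 1
            n_pairs += 1
    if n_pairs == 0:
        raise CodonPairError("no codon pairs in scope")
    freqs = aa_counts / aa_counts.sum()
    q = np.outer(freqs, freqs) * n_pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        dipb = np.where(q > 0, p / q, np.nan)
    return DipeptideBias(p, q, dipb)


def poisson_p_le1(lam):
    """P(X <= 1) for a Poisson variable: (1 + lambda) * exp(-lambda)."""
    arr = np.asarray(lam, dtype=float)
    if np.any(arr < 0):
        raise CodonPairError("lambda must be non-negative")
    result = (1.0 + arr) * np.exp(-arr)
    return float(result) if np.isscalar(lam) or arr.ndim == 0 else result


def classify_rare_codons(
    codon_counts, threshold: float = 0.75
) -> RareCodonClassification:
    """Rare (deterministic) vs common (probabilistic) codon classification.

    For each codon *i*, the mean over all 61 second codons *j* of
    P(X <= 1 | lambda = c_i * F_j); strictly above ``threshold`` means the
    codon essentially cannot form more than one of any pair, so its pair
    counts are treated deterministically.
    """
    c = np.array([codon_counts.counts[x] for x in SENSE_CODONS], dtype=float)
    total = c.sum()
    if total == 0:
        raise CodonPairError("zero sense codons in scope")
    lam = np.outer(c, c / total)
    mean_p = poisson_p_le1(lam).mean(axis=1)
    deterministic = frozenset(
        SENSE_CODONS[i] for i in range(_N_SENSE) if mean_p[i] > threshold
    )
    return RareCodonClassification(
        dict(zip(SENSE_CODONS, mean_p.tolist())), deterministic, threshold
    )


def pair_bias(
    pair_counts: PairCounts,
    codon_counts,
    dipb: DipeptideBias,
    mode: str = "mixed",
    ceiling: str = "all",
    classification: RareCodonClassification | None = None,
) -> PairBiasResult:
    """Observed-vs-expected codon pair bias matrices.

    ``mode="mixed"`` rounds the normalised expectation up to the nearest
    whole number (``ceiling="all"``, the default, applies this to every
    pair; ``ceiling="rare_rows"`` restricts it to rows whose P-site codon
    is rare-classified).  ``mode="naive"`` uses the raw expectation and is
    the comparator that exhibits artificial inflation for rare codons.
    Undefined dipeptide cells propagate as NaN bias; cells with zero
    expectation in naive mode are NaN, never a division by zero.
    """
    c = np.array([codon_counts.counts[x] for x in SENSE_CODONS], dtype=float)
    total = c.sum()
    if total == 0:
        raise CodonPairError("zero sense codons in scope")
    freqs = c / total
    e_raw = np.outer(c, freqs)
    e_norm = e_raw * dipb.dipb[np.ix_(_AA_OF_SENSE, _AA_OF_SENSE)]
    if mode == "mixed":
        if ceiling == "all":
            e_used = np.ceil(e_norm)
        elif ceiling == "rare_rows":
            if classification is None:
                raise CodonPairError("ceiling='rare_rows' needs a classification")
            e_used = e_norm.copy()
            rare_rows = [
                SENSE_INDEX[x] for x in sorted(classification.deterministic)
            ]
            e_used[rare_rows, :] = np.ceil(e_used[rare_rows, :])
        else:
            raise CodonPairError(f"unknown ceiling scope {ceiling!r}")
    elif mode == "naive":
        e_used = e_norm.copy()
    else:
        raise CodonPairError(f"unknown mode {mode!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        bias = np.where(e_used > 0, (pair_counts.observed - e_used) / e_used, np.nan)
    return PairBiasResult(
        e_raw, e_norm, e_used, bias, mode, pair_counts, classification
    )


def call_overrepresented(result: PairBiasResult, fold: float = 3.0):
    """Pairs with bias strictly above ``fold``, sorted by descending bias."""
    calls = []
    with np.errstate(invalid="ignore"):
        rows, cols = np.where(np.nan_to_num(result.bias, nan=-np.inf) > fold)
    for i, j in zip(rows, cols):
        calls.append((result.codons[i], result.codons[j], float(result.bias[i, j])))
    calls.sort(key=lambda t: (-t[2], t[0], t[1]))
    return calls


def call_underrepresented(result: PairBiasResult, fold: float = 3.0):
    """Pairs observed less than 1/fold of expectation (bias < 1/fold - 1)."""
    cutoff = 1.0 / fold - 1.0
    calls = []
    with np.errstate(invalid="ignore"):
        rows, cols = np.where(np.nan_to_num(result.bias, nan=np.inf) < cutoff)
    for i, j in zip(rows, cols):
        calls.append((result.codons[i], result.codons[j], float(result.bias[i, j])))
    calls.sort(key=lambda t: (t[2], t[0], t[1]))
    return calls


@dataclass
class JunctionComposition:
    """Overlapping dinucleotide (cP3, cA1) composition of a pair list."""

    proportions: dict[str, float]
    cp3_at_pct: float
    cp3_gc_pct: float
    n_pairs: int


def junction_dinucleotides(pairs) -> JunctionComposition:
    """Proportions of the 16 junction dinucleotides plus the cP3 AT/GC split."""
    pair_list = [(p[0], p[1]) for p in pairs]
    if not pair_list:
        raise CodonPairError("empty pair list")
    dinucs = Counter(c1[2] + c2[0] for c1, c2 in pair_list)
    n = len(pair_list)
    proportions = {
        a + b: dinucs.get(a + b, 0) / n for a in "ACGT" for b in "ACGT"
    }
    cp3_at = sum(1 for c1, _ in pair_list if c1[2] in "AT") / n
    return JunctionComposition(proportions, 100.0 * cp3_at, 100.0 * (1 - cp3_at), n)


def scan_out_of_frame_stops(cds_set) -> dict:
    """Count junctions spelling UAA/UGA in the two shifted reading frames.

    The +1 frame motif is cP3 + cA1,2; the +2 frame motif is cP2,3 + cA1.
    """
    out = {
        "cP3_cA12": {"TAA": 0, "TGA": 0},
        "cP23_cA1": {"TAA": 0, "TGA": 0},
        "n_junctions": 0,
    }
    for _, sense in _sense_runs(cds_set):
        for c1, c2 in zip(sense, sense[1:]):
            out["n_junctions"] += 1
            plus1 = c1[2] + c2[:2]
            plus2 = c1[1:] + c2[0]
            if plus1 in out["cP3_cA12"]:
                out["cP3_cA12"][plus1] += 1
            if plus2 in out["cP23_cA1"]:
                out["cP23_cA1"][plus2] += 1
    return out


@dataclass
class RepeatScan:
    mono_run_count: int
    junction_counts: dict[int, Counter]
    junction_windows: dict[int, int]
    base_freqs: dict[str, float]

    def expected_count(self, kmer: str) -> float:
        """Expected junction-spanning occurrences under independent bases."""
        k = len(kmer)
        p = 1.0
        for b in kmer:
            p *= self.base_freqs.get(b, 0.0)
        return self.junction_windows[k] * p


def scan_repeats(cds_set, lengths=(4, 5, 6), mono_run_min: int = 6) -> RepeatScan:
    """Homopolymer runs and short repeats spanning codon junctions."""
    mono = 0
    junction_counts: dict[int, Counter] = {k: Counter() for k in lengths}
    junction_windows: dict[int, int] = {k: 0 for k in lengths}
    base_counter: Counter = Counter()
    pattern = re.compile(r"(A{%d,}|C{%d,}|G{%d,}|T{%d,})" % ((mono_run_min,) * 4))
    for rec in cds_set:
        seq = rec.nt_seq
        base_counter.update(seq)
        mono += len(pattern.findall(seq))
        boundaries = range(3, len(seq), 3)  # nucleotide index of each junction
        for k in lengths:
            for b in boundaries:
                for start in range(b - k + 1, b):
                    if start < 0 or start + k > len(seq):
                        continue
                    junction_windows[k] += 1
                    junction_counts[k][seq[start : start + k]] += 1
    total_bases = sum(base_counter[b] for b in "ACGT") or 1
    base_freqs = {b: base_counter[b] / total_bases for b in "ACGT"}
    return RepeatScan(mono, junction_counts, junction_windows, base_freqs)
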