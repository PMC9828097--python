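"""End-to-end pipeline orchestration with a run manifest.

Runs extraction -> usage/CAI -> composition -> codon pairs -> positional
analyses (-> pausing when a score table is supplied) over configured
inputs, writing TSV/JSON outputs and a manifest recording parameters,
package version and input checksums so reruns are verifiably identical.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, codon_pairs, codon_stats, composition, pausing, positional
from .genome_io import (
    DEFAULT_EXCLUSIONS,
    Thresholds,
    assign_groups,
    extract_cds,
    read_annotations,
    read_expression_table,
    read_fasta,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    genome: str
    annotations: str
    expression: str
    outdir: str
    annotations_format: str = "gff3"
    pausing_table: str | None = None
    top7_min: float = 10_000.0
    top18_min: float = 5_000.0
    low8_max: float = 500.0
    pseudocount: float = 0.5
    w_threshold: float = 0.5
    ramp_len: int = 30
    min_gene_len_nt: int = 150
    pair_mode: str = "mixed"
    poisson_threshold: float = 0.75
    overrep_fold: float = 3.0
    cluster_window: int = 30
    cluster_min_count: int = 3
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS
    reference_group: str = "Top18"
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        flat: dict = {}
        for key, value in data.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f for f in cls.__dataclass_fields__}
        unknown = sorted(set(flat) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        if isinstance(flat.get("exclusions"), list):
            flat["exclusions"] = tuple(flat["exclusions"])
        return cls(**flat)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a manifest dict (also written)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        outputs[name] = str(path)

    with stage("extract"):
        for path in (config.genome, config.annotations, config.expression):
            if not Path(path).exists():
                raise FileNotFoundError(path)
        genome = read_fasta(config.genome)[0]
        annotations = read_annotations(
            config.annotations, config.annotations_format, config.exclusions
        )
        expression = read_expression_table(config.expression)
        records = [
            extract_cds(genome, ann, fpkm=expression.get(ann.gene))
            for ann in annotations
            if not ann.excluded
        ]
        thresholds = Thresholds(config.top7_min, config.top18_min, config.low8_max)
        grouping = assign_groups(
            expression,
            thresholds,
            config.exclusions,
            all_genes=[r.gene for r in records],
        )
        by_group = {
            "total": records,
            "Top18": [r for r in records if grouping.group_of(r.gene) in ("Top7", "Top18")],
            "Low8": [r for r in records if grouping.group_of(r.gene) == "Low8"],
        }

    with stage("usage"):
        profiles, counts_by_scope = {}, {}
        for scope, recs in by_group.items():
            if not recs:
                continue
            counts = codon_stats.count_codons(recs, scope=scope)
            counts_by_scope[scope] = counts
            profiles[scope] = codon_stats.build_usage_profile(counts, config.pseudocount)
            emit(f"descriptors_{scope}", codon_stats.descriptor_frame(profiles[scope], counts))
            codon_stats.write_usage_table(counts, outdir / f"usage_table_{scope}.tsv")
            outputs[f"usage_table_{scope}"] = str(outdir / f"usage_table_{scope}.tsv")
        reference_scope = config.reference_group if config.reference_group in profiles else "total"
        reference_w = profiles[reference_scope].w
        classification = codon_stats.classify_codons(reference_w, config.w_threshold)
        emit(
            "optimal_codons",
            pd.DataFrame(
                {
                    "codon": sorted(classification.optimal | classification.non_optimal),
                }
            ).assign(
                optimal=lambda df: [c in classification.optimal for c in df.codon],
                w=lambda df: [reference_w[c] for c in df.codon],
            ),
        )

    with stage("cai"):
        rows = []
        for rec in records:
            score = codon_stats.cai(rec, reference_w)
            rows.append(
                {
                    "gene": rec.gene,
                    "group": grouping.group_of(rec.gene),
                    "fpkm": rec.fpkm if rec.fpkm is not None else math.nan,
                    "cai": score.cai,
                    "length_codons_used": score.length_codons_used,
                }
            )
        emit("cai", pd.DataFrame(rows))

    with stage("demand"):
        per_gene = {}
        fpkm_map = {}
        for rec in records:
            if rec.fpkm is None:
                continue
            key = rec.gene
            while key in per_gene:  # duplicated gene instances stay distinct
                key += "+"
            per_gene[key] = codon_stats.count_codons([rec], scope=key)
            fpkm_map[key] = rec.fpkm
        demand = codon_stats.codon_demand(per_gene, fpkm_map, scope="total")
        emit(
            "demand",
            pd.DataFrame(
                {"codon": list(demand.demand), "demand": list(demand.demand.values())}
            ),
        )
        top_keys = {k for k in per_gene if grouping.group_of(k.rstrip("+")) in ("Top7", "Top18")}
        low_keys = {k for k in per_gene if grouping.group_of(k.rstrip("+")) == "Low8"}
        if top_keys and low_keys:
            d_top = codon_stats.codon_demand(
                {k: per_gene[k] for k in top_keys}, fpkm_map, scope="Top18"
            )
            d_low = codon_stats.codon_demand(
                {k: per_gene[k] for k in low_keys}, fpkm_map, scope="Low8"
            )
            fold = codon_stats.demand_share_fold(d_top, d_low)
            by_kind = codon_stats.demand_fold_by_kind(fold)
            emit(
                "demand_fold_by_kind",
                pd.DataFrame(
                    {"kind": list(by_kind), "mean_fold_bias": list(by_kind.values())}
                ),
            )

    with stage("composition"):
        gc_rows = []
        for scope, recs in by_group.items():
            if not recs:
                continue
            gcp = composition.gc_by_position(recs)
            cds_gc = composition.gc_content("".join(r.nt_seq for r in recs))
            gc_rows.append(
                {
                    "scope": scope,
                    "cds_gc_pct": cds_gc,
                    "gc1_mean": gcp.gc1[0],
                    "gc1_sd": gcp.gc1[1],
                    "gc2_mean": gcp.gc2[0],
                    "gc2_sd": gcp.gc2[1],
                    "gc3_mean": gcp.gc3[0],
                    "gc3_sd": gcp.gc3[1],
                    "gc3_pooled": gcp.pooled[2],
                    "expected_gc3": composition.expected_gc3(cds_gc),
                }
            )
        emit("gc_summary", pd.DataFrame(gc_rows))
        gcp_total = composition.gc_by_position(records)
        emit(
            "gc_per_gene",
            pd.DataFrame(
                gcp_total.per_gene, columns=["gene", "gc1", "gc2", "gc3"]
            ),
        )
        fam_rows = []
        for scope, recs in by_group.items():
            if not recs:
                continue
            for kind, (mean, sd) in composition.gc3_by_family(recs).items():
                fam_rows.append({"scope": scope, "family": kind, "gc3_mean": mean, "gc3_sd": sd})
        emit("gc3_by_family", pd.DataFrame(fam_rows))
        profiles_aa = {
            scope: composition.aa_profile(recs, scope=scope)
            for scope, recs in by_group.items()
            if recs
        }
        emit(
            "aa_profile",
            pd.DataFrame(
                [
                    {"scope": scope, "amino_acid": aa, "per_1000": value}
                    for scope, prof in profiles_aa.items()
                    for aa, value in prof.freq_per_1000.items()
                ]
            ),
        )
        if "Top18" in profiles_aa and "Low8" in profiles_aa:
            changes = composition.aa_fold_change(
                profiles_aa["Top18"], profiles_aa["Low8"]
            )
            emit(
                "aa_fold_change",
                pd.DataFrame(
                    [
                        {"amino_acid": aa, "ratio": r, "significant": s}
                        for aa, (r, s) in changes.items()
                    ]
                ),
            )

    with stage("pairs"):
        scope_records = by_group["total"]
        counts = counts_by_scope["total"]
        pairs = codon_pairs.count_pairs(scope_records, scope="total")
        dipb = codon_pairs.dipeptide_bias(scope_records)
        rare = codon_pairs.classify_rare_codons(counts, config.poisson_threshold)
        result = codon_pairs.pair_bias(
            pairs, counts, dipb, mode=config.pair_mode, classification=rare
        )
        emit("pair_bias", result.to_frame())
        calls = codon_pairs.call_overrepresented(result, config.overrep_fold)
        emit(
            "pair_calls_overrepresented",
            pd.DataFrame(calls, columns=["codon1", "codon2", "bias"]),
        )
        under = codon_pairs.call_underrepresented(result, config.overrep_fold)
        emit(
            "pair_calls_underrepresented",
            pd.DataFrame(under, columns=["codon1", "codon2", "bias"]),
        )
        emit(
            "rare_codon_classification",
            pd.DataFrame(
                [
                    {"codon": c, "mean_p_le1": p, "model": rare.model_of(c)}
                    for c, p in rare.mean_p_le1.items()
                ]
            ),
        )
        if calls:
            junction = codon_pairs.junction_dinucleotides(calls)
            emit(
                "junction_dinucleotides",
                pd.DataFrame(
                    [
                        {"dinucleotide": d, "proportion": p}
                        for d, p in junction.proportions.items()
                    ]
                ),
            )
        oof = codon_pairs.scan_out_of_frame_stops(scope_records)
        with open(outdir / "out_of_frame_stops.json", "w") as fh:
            json.dump(oof, fh, indent=1)
        outputs["out_of_frame_stops"] = str(outdir / "out_of_frame_stops.json")
        repeats = codon_pairs.scan_repeats(scope_records)
        emit(
            "junction_repeats",
            pd.DataFrame(
                [
                    {
                        "k": k,
                        "kmer": kmer,
                        "count": n,
                        "expected": repeats.expected_count(kmer),
                    }
                    for k, counter in repeats.junction_counts.items()
                    for kmer, n in sorted(counter.items())
                ]
            ),
        )

    with stage("positional"):
        cluster_rows = []
        for rec in records:
            track = positional.flag_unfavorable(rec, classification)
            for call in positional.detect_clusters(
                track, config.cluster_window, config.cluster_min_count
            ):
                cluster_rows.append(
                    {
                        "gene": call.gene,
                        "start_codon": call.start_codon,
                        "end_codon": call.end_codon,
                        "n_unfavorable": call.n_unfavorable,
                    }
                )
        emit("clusters", pd.DataFrame(cluster_rows))
        ramp_groups = {
            scope: recs
            for scope, recs in by_group.items()
            if recs and any(len(r.nt_seq) > config.min_gene_len_nt for r in recs)
        }
        stats = positional.ramp_stats(
            ramp_groups, classification, config.ramp_len, config.min_gene_len_nt
        )
        emit("ramp", pd.DataFrame([asdict(s) for s in stats.values()]))
        profile_rows = []
        for scope, recs in by_group.items():
            eligible = [r for r in recs if len(r.sense_codons) >= config.ramp_len]
            if not eligible:
                continue
            prof = positional.cumulative_gc_profile(eligible, config.ramp_len)
            profile_rows.extend(
                {"scope": scope, "position": i + 1, "cumulative_gc": v}
                for i, v in enumerate(prof)
            )
        emit("cumulative_gc", pd.DataFrame(profile_rows))
        sd = positional.scan_sd_motifs(records)
        emit(
            "sd_motifs",
            pd.DataFrame(
                [
                    {"gene": gene, **counts}
                    for gene, counts in sd["per_gene"].items()
                ]
            ),
        )

    if config.pausing_table:
        with stage("pausing"):
            pause_records = pausing.read_pausing_table(config.pausing_table)
            rows = []
            for selection in ("P", "EP", "EPA"):
                means = pausing.mean_pausing_per_codon(pause_records, selection)
                by_box = pausing.relative_pausing_by_box(means, classification)
                for box in by_box.values():
                    rows.append({"selection": selection, **asdict(box)})
            emit("pausing_by_box", pd.DataFrame(rows))

    with stage("manifest"):
        manifest = {
            "version": __version__,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()
            },
            "inputs": {
                "genome": _sha256(config.genome),
                "annotations": _sha256(config.annotations),
                "expression": _sha256(config.expression),
            },
            "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
            "n_genes": len(records),
            "seed": config.seed,
        }
        if config.pausing_table:
            manifest["inputs"]["pausing_table"] = _sha256(config.pausing_table)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
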