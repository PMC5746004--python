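"""End-to-end orchestration: simulate -> call -> assemble -> annotate -> rank.

A run is pure given (config, seed): the same configuration reproduces every
numeric output.  Two scale profiles are provided: ``desk`` (200 kb genome,
60 TUs, 500 trees, 5k negatives) and ``paper`` (2.4 Mb, 413 TUs, 5000
trees, 270k negatives, slower).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .array_signal import call_probes, design_probes, segment
from .coverage_signal import detect_boundaries, gene_expression_table
from .features_rf import (
    SCALAR_FEATURES,
    build_feature_matrix,
    negative_features,
    sample_negatives,
    scalar_ranking,
    train_rank,
)
from .promoter import (
    PromoterMotifModel,
    extract_features,
    promoter_window_length,
    upstream_window,
)
from .sequtil import revcomp, slice1
from .srna import find_intergenic_expressed
from .synthetic import (
    SimConfig,
    generate_genome,
    simulate_coverage,
    simulate_gene_counts,
    simulate_probe_signals,
    truth_genes_frame,
)
from .terminator import classify_termination, find_terminators, termination_summary
from .tu_mapper import assemble_tus, tss_concordance, utr_stats

log = logging.getLogger("tumap")

PROFILES = {
    "desk": dict(genome_length=200_000, n_tus_per_class={"high": 20, "medium": 20, "low": 20},
                 n_convergent_pairs=4, n_trees=500, n_negatives=5000),
    "paper": dict(genome_length=2_400_000, n_tus_per_class={"high": 83, "medium": 153, "low": 177},
                  n_convergent_pairs=20, n_trees=5000, n_negatives=270_000),
}


@dataclass
class RunConfig:
    outdir: str | None = None
    seed: int = 0
    profile: str = "desk"
    fdr: float = 1e-4
    rpkm_threshold: float = 150.0
    n_train: int = 75
    scan_window: int = 100
    terminator_window: int = 200
    n_trees: int | None = None
    n_negatives: int | None = None
    sim: SimConfig | None = None
    # optional pre-computed inputs; when set they replace simulation outputs
    genome_path: str | None = None
    annotation_path: str | None = None
    probe_table_path: str | None = None
    coverage_plus_path: str | None = None
    coverage_minus_path: str | None = None
    counts_path: str | None = None
    write_outputs: bool = True

    def resolved(self) -> "RunConfig":
        prof = PROFILES[self.profile]
        cfg = replace(self)
        if cfg.n_trees is None:
            cfg.n_trees = prof["n_trees"]
        if cfg.n_negatives is None:
            cfg.n_negatives = prof["n_negatives"]
        if cfg.sim is None:
            cfg.sim = SimConfig(
                genome_length=prof["genome_length"],
                n_tus_per_class=dict(prof["n_tus_per_class"]),
                n_convergent_pairs=prof["n_convergent_pairs"],
                seed=cfg.seed,
            )
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _config_hash(cfg: RunConfig) -> str:
    d = dataclasses.asdict(cfg)
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _validate_paths(cfg: RunConfig) -> None:
    for name in ("genome_path", "annotation_path", "probe_table_path",
                 "coverage_plus_path", "coverage_minus_path", "counts_path"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{name}: {p}")


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and return the result bundle.

    The bundle carries every intermediate (truth, segments, intervals, TUs,
    promoter model and calls, terminator classes, importance report, sRNA
    candidates) plus the ``summary`` dict written to summary.json.
    """
    cfg = config.resolved()
    _validate_paths(cfg)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(name)s %(levelname)s %(message)s")
    outdir = io.ensure_dir(cfg.outdir) if cfg.outdir and cfg.write_outputs else None
    res: dict = {"config": cfg}

    stage = "simulate"
    try:
        if cfg.genome_path:
            _, genome = io.read_fasta(cfg.genome_path)
            truth = None
            genes = io.read_gff3_genes(cfg.annotation_path) if cfg.annotation_path else pd.DataFrame(
                columns=["gene_id", "strand", "start", "end"]
            )
        else:
            genome, truth = generate_genome(cfg.sim)
            genes = truth_genes_frame(truth)
        res.update(genome=genome, truth=truth, genes=genes)

        stage = "array"
        if cfg.probe_table_path:
            measurements = io.read_probe_table(cfg.probe_table_path)
            probes = None
        else:
            probes = design_probes(len(genome))
            measurements = simulate_probe_signals(
                genome, truth, probes, cfg.sim.noise_sd_log2, rng=np.random.default_rng(cfg.seed + 10)
            )
        calls = call_probes(measurements, fdr=cfg.fdr)
        segments = segment(calls)
        res.update(probe_calls=calls, segments=segments)
        log.info("array: %d probes, %d significant, %d segments",
                 len(calls), int(calls["significant"].sum()), len(segments))

        stage = "coverage"
        if cfg.coverage_plus_path and cfg.coverage_minus_path:
            coverage = {
                "+": io.read_bedgraph(cfg.coverage_plus_path, len(genome)),
                "-": io.read_bedgraph(cfg.coverage_minus_path, len(genome)),
            }
        else:
            coverage = simulate_coverage(truth, cfg.sim, rng=np.random.default_rng(cfg.seed + 20))
        intervals = detect_boundaries(coverage)
        if cfg.counts_path:
            counts = io.read_tsv(cfg.counts_path)
        else:
            counts = simulate_gene_counts(truth, cfg.sim, rng=np.random.default_rng(cfg.seed + 30))
            counts = counts.merge(genes[["gene_id"]], on="gene_id")
        expression = gene_expression_table(counts, threshold=cfg.rpkm_threshold)
        res.update(coverage=coverage, coverage_intervals=intervals, expression=expression)
        log.info("coverage: %d intervals, %d/%d genes expressed",
                 len(intervals), int(expression["expressed"].sum()), len(expression))

        stage = "tus"
        tus = assemble_tus(segments, intervals, genes)
        concordance = tss_concordance(tus)
        utrs = utr_stats(tus)
        res.update(tus=tus, concordance=concordance, utr_stats=utrs)

        stage = "promoters"
        model, promoter_calls, features = _promoter_stage(genome, tus, cfg)
        res.update(promoter_model=model, promoter_calls=promoter_calls, promoter_features=features)

        stage = "terminators"
        term_calls = _terminator_stage(genome, tus, cfg)
        term_summary = termination_summary([t for t in tus if not t.intergenic])
        res.update(terminator_calls=term_calls, termination_summary=term_summary)

        stage = "rf"
        report = _rf_stage(genome, genes, tus, promoter_calls, features, cfg)
        res["importance_report"] = report

        stage = "srna"
        candidates = find_intergenic_expressed(segments, genes)
        res["srna_candidates"] = candidates

        stage = "summary"
        summary = _summarize(res, cfg)
        res["summary"] = summary
        if outdir:
            _write_outputs(outdir, res, cfg)
    except Exception as exc:  # noqa: BLE001 - abort names the failing stage
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    return res


def _promoter_stage(genome, tus, cfg):
    win_len = promoter_window_length()  # 62 bp training windows
    ranked = sorted(
        [t for t in tus if t.tu_class in ("high", "medium") and not t.ambiguous_strand],
        key=lambda t: -t.fc,
    )
    windows = []
    for tu in ranked[: cfg.n_train]:
        try:
            windows.append(upstream_window(genome, tu.tss, tu.strand, win_len))
        except ValueError:
            continue
    model = None
    if len(windows) >= 10:
        model = PromoterMotifModel().fit(windows)
        log.info("promoter model: %s / %s, spacer mode %d, %.1f bits",
                 model.consensus35_, model.consensus10_, model.spacer_mode_, model.information_bits_)
    calls, features = {}, {}
    if model is not None:
        for tu in tus:
            try:
                window = upstream_window(genome, tu.tss, tu.strand, cfg.scan_window)
            except ValueError:
                continue
            call = model.scan(window, tu_id=tu.tu_id)
            if call is None:
                continue
            pos35_g, pos10_g = _window_to_genome(tu, call, cfg.scan_window)
            calls[tu.tu_id] = (call, pos35_g, pos10_g)
            if tu.first_gene_start is not None:
                try:
                    features[tu.tu_id] = extract_features(
                        genome, tu.strand, pos35_g, pos10_g, tu.tss, tu.first_gene_start
                    )
                except ValueError:
                    continue
    return model, calls, features


def _window_to_genome(tu, call, window_len):
    if tu.strand == "+":
        base = tu.tss - window_len - 1
        return base + call.pos35, base + call.pos10
    base = tu.tss + window_len + 1
    return base - call.pos35, base - call.pos10


def _terminator_stage(genome, tus, cfg):
    out = {}
    for tu in tus:
        anchor = tu.last_gene_end if tu.last_gene_end is not None else tu.tts
        if tu.strand == "+":
            wlo = max(1, anchor + 1 if tu.last_gene_end is not None else anchor - 50)
            whi = min(len(genome), anchor + cfg.terminator_window)
            window = slice1(genome, wlo, whi)
        else:
            whi = min(len(genome), anchor - 1 if tu.last_gene_end is not None else anchor + 50)
            wlo = max(1, anchor - cfg.terminator_window)
            window = revcomp(slice1(genome, wlo, whi))
        # two detection passes: polyT-anchored calls decide rho-independence
        # (a higher-scoring bare hairpin must not displace an overlapping
        # tailed call), bare hairpins support the stem-loop-only class
        full = find_terminators(window, strand=tu.strand, require_polyt=True)
        bare = find_terminators(window, strand=tu.strand, require_polyt=False)
        mapped = [_map_term_call(c, wlo, whi, tu.strand) for c in full + bare]
        tu.termination_class = classify_termination(tu, mapped, tus)
        out[tu.tu_id] = mapped
    return out


def _map_term_call(call, wlo, whi, strand):
    def m(pair):
        if pair is None:
            return None
        a, b = pair
        if strand == "+":
            return (wlo + a - 1, wlo + b - 1)
        return (whi - b + 1, whi - a + 1)

    def m_run(run):
        if run is None:
            return None
        start, length = run
        if strand == "+":
            return (wlo + start - 1, length)
        return (whi - (start + length - 1) + 1, length)

    return dataclasses.replace(
        call, stem5=m(call.stem5), loop=m(call.loop), stem3=m(call.stem3),
        polyT=m_run(call.polyT), polyA=m_run(call.polyA),
    )


def _rf_stage(genome, genes, tus, promoter_calls, features, cfg):
    rows = [(features[t.tu_id], t.tu_class) for t in tus if t.tu_id in features]
    if len(rows) < 10:
        log.warning("rf: only %d promoter rows, skipping", len(rows))
        return None
    footprints = []
    for _tu_id, (_call, p35, p10) in promoter_calls.items():
        lo = min(p35, p10) - 24
        hi = max(p35, p10) + 15
        footprints.append((max(1, lo), min(len(genome), hi)))
    try:
        negatives, starts = sample_negatives(
            genome, genes, footprints, cfg.n_negatives, seed=cfg.seed + 40
        )
    except ValueError as exc:
        log.warning("rf: %s", exc)
        return None
    # a raw intergenic k-mer has no annotated leader; draw leader_len from the
    # promoter pool so the feature is neutral for the negative class
    leader_pool = np.array([f.leader_len for f, _ in rows])
    neg_rng = np.random.default_rng(cfg.seed + 41)
    for w, ld in zip(negatives, neg_rng.choice(leader_pool, size=len(negatives))):
        rows.append((negative_features(w, leader_len=int(ld)), "negative"))
    X, y = build_feature_matrix(rows)
    return train_rank(X, y, n_trees=cfg.n_trees, seed=cfg.seed + 50)


def _summarize(res, cfg) -> dict:
    tus = res["tus"]
    counts = {}
    for tu in tus:
        counts[tu.tu_class] = counts.get(tu.tu_class, 0) + 1
    report = res.get("importance_report")
    model = res.get("promoter_model")
    summary = {
        "provenance": {
            "seed": cfg.seed,
            "profile": cfg.profile,
            "config_hash": _config_hash(cfg),
            "package": "tumap 0.1.0",
        },
        "n_tus": len(tus),
        "tu_class_counts": counts,
        "mean_tu_length": float(np.mean([t.length for t in tus])) if tus else None,
        "termination": res.get("termination_summary"),
        "utr_stats": res.get("utr_stats"),
        "tss_concordance": res.get("concordance", {}).get("summary"),
        "promoter_model": None
        if model is None
        else {
            "consensus35": model.consensus35_,
            "consensus10": model.consensus10_,
            "spacer_mode": model.spacer_mode_,
            "information_bits": model.information_bits_,
            "low_information": bool(model.low_information_),
        },
        "n_promoter_calls": len(res.get("promoter_calls", {})),
        "importance": None
        if report is None
        else {
            "scalar_ranking": scalar_ranking(report),
            "top_positions": report.positional[:10],
            "oob_error_3class": report.oob_error_3class,
            "oob_error_all": report.oob_error_all,
        },
        "n_srna_candidates": len(res.get("srna_candidates", [])),
        "n_expressed_genes": int(res["expression"]["expressed"].sum()),
    }
    return summary


def _write_outputs(outdir: Path, res: dict, cfg: RunConfig) -> None:
    genome = res["genome"]
    io.write_fasta(outdir / "genome.fasta", genome)
    if res["truth"] is not None:
        recs = []
        for tu in res["truth"]:
            lo, hi = tu.span
            recs.append({"type": "transcriptional_unit", "start": lo, "end": hi, "strand": tu.strand,
                         "attrs": {"ID": tu.tu_id, "class": tu.tu_class, "fc": f"{tu.fc:.3f}",
                                   "tss": tu.tss, "tts": tu.tts}})
            p35, p10, sp = tu.promoter
            lo35, hi35 = sorted((p35, p35 + 5 if tu.strand == "+" else p35 - 5))
            recs.append({"type": "promoter", "start": lo35, "end": hi35, "strand": tu.strand,
                         "attrs": {"Parent": tu.tu_id, "spacer": sp}})
            if tu.terminator:
                t35, loop_len, stem_len, polyt, has_a = tu.terminator
                recs.append({"type": "terminator", "start": min(t35, polyt), "end": max(t35, polyt),
                             "strand": tu.strand,
                             "attrs": {"Parent": tu.tu_id, "stem_len": stem_len, "polyA": str(has_a)}})
        io.write_gff3(outdir / "truth.gff3", recs)
    io.write_tsv(outdir / "genes.tsv", res["genes"], comment="gene annotation; 1-based inclusive")
    io.write_probe_table(outdir / "probes.tsv", res["probe_calls"])
    io.write_bedgraph(outdir / "coverage_plus.bedgraph", res["coverage"]["+"])
    io.write_bedgraph(outdir / "coverage_minus.bedgraph", res["coverage"]["-"])
    io.write_tsv(outdir / "expression.tsv", res["expression"], comment="per-gene RPKM")
    io.write_bed6(
        outdir / "segments.bed",
        [(s.start, s.end, f"seg{i}", min(s.mean_fc * 10, 1000), s.strand) for i, s in enumerate(res["segments"])],
    )
    seg_df = pd.DataFrame(
        [(s.strand, s.start, s.end, s.mean_fc, s.n_probes) for s in res["segments"]],
        columns=["strand", "start", "end", "mean_fc", "n_probes"],
    )
    io.write_tsv(outdir / "segments.tsv", seg_df, comment="transcribed segments; 1-based inclusive")
    io.write_bed6(
        outdir / "coverage_intervals.bed",
        [(iv.start, iv.end, f"cov{i}", 0.0, iv.strand) for i, iv in enumerate(res["coverage_intervals"])],
    )
    tu_recs = []
    tu_rows = []
    for tu in res["tus"]:
        lo, hi = tu.span
        tu_recs.append({"type": "transcriptional_unit", "start": lo, "end": hi, "strand": tu.strand,
                        "score": tu.fc,
                        "attrs": {"ID": tu.tu_id, "class": tu.tu_class, "tss_source": tu.tss_source,
                                  "termination": tu.termination_class or "NA"}})
        tu_rows.append((tu.tu_id, tu.strand, tu.tss, tu.tts, ",".join(tu.genes), tu.fc, tu.tu_class,
                        tu.utr5_len, tu.utr3_len, tu.tss_source, tu.termination_class))
    io.write_gff3(outdir / "tus.gff3", tu_recs)
    io.write_tsv(outdir / "tus.tsv", pd.DataFrame(
        tu_rows, columns=["tu_id", "strand", "tss", "tts", "genes", "fc", "class",
                          "utr5_len", "utr3_len", "tss_source", "termination_class"]),
        comment="transcriptional units; 1-based inclusive")
    model = res.get("promoter_model")
    if model is not None:
        (outdir / "promoter_model.json").write_text(model.to_json())
    prom_recs = []
    for tu_id, (call, p35, p10) in res.get("promoter_calls", {}).items():
        strand = "+" if p35 < p10 else "-"
        lo35, hi10 = (p35, p10 + 5) if strand == "+" else (p10 - 5, p35)
        prom_recs.append({"type": "promoter", "start": lo35, "end": hi10, "strand": strand,
                          "score": call.score,
                          "attrs": {"Parent": tu_id, "spacer": call.spacer_len,
                                    "dist10_tss": call.dist10_tss}})
    io.write_gff3(outdir / "promoters.gff3", prom_recs)
    term_recs, term_rows = [], []
    for tu_id, calls in res.get("terminator_calls", {}).items():
        for c in calls:
            lo, hi = min(c.start, c.end), max(c.start, c.end)
            kind = "rho_independent" if c.polyT else "stem_loop"
            term_recs.append({"type": "terminator", "start": lo, "end": hi, "strand": c.strand,
                              "score": c.score,
                              "attrs": {"Parent": tu_id, "class": kind,
                                        "bidirectional": str(c.bidirectional)}})
            term_rows.append((tu_id, c.strand, lo, hi, c.stem_len, c.loop_len,
                              round(c.stem_gc, 3), kind, c.bidirectional, c.score))
    io.write_gff3(outdir / "terminators.gff3", term_recs)
    io.write_tsv(outdir / "terminators.tsv", pd.DataFrame(
        term_rows, columns=["tu_id", "strand", "start", "end", "stem_len", "loop_len",
                            "stem_gc", "class", "bidirectional", "score"]),
        comment="terminator calls; 1-based inclusive")
    feat_rows = []
    for tu_id, f in res.get("promoter_features", {}).items():
        feat_rows.append((tu_id, f.spacer_len, f.leader_len, f.at_up35, f.at_35, f.at_spacer,
                          f.at_10, f.at_down10, f.aligned_bases))
    io.write_tsv(outdir / "promoter_features.tsv", pd.DataFrame(
        feat_rows, columns=["tu_id"] + SCALAR_FEATURES + ["aligned_bases"]),
        comment="promoter feature vectors (62-column gapped alignment); 1-based inclusive")
    srna_rows = [(c.strand, c.start, c.end, c.length, c.mean_fc, c.context) for c in res["srna_candidates"]]
    io.write_tsv(outdir / "srna_candidates.tsv", pd.DataFrame(
        srna_rows, columns=["strand", "start", "end", "length", "mean_fc", "context"]),
        comment="intergenic expressed segments; 1-based inclusive")
    srna_recs = [{"type": "ncRNA", "start": c.start, "end": c.end, "strand": c.strand,
                  "score": c.mean_fc, "attrs": {"context": c.context, "length": c.length}}
                 for c in res["srna_candidates"]]
    io.write_gff3(outdir / "srna_candidates.gff3", srna_recs)
    report = res.get("importance_report")
    if report is not None:
        io.write_tsv(outdir / "rf_report.tsv", pd.DataFrame(
            report.features, columns=["feature", "importance"]),
            comment="feature importances (mean impurity decrease)")
        (outdir / "rf_report.json").write_text(json.dumps({
            "features": report.features[:100],
            "positional": report.positional,
            "oob_error_3class": report.oob_error_3class,
            "oob_error_all": report.oob_error_all,
            "n_trees": report.n_trees,
        }, indent=2))
    (outdir / "summary.json").write_text(json.dumps(res["summary"], indent=2, default=str))
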