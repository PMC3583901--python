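"""End-to-end orchestration: simulate/load -> preprocess -> map -> annotate
-> discover -> quantify -> test -> report.

A single :class:`PipelineConfig` drives every stage; with fixed seeds the
full run is deterministic and re-running writes byte-identical outputs.
Outputs land in a run directory with a MANIFEST and a run log that echoes
all parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import hairpin_discovery as hd
from . import mapping as mp
from . import preprocess as pp
from . import quantification as qt
from . import synthetic_data as sd

logger = logging.getLogger("mirnome")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline parameters in one place.

    Either ``simulation`` (synthetic mode) or the external input paths
    (``genome_path``, ``annotations_path``, ``reads_paths`` with
    ``library_groups``) must be provided.
    """

    output_dir: str = "mirnome_run"
    simulation: sd.SimulationConfig | None = None
    genome_path: str | None = None
    annotations_path: str | None = None
    reads_paths: dict[str, str] = field(default_factory=dict)
    library_groups: dict[str, str] = field(default_factory=dict)
    thresholds: hd.DiscoveryThresholds = field(default_factory=hd.DiscoveryThresholds)
    min_prefix_match: int = 6
    min_polya_tail: int = 4
    index_k: int = 18
    min_overlap_frac: float = 0.5
    pseudocount: float = 1.0
    cutoff_fraction: float = qt.CUTOFF_FRACTION
    fc_threshold: float = qt.FOLD_CHANGE_THRESHOLD
    adapter_seq: str | None = None     # defaults to the simulation adapter
    seed: int = 42
    write_reads: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = raw["simulation"]
            if isinstance(sim.get("polya_len_range"), list):
                sim["polya_len_range"] = tuple(sim["polya_len_range"])
            if isinstance(sim.get("insert_len_range"), list):
                sim["insert_len_range"] = tuple(sim["insert_len_range"])
            raw["simulation"] = sd.SimulationConfig(**sim)
        if "thresholds" in raw and raw["thresholds"] is not None:
            th = raw["thresholds"]
            for k in ("window_sizes", "median_len_range", "gc_range"):
                if isinstance(th.get(k), list):
                    th[k] = tuple(th[k])
            raw["thresholds"] = hd.DiscoveryThresholds(**th)
        return cls(**raw)

    def validate(self) -> None:
        if self.simulation is None:
            for label, p in [("genome_path", self.genome_path),
                             ("annotations_path", self.annotations_path)]:
                if p is None:
                    raise ValueError(f"{label} required when no simulation "
                                     "config is given")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{label}: {p} does not exist")
            for lib, p in self.reads_paths.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"reads for {lib}: {p} does not exist")
                if lib not in self.library_groups:
                    raise ValueError(f"library {lib} has no group label")
            if not self.reads_paths:
                raise ValueError("no read libraries configured")
            if self.adapter_seq is None:
                raise ValueError("adapter_seq required for external reads")


@dataclass
class PipelineResult:
    config: PipelineConfig
    composition: ann.CompositionReport
    candidates: list[hd.HairpinCandidate]
    matrix: qt.ExpressionMatrix
    retained: list[str]
    differential: qt.DifferentialResult
    report: pd.DataFrame
    summary: dict
    truth: sd.GroundTruth | None = None


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler)
               for h in logger.handlers):
        logger.addHandler(logging.StreamHandler())
    logger.setLevel(logging.INFO)
    return handler


def _mirna_name_for(aln: mp.Alignment, index: ann.AnnotationIndex,
                    min_overlap_frac: float) -> str | None:
    best, best_olap = None, 0
    for row in index.overlapping(aln.contig, aln.start, aln.end):
        if row["klass"] != "miRNA_known" or row["strand"] != aln.strand:
            continue
        olap = min(aln.end, row["end"]) - max(aln.start, row["start"])
        if olap >= min_overlap_frac * (aln.end - aln.start) and olap > best_olap:
            best, best_olap = row["name"], olap
    return best


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    manifest: list[str] = []
    try:
        return _run(config, outdir, manifest)
    finally:
        (outdir / "MANIFEST.txt").write_text("\n".join(manifest) + "\n")
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path, manifest: list[str]
         ) -> PipelineResult:
    logger.info("parameters: %s", json.dumps(
        dataclasses.asdict(config), default=str, sort_keys=True))

    # --- stage 1: inputs -------------------------------------------------
    truth = None
    if config.simulation is not None:
        sim = config.simulation
        logger.info("simulating genome (%d bp) and %d libraries",
                    sim.genome_length, len(sim.library_ids))
        genome_seq, annotations, truth = sd.build_genome(sim)
        genome = {sim.contig_name: genome_seq}
        raw_libraries = sd.simulate_all_libraries(truth, sim)
        groups = {lib: sim.group_of(lib) for lib in sim.library_ids}
        adapter = sim.adapter_seq
        sd.write_genome_fasta(genome_seq, outdir / "genome.fa", sim.contig_name)
        ann.write_gff3(annotations, outdir / "annotations.gff3")
        sd.write_truth_tsv(truth, outdir / "truth.tsv")
        manifest += ["genome.fa", "annotations.gff3", "truth.tsv"]
        if config.write_reads:
            reads_dir = outdir / "reads"
            reads_dir.mkdir(exist_ok=True)
            for lib, reads in raw_libraries.items():
                sd.write_fastq(reads, reads_dir / f"{lib}.fastq")
                manifest.append(f"reads/{lib}.fastq")
    else:
        from pyfaidx import Fasta
        fa = Fasta(str(config.genome_path))
        genome = {name: str(fa[name][:]) for name in fa.keys()}
        annotations = ann.read_gff3(config.annotations_path)
        raw_libraries = {lib: pp.read_sequences(p)
                         for lib, p in config.reads_paths.items()}
        groups = dict(config.library_groups)
        adapter = config.adapter_seq

    # --- stage 2: preprocess ---------------------------------------------
    lib_ids = list(raw_libraries)
    per_insert: dict[str, dict[str, int]] = {}
    for lib, reads in raw_libraries.items():
        collapsed, stats = pp.preprocess_reads(
            reads, adapter, config.min_prefix_match, config.min_polya_tail)
        logger.info("preprocess %s: %d reads -> %d kept, %d unique",
                    lib, stats.n_input, stats.n_kept, stats.n_unique)
        for cr in collapsed:
            per_insert.setdefault(cr.insert_seq, {})[lib] = cr.count

    pooled = [pp.CollapsedRead(s, sum(c.values()))
              for s, c in per_insert.items()]
    pooled.sort(key=lambda cr: (-cr.count, cr.insert_seq))
    pp.write_collapsed_fasta(pooled, outdir / "collapsed.fa")
    pp.write_collapsed_tsv(pooled, outdir / "collapsed.tsv")
    manifest += ["collapsed.fa", "collapsed.tsv"]

    # --- stage 3: map ----------------------------------------------------
    logger.info("building %d-mer index over %d contig(s)",
                config.index_k, len(genome))
    index = mp.build_index(genome, config.index_k)
    aln_by_insert = mp.map_reads(pooled, index, config.thresholds.max_loci)
    all_alignments = [a for alns in aln_by_insert.values() for a in alns]
    mp.write_bed(all_alignments, outdir / "alignments.bed")
    mp.write_alignment_tsv(all_alignments, outdir / "alignments.tsv")
    manifest += ["alignments.bed", "alignments.tsv"]

    mapped_totals = pd.Series({
        lib: sum(cnt.get(lib, 0) for s, cnt in per_insert.items()
                 if aln_by_insert.get(s))
        for lib in lib_ids}, dtype=float)
    logger.info("mapped totals per library: %s", mapped_totals.to_dict())

    # --- stage 4: annotate -----------------------------------------------
    ann_index = ann.AnnotationIndex(annotations)
    class_of: dict[tuple[str, int, int, str], str] = {}
    classified = []
    for s, alns in aln_by_insert.items():
        for a in alns:
            key = (a.contig, a.start, a.end, a.strand)
            if key not in class_of:
                class_of[key] = ann.classify_alignment(a, ann_index,
                                                       config.min_overlap_frac)
            for lib, cnt in per_insert[s].items():
                la = mp.Alignment(a.read_ref, a.contig, a.start, a.end,
                                  a.strand, a.n_hits, float(cnt))
                classified.append((la, class_of[key], lib))
    composition = ann.composition(classified)
    composition.fractions.to_csv(outdir / "composition.tsv", sep="\t")
    manifest.append("composition.tsv")
    if "pooled" in composition.fractions.index:
        logger.info("pooled composition: %s",
                    composition.pooled().round(4).to_dict())

    # --- stage 5: discovery ----------------------------------------------
    gated = [a for alns in aln_by_insert.values() for a in alns
             if ann.discovery_gate(class_of[(a.contig, a.start, a.end, a.strand)])]
    logger.info("discovery gate: %d of %d alignments pass",
                len(gated), len(all_alignments))
    candidates = hd.discover_hairpins(
        gated, genome, config.thresholds, seed=config.seed,
        known_annotations=ann_index)
    _write_candidates(candidates, outdir)
    manifest += ["candidates.tsv", "candidates.gff3", "candidates.dot_bracket.txt"]
    conf_counts = {level: sum(c.confidence == level for c in candidates)
                   for level in ("confident", "candidate", "non_confident")}
    logger.info("candidates by confidence: %s", conf_counts)

    # --- stage 6: quantification -----------------------------------------
    counts: dict[str, dict[str, float]] = {}
    for s, alns in aln_by_insert.items():
        if not alns:
            continue
        for a in alns:
            if class_of[(a.contig, a.start, a.end, a.strand)] != "miRNA_known":
                continue
            name = _mirna_name_for(a, ann_index, config.min_overlap_frac)
            if name is None:
                continue
            row = counts.setdefault(name, {})
            for lib, cnt in per_insert[s].items():
                row[lib] = row.get(lib, 0.0) + cnt / a.n_hits
    for cand in candidates:
        if cand.confidence != "confident" or cand.status != "novel":
            continue
        row = counts.setdefault(cand.candidate_id, {})
        for a in cand_block_alignments(cand, gated):
            for lib, cnt in per_insert.get(a.read_ref, {}).items():
                row[lib] = row.get(lib, 0.0) + cnt / a.n_hits

    raw = pd.DataFrame(counts).T.reindex(columns=lib_ids).fillna(0.0)
    raw = raw.sort_index()
    matrix = qt.normalize_rpm(raw, mapped_totals, groups)
    matrix.values.to_csv(outdir / "expression_rpm.tsv", sep="\t")
    manifest.append("expression_rpm.tsv")

    retained = (qt.mir195_cutoff(matrix, fraction=config.cutoff_fraction)
                if qt.MIR195 in matrix.values.index else [])
    diff = qt.group_tests(matrix, config.pseudocount)
    report = qt.table_s3_report(diff, matrix, retained=retained or None,
                                pseudocount=config.pseudocount,
                                fc_threshold=config.fc_threshold)
    diff.table.to_csv(outdir / "differential.tsv", sep="\t")
    report.to_csv(outdir / "report.tsv", sep="\t", index=False)
    manifest += ["differential.tsv", "report.tsv"]

    # --- summary ----------------------------------------------------------
    # specificity is assessed on the abundance-retained set, mirroring the
    # cutoff-then-threshold order of the analysis
    flags = qt.etiology_specific(qt.fold_changes(matrix, config.pseudocount),
                                 threshold=config.fc_threshold)
    if retained:
        flags = flags.loc[flags.index.isin(retained)]
    known_detected = sorted(n for n in matrix.values.index
                            if not n.startswith("hairpin-"))
    summary = {
        "libraries": lib_ids,
        "mapped_totals": {k: float(v) for k, v in mapped_totals.items()},
        "composition_pooled": (composition.pooled().round(6).to_dict()
                               if "pooled" in composition.fractions.index else {}),
        "candidates_by_confidence": conf_counts,
        "novel_candidates": [c.candidate_id for c in candidates
                             if c.status == "novel"
                             and c.confidence in ("confident", "candidate")],
        "known_mirnas_detected": known_detected,
        "n_retained_after_cutoff": len(retained),
        "retained_after_cutoff": sorted(retained),
        "n_hcm_specific": int(flags["hcm_specific"].sum()),
        "n_dcm_specific": int(flags["dcm_specific"].sum()),
        "seed": config.seed,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest.append("summary.json")
    logger.info("summary: %d known miRNAs detected, %d retained after cutoff, "
                "%d HCM-specific, %d DCM-specific", len(known_detected),
                len(retained), summary["n_hcm_specific"], summary["n_dcm_specific"])

    return PipelineResult(config=config, composition=composition,
                          candidates=candidates, matrix=matrix,
                          retained=retained, differential=diff, report=report,
                          summary=summary, truth=truth)


def cand_block_alignments(cand: hd.HairpinCandidate,
                          alignments: list[mp.Alignment]) -> list[mp.Alignment]:
    """Alignments belonging to a candidate's mature-arm block."""
    return [a for a in alignments
            if a.contig == cand.contig and a.strand == cand.strand
            and a.start >= cand.block_start and a.end <= cand.block_end]


def _write_candidates(candidates: list[hd.HairpinCandidate], outdir: Path) -> None:
    rows = []
    for c in candidates:
        rows.append({
            "candidate_id": c.candidate_id, "contig": c.contig,
            "strand": c.strand, "window_start": c.window_start,
            "window_end": c.window_end, "window_size": c.window_size,
            "block_start": c.block_start, "block_end": c.block_end,
            "arm": c.arm, "n_reads": c.n_reads,
            "median_read_len": c.median_read_len,
            "start_heterogeneity": round(c.start_heterogeneity, 4),
            "end_heterogeneity": round(c.end_heterogeneity, 4),
            "gc_content": round(c.gc_content, 4),
            "dicer_overhang": c.dicer_overhang,
            "randfold_p": c.randfold_p if c.randfold_p is not None else "",
            "fold_score": c.fold.score, "shape": c.fold.shape,
            "confidence": c.confidence, "status": c.status,
        })
    pd.DataFrame(rows).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    with open(outdir / "candidates.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for c in candidates:
            attrs = (f"ID={c.candidate_id};confidence={c.confidence};"
                     f"status={c.status}")
            fh.write(f"{c.contig}\tmirnome\tmiRNA_primary_transcript\t"
                     f"{c.window_start + 1}\t{c.window_end}\t.\t{c.strand}\t.\t"
                     f"{attrs}\n")
            fh.write(f"{c.contig}\tmirnome\tmiRNA\t{c.block_start + 1}\t"
                     f"{c.block_end}\t.\t{c.strand}\t.\t"
                     f"ID={c.candidate_id}.mature;Parent={c.candidate_id}\n")
    with open(outdir / "candidates.dot_bracket.txt", "w") as fh:
        for c in candidates:
            fh.write(f">{c.candidate_id} {c.contig}:{c.window_start}-"
                     f"{c.window_end}({c.strand}) score={c.fold.score} "
                     f"shape={c.fold.shape}\n{c.fold.sequence}\n"
                     f"{c.fold.dot_bracket}\n")
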