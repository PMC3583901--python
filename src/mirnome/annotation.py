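"""Annotation-class triage of mapped reads and library composition.

Each alignment is assigned exactly one class using a fixed precedence
(known miRNA first, then the structural ncRNA classes, exon, repeat,
intron, intergenic).  Only intergenic, intronic and repeat-derived reads
pass the discovery gate; known-miRNA reads go to known-miRNA
quantification and the other ncRNA classes are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .mapping import Alignment

# highest first; intergenic is the implicit fallback
CLASS_PRECEDENCE = ["miRNA_known", "rRNA", "tRNA", "snRNA", "snoRNA",
                    "siRNA_other", "exon", "repeat", "intron"]
_RANK = {c: i for i, c in enumerate(CLASS_PRECEDENCE)}

STRAND_AWARE_CLASSES = {"miRNA_known", "rRNA", "tRNA", "snRNA", "snoRNA",
                        "siRNA_other"}
DISCOVERY_CLASSES = {"intergenic", "intron", "repeat"}

NCRNA_CLASSES = {"rRNA", "tRNA", "snRNA", "snoRNA", "siRNA_other"}

__all__ = ["AnnotationIndex", "CompositionReport", "classify_alignment",
           "discovery_gate", "composition", "read_gff3", "write_gff3",
           "CLASS_PRECEDENCE", "DISCOVERY_CLASSES", "NCRNA_CLASSES"]


class AnnotationIndex:
    """Interval lookup over an annotation table.

    Expects a DataFrame with columns contig, start, end (0-based
    half-open), strand, klass, name.
    """

    def __init__(self, annotations: pd.DataFrame):
        self.table = annotations.reset_index(drop=True)
        self._records = self.table.to_dict("records")
        self._trees: dict[str, IntervalTree] = {}
        for idx, row in enumerate(self._records):
            if row["start"] < row["end"]:
                self._trees.setdefault(row["contig"], IntervalTree()).addi(
                    int(row["start"]), int(row["end"]), idx)

    def overlapping(self, contig: str, start: int, end: int) -> list[dict]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return [self._records[iv.data]
                for iv in sorted(tree.overlap(start, end))]


@dataclass
class CompositionReport:
    """Per-class fractions of mapped reads, per library and pooled."""

    fractions: pd.DataFrame  # rows = libraries (+ "pooled"), cols = classes

    def pooled(self) -> pd.Series:
        return self.fractions.loc["pooled"]


def classify_alignment(aln: Alignment, index: AnnotationIndex,
                       min_overlap_frac: float = 0.5) -> str:
    """Highest-precedence class among annotations overlapping at least
    ``min_overlap_frac`` of the read.

    Strand-aware for the miRNA and ncRNA classes; repeats, exons and
    introns match regardless of strand (repeat annotations are typically
    unstranded).
    """
    read_len = aln.end - aln.start
    min_olap = min_overlap_frac * read_len
    best: str | None = None
    for row in index.overlapping(aln.contig, aln.start, aln.end):
        olap = min(aln.end, row["end"]) - max(aln.start, row["start"])
        if olap < min_olap:
            continue
        klass = row["klass"]
        if klass in STRAND_AWARE_CLASSES and row["strand"] != aln.strand:
            continue
        if best is None or _RANK.get(klass, len(_RANK)) < _RANK.get(best, len(_RANK)):
            best = klass
    return best if best is not None else "intergenic"


def discovery_gate(klass: str) -> bool:
    """True for reads usable in de-novo hairpin discovery: intergenic,
    intronic and repeat-derived.  Known-miRNA reads are quantified as
    known; the other ncRNA classes are excluded altogether."""
    return klass in DISCOVERY_CLASSES


def composition(classified: list[tuple[Alignment, str, str]]) -> CompositionReport:
    """Count-weighted class composition of the mapped reads.

    ``classified`` holds (alignment, class, library) triples; multi-mapped
    reads contribute fractional weight count/n_hits per placement so that
    class fractions sum to 1 per library.
    """
    rows = [{"library": lib, "klass": klass, "weight": a.count / max(a.n_hits, 1)}
            for a, klass, lib in classified]
    if not rows:
        return CompositionReport(fractions=pd.DataFrame())
    df = pd.DataFrame(rows)
    table = df.pivot_table(index="library", columns="klass", values="weight",
                           aggfunc="sum", fill_value=0.0)
    pooled = table.sum(axis=0).to_frame().T
    pooled.index = ["pooled"]
    table = pd.concat([table, pooled])
    fractions = table.div(table.sum(axis=1), axis=0)
    return CompositionReport(fractions=fractions)


# ---------------------------------------------------------------------------
# GFF3 I/O (1-based inclusive on disk, 0-based half-open in memory)

_GFF_COLUMNS = ["contig", "source", "type", "start", "end", "score",
                "strand", "phase", "attributes"]


def read_gff3(path) -> pd.DataFrame:
    gff = pd.read_csv(path, sep="\t", comment="#", header=None,
                      names=_GFF_COLUMNS, dtype={"start": int, "end": int})
    records = []
    for _, row in gff.iterrows():
        attrs = dict(kv.split("=", 1) for kv in str(row["attributes"]).split(";")
                     if "=" in kv)
        records.append({
            "contig": row["contig"],
            "start": int(row["start"]) - 1,   # to 0-based half-open
            "end": int(row["end"]),
            "strand": row["strand"],
            "klass": attrs.get("class", row["type"]),
            "name": attrs.get("Name", attrs.get("ID", "")),
        })
    return pd.DataFrame(records,
                        columns=["contig", "start", "end", "strand", "klass", "name"])


def write_gff3(annotations: pd.DataFrame, path, source: str = "mirnome") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, row in annotations.reset_index(drop=True).iterrows():
            attrs = f"ID=ann{i + 1};Name={row['name']};class={row['klass']}"
            fh.write(f"{row['contig']}\t{source}\t{row['klass']}\t"
                     f"{row['start'] + 1}\t{row['end']}\t.\t{row['strand']}"
                     f"\t.\t{attrs}\n")
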