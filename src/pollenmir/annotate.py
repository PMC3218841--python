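"""Hierarchical annotation of mapped small RNA tags.

Every genome-matched tag resolves to exactly one class through a fixed
precedence cascade, reproducing the conventional small RNA cleanup order:
structural ncRNA first (rRNA/tRNA/snRNA/snoRNA fragments dominate these
libraries and are discarded), then known miRNA hairpins, then gene regions
(sense before antisense, exon before intron), then annotated repeats.
Whatever remains is "unannotated" and feeds novel-miRNA prediction.

Known-miRNA hairpin overlap outranks exon overlap so that hairpins residing
inside genes are not lost to the mRNA filter.  ncRNA and repeat overlap are
strand-blind (degraded structural RNA and repeat-derived siRNAs occur on
both strands); exon/intron classes are strand-aware because sense and
antisense gene-derived reads are accounted separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .mapping import MappedTag

NCRNA_CLASSES = frozenset({"rRNA", "tRNA", "snRNA", "snoRNA"})

#: tag classes in precedence order
CLASS_ORDER = [
    "ncRNA", "known_miRNA",
    "exon_sense", "exon_antisense",
    "intron_sense", "intron_antisense",
    "repeat_associated", "unannotated",
]

#: classes retained as candidates for miRNA identification
CANDIDATE_CLASSES = ["known_miRNA", "repeat_associated", "unannotated"]


@dataclass(frozen=True)
class TagAnnotation:
    sequence: str
    cls: str
    feature_ids: tuple


class FeatureIndex:
    """Interval lookup over an annotation table.

    ``features`` needs columns chrom, start, end (0-based half-open),
    strand, cls (rRNA/tRNA/snRNA/snoRNA/exon/intron/repeat/miRNA_hairpin)
    and feature_id.
    """

    def __init__(self, features: pd.DataFrame):
        bad = features[features["end"] <= features["start"]]
        if len(bad):
            raise ValueError(f"{len(bad)} features with end <= start")
        self._trees: dict[str, IntervalTree] = {}
        for chrom, sub in features.groupby("chrom"):
            tree = IntervalTree()
            for row in sub.itertuples():
                tree.addi(int(row.start), int(row.end),
                          (row.cls, row.strand, row.feature_id))
            self._trees[chrom] = tree

    def overlaps(self, chrom: str, start: int, end: int):
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def classify_tag(tag: MappedTag, features: FeatureIndex) -> TagAnnotation:
    """Resolve one mapped tag to its single annotation class.

    Overlap means >= 1 shared base at any of the tag's genomic hits.  The
    class is the first matching category in precedence order; supporting
    feature ids are collected for that class only.
    """
    if tag.n_loci == 0:
        raise ValueError(f"tag {tag.sequence} is unmapped; caller must exclude it")
    support: dict[str, set] = {c: set() for c in CLASS_ORDER[:-1]}
    for hit in tag.hits:
        for cls, fstrand, fid in features.overlaps(hit.chrom, hit.start, hit.end):
            if cls in NCRNA_CLASSES:
                support["ncRNA"].add(fid)
            elif cls == "miRNA_hairpin":
                if fstrand == hit.strand:
                    support["known_miRNA"].add(fid)
            elif cls in ("exon", "intron"):
                rel = "sense" if fstrand == hit.strand else "antisense"
                support[f"{cls}_{rel}"].add(fid)
            elif cls == "repeat":
                support["repeat_associated"].add(fid)
    for cls in CLASS_ORDER[:-1]:
        if support[cls]:
            return TagAnnotation(tag.sequence, cls, tuple(sorted(support[cls])))
    return TagAnnotation(tag.sequence, "unannotated", ())


def classify_all(mapped: list[MappedTag], features: FeatureIndex):
    """Classify every mapped tag; returns ``{sequence: TagAnnotation}``."""
    return {mt.sequence: classify_tag(mt, features)
            for mt in mapped if mt.n_loci > 0}


def quantify_known_mirnas(mapped: list[MappedTag],
                          precursors: dict[str, str],
                          mature_coords: dict[str, tuple],
                          meta: pd.DataFrame | None = None,
                          tol: int = 2) -> pd.DataFrame:
    """Count reads per known miRNA from tags aligning inside its precursor.

    A tag counts toward the mature miRNA when it occurs in the precursor
    with its 5' end within ``tol`` nt of the annotated mature 5' end and a
    length within ``tol`` nt of the mature length (isomiR allowance).
    Tags elsewhere in the precursor count to the hairpin but not the
    mature.  Returns one row per miRNA with per-library mature counts,
    hairpin-other counts, total and the set of libraries with >= 1 read.
    """
    libs: list[str] = []
    for mt in mapped:
        libs = list(mt.counts)
        break
    for mid, (m0, m1) in mature_coords.items():
        prec = precursors[mid]
        if not (0 <= m0 < m1 <= len(prec)):
            raise ValueError(f"mature coordinates of {mid} outside precursor")
    rows = {}
    for mid in precursors:
        rows[mid] = {f"mature_{lib}": 0 for lib in libs}
        rows[mid].update({f"hairpin_{lib}": 0 for lib in libs})
    for mt in mapped:
        if mt.n_loci == 0:
            continue
        for mid, prec in precursors.items():
            pos = prec.find(mt.sequence)
            if pos < 0:
                continue
            m0, m1 = mature_coords[mid]
            is_mature = (abs(pos - m0) <= tol
                         and abs(len(mt.sequence) - (m1 - m0)) <= tol)
            prefix = "mature" if is_mature else "hairpin"
            for lib, n in mt.counts.items():
                rows[mid][f"{prefix}_{lib}"] += n
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "miRNA"
    mature_cols = [f"mature_{lib}" for lib in libs]
    out["total"] = out[mature_cols].sum(axis=1)
    out["libraries_expressed"] = out[mature_cols].apply(
        lambda r: ",".join(lib for lib in libs if r[f"mature_{lib}"] > 0), axis=1)
    if meta is not None:
        out = out.join(meta, how="left")
    return out


def accounting_report(mapped: list[MappedTag],
                      annotations: dict,
                      preprocess_stats: pd.DataFrame | None = None
                      ) -> pd.DataFrame:
    """Per-library read-weighted accounting across annotation classes.

    Returns a table with one row per class (plus ``genome_matched`` and
    ``candidate_pool``) and one column per library.  The candidate pool —
    reads retained for miRNA identification — is the sum of the
    known-miRNA, repeat-associated and unannotated rows.
    """
    libs: list[str] = []
    for mt in mapped:
        libs = list(mt.counts)
        break
    if not libs:
        return pd.DataFrame(
            0, index=CLASS_ORDER + ["genome_matched", "candidate_pool"],
            columns=[], dtype="int64")
    acc = {cls: dict.fromkeys(libs, 0) for cls in CLASS_ORDER}
    acc["genome_matched"] = dict.fromkeys(libs, 0)
    for mt in mapped:
        if mt.n_loci == 0:
            continue
        cls_row = acc[annotations[mt.sequence].cls]
        gm_row = acc["genome_matched"]
        for lib, n in mt.counts.items():
            cls_row[lib] += n
            gm_row[lib] += n
    table = pd.DataFrame(acc, dtype="int64").T.reindex(columns=libs)
    table.loc["candidate_pool"] = table.loc[CANDIDATE_CLASSES].sum(axis=0)
    if preprocess_stats is not None:
        for row in ("total_reads", "high_quality", "reads_18_30"):
            if row in preprocess_stats.columns:
                table.loc[row] = preprocess_stats[row].reindex(libs)
    return table


def candidate_tags(mapped: list[MappedTag], annotations: dict):
    """Unannotated tags forwarded to novel-miRNA prediction."""
    return [mt for mt in mapped
            if mt.n_loci > 0 and annotations[mt.sequence].cls == "unannotated"]
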