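"""Published per-library sequencing statistics for the rice developing-pollen
small RNA study.

The six libraries profile three sequential pollen stages — uninucleate
microspore (UNM), bicellular pollen (BCP) and tricellular pollen (TCP) — with
callus, leaf and root as sporophytic controls.  The table below holds the raw
read counts per accounting class; all percentages and the novel-miRNA
candidate pool are *derived* from these counts by the functions in this
module, mirroring the report-level arithmetic the pipeline performs on its
own accounting output.

Rows ``total_reads`` and ``high_quality`` are on the raw-read scale; the
remaining classes are read-weighted counts of 18–30-nt sequences.
"""

from __future__ import annotations

import pandas as pd

LIBRARIES = ["UNM", "BCP", "TCP", "callus", "leaf", "root"]

#: classes whose reads are retained as the candidate pool for novel-miRNA
#: prediction (everything else is discarded by the annotation cascade)
CANDIDATE_CLASSES = ["known_miRNA", "repeat_associated", "unannotated"]

_COUNTS = {
    "total_reads":       [6450464, 13497446, 14952272, 14009265, 13636372, 12663429],
    "high_quality":      [5982567, 12037307, 13573834, 12447058, 12323660, 11328710],
    "reads_18_30":       [5513740, 10256852, 12212973, 10884533, 10777375, 10424066],
    "genome_matched":    [4415708,  8857467, 10855875,  9007545,  9576588,  8563670],
    "ncRNA":             [3302769,  6424472, 10721753,  6752856,  8556637,  7154132],
    "exon_antisense":    [  31248,    56456,    15122,    42744,    22426,    18385],
    "exon_sense":        [ 317700,   343714,   374377,   144997,   294639,   164069],
    "intron_antisense":  [  12444,    34657,     5858,    34376,    10330,    16897],
    "intron_sense":      [  24045,    13997,    13105,    42672,    31089,    26438],
    "known_miRNA":       [  34930,    73567,    23574,   920584,   438823,   383694],
    "repeat_associated": [ 651296,  1665020,   177549,  1113638,   428592,   912267],
    "unannotated":       [1139308,  1644969,   881635,  1832666,   994839,  1748184],
}

#: published statistics table: one row per accounting class, one column per library
LIBRARY_STATS = pd.DataFrame(_COUNTS, index=LIBRARIES).T

#: total predicted target sites and total miRNAs reported by the study
PUBLISHED_TARGET_SITES = 1353
PUBLISHED_MIRNAS = 367


def candidate_pool(stats: pd.DataFrame | None = None) -> pd.Series:
    """Reads retained for novel-miRNA prediction, per library.

    The pool is the sum of the known-miRNA, repeat-associated and
    un-annotated read counts, i.e. what survives removal of structural
    ncRNA and mRNA-derived fragments.
    """
    stats = LIBRARY_STATS if stats is None else stats
    return stats.loc[CANDIDATE_CLASSES].sum(axis=0)


def high_quality_pct(stats: pd.DataFrame | None = None) -> pd.Series:
    """High-quality reads as a percentage of total raw reads (2 decimals)."""
    stats = LIBRARY_STATS if stats is None else stats
    return (100.0 * stats.loc["high_quality"] / stats.loc["total_reads"]).round(2)


def reads_18_30_pct(stats: pd.DataFrame | None = None) -> pd.Series:
    """18–30-nt reads as a percentage of total raw reads (2 decimals)."""
    stats = LIBRARY_STATS if stats is None else stats
    return (100.0 * stats.loc["reads_18_30"] / stats.loc["total_reads"]).round(2)


def genome_matched_pct(stats: pd.DataFrame | None = None) -> pd.Series:
    """Perfect genome matches as a percentage of 18–30-nt reads (2 decimals)."""
    stats = LIBRARY_STATS if stats is None else stats
    return (100.0 * stats.loc["genome_matched"] / stats.loc["reads_18_30"]).round(2)
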