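"""Raw small RNA read preprocessing.

Converts per-library FASTQ into collapsed unique tags with exact
per-library read counts, following the conventional small RNA cleanup:

1. quality filtering (mean phred and ambiguous-base caps),
2. 3' adaptor trimming by semi-global alignment (reads are longer than the
   18–30-nt inserts, so every usable read runs into the adaptor),
3. length selection to 18–30 nt and collapsing to unique tag sequences.

Counts are conserved: for each library the tag counts sum to the number of
18–30-nt reads that survived filtering, which is the denominator used later
for TPM normalization.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

MIN_TAG_LEN = 18
MAX_TAG_LEN = 30


@dataclass(frozen=True)
class TrimResult:
    insert: str | None
    status: str             # "ok" | "no_adaptor" | "too_short"


def quality_filter(records, q_min: float = 20.0, max_n: int = 0):
    """Keep reads with mean phred >= ``q_min`` and at most ``max_n`` Ns.

    ``records`` yields ``(id, sequence, quality)`` triples (phred+33).
    Returns ``(kept, n_total, n_removed)``.
    """
    kept = []
    n_total = 0
    for idx, (rid, seq, qual) in enumerate(records):
        n_total += 1
        if len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record {idx} ({rid}): "
                             f"sequence and quality lengths differ")
        mean_q = float(np.frombuffer(qual.encode("ascii"), np.uint8).mean()) - 33.0
        if mean_q >= q_min and seq.upper().count("N") <= max_n:
            kept.append((rid, seq.upper(), qual))
    return kept, n_total, n_total - len(kept)


def _semiglobal_trim(seq: str, adaptor: str, min_overlap: int,
                     max_error_rate: float, mismatch: float = 1.0,
                     gap: float = 2.0):
    """Best semi-global alignment of the adaptor prefix against the read.

    The adaptor may start anywhere in the read; the alignment must reach
    either the read 3' end or the adaptor 3' end.  Cost: ``mismatch`` per
    substitution, ``gap`` per indel.  Returns the insert length (adaptor
    start) or None.  Among feasible alignments the lowest error *rate*
    wins, ties broken towards longer adaptor overlap then earlier start.
    """
    n, m = len(seq), len(adaptor)
    inf = float("inf")
    # dp[i][j]: min cost aligning adaptor[:j] ending at read position i,
    # with a free start anywhere in the read; start[i][j] tracks it.
    dp = [[inf] * (m + 1) for _ in range(n + 1)]
    start = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        dp[i][0] = 0.0
        start[i][0] = i
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = dp[i - 1][j - 1] + (0.0 if seq[i - 1] == adaptor[j - 1] else mismatch)
            dele = dp[i - 1][j] + gap       # read base unmatched inside alignment
            ins = dp[i][j - 1] + gap        # adaptor base skipped
            best, src = sub, (i - 1, j - 1)
            if dele < best:
                best, src = dele, (i - 1, j)
            if ins < best:
                best, src = ins, (i, j - 1)
            dp[i][j] = best
            start[i][j] = start[src[0]][src[1]]
    best = None  # (rate, -overlap, start, cost)
    for i in range(1, n + 1):
        for j in range(min_overlap, m + 1):
            if i < n and j < m:
                continue  # alignment must be flush with a 3' end
            cost = dp[i][j]
            if cost <= max_error_rate * j:
                cand = (cost / j, -j, start[i][j], cost)
                if best is None or cand < best:
                    best = cand
    return None if best is None else best[2]


def trim_adaptor(seq: str, adaptor: str, min_overlap: int = 6,
                 max_error_rate: float = 0.2,
                 min_insert: int = MIN_TAG_LEN) -> TrimResult:
    """Locate the 3' adaptor and return the insert 5' of it.

    An exact search handles the overwhelmingly common error-free case
    (full adaptor inside the read, or an adaptor prefix flush with the
    read end); the dynamic-programming alignment is the fallback for reads
    with sequencing errors or indels in the adaptor.
    """
    if len(adaptor) < 6:
        raise ValueError("adaptor must be at least 6 nt")
    seq = seq.upper()
    adaptor = adaptor.upper()
    pos = seq.find(adaptor)
    if pos < 0:
        # adaptor prefix truncated by the read end: longest exact prefix wins
        for k in range(min(len(adaptor), len(seq)) - 1, min_overlap - 1, -1):
            if seq.endswith(adaptor[:k]):
                pos = len(seq) - k
                break
    if pos < 0:
        pos = _semiglobal_trim(seq, adaptor, min_overlap, max_error_rate)
    if pos is None or pos < 0:
        return TrimResult(None, "no_adaptor")
    if pos < min_insert:
        return TrimResult(None, "too_short")
    return TrimResult(seq[:pos], "ok")


def collapse_tags(inserts_by_library: dict[str, list[str]],
                  min_len: int = MIN_TAG_LEN, max_len: int = MAX_TAG_LEN):
    """Collapse trimmed inserts into unique tags with per-library counts.

    Returns ``(tags, stats, length_hist)`` where ``tags`` is a DataFrame
    indexed by tag sequence with one count column per library plus
    ``total``; ``stats`` has per-library ``reads_18_30`` and the fraction
    of 20–24-nt reads; ``length_hist`` counts reads per length 18..30.
    """
    libs = list(inserts_by_library)
    counters = {}
    len_counters = {}
    for lib in libs:
        ctr = Counter()
        lens = Counter()
        for s in inserts_by_library[lib]:
            if min_len <= len(s) <= max_len and "N" not in s:
                ctr[s] += 1
                lens[len(s)] += 1
        counters[lib] = ctr
        len_counters[lib] = lens
    hist = pd.DataFrame(
        {lib: [len_counters[lib].get(n, 0) for n in range(min_len, max_len + 1)]
         for lib in libs},
        index=range(min_len, max_len + 1))
    all_seqs = sorted(set().union(*(c.keys() for c in counters.values())))
    tags = pd.DataFrame(
        {lib: [counters[lib].get(s, 0) for s in all_seqs] for lib in libs},
        index=pd.Index(all_seqs, name="sequence"),
        dtype=np.int64,
    )
    tags["total"] = tags[libs].sum(axis=1)
    reads = hist.sum(axis=0)
    frac = hist.loc[20:24].sum(axis=0) / reads.replace(0, np.nan)
    stats = pd.DataFrame({
        "reads_18_30": reads.astype(np.int64),
        "frac_20_24": frac.fillna(0.0),
    })
    return tags, stats, hist


def preprocess_fastq(path, adaptor: str, q_min: float = 20.0, max_n: int = 0,
                     min_overlap: int = 6, max_error_rate: float = 0.2,
                     min_insert: int = MIN_TAG_LEN):
    """Full per-library preprocessing: FASTQ -> inserts + accounting.

    Returns ``(inserts, stats)`` with stats keys ``total_reads``,
    ``high_quality``, ``no_adaptor`` and ``too_short``.
    """
    with open(path) as fh:
        kept, n_total, _ = quality_filter(FastqGeneralIterator(fh), q_min, max_n)
    inserts = []
    n_noad = n_short = 0
    for _rid, seq, _q in kept:
        res = trim_adaptor(seq, adaptor, min_overlap, max_error_rate, min_insert)
        if res.status == "ok":
            inserts.append(res.insert)
        elif res.status == "no_adaptor":
            n_noad += 1
        else:
            n_short += 1
    stats = {
        "total_reads": n_total,
        "high_quality": len(kept),
        "no_adaptor": n_noad,
        "too_short": n_short,
    }
    return inserts, stats
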