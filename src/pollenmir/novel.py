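"""Novel miRNA prediction from unannotated tags.

A genuine miRNA leaves a characteristic footprint: a single genomic locus
whose flanking sequence folds back into a hairpin, with the mature read
population on one arm, optionally the star (duplex partner with 2-nt 3'
overhangs) on the other, and no repeat ancestry.  Candidates are pushed
through an explicit, individually recorded filter stack:

F1  single perfect genome locus (recently evolved miRNAs are single copy)
F2  total read count across libraries >= ``min_count`` (default 5)
F3  no reads from the opposite strand over the locus (two-strand coverage
    indicates siRNA-like double-stranded precursors)
F4  the flanking genome sequence folds into an acceptable hairpin
F5  neither precursor nor mature resembles the repeat library (MITEs fold
    into hairpins and must be excluded)
F6  mature length 20–24 nt
F7  sequenced in >= 2 libraries, or the star sequence detected in >= 1
F8  at least one predicted target exists (when a target checker is given)

Survivors are deduplicated by precursor locus (a mature and its star both
nominate the same hairpin) and numbered in genomic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd
from intervaltree import IntervalTree

from .fold import fold
from .mapping import MappedTag
from .seqs import revcomp

FILTER_NAMES = ["f1_single_locus", "f2_abundance", "f3_single_strand",
                "f4_hairpin", "f5_repeat", "f6_length", "f7_support",
                "f8_target"]


@dataclass
class HairpinCandidate:
    chrom: str
    start: int              # precursor genomic start (0-based)
    end: int
    strand: str
    precursor: str          # sense-strand precursor sequence
    structure: str          # dot-bracket, same orientation as precursor
    score: int
    arm: str                # "5p" or "3p"
    mature_offset: int      # within precursor
    mature_seq: str
    star_offset: int
    star_seq: str
    n_paired: int           # mature bases paired with the opposite arm
    # genomic coordinates of the predicted star
    star_gstart: int = -1
    star_gend: int = -1


@dataclass
class HairpinEvaluation:
    accepted: bool
    reason: str | None = None
    candidate: HairpinCandidate | None = None


@dataclass
class NovelMiRNA:
    mirna_id: str
    hairpin: HairpinCandidate
    counts: dict
    total_count: int
    n_genome_loci: int
    star_detected: bool
    libraries_expressed: tuple
    filter_flags: dict = field(default_factory=dict)


def _duplex_register(paired):
    """Median antiparallel register of a duplex.

    For pairs (p, q) of an antiparallel helix p + q is constant within a
    perfectly stacked stretch; the median over all mature pairs gives a
    partner estimate q(p) = r - p that is robust to register slippage at
    the duplex ends (internal loops let the fold shift a few terminal
    pairs without changing the dominant register)."""
    regs = sorted(p + q for p, q in paired)
    return regs[len(regs) // 2]


def _assess_mature(pairs, m0, m1, min_paired, max_unpaired, max_bulge_asym):
    """Check the mature/arm criteria on a folded window.

    Returns ``(arm, paired_positions)`` or raises nothing — failures come
    back as ``(None, reason)``.
    """
    mature_len = m1 - m0
    paired = [(p, pairs[p]) for p in range(m0, m1) if pairs[p] >= 0]
    if any(m0 <= q < m1 for _, q in paired):
        return None, "mature_spans_loop"
    if mature_len - len(paired) > max_unpaired:
        return None, "too_many_unpaired"
    if len(paired) < min_paired:
        return None, "insufficient_pairing"
    qs = [q for _, q in paired]
    if all(q >= m1 for q in qs):
        arm = "5p"
    elif all(q < m0 for q in qs):
        arm = "3p"
    else:
        return None, "mature_spans_loop"
    # the mature must stop before the terminal loop of its stem
    ps = [p for p, _ in paired]
    if arm == "5p" and max(ps) < m1 - 1:
        return None, "loop_overlap"
    if arm == "3p" and min(ps) > m0:
        return None, "loop_overlap"
    # duplex bulge symmetry: walk consecutive paired mature bases
    paired.sort()
    for (p, q), (p2, q2) in zip(paired, paired[1:]):
        gap_m = p2 - p - 1
        gap_s = q - q2 - 1
        if gap_s < 0:
            return None, "crossing_pairs"
        if abs(gap_m - gap_s) > max_bulge_asym:
            return None, "asymmetric_bulge"
    return arm, paired


def evaluate_hairpin(genome: dict[str, str], chrom: str, start: int, end: int,
                     strand: str, window: int = 150, min_paired: int = 16,
                     max_unpaired: int = 4, max_bulge_asym: int = 2,
                     min_flank: int = 30, pad: int = 5) -> HairpinEvaluation:
    """Fold the genomic context of a single-locus tag and judge the hairpin.

    Two window arrangements are tried — tag on the 5' arm (extend
    downstream) and tag on the 3' arm (extend upstream) — each up to
    ``window`` nt beyond the tag.  Acceptance requires the mature fully on
    one arm with >= ``min_paired`` bases paired against the opposite arm,
    <= ``max_unpaired`` unpaired mature bases, bulge asymmetry <=
    ``max_bulge_asym`` within the duplex, and no mature/loop overlap.
    The star is placed by the canonical 2-nt 3' overhang duplex geometry.
    """
    contig = genome[chrom]
    best: HairpinCandidate | None = None
    reasons = []
    arrangements = []
    # several window extents per arm: a long window can bury a clean stem
    # in spurious long-range pairings, so shorter extents are tried too
    extents = sorted({e for e in (40, 80, window) if e <= window})
    for ext in extents:
        down = (max(0, start - pad), min(len(contig), end + ext))
        up = (max(0, start - ext), min(len(contig), end + pad))
        for rs, re_ in (down, up):
            got = (re_ - end) if (rs, re_) == down else (start - rs)
            if got < min(min_flank, ext):
                reasons.append("edge")
                continue
            arrangements.append((rs, re_))
    for rs, re_ in arrangements:
        region = contig[rs:re_]
        if strand == "-":
            region = revcomp(region)
            m0 = re_ - end
        else:
            m0 = start - rs
        m1 = m0 + (end - start)
        try:
            fr = fold(region)
        except ValueError:
            reasons.append("fold_window")
            continue
        pairs = list(fr.pairs)
        arm, detail = _assess_mature(pairs, m0, m1, min_paired,
                                     max_unpaired, max_bulge_asym)
        if arm is None:
            reasons.append(detail)
            continue
        reg = _duplex_register(detail)
        # canonical 2-nt 3' overhang duplex geometry
        s0, s1 = reg - (m1 - 3), reg - m0 + 3
        if s0 < 0 or s1 > len(region) or s1 - s0 < 15:
            reasons.append("star_out_of_window")
            continue
        hp_lo = max(0, min(m0, s0) - 2)
        hp_hi = min(len(region), max(m1, s1) + 2)
        struct = "".join(
            "." if pairs[i] < 0 or not (hp_lo <= pairs[i] < hp_hi)
            else ("(" if pairs[i] > i else ")")
            for i in range(hp_lo, hp_hi)
        )
        if strand == "+":
            g_start, g_end = rs + hp_lo, rs + hp_hi
            star_g = (rs + s0, rs + s1)
        else:
            g_start, g_end = re_ - hp_hi, re_ - hp_lo
            star_g = (re_ - s1, re_ - s0)
        cand = HairpinCandidate(
            chrom=chrom, start=g_start, end=g_end, strand=strand,
            precursor=region[hp_lo:hp_hi], structure=struct, score=fr.score,
            arm=arm, mature_offset=m0 - hp_lo,
            mature_seq=region[m0:m1], star_offset=s0 - hp_lo,
            star_seq=region[s0:s1], n_paired=len(detail),
            star_gstart=star_g[0], star_gend=star_g[1],
        )
        if best is None or (cand.n_paired, cand.score) > (best.n_paired, best.score):
            best = cand
    if best is None:
        reason = reasons[0] if reasons else "no_window"
        return HairpinEvaluation(False, reason, None)
    return HairpinEvaluation(True, None, best)


def repeat_similar(seq: str, repeat_library: dict[str, str],
                   max_divergence: float = 0.2) -> bool:
    """True when ``seq`` (either orientation) aligns to any repeat-library
    sequence with <= ``max_divergence`` edits per query base.

    The 80 %-identity screen is implemented as an infix edit-distance
    search over the full query, the conservative reading of "identity over
    >= 80 % of length".
    """
    for rseq in repeat_library.values():
        k = int(len(seq) * max_divergence)
        for q in (seq, revcomp(seq)):
            if len(q) <= len(rseq):
                r = edlib.align(q, rseq, mode="HW", task="distance", k=k)
            else:
                r = edlib.align(rseq, q, mode="HW", task="distance", k=k)
            if r["editDistance"] != -1:
                return True
    return False


def _strand_trees(mapped: list[MappedTag]):
    trees: dict[tuple, IntervalTree] = {}
    for mt in mapped:
        for h in mt.hits:
            trees.setdefault((h.chrom, h.strand), IntervalTree()).addi(
                h.start, h.end, mt.sequence)
    return trees


def predict_novel_mirnas(candidates: list[MappedTag],
                         genome: dict[str, str],
                         all_mapped: list[MappedTag],
                         repeat_library: dict[str, str] | None = None,
                         min_count: int = 5,
                         window: int = 150,
                         min_mature_len: int = 20,
                         max_mature_len: int = 24,
                         star_tol: int = 2,
                         target_checker=None):
    """Run the filter stack over unannotated tags.

    Returns ``(novel, flags)``: the surviving :class:`NovelMiRNA` records
    (deduplicated by precursor locus, numbered miR-N1, miR-N2, ... in
    genomic order) and a DataFrame recording every candidate's filter
    evaluation (None = not reached).

    A missing repeat library skips F5; the flag column then records None
    and the survivors carry ``f5_repeat=None``.
    """
    trees = _strand_trees(all_mapped)
    flags_rows = []
    accepted = []
    for mt in candidates:
        flags = {name: None for name in FILTER_NAMES}
        reason = None
        hairpin = None
        star_detected = False
        while True:
            flags["f1_single_locus"] = mt.n_loci == 1
            if not flags["f1_single_locus"]:
                reason = "multiple_loci"
                break
            flags["f2_abundance"] = mt.total >= min_count
            if not flags["f2_abundance"]:
                reason = "low_abundance"
                break
            hit = mt.hits[0]
            anti = "-" if hit.strand == "+" else "+"
            tree = trees.get((hit.chrom, anti))
            both = bool(tree and tree.overlap(hit.start, hit.end))
            flags["f3_single_strand"] = not both
            if both:
                reason = "both_strands"
                break
            ev = evaluate_hairpin(genome, hit.chrom, hit.start, hit.end,
                                  hit.strand, window=window)
            flags["f4_hairpin"] = ev.accepted
            if not ev.accepted:
                reason = f"hairpin:{ev.reason}"
                break
            hairpin = ev.candidate
            if repeat_library:
                rep = (repeat_similar(hairpin.mature_seq, repeat_library)
                       or repeat_similar(hairpin.precursor, repeat_library))
                flags["f5_repeat"] = not rep
                if rep:
                    reason = "repeat_homology"
                    break
            flags["f6_length"] = (min_mature_len <= len(mt.sequence)
                                  <= max_mature_len)
            if not flags["f6_length"]:
                reason = "mature_length"
                break
            libs_expr = tuple(lib for lib, n in mt.counts.items() if n > 0)
            star_detected = _find_star(trees, hairpin, star_tol)
            flags["f7_support"] = len(libs_expr) >= 2 or star_detected
            if not flags["f7_support"]:
                reason = "single_library_no_star"
                break
            if target_checker is not None:
                flags["f8_target"] = bool(target_checker(mt.sequence))
                if not flags["f8_target"]:
                    reason = "no_target"
                    break
            accepted.append((mt, hairpin, star_detected, libs_expr, dict(flags)))
            break
        flags_rows.append({"sequence": mt.sequence, "total": mt.total,
                           "reason": reason, **flags})
    flags_df = pd.DataFrame(flags_rows)

    # collapse candidates nominating the same precursor locus (mature and
    # star reads both pass the stack); keep the most abundant
    accepted.sort(key=lambda a: (a[1].chrom, a[1].start))
    survivors = []
    for item in sorted(accepted, key=lambda a: -a[0].total):
        hp = item[1]
        clash = any(
            s[1].chrom == hp.chrom and s[1].strand == hp.strand
            and s[1].start < hp.end and hp.start < s[1].end
            for s in survivors
        )
        if not clash:
            survivors.append(item)
    survivors.sort(key=lambda a: (a[1].chrom, a[1].start))
    novel = []
    for i, (mt, hp, star, libs_expr, flags) in enumerate(survivors, start=1):
        novel.append(NovelMiRNA(
            mirna_id=f"miR-N{i}", hairpin=hp, counts=dict(mt.counts),
            total_count=mt.total, n_genome_loci=1, star_detected=star,
            libraries_expressed=libs_expr, filter_flags=flags))
    return novel, flags_df


def _find_star(trees, hairpin: HairpinCandidate, tol: int) -> bool:
    tree = trees.get((hairpin.chrom, hairpin.strand))
    if tree is None or hairpin.star_gstart < 0:
        return False
    s0, s1 = hairpin.star_gstart, hairpin.star_gend
    if hairpin.strand == "+":
        m_g = hairpin.start + hairpin.mature_offset
    else:
        m_g = hairpin.end - hairpin.mature_offset - len(hairpin.mature_seq)
    for iv in tree.overlap(s0, s1):
        if abs(iv.begin - s0) <= tol and abs((iv.end - iv.begin) - (s1 - s0)) <= tol:
            if iv.begin != m_g:       # the mature itself does not count
                return True
    return False


def novel_table(novel: list[NovelMiRNA], libs: list[str]) -> pd.DataFrame:
    """Flat per-novel-miRNA table for export."""
    rows = []
    for nm in novel:
        hp = nm.hairpin
        row = {
            "miRNA": nm.mirna_id, "sequence": hp.mature_seq,
            "chrom": hp.chrom, "precursor_start": hp.start,
            "precursor_end": hp.end, "strand": hp.strand, "arm": hp.arm,
            "mature_start": hp.start + (hp.mature_offset if hp.strand == "+"
                                        else len(hp.precursor) - hp.mature_offset
                                        - len(hp.mature_seq)),
            "total": nm.total_count, "star_detected": nm.star_detected,
            "n_libraries": len(nm.libraries_expressed),
            "structure": hp.structure, "fold_score": hp.score,
        }
        row["mature_end"] = row["mature_start"] + len(hp.mature_seq)
        for lib in libs:
            row[lib] = nm.counts.get(lib, 0)
        rows.append(row)
    return pd.DataFrame(rows)
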