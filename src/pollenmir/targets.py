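"""Plant miRNA target prediction by position-weighted complementarity.

Plant miRNAs pair near-perfectly with their mRNA targets, so targets can
be found by scoring the antiparallel duplex between the miRNA and every
transcript window: each mismatch costs 1.0, each G:U wobble 0.5 and each
single-base bulge 2.0, with costs doubled over the 5'-proximal core
(miRNA positions 2–13) where cleavage-competent pairing is critical.  A
site is accepted when its total penalty is at most 3.0 (configurable).
These constants follow the miRU/psRNATarget family of schemes.

The predicted cleavage site follows the canonical 10/11 rule: the
phosphodiester bond opposite miRNA nucleotides 10 and 11 (from the miRNA
5' end), reported as the transcript coordinate of the first base of the
downstream fragment — the base paired to nucleotide 10 — matching how
5'-RACE reads out cleavage products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .seqs import encode, revcomp

CORE_RANGE = (2, 13)        # miRNA positions (1-based, 5'->3') weighted x2
MISMATCH = 1.0
WOBBLE = 0.5
BULGE = 2.0
DEFAULT_MAX_PENALTY = 3.0

_COMPLEMENT_CODE = {0: 3, 3: 0, 1: 2, 2: 1}    # A-T, C-G on the 0..3 coding


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int                  # 0-based on transcript
    end: int
    penalty: float
    cleavage_pos: int           # transcript coordinate, 10/11 rule
    alignment: tuple            # (miRNA 3'->5', pairing row, target 5'->3')


def _pair_penalty(mir_base: str, tgt_base: str, pos1: int,
                  core_scale: float = 2.0) -> float:
    m, t = mir_base.upper().replace("U", "T"), tgt_base.upper().replace("U", "T")
    if t not in "ACGT":
        raise ValueError(f"ambiguous base {tgt_base!r} in target window")
    if (m, t) in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
        p = 0.0
    elif (m, t) in (("G", "T"), ("T", "G")):
        p = WOBBLE
    else:
        p = MISMATCH
    if CORE_RANGE[0] <= pos1 <= CORE_RANGE[1]:
        p *= core_scale
    return p


def _bulge_penalty(pos1: int, core_scale: float = 2.0) -> float:
    p = BULGE
    if CORE_RANGE[0] <= pos1 <= CORE_RANGE[1]:
        p *= core_scale
    return p


def _pair_symbol(mir_base: str, tgt_base: str) -> str:
    m, t = mir_base.upper().replace("U", "T"), tgt_base.upper().replace("U", "T")
    if (m, t) in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
        return "|"
    if (m, t) in (("G", "T"), ("T", "G")):
        return "o"
    return " "


def score_site(mirna: str, window: str, core_scale: float = 2.0):
    """Score one miRNA/target-window duplex; reference implementation.

    The window must be the miRNA length +-1 (at most one bulge on either
    strand).  Returns ``(penalty, alignment)`` of the best variant, where
    the alignment triple is (miRNA 3'->5', pairing row, target 5'->3').
    Raises ValueError for incompatible window lengths or ambiguous bases.
    ``core_scale`` multiplies costs over miRNA positions 2-13 (set to 1.0
    for an unweighted duplex score).
    """
    L, W = len(mirna), len(window)
    if abs(W - L) > 1:
        raise ValueError(f"window length {W} incompatible with miRNA length {L}")
    variants = []
    if W == L:
        pen = sum(_pair_penalty(mirna[p - 1], window[L - p], p, core_scale)
                  for p in range(1, L + 1))
        variants.append((pen, 0, 0))
    elif W == L + 1:
        for k in range(1, L):        # extra target base after partner of k
            pen = _bulge_penalty(k, core_scale)
            for p in range(1, L + 1):
                t = (L + 1 - p) if p <= k else (L - p)
                pen += _pair_penalty(mirna[p - 1], window[t], p, core_scale)
            variants.append((pen, 1, k))
    else:
        for k in range(2, L):        # miRNA base k unpaired
            pen = _bulge_penalty(k, core_scale)
            for p in range(1, L + 1):
                if p == k:
                    continue
                t = (L - 1 - p) if p < k else (L - p)
                pen += _pair_penalty(mirna[p - 1], window[t], p, core_scale)
            variants.append((pen, 2, k))
    pen, vtype, k = min(variants)
    return pen, _alignment(mirna, window, vtype, k)


def _target_index(vtype: int, k: int, L: int, p: int) -> int:
    """Window index paired with miRNA position ``p`` (1-based)."""
    if vtype == 0:
        return L - p
    if vtype == 1:
        return (L + 1 - p) if p <= k else (L - p)
    if p == k:
        raise ValueError("bulged miRNA base has no partner")
    return (L - 1 - p) if p < k else (L - p)


def _alignment(mirna: str, window: str, vtype: int, k: int):
    """Render the duplex with the miRNA 3'->5' over the target 5'->3'."""
    mir_row, pair_row, tgt_row = [], [], []
    L = len(mirna)
    for t in range(len(window)):
        if vtype == 1 and t == L - k:          # bulged target base
            mir_row.append("-")
            pair_row.append(" ")
            tgt_row.append(window[t])
            continue
        p = None
        for q in range(1, L + 1):
            if vtype == 2 and q == k:
                continue
            if _target_index(vtype, k, L, q) == t:
                p = q
                break
        mir_row.append(mirna[p - 1])
        pair_row.append(_pair_symbol(mirna[p - 1], window[t]))
        tgt_row.append(window[t])
        if vtype == 2 and p == k + 1:      # bulged miRNA base goes here
            mir_row.append(mirna[k - 1])
            pair_row.append(" ")
            tgt_row.append("-")
    # columns run target 5'->3', so the miRNA row reads 3'->5'
    return ("".join(mir_row), "".join(pair_row), "".join(tgt_row))


@njit(cache=False)
def _scan_kernel(lut, tgt, bulge_cost, cutoff):  # pragma: no cover
    """Best duplex variant at every transcript start position.

    ``lut[p-1, base]`` is the pairing penalty of miRNA position p against
    a target base; ``bulge_cost[k]`` the (core-weighted) bulge penalty.
    Returns per-start best penalty, variant type (0 none / 1 target bulge
    / 2 miRNA bulge) and bulge position.
    """
    L = lut.shape[0]
    n = tgt.shape[0]
    big = 1e18
    best_pen = np.full(n, big)
    best_type = np.full(n, -1, dtype=np.int8)
    best_k = np.full(n, -1, dtype=np.int8)
    for s in range(n):
        # no bulge
        if s + L <= n:
            pen = 0.0
            for p in range(1, L + 1):
                pen += lut[p - 1, tgt[s + L - p]]
            if pen < best_pen[s]:
                best_pen[s] = pen
                best_type[s] = 0
                best_k[s] = 0
        # target bulge
        if s + L + 1 <= n:
            for k in range(1, L):
                pen = bulge_cost[k]
                for p in range(1, L + 1):
                    t = (L + 1 - p) if p <= k else (L - p)
                    pen += lut[p - 1, tgt[s + t]]
                    if pen > cutoff and pen >= best_pen[s]:
                        break
                if pen < best_pen[s]:
                    best_pen[s] = pen
                    best_type[s] = 1
                    best_k[s] = k
        # miRNA bulge
        if s + L - 1 <= n:
            for k in range(2, L):
                pen = bulge_cost[k]
                for p in range(1, L + 1):
                    if p == k:
                        continue
                    t = (L - 1 - p) if p < k else (L - p)
                    pen += lut[p - 1, tgt[s + t]]
                    if pen > cutoff and pen >= best_pen[s]:
                        break
                if pen < best_pen[s]:
                    best_pen[s] = pen
                    best_type[s] = 2
                    best_k[s] = k
    return best_pen, best_type, best_k


def _penalty_lut(mirna: str) -> np.ndarray:
    L = len(mirna)
    lut = np.zeros((L, 5))
    code = encode(mirna)
    for p in range(1, L + 1):
        for t in range(5):
            b = int(code[p - 1])
            if t == 4 or b == 4:
                pen = MISMATCH
            elif _COMPLEMENT_CODE.get(b) == t:
                pen = 0.0
            elif (b, t) in ((2, 3), (3, 2)):
                pen = WOBBLE
            else:
                pen = MISMATCH
            if CORE_RANGE[0] <= p <= CORE_RANGE[1]:
                pen *= 2.0
            lut[p - 1, t] = pen
    return lut


def scan_transcripts(mirnas: dict[str, str], transcripts: dict[str, str],
                     max_penalty: float = DEFAULT_MAX_PENALTY):
    """Report every accepted target site of every miRNA.

    Returns ``(sites, per_mirna_counts, average)``: a TargetSite list, a
    Series of target-site counts per miRNA, and the average number of
    targets per miRNA over miRNAs with >= 0 sites.
    """
    if not transcripts:
        raise ValueError("no transcripts supplied")
    sites: list[TargetSite] = []
    enc_tgts = {tid: encode(seq) for tid, seq in transcripts.items()}
    for mid, mseq in mirnas.items():
        L = len(mseq)
        lut = _penalty_lut(mseq)
        bulge_cost = np.array([_bulge_penalty(k) for k in range(L + 1)])
        for tid, tseq in transcripts.items():
            if len(tseq) < L - 1:
                continue
            pen, vtype, bk = _scan_kernel(lut, enc_tgts[tid], bulge_cost,
                                          max_penalty)
            for s in np.nonzero(pen <= max_penalty)[0]:
                s = int(s)
                vt, k = int(vtype[s]), int(bk[s])
                wlen = L + (1 if vt == 1 else -1 if vt == 2 else 0)
                try:
                    cleave_rel = _target_index(vt, k, L, 10)
                except ValueError:      # nt 10 bulged out: bond shifts by one
                    cleave_rel = _target_index(vt, k, L, 11) + 1
                aln = _alignment(mseq, tseq[s:s + wlen], vt, k)
                sites.append(TargetSite(
                    mirna_id=mid, transcript_id=tid, start=s, end=s + wlen,
                    penalty=float(pen[s]), cleavage_pos=s + cleave_rel,
                    alignment=aln))
    counts = pd.Series(0, index=list(mirnas), dtype="int64")
    for site in sites:
        counts[site.mirna_id] += 1
    avg = average_targets_per_mirna(int(counts.sum()), len(mirnas)) \
        if mirnas else 0.0
    return sites, counts, avg


def average_targets_per_mirna(n_sites: int, n_mirnas: int) -> float:
    """Average targets per miRNA, reported to one decimal."""
    if n_mirnas <= 0:
        raise ValueError("need at least one miRNA")
    return round(n_sites / n_mirnas, 1)


def sites_table(sites: list[TargetSite]) -> pd.DataFrame:
    rows = [{
        "miRNA": s.mirna_id, "transcript": s.transcript_id,
        "start": s.start, "end": s.end, "penalty": s.penalty,
        "cleavage_pos": s.cleavage_pos,
        "mirna_3to5": s.alignment[0], "pairing": s.alignment[1],
        "target_5to3": s.alignment[2],
    } for s in sites]
    return pd.DataFrame(rows)


def correlate_expression(mirna_tpm: pd.DataFrame, target_tpm: pd.DataFrame,
                         pairs, r_negative: float = -0.5,
                         r_positive: float = 0.5,
                         pseudocount: float = 1.0) -> pd.DataFrame:
    """Pearson correlation of miRNA and target log2 profiles per pair.

    ``pairs`` yields (miRNA id, target id).  Profiles must share columns.
    class = negative (r <= r_negative), positive (r >= r_positive), else
    uncorrelated; zero-variance profiles are uncorrelated with a flag.
    """
    if list(mirna_tpm.columns) != list(target_tpm.columns):
        raise ValueError("miRNA and target profiles cover different samples")
    rows = []
    for mid, tid in pairs:
        x = np.log2(mirna_tpm.loc[mid].to_numpy(dtype=float) + pseudocount)
        y = np.log2(target_tpm.loc[tid].to_numpy(dtype=float) + pseudocount)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((mid, tid, np.nan, "uncorrelated", True))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        cls = ("negative" if r <= r_negative
               else "positive" if r >= r_positive else "uncorrelated")
        rows.append((mid, tid, r, cls, False))
    return pd.DataFrame(rows, columns=["miRNA", "target", "r", "class",
                                       "zero_variance"])
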