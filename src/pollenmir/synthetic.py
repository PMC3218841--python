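"""Synthetic genomes and simulated small RNA libraries with known truth.

The generator builds a toy genome in which every feature the analysis must
handle is planted at known coordinates: known miRNA hairpins (present in
the hairpin reference), novel hairpins (absent from the reference, to be
rediscovered), rRNA/tRNA/snRNA/snoRNA loci, protein-coding genes with
exon/intron structure, annotated repeats including a perfect
inverted-repeat MITE, and one *unannotated*, diverged MITE copy that folds
like a hairpin but is homologous to the repeat library — the canonical
false positive the repeat screen must remove.

Six libraries (UNM, BCP, TCP, callus, leaf, root) are then simulated:
reads from planted miRNA loci proportional to their expected TPM (with
star co-sampling), siRNA-like reads from repeats whose 21-nt/24-nt length
mixture shifts across libraries, degradation fragments of transcripts and
ncRNA, adaptor read-through, random noise, occasional low-quality reads
and sequencing errors.  A truth ledger records every planted locus, its
expression class and where its target site sits, enabling end-to-end
parameter-recovery tests.

All coordinates are 0-based half-open internally; GFF3 output converts to
the standard 1-based inclusive convention.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqs import random_seq, revcomp, write_fasta

LIBRARY_NAMES = ["UNM", "BCP", "TCP", "callus", "leaf", "root"]
TPM_COLS = [f"tpm_{lib}" for lib in LIBRARY_NAMES]

#: classic Solexa small RNA 3' adaptor
DEFAULT_ADAPTOR = "TCGTATGCCGTCTTCTGCTTG"

CHROM = "chr1"

#: bases that pair (Watson-Crick or G:U wobble) with each base
_PAIR_PARTNERS = {"A": {"T"}, "T": {"A", "G"}, "G": {"C", "T"}, "C": {"G"}}

_NCRNA_LEN = {"rRNA": 300, "tRNA": 80, "snRNA": 120, "snoRNA": 100}

# expression-class templates (TPM over the six libraries); whole-profile
# scaling preserves both the ratio and the Z-score, so amplitudes may vary
_TEMPLATES = {
    "constitutive": [300, 300, 300, 300, 300, 300],
    "pollen_enriched": [900, 150, 100, 3, 3, 3],
    "sporophyte_enriched": [3, 3, 3, 900, 150, 100],
    "stage_specific_UNM": [1500, 0, 0, 0, 0, 0],
    "stage_specific_BCP": [0, 1500, 0, 0, 0, 0],
    "stage_specific_TCP": [0, 0, 1500, 0, 0, 0],
}

_KNOWN_LABEL_CYCLE = ["constitutive", "constitutive", "sporophyte_enriched",
                      "sporophyte_enriched", "pollen_enriched", "constitutive",
                      "sporophyte_enriched", "sporophyte_enriched",
                      "pollen_enriched", "constitutive",
                      "stage_specific_UNM", "stage_specific_TCP"]
_NOVEL_LABEL_CYCLE = ["stage_specific_UNM", "stage_specific_BCP",
                      "stage_specific_TCP", "stage_specific_UNM",
                      "stage_specific_BCP", "stage_specific_TCP",
                      "pollen_enriched", "constitutive",
                      "stage_specific_BCP", "stage_specific_UNM",
                      "stage_specific_TCP", "pollen_enriched",
                      "stage_specific_BCP", "constitutive",
                      "stage_specific_UNM"]


class InfeasiblePackingError(ValueError):
    """Planted features cannot be placed without overlap."""


@dataclass
class SyntheticGenomeSpec:
    genome_length: int = 80_000
    n_known_hairpins: int = 12
    n_novel_hairpins: int = 15
    n_ncrna: dict = field(default_factory=lambda: {"rRNA": 3, "tRNA": 3,
                                                   "snRNA": 2, "snoRNA": 2})
    n_genes: int = 30
    n_repeats: int = 6            # annotated repeats; the first is a MITE
    mature_len: int = 21
    min_gap: int = 60
    seed: int = 0


@dataclass
class LibrarySpec:
    name: str
    total_reads: int = 60_000
    weight_24: float = 0.6        # 24-nt share of the siRNA length mixture
    degradation_fraction: float = 0.30
    noise_fraction: float = 0.10
    antisense_fraction: float = 0.02
    short_insert_fraction: float = 0.01
    low_quality_fraction: float = 0.02
    star_ratio: float = 0.25      # star reads per mature read
    mite_weight: float = 0.10     # share of siRNA reads from the stray MITE
    adaptor: str = DEFAULT_ADAPTOR
    error_rate: float = 0.003     # per-base substitution probability
    read_length: int = 36
    seed: int = 0

    def __post_init__(self):
        if self.name not in LIBRARY_NAMES:
            raise ValueError(f"unknown library {self.name!r}")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be > 0")
        fracs = [self.degradation_fraction, self.noise_fraction,
                 self.antisense_fraction, self.short_insert_fraction]
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("read-category fractions must lie in [0,1] "
                             "and sum to <= 1")


@dataclass
class GenomeBundle:
    genome: dict
    features: pd.DataFrame
    known_precursors: dict
    known_mature_coords: dict
    known_meta: pd.DataFrame
    transcripts: dict
    repeat_library: dict
    go_map: pd.DataFrame
    gene_expression: pd.DataFrame
    truth: pd.DataFrame
    paths: dict = field(default_factory=dict)

    @property
    def expression_truth(self) -> pd.DataFrame:
        mir = self.truth[self.truth["kind"].isin(["known", "novel"])]
        out = mir.set_index("id")[TPM_COLS].copy()
        out.columns = LIBRARY_NAMES
        out["label"] = mir.set_index("id")["label"]
        return out


def _mutate_base(rng, base: str, forbidden: set) -> str:
    choices = [b for b in "ACGT" if b != base and b not in forbidden]
    return str(rng.choice(choices))


def _make_hairpin(rng, mature_len: int, arm: str, loop_len: int = 9,
                  flank: int = 12, mismatch_pos=(5, 13),
                  max_attempts: int = 60, repeat_library: dict | None = None):
    """One planted hairpin locus (sense orientation).

    The star arm is the reverse complement of the mature with two
    substitutions at interior positions, so the mature maps to a single
    genomic locus (a perfect inverted repeat would make the mature match
    its own star arm on the minus strand) while still leaving >= 16 paired
    mature bases with symmetric internal loops.  Each draw is checked by
    the pipeline's own hairpin evaluation in two random sequence contexts
    and redrawn if the fold is not robust — or, when a repeat library is
    given, if the draw is a chance repeat homolog (planted hairpins must
    pass every filter by construction).
    """
    from .novel import evaluate_hairpin, repeat_similar

    for _ in range(max_attempts):
        mature = random_seq(rng, mature_len)
        star = list(revcomp(mature))
        for mp in mismatch_pos:
            si = mature_len - 1 - mp
            star[si] = _mutate_base(rng, star[si], _PAIR_PARTNERS[mature[mp]])
        star = "".join(star)
        loop = random_seq(rng, loop_len)
        core = mature + loop + star if arm == "5p" else star + loop + mature
        locus = random_seq(rng, flank) + core + random_seq(rng, flank)
        if arm == "5p":
            m_off = flank
            s_off = flank + mature_len + loop_len
        else:
            m_off = flank + mature_len + loop_len
            s_off = flank
        ok = True
        if repeat_library and (repeat_similar(mature, repeat_library)
                               or repeat_similar(star, repeat_library)
                               or repeat_similar(locus, repeat_library)):
            ok = False
        for _ctx in range(2 if ok else 0):
            ctx5 = random_seq(rng, 60)
            ctx3 = random_seq(rng, 60)
            toy = {"t": ctx5 + locus + ctx3}
            m0 = len(ctx5) + m_off
            ev = evaluate_hairpin(toy, "t", m0, m0 + mature_len, "+")
            if not ev.accepted:
                ok = False
                break
            if repeat_library and repeat_similar(ev.candidate.precursor,
                                                 repeat_library):
                ok = False
                break
        if ok:
            return {"locus": locus, "mature": mature, "star": star,
                    "arm": arm, "mature_off": m_off, "star_off": s_off,
                    "flank": flank}
    raise RuntimeError("could not draw a fold-robust hairpin")


def _make_target_site(rng, mature: str, perfect: bool):
    """Target-site sequence for a mature miRNA (written 5'->3' on the
    transcript).  Imperfect sites carry two non-pairing substitutions at
    the positions facing miRNA nucleotides 15 and 18 (outside the core:
    penalty 2.0, still accepted) so the site is not an exact reverse
    complement and does not add a second genome locus for the mature."""
    site = list(revcomp(mature))
    if not perfect:
        L = len(mature)
        for p in (15, 18):                 # miRNA position, 1-based
            ti = L - p                     # antiparallel partner index
            site[ti] = _mutate_base(rng, site[ti], _PAIR_PARTNERS[mature[p - 1]])
    return "".join(site)


def _occurrences(genome: dict, seq: str) -> int:
    total = 0
    for s in genome.values():
        for q in (seq, revcomp(seq)):
            start = 0
            while (i := s.find(q, start)) >= 0:
                total += 1
                start = i + 1
    return total


def build_genome(spec: SyntheticGenomeSpec, out_dir=None,
                 validate: bool = True) -> GenomeBundle:
    """Build the toy genome, annotation and truth ledger.

    Deterministic for a fixed ``spec.seed`` (byte-identical files).
    Raises :class:`InfeasiblePackingError` when the requested features do
    not fit in ``genome_length`` with the minimum inter-feature gap.
    """
    rng = np.random.default_rng(spec.seed)
    n_mirnas = spec.n_known_hairpins + spec.n_novel_hairpins
    if n_mirnas > spec.n_genes:
        raise ValueError("need n_genes >= total hairpins so every miRNA "
                         "gets its own target-host gene")

    entries = []   # (kind, entry-id, sequence, payload)

    # --- ncRNA loci -------------------------------------------------------
    for cls, count in spec.n_ncrna.items():
        for i in range(count):
            seq = random_seq(rng, _NCRNA_LEN[cls])
            entries.append((cls, f"{cls}{i + 1}", seq, {}))

    # --- protein-coding genes --------------------------------------------
    gene_layouts = []
    for g in range(spec.n_genes):
        exon_lens = [int(rng.integers(180, 260)) for _ in range(3)]
        intron_lens = [int(rng.integers(100, 180)) for _ in range(2)]
        parts, rel, pos = [], [], 0
        for j in range(3):
            parts.append(random_seq(rng, exon_lens[j]))
            rel.append(("exon", j, pos, pos + exon_lens[j]))
            pos += exon_lens[j]
            if j < 2:
                parts.append(random_seq(rng, intron_lens[j]))
                rel.append(("intron", j, pos, pos + intron_lens[j]))
                pos += intron_lens[j]
        gid = f"g{g + 1:02d}"
        gene_layouts.append({"id": gid, "parts": parts, "rel": rel,
                             "exon_lens": exon_lens})
        entries.append(("gene", gid, None, {"layout": gene_layouts[-1]}))

    # --- repeats (first one a perfect-inverted-repeat MITE) ---------------
    repeat_library = {}
    mite_arm = random_seq(rng, 30)
    mite_spacer = random_seq(rng, 12)
    mite_seq = mite_arm + mite_spacer + revcomp(mite_arm)
    repeat_library["MITE1"] = mite_seq
    entries.append(("repeat", "MITE1", mite_seq, {}))
    for r in range(1, spec.n_repeats):
        seq = random_seq(rng, 200)
        rid = f"repeat{r + 1}"
        repeat_library[rid] = seq
        entries.append(("repeat", rid, seq, {}))

    # stray MITE copy: diverged from the consensus, absent from the
    # annotation but present (via its family) in the repeat library
    stray = list(mite_seq)
    for p in (10, 20):              # arm 1 substitutions
        stray[p] = _mutate_base(rng, stray[p], set())
    for p in (12, 22):              # arm 2 substitutions (offset 42)
        stray[42 + p] = _mutate_base(rng, stray[42 + p], set())
    stray_seq = "".join(stray)
    entries.append(("mite_unannotated", "MITE-stray", stray_seq, {}))

    # --- hairpins ---------------------------------------------------------
    mir_defs = []
    for i in range(spec.n_known_hairpins):
        arm = "5p" if i % 2 == 0 else "3p"
        hp = _make_hairpin(rng, spec.mature_len, arm,
                           repeat_library=repeat_library)
        mid = f"miR-K{i + 1:02d}"
        label = _KNOWN_LABEL_CYCLE[i % len(_KNOWN_LABEL_CYCLE)]
        mir_defs.append({"id": mid, "kind": "known", "strand": "+",
                         "label": label, **hp})
        entries.append(("known_hairpin", mid, hp["locus"], {"def": mir_defs[-1]}))
    for i in range(spec.n_novel_hairpins):
        arm = "5p" if i % 2 == 0 else "3p"
        strand = "-" if i % 4 == 3 else "+"
        hp = _make_hairpin(rng, spec.mature_len, arm,
                           repeat_library=repeat_library)
        mid = f"nov{i + 1:02d}"
        label = _NOVEL_LABEL_CYCLE[i % len(_NOVEL_LABEL_CYCLE)]
        mir_defs.append({"id": mid, "kind": "novel", "strand": strand,
                         "label": label, **hp})
        entries.append(("novel_hairpin", mid, None, {"def": mir_defs[-1]}))

    # --- embed target sites in exons (one host gene per miRNA) -----------
    amplitudes = rng.uniform(0.8, 1.6, size=len(mir_defs))
    for i, mdef in enumerate(mir_defs):
        gid = gene_layouts[i]["id"]
        site = _make_target_site(rng, mdef["mature"],
                                 perfect=(mdef["id"] == "miR-K01"))
        layout = gene_layouts[i]
        exon_j = 1                                   # middle exon
        offset = 40
        part_idx = 2                                 # parts: e0,i0,e1,i1,e2
        exon_seq = layout["parts"][part_idx]
        layout["parts"][part_idx] = (exon_seq[:offset] + site
                                     + exon_seq[offset + len(site):])
        tpos = layout["exon_lens"][0] + offset       # transcript coordinate
        mdef["target_gene"] = gid
        mdef["site_tpos"] = tpos
        mdef["cleavage_pos"] = tpos + len(site) - 10
        mdef["tpm"] = [round(v * amplitudes[i], 3)
                       for v in _TEMPLATES[mdef["label"]]]

    # finalize gene sequences now that sites are embedded
    for kind, eid, _seq, payload in entries:
        if kind == "gene":
            payload["seq"] = "".join(payload["layout"]["parts"])

    # --- pack features into the genome ------------------------------------
    def entry_seq(e):
        kind, _eid, seq, payload = e
        if kind == "gene":
            return payload["seq"]
        if kind == "novel_hairpin":
            d = payload["def"]
            return d["locus"] if d["strand"] == "+" else revcomp(d["locus"])
        if kind == "known_hairpin":
            return payload["def"]["locus"]
        return seq

    order = rng.permutation(len(entries))
    placed = [entries[i] for i in order]
    lengths = [len(entry_seq(e)) for e in placed]
    n = len(placed)
    slack = spec.genome_length - sum(lengths) - (n + 1) * spec.min_gap
    if slack < 0:
        raise InfeasiblePackingError(
            f"{n} features totalling {sum(lengths)} nt plus {n + 1} gaps of "
            f">= {spec.min_gap} nt exceed genome_length={spec.genome_length}")
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    gap_lens = [spec.min_gap + int(x) for x in extra]

    parts = []
    intervals = {}          # entry-id -> (start, end)
    gap_intervals = []      # genomic intervals of gaps, for hairpin repair
    pos = 0
    for i, e in enumerate(placed):
        g = random_seq(rng, gap_lens[i])
        parts.append(g)
        gap_intervals.append((pos, pos + gap_lens[i]))
        pos += gap_lens[i]
        s = entry_seq(e)
        parts.append(s)
        intervals[e[1]] = (pos, pos + len(s))
        pos += len(s)
    g = random_seq(rng, gap_lens[n])
    parts.append(g)
    gap_intervals.append((pos, pos + gap_lens[n]))
    genome_list = list("".join(parts))

    # --- feature annotation (stray MITE and novel hairpins excluded) ------
    feat_rows = []
    for kind, eid, _seq, payload in entries:
        start, end = intervals[eid]
        if kind in _NCRNA_LEN:
            feat_rows.append((CHROM, start, end, "+", kind, eid))
        elif kind == "gene":
            for part, j, rs, re_ in payload["layout"]["rel"]:
                feat_rows.append((CHROM, start + rs, start + re_, "+",
                                  part, f"{eid}_{part}{j + 1}"))
        elif kind == "repeat":
            feat_rows.append((CHROM, start, end, "+", "repeat", eid))
        elif kind == "known_hairpin":
            feat_rows.append((CHROM, start, end, "+", "miRNA_hairpin", eid))
    features = pd.DataFrame(feat_rows, columns=["chrom", "start", "end",
                                                "strand", "cls", "feature_id"])

    # --- truth ledger ------------------------------------------------------
    truth_rows = []
    for mdef in mir_defs:
        start, end = intervals[mdef["id"]]
        L = len(mdef["locus"])
        ml = len(mdef["mature"])
        sl = len(mdef["star"])
        if mdef["strand"] == "+":
            m0 = start + mdef["mature_off"]
            s0 = start + mdef["star_off"]
        else:
            m0 = start + L - mdef["mature_off"] - ml
            s0 = start + L - mdef["star_off"] - sl
        row = {
            "id": mdef["id"], "kind": mdef["kind"], "chrom": CHROM,
            "start": start, "end": end, "strand": mdef["strand"],
            "mature_start": m0, "mature_end": m0 + ml,
            "star_start": s0, "star_end": s0 + sl,
            "mature_seq": mdef["mature"], "star_seq": mdef["star"],
            "arm": mdef["arm"], "label": mdef["label"],
            "target_gene": mdef["target_gene"],
            "site_tpos": mdef["site_tpos"],
            "cleavage_pos": mdef["cleavage_pos"],
            "passes_all_filters": mdef["kind"] == "novel",
        }
        row.update(dict(zip(TPM_COLS, mdef["tpm"])))
        truth_rows.append(row)
    ms, me = intervals["MITE-stray"]
    truth_rows.append({
        "id": "MITE-stray", "kind": "mite_unannotated", "chrom": CHROM,
        "start": ms, "end": me, "strand": "+",
        "mature_start": -1, "mature_end": -1, "star_start": -1,
        "star_end": -1, "mature_seq": "", "star_seq": "", "arm": "",
        "label": "", "target_gene": "", "site_tpos": -1, "cleavage_pos": -1,
        "passes_all_filters": False,
        **{c: 0.0 for c in TPM_COLS},
    })
    truth = pd.DataFrame(truth_rows)

    genome = {CHROM: "".join(genome_list)}

    if validate:
        _validate_plant(genome, truth, gap_intervals, genome_list, rng)
        genome = {CHROM: "".join(genome_list)}

    # --- hairpin reference (known miRNAs only) -----------------------------
    known_precursors, known_mature_coords, meta_rows = {}, {}, []
    for i, mdef in enumerate(mir_defs):
        if mdef["kind"] != "known":
            continue
        known_precursors[mdef["id"]] = mdef["locus"]
        known_mature_coords[mdef["id"]] = (
            mdef["mature_off"], mdef["mature_off"] + len(mdef["mature"]))
        meta_rows.append({"miRNA": mdef["id"],
                          "family": f"fam{i % 5 + 1}",
                          "conserved": i % 2 == 0})
    known_meta = pd.DataFrame(meta_rows).set_index("miRNA")

    # --- transcripts --------------------------------------------------------
    transcripts = {}
    for layout in gene_layouts:
        exons = [layout["parts"][k] for k in (0, 2, 4)]
        transcripts[layout["id"]] = "".join(exons)

    # --- GO map and gene expression ----------------------------------------
    go_map, gene_expression = _make_go_and_expression(
        rng, gene_layouts, mir_defs)

    bundle = GenomeBundle(
        genome=genome, features=features,
        known_precursors=known_precursors,
        known_mature_coords=known_mature_coords, known_meta=known_meta,
        transcripts=transcripts, repeat_library=repeat_library,
        go_map=go_map, gene_expression=gene_expression, truth=truth)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _validate_plant(genome, truth, gap_intervals, genome_list, rng,
                    max_attempts: int = 30):
    """Check planted-locus invariants; repair hairpin context if needed.

    Each mature sequence must occur exactly once in the genome (twice for
    the known miRNA carrying a perfect-complement target site), and every
    planted hairpin must be accepted by the hairpin evaluation.  When the
    random context around a hairpin spoils its fold, the two adjacent gap
    regions are redrawn (deterministically from the build rng).
    """
    from .novel import evaluate_hairpin

    for row in truth.itertuples():
        if row.kind not in ("known", "novel"):
            continue
        expected = 2 if row.id == "miR-K01" else 1
        occ = _occurrences(genome, row.mature_seq)
        if occ != expected:
            raise RuntimeError(
                f"planted mature of {row.id} occurs {occ}x (expected "
                f"{expected}); re-seed the generator")
        for _ in range(max_attempts):
            ev = evaluate_hairpin(genome, row.chrom, row.mature_start,
                                  row.mature_end, row.strand)
            if ev.accepted:
                break
            lo, hi = row.start - 200, row.end + 200
            for gs, ge in gap_intervals:
                if gs < hi and lo < ge:
                    genome_list[gs:ge] = list(random_seq(rng, ge - gs))
            genome[CHROM] = "".join(genome_list)
        else:
            raise RuntimeError(f"could not stabilise hairpin {row.id}: "
                               f"{ev.reason}")


def _make_go_and_expression(rng, gene_layouts, mir_defs):
    gene_ids = [g["id"] for g in gene_layouts]
    fillers = [f"bg{i + 1:03d}" for i in range(270)]
    universe = gene_ids + fillers
    novel_hosts = [m["target_gene"] for m in mir_defs if m["kind"] == "novel"]
    known_hosts = [m["target_gene"] for m in mir_defs if m["kind"] == "known"]
    rows = []

    def add(term, name, branch, genes):
        rows.extend((g, term, name, branch) for g in sorted(set(genes)))

    add("GO:0006333", "chromatin assembly or disassembly",
        "biological_process",
        novel_hosts + list(rng.choice(fillers, size=5, replace=False)))
    add("GO:0003700", "DNA-binding transcription factor activity",
        "molecular_function",
        known_hosts[:6] + list(rng.choice(fillers, size=10, replace=False)))
    add("GO:0006355", "regulation of transcription", "biological_process",
        list(rng.choice(universe, size=40, replace=False)))
    add("GO:0009058", "biosynthetic process", "biological_process",
        list(rng.choice(universe, size=60, replace=False)))
    add("GO:0016301", "kinase activity", "molecular_function",
        list(rng.choice(universe, size=30, replace=False)))
    add("GO:0005634", "nucleus", "cellular_component",
        list(rng.choice(universe, size=50, replace=False)))
    go_map = pd.DataFrame(rows, columns=["gene_id", "term_id", "name",
                                         "branch"])

    host_of = {}
    for m in mir_defs:
        host_of.setdefault(m["target_gene"], m)
    expr_rows = {}
    for gid in gene_ids:
        m = host_of.get(gid)
        if m is None:
            expr_rows[gid] = list(np.round(rng.uniform(80, 400, size=6), 3))
        elif m["id"] == "miR-K02":
            # positive-control pair: target follows its miRNA
            expr_rows[gid] = list(m["tpm"])
        else:
            logs = np.log2(np.asarray(m["tpm"]) + 1.0)
            expr_rows[gid] = list(np.round(2.0 ** np.clip(14.0 - logs, 0,
                                                          None) - 1.0, 3))
    gene_expression = pd.DataFrame.from_dict(
        expr_rows, orient="index", columns=LIBRARY_NAMES)
    gene_expression.index.name = "gene_id"
    return go_map, gene_expression


# ---------------------------------------------------------------------------
# library simulation

def default_library_specs(total_reads: int = 60_000, seed: int = 0,
                          **overrides) -> dict:
    """Six library specs with size-distribution shapes shifting from
    24-nt-dominant early pollen (and callus/root) to 21-nt-dominant
    tricellular pollen and leaf."""
    w24 = {"UNM": 0.70, "BCP": 0.55, "TCP": 0.25,
           "callus": 0.70, "leaf": 0.30, "root": 0.65}
    return {
        name: LibrarySpec(name=name, total_reads=total_reads,
                          weight_24=w24[name], seed=seed * 1009 + i,
                          **overrides)
        for i, name in enumerate(LIBRARY_NAMES)
    }


def simulate_library(bundle: GenomeBundle, spec: LibrarySpec) -> list:
    """Simulate one library; returns FASTQ records as (id, seq, qual).

    Reads from planted miRNA loci are drawn in Poisson numbers around
    ``TPM * total / 1e6`` (mature and, at ``star_ratio``, star); the
    remainder is split into repeat-derived siRNAs (with the library's
    21/24 length mixture), transcript/ncRNA degradation fragments,
    antisense fragments, random noise and short inserts.  Each read is
    insert + 3' adaptor padded/truncated to ``read_length``.
    """
    rng = np.random.default_rng(spec.seed)
    mir = bundle.truth[bundle.truth["kind"].isin(["known", "novel"])]
    tpm = mir[f"tpm_{spec.name}"].to_numpy(dtype=float)
    if bundle.truth[TPM_COLS].to_numpy().sum() == 0:
        raise ValueError("all expected TPMs are zero: nothing to sample")
    n = spec.total_reads
    inserts: list[str] = []

    expected = tpm * n / 1e6
    mature_counts = rng.poisson(expected)
    star_counts = rng.poisson(expected * spec.star_ratio)
    for (_, row), mc, sc in zip(mir.iterrows(), mature_counts, star_counts):
        inserts.extend([row["mature_seq"]] * int(mc))
        inserts.extend([row["star_seq"]] * int(sc))

    n_deg = int(round(spec.degradation_fraction * n))
    n_noise = int(round(spec.noise_fraction * n))
    n_anti = int(round(spec.antisense_fraction * n))
    n_short = int(round(spec.short_insert_fraction * n))
    n_sirna = max(0, n - len(inserts) - n_deg - n_noise - n_anti - n_short)

    chrom_seq = bundle.genome[CHROM]
    repeats = bundle.features[bundle.features["cls"] == "repeat"]
    rep_iv = list(zip(repeats["start"], repeats["end"]))
    stray = bundle.truth[bundle.truth["kind"] == "mite_unannotated"].iloc[0]
    # siRNA production sites on the stray MITE: one 24-mer per arm
    mite_tags = [chrom_seq[stray.start + 3: stray.start + 27],
                 chrom_seq[stray.start + 45: stray.start + 69]]
    for _ in range(n_sirna):
        if rng.random() < spec.mite_weight:
            inserts.append(mite_tags[int(rng.integers(2))])
            continue
        length = _sirna_length(rng, spec.weight_24)
        rs, re_ = rep_iv[int(rng.integers(len(rep_iv)))]
        start = int(rng.integers(rs, max(rs + 1, re_ - length)))
        inserts.append(chrom_seq[start:start + length])

    sources = list(bundle.transcripts.values())
    ncrna = bundle.features[bundle.features["cls"].isin(
        ["rRNA", "tRNA", "snRNA", "snoRNA"])]
    sources.extend(chrom_seq[r.start:r.end] for r in ncrna.itertuples())
    # unspliced pre-mRNA is degraded too: introns contribute fragments
    introns = bundle.features[bundle.features["cls"] == "intron"]
    sources.extend(chrom_seq[r.start:r.end] for r in introns.itertuples())
    lens = np.array([len(s) for s in sources], dtype=float)
    src_p = lens / lens.sum()
    for _ in range(n_deg):
        inserts.append(_fragment(rng, sources, src_p))
    for _ in range(n_anti):
        inserts.append(revcomp(_fragment(rng, sources, src_p)))
    for _ in range(n_noise):
        inserts.append(random_seq(rng, int(rng.integers(18, 31))))
    for _ in range(n_short):
        inserts.append(random_seq(rng, int(rng.integers(8, 15))))

    order = rng.permutation(len(inserts))
    records = []
    err_any = 1.0 - (1.0 - spec.error_rate) ** spec.read_length
    for i, idx in enumerate(order):
        read = (inserts[idx] + spec.adaptor)[:spec.read_length]
        if len(read) < spec.read_length:
            read += random_seq(rng, spec.read_length - len(read))
        if rng.random() < err_any:
            p = int(rng.integers(len(read)))
            read = read[:p] + _mutate_base(rng, read[p], set()) + read[p + 1:]
        qual = ("#" if rng.random() < spec.low_quality_fraction else "I") \
            * len(read)
        records.append((f"{spec.name}_{i + 1:06d}", read, qual))
    return records


def _sirna_length(rng, weight_24: float) -> int:
    center = 24 if rng.random() < weight_24 else 21
    return center + int(rng.integers(-1, 2))


def _fragment(rng, sources, p=None, lo: int = 18, hi: int = 30) -> str:
    idx = int(rng.choice(len(sources), p=p)) if p is not None \
        else int(rng.integers(len(sources)))
    seq = sources[idx]
    length = int(rng.integers(lo, hi + 1))
    length = min(length, len(seq))
    start = int(rng.integers(0, max(1, len(seq) - length + 1)))
    return seq[start:start + length]


def write_fastq(path, records) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# on-disk bundle

def _write_bundle(bundle: GenomeBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["genome"] = out / "genome.fa"
    write_fasta(paths["genome"], bundle.genome)

    paths["features_bed"] = out / "features.bed"
    bed = bundle.features[["chrom", "start", "end"]].copy()
    bed["name"] = bundle.features["cls"] + ":" + bundle.features["feature_id"]
    bed["score"] = 0
    bed["strand"] = bundle.features["strand"]
    bed.to_csv(paths["features_bed"], sep="\t", header=False, index=False)

    paths["features_gff3"] = out / "features.gff3"
    with open(paths["features_gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for r in bundle.features.itertuples():
            fh.write(f"{r.chrom}\tpollenmir\t{r.cls}\t{r.start + 1}\t{r.end}"
                     f"\t.\t{r.strand}\t.\tID={r.feature_id}\n")

    paths["hairpins"] = out / "hairpins_known.fa"
    write_fasta(paths["hairpins"], bundle.known_precursors)
    paths["hairpin_mature"] = out / "hairpins_known_mature.tsv"
    mature = pd.DataFrame(
        [(mid, m0, m1) for mid, (m0, m1) in bundle.known_mature_coords.items()],
        columns=["miRNA", "mature_start", "mature_end"]).set_index("miRNA")
    mature.join(bundle.known_meta).to_csv(paths["hairpin_mature"], sep="\t")

    paths["transcripts"] = out / "transcripts.fa"
    write_fasta(paths["transcripts"], bundle.transcripts)
    paths["repeats"] = out / "repeats.fa"
    write_fasta(paths["repeats"], bundle.repeat_library)
    paths["go_map"] = out / "go_map.tsv"
    bundle.go_map.to_csv(paths["go_map"], sep="\t", index=False)
    paths["gene_expression"] = out / "gene_expression.tsv"
    bundle.gene_expression.to_csv(paths["gene_expression"], sep="\t")
    paths["truth"] = out / "truth.tsv"
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    bundle.paths = {k: str(v) for k, v in paths.items()}


def load_bundle(directory) -> GenomeBundle:
    """Re-load a bundle previously written by :func:`build_genome`."""
    from .seqs import read_fasta

    d = Path(directory)
    bed = pd.read_csv(d / "features.bed", sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score",
                             "strand"])
    cls_id = bed["name"].str.split(":", n=1, expand=True)
    features = pd.DataFrame({
        "chrom": bed["chrom"], "start": bed["start"], "end": bed["end"],
        "strand": bed["strand"], "cls": cls_id[0], "feature_id": cls_id[1]})
    mature = pd.read_csv(d / "hairpins_known_mature.tsv", sep="\t",
                         index_col="miRNA")
    return GenomeBundle(
        genome=read_fasta(d / "genome.fa"),
        features=features,
        known_precursors=read_fasta(d / "hairpins_known.fa"),
        known_mature_coords={m: (int(r["mature_start"]), int(r["mature_end"]))
                             for m, r in mature.iterrows()},
        known_meta=mature[["family", "conserved"]],
        transcripts=read_fasta(d / "transcripts.fa"),
        repeat_library=read_fasta(d / "repeats.fa"),
        go_map=pd.read_csv(d / "go_map.tsv", sep="\t", dtype=str),
        gene_expression=pd.read_csv(d / "gene_expression.tsv", sep="\t",
                                    index_col="gene_id"),
        truth=pd.read_csv(d / "truth.tsv", sep="\t"),
        paths={})


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
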