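"""Synthetic genome/library generator: determinism, ground truth, labels."""

import numpy as np
import pandas as pd
import pytest

from pollenmir.expression import call_enrichment
from pollenmir.synthetic import (LIBRARY_NAMES, TPM_COLS, GenomeBundle,
                                 InfeasiblePackingError, LibrarySpec,
                                 SyntheticGenomeSpec, build_genome,
                                 default_library_specs, file_digest,
                                 load_bundle, simulate_library, write_fastq)


def test_same_seed_byte_identical(tmp_path):
    spec = SyntheticGenomeSpec(seed=42, n_genes=20, n_known_hairpins=4,
                               n_novel_hairpins=5)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    b1 = build_genome(spec, out_dir=d1)
    b2 = build_genome(spec, out_dir=d2)
    for name in b1.paths:
        assert file_digest(b1.paths[name]) == file_digest(b2.paths[name]), name
    specs = default_library_specs(total_reads=2000, seed=3)
    r1 = simulate_library(b1, specs["TCP"])
    r2 = simulate_library(b2, specs["TCP"])
    assert r1 == r2


def test_bundle_roundtrip(tmp_path):
    spec = SyntheticGenomeSpec(seed=5, n_genes=20, n_known_hairpins=4,
                               n_novel_hairpins=5)
    b1 = build_genome(spec, out_dir=tmp_path)
    b2 = load_bundle(tmp_path)
    assert b1.genome == b2.genome
    assert b1.known_precursors == b2.known_precursors
    assert b1.transcripts == b2.transcripts
    pd.testing.assert_frame_equal(
        b1.features.reset_index(drop=True),
        b2.features.reset_index(drop=True), check_dtype=False)


def test_ledger_counts_planted_novel_loci():
    spec = SyntheticGenomeSpec(seed=6, n_novel_hairpins=20, n_genes=32)
    bundle = build_genome(spec)
    novel = bundle.truth[bundle.truth["kind"] == "novel"]
    assert len(novel) == 20
    assert novel["passes_all_filters"].all()


def test_zero_novel_spec():
    spec = SyntheticGenomeSpec(seed=7, n_novel_hairpins=0, n_genes=15)
    bundle = build_genome(spec)
    assert (bundle.truth["kind"] == "novel").sum() == 0


def test_infeasible_packing_named():
    spec = SyntheticGenomeSpec(seed=0, genome_length=5_000)
    with pytest.raises(InfeasiblePackingError, match="genome_length"):
        build_genome(spec)


def test_expression_labels_consistent_with_enrichment(small_bundle):
    """The planted class labels must satisfy the enrichment definition on
    the expected TPM profiles (spec invariant of the truth ledger)."""
    truth = small_bundle.expression_truth
    tpm = truth[LIBRARY_NAMES].astype(float)
    sample = call_enrichment(tpm, "sample")
    group = call_enrichment(tpm, "group")
    for mid, row in truth.iterrows():
        label = row["label"]
        if label == "constitutive":
            sub = sample[sample["miRNA"] == mid]
            assert (sub["zscore"] == 0).all()
            assert not sub["enriched"].any()
        elif label.startswith("stage_specific"):
            stage = label.rsplit("_", 1)[1]
            hit = sample[(sample["miRNA"] == mid)
                         & (sample["target"] == stage)]
            assert hit["enriched"].all()
        elif label == "pollen_enriched":
            hit = group[(group["miRNA"] == mid)
                        & (group["target"] == "pollen")]
            assert hit["enriched"].all()
        elif label == "sporophyte_enriched":
            hit = group[(group["miRNA"] == mid)
                        & (group["target"] == "sporophyte")]
            assert hit["enriched"].all()


def test_planted_matures_unique_and_hairpins_fold(small_bundle):
    from pollenmir.novel import evaluate_hairpin
    from pollenmir.synthetic import _occurrences

    mir = small_bundle.truth[small_bundle.truth["kind"].isin(
        ["known", "novel"])]
    for row in mir.itertuples():
        expected = 2 if row.id == "miR-K01" else 1
        assert _occurrences(small_bundle.genome, row.mature_seq) == expected
        ev = evaluate_hairpin(small_bundle.genome, row.chrom,
                              row.mature_start, row.mature_end, row.strand)
        assert ev.accepted, (row.id, ev.reason)
        assert ev.candidate.n_paired >= 16


def test_novel_hairpins_absent_from_reference(small_bundle):
    novel = small_bundle.truth[small_bundle.truth["kind"] == "novel"]
    for seq in novel["mature_seq"]:
        assert all(seq not in prec
                   for prec in small_bundle.known_precursors.values())


def test_perfect_complement_site_planted(small_bundle):
    from pollenmir.seqs import revcomp

    row = small_bundle.truth.set_index("id").loc["miR-K01"]
    t = small_bundle.transcripts[row["target_gene"]]
    site = t[int(row["site_tpos"]): int(row["site_tpos"])
             + len(row["mature_seq"])]
    assert site == revcomp(row["mature_seq"])


class TestSimulateLibrary:
    def test_record_count(self, small_bundle):
        spec = LibrarySpec(name="UNM", total_reads=1000, seed=1)
        assert len(simulate_library(small_bundle, spec)) == 1000

    def test_invalid_library_name(self):
        with pytest.raises(ValueError):
            LibrarySpec(name="stem")

    def test_fraction_invariants(self):
        with pytest.raises(ValueError):
            LibrarySpec(name="UNM", degradation_fraction=0.9,
                        noise_fraction=0.3)

    def test_all_zero_tpm_fails(self, small_bundle):
        zeroed = small_bundle.truth.copy()
        zeroed[TPM_COLS] = 0.0
        broken = GenomeBundle(**{**small_bundle.__dict__, "truth": zeroed})
        with pytest.raises(ValueError, match="nothing to sample"):
            simulate_library(broken, LibrarySpec(name="UNM", seed=0))

    def test_pure_mirna_library_reads_match_mature(self, small_bundle):
        """With all non-miRNA fractions off and no errors, every read is a
        planted mature or star sequence plus adaptor."""
        spec = LibrarySpec(name="UNM", total_reads=400, seed=2,
                           degradation_fraction=0.0, noise_fraction=0.0,
                           antisense_fraction=0.0, short_insert_fraction=0.0,
                           mite_weight=1.0, low_quality_fraction=0.0,
                           error_rate=0.0)
        recs = simulate_library(small_bundle, spec)
        mir = small_bundle.truth[small_bundle.truth["kind"].isin(
            ["known", "novel"])]
        expected = set(mir["mature_seq"]) | set(mir["star_seq"])
        stray = small_bundle.truth.set_index("id").loc["MITE-stray"]
        chrom = small_bundle.genome[stray["chrom"]]
        expected |= {chrom[int(stray["start"]) + 3: int(stray["start"]) + 27],
                     chrom[int(stray["start"]) + 45: int(stray["start"]) + 69]}
        for _rid, seq, qual in recs:
            assert any(seq.startswith(e) for e in expected)
            assert len(seq) == len(qual) == spec.read_length

    def test_star_cosampling_binomial(self, small_bundle):
        """Star reads appear at ~star_ratio of mature reads (fixed seed)."""
        spec = LibrarySpec(name="callus", total_reads=50_000, seed=9,
                           star_ratio=0.25, error_rate=0.0,
                           low_quality_fraction=0.0)
        recs = simulate_library(small_bundle, spec)
        truth = small_bundle.truth.set_index("id")
        # constitutive known miRNA: high depth in callus
        cands = truth[(truth["kind"] == "known")
                      & (truth["label"] == "constitutive")]
        row = cands.iloc[0]
        n_mat = sum(seq.startswith(row["mature_seq"]) for _r, seq, _q in recs)
        n_star = sum(seq.startswith(row["star_seq"]) for _r, seq, _q in recs)
        assert n_mat > 0
        ratio = n_star / n_mat
        # 3-sigma binomial band around 0.25
        sd = np.sqrt(0.25 / n_mat)
        assert abs(ratio - 0.25) < 4 * sd + 0.02

    def test_fastq_writer_valid(self, small_bundle, tmp_path):
        from Bio.SeqIO.QualityIO import FastqGeneralIterator

        spec = LibrarySpec(name="leaf", total_reads=50, seed=3)
        recs = simulate_library(small_bundle, spec)
        path = tmp_path / "x.fastq"
        write_fastq(path, recs)
        with open(path) as fh:
            parsed = list(FastqGeneralIterator(fh))
        assert len(parsed) == 50
        assert all(len(s) == len(q) for _i, s, q in parsed)
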