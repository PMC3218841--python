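"""End-to-end orchestration of the small RNA analysis stages.

Stage order: preprocess -> map -> annotate -> novel -> expression ->
targets -> GO.  A single YAML config names every input file and parameter;
all randomness derives from one root seed, and a rerun with the same
config is byte-identical (verified via the artifact manifest of SHA-256
digests).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import expression as expr
from . import go_enrich
from . import mapping
from . import novel as nov
from . import preprocess as pp
from . import synthetic
from . import targets as tg
from .seqs import read_fasta
from .synthetic import LIBRARY_NAMES

DEFAULT_PARAMS = {
    "adaptor": synthetic.DEFAULT_ADAPTOR,
    "min_qual": 20.0,
    "max_n": 0,
    "min_overlap": 6,
    "max_error_rate": 0.2,
    "min_len": 18,
    "max_len": 30,
    "novel_min_count": 5,
    "novel_window": 150,
    "kmeans_k_known": 18,
    "kmeans_k_novel": 8,
    "pseudocount": 1.0,
    "max_penalty": 3.0,
    "r_threshold": 0.5,
    "go_alpha": 0.01,
    "seed": 0,
}

REQUIRED_INPUTS = ["genome", "features_bed", "hairpins", "hairpin_mature",
                   "transcripts", "repeats", "go_map", "gene_expression"]


class ConfigError(ValueError):
    pass


@dataclass
class RunReport:
    preprocess: pd.DataFrame
    mapping: pd.DataFrame
    accounting: pd.DataFrame
    known_counts: pd.DataFrame
    novel: list
    tpm: pd.DataFrame
    enrichment: pd.DataFrame
    target_sites: list
    avg_targets_per_mirna: float
    correlation: pd.DataFrame
    go_results: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    @property
    def n_novel(self) -> int:
        return len(self.novel)

    @property
    def n_known_expressed(self) -> int:
        return int((self.known_counts["total"] > 0).sum())

    def summary(self) -> dict:
        enr = self.enrichment
        pollen = enr[(enr["scope"] == "group") & (enr["target"] == "pollen")
                     & enr["enriched"]]
        return {
            "libraries": list(self.preprocess.index),
            "n_known_mirnas": len(self.known_counts),
            "n_known_expressed": self.n_known_expressed,
            "n_novel_mirnas": self.n_novel,
            "n_pollen_enriched": int(len(pollen)),
            "n_target_sites": len(self.target_sites),
            "avg_targets_per_mirna": self.avg_targets_per_mirna,
            "n_go_significant": int(self.go_results["significant"].sum())
            if len(self.go_results) else 0,
        }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cfg["_dir"] = str(Path(path).parent)
    return cfg


def validate_config(cfg: dict) -> dict:
    """Resolve paths and check every referenced file before any stage runs."""
    base = Path(cfg.get("_dir", "."))

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    inputs = cfg.get("inputs", {})
    missing = [k for k in REQUIRED_INPUTS if k not in inputs]
    if missing:
        raise ConfigError(f"config missing input paths: {missing}")
    resolved = {k: resolve(v) for k, v in inputs.items() if k != "libraries"}
    libs = inputs.get("libraries", {})
    if not libs:
        raise ConfigError("config lists no libraries")
    resolved["libraries"] = {name: resolve(p) for name, p in libs.items()}
    for k, p in resolved.items():
        if k == "libraries":
            for name, lp in p.items():
                if not lp.exists():
                    raise ConfigError(f"library {name}: missing file {lp}")
        elif not p.exists():
            raise ConfigError(f"input {k}: missing file {p}")
    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params", {}))
    if not isinstance(params["seed"], int):
        raise ConfigError("seed must be an integer")
    out_dir = resolve(cfg.get("output_dir", "results"))
    return {"inputs": resolved, "params": params, "output_dir": out_dir}


def run_pipeline(config) -> RunReport:
    """Run all stages; ``config`` is a YAML path or a config dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = validate_config(config)
    inputs, params = cfg["inputs"], cfg["params"]
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    def save(name, df, **kw):
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        artifacts[name] = path

    # ---- preprocess -------------------------------------------------------
    lib_order = ([n for n in LIBRARY_NAMES if n in inputs["libraries"]]
                 + [n for n in inputs["libraries"] if n not in LIBRARY_NAMES])
    inserts_by_lib, pstats_rows = {}, {}
    for lib in lib_order:
        fq = inputs["libraries"][lib]
        ins, st = pp.preprocess_fastq(
            fq, params["adaptor"], q_min=params["min_qual"],
            max_n=params["max_n"], min_overlap=params["min_overlap"],
            max_error_rate=params["max_error_rate"],
            min_insert=params["min_len"])
        inserts_by_lib[lib] = ins
        pstats_rows[lib] = st
    tags, cstats, hist = pp.collapse_tags(
        inserts_by_lib, params["min_len"], params["max_len"])
    pstats = pd.DataFrame(pstats_rows).T.join(cstats)
    save("preprocess_stats.tsv", pstats, index_label="library")
    save("length_histogram.tsv", hist, index_label="length")
    save("tags.tsv", tags)

    # ---- map --------------------------------------------------------------
    genome = read_fasta(inputs["genome"])
    index = mapping.GenomeIndex(genome)
    mapped, map_stats = mapping.map_tags(tags, index)
    save("mapping_stats.tsv", map_stats, index_label="library")
    save("hits.bed", mapping.hits_table(mapped), index=False, header=False)

    # ---- annotate ---------------------------------------------------------
    features = _read_features_bed(inputs["features_bed"])
    findex = ann.FeatureIndex(features)
    annotations = ann.classify_all(mapped, findex)
    accounting = ann.accounting_report(mapped, annotations, pstats)
    save("accounting.tsv", accounting, index_label="class")
    precursors = read_fasta(inputs["hairpins"])
    mature_tab = pd.read_csv(inputs["hairpin_mature"], sep="\t",
                             index_col="miRNA")
    mature_coords = {m: (int(r["mature_start"]), int(r["mature_end"]))
                     for m, r in mature_tab.iterrows()}
    meta_cols = [c for c in ("family", "conserved") if c in mature_tab]
    known_counts = ann.quantify_known_mirnas(
        mapped, precursors, mature_coords,
        meta=mature_tab[meta_cols] if meta_cols else None)
    save("known_mirnas.tsv", known_counts)

    # ---- novel ------------------------------------------------------------
    transcripts = read_fasta(inputs["transcripts"])
    repeat_library = read_fasta(inputs["repeats"])

    def has_target(seq):
        sites, _, _ = tg.scan_transcripts({"q": seq}, transcripts,
                                          max_penalty=params["max_penalty"])
        return len(sites) > 0

    candidates = ann.candidate_tags(mapped, annotations)
    novel, flags = nov.predict_novel_mirnas(
        candidates, genome, mapped, repeat_library,
        min_count=params["novel_min_count"], window=params["novel_window"],
        target_checker=has_target)
    libs = list(inputs["libraries"])
    save("novel_mirnas.tsv", nov.novel_table(novel, libs), index=False)
    save("novel_filters.tsv", flags, index=False)

    # ---- expression -------------------------------------------------------
    counts = pd.DataFrame(
        {lib: known_counts[f"mature_{lib}"] for lib in libs})
    for nm in novel:
        counts.loc[nm.mirna_id] = [nm.counts.get(lib, 0) for lib in libs]
    totals = pstats["reads_18_30"]
    tpm = expr.to_tpm(counts, totals)
    save("tpm.tsv", tpm, index_label="miRNA")
    enr = pd.concat([expr.call_enrichment(tpm, "sample"),
                     expr.call_enrichment(tpm, "group")], ignore_index=True)
    save("enrichment.tsv", enr, index=False)
    known_ids = [i for i in tpm.index if i in known_counts.index]
    novel_ids = [nm.mirna_id for nm in novel]
    cluster_frames = []
    for subset, kparam in ((known_ids, "kmeans_k_known"),
                           (novel_ids, "kmeans_k_novel")):
        if len(subset) >= 2:
            k = min(params[kparam], len(subset))
            asg, _ = expr.kmeans_profiles(tpm.loc[subset], k,
                                          seed=params["seed"])
            asg["set"] = "known" if kparam.endswith("known") else "novel"
            cluster_frames.append(asg)
    clusters = (pd.concat(cluster_frames) if cluster_frames
                else pd.DataFrame(columns=["cluster", "set"]))
    save("clusters.tsv", clusters, index_label="miRNA")
    pca = expr.pca_samples(tpm, pseudocount=params["pseudocount"])
    save("pca_scores.tsv", pca.sample_scores, index_label="sample")
    save("pca_contributions.tsv", pca.contributions, index_label="miRNA")
    save("pca_variance.tsv", pca.explained_variance.to_frame("fraction"),
         index_label="component")

    # ---- targets ----------------------------------------------------------
    mirna_seqs = {m: precursors[m][m0:m1]
                  for m, (m0, m1) in mature_coords.items()}
    mirna_seqs.update({nm.mirna_id: nm.hairpin.mature_seq for nm in novel})
    sites, site_counts, avg = tg.scan_transcripts(
        mirna_seqs, transcripts, max_penalty=params["max_penalty"])
    save("target_sites.tsv", tg.sites_table(sites), index=False)
    gene_expr = pd.read_csv(inputs["gene_expression"], sep="\t",
                            index_col="gene_id")
    pairs = sorted({(s.mirna_id, s.transcript_id) for s in sites
                    if s.transcript_id in gene_expr.index
                    and s.mirna_id in tpm.index})
    corr = tg.correlate_expression(
        tpm, gene_expr[list(tpm.columns)], pairs,
        r_negative=-params["r_threshold"], r_positive=params["r_threshold"])
    save("correlation.tsv", corr, index=False)

    # ---- GO ---------------------------------------------------------------
    go_map = go_enrich.read_go_map(inputs["go_map"])
    pollen_libs = [l for l in libs if l in expr.POLLEN]
    pollen_novel = {nm.mirna_id for nm in novel
                    if any(nm.counts.get(l, 0) > 0 for l in pollen_libs)}
    query = sorted({s.transcript_id for s in sites
                    if s.mirna_id in pollen_novel})
    query = [g for g in query if g in set(go_map["gene_id"])]
    if query:
        go_res = go_enrich.enrich(query, go_map, alpha=params["go_alpha"])
    else:
        go_res = pd.DataFrame(columns=["term_id", "name", "branch", "k", "n",
                                       "K", "N", "p", "fdr", "significant"])
    save("go_results.tsv", go_res, index=False)

    # ---- report + manifest ------------------------------------------------
    report = RunReport(
        preprocess=pstats, mapping=map_stats, accounting=accounting,
        known_counts=known_counts, novel=novel, tpm=tpm, enrichment=enr,
        target_sites=sites, avg_targets_per_mirna=avg, correlation=corr,
        go_results=go_res)
    with open(out / "report.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2)
    artifacts["report.json"] = out / "report.json"
    manifest = {name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
                for name, p in sorted(artifacts.items())}
    pd.Series(manifest, name="sha256").to_csv(out / "manifest.tsv", sep="\t",
                                              index_label="artifact")
    report.manifest = manifest
    return report


def _read_features_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score",
                             "strand"])
    cls_id = bed["name"].str.split(":", n=1, expand=True)
    return pd.DataFrame({
        "chrom": bed["chrom"], "start": bed["start"], "end": bed["end"],
        "strand": bed["strand"], "cls": cls_id[0], "feature_id": cls_id[1]})


def make_demo(out_dir, seed: int = 0, total_reads: int = 60_000,
              genome_spec: synthetic.SyntheticGenomeSpec | None = None,
              **library_overrides):
    """Generate a ready-to-run demo: bundle + six libraries + config.

    Returns ``(config_path, bundle)``.  The whole pipeline on the default
    demo completes in minutes on one CPU.
    """
    out = Path(out_dir)
    bundle_dir = out / "bundle"
    if genome_spec is None:
        genome_spec = synthetic.SyntheticGenomeSpec(seed=seed)
    bundle = synthetic.build_genome(genome_spec, out_dir=bundle_dir)
    specs = synthetic.default_library_specs(total_reads=total_reads,
                                            seed=seed, **library_overrides)
    lib_paths = {}
    for name in LIBRARY_NAMES:
        recs = synthetic.simulate_library(bundle, specs[name])
        path = bundle_dir / f"{name}.fastq"
        synthetic.write_fastq(path, recs)
        lib_paths[name] = str(path)
    def absolute(p):
        return str(Path(p).resolve())

    cfg = {
        "output_dir": absolute(out / "results"),
        "inputs": {
            "genome": absolute(bundle.paths["genome"]),
            "features_bed": absolute(bundle.paths["features_bed"]),
            "hairpins": absolute(bundle.paths["hairpins"]),
            "hairpin_mature": absolute(bundle.paths["hairpin_mature"]),
            "transcripts": absolute(bundle.paths["transcripts"]),
            "repeats": absolute(bundle.paths["repeats"]),
            "go_map": absolute(bundle.paths["go_map"]),
            "gene_expression": absolute(bundle.paths["gene_expression"]),
            "libraries": {k: absolute(v) for k, v in lib_paths.items()},
        },
        "params": {"seed": seed},
    }
    config_path = out / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return config_path, bundle
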