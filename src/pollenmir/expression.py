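"""miRNA expression profiling across the six libraries.

Counts are normalized to transcripts per million (TPM) of each library's
clean 18–30-nt reads.  Stage/tissue enrichment combines a fold-ratio and a
Z-score cutoff (both > 2 by default): the ratio asks whether a sample (or
group) stands above the rest, the Z-score whether it stands out relative to
the across-sample spread.  Expression profiles are clustered with K-means
on log2(TPM + 1) and summarized by PCA over samples with mean-centering
only (no unit-variance scaling), reporting per-miRNA score contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

POLLEN = ["UNM", "BCP", "TCP"]
SPOROPHYTE = ["callus", "leaf", "root"]


def to_tpm(counts: pd.DataFrame, library_totals: pd.Series) -> pd.DataFrame:
    """TPM = 1e6 * count / clean-read total of that library."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    totals = library_totals.reindex(counts.columns)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"non-positive library totals: {bad}")
    return counts * 1e6 / totals


def _pop_sd(x: np.ndarray) -> float:
    """Population standard deviation; values that are equal up to floating
    round-off count as a flat profile (sd exactly 0)."""
    sd = float(np.sqrt(np.mean((x - x.mean()) ** 2)))
    if sd <= 1e-9 * max(1.0, float(np.abs(x).max())):
        return 0.0
    return sd


def call_enrichment(tpm: pd.DataFrame, scope: str = "sample",
                    groups: dict | None = None,
                    ratio_cutoff: float = 2.0,
                    z_cutoff: float = 2.0) -> pd.DataFrame:
    """Ratio/Z-score enrichment calls.

    sample scope — for each library i:
        ratio_i = TPM_i / mean(TPM of the other libraries)
        z_i     = (TPM_i - mean(all)) / population sd(all)
    group scope — for each group (default pollen = UNM/BCP/TCP versus the
    sporophytic controls): ratio = mean(group) / mean(complement); z is the
    Z-score of the group's most extreme member on the full profile.

    A zero across-sample sd yields z = 0 (flat profiles are never
    enriched).  Enriched <=> ratio > ratio_cutoff AND z > z_cutoff.
    """
    if scope not in ("sample", "group"):
        raise ValueError(f"unknown scope {scope!r}")
    libs = list(tpm.columns)
    if groups is None:
        groups = {"pollen": [l for l in libs if l in POLLEN],
                  "sporophyte": [l for l in libs if l in SPOROPHYTE]}
    rows = []
    for mirna, profile in tpm.iterrows():
        x = profile.to_numpy(dtype=float)
        mu, sd = x.mean(), _pop_sd(x)
        if scope == "sample":
            for i, lib in enumerate(libs):
                others = np.delete(x, i)
                om = others.mean()
                ratio = np.inf if om == 0 and x[i] > 0 else \
                    (0.0 if om == 0 else x[i] / om)
                z = 0.0 if sd == 0 else (x[i] - mu) / sd
                rows.append((mirna, "sample", lib, ratio, z,
                             bool(ratio > ratio_cutoff and z > z_cutoff)))
        else:
            for gname, members in groups.items():
                rest = [l for l in libs if l not in members]
                if not members or not rest:
                    raise ValueError("each comparison side needs >= 1 library")
                gm = profile[members].mean()
                rm = profile[rest].mean()
                ratio = np.inf if rm == 0 and gm > 0 else \
                    (0.0 if rm == 0 else gm / rm)
                if sd == 0:
                    z = 0.0
                else:
                    devs = {l: (profile[l] - mu) / sd for l in members}
                    z = max(devs.values(), key=abs)
                rows.append((mirna, "group", gname, ratio, z,
                             bool(ratio > ratio_cutoff and z > z_cutoff)))
    return pd.DataFrame(rows, columns=["miRNA", "scope", "target",
                                       "ratio", "zscore", "enriched"])


def kmeans_profiles(tpm: pd.DataFrame, k: int, seed: int = 0,
                    n_init: int = 10, pseudocount: float = 1.0):
    """K-means clustering of log2(TPM + pseudocount) profiles.

    Returns ``(assignments, centroids)``; deterministic for a fixed seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(tpm):
        raise ValueError(f"k={k} exceeds the {len(tpm)} profiles")
    logx = np.log2(tpm.to_numpy(dtype=float) + pseudocount)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(logx)
    assignments = pd.DataFrame({"cluster": labels}, index=tpm.index)
    centroids = pd.DataFrame(km.cluster_centers_, columns=tpm.columns)
    centroids.index.name = "cluster"
    return assignments, centroids


@dataclass
class PcaResult:
    explained_variance: pd.Series      # fraction per component
    sample_scores: pd.DataFrame        # samples x components
    contributions: pd.DataFrame        # miRNAs x components
    contributors: dict                 # component -> list of |contribution|>cut


def pca_samples(tpm: pd.DataFrame, pseudocount: float = 1.0,
                contribution_cutoff: float = 2.0) -> PcaResult:
    """PCA of the samples over log2 miRNA profiles (centering only).

    The data matrix is samples x miRNAs of log2(TPM + pseudocount); each
    miRNA is mean-centered across samples, then decomposed by SVD.  Sample
    scores are the principal-component projections; the per-miRNA score
    contribution to a component is its loading scaled by that component's
    standard deviation, so |contribution| is on the (log2) data scale.
    """
    if tpm.shape[1] < 2 or tpm.shape[0] < 2:
        raise ValueError("need >= 2 samples and >= 2 miRNAs")
    x = np.log2(tpm.to_numpy(dtype=float).T + pseudocount)   # samples x miRNAs
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s ** 2).sum())
    if total == 0:
        raise ValueError("constant expression matrix: no variance to decompose")
    ncomp = int((s > 1e-12 * s[0]).sum())
    comps = [f"PC{i + 1}" for i in range(ncomp)]
    evar = pd.Series((s[:ncomp] ** 2) / total, index=comps)
    scores = pd.DataFrame(u[:, :ncomp] * s[:ncomp], index=tpm.columns,
                          columns=comps)
    nsamp = x.shape[0]
    contrib = pd.DataFrame(
        vt[:ncomp].T * (s[:ncomp] / np.sqrt(nsamp - 1)),
        index=tpm.index, columns=comps)
    contributors = {
        c: contrib.index[contrib[c].abs() > contribution_cutoff].tolist()
        for c in comps
    }
    return PcaResult(evar, scores, contrib, contributors)
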