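"""Orchestration: divergence scan plan, outlier gene sets, and the overlap
between trait-associated and barrier-candidate loci.

The scan plan runs five fixed comparisons derived from the population map:

1. all species-A vs all species-B samples;
2. allopatric A vs allopatric B;
3. sympatric A vs sympatric B;
4. allopatric A vs sympatric A;
5. allopatric B vs sympatric B.

Each comparison yields site-wise F_ST, windowed d_XY for the between-species
comparisons, 99th-quantile outliers, and gene mappings; the best-supported
barrier candidate set is the genes lying in BOTH the F_ST and the d_XY
outlier regions of the between-species scan.  The overlap report intersects
gene sets from all evidence sources, compares window means for
trait-associated windows against the rest (Welch t-tests), and contrasts
trait-gene F_ST between the sympatric and allopatric comparisons
(Wilcoxon rank-sum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from . import divergence
from .core_io import GenotypeMatrix, map_features

__all__ = ["ScanPlan", "ScanResult", "OverlapReport", "build_scan_plan",
           "run_scan_plan", "overlap_report"]

COMPARISON_NAMES = [
    "species_all",
    "species_allopatric",
    "species_sympatric",
    "within_A_contexts",
    "within_B_contexts",
]


@dataclass
class ScanPlan:
    comparisons: dict  # name -> (samples_1, samples_2)
    species: tuple


def build_scan_plan(popmap: pd.DataFrame, exclude: tuple = ("outgroup",)) -> ScanPlan:
    """Derive the five standard comparisons from a population map."""
    pm = popmap[~popmap["species"].isin(exclude)]
    species = sorted(pm["species"].unique())
    if len(species) != 2:
        raise ValueError("scan plan requires exactly two ingroup species")
    a, b = species

    def pick(sp=None, ctx=None):
        sel = pm
        if sp is not None:
            sel = sel[sel["species"] == sp]
        if ctx is not None:
            sel = sel[sel["context"] == ctx]
        return list(sel.index)

    comps = {
        "species_all": (pick(a), pick(b)),
        "species_allopatric": (pick(a, "allopatric"), pick(b, "allopatric")),
        "species_sympatric": (pick(a, "sympatric"), pick(b, "sympatric")),
        "within_A_contexts": (pick(a, "allopatric"), pick(a, "sympatric")),
        "within_B_contexts": (pick(b, "allopatric"), pick(b, "sympatric")),
    }
    return ScanPlan(comps, (a, b))


@dataclass
class ScanResult:
    fst_sites: dict = field(default_factory=dict)  # name -> site table with fst
    fst_outliers: dict = field(default_factory=dict)  # name -> outlier gene set
    fst_means: dict = field(default_factory=dict)
    dxy_windows: dict = field(default_factory=dict)  # name -> window table
    dxy_outliers: dict = field(default_factory=dict)
    best_supported_genes: set = field(default_factory=set)
    skipped: list = field(default_factory=list)


def run_scan_plan(
    gm: GenotypeMatrix,
    popmap: pd.DataFrame,
    windows: pd.DataFrame,
    genes: pd.DataFrame,
    callable_sites=None,
    outlier_q: float = 0.99,
    flank: int = 0,
) -> ScanResult:
    """Run the five-comparison divergence scan and call outlier genes.

    Outlier genes are called by strict overlap with outlier SNPs/windows
    (``flank=0``); the 10 kb flank convention belongs to trait-association
    gene mapping, not to the outlier scans.
    """
    plan = build_scan_plan(popmap)
    res = ScanResult()
    between_species = {"species_all", "species_allopatric", "species_sympatric"}
    for name, (s1, s2) in plan.comparisons.items():
        if not s1 or not s2:
            warnings.warn(f"comparison {name}: a sample set is empty, skipped")
            res.skipped.append(name)
            continue
        table = divergence.fst_scan(gm, [s1, s2])
        res.fst_sites[name] = table
        res.fst_means[name] = divergence.fst_means(table)
        try:
            call = divergence.call_outliers(table["fst"], q=outlier_q)
        except ValueError:
            res.skipped.append(name)
            continue
        snp_hits = table.loc[call.mask, ["chrom", "pos"]]
        mapped = map_features(snp_hits, genes, flank=flank)
        res.fst_outliers[name] = set(mapped["gene_id"])

        if name in between_species:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                div = divergence.window_diversity(
                    gm, {"p1": s1, "p2": s2}, windows, callable_sites
                )
            dxy = div[div["stat"] == "dxy"].reset_index(drop=True)
            res.dxy_windows[name] = dxy
            try:
                dcall = divergence.call_outliers(dxy["value"], q=outlier_q)
            except ValueError:
                continue
            w_hits = dxy.loc[dcall.mask, ["chrom", "start", "end"]]
            mapped_w = map_features(w_hits, genes, flank=0)
            res.dxy_outliers[name] = set(mapped_w["gene_id"])

    if "species_all" in res.fst_outliers and "species_all" in res.dxy_outliers:
        res.best_supported_genes = (
            res.fst_outliers["species_all"] & res.dxy_outliers["species_all"]
        )
    return res


@dataclass
class OverlapReport:
    gene_sets: dict
    pairwise: pd.DataFrame
    full_intersection: set
    window_tests: pd.DataFrame
    context_tests: pd.DataFrame
    notes: list = field(default_factory=list)


def _windows_with_snps(windows: pd.DataFrame, snps: pd.DataFrame) -> np.ndarray:
    """Boolean mask of windows containing >= 1 of the given SNPs."""
    mask = np.zeros(len(windows), dtype=bool)
    if not len(snps):
        return mask
    for i, w in enumerate(windows.itertuples(index=False)):
        sel = (
            (snps["chrom"] == w.chrom)
            & (snps["pos"] - 1 >= w.start)
            & (snps["pos"] - 1 < w.end)
        )
        mask[i] = bool(sel.any())
    return mask


def overlap_report(
    scan: ScanResult,
    trait_genes: dict,
    trait_snps: dict,
    windows: pd.DataFrame,
    gm: GenotypeMatrix,
    genes: pd.DataFrame,
    flank: int = 10_000,
) -> OverlapReport:
    """Intersections of evidence-source gene sets plus the window-mean and
    sympatry/allopatry tests.

    ``trait_genes`` maps a source name (e.g. ``song``, ``chc``) to a gene-id
    set; ``trait_snps`` maps the same names to DataFrames with chrom/pos of
    the significantly associated SNPs.
    """
    gene_sets = {
        "fst_outlier": scan.fst_outliers.get("species_all", set()),
        "dxy_outlier": scan.dxy_outliers.get("species_all", set()),
        **{f"{k}_associated": set(v) for k, v in trait_genes.items()},
    }
    rows = []
    for a, b in combinations(gene_sets, 2):
        sa, sb = gene_sets[a], gene_sets[b]
        rows.append((a, b, len(sa), len(sb), len(sa & sb), len(sa | sb)))
    pairwise = pd.DataFrame(
        rows, columns=["set_a", "set_b", "n_a", "n_b", "n_intersection", "n_union"]
    )
    full = set.intersection(*gene_sets.values()) if gene_sets else set()

    notes = []
    wrows = []
    fst_sites = scan.fst_sites.get("species_all")
    dxy = scan.dxy_windows.get("species_all")
    for source, snps in trait_snps.items():
        if snps is None or not len(snps):
            notes.append(f"{source}: no associated SNPs, window tests skipped")
            continue
        mask = _windows_with_snps(windows, snps)
        if fst_sites is not None:
            wfst = _window_mean_fst(fst_sites, windows)
            a = wfst[mask & ~np.isnan(wfst)]
            b = wfst[~mask & ~np.isnan(wfst)]
            if len(a) > 1 and len(b) > 1:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                wrows.append((source, "fst", float(a.mean()), float(b.mean()),
                              float(t), float(p), len(a), len(b)))
        if dxy is not None:
            v = dxy["value"].to_numpy()
            a = v[mask & ~np.isnan(v)]
            b = v[~mask & ~np.isnan(v)]
            if len(a) > 1 and len(b) > 1:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                wrows.append((source, "dxy", float(a.mean()), float(b.mean()),
                              float(t), float(p), len(a), len(b)))
    window_tests = pd.DataFrame(
        wrows,
        columns=["source", "stat", "mean_assoc", "mean_background",
                 "t", "p", "n_assoc", "n_background"],
    )

    crows = []
    symp = scan.fst_sites.get("species_sympatric")
    allo = scan.fst_sites.get("species_allopatric")
    if symp is not None and allo is not None:
        for source, gset in trait_genes.items():
            if not gset:
                notes.append(f"{source}: empty gene set, context test skipped")
                continue
            snp_genes = map_features(symp[["chrom", "pos"]], genes, flank=flank)
            in_genes = snp_genes[snp_genes["gene_id"].isin(gset)]["feature_index"]
            idx = np.unique(in_genes)
            a = symp["fst"].to_numpy()[idx]
            b = allo["fst"].to_numpy()[idx]
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if len(a) and len(b):
                w, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                crows.append((source, float(w), float(p), len(a), len(b)))
    context_tests = pd.DataFrame(
        crows, columns=["source", "W", "p", "n_sympatric", "n_allopatric"]
    )
    return OverlapReport(gene_sets, pairwise, full, window_tests,
                         context_tests, notes)


def _window_mean_fst(fst_sites: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Mean per-site F_ST of the SNPs inside each window (NaN when empty)."""
    out = np.full(len(windows), np.nan)
    chrom = fst_sites["chrom"].to_numpy()
    pos0 = fst_sites["pos"].to_numpy() - 1
    fst = fst_sites["fst"].to_numpy()
    for i, w in enumerate(windows.itertuples(index=False)):
        sel = (chrom == w.chrom) & (pos0 >= w.start) & (pos0 < w.end)
        vals = fst[sel]
        vals = vals[~np.isnan(vals)]
        if len(vals):
            out[i] = vals.mean()
    return out
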