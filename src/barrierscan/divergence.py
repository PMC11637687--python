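"""Genetic differentiation and divergence scans.

Per-site Weir & Cockerham (1984) F_ST with its a/b/c variance components,
windowed nucleotide diversity (pi) and absolute divergence (d_XY) with
callable-site denominators, and empirical-quantile outlier calling.

Sites that are monomorphic across all populations have an undefined F_ST
(0/0) and are excluded from averages rather than set to zero.  Negative
per-site estimates are retained by default, matching the usual estimator
behaviour; ``clamp_negative=True`` truncates them at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix

__all__ = [
    "wc_fst_site",
    "fst_means",
    "fst_scan",
    "window_diversity",
    "call_outliers",
]


def _pop_site_stats(dosage: np.ndarray):
    """Per-site sample size (diploids), alt frequency and het proportion."""
    called = dosage != MISSING
    n = called.sum(axis=1).astype(float)
    alt = np.where(called, dosage, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n)
        h = np.where(called, dosage == 1, False).sum(axis=1) / n
    return n, p, h


def wc_fst_site(dosages_by_pop: list[np.ndarray], clamp_negative: bool = False):
    """Weir & Cockerham (1984) per-site variance components and F_ST.

    Parameters
    ----------
    dosages_by_pop : list of (n_sites, n_samples_pop) dosage arrays
        One array per population, aligned on sites; ``-1`` marks missing.

    Returns
    -------
    DataFrame with columns ``a, b, c, fst``; ``fst`` is NaN where the
    denominator a+b+c is zero (monomorphic across populations) or fewer than
    two populations have data.
    """
    r = len(dosages_by_pop)
    if r < 2:
        raise ValueError("need at least two populations")
    stats = [_pop_site_stats(d) for d in dosages_by_pop]
    n = np.stack([s[0] for s in stats])  # (r, sites)
    p = np.stack([s[1] for s in stats])
    h = np.stack([s[2] for s in stats])
    has = n > 0
    r_eff = has.sum(axis=0).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_sum = np.where(has, n, 0.0).sum(axis=0)
        nbar = n_sum / r_eff
        nc = (n_sum - np.where(has, n**2, 0.0).sum(axis=0) / n_sum) / (r_eff - 1.0)
        pbar = np.where(has, n * p, 0.0).sum(axis=0) / n_sum
        s2 = np.where(has, n * (p - pbar) ** 2, 0.0).sum(axis=0) / (
            (r_eff - 1.0) * nbar
        )
        hbar = np.where(has, n * h, 0.0).sum(axis=0) / n_sum

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - (r_eff - 1.0) / r_eff * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - (r_eff - 1.0) / r_eff * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        fst = np.where(denom != 0.0, a / denom, np.nan)

    bad = (r_eff < 2) | (nbar <= 1.0)
    for arr in (a, b, c, fst):
        arr[bad] = np.nan
    fst[denom == 0.0] = np.nan
    if clamp_negative:
        fst = np.where(np.isnan(fst), np.nan, np.maximum(fst, 0.0))
    return pd.DataFrame({"a": a, "b": b, "c": c, "fst": fst})


def fst_means(components: pd.DataFrame) -> dict:
    """Mean-of-ratios (per-site average, the headline style) and
    ratio-of-sums (weighted) multi-site F_ST summaries."""
    ok = components["fst"].notna()
    mean_of_ratios = float(components.loc[ok, "fst"].mean()) if ok.any() else np.nan
    denom = components.loc[ok, ["a", "b", "c"]].to_numpy().sum()
    ratio_of_sums = (
        float(components.loc[ok, "a"].sum() / denom) if denom != 0 else np.nan
    )
    return {"mean_of_ratios": mean_of_ratios, "ratio_of_sums": ratio_of_sums}


def fst_scan(
    gm: GenotypeMatrix, sample_sets: list[list[str]], clamp_negative: bool = False
) -> pd.DataFrame:
    """Site-wise WC F_ST between named sample sets; returns the site table
    with a/b/c/fst columns appended."""
    dosages = [gm.dosage[:, gm.sample_indices(s)] for s in sample_sets]
    comp = wc_fst_site(dosages, clamp_negative=clamp_negative)
    return pd.concat([gm.sites.reset_index(drop=True), comp], axis=1)


def _allele_counts(dosage: np.ndarray):
    """(alt count, called allele count) per site for one population."""
    called = dosage != MISSING
    n = 2 * called.sum(axis=1)
    alt = np.where(called, dosage, 0).sum(axis=1)
    return alt.astype(np.int64), n.astype(np.int64)


def window_diversity(
    gm: GenotypeMatrix,
    pops: dict[str, list[str]],
    windows: pd.DataFrame,
    callable_sites: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Windowed pi (per population) and d_XY (per population pair).

    Denominators count allele pairs over all callable sites: variant sites
    contribute their observed pairwise comparisons, and ``callable_sites``
    (invariant genotyped sites per window, aligned with ``windows``) add
    comparisons with zero differences, assuming full genotyping there.  When
    ``callable_sites`` is None the denominator falls back to variant sites
    only and the output is flagged ``variant_only=True``.
    """
    variant_only = callable_sites is None
    if variant_only:
        warnings.warn(
            "no callable invariant-site counts: pi/d_XY use variant sites only"
        )
        callable_sites = np.zeros(len(windows), dtype=int)
    callable_sites = np.asarray(callable_sites)

    counts = {name: _allele_counts(gm.dosage[:, gm.sample_indices(s)])
              for name, s in pops.items()}
    n_full = {name: 2 * len(s) for name, s in pops.items()}
    chrom = gm.sites["chrom"].to_numpy()
    pos0 = gm.sites["pos"].to_numpy() - 1  # internal 0-based

    rows = []
    names = list(pops)
    for widx, w in enumerate(windows.itertuples(index=False)):
        in_w = (chrom == w.chrom) & (pos0 >= w.start) & (pos0 < w.end)
        n_inv = int(callable_sites[widx])
        for name in names:
            alt, n = counts[name]
            a, nn = alt[in_w], n[in_w]
            ok = nn >= 2
            diffs = (a[ok] * (nn[ok] - a[ok])).sum()
            pairs = (nn[ok] * (nn[ok] - 1) // 2).sum()
            pairs += n_inv * (n_full[name] * (n_full[name] - 1) // 2)
            val = float(diffs) / pairs if pairs > 0 else np.nan
            rows.append((w.chrom, w.start, w.end, "pi", name, val, int(ok.sum())))
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a1, n1 = counts[names[i]]
                a2, n2 = counts[names[j]]
                aa1, nn1 = a1[in_w], n1[in_w]
                aa2, nn2 = a2[in_w], n2[in_w]
                ok = (nn1 > 0) & (nn2 > 0)
                diffs = (aa1[ok] * (nn2[ok] - aa2[ok]) + aa2[ok] * (nn1[ok] - aa1[ok])).sum()
                pairs = (nn1[ok] * nn2[ok]).sum()
                pairs += n_inv * n_full[names[i]] * n_full[names[j]]
                val = float(diffs) / pairs if pairs > 0 else np.nan
                rows.append(
                    (w.chrom, w.start, w.end, "dxy",
                     f"{names[i]}|{names[j]}", val, int(ok.sum()))
                )
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "stat", "pops", "value", "n_valid_sites"]
    )
    out.attrs["variant_only"] = variant_only
    return out


@dataclass
class OutlierCall:
    mask: np.ndarray
    threshold: float
    q: float
    n_defined: int


def call_outliers(values, q: float = 0.99) -> OutlierCall:
    """Empirical q-quantile outlier mask (linear-interpolation quantile;
    values >= threshold are outliers, ties included, NaN excluded)."""
    values = np.asarray(values, dtype=float)
    defined = ~np.isnan(values)
    if not defined.any():
        raise ValueError("all values undefined")
    n_def = int(defined.sum())
    if n_def < 100:
        warnings.warn(f"only {n_def} defined values; quantile threshold is noisy")
    threshold = float(np.quantile(values[defined], q))
    vals = values[defined]
    if np.all(vals == vals[0]):
        warnings.warn("constant input: every value sits at the threshold")
    mask = np.zeros(values.shape, dtype=bool)
    mask[defined] = values[defined] >= threshold
    return OutlierCall(mask, threshold, q, n_def)
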