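"""ABBA-BABA introgression tests from population allele frequencies.

Patterson's D and the f4 statistic are computed site-wise from derived-allele
frequencies of populations P1, P2, P3 and an outgroup P4, with significance
from a delete-one block jackknife over contiguous equal-SNP blocks.  Trio
enumeration tests all C(n, 3) population sets, orders each trio canonically
(BBAA-like pattern maximal, D >= 0), applies Benjamini-Hochberg correction
across trios, and flags a trio as significant only when Z > 3, adjusted
p < 0.05 and D > 0.05 all hold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, GenotypeMatrix

__all__ = [
    "TrioResult",
    "population_frequencies",
    "polarize_frequencies",
    "patterson_d",
    "enumerate_trios",
]


@dataclass
class TrioResult:
    p1: str
    p2: str
    p3: str
    outgroup: str
    d: float
    f4: float
    se: float
    z: float
    p: float
    q: float | None
    n_blocks: int
    n_informative_sites: int


def population_frequencies(gm: GenotypeMatrix, pops: dict[str, list[str]]) -> pd.DataFrame:
    """Per-population alt-allele frequencies (NaN where a population is
    entirely missing at a site)."""
    out = {}
    for name, samples in pops.items():
        d = gm.dosage[:, gm.sample_indices(samples)]
        called = d != MISSING
        n = 2.0 * called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = np.where(called, d, 0).sum(axis=1) / n
    return pd.DataFrame(out)


def polarize_frequencies(freqs: pd.DataFrame, outgroup: str,
                         max_outgroup_freq: float = 0.0) -> pd.DataFrame:
    """Convert alt frequencies to derived frequencies using the outgroup.

    Sites where the outgroup allele frequency is within ``max_outgroup_freq``
    of 0 or 1 are kept (default: fixed outgroup only); where the outgroup
    carries the alt allele, frequencies of all populations are flipped so the
    outgroup allele is ancestral.  Other sites are dropped.
    """
    og = freqs[outgroup].to_numpy()
    anc_ref = og <= max_outgroup_freq
    anc_alt = og >= 1.0 - max_outgroup_freq
    keep = (anc_ref | anc_alt) & ~np.isnan(og)
    out = freqs.loc[keep].copy()
    flip = anc_alt[keep]
    out.loc[flip, :] = 1.0 - out.loc[flip, :]
    return out.reset_index(drop=True)


def _block_bounds(n_sites: int, n_blocks: int) -> np.ndarray:
    """Contiguous, equal-SNP block boundaries (n_blocks + 1 edges)."""
    n_blocks = min(n_blocks, n_sites)
    return np.linspace(0, n_sites, n_blocks + 1).round().astype(int)


def patterson_d(
    p1, p2, p3, p4, n_blocks: int = 20,
    labels: tuple = ("P1", "P2", "P3", "outgroup"),
) -> TrioResult:
    """Patterson's D and f4 with delete-one block-jackknife significance.

    Inputs are per-site derived-allele frequencies (already polarized; sites
    with any NaN are dropped).  ABBA = sum (1-p1) p2 p3 (1-p4) and
    BABA = sum p1 (1-p2) p3 (1-p4); D = (ABBA-BABA)/(ABBA+BABA);
    f4 = mean (p1-p2)(p3-p4).  The jackknife deletes one contiguous
    equal-SNP block at a time; SE^2 = (m-1)/m * sum (D_j - mean D_j)^2.
    """
    arr = np.column_stack([np.asarray(x, dtype=float) for x in (p1, p2, p3, p4)])
    arr = arr[~np.isnan(arr).any(axis=1)]
    q1, q2, q3, q4 = arr.T
    abba = (1 - q1) * q2 * q3 * (1 - q4)
    baba = q1 * (1 - q2) * q3 * (1 - q4)
    num = abba - baba
    den = abba + baba
    informative = den > 0
    n_inf = int(informative.sum())
    if den.sum() == 0:
        return TrioResult(*labels, np.nan, 0.0, np.nan, np.nan, np.nan, None, 0, 0)
    d_all = num.sum() / den.sum()
    f4_site = (q1 - q2) * (q3 - q4)
    f4 = float(f4_site.mean()) if len(f4_site) else np.nan

    edges = _block_bounds(len(q1), n_blocks)
    m = len(edges) - 1
    d_jack = np.empty(m)
    for j in range(m):
        keep = np.ones(len(q1), dtype=bool)
        keep[edges[j]:edges[j + 1]] = False
        dj = den[keep].sum()
        d_jack[j] = num[keep].sum() / dj if dj > 0 else d_all
    se = float(np.sqrt((m - 1) / m * ((d_jack - d_jack.mean()) ** 2).sum()))
    if se == 0.0:
        if not np.allclose(d_jack, d_jack[0]) or d_all != 0.0:
            warnings.warn("jackknife SE is zero; Z reported as infinite")
            z = np.inf if d_all > 0 else (-np.inf if d_all < 0 else 0.0)
        else:
            z = 0.0
    else:
        z = d_all / se
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if not np.isfinite(z) and d_all == 0.0:
        p = 1.0
    return TrioResult(*labels, float(d_all), f4, se, float(z), p, None, m, n_inf)


def enumerate_trios(
    freqs: pd.DataFrame,
    outgroup: str,
    n_blocks: int = 20,
    z_min: float = 3.0,
    q_max: float = 0.05,
    d_min: float = 0.05,
    max_outgroup_freq: float = 0.0,
) -> pd.DataFrame:
    """Test every unordered population trio against the outgroup.

    Within each set {A, B, C} the sister pair (P1, P2) and donor P3 are
    chosen so the BBAA-like pattern sum is maximal, and P1/P2 are ordered so
    D >= 0.  BH correction runs across all trios; a trio is flagged
    significant iff Z > z_min AND q < q_max AND D > d_min.
    """
    from statsmodels.stats.multitest import multipletests

    pops = [c for c in freqs.columns if c != outgroup]
    if outgroup not in freqs.columns:
        raise ValueError(f"outgroup {outgroup!r} not in frequency table")
    if len(pops) < 3:
        raise ValueError("need at least three non-outgroup populations")

    pol = polarize_frequencies(freqs, outgroup, max_outgroup_freq)
    og = pol[outgroup].to_numpy()
    results = []
    for trio in combinations(pops, 3):
        best = None
        for p3 in trio:
            p1, p2 = [x for x in trio if x != p3]
            a, b, c = pol[p1].to_numpy(), pol[p2].to_numpy(), pol[p3].to_numpy()
            bbaa = np.nansum(a * b * (1 - c) * (1 - og))
            if best is None or bbaa > best[0]:
                best = (bbaa, p1, p2, p3)
        _, p1, p2, p3 = best
        res = patterson_d(
            pol[p1], pol[p2], pol[p3], og, n_blocks, (p1, p2, p3, outgroup)
        )
        if not np.isnan(res.d) and res.d < 0:
            res = patterson_d(
                pol[p2], pol[p1], pol[p3], og, n_blocks, (p2, p1, p3, outgroup)
            )
        results.append(res)

    table = pd.DataFrame([vars(r) for r in results])
    ok = table["p"].notna()
    table["q"] = np.nan
    if ok.any():
        table.loc[ok, "q"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    table["significant"] = (
        (table["z"] > z_min) & (table["q"] < q_max) & (table["d"] > d_min)
    )
    return table
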