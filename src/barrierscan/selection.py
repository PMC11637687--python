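"""Haplotype-based selective-sweep scans: EHH decay and the integrated
haplotype score (iHS).

EHH at a flanking site is the probability that two haplotypes drawn from the
core allele class are identical over the stretch between the core and that
site.  iHH integrates EHH against physical distance (trapezoid rule) outward
in both directions until EHH drops below a cutoff (default 0.05); the raw
score is ln(iHH_ancestral / iHH_derived), and scores are standardized to
mean 0 / SD 1 within derived-allele-frequency bins so that extreme values
are comparable across frequencies.  Scans are intended to be run per
species on phased haplotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ehh_decay", "ihs_scan", "standardize_ihs"]


def _ehh_curve(hap_class: np.ndarray, start: int, direction: int,
               stop_below: float = 0.0):
    """EHH values walking from the core (column ``start``) in ``direction``.

    Returns (site indices, EHH values); EHH at the core itself is 1 and is
    not included.  Stops at the chromosome end, at EHH = 0, or at the first
    value below ``stop_below`` (that value is still recorded).
    """
    n = hap_class.shape[0]
    denom = n * (n - 1) / 2
    group = np.zeros(n, dtype=np.int64)
    idx_list, ehh_list = [], []
    j = start + direction
    S = hap_class.shape[1]
    while 0 <= j < S:
        group = group * 2 + hap_class[:, j]
        _, group = np.unique(group, return_inverse=True)
        counts = np.bincount(group)
        ehh = (counts * (counts - 1) / 2).sum() / denom
        idx_list.append(j)
        ehh_list.append(ehh)
        if ehh == 0.0 or ehh < stop_below:
            break
        j += direction
    return np.array(idx_list, dtype=int), np.array(ehh_list)


def ehh_decay(haplotypes: np.ndarray, positions: np.ndarray, core: int,
              allele: int, cutoff: float = 0.0):
    """EHH of one allele class at a core site, outward in both directions.

    Returns a DataFrame with columns ``site, pos, direction, ehh`` (direction
    -1 = upstream, +1 = downstream); computation stops once EHH < ``cutoff``
    (or hits zero / the chromosome end).  An allele class with fewer than two
    haplotypes is undefined and raises ValueError.
    """
    members = haplotypes[:, core] == allele
    if members.sum() < 2:
        raise ValueError("allele class has fewer than two haplotypes")
    sub = haplotypes[members]
    rows = []
    for direction in (-1, 1):
        idx, ehh = _ehh_curve(sub, core, direction)
        for j, e in zip(idx, ehh):
            rows.append((j, positions[j], direction, e))
            if e < cutoff:
                break
    return pd.DataFrame(rows, columns=["site", "pos", "direction", "ehh"])


def _ihh_one_side(sub: np.ndarray, positions: np.ndarray, core: int,
                  direction: int, cutoff: float):
    """Trapezoidal integral of EHH vs distance on one side of the core.

    Integration runs from the core (EHH = 1, distance 0) out to the first
    point with EHH < cutoff (that segment included); returns (area,
    truncated) where truncated means the curve never fell below the cutoff
    before the data ended.
    """
    idx, ehh = _ehh_curve(sub, core, direction, stop_below=cutoff)
    area = 0.0
    prev_pos = positions[core]
    prev_ehh = 1.0
    truncated = True
    for j, e in zip(idx, ehh):
        d = abs(positions[j] - prev_pos)
        area += 0.5 * (prev_ehh + e) * d
        prev_pos, prev_ehh = positions[j], e
        if e < cutoff:
            truncated = False
            break
    return area, truncated


def ihs_scan(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    maf_min: float = 0.05,
    cutoff: float = 0.05,
    keep_truncated: bool = True,
    derived_is_alt: bool = True,
) -> pd.DataFrame:
    """Raw iHS for every qualifying site of a phased haplotype matrix.

    ``haplotypes`` is (n_haplotypes, n_sites) with 0 = ancestral, 1 = derived
    (set ``derived_is_alt=False`` if polarization is unavailable and the
    reference allele should be treated as ancestral after flipping — the
    column is then used as-is but results are flagged unpolarized).

    Returns columns ``site, pos, derived_freq, ihh_a, ihh_d, ihs_raw,
    truncated``; sites whose EHH never falls below the cutoff before the
    data end are flagged and kept by default (synthetic regions are short).
    """
    H = np.asarray(haplotypes)
    positions = np.asarray(positions)
    n, S = H.shape
    freq = H.mean(axis=0)
    rows = []
    for s in range(S):
        f = freq[s]
        if min(f, 1 - f) < maf_min:
            continue
        anc = H[:, s] == 0
        der = ~anc
        if anc.sum() < 2 or der.sum() < 2:
            continue
        ihh = {}
        trunc = False
        for name, members in (("a", anc), ("d", der)):
            sub = H[members]
            area = 0.0
            for direction in (-1, 1):
                a, t = _ihh_one_side(sub, positions, s, direction, cutoff)
                area += a
                trunc |= t
            ihh[name] = area
        if ihh["a"] <= 0.0 or ihh["d"] <= 0.0:
            continue
        if trunc and not keep_truncated:
            continue
        rows.append((s, positions[s], f, ihh["a"], ihh["d"],
                     np.log(ihh["a"] / ihh["d"]), trunc))
    out = pd.DataFrame(
        rows,
        columns=["site", "pos", "derived_freq", "ihh_a", "ihh_d",
                 "ihs_raw", "truncated"],
    )
    out.attrs["polarized"] = derived_is_alt
    return out


@dataclass
class IhsStandardization:
    scans: pd.DataFrame
    bin_edges: np.ndarray
    outlier_quantile: float
    outlier_threshold: float


def standardize_ihs(
    scans: pd.DataFrame, n_bins: int = 20, outlier_quantile: float = 0.99
) -> IhsStandardization:
    """Standardize raw iHS within equal-width derived-frequency bins.

    Within each occupied bin the score becomes (raw - bin mean) / bin SD;
    bins with zero SD leave their scores undefined (NaN, warning).  Outliers
    are sites with |standardized score| at or above the ``outlier_quantile``
    empirical quantile of all defined |scores|.
    """
    out = scans.copy()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(out["derived_freq"], edges) - 1, 0, n_bins - 1)
    out["freq_bin"] = which
    out["ihs_std"] = np.nan
    for b in np.unique(which):
        sel = which == b
        if sel.sum() < 50:
            warnings.warn(f"frequency bin {b}: only {sel.sum()} sites")
        vals = out.loc[sel, "ihs_raw"]
        sd = vals.std(ddof=0)
        if sd == 0 or np.isnan(sd):
            warnings.warn(f"frequency bin {b}: zero SD, scores undefined")
            continue
        out.loc[sel, "ihs_std"] = (vals - vals.mean()) / sd
    abs_std = out["ihs_std"].abs()
    defined = abs_std.dropna()
    thresh = float(np.quantile(defined, outlier_quantile)) if len(defined) else np.nan
    out["outlier"] = abs_std >= thresh
    return IhsStandardization(out, edges, outlier_quantile, thresh)
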