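"""Input/output, variant and sample filtering, genomic windows, gene mapping.

Internal coordinates are 0-based half-open throughout; VCF positions are
converted on ingest and egress, BED intervals are taken as-is.  Genotypes are
stored as allele dosages in {0, 1, 2} with ``-1`` marking missing calls; when
every call at every site is phased, the haplotype matrix (sites x 2*samples,
values in {0, 1, -1}) is populated alongside.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "FilterParams",
    "FilterReport",
    "VcfFormatError",
    "read_vcf",
    "write_vcf",
    "read_population_map",
    "write_population_map",
    "apply_filters",
    "make_windows",
    "map_features",
    "read_bed",
    "read_gff3",
]


class VcfFormatError(ValueError):
    """Raised when a VCF cannot be parsed (bad header, malformed record)."""


@dataclass
class GenotypeMatrix:
    """Sites x samples dosage matrix with per-site metadata.

    Attributes
    ----------
    sites : pandas.DataFrame
        Columns ``chrom, pos, ref, alt, qual`` (``pos`` is 1-based, as in
        VCF); one row per retained biallelic SNP.
    samples : list of str
    dosage : ndarray, shape (n_sites, n_samples), int8
        Alt-allele dosage; ``-1`` = missing.
    haplotypes : ndarray or None, shape (n_sites, 2 * n_samples), int8
        Phased alleles, present only when phase is known at every site.
    depth, qual_gt : ndarray or None
        Per-call DP and GQ, same shape as ``dosage``, ``-1`` where absent.
    """

    sites: pd.DataFrame
    samples: list
    dosage: np.ndarray
    haplotypes: np.ndarray | None = None
    depth: np.ndarray | None = None
    qual_gt: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    def __post_init__(self):
        if len(self.sites) != self.dosage.shape[0]:
            raise ValueError("site table and dosage row counts differ")
        if len(self.samples) != self.dosage.shape[1]:
            raise ValueError("sample list and dosage column counts differ")
        if self.haplotypes is not None:
            if self.haplotypes.shape != (self.n_sites, 2 * self.n_samples):
                raise ValueError("haplotype matrix has wrong shape")

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
            depth=None if self.depth is None else self.depth[idx],
            qual_gt=None if self.qual_gt is None else self.qual_gt[idx],
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        hap_idx = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
        return replace(
            self,
            samples=[self.samples[i] for i in idx],
            dosage=self.dosage[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, hap_idx],
            depth=None if self.depth is None else self.depth[:, idx],
            qual_gt=None if self.qual_gt is None else self.qual_gt[:, idx],
        )

    def sample_indices(self, names) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        return np.array([pos[n] for n in names], dtype=int)


def read_vcf(path, region: str | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF (v4.x, optionally bgzipped).

    Multi-allelic records and indels are skipped (count logged); ``./.`` and
    half-calls become missing.  Phase is preserved into the haplotype matrix
    only when every call at every retained site is phased.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise VcfFormatError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    n = len(samples)
    rows, dosages, haps, depths, gqs, phased_ok = [], [], [], [], [], []
    n_skipped = 0
    try:
        it = vcf(region) if region else vcf
        for var in it:
            if len(var.ALT) != 1 or not var.is_snp:
                n_skipped += 1
                continue
            g = np.asarray(var.genotypes, dtype=np.int16)  # (n, 3): a0 a1 phased
            if g.shape[0] != n:
                raise VcfFormatError(
                    f"sample-count mismatch at {var.CHROM}:{var.POS}"
                )
            a0, a1, ph = g[:, 0], g[:, 1], g[:, 2]
            miss = (a0 < 0) | (a1 < 0)
            dos = np.where(miss, MISSING, a0 + a1).astype(np.int8)
            hp = np.empty(2 * n, dtype=np.int8)
            hp[0::2] = np.where(miss, MISSING, a0)
            hp[1::2] = np.where(miss, MISSING, a1)
            dp = var.format("DP")
            gq = var.format("GQ")
            depths.append(
                np.full(n, MISSING, dtype=np.int32)
                if dp is None
                else np.where(dp[:, 0] < 0, MISSING, dp[:, 0]).astype(np.int32)
            )
            gqs.append(
                np.full(n, MISSING, dtype=np.int32)
                if gq is None
                else np.where(gq[:, 0] < 0, MISSING, gq[:, 0]).astype(np.int32)
            )
            rows.append(
                (var.CHROM, var.POS, var.REF, var.ALT[0],
                 float(var.QUAL) if var.QUAL is not None else np.nan)
            )
            dosages.append(dos)
            haps.append(hp)
            phased_ok.append(bool(np.all(ph[~miss] == 1)) if (~miss).any() else True)
    except VcfFormatError:
        raise
    except Exception as exc:
        raise VcfFormatError(f"malformed VCF record in {path}: {exc}") from exc

    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"])
    dosage = (
        np.array(dosages, dtype=np.int8) if dosages else np.empty((0, n), np.int8)
    )
    all_phased = bool(phased_ok) and all(phased_ok)
    hap = (
        np.array(haps, dtype=np.int8)
        if (haps and all_phased)
        else None
    )
    depth = np.array(depths, dtype=np.int32) if depths else None
    gqm = np.array(gqs, dtype=np.int32) if gqs else None
    if depth is not None and np.all(depth == MISSING):
        depth = None
    if gqm is not None and np.all(gqm == MISSING):
        gqm = None
    gm = GenotypeMatrix(sites, samples, dosage, hap, depth, gqm)
    gm.n_skipped_records = n_skipped
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix back to a (plain or gzipped) VCF 4.2 text file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    phased = gm.haplotypes is not None
    with opener(str(path), "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(gm.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        has_dp = gm.depth is not None
        has_gq = gm.qual_gt is not None
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        if has_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        fmt = "GT" + (":DP" if has_dp else "") + (":GQ" if has_gq else "")
        sep = "|" if phased else "/"
        for i, row in enumerate(gm.sites.itertuples(index=False)):
            fields = [
                str(row.chrom), str(row.pos), ".", row.ref, row.alt,
                "." if np.isnan(row.qual) else f"{row.qual:g}", ".", ".", fmt,
            ]
            for j in range(gm.n_samples):
                if phased:
                    a0, a1 = gm.haplotypes[i, 2 * j], gm.haplotypes[i, 2 * j + 1]
                    gt = "./." if a0 == MISSING else f"{a0}{sep}{a1}"
                else:
                    d = gm.dosage[i, j]
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(int(d), "./.")
                parts = [gt]
                if has_dp:
                    dp = gm.depth[i, j]
                    parts.append("." if dp == MISSING else str(int(dp)))
                if has_gq:
                    gq = gm.qual_gt[i, j]
                    parts.append("." if gq == MISSING else str(int(gq)))
                fields.append(":".join(parts))
            fh.write("\t".join(fields) + "\n")


POPMAP_COLUMNS = ["sample", "population", "species", "context", "lat", "lon"]


def read_population_map(path) -> pd.DataFrame:
    """Read the tab-separated population map (sample population species context lat lon)."""
    pm = pd.read_csv(path, sep="\t")
    missing = set(POPMAP_COLUMNS) - set(pm.columns)
    if missing:
        raise ValueError(f"population map missing columns: {sorted(missing)}")
    bad = set(pm["context"].unique()) - {"allopatric", "sympatric"}
    if bad:
        raise ValueError(f"unknown context values: {sorted(bad)}")
    return pm.set_index("sample")


def write_population_map(pm: pd.DataFrame, path) -> None:
    pm.reset_index().rename(columns={"index": "sample"}).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class FilterParams:
    """Thresholds of the variant/sample filter cascade."""

    min_depth: int = 10
    max_site_missing: float = 0.5
    min_qual: float = 30.0
    min_mac: int = 3
    max_indiv_missing: float = 0.5


@dataclass
class FilterReport:
    n_sites_in: int = 0
    n_calls_depth_masked: int = 0
    n_sites_qual: int = 0
    n_sites_missing: int = 0
    n_sites_mac: int = 0
    n_samples_removed: int = 0
    n_sites_mac_recheck: int = 0
    n_sites_out: int = 0
    n_samples_out: int = 0
    all_sites_removed: bool = False
    removed_samples: list = field(default_factory=list)


def _mac(dosage: np.ndarray) -> np.ndarray:
    """Minor allele count per site, ignoring missing calls."""
    called = dosage != MISSING
    alt = np.where(called, dosage, 0).sum(axis=1)
    tot = 2 * called.sum(axis=1)
    return np.minimum(alt, tot - alt)


def apply_filters(
    gm: GenotypeMatrix, params: FilterParams | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the variant/sample filter cascade.

    Order: (1) per-call depth < min_depth -> missing; (2) drop sites failing
    QUAL, site missingness, or minor allele count; (3) drop samples missing at
    >= max_indiv_missing of retained sites; (4) re-check MAC once.
    """
    params = params or FilterParams()
    rep = FilterReport(n_sites_in=gm.n_sites)
    if gm.n_sites == 0:
        rep.all_sites_removed = True
        rep.n_samples_out = gm.n_samples
        return gm, rep

    dosage = gm.dosage.copy()
    hap = None if gm.haplotypes is None else gm.haplotypes.copy()
    if gm.depth is not None:
        # calls without a DP record pass: the filter cannot be assessed for them
        mask = (gm.depth != MISSING) & (gm.depth < params.min_depth)
        rep.n_calls_depth_masked = int((mask & (dosage != MISSING)).sum())
        dosage[mask] = MISSING
        if hap is not None:
            hap[:, 0::2][mask] = MISSING
            hap[:, 1::2][mask] = MISSING
    else:
        warnings.warn("no per-call depth available; depth filter skipped")

    qual = gm.sites["qual"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        qual_ok = ~(qual < params.min_qual)  # NaN QUAL passes
    if gm.sites["qual"].isna().all():
        warnings.warn("no site QUAL available; quality filter skipped")
        qual_ok = np.ones(gm.n_sites, dtype=bool)
    miss_frac = (dosage == MISSING).mean(axis=1)
    miss_ok = miss_frac <= params.max_site_missing
    mac_ok = _mac(dosage) >= params.min_mac
    rep.n_sites_qual = int((~qual_ok).sum())
    rep.n_sites_missing = int((qual_ok & ~miss_ok).sum())
    rep.n_sites_mac = int((qual_ok & miss_ok & ~mac_ok).sum())
    keep_sites = qual_ok & miss_ok & mac_ok

    gm2 = replace(gm, dosage=dosage, haplotypes=hap).take_sites(np.flatnonzero(keep_sites))
    if gm2.n_sites == 0:
        rep.all_sites_removed = True
        rep.n_samples_out = gm2.n_samples
        return gm2, rep

    indiv_miss = (gm2.dosage == MISSING).mean(axis=0)
    keep_samp = indiv_miss < params.max_indiv_missing
    rep.n_samples_removed = int((~keep_samp).sum())
    rep.removed_samples = [s for s, k in zip(gm2.samples, keep_samp) if not k]
    gm3 = gm2.take_samples(np.flatnonzero(keep_samp))

    mac_ok2 = _mac(gm3.dosage) >= params.min_mac
    rep.n_sites_mac_recheck = int((~mac_ok2).sum())
    gm4 = gm3.take_sites(np.flatnonzero(mac_ok2))
    rep.n_sites_out = gm4.n_sites
    rep.n_samples_out = gm4.n_samples
    rep.all_sites_removed = gm4.n_sites == 0
    return gm4, rep


def make_windows(chrom_lengths: dict, size: int = 10_000, step: int = 10_000) -> pd.DataFrame:
    """Tile each chromosome with [start, end) windows from 0; last truncated.

    ``step > size`` would leave uncovered gaps and is rejected.
    """
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    if step > size:
        raise ValueError("step > size would leave gaps between windows")
    rows = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + size, length)))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ gene intervals (0-based half-open, native)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "gene_id", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    if "gene_id" not in df.columns:
        df["gene_id"] = [f"feat{i}" for i in range(len(df))]
    if "strand" not in df.columns:
        df["strand"] = "."
    return df[["chrom", "start", "end", "gene_id", "strand"]]


def read_gff3(path, feature_type: str = "gene") -> pd.DataFrame:
    """Read a minimal GFF3 subset; converts to 0-based half-open intervals."""
    rows = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", attrs.get("Name", f"{f[0]}:{f[3]}"))
            rows.append((f[0], int(f[3]) - 1, int(f[4]), gid, f[6]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])


def map_features(
    features: pd.DataFrame, genes: pd.DataFrame, flank: int = 10_000
) -> pd.DataFrame:
    """Associate SNPs or windows with genes within ``flank`` bp.

    ``features`` needs either a 1-based ``pos`` column (SNPs) or 0-based
    ``start``/``end`` columns (windows).  A SNP at VCF position p maps to gene
    g iff p-1 lies in [g.start - flank, g.end + flank); a window maps on any
    overlap with the flank-extended gene interval.  Many-to-many mappings are
    returned as one row per (feature, gene) pair.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes.itertuples(index=False):
        lo = g.start - flank
        hi = g.end + flank
        if hi <= lo:
            continue
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.gene_id)

    is_point = "pos" in features.columns and "start" not in features.columns
    out = []
    unknown = set()
    for idx, f in enumerate(features.itertuples(index=False)):
        tree = trees.get(f.chrom)
        if tree is None:
            unknown.add(f.chrom)
            continue
        if is_point:
            hits = tree[f.pos - 1]
        else:
            hits = tree.overlap(f.start, f.end)
        for h in hits:
            out.append((idx, f.chrom, h.data))
    if unknown - set(trees):
        warnings.warn(f"features on chromosomes without genes: {sorted(unknown)}")
    return pd.DataFrame(out, columns=["feature_index", "chrom", "gene_id"])
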