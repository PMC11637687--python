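"""Synthetic contact-zone datasets with planted truth.

Four generators cover the data shapes the analysis stages consume:

* :func:`simulate_snp_dataset` — unlinked SNPs for two sister species (plus an
  outgroup) sampled from allopatric and sympatric populations, built on a
  hierarchical Balding–Nichols allele-frequency model, with optional barrier
  loci (elevated divergence) and optional introgression modelled as allele
  frequency mixing restricted to sympatric populations.
* :func:`simulate_forward_region` — a recombining haplotype region from a
  discrete-generation Wright–Fisher population, optionally carrying a hard
  selective sweep; provides the linkage structure the iHS scan needs.
* :func:`simulate_phenotypes` — continuous song traits, non-negative CHC peak
  abundances with a planted factor structure, and body-size covariates, all
  driven by planted QTLs plus polygenic background and noise.
* :func:`simulate_joint_sfs` — an observed joint site-frequency spectrum from
  independent non-recombining coalescent genealogies under the four
  divergence/gene-flow demographic models.

Every generator is exactly reproducible given (config, seed), and every
simulated site carries exactly one primary role in the returned truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit


from ._coalescent import migration_window, sample_sfs_kernel
from .core_io import MISSING, GenotypeMatrix

__all__ = [
    "SONG_TRAITS",
    "CHC_PEAKS",
    "PopulationSpec",
    "SimulationConfig",
    "simulate_snp_dataset",
    "simulate_forward_region",
    "simulate_phenotypes",
    "simulate_joint_sfs",
]

#: The 14 continuous song parameters scored per male (duration/temporal
#: patterning of the two-component song phrase, plus carrier frequency).
SONG_TRAITS = [
    "carrier_frequency",
    "long_chirp_duration",
    "long_chirp_pulse_duration",
    "long_chirp_pulse_interval",
    "long_chirp_pulse_number",
    "long_short_chirp_interval",
    "short_chirp_duration",
    "short_chirp_pulse_duration",
    "short_chirp_pulse_interval",
    "short_chirp_pulse_number",
    "short_chirp_inter_chirp_interval",
    "short_chirp_number",
    "inter_song_interval",
    "song_duration",
]

#: 26 integrated cuticular-hydrocarbon peak abundances.
CHC_PEAKS = [f"chc_peak_{i:02d}" for i in range(1, 27)]


@dataclass
class PopulationSpec:
    pop_id: str
    species: str
    context: str  # "allopatric" | "sympatric"
    lat: float
    lon: float
    n_samples: int


def default_populations() -> list[PopulationSpec]:
    """Two sister species along a latitudinal transect with a central contact
    zone: two allopatric and two sympatric populations per species, 16
    diploids each (desk-scale version of a dense transect sampling design)."""
    return [
        PopulationSpec("A_allo1", "speciesA", "allopatric", -17.0, 145.5, 16),
        PopulationSpec("A_allo2", "speciesA", "allopatric", -19.5, 146.8, 16),
        PopulationSpec("A_symp1", "speciesA", "sympatric", -24.5, 151.5, 16),
        PopulationSpec("A_symp2", "speciesA", "sympatric", -26.0, 152.5, 16),
        PopulationSpec("B_symp1", "speciesB", "sympatric", -24.5, 151.6, 16),
        PopulationSpec("B_symp2", "speciesB", "sympatric", -26.1, 152.7, 16),
        PopulationSpec("B_allo1", "speciesB", "allopatric", -33.5, 151.0, 16),
        PopulationSpec("B_allo2", "speciesB", "allopatric", -37.5, 145.0, 16),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the site-level two-species generator.

    F values are Balding–Nichols drift parameters (the expected Wright F_ST
    of daughter frequencies around their parent frequency).  ``alpha`` mixes
    sympatric population frequencies toward the other species, emulating
    introgression restricted to the contact zone; barrier loci are exempt
    from mixing (that is what makes them barriers).
    """

    seed: int = 0
    populations: list = field(default_factory=default_populations)
    n_sites: int = 5_000
    f_between: float = 0.10
    f_within: float = 0.02
    barrier_fraction: float = 0.0
    barrier_f: float = 0.6
    alpha: float = 0.0
    missing_rate: float = 0.03
    depth_mean: float = 30.0
    qual_mean: float = 200.0
    outgroup_samples: int = 8
    outgroup_f: float = 0.5
    n_chroms: int = 5
    chrom_length: int = 1_000_000

    def __post_init__(self):
        for name in ("f_between", "f_within", "barrier_f"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        if self.barrier_fraction > 0 and self.barrier_f <= self.f_between:
            raise ValueError("barrier_f must exceed f_between")
        if any(p.n_samples < 2 for p in self.populations):
            raise ValueError("every population needs at least 2 samples")


def _bn_draw(rng, parent: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols daughter frequencies around parent frequencies."""
    a = parent * (1.0 - f) / f
    b = (1.0 - parent) * (1.0 - f) / f
    return rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))


def simulate_snp_dataset(config: SimulationConfig):
    """Generate unlinked SNP genotypes for the configured populations.

    Returns
    -------
    gm : GenotypeMatrix
        Genotypes for all ingroup samples plus ``outgroup_samples`` samples of
        population/species ``outgroup`` (skipped when ``outgroup_samples=0``).
    popmap : pandas.DataFrame, indexed by sample
    truth : pandas.DataFrame
        One row per site: ``role`` in {neutral, barrier, introgressed} plus
        the true per-population alt-allele frequencies are retained in
        ``gm.sites`` metadata columns are not added; frequencies are in
        ``truth`` columns ``freq_<pop>``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    S = cfg.n_sites
    species = sorted({p.species for p in cfg.populations})
    if len(species) != 2:
        raise ValueError("exactly two ingroup species are required")

    u = rng.uniform(0.05, 0.95, size=S)  # ancestral frequency per site
    is_barrier = np.zeros(S, dtype=bool)
    n_barrier = int(round(cfg.barrier_fraction * S))
    if n_barrier:
        is_barrier[rng.choice(S, size=n_barrier, replace=False)] = True

    # species-level frequencies: neutral sites drift around u with f_between;
    # barrier loci are divergently selected — the alt allele is pushed toward
    # fixation in one species and loss in the other, with residual frequency
    # noise scaled by (1 - barrier_f)
    sp_freq = {sp: _bn_draw(rng, u, cfg.f_between) for sp in species}
    if n_barrier:
        bidx = np.flatnonzero(is_barrier)
        margin = (1.0 - cfg.barrier_f) / 2.0
        low = rng.uniform(0.0, margin, size=n_barrier)
        high = 1.0 - rng.uniform(0.0, margin, size=n_barrier)
        flip = rng.random(n_barrier) < 0.5
        lo = np.where(flip, high, low)
        hi = np.where(flip, low, high)
        sp_freq[species[0]][bidx] = lo
        sp_freq[species[1]][bidx] = hi
    other = {species[0]: species[1], species[1]: species[0]}

    pop_freq = {}
    for p in cfg.populations:
        base = sp_freq[p.species]
        if p.context == "sympatric" and cfg.alpha > 0.0:
            mixed = base.copy()
            mix_mask = ~is_barrier  # barrier loci resist gene flow
            mixed[mix_mask] = (
                (1.0 - cfg.alpha) * base[mix_mask]
                + cfg.alpha * sp_freq[other[p.species]][mix_mask]
            )
            base = mixed
        pop_freq[p.pop_id] = _bn_draw(rng, base, cfg.f_within)

    samples, pop_of, dosage_cols = [], [], []
    for p in cfg.populations:
        g = rng.binomial(2, pop_freq[p.pop_id][:, None], size=(S, p.n_samples))
        dosage_cols.append(g)
        samples += [f"{p.pop_id}_{i:02d}" for i in range(p.n_samples)]
        pop_of += [p] * p.n_samples

    og_freq = None
    if cfg.outgroup_samples:
        og_freq = _bn_draw(rng, u, cfg.outgroup_f)
        g = rng.binomial(2, og_freq[:, None], size=(S, cfg.outgroup_samples))
        dosage_cols.append(g)
        samples += [f"outgroup_{i:02d}" for i in range(cfg.outgroup_samples)]
        pop_of += [PopulationSpec("outgroup", "outgroup", "allopatric",
                                  0.0, 130.0, cfg.outgroup_samples)] * cfg.outgroup_samples

    dosage = np.concatenate(dosage_cols, axis=1).astype(np.int8)
    N = dosage.shape[1]

    depth = rng.poisson(cfg.depth_mean, size=(S, N)).astype(np.int32)
    gq = rng.integers(30, 99, size=(S, N), dtype=np.int32)
    miss = rng.random((S, N)) < cfg.missing_rate
    dosage[miss] = MISSING

    # site coordinates: random positions across n_chroms, sorted
    chrom_idx = rng.integers(0, cfg.n_chroms, size=S)
    pos = rng.integers(1, cfg.chrom_length + 1, size=S)
    order = np.lexsort((pos, chrom_idx))
    chrom_idx, pos = chrom_idx[order], pos[order]
    u, is_barrier = u[order], is_barrier[order]
    dosage, depth, gq, miss = dosage[order], depth[order], gq[order], miss[order]
    for key in pop_freq:
        pop_freq[key] = pop_freq[key][order]
    if og_freq is not None:
        og_freq = og_freq[order]

    ref = rng.choice(list("ACGT"), size=S)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    qual = rng.gamma(4.0, cfg.qual_mean / 4.0, size=S)
    sites = pd.DataFrame(
        {
            "chrom": [f"chr{c + 1}" for c in chrom_idx],
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "qual": qual,
        }
    )
    gm = GenotypeMatrix(sites, samples, dosage, None, depth, gq)

    popmap = pd.DataFrame(
        {
            "population": [p.pop_id for p in pop_of],
            "species": [p.species for p in pop_of],
            "context": [p.context for p in pop_of],
            "lat": [p.lat for p in pop_of],
            "lon": [p.lon for p in pop_of],
        },
        index=pd.Index(samples, name="sample"),
    )

    role = np.where(
        is_barrier, "barrier", "introgressed" if cfg.alpha > 0 else "neutral"
    )
    truth = pd.DataFrame(
        {"chrom": sites["chrom"], "pos": sites["pos"], "role": role,
         "ancestral_freq": u}
    )
    for pid, fr in pop_freq.items():
        truth[f"freq_{pid}"] = fr
    if og_freq is not None:
        truth["freq_outgroup"] = og_freq
    return gm, popmap, truth


# ---------------------------------------------------------------------------
# forward Wright-Fisher region
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeRegion:
    """Phased haplotypes from a forward simulation."""

    haplotypes: np.ndarray  # (2N, S) uint8
    positions: np.ndarray  # (S,) int64, bp, strictly increasing
    region_bp: int
    truth: pd.DataFrame  # per-site role table (neutral / sweep)
    sweep_final_freq: float | None = None


def _neutral_phase(rng, two_n, region_bp, mu, rec, generations):
    """Neutral Wright-Fisher phase on preallocated buffers (no per-generation
    reallocation; the bulk gamete copy is a single fancy-index assignment).
    Returns (H, pos) with columns sorted by position."""
    n_dip = two_n // 2
    exp_s = 2.0 * two_n * mu * region_bp * (np.log(two_n) + 1.0)
    cap = int(max(512, 6 * exp_s)) + 64
    H = np.zeros((two_n, cap), np.uint8)
    newH = np.zeros((two_n, cap), np.uint8)
    pos = np.zeros(cap, np.int64)
    S = 0
    for gen in range(generations):
        parents = rng.integers(0, n_dip, two_n)
        which = rng.integers(0, 2, two_n)
        rows = 2 * parents + which
        n_co = rng.poisson(rec * region_bp, two_n)
        cur = H[:, :S]
        newH[:, :S] = cur[rows]
        g1 = np.flatnonzero(n_co == 1)
        if len(g1):  # single-crossover gametes vectorized (the common case)
            b = rng.integers(0, region_bp, len(g1))
            mask = pos[:S][None, :] >= b[:, None]
            other = cur[2 * parents[g1] + 1 - which[g1]]
            block = newH[g1, :S]
            block[mask] = other[mask]
            newH[g1, :S] = block
        for g in np.flatnonzero(n_co >= 2):
            breaks = np.sort(rng.integers(0, region_bp, n_co[g]))
            use_other = (np.searchsorted(breaks, pos[:S]) % 2) == 1
            newH[g, :S][use_other] = cur[2 * parents[g] + 1 - which[g], use_other]
        H, newH = newH, H
        n_mut = rng.poisson(mu * region_bp * two_n)
        if n_mut:
            mpos = rng.integers(0, region_bp, n_mut)
            fresh = mpos[~np.isin(mpos, pos[:S])]
            fresh = np.unique(fresh)[:cap - S]
            k = len(fresh)
            if k:
                H[:, S:S + k] = 0
                H[rng.integers(0, two_n, k), S + np.arange(k)] = 1
                pos[S:S + k] = fresh
                S += k
        if gen % 20 == 19 or S > cap - 64:
            tot = H[:, :S].sum(axis=0)
            keep = np.flatnonzero((tot > 0) & (tot < two_n))
            ns = len(keep)
            H[:, :ns] = H[:, keep]
            pos[:ns] = pos[keep]
            S = ns
    tot = H[:, :S].sum(axis=0)
    keep = np.flatnonzero((tot > 0) & (tot < two_n))
    order = keep[np.argsort(pos[keep], kind="stable")]
    return np.ascontiguousarray(H[:, order]), pos[order].copy()


@njit(cache=True)
def _gamete_kernel(H, pos, parents, which, n_co, region_bp, seed):
    """One recombinant gamete per entry of ``parents`` (diploid indices)."""
    np.random.seed(seed)
    n_gam = len(parents)
    S = H.shape[1]
    out = np.empty((n_gam, S), dtype=np.uint8)
    for g in range(n_gam):
        a = H[2 * parents[g] + which[g]]
        if n_co[g] == 0:
            out[g] = a
        else:
            breaks = np.sort(np.random.randint(0, region_bp, n_co[g]))
            b = H[2 * parents[g] + 1 - which[g]]
            seg = np.searchsorted(breaks, pos)
            for i in range(S):
                out[g, i] = b[i] if seg[i] % 2 == 1 else a[i]
    return out


def _make_gametes(rng, H, pos, parents, region_bp, rec):
    n_gam = len(parents)
    which = rng.integers(0, 2, size=n_gam)
    n_co = rng.poisson(rec * region_bp, size=n_gam)
    seed = int(rng.integers(0, 2**31 - 1))
    return _gamete_kernel(H, pos, parents.astype(np.int64),
                          which.astype(np.int64), n_co.astype(np.int64),
                          region_bp, seed)


def simulate_forward_region(
    n_diploid: int = 100,
    region_bp: int = 100_000,
    mu: float = 1e-6,
    rec: float = 1e-6,
    generations: int = 400,
    selection: dict | None = None,
    seed: int = 0,
) -> HaplotypeRegion:
    """Discrete-generation Wright–Fisher simulation of a recombining region.

    Random mating; per-meiosis crossover count ~ Poisson(rec * region_bp);
    infinite-sites mutation at Poisson(mu * region_bp) per gamete.  When
    ``selection={"pos": bp, "s": s, "f_target": 0.9}`` is given, the region
    first runs ``generations`` neutral burn-in generations, then a single
    beneficial copy (additive fitness 1, 1+s, 1+2s) is introduced at ``pos``
    and the run continues until its frequency reaches ``f_target`` (restarting
    the sweep phase whenever the allele is lost, i.e. conditioning on
    survival) or a hard generation cap is hit.

    Population size is deliberately small with inflated mu and rec (scaled
    parameters); defaults give theta = rho = 4*N*mu*L = 40 for the region.
    """
    if n_diploid < 20:
        raise ValueError("n_diploid must be >= 20")
    if selection is not None and selection.get("s", 0.0) < 0:
        raise ValueError("only positive selection (hard sweeps) is supported")
    rng = np.random.default_rng(seed)
    two_n = 2 * n_diploid

    def step(H, pos, sel_col=None, s=0.0):
        if sel_col is not None and s > 0.0:
            dos = H[0::2, sel_col].astype(np.int64) + H[1::2, sel_col]
            w = 1.0 + s * dos
            cum = np.cumsum(w / w.sum())
            parents = np.searchsorted(cum, rng.random(two_n))
            parents = np.minimum(parents, n_diploid - 1)
        else:
            parents = rng.integers(0, n_diploid, size=two_n)
        newH = (
            _make_gametes(rng, H, pos, parents, region_bp, rec)
            if H.shape[1]
            else np.empty((two_n, 0), dtype=np.uint8)
        )
        n_mut = rng.poisson(mu * region_bp * two_n)
        if n_mut:
            mpos = rng.integers(0, region_bp, size=n_mut).astype(np.int64)
            mpos = np.setdiff1d(mpos, pos)  # infinite sites: unique positions
            cols = np.zeros((two_n, len(mpos)), dtype=np.uint8)
            rows = rng.integers(0, two_n, size=len(mpos))
            cols[rows, np.arange(len(mpos))] = 1
            newH = np.concatenate([newH, cols], axis=1)
            pos = np.concatenate([pos, mpos])
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            newH = newH[:, order]
        return newH, pos

    def prune(H, pos, keep_pos=None):
        freq = H.mean(axis=0)
        keep = (freq > 0) & (freq < 1)
        if keep_pos is not None:
            keep |= pos == keep_pos
        return H[:, keep], pos[keep]

    H, pos = _neutral_phase(rng, two_n, region_bp, mu, rec, generations)

    sweep_freq = None
    sweep_pos = None
    if selection is not None and selection.get("s", 0.0) > 0.0:
        s = float(selection["s"])
        f_target = float(selection.get("f_target", 0.9))
        sweep_pos = int(selection.get("pos", region_bp // 2))
        cap = int(selection.get("max_generations", int(200.0 / s)))
        H0, pos0 = H.copy(), pos.copy()
        attempts = 0
        while True:
            attempts += 1
            H, pos = H0.copy(), pos0.copy()
            if sweep_pos in pos:
                col = int(np.searchsorted(pos, sweep_pos))
                H[:, col] = 0
            else:
                col = int(np.searchsorted(pos, sweep_pos))
                H = np.insert(H, col, 0, axis=1)
                pos = np.insert(pos, col, sweep_pos)
            H[rng.integers(0, two_n), col] = 1
            lost = False
            for _ in range(cap):
                col = int(np.searchsorted(pos, sweep_pos))
                H, pos = step(H, pos, sel_col=col, s=s)
                col = int(np.searchsorted(pos, sweep_pos))
                f = H[:, col].mean()
                if f == 0.0:
                    lost = True
                    break
                if f >= f_target:
                    break
                H, pos = prune(H, pos, keep_pos=sweep_pos)
            if not lost:
                col = int(np.searchsorted(pos, sweep_pos))
                f = H[:, col].mean()
                if f >= min(f_target, 0.5):
                    # optional neutral interval after selection ceased, so the
                    # sample looks back at a recently completed partial sweep
                    for _ in range(int(selection.get("post_generations", 0))):
                        H, pos = step(H, pos)
                        H, pos = prune(H, pos, keep_pos=sweep_pos)
                    col = int(np.searchsorted(pos, sweep_pos))
                    sweep_freq = float(H[:, col].mean())
                    break
            if attempts > 500:
                raise RuntimeError("sweep conditioning failed to establish")
        H, pos = prune(H, pos, keep_pos=sweep_pos)

    role = np.full(len(pos), "neutral", dtype=object)
    if sweep_pos is not None:
        role[pos == sweep_pos] = "sweep"
    truth = pd.DataFrame({"pos": pos, "role": role})
    if sweep_pos is not None:
        truth.loc[truth["role"] == "sweep", "sel_coef"] = selection["s"]
    return HaplotypeRegion(H, pos, region_bp, truth, sweep_freq)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    gm: GenotypeMatrix,
    qtl_spec: dict | None = None,
    h2_polygenic: float = 0.1,
    noise_sd: float = 1.0,
    seed: int = 0,
    covariate_trait: str = "long_chirp_pulse_duration",
    n_chc_factors: int = 4,
):
    """Phenotype table (14 song traits, 26 CHC peaks, mass, pronotum) + truth.

    ``qtl_spec`` maps a trait name (song trait or ``chc_factor_k`` for the
    k-th latent CHC factor, 1-based) to a list of ``(site_index, effect)``
    pairs.  Each trait is built as sum(effect * dosage) + a polygenic term
    (many tiny random effects, rescaled to variance ``h2_polygenic``) +
    N(0, noise_sd^2) noise.  CHC peaks load on ``n_chc_factors`` latent
    factors and are pushed through a soft-plus so abundances stay positive.
    Mass and pronotum length are generated correlated with
    ``covariate_trait`` to exercise covariate correction downstream.
    """
    if not 0.0 <= h2_polygenic < 1.0:
        raise ValueError("h2_polygenic must lie in [0, 1)")
    qtl_spec = qtl_spec or {}
    for trait, qtls in qtl_spec.items():
        for site, _ in qtls:
            if not 0 <= site < gm.n_sites:
                raise ValueError(f"QTL site {site} outside matrix for {trait}")
    rng = np.random.default_rng(seed)
    n = gm.n_samples
    dos = gm.dosage.astype(float)
    dos[gm.dosage == MISSING] = np.nan
    site_mean = np.nanmean(dos, axis=1)
    dos = np.where(np.isnan(dos), site_mean[:, None], dos)

    def polygenic():
        n_bg = min(200, gm.n_sites)
        idx = rng.choice(gm.n_sites, size=n_bg, replace=False)
        eff = rng.normal(0, 1, size=n_bg)
        g = eff @ dos[idx]
        sd = g.std()
        return (g - g.mean()) / sd * np.sqrt(h2_polygenic) if sd > 0 else np.zeros(n)

    def build(trait):
        y = np.zeros(n)
        for site, eff in qtl_spec.get(trait, []):
            y += eff * dos[site]
        if h2_polygenic > 0:
            y += polygenic()
        return y + rng.normal(0, noise_sd, size=n)

    table = pd.DataFrame(index=pd.Index(gm.samples, name="sample"))
    for trait in SONG_TRAITS:
        table[trait] = build(trait)

    loadings = rng.normal(0, 1, size=(len(CHC_PEAKS), n_chc_factors))
    factors = np.column_stack(
        [build(f"chc_factor_{k + 1}") for k in range(n_chc_factors)]
    )
    latent = factors @ loadings.T + rng.normal(0, 0.3, size=(n, len(CHC_PEAKS)))
    peaks = np.log1p(np.exp(latent + 1.0))  # soft-plus keeps abundances > 0
    for j, peak in enumerate(CHC_PEAKS):
        table[peak] = peaks[:, j]

    z = table[covariate_trait].to_numpy()
    z = (z - z.mean()) / (z.std() or 1.0)
    table["mass"] = 0.5 * z + rng.normal(0, 1.0, size=n) + 10.0
    table["pronotum"] = 0.3 * z + rng.normal(0, 1.0, size=n) + 5.0

    rows = []
    for trait, qtls in qtl_spec.items():
        for site, eff in qtls:
            rows.append(
                (gm.sites["chrom"].iat[site], gm.sites["pos"].iat[site],
                 site, "qtl", trait, eff)
            )
    truth = pd.DataFrame(
        rows, columns=["chrom", "pos", "site_index", "role", "trait", "effect"]
    )
    return table, truth


# ---------------------------------------------------------------------------
# coalescent joint SFS
# ---------------------------------------------------------------------------

def simulate_joint_sfs(
    model: str,
    params: dict,
    n1: int,
    n2: int,
    n_loci: int,
    seed: int = 0,
    theta_per_locus: float = 0.0,
):
    """Observed joint SFS under a two-deme divergence/gene-flow model.

    ``n1``/``n2`` are haploid sample sizes.  ``params`` holds ``nu1``,
    ``nu2``, ``T1`` and, depending on the model, ``m`` and ``T2`` (see
    :mod:`barrierscan.demography` for semantics).  With the default
    ``theta_per_locus=0`` each locus contributes exactly one segregating
    site, placed on a branch chosen proportionally to length; otherwise
    mutations are Poisson(theta * total length) per locus.
    """
    import warnings as _warnings

    from .demography import JointSFS

    if n_loci < 100:
        _warnings.warn("n_loci < 100: spectrum will be too noisy for inference")
    m = float(params.get("m", 0.0)) if model != "no_mig" else 0.0
    T1 = float(params["T1"])
    T2 = params.get("T2")
    if T2 is not None and not 0 < T2 < T1:
        raise ValueError("T2 must satisfy 0 < T2 < T1")
    lo, hi, _ = migration_window(model, T1, T2)
    counts = sample_sfs_kernel(
        n1, n2, float(params["nu1"]), float(params["nu2"]), T1,
        lo, hi, m, int(n_loci), float(theta_per_locus),
        int(seed) & 0x7FFFFFFF,
    )
    return JointSFS(counts, n1, n2)
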