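"""Synthetic data: pedigree simulation, gene dropping, trait/fitness simulation.

The generator emulates an overlapping-generation, polygynous ungulate
population studied over ~10 birth cohorts: dams are drawn from living adult
females, sires from living adult males with strong reproductive skew (a small
fraction of males fathers most offspring), and a small fraction of matings
occurs between close relatives (kinship >= 0.125), producing occasional close
inbreeding on top of background relatedness.

Genotypes are produced by gene dropping: founders draw chromosome haplotypes
from a finite haplotype pool (which generates linkage disequilibrium between
markers), every founder haplotype copy carries a unique ancestry label, and
meioses place crossovers as a Poisson process on the centimorgan map (no
interference, Haldane model). The realized autozygosity of each individual —
the fraction of the genetic map where its two ancestry labels coincide — is
returned alongside the genotypes and serves as the ground truth that pedigree
and genomic inbreeding estimators are compared against.

Traits are Gaussian with additive genetic, maternal genetic (pedigree-
structured), maternal environment, year-of-birth and residual components plus
negative individual and maternal inbreeding slopes on the realized
autozygosity. Fitness components are binary (logit link: first-year survival,
annual survival) or counts (log link: annual breeding success) with
sex-specific intercepts and inbreeding slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genotypes import MISSING, GenotypeMatrix, MarkerMap
from .pedigree import UNKNOWN, Pedigree, f_ped

# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------


@dataclass
class TraitParams:
    """One Gaussian trait: mean, inbreeding slopes and variance components."""

    name: str
    mean: float
    beta_ind: float
    beta_mat: float
    v_additive: float
    v_maternal_genetic: float
    v_maternal_env: float
    v_year: float
    v_residual: float
    sex_effect: float = 0.0  # added for males


@dataclass
class FitnessLinkParams:
    """One fitness component for one sex: intercept and inbreeding slopes on
    the link scale (logit for survival, log for breeding success)."""

    alpha: float
    beta_ind: float
    beta_mat: float


def _default_traits() -> list[TraitParams]:
    # means/SDs and pedigree-based slopes follow the field study the generator
    # emulates; phenotypic variance is split across the four random components
    # known to matter for these juvenile traits plus residual
    return [
        TraitParams("birthweight", 2.08, -0.42, -3.09, 0.07, 0.04, 0.06, 0.07, 0.12,
                    sex_effect=0.10),
        TraitParams("august_weight", 13.18, -8.36, -7.89, 1.5, 0.8, 0.8, 1.5, 3.0,
                    sex_effect=0.50),
        TraitParams("august_hindleg", 159.48, -28.03, -10.78, 22.0, 11.0, 11.0,
                    22.0, 44.0, sex_effect=2.0),
    ]


def _default_fitness() -> dict[str, dict[str, FitnessLinkParams]]:
    # slopes from pedigree-based annual-fitness models of the emulated system;
    # intercepts give realistic baseline rates (lamb survival ~50-60%, adult
    # survival ~80%, ~1 offspring per adult-year)
    return {
        "first_year_survival": {
            "F": FitnessLinkParams(0.4, -6.42, 2.23),
            "M": FitnessLinkParams(0.0, -22.66, -20.63),
        },
        "annual_survival": {
            "F": FitnessLinkParams(1.4, -5.58, 2.37),
            "M": FitnessLinkParams(1.0, -5.02, -40.42),
        },
        "annual_breeding_success": {
            "F": FitnessLinkParams(-0.2, -2.31, 0.87),
            "M": FitnessLinkParams(0.0, -18.42, 6.25),
        },
    }


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic population."""

    n_cohorts: int = 10
    n_founder_females: int = 60
    n_founder_males: int = 30
    offspring_per_cohort: int = 140
    female_max_age: int = 6
    male_max_age: int = 6
    #: fraction of available sires fathering ``polygyny_mass`` of offspring
    polygyny_top_fraction: float = 0.2
    polygyny_mass: float = 0.8
    #: probability a dam mates a relative with kinship >= 0.125 when available
    close_mating_rate: float = 0.05
    n_chromosomes: int = 26
    #: per-chromosome genetic length in cM (1 cM per Mb). The default genome
    #: is scaled down ~10x relative to a ~2.4 Gb ungulate autosome set so that
    #: the desk-scale marker count keeps SNP-chip-like density (~87 kb
    #: spacing), which the ROH caller's density filter presumes
    chromosome_cm: float = 10.0
    n_snps: int = 3000
    #: number of distinct haplotype variants per LD block in the founder pool;
    #: smaller pools give stronger LD (within-block mean r^2 is roughly
    #: 1/(pool size - 1))
    founder_pool_size: int = 3
    #: mean LD-block length of the founder haplotype pool, in cM
    pool_block_cm: float = 0.25
    genotyping_error: float = 0.0
    missingness: float = 0.001
    n_adult_years: int = 3
    allow_selfing: bool = False  # test mode only
    traits: list[TraitParams] = field(default_factory=_default_traits)
    fitness: dict[str, dict[str, FitnessLinkParams]] = field(
        default_factory=_default_fitness
    )
    fitness_v_year: float = 0.15
    fitness_v_individual: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.close_mating_rate <= 1):
            raise ValueError("close_mating_rate must be in [0, 1]")
        if self.chromosome_cm <= 0 or self.n_chromosomes < 1:
            raise ValueError("map lengths must be positive")
        if min(self.n_founder_females, self.n_founder_males,
               self.offspring_per_cohort) < 1:
            raise ValueError("cohort sizes must be positive")
        for t in self.traits:
            if min(t.v_additive, t.v_maternal_genetic, t.v_maternal_env,
                   t.v_year, t.v_residual) < 0:
                raise ValueError(f"negative variance component in trait {t.name}")

    @property
    def total_map_morgans(self) -> float:
        return self.n_chromosomes * self.chromosome_cm / 100.0


# ----------------------------------------------------------------------
# pedigree simulation
# ----------------------------------------------------------------------


def simulate_pedigree(cfg: SimulationConfig, seed: int | None = None) -> Pedigree:
    """Simulate an overlapping-generation polygynous pedigree.

    Returns a validated :class:`Pedigree` with ``birth_cohort`` and ``sex``
    filled in. Founders form cohort 0; each later cohort's offspring draw dams
    uniformly from living adult females and sires from living adult males with
    reproductive skew; with probability ``close_mating_rate`` the sire is
    instead drawn among the dam's relatives (kinship >= 0.125) if any are
    available.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sire: dict[str, str] = {}
    dam: dict[str, str] = {}
    sex: dict[str, str] = {}
    cohort: dict[str, int] = {}
    order: list[str] = []
    kin_cache: dict[tuple[str, str], float] = {}

    def kinship(a: str, b: str) -> float:
        if a > b:
            a, b = b, a
        key = (a, b)
        val = kin_cache.get(key)
        if val is not None:
            return val
        # recurse through the younger individual (ids are created in order)
        x, y = (a, b) if order_index[a] >= order_index[b] else (b, a)
        sx, dx = sire[x], dam[x]
        if a == b:
            f = kinship(sx, dx) if sx != UNKNOWN and dx != UNKNOWN else 0.0
            val = 0.5 * (1.0 + f)
        else:
            val = 0.0
            if sx != UNKNOWN:
                val += 0.5 * kinship(sx, y)
            if dx != UNKNOWN:
                val += 0.5 * kinship(dx, y)
        kin_cache[key] = val
        return val

    order_index: dict[str, int] = {}

    def add(iid: str, s: str, d: str, sx: str, coh: int) -> None:
        sire[iid], dam[iid], sex[iid], cohort[iid] = s, d, sx, coh
        order_index[iid] = len(order)
        order.append(iid)

    for k in range(cfg.n_founder_females):
        add(f"F0_{k:04d}", UNKNOWN, UNKNOWN, "F", 0)
    for k in range(cfg.n_founder_males):
        add(f"M0_{k:04d}", UNKNOWN, UNKNOWN, "M", 0)

    for coh in range(1, cfg.n_cohorts + 1):
        females = [
            i for i in order
            if sex[i] == "F" and 1 <= coh - cohort[i] <= cfg.female_max_age
        ]
        males = [
            i for i in order
            if sex[i] == "M" and 1 <= coh - cohort[i] <= cfg.male_max_age
        ]
        if not females or not males:
            raise ValueError(f"no available parents for cohort {coh}")
        sire_w = _polygyny_weights(
            len(males), cfg.polygyny_top_fraction, cfg.polygyny_mass, rng
        )
        for j in range(cfg.offspring_per_cohort):
            d = females[rng.integers(len(females))]
            s = None
            if rng.random() < cfg.close_mating_rate:
                relatives = [
                    m for m in males
                    if (m != d or cfg.allow_selfing) and kinship(d, m) >= 0.125
                ]
                if relatives:
                    s = relatives[rng.integers(len(relatives))]
            if s is None:
                s = males[rng.choice(len(males), p=sire_w)]
            child_sex = "F" if rng.random() < 0.5 else "M"
            add(f"{child_sex}{coh}_{j:04d}", s, d, child_sex, coh)

    ped = Pedigree.from_records(
        [(i, sire[i], dam[i]) for i in order], birth_cohort=cohort
    )
    ped.sex = sex
    return ped


def _polygyny_weights(
    n_males: int, top_fraction: float, mass: float, rng: np.random.Generator
) -> np.ndarray:
    """Geometric sire weights such that the top ``top_fraction`` of males holds
    ``mass`` of the total siring probability; rank order is randomised."""
    if n_males == 1:
        return np.ones(1)
    m = max(1, int(np.ceil(top_fraction * n_males)))
    if m >= n_males:
        w = np.ones(n_males)
    else:
        def excess(log_r: float) -> float:
            r = np.exp(log_r)
            ranks = np.arange(n_males)
            w = r**ranks
            return w[:m].sum() / w.sum() - mass

        # geometric ratio in (0, 1); log-parameterised for stability
        lo, hi = np.log(1e-6), np.log(1 - 1e-9)
        if excess(hi) > 0:  # even near-uniform already too skewed (tiny n)
            w = np.ones(n_males)
        else:
            log_r = brentq(excess, lo, hi)
            w = np.exp(log_r) ** np.arange(n_males)
    w = w / w.sum()
    return w[rng.permutation(n_males)]


# ----------------------------------------------------------------------
# gene dropping
# ----------------------------------------------------------------------


def _simulate_map(cfg: SimulationConfig, rng: np.random.Generator) -> MarkerMap:
    """Chip-like marker map: near-regular SNP spacing with jitter, 1 cM per Mb.

    SNP arrays are designed for even genome coverage, so positions are a
    regular grid with +/-30% spacing jitter rather than a uniform scatter
    (which would produce exponentially distributed gaps and frequent spurious
    run splits at the ROH caller's gap threshold).
    """
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    rows = []
    for c in range(cfg.n_chromosomes):
        n = int(per_chrom[c])
        step = cfg.chromosome_cm / n
        cm = (np.arange(n) + 0.5 + rng.uniform(-0.3, 0.3, size=n)) * step
        bp = np.unique((cm * 1e6).astype(np.int64))
        while len(bp) < n:  # collisions after rounding (sub-bp jitter)
            extra = np.int64(rng.uniform(0.5, cfg.chromosome_cm - 0.5) * 1e6)
            bp = np.unique(np.append(bp, extra))
        bp = bp[:n]
        for b in bp:
            rows.append((f"snp{c+1}_{b}", str(c + 1), int(b), b / 1e6))
    table = pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cm"])
    mmap = MarkerMap(table, genome_length_kb=1.0)  # placeholder, fixed below
    mmap.genome_length_kb = mmap.assayed_span_kb()
    return mmap


class _FounderPool:
    """Block-mosaic founder haplotype pool.

    Each chromosome is cut into LD blocks (mean length ``block_cm``); each
    block carries ``pool_size`` distinct variant sequences, polymorphic at
    every SNP. A founder haplotype picks one variant per block uniformly at
    random, so markers within a block are in strong LD (mean r^2 roughly
    1/(pool_size - 1)) while markers in different blocks start in linkage
    equilibrium — a compact stand-in for the block structure that drift and
    recombination produce in a small population.
    """

    def __init__(
        self,
        cm: np.ndarray,
        chrom_slices: list[slice],
        pool_size: int,
        block_cm: float,
        rng: np.random.Generator,
    ) -> None:
        n_snps = len(cm)
        self.pool_size = pool_size
        self.block_of_snp = np.empty(n_snps, dtype=np.int64)
        n_blocks = 0
        for sl in chrom_slices:
            c_cm = cm[sl]
            span = float(c_cm[-1]) + block_cm
            n_bounds = rng.poisson(span / block_cm)
            bounds = np.sort(rng.uniform(0.0, span, size=n_bounds))
            self.block_of_snp[sl] = n_blocks + np.searchsorted(bounds, c_cm)
            n_blocks += n_bounds + 1
        self.n_blocks = n_blocks
        p = rng.uniform(0.15, 0.85, size=n_snps)
        v = (rng.random((pool_size, n_snps)) < p).astype(np.uint8)
        mono = (v.sum(0) == 0) | (v.sum(0) == pool_size)
        while mono.any():
            idx = np.flatnonzero(mono)
            v[:, idx] = (rng.random((pool_size, len(idx))) < p[idx]).astype(np.uint8)
            mono = (v.sum(0) == 0) | (v.sum(0) == pool_size)
        self.variants = v  # pool_size x n_snps
        self._snp_idx = np.arange(n_snps)

    def draw_haplotype(self, rng: np.random.Generator) -> np.ndarray:
        choice = rng.integers(0, self.pool_size, size=self.n_blocks)
        return self.variants[choice[self.block_of_snp], self._snp_idx]


def gene_drop(
    ped: Pedigree, cfg: SimulationConfig, seed: int | None = None
) -> tuple[GenotypeMatrix, MarkerMap, pd.Series]:
    """Drop founder haplotypes down the pedigree with Haldane recombination.

    Returns genotypes, the marker map, and the realized autozygosity per
    individual: the map-length-weighted fraction of the genome where the two
    ancestry labels coincide. Founders get fresh pool haplotypes with unique
    labels, so their realized autozygosity is exactly 0.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    mmap = _simulate_map(cfg, rng)
    n_snps = len(mmap)
    chrom_labels = pd.unique(mmap.chrom)
    chrom_slices: list[slice] = []
    start = 0
    for c in chrom_labels:
        n = int((mmap.chrom == c).sum())
        chrom_slices.append(slice(start, start + n))
        start += n
    cm = mmap.cm
    chrom_len_cm = cfg.chromosome_cm
    # map-length weights per SNP (Voronoi cells on the cM map, clipped at
    # chromosome boundaries); denominator is the total map length
    weights = np.empty(n_snps)
    for sl in chrom_slices:
        c_cm = cm[sl]
        edges = np.concatenate([[0.0], (c_cm[:-1] + c_cm[1:]) / 2, [chrom_len_cm]])
        weights[sl] = np.diff(edges)
    weights = weights / (cfg.n_chromosomes * chrom_len_cm)

    pool = _FounderPool(
        cm, chrom_slices, cfg.founder_pool_size, cfg.pool_block_cm, rng
    )
    hap_alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    hap_labels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    next_label = 0
    dosages = np.empty((len(ped), n_snps), dtype=np.int8)
    true_ibd = np.empty(len(ped))

    def meiosis(parent: str) -> tuple[np.ndarray, np.ndarray]:
        """One gamete: per-chromosome Poisson crossovers, random start phase."""
        a0, a1 = hap_alleles[parent]
        l0, l1 = hap_labels[parent]
        sel = np.empty(n_snps, dtype=bool)
        for sl in chrom_slices:
            c_cm = cm[sl]
            n_x = rng.poisson(chrom_len_cm / 100.0)
            phase = bool(rng.integers(2))
            if n_x == 0:
                sel[sl] = phase
                continue
            xpos = np.sort(rng.uniform(0.0, chrom_len_cm, size=n_x))
            n_before = np.searchsorted(xpos, c_cm)
            sel[sl] = (n_before + phase) % 2 == 1
        alleles = np.where(sel, a1, a0)
        labels = np.where(sel, l1, l0)
        return alleles, labels

    for k, iid in enumerate(ped.ids):
        s, d = ped.parents(iid)
        if s == UNKNOWN or d == UNKNOWN:
            # founder (or half-known: treated as founder for transmission)
            a = (pool.draw_haplotype(rng), pool.draw_haplotype(rng))
            lab = (
                np.full(n_snps, next_label, dtype=np.int32),
                np.full(n_snps, next_label + 1, dtype=np.int32),
            )
            next_label += 2
        else:
            a_s, lab_s = meiosis(s)
            a_d, lab_d = meiosis(d)
            a, lab = (a_s, a_d), (lab_s, lab_d)
        hap_alleles[iid] = a
        hap_labels[iid] = lab
        dosages[k] = a[0] + a[1]
        true_ibd[k] = float(weights @ (lab[0] == lab[1]))

    if cfg.genotyping_error > 0:
        err = rng.random(dosages.shape) < cfg.genotyping_error
        dosages = np.where(err, rng.integers(0, 3, size=dosages.shape), dosages)
    if cfg.missingness > 0:
        miss = rng.random(dosages.shape) < cfg.missingness
        dosages = np.where(miss, MISSING, dosages)

    gm = GenotypeMatrix(
        ids=list(ped.ids),
        markers=list(mmap.table["marker"]),
        dosages=dosages.astype(np.int8),
    )
    truth = pd.Series(true_ibd, index=list(ped.ids), name="true_ibd")
    return gm, mmap, truth


# ----------------------------------------------------------------------
# breeding values down the pedigree
# ----------------------------------------------------------------------


def _breeding_values(
    ped: Pedigree, variance: float, fped: Mapping[str, float],
    rng: np.random.Generator,
) -> dict[str, float]:
    """Additive genetic values sampled down the pedigree: founders N(0, V),
    offspring mid-parent plus Mendelian deviation N(0, V(0.5 - 0.25(F_s+F_d)));
    an unknown parent contributes an independent founder-scale draw."""
    if variance == 0:
        return {i: 0.0 for i in ped.ids}
    sd = np.sqrt(variance)
    bv: dict[str, float] = {}
    for iid in ped.ids:
        s, d = ped.parents(iid)
        if s == UNKNOWN and d == UNKNOWN:
            bv[iid] = rng.normal(0.0, sd)
        elif s != UNKNOWN and d != UNKNOWN:
            mendel_var = variance * (0.5 - 0.25 * (fped[s] + fped[d]))
            bv[iid] = 0.5 * (bv[s] + bv[d]) + rng.normal(
                0.0, np.sqrt(max(mendel_var, 0.0))
            )
        else:
            known = s if s != UNKNOWN else d
            # unknown parent assumed unrelated and non-inbred
            mendel_var = variance * (0.5 - 0.25 * fped[known])
            bv[iid] = 0.5 * bv[known] + rng.normal(
                0.0, np.sqrt(0.25 * variance + max(mendel_var, 0.0))
            )
    return bv


# ----------------------------------------------------------------------
# traits and fitness
# ----------------------------------------------------------------------


def simulate_traits(
    ped: Pedigree,
    true_ibd: pd.Series,
    cfg: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gaussian traits with inbreeding, maternal, genetic and year effects.

    One row per individual: id, sire, dam, sex, cohort, F_ind (realized
    autozygosity), F_mat (dam's, NaN for unknown dam, flagged by
    ``has_maternal``), then one column per configured trait. Individuals with
    unknown dam get no maternal terms.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    sex = getattr(ped, "sex", None) or {
        i: ("M" if rng.random() < 0.5 else "F") for i in ped.ids
    }
    fped = f_ped(ped)
    cohorts = sorted({ped.birth_cohort.get(i, 0) for i in ped.ids})
    rows: dict[str, list] = {
        "id": [], "sire": [], "dam": [], "sex": [], "cohort": [],
        "F_ind": [], "F_mat": [], "has_maternal": [],
    }
    for iid in ped.ids:
        s, d = ped.parents(iid)
        rows["id"].append(iid)
        rows["sire"].append(s or "0")
        rows["dam"].append(d or "0")
        rows["sex"].append(sex[iid])
        rows["cohort"].append(ped.birth_cohort.get(iid, 0))
        rows["F_ind"].append(float(true_ibd[iid]))
        rows["F_mat"].append(float(true_ibd[d]) if d != UNKNOWN else np.nan)
        rows["has_maternal"].append(d != UNKNOWN)
    df = pd.DataFrame(rows)

    for t in cfg.traits:
        a = _breeding_values(ped, t.v_additive, fped, rng)
        m = _breeding_values(ped, t.v_maternal_genetic, fped, rng)
        c_env = {i: rng.normal(0, np.sqrt(t.v_maternal_env)) for i in ped.ids} \
            if t.v_maternal_env > 0 else {i: 0.0 for i in ped.ids}
        year = {y: rng.normal(0, np.sqrt(t.v_year)) if t.v_year > 0 else 0.0
                for y in cohorts}
        vals = np.empty(len(ped.ids))
        for k, iid in enumerate(ped.ids):
            d = ped.dam[iid]
            y = t.mean + t.beta_ind * true_ibd[iid]
            y += t.sex_effect * (sex[iid] == "M")
            y += a[iid] + year[ped.birth_cohort.get(iid, 0)]
            if d != UNKNOWN:
                y += t.beta_mat * true_ibd[d] + m[d] + c_env[d]
            y += rng.normal(0, np.sqrt(t.v_residual)) if t.v_residual > 0 else 0.0
            vals[k] = y
        df[t.name] = vals
    return df


def simulate_fitness(
    ped: Pedigree,
    true_ibd: pd.Series,
    cfg: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Binary and count fitness records on the link scale.

    One first-year-survival row per individual plus ``n_adult_years`` annual
    rows (annual survival, annual breeding success) per individual. Linear
    predictors include sex-specific intercepts, individual and maternal
    inbreeding slopes, a Gaussian year effect and (for annual records) a
    Gaussian individual effect for repeated measures.
    """
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    sex = getattr(ped, "sex", None) or {
        i: ("M" if rng.random() < 0.5 else "F") for i in ped.ids
    }
    v_year, v_ind = cfg.fitness_v_year, cfg.fitness_v_individual
    years = sorted({ped.birth_cohort.get(i, 0) for i in ped.ids})
    years = list(range(min(years), max(years) + cfg.n_adult_years + 2))
    year_eff = {
        comp: {y: rng.normal(0, np.sqrt(v_year)) if v_year > 0 else 0.0
               for y in years}
        for comp in cfg.fitness
    }
    ind_eff = {
        comp: {i: rng.normal(0, np.sqrt(v_ind)) if v_ind > 0 else 0.0
               for i in ped.ids}
        for comp in cfg.fitness
    }

    recs = []
    for iid in ped.ids:
        sx = sex[iid]
        dam = ped.dam[iid]
        f_i = float(true_ibd[iid])
        f_m = float(true_ibd[dam]) if dam != UNKNOWN else np.nan
        coh = ped.birth_cohort.get(iid, 0)

        def eta(comp: str, year: int) -> float:
            p = cfg.fitness[comp][sx]
            e = p.alpha + p.beta_ind * f_i + year_eff[comp][year]
            if dam != UNKNOWN:
                e += p.beta_mat * f_m
            return e

        e = eta("first_year_survival", coh)
        recs.append(
            (iid, sx, dam or "0", coh, coh, f_i, f_m, "first_year_survival",
             int(rng.random() < _expit(e)))
        )
        for age in range(1, cfg.n_adult_years + 1):
            year = coh + age
            e = eta("annual_survival", year) + ind_eff["annual_survival"][iid]
            recs.append(
                (iid, sx, dam or "0", coh, year, f_i, f_m, "annual_survival",
                 int(rng.random() < _expit(e)))
            )
            e = eta("annual_breeding_success", year) \
                + ind_eff["annual_breeding_success"][iid]
            recs.append(
                (iid, sx, dam or "0", coh, year, f_i, f_m,
                 "annual_breeding_success", int(rng.poisson(np.exp(e))))
            )
    return pd.DataFrame(
        recs,
        columns=["id", "sex", "dam", "cohort", "year", "F_ind", "F_mat",
                 "component", "response"],
    )


def _expit(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))
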