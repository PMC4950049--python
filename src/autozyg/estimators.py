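"""Genomic inbreeding estimators: F_hom, F_GRM, F_ROH, g2, HH correlation.

Four individual-level quantities are computed from a SNP panel:

* ``f_hom`` — multilocus homozygosity: the fraction of successfully genotyped
  loci that are homozygous. Scale-free, no allele frequencies required.
* ``f_grm`` — the GRM diagonal (Yang-type "Fhat3") estimator averaging
  ``[x^2 - (1+2p)x + 2p^2] / [2p(1-p)]`` over loci; weights homozygotes of the
  rare allele more heavily and can be negative.
* ``detect_roh``/``f_roh`` — runs of homozygosity by the scanning-window
  algorithm (window homozygosity -> per-SNP hit proportion -> run assembly
  with gap splitting and length/density filters), F_ROH = summed ROH length
  over assayed genome length.
* ``g2_estimate`` — identity disequilibrium: the standardised excess of joint
  heterozygosity at pairs of loci, positive when inbreeding varies between
  individuals. Uncertainty by bootstrap over individuals, significance by
  independently permuting each locus across individuals.

The expected length of a single-path autozygous segment from a common ancestor
``g`` generations back is exponential with mean 1/(2g) Morgans; at 1 cM per Mb
this is 100/(2g) Mb (``expected_roh_length_mb``), the basis for the 5 Mb
minimum-length convention (ancestors up to ~10 generations back).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeError, GenotypeMatrix, MarkerMap

# ----------------------------------------------------------------------
# SNP-by-SNP estimators
# ----------------------------------------------------------------------


def f_hom(gm: GenotypeMatrix) -> pd.Series:
    """Proportion of successfully genotyped loci that are homozygous.

    Individuals with zero non-missing calls get NaN.
    """
    d = gm.dosages
    called = (d != MISSING).sum(axis=1)
    hom = ((d == 0) | (d == 2)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = hom / called
    return pd.Series(np.where(called > 0, f, np.nan), index=gm.ids, name="F_hom")


def f_grm(gm: GenotypeMatrix, p: np.ndarray | None = None) -> pd.Series:
    """GRM-diagonal inbreeding estimator, averaged over non-missing markers.

    Per marker i and individual j with dosage x and reference frequency p:
    ``[x^2 - (1+2p)x + 2p^2] / [2p(1-p)]``. Monomorphic markers are an error —
    they must be removed by QC first.
    """
    if p is None:
        p = gm.allele_freq()
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any((p <= 0) | (p >= 1)):
        bad = np.flatnonzero(~((p > 0) & (p < 1)))
        raise GenotypeError(
            f"monomorphic or uncalled markers in f_grm (e.g. index {bad[0]}); "
            "apply QC filtering first"
        )
    d = gm.dosages.astype(float)
    obs = gm.dosages != MISSING
    x = np.where(obs, d, 0.0)
    per_locus = (x * x - (1 + 2 * p) * x + 2 * p * p) / (2 * p * (1 - p))
    per_locus = np.where(obs, per_locus, 0.0)
    n_obs = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = per_locus.sum(axis=1) / n_obs
    return pd.Series(np.where(n_obs > 0, f, np.nan), index=gm.ids, name="F_GRM")


# ----------------------------------------------------------------------
# Runs of homozygosity
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class ROHParams:
    """Scanning-window ROH parameters (PLINK-style conventions).

    Defaults correspond to: window of 5 SNPs capped at 200 Mb, no heterozygous
    and at most 2 missing calls per homozygous window, hit proportion 0.05,
    runs of at least 15 SNPs and 5 Mb, split at gaps over 1 Mb, and at most
    275 kb per SNP average spacing inside a run.
    """

    window_snps: int = 5
    window_het_max: int = 0
    window_missing_max: int = 2
    min_snps: int = 15
    min_kb: float = 5000.0
    max_gap_kb: float = 1000.0
    density_kb_per_snp: float = 275.0
    window_kb_max: float = 200_000.0
    hit_proportion: float = 0.05

    def __post_init__(self) -> None:
        zero_ok = {"window_het_max", "window_missing_max"}
        for name, val in self.__dict__.items():
            if val < 0 or (val == 0 and name not in zero_ok):
                raise ValueError(f"ROH parameter {name} must be positive")


@dataclass(frozen=True)
class ROHSegment:
    individual: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


def detect_roh(
    gm: GenotypeMatrix, mmap: MarkerMap, params: ROHParams | None = None
) -> list[ROHSegment]:
    """Call runs of homozygosity per individual with the scanning-window method.

    Per chromosome: (1) every window of ``window_snps`` consecutive SNPs
    spanning at most ``window_kb_max`` is homozygous iff it has at most
    ``window_het_max`` heterozygous and ``window_missing_max`` missing calls;
    (2) a SNP is a hit iff the fraction of overlapping homozygous windows is
    at least ``hit_proportion``; (3) maximal runs of hit SNPs, split at
    adjacent-SNP gaps above ``max_gap_kb``, are candidates; (4) candidates are
    kept iff they have at least ``min_snps`` SNPs, span at least ``min_kb``
    and average at most ``density_kb_per_snp`` kb per SNP.
    """
    params = params or ROHParams()
    if len(mmap) != gm.n_markers:
        raise GenotypeError("marker map length does not match genotype matrix")
    segments: list[ROHSegment] = []
    chrom_arr = mmap.chrom
    bp_arr = mmap.bp
    for chrom in pd.unique(chrom_arr):
        cidx = np.flatnonzero(chrom_arr == chrom)
        bp = bp_arr[cidx].astype(np.int64)
        if np.any(np.diff(bp) <= 0):
            raise GenotypeError(f"marker map unsorted on chromosome {chrom}")
        d_chr = gm.dosages[:, cidx]
        for i, iid in enumerate(gm.ids):
            hits = _hit_snps(d_chr[i], bp, params)
            segments.extend(_assemble_runs(hits, bp, str(chrom), iid, params))
    return segments


def _hit_snps(d: np.ndarray, bp: np.ndarray, p: ROHParams) -> np.ndarray:
    """Boolean per-SNP hit mask for one individual/chromosome."""
    m = len(d)
    w = min(p.window_snps, m)
    het = (d == 1).astype(np.int32)
    mis = (d == MISSING).astype(np.int32)
    # window sums via cumulative sums; window t covers SNPs [t, t+w)
    n_win = m - w + 1
    ch = np.concatenate([[0], np.cumsum(het)])
    cm_ = np.concatenate([[0], np.cumsum(mis)])
    het_w = ch[w:] - ch[:-w]
    mis_w = cm_[w:] - cm_[:-w]
    span_ok = (bp[w - 1 :] - bp[: m - w + 1]) / 1000.0 <= p.window_kb_max
    hom_w = (het_w <= p.window_het_max) & (mis_w <= p.window_missing_max) & span_ok
    # SNP j overlaps windows max(0, j-w+1) .. min(j, n_win-1)
    chw = np.concatenate([[0], np.cumsum(hom_w.astype(np.int64))])
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    n_overlap = hi - lo + 1
    n_hom = chw[hi + 1] - chw[lo]
    return n_hom / n_overlap >= p.hit_proportion


def _assemble_runs(
    hits: np.ndarray, bp: np.ndarray, chrom: str, iid: str, p: ROHParams
) -> list[ROHSegment]:
    out: list[ROHSegment] = []
    m = len(hits)
    j = 0
    while j < m:
        if not hits[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and hits[k + 1]:
            # split runs at large inter-SNP gaps
            if (bp[k + 1] - bp[k]) / 1000.0 > p.max_gap_kb:
                break
            k += 1
        n_snps = k - j + 1
        length_kb = (bp[k] - bp[j]) / 1000.0
        if (
            n_snps >= p.min_snps
            and length_kb >= p.min_kb
            and length_kb / n_snps <= p.density_kb_per_snp
        ):
            out.append(ROHSegment(iid, chrom, int(bp[j]), int(bp[k]), n_snps))
        j = k + 1
    return out


def roh_table(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.individual, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.length_kb)
            for s in segments
        ],
        columns=["id", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"],
    )


def f_roh(
    segments: list[ROHSegment],
    mmap: MarkerMap,
    individuals: list[str] | None = None,
) -> pd.Series:
    """F_ROH: summed ROH length / assayed genome length (``genome_length_kb``)."""
    total = pd.Series(0.0, index=individuals if individuals is not None else [])
    for s in segments:
        if s.individual not in total.index:
            total[s.individual] = 0.0
        total[s.individual] += s.length_kb
    return (total / mmap.genome_length_kb).rename("F_ROH")


def expected_roh_length_mb(g: float) -> float:
    """Expected autozygous-segment length (Mb) for a common ancestor ``g``
    generations back: exponential mean 1/(2g) Morgans, at 1 cM per Mb."""
    if g <= 0:
        raise ValueError("generations g must be positive")
    return 100.0 / (2.0 * g)


# ----------------------------------------------------------------------
# Identity disequilibrium g2
# ----------------------------------------------------------------------


@dataclass
class G2Result:
    g2: float
    bootstrap_sd: float
    permutation_p: float
    n_boot: int
    n_perm: int
    seed: int
    degenerate: bool = False


def _g2_core(
    het: np.ndarray, valid: np.ndarray, pairwise_complete: bool = False
) -> float:
    """g2 from an n x L heterozygosity indicator and validity mask.

    Within/between ratio over ordered pairs of distinct loci, with the
    heterozygosity indicator zero at missing calls and denominators n and
    n(n-1). The pair sums collapse exactly to row/column-sum identities, so
    the default path is O(nL). With ``pairwise_complete=True`` each locus
    pair instead averages only over individuals (pairs) valid at both loci —
    an O(nL^2) variant that differs only in the presence of missing calls.
    """
    n, L = het.shape
    if not pairwise_complete:
        r = het.sum(axis=1).astype(np.float64)  # per-individual het count
        s = het.sum(axis=0).astype(np.float64)  # per-locus het count
        return _g2_from_sums(float(r @ r), float(s @ s), float(s.sum()), n, L)
    else:
        h = het.astype(np.float64)
        v = valid.astype(np.float64)
        W = h.T @ h  # joint-het counts per locus pair
        N2 = v.T @ v  # both-valid counts per locus pair
        s = h.sum(axis=0)
        nl = v.sum(axis=0)
        off = ~np.eye(L, dtype=bool)
        with np.errstate(invalid="ignore", divide="ignore"):
            within = np.where(N2 > 0, W / np.maximum(N2, 1), np.nan)
            denom_b = np.outer(nl, nl) - N2
            between = np.where(
                denom_b > 0, (np.outer(s, s) - W) / np.maximum(denom_b, 1), np.nan
            )
        m_within = np.nanmean(within[off])
        m_between = np.nanmean(between[off])
    if m_between == 0 or not np.isfinite(m_between):
        return np.nan
    return float(m_within / m_between - 1.0)


def _g2_from_sums(rr: float, ss: float, T: float, n: int, L: int) -> float:
    """g2 from sufficient statistics: rr = sum_i r_i^2, ss = sum_l s_l^2,
    T = total het count, for n individuals and L loci."""
    denom_pairs = L * (L - 1)
    m_within = (rr - T) / (n * denom_pairs)
    m_between = (T * T - ss - (rr - T)) / (n * (n - 1) * denom_pairs)
    if m_between == 0 or not np.isfinite(m_between):
        return np.nan
    return m_within / m_between - 1.0


def g2_estimate(
    gm: GenotypeMatrix,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
    pairwise_complete: bool = False,
) -> G2Result:
    """Identity disequilibrium g2 with bootstrap SD and permutation p-value.

    Bootstrap resamples individuals; the permutation null shuffles each locus
    column independently across individuals (destroying inbreeding-driven
    covariance in heterozygosity while keeping locus frequencies), and the
    p-value is the upper-tail rank of the observed g2 with the +1 correction.
    Loci with zero observed heterozygotes are dropped with a warning.
    """
    d = gm.dosages
    if d.shape[0] < 3 or d.shape[1] < 2:
        raise GenotypeError("g2 needs at least 3 individuals and 2 loci")
    het = (d == 1)
    valid = d != MISSING
    keep = het.sum(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"g2: dropping {int((~keep).sum())} loci with no observed heterozygotes"
        )
        het, valid = het[:, keep], valid[:, keep]
        if het.shape[1] < 2:
            raise GenotypeError("g2: fewer than 2 informative loci remain")
    n, L = het.shape
    rng = np.random.default_rng(seed)
    obs = _g2_core(het, valid, pairwise_complete)
    degenerate = not np.isfinite(obs)

    boots = np.empty(n_boot)
    exceed = 0
    if pairwise_complete:
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boots[b] = _g2_core(het[idx], valid[idx], True)
        for _ in range(n_perm):
            # independent permutation per locus; het and validity move together
            perm = np.argsort(rng.random(het.shape), axis=0)
            hp = np.take_along_axis(het, perm, axis=0)
            vp = np.take_along_axis(valid, perm, axis=0)
            if _g2_core(hp, vp, True) >= obs:
                exceed += 1
    else:
        # the statistic depends only on the row sums r, column sums s and
        # total T of the het indicator, all linear in the bootstrap counts,
        # so each replicate is O(nL) at worst
        het_f = het.astype(np.float32)
        r = het.sum(axis=1).astype(np.float64)
        for b in range(n_boot):
            counts = np.bincount(
                rng.integers(0, n, size=n), minlength=n
            ).astype(np.float32)
            s_b = counts @ het_f
            rr = float(counts @ (r * r))
            T = float(counts @ r)
            boots[b] = _g2_from_sums(rr, float(s_b @ s_b), T, n, L)
        # column permutations leave s and T unchanged; only r changes
        s = het.sum(axis=0).astype(np.float64)
        ss, T = float(s @ s), float(s.sum())
        for _ in range(n_perm):
            hp = rng.permuted(het, axis=0)
            r_p = hp.sum(axis=1).astype(np.float64)
            if _g2_from_sums(float(r_p @ r_p), ss, T, n, L) >= obs:
                exceed += 1
    bootstrap_sd = float(np.nanstd(boots, ddof=1)) if n_boot > 1 else np.nan
    permutation_p = (exceed + 1) / (n_perm + 1)
    return G2Result(
        g2=obs,
        bootstrap_sd=bootstrap_sd,
        permutation_p=float(permutation_p),
        n_boot=n_boot,
        n_perm=n_perm,
        seed=seed,
        degenerate=degenerate,
    )


# ----------------------------------------------------------------------
# Heterozygosity-heterozygosity correlation
# ----------------------------------------------------------------------


def hh_correlation(
    gm: GenotypeMatrix, n_splits: int = 100, seed: int = 0
) -> dict[str, tuple[float, float]]:
    """Correlation of SNP inbreeding estimators between random marker halves.

    For each split, markers are randomly partitioned into halves and the
    per-individual F_hom (and F_GRM) computed on one half is Pearson-correlated
    with the other half. Returns ``{"F_hom": (mean, sd), "F_GRM": (mean, sd)}``
    over splits. High values mean the panel is informative about genome-wide
    inbreeding (identity disequilibrium).
    """
    L = gm.n_markers
    if L < 2:
        raise GenotypeError("hh_correlation needs at least 2 markers")
    rng = np.random.default_rng(seed)
    p = gm.allele_freq()
    poly = (p > 0) & (p < 1)
    r_hom = np.empty(n_splits)
    r_grm = np.empty(n_splits)
    for k in range(n_splits):
        perm = rng.permutation(L)
        half1, half2 = perm[: L // 2], perm[L // 2 :]
        a_hom = f_hom(gm.subset(markers=half1)).to_numpy()
        b_hom = f_hom(gm.subset(markers=half2)).to_numpy()
        r_hom[k] = _pearson(a_hom, b_hom)
        h1 = half1[poly[half1]]
        h2 = half2[poly[half2]]
        a_grm = f_grm(gm.subset(markers=h1), p=p[h1]).to_numpy()
        b_grm = f_grm(gm.subset(markers=h2), p=p[h2]).to_numpy()
        r_grm[k] = _pearson(a_grm, b_grm)
    return {
        "F_hom": (float(np.nanmean(r_hom)), float(np.nanstd(r_hom, ddof=1))),
        "F_GRM": (float(np.nanmean(r_grm)), float(np.nanstd(r_grm, ddof=1))),
    }


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return np.nan
    return float(np.corrcoef(a[ok], b[ok])[0, 1])
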