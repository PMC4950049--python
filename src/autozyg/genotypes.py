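"""SNP genotype containers, PED/MAP and TSV I/O, QC filters and LD pruning.

Genotypes are stored as reference-allele dosages (0/1/2, with -1 for missing)
in an individuals x markers int8 array. Quality control follows standard chip
practice: individuals are filtered on call rate first, then loci on minor
allele frequency, call rate and an exact Hardy-Weinberg test computed on the
retained individuals. LD thinning uses sliding-window variance-inflation-factor
(VIF) pruning, where VIF = 1/(1 - R^2) of each marker regressed on the other
markers in the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: Total assayed autosome span (first to last SNP summed over chromosomes), in
#: kb. Used as the denominator of F_ROH when not recomputed from a marker map.
DEFAULT_GENOME_LENGTH_KB = 2_434_125.0


class GenotypeError(ValueError):
    pass


@dataclass
class MarkerMap:
    """Marker positions: chromosome label, bp position, optional cM position."""

    table: pd.DataFrame  # columns: marker, chrom, bp[, cm]
    genome_length_kb: float = DEFAULT_GENOME_LENGTH_KB

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "chrom", "bp"}
        if not required.issubset(t.columns):
            raise GenotypeError(f"marker map needs columns {sorted(required)}")
        if self.genome_length_kb <= 0:
            raise GenotypeError("genome_length_kb must be positive")
        for chrom, sub in t.groupby("chrom", sort=False):
            bp = sub["bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise GenotypeError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def bp(self) -> np.ndarray:
        return self.table["bp"].to_numpy()

    @property
    def cm(self) -> np.ndarray:
        if "cm" in self.table.columns:
            return self.table["cm"].to_numpy(dtype=float)
        # 1 cM ~ 1 Mb convention when no genetic map is supplied
        return self.bp / 1e6

    def assayed_span_kb(self) -> float:
        """Sum over chromosomes of (last - first SNP position), in kb."""
        spans = self.table.groupby("chrom", sort=False)["bp"].agg(["min", "max"])
        return float((spans["max"] - spans["min"]).sum() / 1000.0)

    def subset(self, keep: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            self.table.iloc[keep].reset_index(drop=True), self.genome_length_kb
        )


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix (0/1/2; -1 = missing call)."""

    ids: list[str]
    markers: list[str]
    dosages: np.ndarray  # int8, shape (n_individuals, n_markers)
    alleles: list[tuple[str, str]] | None = None  # (ref, alt) per marker

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = self.dosages.shape
        if n != len(self.ids) or m != len(self.markers):
            raise GenotypeError("dosage matrix shape does not match ids/markers")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeError("dosages must be 0, 1, 2 or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def allele_freq(self) -> np.ndarray:
        """Reference-allele frequency per marker from non-missing calls (NaN if
        a marker has no calls)."""
        d = self.dosages
        obs = d != MISSING
        n_called = obs.sum(axis=0)
        ref_count = np.where(obs, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = ref_count / (2.0 * n_called)
        return np.where(n_called > 0, p, np.nan)

    def call_rate_individuals(self) -> np.ndarray:
        return (self.dosages != MISSING).mean(axis=1)

    def call_rate_markers(self) -> np.ndarray:
        return (self.dosages != MISSING).mean(axis=0)

    def genotype_counts(self) -> np.ndarray:
        """Per-marker (n_hom_ref, n_het, n_hom_alt) counts."""
        d = self.dosages
        return np.stack([(d == 2).sum(0), (d == 1).sum(0), (d == 0).sum(0)], axis=1)

    def subset(
        self, individuals: np.ndarray | None = None, markers: np.ndarray | None = None
    ) -> "GenotypeMatrix":
        ids, mk, d, al = self.ids, self.markers, self.dosages, self.alleles
        if individuals is not None:
            ids = [ids[i] for i in np.atleast_1d(individuals)]
            d = d[np.atleast_1d(individuals), :]
        if markers is not None:
            midx = np.atleast_1d(markers)
            mk = [mk[j] for j in midx]
            d = d[:, midx]
            if al is not None:
                al = [al[j] for j in midx]
        return GenotypeMatrix(ids=ids, markers=mk, dosages=d.copy(), alleles=al)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------


def read_map(path: str | Path, genome_length_kb: float | None = None) -> MarkerMap:
    """Read a PLINK .map text file (chrom, marker, cM, bp)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] < 4:
        raise GenotypeError(f"{path}: expected 4 columns (chrom, marker, cM, bp)")
    table = pd.DataFrame(
        {
            "marker": df.iloc[:, 1].astype(str),
            "chrom": df.iloc[:, 0].astype(str),
            "bp": df.iloc[:, 3].astype(np.int64),
            "cm": df.iloc[:, 2].astype(float),
        }
    )
    kw = {} if genome_length_kb is None else {"genome_length_kb": genome_length_kb}
    return MarkerMap(table, **kw)


def read_genotypes(
    ped_path: str | Path,
    map_path: str | Path,
    genome_length_kb: float | None = None,
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read PLINK PED/MAP text files into dosages of the first-listed allele.

    The PED dialect is the standard 6 leading columns (family, id, father,
    mother, sex, phenotype) followed by two allele columns per marker; ``0``
    codes a missing allele. At most two distinct allele symbols per marker are
    allowed. Dosage counts the reference allele, taken as the lexicographically
    first of the observed symbols at each marker — a deterministic convention
    under which write -> read round-trips reproduce dosages exactly. All
    downstream estimators are invariant to the choice of reference.
    """
    mmap = read_map(map_path, genome_length_kb)
    n_mk = len(mmap)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    alleles: list[list[str]] = [[] for _ in range(n_mk)]
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_mk:
                raise GenotypeError(
                    f"{ped_path}:{line_no}: expected {6 + 2 * n_mk} fields "
                    f"(6 + 2 x {n_mk} markers), got {len(parts)}"
                )
            ids.append(parts[1])
            calls = parts[6:]
            row = np.empty(n_mk, dtype=np.int8)
            for j in range(n_mk):
                a, b = calls[2 * j], calls[2 * j + 1]
                if a == "0" or b == "0":
                    row[j] = MISSING
                    continue
                seen = alleles[j]
                for al in (a, b):
                    if al not in seen:
                        if len(seen) >= 2:
                            raise GenotypeError(
                                f"{ped_path}: marker {mmap.table['marker'][j]!r} "
                                f"has >2 alleles ({seen + [al]})"
                            )
                        seen.append(al)
                row[j] = (a == seen[0]) + (b == seen[0])
            rows.append(row)
    dosages = np.vstack(rows) if rows else np.empty((0, n_mk), dtype=np.int8)
    # normalise: reference allele is the lexicographically first observed symbol
    allele_pairs = []
    for j, a in enumerate(alleles):
        if len(a) > 1 and a[1] < a[0]:
            obs = dosages[:, j] != MISSING
            dosages[obs, j] = 2 - dosages[obs, j]
            a = [a[1], a[0]]
        allele_pairs.append((a[0] if a else "A", a[1] if len(a) > 1 else "N"))
    gm = GenotypeMatrix(
        ids=ids,
        markers=list(mmap.table["marker"]),
        dosages=dosages,
        alleles=allele_pairs,
    )
    return gm, mmap


def write_genotypes(
    gm: GenotypeMatrix, mmap: MarkerMap, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write PLINK PED/MAP text files (ref/alt letters A/B when unknown)."""
    t = mmap.table
    with open(map_path, "w") as fh:
        cm = mmap.cm
        for j in range(len(t)):
            fh.write(f"{t['chrom'][j]}\t{t['marker'][j]}\t{cm[j]:g}\t{t['bp'][j]}\n")
    alleles = gm.alleles or [("A", "B")] * gm.n_markers
    code = {2: (0, 0), 1: (0, 1), 0: (1, 1)}
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(gm.ids):
            fields = [iid, iid, "0", "0", "0", "-9"]
            for j in range(gm.n_markers):
                d = int(gm.dosages[i, j])
                if d == MISSING:
                    fields += ["0", "0"]
                else:
                    ia, ib = code[d]
                    ref, alt = alleles[j][0], alleles[j][1]
                    alt = alt if alt != "N" else "B"
                    fields += [(ref, alt)[ia], (ref, alt)[ib]]
            fh.write(" ".join(fields) + "\n")


def read_genotype_tsv(
    path: str | Path, genome_length_kb: float | None = None
) -> tuple[GenotypeMatrix, MarkerMap | None]:
    """Read a genotype TSV: rows = individuals, columns = markers, 0/1/2/NA."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    d = df.to_numpy(dtype=float)
    d = np.where(np.isnan(d), MISSING, d).astype(np.int8)
    gm = GenotypeMatrix(
        ids=[str(i) for i in df.index], markers=[str(c) for c in df.columns], dosages=d
    )
    return gm, None


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        gm.dosages.astype(float), index=gm.ids, columns=gm.markers
    ).replace(float(MISSING), np.nan)
    df.to_csv(path, sep="\t", index_label="id", float_format="%g")


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed count (the standard exact-test rule; no mid-p correction).
    Monomorphic samples return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise GenotypeError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise GenotypeError("total genotype count must be positive")
    n_a = 2 * n_aa + n_Aa  # minor-allele count (relabel below)
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0
    # support: heterozygote counts with the parity of the rare allele count
    het_obs = n_Aa
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het | allele counts) up to a constant:
    #   P(h) prop 2^h / (h! * ((rare-h)/2)! * ((n2-h)/2)!)  with n2 = 2n - rare
    common = 2 * n - rare
    from scipy.special import gammaln

    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln((rare - hets) / 2 + 1)
        - gammaln((common - hets) / 2 + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == het_obs][0]
    # tolerance guards float ties in the <= observed-probability rule
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ----------------------------------------------------------------------
# QC
# ----------------------------------------------------------------------


@dataclass
class QCReport:
    n_individuals_in: int
    n_markers_in: int
    n_individuals_removed_call_rate: int
    n_markers_removed_call_rate: int
    n_markers_removed_maf: int
    n_markers_removed_hwe: int
    n_individuals_out: int
    n_markers_out: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, v) for k, v in self.__dict__.items()], columns=["criterion", "count"]
        )


def qc_filter(
    gm: GenotypeMatrix,
    mmap: MarkerMap | None = None,
    ind_call_rate: float = 0.95,
    locus_call_rate: float = 0.99,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-5,
) -> tuple[GenotypeMatrix, MarkerMap | None, QCReport]:
    """Chip-style QC: drop low-call-rate individuals, then loci failing MAF,
    call-rate or exact-HWE thresholds (evaluated on retained individuals).

    A marker is removed if it fails *any* locus criterion; the report counts
    each criterion independently (a marker can fail several).
    """
    n0, m0 = gm.n_individuals, gm.n_markers
    keep_ind = np.flatnonzero(gm.call_rate_individuals() > ind_call_rate)
    gm2 = gm.subset(individuals=keep_ind)

    p = gm2.allele_freq()
    maf = np.minimum(p, 1 - p)
    cr = gm2.call_rate_markers()
    counts = gm2.genotype_counts()
    hwe_p = np.array(
        [
            hwe_exact_test(int(c[0]), int(c[1]), int(c[2])) if c.sum() > 0 else 1.0
            for c in counts
        ]
    )
    fail_maf = ~(maf >= maf_min)  # NaN freq (no calls) fails too
    fail_cr = cr < locus_call_rate
    fail_hwe = hwe_p < hwe_p_min
    keep_mk = np.flatnonzero(~(fail_maf | fail_cr | fail_hwe))

    report = QCReport(
        n_individuals_in=n0,
        n_markers_in=m0,
        n_individuals_removed_call_rate=n0 - len(keep_ind),
        n_markers_removed_call_rate=int(fail_cr.sum()),
        n_markers_removed_maf=int(fail_maf.sum()),
        n_markers_removed_hwe=int(fail_hwe.sum()),
        n_individuals_out=len(keep_ind),
        n_markers_out=len(keep_mk),
    )
    if len(keep_mk) == 0:
        raise GenotypeError(f"all markers removed by QC: {report.__dict__}")
    gm_out = gm2.subset(markers=keep_mk)
    mmap_out = mmap.subset(keep_mk) if mmap is not None else None
    return gm_out, mmap_out, report


# ----------------------------------------------------------------------
# VIF-based LD pruning
# ----------------------------------------------------------------------


def ld_prune_vif(
    gm: GenotypeMatrix,
    mmap: MarkerMap | None = None,
    vif_max: float = 10.0,
    window_snps: int = 50,
    step_snps: int = 5,
    maf_min: float = 0.05,
) -> np.ndarray:
    """Sliding-window VIF pruning; returns retained marker indices (into gm).

    Markers with MAF below ``maf_min`` are dropped first. Within each window
    the marker with the highest VIF (1/(1-R^2) of its regression on the other
    retained window markers) is removed iteratively until all VIFs are at most
    ``vif_max``; ties drop the later marker. Windows slide by ``step_snps``
    within each chromosome, so the result is deterministic given marker order.
    """
    p = gm.allele_freq()
    maf = np.minimum(p, 1 - p)
    candidates = np.flatnonzero(maf >= maf_min)
    if len(candidates) == 0:
        return candidates
    # centred dosage matrix with missing values imputed to the marker mean
    d = gm.dosages[:, candidates].astype(float)
    obs = d != MISSING
    col_mean = np.where(obs, d, 0).sum(0) / np.maximum(obs.sum(0), 1)
    z = np.where(obs, d, col_mean) - col_mean

    chroms = (
        mmap.chrom[candidates]
        if mmap is not None
        else np.zeros(len(candidates), dtype=int)
    )
    keep = np.ones(len(candidates), dtype=bool)
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(cidx):
            win = cidx[start : start + window_snps]
            _prune_window(z, win, keep, vif_max)
            if start + window_snps >= len(cidx):
                break
            start += step_snps
    return candidates[keep]


def _prune_window(z: np.ndarray, win: np.ndarray, keep: np.ndarray, vif_max: float) -> None:
    """Iteratively drop the highest-VIF marker in one window (in place)."""
    while True:
        active = win[keep[win]]
        if len(active) < 2:
            return
        corr = np.corrcoef(z[:, active], rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        vifs = _vif_from_corr(corr)
        worst = np.nanmax(vifs)
        if not (worst > vif_max):
            return
        # drop the later marker among ties
        drop_local = np.flatnonzero(vifs >= worst * (1 - 1e-9))[-1]
        keep[active[drop_local]] = False


def _vif_from_corr(corr: np.ndarray) -> np.ndarray:
    """VIF_j = [corr^{-1}]_jj; pseudo-inverse guards singular windows."""
    k = corr.shape[0]
    try:
        inv = np.linalg.inv(corr)
        diag = np.diag(inv)
        if np.any(diag < 0):  # numerically indefinite: fall back
            raise np.linalg.LinAlgError
        return diag
    except np.linalg.LinAlgError:
        # singular window (e.g. duplicated column): VIF is infinite for the
        # involved markers; identify them via rank-revealing least squares
        vifs = np.empty(k)
        for j in range(k):
            others = np.delete(np.arange(k), j)
            r = corr[j, others]
            sub = corr[np.ix_(others, others)]
            coef, *_ = np.linalg.lstsq(sub, r, rcond=None)
            r2 = float(np.clip(r @ coef, 0.0, 1.0))
            vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return vifs
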