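"""Estimator comparison, cryptic-inbreeding quantification and pipeline runner.

Builds the per-individual inbreeding table (F_ped, F_hom, F_GRM, F_ROH and
ancestry tier), computes Pearson correlation matrices between estimators per
ancestry tier, quantifies "cryptic" inbreeding (individuals with pedigree F of
zero but genomic F above a threshold), runs marker-subsampling curves, and
orchestrates the whole synthetic pipeline (simulate -> QC -> estimators ->
models -> comparison) into a TSV/markdown report bundle.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import estimators as est
from . import models as mod
from .genotypes import GenotypeMatrix, MarkerMap, ld_prune_vif, qc_filter, write_genotype_tsv
from .pedigree import AncestryTier, Pedigree, classify_ancestry, f_ped, write_pedigree
from .simulate import SimulationConfig, gene_drop, simulate_fitness, simulate_pedigree, simulate_traits

logger = logging.getLogger("autozyg")

ESTIMATOR_COLS = ["F_ped", "F_hom", "F_GRM", "F_ROH"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def build_inbreeding_table(
    ped: Pedigree,
    gm_full: GenotypeMatrix,
    gm_pruned: GenotypeMatrix,
    mmap_pruned: MarkerMap,
    roh_params: est.ROHParams | None = None,
) -> pd.DataFrame:
    """Per-individual table of all four inbreeding estimators plus tier.

    F_hom and F_GRM are computed on the full QC'd panel; F_ROH on the
    LD-pruned panel, as is conventional for ROH calling.
    """
    fp = pd.Series(f_ped(ped), name="F_ped")
    fh = est.f_hom(gm_full)
    fg = est.f_grm(gm_full)
    segments = est.detect_roh(gm_pruned, mmap_pruned, roh_params)
    fr = est.f_roh(segments, mmap_pruned, individuals=gm_pruned.ids)
    tiers = pd.Series(classify_ancestry(ped), name="tier")
    df = pd.concat([fp, fh, fg, fr, tiers], axis=1)
    df = df.loc[[i for i in ped.ids if i in set(gm_full.ids)]]
    df.index.name = "id"
    df["F_ROH"] = df["F_ROH"].fillna(0.0)
    return df


def estimator_correlations(
    table: pd.DataFrame,
    tier_min: AncestryTier = AncestryTier.BOTH_PARENTS_PLUS_MATERNAL_GP,
    columns: Sequence[str] = ESTIMATOR_COLS,
) -> pd.DataFrame:
    """Pearson correlation matrix between inbreeding estimators.

    Restricted to individuals whose ancestry tier is at least ``tier_min``;
    pairwise-complete observations. Constant columns give NaN entries.
    """
    sub = table[table["tier"] >= tier_min]
    if len(sub) < 3:
        raise ValueError(f"fewer than 3 individuals at tier >= {tier_min.name}")
    return sub[list(columns)].corr(method="pearson", min_periods=3)


def cryptic_inbreeding_fraction(
    table: pd.DataFrame,
    genomic_col: str = "F_GRM",
    genomic_threshold: float = 0.1,
    tier_min: AncestryTier = AncestryTier.ONE_PARENT,
) -> float:
    """Fraction of pedigree-noninbred individuals that are genomically inbred.

    Among individuals at tier >= ``tier_min`` with F_ped == 0, the fraction
    with ``genomic_col`` above ``genomic_threshold``.
    """
    sub = table[(table["tier"] >= tier_min) & (table["F_ped"] == 0)]
    sub = sub.dropna(subset=[genomic_col])
    if len(sub) == 0:
        raise ValueError("no pedigree-noninbred individuals in the tier")
    return float((sub[genomic_col] > genomic_threshold).mean())


def marker_subsampling_curve(
    gm: GenotypeMatrix,
    fractions: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 1.0),
    n_reps: int = 10,
    seed: int = 0,
    trait: pd.Series | None = None,
) -> pd.DataFrame:
    """Correlation of subsampled-panel estimators with full-panel estimates.

    For each marker fraction and replicate, recompute F_hom and F_GRM on a
    random marker subset and correlate across individuals with the full-panel
    values (and optionally with a trait). Returns mean and SD per fraction.
    """
    if not all(0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    p_full = gm.allele_freq()
    poly = (p_full > 0) & (p_full < 1)
    full_hom = est.f_hom(gm).to_numpy()
    full_grm = est.f_grm(gm.subset(markers=np.flatnonzero(poly))).to_numpy()
    trait_v = None if trait is None else trait.reindex(gm.ids).to_numpy()
    rows = []
    L = gm.n_markers
    for frac in fractions:
        k = max(2, int(round(frac * L)))
        for rep in range(n_reps):
            idx = np.sort(rng.choice(L, size=min(k, L), replace=False))
            sub = gm.subset(markers=idx)
            r_hom = est._pearson(est.f_hom(sub).to_numpy(), full_hom)
            gidx = idx[poly[idx]]
            r_grm = est._pearson(
                est.f_grm(gm.subset(markers=gidx), p=p_full[gidx]).to_numpy(),
                full_grm,
            )
            row = {"fraction": frac, "rep": rep, "r_F_hom": r_hom, "r_F_GRM": r_grm}
            if trait_v is not None:
                row["r_trait_F_GRM"] = est._pearson(
                    est.f_grm(gm.subset(markers=gidx), p=p_full[gidx]).to_numpy(),
                    trait_v,
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    return df.groupby("fraction").agg(["mean", "std"]).drop(columns="rep")


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------


@dataclass
class PipelineResult:
    pedigree: Pedigree
    inbreeding: pd.DataFrame
    truth: pd.Series
    correlations_relaxed: pd.DataFrame
    correlations_strict: pd.DataFrame
    cryptic: dict[str, float]
    g2: est.G2Result
    trait_fits: dict[str, mod.ModelFit]
    qc_report: pd.DataFrame
    out_dir: Path | None


def run_pipeline(
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    fit_traits: Sequence[str] = ("august_weight",),
    g2_n_perm: int = 200,
    g2_n_boot: int = 200,
) -> PipelineResult:
    """End-to-end synthetic run: simulate -> QC -> estimators -> models -> report.

    Every stage failure is re-raised as :class:`PipelineError` naming the
    stage. With ``out_dir`` set, all tables are written as TSV plus a
    markdown summary; outputs are a pure function of (cfg, seed).
    """
    cfg = cfg or SimulationConfig()
    t0 = time.time()

    def stage(name, fn, *args, **kw):
        try:
            t = time.time()
            out = fn(*args, **kw)
            logger.info("stage %s done in %.1fs", name, time.time() - t)
            return out
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(name, str(e)) from e

    ped = stage("simulate_pedigree", simulate_pedigree, cfg, seed)
    gm, mmap, truth = stage("gene_drop", gene_drop, ped, cfg, seed + 1)
    gm_qc, mmap_qc, qc_rep = stage("qc_filter", qc_filter, gm, mmap)
    keep = stage("ld_prune", ld_prune_vif, gm_qc, mmap_qc)
    gm_pruned = gm_qc.subset(markers=keep)
    mmap_pruned = mmap_qc.subset(keep)
    table = stage(
        "inbreeding_table", build_inbreeding_table, ped, gm_qc, gm_pruned, mmap_pruned
    )
    corr_rel = stage(
        "correlations_relaxed", estimator_correlations, table,
        AncestryTier.BOTH_PARENTS_PLUS_MATERNAL_GP,
    )
    corr_strict = stage(
        "correlations_strict", estimator_correlations, table,
        AncestryTier.FOUR_GRANDPARENTS,
    )
    cryptic = {
        col: stage("cryptic_fraction", cryptic_inbreeding_fraction, table, col)
        for col in ("F_GRM", "F_ROH")
    }
    g2 = stage("g2", est.g2_estimate, gm_qc, g2_n_boot, g2_n_perm, seed + 2)
    traits = stage("simulate_traits", simulate_traits, ped, truth, cfg, seed + 3)
    trait_fits = {
        tr: stage("fit_" + tr, mod.fit_trait_model, traits, tr, ped)
        for tr in fit_traits
    }

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        write_pedigree(ped, out_path / "pedigree.tsv")
        write_genotype_tsv(gm_qc, out_path / "genotypes_qc.tsv")
        truth.rename_axis("id").to_csv(out_path / "true_ibd.tsv", sep="\t")
        table.to_csv(out_path / "inbreeding.tsv", sep="\t")
        corr_rel.to_csv(out_path / "correlations_relaxed.tsv", sep="\t")
        corr_strict.to_csv(out_path / "correlations_strict.tsv", sep="\t")
        qc_rep.to_frame().to_csv(out_path / "qc_report.tsv", sep="\t", index=False)
        traits.to_csv(out_path / "traits.tsv", sep="\t", index=False)
        with open(out_path / "summary.md", "w") as fh:
            fh.write(_summary_md(cfg, seed, table, corr_rel, corr_strict,
                                 cryptic, g2, trait_fits, time.time() - t0))

    return PipelineResult(
        pedigree=ped,
        inbreeding=table,
        truth=truth,
        correlations_relaxed=corr_rel,
        correlations_strict=corr_strict,
        cryptic=cryptic,
        g2=g2,
        trait_fits=trait_fits,
        qc_report=qc_rep.to_frame(),
        out_dir=out_path,
    )


def _summary_md(cfg, seed, table, corr_rel, corr_strict, cryptic, g2,
                trait_fits, elapsed) -> str:
    lines = [
        "# autozyg pipeline summary",
        "",
        f"- seed: {seed}; individuals: {len(table)}; elapsed: {elapsed:.1f}s",
        f"- g2 = {g2.g2:.4g} +/- {g2.bootstrap_sd:.2g} SD (perm P = {g2.permutation_p:.3g})",
        f"- cryptic inbreeding (F_ped=0, genomic>0.1): "
        + ", ".join(f"{k}: {v:.3f}" for k, v in cryptic.items()),
        "",
        "## Estimator correlations (relaxed tier)",
        corr_rel.round(3).to_markdown(),
        "",
        "## Estimator correlations (four-grandparent tier)",
        corr_strict.round(3).to_markdown(),
        "",
    ]
    for tr, fit in trait_fits.items():
        b, se = fit.coef("F_ind")
        lines.append(f"## {tr}: beta_ind = {b:.3f} (SE {se:.3f}), "
                     f"converged={fit.converged}")
        try:
            bm, sem = fit.coef("F_mat")
            lines.append(f"   beta_mat = {bm:.3f} (SE {sem:.3f})")
        except ValueError:
            pass
    return "\n".join(lines) + "\n"
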