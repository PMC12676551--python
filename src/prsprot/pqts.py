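"""PRS construction and protein quantitative trait score (pQTS) scans.

A pQTS association is the slope of a simple linear regression of an
adjusted protein level on a polygenic risk score, p_k = a0 + a1*r_c + e,
tested against a1 = 0. The trans-restricted variant rebuilds the score
per analyte from only the SNPs distal (> 2.5 Mb, or another chromosome)
to the analyte's transcription start site, isolating trans-mediated
signal. Strong single-SNP trans-pQTLs (per-SNP p < 1e-6 by default) are
flagged separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import AdjustedProteinPanel, GenotypePanel, PrsModel

CIS_WINDOW = 2_500_000
PQTS_THRESHOLD = 1e-5
STRONG_TRANS_THRESHOLD = 1e-6

_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


@dataclass
class PrsResult:
    """PRS vector plus the allele-harmonization report."""

    score: np.ndarray
    matched_idx: np.ndarray      # panel column index per matched model SNP
    model_idx: np.ndarray        # scoring-file row per matched model SNP
    flipped: np.ndarray          # True where dosage was flipped to 2 - G
    missing: list[str]
    ambiguous: list[str]

    @property
    def n_matched(self) -> int:
        return len(self.matched_idx)

    @property
    def n_flipped(self) -> int:
        return int(self.flipped.sum())


@dataclass
class PqtsRecord:
    analyte_id: str
    mode: str                    # "full" | "trans_restricted"
    alpha1: float
    se: float
    t_stat: float
    p_value: float
    n_snps_used: int
    significant: bool
    strong_trans_pqtl_ids: list[str] = field(default_factory=list)


def build_prs(geno: GenotypePanel, model: PrsModel) -> PrsResult:
    """Score r_ci = sum_j beta_j * G_ji over harmonized model SNPs.

    SNPs are matched on (chrom, pos); when the scoring file's effect allele
    differs from the panel's, the dosage is flipped to 2 - G before
    weighting. Strand-ambiguous pairs (both alleles in {A,T} or {C,G}) are
    flagged in the report but still scored.
    """
    panel_by_locus = {(c, p): j for j, (c, p)
                      in enumerate(zip(geno.chrom, geno.pos))}
    matched, model_rows, flipped, missing, ambiguous = [], [], [], [], []
    for r in range(model.n_snps):
        j = panel_by_locus.get((model.chrom[r], int(model.pos[r])))
        if j is None:
            missing.append(model.snp_id[r])
            continue
        ea_model, ea_panel = model.effect_allele[r], geno.effect_allele[j]
        if ea_model != ea_panel and any(
                {ea_model, ea_panel} <= s for s in _AMBIGUOUS):
            ambiguous.append(model.snp_id[r])
        matched.append(j)
        model_rows.append(r)
        flipped.append(ea_model != ea_panel)
    if not matched:
        raise ValueError("no scoring-file SNP could be matched in the panel")
    if ambiguous:
        warnings.warn(f"strand-ambiguous allele pairs for {ambiguous}",
                      stacklevel=2)
    matched = np.asarray(matched)
    model_rows = np.asarray(model_rows)
    flipped = np.asarray(flipped, dtype=bool)
    dos = geno.dosages[:, matched].copy()
    dos[:, flipped] = 2.0 - dos[:, flipped]
    score = dos @ model.weight[model_rows]
    return PrsResult(score=score, matched_idx=matched, model_idx=model_rows,
                     flipped=flipped, missing=missing, ambiguous=ambiguous)


def is_cis(snp_chrom: str, snp_pos: int, tss_chrom: str, tss_pos: int,
           window: int = CIS_WINDOW) -> bool:
    """Cis iff same chromosome and |pos - tss| <= window (inclusive)."""
    return str(snp_chrom) == str(tss_chrom) and abs(int(snp_pos) - int(tss_pos)) <= window


def cis_matrix(chrom, pos, tss_chrom, tss_pos,
               window: int = CIS_WINDOW) -> np.ndarray:
    """Boolean (n_snps x n_analytes) matrix, True where the pair is cis."""
    chrom = np.asarray([str(c) for c in chrom])
    tss_chrom = np.asarray([str(c) for c in tss_chrom])
    pos = np.asarray(pos, dtype=np.int64)
    tss_pos = np.asarray(tss_pos, dtype=np.int64)
    same = chrom[:, None] == tss_chrom[None, :]
    near = np.abs(pos[:, None] - tss_pos[None, :]) <= window
    return same & near


def _simple_regression(x: np.ndarray, y: np.ndarray):
    """Vectorized per-column simple OLS of y on x with intercept.

    x is (n,) shared or (n, p) per-column; returns slope, se, t, p arrays.
    """
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for the t-test")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sxx = np.einsum("ij,ij->j", xc, xc) if xc.ndim == 2 else float(xc @ xc)
    sxx = np.atleast_1d(np.asarray(sxx, dtype=float))
    if xc.ndim == 1:
        sxy = xc @ yc
        sxx = np.broadcast_to(sxx, sxy.shape).copy()
    else:
        sxy = np.einsum("ij,ij->j", xc, yc)
    ok = sxx > 0
    slope = np.full(y.shape[1], np.nan)
    slope[ok] = sxy[ok] / sxx[ok]
    fitted = (xc * slope) if xc.ndim == 2 else np.outer(xc, slope)
    rss = np.einsum("ij,ij->j", yc - fitted, yc - fitted)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof / sxx)
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return slope, se, t, p


def pqts_scan(adjusted: AdjustedProteinPanel, geno: GenotypePanel,
              model: PrsModel, mode: str = "full",
              threshold: float = PQTS_THRESHOLD,
              cis_window: int = CIS_WINDOW,
              strong_threshold: float | None = None) -> list[PqtsRecord]:
    """Scan all analytes for association of protein level with the PRS.

    mode="full" regresses every analyte on the complete score;
    mode="trans_restricted" rebuilds the score per analyte from only its
    trans SNPs. With ``strong_threshold`` set, each trans-restricted record
    also lists single SNPs whose own regression p-value falls below it.
    """
    if mode not in ("full", "trans_restricted"):
        raise ValueError(f"unknown mode {mode!r}")
    if list(adjusted.sample_id) != list(geno.sample_id):
        raise ValueError("adjusted panel and genotypes are not sample-aligned")
    prs = build_prs(geno, model)
    y = adjusted.values
    n, p = y.shape
    w = model.weight[prs.model_idx]
    dos = geno.dosages[:, prs.matched_idx].copy()
    dos[:, prs.flipped] = 2.0 - dos[:, prs.flipped]

    cis = cis_matrix([geno.chrom[j] for j in prs.matched_idx],
                     geno.pos[prs.matched_idx],
                     adjusted.tss_chrom, adjusted.tss_pos, window=cis_window)

    if mode == "full":
        if np.ptp(prs.score) == 0:
            raise ValueError("PRS is constant across samples")
        x = prs.score
        n_used = np.full(p, prs.n_matched)
    else:
        # restricted score = full score minus each analyte's cis contribution
        contrib = dos @ (w[:, None] * cis)        # (n, p) cis part per analyte
        x = prs.score[:, None] - contrib
        n_used = (~cis).sum(axis=0)

    slope, se, t, pval = _simple_regression(x, y)

    strong: list[list[str]] = [[] for _ in range(p)]
    if strong_threshold is not None:
        _, _, _, snp_p = _per_snp_pvalues(dos, y)
        hits = (snp_p < strong_threshold) & ~cis
        for jj, kk in zip(*np.nonzero(hits)):
            strong[kk].append(geno.snp_id[prs.matched_idx[jj]])

    records = []
    for k in range(p):
        pv = float(pval[k])
        records.append(PqtsRecord(
            analyte_id=adjusted.analyte_id[k], mode=mode,
            alpha1=float(slope[k]), se=float(se[k]), t_stat=float(t[k]),
            p_value=pv, n_snps_used=int(n_used[k]),
            significant=bool(np.isfinite(pv) and pv < threshold),
            strong_trans_pqtl_ids=strong[k]))
    return records


def _per_snp_pvalues(dos: np.ndarray, y: np.ndarray):
    """All SNP x analyte simple-regression stats via the correlation route."""
    n = y.shape[0]
    xc = dos - dos.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt(np.einsum("ij,ij->j", xc, xc))
    sy = np.sqrt(np.einsum("ij,ij->j", yc, yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / np.outer(sx, sy)
    r = np.clip(r, -1.0, 1.0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / (1.0 - r**2))
    pv = 2.0 * stats.t.sf(np.abs(t), dof)
    pv[~np.isfinite(t)] = np.where(np.isclose(np.abs(r), 1.0), 0.0, np.nan)[~np.isfinite(t)]
    monomorphic = sx == 0
    pv[monomorphic, :] = np.nan
    return r, sx, t, pv


def strong_trans_pqtl_scan(adjusted: AdjustedProteinPanel,
                           geno: GenotypePanel, model: PrsModel,
                           analyte_id: str,
                           threshold: float = STRONG_TRANS_THRESHOLD,
                           cis_window: int = CIS_WINDOW) -> list[str]:
    """Model SNPs trans to the analyte with single-SNP p below threshold."""
    try:
        k = adjusted.analyte_id.index(analyte_id)
    except ValueError:
        raise KeyError(f"analyte {analyte_id!r} not in panel") from None
    prs = build_prs(geno, model)
    dos = geno.dosages[:, prs.matched_idx].copy()
    dos[:, prs.flipped] = 2.0 - dos[:, prs.flipped]
    cis = cis_matrix([geno.chrom[j] for j in prs.matched_idx],
                     geno.pos[prs.matched_idx],
                     [adjusted.tss_chrom[k]], [adjusted.tss_pos[k]],
                     window=cis_window)[:, 0]
    if cis.all():
        raise ValueError(f"analyte {analyte_id!r} has no trans model SNP")
    y = adjusted.values[:, [k]]
    _, sx, _, pv = _per_snp_pvalues(dos, y)
    if np.any(sx == 0):
        mono = [geno.snp_id[prs.matched_idx[j]]
                for j in np.nonzero(sx == 0)[0]]
        warnings.warn(f"monomorphic SNPs skipped: {mono}", stacklevel=2)
    hits = np.nonzero(~cis & (pv[:, 0] < threshold))[0]
    return [geno.snp_id[prs.matched_idx[j]] for j in hits]


def records_to_frame(records: list[PqtsRecord]):
    import pandas as pd

    return pd.DataFrame([{
        "analyte_id": r.analyte_id, "mode": r.mode, "alpha1": r.alpha1,
        "se": r.se, "t_stat": r.t_stat, "p_value": r.p_value,
        "n_snps_used": r.n_snps_used, "significant": r.significant,
        "strong_trans_pqtl_ids": ",".join(r.strong_trans_pqtl_ids),
    } for r in records])
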