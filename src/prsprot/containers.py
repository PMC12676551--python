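"""Core in-memory containers shared across the pipeline stages.

All panels are sample-major: rows are study participants, columns are
variants or analytes. Genomic coordinates are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _as_str_list(x) -> list[str]:
    return [str(v) for v in x]


@dataclass
class GenotypePanel:
    """Sample x SNP dosage matrix with a genomic SNP map.

    Dosages count copies of the recorded effect allele and lie in [0, 2]
    (hard calls or imputed expected dosages).
    """

    dosages: np.ndarray
    snp_id: list[str]
    chrom: list[str]
    pos: np.ndarray
    effect_allele: list[str]
    sample_id: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.snp_id = _as_str_list(self.snp_id)
        self.chrom = _as_str_list(self.chrom)
        self.effect_allele = _as_str_list(self.effect_allele)
        self.sample_id = _as_str_list(self.sample_id)
        n, s = self.dosages.shape
        if not (len(self.snp_id) == len(self.chrom) == len(self.pos)
                == len(self.effect_allele) == s):
            raise ValueError("SNP map length does not match dosage columns")
        if len(self.sample_id) != n:
            raise ValueError("sample_id length does not match dosage rows")
        if len(set(self.snp_id)) != s:
            raise ValueError("snp_id entries must be unique")
        if np.any(self.pos < 1):
            raise ValueError("positions must be >= 1 (1-based coordinates)")
        if self.dosages.size and (self.dosages.min() < -1e-9
                                  or self.dosages.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages; monomorphic columns become zeros."""
        mu = self.dosages.mean(axis=0)
        sd = self.dosages.std(axis=0)
        out = self.dosages - mu
        np.divide(out, sd, out=out, where=sd > 0)
        out[:, sd == 0] = 0.0
        return out


@dataclass
class ProteinPanel:
    """Raw sample x analyte abundance matrix with a TSS map.

    Abundances are positive relative concentrations (pre-log) as reported
    by aptamer-based assays; each analyte is anchored to the transcription
    start site of its encoding gene.
    """

    abundances: np.ndarray
    analyte_id: list[str]
    gene_symbol: list[str]
    tss_chrom: list[str]
    tss_pos: np.ndarray
    sample_id: list[str]

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        self.tss_pos = np.asarray(self.tss_pos, dtype=np.int64)
        self.analyte_id = _as_str_list(self.analyte_id)
        self.gene_symbol = _as_str_list(self.gene_symbol)
        self.tss_chrom = _as_str_list(self.tss_chrom)
        self.sample_id = _as_str_list(self.sample_id)
        n, p = self.abundances.shape
        if not (len(self.analyte_id) == len(self.gene_symbol)
                == len(self.tss_chrom) == len(self.tss_pos) == p):
            raise ValueError("analyte map length does not match columns")
        if len(self.sample_id) != n:
            raise ValueError("sample_id length does not match rows")
        if len(set(self.analyte_id)) != p:
            raise ValueError("analyte_id entries must be unique")
        if np.any(~np.isfinite(self.abundances)):
            raise ValueError("abundance matrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.abundances.shape[1]


@dataclass
class AdjustedProteinPanel:
    """Covariate-adjusted, rank-inverse-normalized protein residuals."""

    values: np.ndarray
    analyte_id: list[str]
    gene_symbol: list[str]
    tss_chrom: list[str]
    tss_pos: np.ndarray
    sample_id: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.tss_pos = np.asarray(self.tss_pos, dtype=np.int64)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    @classmethod
    def like(cls, panel: ProteinPanel, values: np.ndarray) -> "AdjustedProteinPanel":
        return cls(values=values, analyte_id=list(panel.analyte_id),
                   gene_symbol=list(panel.gene_symbol),
                   tss_chrom=list(panel.tss_chrom),
                   tss_pos=panel.tss_pos.copy(),
                   sample_id=list(panel.sample_id))


@dataclass
class PrsModel:
    """Scoring-file content: per-SNP effect allele and external GWAS weight."""

    snp_id: list[str]
    chrom: list[str]
    pos: np.ndarray
    effect_allele: list[str]
    weight: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=float)
        self.snp_id = _as_str_list(self.snp_id)
        self.chrom = _as_str_list(self.chrom)
        self.effect_allele = _as_str_list(self.effect_allele)
        s = len(self.snp_id)
        if not (len(self.chrom) == len(self.pos) == len(self.effect_allele)
                == len(self.weight) == s):
            raise ValueError("scoring-file columns have unequal lengths")
        if len(set(self.snp_id)) != s:
            raise ValueError("snp_id entries must be unique")
        if np.any(~np.isfinite(self.weight)):
            raise ValueError("weights must be finite")

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rsID": self.snp_id, "chr_name": self.chrom,
            "chr_position": self.pos, "effect_allele": self.effect_allele,
            "effect_weight": self.weight,
        })


@dataclass
class SimTruth:
    """Bookkeeping of every nonzero simulated genetic effect.

    ``effects`` rows are (snp_index, protein_index, per-SD effect, kind)
    with kind "cis" or "trans"; ``confounder_loadings`` is the p x q
    loading matrix applied to the shared hidden factors.
    """

    effects: list[tuple[int, int, float, str]] = field(default_factory=list)
    confounder_loadings: np.ndarray | None = None

    def trans_pairs(self) -> set[tuple[int, int]]:
        return {(j, k) for j, k, _, kind in self.effects if kind == "trans"}

    def causal_snps(self, protein: int) -> list[int]:
        return [j for j, k, _, _ in self.effects if k == protein]
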