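"""Synthetic proteogenomic data generator.

Emulates the statistical structure the downstream analyses assume:
LD-blocked diallelic genotypes (Gaussian-copula haplotypes with AR(1)
within-block correlation), a weighted polygenic score, and protein levels
generated on the log scale as cis effects + sparse trans-network effects +
shared hidden confounders + Gaussian noise.

The synthetic genome uses two chromosomes. SNP blocks are laid out from
10 kb with 10 kb spacing; protein transcription start sites are placed
from 200 Mb, so by construction every SNP is distal (trans, > 2.5 Mb)
to every protein unless a cis effect explicitly relocates the SNP next
to its target's TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from .containers import GenotypePanel, PrsModel, ProteinPanel, SimTruth

_N_CHROMS = 2
_SNP_SPACING = 10_000
_BLOCK_GAP = 100_000
_TSS_BASE = 200_000_000
_TSS_SPACING = 1_000_000


@dataclass
class SimConfig:
    """Generator settings.

    network_spec entries are (snp_indices, protein_indices, effect): every
    listed SNP affects every listed protein with the given slope per SD of
    dosage. cis_spec entries are single (snp_index, protein_index, effect)
    pairs; the SNP is relocated into the cis window of that protein.
    """

    n_samples: int = 2000
    n_snps: int = 60
    n_proteins: int = 100
    ld_block_size: int = 5
    ld_rho: float = 0.5
    maf_range: tuple[float, float] = (0.1, 0.5)
    network_spec: list[tuple[list[int], list[int], float]] = field(default_factory=list)
    cis_spec: list[tuple[int, int, float]] = field(default_factory=list)
    n_confounders: int = 2
    confounder_sd: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_snps, self.n_proteins,
               self.ld_block_size) <= 0:
            raise ValueError("dimensions must be positive")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_confounders < 0 or self.confounder_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("confounder/noise settings invalid")
        for snps, prots, _ in self.network_spec:
            if any(not 0 <= j < self.n_snps for j in snps):
                raise ValueError("network_spec SNP index out of range")
            if any(not 0 <= k < self.n_proteins for k in prots):
                raise ValueError("network_spec protein index out of range")
        for j, k, _ in self.cis_spec:
            if not (0 <= j < self.n_snps and 0 <= k < self.n_proteins):
                raise ValueError("cis_spec index out of range")


def protein_tss_map(config: SimConfig) -> tuple[list[str], np.ndarray]:
    """Deterministic TSS layout: proteins alternate between chromosomes."""
    chroms = [str(k % _N_CHROMS + 1) for k in range(config.n_proteins)]
    pos = np.array([_TSS_BASE + (k // _N_CHROMS) * _TSS_SPACING
                    for k in range(config.n_proteins)], dtype=np.int64)
    return chroms, pos


def _snp_layout(config: SimConfig) -> tuple[list[str], np.ndarray]:
    """Blocks assigned round-robin to chromosomes, 10 kb SNP spacing."""
    blocks = [list(range(b, min(b + config.ld_block_size, config.n_snps)))
              for b in range(0, config.n_snps, config.ld_block_size)]
    chrom = [""] * config.n_snps
    pos = np.zeros(config.n_snps, dtype=np.int64)
    next_start = {str(c + 1): _SNP_SPACING for c in range(_N_CHROMS)}
    for b, members in enumerate(blocks):
        c = str(b % _N_CHROMS + 1)
        start = next_start[c]
        for t, j in enumerate(members):
            chrom[j] = c
            pos[j] = start + t * _SNP_SPACING
        next_start[c] = start + len(members) * _SNP_SPACING + _BLOCK_GAP
    # cis effects anchor their SNP inside the target protein's window
    tss_chrom, tss_pos = protein_tss_map(config)
    for j, k, _ in config.cis_spec:
        chrom[j] = tss_chrom[k]
        pos[j] = tss_pos[k] + _SNP_SPACING
    return chrom, pos


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Draw dosages as the sum of two Gaussian-copula haplotypes.

    Within each LD block the latent Gaussians follow an AR(1) process with
    coefficient ``ld_rho``; thresholding at the normal quantile of each
    SNP's minor-allele frequency yields Bernoulli haplotype alleles whose
    pairwise LD increases monotonically with ``ld_rho``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n, s = config.n_samples, config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=s)
    thresh = ndtri(mafs)
    rho = config.ld_rho
    dosage = np.zeros((n, s), dtype=float)
    for _hap in range(2):
        z = np.empty((n, s))
        eps = rng.standard_normal((n, s))
        for start in range(0, s, config.ld_block_size):
            stop = min(start + config.ld_block_size, s)
            z[:, start] = eps[:, start]
            for j in range(start + 1, stop):
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * eps[:, j]
        dosage += (z < thresh)
    chrom, pos = _snp_layout(config)
    snp_id = [f"snp{j + 1:04d}" for j in range(s)]
    alleles = ["A", "C", "G", "T"]
    effect_allele = [alleles[int(a)] for a in rng.integers(0, 4, size=s)]
    sample_id = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypePanel(dosages=dosage, snp_id=snp_id, chrom=chrom, pos=pos,
                         effect_allele=effect_allele, sample_id=sample_id)


def simulate_proteins(
    config: SimConfig, geno: GenotypePanel
) -> tuple[ProteinPanel, SimTruth, np.ndarray]:
    """Generate abundances from the cis/trans/confounder decomposition.

    On the log scale each protein is the sum of its configured genetic
    effects on standardized dosage, loadings on shared N(0,1) hidden
    factors, and N(0, noise_sd) residual noise; abundances are the
    exponential (log-normal measurement scale). Returns the panel, the
    truth object listing every nonzero effect, and the n x q confounder
    score matrix.
    """
    if geno.n_snps != config.n_snps or geno.n_samples != config.n_samples:
        raise ValueError("genotype panel does not match config dimensions")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n, p, q = config.n_samples, config.n_proteins, config.n_confounders
    x = geno.standardized()
    y = np.zeros((n, p))
    truth = SimTruth()
    for snps, prots, eff in config.network_spec:
        for j in snps:
            for k in prots:
                y[:, k] += eff * x[:, j]
                truth.effects.append((j, k, eff, "trans"))
    for j, k, eff in config.cis_spec:
        y[:, k] += eff * x[:, j]
        truth.effects.append((j, k, eff, "cis"))
    confounders = rng.standard_normal((n, q))
    # geometrically decaying factor scales, mimicking the decreasing
    # variance shares of latent factors in omics data (and making the
    # factors identifiable by leading principal components)
    scales = config.confounder_sd * 0.7 ** np.arange(q)
    loadings = rng.standard_normal((p, q)) * scales
    if q:
        y += confounders @ loadings.T
    truth.confounder_loadings = loadings
    y += rng.normal(0.0, config.noise_sd, size=(n, p))
    tss_chrom, tss_pos = protein_tss_map(config)
    panel = ProteinPanel(
        abundances=np.exp(y),
        analyte_id=[f"prot{k + 1:04d}" for k in range(p)],
        gene_symbol=[f"GENE{k + 1:04d}" for k in range(p)],
        tss_chrom=tss_chrom, tss_pos=tss_pos,
        sample_id=list(geno.sample_id),
    )
    return panel, truth, confounders


def simulate_prs_model(config: SimConfig, geno: GenotypePanel,
                       weight_sd: float = 0.1) -> PrsModel:
    """Random scoring file over all panel SNPs, weights ~ N(0, weight_sd^2)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    return prs_model_from_weights(geno, rng.normal(0.0, weight_sd, geno.n_snps))


def prs_model_from_weights(geno: GenotypePanel, weights,
                           snp_subset=None) -> PrsModel:
    """Scoring file with explicit weights, optionally over a SNP subset."""
    idx = list(range(geno.n_snps)) if snp_subset is None else list(snp_subset)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(idx):
        raise ValueError("weights length does not match SNP subset")
    return PrsModel(snp_id=[geno.snp_id[j] for j in idx],
                    chrom=[geno.chrom[j] for j in idx],
                    pos=geno.pos[idx],
                    effect_allele=[geno.effect_allele[j] for j in idx],
                    weight=weights)


def simulate_covariates(config: SimConfig, sample_id,
                        confounders: np.ndarray | None = None):
    """Covariate table: sex, age, and (optionally) the true hidden factors.

    Supplying the hidden-factor columns lets the adjustment stage be tested
    against a known ground truth; real analyses would use estimated factors.
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n = len(sample_id)
    df = pd.DataFrame({
        "sample_id": list(sample_id),
        "sex": rng.integers(0, 2, size=n),
        "age": rng.normal(55.0, 6.0, size=n).round(1),
    })
    if confounders is not None:
        for f in range(confounders.shape[1]):
            df[f"hidden{f + 1}"] = confounders[:, f]
    return df


def simulate_driver_genes(gene_symbols, fraction: float = 0.3,
                          seed: int = 0) -> list[str]:
    """Flag a random subset of measured genes as cancer drivers."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    k = max(1, int(round(fraction * len(gene_symbols))))
    idx = rng.choice(len(gene_symbols), size=k, replace=False)
    return sorted(gene_symbols[i] for i in idx)


def simulate_ceres(gene_symbols, n_cell_lines: int = 10, seed: int = 0,
                   essential_genes=None, essential_shift: float = -0.8):
    """Genes x cell-lines dependency score matrix.

    Background scores ~ N(-0.1, 0.3^2); genes listed in ``essential_genes``
    are shifted by ``essential_shift`` so they fall below the conventional
    -0.5 essentiality cutoff in expectation.
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    scores = rng.normal(-0.1, 0.3, size=(len(gene_symbols), n_cell_lines))
    if essential_genes:
        pos = {g: i for i, g in enumerate(gene_symbols)}
        for g in essential_genes:
            if g in pos:
                scores[pos[g]] += essential_shift
    cols = [f"CL{c + 1:03d}" for c in range(n_cell_lines)]
    return pd.DataFrame(scores, index=list(gene_symbols), columns=cols)


def write_fixture_set(out_dir, geno: GenotypePanel, prs: PrsModel,
                      proteins: ProteinPanel, covariates=None,
                      driver_genes=None, ceres=None,
                      vcf: bool = False) -> dict[str, str]:
    """Write a complete input set in the pipeline's on-disk formats.

    Returns a mapping of logical names to file paths; every file round-trips
    losslessly through the readers in :mod:`prsprot.io`.
    """
    from pathlib import Path

    from . import io as pio

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc
    paths: dict[str, str] = {}
    if vcf:
        paths["genotypes"] = str(out / "genotypes.vcf")
        pio.write_vcf(paths["genotypes"], geno)
    else:
        paths["genotypes"] = str(out / "genotypes.tsv")
        paths["snp_map"] = str(out / "snp_map.tsv")
        pio.write_genotype_tsv(paths["genotypes"], paths["snp_map"], geno)
    paths["scoring"] = str(out / "scoring.tsv")
    pio.write_scoring_file(paths["scoring"], prs)
    paths["proteins"] = str(out / "proteins.tsv")
    paths["analyte_map"] = str(out / "analyte_map.tsv")
    pio.write_protein_tsv(paths["proteins"], paths["analyte_map"], proteins)
    if covariates is not None:
        paths["covariates"] = str(out / "covariates.tsv")
        pio.write_covariates(paths["covariates"], covariates)
    if driver_genes is not None:
        paths["drivers"] = str(out / "driver_genes.txt")
        pio.write_gene_list(paths["drivers"], driver_genes)
    if ceres is not None:
        paths["ceres"] = str(out / "ceres.tsv")
        pio.write_ceres(paths["ceres"], ceres)
    return paths
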