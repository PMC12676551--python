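"""Bundled demonstration dataset: a two-network trans architecture.

Two disjoint SNP->protein networks (8 SNPs -> 12 proteins and
5 SNPs -> 8 proteins, per-SD effect 0.15) are planted alongside one cis
effect, shared hidden confounders and Gaussian noise. Two synthetic
"cancers" carry PRS scoring files: cancer_A's score spans both networks
plus background SNPs, cancer_B's spans only the first network, so the
cross-cancer pleiotropy stage has genuine overlap to find.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import simgen
from .pipeline import RunConfig

NETWORK1 = (list(range(0, 8)), list(range(0, 12)), 0.15)
NETWORK2 = (list(range(10, 15)), list(range(20, 28)), 0.15)
CIS_EFFECT = (30, 40, 0.5)
CORE_PROTEIN_INDEX = 0          # receives all 8 network-1 effects


def demo_sim_config(seed: int = 0, n_samples: int = 1000) -> simgen.SimConfig:
    return simgen.SimConfig(
        n_samples=n_samples, n_snps=60, n_proteins=100,
        ld_block_size=5, ld_rho=0.5, maf_range=(0.1, 0.5),
        network_spec=[NETWORK1, NETWORK2],
        cis_spec=[CIS_EFFECT],
        n_confounders=2, confounder_sd=1.0, noise_sd=1.0, seed=seed)


def make_demo_inputs(out_dir, seed: int = 0, n_samples: int = 1000):
    """Simulate and write the full demo input set; returns (config, truth).

    The returned RunConfig points at the written files and uses settings
    sized for a quick, fully reproducible run.
    """
    out = Path(out_dir)
    cfg = demo_sim_config(seed=seed, n_samples=n_samples)
    geno = simgen.simulate_genotypes(cfg)
    proteins, truth, confounders = simgen.simulate_proteins(cfg, geno)
    covariates = simgen.simulate_covariates(cfg, geno.sample_id, confounders)

    prs_a = simgen.prs_model_from_weights(
        geno, np.full(25, 0.1),
        snp_subset=NETWORK1[0] + NETWORK2[0] + list(range(40, 52)))
    prs_b = simgen.prs_model_from_weights(
        geno, np.full(13, 0.1), snp_subset=NETWORK1[0] + list(range(45, 50)))

    drivers = simgen.simulate_driver_genes(proteins.gene_symbol,
                                           fraction=0.3, seed=seed)
    network_genes = [proteins.gene_symbol[k]
                     for k in NETWORK1[1] + NETWORK2[1]]
    ceres = simgen.simulate_ceres(proteins.gene_symbol, n_cell_lines=10,
                                  seed=seed,
                                  essential_genes=network_genes[:6])

    paths = simgen.write_fixture_set(out / "inputs", geno, prs_a, proteins,
                                     covariates=covariates,
                                     driver_genes=drivers, ceres=ceres)
    from . import io as pio
    scoring_b = str(out / "inputs" / "scoring_cancer_B.tsv")
    pio.write_scoring_file(scoring_b, prs_b)

    run_config = RunConfig(
        genotypes=paths["genotypes"], snp_map=paths.get("snp_map"),
        proteins=paths["proteins"], analyte_map=paths["analyte_map"],
        covariates=paths["covariates"],
        scoring={"cancer_A": paths["scoring"], "cancer_B": scoring_b},
        drivers=paths["drivers"], ceres=paths["ceres"],
        outdir=str(out / "run"), seed=seed,
        archie_K=3, null_M=99, annotate_B=499)
    return run_config, truth
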