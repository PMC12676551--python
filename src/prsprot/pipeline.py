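"""End-to-end orchestration: inputs -> normalize -> pQTS -> ARCHIE ->
competitive test -> annotation, with persisted intermediates and a run
manifest.

Every constant the analysis depends on (pQTS threshold 1e-5, strong
trans-pQTL threshold 1e-6, cis window 2.5 Mb, CERES cutoff -0.5, sparse
CCA settings, resample count M) lives in :class:`RunConfig`; stage code
never hard-codes them. One master seed deterministically derives every
stage seed, so a rerun with the same config reproduces identical numeric
artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotate as ann
from . import archie, io, normalize, nulltest, pqts
from .containers import PrsModel

__version__ = "0.1.0"


@dataclass
class RunConfig:
    genotypes: str = ""
    snp_map: str | None = None
    proteins: str = ""
    analyte_map: str = ""
    covariates: str | None = None
    scoring: dict[str, str] = field(default_factory=dict)  # cancer -> path
    drivers: str | None = None
    ceres: str | None = None
    outdir: str = "prsprot_run"
    seed: int = 0
    n_hidden_factors: int = 0
    pqts_threshold: float = pqts.PQTS_THRESHOLD
    strong_trans_threshold: float = pqts.STRONG_TRANS_THRESHOLD
    cis_window: int = pqts.CIS_WINDOW
    archie_K: int = 5
    lambda_grid: list | None = None
    eigen_floor: float = archie.EIGEN_FLOOR
    cc_variant: str = "normalized"
    null_M: int = 1000
    null_level: float = 0.05
    pool_variant_filter: list | None = None
    ceres_threshold: float = ann.CERES_ESSENTIAL
    annotate_B: int = 1000

    def validate(self) -> None:
        if not self.scoring:
            raise ValueError("at least one scoring file is required")
        for thr in (self.pqts_threshold, self.strong_trans_threshold,
                    self.null_level):
            if not 0 < thr < 1:
                raise ValueError("probability thresholds must lie in (0, 1)")
        if self.cis_window <= 0 or self.archie_K < 1 or self.null_M < 1:
            raise ValueError("invalid window / K / M setting")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seeds: dict[str, int]
    artifacts: dict[str, str]      # logical name -> sha256 of file
    started: float
    finished: float = 0.0

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seeds(master: int, cancers: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    states = ss.generate_state(2 * len(cancers) + 1)
    seeds = {"master": int(master)}
    for i, c in enumerate(cancers):
        seeds[f"null:{c}"] = int(states[2 * i] % (2**31))
        seeds[f"annotate:{c}"] = int(states[2 * i + 1] % (2**31))
    return seeds


def _dump_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return [float(f"{v:.12g}") for v in np.ravel(o)]
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)


def run_all(config: RunConfig) -> RunManifest:
    """Execute every stage, persisting intermediates under config.outdir."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.time()
    cancers = sorted(config.scoring)
    seeds = _stage_seeds(config.seed, cancers)
    artifacts: dict[str, str] = {}

    def persist(name: str, path: Path) -> None:
        artifacts[name] = _sha256(path)

    stage = "load_inputs"
    try:
        geno = io.read_genotypes(config.genotypes, config.snp_map)
        proteins = io.read_protein_tsv(config.proteins, config.analyte_map)
        covariates = (io.read_covariates(config.covariates)
                      if config.covariates else None)
        models: dict[str, PrsModel] = {
            c: io.read_scoring_file(p) for c, p in config.scoring.items()}

        stage = "normalize"
        adjusted = normalize.adjust_protein_panel(
            proteins, covariates, n_hidden_factors=config.n_hidden_factors)
        adj_path = out / "adjusted_proteins.tsv"
        io.write_adjusted_tsv(adj_path, adjusted)
        persist("adjusted_proteins", adj_path)

        per_cancer_targets: dict[str, set] = {}
        gene_of = dict(zip(adjusted.analyte_id, adjusted.gene_symbol))
        report: dict[str, dict] = {}
        for cancer in cancers:
            model = models[cancer]
            stage = f"pqts:{cancer}"
            recs_full = pqts.pqts_scan(
                adjusted, geno, model, mode="full",
                threshold=config.pqts_threshold, cis_window=config.cis_window)
            recs_trans = pqts.pqts_scan(
                adjusted, geno, model, mode="trans_restricted",
                threshold=config.pqts_threshold, cis_window=config.cis_window,
                strong_threshold=config.strong_trans_threshold)
            for mode, recs in (("full", recs_full), ("trans", recs_trans)):
                path = out / f"pqts_{mode}_{cancer}.tsv"
                pqts.records_to_frame(recs).to_csv(
                    path, sep="\t", index=False, float_format=io.FLOAT_FMT)
                persist(f"pqts_{mode}:{cancer}", path)

            stage = f"archie:{cancer}"
            prs_res = pqts.build_prs(geno, model)
            sub = _subset_panel(geno, prs_res.matched_idx, prs_res.flipped)
            ss = archie.build_summary_stats(sub, adjusted,
                                            cis_window=config.cis_window)
            comps = archie.extract_components(
                ss, K=config.archie_K, lambda_grid=config.lambda_grid,
                floor=config.eigen_floor, cc_variant=config.cc_variant)
            comp_path = out / f"archie_{cancer}.json"
            _dump_json([{
                "rank_index": c.rank_index, "q2": c.q2,
                "lambda1": c.lambda1, "lambda2": c.lambda2,
                "selected_snps": [ss.snp_id[j] for j in c.selected_snps],
                "selected_proteins": [ss.analyte_id[j]
                                      for j in c.selected_proteins],
                "u": c.u, "v": c.v,
            } for c in comps], comp_path)
            persist(f"archie:{cancer}", comp_path)

            stage = f"nulltest:{cancer}"
            pool = nulltest.NullPool.from_panels(
                geno, adjusted, cis_window=config.cis_window,
                variant_filter=config.pool_variant_filter)
            comp_sig: list[int] = []
            null_path = out / f"competitive_{cancer}.json"
            if comps:
                results = nulltest.competitive_test(
                    comps, pool, s=len(ss.snp_id), p=len(ss.analyte_id),
                    M=config.null_M, floor=config.eigen_floor,
                    cc_variant=config.cc_variant,
                    seed=seeds[f"null:{cancer}"])
                _dump_json([{
                    "rank_index": r.rank_index, "observed_q2": r.observed_q2,
                    "p_value": r.p_value, "M": r.M, "seed": r.seed,
                } for r in results], null_path)
                comp_sig = [r.rank_index for r in results
                            if r.p_value < config.null_level]
            else:
                _dump_json([], null_path)
            persist(f"competitive:{cancer}", null_path)

            sig_analytes = {r.analyte_id for r in recs_full if r.significant}
            sig_analytes |= {r.analyte_id for r in recs_trans if r.significant}
            archie_analytes = {ss.analyte_id[j] for c in comps
                               if c.rank_index in comp_sig
                               for j in c.selected_proteins}
            targets = {gene_of[a] for a in sig_analytes | archie_analytes}
            per_cancer_targets[cancer] = targets
            report[cancer] = {
                "n_pqts_significant_full": sum(r.significant for r in recs_full),
                "n_pqts_significant_trans": sum(r.significant for r in recs_trans),
                "n_archie_components": len(comps),
                "significant_components": comp_sig,
                "n_target_proteins": len(targets),
            }

            stage = f"annotate:{cancer}"
            annotation: dict = {}
            if config.drivers and targets:
                drivers = io.read_gene_list(config.drivers)
                enr = ann.driver_enrichment(targets, set(gene_of.values()),
                                            drivers)
                annotation["driver_enrichment"] = {
                    "table": [[int(x) for x in row] for row in enr.table],
                    "odds_ratio": enr.odds_ratio, "p_value": enr.p_value}
            if config.ceres and targets:
                ceres = io.read_ceres(config.ceres)
                present = [g for g in sorted(targets) if g in ceres.index]
                if present:
                    obs, _, pv = ann.ceres_bootstrap(
                        present, ceres, B=config.annotate_B,
                        seed=seeds[f"annotate:{cancer}"])
                    essential = sorted({
                        g for line in ceres.columns
                        for g in ann.essential_genes(
                            present, ceres, line,
                            threshold=config.ceres_threshold)})
                    annotation["ceres"] = {
                        "observed_mean": obs, "p_value": pv,
                        "essential_genes": essential, "B": config.annotate_B}
            ann_path = out / f"annotation_{cancer}.json"
            _dump_json(annotation, ann_path)
            persist(f"annotation:{cancer}", ann_path)
            report[cancer]["annotation"] = annotation

        stage = "pleiotropy"
        if len(cancers) >= 2:
            inc, n_ge2, n_all = ann.pleiotropy_table(per_cancer_targets)
            ple_path = out / "pleiotropy.tsv"
            inc.astype(int).to_csv(ple_path, sep="\t")
            persist("pleiotropy", ple_path)
            report["pleiotropy"] = {"shared_ge2": n_ge2, "shared_all": n_all}

        rep_path = out / "report.json"
        _dump_json(report, rep_path)
        persist("report", rep_path)
    except Exception as exc:
        partial = RunManifest(config_hash=_config_hash(config),
                              version=__version__, seeds=seeds,
                              artifacts=artifacts, started=started,
                              finished=time.time())
        partial.write(out / "manifest.partial.json")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = RunManifest(config_hash=_config_hash(config),
                           version=__version__, seeds=seeds,
                           artifacts=artifacts, started=started,
                           finished=time.time())
    manifest.write(out / "manifest.json")
    return manifest


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _subset_panel(geno, idx, flipped):
    """Panel restricted to the matched scoring SNPs, dosages on the
    scoring file's effect-allele orientation."""
    from .containers import GenotypePanel

    dos = geno.dosages[:, idx].copy()
    dos[:, flipped] = 2.0 - dos[:, flipped]
    return GenotypePanel(
        dosages=dos, snp_id=[geno.snp_id[j] for j in idx],
        chrom=[geno.chrom[j] for j in idx], pos=geno.pos[idx],
        effect_allele=[geno.effect_allele[j] for j in idx],
        sample_id=list(geno.sample_id))
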