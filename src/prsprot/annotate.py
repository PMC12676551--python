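"""Annotation of identified protein sets.

Three complementary characterizations: overrepresentation of target
proteins among curated cancer driver genes (one-sided Fisher exact test),
essentiality of the underlying genes in CRISPR knockout screens (CERES
dependency scores, with a resampling test on the mean score), and
cross-cancer pleiotropy tabulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CERES_ESSENTIAL = -0.5


@dataclass
class EnrichmentResult:
    table: np.ndarray        # [[targets&drivers, targets-only],
                             #  [nontarget drivers, nontarget nondrivers]]
    odds_ratio: float
    p_value: float


def driver_enrichment(targets, universe, drivers) -> EnrichmentResult:
    """One-sided (greater) Fisher exact test for driver overrepresentation.

    The displayed odds ratio is the cross-product ratio, with 0.5 added to
    every cell only when some cell is zero.
    """
    targets, universe, drivers = set(targets), set(universe), set(drivers)
    if not targets:
        raise ValueError("target set is empty")
    if not targets <= universe:
        raise ValueError("targets must be a subset of the universe")
    drivers &= universe
    a = len(targets & drivers)
    b = len(targets - drivers)
    c = len(drivers - targets)
    d = len(universe - targets - drivers)
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="greater")
    t = table + 0.5 if 0 in table else table
    orat = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return EnrichmentResult(table=table, odds_ratio=float(orat),
                            p_value=float(p))


def essential_genes(targets, ceres: pd.DataFrame, cell_line: str,
                    threshold: float = CERES_ESSENTIAL) -> list[str]:
    """Target genes with dependency score <= threshold in the cell line."""
    if cell_line not in ceres.columns:
        raise KeyError(f"cell line {cell_line!r} not in CERES matrix")
    out = []
    for g in targets:
        if g not in ceres.index:
            warnings.warn(f"gene {g!r} absent from CERES matrix", stacklevel=2)
            continue
        score = ceres.at[g, cell_line]
        if np.isfinite(score) and score <= threshold:
            out.append(g)
    return out


def ceres_bootstrap(targets, ceres: pd.DataFrame, B: int = 1000,
                    seed: int = 0, exhaustive: bool = False):
    """Resampling test: is the targets' mean dependency score unusually low?

    The statistic is the mean CERES score of the target genes across all
    cell lines; each null draw takes a same-size uniform random gene set
    (without replacement within a draw). Lower means indicate stronger
    essentiality, so p = (1 + #{null <= observed}) / (n_null + 1). With
    ``exhaustive`` the null enumerates every same-size gene subset instead
    of sampling B of them (exact reference distribution; only feasible for
    small matrices).
    """
    import itertools

    targets = [g for g in targets if g in ceres.index]
    if not targets:
        raise ValueError("no target gene present in the CERES matrix")
    if B < 1:
        raise ValueError("B must be >= 1")
    vals = ceres.to_numpy(float)
    gene_index = {g: i for i, g in enumerate(ceres.index)}
    rows = [gene_index[g] for g in targets]
    observed = float(np.nanmean(vals[rows]))
    if exhaustive:
        null_means = np.array([
            np.nanmean(vals[list(pick)])
            for pick in itertools.combinations(range(len(ceres.index)),
                                               len(rows))])
    else:
        rng = np.random.default_rng(seed)
        null_means = np.empty(B)
        for b in range(B):
            pick = rng.choice(len(ceres.index), size=len(rows), replace=False)
            null_means[b] = np.nanmean(vals[pick])
    p = (1.0 + np.sum(null_means <= observed)) / (len(null_means) + 1.0)
    return observed, null_means, float(p)


def pleiotropy_table(per_cancer_sets: dict[str, set]):
    """Protein x cancer incidence matrix with shared-protein counts.

    Returns (incidence DataFrame, n shared by >= 2 cancers, n shared by
    all cancers). Use ``shared_counts`` for an arbitrary cancer subgroup.
    """
    if len(per_cancer_sets) < 2:
        raise ValueError("need protein sets for at least two cancers")
    cancers = list(per_cancer_sets)
    proteins = sorted(set().union(*per_cancer_sets.values()))
    inc = pd.DataFrame(
        [[p in per_cancer_sets[c] for c in cancers] for p in proteins],
        index=proteins, columns=cancers, dtype=bool)
    n_ge2, n_all = shared_counts(inc)
    return inc, n_ge2, n_all


def shared_counts(incidence: pd.DataFrame, group=None) -> tuple[int, int]:
    """(#proteins in >= 2 cancers of the group, #proteins in all of them)."""
    sub = incidence if group is None else incidence[list(group)]
    hits = sub.to_numpy().sum(axis=1)
    return int((hits >= 2).sum()), int((hits == sub.shape[1]).sum())
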