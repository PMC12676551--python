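"""Protein preprocessing: log transform, covariate adjustment, rank-INT.

The pipeline mirrors standard plasma-proteome QC: log-transform relative
abundances, regress out known covariates together with hidden factors
(principal components standing in for latent confounders), and map each
analyte's residuals onto normal scores via the rank-based inverse normal
transform with the Blom offset 3/8 so downstream tests are robust to
outliers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .containers import AdjustedProteinPanel, ProteinPanel

BLOM_OFFSET = 0.375


def log_transform(panel: ProteinPanel) -> ProteinPanel:
    """Elementwise natural log of abundances; all entries must be positive."""
    bad = np.argwhere(panel.abundances <= 0)
    if bad.size:
        i, k = bad[0]
        raise ValueError(
            f"non-positive abundance for analyte {panel.analyte_id[k]!r}, "
            f"sample {panel.sample_id[i]!r}: {panel.abundances[i, k]}")
    return ProteinPanel(abundances=np.log(panel.abundances),
                        analyte_id=list(panel.analyte_id),
                        gene_symbol=list(panel.gene_symbol),
                        tss_chrom=list(panel.tss_chrom),
                        tss_pos=panel.tss_pos.copy(),
                        sample_id=list(panel.sample_id))


def encode_design(cov: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + numeric covariates + one-hot categoricals (drop first).

    Constant columns are dropped (the intercept already spans them).
    """
    cols: list[np.ndarray] = [np.ones(len(cov))]
    names: list[str] = ["intercept"]
    for name in cov.columns:
        if name == "sample_id":
            continue
        col = cov[name]
        if pd.api.types.is_numeric_dtype(col):
            arr = col.to_numpy(float)
            if np.ptp(arr) == 0:
                continue
            cols.append(arr)
            names.append(name)
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            for dname in dummies.columns:
                arr = dummies[dname].to_numpy(float)
                if np.ptp(arr) == 0:
                    continue
                cols.append(arr)
                names.append(dname)
    return np.column_stack(cols), names


def adjust_covariates(panel: ProteinPanel, cov: pd.DataFrame) -> np.ndarray:
    """Per-analyte least-squares residuals on intercept + encoded covariates."""
    y = panel.abundances
    if list(cov["sample_id"].astype(str)) != list(panel.sample_id):
        raise ValueError("covariate sample_id does not align with panel rows")
    x, names = encode_design(cov)
    n, k = x.shape
    if n <= k + 1:
        raise ValueError(f"need more samples ({n}) than design columns ({k})")
    rank = np.linalg.matrix_rank(x)
    if rank < k:
        _, r = np.linalg.qr(x)
        dependent = [names[j] for j in range(k)
                     if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"rank-deficient design; collinear columns: {dependent}")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ coef


def hidden_factors(panel: ProteinPanel, k: int) -> pd.DataFrame:
    """Top-k principal-component scores of the column-centered matrix.

    A light-weight stand-in for latent-factor models used in proteome QC:
    with strong shared confounding the leading PCs recover the hidden
    factor directions.
    """
    if k <= 0:
        raise ValueError("number of hidden factors must be positive")
    y = panel.abundances
    if k >= min(y.shape):
        raise ValueError("k must be smaller than both matrix dimensions")
    yc = y - y.mean(axis=0)
    u, s, _ = np.linalg.svd(yc, full_matrices=False)
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(scores, columns=[f"factor{i + 1}" for i in range(k)])


def inverse_normal_transform(x) -> np.ndarray:
    """Blom rank-based inverse normal transform.

    Value i maps to Phi^{-1}((rank_i - 3/8) / (n + 1/4)); tied values
    receive the average of the normal scores their ordinal ranks span, so
    the output is invariant to any strictly increasing transform of the
    input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("input must be a 1-D vector of length >= 2")
    if np.any(~np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("all values equal: ranks undefined for association use")
    n = len(x)
    order = np.argsort(x, kind="stable")
    scores = ndtri((np.arange(1, n + 1) - BLOM_OFFSET) / (n + 0.25))
    sorted_x = x[order]
    out_sorted = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        out_sorted[i:j + 1] = scores[i:j + 1].mean()
        i = j + 1
    out = np.empty(n)
    out[order] = out_sorted
    return out


def rank_normalize(matrix: np.ndarray) -> np.ndarray:
    """Column-wise inverse normal transform."""
    return np.column_stack([inverse_normal_transform(matrix[:, k])
                            for k in range(matrix.shape[1])])


def adjust_protein_panel(panel: ProteinPanel, cov: pd.DataFrame | None = None,
                         n_hidden_factors: int = 0,
                         log: bool = True) -> AdjustedProteinPanel:
    """Full QC pipeline: log -> (PC hidden factors) -> adjust -> rank-INT."""
    work = log_transform(panel) if log else panel
    if n_hidden_factors:
        factors = hidden_factors(work, n_hidden_factors)
        if cov is None:
            cov = pd.DataFrame({"sample_id": list(panel.sample_id)})
        cov = pd.concat([cov.reset_index(drop=True), factors], axis=1)
    if cov is not None:
        resid = adjust_covariates(work, cov)
    else:
        resid = work.abundances - work.abundances.mean(axis=0)
    return AdjustedProteinPanel.like(panel, rank_normalize(resid))
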