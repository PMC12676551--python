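"""Summary-statistics sparse CCA for trans-network discovery (ARCHIE).

Works entirely from three summary matrices: the SNP LD matrix Sigma_G,
the protein correlation matrix Sigma_P, and the SNP-protein
cross-correlation Sigma_GP (cis pairs masked to zero). The whitened cross
matrix W = Sigma_G^{-1/2} Sigma_GP Sigma_P^{-1/2} is decomposed into
successive sparse component pairs (u, v) by penalized alternating power
iteration with L1 soft-thresholding and unit-L2-ball normalization
(PMD-style). Each component's strength is its cc-value q^2; lower
components come from rank-one deflation W <- W - |q| u v'. Sparsity is
chosen as the smallest penalty on the grid for which the extracted
components select non-overlapping SNP and protein sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import AdjustedProteinPanel, GenotypePanel
from .pqts import CIS_WINDOW, cis_matrix

EIGEN_FLOOR = 1e-3
SUPPORT_TOL = 1e-9


@dataclass
class SummaryStatSet:
    """LD, protein-correlation and cross-correlation matrices for sCCA."""

    sigma_G: np.ndarray
    sigma_P: np.ndarray
    sigma_GP: np.ndarray
    snp_id: list[str]
    analyte_id: list[str]
    trans_mask: np.ndarray | None = None   # True where the pair is usable

    def __post_init__(self) -> None:
        s, p = self.sigma_GP.shape
        if self.sigma_G.shape != (s, s) or self.sigma_P.shape != (p, p):
            raise ValueError("summary matrices have inconsistent dimensions")


@dataclass
class WhitenedCross:
    W: np.ndarray
    floor_G: float
    floor_P: float


@dataclass
class ArchieComponent:
    u: np.ndarray
    v: np.ndarray
    q2: float
    lambda1: float
    lambda2: float
    rank_index: int
    objective_trace: list[float] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (np.any(np.abs(self.u) > SUPPORT_TOL)
                    and np.any(np.abs(self.v) > SUPPORT_TOL))

    @property
    def selected_snps(self) -> np.ndarray:
        return np.nonzero(np.abs(self.u) > SUPPORT_TOL)[0]

    @property
    def selected_proteins(self) -> np.ndarray:
        return np.nonzero(np.abs(self.v) > SUPPORT_TOL)[0]


def build_summary_stats(geno: GenotypePanel, adjusted: AdjustedProteinPanel,
                        cis_window: int = CIS_WINDOW,
                        mask_cis: bool = True,
                        drop_cis_proteins: bool = False) -> SummaryStatSet:
    """Correlation-scale summary statistics from individual-level panels.

    Sigma_GP entries are correlations between standardized dosage and
    adjusted protein level (the per-pair regression slope on the
    correlation scale). Cis pairs are zeroed and masked; with
    ``drop_cis_proteins`` analytes cis to any panel SNP are removed
    entirely instead.
    """
    x = geno.standardized()
    y = adjusted.values
    yc = y - y.mean(axis=0)
    sy = np.sqrt(np.einsum("ij,ij->j", yc, yc))
    ys = np.divide(yc, sy, out=np.zeros_like(yc), where=sy > 0)
    n = x.shape[0]
    cis = cis_matrix(geno.chrom, geno.pos, adjusted.tss_chrom,
                     adjusted.tss_pos, window=cis_window)
    keep = np.ones(len(adjusted.analyte_id), dtype=bool)
    if drop_cis_proteins:
        keep = ~cis.any(axis=0)
        ys, cis = ys[:, keep], cis[:, keep]
    sigma_G = np.corrcoef(x, rowvar=False)
    sigma_P = ys.T @ ys
    np.fill_diagonal(sigma_P, 1.0)
    sigma_GP = (x.T @ ys) / n
    mask = ~cis
    if mask_cis:
        sigma_GP = np.where(mask, sigma_GP, 0.0)
    return SummaryStatSet(
        sigma_G=sigma_G, sigma_P=sigma_P, sigma_GP=sigma_GP,
        snp_id=list(geno.snp_id),
        analyte_id=[a for a, k in zip(adjusted.analyte_id, keep) if k],
        trans_mask=mask)


def inv_sqrt(mat: np.ndarray, floor: float = EIGEN_FLOOR) -> np.ndarray:
    """Symmetric inverse square root with an eigenvalue floor.

    Eigenvalues below ``floor`` are clipped up to it, regularizing the
    near-singular LD / protein-correlation matrices.
    """
    mat = np.asarray(mat, dtype=float)
    if np.max(np.abs(mat - mat.T)) > 1e-8:
        raise ValueError("matrix is not symmetric within 1e-8")
    w, q = np.linalg.eigh((mat + mat.T) / 2.0)
    w = np.clip(w, floor, None)
    return (q * (1.0 / np.sqrt(w))) @ q.T


def build_whitened(ss: SummaryStatSet,
                   floor: float = EIGEN_FLOOR) -> WhitenedCross:
    w = inv_sqrt(ss.sigma_G, floor) @ ss.sigma_GP @ inv_sqrt(ss.sigma_P, floor)
    return WhitenedCross(W=w, floor_G=floor, floor_P=floor)


def soft_threshold(x: np.ndarray, lam: float) -> np.ndarray:
    """Proximal operator of the L1 penalty: sign(x) * max(|x| - lam, 0)."""
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def _normalize(x: np.ndarray) -> np.ndarray | None:
    nrm = np.linalg.norm(x)
    return None if nrm == 0 else x / nrm


def scca_pair(w: np.ndarray, lambda1: float, lambda2: float,
              tol: float = 1e-10, max_iter: int = 500,
              seed: int | None = None) -> ArchieComponent:
    """One sparse component pair by penalized alternating power iteration.

    Initialized at the leading singular pair of W (deterministic). Each
    half-step maximizes the penalized objective
    u'Wv - lambda1*|u|_1 - lambda2*|v|_1 over the unit L2 ball, so that
    objective is non-decreasing along the trace. Full shrinkage at the
    requested penalties yields an empty component (q2 = 0).
    """
    w = np.asarray(w, dtype=float)
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be non-negative")
    if not np.any(w):
        return ArchieComponent(u=np.zeros(w.shape[0]), v=np.zeros(w.shape[1]),
                               q2=0.0, lambda1=lambda1, lambda2=lambda2,
                               rank_index=0)
    uu, _, vvt = np.linalg.svd(w, full_matrices=False)
    u, v = uu[:, 0], vvt[0, :]
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        u_new = _normalize(soft_threshold(w @ v, lambda1))
        if u_new is None:
            return ArchieComponent(u=np.zeros(w.shape[0]),
                                   v=np.zeros(w.shape[1]), q2=0.0,
                                   lambda1=lambda1, lambda2=lambda2,
                                   rank_index=0, objective_trace=trace)
        v_new = _normalize(soft_threshold(w.T @ u_new, lambda2))
        if v_new is None:
            return ArchieComponent(u=np.zeros(w.shape[0]),
                                   v=np.zeros(w.shape[1]), q2=0.0,
                                   lambda1=lambda1, lambda2=lambda2,
                                   rank_index=0, objective_trace=trace)
        u, v = u_new, v_new
        obj = float(u @ w @ v - lambda1 * np.abs(u).sum()
                    - lambda2 * np.abs(v).sum())
        trace.append(obj)
        if abs(obj - prev) < tol:
            break
        prev = obj
    comp = ArchieComponent(u=u, v=v, q2=0.0, lambda1=lambda1,
                           lambda2=lambda2, rank_index=0,
                           objective_trace=trace)
    comp.q2 = cc_value(w, u, v)
    return comp


def cc_value(w: np.ndarray, u: np.ndarray, v: np.ndarray,
             variant: str = "normalized") -> float:
    """Squared canonical correlation captured by a component pair.

    normalized (default): q2 = (u'Wv)^2 / (u'u * v'v), the squared
    cosine-normalized bilinear form (sigma_1^2 at the leading singular
    pair). as_printed: q2 = (u'Wv)^2 / ((u'WW'u) * (v'W'Wv)).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not np.any(u) or not np.any(v):
        raise ValueError("component vectors must be nonzero")
    num = float(u @ w @ v) ** 2
    if variant == "normalized":
        return num / (float(u @ u) * float(v @ v))
    if variant == "as_printed":
        wu = w.T @ u
        wv = w @ v
        return num / (float(wu @ wu) * float(wv @ wv))
    raise ValueError(f"unknown cc-value variant {variant!r}")


def deflate(w: np.ndarray, component: ArchieComponent) -> np.ndarray:
    """Rank-one deflation W_new = W - |q| u v'."""
    if component.empty:
        raise ValueError("cannot deflate with an empty component")
    u, v = component.u, component.v
    if w.shape != (len(u), len(v)):
        raise ValueError("component dimensions do not match W")
    return w - np.sqrt(component.q2) * np.outer(u, v)


def _extract_at_penalty(w: np.ndarray, lambda1: float, lambda2: float,
                        K: int, cc_variant: str, tol: float,
                        max_iter: int) -> list[ArchieComponent]:
    comps: list[ArchieComponent] = []
    work = w.copy()
    for k in range(K):
        c = scca_pair(work, lambda1, lambda2, tol=tol, max_iter=max_iter)
        if c.empty:
            break
        c.q2 = cc_value(work, c.u, c.v, variant=cc_variant)
        c.rank_index = k
        work = deflate(work, c)
        comps.append(c)
    return comps


def _pairwise_disjoint(comps: list[ArchieComponent]) -> bool:
    seen_s: set[int] = set()
    seen_p: set[int] = set()
    for c in comps:
        s, p = set(c.selected_snps), set(c.selected_proteins)
        if s & seen_s or p & seen_p:
            return False
        seen_s |= s
        seen_p |= p
    return True


def _disjoint_prefix_len(comps: list[ArchieComponent]) -> int:
    for k in range(len(comps), 0, -1):
        if _pairwise_disjoint(comps[:k]):
            return k
    return 0


def default_lambda_grid(w: np.ndarray, n_points: int = 16) -> list[float]:
    return list(np.linspace(0.0, 0.9 * np.max(np.abs(w)), n_points))


def extract_components(ss, K: int = 5, lambda_grid=None,
                       floor: float = EIGEN_FLOOR, tol: float = 1e-10,
                       cc_variant: str = "normalized", max_iter: int = 500,
                       seed: int | None = None) -> list[ArchieComponent]:
    """Extract up to K component pairs with non-overlapping supports.

    One sparsity level is applied to the whole sequence: the grid is
    scanned in increasing penalty order and the first level whose nonempty
    components have pairwise-disjoint SNP and protein supports is kept
    (ties on penalty broken by larger total cc-value). If no grid level
    achieves disjointness, the level with the longest disjoint leading run
    is returned in full with a warning.

    ``ss`` may be a SummaryStatSet (whitened internally) or a matrix W.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    w = build_whitened(ss, floor).W if isinstance(ss, SummaryStatSet) else np.asarray(ss, float)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(w)
    pairs = [(float(l), float(l)) if np.isscalar(l) else (float(l[0]), float(l[1]))
             for l in lambda_grid]
    if not pairs:
        raise ValueError("lambda grid is empty")
    pairs.sort(key=lambda t: (t[0] + t[1], t[0]))

    best = None      # (penalty_sum, -total_q2, comps) among fully disjoint
    fallback = None  # (-prefix_len, penalty_sum, comps)
    for l1, l2 in pairs:
        comps = _extract_at_penalty(w, l1, l2, K, cc_variant, tol, max_iter)
        if comps and _pairwise_disjoint(comps):
            key = (l1 + l2, -sum(c.q2 for c in comps))
            if best is None or key < best[0]:
                best = (key, comps)
        elif comps:
            key = (-_disjoint_prefix_len(comps), l1 + l2)
            if fallback is None or key < fallback[0]:
                fallback = (key, comps)
    if best is not None:
        return best[1]
    if fallback is not None:
        warnings.warn("no penalty level on the grid achieves disjoint "
                      "supports; returning the closest run", stacklevel=2)
        return fallback[1]
    warnings.warn("all grid levels yield empty components", stacklevel=2)
    return []
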