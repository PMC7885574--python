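"""Connectedness statistics between management units.

Six metrics are computed pairwise across units and summarized into a single
overall value (the mean over unit pairs):

PEV-based (two-step: individual-level PEV matrix, then a summary)
    PEVD  prediction error variance of a difference; small = well connected
    CD    coefficient of determination: PEVD scaled by the prior variance of
          the contrast, penalizing comparisons between near-identical groups
    r     prediction error correlation ("flock connectedness" in group form)

each with three summaries: group average (GrpAve, block means of PEV/PEC),
individual average (IdAve, averaging pairwise statistics), and contrast
(quadratic form with a zero-sum contrast vector).

VE-based (single-step from the unit-effect covariance matrix)
    VED    variance of the difference of two unit-effect estimates
    CDVED  CD-like scaling of VED by the block means of K
    CR     connectedness rating, the correlation form of VE

each at correction level c in {0, 1, 2}.  With correction 1 (unit-only
models) or 2 (models with extra fixed effects), VE equals the block-mean PEV
exactly, so VED/CDVED/CR coincide with the group-average PEVD/CD/r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mme import PEVStore
from .relmat import RelationshipMatrix, VarianceComponents
from .vestat import VEStore, block_means

#: denominators at or below this are treated as degenerate (pair undefined)
DENOM_TOL = 1e-10

#: zero-sum tolerance for contrast vectors
CONTRAST_TOL = 1e-12


class ContrastError(ValueError):
    """A contrast vector is invalid (non-zero sum, zero, wrong length)."""


class UndefinedContrastError(ValueError):
    """The prior variance of a contrast is ~0: groups genetically identical."""


@dataclass
class ContrastVector:
    """Zero-sum coefficient vector over individuals (relationship-matrix order)."""

    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 1:
            raise ContrastError("contrast must be a 1-d vector")
        if abs(self.x.sum()) > CONTRAST_TOL:
            raise ContrastError(
                f"contrast elements must sum to zero (got {self.x.sum():.3e})"
            )
        if not np.any(self.x):
            raise ContrastError("contrast vector is identically zero")


def unit_contrast(pev_or_index, unit_i: str, unit_j: str, n_individuals: int | None = None) -> ContrastVector:
    """Standard unit-pair contrast: 1/n_i for unit i members, -1/n_j for unit j.

    Accepts a PEVStore or a (unit_index dict, n_individuals) pair.
    """
    if isinstance(pev_or_index, PEVStore):
        index = pev_or_index.unit_index
        n = pev_or_index.PEV.shape[0]
    else:
        index = pev_or_index
        if n_individuals is None:
            raise ValueError("n_individuals required when passing a raw unit index")
        n = n_individuals
    if unit_i == unit_j:
        raise ContrastError("a unit-pair contrast needs two distinct units")
    x = np.zeros(n)
    x[index[unit_i]] = 1.0 / len(index[unit_i])
    x[index[unit_j]] = -1.0 / len(index[unit_j])
    return ContrastVector(x)


@dataclass
class UnitPairResult:
    """Units x units symmetric matrix of one statistic plus its overall mean."""

    statistic: str
    summary: str  # IdAve | GrpAve | Contrast | n/a
    correction: int | None  # 0|1|2 for VE metrics, None otherwise
    matrix: np.ndarray
    unit_labels: list[str]

    @property
    def overall(self) -> float:
        """Unweighted mean of the strictly-off-diagonal upper-triangle entries.

        Undefined pairs (NaN) are excluded from the average.
        """
        iu = np.triu_indices(len(self.unit_labels), k=1)
        vals = self.matrix[iu]
        return float(np.nanmean(vals))

    def pair(self, unit_i: str, unit_j: str) -> float:
        a = self.unit_labels.index(unit_i)
        b = self.unit_labels.index(unit_j)
        return float(self.matrix[a, b])


def overall(result: UnitPairResult) -> float:
    """Overall connectedness: mean of the pairwise statistics across units."""
    return result.overall


# ---------------------------------------------------------------------------
# PEVD: prediction error variance of differences
# ---------------------------------------------------------------------------

def pevd_pairwise(pev: PEVStore, i: int, j: int) -> float:
    """PEVD between individuals i and j: PEV_ii + PEV_jj - 2 PEC_ij."""
    P = pev.PEV
    return float(P[i, i] + P[j, j] - 2.0 * P[i, j])


def pevd_grpave(pev: PEVStore) -> UnitPairResult:
    """Group-average PEVD from block means of PEV and PEC.

    With diagonal-inclusive block means this equals the contrast form for the
    standard unit-pair contrast, entry for entry.
    """
    bm = block_means(pev)
    d = np.diag(bm)
    mat = d[:, None] + d[None, :] - 2.0 * bm
    return UnitPairResult("PEVD", "GrpAve", None, mat, pev.unit_labels)


def pevd_idave(pev: PEVStore) -> UnitPairResult:
    """Individual-average PEVD: mean pairwise PEVD over all cross-unit pairs."""
    P = pev.PEV
    dg = np.diag(P)
    labels = pev.unit_labels
    k = len(labels)
    mat = np.zeros((k, k))
    for a in range(k):
        ia = pev.unit_index[labels[a]]
        for b in range(a + 1, k):
            ib = pev.unit_index[labels[b]]
            # mean over pairs of PEV_ii + PEV_jj - 2 PEC_ij
            val = (
                dg[ia].mean()
                + dg[ib].mean()
                - 2.0 * P[np.ix_(ia, ib)].mean()
            )
            mat[a, b] = mat[b, a] = val
    return UnitPairResult("PEVD", "IdAve", None, mat, labels)


def pevd_contrast(pev: PEVStore, x: ContrastVector) -> float:
    """PEVD of a contrast: x' PEV x."""
    if x.x.shape[0] != pev.PEV.shape[0]:
        raise ContrastError("contrast length does not match number of individuals")
    return float(x.x @ pev.PEV @ x.x)


def pevd_contrast_pairs(pev: PEVStore) -> UnitPairResult:
    """All unit-pair contrasts assembled into a matrix (diagonal 0)."""
    labels = pev.unit_labels
    k = len(labels)
    mat = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            val = pevd_contrast(pev, unit_contrast(pev, labels[a], labels[b]))
            mat[a, b] = mat[b, a] = val
    return UnitPairResult("PEVD", "Contrast", None, mat, labels)


# ---------------------------------------------------------------------------
# CD: coefficient of determination
# ---------------------------------------------------------------------------

def cd_pairwise(
    pev: PEVStore, K: RelationshipMatrix, varcomp: VarianceComponents, i: int, j: int
) -> float:
    """CD between individuals: 1 - PEVD_ij / (sigma2_u (K_ii + K_jj - 2 K_ij)).

    Raises UndefinedContrastError when the pair is genetically (near-)identical,
    since the prior variance of their difference vanishes.
    """
    kd = K.K[i, i] + K.K[j, j] - 2.0 * K.K[i, j]
    if kd <= DENOM_TOL:
        raise UndefinedContrastError(
            f"individuals {i} and {j} are genetically identical (K-difference "
            f"{kd:.2e}); CD is undefined"
        )
    return 1.0 - pevd_pairwise(pev, i, j) / (varcomp.sigma2_u * kd)


def _k_block_means(pev: PEVStore, K: RelationshipMatrix) -> np.ndarray:
    """Diagonal-inclusive block means of K using the PEV store's unit index."""
    proxy = PEVStore(PEV=K.K, individual_ids=K.individual_ids, unit_index=pev.unit_index)
    return block_means(proxy)


def cd_grpave(
    pev: PEVStore, K: RelationshipMatrix, varcomp: VarianceComponents
) -> UnitPairResult:
    """Group-average CD: PEVD_GrpAve scaled by block-mean K differences."""
    pevd = pevd_grpave(pev).matrix
    kbm = _k_block_means(pev, K)
    d = np.diag(kbm)
    kdiff = d[:, None] + d[None, :] - 2.0 * kbm
    k = len(pev.unit_labels)
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 1.0)
    for a in range(k):
        for b in range(a + 1, k):
            if kdiff[a, b] <= DENOM_TOL:
                continue  # genetically identical units stay undefined (NaN)
            mat[a, b] = mat[b, a] = 1.0 - pevd[a, b] / (varcomp.sigma2_u * kdiff[a, b])
    return UnitPairResult("CD", "GrpAve", None, mat, pev.unit_labels)


def cd_idave(
    pev: PEVStore, K: RelationshipMatrix, varcomp: VarianceComponents
) -> UnitPairResult:
    """Individual-average CD as the printed ratio of sums.

    The numerator sums pairwise PEVD and the denominator sums pairwise
    K-differences over all cross-unit pairs; this is NOT the mean of the
    pairwise CD values (the two differ whenever PEVD and K-differences vary
    across pairs).
    """
    P, Km = pev.PEV, K.K
    dgP, dgK = np.diag(P), np.diag(Km)
    labels = pev.unit_labels
    k = len(labels)
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 1.0)
    for a in range(k):
        ia = pev.unit_index[labels[a]]
        for b in range(a + 1, k):
            ib = pev.unit_index[labels[b]]
            npairs = len(ia) * len(ib)
            pevd_sum = (
                dgP[ia].sum() * len(ib)
                + dgP[ib].sum() * len(ia)
                - 2.0 * P[np.ix_(ia, ib)].sum()
            )
            kdiff_sum = (
                dgK[ia].sum() * len(ib)
                + dgK[ib].sum() * len(ia)
                - 2.0 * Km[np.ix_(ia, ib)].sum()
            )
            if kdiff_sum <= DENOM_TOL * npairs:
                continue
            mat[a, b] = mat[b, a] = 1.0 - pevd_sum / (varcomp.sigma2_u * kdiff_sum)
    return UnitPairResult("CD", "IdAve", None, mat, labels)


def cd_contrast(
    pev: PEVStore,
    K: RelationshipMatrix,
    varcomp: VarianceComponents,
    x: ContrastVector,
) -> float:
    """CD of a contrast: 1 - x'PEVx / (sigma2_u x'Kx)."""
    xKx = float(x.x @ K.K @ x.x)
    if xKx <= DENOM_TOL:
        raise UndefinedContrastError(
            f"prior variance of the contrast is degenerate (x'Kx = {xKx:.2e})"
        )
    return 1.0 - pevd_contrast(pev, x) / (varcomp.sigma2_u * xKx)


def cd_contrast_pairs(
    pev: PEVStore, K: RelationshipMatrix, varcomp: VarianceComponents
) -> UnitPairResult:
    """All unit-pair contrast CDs assembled into a matrix (diagonal 1)."""
    labels = pev.unit_labels
    k = len(labels)
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 1.0)
    for a in range(k):
        for b in range(a + 1, k):
            try:
                val = cd_contrast(pev, K, varcomp, unit_contrast(pev, labels[a], labels[b]))
            except UndefinedContrastError:
                continue
            mat[a, b] = mat[b, a] = val
    return UnitPairResult("CD", "Contrast", None, mat, labels)


# ---------------------------------------------------------------------------
# r: prediction error correlation
# ---------------------------------------------------------------------------

def r_pairwise(pev: PEVStore, i: int, j: int) -> float:
    """Prediction error correlation PEC_ij / sqrt(PEV_ii PEV_jj)."""
    P = pev.PEV
    denom = P[i, i] * P[j, j]
    if denom <= DENOM_TOL:
        raise UndefinedContrastError(
            f"PEV diagonal vanishes for pair ({i}, {j}); r is undefined"
        )
    return float(P[i, j] / np.sqrt(denom))


def r_grpave(pev: PEVStore) -> UnitPairResult:
    """Group-average r (flock connectedness): summed cross-block PEC over the
    geometric mean of summed within-unit PEV blocks.

    Block sums and block means give the identical ratio (the 1/n factors
    cancel), so this matches the block-mean form as well.
    """
    bm = block_means(pev)
    d = np.diag(bm)
    labels = pev.unit_labels
    k = len(labels)
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 1.0)
    for a in range(k):
        for b in range(a + 1, k):
            denom = d[a] * d[b]
            if denom <= DENOM_TOL:
                continue
            mat[a, b] = mat[b, a] = bm[a, b] / np.sqrt(denom)
    return UnitPairResult("r", "GrpAve", None, mat, labels)


def r_idave(pev: PEVStore) -> UnitPairResult:
    """Individual-average r: mean pairwise r over all cross-unit pairs."""
    P = pev.PEV
    dg = np.sqrt(np.diag(P))
    labels = pev.unit_labels
    k = len(labels)
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 1.0)
    for a in range(k):
        ia = pev.unit_index[labels[a]]
        for b in range(a + 1, k):
            ib = pev.unit_index[labels[b]]
            denom = np.outer(dg[ia], dg[ib])
            if np.any(denom <= DENOM_TOL):
                continue
            mat[a, b] = mat[b, a] = float((P[np.ix_(ia, ib)] / denom).mean())
    return UnitPairResult("r", "IdAve", None, mat, labels)


def r_matrix(pev: PEVStore) -> np.ndarray:
    """Full individual-level prediction error correlation matrix (diagonal 1)."""
    dg = np.sqrt(np.diag(pev.PEV))
    if np.any(dg**2 <= DENOM_TOL):
        raise UndefinedContrastError("a PEV diagonal element vanishes; r matrix undefined")
    return pev.PEV / np.outer(dg, dg)


def r_contrast(pev: PEVStore, x: ContrastVector) -> float:
    """r of a contrast: x' r x over the pairwise correlation matrix."""
    if x.x.shape[0] != pev.PEV.shape[0]:
        raise ContrastError("contrast length does not match number of individuals")
    R = r_matrix(pev)
    return float(x.x @ R @ x.x)


def r_contrast_pairs(pev: PEVStore) -> UnitPairResult:
    """All unit-pair contrast r values assembled into a matrix."""
    labels = pev.unit_labels
    k = len(labels)
    R = r_matrix(pev)
    proxy = PEVStore(PEV=R, individual_ids=pev.individual_ids, unit_index=pev.unit_index)
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 1.0)
    for a in range(k):
        for b in range(a + 1, k):
            x = unit_contrast(pev, labels[a], labels[b])
            mat[a, b] = mat[b, a] = float(x.x @ proxy.PEV @ x.x)
    return UnitPairResult("r", "Contrast", None, mat, labels)


# ---------------------------------------------------------------------------
# VE-based metrics: VED, CDVED, CR
# ---------------------------------------------------------------------------

def ved(ve: VEStore) -> UnitPairResult:
    """Variance of the difference of unit effects: VE_ii + VE_jj - 2 VE_ij."""
    d = np.diag(ve.VE)
    mat = d[:, None] + d[None, :] - 2.0 * ve.VE
    return UnitPairResult("VED", "GrpAve", ve.correction, mat, ve.unit_labels)


def cdved(
    ve: VEStore,
    K: RelationshipMatrix,
    varcomp: VarianceComponents,
    unit_index: dict[str, np.ndarray],
) -> UnitPairResult:
    """CD-like statistic from VE: 1 - VED / (sigma2_u * block-mean K difference)."""
    proxy = PEVStore(PEV=K.K, individual_ids=K.individual_ids, unit_index=unit_index)
    kbm = block_means(proxy)
    dk = np.diag(kbm)
    kdiff = dk[:, None] + dk[None, :] - 2.0 * kbm
    ved_mat = ved(ve).matrix
    k = len(ve.unit_labels)
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 1.0)
    for a in range(k):
        for b in range(a + 1, k):
            if kdiff[a, b] <= DENOM_TOL:
                continue
            mat[a, b] = mat[b, a] = 1.0 - ved_mat[a, b] / (varcomp.sigma2_u * kdiff[a, b])
    return UnitPairResult("CDVED", "GrpAve", ve.correction, mat, ve.unit_labels)


def cr(ve: VEStore) -> UnitPairResult:
    """Connectedness rating: VE_ij / sqrt(VE_ii VE_jj), diagonal 1.

    With correction 0 this is the classical contemporary-group connectedness
    rating; corrected VE diagonals can touch zero, in which case the affected
    pairs are reported as undefined rather than silently zeroed.
    """
    d = np.diag(ve.VE)
    k = len(ve.unit_labels)
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 1.0)
    for a in range(k):
        for b in range(a + 1, k):
            denom = d[a] * d[b]
            if denom <= DENOM_TOL or d[a] <= 0 or d[b] <= 0:
                continue
            mat[a, b] = mat[b, a] = ve.VE[a, b] / np.sqrt(denom)
    return UnitPairResult("CR", "GrpAve", ve.correction, mat, ve.unit_labels)
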