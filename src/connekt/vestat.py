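"""Variance of unit-effect estimates with fixed-effect corrections.

The unit-by-unit sampling covariance of the estimated management-unit effects,
VE = Var(b_hat_units), approximates the block means of the prediction error
variance matrix.  Two corrections make the approximation exact:

* VE1 (unit the only fixed effect):  VE1 = Var(b_hat) - sigma2_e (X'X)^-1,
  where (X'X)^-1 is diagonal with entries 1/n_i.  Only the diagonal is
  corrected; cross-unit entries carry over from Var(b_hat) unchanged.
* VE2 (unit plus other fixed effects): the four-term expansion combining
  Var(b_hat_1), Var(b_hat_2), and their cross-covariances through the
  projection (X1'X1)^-1 X1'X2.

Under the diagonal-inclusive block-mean convention (every block averaged over
all n_i * n_j of its elements, diagonals included) both corrected forms equal
the block-mean PEV matrix exactly, which makes the VE-based connectedness
statistics coincide with their PEV-based group-average counterparts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mme import MMESystem, PEVStore, fixed_effect_covariance


class CorrectionLevelError(ValueError):
    """The requested correction does not match the model's fixed effects."""


@dataclass
class VEStore:
    """Units x units covariance matrix of unit-effect estimates.

    ``correction`` records which correction produced it: 0 (none),
    1 (one fixed effect: unit only), or 2 (unit plus other fixed effects).
    """

    VE: np.ndarray
    unit_labels: list[str]
    correction: int

    def __post_init__(self) -> None:
        self.VE = np.asarray(self.VE, dtype=float)
        k = len(self.unit_labels)
        if self.VE.shape != (k, k):
            raise ValueError("VE dimension does not match number of units")
        if np.abs(self.VE - self.VE.T).max() > 1e-10:
            raise ValueError("VE matrix is not symmetric")
        if self.correction not in (0, 1, 2):
            raise ValueError("correction must be 0, 1 or 2")


def block_means(
    pev: PEVStore, include_diagonal: bool = True
) -> np.ndarray:
    """Units x units matrix of within/between-unit PEV block means.

    Each (i', j') entry averages the PEV elements between all phenotyped
    members of units i' and j'.  By default diagonal PEV elements are included
    in within-unit blocks (average over all n_i^2 elements); setting
    ``include_diagonal=False`` averages the n_i(n_i - 1) off-diagonal elements
    only, for compatibility with conventions that exclude self-pairs.
    """
    labels = pev.unit_labels
    k = len(labels)
    out = np.empty((k, k))
    for a, ua in enumerate(labels):
        ia = pev.unit_index[ua]
        for b in range(a, k):
            ib = pev.unit_index[labels[b]]
            block = pev.PEV[np.ix_(ia, ib)]
            if a == b and not include_diagonal:
                n = len(ia)
                if n < 2:
                    raise ValueError(
                        f"unit '{ua}' has a single member; diagonal-exclusive "
                        "block mean is undefined"
                    )
                val = (block.sum() - np.trace(block)) / (n * (n - 1))
            else:
                val = block.mean()
            out[a, b] = out[b, a] = val
    return out


def _unit_block(system: MMESystem) -> np.ndarray:
    k = system.design.n_units
    return fixed_effect_covariance(system)[:k, :k]


def ve0(system: MMESystem) -> VEStore:
    """Uncorrected variance of unit-effect estimates (unit block of Var(b_hat))."""
    return VEStore(
        VE=_unit_block(system),
        unit_labels=system.design.unit_labels,
        correction=0,
    )


def ve1(system: MMESystem) -> VEStore:
    """Record-count-corrected VE, exact PEV block means for unit-only models."""
    if system.design.X2.shape[1] != 0:
        raise CorrectionLevelError(
            "correction 1 requires unit to be the only fixed effect; "
            "this model has additional fixed effects - use ve2"
        )
    n_i = system.design.n_per_unit
    correction = np.diag(system.varcomp.sigma2_e / n_i)
    return VEStore(
        VE=_unit_block(system) - correction,
        unit_labels=system.design.unit_labels,
        correction=1,
    )


def ve2(system: MMESystem) -> VEStore:
    """Multi-fixed-effect correction, exact PEV block means for unit + other effects.

    All non-unit columns are treated as one concatenated block X2, and the two
    cross-covariance terms are transposes of each other, so the result is
    symmetric by construction.
    """
    if system.design.X2.shape[1] == 0:
        raise CorrectionLevelError(
            "correction 2 requires at least one fixed effect besides unit; "
            "this model is unit-only - use ve1"
        )
    k = system.design.n_units
    Vb = fixed_effect_covariance(system)
    V11 = Vb[:k, :k]
    V22 = Vb[k:, k:]
    V12 = Vb[:k, k:]
    X1, X2 = system.design.X1, system.design.X2
    n_i = system.design.n_per_unit
    N1_X1tX2 = (X1.T @ X2) / n_i[:, None]  # (X1'X1)^-1 X1'X2
    VE = (
        V11
        - np.diag(system.varcomp.sigma2_e / n_i)
        + N1_X1tX2 @ V22 @ N1_X1tX2.T
        + N1_X1tX2 @ V12.T
        + V12 @ N1_X1tX2.T
    )
    VE = 0.5 * (VE + VE.T)
    return VEStore(VE=VE, unit_labels=system.design.unit_labels, correction=2)


def ve(system: MMESystem, correction: int) -> VEStore:
    """Dispatch to ve0/ve1/ve2 by correction level."""
    if correction == 0:
        return ve0(system)
    if correction == 1:
        return ve1(system)
    if correction == 2:
        return ve2(system)
    raise ValueError("correction must be 0, 1 or 2")
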