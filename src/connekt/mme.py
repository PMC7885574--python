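"""Henderson's mixed model equations and prediction error (co)variances.

For the model y = Xb + Zu + e with u ~ N(0, K sigma2_u) and
e ~ N(0, I sigma2_e), the coefficient matrix is

    C = [[X'X, X'Z], [Z'X, Z'Z + K^-1 lambda]],    lambda = sigma2_e / sigma2_u

and its inverse partitions into blocks C11, C12, C22.  The prediction error
variance matrix of the breeding values is PEV = C22 * sigma2_e, and the
sampling variance of the fixed-effect estimates is Var(b_hat) = C11 * sigma2_e.

Identifiability: the management-unit effect is coded one-hot with no intercept
(so every unit has its own estimable effect, which the unit-variance
connectedness statistics need); every additional categorical fixed effect is
reference-coded by dropping its first level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .relmat import VarianceComponents

logger = logging.getLogger("connekt")


class ModelSpecError(ValueError):
    """The phenotype table or fixed-effect specification is unusable."""


class RankDeficiencyError(ValueError):
    """The fixed-effect design is rank deficient after constraints."""


@dataclass
class PhenotypeTable:
    """One phenotype record per individual with its management-unit label.

    ``frame`` must contain columns ``id``, ``unit``, ``phenotype`` plus any
    categorical fixed-effect columns (e.g. ``sex``).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("id", "unit", "phenotype"):
            if col not in f.columns:
                raise ModelSpecError(f"phenotype table is missing column '{col}'")
        if f["id"].duplicated().any():
            dupes = f.loc[f["id"].duplicated(), "id"].tolist()
            raise ModelSpecError(
                f"repeated records are not supported; duplicated id(s): {dupes}"
            )
        if f["unit"].isna().any():
            raise ModelSpecError("every record needs a non-missing unit label")
        units = f["unit"].astype(str)
        if units.nunique() < 2:
            raise ModelSpecError("connectedness needs at least 2 distinct units")

    @property
    def ids(self) -> list[str]:
        return self.frame["id"].astype(str).tolist()

    @property
    def units(self) -> list[str]:
        return sorted(self.frame["unit"].astype(str).unique())


@dataclass
class DesignMatrices:
    """Incidence matrices for the mixed model.

    X = [X1 | X2] with X1 the one-hot unit block (always first) and X2 the
    reference-coded remaining fixed effects.  Z maps records to individuals in
    the relationship-matrix order; individuals without records get all-zero
    columns so their breeding values are still predicted.
    """

    X: np.ndarray
    Z: np.ndarray
    n_units: int
    unit_labels: list[str]
    x_colnames: list[str]
    individual_ids: list[str]  # K order (columns of Z)
    record_ids: list[str]  # row order of X, Z and y
    y: np.ndarray

    @property
    def X1(self) -> np.ndarray:
        return self.X[:, : self.n_units]

    @property
    def X2(self) -> np.ndarray:
        return self.X[:, self.n_units :]

    @property
    def n_per_unit(self) -> np.ndarray:
        return self.X1.sum(axis=0)

    def unit_index(self) -> dict[str, np.ndarray]:
        """Map unit label -> positions (in K order) of its phenotyped members."""
        rec_pos = {rid: k for k, rid in enumerate(self.record_ids)}
        k_pos = {iid: k for k, iid in enumerate(self.individual_ids)}
        out: dict[str, np.ndarray] = {}
        for u_idx, unit in enumerate(self.unit_labels):
            rows = np.flatnonzero(self.X1[:, u_idx] == 1)
            members = [self.record_ids[r] for r in rows]
            out[unit] = np.array([k_pos[m] for m in members], dtype=int)
        del rec_pos
        return out


@dataclass
class MMESystem:
    """Assembled coefficient matrix, its inverse blocks, and solutions."""

    design: DesignMatrices
    varcomp: VarianceComponents
    C: np.ndarray
    Cinv: np.ndarray
    n_fixed: int
    b_hat: np.ndarray
    u_hat: np.ndarray
    Kinv: np.ndarray = field(repr=False, default=None)

    @property
    def C11(self) -> np.ndarray:
        return self.Cinv[: self.n_fixed, : self.n_fixed]

    @property
    def C12(self) -> np.ndarray:
        return self.Cinv[: self.n_fixed, self.n_fixed :]

    @property
    def C22(self) -> np.ndarray:
        return self.Cinv[self.n_fixed :, self.n_fixed :]

    def absorption_matrix(self) -> np.ndarray:
        """M = I - X (X'X)^- X', the projection removing fixed effects."""
        X = self.design.X
        return np.eye(X.shape[0]) - X @ np.linalg.pinv(X.T @ X) @ X.T


@dataclass
class PEVStore:
    """Prediction error variance/covariance matrix with a unit index.

    ``PEV`` is C22 * sigma2_e over all individuals in relationship-matrix
    order; ``unit_index`` maps each unit label to the positions of its
    phenotyped members, which the block-summary statistics use.
    """

    PEV: np.ndarray
    individual_ids: list[str]
    unit_index: dict[str, np.ndarray]

    @property
    def unit_labels(self) -> list[str]:
        return list(self.unit_index.keys())


def build_design(
    pheno: PhenotypeTable,
    k_individual_ids: list[str],
    fixed_effects: list[str] | None = None,
) -> DesignMatrices:
    """Construct X and Z from a phenotype table, in relationship-matrix order.

    ``fixed_effects`` names categorical columns fitted in addition to the unit
    effect (which is always included and always first).  Each extra effect is
    dummy-coded with its first (sorted) level dropped.  A rank check on the
    final X catches aliasing, e.g. a sex effect perfectly confounded with unit.
    """
    fixed_effects = list(fixed_effects or [])
    f = pheno.frame
    for col in fixed_effects:
        if col not in f.columns:
            raise ModelSpecError(f"unknown fixed-effect column '{col}'")
        if col in ("unit", "id", "phenotype"):
            raise ModelSpecError(f"column '{col}' cannot be used as an extra fixed effect")

    record_ids = pheno.ids
    k_pos = {iid: k for k, iid in enumerate(k_individual_ids)}
    missing = [rid for rid in record_ids if rid not in k_pos]
    if missing:
        raise ModelSpecError(
            f"{len(missing)} phenotyped individual(s) absent from the relationship "
            f"matrix, e.g. {missing[:5]}"
        )

    units = pheno.units
    unit_col = f["unit"].astype(str).to_numpy()
    n = len(f)
    X1 = np.zeros((n, len(units)))
    for j, u in enumerate(units):
        X1[unit_col == u, j] = 1.0
    colnames = [f"unit:{u}" for u in units]

    X2_cols = []
    for col in fixed_effects:
        levels = sorted(f[col].astype(str).unique())
        vals = f[col].astype(str).to_numpy()
        for lev in levels[1:]:  # drop first level: reference coding
            X2_cols.append((vals == lev).astype(float))
            colnames.append(f"{col}:{lev}")
    X = np.column_stack([X1] + X2_cols) if X2_cols else X1

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns: those whose removal does not reduce rank
        aliased = [
            colnames[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise RankDeficiencyError(
            f"fixed-effect design is rank deficient (rank {rank} < {X.shape[1]} "
            f"columns); aliased columns: {aliased}"
        )

    Z = np.zeros((n, len(k_individual_ids)))
    for r, rid in enumerate(record_ids):
        Z[r, k_pos[rid]] = 1.0

    y = f["phenotype"].to_numpy(dtype=float)
    return DesignMatrices(
        X=X,
        Z=Z,
        n_units=len(units),
        unit_labels=units,
        x_colnames=colnames,
        individual_ids=list(k_individual_ids),
        record_ids=record_ids,
        y=y,
    )


def build_mme(
    design: DesignMatrices, Kinv: np.ndarray, varcomp: VarianceComponents
) -> MMESystem:
    """Assemble and invert Henderson's coefficient matrix.

    The full inverse is formed explicitly via a symmetric factorization; the
    problem sizes this package targets (hundreds to a few thousand equations)
    make this the simplest reliable route.  Systems above 10,000 equations get
    a size warning.
    """
    X, Z = design.X, design.Z
    Kinv = np.asarray(Kinv, dtype=float)
    if Kinv.shape != (Z.shape[1], Z.shape[1]):
        raise ValueError(
            f"K inverse is {Kinv.shape} but Z has {Z.shape[1]} individual columns"
        )
    lam = varcomp.lam
    p = X.shape[1]
    C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + Kinv * lam]])
    C = 0.5 * (C + C.T)
    if C.shape[0] > 10_000:
        logger.warning(
            "coefficient matrix has %d equations; dense inversion will be slow",
            C.shape[0],
        )
    try:
        cho = linalg.cho_factor(C, lower=True)
        Cinv = linalg.cho_solve(cho, np.eye(C.shape[0]))
    except linalg.LinAlgError as exc:
        raise RankDeficiencyError(
            "coefficient matrix is singular despite identifiability constraints; "
            "check the fixed-effect design (X'X block) for aliasing"
        ) from exc
    rhs = np.concatenate([X.T @ design.y, Z.T @ design.y])
    sol = Cinv @ rhs
    return MMESystem(
        design=design,
        varcomp=varcomp,
        C=C,
        Cinv=Cinv,
        n_fixed=p,
        b_hat=sol[:p],
        u_hat=sol[p:],
        Kinv=Kinv,
    )


def pev(system: MMESystem) -> PEVStore:
    """Prediction error (co)variance matrix PEV = C22 * sigma2_e."""
    PEV = system.C22 * system.varcomp.sigma2_e
    return PEVStore(
        PEV=PEV,
        individual_ids=system.design.individual_ids,
        unit_index=system.design.unit_index(),
    )


def pev_absorbed(system: MMESystem) -> np.ndarray:
    """PEV via the absorbed form (Z'MZ + K^-1 lambda)^-1 * sigma2_e.

    Algebraically identical to C22 * sigma2_e; kept as an independent route so
    tests can confirm the two derivations agree numerically.
    """
    Z = system.design.Z
    M = system.absorption_matrix()
    inner = Z.T @ M @ Z + system.Kinv * system.varcomp.lam
    return np.linalg.inv(inner) * system.varcomp.sigma2_e


def fixed_effect_covariance(system: MMESystem) -> np.ndarray:
    """Sampling variance of the fixed-effect estimates, Var(b_hat) = C11 sigma2_e."""
    return system.C11 * system.varcomp.sigma2_e


def fixed_effect_covariance_absorbed(system: MMESystem) -> np.ndarray:
    """Var(b_hat) via absorption of the random effects.

    Evaluates [X'X - X'Z (Z'Z + K^-1 lambda)^-1 Z'X]^-1 sigma2_e, the direct
    expression for the unit-effect variance; used as an independent check on
    the C11 route.
    """
    X, Z = system.design.X, system.design.Z
    inner = Z.T @ Z + system.Kinv * system.varcomp.lam
    absorbed = X.T @ X - X.T @ Z @ np.linalg.solve(inner, Z.T @ X)
    return np.linalg.inv(absorbed) * system.varcomp.sigma2_e
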