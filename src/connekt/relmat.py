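"""Relationship matrices: pedigree-based (numerator, A) and genomic (G).

The genetic covariance structure of a group of individuals enters the mixed
model through a relationship matrix K, either the numerator relationship
matrix A computed from a pedigree by the tabular method, or a genomic
relationship matrix G computed from biallelic marker genotypes (VanRaden
method 1). Both are returned as :class:`RelationshipMatrix` objects carrying
individual labels, and can be regularized and inverted for use in the mixed
model equations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger("connekt")

#: token for an unknown parent in pedigree files (livestock convention)
MISSING_PARENT = "0"

#: default ridge added to a singular relationship matrix before inversion
DEFAULT_EPSILON = 1e-8

#: absolute symmetry tolerance for relationship matrices
SYMMETRY_TOL = 1e-10


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id, unknown parent)."""


class DegenerateInputError(ValueError):
    """Input carries no usable information (e.g. all markers monomorphic)."""


@dataclass
class PedigreeTable:
    """Ordered pedigree records (individual, sire, dam), unknown parent = None.

    Records are validated on construction: ids must be unique and the
    parent-offspring graph must be acyclic.  ``topo_sorted`` returns an
    equivalent table whose parents always precede their offspring, which the
    tabular A-matrix recursion requires.
    """

    records: list[tuple[str, str | None, str | None]]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate individual id(s): {dupes}")
        self._index = {i: k for k, i in enumerate(ids)}
        self._check_acyclic()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PedigreeTable":
        """Build from a DataFrame with columns id, sire, dam ('0' = unknown)."""
        required = {"id", "sire", "dam"}
        if not required.issubset(frame.columns):
            raise PedigreeError(f"pedigree table needs columns {sorted(required)}")
        records = []
        for row in frame.itertuples(index=False):
            sire = None if str(row.sire) == MISSING_PARENT else str(row.sire)
            dam = None if str(row.dam) == MISSING_PARENT else str(row.dam)
            records.append((str(row.id), sire, dam))
        return cls(records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (i, s if s is not None else MISSING_PARENT, d if d is not None else MISSING_PARENT)
            for i, s, d in self.records
        ]
        return pd.DataFrame(rows, columns=["id", "sire", "dam"])

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def parents(self, individual: str) -> tuple[str | None, str | None]:
        rec = self.records[self._index[individual]]
        return rec[1], rec[2]

    def _check_acyclic(self) -> None:
        # iterative DFS over the offspring -> parent graph
        WHITE, GREY, BLACK = 0, 1, 2
        color = {i: WHITE for i in self._index}
        for start in self._index:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            while stack:
                node, stage = stack.pop()
                if stage == 0:
                    if color[node] == GREY:
                        raise PedigreeError(f"pedigree contains a cycle through '{node}'")
                    if color[node] == BLACK:
                        continue
                    color[node] = GREY
                    stack.append((node, 1))
                    for p in self.records[self._index[node]][1:]:
                        if p is None:
                            continue
                        if p not in self._index:
                            raise PedigreeError(f"parent '{p}' of '{node}' has no pedigree record")
                        if color[p] == GREY:
                            raise PedigreeError(f"pedigree contains a cycle through '{p}'")
                        if color[p] == WHITE:
                            stack.append((p, 0))
                else:
                    color[node] = BLACK

    def topo_sorted(self) -> "PedigreeTable":
        """Return a copy where every parent precedes its offspring."""
        order: list[str] = []
        done: set[str] = set()
        # Kahn-style: repeatedly emit individuals whose parents are all done
        pending = list(self.ids)
        while pending:
            progressed = False
            remaining = []
            for i in pending:
                s, d = self.parents(i)
                if (s is None or s in done) and (d is None or d in done):
                    order.append(i)
                    done.add(i)
                    progressed = True
                else:
                    remaining.append(i)
            if not progressed:  # pragma: no cover - acyclicity already checked
                raise PedigreeError("pedigree cannot be topologically sorted")
            pending = remaining
        recs = [self.records[self._index[i]] for i in order]
        return PedigreeTable(recs)


@dataclass
class MarkerMatrix:
    """Individuals x markers genotype matrix with entries in {0, 1, 2}."""

    values: np.ndarray
    individual_ids: list[str]
    marker_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype matrix must be 2-dimensional")
        if self.values.shape[0] != len(self.individual_ids):
            raise ValueError(
                f"{self.values.shape[0]} genotype rows but "
                f"{len(self.individual_ids)} individual ids"
            )
        if not np.isin(self.values, (0, 1, 2)).all():
            bad = np.unique(self.values[~np.isin(self.values, (0, 1, 2))])
            raise ValueError(f"genotypes must be coded 0/1/2; found {bad.tolist()}")
        if self.marker_ids is None:
            self.marker_ids = [f"m{k+1}" for k in range(self.values.shape[1])]


@dataclass
class RelationshipMatrix:
    """Symmetric genetic covariance structure K with individual labels."""

    K: np.ndarray
    individual_ids: list[str]
    source: str = "pedigree"  # "pedigree" | "genomic"

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.individual_ids)
        if self.K.shape != (n, n):
            raise ValueError(f"K is {self.K.shape} but {n} ids were given")
        if np.abs(self.K - self.K.T).max() > SYMMETRY_TOL:
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def position(self, individual: str) -> int:
        return self.individual_ids.index(individual)


@dataclass(frozen=True)
class VarianceComponents:
    """Additive genetic and residual variances; lambda = sigma2_e / sigma2_u."""

    sigma2_u: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if not (self.sigma2_u > 0 and self.sigma2_e > 0):
            raise ValueError("sigma2_u and sigma2_e must both be positive")

    @property
    def lam(self) -> float:
        return self.sigma2_e / self.sigma2_u

    @classmethod
    def from_h2(cls, h2: float, sigma2_p: float = 1.0) -> "VarianceComponents":
        """Variance components from heritability at a given phenotypic variance."""
        if not 0.0 < h2 < 1.0:
            raise ValueError("heritability must lie strictly between 0 and 1")
        return cls(sigma2_u=h2 * sigma2_p, sigma2_e=(1.0 - h2) * sigma2_p)

    @classmethod
    def from_lambda(cls, lam: float, sigma2_e: float = 1.0) -> "VarianceComponents":
        if lam <= 0:
            raise ValueError("lambda must be positive")
        return cls(sigma2_u=sigma2_e / lam, sigma2_e=sigma2_e)


def build_A(pedigree: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    After topological sorting, each individual's row is the average of its
    parents' rows; the diagonal is 1 plus half the relationship between its
    parents (1 + inbreeding coefficient F).  Founders get diagonal 1.  The
    result is returned in the pedigree's original id order, so the output is
    invariant to the input record order.
    """
    sorted_ped = pedigree.topo_sorted()
    ids = sorted_ped.ids
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for j, (ind, sire, dam) in enumerate(sorted_ped.records):
        s = pos[sire] if sire is not None else None
        d = pos[dam] if dam is not None else None
        row = np.zeros(j)
        if s is not None:
            row += 0.5 * A[s, :j]
        if d is not None:
            row += 0.5 * A[d, :j]
        A[j, :j] = row
        A[:j, j] = row
        if s is not None and d is not None:
            A[j, j] = 1.0 + 0.5 * A[s, d]
        else:
            A[j, j] = 1.0
    # restore original order
    original = pedigree.ids
    perm = [pos[i] for i in original]
    A = A[np.ix_(perm, perm)]
    return RelationshipMatrix(A, original, source="pedigree")


def build_G(
    markers: MarkerMatrix,
    freq_mode: str = "observed",
    freqs: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Genomic relationship matrix, VanRaden method 1.

    G = W W' / (2 * sum_m p_m (1 - p_m)), where W is the genotype matrix with
    each column centered by twice the allele frequency p_m.  Frequencies are
    either observed column means / 2 (default) or supplied by the caller.
    Monomorphic markers carry no information and are dropped with a warning.

    Raises
    ------
    DegenerateInputError
        if every marker is monomorphic (zero denominator).
    """
    M = np.asarray(markers.values, dtype=float)
    if freq_mode == "observed":
        p = M.mean(axis=0) / 2.0
    elif freq_mode == "supplied":
        if freqs is None:
            raise ValueError("freq_mode='supplied' requires a frequency per marker")
        p = np.asarray(freqs, dtype=float)
        if p.shape != (M.shape[1],):
            raise ValueError("one allele frequency per marker is required")
    else:
        raise ValueError(f"unknown freq_mode {freq_mode!r}")

    poly = (p > 0.0) & (p < 1.0)
    n_mono = int((~poly).sum())
    if n_mono == M.shape[1]:
        raise DegenerateInputError("all markers are monomorphic; G is undefined")
    if n_mono:
        msg = f"dropping {n_mono} monomorphic marker(s) from G construction"
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
        M = M[:, poly]
        p = p[poly]

    W = M - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = W @ W.T / denom
    G = 0.5 * (G + G.T)  # enforce exact symmetry against fp noise
    return RelationshipMatrix(G, list(markers.individual_ids), source="genomic")


def regularize_and_invert(
    K: RelationshipMatrix | np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> tuple[np.ndarray, float]:
    """Invert K via Cholesky, adding epsilon*I on the diagonal only if needed.

    Returns the inverse and the ridge actually applied (0.0 when K factorized
    cleanly).  A singular K (e.g. duplicated individuals in G) triggers the
    jitter path with a warning rather than failing outright.
    """
    mat = K.K if isinstance(K, RelationshipMatrix) else np.asarray(K, dtype=float)
    if np.abs(mat - mat.T).max() > SYMMETRY_TOL:
        raise ValueError("cannot invert a non-symmetric relationship matrix")
    try:
        cho = linalg.cho_factor(mat, lower=True)
        return linalg.cho_solve(cho, np.eye(mat.shape[0])), 0.0
    except linalg.LinAlgError:
        pass
    msg = f"relationship matrix is singular or indefinite; adding ridge {epsilon:g} to diagonal"
    logger.warning(msg)
    warnings.warn(msg, UserWarning, stacklevel=2)
    jittered = mat + epsilon * np.eye(mat.shape[0])
    cho = linalg.cho_factor(jittered, lower=True)
    return linalg.cho_solve(cho, np.eye(mat.shape[0])), epsilon
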