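"""Synthetic cattle-style data with known genetic structure.

Generates a multi-generation pedigree under random mating with non-overlapping
generations, drops founder alleles down it with Haldane-model recombination to
produce biallelic marker genotypes, clusters individuals into management units
by k-medoids on a dissimilarity matrix derived from the numerator relationship
matrix, and simulates a single phenotype with a sex covariate at a chosen
heritability.  The default configuration mirrors a typical simulated beef
cattle data set: 2,500 individuals over five generations, 10,000 markers
evenly spaced over 29 chromosome pairs of 100 cM each, heritability 0.6.

Breeding values are drawn directly from N(0, K sigma2_u) — the model every
connectedness statistic assumes — rather than from explicit QTL effects, so
the marker panel and the phenotype are coupled only through the pedigree.

All randomness flows from a single seed; identical configurations produce
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mme import PhenotypeTable
from .relmat import MarkerMatrix, PedigreeTable, RelationshipMatrix, build_A

__all__ = [
    "SimConfig",
    "ExampleData",
    "simulate_pedigree",
    "sex_of",
    "drop_genotypes",
    "assign_units",
    "simulate_phenotypes",
    "make_example",
    "gene_drop_relationship",
    "kmedoids",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data set.

    Defaults reproduce the canonical example: 100 founders plus four
    generations of 600 offspring = 2,500 individuals over five generations.
    Founder allele frequencies are Uniform(0.05, 0.95); the sex effect is
    0.5 phenotypic standard deviations; phenotypic variance is normalized
    to 1 so sigma2_u = h2 and sigma2_e = 1 - h2.
    """

    n_founders: int = 100
    generations: int = 5
    offspring_per_generation: int = 600
    n_markers: int = 10_000
    n_chromosomes: int = 29
    chrom_length_cm: float = 100.0
    founder_freq_range: tuple[float, float] = (0.05, 0.95)
    h2: float = 0.6
    sex_effect: float = 0.5
    n_units: int = 5
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie strictly in (0, 1)")
        for name in ("n_founders", "generations", "offspring_per_generation",
                     "n_markers", "n_chromosomes", "n_units"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_founders < 4:
            raise ValueError("need at least 2 founders per sex")

    @property
    def n_individuals(self) -> int:
        return self.n_founders + (self.generations - 1) * self.offspring_per_generation

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def sex_of(position: int) -> str:
    """Sex by birth order: alternating, even positions male."""
    return "M" if position % 2 == 0 else "F"


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> PedigreeTable:
    """Random-mating pedigree with non-overlapping generations.

    Founders form generation 1 with unknown parents; each later generation's
    offspring draw a sire uniformly from the previous generation's males and a
    dam from its females.  Parents always precede offspring in the record
    order.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    records: list[tuple[str, str | None, str | None]] = []
    prev_ids: list[str] = []
    counter = 0
    for _ in range(config.n_founders):
        records.append((str(counter + 1), None, None))
        counter += 1
    prev_ids = [r[0] for r in records]
    for _gen in range(1, config.generations):
        males = [i for i in prev_ids if sex_of(int(i) - 1) == "M"]
        females = [i for i in prev_ids if sex_of(int(i) - 1) == "F"]
        new_ids = []
        for _ in range(config.offspring_per_generation):
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
            iid = str(counter + 1)
            records.append((iid, sire, dam))
            new_ids.append(iid)
            counter += 1
        prev_ids = new_ids
    return PedigreeTable(records)


def _marker_map(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced marker positions: (chromosome index, position in cM)."""
    base = config.n_markers // config.n_chromosomes
    extra = config.n_markers % config.n_chromosomes
    chrom = []
    pos = []
    for c in range(config.n_chromosomes):
        m = base + (1 if c < extra else 0)
        chrom.extend([c] * m)
        # evenly distributed across (0, L)
        pos.extend(((np.arange(m) + 0.5) / m * config.chrom_length_cm).tolist())
    return np.array(chrom), np.array(pos)


def drop_genotypes(
    pedigree: PedigreeTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    return_frequencies: bool = False,
):
    """Gene-drop genotypes for every pedigree member.

    Founder haplotypes are Bernoulli draws at per-marker allele frequencies
    sampled from the configured uniform range (Hardy-Weinberg proportions);
    offspring inherit one recombinant gamete per parent with crossovers placed
    under the Haldane model at the configured map.  Genotypes are the
    haplotype sums, coded 0/1/2.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    ped = pedigree.topo_sorted()
    ids = ped.ids
    pos_of = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    m = config.n_markers
    chrom, cm_pos = _marker_map(config)
    global_pos = chrom * config.chrom_length_cm + cm_pos
    lo, hi = config.founder_freq_range
    freqs = rng.uniform(lo, hi, size=m)

    haps = np.zeros((n, 2, m), dtype=np.int8)
    mean_xo = config.chrom_length_cm / 100.0
    n_chrom = config.n_chromosomes

    def gamete(parent_idx: int) -> np.ndarray:
        start_phase = rng.integers(2, size=n_chrom)
        n_xo = rng.poisson(mean_xo, size=n_chrom)
        total = int(n_xo.sum())
        if total:
            offsets = np.repeat(np.arange(n_chrom) * config.chrom_length_cm, n_xo)
            xo = np.sort(rng.uniform(0, config.chrom_length_cm, total) + offsets)
            crossings = np.searchsorted(xo, global_pos)
        else:
            crossings = np.zeros(m, dtype=int)
        phase = (start_phase[chrom] + crossings) % 2
        return np.where(phase == 0, haps[parent_idx, 0], haps[parent_idx, 1])

    for k, (iid, sire, dam) in enumerate(ped.records):
        if sire is None and dam is None:
            haps[k, 0] = rng.random(m) < freqs
            haps[k, 1] = rng.random(m) < freqs
        else:
            # both-parent pedigrees only in simulation; single known parent
            # falls back to a founder gamete on the unknown side
            haps[k, 0] = (
                gamete(pos_of[sire]) if sire is not None else (rng.random(m) < freqs)
            )
            haps[k, 1] = (
                gamete(pos_of[dam]) if dam is not None else (rng.random(m) < freqs)
            )

    geno = haps.sum(axis=1, dtype=np.int8)
    # restore original pedigree order
    perm = [pos_of[i] for i in pedigree.ids]
    markers = MarkerMatrix(
        values=geno[perm],
        individual_ids=list(pedigree.ids),
        marker_ids=[f"snp{c+1}_{k}" for k, c in zip(range(1, m + 1), chrom)],
    )
    if return_frequencies:
        return markers, freqs
    return markers


def kmedoids(
    D: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> np.ndarray:
    """Alternating k-medoids (PAM-style) on a precomputed dissimilarity matrix.

    Greedy BUILD initialization followed by alternate assignment/medoid-update
    sweeps until the medoid set is stable.  Returns cluster labels 0..k-1;
    every cluster is non-empty.
    """
    n = D.shape[0]
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n clusters")
    # BUILD: first medoid minimizes total dissimilarity; each next medoid
    # maximizes the decrease in total nearest-medoid dissimilarity
    medoids = [int(np.argmin(D.sum(axis=0)))]
    nearest = D[medoids[0]].copy()
    for _ in range(1, k):
        gains = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        nxt = int(np.argmax(gains))
        medoids.append(nxt)
        nearest = np.minimum(nearest, D[nxt])
    medoids = np.array(medoids)

    for _ in range(max_iter):
        labels = np.argmin(D[medoids], axis=0)
        # keep clusters non-empty: give an empty cluster the point farthest
        # from its current medoid assignment
        for c in range(k):
            if not np.any(labels == c):
                far = int(np.argmax(D[medoids[labels], np.arange(n)]))
                labels[far] = c
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    labels = np.argmin(D[medoids], axis=0)
    for c in range(k):
        if not np.any(labels == c):
            far = int(np.argmax(D[medoids[labels], np.arange(n)]))
            labels[far] = c
    return labels


def assign_units(
    K: RelationshipMatrix,
    n_units: int,
    rng: np.random.Generator | None = None,
    dissimilarity: str = "one-minus-scaled",
) -> np.ndarray:
    """Management-unit labels from k-medoids on a relationship-derived distance.

    The default dissimilarity is D = 1 - K / max(K); the alternative
    ``"max-minus"`` uses D = max(K) - K.  Labels are strings "u1".."u{k}" in
    the order of K's individuals.
    """
    if n_units < 2:
        raise ValueError("connectedness analysis needs at least 2 units")
    rng = rng if rng is not None else np.random.default_rng(0)
    kmax = K.K.max()
    if dissimilarity == "one-minus-scaled":
        D = 1.0 - K.K / kmax
    elif dissimilarity == "max-minus":
        D = kmax - K.K
    else:
        raise ValueError(f"unknown dissimilarity {dissimilarity!r}")
    np.fill_diagonal(D, 0.0)
    labels = kmedoids(D, n_units, rng)
    return np.array([f"u{c+1}" for c in labels])


def simulate_phenotypes(
    K: RelationshipMatrix,
    config: SimConfig,
    units: np.ndarray,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Phenotypes y = sex effect + u + e with u ~ N(0, K h2), e ~ N(0, 1 - h2).

    True unit effects are zero (the unit enters the analysis model as a fixed
    effect but contributes nothing to the simulated signal).  Sex alternates
    by birth order; males carry the configured sex effect.  Returns a frame
    with columns id, sex, unit, phenotype, u (true breeding value retained for
    validation).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    n = K.n
    if len(units) != n:
        raise ValueError("one unit label per individual is required")
    sigma_u = np.sqrt(config.h2)
    sigma_e = np.sqrt(1.0 - config.h2)
    # Cholesky of K with a tiny jitter fallback for semidefinite pedigrees
    try:
        L = np.linalg.cholesky(K.K)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(K.K + 1e-10 * np.eye(n))
    u = sigma_u * (L @ rng.standard_normal(n))
    e = sigma_e * rng.standard_normal(n)
    sexes = np.array([sex_of(k) for k in range(n)])
    y = np.where(sexes == "M", config.sex_effect, 0.0) + u + e
    return pd.DataFrame(
        {
            "id": K.individual_ids,
            "sex": sexes,
            "unit": units,
            "phenotype": y,
            "u": u,
        }
    )


@dataclass
class ExampleData:
    """Bundle of simulated pedigree, genotypes, and phenotypes."""

    pedigree: PedigreeTable
    markers: MarkerMatrix
    phenotypes: pd.DataFrame  # columns: progeny, sire, dam, sex, unit, phenotype
    A: RelationshipMatrix
    true_u: np.ndarray = field(repr=False, default=None)

    def phenotype_table(self) -> PhenotypeTable:
        """Analysis-ready phenotype table (id/unit/sex/phenotype)."""
        f = self.phenotypes.rename(columns={"progeny": "id"})
        return PhenotypeTable(f[["id", "sex", "unit", "phenotype"]].copy())


def make_example(config: SimConfig | None = None) -> ExampleData:
    """Full synthetic data set: pedigree, genotypes, units, phenotypes.

    With the default configuration this yields 2,500 individuals, a
    2,500 x 10,000 genotype matrix, and a 2,500 x 6 phenotype frame with
    columns progeny, sire, dam, sex, unit, phenotype.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    ped = simulate_pedigree(config, rng)
    markers = drop_genotypes(ped, config, rng)
    A = build_A(ped)
    units = assign_units(A, config.n_units, rng)
    pheno = simulate_phenotypes(A, config, units, rng)
    ped_frame = ped.to_frame()
    out = pd.DataFrame(
        {
            "progeny": ped_frame["id"],
            "sire": ped_frame["sire"],
            "dam": ped_frame["dam"],
            "sex": pheno["sex"],
            "unit": pheno["unit"],
            "phenotype": pheno["phenotype"],
        }
    )
    return ExampleData(
        pedigree=ped, markers=markers, phenotypes=out, A=A, true_u=pheno["u"].to_numpy()
    )


def two_unit_design(
    n_sires: int = 4,
    n_dams: int = 8,
    offspring_per_dam: int = 2,
    n_links: int = 0,
) -> tuple[PedigreeTable, np.ndarray]:
    """Two-unit pedigree with a controllable number of across-unit sire links.

    Each unit has its own founder sires and dams; every dam produces
    ``offspring_per_dam`` offspring by a within-unit sire.  ``n_links`` of the
    second unit's matings use a first-unit sire instead, creating genetic
    connections between the units.  With ``n_links=0`` the pedigree (and hence
    the numerator relationship matrix) is block-diagonal: the units are fully
    disconnected.  Returns the pedigree and one unit label per individual
    (founders belong to their own unit).
    """
    max_links = n_dams * offspring_per_dam
    if not 0 <= n_links <= max_links:
        raise ValueError(f"n_links must be in [0, {max_links}]")
    records: list[tuple[str, str | None, str | None]] = []
    units: list[str] = []
    sires: dict[int, list[str]] = {}
    dams: dict[int, list[str]] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return str(counter)

    for g in (1, 2):
        sires[g] = [new_id() for _ in range(n_sires)]
        dams[g] = [new_id() for _ in range(n_dams)]
        for i in sires[g] + dams[g]:
            records.append((i, None, None))
            units.append(f"u{g}")
    link_count = 0
    for g in (1, 2):
        k = 0
        for dam in dams[g]:
            for _ in range(offspring_per_dam):
                if g == 2 and link_count < n_links:
                    sire = sires[1][link_count % n_sires]
                    link_count += 1
                else:
                    sire = sires[g][k % n_sires]
                records.append((new_id(), sire, dam))
                units.append(f"u{g}")
                k += 1
    return PedigreeTable(records), np.array(units)


def gene_drop_relationship(
    pedigree: PedigreeTable,
    n_replicates: int = 20_000,
    rng: np.random.Generator | None = None,
) -> RelationshipMatrix:
    """Monte-Carlo estimate of the numerator relationship matrix by allele dropping.

    Unique founder allele labels are dropped down the pedigree independently
    in each replicate; A_ij is estimated as twice the kinship, the average
    probability that a random allele from i is identical by descent to a
    random allele from j (the diagonal estimates 1 + F).  Serves as an
    independent check on the tabular A-matrix recursion.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    ped = pedigree.topo_sorted()
    ids = ped.ids
    pos = {i: k for k, i in enumerate(ids)}
    n, R = len(ids), n_replicates
    alleles = np.zeros((n, 2, R), dtype=np.int32)
    next_label = 0
    for k, (_iid, sire, dam) in enumerate(ped.records):
        for side, parent in ((0, sire), (1, dam)):
            if parent is None:
                alleles[k, side] = next_label
                next_label += 1
            else:
                pick = rng.integers(2, size=R)
                p = pos[parent]
                alleles[k, side] = np.where(pick == 0, alleles[p, 0], alleles[p, 1])
    A_hat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            share = sum(
                (alleles[i, a] == alleles[j, b]).mean()
                for a in (0, 1)
                for b in (0, 1)
            )
            A_hat[i, j] = A_hat[j, i] = share / 2.0
    perm = [pos[i] for i in pedigree.ids]
    return RelationshipMatrix(
        A_hat[np.ix_(perm, perm)], list(pedigree.ids), source="pedigree"
    )
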