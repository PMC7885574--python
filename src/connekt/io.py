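"""File input/output and the end-to-end analysis pipeline.

File dialects
-------------
* Pedigree CSV: header ``id,sire,dam``; ``0`` marks an unknown parent.
* Genotype file: whitespace-delimited; first column individual id, remaining
  columns genotypes coded 0/1/2; an optional first header row of marker ids.
* Phenotype CSV: header row with at least ``id``, ``unit`` and ``phenotype``
  columns plus any categorical fixed-effect columns.
* Output matrices: comma-separated units x units tables with unit labels as
  header row and first column; undefined pairs written as ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connect as cn
from . import vestat as vs
from .mme import PhenotypeTable, build_design, build_mme, pev
from .relmat import (
    DEFAULT_EPSILON,
    MISSING_PARENT,
    MarkerMatrix,
    PedigreeTable,
    RelationshipMatrix,
    VarianceComponents,
    build_A,
    build_G,
    regularize_and_invert,
)

logger = logging.getLogger("connekt")

PEV_METRICS = ("PEVD", "CD", "r")
VE_METRICS = ("VED", "CDVED", "CR")
SUMMARIES = ("IdAve", "GrpAve", "Contrast")


class ParseError(ValueError):
    """Malformed input file; message carries file and line context."""


def read_pedigree(path: str | Path) -> PedigreeTable:
    """Read a pedigree CSV (columns id, sire, dam; '0' = unknown parent)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse as CSV ({exc})") from exc
    missing = {"id", "sire", "dam"} - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing pedigree column(s) {sorted(missing)}")
    return PedigreeTable.from_frame(frame)


def write_pedigree(ped: PedigreeTable, path: str | Path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_genotypes(path: str | Path) -> MarkerMatrix:
    """Read a whitespace-delimited genotype matrix (first column = id).

    A first row whose genotype fields are not all integers in {0,1,2} is
    treated as a header of marker ids.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty genotype file")
    first = lines[0].split()
    marker_ids = None
    start = 0
    if len(first) > 1 and not all(tok in ("0", "1", "2") for tok in first[1:]):
        marker_ids = first[1:]
        start = 1
    ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        toks = line.split()
        ids.append(toks[0])
        row = []
        for col, tok in enumerate(toks[1:], start=2):
            if tok not in ("0", "1", "2"):
                raise ParseError(
                    f"{path}:{lineno}: genotype {tok!r} in field {col} is not 0/1/2"
                )
            row.append(int(tok))
        rows.append(row)
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError(f"{path}: rows have differing marker counts {sorted(widths)}")
    return MarkerMatrix(np.array(rows, dtype=np.int8), ids, marker_ids)


def write_genotypes(markers: MarkerMatrix, path: str | Path, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header and markers.marker_ids is not None:
            fh.write("id " + " ".join(markers.marker_ids) + "\n")
        for iid, row in zip(markers.individual_ids, markers.values):
            fh.write(iid + " " + " ".join(str(int(v)) for v in row) + "\n")


def read_phenotypes(path: str | Path, unit_col: str = "unit") -> PhenotypeTable:
    """Read a phenotype CSV; ``unit_col`` names the management-unit column."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse as CSV ({exc})") from exc
    if unit_col != "unit":
        if unit_col not in frame.columns:
            raise ParseError(f"{path}: no column named '{unit_col}'")
        frame = frame.rename(columns={unit_col: "unit"})
    for col in ("id", "unit", "phenotype"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing phenotype column '{col}'")
    frame["id"] = frame["id"].astype(str)
    bad = frame.index[pd.to_numeric(frame["phenotype"], errors="coerce").isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ParseError(
            f"{path}:{bad[0] + 2}: phenotype value {frame.loc[bad[0], 'phenotype']!r} "
            "is not numeric"
        )
    return PhenotypeTable(frame)


def write_phenotypes(pheno: pd.DataFrame | PhenotypeTable, path: str | Path) -> None:
    frame = pheno.frame if isinstance(pheno, PhenotypeTable) else pheno
    frame.to_csv(path, index=False)


def read_contrast(path: str | Path, individual_ids: list[str]) -> cn.ContrastVector:
    """Read a contrast CSV of (id, coefficient); unlisted individuals get 0."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={0: str})
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: contrast file needs columns id,coefficient")
    frame.columns = ["id", "coefficient"] + list(frame.columns[2:])
    pos = {iid: k for k, iid in enumerate(individual_ids)}
    x = np.zeros(len(individual_ids))
    for rowno, row in enumerate(frame.itertuples(index=False), start=2):
        iid = str(row.id)
        if iid not in pos:
            raise ParseError(f"{path}:{rowno}: unknown individual '{iid}'")
        x[pos[iid]] = float(row.coefficient)
    return cn.ContrastVector(x)


def cross_check_ids(
    pheno: PhenotypeTable, K_ids: list[str]
) -> None:
    """Every phenotyped individual must appear in the relationship source."""
    known = set(K_ids)
    missing = [i for i in pheno.ids if i not in known]
    if missing:
        raise ParseError(
            f"{len(missing)} phenotyped individual(s) missing from the relationship "
            f"source (first few: {missing[:5]})"
        )


def write_result(result: cn.UnitPairResult, prefix: str | Path) -> tuple[Path, Path]:
    """Write a statistic's units x units matrix and its overall summary."""
    prefix = Path(prefix)
    tag = result.summary if result.correction is None else f"c{result.correction}"
    matrix_path = prefix.parent / f"{prefix.name}_{result.statistic}_{tag}.csv"
    frame = pd.DataFrame(result.matrix, index=result.unit_labels, columns=result.unit_labels)
    frame.to_csv(matrix_path, index_label="unit", na_rep="NA")
    overall_path = prefix.parent / f"{prefix.name}_{result.statistic}_{tag}_overall.csv"
    with open(overall_path, "w") as fh:
        fh.write("statistic,summary,correction,overall\n")
        fh.write(
            f"{result.statistic},{result.summary},"
            f"{'' if result.correction is None else result.correction},"
            f"{result.overall!r}\n"
        )
    return matrix_path, overall_path


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    ``metric``/``summary``/``correction`` select the statistic: summaries
    apply to the PEV family (PEVD, CD, r) and corrections to the VE family
    (VED, CDVED, CR); mixing them is rejected up front.
    """

    pheno_path: str
    out_prefix: str
    ped_path: str | None = None
    geno_path: str | None = None
    metric: str = "PEVD"
    summary: str | None = None
    correction: int | None = None
    h2: float | None = None
    lam: float | None = None
    fixed_effects: list[str] = field(default_factory=list)
    unit_col: str = "unit"
    contrast_path: str | None = None
    epsilon: float = DEFAULT_EPSILON
    run_all: bool = False

    def __post_init__(self) -> None:
        if (self.ped_path is None) == (self.geno_path is None):
            raise ValueError("exactly one of a pedigree or a genotype file is required")
        if self.h2 is None and self.lam is None:
            raise ValueError("supply variance components via h2 or lambda")
        if self.run_all:
            return
        if self.metric in PEV_METRICS:
            if self.correction is not None:
                raise ValueError(
                    f"correction applies to VE metrics only, not {self.metric}"
                )
            if self.summary not in SUMMARIES:
                raise ValueError(
                    f"PEV metric {self.metric} needs a summary in {SUMMARIES}"
                )
        elif self.metric in VE_METRICS:
            if self.summary is not None:
                raise ValueError(
                    f"summary applies to PEV metrics only, not {self.metric}"
                )
            if self.correction not in (0, 1, 2):
                raise ValueError(
                    f"VE metric {self.metric} needs a correction in (0, 1, 2)"
                )
        else:
            raise ValueError(f"unknown metric {self.metric!r}")

    def varcomp(self) -> VarianceComponents:
        if self.lam is not None:
            return VarianceComponents.from_lambda(self.lam)
        return VarianceComponents.from_h2(self.h2)


def _compute_statistic(
    metric: str,
    summary: str | None,
    correction: int | None,
    system,
    pev_store,
    K: RelationshipMatrix,
    varcomp: VarianceComponents,
    contrast: cn.ContrastVector | None,
):
    """Dispatch one (metric, summary/correction) combination."""
    if metric in PEV_METRICS:
        if summary == "Contrast" and contrast is not None:
            if metric == "PEVD":
                return cn.pevd_contrast(pev_store, contrast)
            if metric == "CD":
                return cn.cd_contrast(pev_store, K, varcomp, contrast)
            return cn.r_contrast(pev_store, contrast)
        table = {
            ("PEVD", "GrpAve"): lambda: cn.pevd_grpave(pev_store),
            ("PEVD", "IdAve"): lambda: cn.pevd_idave(pev_store),
            ("PEVD", "Contrast"): lambda: cn.pevd_contrast_pairs(pev_store),
            ("CD", "GrpAve"): lambda: cn.cd_grpave(pev_store, K, varcomp),
            ("CD", "IdAve"): lambda: cn.cd_idave(pev_store, K, varcomp),
            ("CD", "Contrast"): lambda: cn.cd_contrast_pairs(pev_store, K, varcomp),
            ("r", "GrpAve"): lambda: cn.r_grpave(pev_store),
            ("r", "IdAve"): lambda: cn.r_idave(pev_store),
            ("r", "Contrast"): lambda: cn.r_contrast_pairs(pev_store),
        }
        return table[(metric, summary)]()
    ve_store = vs.ve(system, correction)
    if metric == "VED":
        return cn.ved(ve_store)
    if metric == "CDVED":
        return cn.cdved(ve_store, K, varcomp, pev_store.unit_index)
    return cn.cr(ve_store)


def run(config: RunConfig) -> dict[str, cn.UnitPairResult | float]:
    """Execute the full pipeline and write matrix, overall, and log files.

    Stages: relationship matrix -> mixed model equations -> PEV (and VE when
    a VE-family metric is requested) -> connectedness statistic(s).
    Returns the computed results keyed by "metric_tag".
    """
    log_path = Path(f"{config.out_prefix}.log")
    log_path.parent.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_inner(config)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_inner(config: RunConfig) -> dict[str, cn.UnitPairResult | float]:
    varcomp = config.varcomp()
    logger.info(
        "defaults in effect: ridge epsilon=%g, degenerate-denominator tol=%g, "
        "block means include diagonal elements; lambda=%g (sigma2_u=%g, sigma2_e=%g)",
        config.epsilon, cn.DENOM_TOL, varcomp.lam, varcomp.sigma2_u, varcomp.sigma2_e,
    )

    try:
        pheno = read_phenotypes(config.pheno_path, config.unit_col)
        if config.ped_path is not None:
            K = build_A(read_pedigree(config.ped_path))
        else:
            K = build_G(read_genotypes(config.geno_path))
    except Exception as exc:
        raise type(exc)(f"[input stage] {exc}") from exc
    cross_check_ids(pheno, K.individual_ids)
    logger.info("relationship matrix: %s, %d individuals", K.source, K.n)

    try:
        Kinv, eps_used = regularize_and_invert(K, config.epsilon)
        if eps_used:
            logger.info("applied ridge %g to the relationship matrix", eps_used)
        design = build_design(pheno, K.individual_ids, config.fixed_effects)
        system = build_mme(design, Kinv, varcomp)
        pev_store = pev(system)
    except Exception as exc:
        raise type(exc)(f"[mixed-model stage] {exc}") from exc

    contrast = None
    if config.contrast_path is not None:
        contrast = read_contrast(config.contrast_path, K.individual_ids)

    combos: list[tuple[str, str | None, int | None]]
    if config.run_all:
        unit_only = design.X2.shape[1] == 0
        ve_corrections = (0, 1) if unit_only else (0, 2)
        combos = [(m, s, None) for m in PEV_METRICS for s in SUMMARIES]
        combos += [(m, None, c) for m in VE_METRICS for c in ve_corrections]
    else:
        combos = [(config.metric, config.summary, config.correction)]

    results: dict[str, cn.UnitPairResult | float] = {}
    for metric, summary, correction in combos:
        try:
            res = _compute_statistic(
                metric, summary, correction, system, pev_store, K, varcomp, contrast
            )
        except Exception as exc:
            raise type(exc)(f"[connectedness stage: {metric}] {exc}") from exc
        tag = summary if correction is None else f"c{correction}"
        key = f"{metric}_{tag}"
        results[key] = res
        if isinstance(res, cn.UnitPairResult):
            matrix_path, overall_path = write_result(res, config.out_prefix)
            logger.info(
                "%s: wrote %s (overall=%.6g)", key, matrix_path, res.overall
            )
        else:
            scalar_path = Path(f"{config.out_prefix}_{key}_contrast.csv")
            with open(scalar_path, "w") as fh:
                fh.write("statistic,value\n")
                fh.write(f"{metric},{res!r}\n")
            logger.info("%s (user contrast): wrote %s (value=%.6g)", key, scalar_path, res)
    return results
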