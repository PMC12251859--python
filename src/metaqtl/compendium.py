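"""Multi-study QTL compendium: ingestion, validation, QC and CI imputation.

A meta-QTL study starts from a compendium table with one row per literature
QTL: trait (plant height PH or ear height EH), chromosome, peak position on
the source study's genetic map, 95% confidence interval, LOD score,
phenotypic variance explained (PVE, %), mapping-population design and size,
and the flanking markers. Quality control removes weakly supported QTLs
(PVE < 1% or LOD < 1.5, strict inequalities).

When a study did not report a confidence interval, the 95% CI width is
imputed with the Darvasi-Soller population-size approximation::

    width = 530 / (N * R^2)   for F2-derived designs (F2, BC, F2:3, F3, F4)
    width = 163 / (N * R^2)   for homozygous immortal designs (RIL, DH)

where ``N`` is the population size and ``R^2 = pve_percent / 100`` the
proportion of variance explained.  The 530/163 numerators are the standard
constants for a 95% interval in F2/backcross vs. recombinant-inbred
designs.  Note the percentage is converted to a proportion before use:
N = 200, PVE = 10% gives a plausible 26.5 cM, whereas feeding the raw
percentage would give an absurd 0.265 cM.  Imputed intervals are centered
on the peak and floored at 0 cM.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TRAITS = ("PH", "EH")

#: Designs whose CI width uses the 530/(N R^2) form (F2-like segregating
#: families) vs. the 163/(N R^2) form (homozygous immortal lines).
F2_DERIVED = frozenset({"F2", "BC", "F2:3", "F3", "F4"})
IMMORTAL = frozenset({"RIL", "DH"})
POPULATION_TYPES = ("F2", "BC", "F2:3", "F3", "F4", "RIL", "DH")

MIN_PVE_PERCENT = 1.0
MIN_LOD = 1.5

#: Required header of the compendium CSV/TSV (empty string = absent value).
QTL_TABLE_COLUMNS = (
    "qtl_id", "study_ref", "trait", "chromosome", "source_map_id",
    "position_cM", "ci_lo_cM", "ci_hi_cM", "lod", "pve_percent",
    "population_type", "population_size", "flank_left", "flank_right",
)


@dataclass(frozen=True)
class QTLRecord:
    """One literature QTL as curated into the compendium."""

    qtl_id: str
    study_ref: str
    trait: str
    chromosome: int
    source_map_id: str
    position: float
    population_type: str
    population_size: int
    ci_lo: float | None = None
    ci_hi: float | None = None
    lod: float | None = None
    pve_percent: float | None = None
    flank_left: str | None = None
    flank_right: str | None = None
    #: source row number in the input table, for error reporting only
    row: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"{self.qtl_id}: trait must be one of {TRAITS}, got {self.trait!r}")
        if not 1 <= int(self.chromosome) <= 10:
            raise ValueError(f"{self.qtl_id}: chromosome must be in 1..10, got {self.chromosome}")
        if self.population_type not in POPULATION_TYPES:
            raise ValueError(
                f"{self.qtl_id}: population_type must be one of {POPULATION_TYPES}, "
                f"got {self.population_type!r}"
            )
        if self.population_size <= 0:
            raise ValueError(f"{self.qtl_id}: population_size must be positive")
        if self.position < 0:
            raise ValueError(f"{self.qtl_id}: position must be >= 0 cM")
        if (self.ci_lo is None) != (self.ci_hi is None):
            raise ValueError(f"{self.qtl_id}: CI bounds must be both present or both absent")
        if self.ci_lo is not None and self.ci_hi is not None:
            if not self.ci_lo <= self.position <= self.ci_hi:
                raise ValueError(
                    f"{self.qtl_id}: CI ({self.ci_lo}, {self.ci_hi}) must bracket "
                    f"the peak position {self.position}"
                )
        if self.lod is not None and self.lod < 0:
            raise ValueError(f"{self.qtl_id}: LOD must be >= 0")
        if self.pve_percent is not None and not 0 < self.pve_percent <= 100:
            raise ValueError(f"{self.qtl_id}: pve_percent must be in (0, 100]")

    @property
    def has_ci(self) -> bool:
        return self.ci_lo is not None and self.ci_hi is not None

    @property
    def ci_width(self) -> float | None:
        if not self.has_ci:
            return None
        return self.ci_hi - self.ci_lo  # type: ignore[operator]


def _opt_float(raw: str) -> float | None:
    raw = raw.strip()
    return None if raw == "" else float(raw)


def _opt_str(raw: str) -> str | None:
    raw = raw.strip()
    return raw or None


def read_qtl_table(path: str | Path) -> list[QTLRecord]:
    """Read a compendium CSV/TSV into validated :class:`QTLRecord` objects.

    The delimiter is taken from the file suffix (``.tsv``/``.tab`` tab,
    otherwise comma).  Absent optional values are kept absent (``None``),
    never coerced to zero.  Errors name the offending row and column.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in QTL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    records: list[QTLRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.to_dict("records")):
        rownum = i + 2  # 1-based, counting the header line
        qtl_id = str(row["qtl_id"]).strip()
        if qtl_id in seen:
            raise ValueError(f"{path} row {rownum}: duplicate qtl_id {qtl_id!r}")
        seen.add(qtl_id)

        def get(col: str, conv, _row=row, _n=rownum):
            try:
                return conv(str(_row[col]))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path} row {_n}, column {col!r}: {exc}") from exc

        try:
            rec = QTLRecord(
                qtl_id=qtl_id,
                study_ref=str(row["study_ref"]).strip(),
                trait=str(row["trait"]).strip(),
                chromosome=get("chromosome", lambda s: int(float(s))),
                source_map_id=str(row["source_map_id"]).strip(),
                position=get("position_cM", float),
                population_type=str(row["population_type"]).strip(),
                population_size=get("population_size", lambda s: int(float(s))),
                ci_lo=get("ci_lo_cM", _opt_float),
                ci_hi=get("ci_hi_cM", _opt_float),
                lod=get("lod", _opt_float),
                pve_percent=get("pve_percent", _opt_float),
                flank_left=_opt_str(str(row["flank_left"])),
                flank_right=_opt_str(str(row["flank_right"])),
                row=rownum,
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {rownum}: {exc}") from exc
        records.append(rec)
    return records


def records_to_frame(records: Iterable[QTLRecord]) -> pd.DataFrame:
    """Render records back into the documented tabular schema."""
    rows = []
    for r in records:
        rows.append({
            "qtl_id": r.qtl_id, "study_ref": r.study_ref, "trait": r.trait,
            "chromosome": r.chromosome, "source_map_id": r.source_map_id,
            "position_cM": r.position,
            "ci_lo_cM": "" if r.ci_lo is None else r.ci_lo,
            "ci_hi_cM": "" if r.ci_hi is None else r.ci_hi,
            "lod": "" if r.lod is None else r.lod,
            "pve_percent": "" if r.pve_percent is None else r.pve_percent,
            "population_type": r.population_type,
            "population_size": r.population_size,
            "flank_left": r.flank_left or "", "flank_right": r.flank_right or "",
        })
    return pd.DataFrame(rows, columns=list(QTL_TABLE_COLUMNS))


def write_qtl_table(records: Iterable[QTLRecord], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    records_to_frame(records).to_csv(path, sep=sep, index=False)


def quality_filter(records: Sequence[QTLRecord]) -> tuple[list[QTLRecord], list[QTLRecord]]:
    """Partition records into (kept, removed) by the QC thresholds.

    A record is removed iff its PVE is strictly below 1% or its LOD is
    strictly below 1.5.  Absent values never trigger removal; records
    missing both support statistics survive but are logged, since the
    condition cannot be evaluated for them.  Input order is preserved.
    """
    kept: list[QTLRecord] = []
    removed: list[QTLRecord] = []
    untestable: list[str] = []
    for r in records:
        fail = (r.pve_percent is not None and r.pve_percent < MIN_PVE_PERCENT) or (
            r.lod is not None and r.lod < MIN_LOD
        )
        (removed if fail else kept).append(r)
        if r.pve_percent is None and r.lod is None:
            untestable.append(r.qtl_id)
    if untestable:
        logger.warning(
            "QC could not be evaluated for %d record(s) missing both PVE and LOD: %s",
            len(untestable), ", ".join(untestable),
        )
    return kept, removed


def impute_ci_width(population_type: str, population_size: int, pve_percent: float) -> float:
    """Darvasi-Soller 95% CI width (cM) from design, N and PVE (%)."""
    if population_size <= 0:
        raise ValueError(f"population_size must be positive, got {population_size}")
    if pve_percent <= 0:
        raise ValueError(f"pve_percent must be positive, got {pve_percent}")
    if population_type in F2_DERIVED:
        numerator = 530.0
    elif population_type in IMMORTAL:
        numerator = 163.0
    else:
        raise ValueError(f"unknown population_type {population_type!r}")
    r2 = pve_percent / 100.0
    return numerator / (population_size * r2)


def complete_cis(records: Sequence[QTLRecord]) -> list[QTLRecord]:
    """Fill missing confidence intervals by Darvasi-Soller imputation.

    Records that already carry a CI are returned untouched.  For the rest
    the imputed width is centered on the peak, with the lower bound floored
    at 0 cM (the upper bound is not shifted to compensate).  Idempotent.
    """
    failed: list[str] = []
    out: list[QTLRecord] = []
    for r in records:
        if r.has_ci:
            out.append(r)
            continue
        if r.pve_percent is None:
            failed.append(r.qtl_id)
            continue
        width = impute_ci_width(r.population_type, r.population_size, r.pve_percent)
        lo = max(0.0, r.position - width / 2.0)
        hi = r.position + width / 2.0
        out.append(replace(r, ci_lo=lo, ci_hi=hi))
    if failed:
        raise ValueError(
            "cannot impute CI (missing PVE) for: " + ", ".join(failed)
        )
    return out
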