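"""Genetic maps and homothetic QTL projection onto a reference map.

Each source study reports QTLs on its own linkage map; meta-analysis needs
them all in one coordinate system.  A QTL is transferred onto the
reference (consensus) map by homothetic scaling: for each point of
interest (peak, CI lower bound, CI upper bound) the tightest pair of
markers shared between the source and reference maps that brackets the
point defines an affine map

    ref(x) = ref_left + (x - src_left) * (ref_right - ref_left) / (src_right - src_left)

which is exact at the shared anchors and preserves relative distances
between them.  The three points of one QTL may use different anchor
pairs, which keeps wide CIs from being stretched through a single
interval.  Points falling outside the span of shared markers are not
extrapolated; the QTL fails with ``no_common_flank``, mirroring how
literature QTLs are lost when their maps share too few markers with the
reference scaffold.
"""
from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .compendium import QTLRecord

logger = logging.getLogger(__name__)


class ProjectionStatus(str, Enum):
    PROJECTED = "projected"
    NO_COMMON_FLANK = "no_common_flank"
    DEGENERATE_INTERVAL = "degenerate_interval"


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker/cM scaffold, per chromosome, for one study or the reference.

    ``chromosomes`` maps chromosome number to an ordered tuple of
    ``(marker_name, position_cM)``; positions are non-decreasing and names
    unique within a chromosome, with at least two markers per non-empty
    chromosome.
    """

    map_id: str
    chromosomes: Mapping[int, tuple[tuple[str, float], ...]]

    def __post_init__(self) -> None:
        for chrom, markers in self.chromosomes.items():
            if len(markers) < 2:
                raise ValueError(
                    f"map {self.map_id!r} chromosome {chrom}: needs >= 2 markers"
                )
            names = [m for m, _ in markers]
            if len(set(names)) != len(names):
                raise ValueError(
                    f"map {self.map_id!r} chromosome {chrom}: duplicate marker names"
                )
            pos = [p for _, p in markers]
            if any(b < a for a, b in zip(pos, pos[1:])) or pos[0] < 0:
                raise ValueError(
                    f"map {self.map_id!r} chromosome {chrom}: positions must be "
                    "non-negative and non-decreasing"
                )

    def markers(self, chromosome: int) -> tuple[tuple[str, float], ...]:
        return self.chromosomes[chromosome]

    def positions(self, chromosome: int) -> dict[str, float]:
        return dict(self.chromosomes[chromosome])

    @property
    def chromosome_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.chromosomes))


class CommonMarker(NamedTuple):
    name: str
    source_cM: float
    reference_cM: float


@dataclass(frozen=True)
class ProjectionResult:
    qtl_id: str
    status: ProjectionStatus
    new_position: float | None = None
    new_ci_lo: float | None = None
    new_ci_hi: float | None = None
    #: anchor marker-name pair used per projected point (lo, peak, hi)
    anchors_used: tuple[tuple[str, str], ...] = field(default=())
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.status is ProjectionStatus.PROJECTED:
            assert self.new_ci_lo is not None and self.new_ci_hi is not None
            assert self.new_ci_lo <= self.new_position <= self.new_ci_hi  # type: ignore[operator]


def read_genetic_maps(path: str | Path) -> dict[str, GeneticMap]:
    """Read one or many maps from a TSV (map_id, chromosome, marker, position_cM)."""
    df = pd.read_csv(path, sep="\t", dtype={"map_id": str, "marker": str})
    required = {"map_id", "chromosome", "marker", "position_cM"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    maps: dict[str, GeneticMap] = {}
    for map_id, grp in df.groupby("map_id", sort=False):
        chroms: dict[int, tuple[tuple[str, float], ...]] = {}
        for chrom, sub in grp.groupby("chromosome", sort=True):
            sub = sub.sort_values("position_cM", kind="stable")
            chroms[int(chrom)] = tuple(
                (str(m), float(p)) for m, p in zip(sub["marker"], sub["position_cM"])
            )
        maps[str(map_id)] = GeneticMap(map_id=str(map_id), chromosomes=chroms)
    return maps


def write_genetic_maps(maps: Iterable[GeneticMap], path: str | Path) -> None:
    rows = [
        {"map_id": gm.map_id, "chromosome": chrom, "marker": name, "position_cM": pos}
        for gm in maps
        for chrom in gm.chromosome_ids
        for name, pos in gm.markers(chrom)
    ]
    pd.DataFrame(rows, columns=["map_id", "chromosome", "marker", "position_cM"]).to_csv(
        path, sep="\t", index=False
    )


def common_markers(
    source: GeneticMap, reference: GeneticMap, chromosome: int
) -> list[CommonMarker]:
    """Markers shared by both maps on one chromosome, sorted by source position."""
    src = source.positions(chromosome) if chromosome in source.chromosomes else {}
    ref = reference.positions(chromosome) if chromosome in reference.chromosomes else {}
    shared = set(src) & set(ref)
    out = [CommonMarker(name, src[name], ref[name]) for name in shared]
    out.sort(key=lambda c: (c.source_cM, c.name))
    return out


def project_point(
    x: float, src_left: float, src_right: float, ref_left: float, ref_right: float
) -> float:
    """Affine (homothetic) transfer of ``x`` between two anchor intervals.

    Exact at the anchors; if the reference anchors are order-reversed the
    map simply reverses orientation.
    """
    if src_left == src_right:
        raise ZeroDivisionError("degenerate source interval (zero marker separation)")
    if src_left > src_right:
        raise ValueError("src_left must be < src_right")
    t = (x - src_left) / (src_right - src_left)
    return ref_left + t * (ref_right - ref_left)


def _project_one(common: Sequence[CommonMarker], x: float):
    """Project one point through its tightest bracketing common-marker pair.

    Returns ``(ref_position, (left_name, right_name))`` or a
    ProjectionStatus on failure.
    """
    srcs = [c.source_cM for c in common]
    if not common or x < srcs[0] or x > srcs[-1]:
        return ProjectionStatus.NO_COMMON_FLANK
    i = bisect_left(srcs, x)
    if srcs[i] == x:  # exactly on a shared marker: fixed point
        c = common[i]
        return c.reference_cM, (c.name, c.name)
    left, right = common[i - 1], common[i]
    if left.source_cM == right.source_cM:  # pragma: no cover - defensive
        return ProjectionStatus.DEGENERATE_INTERVAL
    pos = project_point(x, left.source_cM, right.source_cM,
                        left.reference_cM, right.reference_cM)
    return pos, (left.name, right.name)


def project_qtl(
    qtl: QTLRecord, source: GeneticMap, reference: GeneticMap
) -> ProjectionResult:
    """Project one QTL (CI lower bound, peak, CI upper bound) onto the reference.

    Each of the three points is bracketed independently by the tightest
    pair of common markers on the source map.  If the reference positions
    of an anchor pair are locally order-reversed the affine map reverses
    orientation; the projected CI bounds are re-sorted so lo <= hi and the
    peak is clamped into the sorted interval.
    """
    if not qtl.has_ci:
        raise ValueError(f"{qtl.qtl_id}: CI must be completed before projection")
    if qtl.chromosome not in source.chromosomes:
        raise ValueError(
            f"{qtl.qtl_id}: chromosome {qtl.chromosome} absent from map {source.map_id!r}"
        )
    common = common_markers(source, reference, qtl.chromosome)
    points = (qtl.ci_lo, qtl.position, qtl.ci_hi)
    projected: list[float] = []
    anchors: list[tuple[str, str]] = []
    for x in points:
        res = _project_one(common, x)  # type: ignore[arg-type]
        if res is ProjectionStatus.NO_COMMON_FLANK:
            return ProjectionResult(
                qtl.qtl_id, ProjectionStatus.NO_COMMON_FLANK,
                reason=f"point {x} cM outside the common-marker span",
            )
        if res is ProjectionStatus.DEGENERATE_INTERVAL:
            return ProjectionResult(
                qtl.qtl_id, ProjectionStatus.DEGENERATE_INTERVAL,
                reason=f"zero source-map separation bracketing {x} cM",
            )
        pos, pair = res
        projected.append(pos)
        anchors.append(pair)
    lo, hi = sorted((projected[0], projected[2]))
    peak = min(max(projected[1], lo), hi)
    return ProjectionResult(
        qtl.qtl_id, ProjectionStatus.PROJECTED,
        new_position=peak, new_ci_lo=lo, new_ci_hi=hi,
        anchors_used=tuple(anchors),
    )


def project_compendium(
    records: Sequence[QTLRecord],
    source_maps: Mapping[str, GeneticMap],
    reference: GeneticMap,
) -> tuple[list[ProjectionResult], float]:
    """Project every record onto the reference; return results and the success rate."""
    unresolved = sorted({r.source_map_id for r in records} - set(source_maps))
    if unresolved:
        raise ValueError(f"unresolvable source_map_id(s): {', '.join(unresolved)}")
    results = []
    for r in records:
        res = project_qtl(r, source_maps[r.source_map_id], reference)
        if res.status is not ProjectionStatus.PROJECTED:
            logger.info("QTL %s not projected: %s (%s)", r.qtl_id, res.status.value, res.reason)
        results.append(res)
    n_ok = sum(1 for r in results if r.status is ProjectionStatus.PROJECTED)
    rate = n_ok / len(results) if results else 0.0
    return results, rate


def apply_projection(
    records: Sequence[QTLRecord], results: Sequence[ProjectionResult],
    reference_map_id: str = "reference",
) -> list[QTLRecord]:
    """Replace coordinates of successfully projected records with reference ones.

    Unprojected records are dropped.  Pairing is by qtl_id.
    """
    from dataclasses import replace

    by_id = {res.qtl_id: res for res in results}
    out = []
    for r in records:
        res = by_id.get(r.qtl_id)
        if res is None or res.status is not ProjectionStatus.PROJECTED:
            continue
        out.append(replace(
            r, position=res.new_position, ci_lo=res.new_ci_lo, ci_hi=res.new_ci_hi,
            source_map_id=reference_map_id,
        ))
    return out


def projection_frame(results: Sequence[ProjectionResult]) -> pd.DataFrame:
    rows = [{
        "qtl_id": r.qtl_id, "status": r.status.value,
        "position_cM": r.new_position, "ci_lo_cM": r.new_ci_lo, "ci_hi_cM": r.new_ci_hi,
        "reason": r.reason or "",
    } for r in results]
    return pd.DataFrame(rows, columns=["qtl_id", "status", "position_cM",
                                       "ci_lo_cM", "ci_hi_cM", "reason"])


@dataclass(frozen=True)
class MapSummary:
    total_length_cM: float
    marker_count: int
    mean_interval_cM: float
    n_chromosomes: int
    skipped_chromosomes: tuple[int, ...] = ()


def map_summary(gmap: GeneticMap) -> MapSummary:
    """Total length, marker count and mean inter-marker interval of a map.

    Chromosomes with fewer than two markers are excluded with a warning
    (GeneticMap forbids them at construction, but partially built inputs
    reach this through the frame-free constructor).  The mean interval
    divides total length by (markers - chromosomes), the number of
    intervals on the included chromosomes.
    """
    total = 0.0
    markers = 0
    nchrom = 0
    skipped: list[int] = []
    for chrom in gmap.chromosome_ids:
        mk = gmap.markers(chrom)
        if len(mk) < 2:  # pragma: no cover - construction forbids, defensive
            logger.warning("map %s chromosome %s has < 2 markers; excluded", gmap.map_id, chrom)
            skipped.append(chrom)
            continue
        total += mk[-1][1] - mk[0][1]
        markers += len(mk)
        nchrom += 1
    if nchrom == 0:
        raise ValueError(f"map {gmap.map_id!r} has no chromosome with >= 2 markers")
    return MapSummary(
        total_length_cM=total, marker_count=markers,
        mean_interval_cM=total / (markers - nchrom),
        n_chromosomes=nchrom, skipped_chromosomes=tuple(skipped),
    )
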