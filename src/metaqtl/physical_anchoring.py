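"""Genetic-to-physical anchoring of MQTLs and candidate-gene extraction.

A marker-anchor table (marker, chromosome, cM on the reference map, bp on
the genome assembly) lets each MQTL's genetic CI be converted to a
physical interval by piecewise-linear interpolation across *all* anchors
on the chromosome — not just the two flanking markers — so that a flank
lacking a physical position degrades gracefully onto the next informative
anchor.  Endpoints beyond the anchored span clamp to the terminal
anchors.  Genes overlapping the physical interval (closed-interval,
1-based, any base of overlap counts) are extracted from a GFF3 annotation
and tallied into broad functional categories (hormone, cell wall, sugar,
photosynthesis, cytoskeleton, other) by case-insensitive keyword matching
of their annotation text; a gene may carry several tags.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .meta_analysis import MQTL

logger = logging.getLogger(__name__)

ANCHOR_COLUMNS = ("marker", "chromosome", "cM", "bp")

#: Fixed category order used for exclusive (primary-tag) classification.
CATEGORIES = ("hormone", "cell wall", "sugar", "photosynthesis", "cytoskeleton")
OTHER = "other"


@dataclass(frozen=True)
class MarkerAnchor:
    marker: str
    chromosome: int
    genetic_pos: float
    physical_pos: int


@dataclass(frozen=True)
class GeneModel:
    """One gene feature (1-based inclusive bp coordinates)."""

    gene_id: str
    chromosome: int
    start: int
    end: int
    annotation: str = ""
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start must be <= end")


def read_anchor_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if missing := set(ANCHOR_COLUMNS) - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def _chromosome_anchors(anchors: pd.DataFrame, chromosome: int) -> tuple[np.ndarray, np.ndarray]:
    sub = anchors.loc[anchors["chromosome"] == chromosome].sort_values("cM", kind="stable")
    if len(sub) < 2:
        raise ValueError(f"chromosome {chromosome}: need >= 2 anchors, have {len(sub)}")
    cm = sub["cM"].to_numpy(dtype=float)
    bp = sub["bp"].to_numpy(dtype=float)
    if np.any(np.diff(bp) < 0):
        logger.warning(
            "chromosome %s: anchors not physically monotone (genetic order vs bp); "
            "interpolation will follow the anchors as given", chromosome,
        )
    if np.any(np.diff(cm) == 0):
        # degenerate guard: collapse duplicate cM, keeping the first anchor
        keep = np.concatenate(([True], np.diff(cm) > 0))
        cm, bp = cm[keep], bp[keep]
        if len(cm) < 2:
            raise ValueError(f"chromosome {chromosome}: anchors collapse to < 2 distinct cM")
    return cm, bp


def genetic_to_physical(
    interval: tuple[float, float], chromosome: int, anchors: pd.DataFrame
) -> tuple[int, int]:
    """Interpolate a (cM, cM) interval to a sorted (bp, bp) interval.

    Each endpoint is linearly interpolated between its bracketing anchors;
    endpoints outside the anchored span clamp to the terminal anchors
    (numpy.interp semantics).
    """
    cm, bp = _chromosome_anchors(anchors, chromosome)
    lo, hi = np.interp(sorted(interval), cm, bp)
    lo, hi = sorted((lo, hi))
    return int(round(lo)), int(round(hi))


def attach_physical(mqtls: Sequence[MQTL], anchors: pd.DataFrame) -> list[MQTL]:
    """Fill each MQTL's physical interval from its genetic CI."""
    out = []
    for m in mqtls:
        lo, hi = genetic_to_physical((m.ci_lo, m.ci_hi), m.chromosome, anchors)
        out.append(replace(m, physical_lo=lo, physical_hi=hi))
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene features from a GFF3 file (ID plus description/Note text)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for f in db.features_of_type("gene"):
        seqid = str(f.seqid)
        chrom = int(seqid[3:]) if seqid.lower().startswith("chr") else int(seqid)
        text = " ".join(
            v for key in ("description", "Note", "product")
            for v in f.attributes.get(key, [])
        )
        gene_id = (f.attributes.get("ID") or [f.id])[0]
        genes.append(GeneModel(
            gene_id=str(gene_id), chromosome=chrom,
            start=int(f.start), end=int(f.end), annotation=text,
        ))
    return genes


def genes_in_interval(
    interval: tuple[int, int], chromosome: int, genes: Sequence[GeneModel]
) -> list[GeneModel]:
    """Genes with any base of overlap with the closed interval, sorted by start."""
    lo, hi = sorted(interval)
    hits = [
        g for g in genes
        if g.chromosome == chromosome and g.start <= hi and g.end >= lo
    ]
    hits.sort(key=lambda g: (g.start, g.gene_id))
    return hits


@dataclass(frozen=True)
class GeneClassification:
    per_gene: Mapping[str, tuple[str, ...]]
    #: multi-tag counts per category (a gene may appear under several)
    counts: Mapping[str, int]
    #: primary-tag counts: each gene counted once, under its first category
    exclusive_counts: Mapping[str, int]
    percentages: Mapping[str, float]
    total: int


def classify_genes(
    genes: Sequence[GeneModel], keyword_map: Mapping[str, str] | None = None
) -> GeneClassification:
    """Tag genes by case-insensitive substring search of annotation text.

    ``keyword_map`` maps a search term to a category; the packaged default
    covers hormone biosynthesis/signalling, cell wall (cellulose, expansin,
    lignin), sugar metabolism/transport, photosynthesis and cytoskeleton
    vocabularies.  Genes matching no term fall into ``other``.  Multi-tag
    percentages are reported against total genes (2 dp) and may sum past
    100%; exclusive counts assign each gene its first matching category in
    the fixed :data:`CATEGORIES` order and sum to the total.
    """
    if keyword_map is None:
        from .datasets import load_keyword_map

        keyword_map = load_keyword_map()
    terms = [(term.lower(), cat) for term, cat in keyword_map.items()]
    per_gene: dict[str, tuple[str, ...]] = {}
    counts = {cat: 0 for cat in (*CATEGORIES, OTHER)}
    exclusive = {cat: 0 for cat in (*CATEGORIES, OTHER)}
    for g in genes:
        text = g.annotation.lower()
        tags = sorted(
            {cat for term, cat in terms if term in text},
            key=lambda c: CATEGORIES.index(c) if c in CATEGORIES else len(CATEGORIES),
        )
        if not tags:
            tags = [OTHER]
        per_gene[g.gene_id] = tuple(tags)
        for t in tags:
            counts[t] += 1
        exclusive[tags[0]] += 1
    total = len(genes)
    percentages = {
        cat: round_half_up(100.0 * c / total) if total else 0.0
        for cat, c in counts.items()
    }
    return GeneClassification(
        per_gene=per_gene, counts=counts, exclusive_counts=exclusive,
        percentages=percentages, total=total,
    )


def extract_candidate_genes(
    mqtls: Sequence[MQTL], genes: Sequence[GeneModel],
    keyword_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-MQTL candidate genes with their category tags (mqtls must be anchored)."""
    if keyword_map is None:
        from .datasets import load_keyword_map

        keyword_map = load_keyword_map()
    rows = []
    for m in mqtls:
        if m.physical_lo is None or m.physical_hi is None:
            raise ValueError(f"{m.mqtl_id}: physical interval not filled; run attach_physical")
        hits = genes_in_interval((m.physical_lo, m.physical_hi), m.chromosome, genes)
        cls = classify_genes(hits, keyword_map)
        for g in hits:
            rows.append({
                "mqtl_id": m.mqtl_id, "gene_id": g.gene_id, "chromosome": g.chromosome,
                "start": g.start, "end": g.end,
                "categories": ";".join(cls.per_gene[g.gene_id]),
                "annotation": g.annotation,
            })
    return pd.DataFrame(
        rows, columns=["mqtl_id", "gene_id", "chromosome", "start", "end",
                       "categories", "annotation"],
    )


@dataclass(frozen=True)
class SpanSummary:
    min_Mb: float
    max_Mb: float
    spans_Mb: Mapping[str, float]


def physical_span_summary(mqtls: Sequence[MQTL]) -> SpanSummary:
    """Physical span of each anchored MQTL in Mb (2 dp, half-up rounding)."""
    spans: dict[str, float] = {}
    for m in mqtls:
        if m.physical_lo is None or m.physical_hi is None:
            raise ValueError(f"{m.mqtl_id}: physical interval not filled")
        spans[m.mqtl_id] = round_half_up((m.physical_hi - m.physical_lo) / 1e6)
    if not spans:
        raise ValueError("no anchored MQTLs")
    return SpanSummary(min_Mb=min(spans.values()), max_Mb=max(spans.values()), spans_Mb=spans)
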