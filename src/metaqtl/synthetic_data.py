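"""Synthetic multi-study QTL scenarios with known ground truth.

The generator emulates the statistical structure of a literature-curated
maize PH/EH QTL compendium: a panel of 13 mapping studies of heterogeneous
design (F2, F2:3, F3, F4, RIL, DH) and size (120-271 individuals), each
re-detecting a set of true loci on its own sparser, length-distorted
linkage map.  Each detected QTL reports a peak position perturbed by
Gaussian noise whose standard deviation is tied to the Darvasi-Soller CI
width (sigma = width/3.92), so the simulated 95% CIs are calibrated
exactly as the meta-analysis assumes.  PVE is drawn uniformly from the
observed 3.23-31.93% range and LOD follows an invented PVE-coupled form
(2.5 + 0.45 PVE + noise, floored at 1.6) matching the reported 2.5-20.5
range qualitatively.  Every output is a pure function of (config, seed).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compendium import (
    QTLRecord, complete_cis, impute_ci_width, quality_filter, write_qtl_table,
)
from .map_projection import (
    GeneticMap, ProjectionResult, apply_projection, project_compendium,
    write_genetic_maps,
)
from .meta_analysis import MQTL, CriteriaTable, meta_analyze

#: Annotation vocabulary sampled for toy genes; terms deliberately overlap
#: the packaged keyword->category table so classification is exercised.
GENE_VOCABULARY = (
    "auxin response factor 12", "abscisic acid receptor PYL4",
    "gibberellin 20-oxidase 1", "brassinosteroid insensitive 1",
    "cytokinin dehydrogenase 3", "ethylene-responsive transcription factor 5",
    "cellulose synthase 10", "cellulose synthase-like protein D3",
    "expansin A4", "expansin B2", "xyloglucan endotransglucosylase 7",
    "phenylalanine ammonia-lyase", "sucrose synthase 3",
    "sucrose transporter 1", "glucose transporter 3", "beta-amylase 5",
    "photosystem II reaction center protein", "chlorophyll a-b binding protein",
    "cryptochrome-1", "actin depolymerization factor 3",
    "MADS-box transcription factor 47", "hypothetical protein",
)


@dataclass(frozen=True)
class StudyConfig:
    """One simulated mapping study (design, size, map coarseness/distortion)."""

    study_id: str
    population_type: str
    population_size: int
    marker_spacing: float = 12.0    # cM between retained markers on the study map
    length_jitter_sd: float = 0.15  # sd of log-normal per-interval length factors


def default_studies() -> tuple[StudyConfig, ...]:
    """A 13-study panel mirroring the designs and sizes of published maize
    PH/EH mapping experiments (F2/F2:3/F3/F4/RIL/DH, N = 120-271)."""
    panel = [
        ("S01", "F2", 180), ("S02", "RIL", 271), ("S03", "F2:3", 211),
        ("S04", "F2", 187), ("S05", "F2", 192), ("S06", "F3", 187),
        ("S07", "F4", 187), ("S08", "F2", 120), ("S09", "F2:3", 184),
        ("S10", "DH", 162), ("S11", "RIL", 202), ("S12", "F2:3", 218),
        ("S13", "RIL", 165),
    ]
    return tuple(StudyConfig(sid, pt, n) for sid, pt, n in panel)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions of one synthetic scenario (seed is mandatory)."""

    seed: int
    chromosomes: int = 3
    chromosome_length: float = 300.0
    #: true locus positions, identical on every chromosome; >= 40 cM apart
    true_loci: tuple[float, ...] = (50.0, 150.0, 250.0)
    studies: tuple[StudyConfig, ...] = field(default_factory=default_studies)
    qtls_per_locus: int = 8
    pve_range: tuple[float, float] = (3.23, 31.93)
    #: per study x locus detection probability; None derives it as
    #: qtls_per_locus / n_studies so each locus collects ~qtls_per_locus QTLs
    detect_prob: float | None = None
    ci_missing_fraction: float = 0.3
    reference_marker_spacing: float = 5.0
    #: multiplies the calibrated peak-noise sd; 0 gives the noiseless limit
    position_noise_scale: float = 1.0
    genes_per_chromosome: int = 40

    def __post_init__(self) -> None:
        if not self.true_loci:
            raise ValueError("need at least one true locus")
        if any(not 0 <= p <= self.chromosome_length for p in self.true_loci):
            raise ValueError("true loci must lie within the chromosome length")
        lo, hi = self.pve_range
        if not 0 < lo <= hi <= 100:
            raise ValueError("pve_range must be within (0, 100]")

    @property
    def effective_detect_prob(self) -> float:
        if self.detect_prob is not None:
            return self.detect_prob
        return min(1.0, self.qtls_per_locus / len(self.studies))


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth: locus positions and the locus each QTL came from."""

    loci: Mapping[int, tuple[float, ...]]
    assignments: Mapping[str, tuple[int, int]]  # qtl_id -> (chromosome, locus index)


def generate_reference_map(
    chromosomes: int, chromosome_length: float, marker_spacing: float, seed: int,
    map_id: str = "reference",
) -> GeneticMap:
    """Dense reference scaffold with markers at jittered ~spacing intervals."""
    if chromosome_length <= 0:
        raise ValueError("chromosome_length must be positive")
    rng = np.random.default_rng(seed)
    chroms: dict[int, tuple[tuple[str, float], ...]] = {}
    for c in range(1, chromosomes + 1):
        positions = [0.0]
        while True:
            gap = rng.uniform(0.5 * marker_spacing, 1.5 * marker_spacing)
            if positions[-1] + gap > chromosome_length:
                break
            positions.append(positions[-1] + gap)
        if len(positions) < 2:
            positions.append(chromosome_length)
        chroms[c] = tuple((f"m{c}_{i + 1}", p) for i, p in enumerate(positions))
    return GeneticMap(map_id=map_id, chromosomes=chroms)


def derive_source_map(
    reference: GeneticMap, keep_fraction: float, length_jitter_sd: float, seed: int,
    map_id: str = "source",
) -> GeneticMap:
    """Study-specific map: random marker subset with length-distorted intervals.

    Chromosome-end markers are always retained; each surviving interval's
    length is multiplied by an independent log-normal factor (median 1,
    log-sd ``length_jitter_sd``).  With jitter 0 all retained markers keep
    their reference positions exactly.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    chroms: dict[int, tuple[tuple[str, float], ...]] = {}
    for c in reference.chromosome_ids:
        markers = reference.markers(c)
        n = len(markers)
        keep = np.ones(n, dtype=bool)
        if n > 2:
            keep[1:-1] = rng.random(n - 2) < keep_fraction
        kept = [markers[i] for i in range(n) if keep[i]]
        if len(kept) < 2:
            raise ValueError(f"keep_fraction {keep_fraction} leaves < 2 markers")
        positions = [kept[0][1]]
        for (_, a), (_, b) in zip(kept, kept[1:]):
            factor = rng.lognormal(mean=0.0, sigma=length_jitter_sd) if length_jitter_sd > 0 else 1.0
            positions.append(positions[-1] + (b - a) * factor)
        chroms[c] = tuple((name, pos) for (name, _), pos in zip(kept, positions))
    return GeneticMap(map_id=map_id, chromosomes=chroms)


def _reference_to_source(x: float, reference: GeneticMap, source: GeneticMap, chromosome: int) -> float:
    """Transfer a reference-coordinate position into study-map coordinates."""
    src = source.markers(chromosome)
    refpos = reference.positions(chromosome)
    xp = np.array([refpos[name] for name, _ in src])
    fp = np.array([p for _, p in src])
    return float(np.interp(x, xp, fp))


def simulate_qtls(
    truth: ScenarioTruth,
    reference: GeneticMap,
    source_maps: Mapping[str, GeneticMap],
    config: ScenarioConfig,
    seed: int,
) -> tuple[list[QTLRecord], dict[str, tuple[int, int]]]:
    """Simulate per-study QTL reports for the true loci.

    For each study x chromosome x locus, the locus is detected with the
    configured probability; a detected QTL draws its PVE, derives its
    Darvasi-Soller CI width, and reports a peak at the truth (transferred
    into the study's own map coordinates) plus calibrated Gaussian noise.
    A configurable fraction of records omits the CI, to exercise
    downstream imputation.  Returns the records and their truth
    assignments.
    """
    rng = np.random.default_rng(seed)
    p_detect = config.effective_detect_prob
    records: list[QTLRecord] = []
    assignments: dict[str, tuple[int, int]] = {}
    for study in config.studies:
        smap = source_maps[study.study_id]
        for chrom, loci in sorted(truth.loci.items()):
            for li, true_pos in enumerate(loci):
                if rng.random() >= p_detect:
                    continue
                trait = "PH" if rng.random() < 0.5 else "EH"
                pve = float(rng.uniform(*config.pve_range))
                width = impute_ci_width(study.population_type, study.population_size, pve)
                sigma = (width / (2 * 1.96)) * config.position_noise_scale
                x_src = _reference_to_source(true_pos, reference, smap, chrom)
                peak = max(0.0, x_src + float(rng.normal(0.0, sigma)) if sigma > 0 else x_src)
                lod = max(1.6, 2.5 + 0.45 * pve + float(rng.normal(0.0, 0.5)))
                omit_ci = rng.random() < config.ci_missing_fraction
                qtl_id = f"{study.study_id}.c{chrom}.l{li + 1}.{trait}"
                rec = QTLRecord(
                    qtl_id=qtl_id, study_ref=study.study_id, trait=trait,
                    chromosome=chrom, source_map_id=study.study_id,
                    position=peak,
                    population_type=study.population_type,
                    population_size=study.population_size,
                    ci_lo=None if omit_ci else max(0.0, peak - width / 2),
                    ci_hi=None if omit_ci else peak + width / 2,
                    lod=lod, pve_percent=pve,
                )
                records.append(rec)
                assignments[qtl_id] = (chrom, li)
    return records, assignments


def generate_anchors_and_genes(
    reference: GeneticMap, genes_per_chromosome: int, seed: int,
    anchor_stride: int = 5,
) -> tuple[pd.DataFrame, str]:
    """Marker physical anchors and a toy GFF3 gene annotation.

    Every ``anchor_stride``-th reference marker (plus chromosome ends)
    receives a physical position, accumulated with a monotone cM->bp drift
    of Uniform(0.5, 1.5) Mb/cM per anchored interval.  Genes are placed
    uniformly over the anchored span with lengths of 2-10 kb and
    annotation text sampled from :data:`GENE_VOCABULARY`.
    """
    rng = np.random.default_rng(seed)
    anchor_rows = []
    gff_lines = ["##gff-version 3"]
    for c in reference.chromosome_ids:
        markers = reference.markers(c)
        idx = sorted(set(range(0, len(markers), anchor_stride)) | {len(markers) - 1})
        bp = 100_000
        prev_cm = markers[idx[0]][1]
        for i in idx:
            name, cm = markers[i]
            bp += int(round((cm - prev_cm) * rng.uniform(0.5, 1.5) * 1e6))
            prev_cm = cm
            anchor_rows.append({"marker": name, "chromosome": c, "cM": cm, "bp": bp})
        span_lo, span_hi = 100_000, bp
        starts = np.sort(rng.integers(span_lo, max(span_lo + 1, span_hi - 10_000),
                                      size=genes_per_chromosome))
        for gi, start in enumerate(starts, start=1):
            length = int(rng.integers(2_000, 10_001))
            desc = GENE_VOCABULARY[int(rng.integers(len(GENE_VOCABULARY)))]
            gff_lines.append(
                f"chr{c}\tsynthetic\tgene\t{int(start)}\t{int(start) + length}\t.\t+\t.\t"
                f"ID=g{c}_{gi:03d};description={desc}"
            )
    anchors = pd.DataFrame(anchor_rows, columns=["marker", "chromosome", "cM", "bp"])
    return anchors, "\n".join(gff_lines) + "\n"


@dataclass(frozen=True)
class Scenario:
    config: ScenarioConfig
    truth: ScenarioTruth
    reference: GeneticMap
    source_maps: Mapping[str, GeneticMap]
    records: tuple[QTLRecord, ...]
    anchors: pd.DataFrame
    gff3_text: str


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate a full scenario (maps, compendium, anchors, genes) from one seed."""
    root = np.random.default_rng(config.seed)
    # one derived sub-seed per component, in a fixed draw order
    seeds = root.integers(0, 2**31 - 1, size=4 + len(config.studies))
    reference = generate_reference_map(
        config.chromosomes, config.chromosome_length,
        config.reference_marker_spacing, seed=int(seeds[0]),
    )
    truth = ScenarioTruth(
        loci={c: tuple(config.true_loci) for c in reference.chromosome_ids},
        assignments={},
    )
    source_maps = {}
    for i, study in enumerate(config.studies):
        keep = min(1.0, config.reference_marker_spacing / study.marker_spacing)
        source_maps[study.study_id] = derive_source_map(
            reference, keep_fraction=keep, length_jitter_sd=study.length_jitter_sd,
            seed=int(seeds[4 + i]), map_id=study.study_id,
        )
    records, assignments = simulate_qtls(
        truth, reference, source_maps, config, seed=int(seeds[1])
    )
    truth = ScenarioTruth(loci=truth.loci, assignments=assignments)
    anchors, gff3_text = generate_anchors_and_genes(
        reference, config.genes_per_chromosome, seed=int(seeds[2])
    )
    return Scenario(
        config=config, truth=truth, reference=reference, source_maps=source_maps,
        records=tuple(records), anchors=anchors, gff3_text=gff3_text,
    )


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well estimated MQTLs recover the generating truth."""

    k_errors: Mapping[int, int]         # per chromosome: estimated k - true k
    position_rmse: float                # cM, over true loci matched to nearest MQTL
    mean_abs_error: float               # cM
    ci_coverage: float                  # fraction of true loci inside some MQTL CI
    n_loci: int


def recovery_metrics(mqtls: Sequence[MQTL], truth: ScenarioTruth) -> RecoveryMetrics:
    est_chroms = {m.chromosome for m in mqtls}
    if unknown := est_chroms - set(truth.loci):
        raise ValueError(f"MQTLs on chromosomes absent from the truth: {sorted(unknown)}")
    k_errors: dict[int, int] = {}
    errors: list[float] = []
    covered = 0
    n_loci = 0
    for chrom, loci in sorted(truth.loci.items()):
        ests = [m for m in mqtls if m.chromosome == chrom]
        k_errors[chrom] = len(ests) - len(loci)
        for locus in loci:
            n_loci += 1
            if ests:
                errors.append(min(abs(m.position - locus) for m in ests))
            if any(m.ci_lo <= locus <= m.ci_hi for m in ests):
                covered += 1
    rmse = math.sqrt(sum(e * e for e in errors) / len(errors)) if errors else math.inf
    mae = sum(errors) / len(errors) if errors else math.inf
    return RecoveryMetrics(
        k_errors=k_errors, position_rmse=rmse, mean_abs_error=mae,
        ci_coverage=covered / n_loci if n_loci else 0.0, n_loci=n_loci,
    )


@dataclass(frozen=True)
class ScenarioRun:
    """End-to-end result of running the pipeline on one generated scenario."""

    scenario: Scenario
    kept: tuple[QTLRecord, ...]
    removed: tuple[QTLRecord, ...]
    completed: tuple[QTLRecord, ...]
    projections: tuple[ProjectionResult, ...]
    projection_rate: float
    mqtls: tuple[MQTL, ...]
    criteria: Mapping[int, CriteriaTable]
    metrics: RecoveryMetrics


def run_scenario(config: ScenarioConfig, kmax: int | None = None) -> ScenarioRun:
    """QC -> CI completion -> projection -> meta-analysis -> recovery metrics."""
    sc = generate_scenario(config)
    kept, removed = quality_filter(list(sc.records))
    completed = complete_cis(kept)
    projections, rate = project_compendium(completed, sc.source_maps, sc.reference)
    projected = apply_projection(completed, projections, sc.reference.map_id)
    mqtls, criteria = meta_analyze(projected, kmax=kmax, reference=sc.reference)
    metrics = recovery_metrics(mqtls, sc.truth)
    return ScenarioRun(
        scenario=sc, kept=tuple(kept), removed=tuple(removed),
        completed=tuple(completed), projections=tuple(projections),
        projection_rate=rate, mqtls=tuple(mqtls), criteria=criteria, metrics=metrics,
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> None:
    """Materialize a scenario as the on-disk formats the CLI pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_qtl_table(scenario.records, outdir / "qtl.csv")
    write_genetic_maps(scenario.source_maps.values(), outdir / "maps.tsv")
    write_genetic_maps([scenario.reference], outdir / "ref.tsv")
    scenario.anchors.to_csv(outdir / "anchors.csv", index=False)
    (outdir / "genes.gff3").write_text(scenario.gff3_text)
    truth = {
        "loci": {str(c): list(l) for c, l in scenario.truth.loci.items()},
        "assignments": {q: list(a) for q, a in scenario.truth.assignments.items()},
        "config": {
            **{k: v for k, v in asdict(scenario.config).items() if k != "studies"},
            "studies": [asdict(s) for s in scenario.config.studies],
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
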