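"""Per-chromosome Gaussian meta-analysis of projected QTLs.

Each projected QTL contributes an observed peak position ``x_i`` (cM on
the consensus map) with a standard deviation ``sigma_i`` derived from its
95% CI (``sigma = width / 3.92``).  Assuming each observation is drawn
from a Gaussian centered on one of ``k`` underlying consensus loci
(MQTLs), the best hard assignment of position-sorted QTLs into ``k``
contiguous clusters is found exactly by dynamic programming over segment
boundaries; within a cluster the maximum-likelihood locus position is the
inverse-variance weighted mean

    mu = sum(x_i / sigma_i^2) / sum(1 / sigma_i^2),
    se = sqrt(1 / sum(1 / sigma_i^2)),

so each MQTL's 95% CI (mu +/- 1.96 se) is never wider than its most
precise member's CI.  The number of loci is chosen by five information
criteria (AIC, AICc, AIC3, BIC, AWE).  These are scored on the
observed-data likelihood of the Gaussian *mixture* the partition implies
(component means from the partition, mixing proportions equal to cluster
occupancies), with p = 2k - 1 free parameters (k means and k - 1
proportions; member variances are known).  Scoring the mixture rather
than the hard-assignment likelihood matters: the maximized
hard-assignment likelihood keeps growing with k because each extra
cluster gets to pick its best split point, and under that likelihood
every AIC-family criterion systematically over-splits; the mixture
likelihood charges each point for the uncertainty of its component
membership and is the likelihood the criteria are defined for.  Each
criterion votes for its minimizing k and the k holding at least three of
the five votes wins; failing a 3-vote consensus, plurality wins with
ties broken toward smaller k (parsimony).

The search over contiguous segments of the position-sorted list is exact:
it enumerates, implicitly, all C(n-1, k-1) such partitions, and any
optimal hard Gaussian clustering on a line is contiguous.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from ._utils import round_half_up
from .compendium import QTLRecord
from .map_projection import GeneticMap

#: 95% two-sided Gaussian quantile used throughout (CI width = 3.92 sigma).
Z95 = 1.96

CRITERIA = ("AIC", "AICc", "AIC3", "BIC", "AWE")

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class QTLObservation:
    """One projected QTL as seen by the meta-analysis."""

    qtl_id: str
    x: float
    sigma: float
    trait: str

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"{self.qtl_id}: sigma must be positive")


@dataclass(frozen=True)
class ChromosomeQTLSet:
    """Position-sorted QTL observations on one chromosome."""

    chromosome: int
    items: tuple[QTLObservation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "items", tuple(sorted(self.items, key=lambda o: (o.x, o.qtl_id)))
        )

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class ClusterFit:
    mu: float
    se: float
    loglik: float
    member_qtl_ids: tuple[str, ...]


@dataclass(frozen=True)
class PartitionModel:
    k: int
    #: (start, end) half-open index ranges over the sorted items
    boundaries: tuple[tuple[int, int], ...]
    clusters: tuple[ClusterFit, ...]
    loglik: float


@dataclass(frozen=True)
class CriteriaTable:
    """Information-criterion values per candidate k, the votes, and the winner."""

    rows: Mapping[int, Mapping[str, float]]
    criterion_choice: Mapping[str, int]
    votes: Mapping[int, int]
    chosen_k: int


@dataclass(frozen=True)
class MQTL:
    """A consensus locus: ML position, 95% CI and its member QTLs."""

    mqtl_id: str
    chromosome: int
    position: float
    ci_lo: float
    ci_hi: float
    trait_class: str
    n_members: int
    member_qtl_ids: tuple[str, ...] = ()
    se: float | None = None
    flank_left: str | None = None
    flank_right: str | None = None
    physical_lo: int | None = None   # bp, filled by physical anchoring
    physical_hi: int | None = None

    def __post_init__(self) -> None:
        if self.ci_lo > self.ci_hi:
            raise ValueError(f"{self.mqtl_id}: ci_lo must be <= ci_hi")
        if self.n_members < 1:
            raise ValueError(f"{self.mqtl_id}: an MQTL needs >= 1 member QTL")

    @property
    def ci_width(self) -> float:
        return self.ci_hi - self.ci_lo


def sd_from_ci(ci_lo: float, ci_hi: float) -> float:
    """Standard deviation implied by a 95% CI (width / 3.92)."""
    width = ci_hi - ci_lo
    if width <= 0:
        raise ValueError(f"CI width must be positive, got {width}")
    return width / (2.0 * Z95)


def cluster_mle(xs: Sequence[float], sigmas: Sequence[float]) -> tuple[float, float, float]:
    """ML position, its standard error and the log-likelihood of one cluster."""
    x = np.asarray(xs, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    if x.size == 0 or x.size != s.size:
        raise ValueError("xs and sigmas must be equal-length and non-empty")
    if np.any(s <= 0):
        raise ValueError("sigmas must be positive")
    w = 1.0 / s**2
    mu = float(np.sum(w * x) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    loglik = float(np.sum(-0.5 * _LOG_2PI - np.log(s) - 0.5 * w * (x - mu) ** 2))
    return mu, se, loglik


class _SegmentScorer:
    """O(1) weighted-Gaussian segment log-likelihoods via prefix sums."""

    def __init__(self, xs: np.ndarray, sigmas: np.ndarray):
        w = 1.0 / sigmas**2
        self.cw = np.concatenate(([0.0], np.cumsum(w)))
        self.cwx = np.concatenate(([0.0], np.cumsum(w * xs)))
        self.cwx2 = np.concatenate(([0.0], np.cumsum(w * xs**2)))
        const = -0.5 * _LOG_2PI - np.log(sigmas)
        self.cconst = np.concatenate(([0.0], np.cumsum(const)))

    def loglik(self, i: int, j: int) -> float:
        """Log-likelihood of items [i, j) as one cluster at its ML mean."""
        sw = self.cw[j] - self.cw[i]
        swx = self.cwx[j] - self.cwx[i]
        swx2 = self.cwx2[j] - self.cwx2[i]
        quad = max(swx2 - swx * swx / sw, 0.0)  # clip tiny negative round-off
        return (self.cconst[j] - self.cconst[i]) - 0.5 * quad

    def mu_se(self, i: int, j: int) -> tuple[float, float]:
        sw = self.cw[j] - self.cw[i]
        return (self.cwx[j] - self.cwx[i]) / sw, math.sqrt(1.0 / sw)


def _dp_partitions(
    xs: np.ndarray, sigmas: np.ndarray, kmax: int
) -> tuple[_SegmentScorer, np.ndarray, np.ndarray]:
    """Best contiguous partition for every k = 1..kmax by dynamic programming.

    Returns (scorer, best, back) where best[k, j] is the maximal total
    log-likelihood of splitting the first j items into k segments and back
    holds the split points for reconstruction.
    """
    n = xs.size
    scorer = _SegmentScorer(xs, sigmas)
    seg = np.full((n + 1, n + 1), -np.inf)
    for i in range(n):
        for j in range(i + 1, n + 1):
            seg[i, j] = scorer.loglik(i, j)
    best = np.full((kmax + 1, n + 1), -np.inf)
    back = np.zeros((kmax + 1, n + 1), dtype=int)
    best[0, 0] = 0.0
    for k in range(1, kmax + 1):
        for j in range(k, n + 1):
            cand = best[k - 1, k - 1:j] + seg[k - 1:j, j]
            m = int(np.argmax(cand))
            best[k, j] = cand[m]
            back[k, j] = m + k - 1
    return scorer, best, back


def _reconstruct(back: np.ndarray, k: int, n: int) -> list[tuple[int, int]]:
    bounds: list[tuple[int, int]] = []
    j = n
    for kk in range(k, 0, -1):
        i = int(back[kk, j])
        bounds.append((i, j))
        j = i
    bounds.reverse()
    return bounds


def best_partition(qset: ChromosomeQTLSet, k: int) -> PartitionModel:
    """Optimal partition of the sorted QTLs into ``k`` contiguous clusters."""
    n = len(qset)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    xs = np.array([o.x for o in qset.items])
    sigmas = np.array([o.sigma for o in qset.items])
    scorer, best, back = _dp_partitions(xs, sigmas, k)
    bounds = _reconstruct(back, k, n)
    clusters = []
    for i, j in bounds:
        mu, se = scorer.mu_se(i, j)
        clusters.append(ClusterFit(
            mu=mu, se=se, loglik=scorer.loglik(i, j),
            member_qtl_ids=tuple(o.qtl_id for o in qset.items[i:j]),
        ))
    return PartitionModel(
        k=k, boundaries=tuple(bounds), clusters=tuple(clusters),
        loglik=float(best[k, n]),
    )


def mixture_loglik(
    xs: Sequence[float], sigmas: Sequence[float],
    mus: Sequence[float], weights: Sequence[float],
) -> float:
    """Observed-data log-likelihood of a k-component Gaussian location mixture.

    Component c has mean ``mus[c]`` and mixing proportion ``weights[c]``;
    observation i keeps its own known sigma.  This is the likelihood the
    information criteria score: unlike the hard-assignment likelihood it
    does not reward a model merely for carving off its best split point.
    """
    x = np.asarray(xs, float)[:, None]
    s = np.asarray(sigmas, float)[:, None]
    mu = np.asarray(mus, float)[None, :]
    logw = np.log(np.asarray(weights, float))[None, :]
    comp = logw - 0.5 * _LOG_2PI - np.log(s) - 0.5 * ((x - mu) / s) ** 2
    return float(logsumexp(comp, axis=1).sum())


def information_criteria(
    loglik: float, k: int, n: int, n_params: int | None = None
) -> dict[str, float]:
    """AIC-family criteria for a k-cluster model of n observations.

    The default free-parameter count is the mixture convention
    p = 2k - 1 (k component means plus k - 1 mixing proportions; the
    per-observation variances are known, not fitted); pass ``n_params``
    to use another convention.  AICc is infinite when its small-sample
    correction denominator n - p - 1 is non-positive.  AWE uses the
    Banfield-Raftery penalty 2p(3/2 + ln n).
    """
    if n < 1 or not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    p = 2 * k - 1 if n_params is None else n_params
    if p < 1:
        raise ValueError("n_params must be >= 1")
    aic = -2.0 * loglik + 2.0 * p
    aicc = aic + 2.0 * p * (p + 1) / (n - p - 1) if n - p - 1 > 0 else math.inf
    return {
        "AIC": aic,
        "AICc": aicc,
        "AIC3": -2.0 * loglik + 3.0 * p,
        "BIC": -2.0 * loglik + p * math.log(n),
        "AWE": -2.0 * loglik + 2.0 * p * (1.5 + math.log(n)),
    }


def select_k(
    rows: Mapping[int, Mapping[str, float]]
) -> tuple[int, dict[int, int], dict[str, int]]:
    """Vote over candidate k: each criterion backs its minimizing k.

    Ties within a criterion go to the smallest k.  The chosen k is the one
    holding >= 3 of the 5 votes; with no such consensus, plurality wins
    and remaining ties again go to the smallest k.
    """
    ks = sorted(rows)
    choice: dict[str, int] = {}
    for crit in CRITERIA:
        vals = [(rows[k][crit], k) for k in ks]
        finite = [(v, k) for v, k in vals if math.isfinite(v)]
        pool = finite if finite else vals
        best_val = min(v for v, _ in pool)
        choice[crit] = min(k for v, k in pool if v == best_val)
    votes = Counter(choice.values())
    consensus = [k for k, c in votes.items() if c >= 3]
    if consensus:
        chosen = consensus[0]
    else:
        top = max(votes.values())
        chosen = min(k for k, c in votes.items() if c == top)
    return chosen, dict(votes), choice


def _trait_class(traits: Iterable[str]) -> str:
    ts = set(traits)
    return "PH, EH" if ts == {"PH", "EH"} else next(iter(ts))


def _flanks(
    reference: GeneticMap | None, chromosome: int, ci_lo: float, ci_hi: float
) -> tuple[str | None, str | None]:
    """Reference-map markers delimiting the CI: last marker at or left of
    ci_lo and first marker at or right of ci_hi (terminal markers when the
    CI reaches past the map end)."""
    if reference is None or chromosome not in reference.chromosomes:
        return None, None
    mk = reference.markers(chromosome)
    left = mk[0][0]
    for name, pos in mk:
        if pos <= ci_lo:
            left = name
        else:
            break
    right = mk[-1][0]
    for name, pos in reversed(mk):
        if pos >= ci_hi:
            right = name
        else:
            break
    return left, right


def meta_analyze_chromosome(
    qset: ChromosomeQTLSet,
    kmax: int | None = None,
    reference: GeneticMap | None = None,
    id_prefix: str = "MQTL",
) -> tuple[list[MQTL], CriteriaTable]:
    """Full meta-analysis of one chromosome: model scan, vote, MQTL estimation.

    Runs the exact partition search for every k up to ``kmax`` (default
    min(n, 10)), scores the five criteria, selects k by vote, and converts
    each cluster of the winning model into an MQTL with position mu and CI
    mu +/- 1.96 se.  MQTLs are indexed left to right as
    ``{id_prefix}{chromosome}-{index}``.
    """
    n = len(qset)
    if n == 0:
        raise ValueError("empty chromosome QTL set")
    kmax = min(n, 10) if kmax is None else min(kmax, n)
    xs = np.array([o.x for o in qset.items])
    sigmas = np.array([o.sigma for o in qset.items])
    scorer, best, back = _dp_partitions(xs, sigmas, kmax)
    rows = {}
    for k in range(1, kmax + 1):
        bounds = _reconstruct(back, k, n)
        mus = [scorer.mu_se(i, j)[0] for i, j in bounds]
        weights = [(j - i) / n for i, j in bounds]
        rows[k] = information_criteria(mixture_loglik(xs, sigmas, mus, weights), k, n)
    chosen_k, votes, choice = select_k(rows)
    table = CriteriaTable(rows=rows, criterion_choice=choice, votes=votes, chosen_k=chosen_k)

    mqtls: list[MQTL] = []
    for idx, (i, j) in enumerate(_reconstruct(back, chosen_k, n), start=1):
        members = qset.items[i:j]
        mu, se = scorer.mu_se(i, j)
        ci_lo, ci_hi = mu - Z95 * se, mu + Z95 * se
        # inverse-variance pooling can only sharpen: 2*1.96*se <= 3.92*min(sigma)
        assert 2 * Z95 * se <= 2 * Z95 * min(o.sigma for o in members) + 1e-9
        left, right = _flanks(reference, qset.chromosome, ci_lo, ci_hi)
        mqtls.append(MQTL(
            mqtl_id=f"{id_prefix}{qset.chromosome}-{idx}",
            chromosome=qset.chromosome,
            position=mu, ci_lo=ci_lo, ci_hi=ci_hi, se=se,
            trait_class=_trait_class(o.trait for o in members),
            n_members=len(members),
            member_qtl_ids=tuple(o.qtl_id for o in members),
            flank_left=left, flank_right=right,
        ))
    return mqtls, table


def observations_from_records(
    records: Sequence[QTLRecord],
) -> dict[int, ChromosomeQTLSet]:
    """Group completed/projected records into per-chromosome observation sets."""
    by_chrom: dict[int, list[QTLObservation]] = {}
    for r in records:
        if not r.has_ci:
            raise ValueError(f"{r.qtl_id}: record lacks a CI; run complete_cis first")
        by_chrom.setdefault(r.chromosome, []).append(QTLObservation(
            qtl_id=r.qtl_id, x=r.position,
            sigma=sd_from_ci(r.ci_lo, r.ci_hi),  # type: ignore[arg-type]
            trait=r.trait,
        ))
    return {
        chrom: ChromosomeQTLSet(chromosome=chrom, items=tuple(obs))
        for chrom, obs in sorted(by_chrom.items())
    }


def meta_analyze(
    records: Sequence[QTLRecord],
    kmax: int | None = None,
    mode: str = "pooled",
    reference: GeneticMap | None = None,
) -> tuple[list[MQTL], dict[int, CriteriaTable]]:
    """Meta-analyze a projected compendium across chromosomes.

    ``mode='pooled'`` analyzes PH and EH QTLs together per chromosome (the
    trait class of each MQTL then reflects its members); ``'per-trait'``
    runs each trait separately, with MQTL ids prefixed by the trait.
    """
    if mode not in {"pooled", "per-trait"}:
        raise ValueError(f"mode must be 'pooled' or 'per-trait', got {mode!r}")
    mqtls: list[MQTL] = []
    tables: dict = {}
    if mode == "pooled":
        for chrom, qset in observations_from_records(records).items():
            found, table = meta_analyze_chromosome(qset, kmax=kmax, reference=reference)
            mqtls.extend(found)
            tables[chrom] = table
    else:
        for trait in ("PH", "EH"):
            subset = [r for r in records if r.trait == trait]
            for chrom, qset in observations_from_records(subset).items():
                found, table = meta_analyze_chromosome(
                    qset, kmax=kmax, reference=reference, id_prefix=f"{trait}_MQTL"
                )
                mqtls.extend(found)
                tables[(trait, chrom)] = table
    return mqtls, tables


@dataclass(frozen=True)
class MQTLSummary:
    n_mqtls: int
    per_chromosome: Mapping[int, int]
    ci_width_min: float
    ci_width_mean: float
    ci_width_max: float
    member_total: int
    members_min: int
    members_max: int
    trait_class_counts: Mapping[str, int]


def mqtl_summary(mqtls: Sequence[MQTL]) -> MQTLSummary:
    """Descriptive statistics over a set of MQTLs (cM values rounded to 2 dp)."""
    if not mqtls:
        raise ValueError("empty MQTL list")
    widths = [m.ci_width for m in mqtls]
    members = [m.n_members for m in mqtls]
    return MQTLSummary(
        n_mqtls=len(mqtls),
        per_chromosome=dict(sorted(Counter(m.chromosome for m in mqtls).items())),
        ci_width_min=round_half_up(min(widths)),
        ci_width_mean=round_half_up(sum(widths) / len(widths)),
        ci_width_max=round_half_up(max(widths)),
        member_total=sum(members),
        members_min=min(members),
        members_max=max(members),
        trait_class_counts=dict(Counter(m.trait_class for m in mqtls)),
    )
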