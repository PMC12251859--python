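# Methods

## Statistical model

The meta-analysis treats each projected QTL on a chromosome as a noisy
observation of one of *k* underlying consensus loci:

    x_i | z_i = c  ~  Normal(mu_c, sigma_i^2),

where `x_i` is the reported peak (cM on the consensus map) and `sigma_i`
is known per observation, derived from the QTL's 95% CI as
`sigma_i = width_i / 3.92` (a 95% Gaussian interval is ±1.96 sd; the
constant 1.96 is used throughout rather than a recomputed quantile, so
CI ↔ sd conversions are exactly inverse).  The model assumes
independence across studies, no systematic projection bias, and
correctly calibrated member CIs.

**Estimation.**  For a fixed assignment, the ML estimate of a cluster
position is the inverse-variance weighted mean, with
`se = (Σ 1/σ_i²)^(-1/2)`.  Since `se² ≤ min σ_i²`, an MQTL's 95% CI can
never be wider than its most precise member's CI — this is asserted at
run time on every analysis.

**Partition search.**  Assignments are hard and restricted to contiguous
segments of the position-sorted observations; the optimum over all
C(n−1, k−1) such partitions is found exactly by dynamic programming with
prefix-sum segment scores (O(n²) score table, O(k·n²) recursion).  For
1-D Gaussian location clustering with per-point variances, an optimal
hard clustering is contiguous in position, so nothing is lost by the
restriction.  Exactness is tested against brute-force enumeration.

**Model selection.**  Five criteria — AIC, AICc, AIC3, BIC and AWE (the
Banfield–Raftery form `−2L + 2p(3/2 + ln n)`) — are computed for
k = 1..kmax; each votes for its minimizing k (ties toward smaller k),
and the k holding at least three votes is chosen.  If no k reaches three
votes, plurality wins, ties again toward smaller k (parsimony).  AICc is
set to +∞ when its correction denominator `n − p − 1` is non-positive;
if every candidate k is infinite under a criterion, that criterion falls
back to voting for the smallest k.

Two scoring choices deserve emphasis, because the design was genuinely
open:

- **Likelihood scored by the criteria.**  The criteria are evaluated on
  the observed-data likelihood of the Gaussian mixture implied by the
  fitted partition (component means from the partition, mixing
  proportions equal to cluster occupancies), *not* on the maximized
  hard-assignment likelihood.  The hard-assignment likelihood grows with
  k through best-split selection — each extra cluster gets to carve off
  whichever boundary most improves the fit — and under it every
  AIC-family criterion systematically over-splits (in simulation with
  three well-separated true loci, the vote recovered k = 3 in under 5%
  of replicates).  The mixture likelihood charges each observation for
  the uncertainty of its component membership, which is the likelihood
  these criteria are defined for; with it the same vote recovers the
  true k in ≈ 99% of replicates.
- **Free-parameter count** `p = 2k − 1`: k component means plus k − 1
  mixing proportions (per-observation variances are known, not fitted).
  `information_criteria` accepts an `n_params` override for other
  conventions.

## Confidence-interval imputation

Missing 95% CIs are imputed from population design, size N and PVE via
the Darvasi–Soller approximations `530/(N·R²)` (F2-like segregating
families: F2, BC, F2:3, F3, F4) and `163/(N·R²)` (homozygous immortal
designs: RIL, DH).  Three conventions are deliberate:

- PVE enters as the variance proportion `R² = pve_percent/100`.
  With N = 200 and PVE = 10% this gives 26.5 cM — a realistic width —
  whereas feeding the raw percentage would give 0.265 cM.
- F2-derived selfed families use the F2 constant; DH, like RIL, is an
  immortal homozygous design and uses the RIL constant.
- Imputed intervals are centered on the peak and the lower bound is
  floored at 0 cM without shifting the upper bound, so the peak always
  stays inside the interval.

QC thresholds (PVE < 1%, LOD < 1.5) are strict inequalities; records
missing both statistics cannot be evaluated and are kept with a logged
warning.

## Projection

Peak and both CI bounds are projected independently, each through the
tightest pair of shared markers bracketing it (pairs may differ per
point); a point exactly on a shared marker maps to that marker's
reference position (fixed point, to machine precision).  There is no
extrapolation: a point outside the shared-marker span fails the whole
QTL with `no_common_flank`, mirroring how literature QTLs are lost when
maps share too few markers.  If a local anchor pair is order-reversed on
the reference, the affine map reverses orientation; projected CI bounds
are re-sorted and the peak clamped into the sorted interval, so every
projected QTL satisfies lo ≤ peak ≤ hi even through locally inverted
map regions.  Extreme per-interval scale factors are not clamped.

`map_summary` counts (markers − chromosomes) inter-marker intervals when
averaging; chromosomes with fewer than two markers are excluded.

## Physical anchoring

cM → bp conversion interpolates piecewise-linearly across *all* anchors
of a chromosome rather than looking up only the CI's flanking markers;
this degrades gracefully when a flanking marker lacks a physical
position (the interpolation simply uses the nearest informative
anchors).  Endpoints beyond the anchored span clamp to the terminal
anchors.  Anchors violating cM/bp monotonicity are flagged but used as
given; duplicate-cM anchors collapse to the first.  Gene overlap uses
closed, 1-based inclusive intervals: a gene abutting an interval
boundary by a single base is included.  Functional classification is a
keyword tally (case-insensitive substring match) against a packaged
term → category table; it is a descriptive tally, not an enrichment
test — no ontology, background set or p-values are involved.

## Synthetic scenarios

The generator emulates the statistical structure of a 13-study maize
PH/EH compendium:

| parameter | default | rationale |
|---|---|---|
| chromosomes × length | 3 × 300 cM | enough to exercise per-chromosome analysis cheaply |
| true loci | 50, 150, 250 cM | three well-separated major loci (≥ 40 cM apart) |
| study panel | 13 studies: 4 F2, 3 F2:3, F3, F4, 3 RIL, DH; N = 120–271 | mirrors the designs/sizes of the published panel |
| QTLs per locus | 8 (detection prob. 8/13 per study × locus) | typical replication of a major locus across a compendium |
| PVE | Uniform(3.23, 31.93) % | the published per-QTL PVE range |
| LOD | 2.5 + 0.45·PVE + N(0, 0.5), floored at 1.6 | invented coupling reproducing the published 2.5–20.5 range qualitatively |
| reference marker spacing | ~5 cM (jittered) | dense IBM2-like scaffold |
| study maps | keep ≈ spacing ratio of markers; per-interval log-normal length jitter (sd 0.15) | sparser, length-distorted study maps |
| CI omitted | 30% of records | exercises downstream imputation |

Peak noise is tied to the Darvasi–Soller width (`sd = width/3.92`, drawn
in the study's own map coordinates), so simulated CIs are calibrated 95%
intervals — exactly the self-consistency the meta-analysis assumes.
Setting `position_noise_scale = 0` and study jitter 0 gives the
noiseless limit, in which the pipeline must (and does) recover every
true position to ≈ 1e−13 cM.

What the generator does **not** emulate: genotype/phenotype simulation
and actual QTL mapping, marker-order conflicts between maps (marker
order is always a sub-order of the reference), correlated detection
across studies, trait-specific architecture (each QTL's trait is an
independent coin flip), and duplicated reporting of one QTL across
papers.  Passing recovery tests therefore show the estimator chain is
correct and calibrated under the stated model — not that real
compendia satisfy that model.

## Numerical choices

- Weighted segment log-likelihoods use prefix sums with a clip of tiny
  negative round-off in the quadratic term; DP vs brute-force agreement
  is asserted to 1e−9.
- Reported cM/Mb summary values round to 2 decimals, half-up (matching
  how published tables round), via `decimal` arithmetic.
- Criterion vote ties and no-consensus fallbacks resolve toward smaller
  k; within-criterion ties pick the smallest minimizing k.
- `kmax` defaults to min(n, 10) per chromosome.
- All generators are pure functions of (config, seed); scenario
  sub-seeds derive from one root generator in a fixed order.

## Pooled vs per-trait analysis

By default PH and EH QTLs are pooled per chromosome and each MQTL's
trait class is the union of its members (rendered `PH, EH` when mixed),
since consensus regions frequently control both traits.  A `per-trait`
mode runs the two traits separately (MQTL ids prefixed by trait) for
workflows that meta-analyze traits independently and merge afterward.

## Known limitations

- Consensus-map *construction* is out of scope: the reference map is
  taken as the consensus scaffold and projection targets it directly; no
  multi-map marker-order reconciliation is attempted.
- The packaged 29-MQTL reference table is transcribed as printed, and
  the printed source is not fully self-consistent: one row's position
  lies outside its own CI, and one row's physical interval (32.18 Mb)
  exceeds the summary's stated 30.08 Mb maximum.  The loaders preserve
  the rows as printed rather than "correcting" them.
- Gene classification percentages can exceed 100% in total because a
  gene may carry several tags; exclusive (first-tag) counts sum to the
  gene total.
- Hard assignment cannot represent a QTL genuinely supported by two
  overlapping loci; a soft-assignment EM mixture is deliberately not
  implemented.
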