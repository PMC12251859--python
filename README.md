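# metaqtl

Meta-QTL analysis of maize (*Zea mays* L.) plant height (PH) and ear
height (EH): a tested, reusable implementation of the full pipeline that
turns a multi-study compendium of literature QTLs into consensus loci
(MQTLs) with narrowed confidence intervals, physical coordinates and
candidate genes.

It is written for quantitative geneticists and breeders who curate QTL
results from heterogeneous bi-parental mapping experiments (F2, BC,
F2:3/F3/F4 families, RILs, DH lines, each on its own linkage map) and want
stable genomic regions for marker-assisted selection.

## What the pipeline computes

1. **Compendium QC and CI imputation** (`metaqtl.compendium`).
   QTLs with PVE < 1% or LOD < 1.5 are removed.  A missing 95% CI is
   imputed with the Darvasi–Soller population-size approximation

   ```
   width = 530 / (N · R²)    F2-derived designs (F2, BC, F2:3, F3, F4)
   width = 163 / (N · R²)    homozygous immortal designs (RIL, DH)
   ```

   where `N` is the population size and `R² = PVE/100` the proportion of
   variance explained; the interval is centered on the peak and floored
   at 0 cM.

2. **Consensus-map projection** (`metaqtl.map_projection`).
   Each QTL's CI bounds and peak are transferred onto a reference map
   (an IBM2-2008-Neighbors-like scaffold) by homothetic scaling between
   the tightest pair of shared flanking markers bracketing each point:
   `ref(x) = ref_L + (x − src_L)·(ref_R − ref_L)/(src_R − src_L)`.
   Points outside the shared-marker span are not extrapolated; such QTLs
   are reported as unprojectable.

3. **Gaussian meta-analysis** (`metaqtl.meta_analysis`).
   On each chromosome, projected peaks `x_i` with known standard
   deviations `σ_i = CI width / 3.92` are partitioned into `k` contiguous
   clusters by an exact dynamic program maximizing
   `Σ_c Σ_{i∈c} log φ(x_i; μ_c, σ_i²)`.  Each cluster's ML position is the
   inverse-variance weighted mean `μ = Σ(x_i/σ_i²)/Σ(1/σ_i²)` with
   `se = (Σ 1/σ_i²)^{-1/2}`, so the MQTL CI `μ ± 1.96·se` is never wider
   than its sharpest member's CI.  The number of loci is selected by five
   information criteria (AIC, AICc, AIC3, BIC, AWE) scored on the
   Gaussian-mixture likelihood implied by the fitted partition, each
   voting for its minimizing `k`; a `k` with ≥ 3 of the 5 votes wins.

4. **Physical anchoring and candidate genes**
   (`metaqtl.physical_anchoring`).  MQTL CIs are interpolated from cM to
   bp through a marker-anchor table, overlapping genes are pulled from a
   GFF3 annotation, and annotations are tallied into functional
   categories (hormone, cell wall, sugar, photosynthesis, cytoskeleton).

5. **Synthetic scenarios with known truth** (`metaqtl.synthetic_data`).
   A seeded generator emulates a 13-study compendium (designs and sizes
   matching the published panel, PVE ∈ [3.23, 31.93]%), study-specific
   sparser and length-distorted maps, and calibrated peak noise
   (sd = Darvasi–Soller width / 3.92), enabling end-to-end parameter
   recovery tests.

A packaged reference table (`metaqtl.datasets.load_reference_mqtls`)
carries a published 29-MQTL maize PH/EH meta-analysis result, used to
validate the pipeline's descriptive statistics.

## Worked example

```python
import metaqtl as mq

run = mq.run_scenario(mq.ScenarioConfig(seed=42))
print(f"simulated QTLs: {len(run.scenario.records)}  "
      f"kept after QC: {len(run.kept)}  projected: {run.projection_rate:.3f}")
for m in run.mqtls:
    print(f"{m.mqtl_id:9s} chr{m.chromosome}  pos {m.position:7.2f} cM  "
          f"CI [{m.ci_lo:7.2f}, {m.ci_hi:7.2f}]  members {m.n_members:2d}  {m.trait_class}")
```

prints

```
simulated QTLs: 75  kept after QC: 75  projected: 0.987
MQTL1-1   chr1  pos   50.39 cM  CI [  48.94,   51.83]  members  9  PH, EH
MQTL1-2   chr1  pos  150.03 cM  CI [ 148.73,  151.32]  members  8  PH, EH
MQTL1-3   chr1  pos  249.34 cM  CI [ 248.06,  250.61]  members  7  PH, EH
MQTL2-1   chr2  pos   50.05 cM  CI [  48.69,   51.41]  members  6  PH, EH
MQTL2-2   chr2  pos  149.38 cM  CI [ 148.51,  150.26]  members  9  PH, EH
MQTL2-3   chr2  pos  250.00 cM  CI [ 249.20,  250.81]  members  9  PH, EH
MQTL3-1   chr3  pos   50.45 cM  CI [  49.51,   51.40]  members  9  PH, EH
MQTL3-2   chr3  pos  150.81 cM  CI [ 149.60,  152.01]  members 11  PH, EH
MQTL3-3   chr3  pos  250.59 cM  CI [ 249.74,  251.45]  members  6  PH, EH
```

The scenario plants three true loci per chromosome at 50/150/250 cM;
here the pipeline recovers all nine (k correct on every chromosome, mean
absolute position error 0.40 cM, every true locus inside its MQTL CI).
Note how each MQTL CI (≈ 1–3 cM wide) is far narrower than the member
QTL CIs that produced it (typically 4–90 cM): that narrowing is the point
of meta-analysis.

The same stages are scriptable from a shell:

```
metaqtl simulate --seed 42 --outdir sim/
metaqtl qc      --in sim/qtl.csv --out kept.csv --log qc.json
metaqtl project --qtl kept.csv --maps sim/maps.tsv --reference sim/ref.tsv --out projected.csv
metaqtl meta    --in projected.csv --reference sim/ref.tsv --out mqtl.tsv --criteria criteria.json
metaqtl anchor  --mqtl mqtl.tsv --anchors sim/anchors.csv --gff sim/genes.gff3 --out genes.tsv
```

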