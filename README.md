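# idseg

Infant brain MRI segmentation of the bilateral hippocampus and amygdala on
T2-weighted scans, with the full analysis pipeline around it: multi-rater
STAPLE consensus ground truth, a multi-view 2D fully-convolutional
segmentation network with weighted probability fusion, a transfer-learning
fine-tune/LOOCV harness, a DSC/ICC/ASD evaluation suite, and a
morphometry–behavior partial-correlation stage.  A synthetic infant-brain
phantom generator makes every stage testable at desk scale without any data
download.

It is written for infant-neuroimaging researchers who need reliable
subcortical volume estimates from T2w scans — the amygdala and hippocampus
are small, strongly curved, and poorly contrasted against each other, which
defeats many atlas- and clustering-based pipelines — and for anyone who
wants a self-contained, fully seeded re-implementation of this kind of
segmentation-plus-statistics workflow.

## The model

Three identical 2D encoder–decoder networks (one per principal view) in the
QuickNAT family: four encoder stages of dense blocks (two 5×5 convolutions
with input concatenation and a 1×1 compression, each preceded by batch norm
and a shared single-parameter PReLU), 2×2 index-preserving max pooling, a
dense bottleneck, four decoder stages with max-unpooling and encoder skip
concatenation, and a 1×1 classifier.  The default configuration (64 feature
maps, 88-class pre-training head) has exactly **3,520,871** trainable
parameters per view and **10,562,613** in total.  The per-voxel label is

```
L(x) = argmax( λ1·p_axial(x) + λ2·p_coronal(x) + λ3·p_sagittal(x) ),
λ = (0.4, 0.4, 0.2)
```

Transfer protocol: pre-train on a large automatically-labelled cohort
(80/20 split), then fine-tune on a small manually-labelled target set for
5 epochs with only the last layers unfrozen followed by 15 epochs of the
whole network (lr 5·10⁻⁴, batch 8), evaluated by leave-one-out
cross-validation against an ablation arm trained from random
initialization.

Consensus ground truth: per-structure binary STAPLE (EM estimation of the
latent truth and each rater's sensitivity/specificity), with a 0.6 minimum
inter-rater Dice QC gate.  Accuracy metrics: Dice overlap, ICC(3,1) on
voxel pairs in a region of interest, and average (symmetric) surface
distance in mm.  Brain–behavior stage: TBV-adjusted regional volumes
against CBCL T scores by Spearman rank partial correlation, adjusting for
postmenstrual age at scan, maternal education, and maternal mood (EPDS).

The network and its backpropagation are implemented in NumPy with
Numba-compiled kernels; no deep-learning framework is required.

## Worked example

Simulate three raters tracing one phantom, gate them through QC, fuse them
with STAPLE, and score the consensus against the ground truth:

```python
from idseg import (PhantomSpec, RaterNoiseSpec, generate_phantom,
                   simulate_raters, consensus_multilabel, interrater_qc,
                   evaluate_pair)

vol, truth = generate_phantom(PhantomSpec(seed=7))
raters = simulate_raters(truth, k=3, noise=RaterNoiseSpec(seed=7))
print(interrater_qc(raters).to_string(index=False))
consensus = consensus_multilabel(raters)
report = evaluate_pair(consensus, truth)
print(report.frame().pivot(index="structure", columns="metric",
                           values="value").round(3))
```

```
 structure_code  mean_pairwise_dsc  n_pairs  undefined  passed
              1           0.804344        3      False    True
              2           0.732680        3      False    True
              3           0.806210        3      False    True
              4           0.686708        3      False    True
metric               asd    dsc    icc
structure
left_amygdala      0.085  0.970  0.969
left_hippocampus   0.056  0.967  0.965
right_amygdala     0.143  0.947  0.945
right_hippocampus  0.065  0.969  0.968
```

All four structures pass the 0.6 inter-rater Dice gate (codes 1/2 are the
left/right hippocampus, 3/4 the left/right amygdala; the simulated raters
are calibrated to agree at ≈ 0.76 on average).  The STAPLE consensus is far
closer to the truth than any individual rater: Dice ≈ 0.95–0.97, ICC ≈ 0.95,
and mean surface error below 0.15 mm at 0.9 mm voxels.

The behavior stage on a 50-subject synthetic cohort (the generator embeds a
negative right-amygdala association):

```python
from idseg import generate_cohort, measure_cohort, brain_behavior_matrix

cohort, table = generate_cohort(50, seed=7)
mat = brain_behavior_matrix(measure_cohort(cohort, table.frame))
print(mat[(mat.measure == "adj_right_amygdala")
          & (mat.outcome == "cbcl_total")]
      [["measure", "outcome", "rho", "df", "p"]].round(4))
```

```
           measure    outcome     rho  df      p
adj_right_amygdala cbcl_total -0.4756  45 0.0007
```

A partial rho of −0.48 with df = 45 at n = 50: larger volumes at birth track
fewer total problems at age 2 in this synthetic cohort, and 3 of the 12
volume × outcome cells are flagged at p < 0.05.  (At n = 50 the point
estimate scatters around the embedded −0.62; the acceptance run below
recovers it at n = 500.)

A `click` CLI mirrors the library (`idseg phantom`, `idseg staple`,
`idseg pretrain`, `idseg finetune`, `idseg loocv`, `idseg segment`,
`idseg evaluate`, `idseg correlate`); run `idseg --help`.

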