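# Methods

## Problem

Small-variant calling in a child–mother–father trio is usually run as three
independent per-sample analyses. That wastes the strongest prior available in
family data: at autosomal loci the child carries one allele from each parent,
so a joint caller can both borrow read evidence across the family and be
penalised for emitting genotype triples that violate Mendelian inheritance.
This package implements the core of such a trio caller at desk scale: a
Trio-to-Trio convolutional network over pileup feature tensors, a
Mendelian-constraint loss used during fine-tuning, the surrounding candidate
selection/filtering pipeline, and trio-level evaluation — all exercisable on
a built-in simulator so the method runs end to end without sequencing data.

## Genotype space

Diploid genotypes live in a 21-class space: the unordered pairs over six
allele classes {A, C, G, T, Ins, Del}. Ins and Del are opaque classes with no
length semantics — the caller decides *that* an insertion or deletion is
present, not its sequence. Classes are ordered lexicographically by the
canonical allele order (AA, AC, AG, AT, AIns, ADel, CC, …, DelDel); this
ordering is an artifact convention that only needs to be used consistently
across labels, network heads and the prior table.

For a trio genotype (child, parent1, parent2) the **mismatch count** is the
minimum, over the two ways of assigning the child's two alleles to the two
parents, of the number of child alleles absent from the assigned parent's
genotype. It is 0, 1 or 2, and symmetric under swapping the parents. The
minimum is the most permissive reading for unphased genotypes: a triple is
only called a violation when *no* assignment explains the child. Enumerating
all 21³ = 9261 triples gives 1281 consistent, 5130 one-mismatch and 2850
two-mismatch triples (regression-tested constants).

The **valid degree** β of a triple is a prior weight built from the
per-generation mutation rate μ (default 1e-8):

    β(i,j,k) = (1-μ)²  if the triple is Mendelian-consistent,
               μ       if one child allele is unexplained,
               μ²      if both are.

## Losses

Each genotype head is trained with a focal loss −(1−p_t)^γ·log(p_t), γ = 2
by default (the canonical focusing exponent; γ = 0 recovers cross-entropy).
The log is capped with a small ε.

The trio distribution is the product p_trio(i,j,k) = p_c,i·p_p1,j·p_p2,k of
the three softmax outputs, which normalizes to 1 by construction. Its
expected valid degree

    V_trio = Σ_{i,j,k} β(i,j,k) · p_c,i · p_p1,j · p_p2,k  ∈ (0, 1)

is computed in grouped form — the product mass in each of the three mismatch
classes is accumulated first, then weighted by the class's β value — which
agrees with the direct 9261-term sum to ~1e-15 and is cheap enough to run
per batch. The Mendelian penalty is

    MCVLoss = −α · log(V_trio + ε),   α = 1, ε = 1e-9 by default,

and the combined objective is the sum of the three focal terms, MCVLoss and
an L2 weight penalty. MCVLoss is averaged over the batch, matching the
focal terms' reduction (sum-vs-mean is not dictated by the loss definition;
mean keeps the α scale independent of batch size). Gradients of the penalty
with respect to the three probability rows are the β-weighted partial sums,
chained through the softmax; under the simplex constraint the descent
direction moves mass from violating to consistent triples, which is
property-tested numerically.

## Network

All architectures share a trunk: same-padded 3×3 convolution → residual
block(s) → spatial pyramid pooling (bins 1, 2, 4) → dense layer, over input
tensors of 8 feature channels × reference window × read-depth rows. Pyramid
pooling makes the dense stack independent of window/depth sizes. Heads are
per-sample 21-way genotype classifiers (optional auxiliary heads: zygosity
and two INDEL-length tasks, off by default — the Mendelian penalty acts only
on the genotype heads).

* **One-to-One** consumes a single sample's tensor and predicts that sample.
* **Trio-to-One** consumes the trio-stacked tensor and predicts one member
  (a child model and a parent model are trained separately when all three
  members are needed).
* **Trio-to-Trio** consumes the trio-stacked tensor and predicts all three
  members from one model, in four shapes: **A** splits only the final dense
  layer into three heads (default); **B** gives each member its own dense
  stack; **C** runs the trunk per sample with shared weights and concatenates
  before the dense layers; **D** adds an extra shared residual block before
  the split. Shape A has the fewest parameters (A < D < C < B, frozen as a
  regression test).

Trio stacking concatenates the three samples' read rows within each of the
8 channels, in fixed family order child → parent1 → parent2, so per-channel
semantics are preserved while the depth axis triples.

The engine is a small numpy layer library with explicit backward passes and
Adam; float32 throughout (verified against finite differences in float64).
This keeps the whole package importable with a scientific-Python base stack
and is entirely adequate at the problem sizes the package targets.

## Simulator

The simulator stands in for the upstream alignment/pileup stack and defines
the study conditions:

* Per site, an alt allele frequency is drawn (default uniform on
  (0.05, 0.95), exercising all Hardy–Weinberg genotype mixes at candidate
  sites); parents are drawn from Hardy–Weinberg at that frequency; the child
  inherits one uniformly chosen allele per parent. Each transmitted allele
  mutates to the site's other allele with probability `denovo_rate`, so the
  expected fraction of sites with a de novo event is 1−(1−m)². Note the
  *genotype-level* violation fraction is strictly smaller: a mutated allele
  can coincide with an allele the parent happens to carry.
* Sites are biallelic, SNPs by default with a 10% INDEL fraction (Ins/Del
  classes), so all 21 genotype classes occur.
* Reads: Poisson(coverage) per sample, capped at the tensor's depth rows by
  subsampling; each read carries one of the sample's two alleles and is
  miscalled per base with probability `base_error` (default 0.05, an
  ONT-scale rate). The 8 channels are reference base, read base, base
  quality, mapping quality, strand, insertion flag, deletion flag and
  haplotype tag. Allele identities are encoded as scalars centred on
  [−1, 1]; a zero-mean spread conditions the convolutional stack much better
  than a one-sided encoding. The haplotype tag is perfectly phased —
  phasing itself is out of scope.
* Coverage presets mirror a training scheme in which the child is kept at
  high coverage (10/30/60/80×) and only parents are downsampled.

What the simulator does **not** model: homopolymer-dependent ONT error,
alignment artifacts, imperfect phasing, multiallelic sites, structural
variants, population LD structure. Passing tests therefore demonstrate the
machinery and its qualitative behaviour, not real-data accuracy.

## Pipeline

Candidate selection keeps, per sample, every upstream variant call with alt
allele fraction > 0.08 plus the lowest-quality 20% stratum of reference
calls ("low quality" is defined as the bottom quality quantile, which makes
the draw deterministic and seedable), then unites candidates across the
family so every member is genotyped at every union site. Training labels are
purged of Mendelian-violating sites before fitting.

Training is two-step: stage 1 optimizes the focal terms alone (α forced to
0) at learning rate 1e-3; stage 2 fine-tunes from the stage-1 weights with
MCVLoss enabled at 1e-5. The optimizer is Adam with seeded shuffling;
divergence (non-finite loss) aborts with a checkpoint of the last finite
state. Calls take the argmax genotype per site per member; QUAL is the
Phred-scaled residual (1 − max probability), capped at 60. Predicted alleles
outside the site's REF/ALT context extend the ALT list (bases as
substitutions, Ins as an anchored insertion, Del as the anchored deletion or
symbolic `<DEL>` when the REF is a single base).

## Evaluation

The three per-sample VCFs are merged at the union of their sites; a member
without a record at a site is treated as homozygous reference for violation
counting (mirroring the common merge-with-`-0` workflow) but as *unknown*
for the de novo definition. Violations are counted over all merged sites
under the 21-class predicate, with a pattern histogram keyed by
(parent1, parent2, child) GT strings. De novo candidates are child ref/alt
het calls above a QUAL gate with both parents homozygous-reference or
unknown, optionally restricted to confident BED regions, and scored against
the simulator's per-site de novo flag. Precision/recall/F1 use exact
position + allele + genotype matching with an SNP/INDEL split;
representation-aware matching is unnecessary because the simulator and
caller emit left-aligned biallelic records. Half-called genotypes are
treated as missing.

## The scaled study

The end-to-end experiment (`trionet.experiments.TrioStudy`, also driven by
`scripts/acceptance.py`) simulates 50 000 sites at child 30× / parents 15×
with de novo rate 1e-3, renders window-5 × 12-row tensors, trains a Model-A
network on 14 000 Mendelian-clean sites (8 epochs stage 1, 2 epochs
fine-tuning, batch 32) and holds out 6 000 sites. Arms: fine-tuning at
α ∈ {0, 1, 10} from the same stage-1 weights, and a One-to-One ablation
trained on the pooled per-member blocks subsampled to the same example
count. Problem sizes were chosen so the whole study trains in minutes on one
CPU core while leaving the qualitative contrasts (violations fall when the
penalty is enabled and when the model sees the whole family) clearly
measurable. Held-out genotype F1 is exact-match F1 pooled over the three
members.

## Known limitations

* The read model is deliberately simple; absolute F1 numbers on simulated
  data say nothing quantitative about real ONT data.
* Trunk widths, kernel sizes and tensor dimensions are desk-scale choices,
  far smaller than a production caller's.
* Sex chromosomes (haploid inheritance), multi-generation pedigrees and
  gVCF output are out of scope.
* The Trio-to-One parent model shares the child model's architecture; which
  member's head it emits is a configuration choice.
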