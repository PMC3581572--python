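# Methods

## Scope and intent

`orthosim` reproduces, at desk scale, a simulation pipeline for
benchmarking orthology inference: genome evolution with known history,
baseline inference (BBH, RSD), exact truth extraction, and
precision/recall scoring. This note records the models, the parameter
choices and their rationale, the numerical decisions, and what the
simulations do and do not show about real data.

## Species trees

Branch lengths are interpreted directly as PAM distances (1 PAM = 1
expected substitution per 100 sites); all event rates are expressed per
PAM, which ties gene-level and sequence-level processes to a single clock.

The benchmark's species-tree regimes are characterised by summary
statistics (leaf count, total length, min/mean/max root-to-leaf height,
mean pairwise leaf distance) rather than fixed topologies. Six regimes are
shipped: three "bacteria-like" (G1–G3; 30 species, total lengths
763.6/831.0/945.6 PAM) and three "mammalia-like" (M1–M3; 20 species,
totals 101.2/119.9/57.59 PAM). `surrogate_tree` draws a pure-birth (Yule)
topology — with a final exponential holding time so terminal branches are
never zero — applies mild lognormal rate jitter (σ = 0.25 per branch) so
trees are not exactly ultrametric, and rescales all branches so that *one*
chosen statistic (total length by default, or mean height) matches the
target exactly. A rescale-and-reject loop enforces the sampling constraint
that every leaf pair is ≥ 1 PAM apart. One statistic is matched exactly
rather than all simultaneously because a single birth–death shape cannot
generally achieve a prescribed height-to-length ratio; the achieved
statistics are always returned alongside the tree so the user can see the
residual mismatch. Calibration experiments that depend on event *rates
along lineages* match mean height; experiments that depend on *total
evolutionary opportunity* (e.g. indel accumulation) match total length.

## Substitution model

The WAG empirical amino-acid model, with the published exchangeabilities S
and stationary frequencies π shipped as a plain-text data file
(`src/orthosim/data/wag.txt`, format documented in its header). The rate
matrix is Q = S·diag(π) with the diagonal set for zero row sums, globally
rescaled so −Σᵢ πᵢ Qᵢᵢ = 0.01 — exactly one expected substitution per 100
sites per PAM. WAG is reversible, so Q is symmetrised by the π^(1/2)
similarity transform and eigendecomposed once; every transition matrix
P(d) = exp(Qd) used in simulation, scoring-matrix construction and
likelihood evaluation comes from that one decomposition (verified against
`scipy.linalg.expm` to 1.4·10⁻¹⁵, Chapman–Kolmogorov to the same order).

Sites evolve independently and identically: no among-site or among-family
rate variation, by design. Branch evolution samples each site's new
residue directly from its row of P(b) — the exact marginal — rather than
simulating intermediate jumps, which would only matter if intermediate
states were observed.

## Gene-level events

Duplication, loss and transfer are independent Poisson processes per gene
lineage per PAM. Because a transfer couples two lineages that may sit on
different species branches, each family is simulated with an event queue
on a global clock, where "time" is depth from the root in PAM. A
duplication copies one gene in place; a loss terminates the lineage; a
transfer picks a recipient among species branches whose depth interval
spans the event depth (the donor's own branch excluded, chosen uniformly
by branch, then uniformly among the family's resident copies), terminates
the recipient's copy (logged as `replaced`), and attaches the transferred
lineage as the second child of a transfer node. If no eligible recipient
carries a copy of the family — prior loss, or no contemporaneous branch —
the transfer is skipped and logged; LGT is strictly orthologous
replacement, never a de-novo gain. Contemporaneity via depth-from-root is
the simplest well-defined rule on non-ultrametric trees; skipped transfers
are rare in practice (≲ 1% of attempts at benchmark rates).

**Event-background counting.** The calibration quantity "x% of genes with
a duplication (transfer) background" counts extant genes whose unpruned
root-to-leaf lineage passes the *new copy* side of at least one event —
the gene "arose by" duplication or transfer. With this one-sided marking
the expected background is exactly 1 − exp(−λ·h̄) for mean tree height h̄
(each surviving path encounters marked events at backward rate λ), which
is what makes rate 0.0065 on a height-17.48 tree a ~10% duplication
background and rate 0.0025 on a height-41.36 tree a ~10% transfer
background. Marking both children of an event would double the backward
rate and the measured background (~21% at the same rates; verified
numerically), so it is not what the published rate tables were tuned to.
Counters are carried on lineages during simulation, so events whose
sibling subtree was later lost still count.

Setting λ_loss = λ_dup keeps genome sizes roughly constant (a critical
birth–death process); this is asserted to within 10% in the tests.

## Sequences, indels and the true alignment

Root genomes hold one stationary sequence per family, with integer lengths
drawn from a gamma distribution and redrawn until ≥ 50 residues. The
published regime descriptions give only summary magnitudes for lengths, so
the defaults are mean 320 / sd 190 residues (bacteria-like) and 480 / 330
(mammalia-like) — plausible proteome-scale values, configurable, and only
weakly coupled to the benchmark outcomes.

Along each gene-tree branch of length b, indel events are placed by
Gillespie sampling with total rate (r_ins + r_del)·L(t) per PAM, L(t)
being the current length, insertion vs deletion chosen proportionally to
the rates. Indel lengths are Zipf, P(ℓ) ∝ ℓ^(−c) on {1..L_max} with
c = 1.821 and L_max = 50 (the classical empirical indel-length exponent;
both configurable). Insertions draw stationary content and a uniform
position; deletions draw a uniform start and truncate at the sequence end.
Substitutions are then applied over the full branch length. A sequence
that shrinks below one residue is kept, flagged degenerate, and logged.

Every insertion allocates fresh columns in a per-family master column
order (a doubly linked list); each lineage's residues remain a subsequence
of that order, so after simulation the exact multiple alignment of the
extant members is read off directly. Stripping gaps from any alignment
row reproduces the stored gene sequence byte for byte (asserted in tests).
Evolution along the stem above the first surviving bifurcation is skipped:
shared history above the root of the extant family changes neither
pairwise divergences nor the alignment.

At the default indel rate (1.25·10⁻⁴ per site per PAM, each direction),
trees rescaled to the G1 and M1 total lengths yield true-alignment gap
contents of ~24% and ~4% respectively — the two published gap statistics —
with no further tuning; this is an emergent check on the indel machinery,
tree scaling and alignment bookkeeping together.

## Artefacts

Sequencing/assembly error is modelled as one contiguous `X` run per gene:
a proportion p ~ Normal(μ, σ) clamped to [0, 1], stretch length
round(p·L) (round-half-to-even for determinism), start uniform among
valid placements. The published description fixes σ to a value not
legible in the source, so the default is σ = μ/3, which keeps clamping
rare across the μ = 0.06–0.18 range; σ is an explicit parameter
everywhere. Masking is copy-on-write: trees, alignments and the event log
are shared with the unmasked dataset, since masking does not alter
history. Genes with p ≤ 0 are left unmasked and logged.

## Inference baselines

All-vs-all local alignment uses Smith–Waterman with affine gaps
(open 12, extend 2, in half-bit units; a length-k gap costs
12 + 2(k−1)). The scoring matrix is derived from the simulator's own
substitution process: M[a,b] = round(2·log₂(P_ab(d*)/π_b)) at reference
distance d* = 120 PAM — internally consistent with the data-generating
model, in the spirit of classical PAM-series matrices. The alignment
engine is Biopython's `PairwiseAligner` (C implementation); its scores are
verified exactly against exhaustive enumeration of all local alignments on
short sequences. The default hit threshold of 85 half-bits keeps
shuffled-sequence false positives negligible at benchmark lengths while
retaining genuine homologs across the divergence range of all six regimes.

`X` scores 0 against everything, is excluded from the "aligned characters"
count used for the normalised score (score ÷ aligned characters in both
sequences), and X-containing columns never enter distance estimation —
ambiguity is uninformative, not penalised. This asymmetry (scores absorb
the damage, distances ignore it) is precisely the mechanism by which
artefacts weaken the score–distance correlation and hence score-based
methods.

ML distances maximise Σ_cols log(πₐ·P_ab(d)) over d ∈ [0.01, 1000] PAM
with bounded Brent (tolerance 10⁻⁴), using a 20×20 count matrix so cost is
independent of alignment length; variance is the inverse observed Fisher
information by central difference; an optimum within tolerance of a search
bound is flagged. The estimator is checked against a 0.01-PAM grid search
and recovers d = 50 within 5% in mean over replicate pairs.

BBH and RSD report a pair iff each gene is the other's *unique* best
(highest score / smallest distance) among its hits in the partner genome.
Exact ties exclude the gene rather than being broken arbitrarily:
deterministic, and measure-zero on continuous scores.

For simulated data the all-vs-all phase can be restricted to gene pairs
sharing a family tag (`within_families=True`, the scenario runner's
default): cross-family pairs are unrelated stationary sequences whose
scores fall below the hit threshold, so the restriction changes neither
hits nor best hits, only the constant factor of the search. The full
search remains the default for untagged input and is tested to agree.

## Truth and scoring

Pair classification follows the gene-tree LCA's event label: speciation →
ortholog, duplication → paralog, transfer → xenolog. The truth set is the
union, over speciation nodes, of the Cartesian products of distinct
children's leaf sets (cross-species pairs only) — provably identical to
LCA classification, and both routes are implemented and tested against
each other. Xenologs are excluded from truth, so any method that reports a
transferred gene as ortholog of its replaced copy's relatives loses
precision; this is the deliberate reading under orthologous replacement.
The LCA rule is applied uniformly: pairs whose LCA is a speciation node
above a transfer remain orthologs even when one side descends through the
transfer. Group files (OrthoMCL-style `id: member member ...` and plain
one-group-per-line) and NHX-annotated trees (`Ev=S/D/T` and `D=Y/N`
dialects) reduce to pair sets with the same semantics.

Precision = TP/(TP+FP) and recall = TP/(TP+FN) are computed per replicate;
replicate aggregation reports the mean with a Student-t 95% confidence
half-width (df = n−1). Aggregating per-replicate metrics rather than
pooling counts is the default because the benchmark's headline plots show
confidence intervals *of the mean values*; pooled (micro-averaged)
aggregation is also provided, and the two coincide when replicate sizes
are equal. An empty prediction set yields a flagged undefined precision —
never silently 1.0 or 0.0.

## Reproducibility and problem sizes

Every stochastic component draws from a caller-supplied
`numpy.random.Generator`; the scenario runner derives one generator per
replicate as `default_rng([base_seed + r])` and uses it across stages in a
fixed order, so the configuration hash plus base seed determine every
output byte (asserted end to end on a smoke scenario).

Computations in the test suite and acceptance script run at desk scale,
chosen as the package's own default profile: 200 root families per
replicate (vs 1000 at full scale; `--paper-scale` restores 1000), reduced
species counts (4–10) for inference-heavy checks, and event-background
calibrations measured genealogy-only (sequence content cannot affect
them), pooled over 5 replicate runs on one surrogate tree — the same
pooling the original calibration used. At these sizes the calibration
statistics sit well inside their tolerance bands and the full suite runs
in minutes on one CPU.

## What passing does and does not show

The generator emulates the *modelled* forces only: no genome
rearrangement, gene fusion/fission, domain shuffling, codon-level effects,
rate heterogeneity, compositional drift, or biased duplication of long
genes; artefacts are single clean X runs, not read-level error processes.
Surrogate trees match summary statistics, not the original topologies, so
absolute precision/recall values are comparable only in trend, not point
by point — the alignment matrix and threshold of the original all-vs-all
phase are likewise unpublished. Conclusions that survive these caveats are
the qualitative ones the benchmark was built to expose: duplication trades
recall for precision under reciprocal-best criteria, orthologous
replacement degrades precision for every pair-based method, indels mainly
cost recall, and ambiguity hurts score-based selection more than
distance-based selection.
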