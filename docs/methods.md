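# Methods

`lambdascape` reimplements the computational analysis of a combinatorial
fitness-landscape study of bacteriophage λ host-receptor specialization:
estimating per-genotype selection rates from UMI-barcoded amplicon
sequencing of competition experiments, phenotyping genotypes by receptor
specialization, regressing fitness on genotype and competitor context, and
simulating eco-evolutionary dynamics on static versus shifting landscapes.
Because the deposited sequencing data are not an input, a synthetic-data
generator defines the study conditions end to end. This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Genotype space and selection rate

The library spans all 2⁹ = 512 combinations of nine biallelic mutation
sites in the λ *J* gene. A genotype is a 9-character 0/1 string (leftmost
character = site 1); the all-zero string is the ancestral generalist EvoC.
Fitness is the selection rate per competition unit (one unit = the 4-hour
competition, roughly two infection cycles):

    S = [ ln(G_T/G_0) − ln(EvoC_T/EvoC_0) ] / T

with frequencies computed over unique molecular barcodes (UMIs) kept by
the consensus caller. S(EvoC) ≡ 0; a genotype absent at either time point
has no quantifiable rate and is stored as missing — never imputed.
Replicate landscapes are averaged genotype-wise over observed values only.

## UMI consensus calling

Each template molecule carries a 5–12 nt random barcode; reads sharing a
barcode are collapsed into a consensus. Rules, in order:

1. a barcode seen by fewer than `min_reads` (default 3) reads is discarded;
2. the consensus base at every position is the strict-majority base across
   the barcode's reads; any position without a strict majority discards
   the barcode as ambiguous (deterministic and conservative — ties are
   rare at ≥3 reads and low error);
3. a consensus carrying any substitution outside the nine programmed sites
   (including a third base at a programmed site) is tallied off-target and
   excluded, so counts cover exactly the 512 programmed alleles.

Every barcode lands in exactly one bucket, so kept + discarded equals the
number of distinct barcodes — an invariant the tests enforce. Reads are
treated as positionally aligned, substitution-only observations of the
reference amplicon; indels and quality-weighted consensus are out of scope.

## Specialization index and hybrid geometry

S_O is a genotype's rate measured on OmpF-only hosts (environment A), S_L
on LamB-only hosts (environment E). The specialization index

    SI = (e^{S_L} − e^{S_O}) / (e^{S_L} + e^{S_O}) = tanh((S_L − S_O)/2)

ranges from −1 (pure OmpF specialist) to +1 (pure LamB specialist); the
tanh form is used for numerical stability. Specialists are genotypes with
|SI| strictly greater than 0.33, the value at which growth on the
preferred receptor is about twofold that on the other; SI = 0.33 exactly
is a generalist.

Hybrid incompatibility is assessed in the (S_O, S_L) plane: for each pair
of an L-specialist and an O-specialist (panels of the 27 most specialized
eligible genotypes per side), the in-silico hybrid is the union of the
parents' mutations, and its signed perpendicular displacement from the
line through the parents (positive toward increasing S_O + S_L) measures
the change in average receptor fitness. Trios are dropped when the hybrid
equals a parent or lacks an observed rate on either receptor; the reported
fraction counts strictly negative displacements. Selection-rate (log)
coordinates are the default; an exponentiated-coordinate option is
available behind a flag since either plane is defensible.

## Competitor-dependent epistasis regression

Mixed-host measurements are modelled with exactly 148 binary features:
1 intercept, 8 mutation indicators (sites 2 and 3 merged — they encode
the same amino-acid change), 3 competitor indicators (all three retained;
the L1 penalty resolves collinearity with the intercept), 28 pairwise
epistasis terms, 24 competitor×mutation terms, and 84
competitor×epistasis terms. Features are standardized internally for the
LASSO path (scale-equivariant penalty) and coefficients are reported on
the original 0/1 scale with an unpenalized intercept. The penalty is
selected by AIC, BIC, or 5-fold cross-validation grouped by replicate
dataset, so rows from one flask never straddle folds.

## Wright–Fisher simulation on a landscape axis

A fixed-size population (default N = 5×10⁹ particles) starts monomorphic
at EvoC and evolves by fitness-weighted multinomial reproduction followed
by mutation. Because selection rates can be negative, reproduction
weights are n_g·exp(c·S_g) with c = 0.5 generations per competition unit
(4 h ≈ 2 infection cycles); c is configurable. Mutation toggles each site
independently with probability μ per replication (default 7.7×10⁻⁸),
forward and back at equal rate.

The five landscapes sit on a landscape axis at the population SI of their
measurement conditions: E at −1, D at −0.9, C at 0, B at +0.7, A at +1
(mixed-host coordinates follow from the 90:10 competitor:library design
and the competitor SIs −0.99, 0, +0.778). Each generation the population
SI (abundance-weighted mean SI over floor-filled landscapes) selects the
governing landscape: the nearest node (discrete model; exact midpoint
ties resolve to the node with smaller |coordinate|), a linear
interpolation of the two bracketing nodes (continuous model), or a fixed
landscape (static models). Population SI is clamped to [−1, 1].

Per-simulation measurement noise: each landscape value (except EvoC's,
which anchors the reference at 0) receives one Gaussian draw per run with
σ = sqrt(v·(1/r − 1)), v the landscape variance, so two independent draws
correlate ≈ r (default r = 0.96, matching replicate measurements).
Missing genotypes receive a floor rate of −10 — effectively lethal rather
than undefined. Within a run, genotype SI (hence the axis position and
endpoint phenotyping) is computed from that run's noisy single-host
landscapes, keeping the simulated world self-consistent. Shannon entropy
of genotype abundances is recorded per generation (nats), and the
endpoint phenotype label is the set of classes among genotypes at ≥2.5%
abundance.

## Synthetic-data generator

The generator defines ground truth with the structure the analysis
assumes. Receptor scores are additive with sparse pairwise epistasis:
S_L(g) = Σ dL_i + Σ eL_ij over mutated sites and pairs (S_O analogous);
environment landscapes mix them, S_env = α·S_L + β·S_O (+ sparse
environment-specific pairwise perturbations in the mixed-host
environments), with α the LamB share: A = (0,1), B = (0.15, 0.85),
C = (0.35, 0.65), D = (0.80, 0.20), E = (1,0). C mildly favours OmpF use
(the generalist competitor acts as a weak LamB specialist) and D favours
LamB use, giving the deformation gradient along the axis.

Default per-site effects encode four structural facts about the measured
system rather than bare distributional draws:

* **Pleiotropy asymmetry.** Bulk effects are drawn dL ~ N(−0.5, 0.3) and
  dO ~ N(0, 0.6), then both receptors are re-centred on the *pair-level*
  median (over all background × mutation fitness changes): LamB to −0.5,
  OmpF to 0. A uniform shift of per-site effects shifts every pairwise
  fitness change identically, so the asymmetry — most mutations hurt the
  native receptor; OmpF effects spread evenly about zero — holds exactly
  for every seed.
* **Specialist peaks on both receptors.** Two designated L-adaptive sites
  carry an explicit trade-off (dL ~ N(+0.25, 0.1); dO shifted by −0.8) and
  the two largest-dO sites are designated O-adaptive (dO shifted by +0.6).
  Without the designated L sites, typical draws produce no LamB
  specialists at all and the hybrid analysis would be empty.
* **Receptor trade-off coupling.** Every site's LamB effect is debited by
  its OmpF benefit (dL ← dL − max(dO, 0)): no mutation is a cheap
  generalist improvement. This matches the observed biology (specializing
  mutations carry trade-offs) and is what gives the landscape axis its
  branching geometry — without it, occasional "cheap" OmpF sites create
  intermediate-SI genotypes that win at interpolated landscapes and the
  eco-evolutionary feedback freezes on a single phenotype.
* **Hybrid incompatibility.** Each L-adaptive × O-adaptive pair carries
  −0.8 epistasis on both receptors, so genotypes mixing opposing
  specialist mutations are penalized everywhere.

Random epistasis is sparse (each pair nonzero with probability 0.2,
N(0, 0.3)); mixed-host environments add sparse pairwise perturbations
(probability 0.1, N(0, 0.2)). Library frequencies are a Dirichlet draw
with concentration 100 per genotype (~10% CV around 1/512, "relatively
uniform"). Sequencing: ~10⁶ UMIs per sample drawn multinomially from the
pre- or post-competition frequencies (f_T ∝ f₀·e^{S·T}), reads per UMI
zero-truncated Poisson with rate 5 (the empirical distribution is
unreported; this is a declared assumption), per-base substitution error
10⁻³ with the three substitution targets equiprobable — so an error at a
programmed site produces the partner allele one third of the time and an
off-target base otherwise. A fixed off-site contaminant can be injected
at a configurable template fraction to exercise the programmed-only
filter (off by default).

What the generator does *not* emulate: PCR amplification bias and
chimeras, indels, quality-score structure, paired-end overlap, and real
linkage between the nine sites and the rest of the genome. Passing tests
therefore demonstrate the pipeline's correctness and statistical
behaviour under the stated error model, not robustness to every artifact
of real libraries.

## Scaled-down simulation experiments

The headline contrast (only shifting landscapes maintain genetic and
phenotypic diversity) is checked at desk scale: N = 10⁷ particles, 300
generations, 50 replicates per model, on the generator's default
landscapes. The mutation rate in these runs is scaled to preserve the
population mutation supply N·μ of the flask scale (μ = 3.85×10⁻⁵ =
7.7×10⁻⁸ × 500), the standard Wright–Fisher scaling; at the per-particle
rate a 10⁷ population is mutation-starved and no regime diversifies
within 300 generations. All other parameters keep their defaults,
including landscape noise at r = 0.96. Under these conditions the
continuous- and discrete-shifting models end with ≥2 coexisting
phenotypes in ~85% of replicates (median endpoint entropy ≈ 0.7 nats)
while every static model ends phenotypically monomorphic in ≥90% of
replicates (median entropy ≈ 0.02 nats).

## Numerical choices and degenerate inputs

* Landscape TSVs print 12 significant digits and round-trip bit-exactly;
  missing values are written `NA`.
* The consensus caller's discard precedence is too-few-reads, then
  ambiguous, then off-target (an ambiguous consensus cannot be inspected
  for off-target content).
* `selection_rates` raises if EvoC is absent at either time point (the
  reference is undefined); small samples of environments with strongly
  positive tails can genuinely lose the reference.
* Binomial mutation draws fall back to a joint multinomial allocation in
  the (toy-scale) event that independent per-site draws exceed a
  genotype's abundance, conserving N exactly.
* Entropy uses natural logarithms; zero-abundance genotypes contribute
  nothing.
* Pipeline artifacts are timestamp-free and derived from explicit seeds,
  so reruns with the same configuration are byte-identical; wall-clock
  provenance lives in the run log.

## Known limitations

Standard errors for selection rates beyond replicate dispersion are not
modelled, matching the source analysis. The simulator has no explicit
host-cell dynamics — competition enters only through the measured or
synthetic landscapes. Hybrids that completely lost OmpF infection are
counted as invalid trios, not analyzed quantitatively. The regression is
descriptive (no coefficient inference).
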