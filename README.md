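# lambdascape

Fitness landscapes of bacteriophage λ host-receptor specialization, from
UMI-barcoded competition sequencing to eco-evolutionary simulation.

When the generalist λ strain EvoC (able to infect *E. coli* through both
the LamB and OmpF outer-membrane receptors) is cultured on a mixture of
hosts expressing one receptor each, it repeatedly speciates into two
coexisting receptor specialists. `lambdascape` implements the
computational analysis behind that observation for a combinatorial
library of all 2⁹ = 512 combinations of nine *J*-gene mutations, measured
in five competition environments spanning the receptor-competition
spectrum. It is aimed at researchers working with deep mutational
scanning / combinatorial-library fitness data and at modellers studying
frequency-dependent (shifting) fitness landscapes. Because the original
sequencing data are not required, a first-class synthetic-data generator
reproduces the study conditions so the entire pipeline is testable from
scratch.

## What it computes

**Selection rates from barcoded counts.** Reads sharing a unique
molecular barcode (UMI) are collapsed into an error-corrected consensus
(≥3 reads, strict per-position majority, off-target consensus excluded),
and each genotype *G*'s fitness over a competition of duration *T* is

    S = [ ln(G_T/G_0) − ln(EvoC_T/EvoC_0) ] / T

relative to the ancestor EvoC (S(EvoC) ≡ 0; unobserved genotypes are
missing, not imputed).

**Receptor-specialization phenotyping.** With S_L and S_O the rates on
LamB-only and OmpF-only hosts,

    SI = (e^{S_L} − e^{S_O}) / (e^{S_L} + e^{S_O})   ∈ [−1, +1],

|SI| > 0.33 (a twofold growth-rate ratio) defines a specialist. Hybrids
of opposing specialists (union of parental mutations) are scored by their
signed perpendicular displacement from the parent-connecting line in the
(S_O, S_L) plane — negative means hybrid incompatibility.

**Competitor-dependent epistasis.** Mixed-host fitness is regressed on a
148-feature design (intercept; 8 mutation terms, sites 2/3 merged; 3
competitor terms; 28 G×G; 24 C×G; 84 C×G×G) with LASSO regularization
tuned by AIC, BIC, or grouped cross-validation.

**Eco-evolutionary Wright–Fisher simulation.** A population of N
particles evolves by fitness-weighted multinomial reproduction
(weights n·e^{cS}) and per-site mutation, on either a static landscape or
a landscape chosen each generation by the population's mean SI along a
landscape axis (nearest measured landscape, or a linear interpolation of
the two bracketing ones). Per-generation Shannon entropy, population SI,
and endpoint phenotype sets are recorded.

## Worked example

```python
import numpy as np
from lambdascape import synthetic, counting, fitness, phenotyping, simulator

model = synthetic.GroundTruthModel.default(seed=0)
truth = synthetic.generate_true_landscapes(model)
f0 = synthetic.generate_library_frequencies(seed=1)

t0, t4 = synthetic.simulate_competition_reads(truth["C"], f0, n_umis=100_000, seed=2)
gc0 = counting.count_sample(t0, min_reads=3)
gc4 = counting.count_sample(t4, min_reads=3)
print(f"kept {gc0.counts.sum()} of {gc0.total_umis} barcodes at t0; discarded {gc0.discarded}")

table = fitness.selection_rates(gc0, gc4)
mask = np.isfinite(table.S)
r = np.corrcoef(table.S[mask], truth["C"].values[mask])[0, 1]
print(f"quantified {mask.sum()}/512 genotypes; r(estimate, truth) = {r:.3f}")

records = phenotyping.phenotype_table(truth["A"], truth["E"])
print(records["phenotype_class"].value_counts().to_dict())
trios, fraction = phenotyping.hybrid_analysis(records, k=27)
print(f"valid trios: {int(trios['valid'].sum())}; fraction below parental line: {fraction:.2f}")

config = simulator.SimulationConfig(
    N=10_000_000, generations=300, model="continuous_shifting", mu=3.85e-5, seed=5
)
trajectory = simulator.run_simulation(config, truth)
print(f"endpoint phenotypes: {trajectory.endpoint_label}; "
      f"final entropy {trajectory.entropy[-1]:.2f} nats; "
      f"population SI {trajectory.population_si[-1]:+.2f}")
```

Output:

```
kept 88309 of 100000 barcodes at t0; discarded {'too_few_reads': 11641, 'ambiguous_consensus': 46, 'off_target_genotype': 4}
quantified 512/512 genotypes; r(estimate, truth) = 0.990
{'O_specialist': 374, 'generalist': 74, 'L_specialist': 64}
valid trios: 712; fraction below parental line: 0.99
endpoint phenotypes: O+G; final entropy 0.55 nats; population SI -0.35
```

Reading the numbers: of 100,000 template barcodes, 88,309 pass the
three-read consensus filter (the rest are mostly barcodes seen fewer than
three times); the estimated selection rates correlate r = 0.99 with the
generating truth at this depth. Phenotyping the library finds OmpF
specialists dominating, with 64 LamB specialists and 74 generalists; 712
of the 729 specialist×specialist hybrids are valid trios and 99% fall
below the parental line — pervasive hybrid incompatibility. The
continuous-shifting simulation ends with an OmpF specialist *coexisting*
with a generalist (entropy 0.55 nats); the same run on any static
landscape ends phenotypically monomorphic.

The full pipeline (generate → count → fitness → phenotype → regress →
simulate → report) runs from one config:

```bash
lambdascape run --out demo_run          # built-in demo configuration
lambdascape report --run-dir demo_run
```

Individual stages are also available as subcommands (`generate`, `count`,
`fitness`, `phenotype`, `regress`, `simulate`); see `lambdascape --help`.

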