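# fluxmod

**Does the need to survive in many environments make metabolic networks
modular?** `fluxmod` studies this question *in silico*. It samples metabolic
network *genotypes* — fixed-size subsets of a global universe of reactions —
that are *viable* (able to synthesise all biomass precursors, as judged by
flux balance analysis) in a required set of minimal environments, and
measures how modular those networks are as the number of required
environments grows. It is aimed at systems biologists working on
constraint-based models and on the structure of genotype spaces.

## The model

A reaction universe is a stoichiometric matrix **S** (m metabolites × N
reactions) with reversibility flags, exchange reactions (positive flux =
secretion, negative = uptake) and one biomass reaction whose substrates
define the precursor demands. A genotype is a bit string G = (b₁, …, b_N)
selecting n reactions; an environment is a minimal medium: the set of
external metabolites whose uptake is open (base inorganics plus one carbon
source). Viability in an environment means the FBA optimum

&nbsp;&nbsp;&nbsp;&nbsp;max Z = max { cᵀv : S v = 0, a ≤ v ≤ b }

with c the biomass reaction indicator is strictly positive. The
*environmental versatility* V_env of a phenotype is the number of
environments in which viability is required.

Genotypes with a given phenotype are sampled uniformly by a Markov chain:
each step swaps one present reaction for one absent one (preserving n) and
accepts the proposal iff the new genotype keeps the phenotype. Modules are
*fully coupled sets* (FCSs): maximal sets of reactions whose pairwise flux
ratios are fixed — and nonzero — across every steady state, found with the
ratio LPs R_max = max v₁ and R_min = min v₁ subject to S v = 0, bounds, and
v₂ = 1 (a pair is coupled iff R_max = R_min ≠ 0). Modularity of a genotype
is summarised by **M**, the number of reactions inside FCSs, and **s**, the
number of FCSs. Two further analyses characterise the modules: the
coherence statistic **Q** (fraction of an FCS sharing its dominant pathway
annotation) with an h-index and an annotation-swap randomization test, and
the *scope distance* of each reaction from the nutrients (the network
expansion iteration at which it first fires, minimised over environments).

Because the analyses need a reaction universe with known structure, the
package ships a synthetic-universe generator: nutrient-specific catabolic
chains feeding a shared core, redundant routes to the biomass precursors,
cofactor loops, futile cycles, deep downstream pathways and blocked
distractor reactions, each with designed FCSs, scope distances and pathway
labels that serve as ground truth in the test-suite oracles.

## Worked example

```python
import numpy as np
import fluxmod as fm

universe, annotations, envs, truth = fm.generate(fm.SynthConfig())
n = int((~universe.swappable).sum()) + 40          # genotype size

rng = np.random.default_rng(2026)
families = fm.build_nested_environment_sets(envs, [8, 4, 2, 1],
                                            replicates=3, pivot_size=8, rng=rng)
curve, cells = fm.versatility_curve(universe, families, n=n, burn_in=1000,
                                    chain_length=10_000, thinning=100, seed=2026)
print(curve[curve.replicate == 0].to_string(index=False))
```

prints (replicate 0):

```
 replicate  v_env  mean_M  mean_s    sem_M    sem_s  ensemble_size  acceptance_rate
         0      1   13.38    5.13 0.352131 0.120315            100         0.837909
         0      2   15.55    5.90 0.316985 0.106837            100         0.757091
         0      4   19.02    7.01 0.263994 0.089324            100         0.605545
         0      8   28.65   10.20 0.097830 0.040202            100         0.295091
```

Each row is an ensemble of 100 sampled genotypes viable in V_env
environments. Both the mean number of reactions in modules ⟨M⟩ (13.4 → 28.7)
and the mean number of modules ⟨s⟩ (5.1 → 10.2) rise with versatility: every
additional required nutrient forces its catabolic pathway — itself a fully
coupled set — into every viable genotype. Comparing the consensus reactions
found in at least half the genotypes at V_env = 8 versus V_env = 1, the
difference set sits markedly closer to the nutrients (mean scope distance
2.2 versus 4.3 for the whole universe; two-sample K-S p ≈ 5×10⁻⁴).

The same stages are available from a shell via the `fluxmod` CLI
(`synth`, `validate`, `viability`, `fcs`, `sample`, `scope`, `coherence`,
`curve`, `compare-scope`), each writing TSV tables plus a JSON manifest.

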