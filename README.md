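# moietydeconv

Deconvolution of <sup>13</sup>C mass-isotopologue distributions of modular
metabolites into the labeling fractions of their biochemical subunits, under
non-steady-state conditions.

A composite metabolite such as UDP-GlcNAc is modeled as independent subunits
(glucose, ribose, acetyl, uracil), each existing in a small set of allowed
<sup>13</sup>C label states. The observed isotopologue profile is the
convolution of the per-subunit label distributions; the package inverts this
forward model with a hybrid simulated-annealing/genetic optimizer, selects
among variant labeling models by AICc, and fits exponential kinetics to the
deconvoluted timecourses.

## Components

| module                    | purpose |
|---------------------------|---------|
| `moietydeconv.model`      | subunit state spaces, closure-constrained parameter sets, forward convolution model |
| `moietydeconv.correction` | natural-abundance (binomial) stripping and mole-fraction normalization |
| `moietydeconv.optimize`   | hybrid GA/annealing fit of subunit fractions (population 20, 5% crossover, 3 mutations/step, linear annealing, replicate statistics) |
| `moietydeconv.selection`  | variant-model grammar expansion and AIC/AICc ranking |
| `moietydeconv.kinetics`   | exponential rise/decay fits and half-lives |
| `moietydeconv.simulate`   | synthetic timecourse generator with known ground truth |
| `moietydeconv.io` / `cli` | tabular isotopologue format (CSV/TSV, columns `time, m0..mN`) and the `moietydeconv` command |

The default model definition (`src/moietydeconv/data/udp_glcnac.json`)
describes UDP-GlcNAc: subunit carbons 6/5/2/4, allowed labels
{0,6}/{0,5}/{0,2}/{0,1,2,3} — 32 isotopomers, 17 mass shifts (m0–m16),
6 free parameters. A paper-scale variant grammar
(`data/variant_grammar.json`, 48 variants) is shipped for model selection.

## CLI

```sh
# synthetic timecourse with ground truth
moietydeconv simulate --seed 7 --out sim.tsv --truth-out truth.json

# strip natural abundance (1.1% 13C, 17 carbons) and normalize
moietydeconv correct sim.tsv --p13 0.011 --carbons 17 --out corrected.tsv

# fit subunit fractions per timepoint
moietydeconv fit corrected.tsv --steps 100000 --repeats 10 --seed 1 \
    --out-params params.tsv --out-report fit.json

# rank variant labeling models by AICc
moietydeconv select corrected.tsv \
    --variants src/moietydeconv/data/variant_grammar.json \
    --steps 20000 --repeats 3 --seed 1 --out ranking.tsv

# kinetics of one deconvoluted component
moietydeconv kinetics params.tsv --form rise --component r5
```

Optimizer defaults mirror the published protocol (10<sup>6</sup> steps,
50 repeats); pass `--steps`/`--repeats` to scale down for quick runs.

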