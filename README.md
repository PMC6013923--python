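# mitoflux

Constraint-based analysis of enterocyte mitochondrial metabolism under
dietary lipid interventions.

Small-intestinal enterocytes are the first cells to see dietary fat, and
how their mitochondria shift between glucose oxidation and fatty-acid
β-oxidation when the diet changes is hard to disentangle experimentally.
`mitoflux` addresses this with a stoichiometric (constraint-based) model
of the enterocyte mitochondrion: fluxes **v** are restricted to the
steady-state polytope `{v : S·v = 0, lb ≤ v ≤ ub}`, diets enter purely as
uptake ceilings on exchange reactions, maximal ATP production is the
simulation objective, and the near-optimal flux space is characterized
by ACHR (artificial-centering hit-and-run) sampling. Per-reaction flux
distributions are then compared across diets with one-way ANOVA followed
by Tukey–Kramer post hoc letters.

The package is aimed at systems-biology practitioners: it provides the
compartmentalized model container with JSON/SBML(FBC)/tabular I/O, a
reduced but fully elementally balanced enterocyte mitochondrial network
with analytic β-oxidation stoichiometry, seven built-in murine diet
compositions (three fish-oil doses, four lipid/carbohydrate ratios), the
diet-to-bound conversion, an LP flux-balance layer (HiGHS), the ACHR
sampler, the cross-diet statistics, and a CLI that chains them.

## Worked example

```python
import mitoflux as mf

model = mf.build_fixture_model()
report = mf.check_model_integrity(model)

runs = {}
for i, name in enumerate(("FAT10", "FAT45")):
    constrained = mf.constrain_to_diet(model, name)
    print(f"{name}: max ATP = {mf.fba_max_atp(constrained).objective_value:.3f}")
    cfg = mf.SamplerConfig(n_points=500, steps_per_point=100, seed=1 + i)
    runs[name] = mf.achr_sample(constrained, cfg, diet_label=name)

for rxn in ("PDHm", "FAOXC160"):
    comp = mf.compare_groups(list(runs.values()), rxn)
    for lab in comp.group_labels:
        print(f"{rxn} {lab}: median {comp.medians[lab]:.4f} "
              f"letters {comp.letters[lab]}")
```

prints

```
FAT10: max ATP = 82.595
FAT45: max ATP = 80.021
PDHm FAT10: median 4.5009 letters a
PDHm FAT45: median 2.0482 letters b
FAOXC160 FAT10: median 0.0241 letters a
FAOXC160 FAT45: median 0.1710 letters b
```

Reading this: both diets support similar maximal ATP output
(mmol gDW⁻¹ h⁻¹), but the flux *routes* differ. Moving from the low-fat
FAT10 diet to the high-fat FAT45 diet, the sampled median flux through
pyruvate dehydrogenase (PDHm — carbohydrate entry into the TCA cycle)
falls from 4.50 to 2.05, while β-oxidation of dietary palmitate
(FAOXC160) rises seven-fold. Distinct Tukey–Kramer letters (`a` vs `b`)
mean the two diets differ significantly at α = 0.05 across the 500
sampled steady states.

The same study runs end-to-end from a config file:

```
mitoflux run study.yaml --out results/
```

with a `study.yaml` such as

```yaml
model: fixture
diets: [FAT10, FAT20, FAT30, FAT45]
sampler: {seed: 1}
```

producing per-diet sample matrices (TSV), summaries, comparison tables
with compact letter displays, and a reproducibility manifest. See
`mitoflux --help` for the individual `build-fixture`, `diets list`,
`constrain`, `check`, `fba`, `sample` and `compare` subcommands, and
`docs/methods.md` for the model, the diet-to-bound conversion, the
sampler internals and the known limitations.

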