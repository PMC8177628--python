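# multibof

Flux-balance analysis with environment-dependent biomass objective
functions. The package implements three ways of using several measured
biomass compositions in a constraint-based (FBA) model:

- **BTW** (biomass tradeoff weighting): every biomass pseudo-reaction enters
  the objective with coefficient one and the LP distributes flux among them.
- **HIP** (higher-dimensional-plane interpolation): a per-compound affine map
  from nutrient-uptake coordinates (e.g. glucose x ammonium) to biomass
  coefficients, fit through measured (environment, composition) points;
  negative extrapolations are clamped to 1% of a reference coefficient and
  the result is renormalized to 1 g gCDW⁻¹.
- **HIP-I**: iterative HIP — the FBA optimum's realized uptake fluxes
  re-query the map until the uptake vector is self-consistent within a
  tolerance (default ε = 1e-3, at most k_max = 100 iterations).

Around these sit the supporting machinery: biomass-composition construction
(merging, compound removal, unit-mass normalization, per-group environmental
scaling), a HiGHS-backed LP core (FBA, lexicographic acetate maximization,
parsimonious flux minimization, respiratory quotient), phenotype phase-plane
scans with relative grids, and single-gene knockout screens with
growth-ratio binning and an angle-based similarity score against
experimental essentiality tables.

## Layout

| module | contents |
| --- | --- |
| `multibof.model_io` | model dataclasses, SBML-FBC/COBRA-JSON I/O, deterministic toy fixture models |
| `multibof.bof` | `BiomassComposition`, merging/scaling/normalization, artificial-BOF pipeline, TSV tables |
| `multibof.fba` | LP core: `solve_fba`, `apply_environment`, `max_secretion_at_optimal_growth`, `pfba_minimize`, `respiratory_quotient` |
| `multibof.methods` | `build_btw`/`solve_btw`, `fit_affine_map`/`hip_bof`/`hip_solve`, `hip_i_solve` |
| `multibof.scans` | `scan_phase_plane`, `relative_grid` |
| `multibof.essentiality` | GPR evaluation, `single_gene_deletion`, bins, group tallies, `similarity_angle` |
| `multibof.cli` / `multibof.config` | `multibof` command-line entry point and validated run configuration |

## CLI

```sh
multibof make-toy --seed 1 --out toy.json
multibof fba --model toy.json --objective BIOMASS_A \
    --env "EX_glc__D_e=8,EX_nh4_e=4" --mode upper_bound --out run/
multibof build-bofs --model toy.json --source BIOMASS_A --source BIOMASS_B \
    --groups groups.tsv --out bofs/
multibof btw --model toy.json --bof bofs/bof_UL.tsv --bof bofs/bof_NL.tsv \
    --env "EX_glc__D_e=8,EX_nh4_e=4" --out btw_run/
multibof hip-i --model toy.json --measurements measurements.json \
    --env "EX_glc__D_e=2,EX_nh4_e=8" --out hipi_run/
multibof phase-plane --model toy.json --method single --bof BIOMASS_A \
    --glc 0:18:10 --nh4 0:8.5:10 --mode upper_bound --out pp/
multibof knockout --model toy.json --method fixed --bof BIOMASS_A \
    --env "EX_glc__D_e=8,EX_nh4_e=4" --out ko/
multibof similarity --u 237,8,1054 --v 226,60,1013
```

Every artifact-producing run writes a `manifest.json` (command, validated
config, config hash, package version, seed) beside its outputs. Declarative
configuration files (JSON/YAML, unknown keys rejected) can be passed with
`--config`; command-line flags win.

Measurement sets are a JSON bundle naming the environment dimensions plus,
per measurement, its coordinates and a BOF table TSV
(`compound_id  side  coefficient  group  molecular_weight`); see
`tests/test_cli.py` for a complete example.

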