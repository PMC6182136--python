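# transposim

Stochastic kinetics of transpososome assembly for cut-and-paste DNA
transposons. The package simulates the two assembly pathways —
**synapsis by naked-end capture (S-NEC)**, where a pre-formed transposase
multimer binds one transposon end and then recruits the naked partner end,
and **synapsis by protein dimerization (S-PD)**, where monomers bind the
two ends independently and then dimerize — and the consequences of the
choice of pathway:

* **Over-production inhibition (OPI)** emerges in S-NEC when both ends are
  occupied by separate multimers, leaving no naked end to recruit.
* **Genome-size dependence**: non-specific DNA sequesters transposase, so
  S-PD reactions slow down in large genomes while S-NEC reactions above
  the OPI peak speed up; cis-acting transposase makes both flat.
* **Mutant single-chain-dimer predictions**: product classes (uncut /
  single-end cut / double-end cut) and relative activity for active-site
  (DDE→ADE) and dimer-interface (G462D) mutations, including the
  double-dimer assembly hypothesis and its ≤ 50 % activity bound.
* **Genomic invasion**: generation-based copy-number dynamics with
  trans- or cis-acting expression and an optional trans-acting inhibitor;
  copy-number regulation emerges from the S-NEC kinetics alone.

## Layout

| module | contents |
| --- | --- |
| `transposim.model_core` | parameter types (`RateConstants`, `GenomeContext`, `MutantSpec`), unit conversions, closed-form arithmetic |
| `transposim.pathways` | reaction-network builders per pathway/mutant/genome, cleavage-product combinatorics |
| `transposim.engines` | Gillespie SSA (direct method), mean-field ODE integration, exact CTMC oracle, first-passage sampling |
| `transposim.sweeps` | dose-response and genome-size sweeps, OPI detection, rate estimation |
| `transposim.invasion` | generation-based transposon invasion simulation |
| `transposim.synthetic_data` | archetype parameter ensembles (Tn5-monomer, Tn5 single-chain dimer, Hsmar1), dwell-time samples, rate-recovery fits, golden fixtures |
| `transposim.cli` | `transposim` command-line interface |

## CLI

```sh
transposim describe --archetype tn5_scd           # reaction network as JSON
transposim ssa --archetype hsmar1 --seed 7 --out traj.tsv
transposim dose-response --archetype hsmar1 --out dr.tsv
transposim genome-sweep --archetype tn5_monomer --transposase 1e-7 --out gs.tsv
transposim invasion --archetype hsmar1 --generations 100 --out inv.tsv
transposim validate                               # SSA vs exact-oracle suite
transposim fixtures --outdir fixtures/            # regenerate golden bundles
```

Every table is TSV with one header row; every output file gets a JSON
sidecar with the fully resolved configuration, the seed and the package
version, so any run can be reproduced bit-identically.

Configurations can also be given as YAML/JSON files (`--config run.yaml`)
with explicit `rates`, `pathway`, `architecture` and genome fields; CLI
flags override file values.

## Modeling notes

Rate constants for the archetypes are pinned in
`transposim.synthetic_data.ARCHETYPE_DEFAULTS`. Only a handful of values
are anchored by measurement (the Hsmar1 10-minute single-end dwell, its
3-hour multimer subunit-exchange half-life, the sub-minute dwell typical
of helix–turn–helix binders); the remaining magnitudes are calibrated
choices, and the file documents which is which. Simulation state is
integer molecule counts in a configurable reference volume (default 1 fL);
all internal times are seconds and concentrations molar.
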