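# endoquant

Quantification tools for fluorescence microscopy of receptor trafficking
in polarized embryonic tissue. Non-canonical Wnt signalling (the
Wnt5a/Ror2 branch that steers convergent-extension movements during
gastrulation) works through receptor complexes that cluster at the plasma
membrane and are internalized by caveolin- and clathrin-dependent
endocytosis — preferentially from the apical surface of polarized cells.
Measuring that behaviour from images takes five recurring analyses, and
this package implements all of them as a tested, scriptable pipeline:

1. **Colocalization** of a cluster channel with a membrane marker
   (Manders coefficient M2) plus per-cluster membrane/cytoplasm
   classification.
2. **Membrane/cytoplasm intensity ratios** from line profiles drawn
   across the cell boundary:
   `ratio = (I_membrane − I_outside) / (I_inside − I_outside)`.
3. **Apico-basal z-distributions**: the fraction of fluorescent spots
   visible in each optical section of a 10 × 1 µm stack, from basal
   (0 µm) to apical (9 µm).
4. **Single-particle tracking**: spot detection with a strict
   1000-photon gate, frame-to-frame linking below a 2.5 µm displacement
   radius, MSD-based diffusion estimation, and detection of
   cross-channel *comigrating* trajectory pairs (two colours moving
   together — the signature of a shared endocytic carrier).
5. **Screening statistics**: the >3.8-fold / p < 0.05
   differential-expression filter, 2^−ΔΔCt qPCR relative expression,
   Welch/Student t-tests and χ² phenotype contingency tests.

A synthetic-data module generates every input class — two-channel cell
images, z-stacks, two-colour Brownian movies, expression and phenotype
tables — with recorded ground truth, so the whole pipeline is exercisable
and testable without microscope data. See `docs/methods.md` for models,
parameters and limitations.

## Worked example

Run the colocalization analysis on a generated cell (80% of 50 clusters
placed on the membrane, Poisson noise, seed 1):

```sh
$ endoquant coloc --seed 1 --outdir ex_coloc
$ cat ex_coloc/coloc.json
{
  "fraction_membrane": 0.8,
  "image_id": "synthetic_cell_0",
  "m2": 0.2146409435495911,
  "marker_threshold": 85.16015625,
  "n_cytoplasm": 10,
  "n_membrane": 40,
  "truth_membrane_fraction": 0.8
}
```

All 50 clusters were detected; 40 fell on the membrane band and 10 in the
cytoplasm, recovering the generated 80% membrane fraction exactly. The
M2 value (0.21) is the fraction of total cluster-channel *intensity* on
marker-positive pixels — lower than the cluster fraction because the
uniform photon background contributes to the denominator.

Comigration on a two-colour Brownian movie with 3 designated comigrating
pairs among 20 particles per channel:

```sh
$ endoquant comigrate --seed 1 --outdir ex_com
$ head -3 ex_com/comigration.csv
id_a,id_b,overlap,mean_sep_um,comigrating
0,0,200,0.033942708909294746,True
0,1,200,5.9823125178211125,False
```

Exactly the 3 planted pairs are flagged `comigrating` (mean separation
≈ 0.03 µm ≈ the simulated localization jitter); independent pairs sit
micrometres apart.

Other subcommands: `generate`, `profiles`, `axialdist`, `track`,
`screen`, `phenotype`, and `demo` (runs everything end to end; two runs
with the same seed produce byte-identical reports). Parameters are
overridden with `--set key=value`; every run writes `metadata.json`
recording the seed, a config hash and per-parameter provenance.

The library API mirrors the CLI: `endoquant.synthgen` (generators),
`detection`, `coloc`, `profiles`, `axialdist`, `tracking`, `stats`, and
`pipeline` (I/O and orchestration).

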