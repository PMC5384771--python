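# sypflux

Quantitative analyses of synaptonemal complex (SC) dynamics in
*C. elegans* pachytene, packaged as a tested pipeline over a
ground-truthed synthetic gonad generator.

During meiotic prophase, SC central-region proteins (SYP-1..4) hold paired
homologous chromosomes together. Fluorescence recovery after
photobleaching (FRAP) of GFP-tagged SYP proteins shows that the SC is
dynamic early in pachytene — bound subunits exchange with a nucleoplasmic
pool — and becomes stable late, and that crossover-designated
recombination intermediates (marked by COSA-1/MSH-5 foci) trigger this
stabilisation chromosome by chromosome, with SYP protein becoming
preferentially enriched on the SC that carries the focus. This package
implements the measurement and inference layer of that analysis for
anyone who wants to quantify SC dynamics or per-chromosome SC signal:

- **Synthetic gonads** (`sypflux.synthetic`, `sypflux.render`): nuclei
  ordered along the distal→proximal axis with a ~2.1-fold intensity ramp,
  six SC space curves per nucleus (one labelled X), Poisson-distributed
  recombination foci with genotype-dependent rates, focus-triggered
  signal-conserving enrichment, compartment exchange kinetics, z-stack and
  single-plane photobleaching, and rendering to 3D stacks with PSF blur
  and Poisson-Gaussian noise. Ground truth (traces, foci, kinetics) is
  exported alongside every render.
- **FRAP quantification** (`sypflux.frap`): sum projections, ROI
  fluorometry with background correction, the extent-of-recovery
  statistic E(t) = [F_bl(t)/F_nuc(t)] / [F_bl(pre)/F_nuc(pre)], plateau
  estimation, exponential fitting with closed-form mobile-fraction
  inversion f̂ = (Ê∞·T − s)/(T − s), T = 1 − a(1 − s), and the
  strong-recovery (evening-out) call.
- **SYP distribution** (`sypflux.distribution`): per-chromosome mean
  intensities, even/uneven classification (max/median ≥ θ), 3D focus
  detection and nearest-trace assignment, gonad position windows, and the
  intensity-ramp fit.
- **Inference** (`sypflux.stats`): zero-class Poisson break-number
  estimation λ̂ = −ln p̂₀ with log-Wilson confidence intervals,
  heterosynapsis attenuation, a one-sample proportion z-test,
  Mann-Whitney, Fisher exact, chi-square, and position-trend regression.

## Worked example

Simulate FRAP cohorts for wild type and the crossover-defective panel and
test the early→late decline in recovery:

```
$ python analysis/02_frap_recovery.py --seed 1
wt         early 0.846 late 0.411 decline  51.4%  p=3.7e-05
spo11      early 0.853 late 0.832 decline   2.5%  p=0.26
cosa1      early 0.848 late 0.857 decline  -1.0%  p=0.44
plk2       early 0.852 late 0.853 decline  -0.1%  p=0.84
wild-type plateau vs position: slope -0.62, R^2 = 0.94
```

Each line gives the median extent-of-recovery plateau for early and late
pachytene nuclei (n = 12 per stage), the percent decline of the late
median relative to the early one, and the two-tailed Mann-Whitney p.
Wild-type recovery drops by about half as nuclei progress — the SC has
stabilised — while the break-initiation (`spo11`), crossover-maturation
(`cosa1`) and polo-like-kinase (`plk2`) mutants stay dynamic throughout;
the plateau-versus-position regression slope summarises the same decline
per unit of normalized gonad length. The other numbered scripts under
`analysis/` cover gonad synthesis and the intensity ramp (01), evenness
scoring, focus detection and X-association (03), zero-class break-number
inference and heterosynapsis attenuation (04), and full-pipeline reports
(05). The `sypflux` command-line tool exposes the same stages
(`simulate`, `frap`, `distribution`, `infer`, `report`, `all`) with
`--scenario` presets for the genotype panel.

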