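# dropquant

Absolute quantification of rare gene targets by droplet digital PCR
(ddPCR), built for the crude-lysate workflow: unextracted whole-cell
lysate partitioned into ~20,000 droplets per reaction, a rare target
(e.g. T-cell receptor excision circles, TRECs) on channel 1 and a
diploid reference gene (RPP30) counting genome equivalents on
channel 2. It is aimed at labs quantifying targets at 10⁻³–10⁻⁴ copies
per cell from as few as a couple of hundred cells, where every droplet
matters and the analysis around the Poisson estimate — thresholds, QC,
replicate merging, detection limits — decides whether a measurement is
believable.

## The model

Target copies load into droplets of volume `V` as Poisson(c·V), so the
fraction of negative droplets estimates `e^(−λ)` with `λ = c·V`:

```
λ̂ = −ln(N_neg / N)          copies per droplet
ĉ  = λ̂ / V_droplet          copies per µL,  SE(λ̂) = √((1−p)/(N·p)),  p = N_neg/N
```

with `V_droplet = 0.70 nL` by default — the microscopy-measured droplet
volume, smaller than the 0.85 nL the instrument software assumes.
Around this estimator the package provides:

* **classification** — per-channel thresholds at pooled-blank
  mean + 7·SD, rectangular exclusion regions for artifact clusters,
  droplet QC (> 10,000 accepted droplets/well), and merging of
  replicate wells into one ~80,000-droplet measurement;
* **quantification** — concentrations with 95% CIs, cells/reaction from
  the reference channel (2 copies/cell), copies/reaction and
  targets/cell;
* **validation** — LOB (mean + 1.645·SD of blanks), LOD
  (LOB + 1.645·SD of the lowest level), LOQ (lowest level with
  CV ≤ 35%), replicate CV tables, and probit hit-rate analysis;
* **method comparison** — OLS with slope-CI-contains-1 flag, Spearman
  ρ, Bland-Altman bias and limits of agreement;
* **droplet imaging** — monolayer micrograph segmentation to measured
  droplet volumes (area → equivalent diameter → sphere);
* **simulation** — a droplet-level plate generator with known ground
  truth (Poisson loading, amplitude clusters with rain, blank wells,
  dilution series, crude-lysate artifacts, monolayer images).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate a plate (three dilution levels in triplicate plus six blank
wells), then analyse it:

```
$ dropquant simulate --out demo/plate --seed 7 --levels 0.016,0.0016,0.0003 \
      --replicates 3 --blanks 6 --droplets 20000
wrote 15 wells to demo/plate

$ dropquant validate demo/plate
Assay validation report
=======================
LOB: 0
LOD: 0.000444247
LOQ: 0.0146546 (level level_0.016, CV 14.15%)
Mean intra-assay CV: 49.46%

      sample  dilution  n     mean       sd    cv_pct
 level_0.016    0.0160  3 0.014655 0.002073 14.148716
level_0.0016    0.0016  3 0.001179 0.001022 86.712322
level_0.0003    0.0003  3 0.000568 0.000270 47.507444

 concentration  n_detected  n_replicates  hit_rate
        0.0160           3             3  1.000000
        0.0016           2             3  0.666667
        0.0003           3             3  1.000000
```

Reading it: thresholds fitted from the six blanks classified no blank
droplet positive, so the limit of blank is 0. The top level
(0.016 targets/cell) is recovered at 0.0147 with a 14% CV; the two
rarer levels carry 47–87% CVs and one missed detection — single
~20,000-droplet wells expect only ~1–8 target copies there, which is
exactly why replicate wells are merged for rare targets
(`--replicates 1` with four wells per group in the library API, or
`merge_wells_per_replicate=4` in `simulate_dilution_series`). `dropquant
quantify demo/plate` prints the per-group concentration table behind
these numbers.

The same analysis from Python, statsmodels-style:

```python
from dropquant import DropletPlateModel, RunConfig, to_concentration

results = DropletPlateModel.from_directory("demo/plate", RunConfig()).fit()
print(results.summary())              # thresholds, estimates, validation
results.to_csv("demo/results")        # classification.csv, concentrations.csv, ...

est = to_concentration(n_neg=9000, n_total=10000, droplet_volume_nl=0.70)
print(f"{est.concentration_per_ul:.1f} copies/uL "
      f"(95% CI {est.ci95[0]:.2f}-{est.ci95[1]:.2f})")
# 150.5 copies/uL (95% CI 141.18-159.85)
```

Droplet volume from a monolayer image:

```
$ dropquant volume mono0.png mono1.png mono2.png mono3.png --pixel-scale 0.5
droplets measured: 300
mean volume: 0.7032 nL (SD 0.0419; 95% CI 0.6985-0.7080)
```

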