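# bindnet

Simulation and analysis of the neurophysiology of **event-file binding** —
the transient association of stimulus features and responses formed when we
act on an object, and the costs that arise when only part of that binding
repeats.

The package targets the S1–S2 *partial repetition* paradigm: a first
stimulus (S1) accompanied by a cued keypress (R1) is followed by a second
stimulus (S2) requiring a choice response (R2). Stimulus features
(orientation, location, color) and the response may repeat or alternate
independently, so performance shows the binding signature — feature overlap
helps when the response also repeats and hurts when it alternates. `bindnet`
implements the complete analysis chain for the EEG correlates of this
effect, together with a synthetic-data generator that produces multichannel
epochs with known ground truth, so every stage of the chain is testable
without access to participant data.

## What the pipeline computes

1. **Preprocessing** — zero-phase 0.5–20 Hz band-pass (order-8 Butterworth
   response), average reference, ±150 µV amplitude and 0.5 µV/100 ms
   flatline artifact rejection, spherical-spline surface Laplacian (CSD,
   µV/m²), −200–0 ms baseline, segmentation into feature-overlap × response
   cells.
2. **ERP analysis** — condition averages, P3 mean amplitude (400–700 ms at
   Cz), and a data-driven electrode validation: each electrode is compared
   to the mean of the others with paired *t*-tests, Bonferroni-corrected
   over 60 electrodes (per-test threshold *p* = .0008).
3. **RIDE decomposition** — residue iteration decomposition of single
   trials into a stimulus-locked S cluster, a response-locked R cluster,
   and a latency-variable central C cluster, estimated by iterated median
   (L1) waveforms with per-trial C-latency estimation.
4. **Network analysis** — the imaginary part of coherency between all
   channel pairs in the theta (4–8 Hz) and alpha (8–12 Hz) bands,
   percentile-thresholded binary adjacency (85% / 90% thresholds), and the
   small-world statistic

   ω = L_rand / L − C / C_latt

   where C and L are the clustering coefficient and characteristic path
   length of the measured graph and the references come from matched
   Watts–Strogatz models (β = 1 random, β = 0 ring lattice). ω ≈ 0 marks a
   small-world graph; ω > 0 random-like, ω < 0 lattice-like organization.
5. **Statistics** — 2×2 repeated-measures ANOVA (feature overlap × response
   relation) with partial η², Bonferroni-corrected paired post-hocs, and an
   interaction report across all dependent measures.

The synthetic generator injects each piece of structure the chain is meant
to detect: a C component whose amplitude carries the overlap × response
interaction, per-trial C-latency jitter, and theta-band coupling with 90°
phase lags whose topology (ring lattice vs fully rewired) depends on the
condition — so partial-repetition costs come with a more random, less
efficient network and benefits with a more lattice-like one.

## Worked example

```python
from bindnet import RunConfig, run_simulation_study

cfg = RunConfig(seed=7, n_subjects=5, n_repeats=3, n_channels=30,
                bands={"theta": (4.0, 8.0)}, percentiles=(85.0,),
                output_dir="bindnet_out")
bundle = run_simulation_study(cfg)
cols = ["measure", "interaction_F", "interaction_p",
        "interaction_partial_eta_sq"]
print(bundle["report"][cols].round(4).to_string(index=False))
```

simulates five subjects (384 trials each, 30 channels) end to end in about
20 s and prints:

```
       measure  interaction_F  interaction_p  interaction_partial_eta_sq
      accuracy        10.2718         0.0327                      0.7197
            rt        18.3551         0.0128                      0.8211
            p3        18.0931         0.0131                      0.8189
     c_cluster        15.9393         0.0162                      0.7994
omega_theta_85        31.3913         0.0050                      0.8870
```

One row per dependent measure with the overlap × response interaction test
(F, p and partial η² with 1 and 4 degrees of freedom): the crossover
injected into behavior, into the C component's amplitude, and into the
theta coupling topology is recovered on every measure — the strongest
effect sits on the small-world ω, where lattice-like vs random-like
coupling separates cleanly. The same run writes `behavior.tsv`, `measures.tsv`,
`network.tsv` (per subject × condition × band × threshold: C, L, the
Watts–Strogatz references and ω), `anova_report.tsv` and `summary.json` to
the output directory.

A command-line interface mirrors the library:

```
bindnet simulate --seed 1 --n-repeats 3 --out subject.h5
bindnet preprocess subject.h5 --out subject_csd.h5
bindnet network subject.h5 --out network.tsv --percentile 85
bindnet run-all --config config.json
```

## Layout

```
src/bindnet/
  containers.py   EpochSet / Montage / TrialRecord + HDF5 and TSV I/O
  design.py       factorial paradigm and behavioral model
  simulate.py     synthetic EEG with injected ground truth
  preprocess.py   filtering, referencing, rejection, CSD, segmentation
  csd.py          spherical-spline surface Laplacian
  erp.py          condition averages, amplitudes, electrode validation
  ride.py         S/C/R residue iteration decomposition
  network.py      imaginary coherence, graph metrics, small-world omega
  stats.py        repeated-measures ANOVA, post-hocs, effect sizes
  pipeline.py     end-to-end simulation study
  cli.py          command-line interface
```

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
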