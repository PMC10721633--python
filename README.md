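# spotdrop

Analysis of single-molecule TIRF "disappearing spot" experiments that
quantify DnaA-mediated DNA strand separation, plus the companion
fluorescence-quench (BHQ) plate-assay kinetics.

In the imaging assay, fluorescently labelled DNA scaffolds are
immobilized on a coverslip and imaged as diffraction-limited spots in
a 10-min time-lapse (one frame every 5 s, 121 frames). When DnaA·ATP
separates the DNA strands, the labelled oligonucleotide leaves the
evanescent field and its spot disappears. The analysis chain is:

1. **drift correction** — subpixel phase cross-correlation against
   frame 0, with a validity mask for border fill;
2. **spot detection** — smoothed local maxima above a robust
   (median + k·1.4826·MAD) threshold on a reference image, fixed
   circular ROIs with background annuli;
3. **intensity traces** — per frame, ROI sum minus annulus-median
   background, normalized to the mean of the first 5 frames;
4. **drop calling** — a spot is a *drop* iff its normalized intensity
   is strictly below **0.75** of initial for **5 sequential frames**;
5. **summaries** — per-condition drop fractions `n_drops / n_total`
   with Wilson 95% confidence intervals and replicate mean ± SD.

Because raw movies for this assay are not deposited anywhere, the
package ships a forward-model simulator (Gaussian PSF, competing
drop/photobleach exponential events, stage drift, Poisson + read
noise) with per-spot ground truth, and condition presets that encode
the assay's published end-point counts (e.g. ATP 255/330,
ADP 48/413, no protein 44/340) as generating probabilities. A second
module handles plate-reader strand-separation kinetics: per-timepoint
background subtraction over triplicates, early-window rates, and melt
temperatures from dF/dT.

## Worked example

Simulate the DnaA·ATP condition (330 spots, generating drop
probability 255/330 ≈ 0.773) and run the full pipeline:

```python
from spotdrop import (SimulationConfig, simulate_movie, analyze_movie,
                      condition_preset, match_spots_to_truth,
                      relabel_calls, evaluate_against_truth)

preset = condition_preset("ATP")
config = SimulationConfig(
    field_shape=(256, 256),          # reduced field: all 330 spots in one view
    n_spots=preset.n_spots,
    min_spacing=6 * 0.16,            # 6 px in µm
    drop_probability=preset.drop_probability,
    photobleach_rate=0.0,
    seed=1,
)
movie, truth = simulate_movie(config)
result = analyze_movie(movie)        # register → detect → trace → call
s = result.summary("ATP")
print(f"{s.condition}: {s.n_drops} drops / {s.n_total} usable spots "
      f"= {100*s.fraction:.1f}% (95% CI {100*s.ci_low:.1f}-{100*s.ci_high:.1f}%)")

mapping = match_spots_to_truth(result.spots, truth)
m = evaluate_against_truth(relabel_calls(result.calls, mapping), truth)
print(f"recall {m.recall:.3f}, precision {m.precision:.3f}, "
      f"median frame error {m.median_frame_error:.1f}")
```

Output:

```
ATP: 241 drops / 330 usable spots = 73.0% (95% CI 68.0-77.5%)
recall 1.000, precision 1.000, median frame error 0.0
```

The simulated ground truth for this seed contains exactly 241 drops
out of 330 spots (a binomial draw around 0.773): the pipeline
recovered every event, at the correct frame, with no false positives.

The same stages are available as a CLI for working with movie files:

```sh
spotdrop simulate --preset ATP --out movie.tif --truth truth.csv --seed 1
spotdrop register --in movie.tif --out corrected.tif --drift drift.csv
spotdrop detect   --in corrected.tif --out spots.csv
spotdrop trace    --in corrected.tif --spots spots.csv --out traces.csv
spotdrop call     --traces traces.csv --out events.csv
spotdrop summarize --events events.csv --condition ATP --out summary.csv
```

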