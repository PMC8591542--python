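# ermorph

Quantitative analysis of endoplasmic reticulum (ER) morphology in budding
yeast fluorescence microscopy, built for genome-scale screens of ER
expansion.  The package re-implements, as a tested and reusable pipeline,
the three computational stages such a screen needs:

1. **Mid-section morphometry** (`ermorph.midcell`) — automated cell
   segmentation in optical mid sections (cytosolic BFP: Fourier bandpass →
   Frangi vesselness → Otsu → opening + size filter → interior labelling →
   MAD brightness filter → watershed), per-cell refocusing on the
   curvature marker, a cell border from the **minimum-volume enclosing
   ellipse** of the segmented ER, and three ER-size metrics measured in the
   5-px periphery band *B* inside that border:

   * peripheral ER size  = |ER ∩ B| / |B|
   * ER profile size     = mean area of connected ER profiles in B / |B|
   * ER gaps per µm      = number of connected components of B \ ER per µm
     of cell periphery

   followed by a 2.5-SD population filter over all per-cell measurements.

2. **Cortical tubule/sheet classification** (`ermorph.cortical`) — the
   tangential view of the cortical ER is segmented per channel in two
   ring-kernel passes (small features = tubules, large features = sheets;
   a pixel must exceed the mean of its surrounding ring by a configurable
   *strength* and exceed an Otsu-derived background level).  Sheets are
   separated from tubules by a morphological opening controlled by the
   *trimming factor*; sheet-like regions of the curvature marker (Rtn1,
   which labels tubules and sheet rims but not sheet interiors) that overlap
   the general-ER mask are re-labelled **tubular clusters** and moved to the
   tubule class.  Tubules and sheets exactly partition the total-ER mask.

3. **Screen Z-scoring** (`ermorph.screen`) — plate-mean normalization of
   marker intensity with LOWESS corrections against cell size and cell
   count, a per-plate *background population* (rows within 1.5 SD of the
   plate's mean corrected intensity), per-field Z = (sample − BP mean) /
   BP SD per metric, LOWESS corrections against well order and cell count,
   signed max-|Z| aggregation over the two fields of each well, and hit
   calling (Z < −2 for peripheral ER size and profile size, Z > 2 for gaps,
   in ≥ 2 of the 3 metrics).

Because raw screen images of this kind are rarely deposited, the package
ships a first-class **synthetic-microscopy generator** (`ermorph.synth`)
that renders seeded multi-channel fields (bright-field, cytosolic BFP,
general ER marker, high-curvature ER marker; five optical slices spaced
1 µm with focus-dependent blur) plus pixel-exact ground truth, and seeded
screen tables with plate offsets, smooth covariate trends and planted
mutant effects.  Every pipeline stage is validated against this ground
truth.

## Worked example

```python
from ermorph.synth import mid_spec, render_mid_field
from ermorph.midcell import analyze_mid_field

field = render_mid_field(mid_spec(seed=7, er_band_coverage=0.9, n_gaps_per_cell=2))
cells, table, _ = analyze_mid_field(field.channels)
print(table[["label", "peripheral_er_size", "er_profile_size",
             "er_gaps_per_um", "n_gaps"]].round(3).to_string(index=False))
```

```
 label  peripheral_er_size  er_profile_size  er_gaps_per_um  n_gaps
     1               0.801            0.400           0.141       2
     2               0.848            0.424           0.150       2
     3               0.858            0.429           0.182       2
     ...
```

Each row is one segmented cell: the rendered field covers 90% of the cell
border with ER interrupted by 2 gaps, and the pipeline reads back a
peripheral ER size of ~0.8–0.86 (slightly below the rendered 0.9 because
segmentation trims the blurred profile edges) and exactly 2 gaps per cell.
With two 50%-arcs the profile size is half the peripheral size, as here.

Scoring a simulated screen with one strong planted hit:

```python
from ermorph.synth.screen import ScreenSimSpec, simulate_screen_table
from ermorph.screen import ERExpansionScreen

planted = {"mutX": {"peripheral_er_size": -4.0, "er_profile_size": -4.0}}
table, truth = simulate_screen_table(
    ScreenSimSpec(n_plates=4, wells_per_plate=100, seed=3, planted_hits=planted))
results = ERExpansionScreen(table).fit()
print(results.summary())
```

```
ER expansion screen scoring
============================================
plates:            4
samples scored:    400
fields scored:     800
low-count dropped: 0
hits called:       4 (1.02% of mutants)

aggregated Z per metric (mean / SD):
  z_peripheral   -0.023 / 1.024
  z_profile      -0.032 / 1.039
  z_gaps         -0.007 / 1.067
```

`results.hits` lists the called strains; the planted mutant is recovered at
Z = (−3.3, −5.1, +0.4) — flagged on both planted metrics — alongside three
borderline null strains, consistent with the ~0.7% null hit rate of the
2-of-3 rule at these thresholds.

## Command line

```bash
ermorph simulate --section mid --out field/ --seed 1
ermorph segment-mid --bfp field/bfp.tif --sec63 field/sec63.tif \
    --rtn1 field/rtn1.tif --out segmented/
ermorph classify-cortical --sec63 g.tif --rtn1 h.tif --cells m.tif --out cls/
ermorph simulate-screen --out screen/ --seed 1
ermorph score-screen --table screen/screen.csv --out scored/
```

Channels are multi-page TIFF (pages = z-slices), label masks 16-bit TIFF,
tables CSV, parameters YAML; `segment-mid` and `classify-cortical` also
write QC overlay PNGs.

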