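# onhcolor — optic nerve head hemoglobin colorimetry

Axonal loss in the optic nerve shows up at the fundus as progressive
pallor of the optic disc (papilla), but the eye of an examiner cannot
quantify it — visible pallor requires more than half the nerve fibers to
be gone.  Because the disc contains essentially a single pigment,
hemoglobin (Hb), its color *can* be quantified: the amount of Hb behind
each pixel of an ordinary RGB fundus photograph determines how much red
is reflected relative to green.  `onhcolor` implements this measurement
for researchers studying optic-nerve involvement in neurodegenerative
disease (e.g. Parkinson's disease cohorts) and for anyone who needs a
fully reproducible, openly specified disc-colorimetry pipeline.

## The measurement

For a pixel with reflectances $(r, g, b)$ the Hb index is the
vessel-referenced red–green contrast

$$h = \frac{r - \tilde g}{\max(r, \varepsilon)}, \qquad
\mathrm{Hb\%} = 100 \cdot \frac{h_{\text{pixel}}}{h_{\text{vessel}}},$$

where $h_{\text{vessel}}$ is computed from the median channel values over
the central retinal vessels — whole blood inside the eye, the internal
100%-Hb reference.  Vessels and tissue sit under the same illumination
and behind the same crystalline lens, so intensity and spectral drifts
cancel.  Lens yellowing (cataract) attenuates blue by a factor
$\kappa$ and green by roughly $(\kappa+1)/2$; $\kappa$ is estimated from
the vessels' blue/green ratio against a clear-lens calibration constant
and the green channel is rescaled ($\tilde g = g \cdot 2/(\hat\kappa+1)$)
before the index is formed.

The disc is delimited semi-automatically (bright-region threshold +
least-squares ellipse fit, optionally seeded or supplied externally),
vessels are detected by a robust two-channel darkness rule, and the disc
is partitioned into **24 sectors** — eight 45° wedges crossed with three
concentric rings at 1/3 and 2/3 of the disc radius (inner ring ≈ cup,
outer ring ≈ neuroretinal rim).  Per-sector and whole-disc mean Hb
percentages feed the cohort statistics: Kolmogorov–Smirnov (Lilliefors)
normality gate, two-sample pooled-variance Student's *t* with Bonferroni
family correction (Hb family m=25 → P<0.002), and Pearson correlations
against RNFL thickness tables and disease stage.

No public fundus dataset carries per-sector Hb ground truth, so the
package ships a first-class synthetic generator (`onhcolor.synth`): a
two-endmember optical forward model with a branching vessel tree,
illumination gradients, lens attenuation and sensor noise, plus a cohort
simulator whose defaults follow a reference clinical case-control cohort
(155 Parkinson's / 91 healthy subjects).  The forward model is deliberately
not the inverse of the estimator, so recovery experiments are
non-circular.

## Worked example

```python
from onhcolor.pipeline import analyze_fundus
from onhcolor.synth import SubjectSpec, render_fundus

rendered = render_fundus(SubjectSpec(subject_id="demo", seed=11))
result = analyze_fundus(rendered.image)
print(f"estimated mean Hb: {result.profile.mean_hb:.2f}%  "
      f"(truth {rendered.true_profile.mean_hb:.2f}%)")
```

prints

```
estimated mean Hb: 67.79%  (truth 67.88%)
```

i.e. the pipeline recovers this subject's true whole-disc Hb percentage
to within a tenth of a point; across the 24 sectors the largest error for
this image is 0.64 points.  The `examples/` directory contains one short
script per capability (single-image analysis, dilution linearity, lens
compensation, pseudoimage rendering, cohort comparison); each prints the
numbers it computes and what they mean.  A thin CLI mirrors the common
operations: `onhcolor qc|segment|analyze|simulate|cohort --help`.

## Layout

```
src/onhcolor/
  io.py            image I/O, normalization, quality gates
  segmentation.py  disc delimitation, vessel detection
  hb.py            lens compensation, Hb map, pseudoimages
  sectors.py       24-sector partition, aggregation, eye mirroring
  stats.py         t-tests, Bonferroni, Pearson, report tables
  synth.py         forward model + cohort simulator (ground truth)
  pipeline.py      end-to-end drivers
  cli.py           thin typer CLI
docs/methods.md    model, assumptions, parameter choices, limitations
```
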