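# octquant

Quantitative OCT monitoring of the vitreoretinal interface after an
intravitreal injection of a sustained-release drug formulation.

When a particulate depot formulation (for example brimonidine adsorbed on
Laponite clay, injected at a 1/10 drug:carrier weight ratio) is placed in
the vitreous, it appears on cross-sectional OCT b-scans as hyperreflective
aggregates that slowly disperse, settle onto the inner limiting membrane
(ILM) and disappear as the depot degrades.  `octquant` turns stacks of
b-scans — 61 scans of 1536 × 496 pixels per eye per visit on the rodent
Spectralis posterior-pole protocol — into objective longitudinal markers of
that process, for researchers developing intravitreal drug-delivery systems
who want a non-invasive readout of depot degradation:

- **VIT/RPE relative intensity** — the mean vitreous pixel intensity
  divided by the mean intensity of the retinal pigment epithelium (RPE)
  band, averaged over the 61 b-scans of an eye.  Using the RPE as an
  internal reference makes the marker dimensionless and insensitive to
  device gain, so values compare across visits without contrast
  adjustment.
- **Aggregate load** — speckle is suppressed with a median filter,
  connected hyperreflective components inside the vitreous are labelled,
  components below a physical minimum area (500 µm², excluding
  physiological debris) are discarded, and the count, total area and mean
  area per eye are reported.  Two pixel-area calibrations are supported:
  the device's printed area ratio (3815 µm²/pixel) and the isotropic one
  implied by the 3 µm pixel pitch (9 µm²/pixel); every result records
  which was used.
- **ILM–RNFL thickness** — aggregates settling on the retinal surface are
  indistinguishable from the ILM–retinal-nerve-fibre-layer band, so the
  co-layer is segmented as one unit and its mean thickness tracks the
  deposited mass.
- **Longitudinal statistics** — per-week group time series,
  Kolmogorov–Smirnov distribution checks, Mann–Whitney U cohort
  comparisons, paired Wilcoxon within-eye change, linear and logarithmic
  trend fits (y = a·ln x + b), and Pearson correlation of imaging markers
  with measured drug levels (ng/mL).

Raw scans from such studies are generally not public, so the package ships
a first-class synthetic generator: layered b-scan phantoms with
multiplicative lognormal speckle, planted elliptical aggregates with known
pixel support, and whole longitudinal studies whose aggregate load rises to
a swelling peak two weeks after injection, decays fast to week 6 and
plateaus from week 12, with exponentially decaying drug levels.  Every
generated object carries its ground truth, which is how the pipeline is
validated.

## Worked example

```python
from octquant import PhantomParams, PipelineConfig, gen_session, run_eye

phantom = PhantomParams(n_rows=248, n_cols=512, ilm_row=100, rnfl_outer_row=115,
                        rpe_inner_row=190, rpe_outer_row=205,
                        vit_mean=60.0)            # hazy treated-eye vitreous
session, truth = gen_session(phantom, n_bscans=5, n_aggregates_per_scan=4,
                             area_px=(112, 224), contrast=(2.0, 2.5),
                             seed=42, eye_id="T00", week=2.0)
config = PipelineConfig(calibration="isotropic")   # 9 um^2/pixel
result, retained = run_eye(session, config)
```

prints (via the report lines in the example script):

```
eye T00, week 2
VIT/RPE relative intensity : 0.3064  (truth 0.3000)
aggregates retained        : 20  (planted 20)
total aggregate area       : 29709 um^2  (planted 30150)
mean aggregate area        : 1485 um^2
ILM-RNFL thickness         : 46.4 um  (truth 45.0)
```

The estimated VIT/RPE ratio lands within ~2% of the generator's
µ_vit/µ_RPE = 0.30, all twenty planted aggregates are recovered with ~1.5%
total-area error, and the co-layer thickness matches the constructed
15-row band at 3 µm/pixel.

The same pipeline is available from the shell:

```
octquant generate --design design.yaml --out study/
octquant analyze-study study/ --config config.yaml --out results/
octquant report results/study_results.tsv --plots --out results/
```

AVI exports from the device must be decoded to frame directories (e.g.
with ffmpeg) before analysis; the numeric core only accepts decoded
frames.

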