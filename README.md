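# stedclust

Quantitative analysis of two-colour STED micrographs of membrane
sheets, built around an object-based view of protein nanodomains:
membrane proteins such as tetraspanins concentrate in diffraction-
limited spots ("maxima"), a subset of well-formed spots are rated
*clusters*, and questions about co-assembly and agglomeration are
answered from cluster positions and intensities rather than from pixel
correlation.

The package provides the complete pipeline plus a synthetic-data
generator with ground truth, so every stage can be validated:

1. **Preprocessing** — spectral crosstalk correction
   (`out = max(long_red − 0.5·red, 0)`) and Gaussian noise reduction
   (σ = 0.5 px).
2. **Maxima detection** — local maxima with a *noise tolerance* t
   (ImageJ-style prominence): a candidate peak p is reported iff the
   8-connected region of pixels above `I(p) − t` reachable from p
   contains neither a higher pixel nor a previously accepted maximum.
3. **Quantification** — per maximum: mean intensity in a 100 nm
   (13-pixel) circular ROI in both channels, background-corrected;
   intensity-weighted mass centre at sub-pixel resolution; 31 px × 3 px
   linescans fitted with `b + A·exp(−(x−μ)²/2σ²)`. A maximum is a
   **cluster** iff the best fit has R² > 0.8 and |μ − 15| ≤ 5 px, and
   its size is FWHM = 2√(2 ln 2)·σ.
4. **Spatial statistics** — directional shortest distances between the
   cluster mass centres of the two channels (overlap: d ≤ 60 nm),
   cluster densities per µm², and per-maximum crowding: the number of
   same-channel maxima within a 900 nm circle (self excluded).
5. **Statistics** — decomposition of crowding histograms into one or
   two Gaussians by least squares (area fraction of component i is
   `Aᵢσᵢ/ΣAⱼσⱼ`, F-test model preference); through-origin regression
   `slope = Σxy/Σx²` of paired maxima intensities with a 2 a.u. noise
   gate; replicate aggregation with a two-sided unpaired Student's
   t-test.
6. **Simulation** — a clustered point process (CSR background plus a
   Thomas-type parent–child process for µm-scale "arranged crowds"),
   configurable channel composition, log-normal spot brightness, exact
   Gaussian-PSF rendering, Poisson + read noise, per-spot detection
   dropout — with the full ground truth table written alongside the
   images.

## Worked example

Simulate a 10.24 µm × 10.24 µm membrane sheet pair (100 nm PSF) and
analyse it:

```sh
stedclust simulate --config sim.toml --outdir data --seed 42
# wrote 614 assemblies to data
stedclust analyze --self data/channel_A.tif --other data/channel_B.tif \
    --params params.toml --self-channel CD9 --other-channel CD81 --outdir run
```

prints the per-channel summary (also written to `run/summary.csv`):

```
channel  n_maxima  n_clusters  density_per_um2  overlap_pct  mean_neighbors  ...
    CD9       468         326         3.108978    55.214724        2.474359
   CD81       486         352         3.356934    52.272727        2.650206
```

Reading: both channels show ~3.1–3.4 clusters/µm². 55% of CD9 clusters
have a CD81 cluster within 60 nm (and 52% vice versa) — close to the
simulated truth, where 40% of all assemblies carry both labels, i.e.
57% of the CD9-bearing ones. Maxima average ~2.5 neighbours within
their 900 nm circle, as expected for an unorganized (CSR) pattern at
this density.

Decomposing a crowding histogram (here 5000 counts drawn from a 68/32
mixture of populations with ~3.5 and ~12 neighbours):

```sh
stedclust decompose neighbors.csv --k 2
```

```json
{
  "components": [
    {"amplitude": 14.77, "mean": 3.42, "sd": 1.82},
    {"amplitude": 4.42,  "mean": 11.83, "sd": 2.99}
  ],
  "area_fractions": [0.671, 0.329],
  "r2": 0.996,
  "model_preferred": "double"
}
```

The second (higher-mean) Gaussian is the arranged-crowd population: 33%
of the area, mean ≈ 11.8 neighbours — recovering the simulated 32% /
~12 within sampling error.

`stedclust report COND_A COND_B --metric overlap_pct` aggregates
per-sheet summaries into replicate means and tests the two conditions
(two-sided unpaired t-test, stars at p < 0.05 / 0.01 / 0.001).

Every run writes a `manifest.json` with the parameters used and SHA-256
checksums of all outputs; identical inputs reproduce byte-identical
bundles.

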