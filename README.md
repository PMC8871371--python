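# omiflim

Label-free **optical metabolic imaging** analysis for fluorescence-lifetime
microscopy (FLIM) of immune cells, with a synthetic TCSPC data generator so
the whole pipeline runs and validates without a microscope.

Autofluorescence of the metabolic coenzymes NAD(P)H and FAD reports the
intracellular redox state of single cells in live tissue. `omiflim`
implements the full analysis chain used to study macrophage metabolism in
wounded zebrafish larvae:

1. **simulate** — render per-pixel TCSPC decay cubes (256 time bins,
   Poisson photon counting, 260 ps Gaussian IRF) plus mCherry/GFP reporter
   images for cohorts of cells nested in larvae nested in experiment days,
   with known ground truth;
2. **fit** — recover per-pixel two-component decays by IRF-convolved
   bounded least squares:
   `I(t) = α₁e^(−t/τ₁) + α₂e^(−t/τ₂) + C`, α₁+α₂ = 1, τ₁ < τ₂;
3. **segment** — macrophage masks from the mCherry channel
   (rescale-by-max, threshold 0.15, 8-connected labeling) and per-cell
   TNFα classification from the GFP reporter;
4. **endpoints** — per-cell means of the optical redox ratio
   ORR = I_NAD(P)H / (I_NAD(P)H + I_FAD), mean lifetimes
   τₘ = α₁τ₁ + α₂τ₂ for both channels, component lifetimes/fractions, and
   the OMI index ORRᵢ/⟨ORR⟩ + τₘᴺᵢ/⟨τₘᴺ⟩ − τₘᶠᵢ/⟨τₘᶠ⟩;
5. **stats** — Gaussian general linear models per endpoint with day
   blocking and **cluster-robust (CR1) standard errors clustered by
   larva**, reporting estimated group means with 95% CI and fold-change
   contrasts with p-values.

See `docs/methods.md` for the models, defaults, and numerical choices.

## Worked example

Simulate a two-day cohort of six larvae (ten macrophages each, half
TNFα+), push every field through fitting, segmentation and per-cell
averaging, and test whether TNFα+ cells are more oxidized:

```python
from omiflim import CohortDesign, GlmSpec, fit_glm
from omiflim.pipeline import run_cohort

design = CohortDesign(
    treatments=("control",), tnfa_fraction=0.5,
    n_days=2, larvae_per_day=3, cells_per_larva=10,
    field_shape=(64, 64), radius_range=(3.0, 4.0), seed=7,
)
cells, truth = run_cohort(design)
print(cells[["cell_id", "larva_id", "tnfa_status", "orr",
             "nadph_tm", "nadph_a1", "omi"]].head(5).round(3))

res = fit_glm(cells, GlmSpec(outcome="orr", treatment="tnfa_status",
                             block="day_id", log_transform=True,
                             cluster="larva_id"))
print(res.group_means.round(4))
print(res.contrasts.round(4))
```

Output:

```
 cell_id      larva_id tnfa_status   orr  nadph_tm  nadph_a1   omi
       1 control-d0-l0    negative 0.669     1.102     0.632 1.212
       2 control-d0-l0    negative 0.655     1.031     0.666 1.141
       3 control-d0-l0    negative 0.671     0.929     0.662 1.171
       4 control-d0-l0    negative 0.692     1.075     0.632 1.262
       5 control-d0-l0    negative 0.664     0.853     0.688 1.089

   group   mean  ci_low  ci_high
negative 0.6711  0.6677   0.6744
positive 0.5711  0.5676   0.5746

 group_a  group_b  type  estimate  ci_low  ci_high  p_value
negative positive ratio    1.1751   1.164   1.1863      0.0
```

The estimated redox ratio of TNFα− cells is 0.671 (95% CI 0.668–0.674)
versus 0.571 for TNFα+ cells: TNFα+ macrophages are ~17% more oxidized
(fold change 1.175, CI 1.164–1.186), recovering the ~15% reduction the
generator injected. The OMI index averages exactly 1 over the cohort by
construction. p-values use a t reference with (larvae − 1) degrees of
freedom, so the clustering of cells within larvae is respected.

The same pipeline runs from the shell:

```sh
omiflim run-all --seed 7 --out runs/demo        # full chain + manifest
omiflim simulate --seed 1 --out runs/sim        # individual stages
omiflim fit --cube runs/sim/field_000/nadph.tif --irf runs/sim/irf.csv \
    --channel nadph --out runs/maps.tif
omiflim stats --table runs/demo/cells.csv --outcome orr \
    --treatment tnfa_status --cluster larva_id --log --out runs/stats
```

Decay cubes and parameter maps travel as multi-page TIFF with JSON
sidecars, tables as CSV, and `run-all` writes a manifest with the seed,
every parameter, and a checksum of every artifact, so a rerun with the
same configuration reproduces identical outputs.

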