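# imic — immunofluorescence multichannel image cytometry

`imic` quantifies cell lineages and their marker-coexpression patterns in
4-channel fluorescence images of tissue sections: a DAPI nuclear
counterstain plus three antibody channels — AF488 (pancytokeratin,
epithelial cells), eFluor 570 (vimentin, connective-tissue cells) and
AF594 (CD45/CD18, leukocytes). It is written for tissue cytometry of
upper-airway mucosa (epithelium over lamina propria), where flow
cytometry is impossible without destroying the tissue context, but the
pipeline is generic for any three-marker panel with a nuclear master
channel.

The pipeline:

1. **Nuclear segmentation** in the DAPI channel (smoothing → threshold →
   watershed splitting of conglomerates), then the *remove labels* gate
   keeping only biologically plausible nuclei with area in [40, 100] µm².
2. **Cell-mask growing** per marker channel: masks grow outward and
   inward from the nuclear margin in 0.5 µm rings until a sudden
   intensity step (a ≥ 50% drop between consecutive ring medians) or the
   per-channel limit — 2.0 steps for AF488/AF594, 4.0 for eFluor 570,
   whose elongated vimentin-positive cells need deeper growth.
3. **Positivity gating** by the cell/background ratio r = m/b, where m is
   the cell's mean mask intensity and b the median intensity of the
   nucleus-free background. The per-channel threshold τ is the upper
   bound of the distribution-free 95% CI of the median ratio over a 30%
   random cell sample; a cell is positive iff r > τ (strict). The
   relative-difference form (m−b)/m is also available and provably
   classifies identically.
4. **Population analysis**: the three positivity booleans map onto 8
   populations (3 single, 3 double, triple positive, triple negative),
   cross-tabulated by tissue region and diagnosis group with percentages
   per stratum, plus paired Wilcoxon and Bonferroni-corrected pairwise
   proportion tests.
5. **Quality controls**: isotype-control ROC per channel (Mann–Whitney
   AUC) and channel-spillover quantification from single-stain runs
   (off-target positivity against a 1% bound).

Because public datasets for this assay do not exist, the package ships a
first-class **synthetic tissue phantom** generator (`imic.phantom`): a
pseudostratified epithelial band over a lamina propria, non-overlapping
elliptical nuclei (lognormal areas, 64 µm² median) at 3486 cells/mm²,
cytoplasmic marker annuli, gland clusters, diffuse background, sub-1%
channel spillover and 14-bit camera noise — with a full per-cell ground
truth table, plus matched isotype-control and single-stain slides. Every
stage of the pipeline is validated against this truth.

## Worked example

```python
import imic

cfg = imic.PhantomConfig(width_px=1380, height_px=1380, seed=1)  # 0.35 mm field
stack, truth, regions = imic.generate_phantom(cfg)
result = imic.analyze_stack(stack, regions, seed=1)

for c, t in result.thresholds.items():
    print(c, round(t.tau, 3))
print(result.populations.percentages("all", "lamina_propria").round(1))
```

prints (seed 1):

```
af488 1.443
efluor570 2.691
af594 1.664
population
cytokeratin_single_positive             29.0
vimentin_single_positive                14.8
cd45cd18_single_positive                 7.3
cd45cd18_vimentin_double_positive       16.3
cytokeratin_vimentin_double_positive     3.4
cytokeratin_cd45cd18_double_positive     9.8
triple_positive                          5.2
triple_negative                         14.2
```

The three numbers after the channel names are the realized
cell/background-ratio thresholds τ; the table gives the percentage of
lamina-propria cells in each marker-combination population. On this
small field the percentages track the generator's truth to within a few
points; the residual drift comes from overlap artifacts (a bright
neighbour's cytoplasm leaking into a negative cell's mask) — the same
effect that inflates double-positive counts in real tissue — and shrinks
with field size. The `examples/` directory has one short script per
capability (phantom generation, segmentation + gate, growing +
quantification, gating + populations, controls + statistics); each prints
its numbers with a line of interpretation.

A thin CLI covers the same stages from a shell
(`imic simulate | run | classify | qc`; see `imic --help`). The
`classify` subcommand is the tabular entry point for users who bring
their own per-cell intensity tables.

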