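# canapy

Spatial phylogenetics for gridded species ranges: range-weighted
**phylogenetic endemism (PE)**, **CANAPE** classification of neo-, paleo-
and mixed-endemism hotspots, spatially explicit driver regression, and
protection-coverage accounting — with a synthetic-scenario generator so
the whole pipeline runs and is testable without any data downloads.

It is written for macroecologists who have (i) a rooted, dated phylogeny
(Newick), (ii) presence–absence of species over equal-area grid cells,
and (iii) per-cell environmental, threat and protection layers, and who
want to ask: *where is evolutionary history geographically rarest, is
that rarity old or young, what drives it, and how well is it protected?*

## The metrics and the test

For a branch *b* with length *L_b*, let *R_b* be the number of grid cells
occupied by at least one descendant tip. Then per cell *c*

```
PE(c) = Σ_{b : b present in c} L_b / R_b
```

optionally divided by total tree length so PE is the proportion of the
tree restricted to the cell. **RPE** = PE_original / PE_equal, where
PE_equal is computed on a comparison tree with identical topology and all
branch lengths equal (total length preserved): RPE strips out branch-length
information, so high RPE marks concentrations of rare *long* branches
(paleo-endemism) and low RPE rare *short* branches (neo-endemism).

Significance comes from a tip-shuffle null (999 iterations by default):
permuting the tip labels preserves topology, the branch-length multiset,
per-cell richness and per-species range size. CANAPE then classifies each
cell: a cell passes the gate if PE_original or PE_equal is above the
97.5% null quantile; gated cells are **paleo** (RPE significantly high),
**neo** (RPE significantly low) or **mixed** (neither). Neo, paleo and
mixed cells together are the endemism *hotspots*. Only cells with ≥ 5
species are analysed.

Downstream, log10 PE is regressed on standardized drivers (current MAT
and AP, paleoclimate anomalies = past − present, elevation range) by OLS
and by a maximum-likelihood **SAR error model**
`y = Xβ + u, u = λWu + ε` over k-nearest-neighbour spatial weights
(k chosen by AIC), with VIF, Moran's *I* and correlogram diagnostics.
Hotspot/non-hotspot contrasts in environment, human modification and
future climate anomalies use **Fisher–Pitman permutation tests** (exact
enumeration when feasible), with max-T-adjusted post-hoc comparisons and
a compact letter display. Protection coverage of hotspot classes is
reported for an existing protected-area mask and nested top-17/30/50%
priority-area masks.

## Worked example

The bundled synthetic scenario plants three 3×3 refugium blocks (paleo,
neo, mixed endemics) in an 18×14 lattice of 252 cells with 140 species:

```bash
canapy run --seed 0 --iters 999 --out-dir demo_out
```

or in Python:

```python
from canapy import PipelineConfig, ScenarioSpec, run_pipeline
result = run_pipeline(PipelineConfig(out_dir="demo_out",
                                     scenario=ScenarioSpec(seed=0),
                                     n_iter=999, seed=0))
print(result.category_table)
```

prints (seed 0):

```
       category  count  fraction  percentage
            neo      5  0.031646         3.2
          paleo     10  0.063291         6.3
          mixed      4  0.025316         2.5
non_significant    139  0.879747        88.0
        hotspot     19  0.120253        12.0
```

19 of 158 analysed cells are endemism hotspots, and every planted block
is recovered (9 paleo, 5 neo, 4 mixed cells classified as planted). The
driver stage reports the SAR error model (best k = 5) with spatial-error
parameter λ = 0.87 and Nagelkerke pseudo-R² = 0.69 against adjusted
R² = 0.37 for the OLS, whose residual autocorrelation the SAR fit removes
(Moran's *I* on the whitened residuals: p = 0.54). Hotspot cells show
significantly smaller paleoclimate anomalies and larger elevation ranges
than non-hotspots (Fisher–Pitman p < 0.01), and coverage of hotspots
rises from 5.3% under the existing-PA mask to 73.7% / 89.5% / 89.5%
under the top-17/30/50% priority masks.

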