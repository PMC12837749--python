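# camtrapnet

Camera-trap surveys record which species visit which sites and when. For
community ecologists asking *how a community is structured around a focal
species* — which species share space with it, which track it, and which avoid
it in space or time — those detections can be distilled into a species
association network. `camtrapnet` implements that full analysis path as a
tested Python library: from raw detection records to a two-layer network of
symmetric spatial associations and directed one-way dependencies, with a
synthetic community generator so every stage can be validated against planted,
known structure.

## What it computes

Starting from records `(site, species, timestamp)`:

1. **Independence filtering.** Records of the same species at the same site
   within 30 min of an event's first photograph are merged into one
   *independent detection event* (window configurable). Events are tabulated
   into an `r × S` site × species count matrix with a presence view.
2. **Abundance screen.** Relative abundance index
   `RAI_i = 100 · n_i / Σ n_i`; species with RAI above the community mean
   (100/S) are carried into the association analyses.
3. **Niche metrics.** From usage shares `P_ij` (species *i*'s fraction of
   events at site *j*): Levins breadth `B_L = 1/Σ_j P_ij²`, Shannon breadth
   `B_S = −Σ_j P_ij ln P_ij`, and the Pianka overlap
   `O_ik = Σ_j P_ij P_kj / √(Σ_j P_ij² Σ_j P_kj²)`.
4. **Community association.** Schluter's variance ratio
   `V_R = [(1/N) Σ_j (T_j − t̄)²] / [Σ_i p_i(1 − p_i)]` with `T_j` the
   species richness of site *j*; `V_R = 1` under independence. Its statistic
   `W = V_R · N` is referred to a two-sided chi-square band.
5. **Pairwise association.** From each 2 × 2 presence table (a = both,
   b/c = one only, d = neither): `φ = (ad − bc)/√((a+b)(a+c)(b+d)(c+d))` and
   the Yates-corrected `χ² = n(|ad − bc| − n/2)₊² / ((a+b)(a+c)(b+d)(c+d))`,
   classed against 3.841 (p = 0.05) and 6.635 (p = 0.01).
6. **Directed predictability.** Goodman–Kruskal asymmetric lambda: the
   proportional reduction in error predicting one species' presence from the
   other's, with bootstrap prediction-rate limits (`L_B` upper, `λ_BO`
   lower); `λ_BO > 0` flags a one-way "commensal" dependence.
7. **Diel activity overlap.** Event times become radians on the day-circle;
   von Mises kernel densities (Taylor plug-in bandwidth) give the overlap
   `Δ = ∮ min(f̂₁, f̂₂)` (small-sample Δ1 below 75 events, else Δ4), with a
   1000-rep smoothed-bootstrap 95% CI and a permutation test on 1 − Δ.
8. **Network assembly.** Abundance-screened species become nodes; significant
   φ/χ² pairs become signed undirected edges; significant lambdas become
   directed edges. Export as edge-list CSV and GraphML.

A Gaussian-copula community generator (`camtrapnet.simulate`) produces
detections with planted occupancies, pairwise associations (targeted as
latent correlations or φ values), overdispersed counts, and von Mises mixture
diel profiles. Three presets ship with the package, including `paper_like`: a
67-site, one-year, 12-species design with a strongly co-occurring pair, a
commensal pair, and a bimodal crepuscular focal species.

## Worked example

```python
from camtrapnet import build_matrix, filter_independent, rai_table, variance_ratio
from camtrapnet.association import pairwise_association_table, lambda_table
from camtrapnet.simulate import load_preset, simulate_presence, simulate_detections

spec = load_preset("paper_like")
presence = simulate_presence(spec, seed=42)
records = simulate_detections(presence, spec, seed=43)
matrix = build_matrix(filter_independent(records))

community = variance_ratio(matrix.presence)
abundance = rai_table(matrix.event_counts())
selected = list(abundance.index[abundance["selected"]])
pairs = pairwise_association_table(matrix, selected)
print(pairs[pairs["class"] != "none"].round(3))
```

prints (seed 42/43):

```
species_a            species_b   phi  chi2_yates     sign              class
 elephant red_bellied_squirrel 0.601      21.701 positive highly_significant
  muntjac            wild_boar 0.912      52.099 positive highly_significant
```

— exactly the two planted associations: the muntjac–wild boar pair co-occurs
far more often than chance (φ = 0.91, χ² ≫ 6.635), and the squirrel sits
inside the elephant's range. The direction of the latter shows in lambda:

```
           predictor            predicted  lambda   L_B  lambda_BO  significant
            elephant red_bellied_squirrel   0.545 0.883      0.381         True
red_bellied_squirrel             elephant   0.286 0.571     -0.081        False
```

Knowing elephant presence reduces the error in predicting squirrel presence
by 55% (lower limit 0.38 > 0), while the reverse direction is not
significant — a one-way, commensal-style spatial dependence. Activity
overlap between a crepuscular and a nocturnal profile
(`examples/04_activity_overlap.py`):

```
overlap Delta (delta4) = 0.48  [95% CI 0.44-0.53]
permutation p for equal rhythms = 0.000
```

Δ is the shared area under the two diel activity curves (1 = identical
rhythms); here the species share about half their activity time and their
rhythms differ significantly.

Each script in `examples/` is a short, runnable walk-through of one
capability; `examples/05_full_pipeline.py` (or
`camtrapnet run-all --preset paper_like --seed 11 --out-dir out/`) produces
the full report directory: events, matrix, abundance, breadth, overlap,
community, pairwise, lambda, activity and network tables plus a manifest.

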