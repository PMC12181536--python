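# senetrace

Single-cell analysis of **diverging senescence subpopulations** from
multiplexed immunofluorescence (4i) time courses.

When cultured cells are pushed into senescence by sustained DNA damage
(e.g., continuous etoposide), bulk measurements show a smooth two-phase
story: markers and nuclear area rise until about day 11, then plateau.  At
the single-cell level that plateau is a mixture of discrete states appearing
at different times — a senescent transitional population within two days,
a large-nuclear senescent population around day 11, and a rare
high-concentration, SASP-producing population (cytoplasmic IL-6/JAK2/pSTAT3)
only from day 17, still under 10% of cells at day 31.  `senetrace`
implements the analysis chain that resolves this structure and exercises it
end to end on synthetic data with the same statistical structure.

## What the package does

1. **Quantify** (`senetrace.quantify`) — registers imaging rounds by phase
   correlation, segments nuclei (Otsu + watershed, or external masks), and
   extracts per-cell features: nuclear area `A` (px), per-marker nuclear
   mean `m̄`, nuclear **total** `T = A · m̄` (the total-protein proxy), and
   the mean over a 5-pixel cytoplasmic ring around each nucleus.
2. **Embed** (`senetrace.embed`) — z-normalizes features, subsamples up to
   1,200 cells per time point with a density-preserving sketch, and computes
   a 3D diffusion-potential embedding: adaptive α-decay kernel → diffusion
   operator `P` → `P^t` (t by von Neumann entropy knee or fixed) → potential
   distances → metric MDS.
3. **Cluster** (`senetrace.cluster`) — k-means with the cluster count chosen
   to maximize `recall × purity` of the untreated control cells in a single
   cluster, then maps clusters onto six biological roles (healthy, two
   transitional, three terminal).
4. **Lineage** (`senetrace.lineage`) — minimum spanning tree over cluster
   centroids rooted at the healthy cluster, principal curves per
   root-to-leaf path, arc-length pseudotime, and truncation of trajectories
   that drift backwards in experimental time.
5. **Pseudotime statistics** (`senetrace.pstats`) — Loess trend curves with
   variation bands, two-sample Kolmogorov–Smirnov comparisons between
   lineages with a log-space tail (the star scale runs `*` p<0.05 down to
   `****` p<1e-300), and last-10%-of-lineage summaries.
6. **Synthetic data** (`senetrace.synthetic`) — a generative model of the
   13-time-point, 16-marker study with planted subpopulations, staged
   emergence, dilution coupling (`mean ≡ total / area`), and rendered
   phantom image scenes for pixel-exact tests of the quantification stage.

Everything is wrapped in a statsmodels-style pair:
`SenescenceTrajectoryModel(features).fit(seed=...)` returns a
`TrajectoryResults` with `composition`, `lineage_set`, `summary()`,
`trend_curve()`, `compare()`, `final_window()` and plotting helpers.
A `senetrace` CLI exposes each stage (`simulate`, `quantify`, `embed`,
`cluster`, `lineage`, `pstats`, `run-all --config cfg.yaml`).

## Worked example

```python
from senetrace import default_scenario, sample_cells, SenescenceTrajectoryModel

features, truth = sample_cells(default_scenario(cells_per_time_point=150, rng_seed=1))
res = SenescenceTrajectoryModel(features).fit(seed=1, subsample_n=150,
                                              k_range=range(2, 13), n_init=5)
print(res.summary())
```

```
Senescence trajectory analysis
==================================
cells: 1950   time points: 13 (day 0..31)   seed: 1
clusters: k=7 selected by control anchoring (score 0.259)
roles (cells): healthy=579, senescent_transitional=342, nonsenescent_transitional=276, large_nuclear=293, high_concentration=39, nonsenescent_terminal=421
day 2: healthy=0.647, senescent_transitional=0.180, nonsenescent_transitional=0.127, nonsenescent_terminal=0.047
day 31: healthy=0.053, senescent_transitional=0.127, nonsenescent_transitional=0.107, large_nuclear=0.373, high_concentration=0.060, nonsenescent_terminal=0.280
lineages: 3 (terminal roles: large_nuclear, high_concentration, nonsenescent_terminal)
  lineage 0 -> large_nuclear: length 6.3
  lineage 1 -> high_concentration: length 4.84
  lineage 2 -> nonsenescent_terminal: length 1.95, truncated at 1.95
```

Reading the output: the control-anchored criterion picked k=7 clusters,
which the role map merges into the six subpopulations; at day 2 the
senescent transitional state already holds 18% of cells (planted: 17%),
while the high-concentration state reaches 6% at day 31 (planted: 7.8%;
both fractions fluctuate with the multinomial draw at 150 cells per time
point).  Three lineages leave the healthy cluster, and both senescent
lineages pass through the transitional cluster.  Feature dynamics along a
lineage come from the results object:

```python
a, b = res.lineage_index("large_nuclear"), res.lineage_index("high_concentration")
c = res.compare("nuclear_area_px", a, b)
print(f"D={c.statistic:.3f}, p={c.pvalue:.3g} {c.stars}")
# D=0.239, p=1.55e-27 *
```

## Layout

```
src/senetrace/    synthetic.py quantify.py embed.py cluster.py
                  lineage.py pstats.py model.py pipeline.py cli.py
tests/            unit, property and acceptance tests (pytest)
docs/methods.md   model assumptions, parameter choices, limitations
```
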