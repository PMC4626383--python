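# mosaicweb

Spatio-temporal analysis of bipartite plant–flower-visitor networks on an
elevation × month sampling grid.

Tropical mountain forests host plant–pollinator systems that are anything
but static: species flower or fly for a month or two, turn over every
hundred meters of elevation, and interact opportunistically. Sampling such
a system as a grid of small networks — one matrix per (altitude, month)
cell — raises questions a single cumulative web cannot answer: does
topology vary more with time or with elevation, does specialization climb
with altitude, how much of the link identity survives from one cell to the
next, and how badly does pooling everything into one matrix distort the
picture?

`mosaicweb` is a tested pipeline for exactly this design, aimed at
community ecologists working with bipartite interaction records. It
provides:

- **Topology metrics** per network: P, A, S, M = A·P, A:P, I, connectance
  C = I/M, links per species L = I/S (L_P = I/P, L_A = I/A), specialist
  fractions, nestedness by decreasing fill / paired overlap (NODF, 0–100,
  binary and weighted), quantitative linkage density and weighted
  connectance LD/S, interaction strength asymmetry (ISA ∈ [−1, 1], positive
  = higher trophic level more dependent), and the network-level
  specialization index H2′ = (H2max − H2)/(H2max − H2min) with
  margin-constrained integer entropy extrema.
- **A connectance-preserving null model**: I cells placed uniformly, the
  remaining T − I events scattered over them; shape, fill and total are
  conserved in every replicate, and observed-vs-null contrasts are reported
  per index.
- **Turnover analyses**: Bray–Curtis dissimilarity Σ|x−y|/Σ(x+y), SIMPER
  decomposition of between-group dissimilarity into per-species
  contributions, occupancy spans, and link-identity turnover across both
  grid axes.
- **A statistical layer** routing each metric to ANOVA or Kruskal–Wallis by
  Shapiro–Wilk/Levene checks, low-vs-high elevation contrasts (pooled t or
  Welch by Levene), linear/quadratic fits against altitude and
  precipitation, and the individual-vs-cumulative network comparison.
- **A seeded mosaic generator** reproducing the statistical signature of
  such campaigns (short phenologies, bimodal precipitation driving
  richness, altitude-increasing specialist fractions, visitor attenuation
  above a thermal divide, empty cells) with a ground-truth ledger for
  recovery tests.

## Worked example

The numbered scripts under `analysis/` run the full study on a generated
mosaic and write their tables to `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_network_metrics.py
python analysis/03_null_comparisons.py
python analysis/04_turnover.py
python analysis/05_inference.py
```

Output of the chain (seed 101):

```
grid cells: 64; non-empty units: 45; admitted (>=2 species per side): 40
mean per-unit metrics:
P        3.150
A        6.650
S        9.800
M       21.650
I        8.125
C        0.435
L        0.831
NODF    20.783
fraction of units with zero NODF: 0.47
...
mean pairwise Bray-Curtis (insect): 0.74
links unique to one altitude: 80%; to one month: 89% (350 interaction records)
altitude: significant at 0.05 for ['pct_spec_P']
time: significant at 0.05 for ['I', 'L']
connectance: individual 0.43 vs cumulative altitude 0.19 / time 0.31 (chi2=19.3)
```

Read: the generated campaign yields mostly small (≈3 plants × 7 visitors),
highly connected (C ≈ 0.44) networks with frequent complete non-nestedness
(47% of units at NODF = 0); visitor assemblages are ~74% dissimilar
between cells; most link identities occur at a single altitude or month;
link-count metrics (I, L) respond to time (precipitation), the plant
specialist fraction to altitude; and pooling cells into cumulative networks
inflates size while deflating connectance — the individual-vs-cumulative
contrast the grid design exists to expose.

The same stages are available as a CLI for arbitrary long-format records
(`unit,altitude,month,plant,insect[,count]`):

```bash
mosaicweb simulate --seed 1 --out records.csv
mosaicweb metrics records.csv --out metrics.tsv
mosaicweb nullcompare records.csv --replicates 1000 --seed 1 --out nulls.tsv
mosaicweb infer records.csv --out-prefix reports
mosaicweb run --config config.yaml --out run_dir/   # everything + manifest
```

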