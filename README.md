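# villustat

Spatial and compositional statistics for crypt–villus immune
microenvironments, built for studies of intestinal graft-versus-host disease
(GVHD) where donor T cells and myeloid cells infiltrate the gut epithelium.
The package targets analysts working with high-definition spatial
transcriptomics (Visium-HD-class, ~2 µm spots) plus paired single-cell
RNA/TCR data, and ships a seeded synthetic-tissue generator so every
statistic can be exercised against planted ground truth without raw data.

## What it computes

- **Spot allocation plot (SAP).** Every spot is mapped to
  `(X, Y) = (d_ent, d_sm)`: the Euclidean distances (µm) to the nearest
  enterocyte-annotated and nearest smooth-muscle-annotated spot, computed
  with a k-d tree. This encodes position along the crypt–villus axis: crypts
  sit at small `d_sm` and large `d_ent`.
- **Crypt regions.** Connected components (8-connectivity on the capture
  grid) of crypt-annotated spots; immune spots are attributed to their
  nearest region within a configurable radius.
- **Polarization scoring.** Signature score `S = mean over signature genes of
  log1p(count × scale / library size)`; the polarization delta
  `Δ = S_M2 − S_M1` summarizes the macrophage M1↔M2 balance per spot.
- **Gene positive rate.** `|{spots in subset with raw count > t}| / |subset|`
  with `t = 0` by default ("expression > 0"), e.g. cell-cycle genes over
  crypt spots.
- **Ro/e enrichment.** Observed over chi-square-expected cell counts per
  (group, subset): `E_ij = n_i· n_·j / n··`, `Ro/e > 1` = enrichment.
- **TCR repertoire statistics.** Gini index
  `G = Σ_ij |x_i − x_j| / (2 n² μ)` over clonotype sizes, Shannon entropy
  `H = −Σ p_i ln p_i` of clonotype frequencies, and clone-size class
  compositions ({1, 2, >2}; ">2" = expanded).
- **Proximity network.** Per cell-type pair, the number of spot pairs in the
  same crypt region within a fixed radius, tested against labels permuted
  within each region: `p = (1 + #{null ≥ obs}) / (1 + n_perm)`.

## Worked example

```python
import villustat as vs
from villustat.signatures import DEFAULT_M1, DEFAULT_M2

spots, counts, truth = vs.simulate_section(vs.cko_like_tissue(seed=3))
lognorm = vs.normalize_counts(counts)
delta = vs.polarization_delta(vs.signature_score(lognorm, DEFAULT_M1),
                              vs.signature_score(lognorm, DEFAULT_M2))
mac = spots.loc[spots.cell_type.isin(["M1", "M2"]), "spot_id"]
print(delta.loc[delta.spot_id.isin(mac), "delta"].mean())
```

Running `python examples/03_polarization_and_positive_rates.py` prints

```
WT-like: macrophage-spot M2-M1 delta = +0.825; Mki67+ crypt spots = 3392/5049 (67.2%)
cKO-like: macrophage-spot M2-M1 delta = -0.907; Mki67+ crypt spots = 1764/5049 (34.9%)
```

i.e. the WT-like condition is M2-dominant (positive Δ) with intact crypt
proliferation, while the cKO-like condition flips to M1 dominance and loses
half of its Mki67⁺ crypt spots — exactly the planted biology. Likewise
`examples/05_proximity_network.py` recovers the planted CD8T–M1
co-clustering inside crypt regions (z ≈ 5.5, p ≈ 0.001) while unplanted
edges stay at their null.

The other `examples/*.py` scripts cover section simulation, SAP coordinates,
Ro/e + repertoire statistics, and the full pipeline; a thin CLI mirrors them
(`villustat run`, `villustat sap`, `villustat roe`, ...).

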