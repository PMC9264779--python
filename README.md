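# fishdiv

Presence/absence biodiversity statistics for taxonomic checklists
distributed over sites — built for freshwater-fish survey data of the kind
collected across river sub-basins, where each site contributes a species
list rather than abundances.

Given three CSV tables (a checklist with the full rank path
phylum → class → order → family → genus → species plus optional 0/1 flags
such as *endemic*, *cave*, *threatened*, *alien*; a binary site × species
occurrence matrix; and a per-site table of hydrological/environmental
drivers), the package computes:

- **G-F diversity indices.** The genus-level index is the Shannon entropy
  (nats) of the partition of species among genera,
  *D*<sub>G</sub> = −Σ<sub>j</sub> (S<sub>j</sub>/S) ln(S<sub>j</sub>/S);
  the family-level index sums each family's within-family genus entropy,
  *D*<sub>F</sub> = Σ<sub>k</sub> [−Σ<sub>i</sub> (S<sub>ki</sub>/S<sub>k</sub>) ln(S<sub>ki</sub>/S<sub>k</sub>)];
  and the standardized contrast is *D*<sub>G-F</sub> = 1 − *D*<sub>G</sub>/*D*<sub>F</sub>
  (0 when *D*<sub>F</sub> = 0).
- **Taxonomic distinctness.** Average taxonomic distinctness
  Δ⁺ = (ΣΣ<sub>i&lt;j</sub> w<sub>ij</sub>) / [S(S−1)/2] and its variation
  Λ⁺ = (ΣΣ<sub>i&lt;j</sub> (w<sub>ij</sub> − Δ⁺)²) / [S(S−1)/2], where
  w<sub>ij</sub> is a rank-path weight (same genus 16.667, same family
  33.333, same order 50.000, same class 66.667, same phylum 83.333),
  with a randomization **confidence funnel**: for each subset size *m*,
  10,000 uniform subsets of the master list give the expected mean and
  empirical 95% limits, and each site is classified *below / within /
  above* the funnel.
- **Beta-diversity partitioning.** Pairwise and multiple-site
  decomposition of Sørensen and Jaccard dissimilarity into turnover
  (β<sub>sim</sub>, β<sub>jtu</sub>) and nestedness (β<sub>sne</sub>,
  β<sub>jne</sub>) components, with β<sub>sor</sub> = β<sub>sim</sub> +
  β<sub>sne</sub> and β<sub>jac</sub> = β<sub>jtu</sub> + β<sub>jne</sub>
  holding as identities.
- **Community structure.** Jaccard/Sørensen/Bray–Curtis site similarity,
  UPGMA or complete-linkage dendrograms, similarity-threshold cuts into
  groups, and Newick export.
- **Drivers.** Mantel and partial Mantel permutation tests (Spearman,
  9999 permutations, add-one p-values) of the beta components against
  |Δattribute| driver distances, with per-driver handling of missing
  attribute values.

A synthetic metacommunity generator produces checklists and occurrence
matrices with the statistical structure the analysis assumes (skewed genus
sizes, a 1-D richness gradient, nested / turnover / mixed assembly), so the
whole pipeline is testable without any proprietary species list.

## Worked example

```python
import fishdiv as fd

cfg = fd.guangxi_preset(seed=2022)     # 380 spp, 158 genera, 43 families,
cl, mx = fd.generate_dataset(cfg)      # 17 orders over 12 sub-basins

fd.gf_per_site(mx, cl).loc[["LGR", "BDR", "ALL"]].round(2)
#        d_g    d_f  d_gf  s_total  p_genera  m_families
# LGR   4.38  27.79  0.84      185       107          39
# BDR   2.81   1.39 -1.03       18        17          15
# ALL   4.74  38.17  0.88      331       150          42

ms = fd.multi_site(mx)
{k: round(v, 2) for k, v in ms.as_dict().items()}
# {'beta_sor': 0.83, 'beta_sim': 0.7, 'beta_sne': 0.13,
#  'beta_jac': 0.91, 'beta_jtu': 0.83, 'beta_jne': 0.08}
```

The per-site rows show the richest sub-basin (LGR, 185 species) with high
genus- and family-level diversity, while the depauperate BDR (18 species)
has more family diversity than its genus entropy can balance, pushing its
G-F contrast negative. The multi-site decomposition shows turnover
(β<sub>sim</sub> = 0.70) dominating nestedness (β<sub>sne</sub> = 0.13):
compositional differences among these sites come mostly from species
replacement, not from poor sites being subsets of rich ones. The `ALL` row
pools the species actually recorded at the sites (331 of the 380-species
pool; the remainder are pool species the sampled sites never record).

The funnel for the same pool (sizes 18, 100, 185; 10,000 draws, seed 1):

```python
fd.funnel(cl, sizes=[18, 100, 185], n_draws=10_000, seed=1).table.round(1)
#   m  delta_mean  delta_sd  delta_lo  delta_hi  lambda_mean ...
#  18        66.4       2.1      62.3      70.4        118.7
# 100        66.4       0.8      64.8      67.8        123.2
# 185        66.4       0.5      65.4      67.2        123.6
```

The Δ⁺ expectation is flat in *m* (subset means are unbiased for the
master value, here 66.4) while the limits tighten as subsets grow — the
funnel shape used to flag taxonomically impoverished sites.

The same analyses are available from the shell:

```bash
fishdiv synth --preset guangxi --seed 2022 --outdir data/
fishdiv all --preset guangxi --seed 2022 --outdir out/
```

`fishdiv all` writes the composition tables, per-site indices, funnel and
classification tables, the six pairwise beta matrices with per-site and
multi-site summaries, the Newick tree with its group assignment, the
Mantel grid, and a manifest of config/seeds/versions that makes the run
reproducible byte-for-byte.

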