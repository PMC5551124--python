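# monnet

Design of supplementary air-pollution monitoring networks for
epidemiological studies.

Regulatory monitoring networks are built to enforce air-quality standards,
not to capture the exposure contrasts across people's residences that
cohort studies need. `monnet` implements a site-selection design that adds
a fixed number of new monitors to an existing network so that the combined
network better represents residential exposure variability. It was built
for the dense-city setting — tens of regulatory monitors, tens of
thousands of residences, a few hundred practical candidate spots (public
buildings such as community service centres) — and works from three
ingredients: hourly pollutant measurements at the existing monitors,
planar coordinates for all locations, and a matrix of geographic
covariates (proximity to and density of pollution sources).

## Method

The design runs in three steps on three location roles — **current**
(existing monitors), **subject** (residences), **candidate** (potential
new monitor spots):

1. **Land use regression (LUR).** Hourly measurements are reduced to QC'd
   annual averages (daily mean for days with ≥ 18 of 24 hourly values; a
   site-year counts only with ≥ 10 months covered, ≤ 91 missing days, and
   < 45 consecutive missing days). Annual averages are regressed on
   geographic covariates by forward selection: at each step the candidate
   with the largest R² gain enters if significant (α = 0.05), is removed
   and barred if its VIF exceeds 10 or its |Pearson r| with a selected
   variable exceeds 0.7, and selection stops at five variables. Skill is
   summarised by leave-one-out cross-validated R² = 1 − MSE/var(y).

2. **Clustering.** All locations (every role pooled) are clustered by
   k-means in the z-scaled space of the selected covariates, taking the
   best of many random restarts by total within-cluster sum of squares
   (SSW). The number of clusters k is guided by the decrease in overall
   deviation,

   DiD(%) = 100 × (1 − (1/J) Σⱼ Σₖ SSWⱼₖ / SSEⱼ),

   evaluated for k = 1…k_max on two characteristic sets — the LUR
   predictions (J = 1) and the selected covariates (J = 5) — and k is
   taken at the start of the common plateau (user-overridable).

3. **Allocation.** Within each cluster the current-to-subject proportion
   measures how well residences are represented by monitors. New sites are
   placed one at a time in the cluster with the minimum proportion (among
   clusters that still have candidates); each placed site counts as a
   current location from the next step on, and the concrete candidate is
   drawn uniformly at random within the cluster.

A robustness module reruns the clustering on repeated 90% subsamples and
summarises agreement with the full-data partition by the adjusted Rand
index. A synthetic-city generator provides locations, sources, covariates
and concentration surfaces with the structure the method assumes, for
testing and experimentation.

## Worked example

The package ships the per-cluster count tables of the design's published
PM2.5 and NO2 applications (9 and 8 clusters over 37 monitors, 31,097
residences, 412 candidate spots). Allocating 20 sites on the PM2.5 table:

```sh
$ monnet allocate --fixture pm25_table2 --n-new 20 --log picks.csv
cluster 2: 1 new site(s)
cluster 3: 6 new site(s)
cluster 7: 4 new site(s)
cluster 8: 8 new site(s)
cluster 9: 1 new site(s)
```

Clusters 2 and 7 start with zero monitors (proportion 0), so they are
served first; cluster 8 (3 monitors for 6,780 residences, proportion
4.4×10⁻⁴) absorbs the most sites; clusters with no candidates receive
none regardless of their proportion. The pick log records the proportion
that justified each placement:

```
step,cluster,ratio_before_pick
1,2,0.0
2,7,0.0
3,8,0.0004424778761061947
4,7,0.0004452359750667854
5,8,0.0005899705014749262
...
```

The same run from Python:

```python
from monnet import ClusterCounts, allocate, load_fixture

counts = ClusterCounts.from_fixture(load_fixture("pm25_table2"))
result = allocate(counts, n_new=20)
print(result.new_sites)   # {1: 0, 2: 1, 3: 6, 4: 0, 5: 0, 6: 0, 7: 4, 8: 8, 9: 1}
```

An end-to-end synthetic design (generation → QC → LUR → clustering →
allocation → stability) runs with `monnet run --out-dir out --seed 1` and
is summarised by `monnet report --out-dir out`.

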