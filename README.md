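# elevdiv

Analysis toolkit for small-mammal trap surveys along elevational
gradients.  It was built around a two-mountain survey design (a tall
peak surveyed from ~500 to ~3,200 m and a lower neighbour from ~500 to
~2,400 m, six trapping locations per mountain) and implements the full
statistical pipeline such a survey needs:

* **Survey accounting** — capture records, trap-night effort, trap
  success (captures per 100 trap nights), species accumulation curves,
  and camera-trap relative abundance; filters for arboreal/pitfall
  trap classes and recaptured individuals.
* **Alpha diversity** — per-site richness *S*, Shannon *H′* (natural
  log), Simpson's *D* = 1 − Σp², Pielou's *J′* = *H′*/ln *S*.
* **Mid-domain-effect null model** — species elevational ranges are
  discretised into 50 m bands; range midpoints are shuffled (soft or
  hard domain boundaries, 5,000 repetitions) to produce the null
  richness envelope that geometric constraints alone would generate,
  against which observed richness is classified per band.
* **Beta diversity** — Sorensen dissimilarity partitioned into
  turnover and nestedness components, pairwise and multi-site:
  β_SOR = β_SIM + β_SNE with β_sim = min(b,c)/(a+min(b,c)) pairwise and
  the multi-site analogue built from Σmin(b_ij, b_ji), Σmax(b_ij, b_ji)
  and ΣS_i − S_T; neighbor-joining clustering of sites from the
  pairwise distance matrix, written as Newick.
* **Endemism** — per-site proportions of endemic species and of
  captures belonging to endemics (unclassifiable species excluded from
  numerator and denominator), bootstrap percentile envelopes, and a
  permutation test for the contribution of endemics to turnover:
  β_SIM is recomputed without endemics and compared to 5,000 random
  species subsets of the same size drawn without replacement from the
  mountain's classified species pool.
* **Synthetic surveys** — a generator with known ground truth
  (contiguous species ranges, declining richness, elevation-correlated
  endemism, geometric dominance, detection thinning over trap nights)
  so every stage is testable without external data.

## Worked example

```python
import elevdiv as ed

ds, truth = ed.simulate_survey(ed.paperlike_preset(), seed=1)
flt = ed.filter_records(ds)          # ground traps, first captures only
am = ed.build_abundance_matrix(flt)

print(ed.diversity_profile(am)[["mountain", "location", "S", "H", "J"]].head(3))
part = ed.multisite_partition(am.to_incidence().for_mountain("B"))
print(f"beta_SOR={part.beta_sor:.2f} beta_SIM={part.beta_sim:.2f} "
      f"beta_SNE={part.beta_sne:.2f}")
res = ed.endemic_removal_test(am.to_incidence().for_mountain("B"),
                              ds.meta, reps=5000, seed=4)
print(f"beta_SIM {res.full.beta_sim:.2f} -> {res.observed.beta_sim:.2f} "
      f"without endemics, p={res.p_sim:.4f} ({res.direction_sim})")
```

prints

```
  mountain location   S         H         J
0        A      500   8  1.678499  0.807187
1        A      900  13  2.108536  0.822058
2        A     1500  11  2.119876  0.884057
beta_SOR=0.62 beta_SIM=0.51 beta_SNE=0.10
beta_SIM 0.51 -> 0.32 without endemics, p=0.0020 (decrease)
```

Richness *S* declines toward the summits (this seed's full profile
falls from 13 species at 900 m to 2 at 3,200 m on mountain A); on
mountain B roughly half of the Sorensen dissimilarity among sites is
turnover, and removing the endemic species collapses that turnover far
below what random equal-size species subsets produce (p ≈ 0.002) —
the endemics are what replaces the lowland community at height.

The `examples/` directory holds one short script per capability
(survey tables, alpha diversity, MDE null, beta/clustering, endemism,
full pipeline).  A thin CLI wraps the pipeline:

```sh
elevdiv all -c config.yml          # or: simulate / alpha / mde / beta / endemism
```

Every run writes tidy CSV/JSON outputs plus a manifest with file
hashes and per-stage seeds; identical configurations reproduce
identical outputs.

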