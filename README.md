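# hospgroups

Tools for grouping hospitals (or other health-care facilities) into
planning regions from patient-origin data. State Certificate-of-Need
programs allocate inpatient beds to *hospital groups* — clusters of
facilities that draw patients from the same communities and sit near each
other — and the composition of those groups carries regulatory weight, so
the grouping procedure must be objective and exactly reproducible.
`hospgroups` implements such a procedure end to end:

1. **Features.** From an n × z origin–destination matrix of patient days
   (facility × areal unit, e.g. zip code), compute each facility's
   Commitment Index profile, CI<sub>ij</sub> = Pd<sub>ij</sub>/Pd<sub>i</sub> —
   the fraction of facility *i*'s patient days contributed by unit *j*,
   which is insensitive to facility size. Join it with the facility's row
   of the inter-facility travel-distance matrix, rescaled to [0, 1] by the
   maximum pairwise distance, giving m = z + n attributes per facility.
2. **Clustering.** For every K, cluster with 2-step *Ward-seeded K-means*:
   Ward's minimum-variance hierarchical clustering cut at K supplies
   deterministic seed centers, and Lloyd iteration then descends on the
   K-means objective J(C) = Σ<sub>k</sub> Σ<sub>x∈c_k</sub> ‖x − μ<sub>k</sub>‖².
   The same inputs always yield the same partition — no random starts.
3. **Selecting K.** Compute the incremental F statistic
   incF<sub>i</sub> = ((R²<sub>i</sub> − R²<sub>i−1</sub>)/(k<sub>i</sub> − k<sub>i−1</sub>)) /
   ((1 − R²<sub>i</sub>)/(n − (k<sub>i</sub> − 1))) across the sweep, take its
   strict local maxima as candidate solutions, then apply three decision
   rules: drop candidates with any group larger than 20 hospitals, keep
   those with the fewest single-hospital groups, and break ties toward the
   largest K.
4. **New facilities.** A proposed facility is assigned to the group whose
   center is nearest in the distance-block subspace (Euclidean d between
   the center's distance columns and the facility's rescaled distance
   vector) — geography only, no speculative market survey.

A gravity-model synthetic-region generator (lognormal facility sizes,
exponential distance decay, planted community structure) makes the whole
pipeline testable without access to confidential inpatient databases, and
evaluation utilities (Calinski–Harabasz pseudo-F, matched-membership
agreement between partitions, adjusted Rand index, K^N/K! solution-space
estimate) support comparing configurations.

## Worked example

```bash
hospgroups simulate --seed 7 --out-dir sim/
hospgroups cluster --od sim/od.csv --distances sim/distances.csv \
    --registry sim/registry.csv --out-dir sol/
```

prints

```
synthetic region with 16 facilities, 32 units written to sim
selected K = 4 (r2 = 0.946185); outputs in sol
```

The generator planted 4 communities of 4 facilities each; the sweep's
incremental-F maxima and the decision rules pick K = 4, whose groups
reproduce the planted communities exactly (adjusted Rand index 1.0 against
`sim/labels.csv`), explaining 94.6 % of the feature variance. The same
selection logic applied to a published statewide candidate table of 52
solutions (bundled as `hospgroups.transcribe_table1()`):

```python
>>> import hospgroups as hg
>>> audit = hg.select_k(hg.transcribe_table1(), hg.SelectionRules(max_group_size=20))
>>> audit.selected_k
33
```

Candidates below 29 clusters fail the 20-hospital size cap; among the
survivors the minimum single-hospital-group count is 1, shared by K = 29,
31 and 33; the tie rule selects 33.

The remaining subcommands: `select` re-runs the heuristic on an existing
candidate table, `assign` places a new facility into a stored solution,
and `evaluate` scores agreement between two membership files.

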