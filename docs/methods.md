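# Methods

## Model and procedure

The package partitions n facilities into K groups using two attributes of
similarity: *where their patients come from* and *where the facilities
are*. Both are encoded as rows of a single feature matrix.

**Commitment Index block.** From the origin–destination patient-day
matrix, CI[i, j] = Pd[i, j] / Pd[i] gives the fraction of facility i's
total patient days contributed by areal unit j. Rows sum to 1, so two
facilities with the same catchment shape but very different volumes have
near-identical CI rows; this size-insensitivity is the reason CI, not the
Relevance Index RI[i, j] = Pd[i, j] / Pd[j], enters the feature space. RI
(a unit's dependence on a facility) is computed for diagnostics only.

**Distance block.** Each facility's row of the inter-facility travel
distance matrix, divided by the single maximum pairwise distance, so all
entries lie in [0, 1] like the CI block. Using the full n-vector of
distances instead of x, y coordinates lets the matrix encode road-network
realities (shorelines, bays) that Euclidean coordinates misrepresent; the
package consumes any valid distance matrix and does not itself do routing.
The divisor d_max is stored with the solution because a *new* facility's
distance vector must be rescaled by the same constant, never recomputed.

**Clustering.** For each K the partition minimizing
J(C) = Σ_k Σ_{x_i ∈ c_k} ‖x_i − μ_k‖² is approximated by Lloyd descent
seeded with the centers of a Ward's minimum-variance hierarchical
clustering cut at K. Ward seeding removes the randomness of conventional
K-means initialization: the whole pipeline is a deterministic function of
its input files, which matters because group membership has regulatory
consequences and results must be replicable byte for byte. The exhaustive
alternative is hopeless — the number of K-group assignments grows as
K^N/K!, about 9 × 10²⁰³ at K = 50, N = 158 — and random-start K-means
lands in a different local optimum nearly every run at that scale. On
planted-structure fixtures the Ward-seeded solution's J(C) matches or
beats the best of 100 random starts (tested over seeded replicates).

**Number of groups.** R² = 1 − RSS/TSS increases monotonically in K, so
the sweep is scored by the incremental F statistic

    incF_i = ((R²_i − R²_{i−1}) / (k_i − k_{i−1}))
             / ((1 − R²_i) / (n − (k_i − 1)))

on the consecutive grid K = 2..n−1 (with the analytically forced R² = 0
reference at K = 1, so incF at K = 2 is defined). Candidates are strict
local maxima of incF; grid endpoints have no two-sided neighbour and are
never candidates, which is why the smallest possible candidate is K = 3.
Three decision rules then pick the final K: (1) discard candidates whose
largest group exceeds `max_group_size` hospitals (default 20);
(2) keep candidates with the fewest single-hospital groups; (3) take the
largest surviving K. The rules are exposed as configuration
(`SelectionRules`) because they encode planning policy, not statistics:
other applications should adjust them. If no candidate passes the size
cap the selection fails loudly (exit code 3) with a suggestion to relax
the cap, rather than silently returning a worse solution.

A merged "tandem" observation — facilities that report utilization
jointly — counts all of its member hospitals toward group sizes and is
never counted as a single-hospital group. Its OD row is the *sum* of the
member rows (patient days conserved exactly) and its distance row the
*mean* of the member rows, with self-distance forced to 0.

**New-facility assignment.** d_k = ‖c_k[z+1..m] − h‖₂ against each group
center's distance-block columns; the facility joins the argmin group.
Projected-utilization assignment is deliberately not implemented: market
surveys for unbuilt facilities are speculative, while location is known.

**Comparing configurations.** `fit_stats` scores arbitrary external
partitions (e.g. a legacy configuration) with the same RSS/TSS/R²
definitions, and the Calinski–Harabasz pseudo-F
F = (R²/(K−1)) / ((1−R²)/(n−K)) penalizes K so solutions of different
sizes can be compared. `solution_agreement` pairs the groups of two
partitions by maximum-weight bipartite matching on shared-member counts
(scipy's linear-sum assignment) and reports the percentage of common
facilities in matched pairs plus the count of identically-membered pairs;
facilities present in only one partition are excluded first. Bipartite
matching is the least-assumptive reading of "agreement between
counterparts" — other correspondence rules exist, and scores from other
implementations may differ accordingly.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| `max_group_size` | 20 hospitals | decision-rule cap on any one group |
| `distance_weight` | 1.0 | optional scalar on the distance block; 1.0 preserves the implicit z-vs-n block weighting of the plain join (sensitivity-analysis extension) |
| convergence tol | 1e-10 relative SSE, ≤1000 iterations | Lloyd stopping rule |
| symmetry tol | 1e-6 relative | distance matrices asymmetric beyond this are rejected; below it, averaged |

Deterministic conventions: facilities and units are ordered
lexicographically everywhere; nearest-center ties resolve to the lowest
group index; a group emptied during Lloyd iteration is re-seeded with the
point farthest from its current center (drawn from a group of ≥2, so K is
preserved); ties in minimum assignment distance d go to the lowest group
index. R² exactly 1 (possible at K near n) makes incF undefined there;
such grid points are flagged and excluded from the maxima search rather
than clamped.

Ward seeding uses scipy's `linkage(..., method="ward")` on the raw
observation vectors, i.e. the standard minimum-variance criterion on
Euclidean distances. Refinement is plain Lloyd; any SSE-descent variant
yields the determinism and fit properties the pipeline needs, and on
small fixtures the refined J(C) matches both exhaustive enumeration and
an independent Lloyd implementation (scikit-learn) started from the same
seeds.

## Synthetic regions

`generate_region` emulates the statistical shape of a statewide inpatient
database: communities on a circle (adjacent centers 30 km apart by
default), 4 facilities and 8 areal units scattered N(0, 4–5 km) within
each of 4 communities, lognormal bed counts (median ≈ 150), and
integer patient-day flows drawn per unit as Poisson(2500) totals split by
a multinomial with gravity weights

    p(i | j) ∝ beds_i^α · exp(−β d_ij) · γ^[same community],

α = 1, β = 0.15/km, γ = 5 by default. These defaults describe a strongly
separated region — within-community travel ~5 km against ~30 km between
communities, so the decay factor alone favours a unit's own community
~40-fold — which is the regime the grouping methodology targets; a
structureless null is obtained with α = 0, β = 0, γ = 1. Multinomial
sampling keeps patient days integer and exactly conserved, so CI
denominators behave like real counts.

What the generator does *not* emulate: road-network (non-Euclidean)
distances, shoreline geography, temporal drift in utilization, hospital
openings and closures, and the long-tailed unit sizes of real zip-code
data. Passing recovery tests therefore show that the pipeline finds
planted community structure under the gravity model, not that any
particular real region has such structure.

Experiment sizes — 16 facilities × 32 units, 20 recovery replicates, 10
seeding fixtures × 100 random starts — were chosen so the full suite
exercises every pipeline stage in seconds; all the properties tested are
scale-free (stochasticity of CI/RI, SSE descent, determinism, strict
local-maxima detection), so small regions test them as well as large ones.

## Known limitations

- K-means + Ward gives no global-optimality guarantee; the package checks
  optimality only on exhaustively enumerable fixtures.
- The incF heuristic has no statistical guarantee of finding a "true" K;
  it formalizes a defensible choice, which is all the problem admits.
- The agreement score depends on the group-matching rule (see above).
- Bed counts of merged facilities are summed when available, but nothing
  downstream consumes them; only `member_count` matters to the rules.
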