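# nucbench

Benchmarking computations for 3D genome contact data, exercised end-to-end on
synthetic contact matrices with planted ground truth.

Chromosome-conformation assays — Hi-C, Micro-C, SPRITE, GAM, ChIA-PET,
PLAC-seq — all report on how the genome folds, but they differ in dynamic
range and in how well they recover each folding feature: the contact-frequency
distance scaling P(s), A/B compartments, TAD boundaries, and focal chromatin
loops. Comparing assays fairly requires one pipeline that computes all of
these quantities the same way from any binned contact matrix, plus data where
the right answer is known. `nucbench` provides both:

* a **synthetic-data generator** that plants compartments, insulating
  boundaries, focal loops, promoter–enhancer wiring, multiway proximity
  clusters and nuclear-position-like 1D tracks into a contact expectation with
  known parameters, then samples reads from it;
* the **analysis stack** used to compare assays: matrix balancing, P(s) and
  its log-log derivative, compartment eigenvectors and saddle-plot strengths,
  diamond insulation and boundary calling, donut-background loop calling, APA,
  anchor-union/upset analysis, chromatin-state fold enrichment, loop
  clustering, SPRITE cluster-to-pair conversion, and cross-dataset
  concordance.

## The model at the core

The generator's cis expectation at bins *i < j* is multiplicative, one factor
per benchmarked feature:

```
E[i,j]  =  s^-alpha  ·  c(i,j)  ·  g(i,j)  ·  l(i,j)
```

* `s^-alpha` — power-law distance decay with separation *s*;
* `c(i,j) = 1 + delta` if the bins share a planted A/B compartment label,
  else 1 (the plaid);
* `g(i,j) = gamma^k`, *k* the number of planted insulator bins strictly
  between *i* and *j* (capped at 3) — TAD boundaries;
* `l(i,j) = beta` on planted loop pixels, `(1+beta)/2` on the one-bin
  shoulder, else 1.

Trans contacts get `trans_rate · mean(cis) · c(i,j)`. The normalized model is
sampled multinomially at a configured depth. Every planted quantity is
recorded and becomes the oracle for the downstream analyses:

* **P(s)** — zero-inclusive mean balanced contact in geometric distance bins;
  its local log-log slope recovers `-alpha`, and a local slope maximum at
  100–200 kb is the signature of cohesin-scale loops.
* **Compartments** — leading eigenvectors of (O/E − 1); saddle plots rank
  bins by the eigenvector (or any nuclear-position track) into Q quantiles,
  and compartment strength is the homotypic corner mean (A-A or B-B) over the
  heterotypic (A-B) corner mean.
* **Insulation** — `log2` of the w×w diamond mean crossing each bin,
  geometric-mean-centered per chromosome; boundaries are prominence-filtered
  local minima.
* **Loops** — Poisson upper-tail test of each candidate pixel against the
  strongest of four local backgrounds (donut, lower-left, horizontal,
  vertical), BH-corrected; APA aggregates the 21×21-pixel O/E window over a
  loop list.
* **SPRITE clusters** — a cluster of *n* distinct bins contributes all
  n(n−1)/2 pairs weighted 2/n (total mass n−1); stratifying by cluster size
  reproduces the flatter P(s), higher trans fraction and weaker
  compartmentalization of large clusters.

## Worked example

```python
import numpy as np
from nucbench import SimulationConfig, build_expected_matrix, sample_contacts, balance_ic
from nucbench.genome_model import generate_tracks
from nucbench.scaling_curves import compute_ps, fit_slope
from nucbench.compartments import compute_eigenvector, compartment_strength
from nucbench.insulation import insulation_score, call_boundaries
from nucbench.loops import call_loops

# one 10 Mb chromosome at 25 kb bins: alpha=1, plaid delta=1, boundary
# attenuation gamma=0.5, 30 focal loops with beta=3 at 100-200 kb
cfg = SimulationConfig(seed=3)
expected, truth = build_expected_matrix(cfg)
matrix = balance_ic(sample_contacts(expected, depth=10_000_000, seed=3))
tracks = generate_tracks(truth, cfg)

slope = fit_slope(compute_ps(matrix), (100_000, 1_000_000))
ev = compute_eigenvector(matrix, tracks["son"])
aa, bb, _ = compartment_strength(matrix, ev, Q=10)
bounds = call_boundaries(insulation_score(matrix, window=250_000))
loops = call_loops(matrix, distance_range=(100_000, 300_000), fdr=0.05)
```

Output:

```
P(s) slope (100 kb - 1 Mb): -1.280
EV1 sign agreement with planted labels: 98.5%
compartment strength A-A: 5.39, B-B: 2.47
boundaries called: 14 (7/10 planted label changes recovered)
loops called: 62 (recall of 30 planted loops: 0.83)
```

The fitted slope is steeper than −1 because plaid, boundary and loop factors
ride on top of the pure decay (a decay-only run recovers −1.00 ± 0.05); the
eigenvector recovers the planted labels nearly everywhere; strengths above 1
quantify the plaid contrast; most planted boundaries are re-called within one
bin (under the full structured model some weak or end-proximal minima are
missed, and plaid edges can add calls); and the loop calls at FDR 5% recover
most planted pixels within ±1 bin. The same stack runs from the shell via the
`nucbench` CLI (`nucbench simulate`, `nucbench balance`, `nucbench ps`,
`nucbench compartments`, `nucbench saddle`, `nucbench insulation`,
`nucbench loops call|apa|union|enrich|ep-count`, `nucbench sprite
pairs|hist`, `nucbench concord`).

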