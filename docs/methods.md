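# Methods

This note records the models implemented in `allograph`, the
assumptions behind them, the defaults and why they were chosen, and
what the synthetic fixtures do and do not establish about real data.

## Atomistic graph model

Every atom of the filtered structure is a node. Edges and weights
(all stored as positive magnitudes, kJ/mol):

| type | criterion | weight |
|---|---|---|
| covalent | d ≤ r_cov(u) + r_cov(v) + 0.45 Å (Cordero radii); CONECT hints accepted up to 1.5× that limit | mean bond-dissociation energy by element pair and bond order (e.g. C–C 346, C–N 305, C=O 749, S–S 266); order from the residue's chemical-component template |
| hydrogen bond | explicit H: H···A ≤ 3.0 Å, ∠D–H···A ≥ 90°; fallback without H: D···A ≤ 3.5 Å, donor/acceptor per residue-type table, outward angle test at D | 12–10 potential \|E\| = V₀·\|5(R₀/R)¹² − 6(R₀/R)¹⁰\|·cos²θ with V₀ = 33.5 kJ/mol, R₀ = 2.8 Å (D···A); ideal geometry assumed in the fallback |
| hydrophobic | apolar C/S (no covalent N/O/charged neighbour), different residues, d ≤ 8 Å | ε·exp(−(d − r₀)/σ), ε = 4.6 kJ/mol, r₀ = 3.8 Å, σ = 1 Å |
| salt bridge / electrostatic | opposite formal charges (Arg, Lys, His / Asp, Glu, OXT, phosphate O); ≤ 4 Å → salt bridge, 4–8 Å → electrostatic | screened Coulomb k·\|q₁q₂\|/(ε_r(d)·d) with ε_r(d) = 4d, i.e. k/(4d²), k = 1389.35 kJ·Å/mol |
| π–π stacking | nucleobase six-rings (protein rings optional), centroid distance ≤ 5.5 Å, plane angle ≤ 30° | constant 8 kJ/mol; edge joins the two atoms nearest the centroids, length = centroid distance |

These functional forms are deliberately simple, tabulated
approximations; every constant can be overridden from a YAML file via
`EnergyConfig`. Exact absolute energies are *not* the point: the
downstream quantile scores are rank-based and therefore robust to
monotone changes of any one weight family. Hydrogens are used when
present but never added (no protonation step); the heavy-atom
hydrogen-bond fallback exists for exactly this case, so absolute
hydrogen-bond energies differ from what a protonated structure would
give. Parallel edges of different types between the same atom pair are
kept itemized for reporting but summed into a single weight for all
matrix operations.

Alternate locations are resolved by keeping, per atom identity, the
record with the highest occupancy (ties: first in file). Insertion
codes are part of the residue identity, and residue order follows file
order throughout.

## Bond-to-bond propensity

With incidence matrix B (node × edge, fixed arbitrary orientation
u→v, u < v), weight diagonal W and Laplacian L = BWBᵀ, the transfer
operator is M = ½·W·Bᵀ·L⁺·B. A column M_{·,b′} is computed with one
sparse solve: the right-hand side B e_{b′} is deflated (per-component
mean removed), the system is solved with a sparse LU factorization of
L grounded at one node per connected component, the solution deflated
again, and the relative residual checked against 1e-10. Absolute
values make every reported quantity independent of the orientation
convention. The propensity of bond b is Π_b = Σ_{b′∈source} |M_{b,b′}|;
the cost is one solve per source bond (asserted in tests), never m².

Normalisation is over **non-source** bonds (they sum to 1); source
bonds are reported raw but excluded from scoring, because the scoring
question is about the rest of the structure relative to the source.
Residue propensities add each non-source bond's normalised value to
both endpoint residues (once for intra-residue bonds) — a residue's
propensity deliberately reflects all of its interactions, so
inter-residue bonds are double-counted across the residue table.

Distances: a bond sits at its midpoint; its distance from the source
is the minimum Euclidean distance to any source atom. Residue distance
is the minimum over its atoms.

## Markov transients

P = αI + (1−α)D⁻¹A, rows sum to one, stationary distribution
π ∝ weighted degree for any α. The walk starts uniform over the
source atoms (not degree-weighted). t₁/₂ is the **first** crossing
time p_i(t) ≥ π_i/2 — no sustained-crossing requirement; optional
linear interpolation between the bracketing steps is off by default.
Default α = 0 (the pure chain); if a period-2 oscillation is detected
(bipartite graphs) the run is retried once at α = 0.5 and the α used
is recorded. Probability mass is checked to 1e-12 at every step and
renormalized after the check so rounding cannot accumulate over long
runs. t_max defaults to 10⁶ steps; non-convergence reports the worst
node and suggests laziness.

## Quantile scoring

Raw measures are transformed to log₁₀ (floored at 1e-300) and
regressed on distance from source with linear quantile regression,
fitted by exact linear programming (HiGHS) — deterministic, and
cross-checked in the tests against statsmodels' IRLS implementation.
The τ-grid is 0.01…0.99 step 0.01 plus 0.995 (100 levels). Quantile
crossing is resolved by sorting the 100 fitted values per item. For
propensities (higher = better) an item scores the largest τ whose line
lies at or below it, 0 if below all; for half-times (lower = better)
the score is 1 − (smallest τ whose line lies at or above it), so fast
atoms score high. Items exactly on a shared line share the largest
qualifying τ. Degenerate distance vectors fall back to intercept-only
fits at the empirical quantile.

Residue scores default to *aggregate-then-score*: the residue-level
measure (summed bond propensity; minimum atom half-time) is re-scored
by the same quantile procedure against the residue's minimum distance.
The alternative (*mean of member-item scores*) is available via
`mode="mean"`. The minimum half-time was chosen for residue
aggregation because a residue is reached when its first atom is.

## Site significance

A site's score is its mean residue quantile score. The null is built
from sites sampled with the same residue count k and diameter
(max pairwise Cα distance; heavy-atom centroid for ligands and
nucleotides): draw a seed residue uniformly, collect residues within
the diameter ball, draw k without replacement, accept when the
realized diameter is within 110% of the query diameter; after 100
failed draws the tolerance relaxes by 5 points with a logged warning.
1000 surrogates by default, seeded (CLI defaults: surrogates 1000,
bootstrap seed offset +1000, both derived from `--seed`). The 95% CI
is a percentile bootstrap (default B = 10000) over the surrogate
means, and p = (1 + #{surrogate ≥ site})/(n + 1), which can never be
exactly zero. The four detection measures are S1 = mean score
(≥ 0.9), S2 = p-value (≤ 0.05), S3 = max residue score (≥ 0.95),
S4 = fraction of residues above 0.5 (> 0.5); a site is "detected"
when any one criterion is met. These four are stand-in definitions:
the literature source for this family of scorings defines them in
supplementary material not reproduced here.

## Synthetic fixtures and what passing tests show

The fixture module generates everything the tests need offline:

- toy graph families (path, cycle, tree, complete, barbell, grid,
  random-connected) with unit or seeded-uniform weights and
  deterministic dummy coordinates — these carry the analytic spectral
  content (trees ⇒ M = ½I; C3 closed form; trace identity);
- idealized miniature PDB structures built from standard internal
  coordinates (bond lengths 1.33/1.46/1.53 Å, α-helix φ/ψ = −57/−47):
  an extended GLY-ALA-SER tripeptide with two waters, an ALA 10-mer
  helix whose geometry guarantees i→i+4 backbone hydrogen bonds, a
  4-step stack of nucleobase six-rings, and a C2-symmetric dimer;
- a jittered-lattice pseudo-protein (256 residues, ~4 Å spacing) for
  the statistical calibration of surrogate-site p-values and bootstrap
  coverage.

These fixtures have ideal geometry, no missing atoms, no alternate
conformations, no solvent shells and no side-chain rotamer variety.
Passing tests therefore establish the *mathematics* (operators,
solvers, scores, statistics) and the *detection criteria* exactly, but
say nothing about how well the simplified energy model ranks sites on
real, noisy crystal structures — that judgement requires real PDB
entries, which the package analyses through the same code paths.

A note on calibration scale: on very small structures (≲100 residues)
surrogate sites necessarily overlap and their means correlate, which
makes the empirical p-value slightly liberal (observed ≈0.06–0.07 at
64 residues) and the null lumpy; at 256 residues the rate is back
within the nominal bound (0.03–0.05). Site scoring is intended for
protein-scale structures.

## Numerical choices

- Laplacian solves: sparse LU on the grounded system; residual bound
  1e-10 enforced, solver deterministic, outputs bit-stable per
  platform.
- Transfer-operator work scales with the number of source bonds
  (one solve each), not with the number of edges squared.
- Item-vs-line comparisons in scoring use a 1e-9 tolerance so LP
  solutions passing exactly through points behave as "on the line".
- Ties in rankings are broken by bond/residue order (stable sorts).
- Problem sizes used by `scripts/acceptance.py` — 10 random trees up
  to n = 50, a 120-node trace-identity graph, an 80-node Markov
  oracle, n = 1000 quantile calibration, 300 surrogate-calibration
  replicates of 200 surrogates on the 256-residue lattice — were
  chosen so the whole script completes in well under a minute while
  keeping every statistical check comfortably powered.

## Known limitations

- No protonation: hydrogen-bond energetics with and without explicit
  hydrogens differ systematically (rank-based scores absorb most of
  this).
- Formal unit charges on every listed ionisable atom over-count
  multi-atom groups (e.g. Arg); the screened-Coulomb dielectric is a
  crude solvent model.
- mmCIF is not supported; only PDB v3.3 fixed-width files.
- Assemblies are built strictly from REMARK 350; no symmetry
  inference.
- The four detection measures are stand-ins, not the original
  supplementary definitions.
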