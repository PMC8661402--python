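# allograph

Allosteric signalling analysis on atomistic, energy-weighted graphs of
biomolecular structures.

Allostery — regulation of a protein's active site by binding events at a
distant site — leaves a physical footprint in the network of covalent
bonds and weak interactions that couple every atom of a structure.
`allograph` turns a PDB structure into an atomistic graph (one node per
atom; edges for covalent bonds, hydrogen bonds, hydrophobic contacts,
salt bridges/electrostatics and π–π stacking, weighted by interaction
energy in kJ/mol) and quantifies how strongly and how fast fluctuations
injected at a chosen *source* site (typically a bound ligand) reach
every other bond, atom and residue. It is aimed at structural biologists
and method developers who want scriptable, offline allosteric-site
scoring with explicit statistics.

## Methods

**Bond-to-bond propensity.** With incidence matrix *B* (node × edge,
arbitrary fixed orientation), edge-weight diagonal *W* and weighted
Laplacian *L* = *BWB*ᵀ, the edge-to-edge transfer operator is

    M = ½ · W · Bᵀ · L⁺ · B

and the propensity of bond *b* for a source-bond set *S* is
Π_b = Σ_{b′∈S} |M_{b,b′}|, normalised over non-source bonds. Each
column costs one sparse Laplacian solve; the m×m operator is never
formed. On trees M = ½I exactly, and trace(M) = (n − #components)/2 —
identities the test suite checks against dense eigendecompositions.

**Markov transient half-times.** A discrete random walk with
P = αI + (1−α)D⁻¹A starts uniformly on the source atoms; each atom's
t₁/₂ is the first step at which its occupation probability reaches half
its stationary value π_i = d_i/Σd_j. Small t₁/₂ = fast communication.

**Quantile scoring.** Propensities decay and half-times grow with
distance from the source, so raw values are not comparable across a
structure. Linear quantile regressions of log₁₀(measure) on distance
are fitted by exact linear programming over τ = 0.01…0.99, 0.995, and
each bond/atom/residue scores the highest τ whose line it beats —
a score in [0, 1], uniform under the null.

**Site significance.** A site of interest gets its mean residue
quantile score compared against sites of the same residue count and
diameter sampled anywhere in the structure (default 1000), with a
percentile-bootstrap 95% CI and an add-one-corrected empirical
p-value, plus four detection measures (mean score, p-value, max
residue score, fraction above 0.5).

## Worked example

No downloads needed — the built-in fixture module writes miniature
idealized structures:

```
python -c "from allograph import fixtures; open('helix.pdb','w').write(fixtures.make_mini_pdb('helix10'))"
allograph run --pdb helix.pdb --source A:ALA:1 \
    --site "A:ALA:8,A:ALA:9,A:ALA:10" --method propensity \
    --n-surrogates 200 --out run_helix
allograph summarize run_helix -k 5
```

prints the top residues by distance-debiased quantile score:

```
residue  propensity  distance_A  is_source  quantile_score
A:ALA:3    0.325990    3.270479      False           0.995
A:ALA:9    0.004903    9.330978      False           0.995
A:ALA:7    0.022987    7.075550      False           0.810
A:ALA:4    0.256691    3.207526      False           0.740
A:ALA:8    0.010802    7.997675      False           0.560
```

Residue 9 carries far less raw propensity than residue 3 (0.005 vs
0.326) but sits three turns up the helix; after removing the distance
trend both score 0.995 — residue 9 is unusually well connected *for its
distance*. `run_helix/site_scores.json` holds the site comparison: the
C-terminal site scores mean_qs = 0.605 against a surrogate mean of
0.641 (95% CI [0.628, 0.654]), empirical p = 0.69 — unremarkable on
this tiny helix, but its best residue (0.995 ≥ 0.95) triggers the
max-residue detection criterion. The run directory also contains
per-bond/per-atom/per-residue CSVs, PDB files with scores in the
B-factor column for 3D colouring, the graph summary and a run-metadata
JSON with all seeds.

The same workflow applies to real structures: `--pdb yourfile.pdb`
(or `--pdb-id XXXX` with network access), `--source A:GLC:601` for a
bound ligand, `--site` for any site you want scored.

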