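# Methods

`grindqsar` implements a ligand-based modelling workflow for congeneric
small-molecule inhibitor series: classical Hansch (2D) QSAR, alignment-free
grid-independent 3D descriptors with PLS modelling, and docking
post-analysis (pose clustering, enrichment). This note records the models,
the parameter choices that matter, and what the synthetic test data do and
do not establish.

## Molecular interaction fields

For a molecule with atoms at **r**ⱼ, partial charges qⱼ and probe-interaction
types, the energy of a probe at lattice point **x** is

    E(x) = Σⱼ E_lj(rⱼ) + Σⱼ E_hb(rⱼ) + Σⱼ E_el(rⱼ)

* **Lennard-Jones**: `A/r¹² − B/r⁶` with per-element coefficients derived
  from generic well depths ε and contact radii σ (`A = 4εσ¹²`, `B = 4εσ⁶`;
  e.g. carbon ε = 0.10 kcal/mol, σ = 3.40 Å).
* **Hydrogen bond**: a distance Gaussian `E_hb = E_min·exp(−(r−r₀)²/0.25)`
  with `E_min = −4.0` kcal/mol and `r₀ = 1.9` Å, applied between a probe and
  its type-matched partner atoms only. For partner atoms the H-bond term
  *replaces* the generic LJ term: the 1.9 Å optimum lies inside the generic
  steric wall, which would otherwise cancel the well. The angular dependence
  of hydrogen bonding is deliberately omitted — the downstream correlogram
  consumes node positions and energies, not orientations.
* **Electrostatics**: `332.0·q_probe·q_atom/(ε(r)·r)` with the
  distance-dependent dielectric `ε(r) = 4r`, i.e. `332/(4r²)`.

Distances are clamped at 0.5 Å (no singularities) and atoms beyond 8 Å
contribute nothing. The lattice covers the molecular bounding box plus a
margin (defaults: 0.5 Å spacing, 4 Å margin).

Probe semantics follow the classical convention: **O** is a carbonyl-type
acceptor probe and therefore maps the molecule's H-bond *donors*; **N1** is
an amide-NH donor probe mapping the molecule's *acceptors*; **DRY** sums an
enhanced dispersive term over hydrophobic atoms (carbon ε raised to 0.30
kcal/mol, standing in for the entropic water-displacement reward) plus a
repulsion-only wall and a Gaussian penalty near polar atoms; **TIP** is a
pure shape probe with a uniform modest well (ε = 0.10 kcal/mol) at a 0.5 Å
reduced radius, so only dense atom neighbourhoods register as steric
hotspots. Node-retention cutoffs default to −0.5 (DRY), −2.5 (O, N1) and
−0.75 (TIP) kcal/mol; all parameters are overridable from YAML. These are
generic GRID-like values chosen for sane behaviour on the test chemistry,
not a reproduction of any proprietary parameterization — absolute field
values from commercial engines will differ; the pipeline's structure and
statistical behaviour are what this package reproduces.

## Grid-independent descriptors

Node extraction keeps sub-cutoff lattice nodes and greedily selects up to
100 per probe, each step maximizing `|E|·(1 + 0.5·d_min)` where `d_min` is
the distance to the already-selected set — an energy–spread trade-off in the
spirit of published hotspot-extraction algorithms, whose exact weighting is
not public; ours is fixed and documented here.

Encoding is the maximum auto-/cross-correlogram: for each of the 10 probe
pairs and each 0.4 Å distance bin (75 bins, a 0–30 Å window), the descriptor
value is the largest product `|E_i|·|E_j|` over node pairs whose distance
falls in the bin, with the witnessing node pair stored. The 0.4 Å bin width
matches the width of the pharmacophore distance ranges the descriptor is
meant to resolve. Distances beyond the window raise in strict mode; the
fixed-width matrix builder ignores and counts them (a finite correlogram
window is inherent to the descriptor). A consistency post-filter that keeps
variables with nonzero support in ≥ 30 % of molecules approximates
"consistently large" variable selection; it is off by default.

## Regression and validation

PLS1 is implemented as NIPALS on autoscaled variables (unit variance,
ddof = 1; zero-variance columns dropped). The latent dimension (cap 5,
appropriate for n ≈ 90) maximizes leave-one-out q²; every LOO fold refits
from scratch including re-centering and re-scaling. Reported statistics:
r² = 1 − SSE/SS_tot, q² = 1 − PRESS/SS_tot, RMSE = √(SSE/n),
SDEP = √(PRESS/n) (the √(PRESS/(n−1)) variant is also exposed, since usage
in the literature is split).

The 2D path uses ordinary least squares; its LOO uses the exact hat-matrix
identity `e₍₋ᵢ₎ = eᵢ/(1 − hᵢᵢ)`, algebraically identical to refitting. The
shipped single-descriptor activity model,
log(1/IC50[μM]) = −3.52250 + 0.23173·MR, is carried as constants: MR here is
Wildman–Crippen SMR, which differs in absolute value from proprietary
descriptor implementations, so the coefficients are not re-derivable from
our descriptors. Descriptor pre-selection ranks by |Pearson r| with the
response (a transparent stand-in for proprietary contingency scoring).

FFD variable selection builds a two-level resolution-III design from a
Hadamard matrix (seed-randomized column assignment and sign flips; balanced,
orthogonal inclusion patterns), augments the real variables with 20 %
dummies, evaluates each run by LOO SDEP, and keeps a variable only if its
effect — mean SDEP over runs excluding it minus mean over runs including
it — clears the dummy noise floor (mean |dummy effect|). One refinement pass
repeats the screen on the reduced set. Dummies carry no information by
construction, so their effects delimit pure estimation noise.

The diverse train/test split is maximin selection on z-scored descriptors:
the first test pick maximizes mean distance to all points, each later pick
maximizes its minimum distance to the chosen set; test size is
floor(fraction·n) (111 compounds at 20 % → 22/89). The z-scoring and the
Euclidean metric are this package's choices; the source literature for such
splits rarely states either.

## Docking post-analysis

Common-scaffold RMSD is computed in the shared receptor frame without
superposition (a Kabsch option exists for frame-free use). Pose clustering
is complete-linkage agglomeration cut at 2.5 Å by default — complete linkage
bounds the intra-cluster scaffold spread, matching the intent of a
"common binding mode"; the linkage is configurable. The per-cluster report
lists distinct ligand coverage (the "12/12 ligands" criterion for a
consensus mode).

Enrichment uses EF@x% = (tp/(tp+fp))/(TA/N) with ranking by descending
score and stable tie-breaking; note that EF is bounded by N/selected, so
EF@1% saturates near 100 on a ~5000-compound screen when all actives rank
at the top. A typeset variant of this formula that divides by TA and N
sequentially is dimensionally inconsistent with reported EF magnitudes and
is not implemented. ROC curves and AUC (trapezoid, equal to the normalized
Mann–Whitney U) come from scikit-learn.

LipE = pIC50(molar) − clogP = (6 − log₁₀ IC50[μM]) − clogP; the molar pIC50
convention is the only one consistent with the LipE magnitudes commonly
printed alongside sub-μM compounds.

## Synthetic data: what it emulates and what it does not

The library generator produces a desk-scale stand-in for an aligned
congeneric series (~100 rigid molecules, IC50 0.019–230 μM):

* a **hydrophobic spine** of carbons — the invariant common core. It is
  placed beyond the 30 Å correlogram window from the variable features, so
  its DRY/TIP background is bin-for-bin identical across the library, the
  synthetic analogue of a shared scaffold contributing no between-compound
  variance (autoscaling drops constant columns);
* **collimated feature sites**: each donor (O–H) or acceptor (N) sits under
  an 8-chlorine collimator ring with an axial guard, leaving a single open
  approach direction so each feature contributes exactly one deep probe
  hotspot — a crude but effective stand-in for the directionality of real
  hydrogen bonds;
* **planted distances**: pattern-positive molecules carry their feature
  pair at the planted distance (donor–donor 15.4 Å, acceptor–acceptor
  21.4 Å by default), pattern-negative molecules at one of five decoy
  distances. Displacement vectors are snapped to lattice-commensurate
  components and the ≤ 0.1 Å distance jitter stays below half the lattice
  spacing, so the winning hotspot nodes — and hence the binned distance —
  cannot move between molecules. Activities are
  `y = −0.8 + β·1[OO] + β·1[NN] + ε` with β = 1 and σ = 0.354, giving a
  true R² of 0.8 at pattern prevalence ½; IC50 = 10^(−y), clipped to the
  configured range.

The paper-like encoding configuration deepens the O/N1 retention cutoff to
−3.5 kcal/mol so that only the single deepest node per collimated site
survives, which keeps the correlograms sharp (one bin per planted pair).

What passing the planted-recovery experiment shows: the chain
fields → hotspots → correlograms → autoscaled PLS transmits metric
pharmacophore information faithfully and the model selection (LOO) and
feature reporting recover it at realistic noise. What it does not show:
performance on flexible, conformationally noisy, unaligned real chemistry —
real series have correlated substituent effects, multiple interaction
motifs per site and alignment error, none of which the rigid generator
reproduces. The `generate_realistic_library` mode (RDKit-embedded quinoline
derivatives with Gasteiger charges) exercises the code paths on real
chemistry but carries no planted signal.

Pose-set and ranking generators are simpler: poses scatter around planted
binding-mode centroids (within-cluster RMSD ≈ spread), actives score
N(separation, 1) against N(0, 1) decoys (12 actives vs 5200 decoys by
default, AUC → Φ(separation/√2)).

## Numerical choices and degenerate inputs

* Distance clamp 0.5 Å; interaction cutoff 8 Å; lattice node counts are
  `ceil((extent + 2·margin)/spacing) + 1` per axis.
* Constant descriptor columns: dropped with a log message in PLS; an error
  in OLS (where the design would be singular); correlation 0 in selection.
* Ties: descriptor selection and node extraction break ties on the lower
  index; pose-cluster labels are renumbered by decreasing size.
* Empty hotspot sets are a warning, not an error (a probe may legitimately
  find nothing on sparse chemistry).
* All randomness flows from explicit integer seeds; the FFD design and the
  diverse-split tie-break are the only stochastic elements outside the
  generators.

## Problem sizes used by the shipped experiments

The reference experiments run at the scale the generator emulates: 89
training molecules, 10 library seeds for the recovery experiment, 500
replicates for regression nulls, 1000 label shuffles for the enrichment
null, a 12-active/5200-decoy screen and 12×10 poses around 6 binding modes.
These sizes keep a full run of the test suite and the acceptance script in
the minutes range on a single CPU.

## Known limitations

* Field parameterization is generic; absolute energies are not comparable
  with commercial MIF engines.
* No conformational sampling: fields are computed on the given conformer.
* The FFD noise floor is a heuristic; on marginal variables (effect of the
  order of the dummy band) its keep/remove decision is seed-dependent.
* The correlogram window is finite (30 Å default); longer-range feature
  pairs are invisible to the descriptor.
* MOL2 reading trusts the file's partial charges; SDF input gets Gasteiger
  charges, which are crude for unusual chemotypes.
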