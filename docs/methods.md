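# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `lectnet`. It is written for users who want to know
exactly what the package computes and what its tests do and do not
demonstrate.

## Residue classification from solvent accessibility

Solvent-accessible surface area is computed by Shrake–Rupley sphere
sampling: 960 deterministic golden-spiral points per atom on the expanded
sphere of radius `r_vdw + probe`, probe radius 1.4 Å. Van der Waals radii
are a bundled per-element table (C 1.70, N 1.55, O 1.52, S 1.80, …);
relative SASA divides the per-residue absolute area by the residue type's
theoretical maximum (Tien et al. 2013 values). Both tables can be replaced
by a user file. At 960 points an isolated atom's area is exact to machine
precision (every point is exposed) and two-atom overlap areas agree with a
10 000-point run within 2 %; an independent implementation (biotite) agrees
on total areas within 2 %.

A residue is *solvent exposed* when its relative SASA exceeds 0.20. This
cutoff is a package choice: classification sources rarely state one, and
common conventions range from 0.05 to 0.25. Whole-residue (not
side-chain-only) SASA is used. The categories are:

* **interface** — exposed in the monomer, not exposed in the complex;
* **surface** — exposed in both;
* **interior** — not exposed in the monomer;
* **ligand-binding** — any heavy atom within 3.9 Å of a ligand heavy atom
  (e.g. mannose, residue name MAN). Ligand binding takes precedence over
  the other categories in the single-label output but is also emitted as an
  independent flag so overlapping sets can be reported.

Interface contact pairs are cross-chain residue pairs whose minimum
heavy-atom distance is below 4.0 Å; distances are reported rounded to two
decimals but compared unrounded. Hydrogens and waters are excluded
everywhere; for alternate conformations the highest-occupancy conformer is
kept.

## Dynamical residue networks

Motion correlation uses Cα displacement vectors over the selected frame
range, `C_ij = ⟨Δr_i·Δr_j⟩ / (⟨Δr_i²⟩⟨Δr_j²⟩)^{1/2}`; the diagonal is set
to exactly 1 and a residue with zero displacement variance is an error. A
pair of residues is a *persistent contact* when a pair of heavy atoms, one
from each residue, is within 4.5 Å in at least 75 % of frames (the boundary
counts). Sequence-consecutive residues of the same chain never carry an
edge. Edges exist for persistent pairs with `C_ij > 0` and have weight
`−log C_ij`; anticorrelated pairs (C ≤ 0) are removed because the analysis
targets residues moving in the same direction.

Numerical choices here:

* **Log base** — natural log. Shortest-path structure, betweenness,
  closeness and DPL *rankings* are invariant to the base (it is a uniform
  scale factor on all weights, and the tests assert this invariance); only
  the absolute magnitudes of CPL and DPL depend on it.
* **No trajectory superposition** is performed: the synthetic generator
  produces fluctuations without global rotation/translation drift. For real
  trajectories the caller should superpose frames beforehand if needed.
* **Frame range** — the caller selects it (`frame_start`), e.g. to drop an
  equilibration prefix; nothing is hard-coded.
* Networks are built per trajectory; no cross-replica averaging.

## Graph metrics

All-pairs shortest paths use a Floyd–Warshall recursion that also counts
distinct shortest paths; two path lengths are considered tied under an
absolute tolerance of 1e-9 (float weights make exact ties rare, but the
counting definition needs a rule). Betweenness is the raw count of shortest
paths between all unordered node pairs passing through a node as an
interior vertex — not the Brandes-normalised fraction; the z-scoring that
feeds the outlier flags removes the overall scale anyway. Closeness
restricts `n` and the distance sum to the node's connected component;
isolated nodes get 0 with a warning. CPL averages over unordered reachable
pairs. DPL(x) is CPL(G−x) − CPL(G), positive when removal lengthens paths.
If removing x disconnects pairs they are dropped from the post-removal
average and counted in a reported `dpl_disconnected_pairs` column; if a
removal disconnects *every* remaining pair its DPL is NaN and it is never
flagged. Z-score flags use the cutoffs 1.5 (betweenness) and 1.0 (DPL) by
default; closeness tiers are competition-ranked percentiles — high = top
20 %, intermediate = 20–60 %, low = rest, ties sharing the better tier.

The metric suite is verified against exhaustive path enumeration on random
graphs (n ≤ 8), against networkx Dijkstra distances, and on closed-form
fixtures (stars, paths, cycles, complete graphs).

## Mean-field direct coupling analysis

The DCA pipeline is the classic mean-field recipe on the 21-state alphabet
(20 amino acids + gap):

1. columns with **more than 50 %** gaps are removed (exactly 50 % is kept);
2. sequence weights `1/m_a`, where `m_a` counts sequences with **more than
   80 %** identity to sequence *a* (gaps compared as a state, self
   included); `M_eff = Σ 1/m_a`;
3. frequencies with a **bare** pseudocount λ = 0.5:
   `f_i(A) = (λ/21 + Σ_a δ/m_a) / (λ + M_eff)` and the analogous pair
   formula with λ/21²; these satisfy Σ_A f_i = 1 and Σ_B f_ij = f_i exactly
   (asserted to 1e-12);
4. couplings `e_ij = −(C^emp)^{-1}` from the empirical covariance
   `f_ij − f_i f_j`, assembled and inverted on a reduced q−1 = 20-state
   basis with the gap as the zero reference state (the full 21-state matrix
   is singular by construction);
5. per pair, an isolated two-site model
   `P^d_ij(A,B) ∝ exp[e_ij(A,B) + h̃_i(A) + h̃_j(B)]` whose fields are
   fitted so its marginals equal `f_i, f_j`;
   `DI_ij = Σ P^d ln(P^d / f_i f_j)` (natural log, hence DI ≥ 0, and DI = 0
   exactly when the couplings vanish). Pairs with DI > 0.8 and sequence
   separation ≥ 2 columns are flagged as coevolving.

**A caution on the bare pseudocount.** With λ = 0.5 (rather than the
λ ≈ M_eff convention used by much of the mean-field DCA literature) the
covariance matrix is only weakly regularised. On deep alignments this
merely adds O(1) sampling noise to individual couplings; on shallow
alignments (M far below L·20, which includes realistic lectin families of a
few dozen sequences) the inverse produces couplings of magnitude up to
~1e3. The DI statistic remains well behaved — under a no-coupling null it
stays near 0.05, two orders of magnitude below the 0.8 decision threshold —
but individual coupling values should not be over-interpreted.

**Two-site field fitting.** The fields are fitted by an alternating
(Sinkhorn-type) marginal-matching iteration run entirely in the log domain,
initialised at the independent-model fields, with convergence tolerance
1e-4 on the worst marginal error and a cap of 5000 iterations (both
configurable). The log domain makes arbitrarily large couplings safe from
overflow. Extreme couplings can create float-level hard zeros in
`exp(e_ij)`, in which case the iteration provably stalls at its projection
onto the feasible support: a stall above tolerance but within 100× of it is
accepted with a warning (the DI error is of the same order as the residual,
~1e-3 at worst, immaterial against the 0.8 threshold); a larger residual
raises an error naming the pair. The tolerance was set at 1e-4 because the
1e-6 one might ask for is unreachable on degenerate pairs and buys no
decision-relevant precision.

Restriction of the analysis to a column subset (e.g. the interface
positions of a structure) is supported via an explicit `columns` argument;
the package deliberately does not guess a structure-to-alignment mapping.

## Conservation grading and HP patterns

The per-column conservation score is `1 − H/ln 20`, where H is the Shannon
entropy of the column's amino-acid distribution with gaps excluded; columns
that are all gaps are undefined (grade 0, flagged), and columns over 50 %
gaps carry a flag. Grades 1–9 are equal-width bins of the score, 9 most
conserved. This is an information statistic, **not** a phylogenetic rate
model: it ignores tree structure and sequence non-independence, so its
grades are not comparable to rate-based conservation grades beyond rank
ordering. Rate-model conservation was deliberately left out of scope.

Hydrophobic–polar pattern analysis classifies the residue pair at two
designated columns for each sequence as polar–polar, polar–hydrophobic or
hydrophobic–hydrophobic, using the 8-residue hydrophobic set
{A, V, L, I, M, F, W, C} (configurable — worth noting because methionine is
hydrophobic under any standard scale yet polar under some informal usage;
the default keeps it hydrophobic). Replicates subsample sequences without
replacement (defaults: 31 of the single-domain and 11 of the double-domain
sequences, 5 replicates) from a single seeded RNG stream. Sequences with a
gap at either designated column cannot be classified and are excluded from
the sampling pool, so class counts always sum to the subsample size.

## Synthetic generators

The generators emulate the *statistical* assumptions of the analysis, not
molecular physics — no force field, solvent, thermostat or realistic
side-chain packing. Consequently, passing tests demonstrate that the
pipeline recovers planted structure under its own model assumptions; they
do not validate force-field accuracy or alignment quality on real data.

* **Trajectories** — frames are reference coordinates plus Gaussian
  displacements drawn per axis from N(0, amplitude²·C) across residues,
  where C is the planted correlation matrix (symmetric PSD, unit diagonal;
  the matrix square root comes from an eigendecomposition). All heavy atoms
  of a residue move rigidly with its Cα, so persistence is controlled by
  the reference geometry. Default amplitude 0.25 Å keeps designed contacts
  (~3.4 Å) safely inside and non-contacts (≥ 5.4 Å) safely outside the
  4.5 Å cutoff. The measured correlation converges to the planted matrix
  (within ±0.05 at 5000 frames, tested).
* **Contact topologies** — an arbitrary designed contact graph is embedded
  in 3-D by penalised least squares (designed pairs at 10 Å centre
  distance, all others ≥ 12.5 Å), then each residue gets a Cα at its centre
  and one "arm" atom extended 3.3 Å toward each designed partner. Residue
  numbers are spaced by two so the consecutive-residue edge exclusion never
  interferes with designed contacts.
* **Bottleneck system** — two blobs of strongly co-moving residues (ring
  contact geometry, within-blob correlation 0.7 from a shared factor), one
  bridge residue touching two hub residues of each blob (correlation 0.50
  to blob members), and a weakly correlated detour path (~0.25–0.29) that
  keeps the network connected when the bridge is removed. All shortest
  inter-blob paths cross the bridge (weight 2×0.69 versus ~6.7 via the
  detour), so the bridge attains the top betweenness; because removal
  reroutes all that traffic onto the detour, it also attains the top DPL.
  The correlation matrix is a factor model, hence PSD by construction.
* **Toy dimer** — chain A is an extended pseudo-peptide (3.8 Å spacing,
  five heavy atoms per residue); chain B is a closed atomic cage (cylinder
  radius 4 Å, grid spacing < 3 Å, annular end caps) around the middle third
  of chain A. A 1.4 Å probe cannot enter the cage, so patch residues have
  complex relative SASA ≈ 0 against monomer values ≈ 0.77, while
  patch-adjacent residues stay ≥ 0.31 and cage residues ≥ 0.57 — wide
  margins on both sides of the 0.20 threshold, so the planted interface set
  is recovered exactly (10/10 seeds, tested). The cage walls sit
  asymmetrically (−0.7/+1.6 Å beyond the patch) because the pseudo-residue
  geometry extends its carbonyl-side atoms toward +x.
* **Potts alignments** — sequences are sampled from
  `P(A_1…A_L) ∝ exp[Σ e_ij(A_i,A_j) + Σ h_i(A_i)]` with planted couplings
  `e_ij(A,B) = s·δ(A,B)` on designated column pairs (a Potts ferromagnet on
  20 states). Each of the M sequences is an independent Markov chain; all
  chains are swept in parallel with single-site heat-bath updates, 100
  sweeps of burn-in by default, final states taken as the sample (parallel
  independent chains make thinning unnecessary). Gaps are inserted
  independently afterwards with a configurable probability (default
  conditions use 2 %). Exact sampling is intractable at L = 30; the burn-in
  default was chosen so that a single strongly coupled pair dominates the
  empirical mutual information (tested) and null columns are uniform within
  sampling error (tested).

## Study conditions used by the acceptance script

The synthetic study conditions mirror the sizes of the original analysis
wherever those are stated: HP resampling draws 31 of 46 single-domain and
11 of 16 double-domain sequences with 5 replicates; DCA thresholds are
DI > 0.8, identity 0.8, λ = 0.5, 50 % gap filtering; network thresholds are
4.5 Å / 75 % persistence and z cutoffs 1.5 / 1.0; contact analysis uses
4.0 Å. Where the original inputs are not reproducible on a desktop
(30 ns solvated MD, curated family alignments), the script substitutes the
synthetic generators at these sizes: 5000-frame trajectories for
correlation recovery, 2000-frame bottleneck trajectories, Potts alignments
with L = 30, M = 2000 and five planted pairs at strength 3.0, twenty
random connected 50-node graphs for the betweenness–DPL relation, and ten
toy dimers. These sizes keep the full script under ~2 minutes on one CPU.

## Known limitations

* The crystal-structure contact check requires PDB entry 1KJ1, which is not
  redistributable with the package; without `data/1KJ1.pdb` that single
  test reports its missing input.
* mfDCA only: no pseudolikelihood variant, no average-product correction.
  On shallow alignments the bare-pseudocount couplings are noisy (see
  above).
* Entropy-based conservation is not a substitute for rate-model grades.
* The synthetic trajectory model has no global rotation, anisotropy or
  anharmonicity; correlation recovery results say nothing about the
  superposition step real MD data would need.
* Multi-model PDB is the only trajectory format; convert binary formats
  upstream.
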