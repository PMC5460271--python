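# lectnet

Residue-network and coevolution analysis of bulb-type lectin dimer
recognition.

Bulb-type (mannose-binding) plant lectins are beta-prism II proteins that
are biologically active as dimers. Which residues let two monomers find and
recognise each other? `lectnet` implements a hybrid structural /
dynamical / evolutionary analysis of this question for people working on
protein–protein recognition:

* **Structure** — residues of a dimer are classified from solvent
  accessibility (Shrake–Rupley SASA): *interface* residues are exposed in
  the monomer but buried in the complex, *surface* residues are exposed in
  both, *interior* residues are buried already in the monomer, and
  ligand-binding residues are detected by a heavy-atom distance criterion.
  Cross-chain contact pairs are reported with minimum heavy-atom distances.
* **Dynamics** — a residue interaction network is built from a trajectory:
  nodes are residues, and two nonconsecutive residues are linked when their
  heavy atoms stay within 4.5 Å in ≥ 75 % of frames and their Cα motions are
  positively correlated. Edge weights are

  `W_ij = −log C_ij`,  with  `C_ij = ⟨Δr_i·Δr_j⟩ / (⟨Δr_i²⟩⟨Δr_j²⟩)^1/2`,

  so strongly co-moving residues are close in the network. On this weighted
  graph the package computes closeness `C(x) = (n−1)/Σ_y d(x,y)`, raw
  shortest-path betweenness, the characteristic path length (CPL) and the
  delta path length (DPL, the CPL change caused by removing a node), plus
  z-score outlier flags and closeness tiers (top 20 % / 20–60 % / rest).
* **Evolution** — mean-field direct coupling analysis (DCA) of aligned
  lectin families: gap-rich columns are dropped, sequences are reweighted
  (> 80 % identity), frequencies are estimated with a pseudocount λ = 0.5
  over the 21-state alphabet, couplings come from the negative inverse of
  the empirical covariance, and each column pair is scored by direct
  information, `DI_ij = Σ_AB P^d_ij(A,B) ln [P^d_ij(A,B) / f_i(A) f_j(B)]`,
  with DI > 0.8 flagged as a coevolution signal. Alongside DCA there is an
  entropy-based 9-grade conservation score and a hydrophobic–polar
  pattern resampling of interface position pairs in single- vs
  double-domain lectin families.

Because molecular-dynamics trajectories and curated alignments are
expensive inputs, the package ships first-class synthetic generators
(`lectnet.synthetic`) with planted ground truth — correlated-fluctuation
trajectories, contact-graph topologies, a toy dimer with a designed buried
patch, and Gibbs-sampled Potts alignments — so the entire pipeline is
testable end to end.

## Worked example

Build a network from a synthetic trajectory with a planted communication
bottleneck and ask which residue the metrics single out:

```python
from lectnet.synthetic import make_bottleneck_system, simulate_trajectory
from lectnet.network import network_from_trajectory
from lectnet.graphmetrics import network_metrics

spec, truth = make_bottleneck_system(seed=1, n_frames=2000)
g = network_from_trajectory(simulate_trajectory(spec))
table, summary = network_metrics(g)
print(f"network: {summary['n_nodes']} residues, {summary['n_edges']} edges, "
      f"CPL = {summary['cpl']:.3f}")
for _, row in table.sort_values("betweenness_z", ascending=False).head(3).iterrows():
    print(f"  {row['node']:>5s}  betweenness z = {row['betweenness_z']:+.2f}   "
          f"DPL z = {row['dpl_z']:+.2f}   tier = {row['closeness_tier']}")
print("planted bottleneck:", truth["bridge_node"])
```

prints

```
network: 23 residues, 27 edges, CPL = 2.789
   A:34  betweenness z = +3.01   DPL z = +4.25   tier = high
    A:4  betweenness z = +1.24   DPL z = -0.12   tier = high
   A:20  betweenness z = +1.00   DPL z = -0.13   tier = high
planted bottleneck: A:34
```

The residue planted as the sole bridge between the two co-moving modules
(A:34) attains by far the highest betweenness and DPL z-scores — exactly
the signature used to call a residue critical for inter-monomer
communication — while the hub residues it touches (A:4, A:20) rank next.

A command-line interface mirrors the library (`lectnet classify`,
`network`, `metrics`, `dca`, `conserve`, `hp`, `simulate`, `run-all`,
`report`); `lectnet run-all --config run.yaml` executes every configured
stage and `lectnet report` summarises the outputs.

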