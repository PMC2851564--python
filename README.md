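# aakdyn

Coarse-grained dynamics of amino-acid-kinase-like proteins: elastic-network
normal modes, their overlap with crystallographic conformational changes, a
Markov model of intramolecular communication, and conservation of slow modes
across protein-family members via subsystem normal-mode analysis.

The package is aimed at structural biologists and molecular modellers who
want to ask, for an enzyme such as N-acetyl-L-glutamate kinase (NAGK) and
its amino-acid-kinase relatives: which large-amplitude motions does the fold
itself encode, do those motions explain the open↔closed transition seen in
crystal structures, how do signals travel between binding sites and the
catalytic centre, and are the slow modes conserved across the family?

## Models

**GNM.** The Gaussian network model places a node at each Cα and a uniform
spring between every pair within a cutoff R_c (default 10 Å). The N×N
Kirchhoff matrix **Γ** (Γ_ij = −γ for contacts, zero row sums) determines
isotropic fluctuations through its non-zero modes (λ_k, **u**_k):

    ⟨(ΔR_i)²⟩ = (3k_BT/γ) Σ_k λ_k⁻¹ (u_k)_i² ,    B_i = (8π²/3) ⟨(ΔR_i)²⟩

Minima of a slow-mode shape where the sign flips between sequence
neighbours are mechanical hinges.

**ANM.** The anisotropic network model penalises changes of the scalar
inter-node distance; its 3N×3N Hessian (cutoff default 15 Å) has 3N−6
non-zero modes carrying directionality. How well m modes describe an
observed deformation **Δr** (after least-squares superposition) is the
cumulative overlap

    CO(m) = [ Σ_{k=1..m} cos²(u_k, Δr) ]^½ ,

which reaches 1 over the complete internal basis. Conformers along mode k
are R± = R⁰ ± s_k λ_k^{−1/2} **u**_k.

**Communication.** Residue affinities a_ij = N_ij/√(N_i N_j) count
heavy-atom contacts within 4 Å, normalised by residue atom counts. The
column-stochastic matrix m_ij = a_ij/d_j defines a random walk whose
hitting time H(j|i) — expected steps from i to j — follows in closed form
from the degrees and the pseudoinverse of the weighted Laplacian
**Γ̃** = **D** − **A**; commute times obey τ_ij = Vol · R_eff(i,j).
Maximum-likelihood pathways are Dijkstra shortest paths under the edge
cost −log m_ij.

**Subsystem modes.** For an aligned subsystem S coupled to an environment
E, the effective Hessian is the Schur complement
H̃ = H_SS − H_SE H_EE⁻¹ H_ES; its modes are the subsystem's collective
motions with the environment's elastic response folded in. Family-level
conservation is summarised as ⟨CO(10)⟩ × 100 between the first ten modes
of two aligned structures.

## Worked example

Synthetic structures with known dynamics are built in; a two-lobe dumbbell
with a designed hinge at node 20 plays the role of an open enzyme:

```python
import numpy as np
from aakdyn import (ToySpec, make_toy, build_kirchhoff, build_hessian,
                    decompose, find_hinges, cumulative_overlap,
                    deformation_vector, build_affinity, build_markov,
                    hitting_times, mean_receive_time, shortest_path)
from aakdyn.synthetic_data import deform_toy

protein = make_toy(ToySpec("dumbbell", 40))          # two lobes + hinge
gnm = decompose(build_kirchhoff(protein, cutoff=10.0))
anm = decompose(build_hessian(protein, cutoff=15.0))

hinges = find_hinges(gnm.mode(1), chains=protein.chains)
print("GNM mode-1 hinge nodes:", hinges)

closed = deform_toy(protein, mode=1, amplitude=1.0)  # synthetic closed form
dr = deformation_vector(protein, closed)
co = cumulative_overlap(anm, dr, 10)
print(f"deformation RMSD: {dr.rmsd:.2f} A")
print("CO(1), CO(3), CO(10):", np.round(co[[0, 2, 9]], 3))

comm = hitting_times(build_affinity(protein, threshold=4.0))
profile = mean_receive_time(comm)
print("best receiver:", protein.labels[int(np.argmin(profile))],
      f"(mean hitting time {profile.min():.0f} steps)")
path, cost = shortest_path(build_markov(comm.affinity), 0, 39)
print(f"optimal 1->40 pathway: {len(path)} residues, cost {cost:.1f}")
```

prints

```
GNM mode-1 hinge nodes: [20]
deformation RMSD: 1.00 A
CO(1), CO(3), CO(10): [1. 1. 1.]
best receiver: A:GLY20 (mean hitting time 678 steps)
optimal 1->40 pathway: 13 residues, cost 17.5
```

The hinge detector recovers the designed bridge node; a structure deformed
along mode 1 is fully explained by that single mode (CO(1) = 1); and the
hinge region — the least mobile site — is also the most efficient receiver
of random-walk signals, mirroring the behaviour of catalytic residues in
real enzymes.

The same analyses run from the shell: `aakdyn gnm`, `aakdyn overlap`,
`aakdyn conformers`, `aakdyn comm`, `aakdyn path`, `aakdyn compare`,
`aakdyn synth`, and `aakdyn run --config study.yaml` for the full
three-stage pipeline (see `aakdyn --help`).

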