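# mgatekit

Trajectory analyses for pseudo-symmetric membrane carriers — the
mitochondrial carrier family (MCF) fold in particular — aimed at the
structural-bioinformatics questions around the *matrix gate*: the
salt-bridge/H-bond network that seals the matrix side of the
cytosol-open carrier.

Carriers of this family are built from three homologous domains, each
an odd/even helix pair (H1–H2, H3–H4, H5–H6), with conserved
Px[DE]xx[KR] motifs contributing one acidic and one basic residue per
odd helix to the gate. mgatekit quantifies, per trajectory:

- **interaction occupancies** — per-frame detection of salt bridges
  (min side-chain N···O ≤ 4.0 Å), H-bonds (D–A ≤ 3.5 Å, H–D–A ≤ 30°),
  Arg–Arg guanidinium stacking (centroids ≤ 5.0 Å, planes within 30°)
  and ligand contacts, turned into % occupancy over an analysis window
  and classified intra-helical / inter-helical / other;
- **inter-domain attachment scores** — summed inter-helical occupancy
  per domain pair (how tightly two domains hold together);
- **ψ, the C3-symmetry deviation** — for each *triplet* (the three
  residues at equivalent positions across domains, e.g. residues 33,
  138, 235), the mean absolute deviation of its Cα-triangle angles from
  60°: ψ = (|θ₁−60°| + |θ₂−60°| + |θ₃−60°|)/3, zero iff equilateral;
- **RMSF profiles** after least-squares superposition onto the
  (iteratively refined) window-average structure;
- **minimum-distance series and gap events** — per-frame minimum
  heavy-atom distance between two groups, with detection of crevice
  openings (maximal runs above a cutoff, minimum duration) and
  bridging-solvent counts.

A synthetic **toy-carrier generator** provides validation inputs with
exact ground truth: six ideal helices with exact threefold symmetry,
optional injected domain-1 asymmetry, isotropic positional noise,
solvent slabs, and "channels" — charge-site pairs whose contact state
follows a two-state Markov process with bands constructed so that
geometric detection recovers the state sequence with zero errors. See
`docs/methods.md` for the full model description.

## Worked example

```python
import mgatekit as mg

# a toy carrier: 6 x 12 residues, two salt-bridge channels with known kinetics
spec = mg.ToyCarrierSpec(
    helix_length=12, n_frames=2000, seed=11, noise_sigma=0.2,
    channels=[
        mg.ChannelSpec(res_a=3, res_b=27, k_on=0.2, k_off=0.1),    # H1-H3
        mg.ChannelSpec(res_a=5, res_b=53, k_on=0.05, k_off=0.45),  # H1-H5
    ])
structure, helix_map, triplet_map = mg.build_toy_carrier(spec)
trajectory, truth = mg.simulate_trajectory(structure, spec)

config = mg.AnalysisConfig(
    helix_map=helix_map,
    domain_map={"H1": "D1", "H2": "D1", "H3": "D2",
                "H4": "D2", "H5": "D3", "H6": "D3"},
    triplet_offsets={"odd": (0, 24, 48)},
    triplets=[3, 5, 9],
    interactions=[
        mg.InteractionSpec(kind="salt_bridge", sel_a="resid 3",
                           sel_b="resid 27", label_a="R3", label_b="D27"),
        mg.InteractionSpec(kind="salt_bridge", sel_a="resid 5",
                           sel_b="resid 53", label_a="R5", label_b="D53"),
    ],
    frame_window=mg.FrameWindow(0.2, 1.0),   # discard the first 20% of frames
)
bundle = mg.run_pipeline(config, structure, trajectory)
print(bundle.occupancy_table[["res_a", "res_b", "class", "occupancy_pct"]])
print(bundle.symmetry_summary)
print("attachment scores:", bundle.attachment)
print("true on-fractions:", {k: round(v, 3) for k, v in truth.realized_fractions.items()})
```

Output:

```
  res_a res_b          class  occupancy_pct
0    R3   D27  inter_helical           67.9
1    R5   D53  inter_helical            9.8

   triplet  mean_psi_deg  sd_psi_deg
0        3      0.917429    0.473473
1        5      0.654451    0.339594
2        9      0.718994    0.383858

attachment scores: {('D1', 'D2'): 67.9, ('D1', 'D3'): 9.8, ('D2', 'D3'): 0.0}
true on-fractions: {'3:27': 0.681, '5:53': 0.096}
```

Both channels connect domain 1 to another domain and classify as
inter-helical; their measured occupancies (67.9%, 9.8%) equal the
generator's realized on-fractions over the analysis window. The mean ψ
values of ~0.7–0.9° reflect only the 0.2 Å positional noise — the
underlying bundle is exactly threefold symmetric, and a noiseless run
gives ψ = 0 for every triplet.

The same analyses run from the shell on PDB inputs:

```
mgatekit synth   --spec toy.yaml --out system/ --seed 7
mgatekit analyze --topology system/reference.pdb --traj system/trajectory.pdb \
                 --config analysis.yaml --out report/
mgatekit compare --a report_wt/ --b report_mutant/ --out delta.csv
```

`analyze` writes `occupancy_table.csv`, `network.json`,
`attachment_scores.json`, `psi_series.csv` / `psi_summary.csv`,
`rmsf.csv`, per-pair `distance_*.csv` / `gap_events_*.csv`,
`solvent_counts.csv` and a `provenance.json` carrying the config hash.
`compare` reports per-edge occupancy deltas (B − A; edges absent from
one system count as 0%), plus ψ and RMSF deltas.

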