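# permeopath

Trajectory analysis of substrate permeation pathways in membrane
transporters of the neurotransmitter:Na⁺ symporter (NSS) fold — the family
of the dopamine transporter (DAT) and its prokaryotic homolog LeuT.

Molecular-dynamics and steered-pulling (SMD) simulations of these
transporters are typically characterized by a recurring set of
trajectory-level measurements: which residues line the primary (S1) and
vestibular (S2) binding sites, which residues the substrate "sees" on its
way in or out, how water penetrates along the membrane normal, how helices
kink at Gly/Pro hinge residues, and which regions move rigidly between
conformational states. `permeopath` implements that analysis layer as a
tested, reusable library with a CLI, plus synthetic-system generators with
known ground truth so every stage can be validated end to end without any
simulation data.

## What it computes

- **Binding-site occupancy** — a residue belongs to a site if it spends more
  than a threshold fraction *f* (default 5%) of analyzed frames within a
  cutoff *d* (default 3.5 Å, heavy-atom minimum distance) of the substrate.
- **Pathway classification** — for a pulling trajectory, each residue's
  contact percentage over its own contact window,
  *n*<sub>seen</sub> / (last − first + 1), with the pathway defined by the
  maximum over trajectories exceeding *f*, after excluding site residues.
- **Helix kink geometry** — bend angle θ between pre- and post-pivot helix
  axes and the face-shift angle (rotation of the helical register across the
  kink, measured in the plane perpendicular to the shared axis), per frame
  and summarized as mean ± std.
- **Iterative weighted superposition** — Kabsch fits where each refinement
  pass reweights residue *i* by *w<sub>i</sub>* = 1/(RMSD*<sub>i</sub>*² + ε),
  partitioning structures into rigid (≈1–2 Å) and mobile (≈3–6 Å) segments;
  plus superposition-free difference distance matrices.
- **Solvation** — water counts per z-bin along the membrane normal
  (z = 0 at the membrane center), and Shrake–Rupley SASA with lipid-exposed
  surface counted as buried, normalized per residue by its SASA in an
  extended Gly-X-Gly tripeptide.
- **Energetics** — group–group nonbonded energies
  *E* = *Cq₁q₂/r* + ε[(r<sub>min</sub>/r)¹² − 2(r<sub>min</sub>/r)⁶]
  with *C* = 332.0636 kcal·Å/(mol·e²), e.g. substrate–water interaction
  energy along a pulling path.
- **Torsion statistics** — φ/ψ/χ1/χ2 series, g+/t/g− rotamer states, and
  Spearman rank correlation between angle series (unwrapped across the
  ±180° seam).

## Worked example

Generate the bundled synthetic system (scripted ligand contacts, a helix
kinked 30° with a 45° face shift at residue 20, a two-domain ensemble, a
water slab, and a ligand-into-water approach) and run the full pipeline:

```sh
permeopath simulate --out demo --seed 1
permeopath run demo/config.txt
```

`demo/results/sites.tsv` recovers the scripted contact fractions exactly:

```
Index   Residue  Ca_z_A  pct
1.46    1        0.00    30
1.49    4        60.00   10
1.52    7        120.00  20
```

i.e. residues 1, 4 and 7 (generic labels 1.46/1.49/1.52) were scripted into
contact for 30, 10 and 20 of 100 frames. Residue 9, in contact only 4% of
the time (below the 5% site threshold) but in 4 of the 7 frames of its own
contact window, appears only in `pathway.tsv` at 57% — the windowed pathway
statistic. `kinks.tsv` reports the imposed helix distortion:

```
Residue  bend_avg  bend_std  face_shift_avg  face_shift_std
20       30.0      0.0       45.0            0.0
```

and `residue_rmsd.tsv` labels all 16 core residues of the two-domain
ensemble `rigid` (RMSD < 0.01 Å) and all 8 hinge-swung arm residues
`mobile` (RMSD > 3 Å). Every table carries a provenance header (config
hash, seed, package/numpy versions, numeric conventions); rerunning with
the same config is byte-identical.

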