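# minifil

Coarse-grained modelling of nonmuscle myosin II (NM2) minifilament assembly:
sequence-derived charge chains, screened electrostatics of staggered
coiled-coil rods, worm-like-chain splaying, and mean-first-passage contact
times for homo- and hetero-dimers.

## The problem

NM2 motors assemble into ~300 nm minifilaments of ~30 monomers whose ~160 nm
coiled-coil tails ("rods") pack side by side at characteristic axial offsets:
parallel staggers of 14.3, 43.2 and 72 nm and an antiparallel overlap of
43–45 nm.  Because a coiled coil rises 0.1456 nm per residue, the parallel
staggers are odd multiples of 98 residues — the half-period of the rod's
196-residue charge repeat.  Which staggers survive, and for how long, shapes
the dynamic behaviour (splitting, concatenation, isoform exchange) seen in
live-cell microscopy.  This package models dimer formation — the elementary
step of assembly — for users who want to rank staggers, isoform pairings, or
rod mutants by the stability of their contacts.

## The model

1. **Charge chain.** Each heavy-chain rod becomes a line of point charges on
   a 0.1456 nm lattice: +2e for Arg/Lys, −2e for Asp/Glu (two heavy chains
   per rod), 0 otherwise; charges at heptad positions *a*/*d* (buried in the
   coiled-coil core) are cancelled; skip residues are kept as sites.
2. **Electrostatics.** Two rods at lateral distance 2 nm interact through the
   linearised (Debye–Hückel) screened Coulomb energy
   `E = Σᵢⱼ qᵢqⱼ (l_B/rᵢⱼ) exp(−rᵢⱼ/l_DH)` with Bjerrum length
   l_B ≈ 0.7 nm and screening length l_DH ≈ 1.3 nm (~100 mM salt),
   scanned over the stagger s.
3. **Splaying.** At stagger s and overlap L_o the mobile rod is straight
   along its attached C-terminal segment, then bends away along a circular
   arc (worm-like chain, `E_bend = l_p L_a / 2R²` in k_BT, l_p = 130 nm);
   R ∈ [75, 300] nm and L_a ∈ [15, 40] nm are fixed per cell by grid
   minimisation of the total energy.
4. **Contact time.** With the stagger held fixed, the overlap diffuses in
   V(L_o) between a reflecting boundary at L_max(s) and an absorbing
   boundary at L_o = 0; the mean first passage time from a 3.6 nm initial
   tip contact, `T₁ = (1/D)∫₀^{x₀} e^{V(z)} ∫_z^{a} e^{−V(y)} dy dz`,
   is reported as D·T₁ in nm² (only relative values are meaningful).

## Worked example

The package ships a synthetic rod generator with the NM2 charge skeleton
(196-site repeat, five negative blocks, charge-complementary positive
C-terminal tip), so everything runs without sequence downloads:

```bash
python examples/stagger_scan.py
python examples/contact_times.py
```

prints

```
parallel:
  energy range [-5.8, +34.7] kBT
  local minima at [ 14.3  42.8  71.3  99.9 128.4] nm  (= [ 98 294 490 686 882] sites)
...
parallel: global peak D*T1 = 623 nm^2 at s = 14.3 nm
  peak staggers (sites): [ 98 294 490 686 875]
antiparallel: global peak D*T1 = 2.26e+04 nm^2 at s = 43.8 nm
...
antiparallel / parallel peak contact time: 36x
```

Straight-rod energy minima and contact-time peaks fall at the odd multiples
of 98 residues (14.3 nm, 42.8 nm, 71.3 nm, ...), and antiparallel contacts
outlive parallel ones by well over an order of magnitude — antiparallel
dimers act as nucleation seeds while parallel rods attach transiently and
splay.  `examples/splay_landscape.py` and `examples/heterodimer_matrix.py`
show the overlap potentials behind these numbers and the ordered-pair
(straight rod first, bent rod second) contact-time matrix.

To run on the real heavy chains, fetch the sequences once on a networked
machine (`python scripts/fetch_sequences.py`) and point the CLI or
`minifil.config.RunConfig` at the resulting FASTA and rod annotations
(rod boundaries, heptad phase or a per-residue register TSV, skip residues):

```bash
minifil scan --fasta data/isoforms/isoforms.fasta --orientation antiparallel
minifil contact-time --config my_run.yaml
```

All commands write TSV files whose header comments record the full
parameter set.

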