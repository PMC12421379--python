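# g4kit

Structural annotation of G-quadruplex (G4) nucleic acids from atomic
coordinates, with the accompanying solution-biophysics calculations.

G-rich sequences such as the ALS/FTD-linked GGGGCC (G4C2) repeats of
*C9orf72* fold into four-stranded quadruplexes: stacks of planar G-tetrads
— cyclic arrangements of four guanines, each donating Hoogsteen hydrogen
bonds N1→O6 and N2→N7 to its neighbor — held together by channel K⁺ ions.
Interpreting such structures means answering a standard set of questions:
which guanines form which tetrads, in which hydrogen-bond direction; is the
fold parallel, antiparallel or hybrid; which loops are propeller, lateral
or diagonal; how wide are the four grooves; where do the channel cations
sit; do cytosines form C·C⁺ pairs or quadruple base pairs; what are the
backbone torsions, glycosidic syn/anti states and sugar puckers?  `g4kit`
answers them programmatically, for deposited PDB/mmCIF files or for its own
synthetic test structures, and adds the two desk calculations used
alongside: Boltzmann-sigmoid melting fits (Tm) for CD melting curves and
theoretical oligonucleotide masses for SEC-MALS oligomer-state assignment.

For structural bioinformaticians and nucleic-acid crystallographers who
want reproducible, scriptable G4 annotation instead of by-eye calls.

## The core methods

* **Tetrad detection** — directed Hoogsteen graph over guanines; a
  4-cycle is a tetrad when the mean of its eight N1–O6/N2–N7 heavy-atom
  distances is ≤ 3.4 Å and the four bases are coplanar (≤ 1.0 Å rms).
  Verified against exhaustive enumeration.
* **Core assembly & topology** — stacked tetrads are chained into cores;
  strand columns come from bijective ring-centroid assignment; topology is
  read from the sign pattern of each column's 5'→3' projection on the core
  axis (4+0 parallel, 2+2 antiparallel, 3+1 hybrid).
* **Grooves** — per-layer phosphate–phosphate distances between adjacent
  columns, classified narrow < 12 Å ≤ medium < 19 Å ≤ wide.
* **Loops, ions, interfaces** — propeller/lateral/diagonal loop classes
  from anchor faces and corners; channel-ion assignment from O6
  coordination between adjacent layers; 5'-5' dimer stacking register
  (Form-1/1 vs Form-1/7) from axis-projected base overlap.
* **Torsions & pucker** — α…ζ, χ with syn/anti calls, and
  Altona–Sundaralingam pseudorotation: tan P = ((ν4+ν1)−(ν3+ν0)) /
  (2ν2(sin 36° + sin 72°)), 36° pucker bins (C3'-endo, …, C2'-endo, …).
* **Melting fits** — (y−min)/(max−min) normalization, then least-squares
  y(T) = bottom + (top−bottom)/(1+exp((Tm−T)/s)), single or two-component.
* **Masses** — average residue masses minus the 5'-OH linkage constant,
  times the oligomer copy number.

Details, conventions and numerical choices: [docs/methods.md](docs/methods.md).

## Worked example

Build a synthetic four-layer antiparallel quadruplex and annotate it:

```sh
g4kit build --topology antiparallel --layers 4 --out anti.pdb
g4kit analyze anti.pdb
```

Key fields of the resulting JSON report:

```
"topology": "antiparallel",
"tetrads": ["G1·G10·G13·G22", "G2·G9·G14·G21", "G3·G8·G15·G20", "G4·G7·G16·G19"],
"glycosidic_pattern": ["anti", "syn", "anti", "syn"],          (per tetrad)
"grooves":  wide 21.6 / narrow 8.7 / wide 21.6 / narrow 8.7 Å  (mean P–P)
"loops":    C5-C6 lateral, C11-C12 lateral, C17-C18 lateral
"channel_ions": 3 × K⁺, one per layer interval, 8 O6 contacts each
```

Read: a monomeric chair-type antiparallel G4 — four tetrads whose members
alternate syn·anti around each layer, three edgewise (lateral) CC loops,
two wide and two narrow grooves, and three channel potassiums each caged
by eight guanine O6 atoms.  The same command annotates deposited files
(`g4kit analyze deposited.cif`), with `--assembly-op` to expand a symmetry
mate first.

Melting and mass one-liners:

```sh
g4kit mass "GGGGCCGGGGCCGGGGCCGGGGCC" --copies 2
{"base_counts": {"C": 8, "G": 16}, "copies": 2, "mass_da": 15037.68, "mass_kda": 15.0}

g4kit melt curve.csv            # CSV: temperature_C, signal -> fit JSON
```

The 24-mer d(GGGGCC)₄ weighs 7.5 kDa per strand — 15.0 kDa for a dimer —
the numbers one compares against SEC-MALS masses to assign monomer vs
dimer in solution.

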