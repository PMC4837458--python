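# pprkit

Design and analysis of **designer pentatricopeptide repeat (dPPR) proteins** —
modular single-stranded-RNA binders for programmable RNA recognition.

Pentatricopeptide repeat (PPR) proteins are helical-hairpin solenoids, found
mostly in plant organelles, that bind ssRNA one nucleotide per 35-amino-acid
repeat. Which base a repeat reads is set by the amino-acid pair at
repeat-internal positions 5 and 35 — the *PPR code*: **ND → U, NS → C,
SN → A, TD → G**, with the degenerate codes **NN → U/C, TN → A, SD → G**.
Stringing code-programmed repeats between stabilizing N- and C-terminal caps
yields a protein that reads out an arbitrary RNA word, N-terminus to
C-terminus matching 5′ to 3′.

`pprkit` is for protein engineers and RNA biologists who want to

* **design** a dPPR construct for a given ssRNA target (`design`),
* **predict** the RNA target of an existing repeat array from its protein
  sequence, and scan transcripts for candidate sites (`scan`, `predict`),
* **measure** the structural quantities that characterize an RNA-bound dPPR:
  pruned Cα superposition RMSD (Kabsch), superhelix rise/twist/period/
  diameter/handedness, base-recognition hydrogen bonds including the
  U-vs-C-discriminating water bridges, Val2 base sandwiches and
  Lys13–phosphate salt bridges (`superpose`, `helix`, `hbonds`, `contacts`),
* **fit** equilibrium dissociation constants from EMSA-style titrations with
  the protein-excess isotherm *f* = [P] / (K_d + [P]) (`fitkd`, `simulate`).

The packaged 35-aa repeat template and terminal caps are *synthetic*
stand-ins with the correct architecture (code slots at 5/35, Val2 clamp,
Lys13, cap lengths matching the crystal-construct numbering); supply your
own scaffold YAML to design against a different template.

## Worked example

Design a ten-repeat protein against 5′-UUUUCCUUUU-3′ (a poly-U word with a
CC core):

```text
$ pprkit design --target UUUUCCUUUU
>dPPR_UUUUCCUUUU target_rna=UUUUCCUUUU
MGSVSNALEALVAERSRDLVRSGDLSGALEVFSEAVRSGVRLNAYSYNALILVTYNTLID
GLAKAGKLDEALELFEEMREKGIKPDLVTYNTLIDGLAKAGKLDEALELFEEMREKGIKP
...
```

The record is a 450-residue construct: a 51-aa N-terminal cap, ten 35-aa
repeats (one per nucleotide — repeats 1–4 carry code ND for U, repeats 5–6
NS for C, repeats 7–10 ND), and a 49-aa C-terminal cap. `--annot` writes a
TSV mapping each repeat to its code, target base and residue span;
`--offset 122` renumbers it to the crystal-construct convention (repeats at
residues 174–523).

The inverse direction recovers the target from the protein alone:

```python
from pprkit import design_dppr, scan_protein, predict_target

protein = design_dppr("UUUUCCUUUU").full_sequence
array = scan_protein(protein)[0]          # one tandem array, 10 repeats
ppm = predict_target(array, protein)      # per-repeat base probabilities
print(ppm.argmax_string())                # -> UUUUCCUUUU
```

Fit a K_d from a titration (here a simulated gel with 5% quantitation noise
on the standard 0–200 nM lane series; true K_d 25 nM):

```text
$ pprkit --seed 7 simulate --kd 25 --noise 0.05 --out curve.tsv
$ pprkit --seed 7 fitkd curve.tsv --bootstrap 500
{"kd_nM": 26.1249, "hill": 1.0, "rss": 0.010961, "ci95_nM": [21.908, 29.64]}
```

The fitted K_d of 26.1 nM (bootstrap 95% CI 21.9–29.6 nM) brackets the
simulated truth; `rss` is the residual sum of squares of the isotherm fit.

Structural geometry works on PDB/mmCIF files:

```bash
pprkit helix complex.pdb --anchor 174 --repeats 10   # rise/twist/period/handedness
pprkit superpose a.pdb b.pdb --prune-sigma 2 --cycles 5
pprkit hbonds complex.pdb --water-bridges
pprkit contacts complex.pdb
```

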