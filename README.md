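# qtybarrel

Design and characterization of water-soluble variants of beta-barrel
outer membrane proteins (OMPs) via the **QTY code** — the fixed
hydrophobic-to-hydrophilic substitution map

```
L → Q    (leucine → glutamine)
I → T    (isoleucine → threonine)
V → T    (valine → threonine)
F → Y    (phenylalanine → tyrosine)
```

applied to every L/I/V/F inside annotated transmembrane (TM)
beta-strands, and nowhere else.  Each pair shares a closely similar
side-chain shape, so the design swaps the lipid-facing hydrophobic
surface for a hydrogen-bonding one while barely perturbing geometry,
mass, or charge.

The package is for structural bioinformaticians studying OMPs (bacterial
outer membranes, mitochondria, chloroplasts) who want to generate QTY
variant sequences and quantify what the design changes:

- **TM and overall variation** — changed residues over TM residues
  (`tm_changed / tm_total`) and over the whole chain, printed in the
  conventional `27.22 (49/180)` style;
- **pI** — isoelectric point under the Bjellqvist per-group
  Henderson–Hasselbalch model (Expasy-style pKa set, bisection root);
- **MW** — average-isotopic molecular weight (Expasy residue masses +
  one water);
- **hydropathy** — Kyte–Doolittle sliding-window profiles and GRAVY,
  the sequence-level counterpart of a rendered hydrophobic surface;
- **structural agreement** — CA-only Kabsch superposition RMSD between
  a native structure and a predicted variant model, with per-region
  (strand vs loop) breakdown; strand ranges can be derived from PDB
  SHEET records;
- **synthetic barrels** — an idealized-cylinder barrel generator with
  exact ground truth (planted L/I/V/F counts, per-position facing,
  known coordinates) so the entire pipeline is testable offline.

Variant structure prediction itself is out of scope: predicted models
are inputs.

## Worked example

Generate a 16-stranded toy barrel, design its QTY variant, and
characterize both:

```bash
qtybarrel simulate --n-strands 16 --strand-len 10 --loop-len 6 \
    --phob 0.55 --seed 7 --out-prefix toy
# toy_barrel_n16s10_seed7: 256 residues, 38 planted L/I/V/F

qtybarrel design --fasta toy.fasta --topology toy.topology.tsv \
    --out-fasta toy_qty.fasta --out-subs subs.tsv
# toy_barrel_n16s10_seed7: 38 substitutions, TM 23.75 (38/160), overall 14.84%

qtybarrel report --fasta toy.fasta --topology toy.topology.tsv
```

which prints (tab-separated):

```
protein_id               variant_id                   pI_nat  pI_qty  MW_kDa_nat  MW_kDa_qty  TM_variation    overall_variation  RMSD_A
toy_barrel_n16s10_seed7  toy_barrel_n16s10_seed7_QTY  4.88    4.88    27.91       28.09       23.75 (38/160)  14.84
```

Reading the row: 38 of the 160 TM-strand residues were L/I/V/F and were
replaced (23.75% TM variation; 14.84% of the whole 256-residue chain).
The pI is untouched (4.88 → 4.88 — Q, T and Y carry no charge), the mass
rises only 0.18 kDa, and `qtybarrel physchem` shows the GRAVY dropping
from −1.316 to −2.121: the variant is markedly more hydrophilic at
essentially unchanged size and charge.  The `RMSD_A` column fills in
when native and model PDB files are supplied (`qtybarrel superpose`, or
`report --structures`).

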