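# Methods

## The QTY design model

The package treats QTY design as a deterministic sequence transform
governed by a topology annotation.  A topology is an ordered,
non-overlapping list of 1-based inclusive segments of kind `tm_strand`
or `other`; the union of `tm_strand` segments is the transmembrane (TM)
residue set.  Within that set, every leucine becomes glutamine, every
isoleucine and valine becomes threonine, and every phenylalanine becomes
tyrosine; nothing else changes.  Two modeling assumptions deserve
mention:

- **All TM-strand L/I/V/F are substituted, not only lipid-facing
  positions.**  In a real barrel roughly alternate strand positions face
  the lipid; restricting the code to those would require a
  residue-facing assignment the sequence alone does not carry.  The
  all-positions rule is simple, reproducible, and yields TM variation
  percentages in the low-to-mid 20s–30s for natural barrel strand
  annotations, consistent with characterized QTY barrel designs.
- **Loops and helices are never touched**, however hydrophobic.  The
  design target is the membrane-embedded surface only.

Because Q, T, Y are not themselves substrates of the map, the transform
is idempotent, and the residue multiset outside the TM set is conserved
exactly.  Both properties are enforced by tests.

Variation statistics follow the conventional table form: TM variation is
`tm_changed / tm_total` and overall variation `tm_changed / length`
(QTY changes nothing outside TM strands, so overall_changed equals
tm_changed).  Percentages are rounded half-up to two decimals; full
counts are always carried alongside so no precision is lost, and the
report stage re-derives each printed percentage from its printed counts
before writing (a self-audit against formatting drift).

## Isoelectric point and molecular weight

pI uses the Bjellqvist per-group model: the net charge at pH *p* is

```
Z(p) =  Σ_pos  n_i / (1 + 10^(p − pKa_i))  −  Σ_neg  n_j / (1 + 10^(pKa_j − p))
```

with positive groups {N-terminus, K 10.0, R 12.0, H 5.98} and negative
groups {C-terminus, D 4.05, E 4.45, C 9.0, Y 10.0}; terminal pKa values
are residue-specific where the Bjellqvist table provides them (N-term
default 7.5 with A 7.59, M 7.00, S 6.93, P 8.36, T 6.82, V 7.44, E 7.70;
C-term default 3.55 with D 4.55, E 4.75).  Cysteines are treated as
reduced.  The termini guarantee `Z(0) > 0 > Z(14)`, so bisection on
[0, 14] always converges; it is iterated 60 times (interval ~1e-17), far
past the 0.002 pH bracket that would already suffice for two-decimal
reporting, because for a large acidic protein the charge slope near the
root is steep enough that a 0.002-wide bracket can leave |Z| above 0.01.
The implementation is cross-checked in the tests against an exhaustive
1e-4-step pH grid search and against Biopython's independent
`IsoelectricPoint` (agreement to ~1e-4 pH).

MW is the sum of average-isotopic residue masses (the Expasy table,
embedded as constants) plus one water (18.01524 Da); kDa values are
rounded half-up to two decimals.  A useful exact identity falls out: the
MW change of a QTY design equals the sum of per-substitution residue
mass differences (L→Q +14.97, I→T −12.05, V→T +1.97, F→Y +16.00 Da),
which the tests verify to 1e-6 Da.  Consequences the model predicts and
the tests confirm: QTY leaves the pI of acidic proteins essentially
unchanged (tyrosine's pKa of 10 is far above such a pI) and weakly
lowers it for basic proteins (added tyrosines titrate below pH ~10),
while MW rises slightly unless the design is isoleucine-heavy.

## Hydropathy

Kyte–Doolittle sliding-window means (default window 9, an odd window on
the scale of a beta-strand) quantify surface hydrophobicity at sequence
level; GRAVY is the whole-chain mean.  Every QTY replacement strictly
lowers the per-residue score (Q −3.5 < L 3.8; T −0.7 < I 4.5 and V 4.2;
Y −1.3 < F 2.8), so the GRAVY delta (native − variant) is strictly
positive for any non-empty design.  This is an explicit proxy: it tracks
composition, not the 3-D clustering of hydrophobic patches, and no
solvent-accessible-surface computation is attempted.

## Structure comparison

CA atoms are read from PDB-format files (gemmi parser; ATOM records
only, first model, altloc blank or A, one CA per residue in file
order).  Strand ranges may be derived from SHEET records (one segment
per record, overlapping/adjacent ranges merged) — note SHEET annotates
*all* sheet structure, so for soluble-domain-containing proteins this
overestimates the membrane-spanning set.

Superposition is the closed-form Kabsch solution: SVD of the
cross-covariance of centered paired coordinates, with the determinant
correction that forbids reflections.  RMSD is reported over **all**
paired CA atoms with no outlier rejection.  Published superposition
numbers for QTY barrel models (0.2–0.4 Å) come from tools whose default
alignment runs outlier-rejection cycles and from predicted models that
are not deposited, so they are not bit-reproducible targets for an
all-pair RMSD; an optional single-pass trimmed mode (drop pairs > 2 Å,
re-fit once) is provided for rough comparability.  Region-wise RMSD
(strand vs loop) reuses the single global fit — no per-region re-fit —
so the global mean-square is exactly the pair-count-weighted mean of the
region mean-squares.  Pairing is by residue number (with insertion codes
ordered after their number) or by order; degenerate inputs (fewer than
3 pairs, collinear sets) are rejected.  Tests check Kabsch optimality
against a beam-searched rotation-grid oracle (1e-3 Å on 4-point
instances) and against scipy's `align_vectors`.

## Synthetic barrels

`make_toy_barrel` generates an n-stranded barrel: strands of length s
alternate with loops of length l, total length n·(s+l).  Within a
strand, even offsets are membrane-facing and odd offsets lumen-facing;
membrane-facing residues are L/I/V/F with probability
`hydrophobic_fraction` (else polar from {S,N,G,A,D,E,K,R}), lumen and
loop residues are always polar.  CA coordinates sit on a cylinder:
strand k at azimuth 2πk/n, radius d / (2 sin(π/n)) with d = 4.6 Å
inter-strand spacing, 3.3 Å axial rise per residue, antiparallel strands
alternating direction, loops as sinusoidal arcs over the rims.  One
`numpy` generator seeded from the spec drives all draws — no global RNG
state — so identical specs are bit-identical.

Defaults are chosen to emulate the characterized barrel study set:
n_strands = 16 (the BamA/Omp85 architecture), strand_len = 10,
loop_len = 6, and hydrophobic_fraction = 0.55, which under the parity
facing design gives an expected TM variation of 0.55/2 = 27.5%, the
midpoint of the 22–32% range observed across real OMP designs.  The
generator's ground truth (`planted_livf`, per-position facing) makes
parameter recovery exact: the engine's `tm_changed` must equal the
planted count, and fraction 1.0 must give exactly 50.00% TM variation.

What the toy data does **not** emulate: barrel shear (strands are
axis-parallel), hydrogen-bond registry, side chains, realistic loop
conformations, and sequence correlations beyond the facing pattern.
Passing tests therefore demonstrate correctness of the bookkeeping,
statistics, and numerics — not that the geometry or composition of any
real OMP is reproduced.  Real-protein agreement is exercised separately
by the reference-set tests, which require the public sequences and
structures (see README).

`perturb_structure` adds independent per-coordinate Gaussian noise with
separate strand/loop sigmas; for noise σ on every coordinate the
expected CA RMSD is ≈ σ√3, which the tests assert within ±20%.

## Pipeline sizes and determinism

The acceptance script runs a cohort of 5 barrels at the defaults
(256 residues each, 160 TM) — large enough for stable means, small
enough to run in seconds — and derives all randomness from a single
`--seed` via `numpy.random.SeedSequence`, so output is byte-reproducible
per seed.  The report stage isolates per-protein failures (remaining
proteins still run; the CLI exits non-zero if any failed) and renders a
deterministic TSV: identical inputs and configuration give identical
bytes.

## Known limitations

- Topology quality bounds design quality: SHEET-derived strands include
  soluble-domain sheets, and curated TM annotations differ between
  sources; published per-protein variation counts depend on the exact
  annotation used, which is rarely stated.
- pI/MW of published tables may refer to truncated constructs rather
  than full or mature chains; only comparisons on an explicitly stated
  construct are meaningful.
- The hydropathy proxy and the all-positions substitution rule are
  deliberate simplifications, documented above.
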