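# tgfcys

Conserved prodomain cysteines and disulfide-partner inference in the human
TGF-β family.

## The problem

The 33 human TGF-β family proteins (8 TGF-β, 8 Activin, 17 BMP subfamily
members) are synthesized as signal-sequence / prodomain / ligand precursors
and are regulated through two disulfide-dependent mechanisms: dimerization,
mediated by prodomain cysteines near the carboxy-terminal β8 helix, and
latency through covalent binding partners (LTBP, fibrillin, LRC32/GARP,
SELE), mediated by a cysteine in the amino-terminal Association (Assn)
region.  The cysteines responsible are experimentally known for only a few
proteins.  `tgfcys` is for sequence-analysis and signaling researchers who
want to (re)run the comparative pipeline that extends this picture: find
which family members carry conserved cysteines at these two locations,
intersect them with cysteine-affecting disease mutations, and turn shared
mutant phenotypes into concrete heterodimer and partner-binding hypotheses.

## The method

1. **Trimming with precursor numbering** — precursors are cut to prodomains
   (signal end + 1 … cleavage position) but every residue keeps its
   precursor coordinate (Met1 = 1), so reported positions match mutation
   databases.
2. **Consensus shading and conserved-cysteine detection** — for an
   alignment column with *n* rows (gaps count in the denominator), residue
   *r* with similarity group *G(r)* is shaded when
   freq(G(r)) ≥ *c* (default cutoff *c* = 0.2); it is an *identity* cell if
   it is the plurality residue of its group, otherwise *similar*.  A column
   is a conserved-cysteine column when count(C)/n ≥ *c* inside a region
   window.  Within each window the first conserved column is the anchor:
   a cysteine there is **Cys@1**, at anchor+2 columns **Cys@3**, at
   anchor+3 **Cys@4** (so TGFB2 carries β8Cys@1/3/4 at Cys254/256/257).
3. **Mutation catalog** — records (protein, position, ref, alt, phenotype)
   are classified as cysteine **loss** (C→X, stop, or in-frame deletion),
   **gain** (X→C) or other, and contextualized as conserved-prodomain,
   other-prodomain, ligand, or partner-domain sites.
4. **Common-mutant-phenotype inference** — mutations in two proteins with
   the same phenotype suggest a lost shared interaction.  Qualifying
   heterodimer evidence is a cysteine loss at a conserved prodomain
   position or in the ligand, or a curated gain near a conserved region;
   each phenotype yields one hypothesis per protein pair (a homotypic
   dimer when a sole-holder protein has evidence at ≥ 2 positions), minus
   the curated known-interaction set.  A conserved-position loss whose
   phenotype recurs among partner-protein cysteine losses yields a
   (family protein, partner) binding edge.
5. **Partner-domain comparison** — cysteine spacings |*p₂* − *p₁*| are
   compared against the LTBP1 TGFB1-binding pair (25 residues, tolerance
   5), and aligned TB/EGF domains are scanned column-wise for acidic (D/E)
   docking-site residues conserved in all rows, in the LTBP1 reference
   only, or in the non-reference rows only.

## Worked example

The packaged fixture encodes the documented human family coordinates in
synthetic scaffold sequences (see `docs/methods.md`).  Running the
inference stage:

```sh
$ tgfcys infer --fixture --out out/
novel heterodimers: 7 (within 4: {'Activin': 1, 'BMP': 1, 'TGF-beta': 2}; across 3)
novel partner edges: 17 over 8 partners
```

Seven previously undemonstrated heterodimer pairs emerge: within-subfamily
GDF5–GDF6 (colon adenocarcinoma), INHBB–INHBE (plasma cell tumors),
TGFB2–TGFB2 (Holt–Oram) and TGFB2–TGFB3 (Loeys–Dietz), plus three
across-subfamily pairs of TGFB2 with INHA, INHBA and INHBB.  The 17 partner
edges connect INHBE, GDF6 and TGFB2 to 8 distinct partners through shared
tumor phenotypes.  `out/hypotheses.json` lists every hypothesis with its
supporting mutations; `out/summary.yaml` holds the counts.  The other
stages are `tgfcys conserve` (conserved-cysteine table and BoxShade-style
shaded alignment), `tgfcys mutations`, `tgfcys domains` (spacing and
docking reports) and `tgfcys synth` (synthetic families with planted
truth).

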