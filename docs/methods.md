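# Methods

## Coordinates and trimming

All positions are 1-based precursor coordinates (Met1 = 1) with inclusive
spans.  Signal sequence and ligand are removed before any column statistics,
but the prodomain remembers its precursor offsets, so a conserved cysteine
reported at 33 is precursor residue 33.  This matches how mutation
databases and structural work cite positions, at the cost of carrying a
per-row start offset through every alignment operation.  Annotation tables
may leave the signal fields empty (no signal peptide); a present signal
span must start at residue 1 and end before the cleavage position, and the
cleavage position must leave a non-empty ligand.  'X' residues are
tolerated in sequences but belong to no similarity group and never shade.

## Conservation model

Shading follows the BoxShade consensus convention.  For a column with
*n* rows — gaps count in the denominator, so proteins absent from a region
dilute conservation — residue *r* is shaded when the summed frequency of
its biochemical similarity group reaches the cutoff; it is an identity cell
if it is the plurality residue of its group (ties broken by count, then
alphabetically), otherwise a similar cell.  Gaps are never shaded.  The
default cutoff is 0.2 for both shading and conserved-column detection; the
two are independently configurable because a permissive shading cutoff and
a detection threshold need not move together.  Threshold comparisons are
closed (≥): with 33 family rows plus the GDNF outgroup row (n = 34), a
column needs ⌈0.2·34⌉ = 7 cysteines to count as conserved.

Conserved-cysteine columns are sought only inside the two region windows
(Assn near the amino terminus, β8 near the cleavage site).  The windows are
configuration — inclusive alignment-column spans chosen against structural
anchors — because their boundaries come from visual/structural judgment
that this package does not attempt to automate.  Within a window the first
conserved column is the anchor; Cys@1/Cys@3/Cys@4 sit at anchor offsets
0/+2/+3 measured in alignment columns (not ungapped residues), so proteins
with local indels still receive comparable labels.  There is deliberately
no Cys@2: the nomenclature names the first, middle (third) and fourth
residues of a four-residue region.

The default similarity partition is {FYW} {ILVM} {RK} {DE} {ST} {NQ} {A}
{G} {P} {C} {H}.  Cysteine is its own group on purpose: a cysteine column
can only be supported by cysteines.

Census percentages are round-to-nearest of 100·count/33; GDNF is carried
as an outgroup alignment row (it contributes to column denominators) but is
excluded from every family count.

## Mutation catalog

Effect classification is purely syntactic: C→non-C is a cysteine loss —
including stops and in-frame deletions that start at the cysteine — and
non-C→C a gain.  Phenotype strings are normalized by lowercasing and
whitespace collapse only; merging beyond that happens exclusively through a
curated synonym map (e.g. "endometrial adenomas" → "endometrial
adenocarcinoma").  Fuzzy matching is deliberately absent: the source
databases distinguish, e.g., squamous-cell from adenocarcinoma lung
tumors, and silently merging phenotype strings would manufacture evidence.
Context resolution gives priority to an exact (protein, position) hit in
the conserved-cysteine table; remaining family positions split at the
cleavage site into other-prodomain versus ligand, and partner positions
resolve through the annotated domain spans or fall to UNMAPPED.  Unknown
proteins annotate as UNMAPPED rather than erroring, so a catalog can carry
records for proteins outside the configured rosters.

## Inference rules

Qualifying heterodimer evidence per (protein, phenotype): a cysteine loss
at a conserved prodomain position, a cysteine loss in the ligand (read as
corroboration that disulfide function, not a specific fold, is what the
phenotype reports), or a cysteine *gain* carrying a curated `near_region`
flag — structural proximity of a new cysteine to a conserved pair is a
judgment call, so it ships as data, not code.  Each phenotype yields one
hypothesis per unordered pair of distinct qualifying proteins.

The homotypic rule was the one genuinely open design point.  A protein with
same-phenotype qualifying evidence at two or more distinct positions could
always be read as a homodimer hypothesis, but when *other* proteins share
the phenotype, multi-site evidence in one protein is better read as
corroborating the cross-protein pairs (a prodomain+ligand pair in one
protein co-occurring with a second protein's mutation does not
independently argue for a homodimer).  The rule implemented is therefore:
emit a homotypic hypothesis only for a *sole holder* of a phenotype's
qualifying evidence with ≥ 2 distinct positions.  This is what closes the
within/across-subfamily arithmetic of the study this package reproduces;
the more permissive "always emit" reading over-counts within-subfamily
pairs.  Homotypic pairs count as within-subfamily.

Partner edges require a conserved-position cysteine loss on the family side
(anchor) and at least one cysteine loss on the partner side sharing the
normalized phenotype; the partner mutations need not fall inside annotated
domains.  Edges are deduplicated as unordered (family, partner) pairs for
headline counts — one biological interaction may be supported by several
phenotypes.  Novelty is membership against a curated known-interaction set
(TGFB1 homodimer, INHA–INHBB, and TGFB1 with LTBP1/3/4 and LRC32/33);
TGFB2–TGFB3 is deliberately not in the set because the β8-based route to
that dimer is counted as a new finding.  Non-novel hypotheses are still
emitted for validation; headline counts tally novel ones.  Output order is
lexicographic by (phenotype, members) so reruns are byte-identical.

## Partner domains

Cysteine spacing is |p₂ − p₁| of precursor positions; this convention
reproduces the documented 25 (LTBP1 Cys1359/1384), 35 (LTBP1 Cys559/594)
and 139 (LRC32 Cys211/350).  The spacing tolerance defaults to 5 so that
spacings of 27–28 residues classify as similar to the 25-residue reference
while 35 and 139 do not.  Docking-site comparison classifies each column of
a TB/EGF domain alignment by where acidic (D/E) residues sit relative to
the LTBP1 reference row: conserved in all rows, reference-only, or
non-reference-only; gap cells are never acidic, and the reference
insertion (the two-residue FP insertion between TB cysteines 6 and 7,
opposite gaps in the fibrillins) is reported descriptively rather than
scored.  Canonical domain cysteine counts (8 for TB, 6 for EGF) are
checked as warnings, not errors, because transcribed spans may be partial.

## The packaged fixture

The fixture transcribes documented facts — conserved-cysteine positions
and labels, the mutation catalog with phenotypes, partner domain
architecture and reference cysteine pairs — into tables, and embeds them
in *synthetic* scaffold sequences (deterministic non-cysteine filler with
cysteines and mutation reference residues planted at the documented
positions; filenames carry `.synthetic.`).  Real precursor sequences are
not redistributed.  Where only census totals, not per-protein identities,
are documented (which subfamily members carry which β8 label; the unnamed
partner mutations behind per-partner counts), membership was chosen once
to satisfy every stated total simultaneously — 21 proteins with β8
cysteines (13 BMP / 4 Activin / 4 TGF-β), 16 with Assn cysteines
(5 / 6 / 5), 24 distinct overall, AssnCys@4 confined to the four INHBs
plus MSTN and GDF11 — and those rows are marked `table-transcription` in
the provenance column, versus `results-text` for rows with verbatim
documented coordinates.  These totals force each subfamily's β8 set to be
a subset of its Assn-or-β8 union in a specific way; one consequence is
that INHA carries no conserved-cysteine row in the fixture and enters the
endometrial inference through its ligand mutation, which leaves every
downstream count unchanged.  A `MANIFEST.sha256` protects the fixture
files; loading verifies checksums and fails on any mismatch.

The fixture alignment uses a fixed geometry (Assn block at columns 70–73,
β8 block at 305–308, width 370) with each row right-aligned against the
Assn anchor and padded with gaps elsewhere.  This is a layout device, not
a claim about the true alignment; all column statistics and coordinate
mapping behave exactly as they would on a computed alignment.

## Synthetic data

The generator emulates the *detection problem*, not protein evolution:
sequences are uniform over the 19 non-cysteine residues (no substitution
model, no phylogenetic correlation), planted cysteine columns sit at
labeled offsets inside the region windows, planted interaction pairs get
qualifying cysteine losses sharing a unique phenotype, and noise mutations
get singleton phenotypes that can never form a pair.  Passing tests
therefore show that the pipeline recovers planted signal exactly and is
robust to phenotype noise by construction — they do not show robustness to
misalignment, compositional bias, or phenotype-vocabulary drift in real
databases.  Gap-free generation is the default; an indel mode plants gap
blocks away from the conserved columns to exercise coordinate mapping.
The generator validates that every planted column clears the detection
threshold, so ground truth is derivable from the configuration without
running the pipeline; a single seed fixes all randomness and equal seeds
give byte-identical files.

## Problem sizes and determinism

The shipped analyses are desk-scale: a 34 × 370 alignment, a 63-record
catalog, ten partners.  The test suite's property checks (brute-force
oracle equivalence, threshold monotonicity, coordinate round-trips,
20-seed planted-truth recovery) run on families of ≤ 20 proteins and
complete in seconds.  Every pipeline stage is deterministic; the only
randomness anywhere is the synthetic generator's seed.

## Known limitations

No statistical model of phenotype co-occurrence is attempted (none exists
in the reproduced analysis): a shared phenotype string is treated as
categorical evidence.  Expression-based filtering of hypotheses is out of
scope.  Multiple alignments are consumed, never computed; region windows
are user configuration; signal peptides and cleavage sites are annotations,
not predictions.  Phenotype reconciliation across source databases lives
entirely in the synonym map and inherits its curation quality.
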