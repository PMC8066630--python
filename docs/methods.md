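# Methods

## The procedure

`coiauth` implements a DNA-barcoding authentication pipeline for seafood
products, built around the standard ~650 nt COI (cytochrome oxidase I)
amplicon, and applies it to a packaged 60-product Italian sushi survey
(19 Northern, 20 Central, 21 Southern products; up to three replicate DNA
extractions per product, 163 sequences in total).

The pipeline has four stages:

1. **Amplicon QC with NUMT screening** (`seq_qc`). Reads are primer-trimmed,
   then translated in all six frame/strand combinations under the vertebrate
   mitochondrial genetic code (NCBI table 2: AGA/AGG are stops, ATA is Met,
   TGA is Trp). A genuine mitochondrial COI fragment is protein-coding and
   stop-free in one frame; nuclear mitochondrial pseudogenes (NUMTs) betray
   themselves through premature stops, frameshifts, or short length —
   vertebrate NUMTs are generally under 600 bp, which is used as a hard size
   floor. The frame with the fewest internal stops is selected, with a
   deterministic tie-break (forward strand before reverse, frame 0 before 1
   before 2). A read is NUMT-flagged iff the best frame still contains a
   stop, or the read is shorter than 600 nt.

2. **Species assignment** (`species_assignment`). Each QC-passed read is
   aligned end-to-end (optimal global alignment, dynamic programming) against
   every record of a curated, taxonomy-annotated reference panel — a local,
   reproducible replacement for a live BLAST/BOLD search. Percent identity is
   100 × matches / alignment columns, counting gap columns in the
   denominator; coverage is 100% by construction for global alignment. The
   top-identity hit(s) decide the call: if all hits tied at the top identity
   (at 2-decimal reporting precision) belong to one species, the read is
   assigned; a cross-species tie yields an explicit `ambiguous` status; no
   hit at the identity threshold yields `unassigned`. Replicates of one
   product are combined by unanimity: agreement assigns the product,
   disagreement flags `multi_species`, and ambiguous replicates are recorded
   but cannot overrule a unanimous species.

3. **Trade-name compliance** (`name_compliance`). A regulatory rule table
   maps each normalized trade name to the taxa it lawfully declares, each at
   an explicit rank (species, genus or family). A product is **misdescribed**
   when the identified species matches *none* of: the scientific names
   explicitly declared on the menu, and the taxa the menu name resolves to
   under the rule list. Matching one constraint suffices for compliance.
   Umbrella names are evaluated at genus rank — "tobiko" covers the
   flying-fish genera *Hirundichthys* and *Cheilopogon*, "ikura" covers
   *Oncorhynchus* — so a congeneric flying fish sold as tobiko is compliant
   while capelin (*Mallotus villosus*) roe is not. Products whose barcode
   call is not an assigned binomial get an `unresolved` verdict and are
   excluded from all rate denominators (mirroring the survey's 17 failed
   extractions).

4. **Stratified reporting** (`survey_report`). Misdescription rates are
   per product (one table row = one product), computed for every
   region × retail-type × category stratum including `"all"` wildcards, so
   wildcard counts equal the sum of their refinements by construction.
   Display rounding is half-up to the nearest integer percent; raw rates are
   always retained alongside.

## Parameters that matter

| Parameter | Default | Why |
|---|---|---|
| `min_length_nt` | 600 nt | NUMT size heuristic (hard fail below) |
| `max_length_nt` | 700 nt | amplicon plausibility ceiling |
| `expected_window` | 636–655 nt | observed clean-amplicon range; outside it passes with a warning — the observation is separated from the filter |
| `max_n_fraction` | 1% | Sanger ambiguity tolerance; N codons translate to X and never count as stops |
| `genetic_code_id` | 2 | COI is mitochondrial; the stop-codon check presumes the vertebrate mito code |
| `min_identity_pct` | 97.0 | acceptance threshold for a hit; the survey's observed identities (98.17–99.85%) sit comfortably above it |
| `tie_tolerance` | 0.00 | ties are *identical* 2-decimal identities, per the top-hit tie rule |
| alignment scores | +1/−1/−2 (linear) | unstated in the source workflow; near-identical sequences are insensitive to the choice, which the suite verifies against an enumeration oracle under a second scheme |
| primers | unset | the survey's primer pair is not part of the packaged data; trimming is skipped when unset |

Percent identities are reported rounded half-up to 2 decimals, matching the
survey tables' precision. N counts as neither match nor mismatch but occupies
an alignment column (conservative identity under ambiguity). Coordinates are
0-based half-open; `frame_offset` counts skipped leading bases.

An edit-distance prefilter (edlib) may skip references that provably cannot
reach the identity threshold — for any alignment, mismatch+gap columns are at
least the Levenshtein distance, so identity ≤ 100·(|q|+|r|−d)/(|q|+|r|) — but
correctness is defined by the full global alignment, and the suite checks the
filtered and unfiltered paths agree.

## The synthetic-data generator

`synthetic_data` generates study conditions matching the packaged survey's
regime: 651 nt amplicons (a whole number of codons, ~650 as in the survey),
reference species diverged by ≥ 10% (verified pairwise after generation),
queries mutated to a controlled identity (default 98.5%, inside the observed
98.17–99.85% band), up to three replicates per product, and a known
mislabeling fraction. Mutations are substitution-only — accepted survey
sequences showed no indels — with the replacement base uniform over the
admissible alternatives and, under `preserve_frame`, never creating an
in-frame stop (every codon position admits a non-stop alternative under the
mito code). NUMT decoys carry the defects instead: `stop_insert` places stop
codons in all six frames via a 22-mer with TAA in every phase of both
strands, `frameshift` deletes one base, and `truncate` drops the read below
the 600 nt floor; every decoy is verified to fail the screen before it is
returned.

What the generator does **not** emulate: phylogenetically realistic sequence
evolution (no transition/transversion bias, no rate heterogeneity),
chromatogram quality, PCR/sequencing error, heteroplasmy, or co-amplified
mixtures. Passing recovery tests therefore demonstrates the pipeline's
correctness under idealized substitution noise, not robustness to real Sanger
artifacts.

Rate-recovery checks run at 200 products × 1 replicate over 20 seeds (the
sizes keep the whole suite fast while leaving the binomial noise of the
generator visible), and measure the recovered rate against each seed's
*realized* ground-truth rate: at n = 200 even a perfect pipeline differs from
the nominal 25% parameter by ≈ 2.4 points in expectation from binomial
sampling alone, so recovery is properly a fidelity measure, not a sampling
measure.

## Reproducing the packaged survey

Feeding the fixtures' declared and identified species columns through the
compliance engine reproduces the recorded misdescription marking for all 60
products and the survey's per-product rates exactly: Central overall 40%
(8/20), Northern tuna 67% (4/6), Central and Southern tuna 100% (6/6, 4/4),
tuna overall 87.5% (14/16, with exactly 2 compliant red-tuna products),
Northern white fish 11% (1/9), Northern roe 33% (1/3), Northern takeaway 25%
(2/8), Central restaurant 50% (5/10); 16 identified species, 16 roe products,
identity range 98.17–99.85, 163 processed sequences.

One fixture subtlety is load-bearing: the Northern product DAL1E declares
*Hirundichthys affinis* but the identified *H. oxycephalus* is **not** marked
misdescribed — only the genus-rank tobiko rule explains the recorded verdict.
The engine therefore always evaluates the union of the declared-name column
and the label resolution, never the column alone.

## Printed figures that do not reconcile per-product

The following survey figures cannot be reproduced under per-product counting
of the packaged tables; they are surfaced here, left out of the reproduction
targets, and the per-product recomputation is given instead:

- **Northern overall 31.8%**: the Northern table yields 6/19 = 31.6%.
  (6/19 would print as 31.8 only under 6.04/19 or 7/22; no per-product
  reading of the table produces it.)
- **Southern takeaway 50%**: the Southern table has 6 takeaway products of
  which 2 are misdescribed → 33.3%. The printed figure reconciles only
  partially under per-venue counting (2 of 4 Southern takeaway venues had a
  misdescribed product).
- **Southern restaurant 33.3%**: per-product the Southern restaurants show
  6/15 = 40.0%; per-venue counting gives 4 affected venues of 6 ≈ 66.7%;
  neither yields 33.3%.
- **Central roe 20%**: the Central table has 6 roe products, 1 misdescribed
  → 16.7% (1/5 = 20% would require dropping one compliant roe product).
- **"61 sushi samples … 45 fish samples"**: the three tables list 60
  products, of which 44 are fish (non-roe) — a one-sample discrepancy in
  both counts.
- **"17 species should have been detected, but we found a total of 29"**:
  neither count is reconstructible from the tables; the tables support 16
  distinct identified species, which is the figure the pipeline reproduces.

## Known limitations

- The packaged rule list covers the trade names occurring in the survey plus
  a documented extension format; it is not a full transcription of the
  Italian decree's species list.
- The fixture tables footnote some declared names as "not present in the
  Italian D.M. 2008" while the survey text cites the 2017 decree; the
  footnote is carried verbatim (`declared_unlisted`) and the discrepancy is
  surfaced, not resolved.
- Economic direction of a substitution (up- vs down-grading) is reported as
  free-text rationale only; no computation is defined for it.
- End-trimming beyond primer removal (quality-based clipping) is left to the
  caller; the QC stage assumes base-called, assembled sequences.
- Global alignment assumes near-full-length queries; heavily clipped
  fragments would be penalized end-to-end and should be handled upstream.
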