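# Methods

`haloriscan` predicts *orc/cdc6*-associated replication origins in
multi-replicon haloarchaeal genomes and classifies their evolutionary
relationships.  This note documents the models, the decision rules, the
synthetic benchmark that every stage is tested against, and the numerical
and design choices a maintainer would want to know about.

## The prediction model

Haloarchaeal genomes (typically 60–65% GC, one chromosome plus
minichromosomes and megaplasmids, all circular) initiate replication at
origins bound by Orc/Cdc6 initiator proteins.  A canonical origin of this
class consists of:

* an *orc/cdc6* gene directly adjacent to the origin;
* ORB elements (origin recognition boxes) of ~20–40 bp in the intergenic
  region (IR) flanking that gene, usually as an inverted pair;
* a terminal **G-string** — a run of G residues at the end of each ORB —
  which is specific to halophilic archaea;
* an AT-rich duplex-unwinding stretch between the paired ORBs, conspicuous
  against the high-GC background.

The pipeline operationalizes this definition in five stages.

### 1. Initiator screen (`cdc6_screen`)

Every CDS product is aligned to a panel of seed initiator sequences by
Smith–Waterman local alignment (BLOSUM62, affine gaps 11/1, via
Biopython's `PairwiseAligner`).  A protein is an initiator hit when its
best seed alignment reaches **30% identity over ≥150 aligned columns**
(both configurable); it *passes* the screen when it additionally exceeds
**300 aa** and carries a Walker-A box (`[AG]-x(4)-G-K-[ST]`) in its
N-terminal 60% — the sequence signature of the AAA+ ATPase domain.  A
winged-helix composition score over the C-terminal third (basic-residue
enrichment plus α-helical hydropathy periodicity) is reported for review
but never gates, because winged-helix evidence in this family rests on
homology rather than a sharp sequence motif.  Identity/coverage floors
replace E-value cutoffs deliberately: E-values depend on database size
and calibration constants, whereas identity over a minimum span is
reproducible and self-contained.

An optional iterative profile rescreen recovers divergent family members:
a position-specific log-odds profile (background-pseudocount weight 5) is
built from the passing hits mapped onto the longest member, slid
*ungapped* over every remaining CDS, and members above 0 bits/column mean
log-odds over ≥150 columns join the hit list.  The ungapped slide is
adequate under substitution-dominated divergence; proteins whose
divergence from the family is indel-rich may be missed — a known
limitation.

The packaged seed panel (`data/synthetic_orc_cdc6_seeds.faa`) is a
deterministic synthetic stand-in: eight 420-aa Walker-A-bearing proteins.
For real genomes a user should substitute experimentally supported
initiator sequences via `seeds_path`.

### 2. IR extraction and ORB motif discovery (`orb_discovery`)

For each passing initiator the two flanking IRs (to the nearest annotated
gene boundary, capped at 5 kb, wrapping across the coordinate origin of
circular replicons) are collected.  Because ORBs sit directly adjacent to
the gene, the pipeline trims each IR to its gene-proximal 800 bp
(`motif_ir_trim`) for motif work; this bounds EM cost and the exposure to
spurious scan hits in long IRs.

The ORB motif is learned per genome with a ZOOPS ("zero or one
occurrence per sequence") EM mixture model over both strands:

* Each IR either lacks an occurrence (probability 1−γ) or contains
  exactly one at a uniformly chosen position/strand (γ/mᵢ per placement).
* E-step: placement responsibilities from the PWM/background likelihood
  ratio; M-step: PWM from responsibility-weighted window counts
  (pseudocount 0.25·background per column) and γ from the expected number
  of motif-bearing IRs.
* The log likelihood is expressed relative to the all-background model,
  so the converged value is the motif's likelihood-ratio score; EM stops
  at Δ < 1e-6 (max 200 iterations).
* The background is the 0-order composition of the IR set (per replicon
  would be equivalent at these lengths); widths are searched over
  {20, 25, 30, 35, 40}.

Three practical devices make the search reliable at this scale:

* **Seed triage.**  Candidate seed windows (half drawn from windows with
  a terminal G-run, half uniform) are ranked by how many sequences
  contain a ≥75%-identical window; only the most enriched seeds are run
  to convergence (`n_restarts` of them, default 20).
* **Register refinement.**  The converged register is a local optimum
  and often sits a few columns off; the ranking winner is hill-climbed
  over ±3-column shifts until the likelihood stops improving.
* **Width ranking by BIC-penalized likelihood ratio**
  (LLR − 1.5·width·ln(expected sites)), which stops wider windows from
  absorbing uninformative flanking columns.

Within the pipeline, models whose consensus carries a terminal G-run
outrank those that do not (`g_string_rank`).  This mirrors the method's
own definition — only G-string-bearing repeats count as candidate ORBs —
and serves two purposes: it stops the learner from locking onto the
AT-rich unwinding element (itself a strongly conserved positional signal
in origin IRs), and it pins the model to the G-form strand so scanned
elements carry the G-string rather than its complement.  The generic
`discover_motifs` default applies no such preference; a two-strand
mixture model is identifiable only up to reverse complement, and tests
treat the two strand forms as equivalent.

IRs are then scanned with the learned PWM on both strands; positions with
log-odds ≥ `min_bits` (default 8 bits) become ORB elements, resolved
greedily non-overlapping (highest score, ties leftmost/forward).  Each
element is checked for a G-string: a G-run of ≥5 ending within 10 bp of
either element end (both ends accepted because the literature does not
fix one).  Forward/reverse element pairs with an inner gap ≤400 bp are
matched greedily by combined score into inverted pairs.  AT-rich segments
require a 50-bp window reaching background-AT + 0.25 and are tightened by
a maximum-sum (Kadane) refinement; the 0.25 margin (≈3.6σ above a random
62%-GC window, versus ≈2.2σ at 0.15) keeps plain background from
qualifying.  AT evidence is reported with each call but never gates it.

A **second motif family** is searched for dual origins: round-one
occurrences are masked (replaced by background-sampled bases), the masked
IRs of *all* genomes are pooled and cut into overlapping 260-bp chunks
(so an inverted pair inside one IR counts as two sequences for ZOOPS),
and the EM is rerun.  The second model is accepted only if it expects ≥2
sites and its consensus differs from every genome's first model by more
than width/4; its scan hits are admitted for a gene only where they
independently form a candidate-grade arrangement, so stray second-family
singletons cannot perturb primary calls.

### 3. Origin calls (`origin_call`)

Per gene, qualifying (G-string-bearing) ORBs are evaluated in the order
dual → candidate → deficient → none:

* **candidate** — ≥2 qualifying ORBs as an inverted pair within one IR,
  or across both IRs with more than one element on some side;
* **deficient** — qualifying ORBs present but never reaching that
  arrangement; the canonical case is exactly one lone ORB in each
  flanking IR, which the literature treats as a deficient origin rather
  than a functional one (for this reason the candidate "both IRs" branch
  explicitly excludes the one-per-side-no-pair pattern);
* **dual** — two ORB sets from distinct motif families (consensus
  Hamming distance > width/4 at the best ungapped offset), each
  independently satisfying the candidate rule;
* **none** — no qualifying ORB.

The origin interval is the minimal span covering the qualifying ORBs and
the AT-rich segment; layout (upstream/downstream/both) is relative to the
gene's coding orientation.  Per-replicon summaries report the initiator
count, the origin-associated count (status candidate or dual), and their
integer-rounded percentage; origins are named oriC1…oriCn per
chromosomal replicon and oriP1…n per plasmid-class replicon, with a `*`
marking deficient loci.

### 4. Families and evolution (`family_evo`)

Origin-associated initiators are clustered into families by
single-linkage connected components of the ≥80% pairwise-identity graph
(local alignment; alignments shorter than 100 columns count as 0% so a
short high-identity segment cannot chain unrelated proteins; a warning is
logged when chaining drags a family's minimum pairwise identity below
the threshold).  Naming follows the field's convention: the family
present in every genome is **oriC1** (ancestral), the next two largest
are **oriCa**/**oriCb** (ties broken by lexicographically smallest member
id), the rest F3, F4, …  A linkage-consistency score (mean pairwise ORB
consensus similarity, strand- and offset-tolerant) quantifies the
expectation that same-family initiators bind similar ORBs.

An origin is flagged **later-acquired** when a gene annotated as
transposase/integrase/insertion-sequence lies within 10 kb (configurable,
and reported with every flag; "nearby" has no established value) of the
origin interval, distance measured on the circle.

Trees are neighbour-joining (scikit-bio's Saitou–Nei implementation) over
Poisson-corrected distances −ln(1−p), with p the proportion of differing
residues over ungapped columns of a pairwise global alignment; negative
NJ branch lengths are clamped to zero with a note.  A column-resampling
bootstrap over bipartitions is available (`bootstrap_nj`).  NJ with
distance bootstrap stands in for likelihood phylogenetics deliberately:
the package's claims rest on topology-level family structure only.

### 5. Pipeline (`pipeline`)

`RunConfig` centralizes every threshold; a run derives one RNG seed per
stage from `motif_seed` and fixed labels, so results are bitwise
reproducible for a fixed config and stage-level reproducibility survives
pipeline edits.  The manifest records the config hash and the per-stage
funnel (CDS → passing initiators → origin-associated), which is monotone
by construction.  Outputs: BED + GFF3 of origins and ORBs, per-replicon
TSV summary, per-genome later-acquired TSV, family table, newick tree,
manifest JSON.

## The synthetic benchmark (`synthetic_data`)

Because the real validation data are annotated genome assemblies plus
wet-lab replication assays, the test bed is a generator that plants every
structure the pipeline is supposed to find, with full ground truth:

* 5 genomes × (500 kb chromosome + 300 kb minichromosome + 200 kb
  megaplasmid), circular, 62% GC background; initiator counts 4/2/1 per
  replicon.
* A master ORB consensus (the shared element
  `TAACAGCGGAAACAGTGGGGTGGGGGGGT`, terminal run of 7 Gs); each planted
  family and each singleton origin uses the master mutated at 12% per
  base outside the protected G-run, and each planted element is the
  family consensus mutated at 5%.  The G-run and the initiator Walker-A
  box are never mutated — these are the functionally constrained
  positions whose conservation defines the signals being detected.
* One universal initiator family ("U") in every genome plus two partial
  families, members diverged 5% from the family ancestor (≈90% pairwise
  identity); singleton initiators are seed-panel proteins mutated to
  40–90% identity.
* Planted statuses per gene: dual 10%, deficient 15% (one lone forward
  ORB per flanking IR), none 25% (no ORBs, occasionally a shuffled-ORB
  decoy IR), candidate the remainder — so ~60% of initiators are
  origin-associated, matching the field's reported proportion of roughly
  two-thirds.  Dual genes carry a second, unrelated consensus (also
  G-string-terminal).
* 40% of planted origins receive a transposase/integrase gene adjacent to
  the origin block (mirroring the reported 42/102); other decoy genes are
  annotated hypothetical.
* Replicons are assembled by sequential block construction
  (spacer–IR–gene–IR–decoy), which cannot create overlaps; spacers are
  sized so blocks are ≥10 kb apart, keeping mobility flags unambiguous.
  Replicon lengths are therefore met to within a few hundred bp rather
  than exactly.
* Planted proteins are reverse-translated with codon choice weighted by
  the background base composition, so CDSs do not form detectable GC
  islands.

What the generator does **not** emulate: real intergenic sequence
structure (promoters, terminators, repeat families), transcription-unit
architecture, indel divergence within initiator families, annotation
errors, assembly gaps, or origins not adjacent to *orc/cdc6* genes.
Passing the synthetic benchmark therefore demonstrates that the
implementation is faithful to the stated origin model at realistic
divergence and composition — not that the model captures every real
origin; on real assemblies, counts shift with annotation vintage.

## Problem sizes used in tests

The test suite runs the full pipeline on 20 seeded replicates of the
default 5-genome cohort (~1 Mb per genome) with 4 EM restarts per width,
motif recovery on 50 seeded 20-IR replicates at width 30 with 6
restarts, and family naming on 20 seeded 15-genome cohorts with one
40-kb replicon each.  These sizes were chosen so the whole suite
completes on a single CPU in well under half an hour while every
stochastic assertion still pools hundreds of planted events;
`scripts/acceptance.py` re-runs the pipeline on one full default cohort.

## Known limitations

* Deterministic identity/coverage thresholds are not E-values; extremely
  divergent initiators below 30%/150 columns are found only via the
  profile rescreen, which is ungapped.
* ZOOPS assumes at most one occurrence per sequence; multiple same-family
  pairs within one IR rely on the PWM scan (which has no such cap), and
  the second-family search relies on IR chunking.
* Greedy inverted-pair matching is not globally optimal on pathological
  element layouts; on planted well-separated layouts it equals the
  exhaustive assignment optimum, which the tests verify.
* Single-linkage clustering can chain families through intermediate
  members; the code logs this, as the choice follows the pairwise
  ≥80%-identity grouping rule rather than complete linkage.
* Dual origins occurring once per cohort give the second-motif EM only
  two instances in one IR; detection of such singleton duals is
  best-effort and they are otherwise called candidate.
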