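# Methods

This note documents the models and procedures inside `acmghl`, the
parameters that matter, the synthetic data the tests run on, and the
design decisions taken where the underlying guidelines leave room.

## Scope and evaluation unit

The engine evaluates 12 ACMG/AMP criteria — seven pathogenic (PVS1, PS1,
PM1, PM2, PM4, PM5, PP3) and five benign (BA1, BS1, BP3, BP4, BP7) — the
subset that requires no per-patient data (no segregation, phenotype match,
functional assays or case/control counts).  Criteria are evaluated per
(variant, transcript).  For the variant-level report, each criterion takes
its most decisive transcript outcome: triggered beats not-triggered beats
not-applicable, and among triggered outcomes the highest strength wins;
comments name the deciding transcript.  The reporting transcript (first
phenotype-relevant, then lexicographic id) supplies the gene for the
population criteria.  Note this is a per-criterion merge, not a single
most-pathogenic-transcript pick; with one transcript per gene — the common
case and the fixture layout — the two coincide.

Coordinates are 0-based half-open internally; VCF input is converted at
the boundary.  Multi-allelic records are split and indels are
left-normalised (parsimony + left alignment) before evaluation.

## Refined PVS1

For stop-gain, frameshift, stop-loss, in-frame, splice-site and
start-loss consequences:

1. **Observed CDS.**  The variant is applied to the reference coding
   sequence, kept partitioned per exon.  Canonical splice-site disruption
   (±2 intronic bases) is modelled as skipping the adjacent exon — the
   exon 5' of the intron for donors, 3' for acceptors; a config switch
   (`splice_model: retain`) models intron retention instead.  Exon
   skipping is the conventional single-event disruption model; real
   splicing outcomes vary, which is a stated limitation.
2. **PTC.**  The 5'-closest in-frame stop of the observed sequence is
   located.  It is *premature* only if it is not the final complete
   codon; in-frame deletions/duplications therefore produce no PTC and
   fall through to PM4, which by construction makes PVS1 and PM4 mutually
   exclusive.
3. **NMD.**  The transcript escapes NMD if the PTC lies (i) within the
   last 50 bases of the penultimate exon, (ii) at most 200 bases
   downstream of the start codon, or (iii) in an intronless transcript —
   checked in that order; otherwise NMD is predicted.  The common "PTC in
   the last exon" escape clause is deliberately not part of the default
   rule; `nmd_last_exon_escape: true` adds it.  Window sizes are the
   literature-standard 50 nt / 200 nt values.
4. **Grading.**  NMD destroying a phenotype-relevant transcript is very
   strong evidence.  An NMD-escaping truncation is graded by the region it
   removes: inside a protein domain, strong if the domain is marked
   critical, else moderate; outside domains, membership of a clinically
   significant exon of a phenotype-relevant transcript is required, and
   the strength is strong when the truncation removes strictly more than
   10% of the reference protein, else moderate.  Branches not fixed by
   the guideline text follow the published PVS1-refinement flowchart and
   are unit-tested branch by branch.
5. **Start loss.**  If another transcript of the gene starts elsewhere,
   the criterion is withheld (the alternative start may rescue
   translation; the guidelines do not specify this case).  Otherwise the
   nearest in-frame ATG within 200 bases downstream is the rescue start:
   a pathogenic curated entry (≥ 1 review star) between the two starts
   yields PVS1 moderate, else supporting.  No rescue ATG at all is
   floored at supporting.

## PS1 / PM5 and PM1

The affected codon's two or three genomic positions are computed
strand-aware; codons split across exon junctions contribute positions in
both exons, all of which are searched.  Curated missense records at those
positions are filtered to the gene's strand and to a review-star floor
(default 1, user-overridable).  PS1 fires on an identical resulting
residue; PM5 on a different residue, at strong strength when at least two
*distinct alternate residues* are curated pathogenic (residue-level
counting avoids double-counting protein-equivalent genomic variants; a
config flag switches to genomic-variant counting).  "Pathogenic" means
exactly that significance; `ps1_include_likely` widens it.  PM1 is a pure
interval test against critical regions that contain no benign curated
entry; the fixture generator derives that track by subtraction, and the
engine never re-derives it.

## PM4 / BP3

Both operate on the variant-affected coding region (the reference span
intersected with the CDS, or the skipped exon for splice variants) —
one shared definition with PVS1.  PM4 requires PVS1 silent at every
strength, no repeat-track overlap, and a protein-length change strictly
above 10%.  Observed protein length runs to the first in-frame stop;
stop-loss extends translation into the 3' UTR to the next in-frame stop
(to the transcript end, with a warning, if none exists).  BP3 applies to
in-frame and stop-gain variants whose affected region overlaps a repeat
region that intersects no protein domain.  Applying BP3 to stop-gain
variants is unusual for an in-frame criterion but is implemented as the
hearing-loss specification describes it.

## PP3 / BP4 / BP7

Scores are supplied per variant (the engine never runs predictors):
missense pathogenicity (REVEL-, CADD-style), conservation (phyloP-style)
and splicing (dbscSNV-style probabilities, MaxEntScan-style ref/alt
scores).  Missense: PP3 needs (REVEL **or** CADD above the pathogenic
cutoff) **and** conservation at/above the conserved cutoff; BP4 needs low
REVEL (CADD low or absent), conservation below the non-conserved cutoff,
and an explicit no-splice-effect prediction.  Variants without amino-acid
impact (synonymous, intronic, other — canonical splice sites excluded
entirely): predicted splice effect + high conservation → PP3; no effect +
low conservation → BP7 for synonymous, BP4 otherwise.  A splice effect is
called when any probability reaches its cutoff or the splice score
changes by at least the relative delta; "no effect" requires every
available splice score to stay below cutoff; with no splice score there
is no prediction, which blocks the benign criteria (absence of evidence
is not evidence of absence) but not PP3's missense arm.  Missing required
scores leave a criterion not-triggered with an "insufficient scores"
comment.

Default cutoffs (all overridable in the config): REVEL ≥ 0.7 pathogenic /
≤ 0.15 benign, CADD ≥ 20 / ≤ 10, phyloP ≥ 1.5 conserved / < 0.1
non-conserved, splice probability ≥ 0.6, relative splice-score change
≥ 10%.  These follow the hearing-loss specification and the predictors'
conventional operating points; they are engine configuration, not claims
about any particular dataset.

## Population criteria

Per-gene inheritance modes come from a TSV (missing gene → unknown).
Autosomal dominant and recessive carry separate allele-frequency cutoffs;
X-linked adopts the dominant set; unknown takes the strictest value per
criterion (min of AD/AR for PM2's rarity test, max for BA1/BS1's
commonness tests); mitochondrial behaves like unknown plus a warning,
since the framework is validated only for Mendelian disorders.  Defaults
(fractions): BA1 0.001 AD / 0.005 AR; BS1 0.0002 / 0.003; PM2 0.00002 /
0.00007 — the hearing-loss specification's values, shipped as config.

BA1/BS1 trigger when any subpopulation frequency or the median across
subpopulations reaches the cutoff (the even/odd median over present
subpopulations); variants on the known-pathogenic high-frequency
exclusion list are exempt from both.  PM2 triggers when the variant is
absent from the frequency resource (absence counts as frequency zero) or
every subpopulation is at/below the PM2 cutoff.  PM2 and BS1 are emitted
at supporting strength per the hearing-loss demotions; config switches
restore their default strengths.

## Classification and posterior

The standard combining table is committed as an explicit pattern list
(minimum counts per strength); evidence matching both a pathogenic and a
benign pattern is conflicting and yields VUS, as does no evidence.  Two
hearing-loss refinements: PVS1 (very strong) with PM2 (Supporting) in an
autosomal-recessive gene → likely pathogenic; BS1 at any strength with no
pathogenic criterion → likely benign.  Strength-modified criteria count
at their modified strength throughout.

The posterior uses prior 0.1 and odds 350 with exponent weights 1/8, 1/4,
1/2, 1.  Benign evidence contributes negatively at the weight of its
strength; stand-alone benign (BA1) is weighted −1.  The cited framework
defines pathogenic exponents only; the symmetric extension is the
established practice of point-based adaptations and reproduces the 0.05072
threshold for one supporting benign criterion.  VUS refinement uses
inclusive comparisons exactly as printed: posterior ≥ 0.49988 →
Pathogenic, ≤ 0.05072 → Benign.  Note 0.49988 is the *rounded* posterior
of {moderate + supporting}; the unrounded value (0.4998773…) is a hair
below the printed threshold, so that exact evidence set is, deliberately,
not refined — the thresholds are applied as printed, not re-derived.

## Evaluation utilities

For benchmarking, five-tier classes collapse to Benign / VUS / Pathogenic.
Per-class scores derive from the posterior — score(Pathogenic) = p,
score(Benign) = 1 − p, score(VUS) = 1 − |2p − 1|, renormalised — and feed
one-vs-rest micro-averaged ROC AUC and average precision (classes absent
from the truth are skipped with a warning).  Activation-frequency
comparisons use r = log10(α_tool / α_manual) per (criterion, class);
ratios with α_manual = 0 are undefined and masked, α_tool = 0 maps to −∞
(rendered as matrix minimum − 1).  The score construction is a documented,
pluggable choice; published curves for other tools used unstated scores,
so no external AUC value is asserted.

## Synthetic fixtures

The generator builds a ~5 kb toy chromosome holding seven genes on both
strands (1–4 exons, 50–120 codons, 60 nt introns, 30/150 nt UTRs), each
designed to exercise specific branches: a four-exon NMD substrate, a
minus-strand gene with an exon-junction codon for PS1/PM5, an intronless
gene, a minus-strand gene with critical/non-critical domains, a
non-phenotype-relevant gene carrying the repeat track, and two start-loss
genes (with and without a curated rescue entry).  Filler codons exclude
stops and ATG so that planted codons alone control stop positions and
rescue starts.  The 28-variant panel covers every criterion branch; the
companion resources (mini curated-variant table, three-subpopulation
frequencies, five BED tracks, inheritance map, score table, exclusion
list) are co-designed so that each variant triggers exactly its intended
evidence.

Expected outcomes are computed at generation time by straight-line
bookkeeping on the generator's own data structures — string edits in
transcript space, interval comparisons against the intervals it placed,
threshold comparisons against the frequencies it assigned, an inline
closed-form posterior and an inline restatement of the combining rules —
never by calling the engine.  The end-to-end test demands exact equality
of criterion states and classes and 5-decimal equality of posteriors.

What passing does and does not show: the fixtures validate coordinate
arithmetic, strand handling, every decision branch and the combination
machinery, but they are not population-genetically realistic (frequencies
are planted, not simulated), contain one transcript per gene, no
overlapping genes, no multi-exon-spanning indels and no sequencing
artefacts.  Real-data behaviour additionally depends on the quality of
the supplied annotation resources.

Problem sizes throughout (toy chromosome, 28 variants, ≤ 4096-subset
enumeration, exhaustive PTC scans over ~600 codons) were chosen so the
whole suite verifies the logic exhaustively at desk scale; the full test
run takes a few seconds.

## Known limitations

* Splice-site disruption is modelled as single-exon skipping (or whole
  intron retention); partial effects and cryptic splice sites are out of
  scope.
* Variants straddling a coding-segment boundary (e.g. an indel across an
  exon/intron junction) are not evaluated for PVS1 and annotate as
  `other`.
* The 12 unautomatable criteria (PS2–PS4, PM3, PM6, PP1, PP4, BS2–BS4,
  BP2, BP5) are absent by design; classes lean conservative (more VUS)
  compared to full manual curation, which is exactly what the posterior
  refinement mitigates.
* In-silico scores are inputs; the engine does not compute REVEL, CADD,
  phyloP or splice predictions.
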