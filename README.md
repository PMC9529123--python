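# acmghl

Offline, rule-transparent ACMG/AMP variant classification specialised for
hereditary hearing loss.

Clinical laboratories interpreting gene-panel or exome data for hearing
impairment face hundreds of candidate variants across >100 deafness genes.
The ACMG/AMP framework scores each variant against evidence criteria
(PVS1 … BP7) and combines them into five pathogenicity tiers; the ClinGen
Hearing Loss expert panel (VCEP-HL) sharpened those criteria with
disease-specific thresholds, making them automatable.  `acmghl` implements
the 12 criteria that need no per-patient information:

* **PVS1** (all strengths) — refined loss-of-function assessment with
  nonsense-mediated decay (NMD) prediction and start-loss handling,
* **PS1 / PM5 (PM5 Strong)** — curated-variant matching at the affected
  codon, strand- and exon-junction-aware,
* **PM1** — critical protein regions free of benign curated entries,
* **PM4 / BP3** — protein-length change and repeat-region logic,
* **PP3 / BP4 / BP7** — aggregation of conservation, missense and splicing
  predictors,
* **PM2 (Supporting) / BA1 / BS1 (Supporting)** — allele-frequency tests
  with inheritance-mode-specific thresholds.

Every criterion returns a state *and a comment explaining the decision*,
so a curator can audit each call.  All annotation sources are local flat
files (TSV/BED/FASTA) — the engine runs with no network access.

## Posterior pathogenicity probability

Beyond the categorical class, each variant gets a Bayesian posterior
probability of pathogenicity.  With prior π = 0.1 and odds of
pathogenicity O_PVSt = 350 for very-strong evidence, a triggered criterion
of strength *s* contributes the fractional exponent
w(s) ∈ {1/8, 1/4, 1/2, 1} (supporting, moderate, strong, very strong;
benign evidence enters negatively, stand-alone benign as −1):

    x = Σ_pathogenic w(s) − Σ_benign w(s)
    O = O_PVSt ^ x
    posterior = O·π / ((O − 1)·π + 1)

Because only a subset of criteria is automatable, variants that a full
manual work-up would resolve often land in VUS.  The posterior re-classifies
those calls: VUS with posterior ≥ 0.49988 (the posterior of one moderate +
one supporting pathogenic criterion) → Pathogenic; VUS with posterior ≤
0.05072 (one supporting benign criterion) → Benign.  Non-VUS classes pass
through unchanged.

## Worked example

The package ships a seedable generator for a toy genome, transcripts,
annotation resources and a variant panel:

```bash
acmghl fixtures --seed 7 --out-dir fix
acmghl annotate fix/panel.vcf --resources fix/resources.yaml --out-dir out
acmghl classify out/panel.annotated.tsv --resources fix/resources.yaml --out-dir out
```

Selected rows of `out/panel.classified.tsv`:

| id  | gene | consequence | p.          | PVS1 | PM2            | class             | posterior | refined    |
|-----|------|-------------|-------------|------|----------------|-------------------|-----------|------------|
| v01 | TOYA | stop_gained | p.Gln71Ter  | PVS1 | PM2_Supporting | likely_pathogenic | 0.98779   | Pathogenic |
| v05 | TOYB | missense    | p.Arg34Ile  | n/a  | not_triggered  | VUS               | 0.67519   | Pathogenic |
| v10 | TOYB | missense    | p.Thr66Ala  | n/a  | not_triggered  | VUS               | 0.05072   | Benign     |
| v11 | TOYB | synonymous  | p.Leu71Leu  | n/a  | not_triggered  | benign            | 0.00032   | Benign     |
| v13 | TOYB | synonymous  | p.Leu73Leu  | n/a  | not_triggered  | likely_benign     | 0.05072   | Benign     |

Reading the rows: v01 is a nonsense variant predicted to undergo NMD in a
phenotype-relevant transcript (PVS1 very strong, comment: *"NMD predicted
(PTC at CDS offset 210); affected region intersects phenotype-relevant
transcript TOYA-T1"*) and is absent from the frequency resource
(PM2 Supporting); in this autosomal-recessive gene the hearing-loss
refinement classifies the pair as likely pathogenic.  v05 matches a
curated pathogenic change at the same codon (PS1) but a single strong
criterion is categorically still VUS — the posterior 0.675 ≥ 0.49988
refines it to Pathogenic.  v10 triggers only BP4; its posterior 0.05072
sits exactly at the benign threshold and the call is refined to Benign.
v11 is common in every subpopulation (BA1, stand-alone benign), and v13
sits in the BS1 band, which the hearing-loss refinement alone turns into
likely benign.

The same machinery is importable as a library:

```python
from acmghl import classify_variant, load_resources, GenomicVariant
bundle = load_resources("fix/resources.yaml")
cv = classify_variant(GenomicVariant.from_vcf("chr1", 501, "C", "T"), bundle)
print(cv.acmg_class.value, f"{cv.posterior:.5f}", cv.refined_broader_class.value)
# likely_pathogenic 0.98779 Pathogenic
```

## Layout

```
src/acmghl/
  core.py                 domain types (variants, transcripts, criteria)
  resources.py            flat-file annotation resources + indexed queries
  consequence.py          minimal per-transcript consequence annotation
  pvs1.py                 observed CDS, NMD prediction, refined PVS1 tree
  criteria_clinvar.py     PS1, PM5 (Strong), PM1
  criteria_regions.py     PM4, BP3
  criteria_scores.py      PP3, BP4, BP7
  criteria_population.py  PM2 (Supporting), BA1, BS1 (Supporting)
  classify.py             combining table, posterior, VUS refinement, engine
  evaluation.py           activation-frequency log ratios, micro ROC/AP
  io_tabular.py           VCF ingestion, normalisation, tabular output
  synthetic.py            seedable toy genome / resources / golden panel
  cli.py                  acmghl annotate | classify | fixtures
docs/methods.md           model, parameters, design choices, limitations
```

`acmghl` is a research tool; its output is not a clinical diagnosis.
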