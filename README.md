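# panlineage

Comparative pan-genome analysis for cohorts of conspecific bacterial
isolates sampled across the human lifespan — the kind of collection where
one asks: *which accessory genes track host age, and how often are strains
passed between family members?*

The package implements, as one tested pipeline:

* **Gene families** — all-against-all protein comparison with a local
  Smith–Waterman aligner (BLOSUM62, affine gaps 11/1; cut-offs E ≤ 10⁻⁴,
  ≥ 50% identity over ≥ 50% of either sequence) followed by Markov
  clustering (MCL, inflation 2.0) of the score-weighted reciprocal graph.
* **Pan-genome structure** — strains × gene-families presence/absence and
  copy-number matrices, the core/dispensable partition, single-copy core
  selection, covariance-distance strain dendrograms, and the Spearman
  correlation between per-strain ORF count and host age.
* **Age enrichment** — for every dispensable family carried by 6 to
  *n* − 6 strains, a Mann–Whitney U test of carrier vs non-carrier host
  ages with one global Storey q-value correction; families with q < 0.2
  are called *younger*- or *older*-enriched, and detection-rate z-score
  profiles are clustered into infant / adult / elderly groups.
* **CRISPR typing** — detection of repeat-spacer arrays (repeat 23–55 bp,
  ≥ 3 copies, spacers 0.6–2.5× the repeat), ordered-spacer comparison
  between strains (full / partial / none via longest common subsequence),
  and strain-specific PCR primer design anchored in globally unique
  spacers with in-silico specificity screening.
* **Transmission calling** — within-family strain pairs are *transmitted*
  when fragment-based ANI ≥ 99.5% and the spacer arrays match (fully or
  partially), or — for array-free strains — gene-content Jaccard ≥ 0.95.
  Transitive chains are reported as multi-generation components.
* **Core phylogeny** — single-copy core families aligned and concatenated,
  neighbor-joining under Jukes–Cantor distances, 100 bootstrap replicates,
  majority-rule consensus, outgroup rooting.

Because real strain collections of this kind are not redistributable, the
package ships a first-class synthetic-cohort generator
(`panlineage.synthetic_cohort`) that emulates the study design it targets:
113 genomes distributed over 14 host-age bins, a logistic age-carriage
model for dispensable families, family-clonal strains (including one
three-generation chain) and planted CRISPR arrays — all recorded in a
machine-readable truth ledger so recovery can be scored exactly.

## Worked example

```python
from panlineage import pipeline

cfg = pipeline.PipelineConfig(out_dir="results", profile="mini", seed=1)
result = pipeline.run_all(cfg)
metrics = pipeline.evaluate_against_truth(result)
print(f"families recovered exactly: {metrics['gf_recovery_pct']:.1f}%")
print(f"ORF count vs host age: rho={metrics['orf_age_rho']:.2f} "
      f"(p={metrics['orf_age_p']:.3f})")
print(f"transmission precision/recall: "
      f"{metrics['transmission_precision']:.2f}/{metrics['transmission_recall']:.2f}")
print(f"clone-chain clade support: {metrics['clone_clade_support']:.0f}%")
```

prints, for the 30-strain reduced fixture:

```
families recovered exactly: 100.0%
ORF count vs host age: rho=-0.38 (p=0.037)
transmission precision/recall: 1.00/1.00
clone-chain clade support: 100%
```

meaning every planted gene family was reconstructed with exactly its true
gene set, strains from younger hosts carry significantly more genes, all
five planted transmission events (and no spurious ones) were called, and
the three-generation clone chain appears as a maximally supported clade in
the rooted core-genome consensus tree.

The same stages are exposed on the command line:

```bash
panlineage fixture --profile mini --seed 1 --out cohort/
panlineage orthology --proteins cohort/proteins --out families.tsv
panlineage pangenome --families families.tsv --meta cohort/metadata.tsv \
    --out matrix.tsv --dendrogram strains.nwk
panlineage enrich --matrix matrix.tsv --meta cohort/metadata.tsv --out enrichment.tsv
panlineage crispr --genomes cohort/genomes --out arrays.tsv
panlineage transmit --genomes cohort/genomes --meta cohort/metadata.tsv \
    --out calls.tsv
panlineage run --profile mini --seed 1 --out results/
```

## Layout

```
src/panlineage/
  io_formats.py        FASTA / metadata / matrix / age-segmentation IO
  synthetic_cohort.py  cohort generator + truth ledger
  orthology.py         Smith-Waterman hit graph + MCL gene families
  pangenome.py         presence matrix, core partition, strain clustering
  age_enrichment.py    detection rates, Mann-Whitney, q-values, direction calls
  crispr_typing.py     array detection, spacer comparison, primer design
  transmission.py      fragment ANI, Jaccard, transmission verdicts
  core_phylogeny.py    progressive alignment, NJ, bootstrap consensus
  pipeline.py          orchestration, manifest, truth evaluation
  cli.py               click command line
docs/methods.md        model and parameter documentation
```
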