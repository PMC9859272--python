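# paravar

Gene-family variant interpretation built on evolutionary conservation:

* **Conservation profiles** — reference-anchored codon alignments of a
  gene's orthologs are scored per codon: synonymous/nonsynonymous
  substitution counts against the human reference, a z-standardized dN−dS
  signal from single-nucleotide neighbor enumeration, a quantized 0–2
  conservation score, and a 21-codon sliding-window profile normalized per
  gene to [0, 1].
* **Shared domain coordinates** — paralogs are aligned on a common domain
  frame (positions 1..L inside the domain, negative upstream, no position
  zero; an alternate numbering offset by +2 is supported). Cross-paralog
  per-position amino-acid usage and conservation statistics, and signed
  segregation profiles of a focal gene against its siblings.
* **Variant integration** — four TSV schemas emulating population
  (gnomAD-like), clinical (ClinVar-like), phenotype-matched (Geno2MP-like)
  and somatic (COSMIC-like) databases, aggregated per residue with domain
  and conservation context, overlap categories by source combination, and a
  domain enrichment ratio.
* **Prioritization** — cross-paralog clinical-evidence positions,
  multi-change single-gene sites, the in-domain phenotype-database filter
  (CADD > 20, score ≥ 1), the outside-domain conserved-context rule
  (score ≥ 1, window sum ≥ 10), and a somatic high-risk summary by tumor
  type at clinically evidenced positions.
* **Synthetic families** — a star-tree ortholog simulator with
  region-specific substitution rates and nonsynonymous fractions whose
  ground truth is exactly what the conservation counter must recover, plus
  planted variant tables in all four schemas.

Reference tables transcribed from the source study (literature variants,
in-domain clinical variants, phenotype-database candidates, outside-domain
candidates) are packaged as TSV fixtures under `paravar/fixtures/`.

## CLI

```bash
paravar simulate bundle/ --seed 3 --n-genes 4 --species 30 --length 120 \
    --domain-start 31 --domain-end 109        # synthetic family + fixtures
paravar conserve bundle/GENE1.fasta --out profile.tsv
paravar map --alignments bundle/ --annotations bundle/annotations.tsv --out table.tsv
paravar run-all --alignments bundle/ --annotations bundle/annotations.tsv \
    --outdir out/ \
    --variants gnomad=bundle/variants_gnomad.tsv \
    --variants clinvar=bundle/variants_clinvar.tsv \
    --variants geno2mp=bundle/variants_geno2mp.tsv \
    --variants cosmic=bundle/variants_cosmic.tsv \
    --variants literature=bundle/variants_literature.tsv
paravar fixtures table4 --out table4.tsv      # packaged reference tables
paravar report                                # headline counts from fixtures
```

`run-all` also accepts a YAML config (`--config config.yaml`) mirroring
`paravar.pipeline.PipelineConfig`; flags override the file. The output
directory contains per-gene profile TSVs, the cross-paralog position table,
per-residue site summaries, overlap categories, priority calls, the
enrichment table, a `summary.json` with headline counts and a
`manifest.json`. Reruns on identical inputs are byte-identical.

## Layout

```
src/paravar/
  _codons.py       codon translation, single-nucleotide neighbors, site counts
  conservation.py  alignment filtering, per-codon statistics, window profile
  coords.py        domain coordinate system, paralog table, segregation
  variants.py      variant schemas, per-residue aggregation, enrichment
  prioritize.py    prioritization rules
  synthetic.py     family simulator with exact ground truth
  pipeline.py      end-to-end driver
  cli.py           click CLI
  fixtures/        packaged reference tables + loaders
tests/             pytest suite (tests/test_acceptance.py holds the criteria)
scripts/acceptance.py
```
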