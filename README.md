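# virotu

Community analysis of soil-virome viral populations (vOTUs) from
read-mapping coverage, built for replicated plant-microbiome study
designs — specifically the crossed layout of two *Spartina alterniflora*
growth phenotypes (short, tall) by three root-zone compartments (bulk
sediment, rhizosphere, root) with four replicates, 24 samples in all.
It is aimed at microbial ecologists who have mapped metagenomic reads to
a viral contig catalog and want the downstream community statistics
without re-deriving them per project.

## What it computes

Given per-(vOTU, sample) coverage summaries (contig length, covered
bases, mapped reads — e.g. digested from `samtools depth` output):

* **Catalog construction** — minimum contig length (≥ 5,000 bp) and
  greedy longest-first dereplication of sequences into populations at
  ≥ 95% average nucleotide identity and ≥ 80% alignment coverage, with
  the longest member as representative.
* **Presence calling** — a vOTU is present in a sample iff its breadth
  of coverage ≥ 75% of the contig length.
* **Relative abundance** — transcripts per million (TPM): per sample,
  TPMᵢ = 10⁶ · (rᵢ/Lᵢ) / Σⱼ(rⱼ/Lⱼ), with rᵢ mapped reads and Lᵢ the
  contig length in kb. Every sample with counted reads sums to 10⁶.
* **Diversity** — per-sample richness with group labels; permutation
  rarefaction (species-accumulation) curves; exact two-sided
  Mann–Whitney tests for richness contrasts between small groups
  (exact null enumeration for n ≤ 8 per group without ties, otherwise
  the tie- and continuity-corrected normal approximation); Bray–Curtis
  dissimilarity; non-metric multidimensional scaling (Kruskal stress-1,
  multi-restart SMACOF with isotonic regression); PERMANOVA
  (Anderson's pseudo-F on the dissimilarity matrix, permutation p).
* **Co-occurrence** — multi-sample vOTUs (≥ 2 samples) classified by
  the phenotypes (3 classes) and compartments (7 classes) they span,
  tested against a **richness-conserving randomization null**: each
  sample is redrawn at its observed richness from the full vOTU
  catalog, the classification recomputed per replicate, and observed
  class counts compared with the replicate-mean expectation by a
  Pearson χ² goodness-of-fit test. An exhaustive-enumeration oracle
  (`exact_null_expectations`) validates the Monte-Carlo null on small
  instances.
* **Annotation filters** — HMM-hit thresholds (bit score > 30, e-value
  ≤ 0.01); the positional auxiliary-metabolic-gene (AMG) rule
  (metabolic gene, interior to the contig, immediately flanked by
  viral-annotated genes on both sides); order-level joining of host
  predictions against biogeochemical function tables and per-cell host
  coverage summaries.
* **Synthetic data** — a generator that emulates the study structure
  (phenotype fidelity, compartment proximity classes, overdispersed
  depth over log-uniform contig lengths) with recoverable ground truth,
  so the whole pipeline is testable without sequencing data.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_presence_abundance.py
python analysis/03_diversity.py --seed 1
python analysis/04_cooccurrence.py --seed 1
python analysis/05_annotation.py
```

With seed 1 this prints (abridged):

```
769 vOTUs x 24 samples, 2073 presences; ground-truth occupancy recovered exactly: True
NMDS stress: 0.147 (converged: True)
PERMANOVA phenotype: F=2.51 R2=0.102 p=0.001
535 of 769 vOTUs occur in >= 2 samples (30% singletons)

phenotype sharing (observed vs null expectation, chi2=780.2, p=3.84e-170):
          class  observed  expected
     short-only       207     64.69
      tall-only       201     65.91
both-phenotypes       127    404.40
```

Reading this: presence calling inverted the generator exactly (every
simulated occupancy was recalled at the 75% breadth rule); community
composition separates by phenotype (PERMANOVA p = 0.001); and far fewer
multi-sample vOTUs span both phenotypes (127) than the
richness-conserving null expects (≈ 404), the signature of
phenotype-structured viral communities. The compartment table in the
same run shows the complementary proximity pattern: zero vOTUs shared
exclusively between bulk sediment and root, with rhizosphere+root
sharing well above expectation.

The same stages are available as a CLI (`virotu simulate|presence|
abundance|diversity|cooccur|annotate|run-all`) and as a config-driven
pipeline (`virotu.pipeline.run_pipeline`).

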