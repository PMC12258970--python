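# sigkit

A toolkit for finding and validating **weak mutational signatures** in
cancer genomes — the situation where a mutational process contributes only
5–10% of a tumour's substitutions, shows up in about half of a cohort, and
is easily masked or mis-decomposed unless the analysis is stratified and
checked carefully. The package implements the full pipeline such a study
needs, end to end, with a synthetic-cohort generator carrying known ground
truth so every stage is testable:

- **catalogs** — classify somatic single-base substitutions into the
  SBS-96 / SBS-288 (transcriptional strand) / SBS-1536 (pentanucleotide)
  channel schemas and build channels × samples count matrices; read the
  mutation TSV interchange format, minimal VCFs, and annotate contexts from
  a reference FASTA.
- **extraction** — de novo signature discovery by bootstrapped NMF under
  the generalized Kullback–Leibler objective, consensus clustering of
  replicate solutions with silhouette stability, and data-driven rank
  suggestion (`SignatureExtraction(matrix).fit()` → result with
  `summary()`).
- **decomposition** — express a de novo signature as a nonnegative mixture
  of reference signatures, naively or with aetiology subgroups excluded
  (e.g. no treatment or repair-deficiency signatures in a treatment-naive,
  repair-proficient cohort); flag signatures as **novel** when no mixture
  reaches cosine 0.90.
- **attribution** — per-sample signature activities by nonnegative least
  squares with backward pruning, and per-sample positivity calls.
- **timing** — early- vs late-clonal classification of mutations from
  cancer-cell fraction, multiplicity and copy number; phase-specific
  attribution and McNemar contrasts ("is this signature preferentially
  late?").
- **cohortqc** — the stratification filters that define a
  repair-proficient analysis set (burden and indel hypermutator cutoffs,
  low-count removal, flag-signature screening).
- **analysis** — cosine / Spearman profile comparisons (full and per
  substitution type), covariate-adjusted log-linear burden associations
  with fold changes, Benjamini–Hochberg q-values.
- **simulate** — cohorts with sparse known exposures, lognormal burdens
  (~10⁴ per sample), hypermutator spike-ins (~10⁵), clonal-timing
  annotations and indel burdens linked to a target signature's activity.

The scientific core in brief: a catalog **V** (channels × samples) is
factorized as **V ≈ W·H** with **W** ≥ 0 the signatures (column simplices)
and **H** ≥ 0 the exposures, minimizing the generalized KL divergence
D(V‖WH). Stability of each signature across bootstrap replicates
(silhouette under cosine distance) and reconstruction quality select the
rank. De novo signatures are then matched against references by nonnegative
least squares, and per-sample activities, timing asymmetry (McNemar on
paired early/late positivity) and burden associations
(log-burden ~ status + covariates, fold change = e^β) characterize the
signature. See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

Simulate a cohort with three ubiquitous signatures plus a weak target
(5–10% of mutations, ~53% prevalence), extract signatures de novo, and ask
which samples carry them:

```python
import numpy as np
from sigkit import CohortScenario, simulate_cohort, SignatureExtraction
from sigkit.decomposition import match_signatures
from sigkit.attribution import attribute_cohort, positivity

scenario = CohortScenario(
    n_samples=80,
    prevalence=(0.8, 0.7, 0.9, 0.53),     # three baselines + weak target
    burden_log10_mean=np.log10(5000),
    burden_log10_sd=0.0,
    seed=42,
)
cohort = simulate_cohort(scenario, make_records=False)

model = SignatureExtraction(cohort.catalog, k_range=range(2, 7), n_replicates=20)
result = model.fit(seed=0)
print(result.summary())

match = match_signatures(result.suggested.consensus_signatures, cohort.signatures)
print(match.as_frame().round(4).to_string(index=False))

exposures = attribute_cohort(cohort.catalog, result.suggested.consensus_signatures)
print(positivity(exposures).positive_fraction().round(3).to_string())
```

Output:

```
De novo signature extraction
  replicates per rank: 20
  rank selection: largest k with min stability >= 0.8 and mean reconstruction cosine >= 0.95

   min_stability  mean_stability  mean_reconstruction_cosine  suggested
k
2         0.9577          0.9683                      0.9486      False
3         0.9998          0.9998                      0.9952      False
4         0.9976          0.9993                      0.9989       True
5        -0.8237          0.5397                      0.9989      False
6        -0.7502          0.3424                      0.9989      False

  suggested k = 4

       a      b  cosine
DENOVO_A TRUE_A  0.9999
DENOVO_B TRUE_B  0.9999
DENOVO_C TRUE_C  0.9998
DENOVO_D TRUE_D  0.9984

DENOVO_A    0.838
DENOVO_B    0.788
DENOVO_C    0.900
DENOVO_D    0.575
```

Reading it: the rank rule picks k = 4 (larger ranks split true signatures,
collapsing their stability to negative silhouettes); each consensus
signature matches one planted truth signature at cosine ≥ 0.998, including
the weak target `TRUE_D`; and attribution finds the target in 57.5% of
samples — the three baselines appear at their simulated prevalences, the
target near its 53% prevalence.

The same pipeline is available from the shell:

```bash
sigkit simulate --seed 5 --n-samples 100 --out sim/
sigkit qc --matrix sim/catalog.SBS96.tsv --indels sim/indel_burdens.tsv --out qc/
sigkit extract --matrix qc/catalog.retained.tsv --seed 9 --out extract/
sigkit decompose --signatures extract/signatures.suggested.tsv \
    --references refs.tsv --tags tags.tsv --mode optimized \
    --exclude treatment --out decomposition.tsv
```

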