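# Methods

## The measurement model

The assay's unit of measurement is the *probe*: one bisulfite-PCR amplicon
with primers designed on the fully-methylated converted top strand and a set
of CpG cytosines strictly between the primer footprints. Because cancer
hypermethylation at the targeted regions is observed to be all-or-none at
the epiallele level, the informative statistic is not average methylation
but the fraction of reads methylated at *every* interrogated CpG
(f = fully-methylated reads / passing reads). Requiring all CpGs to agree
makes a single sequencing error insufficient to create a false
fully-methylated read, which is what lets the signal survive a large excess
of unmethylated normal cfDNA.

Scoring rules, with defaults:

| rule | default | rationale |
| --- | --- | --- |
| read length filter | strictly > 100 bp | removes primer dimers and fragments |
| alignment identity | ≥ 0.90, CpG C/T counted as match | BiQ-style "90% homology" |
| CpG identifiability | no gap/non-C/T base at any CpG offset | all CpGs must be readable |
| evaluable probe | ≥ 100 passing reads | below this, partially converted templates produce spurious positives |
| positive probe | f ≥ 0.1 | empirical break between positive and negative probes |
| positive sample | MI > 2.5 (MI ≥ 3) | integer MI; controls range 0–2 |
| probe QC | drop if positive in ≥ 3 controls | sporadic background elimination; BRCA1 exempt |

MI counts positive probes among MI-eligible probes only: a BRCA1 promoter
probe is carried in the panel for its predictive value but never counted,
and a BRCA1-positive result in a panel-negative sample is flagged with a
caveat, since isolated BRCA1 promoter methylation can be of hematopoietic
origin.

Non-evaluable probes count as negative for the MI and are reported
separately; an alternative that renormalises MI by the evaluable count is
deliberately not the default, because the fixed-count rule is what the
decision threshold of 2.5 was defined against.

## Panel discovery

Selection operates on centered beta values β′ = β − c with c = 0.5, so the
thresholds are β′ > −0.1 in ≥ 50% of tumours (i.e. β > 0.4) and per-tissue
normal mean β′ < −0.3 (β < 0.2). The centering constant and both thresholds
are arguments, so an M-value-style recoding can be substituted without
touching the selection logic. Normal tissues are tested per-group (each
tissue mean must be low), not pooled — a single methylated tissue vetoes a
CpG. Missing betas are excluded pairwise and never imputed.

Chaining uses single linkage on C-coordinate distance at 300 bp: maximal
runs of selected CpGs with consecutive gaps ≤ 300 bp, runs of length 1
discarded. Input order is validated, not silently re-sorted. Exclusion
masking removes a candidate on ≥ 1 bp overlap with any mask interval; all
intervals are 0-based half-open, so abutting intervals do not overlap.
Regions known a priori (prognostic regions, the BRCA1 promoter) bypass
selection: they can be supplied directly as candidates/primer pairs and
still pass primer validation.

Primer Tm uses the Biopython nearest-neighbour model at 250 nM primer,
50 mM Na⁺. Commercial design software differs by a few °C; Tm agreement
with any particular tool is a non-goal, so Tm checks on simulated panels
are advisory while the length and CpG-count constraints are enforced.

## Alignment and calling

Reads are aligned to the fully-methylated reference only, semi-globally
(free end gaps on both sequences; match +1, mismatch −1, linear gap −2,
all configurable). At CpG cytosine offsets a read T scores as a match, so
unmethylated reads are not penalised and a separate unmethylated reference
is unnecessary. Identity is matching columns over alignment columns with
end-gap columns excluded; the identity denominator therefore includes CpG
positions (with C/T tolerance). Reads shorter than half the amplicon fail
immediately (`short_alignment`). The row recurrence is vectorised (the
linear gap cost turns the in-row horizontal chain into a running maximum),
with a gap-free fast path taken only when it is provably optimal
(mismatch-free placement, identity 1). A plain-Python dynamic program with
identical tie-breaking serves as the test oracle.

Demultiplexing matches the forward primer against the read prefix within 2
mismatches (configurable; 0 recovers exact prefix splitting), trying both
orientations; ties between probes are routed to an unassigned bin rather
than guessed. Base qualities are carried but unused in calling; a quality
floor exists as a configuration hook, default off.

## The synthetic-data generator

The generator emulates the statistical structure the assay assumes, not the
chemistry. Templates are strictly all-or-none methylated. Per probe and
sample, reads are drawn Poisson(depth); each read descends from a tumour
template with probability governed by the tumour fraction. Noise model, per
base: unmethylated cytosines (CpG and non-CpG) convert with probability
`conversion_rate` (default 0.99); methylated CpGs read out as converted
with probability `meth_cpg_error` (default 0.005); substitutions at
`seq_error` (default 0.002, substitutions only — indel noise is out of
scope to keep oracle checks simple); a `short_read_fraction` of reads is
truncated to exercise the length filter. Primer footprints are stamped
with the primer's own (methylated-converted) sequence after template noise,
because PCR products carry the primer sequence regardless of template
state — this is also the mechanism of the methylation bias.

Two optional mechanisms model the assay's physics at low ctDNA input:

* `methylation_bias` multiplies the sampling weight of methylated
  templates (the primers amplify methylated DNA preferentially but not
  exclusively). Its true magnitude is unquantified, so the default is 1
  (off).
* `templates_per_probe` draws a finite pool of genome equivalents per
  probe (tumour templates ~ Binomial(M, tumour_fraction)). Below one
  genome equivalent per aliquot individual targets are simply absent, which
  is what makes probe positivity — and hence MI — rise smoothly with
  tumour fraction instead of switching at f = 0.1. Default None (infinite
  pool, per-read Bernoulli).

Inter-tumour heterogeneity is modelled by `probe_meth_prob`: each probe's
tumour compartment is methylated with this probability per case (real
tumours are positive for only a subset of the panel). Control samples run
at tumour fraction 0 with an independent per-probe sporadic background
probability, matching the observed randomness of healthy-control positives
across probes.

Simulated reads are bare amplicons — no sequencing adapters or barcodes.
Real reads carry universal tails that push them past the 100 bp filter, so
simulated panels intended for end-to-end runs use products of 105–150 bp;
with the default 75–150 bp range, probes shorter than 100 bp lose all reads
to the filter, which is itself a useful negative control. Beta-matrix
simulation plants DMR clusters (intra-cluster gaps 50–250 bp) among
background CpGs spaced 400 bp apart, so the 300 bp chaining rule can never
join background CpGs; planted CpGs are high-beta in a configurable fraction
of tumours only.

What the generator does **not** emulate: cfDNA fragment-length
distributions, per-cycle polymerase error accumulation, Ion Torrent
homopolymer indels, batch effects, and array-specific beta distortions
(probe type chemistry, background drift). Passing tests therefore
demonstrate correctness of the decision rules and estimators under the
assay's idealised assumptions, not robustness to every artifact of real
instruments.

## Problem sizes and determinism

All randomness flows through one `numpy` generator per run; identical seeds
reproduce outputs byte for byte. The bundled verification runs use panels
of 8–12 probes, depths of 150–1000 reads per probe, cohorts of 8+8 samples,
beta matrices of 300–1000 CpGs and 200 discovery replicates — sizes chosen
so the full suite and the acceptance script each complete in well under a
minute of CPU while leaving binomial margins far wider than the effects
being measured.

## Known limitations

* Top-strand conversion only; bottom-strand (G→A) assays are out of scope.
* Single-end reads; no paired-end merging.
* No conversion-efficiency estimation from non-CpG cytosines (a natural
  extension; the read floor already suppresses partial-conversion
  artifacts).
* The ROC operating table reports achievable points on integer MI scores;
  with few samples the curve is coarse by construction.
* Replicate samples are reported separately; no averaging rule is applied.
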