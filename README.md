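# ctmeth

Targeted bisulfite amplicon sequencing toolkit for methylation-based ctDNA
liquid biopsies.

Tumours carry frequent, consistent, region-level DNA hypermethylation events.
A liquid biopsy built on them works in four computational stages, all
implemented here:

1. **Panel discovery** (`ctmeth.panel_discovery`) — from a 450k-style beta
   matrix (per-CpG methylation level β ∈ [0, 1] across tumour and
   normal-tissue cohorts), select CpGs where the centered beta β′ = β − 0.5
   exceeds −0.1 in at least 50% of tumours while every normal-tissue mean β′
   is below −0.3; chain selected CpGs within 300 bp into candidate regions
   (≥2 CpGs each); subtract blood-methylated exclusion intervals; and check
   primer pairs against the design constraints (product 75–150 bp, primers
   21–31 bp, nearest-neighbour Tm 64–72 °C with ≤5 °C differential, ≥2
   inter-primer CpGs).
2. **Reference construction** (`ctmeth.bisref`) — in-silico bisulfite
   conversion (C→T except methylated CpG cytosines) builds each amplicon's
   fully-methylated and fully-converted references plus the index of
   inter-primer CpG offsets that will be scored.
3. **Read processing** (`ctmeth.readproc`) — retain reads strictly longer
   than 100 bp, demultiplex by forward-primer prefix (≤2 mismatches,
   ties unassigned, reverse-complement rescue), align each primer-trimmed
   read to its probe's methylated reference with free end gaps (a read T
   at a CpG cytosine is the unmethylated epiallele, scored as a match), and
   call per-CpG states. A read passes at alignment identity ≥ 0.90 with
   every CpG identifiable; a passing read methylated at **all** CpGs is a
   fully-methylated read.
4. **Scoring** (`ctmeth.scoring`) — per probe, the fully-methylated read
   fraction f = fully-methylated / passing reads; a probe needs ≥100
   passing reads to be evaluable and is positive when f ≥ 0.1. The
   per-sample **Methylation Index (MI)** counts positive MI-eligible probes
   (the BRCA1 promoter probe is carried for its treatment relevance but
   excluded from the MI); a sample is called positive when MI > 2.5, i.e.
   MI ≥ 3. Probe QC drops probes positive in ≥3 control samples. Cohort
   performance is summarised by rank-based AUC and sensitivity at 100%
   specificity (cases strictly above the maximum control MI).

Two supporting modules make the package self-contained: a CHIP variant
filter (`ctmeth.variant_filter`: exonic, non-synonymous, p < 0.01,
coverage > 50, VAF 0.02–0.43, no common-SNP flag, all MAF ≤ 0.02) for
screening clonal-hematopoiesis background in controls, and a seeded
synthetic-data generator (`ctmeth.simulator`) producing legal panels over
synthetic genomes, all-or-none methylated template mixtures at tunable
tumour fraction, depth and noise, and beta matrices with planted DMRs —
every simulated object ships with a ground-truth table.

## Worked example

Simulate a six-probe panel and one sample at 20% tumour fraction, then call
and score it:

```bash
ctmeth simulate reads --config demo.yaml --seed 7 --out demo_sim
# demo.yaml: n_probes: 6, depth_per_probe: 300, tumour_fraction: 0.2,
#            amplicon_len: [105, 150], cpgs_per_probe: [3, 8]
ctmeth call --panel demo_sim/panel.tsv --fastq demo_sim/reads.fastq \
            --sample-id demo --out demo_called
```

prints

```
{"sample_id": "demo", "methylation_index": 6, "call": "positive",
 "brca1_methylated": false, "brca1_caveat": false, "n_evaluable": 6}
```

and `demo_called/demo.probes.tsv` holds the per-probe fractions:

```
probe_id    pass_reads  fully_methylated_reads  fraction  evaluable  positive
probe_001   311         65                      0.209     True       True
probe_002   305         51                      0.167     True       True
...
```

Every probe's fully-methylated fraction sits near the simulated 20% tumour
fraction (scatter is binomial; probe_002 is low because the methylated-CpG
read-out error compounds over its CpGs), all six probes clear the 0.1
positivity cutoff, so MI = 6 > 2.5 and the sample is called positive.
The same pipeline is available as a library:

```python
from ctmeth import SimConfig, simulate_genome_and_panel, simulate_reads, run_sample

cfg = SimConfig(seed=7, n_probes=6, amplicon_len=(105, 150), depth_per_probe=300,
                tumour_fraction=0.2)
_, panel = simulate_genome_and_panel(cfg)
reads, truth = simulate_reads(panel, cfg)
report = run_sample(reads, panel, sample_id="demo")
print(report.methylation_index, report.call)
```

Other entry points: `ctmeth discover` (beta matrix → candidate BED),
`ctmeth build-panel` (genome FASTA + primers → converted references),
`ctmeth qc`, `ctmeth roc`, `ctmeth chip-filter`, and
`ctmeth simulate panel|reads|beta|cohort`.

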