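# cyanophage

A toolkit for the computational side of characterizing a freshwater
cyanophage isolate: competitive metagenomic read recruitment with
length/size-normalized abundances, translated homology and shared-ORF
(synteny) analysis under the e < 10⁻⁵ homolog rule, and one-step
growth-curve kinetics (latent period, burst size, and the DNase-corrected
packaged-DNA fraction). Everything runs on synthetic data generated
in-package with known ground truth, so each stage is testable end to end
without external databases.

## Who this is for

Phage ecologists and viromics researchers who want the analyses behind a
phage characterization study — "how abundant is my isolate's genotype in
public viromes?", "which genes does it share with uncultured relatives?",
"what are its infection kinetics?" — as tested, reproducible code rather
than one-off command pipelines.

## The methods at the core

**Competitive recruitment.** Reads are prefiltered by a translated search
of the target proteome against the read set (tBLASTn analog, E < 10⁻⁵).
Candidates are then searched as translated queries against the union of
the target proteome and a reference panel of competing phage proteomes;
a read is recruited only if its single best hit (highest bit score)
belongs to the target. Abundance is normalized as

```
A = n_hits / (L_genome[kb] × N_metagenome[Gbp])
```

and phages of close genetic proximity are grouped by summing member
abundances. Outputs include a position-vs-identity map table and the
fraction of genes covered by ≥ 1 recruited read.

**Translated search.** An in-house seed-and-extend local aligner over
BLOSUM62 with affine gaps: exact k-mer seeding (k = 3), a same-diagonal
two-seed rule, ungapped X-drop extension as a trigger, then exact
Smith–Waterman on surviving pairs — so reported scores never exceed the
optimum an exhaustive aligner would find. Significance uses the
Karlin–Altschul statistic E = K·m·n·e^(−λS) with standard gapped BLOSUM62
constants (λ = 0.267, K = 0.041).

**Growth kinetics.** From a one-step growth experiment sampled every 3 h
for 48 h (undigested and DNase-digested free-phage qPCR series plus host
counts): the latent period is the last sampling time before the first
sustained rise (two consecutive points > 2× the post-adsorption
baseline); burst size is (mean plateau − post-adsorption residual) /
infected cells, with the initial host count as the default divisor (at
MOI ≈ 2 essentially all cells are infected); the packaged-DNA fraction is
the time-averaged digested/undigested ratio, reported alongside the
plateau burst ratio because the two conventions genuinely differ.

## Worked example

```
$ python analysis/01_simulate_study_system.py --seed 1
target genome: 42000 bp, GC 63.4%, 47 genes
panel: 10 members in 5 groups
lake_virome: 800 reads, 257 from the target genome
ocean_virome: 800 reads, 70 from the target genome

$ python analysis/02_recruit_viromes.py
lake_virome: 583 candidates -> 217 recruited; gene coverage 96%; in-gene sensitivity 100.0%; false recruitment 0.00%
ocean_virome: 544 candidates -> 60 recruited; gene coverage 68%; in-gene sensitivity 100.0%; false recruitment 0.00%

$ python analysis/04_growth_kinetics.py --seed 1
10 simulated experiments:
  latent period median   24 h  (truth 24 h)
  burst (undigested)     255.1 copies/cell  (truth 250)
  burst (DNase-digested) 48.7 virions/cell  (truth 50)
  packaged fraction: time-averaged 0.59, plateau ratio 0.19
  lysis called in all experiments: True
```

Reading the numbers: of the 800 lake-virome reads, 583 carry a translated
hit to some target protein (many come from the 55–70%-identity panel
relatives), but only 217 — essentially all of the reads that truly
originate inside target genes — survive the best-hit competition. The
simulated one-step growth experiments return the generator's truth within
a few percent: free phage first rises between 24 h and 27 h (latent
period 24 h), total DNA copies give a burst near 250 per cell while the
DNase-protected subset gives 50, and the time-averaged packaged fraction
(0.59 here) exceeds the plateau ratio (0.19) because the early samples are
dominated by the fully packaged inoculum.

The same stages are available as a CLI (`cyanophage simulate-genome`,
`simulate-reads`, `simulate-infection`, `recruit`, `annotate`, `synteny`,
`growth`, `plot`, `fetch`) for use on real FASTA/FASTQ/TSV inputs.

## Layout

```
src/cyanophage/    library (sequence core, translated search, annotation,
                   recruitment, growth kinetics, synthetic data, CLI)
analysis/          numbered drivers reproducing the study's analyses on
                   synthetic data; tables land in results/
tests/             pytest suite, including property tests (hypothesis)
docs/methods.md    models, estimators, parameter choices, limitations
```
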