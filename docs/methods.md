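# Methods

This note records the models and procedures the toolkit implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Sequence core

Sequences are restricted to {A, C, G, T, N} for nucleotides (other IUPAC
ambiguity codes are rejected at parse time) and the 20 standard residues
plus X and `*` for proteins. All coordinates are 0-based half-open
internally; 1-based inclusive coordinates appear only in GFF3 and
outfmt-6-style reports. Translation uses table 11 (bacterial/phage), stop
codons render as `*`, and trailing partial codons are dropped.

The ORF caller reports all maximal complete start-to-stop ORFs on both
strands: start codons {ATG, GTG, TTG}, stops {TAA, TAG, TGA}, default
minimum length 90 nt. "Maximal" means the ORF for each stop codon starts
at the first start codon after the previous in-frame stop — the longest
complete ORF per stop-to-stop segment, matching prokaryotic-caller
convention. GC content is (G+C)/(A+C+G+T) with N excluded from the
denominator.

## Translated search

The aligner is a seed-and-extend heuristic for protein-level local
alignment, with four modes selecting which sides are six-frame translated
(protein–protein, protein–nucleotide, nucleotide–protein, and
translated–translated).

Pipeline: exact k-mer seeding (default k = 3) against a subject-side
index; a candidate diagonal must carry at least two seeds (substitutions
dominate the divergence this toolkit models, so genuine homologies put
many seeds on one diagonal while chance 3-mer matches essentially never
repeat one); surviving diagonals get an ungapped X-drop extension
(X = 20) and must reach a trigger score (25); pairs that trigger are then
aligned *exactly* with affine-gap Smith–Waterman (BLOSUM62, gap open 11,
gap extend 1, the open penalty charged on the first gap position).
Because the final score comes from the exact aligner, every reported
score equals the Smith–Waterman optimum for its pair; the heuristic can
only miss pairs whose seeds are too sparse. This bound is enforced by a
test over random pairs and holds by construction.

Significance: E = K·m·n·e^(−λS) with the standard gapped BLOSUM62
constants λ = 0.267, K = 0.041; m is the query length and n the total
database residues (translated length for nucleotide sides); bit score is
(λS − ln K)/ln 2. No attempt is made to reproduce NCBI composition-based
statistics — E-values here are internally consistent, monotone in score
and linear in the search space, which is what thresholding at 10⁻⁵
requires. Identity is identical columns over aligned columns, gap columns
included.

Best-hit selection (the max_target_seqs = 1 analog) is deterministic:
highest bit score, ties broken by lower E-value, then lexicographically
smallest subject id. A tool whose tie winner depends on input order
cannot be reproducible; this rule can.

## Annotation, categories, synteny

An ORF is annotated when its best hit against the reference protein set
has E < 10⁻⁵ (configurable), otherwise it is counted hypothetical;
annotated + hypothetical always equals the ORF total. Functional
categories come from ordered, case-insensitive keyword rules on the
product string (terminase/maturase → DNA packaging; integrase/KilA-N →
lysogeny; amidase/lysozyme/peptidase → lysis; polymerase, ssDNA-binding,
endodeoxyribonuclease, NrdR, primase … → nucleic-acid metabolism; capsid,
tail, portal, connector … → structural; MarR/"transcriptional regulator"
→ transcriptional regulator; anything else → other). Rule order matters
and is part of the contract: "transcriptional regulator NrdR" is
nucleic-acid metabolism, not a generic regulator.

Shared-ORF (synteny) counting is directional: an ORF of genome A is
shared with genome B when its protein has ≥ 1 sub-cutoff hit anywhere in
the six-frame translation of B. Whether the published counts in studies
of this kind come from whole-genome translated comparison or
protein-vs-genome searches is usually unstated; the protein-vs-six-frame
convention used here is a documented choice, and both directions are
reported since the counts need not agree. Self-synteny of a genome equals
its ORF count, and the count is monotone in the cutoff — both are tested
invariants.

The genome-map track table renders rings: ring 1/2 are + / − strand ORFs
with categories, and each comparator genome adds a ring of translated-hit
intervals mapped back to target coordinates with percent identity.

## Competitive recruitment

Stage 1 (prefilter) searches the target proteome against the six-frame
translated reads and keeps reads with any sub-cutoff hit. Stage 2 searches
each candidate read against the union of the target proteome and the
panel proteomes and recruits the read only when the best hit belongs to
the target. The whole read (not just the hit region) is used in stage 2.
Exact bit-score ties between target and panel are *not* recruited — the
conservative resolution, chosen over input-order-dependent behaviour —
and are logged. A recruited read contributes exactly one recruitment,
attributed to one gene (its best hit), so read counts are conserved:
recruited ⊆ candidates ⊆ reads.

Recruited positions on the genome are mapped from the winning hit's
subject-protein coordinates through the gene's genome coordinates,
strand-aware; the map table reports interval midpoints for plotting.

Abundance: n_hits / (genome length in kb × metagenome size in Gb).
"Metagenome size" is measured in *bases* (Gbp), not file bytes — bytes
depend on compression and format and would make the statistic
irreproducible. Group abundances are plain sums over member phages. The
statistic is exactly scale-invariant (same factor on hits and bases
cancels), which is tested.

Gene coverage is the fraction of ORFs overlapped by ≥ 1 recruited read.

## One-step growth-curve estimators

The experiment: phage added at MOI ≈ 2 to a dilute host culture
(~9.5 × 10⁴ cells/mL, low enough to avoid re-infection), free phage in
filtrate quantified by qPCR every 3 h for 48 h, each sample measured
undigested (total phage DNA copies) and after DNase I digestion
(capsid-protected copies only).

* **Latent period** — last sampling time before the first sustained
  rise, defined as two consecutive points each above rise_factor
  (default 2) × baseline, where baseline is the series minimum after the
  adsorption window (default 0–6 h). Requiring two consecutive points
  rejects single qPCR spikes. If the series already rises at the first
  post-adsorption sample the estimate is bounded at the window end. No
  rise ⇒ explicit no-burst error. Resolution is one sampling interval by
  construction.
* **Burst size** — (mean of the final three samples − post-adsorption
  residual) / n_infected. The residual (unadsorbed inoculum) is the
  post-adsorption minimum. n_infected defaults to the initial host
  count: at MOI 2 the Poisson probability of ≥ 1 adsorbed phage is
  ~0.86 and synchronous designs treat the culture as fully infected; the
  divisor is configurable for other designs. If the final three samples
  are still rising (last > 1.3 × first) the estimate is flagged
  provisional with a warning rather than silently reported.
* **Packaged fraction** — per-time digested/undigested ratios clipped to
  [0, 1], averaged over time points with undigested signal above a floor
  (default 10 copies/mL, a 0/0 guard). The time-averaged mean and the
  plateau burst ratio (digested burst / undigested burst) are *different
  conventions*: with a fully packaged inoculum the time average is pulled
  toward 1 by pre-burst samples and always exceeds the plateau ratio.
  Both are reported so either convention can be read off; reports of a
  packaged-DNA percentage in this kind of experiment are ambiguous
  without stating which was used.
* **Decision rules** — culture lysis: treated/control strictly below
  0.5 at the final sample (a strict "more than 50% decrease"); host-range
  infectivity by OD uses the same strict rule.

## Synthetic-data generators

All generators are pure functions of their seed (bit-identical reruns,
tested).

* **Genomes** — non-overlapping complete ORFs packed into a fixed length
  with multinomially distributed intergenic gaps; gene bodies are
  GC-biased codons resampled to exclude in-frame stops; an in-frame stop
  codon is planted immediately upstream of every gene so the ORF caller
  recovers exactly the recorded coordinates (truth ⊆ called). Realized
  GC is corrected to within ±0.01 of target by flipping intergenic
  positions outside the planted stops. Defaults emulate the study
  system: 42 kb, GC 0.634, 47 genes.
* **Homologs/panels** — homologs are made by substituting exactly
  round((1 − identity)·L) positions, so realized exact-position identity
  is within one residue of target; group identities default to the
  30–80% band observed among related cyanopodoviruses. Panel members get
  a synthetic genome encoding their proteome (one forward CDS per
  protein, initiator Met preserved, upstream stop planted) so labeled
  reads can be drawn from competitors.
* **Reads** — multinomial origin in community weights, uniform positions,
  equiprobable strands, i.i.d. substitution errors (default rate 0.01,
  read length 150 nt — short-read virome scale); truth labels carry
  origin, interval, strand and error count. No indels, no quality
  profiles, no chimeras.
* **Infections** — inoculum = MOI × host0 declines exponentially during
  the adsorption window (90% adsorbed by 6 h by default); release follows
  a normalized logistic ramp that is exactly 0 at the latent period
  (24 h) and 1 at the rise end (36 h); undigested copies = surviving
  inoculum + burst_total (250) per infected cell released so far;
  digested copies = packaged subset (burst_packaged 50; inoculum counted
  at its packaged fraction, default 1.0). With the 12/12 light-cycle flag
  set, release increments falling in dark phases are dropped (release
  pauses; it is not deferred). The control host grows logistically
  (0.03 h⁻¹ toward 10⁶ cells/mL — slow cyanobacterial growth); the
  infected culture declines with release. Noise is multiplicative
  lognormal per observation with CV 0.15 by default — a qPCR-like error
  model chosen in the absence of a published replicate-variance model.

What passing tests on these data do **not** show: performance on real
viromes with indel errors, uneven coverage, host-genome contamination
(reads from host homologs of phage-carried genes can inflate
recruitment, the known caveat for peptidase-like genes), or divergence
with insertions/deletions and domain shuffling rather than point
substitution. The generators are deliberately substitution-only, which is
also why the same-diagonal two-seed rule in the search is safe here.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 12–42 kb genomes,
10–47 genes, panels of ≤ 10 members, 300–1,000 reads per community,
10-seed replication for stochastic checks. These sizes were chosen so the
full suite exercises every stage end to end in minutes on one core while
keeping binomial/median statistics tight enough for the stated
tolerances. Degenerate inputs fail loudly and specifically: empty
alphabets, infeasible genome packing, zero denominators, series without a
rise, ratios with washed-out denominators all raise typed errors rather
than returning NaN.

## Known limitations

* E-values are not NCBI-comparable in absolute terms; only thresholding
  behaviour is claimed.
* The seeded search can miss heavily gapped or very short homologies
  (< 2 shared k-mers on a diagonal); the Smith–Waterman oracle is exposed
  for exhaustive small-scale checks.
* The recruitment panel is an explicit input; no bundled database exists,
  so absolute environmental abundances from published studies (which
  depend on particular database snapshots and multi-Gb viromes) are out
  of reach by design.
* The infection model is bookkeeping, not mechanism: no ODE dynamics, no
  re-infection, no eclipse-phase intracellular DNA, and host decline is
  tied directly to the release ramp.
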