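# Methods

This note documents the models behind `xrseqtools`: what the synthetic
data emulates, the estimators and their assumptions, the numerical
choices, and what passing the test suite does and does not establish
about real sequencing data.

## The simulation model

### Genomes

`make_toy_genome` draws i.i.d. uniform A/C/G/T sequence (GC fraction
configurable, default 0.5) and packs non-overlapping genes with a minimum
inter-gene gap; residual slack is distributed randomly between genes so
layouts differ across seeds. Each gene gets a 5′UTR / exon / intron /
3′UTR tiling (1–3 introns, mirror-imaged for minus-strand genes).
`make_species_pair` builds a target and a spike genome and verifies that
every 24-mer — forward and reverse complement — is unique in the combined
universe, regenerating on collision. This makes exact alignment of any
trimmed read of ≥ 24 nt unambiguous, so species attribution downstream is
error-free by construction. Default sizes (target 2 × 300 kb with 24
genes, spike 140 kb) are a deliberate desk-scale stand-in for real
genomes: large enough for ≥ 10⁴-read libraries and stable fractions,
small enough that a full pipeline run takes seconds.

### Damage

UV photoproducts form only at dipyrimidine sites (TT/TC/CT/CC read 5′→3′
on the damaged strand); both strands are scanned independently and each
site is damaged with a single per-site Bernoulli probability. Dose enters
only through this rate — no dose–response curve is modelled, mirroring
fixed-dose experimental designs. A lesion's position is stored as the
reference coordinate of the dinucleotide's left edge; on the minus strand
the damaged dinucleotide is the reverse complement of the reference
slice.

### Genotype-dependent excision

A `GenotypeSpec` holds two efficiencies: the probability that a lesion on
the transcribed strand (the template strand) of an active gene is excised
during the experiment window (`tcr_efficiency`), and the probability for
every other lesion (`global_efficiency`). An optional
`spurious_transcription_rate` lets a fraction of non-TS lesions be
repaired at the TCR rate, emulating pervasive transcription outside
annotated genes; it defaults to 0 and `active_gene_fraction` defaults to
1 (essentially the whole toy genome is transcribed). Excision counts per
lesion are Binomial in the cell-equivalent input, so expected library
yield is linear in cell number — the assumption the serial-dilution
calibration tests.

The five presets encode the qualitative phenotypes of the simulated cell
lines: WT (global 0.5, TCR 0.7 — strong global repair, mild TS excess),
XPC_KO (0.005 / 0.5 — TCR only), CSB_KO (0.4 / 0.4 — global only),
XPC_CSB_KO (8.6·10⁻⁴ / 5·10⁻³ — residual, TCR-dominated repair near 0.3%
of WT), and XPC_CSB_CSA_KO (2.7·10⁻⁴ uniform — near 0.05% of WT, no TS
excess). Preset efficiencies are nominal; `calibrate_knockout` solves for
the two efficiencies exactly on a given genome from (a) the desired
per-cell excision rate relative to WT and (b) either a TCR/global ratio
or the expected intergenic share of excision events, using the genome's
own dipyrimidine site counts per annotation category. The quantification
experiments use the calibrated form so the planted truth is exact in
expectation.

### Excision geometry

The dual-incision product carries the lesion `offset5` nt from its 5′ end
(support {19, 20, 21}) and `offset3` nt from the dinucleotide's 3′ edge to
the 3′ incision (support {5, 6}); an optional post-excision 3′ nibble of
0–2 nt models degradation of the released oligomer. Defaults are
offset5 {19: 0.70, 20: 0.20, 21: 0.10}, offset3 {5: 0.80, 6: 0.20},
nibble {0: 0.85, 1: 0.10, 2: 0.05}. These weights were chosen
analytically so the fragment-length distribution has support exactly
[24, 29] nt with its mode and median at 26 nt — the canonical
excised-oligomer size — both before and after the damage-register filter;
uniform incision-offset weights would shift the median to 27 nt. The
sub-26-nt weights are explicit knobs, not measured quantities: the true
length distribution of degraded products is not well characterised.

A consequence worth knowing: a fragment nibbled such that its lesion no
longer sits 5–6 nt from the 3′ end cannot pass the damage-site filter
except by sequence chance (~37% in a GC-0.5 genome). End-to-end recovery
of *register-eligible* fragments is essentially complete (> 99%, losses
only to exact-duplicate removal), while nibbled-out-of-register fragments
are filtered away — the same selection the filter applies to real
libraries.

### Spike-in mixing

The spike species is repaired with global repair only, at fixed damage
and efficiency, regardless of the target genotype — it is an external
standard. `mix_spikein` draws exactly `spike_quantity` spike fragments
(default 2000) without replacement from the spike event pool, interleaves
them with all target fragments in random order, appends the sequencing
adapter, and records every read in the truth manifest (species, locus,
strand, lesion position and type, incision offsets, annotation category,
TS/NTS label). FASTA is the default library format; FASTQ output uses a
constant quality.

Not modelled: sequencing errors, PCR duplication beyond exact repeats,
immunoprecipitation-efficiency differences between damage types, and a
mitochondrial compartment (the spike species plays the
negative-control/standard role). Passing tests therefore demonstrates
correctness of the *computational* pipeline under clean reads and exact
alignment, not robustness to sequencing noise or mapping ambiguity in a
repetitive genome.

## Read processing

Trimming removes the 3′ adapter by exact match: cut at the first full
occurrence, otherwise remove the longest read suffix equal to an adapter
prefix of ≥ 3 nt. Deduplication keeps the first occurrence of each
distinct sequence and precedes alignment. The aligner is an
exact-substring search (12-mer seed, full-sequence verification, both
strands of both species); reads containing N, reads with no hit, and
reads with more than one hit are dropped — quantification depends on
species attribution, so ambiguity is fatal per read. On genomes ≤ 50 kb
the aligner is tested equal to a brute-force all-positions scan.

The damage filter keeps reads of 24–29 nt carrying a pyrimidine pair in
at least one of two registers: 1-based positions (L−7, L−6) ("A", lesion
6 nt from the 3′ end) or (L−6, L−5) ("B", 5 nt), matching the 3′-incision
geometry. Both registers are accepted (OR) and the firing registers are
recorded per read, since the incision distance itself varies between 5
and 6 nt.

## Repair analytics

Unit-gene profiles use genes longer than 5 kb with ≥ 5 kb to the nearest
neighbour on both sides (chromosome ends count as open space). Each read
is assigned to the gene containing its midpoint; TS means read strand ≠
gene strand. The gene is divided into 100 bins TSS→TES in its own
orientation (ties at bin edges floor to the lower bin), per-gene per-bin
counts are converted to RPKM with the gene's own bin length and the
sample's total filtered-read count, and bins are averaged across genes
(genes with no reads contribute zeros). Averaging RPKM per gene — rather
than pooling counts across genes before normalising — weights genes
equally; with pooled normalisation long genes would dominate, so profile
magnitudes are not directly comparable between the two conventions.

The genomic-location classifier paints per-base category maps and
resolves overlaps by priority promoter > 5′UTR > 3′UTR > exon > intron >
downstream > intergenic. Promoter and downstream spans are configurable
(default 1 kb each side of TSS/TES on the gene strand). All genes
participate here — the unit-gene length/gap selection applies only to
metaprofiles and ratios. Without feature substructure only genic vs
intergenic is reported.

Composition profiles give the read-length histogram (15–40 nt window,
extended as needed) and, for one length stratum (default 26 nt), the
frequency of each of the 16 dinucleotides at each start position; the
dipyrimidine sum per position is the damage-register enrichment curve,
which peaks 19–21 nt from the 5′ end.

## Quantification

With a constant spike quantity, the target/spike filtered-read ratio is
proportional to excised oligomers per cell. Relative repair is
RR% = 100 · (ratio_s/ratio_r) · (cells_r/cells_s). Uncertainty uses a
binomial bootstrap over read species labels (default 1000 replicates,
percentile interval) — the counting noise of the measurement itself; no
between-library overdispersion is modelled, because the generator has
none. Dilution series are fit through the origin (zero cells ⇒ zero
product); R² is uncentred for the through-origin model so exact
proportional data gives exactly 1, and a free-intercept fit is available
for diagnostics. The detection limit is the smallest RR% whose lower
bootstrap confidence bound clears the largest background RR% observed in
repair-null replicates, found by bisection (2% relative tolerance)
against a candidate sample constructed at the reference's spike depth.

RR% is invariant to proportional library subsampling in expectation, and
with calibrated knockouts the estimator recovers planted levels of 0.3%
and 0.05% of wild type within seed-level bootstrap CIs over 20 replicate
simulations.

## Numerical and design choices

- Coordinates are 0-based half-open throughout; strands are `+`/`−`.
- All randomness flows through `numpy.random.Generator`; compound
  experiments derive child seeds with `SeedSequence.spawn`, so a fixed
  seed fixes every output byte (asserted in tests).
- Problem sizes in the recovery experiments (600 kb target genome,
  damage rates 0.1–0.2, ~1.5–2.5 × 10⁴ filtered wild-type reads per
  library, 20 replicate seeds for quantification) were chosen so planted
  values are recovered with standard errors several-fold smaller than the
  quantities themselves while a full run stays around a minute.
- The location-recovery experiment scales the double-knockout-profile
  genotype up to its feasible library size; the intergenic share — the
  quantity under test — is invariant to that scaling.
- Degenerate inputs: empty gene sets, empty strata, zero spike reads, a
  zero-ratio reference, and infeasible gene packings or calibrations all
  raise explicit errors (or warn, for an empty composition stratum); a
  TS count with zero NTS reads reports an infinite ratio with a flag
  rather than raising.

## Known limitations

- The exact-match aligner and collision-free toy universe sidestep
  mappability, mismatches and multi-mapping heuristics of real aligners.
- Bernoulli damage ignores sequence-context and chromatin effects on
  photoproduct formation and repair.
- The bootstrap understates uncertainty for real replicate experiments,
  which carry biological and library-preparation variance the generator
  does not emulate.
- Profile magnitudes depend on the per-gene RPKM-averaging convention
  (see above) when compared against pipelines that pool counts first.
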