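# Methods

`recseq` simulates and analyzes restriction-digested extrachromosomal
circular DNA sequencing (REC-seq) in a yeast-like system. This note records
the models, the parameters that matter, and the numerical choices, so that
results are interpretable and reproducible.

## The selection protocol being modelled

Extrachromosomal circular DNA (eccDNA) is vastly outnumbered by linear
chromosomal DNA, and after plain exonuclease enrichment the circle pool is
dominated by two high-copy nuisance species: rDNA-derived circles (ERCs) and
the endogenous 2-micron plasmid. REC-seq removes them by splitting the
sample into three reactions, digesting each with a different restriction
enzyme chosen so that every nuisance circle carries at least one site for
*every* enzyme, then destroying all linear molecules with exonucleases (ExoV
degrades linear dsDNA from its ends and ExoI removes residual single
strands; covalently closed circles are resistant). Reuniting the reactions
leaves any circle that lacks a site for at least one enzyme, at a weight of
(site-free enzymes)/3 of its input. A panel variant swaps one enzyme for
SmaI, which cuts the rDNA repeat but not the 2-micron plasmid, deliberately
keeping the plasmid as a cross-sample normalization anchor.

`libsim.run_recseq` implements this literally at the molecule level: three
equal-weight aliquots, `rounds` (default 2, matching the two successive
overnight treatments) cycles of stochastic digestion (`p_cut`, default 1.0
— repeated enzyme additions imply near-complete digestion) followed by
exonuclease selection, then reunification. With complete digestion the
survival rule is exact and is cross-checked in the tests against brute-force
site enumeration.

## Synthetic reference

`genome.default_genome_spec` builds a ~160 kb miniature of the relevant
genome architecture (three linear chromosomes plus a 6.3 kb circular
episome carried as an extra contig; the episome is linearized for mapping):

| element | size | motif constraints |
|---|---|---|
| copper-array-like tandem array (chrI) | 2 kb unit x 9 | unit free of EagI/PvuI/PvuII/SmaI sites |
| rDNA-like tandem array (chrIII) | 3 kb unit x 5 | unit contains >= 1 site for each of the four |
| 2-micron-like episome | 6.3 kb circular | contains EagI/PvuI/PvuII sites, no SmaI site |
| subtelomeric circle donors | 4 kb at each chromosome end | EagI-free (survive one reaction in three) |
| retrotransposon-like regions (chrII) | 2 x 6 kb | EagI-free |
| ubiquitin-ligase-like locus (chrI) | 0.6 kb | excluded region (artifactual circle source) |

Background sequence is i.i.d. uniform ACGT from the spec seed; chance motif
occurrences outside declared constraints are allowed (realistic incidental
cutting). Constraint scrubbing treats units as circular, so forbidden
motifs are also absent across head-to-tail junctions of tandem copies and
across the junction of any circle excised on unit boundaries. Coordinates
are 0-based half-open throughout; BED follows BED convention. Recognition
sites are blunt single-position cuts at the motif start; overhang chemistry
is not modelled because only site presence and fragment lengths matter
downstream. All default motifs are palindromic, so a forward-strand scan
finds every site.

## Circle population dynamics in ageing mothers

Each division applies formation -> replication -> segregation in that
order (newly formed circles are immediately exposed to loss, the
conservative choice): `Poisson(lambda_form)` new circles, each circle
duplicating with probability `p_rep` (origin efficiency), each copy
retained in the mother with probability `p_ret` (asymmetric retention at
the nuclear periphery; daughters are non-replicative and not tracked).
Formation is Poisson rather than Bernoulli so rates above one per division
are expressible. With `a = (1 + p_rep) * p_ret` the exact expectation is

    E[c_t] = a^t c0 + lambda_form * a * (a^t - 1) / (a - 1)

(`c0 + lambda_form * t` at `a = 1`), which serves as the analytic oracle
for the simulator (checked to 3 standard errors over a parameter grid at
10,000 mothers).

Preset magnitudes are illustrative constants, not measurements; they were
chosen once so the qualitative regimes hold and are not tuned thereafter:

* native-array circles must sit in the sub-critical regime `a < 1`
  (replication efficiency below the segregation loss rate), so a marked
  circle with no formation decays to near-undetectability by division 24
  (`p_rep = 0.05`, `p_ret = 0.8`, `a = 0.84`, 24-division retention 1.5%);
* an added high-efficiency origin flips the same circle super-critical
  (`p_rep = 0.95`, `a = 1.56`: maintained and amplified), as does the
  rDNA-circle preset (`p_rep = 0.9`);
* transcriptional induction raises formation ten-fold
  (`lambda_form` 0.5 vs 0.05 per division), which is the planted fold the
  end-to-end analysis must recover;
* the retention-mutant preset halves `p_ret` to 0.5.

Because mean copy number at fixed division scales linearly with
`lambda_form` at equal `a`, the induced/uninduced abundance ratio equals
the formation-rate ratio exactly — a clean planted truth.

## Libraries and reads

Library pools are assembled per mode: `total` (chromosomes at unit weight
plus every circle at its abundance), `exo_only` (exonuclease selection with
no digestion), and `recseq` (the full protocol). In both selected modes
the chromosomal background leaks through at 0.1% of its total-mode weight,
mimicking incomplete exonuclease digestion. Fragments are drawn
proportional to weight x length (uniform shearing); insert lengths are
Normal(300, 60) clipped to [100, 700] bp (a fragmentase-plus-bead-cleanup
midrange window); mates are 75 bp; substitution errors at 0.1%/base;
qualities are constant. Circular molecules yield junction-spanning
fragments which the mapper cannot place — a realistic coverage dip at
circle junctions. Tandem-array circle junctions are unit boundaries and
therefore map seamlessly, as real homologous-recombination circles do.
Read names carry truth tags (`src=<species id>`) for validation.

Between-replicate biological variability is a gamma multiplier on each
species' abundance with CV 0.10, giving mildly over-dispersed counts across
replicates as real biological triplicates show.

## Mapping and deduplication

The built-in mapper seeds each mate with its first 31-mer (both
orientations) in an exact k-mer index, extends full-length allowing <= 2
substitutions, and keeps a pair only when both mates resolve at a unique
best score on one contig in convergent orientation with outer span
<= 2000 bp; pairs with an unmapped or ambiguous mate are discarded whole
(no singletons). Mates whose tied best hits all fall on one tandem array,
congruent modulo the unit, are assigned to the leftmost tied unit and
flagged `multi_unit` — array units are identical by construction, so
within-array signal is kept without claiming per-unit resolution. A
consequence is that array coverage concentrates into the first unit(s);
region-level quantities (fold enrichment, differential bins) are
unaffected because both samples concentrate identically. Reads with a
substitution error inside the 31 bp seed are lost (~3% per mate at the
default error rate), uniformly across species.

Deduplication is two passes, both first-occurrence-wins and idempotent:
(1) by exact sequence identity of the first 50 bp of both raw mates;
(2) by alignment position (contig, fragment start, fragment end) of the
proper-pair outer span. Outer-span keys (rather than per-mate coordinates)
are the single documented choice where conventions differ.

## Quantification and normalization

Deduplicated fragments are counted into 20 bp (profiles) and 100 bp
(statistics) bins tiling each contig from 0; a fragment increments every
bin its span overlaps; fragments touching excluded features (rDNA-like,
episome, the ubiquitin-ligase-like locus) are dropped entirely and bins
wholly inside exclusions are omitted. Within-library values are
fragments-per-million-included. For episome-sparing (SmaI-variant) runs,
cross-sample scaling uses

    SF1 = ((2u in total DNA) / (nonrepetitive chromosomal in total DNA)) / (2u in REC-seq)
    SF  = SF1 / SF1(control)

so the control sample is untouched (SF == 1 identically) and other samples
receive a minimal linear correction that preserves between-sample episome
differences. "Nonrepetitive" excludes all annotated repeat features, since
abundant circle species inflate even total-DNA counts at their loci. Fold
enrichment over a region is the ratio of mean per-bin values with a 0.5
pseudocount per bin on both sides (needed for zero-count bins; it biases
folds toward 1 when per-bin counts are small, so fold estimates are read
from well-covered regions).

## Differential enrichment

Counts on the 100 bp grid are compared between conditions with a
conditional negative-binomial exact test: library sizes equalized by
median-ratio scaling (integer-rounded — a documented approximation), a
common dispersion estimated as the median of per-bin method-of-moments
values `max(0, (s^2 - m)/m^2)` over bins with mean >= 5 (pooled
within-group variance), then each bin's group-A total tested against its
conditional law given the bin total (the negative-binomial mean parameter
cancels under conditioning; with dispersion 0 the law is binomial, and the
tests cross-check that path against an independent enumeration and
`scipy.stats.binomtest`). Two-sided p-values sum the probabilities of
splits as or less likely than observed. Default is no multiple-testing
correction at alpha 0.05 (Benjamini-Hochberg available). This estimator
and test are a defined stand-in for external count-model packages whose
internal settings are not reproducible here; parity of p-values with any
external tool is not claimed — the scientific output is the
locus-specific enrichment flag.

Known calibration property: with 3+3 replicates the pooled within-group
variance has 4 degrees of freedom and the *median* method-of-moments
dispersion runs ~16% low (median of chi-square_4/4 is 0.84), so the
pipeline with estimated dispersion rejects ~7% of null bins at nominal 5%.
At the true dispersion the exact test is correctly calibrated
(5.0% +/- 1% measured at 10,000 null bins). The estimator is kept in its
simple defined form; users needing strict nominal control should use the
BH flag or supply a known dispersion.

## Problem sizes and reproducibility

The shipped study conditions are 2 conditions x 3 replicates x 200,000
pairs per REC-seq library on the ~160 kb reference, with one 50,000-pair
exonuclease-only library per condition; the episome-sparing normalization
demonstration uses 40,000-pair libraries. Calibration simulations use
10,000 null bins and 1,000 planted bins; ageing checks use 10,000 mothers
per grid point. A full run completes in a few minutes on one CPU. One
master seed drives every stage through derived `SeedSequence` streams
(`pipeline.stage_seed`); identical configuration and seed reproduce
byte-identical artifacts (gzip streams are written with zeroed
timestamps), which the manifest checksums verify.

## What the simulation does and does not show

The generator reproduces the *logic* of the protocol — selection by site
content, anchor-based scaling, locus-specific enrichment against a stable
background — with known truth, so passing tests demonstrate that the
analysis recovers planted signals under the stated noise model. It does
not model: PCR amplification bias or chimeras, base-quality structure,
adapter read-through, GC or mappability bias, partial/star enzyme
activity, nicked-circle topology classes, cell-to-cell abundance
heterogeneity beyond the gamma replicate model, or the true sequence of
any real genome (the reference is random sequence with the relevant repeat
architecture, ~80x smaller than a yeast genome — composition fractions
such as "% reads from the episome" therefore scale differently than in
real libraries). Conclusions about real data quality, mappability or
contamination require real-data controls.
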