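# Methods

`ieskit` models and measures programmed DNA elimination in *Paramecium*-like
genomes: the precise excision of short, TA-bounded internal eliminated
sequences (IESs) from the developing somatic macronuclear (MAC) genome, its
failure modes, and the small RNAs that guide it. Because the real analyses
run on deep sequencing of knockdown cultures, the package pairs every
analysis with a ground-truth simulator so that each estimator can be
validated against known parameters.

## Coordinate and length conventions

All intervals are 0-based half-open internally; GFF3 output is 1-based
inclusive. An IES is stored with **both** boundary TA dinucleotides
(`sequence`, length `L + 2`) but reported with the **one-TA length** `L`:
excision deletes `[start, start + L)` from the MAC+IES scaffold, so the
right-hand TA remains in the MAC as the junction TA. A 28 bp IES therefore
has a 30 bp stored sequence. This makes excision a pure deletion and the
excised genome byte-identical to the MAC reference, which the simulator
asserts per scaffold.

## The synthetic dataset

The generator (`ieskit.simulate`) emulates the study conditions rather than
any particular sequencing run.

**Genome background.** MAC scaffolds are i.i.d. sequence with an AT-rich
composition (A = T = 0.35, C = G = 0.15), in line with the strong AT bias
of ciliate somatic genomes. IESs are inserted at randomly chosen TA sites
with a minimum spacing (260 bp default) so that a fragment rarely spans two
IESs.

**IES lengths** (one-TA) follow a discretized Gaussian mixture with peaks
every 10 bp from 28 bp (12 peaks, per-peak SD 1.5 bp, geometric weight
decay 0.6), a multiplicative depletion (factor 0.2) of the "forbidden"
38–46 bp window, and a 1% exponential tail (scale 400 bp) out to 5 kb;
lengths are truncated below at 26 bp. The real distribution fixes the peak
positions, the forbidden window and the 26 bp minimum; the per-peak spread,
weight decay and tail law are not published, so they are explicit
configuration knobs with the above defaults chosen to reproduce the
qualitative shape (dominant 28 bp mode, visible periodicity to ~140 bp,
rare long IESs).

**IES ends.** The sequence starts and ends with TA; the three sub-terminal
bases inward of each TA are drawn from a length-stratified table (short
stratum ≤ 36 bp strongly TAG-like — T at position 1, A at 2, G at 3 — and a
longer stratum shifted toward C at position 1, i.e. TACAG-like ends),
mirroring the measured length dependence of end-base preferences. The right
end is generated in reverse-complement orientation so that one table serves
both ends. Interior bases are i.i.d. from A = T = 0.4, C = G = 0.1, the
composition of interior IES positions more than 10 bp from a TA, which is
also the default logo background.

**DNA reads.** Fragment starts are uniform over MAC coordinates; walking
rightward, each IES junction encountered is expanded to the retained form
independently with probability ρ (the IES's true retention fraction), so
both mates of a fragment share one molecule state. Insert lengths are
Normal(300, 30) truncated below at twice the read length (100 nt). The
`coverage` knob is mean per-base read depth: `coverage × L / (2 ×
read_len)` fragments per scaffold. Base-call errors default to 0 so
truth-based oracles are exact; a uniform substitution rate is available.
Ground truth is written as coordinate-sorted SAM against the MAC+IES
reference (excised-form junction reads carry a deletion CIGAR over the IES)
and, for reads composed purely of MAC-destined bases, against the MAC
reference (contiguous there even across excised junctions). Reads that
start downstream of a retained IES never contain it; consequently coverage
inside long retained IESs comes only from fragments entering from the left.
This asymmetry does not affect boundary counting (below).

**Small RNAs.** scnRNAs are fixed 25 nt windows uniform over the MAC+IES
scaffolds, so a fraction spans IES boundaries. iesRNA lengths are a
discretized Gaussian over 21–31 nt with mode 27 (SD 2), truncated per IES
so a read never extends past the IES; starts are a 50/50 mixture of uniform
placement and placement within 5 nt of either end (the end-accumulation
tendency; the true proportion is unpublished and configurable). Per-IES
iesRNA counts are multinomial with weights `L × (0.25 + 0.75 ρ)`: abundance
increases with retention, the generative analogue of iesRNAs being produced
from excised-and-transcribed copies. Reads from IESs whose full sequence is
duplicated elsewhere are flagged non-unique. Idealized exact-match
"alignments" are emitted for the two-stage assignment: reads touching no
IES base are written (coordinate-lifted) against MAC, the rest against
MAC+IES.

**Planted excision errors.** Cryptic deletions remove a TA…TA span (26–30
bp default) away from any junction; alternative-boundary deletions run from
an annotated junction TA to a nearby downstream TA. Each planted deletion
is emitted in several read pairs whose CIGAR places the deletion at its
left-shifted (aligner-style) position, while the truth records the
canonical TA-bounded placement.

**What the simulator does not model:** PCR duplicates, GC bias, indel
sequencing errors, old-MAC carry-over, copy-number differences, imprecise
elimination with chromosome fragmentation, and sRNA contaminant classes.
Passing tests therefore demonstrate estimator correctness under clean
sampling, not robustness to library artifacts.

## Retention scores (IRS)

For each IES, reads containing the IES sequence across an end (IES⁺) and
reads spanning the macronuclear junction TA (IES⁻) are counted and

    IRS = IES⁺ / (IES⁺ + IES⁻).

Reads are counted **only at ends/junctions** (never by interior coverage),
each read at most once per IES, and only pairs in which both mates map
uniquely (mapping quality > 0) are used. A crossing requires at least
`min_anchor` = 5 contiguous aligned bases on each side of the end; the
anchor must be ≥ 3 so the two shared junction-TA bases can never satisfy
the inner anchor of the right end on their own. On MAC+IES alignments the
excised form is recognized as a deletion shift-equivalent to the IES
excision interval (the equivalence is checked against the reference, so
aligner left-shifting is harmless).

`compute_irs` defaults to counting retained-form reads at the **left end
only**. The fragments that witness the left end of a retained molecule are
exactly the fragments that would witness the junction had the molecule been
excised, so conditional on being informative a read is a Bernoulli(ρ) trial
and IRS is an unbiased estimator of ρ with exact binomial sampling
behaviour. Counting both ends (`end_policy="both"`) uses up to twice as
many reads but overweights the retained form for long, well-covered IESs
(the retained molecule offers two crossing windows against the excised
form's one), inflating IRS toward the middle of the range. The classifier
itself (`classify_read`) recognizes either end by default.

A hard limit worth knowing: with n informative reads, the correlation
between IRS and a Uniform(0,1) ρ is √(n/(n+2)), and n cannot exceed the
local read depth (every informative read covers the junction base). At 50×
coverage n ≈ 45 and r(IRS, ρ) ≈ 0.98; pushing r above 0.99 requires ~100
informative reads per IES, i.e. ~110× coverage, regardless of counting
rule.

## TA-indels

Within-read deletions of 5 bp–10 kb against the MAC reference are
extracted, realigned over their full shift-equivalence class, and kept when
some placement is TA-bounded. The default rule is the literal one — the
deleted span starts with TA and ends with TA — with a stricter
`rule="junction"` variant (span starts with TA and the two bases after the
span are TA, exactly mirroring IES excision chemistry) available. The
canonical placement is the leftmost qualifying one; when no placement
qualifies the leftmost equivalent placement is returned flagged non-TA, so
realignment is a pure function of the equivalence class. Deletions whose
deleted span contains N are excluded. A deletion with a canonical endpoint
at an annotated junction (start at the junction T, or end at the junction
TA's end; tolerance 0 by default) is classified alternative-boundary,
otherwise cryptic. Residual IES retention is not a deletion against MAC and
is measured by the retention module instead. Rates are reads-with-TA-indels
per million mapped reads; identical canonical deletions are merged only for
the catalog.

## Quasi-IESs

For a 5-bp end motif m starting with TA (TATAG, TACAG, TATTG in practice),
a quasi-IES is a segment with m at `[i, i+5)` and revcomp(m) at `[j−5, j)`;
its one-TA length is `j − 2 − i` so the trailing TA of the inverted repeat
plays the junction role. The scan indexes motif occurrences and pairs them
within the length window (26–150 bp default), reporting overlapping and
nested hits; it is strand-asymmetric by construction, and scanning the
reverse complement yields the mirrored set. Expected counts come either
from the independent-site closed form (genome base composition) or from
dinucleotide-preserving shuffles of each scaffold (random-Eulerian-walk
shuffle, seeded); observed/expected per length is the depletion readout.

## End-base analytics and logos

Sub-terminal positions 1–3 (position 1 adjacent to the TA) are tallied per
IES length or per retention bin; the right end is read on the reverse
complement when both ends are pooled, and the default is the left end only
(one end suffices and keeps groups independent). Binned series are smoothed
with an EWMA using α = 2/(span+1), s₁ = x₁. Logos are relative-entropy
(KL) logos against the non-uniform interior background: per column, total
information Σ p·log₂(p/q) clamped at ≥ 0, letter heights p × total. This is
the only logo form that honours a non-uniform background; letters rarer
than background shrink the stack through the total rather than plotting
negative heights. Two-sample logos test each (position, base) indicator
with a Welch t-test between groups and Bonferroni-correct by positions × 4;
the test variant and family size are configurable since the original choice
is not published. Retention-trend profiles restrict to ~10 bp length
windows around one length peak (removing the length–retention confound, and
the mean length is checked to be flat across bins on simulated data) and
report trends only within 2 SD of the mean IRS.

## sRNA densities

Reads are assigned MAC-first (a read matching the somatic genome is somatic;
only the remainder is mapped to MAC+IES), keeping only single-location
matches; per-length totals over 15–35 nt (read inclusively — the bounds
are configurable) normalize densities per million. A 27 nt read counts
toward an IES when fully contained in its interval; a 25 nt read when it
overlaps by ≥ 1 base (boundary-spanning scnRNAs); both policies are
configurable since the original containment rule is unstated. Density is
count per IES base. Profiles are per-0.01-IRS-bin medians, EWMA span 5,
trimmed at 2 SD of the mean IRS, with densities above 0.4 excluded from
the profile (kept in tables). The flat-scnRNA check is run on an
iesRNA-free simulation — the generative analogue of a DCL5 knockdown,
which is also how the real analysis isolates scnRNAs in the 25 nt class —
because 25 nt iesRNAs otherwise re-introduce the retention association.

## Pair correlations

Identical-IES pairs are groups of IESs with byte-identical full sequence;
pairs whose flanks (one read length each side, default 100 bp) are also
identical are excluded as indistinguishable at the read level. Score
filters (drop zero scores, scaffold-length threshold, score-versus-control
ratio) mirror common practice and are off or permissive by default; the
ratio filter's direction is ambiguous in the field's usage, so the
threshold is a plain `score ≥ ratio × control`. Adjacent pairs take IESs
separated by exactly k intervening IESs with a genomic gap cap; a seeded
random-pair generator provides the null. Correlations are Pearson and
Spearman with two-tailed p-values; zero-variance margins return NaN with
the sample size.

## Problem sizes and numerical choices

Validation runs use desk-scale genomes (tens of kb, hundreds of IESs,
25–50× coverage, 10⁴–10⁵ sRNA reads), chosen so every distributional check
has enough events for its stated tolerance while the full suite stays
fast. Frequency tables assert to within multinomial sampling error; logo
closed forms to 1e-9; EWMA to 1e-12; set-valued results (quasi-IES scan,
TA-indel recovery) exactly. All randomness flows through
`numpy.random.default_rng` seeded from a single configuration seed (reads,
sRNAs and planted errors use fixed offsets of it), and identical
configurations produce byte-identical outputs, which the pipeline manifest
records as per-file checksums.
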