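# Methods

`phagetir` quantifies translation-initiation signals and codon adaptation
in bacteriophage protein-coding genes and compares groups of phage
genomes (clades, or virulent vs temperate lifestyles). This note records
the models and conventions the package implements, the choices made where
the design was genuinely open, and what the synthetic-data tests do and
do not establish.

## Gene extraction and analysis windows

Genomes are read from GenBank flat files (or FASTA plus a gene-coordinate
TSV). Coordinates are 1-based inclusive; offsets around the start codon
use the convention that -1 is the base immediately 5' of the start codon
and +1 its first base, with no position 0, so the -4..+37 window spans
4 + 37 = 41 nt. Three windows are extracted per CDS: the upstream 30 nt
(SD search space), the upstream 40 nt, and -4..+37. All analysis is done
on the RNA alphabet (T converted to U on extraction); input may be DNA or
RNA. Only CDSs of at least 33 codons are analysed, which damps
stochastic fluctuation in per-gene codon usage.

Conventions for cases the window geometry leaves open:

* Circular genomes wrap windows across the origin. On linear contigs a
  window running off the end is truncated; truncated windows are excluded
  from folding statistics, because the MFE of a shorter window is not
  comparable to full-length ones, and a gene with a truncated or
  ambiguous upstream is excluded from both the numerator and denominator
  of P_SD.
* Compound (join) CDS locations are anchored at the 5'-most exon's
  boundary for all windows — the initiation context is defined at the
  start codon — while the spliced sequence is used for codon counts.
* Windows containing ambiguity codes (N etc.) exclude the gene from the
  SD and MFE computations for that window.

## SD detection and D_toAUG

The anti-SD is the free 3' tail of the SSU rRNA; the default is the
canonical 13-nt E. coli 16S tail `GAUCACCUCCUUA` and it is a required,
overridable input for other hosts. The detector enumerates every
*maximal* perfect antiparallel Watson–Crick duplex (A:U, G:C; no G:U
wobble, which is off by default because the operational definition
requires perfect pairing) of length >= 4 between the upstream 30 nt and
the tail. Maximality means a 6-bp duplex is one match, never also its
nested 4/5-mers — the "consecutively matched sites" statistic counts the
full run. The positional score of a duplex is

    D_toAUG = tail_overhang + L + spacer,

the distance from the rRNA 3' terminus to the first base of the start
codon with the duplex formed. A gene has an SD when some duplex has
D_toAUG in the configured window (default 10..20, where the empirical
distribution of duplex positions is concentrated with mode 13; the
window can be disabled for position-free host-gene scans). P_SD is the
percentage of genes with an SD; M_SD averages the *best* duplex length
(longest; ties broken by |D_toAUG - 13|, then 5'-most) over SD-containing
genes. Averaging best-per-gene rather than all matches is a choice; the
longest duplex is the standard strength proxy, and per-genome M_SD values
around 6 imply run lengths, not averages over nested fragments.
D_toAUG histograms and tail-site participation counts are computed over
*all* maximal matches, not best-per-gene.

## Folding stability

MFE of the upstream-40 and -4..+37 windows is computed with the
ViennaRNA nearest-neighbor model at 37 degC, lonely pairs disallowed,
and no G/U pairs closing helices (`noLP`, `noGUclosure`). Values are
engine-native kcal/mol and are used comparatively only; sequences that
form no stable structure score 0. Per-genome summaries are unweighted
per-gene means over genes with complete, unambiguous windows.

The SD-substitution control replaces a 6-mer in each window with a
canonical SD motif (AGGAGG), refolds, and tests the paired delta-MFE
against zero. The substitution site is the best SD location when it lies
inside the window, else the central 6-mer — the control asks whether SD
presence per se changes stability, so the SD site is the natural target;
the -4..+37 window, which contains no upstream SD, always uses its
centre. A paired delta of exactly zero across genes (e.g. replacing the
motif by itself) is reported as t = 0, P = 1.

## Codon adaptation

RSCU is observed codon count over the expected count under uniform
synonym usage. Synonymous families are partitioned either per amino acid
(method 1) or with the sixfold Leu/Ser/Arg families split into their
fourfold + twofold subfamilies (method 2, the default for weights):
CUN+UUR, UCN+AGY, CGN+AGR.

The I_TE weights correct host highly-expressed-gene (HEG) usage for
background mutation bias. Within each method-2 subfamily:

    E_i  = background frequency of codon i's third nucleotide,
           renormalised over the subfamily
    raw_i = P_i / E_i          (P_i = observed HEG proportion)
    w_i  = raw_i / max(raw)    so 0 < w_i <= 1, max = 1 per subfamily

Background frequencies default to third-position frequencies of the host
coding set and are configurable. Unobserved HEG codons are floored at a
pseudo-count of 0.5 so a missing codon cannot zero a geometric mean.
I_TE of a gene is the geometric mean of w over its codons with defined
weights; the start codon (fixed AUG), stops, and single-codon families
(Met, Trp) carry no signal and are excluded. This weight formula is a
reconstruction from the index's published description ("RSCU corrected
for mutation bias" with method-2 family splitting); scores are
internally comparable but not guaranteed bit-identical to other
implementations. Classical CAI weights (the same construction with a
uniform background) are provided as a comparator, and phage–host RSCU
correlations (r_RSCU) can be taken against host all-gene RSCU, HEG RSCU,
or the w vector.

## Statistics

All tests are two-tailed. Two-sample t statistics use the A - B sign
convention; Welch degrees of freedom are Welch–Satterthwaite and are also
reported rounded to the nearest integer, the customary printed form. The
variance-ratio F puts the larger variance in the numerator and doubles
the smaller tail probability (comparative reports sometimes print the
one-sided tail for this test; the statistic is unaffected). The 2x2
chi-square is Pearson's without Yates continuity correction. Group means
are unweighted across genomes; for P_SD the gene-weighted pooled
proportion is emitted alongside, since published per-clade values can be
either flavour — both are reported and neither silently preferred.

Independent contrasts follow Felsenstein's recursion: at each internal
node of the (rooted, bifurcating; polytomies are resolved into
zero-length bifurcations) tree, the contrast is
(x_left - x_right)/sqrt(v_left + v_right), the ancestral value is the
variance-weighted mean, and the ancestral branch variance is inflated by
v_l v_r/(v_l + v_r). Contrast signs depend on arbitrary child order, so
the two-trait correlation is computed through the origin,
r = sum(xy)/sqrt(sum(x^2) sum(y^2)), with df = (number of contrasts) - 1
and t = r sqrt(df/(1 - r^2)). On a star tree with equal branch lengths
this reduces to the ordinary correlation of tip values, which the tests
exploit as an analytic limit.

## Synthetic data: what it emulates and what it does not

The generator plants, per gene and with probability `p_sd`, an SD whose
duplex pairs the tail segment ending 2 nt from the 3' terminus (the aSD
core), with duplex length and D_toAUG drawn from configurable
distributions (defaults: lengths peaked at 6, D_toAUG a discrete
triangle on 10..20 with mode 13). Backgrounds are rejection-sampled to
contain no spurious >= 4-nt tail complement when `clean_negative` is set
(about half of random 30-mers qualify, so this is cheap), and a plant
whose flanks accidentally extend the duplex is resampled, so the planted
(L, D_toAUG) is exactly recoverable. Flank composition is i.i.d. at the
requested GC, which monotonically controls folding stability. Codons are
drawn from a mixture of ground-truth weights and uniform synonym choice.
The default two-clade parameter sets mirror the observed contrasts: A =
8 genomes x 60 genes, p_sd 0.94, SD lengths {5: 0.1, 6: 0.9} (mean 5.9),
flank GC 0.35, selection 0.85; B = 16 x 60, p_sd 0.68, lengths
{4: 0.2, 5: 0.6, 6: 0.2} (mean 5.0), flank GC 0.50, selection 0.25.

Real initiation regions are not i.i.d. in composition, carry overlapping
genes, operonic structure, leaderless transcripts, and SDs whose
positions co-evolve with structure; the generator has none of that. A
passing recovery test therefore shows the pipeline measures what it
claims on data satisfying its assumptions — it does not validate the
biological conclusions on real genomes, for which the per-genome tables
of published scans are the reference points.

## Problem sizes and numerics

The planted-clade recovery check uses 50 replicates of the full 24-genome,
60-gene-per-genome design (about 150 s, single CPU); the
Brownian-motion check uses 24 tips and 200 replicates; matcher
equivalence uses 1000 random upstream/tail pairs. Folding a 40-mer costs
well under a millisecond, so all sizes are chosen for statistical
resolution rather than cost. Floating-point conventions: statistics are
compared to independent recomputations at 1e-8..1e-12; published
statistics recomputed from tables printed at 3-4 decimals are asserted
to a few parts in 1e-3 (the rounding of the inputs propagates into the
third decimal of a t statistic). Summary TSVs are re-read with
round-trip float parsing so a report recomputed from its own emitted
tables is bit-identical.

## Known limitations

* Folding-engine dialect: printed MFE means from other engine versions
  can differ in the second decimal; MFE values are comparative, and the
  engine and flags are echoed into outputs for provenance.
* The I_TE weight formula is an interpretation (see above).
* Methods 3–4 of the family-splitting scheme, tRNA-based indices (tAI),
  partition-function folding, and lifestyle classification itself are out
  of scope; lifestyle/clade labels are user-supplied metadata.
* M_SD is undefined (reported missing) for genomes with no SD-containing
  genes.
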