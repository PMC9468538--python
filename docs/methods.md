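# Methods

## The problem

Genome-wide association studies (GWAS) of durum wheat quality traits each
report a handful of marker-trait associations (MTAs) in their own coordinate
systems, panels, and trait vocabularies. `mqtlhot` pools such studies into a
single meta-analysis: every MTA is placed on one consensus genetic map, the
local density of positional evidence is summarized by a per-cM overview index,
dense regions are called as QTL hotspots, the practically useful subset is
selected as "breeding QTL", and the hotspot markers are traced into other
grass genomes (*Brachypodium distachyon*, rice, maize) to call conserved
ortho-MQTL regions.

## Model and procedure

### Positional uncertainty and the overview index

An MTA with a 95% confidence interval of width CI (cM) is modelled as a
Gaussian positional distribution centred on its projected position with
standard deviation

    s = CI / 3.92        (3.92 = 2 x 1.96),   s^2 = (CI / 3.92)^2.

The chromosome is discretized once, into half-open 1-cM bins [k, k+1) with
the left edge at 0. The overview index of a bin is the total probability mass
the MTAs of that chromosome place in it:

    u_k = sum_i [ Phi((k+1 - mu_i)/s_i) - Phi((k - mu_i)/s_i) ],

with Phi the standard normal CDF. Mass beyond the chromosome ends is
truncated, not renormalized (flagged in output), so each MTA contributes at
most 1 and the genome-wide mean of u is close to N_MTA / total map length —
for 395 MTAs on a 2,630-cM map, 0.150. The hotspot threshold is this
empirical mean; the *high* threshold is five times the mean (0.75 at paper
scale). The number of contributing studies is carried in the configuration
and reported, but does not scale u.

### Peaks, hotspots, members

A peak is a local maximum of u restricted to bins at or above the threshold;
a plateau of equal values counts once, at its leftmost bin. Each peak carries
its contiguous supra-threshold run. Runs on one chromosome that touch,
overlap, or are separated by at most `merge_gap_cM` (default 2) empty bins
merge into one hotspot whose genetic CI is the merged run span. Members are
the MTAs whose symmetric CI interval (mu +/- CI/2) overlaps the hotspot CI;
`pve_mean` averages the members that report a PVE. Ids run left-to-right
within chromosomes ordered 1A..7B, sequentially genome-wide.

### CI imputation and projection

MTAs lacking a CI (203 of 395 at paper scale) receive the per-chromosome LD
decay distance as a surrogate CI width — interpreted as the *full* width,
since that is what the standardization consumes — placed symmetrically about
the position. Projection onto the consensus map is homothetic: a position is
rescaled linearly between the nearest flanking markers shared by both maps;
beyond the shared span the nearest interval's ratio is extended and the
record flagged `extrapolated` rather than dropped, preserving MTA counts.
Markers present by name on the consensus map are placed by lookup (`identity`
flag) — the dominant case, because the pooled studies used SNP panels largely
shared with the consensus map. CI widths are rescaled by the same local
ratio as the position and clamped to the chromosome.

Genetic-to-physical conversion interpolates Mb over cM piecewise-linearly
through per-chromosome anchor tables for each reference assembly ("Svevo",
"CS"). Anchor inversions (non-monotone Mb) warn but interpolate, since real
maps contain them.

### Breeding selection

A hotspot is a breeding QTL iff its physical CI on the primary assembly
(Svevo) is narrower than 20 Mb and either (a) it has >= 5 member MTAs with
mean PVE >= 0.04, or (b) 3-4 members with mean PVE > 0.1. Hotspots with
fewer than 3 members, or whose members all lack a PVE, are never selected.
The >= in branch (a) is deliberate: the published selected-hotspot table
contains a 5-member hotspot with mean PVE exactly 0.04.

### Bin distributions

Each chromosome is cut into five equal-length segments on the genetic and on
the physical axis; every hotspot is placed once per scale by its CI midpoint.
Because recombination is suppressed around the centromere, a distribution
that is flat in cM concentrates in the outer physical fifths; the report
carries both distributions and their per-bin difference.

### Ortho-MQTL calling

Marker sequences aligned against each target genome at three stringency
rounds (high/medium/low; the aligner itself is out of scope — SAM files are
consumed) are filtered by aligned-length fraction strictly > 0.60 of the
marker length and MAPQ strictly > 10. Per marker and genome the
highest-stringency round with a surviving hit wins; within it the unique
best-MAPQ primary hit is kept, and an equal-MAPQ tie across distinct loci
drops the marker as ambiguous. A hotspot's marker hits on one target
chromosome are clustered by single linkage at `max_gap_bp` (default 5 Mb);
clusters with >= `min_markers` (default 2) distinct markers become
ortho-MQTL regions. Genes intersecting a region (half-open overlap) are
looked up in the genome's GFF3 annotation. Internal coordinates are 0-based
half-open throughout; SAM's 1-based input and gffutils' 1-based inclusive
queries are converted at the boundary.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the published study conditions: 10 studies with the
published panel sizes (1,598 genotypes) and per-study MTA counts (395 total);
14 chromosomes totalling 2,630 cM; CI widths log-normal(mu=0.8957,
sigma=0.7480), fitted exactly to the two published quantiles (83% <= 5 cM,
97% <= 10 cM; implied mean 3.24 cM against the published average 3.3),
truncated to the published 0.1-43 cM range; 203/395 CIs masked missing; PVE
Beta(0.730, 11.095), fitted exactly to 79% < 0.1 and 95% < 0.2; trait YPC at
24%. Positions are a mixture of 25 planted Gaussian clusters (sd 1.5 cM,
>= 20 cM apart, >= 10 cM from ends) and 5% uniform background; the planted
clusters are the ground truth for recovery scoring. A background share this
small reflects a meta-analysis database dominated by replicated, clustered
associations; isolated MTAs with very small CIs can legitimately exceed the
high threshold on their own, so a heavy background would make single-MTA
hotspots common. Anchor tables follow a tanh curve (steepness 8) that sends
~83% of genetically uniform mass into the outer physical fifths, emulating
pericentromeric recombination suppression.

Synteny fixtures plant regions per hotspot with genome probabilities 0.9
(bd), 0.6 (os), 0.15 (zm) — mirroring the published skew of ortho markers —
plus decoy hits sitting exactly on each filter boundary and equal-MAPQ
double hits that must be dropped as ambiguous. Read sequences are
placeholder homopolymers with CIGAR-consistent lengths.

The generator does **not** emulate LD structure, genotype data, marker
density variation, study-specific map distortions (all synthetic MTAs carry
consensus-map markers, so projection is identity in the default pipeline;
anchor-based projection is exercised by constructed maps in tests), trait
correlations, or real sequence content. Passing tests therefore demonstrate
the correctness and calibration of the *method*, not the reproduction of the
published hotspot list, which depends on the unpublished per-MTA supplement.

## Numerical choices and degenerate inputs

- Coordinates stay continuous until reporting (2 decimals); the 1-cM grid
  discretizes exactly once.
- Truncated Gaussian tails are not renormalized; the mass-conservation test
  applies to MTAs >= 4 s from chromosome ends (|sum u - N| < 1e-4 N).
- Plateaus in peak detection break ties to the leftmost bin.
- A CI that straddles a chromosome end after projection is clamped; the
  width shrinks and the record is flagged.
- LD-decay CIs are assumed symmetric about the MTA position (the source
  material does not say); noted in output metadata via `ci_source`.
- Zero-length markers in SAM input are dropped with a warning; unknown
  chromosomes in GFF3 queries return empty with a warning.
- `merge_gap_cM = 2`, `max_gap_bp = 5e6`, `min_markers = 2` are exposed in
  configuration: the published analysis states that peak merging and synteny
  clustering occurred but not their parameters.

## Problem sizes in the default test run

Unit and property tests run on the 395-MTA default database (generated in
well under a second); calibration and recovery properties pool 20 seeded
replicates each. The full suite completes in a few seconds on one CPU; the
acceptance script generates one paper-scale database and finishes in about a
second.

## Known limitations

- The hotspot counts of the source analysis (peak counts at the two
  thresholds, the 92-hotspot set, per-chromosome MTA counts) are not
  reproducible without the unpublished supplementary MTA table; the package
  validates the published aggregate tables it ships and the method's
  invariants instead.
- Classical likelihood-based meta-QTL clustering (Goffinet-Gerber style
  model selection) is out of scope; hotspots here are threshold crossings of
  the overview index.
- Orthology is positional only: clustered alignments, not gene-tree
  inference.
- The merge step's "quality of the markers" redundancy criteria are not
  defined in the source material; only alignment-level criteria (round,
  MAPQ, primary/secondary, locus ties) are implemented.
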