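# Methods

## The model

A lineage starts from an intact diploid G1 cell on a declared karyotype.
One fusion event creates a dicentric configuration; everything downstream is
a sequence of typed stochastic events applied to derivative chromosomes
(ordered paths of oriented reference segments with haplotype labels).

**Fusion.** Three topologies, drawn from `p_fusion_type` (default
0.4 : 0.4 : 0.2):

- *sister* — the two sister chromatids of one homolog fuse at their q
  termini, giving a single mirror-symmetric dicentric;
- *non-sister* — one chromatid of each homolog fuses; the free sister
  chromatids segregate to whichever daughter lacks that haplotype's
  centromere;
- *chromosome-type* — two different chromosomes fuse before replication, so
  replication yields a pair of identical dicentrics whose kinetochores
  attach in antiparallel orientation.

The chromosome-type default (0.2) reflects the observed 4 of 20 daughter
pairs with internal-segment exchange.

**Bridge lifetime.** Exponential with median 10 h, right-censored at the
24 h cell cycle (censoring probability 2^(−2.4) ≈ 0.19). Censored bridges
persist into mitosis; their descendants micronucleate at the higher
"unbroken" rate (0.65 vs 0.52).

**Breakage.** The break position is uniform on the inter-centromere path,
excluding a `min_break_offset` = 2.5 Mb window around the fusion junction.
The exclusion is an empirical calibration: every observed daughter pair
showed a reciprocal exchange above the 2.5 Mb detection scale, which a
fully uniform law on a 40 Mb desk genome would violate ~14% of the time
(on a full-size chromosome the same exclusion is a ~2% correction, so this
is a deliberate desk-scale compensation, not new biology). Chromatid-type
dicentrics yield reciprocal *terminal* gain/loss (Type 1); the antiparallel
chromosome-type pair breaks at two positions (≥ 2.5 Mb apart) and yields
reciprocal *internal* gain/loss (Type 2). An exchange whose path interval
straddles the fusion junction is genomically terminal on each partner
chromosome and is labelled accordingly.

**Local fragmentation** (probability 0.5 per breakage; the two modes are
reported without frequencies, so they are weighted equally). The zone
extends from the break *away from the fusion point* — i.e. into the flank
that ends up in the loss daughter — so retained fragments appear as islands
inside a larger region of complete haplotype loss, which is where such
fragments are observed. Fragment count is 1 + Poisson(3); lengths are
log-uniform on [100 kb, 5 Mb] (both stated modeling assumptions). Each
fragment is retained with probability `replicated_fraction + retention_floor`
= 0.27 + 0.25: the 0.27 is the measured fraction of bridge DNA replicated in
interphase, implementing the bias toward segmental loss from
under-replication; the floor is a free choice fixed at design time so that
roughly half of fragments survive. Retained fragments are end-joined in
uniformly random order and orientation onto either daughter's stub
(producing exactly n junctions for n fragments); non-retained fragments are
lost, or circularized with probability `p_circularize_fragment` (default 0,
the extrachromosomal-circle option).

**TST chains** (probability 0.2 per breakage, matching 4/20). Chain
generation draws 2–10 source hotspots (each a 1–10 kb window, mostly inside
the fragmented zone, occasionally on an intact chromosome), with
~Poisson(10) breakpoints per hotspot; hotspot count is capped below the
planned insertion count so that hotspots are reused, as in the observed
chains. Insertion lengths are log-normal with median exactly 183 bp and
sigma 0.65 (≈95% of mass in [50, 1000] bp). Joins between chain members
follow the observed 5 : 2 : 6 blunt : microhomology : untemplated mix;
microhomology joins are realized in sequence by placing the next source so
its upstream flank matches the previous insertion's tail, so a classifier
reading only the sequence recovers the planted class. A simple-break draw
that also draws TST is upgraded to single-fragment fragmentation (TST
repair needs fragmented ends), keeping the net TST rate at `p_tst`.

**Kataegis** attaches to half of TST-positive events (two of the four TST
pairs showed it). A cluster is ≥ 6 substitutions (6 + Poisson(4)), all
C→T/C→G at TpC sites of the lazy reference on one strand, with
inter-mutation gaps exponential (mean 300 bp) snapped to the next TpC site.

**Mitotic second wave.** A cell carrying a broken-bridge stub (or a
micronuclear chromosome — same contract) suffers Poisson(8) extra
breakpoints confined to the terminal 5 Mb window behind the break
(`stub_region_bp`, a stated assumption for the under-replicated region),
with fragments re-ligated or lost as above. Both daughters inherit the
re-ligated product; complementary partitioning of second-wave fragments
between daughters is not modeled.

**Mis-segregation.** Bridge-descendant cells micronucleate one daughter
with probability 0.52 (0.65 if the bridge never broke); the micronucleus
contains the bridge chromosome with probability 0.80 and a centromere with
probability 0.62 — otherwise only an acentric distal piece mis-segregates.
Micronuclear centromeres are flagged inactivated (probability 1.0 by
default) so the chromosome keeps mis-segregating; the mechanism is left as
a flag. Cells without bridge history never micronucleate. Micronuclear
chromosomes shatter rarely in interphase (1/10) and nearly always after the
next mitosis (8/9).

**Later generations.** Uncapped ends either continue BFB (probability 0.5
per division — unquantified in the source, exposed as config) with a
log-uniform 0.5–3 Mb terminal delta biased toward loss (loss probability
1 − replicated_fraction), or are capped by translocation (probability 0.2)
with an acrocentric partner 85% of the time. Populations expand by binary
division under a viability rule (death on a dicentric derivative or on zero
copies of any chromosome arm) with neutral down-sampling to a cap.

## Synthetic observables

Read-level data is deliberately not simulated; every detector consumes
binned haplotype-resolved counts. Per bin, a single cell emits
Poisson(CN × reads-per-copy × A) reads with A log-normal (sigma 0.45,
mean 1) for amplification dispersion, zeroed with dropout probability 0.10
— calibrated so ~90% of bins of a CN = 1 homolog carry at least one read at
the default 25x depth, the coverage statement of the single-cell protocol
being emulated. CN = 0 bins emit exactly zero (no mapping noise). Bulk
profiles are cell-weighted mean CN plus Gaussian noise (sigma 0.05).
Haplotype assignment is taken as known (truth phasing); phasing inference
is out of scope. The emulator does not model GC bias, mappability, or the
long-range covariance of real whole-genome amplification, so passing tests
demonstrate detector correctness under this noise family, not performance
on real libraries.

Default bin sizes mirror the plotting conventions of the study design:
1 Mb (genome overview), 250 kb (chromosome zoom, daughter-pair analyses),
25 kb (population and fragment-island analyses).

## Detection choices

**Segmentation.** Recursive binary segmentation on normalized coverage
with a two-sample t statistic (threshold 5.0, minimum 3 bins per side),
extended with a circular-segmentation-style interior-window test: a short
interior event dilutes any single cut's mean difference, so every interior
window up to 300 bins is tested (geometric width ladder plus O(1)
coordinate-descent refinement of the two cuts). Because the window scan
performs many more tests, it carries a higher critical value (factor 1.3).
Before segmentation, zero runs of ≤ 2 bins flanked by covered bins are
imputed as amplification dropout; longer zero runs are real loss and keep
their exact extent. Adjacent segments with equal integer calls are merged.
Integer calls are rounded normalized means.

**Reciprocity.** Events are anchored on the *loss* interval — lost DNA
emits nothing, so its boundaries are sharp — and confirmed by gain evidence
in the sibling: either an overlapping segment called at ≥ baseline + 1
(at least half the event size, overlapping at least half its own length),
or directly by sibling coverage (some window of the minimum event size
inside the loss interval with mean ≥ baseline + 0.5 at ≥ 3 sigma). Events
below 2.5 Mb are discarded; an interval reaching a chromosome end is
Type 1, otherwise Type 2. Requiring both daughters prevents an internal
gain from being misread as a replication-based duplication.

**Fragment islands.** Loss regions are runs of < 0.5-copy segments
(total zero span ≥ 2 Mb) tolerating embedded islands < 1.5 Mb. Within a
loss region, islands are runs of covered bins (single-bin gaps allowed,
CN ≥ 1 by construction since a lost haplotype emits nothing); an island
qualifies when its span is at least `min_frag` minus one bin per side,
because dropout can erase a boundary bin on each side. With 25-kb bins this
places the ≥ 95% detection floor at 100 kb: a 50 kb fragment spans two
bins and both must survive dropout (~81%).

**TST parsing.** Every 20-mer of every insertion sequence is located
exactly in the lazy reference (2-bit collision-free hashing, both strands),
first in ±150 kb windows around junction breakends, then genome-wide for
unanchored k-mers; anchors are greedily extended to maximal exact matches.
Decomposition boundaries are ambiguous up to accidental flank homology
(a few bp), which tests tolerate. A call is TST-positive with ≥ 2 tandem
insertions of 50–1000 bp in one junction and ≥ 2 source hotspots holding
≥ 3 breakpoints (both endpoints of each templated segment count).

**Homology classification.** The homology length is the longest exact
match between the end of the side-1 retained sequence and the reference
context immediately upstream of the side-2 breakend: ≤ 1 bp blunt, ≥ 2 bp
microhomology; 2–20 bp of unanchorable inserted sequence is an untemplated
insert, reported without asserting mechanism (it may be unmappable
microhomology from repeats or mismatches).

**Kataegis.** ≥ 6 mutations, inter-mutation distance ≤ 1 kb, TpC-context
fraction ≥ 0.5 (verified against the reference). The operational definition
is field convention; the source gives none.

**Chromothripsis.** Positive when (i) ≥ 10 distinct breakpoints (junction
breakends plus CN transitions, deduplicated within 1 kb), (ii) CN takes
≤ 3 integer states across ≥ 10 intervals delimited by those breakpoints,
(iii) breakpoints confined to ≤ 2 chromosomes, and (iv) ≥ 3 of the 4
junction orientation classes present. The criteria are cited by reference
in the source; these thresholds are the conventional reading, exposed as
configuration.

**Sloping transitions.** Constant, single-step, and two-plateau linear
ramp models are fitted by least squares and selected by BIC (k = 2, 4, 5);
a "slope" call requires the fitted ramp to span ≥ 2 Mb. The ramp bounds are
grid-searched then refined to single-bin resolution.

## Reproducibility and problem sizes

All randomness flows through counter-based Philox generators keyed by
(seed, stream), so event logs are byte-identical across runs and platforms.
The bundled analyses use: 20 daughter pairs at 250-kb bins (the study's
pair count); 200 replicates per fragment size at 25-kb bins; 150
two-generation lineages for the generation contrast; populations of ≤ 300
cells over 8 generations with 200 cells profiled. These sizes keep every
driver and the full test suite in the minutes range while leaving Monte
Carlo error well below the margins being tested.

## Known limitations

- Mechanics (force generation, nuclear-envelope dynamics) are stochastic
  parameters, not physics; breakage timing and position carry the biology.
- Second-wave products are copied to both daughters rather than partitioned
  complementarily.
- The 0.62 micronucleus-centromere frequency is implemented by choosing
  whether the mis-segregating unit includes the centromere, not by modeling
  centromere biology; inactivation is a flag.
- Fragment-size, fragment-count, per-generation BFB-continuation and
  second-wave laws are stated assumptions where the source prints no value.
- The sequence model is i.i.d. uniform bases: no repeats, so TST insertions
  are always uniquely mappable at 20 bp — the "ambiguous origin" class
  arises only from explicitly untemplated bases, unlike real genomes.
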