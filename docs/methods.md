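# Methods

## Data model and coordinate conventions

Every somatic call is an `AnnotatedVariant` with 1-based, fully-closed
coordinates; identity across regions is the exact `(chrom, pos, ref, alt)`
tuple.  No fuzzy matching of nearby indels is attempted and chromosome
names are compared verbatim — silent harmonization hides data errors, so a
manifest-level rename map is the only normalization offered.  Inputs are
assumed left-aligned; the VCF reader preserves the shared leading base of
indel records rather than re-normalizing, to avoid silent coordinate
shifts.  Whether SNVs and indels should be matched across regions by
identical alleles or by position only is not settled practice; exact-tuple
matching is this package's documented choice, and all passing variants
(SNV and indel) enter the clonality and Jaccard computations by default.

## Filtering

Five exclusion rules with defaults: population allele frequency > 1% in
any configured database (gnomAD, ExAC, and a configurable Korean-population
column; absence from all databases passes), an upstream 8-oxoguanine
artifact flag, fewer than 3 alternate reads, depth < 20, VAF < 3%.  The
thresholds are phrased as strict exclusions, so boundary values (exactly
3 reads, depth 20, VAF 3%, frequency 1%) pass.  The passing set is
independent of rule order; only the report's attribution of *which* rule
removed a variant uses the fixed order (population → OxoG → alt count →
depth → VAF).  Hotspot review returns KRAS codon 12/13/61 variants removed
*solely* by the VAF rule; rescue is never automatic because the analogous
step in practice is a manual IGV review.

## Clonality, ITH and relatedness

The per-patient presence matrix is binary over regions × variant keys.
Classification is purely presence/absence — no cancer-cell-fraction
clustering and no subclonal deconvolution; VAFs exist in the model only so
the filters have realistic evidence to act on.  The ITH index is the
percentage of non-truncal mutations.  It is *undefined* when a patient has
no truncal mutation: that situation indicates independent tumors, and
reporting 100% heterogeneity would misstate the biology.  Summary tables
publish branch and private mutations as one "branch" total; the package
computes the three-way split and reports the two-way total alongside it.

Reported values round half-to-even on the decimal literal (1 decimal for
ITH, 2 for Jaccard) while full precision is kept internally; builtin float
rounding disagrees at exact decimal ties (`round(0.505, 2)` yields 0.51,
whereas a 0.505 median should print 0.50).  The cohort ITH median is taken
over the per-patient indices *as reported* at one decimal — cohort medians
in clinical tables are assembled from the published per-patient values, and
this convention reproduces them; patients with undefined ITH are excluded.
The median of an even count is the mean of the two middle values.

Relatedness thresholds are not established in the literature, so the
defaults (unrelated iff Jaccard ≤ 0.05 *and* no shared driver variant;
related iff Jaccard ≥ 0.15 *or* any shared identical driver among KRAS,
NKX2-1, TP53, ARID1A) keep an explicit indeterminate band rather than
forcing a binary call.  Observed extremes motivate the band: clonally
related region pairs sit at 0.16–0.60, independent primaries at ≈ 0.01.

## Phylogeny

Hamming distances are raw disagreement counts over variant keys — no
per-site normalization, since the profiles share one coordinate system.
An all-absent "Normal" pseudo-sample is included by default (disable with
a flag): it anchors the germline state and makes the trunk length of a
single-origin patient equal its truncal mutation count.  Neighbor joining
follows the standard Q-criterion/branch-length formulas; two unspecified
details are fixed deterministically: Q-ties break on the lexicographically
smallest label pair (a joined cluster carries its smallest leaf label) and
negative branch-length estimates clamp to 0.  On additive matrices the
implementation provably recovers the generating topology (tested by
brute-force enumeration of all 15 unrooted 5-leaf topologies with
non-negative least-squares branch fits, and against scikit-bio's NJ).

## TMB

"Nonsynonymous missense mutations per megabase" reads literally as
missense-only, which is the default counting mode; `all_nonsynonymous`
additionally counts nonsense, frameshift, inframe-indel and splice
variants.  Callable megabases must be supplied per region — typical values
are the capture-kit target size — because a hidden exome-size constant
would silently distort comparisons across kits.  Germline subtraction is
assumed done upstream by matched-normal calling.

## Mutational signatures

Spectra use the canonical 96-channel order (substitution class, then 5'
flank, then 3' flank) with pyrimidine-strand collapsing; any catalog whose
rows deviate from that order is rejected outright, since silent channel
permutation is the classic bug in this computation.  Refitting solves
non-negative least squares over the candidate signatures, then removes
signatures greedily while the cheapest removal costs less than
`epsilon_cos = 0.01` in reconstruction cosine, then zeroes exposures below
`min_exposure = 0.05` of the total and refits once.  The thresholds are
configuration, not constants; the procedure is deterministic, scale
invariant (fractions are fitted, not counts), and reports the
reconstruction cosine as its diagnostic.  De-novo signature extraction
(NMF) is out of scope; the catalog is fixed input.

The packaged catalog is a **synthetic stand-in** over signature ids 1, 2,
4, 5, 6, 13, 15, 17: each column concentrates 85% of its mass on channels
characteristic of the corresponding process (CpG C>T for 1, TpC-context
C>T / C>G for the APOBEC pair 2/13, broad C>A for 4, flat 5, NpTpT T>G for
17) over a uniform background.  Pairwise column cosines stay below 0.5, so
two-signature mixtures are identifiable; with n = 1000 SNVs, mean absolute
exposure-recovery error over 50 seeded mixtures is ≤ 0.05.  The flat
signature 5 is the hardest to detect and is often eliminated — the same
behavior real refitting tools show for it.  Any real reference catalog in
the same TSV layout drops in unchanged.

## Synthetic cohorts

The generator's defaults are the study conditions the package targets:
seven patients, 2–5 regions each (24 regions), mean depth 200×, purity
0.4, callable 40 Mb per region, and per-patient truncal / branch+private
counts of 37/37, 31/30, 24/112, 36/68, 25/78, 0/42 and 17/41 — so the
noiseless per-patient ITH indices are 50.0, 49.2, 82.4, 65.4, 75.7, N/A
and 70.7 with cohort median 68.1%.  One two-region patient is a double
primary: each lobe has its own trunk (one lobe KRAS-mutant, the other
wild-type) and the lobes share zero variants.  Each patient's regions
follow a random bifurcating topology; branch mutations attach to random
internal clades.  Channels are drawn from the patient's signature mixture
and materialized on a random strand, exercising the pyrimidine collapse;
read evidence is depth ~ Poisson(200), alt ~ Binomial(depth, purity/2)
with CCF fixed at 1 (configurable per branch).  Three common-SNP and three
OxoG contaminants per region give the filters true positives.

What the simulator does *not* model: read-level errors (simulation starts
at annotated calls, where the analysis starts), copy-number and purity
variation across regions, mutation hotspot clustering along the genome,
and FFPE deamination damage beyond the OxoG flag.  Passing tests therefore
demonstrate algorithmic correctness under the stated generative model, not
robustness to every artifact of real FFPE exomes; the dropout-degradation
driver probes the most consequential failure mode (false-negative presence
calls convert truncal to branch and inflate ITH).

## Numerical and degenerate-input conventions

Jaccard of two empty regions (empty union) is undefined, flagged per pair,
and NaN in outputs; an empty-versus-nonempty pair is 0.  A patient with a
single region has no defined clonality and is rejected.  Empty spectra
cannot be refit (error), and zero vectors have cosine 0 by convention.
Simulation, pipeline runs and file emission are deterministic given the
seed; reruns are byte-identical.

## Problem sizes

Tests and the acceptance script run the full seven-patient cohort
(~60–140 passing variants per patient), 50-seed signature-recovery
batches at 1000 SNVs, and NJ consistency trials up to 6 taxa; the complete
suite plus acceptance finishes in well under a minute on one core.
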