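# Methods

`feomics` re-implements, as a tested library, the computational core of a
multi-omics characterization of the low-iron response of an oceanic diatom:
differential digital gene expression from two cDNA read libraries,
¹⁴N/¹⁵N metabolic-labeling proteomics quantification, positional promoter
motif screening, sister-clade classification of gene trees for lateral gene
transfer (LGT), cylinder-model cell morphometry, RT-qPCR ΔΔC_T and assembly
statistics. All Fe(−)/Fe(+) ratios are oriented iron-limited over
iron-replete.

## Differential digital expression (`ddge`)

Each gene's read counts x_i in m libraries of total sizes N_i are compared
against the null of a common proportion p̂ = Σx_i / ΣN_i with the Stekel
log-likelihood ratio statistic

    R = Σ_i x_i ln(x_i / x̂_i),   x̂_i = N_i p̂,   0·ln 0 ≡ 0.

R is zero iff all proportions are equal and 2R is asymptotically χ²(m−1).
Two calibrations are provided:

- `chi2`: the χ² upper tail at 2R — fast, but anticonservative for the
  small counts typical of EST contigs;
- `parametric_bootstrap` (default): counts are redrawn per library as
  Binomial(N_i, p̂) and p = (1 + #{R* ≥ R})/(n_boot + 1). With the default
  n_boot = 999 the smallest attainable p is 10⁻³; analyses that need to
  resolve far smaller tail probabilities (e.g. genome-wide discovery after
  Benjamini–Hochberg correction) should use the χ² calibration or raise
  n_boot.

Multiple testing uses Benjamini–Hochberg (statsmodels) at a configurable
α (default 0.05); the direction call compares x₁/N₁ to x₂/N₂ with the first
library taken as Fe(−). Genes absent from one library keep their zero count
— absence is informative. Compartment aggregates (chloroplast,
mitochondrial, rRNA) sum member-gene counts per library and report the
Fe(−)/Fe(+) ratio.

The default library size in the synthetic generator is 95,000 reads per
library, the scale of the study's two pooled 454 cDNA libraries. Counts are
pure multinomial draws; no overdispersion model is offered, since none is
claimed for the real data. Consequences: the type-I calibration properties
verified by the tests speak to multinomial sampling noise only, not to
biological replicate variance (the study had one library per condition, so
there is no information to fit overdispersion from).

## Proteomics quantification (`protquant`)

The chain from match-level records to protein-group ratios is:

1. **Hit distinctiveness** (threshold 2): keep records whose second-best
   candidate E-value is at least twice the best; records without a
   runner-up are kept. The original pipeline does not publish the exact
   definition of its distinctiveness score; the second-best/best E-value
   ratio is the simplest monotone quantity consistent with "threshold of 2".
2. **Target-decoy FDR** (target 1%): the largest E-value threshold t with
   #decoys(E ≤ t) / #targets(E ≤ t) ≤ 0.01 is selected by scanning all
   observed E-values; survivors are targets only. The estimator is the
   plain decoy/target count ratio (no +1 correction, no π₀).
3. **Precursor mass accuracy**: |ppm| ≤ 5, boundary inclusive (the study
   discards strictly ">5 ppm").

The cascade order is fixed (distinctiveness → FDR → ppm) and matters: a
decoy with poor mass accuracy still participates in FDR estimation. The
test suite demonstrates the order sensitivity explicitly.

Protein inference is parsimony grouping: proteins with identical surviving
peptide sets merge; a protein whose peptide set is a strict subset of
another's is absorbed into every strict superset's group; peptides shared
between groups are marked non-unique. Quantification forms one ratio per
(peptide, SDS-PAGE band, charge) combination ("PBC", the atomic unit):
spectra within a PBC are pooled as mean light / mean heavy before the ratio
is taken, so duplicated spectra collapse. Group ratios are the median of
member PBC ratios with quartiles by linear interpolation (numpy default),
fixed so q1/q3 are bit-reproducible. Labeling orientation defaults to
heavy = Fe(+); a flag flips it, since the study states only that
differentially labeled cultures were mixed. Equal-protein ratios convert to
per-cell ratios by multiplying with the Fe(−)/Fe(+) total-protein biomass
ratio (≈ 0.5 from the BCA assay).

## Promoter motif screen (`promoscan`)

Promoter windows are upstream flanks on the coding strand anchored at the
translation start (first base of the start codon, taken from the first CDS
base of the gene model). An offset of n places the motif's 5' end n bases
upstream (positions −n … −n+|motif|−1); the genome-wide screen reports
perfect matches with offsets in the inclusive window [150, 250], the
positional band of the conserved iron-regulated 8-mer ACACGTGC (≈ −200).
Matching is coding-strand only by default: the 8-mer is not its own reverse
complement (its CACGTG E-box core is), and the screen counts perfect
matches in promoter orientation; a flag enables both strands. Window bounds
apply to the motif's 5' end and are inclusive on both ends; the published
wording gives no base-exact edge convention, so the inclusive reading was
fixed and is pinned by tests.

The conserved-positional-k-mer finder is a defined exact-match stand-in for
probabilistic motif discovery across orthologous promoters: a k-mer is
reported when one common center inside the window has, in every promoter,
an occurrence within the positional tolerance; candidates are ranked by the
smallest achievable maximum deviation. Because offsets and tolerances are
integers, scanning integer centers is exact.

## LGT census (`lgtcensus`)

Tier 1 tallies best database hits at E ≤ 10⁻³⁰ into lineage groups,
separating vertical candidates (stramenopile best hit) from LGT candidates.
Tier 2 classifies gene trees: after rooting (midpoint by default, outgroup
optional — the study's exact rooting procedure is in unavailable
supplementary material), the query clade is grown while it contains only
conspecific leaves (so recent paralogs do not mask the donor), and the
sister clade decides the verdict: no stramenopiles → `lgt_confirmed`,
purely stramenopile → `vertical`, a heterogeneous mix → `unresolved`. The
mixed rule mirrors the study's 18 ambiguous "heterogenous mix" cases
without guessing a sharper criterion. Verdicts are invariant to leaf
rotations, and midpoint rooting is idempotent (tested).

The synthetic tree generator plants these three topology classes with the
query-side leaves 1.1 below their top node and far leaves 1.0 below theirs,
so the midpoint of the longest path falls strictly inside the central edge
and rooting preserves the planted bipartition deterministically.

## Cell morphometry and ΔΔC_T (`physiology`)

The cell is a closed cylinder (V = π(d/2)²h, S = 2π(d/2)² + πdh — both
caps, matching the diatom valve-plus-girdle geometry) that grows by a
gradual two-fold height increase per cycle. Population means over an
unsynchronized culture are back-calculated to a "cellular unit" (freshly
divided cell) as the lower end L of the range [L, 2L] whose arithmetic
center is the mean: L = mean/1.5. This convention reproduces both tabulated
unit volumes (100 and 80 µm³) from the printed mean dimensions; a geometric
alternative (L = mean/√2) is available but non-default. The tabulated unit
surfaces are not consistent with a single rule — the iron-limited value
matches the raw mean surface while the iron-replete one matches a surface
re-derived from the unit volume at fixed diameter — so
`unit_cell_from_population` reports both conventions and adjudicates
neither. For a single cell the /1.5 division is applied verbatim and
flagged; it is biased because one cell is not a population mean.

ΔC_T = C_T(gene) − C_T(housekeeping) per condition and
ΔΔC_T = ΔC_T@Fe(+) − ΔC_T@Fe(−); positive values mean induction at low
iron. Per-plate constant offsets cancel (tested). Housekeeping references
in the study were 18S rRNA and RPB1; any reference id is accepted.

## Assembly statistics (`asmstats`)

N50 is the largest L such that contigs of length ≥ L hold at least half the
assembly — ties at exactly half count, per the published parenthetical
definition. The genome-size estimate divides total sequenced bases by the
median coverage of long contigs (≥ 10 kb by default). On the published
inputs (725 Mb of reads, 8.7-fold median coverage) this gives 83.3 Mb; the
published figure of 81.6 Mb is not reproducible from the printed inputs
because the numerator actually used is not shown, so the package reports
the computed value and documents the gap rather than matching the print.

## Synthetic data (`synthio`)

Generators draw from a single numpy Generator seeded per spec; identical
seeds are bit-identical, and each generator returns a machine-readable
truth table. Defaults are the study conditions where stated (95,000 reads
per library; 20 measured cells; unit dimensions 5.9 × 5.5 µm for the
iron-replete condition; 198 trees split 180/10/8; promoter motif at offset
200 within a 500-base window). Where the study states nothing, one
realistic choice was fixed: lognormal (σ = 1) baseline transcript
abundances for the skew of EST libraries; PSM target E-values log-uniform
over 10⁻¹²…10⁻⁴ with decoys over 10⁻³…1 (stochastically dominated, so FDR
thresholding is informative — the study does not describe its decoy
construction); multiplicative lognormal intensity noise with CV 0.1;
precursor ppm noise SD 1.5; cell growth-phase distribution uniform by
default with an exponential-age alternative (density 2·ln2·2^(−a), a ∈
[0,1]), since the population age structure is not stated.

Non-planted promoters are made motif-free by rejection sampling (the whole
window is resampled until no perfect, including overlapping, occurrence
exists), giving the screen a clean false-positive surface; planted
promoters carry exactly one occurrence at the configured offset. What is
not emulated: read-level artifacts (no FASTQ/quality values), count
overdispersion, spectra (only match-level records), alignment/assembly
structure, and real promoter base composition (windows are i.i.d. uniform
ACGT). Passing recovery tests therefore demonstrate correctness of the
inference chain under the stated sampling models, not robustness to the
full noise structure of real data.

## Numerical choices and problem sizes

- R is clipped at zero (Gibbs' inequality; float residue only).
- Bootstrap p-values use the +1/(n_boot+1) correction; n_boot ≥ 100 is
  enforced.
- Quartiles: linear interpolation, fixed for reproducibility.
- FDR threshold scan only considers cut points between distinct E-values.
- The statistical test-suite properties run at the study's library size
  (N = 95,000) with 2,000 null genes for calibration, 100 simulations for
  power, 30 seeded proteomics instances, and 198-tree batches; these sizes
  put Monte-Carlo error well inside the asserted bands while keeping the
  whole suite in a few seconds.
- The power property is checked with the χ² calibration: the planted
  5-fold signal sits at 2R ≈ 280 where the χ² approximation is essentially
  exact, while a 999-replicate bootstrap cannot resolve adjusted p-values
  below BH-corrected 0.01. The type-I property uses the default bootstrap.

## Known limitations

- The published genome-scale counts (10,109 conserved models, 45
  motif-bearing genes, 1,695 peptides, the best-hit taxon breakdown) depend
  on the real assembly and external databases and are out of desk-scale
  scope; the corresponding code paths are exercised on synthetic inputs
  with planted truth instead.
- The χ² calibration is anticonservative for genes with expected counts
  below ~5; use the bootstrap there.
- Protein grouping resolves ties by absorbing strict subsets only;
  partially overlapping peptide sets remain separate groups, which can
  differ from pipelines that split shared evidence quantitatively.
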