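# Methods

## Scope and assumptions

`estmir` re-implements the EST-mining protocol for plant miRNA discovery as a
deterministic, self-contained library. The protocol assumes (i) mature miRNA
sequences are conserved across plant species while precursors are not, so
homology search runs at the mature level; (ii) plant miRNA targets are
near-perfectly complementary to the mature, so a substitution-only search
finds them; (iii) EST clusters group redundant single-pass reads of one
transcription locus, so intra-cluster disagreement is either sequencing error
or genuine polymorphism.

Two steps of the original protocol are replaced by explicit, testable
components rather than wrapped external programs:

* **BLASTn → exhaustive scanner.** Every full-length ungapped window of every
  EST, on both strands, is compared positionally against every non-redundant
  mature. This is complete (no seeding heuristics, no e-value cutoffs) and
  exactly reproducible; the trade-off is that gapped homology is not found.
  "Fewer than 4 mismatches" is read strictly as `max_mm = 3`.
* **mfold → bundled nearest-neighbor DP.** Folding uses this package's own
  energy model (below). Consequently all ΔG/MFEI *numbers* are on this
  model's scale, not mfold's; hairpin verdicts are threshold-based and the
  thresholds are the protocol's published ones. Any backend returning a
  dot-bracket plus its energy can be plugged in instead (the `fold_fn`
  parameter downstream).

## Species-representation statistic

For species *s* with *m* of *M* reference deposits (redundant set — identical
sequences deliberately re-included, since each deposit is an independent
database entry) and *k* of *K* matched deposits, the reported statistic is
the **binomial point mass** at the observed count, `p = Binom(K, m/M).pmf(k)`,
with direction over/under by comparing k/K to m/M. The point mass is what
reproduces the published per-species values for this analysis, including the
closed-form k = 0 rows `(1 − m/M)^K`; it is *not* a calibrated tail
probability, and that caveat is deliberate: a `tail` mode (one-sided
`P(X ≥ k)` or `P(X ≤ k)`) is provided and its null calibration is
demonstrated by simulation (`null_enrichment_sim`: matched sets drawn
uniformly without replacement; the empirical rate of tail-p ≤ α stays below
α plus Monte-Carlo error because the statistic is discrete and the draw is
without replacement). Evaluation is via `scipy`'s log-pmf; a result that
underflows a float is clamped to the smallest positive value so the contract
p ∈ (0, 1] holds. Percentages are rounded half-away-from-zero to one
decimal; p-values print with two significant digits. No multiple-testing
correction is applied (raw thresholds 0.05/0.01/0.005/0.001 are swept).

## Folding energy model

A compact Turner-style nearest-neighbor model, chosen so the dynamic-program
minimum can be verified against exhaustive structure enumeration on short
sequences:

* allowed pairs AU/UA/CG/GC/GU/UG (wobble configurable), lonely pairs
  allowed, minimum hairpin loop 3 nt, no pseudoknots;
* a 6×6 stacking-energy table (kcal/mol, all negative; GC/GC −3.4 …
  UG/GU −0.3) applied only to directly stacked pairs;
* hairpin/bulge/internal-loop initiation penalties tabulated to size 6–9 and
  extrapolated logarithmically (Jacobson–Stockmayer slope 1.75·RT at 37 °C);
  internal loops add 0.5 kcal/mol per asymmetry unit, capped at 3;
* multiloops cost a + b·branches + c·unpaired with a = 3.4, b = 0.4, c = 0.1;
  bulges break stacking (no stack term across a bulge);
* external (exterior-loop) bases are free, so the MFE is always ≤ 0.

The minimizer is a Zuker-style DP (arrays V, WM and an external array W) with
interior loops capped at 30 nt combined — irrelevant below 30 nt, where the
oracle comparison runs — and a deterministic traceback that prefers pairing
over bifurcation, smaller 5′ index first. The DP kernel is JIT-compiled with
numba when available and runs identically in pure Python otherwise. `N` is
accepted as an unpairable placeholder (consensus sequences can contain it);
other non-RNA symbols are errors.

Derived indices: AMFE = |ΔG|·100/length; MFEI = AMFE/GC% (positive
convention). MFEI at GC% = 0 is undefined and returned as NaN, which the
precursor screen rejects.

## Precursor extraction and screening

Around a sense hit the consensus is folded in a window of up to 250 nt per
side. The miRNA/miRNA* duplex is read off the structure: the duplex side is
the side of the mature (5′ or 3′) holding the majority of mature-position
partners; positions paired elsewhere count as unpaired (NM). The candidate
is trimmed to the duplex ends plus 13-nt pri-extension flanks, refolded, and
the trim is iterated (≤ 4 rounds) until the bounds are stable, because the
trimmed molecule can realize a slightly different duplex extent than the
wide window did. "13 nt before the 5′ hit / after the 3′ hit" is interpreted
as flanks beyond the two duplex ends (the hairpin's outer ends).

Acceptance requires **MFEI > 0.85 (strict)**, **NM ≤ 4**, and — quantifying
"few and small asymmetric bulges" — at most **2 bulges of ≤ 3 nt**, where a
bulge is the one-sided surplus of unpaired bases between consecutive duplex
pairs (symmetric internal loops are mismatches, already counted by NM). All
four limits are configurable (`PipelineConfig`). Family assignment against a
user-supplied hairpin library is by local alignment (match +2, mismatch −3,
gap −5/−2) reporting raw score and identity; no e-values are computed since
they would require a database-size calibration this artifact does not own.

## Cluster assembly and variant calling

Star alignment: the longest member is the backbone; every other member is
aligned to it end-gap-free (match +1, mismatch −1, gap −2), and pairwise
alignments are merged into columns keyed `(backbone_index, insertion_ordinal)`.
Members below 60% identity over their aligned span are excluded with a
warning (chimera guard). Consensus is the per-column majority; ties prefer
the lexicographically smallest base and flag the column low-confidence;
gap-majority columns are dropped from the consensus string but kept for
indel calling. Assembly is deterministic given member order, and gap
*placement* within repeat runs follows the aligner's canonical choice — calls
at a planted indel may therefore sit a few columns from the planted
coordinate, within the same region.

A column with ≥ 2 observed symbols inside a miRNA-relevant region (target
site or mature span from the consensus re-scan) is a variant: base/base →
SNP, base/gap → indel. Alternative alleles carried by ≥ 2 members are
`candidate_true` (the published two-independent-copies heuristic — "member"
stands in for "independent sequence", since clone/library provenance is not
modeled); singletons are reported as `low_support`. Positions map to miRNA
coordinates (1-based from the mature 5′ end; antisense mapping
`pos = span_end − coord` for target sites) with flags for the 2–12 critical
window and 10/11 cleavage positions. Precursor SNPs are refolded per allele:
ΔΔG = ΔG(alt) − ΔG(ref), positive = destabilizing, exactly antisymmetric
under allele swap; indels that destroy the duplex are reported with a
`structure_lost` flag rather than an error.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *statistical shape* the pipeline consumes:
multi-species mature sets with configurable per-species counts and optional
cross-species duplicates; EST clusters as noisy full-length copies of one
template (i.i.d. substitution noise at rate ε, optional end truncation of
non-carrier members up to 30 nt); designed hairpins (star = reverse
complement with planted non-complementary positions, wobble-excluded so the
engine cannot re-pair them; {A,C} loops; flanks resampled up to 50× until the
realized duplex matches the design, the *realized* values being what the
manifest records); antisense target sites with controlled mismatch patterns
placed ≥ 40 nt from EST ends; and variants with controlled allele support
(member 1 always stays a pristine template copy so the backbone and the
reference allele are well-defined; a requested SNP allele equal to the
template base is replaced so a polymorphism is actually planted).

It does **not** emulate: chromatogram-style indel error hotspots, chimeric or
vector-contaminated reads, codon structure or composition bias beyond a
configurable background GC (default 45%, cereal-EST-like), paralogy, or
expression-level cluster-size variation. Passing the seeded end-to-end tests
therefore demonstrates the pipeline's correctness on data satisfying the
protocol's own assumptions, not robustness to every real-EST artifact. One
consequence of random background: a ~21-nt mature can match background with
≤ 3 mismatches by chance (≈0.1 expected events per default-sized dataset), so
seed-robust checks assert planted-feature *recall*, not exact equality of
matched counts.

Default study-shaped scenario (`default_config`): 8 species (counts 40…4,
skewed so planted matches concentrate in two species), 150 matures of
20–22 nt, 12 clusters of 5–8 members ≈ 80 ESTs, 3 planted precursors
(NM* = 0/2/1, loops 6–10, both arms), 6 planted targets (0–4 mismatches,
including one beyond the scan limit and one in a non-protein-coding cluster),
4 planted variants (SNPs at miRNA positions 11/12/15 and a 2-nt deletion at
position 10, supports 1–2), ε = 0. These sizes keep the full test suite and
the acceptance script at desk scale (minutes) while exercising every verdict
path; they are the package's chosen study conditions, stated here once and
used everywhere.

## Numerical and degenerate-input choices

* Scanner: N on either side of a comparison is a mismatch; U ≡ T; empty
  inputs yield empty outputs; overlapping hits are all reported, ordered by
  (est_id, start, orientation, mature id).
* Coordinates: 0-based half-open internally; 1-based inclusive in
  human-readable tables; miRNA coordinates 1-based from the 5′ end.
* Traceback ties in the folding DP are broken toward pairing, smaller 5′
  index first; energies compare with a 1e-9 tolerance inside the traceback
  only (table values are reconstructed with the identical expressions, so
  this never changes the minimum).
* `fold` accepts 10–1000 nt; shorter is an error ("too short to fold").
* Insertion columns report the preceding consensus coordinate plus an
  insertion ordinal; the VCF-like export is explicitly consensus-relative.

## Known limitations

* Ungapped scanning misses indelled homologs a gapped BLASTn would find.
* The folding model is a teaching-grade nearest-neighbor set: adequate for
  hairpin/no-hairpin decisions and relative ΔΔG signs, not for quantitative
  comparison with Turner-parameter engines.
* GO-style functional enrichment is reduced to a plain term→category tally.
* The binomial point-mass "p-value" is a fidelity choice, not an inferential
  one; use the tail mode when calibration matters.
* Star-alignment assembly presumes near-identical cluster members; genuinely
  divergent clusters are handled only by the 60%-identity exclusion guard.
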