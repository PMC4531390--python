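# Methods

`oaphys` reimplements, as a tested pipeline, the computational core of a
multi-assay ocean-acidification exposure study on adult Pacific oysters
(*Crassostrea gigas*): seawater carbonate-system speciation, spectral-count
shotgun-proteomics quantification with differential-abundance classification,
shell micromechanics, and organismal metrics.  A seeded synthetic-data module
emulates each assay's raw tables so the whole pipeline runs and is scored
without any external download.

## Carbonate chemistry (`oaphys.carbonate`)

The monitoring configuration measures pH (total hydrogen-ion scale, DuraFET,
corroborated spectrophotometrically), total alkalinity A_T (open-cell
titration), temperature and salinity.  With pH known the alkalinity balance

A_T = [HCO3⁻] + 2[CO3²⁻] + [B(OH)4⁻] + [OH⁻] − [H⁺]_free − [HSO4⁻] − [HF]

is linear in DIC, so speciation is closed-form: all non-carbonate terms are
evaluated at the measured pH and subtracted, and the carbonate alkalinity
determines DIC through the K1/K2 equilibria.  No iteration is needed; the
round-trip reconstruction of A_T from the returned species is used as a
self-check (tolerance 10⁻³ μmol/kg; in practice the closed form reproduces it
to machine precision).

Constant choices (all total scale, mol/kg-SW, surface pressure): K1/K2 from
the Lueker et al. (2000) refit of Mehrbach; KHSO4 Dickson (1990); KB Dickson
(1990); KW Millero (1995); K0 Weiss (1974); calcite/aragonite solubility
Mucci (1983); borate from Uppström (1974); calcium from the Riley & Tongudai
salinity ratio.  These are the defaults of the calculators commonly used with
pH+A_T input pairs.  Phosphate and silicate alkalinity are zero (not
measured); pCO2 is reported as partial pressure in μatm with no fugacity
correction (the difference is ~0.3% at these temperatures).

Limitations: derived values for a treatment computed from *mean* measured
inputs differ from the mean of per-day calculations when pH varies (Jensen's
inequality; noticeable at the 2800 μatm treatment where pH s.d. is 0.10).
The reproduction test therefore uses ±1 printed s.d. (or ±10% where the s.d.
is smaller) as its band.

## Proteomics quantification (`oaphys.proteomics`)

The ingestion contract is a simplified PSM TSV (peptide, protein_id,
PeptideProphet-style probability, injection_id) plus a design table mapping
48 injections to 16 oysters in 4 treatments; running search engines or
parsing pepXML is out of scope.  Filters, in order:

1. PSM probability ≥ 0.9 (inclusive);
2. protein retained only with ≥ 8 spectral counts summed over all
   injections (inclusive, applied after the probability filter);
3. within an oyster, a protein is *expressed* only with ≥ 2 unique peptide
   sequences pooled across that oyster's technical injections; sub-threshold
   entries are zeroed **before** NSAF normalization, so they contribute
   nothing to the denominator.

NSAF for protein i in oyster j: (SpC_ij/L_i) / Σ_k (SpC_kj/L_k), where
SpC_ij is the mean spectral count over the oyster's technical injections and
L_i the protein length in residues.  Columns therefore sum to 1 per oyster.
Unique peptides are counted per oyster (not per injection), by exact sequence
string without I/L folding.  Averaging uses however many injections the
design lists for the oyster (a warning fires if ≠ 3), so partial designs
remain usable.

## Differential abundance (`oaphys.abundance`)

Pairwise contrasts (reference group a vs comparison group b, four oysters
each in the full design):

* fold change = mean NSAF(b) / mean NSAF(a); proteins detected (expression
  mask) in only one of the two groups get an `up`/`down` exclusive sentinel
  instead of a ratio;
* two-sided two-sample t-test (pooled variance by default, Welch optional),
  computed only for proteins expressed in **all** oysters of both groups;
  degenerate zero-variance-equal-mean cases give p = 1, and p is clamped to
  [1e-300, 1];
* Storey positive-FDR q-values: π₀ estimated by the smoother method —
  π₀(λ) = #{p>λ}/(m(1−λ)) over λ ∈ {0, 0.05, …, 0.90}, cubic fit evaluated
  at λ = 0.90, clipped to (0, 1] — then q_(i) = min_{j≥i} π₀ m p_(j)/j.
  With π₀ = 1 this reduces exactly to Benjamini–Hochberg, which the tests
  assert.  With fewer than 20 p-values the smoother is unreliable and π₀
  falls back to 1 (conservative).

A protein is differentially abundant (DA) if any of: |log2 fold| ≥ 1
(inclusive) with detection in more than one oyster across the two groups
combined; q < 0.10 (only defined for fully expressed proteins); or exclusive
detection in one treatment.  Changes beyond 5-fold carry an extra flag.
Directionality is up/down in the comparison group.  The three-comparison
overlap summary reports the 7 Venn region counts and, per pair of
comparisons, the fraction of shared DA proteins with concordant direction.

Interpretation choices left open by the source workflow, fixed here: "more
than one oyster" counts expressed oysters over both groups combined; the
q-value eligibility requires full expression in *both* groups; the 2-fold
rule is symmetric in log space and inclusive at the boundary.

Annotation is limited to filtering precomputed BLAST tabular output
(outfmt 6): best hit per query with e-value ≤ 1e-10 (inclusive), ties broken
by bit score.

## Shell micromechanics (`oaphys.mechanics`)

VHN = 1.8544·F/d² with F in kgf and d = mean of the two indent diagonals in
mm (the 1.8544 constant is fixed by the Vickers pyramid geometry); H in GPa
is VHN × 0.0098066.  Fracture toughness uses the Anstis-type indentation
relation K_c = 0.0154·(E/H)^0.5·P/C^1.5 with E = 73 GPa by default (the
empirical foliated-shell modulus for *C. gigas*), P in N and the crack-circle
radius C converted μm → m, reported in MPa·m^0.5.

Workflow: per-indent VHN and K_c, averaged per shell; per-treatment shell
means pass a Tukey-fence outlier filter (beyond 1.5·IQR outside the
quartiles, linear-interpolation quartiles; skipped with a warning below
n = 4); then one-way ANOVA + Tukey HSD and Welch ANOVA + Games-Howell.
Welch's F uses the standard Satterthwaite-type second degree of freedom;
Games-Howell refers q = |Δ|/√(se²/2) with per-pair Welch df to the
studentized-range distribution.  Both are validated against independent
implementations and against direct formula evaluation.  Normality and
variance-homogeneity checks are left to standard library routines.

## Organismal statistics (`oaphys.organismal`)

* Relative growth rate: (mean ln m_end − mean ln m_start)/days (cohort-level,
  scale-invariant), default 29 days.  The time × pCO2 model on buoyant
  weight is a two-way fixed-effects ANOVA with interaction (Type II sums of
  squares, statsmodels OLS).
* Glycogen: triplicate A570 readings are blank-corrected, converted through a
  user-supplied linear standard curve (the kit curve is lot-specific and not
  hard-coded), scaled by dilution factor and extract volume (defaults 200 μl
  extract, 50 μl per well) and divided by extracted tissue mass; the
  triplicate CV must be < 20% to pass QC.  Negative corrected responses clip
  to zero with a warning.
* Fatty acids: peak areas normalize to within-sample proportions; Bray-Curtis
  dissimilarity BC(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) is computed on proportions,
  optionally log-shifted with log(x + c), c = half the smallest nonzero
  proportion (zero handling is not standardized in the field; the constant
  and the transform are exposed as options).  After the log the values are
  shifted to be non-negative so the Bray-Curtis axioms (symmetry, zero
  diagonal, range [0,1]) continue to hold.
* ANOSIM: Clarke's R = (r̄_between − r̄_within)/(n(n−1)/4) on midranked
  pairwise dissimilarities; sampled-permutation p = (1 + #{R* ≥ R})/(1 + B),
  and an exact mode enumerates all label orderings for n ≤ 7.  Ordination
  (NMDS) itself is delegated to standard routines; this module only produces
  its input.

## Synthetic data (`oaphys.simulate`)

The generators' defaults are the study conditions: 4 treatments (400 and
2800 μatm, each ± mechanical stress) × 4 oysters × 3 technical injections;
1000 proteins of 150–600 residues.  Counts per (protein, oyster, injection)
are negative binomial (size 20, i.e. mild technical overdispersion) around
mean = baseline × length × treatment fold effect × a per-oyster lognormal
biological factor (CV 0.3, the dominant variance component, as in real
biological replicates).  Baselines are lognormal (median 0.016 counts per
residue, σ = 1), giving a median of ~6 spectral counts per protein per
injection and ~500k PSMs per run — the scale of the study's 700k filtered
peptides.  10% of proteins carry fold effects of 2× or 4× (up or down) in
one or more non-reference treatments.  Each spectral count becomes a PSM row
with a probability drawn from Beta(20,1) for true hits and Beta(1,8) for the
10% decoy fraction, so the 0.9 probability filter removes essentially all
decoys and a known share of true hits.  Peptides are synthetic strings keyed
to (protein, index), unique across proteins by construction — shared-peptide
inference is deliberately out of scope.

What this emulates well: count overdispersion, the informativeness of every
filter, partial detection and exclusivity at low abundance.  What it does
not: shared peptides and protein-inference ambiguity, missingness beyond
count sampling, retention-time or m/z structure, and correlated protein
responses.  Passing DA-recovery tests therefore demonstrates the decision
rule's behaviour under realistic count noise, not search-engine performance.

The other generators draw shell hardness as a two-level hierarchy (shell
means around a treatment mean, indents around the shell mean, diagonals
back-computed from the Vickers relation), fatty-acid profiles from a
Dirichlet with optional group-specific concentration shifts, glycogen plates
by inverting the assay math around a known true content with configurable
triplicate CV, and growth tables as lognormal start masses with
exponential per-treatment growth.  Every generator is deterministic in its
seed and emits a truth table.

## Problem sizes and numerical choices

The reference proteomics simulation (1000 proteins, full 48-injection
design) runs the whole quantification + classification chain in a few
seconds; calibration checks use 2000 ANOVA replicates, 120 null
micromechanics replicates and ~25-replicate ANOSIM batches, sized so the
full suite completes in well under five minutes on one CPU.  Permutation
p-values include the observed statistic in the numerator and denominator so
they are never zero.  ANOSIM uses midranks for ties; the ANOVA helpers
return (F = 0, p = 1) for fully degenerate inputs rather than NaN.

Known limitations: the carbonate module only solves the (pH, A_T) input
pair and surface pressure; the q-value smoother needs a few hundred
p-values to estimate π₀ stably (below 20 it is pinned at 1); Games-Howell
p-values rely on `scipy.stats.studentized_range`, which loses precision for
very large q; heat-shock survival modelling (Cox regression) and GO/pathway
enrichment are intentionally not implemented.
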