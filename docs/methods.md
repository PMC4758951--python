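# Methods

## The model

A transcription factor binding a double-stranded DNA probe is described
at thermodynamic equilibrium. Relative to the highest-affinity
("reference") sequence S_ref of length L, any length-L window S binds
with

    Ka(S) / Ka(S_ref) = exp(-ddG(S)/RT),

and ddG(S)/RT is additive over sequence features: one mononucleotide
feature per position (blocks of 4 mutually exclusive features — the
exponentiated block is a PSAM column) and optionally one
adjacent-dinucleotide feature per neighbouring pair (blocks of 16; the
PSAM extended this way is an FSAM). All free energies are stored as the
dimensionless ratio ddG/RT; RT never appears on its own.

A probe of length P presents 2(P-L+1) views: every forward offset plus
the reverse complement of each forward window (the reverse view at
offset o is defined as the reverse complement of the forward window at
o, so the γ vector has exactly 2(P-L+1) entries). Measured intensity is

    y(S) = β0 + β1 Σ_v γ_v exp(-ddG(S_v)/RT)                (linear)
    y(S) = β0 + β1 Σ_v x_v/(1+x_v),
           x_v = s·γ_v·exp(-ddG(S_v)/RT) + exp(-ddG_ns/RT)  (saturating)

γ_v ≥ 0 is the positional/orientational bias shared across probes,
max-normalised to 1 for identifiability (its overall scale folds into
β1). In the saturating form each view's occupancy follows the
equilibrium curve x/(1+x); s is an explicit free-protein concentration
scale. Because γ is max-normalised the concentration scale must appear
somewhere — with s free the saturating model nests the linear one
(s → 0, β1 → β1/s), which is also what makes the nonlinear fit
well-posed. ddG_ns/RT is a non-specific binding floor shared by all
views; it is deliberately not multiplied by γ_v.

## Inference pipeline

1. **Seed discovery.** Probe intensities are fit as y(S) = Σ_m β_m X_m(S)
   over all 4^K oligomers (K = 8 by default), X_m counting occurrences on
   both strands with overlaps. Starting from β_m = 1e-4, each round
   computes for every probe carrying m the coefficient that would predict
   its intensity exactly, takes the 15% two-sided trimmed mean of those
   values, clips at 0, and moves β_m a step α = 0.1 toward it; rounds
   stop at a 1e-6 relative change or 200 iterations. The seed is the
   argmax coefficient **among oligomers observed in ≥ `min_support`
   (default 20) probes**: an oligomer seen in only a few probes can
   explain them exactly whatever its true affinity, so its coefficient
   carries no evidence. On a real universal array every 8-mer occurs ≥16
   times and the rule is inactive in spirit; at desk-scale simulated
   coverage it is what keeps the choice identifiable. Counts are
   strand-merged, so β_m = β_revcomp(m) identically; the lexicographically
   smaller orientation is reported, and "the seed" always means the
   strand-merged pair.

2. **Block-wise robust regression.** With the seed as S_ref (off-seed
   bases initialised at ddG/RT = 1 to break the degeneracy of an all-zero
   start), each mono block in turn is re-estimated by linear regression
   of y on the per-feature regressors Σ_{v∋φ} γ_v exp(-(ddG(S_v)-ddG_φ)/RT),
   holding all other blocks fixed; fitted coefficients map back through
   ddG_φ/RT = -log(β_φ/β_PSAM). Mono blocks are re-anchored so the
   best base sits at 0 (and the reference sequence is updated to the
   per-position minimum, the column shifts being absorbed into β1).
   β_φ ≤ 0, or a feature carried only by negligible-affinity views
   (regressor norm < 1e-9 of the block maximum), maps to a ddG ceiling
   of 10 — "never observed bound". γ is re-estimated by robust
   regression in every round. Rounds stop when max |Δ ddG/RT| < 1e-4 or
   after 20 rounds. β_PSAM is the robust β1 recorded once the mono-only
   phase has converged, and stays frozen afterwards.

3. **Dinucleotides.** After the PSAM phase, rounds cycle over *all*
   blocks, mono and di. This matters: a di feature's marginal effect is
   first absorbed by the PSAM, and only re-fitting mono with the di terms
   in place separates main effects from interactions (a single di-only
   pass under-recovers a planted interaction by ~40%). Di values keep the
   β_PSAM normalisation (no zero anchor), which leaves most of them near
   zero.

4. **Robust regression.** Every regression is iteratively reweighted
   least squares: Huber weights w_i = min(1, c·σ̂/|r_i|) with c = 1.345
   and σ̂ = 1.4826·median|r|, plus hard trimming (weight 0) of the
   ⌊0.20·n⌋ largest-residual probes, iterated to coefficient convergence.
   Setting `robust=False` replaces every fit by ordinary least squares —
   used only for method contrasts. When the fit is essentially exact
   (σ̂ ≈ 0) all weights are 1 and nothing is trimmed.

5. **Saturation (optional, off by default).** β0, β1, log s and
   ddG_ns/RT are fit by Levenberg–Marquardt with the robust-stage probe
   weights carried over, ddG_ns initialised large (near-zero non-specific
   binding) and log s started from several concentration regimes
   (-2, 0, 2, 4) because the cost surface has a near-linear local
   optimum at small s. On failure the linear-stage parameters are kept.

## Identifiability and gauge structure

Three exact or near-exact degeneracies shape both the fitter and the
tests; they are properties of the model class, not of this
implementation.

* **Strand flip.** With both-strand view sums and a strand-symmetric γ,
  a matrix and its reverse-complement transform M'(p,b) = M(L-1-p, comp b)
  predict identically — PBM data cannot orient a motif. Around a
  palindromic reference this means the antisymmetric component of the
  matrix is unidentifiable; the symmetric component is what the data
  determine. The default synthetic truth is therefore exactly
  reverse-complement symmetric (a homodimeric E-box), which is also the
  physically consistent choice.
* **Per-block additive gauge.** Adding a constant to all features of one
  block multiplies every view's affinity by a constant, absorbed by β1.
  Mono blocks are fixed by the zero-anchor; di blocks by the β_PSAM
  convention.
* **Cross-block gauge.** Di blocks subsume mono marginals: adding δ to
  the 16 di features sharing a second base equals adding δ to that mono
  feature. The gauge-invariant content of a fitted di block is the
  *double difference* (interaction) over its two positions; planted
  interactions are asserted in that invariant, averaged with the
  strand-mirror block (whose antisymmetric combination is flat to first
  order at a symmetric optimum).

## Refinement

* **Palindromy.** Forward-only and reverse-only PSAMs are fit
  separately; the reverse matrix is reverse-complemented and compared on
  the relative-affinity scale. Mean per-column L1 ≤ 0.1 flags the motif
  symmetric. Symmetrisation re-seeds with the best reverse-complement-
  palindromic K-mer within Hamming distance 2 of the seed and projects
  the matrix onto the tied subspace ddG(p,b) = ddG(L-1-p, comp b) after
  every round; for odd L the centre column's complementary pairs are
  tied too, which is what makes affinity(S) = affinity(revcomp(S)) hold
  exactly. Tied fits share γ between strands (the two strand columns are
  identical, so separate coefficients would be exactly collinear).
* **Motif length.** Columns are added greedily on either side, refitting
  on a 90% training split and keeping a step iff R² on the seeded 10%
  held-out split increases (training R² of nested models never
  decreases, so held-out is the meaningful criterion). Growth stops at
  the first decrease per side or at the probe boundary.
* **Poly-G/C.** A reference with ≥4 consecutive C is modelled from the
  forward strand only; ≥4 consecutive G from the reverse strand only
  (probe synthesis biases poly-G runs). Applied when the seed is chosen.

## Multiple binding modes

Mode 1 is fit normally; further modes are fit to the residuals of the
current combined model; each mode is then iteratively re-fit against
what the others leave unexplained, blending old and new free energies
with step α = 0.1 on the ddG/RT scale; a final robust multiple
regression of y on the per-mode signals gives relative Ka coefficients
(anchored at mode 1, modes ordered by coefficient) and p-values. A
candidate that rediscovers an existing mode — same or reverse-complement
seed, mono matrices within 0.05 mean L1, or per-probe signal correlation
> 0.9 (which catches shifted rediscoveries that the matrix distance
misses) — stops the selection. A retained mode must have p ≤ 0.01 *and*
incremental weighted R² ≥ 0.01: residual-stage selection makes training
p-values optimistic, and the p-threshold alone retains noise modes at
realistic probe counts.

## Genome scoring

Total promoter affinity is the sliding-window sum Σ_m relKa_m Σ_v
exp(-ddG_m(S_v)/RT) over both strands (no γ — positional bias is a PBM
artifact, not a property of the factor). Genes ranked by this score are
tested per GO category with the two-sided Wilcoxon–Mann–Whitney test
(exact enumeration when the smaller group ≤ 10 and the total ≤ 50, else
the tie-corrected normal approximation; a one-sided high-affinity
alternative is available on the CLI), Bonferroni-corrected over the
categories actually tested. ChIP enrichments, normalised to max 1 and
optionally pre-aggregated as 10% trimmed means per K-mer, are fit to the
occupancy curve scale·P·a/(P·a+1); the fit is parametrised by the
low-concentration slope and P with nonnegativity bounds so the linear
regime P → 0 is a well-behaved boundary.

## Synthetic data: what it emulates and what it does not

The generator mirrors a universal-PBM-like geometry: fixed-length random
probes (36 bp default; most tests use 30 bp), intensities from the
forward model with a named γ profile (flat / linear ramp 0.3→1 /
end-dip), Gaussian noise scaled to the signal sd (5% default),
multiplicative ×10 "bright-spot" outliers on a seeded subset, and binding
sites planted in 35% of probes. Planted sites are *sampled from the
model's per-position Boltzmann distribution* (temperature 0.85) rather
than copied exactly: a universal array's power comes from partial sites
occurring abundantly and independently of perfect sites, and exact-
consensus planting destroys precisely that property (every shifted
sub-8-mer of the site then co-occurs with it almost always, which is
what defeats seed identifiability). Every dataset ships a
machine-readable truth record (models, γ, response, outlier flags).

What the generator does not emulate: de Bruijn coverage guarantees
(every 8-mer ≥16 occurrences — desk-scale random probes cover 8-mers
only O(1) times, which is why the seed stage needs its support rule),
spatial array artifacts, sequence-dependent probe synthesis failures
beyond the poly-G/C rule, and cross-array normalisation. Passing tests
therefore demonstrate correct inference under the stated forward model
and realistic noise/outlier structure, not robustness to every
technology bias of real arrays.

## Problem sizes and defaults

Recovery experiments use 5,000 probes × 30 bp for the single reference
fit (Pearson r and RMSE of mono ddG/RT, γ profile correlation),
1,200–1,500 probes per replicate for the 20-replicate contrasts
(robust vs least squares, seed recovery), 3,000 for dinucleotide and
motif-length experiments and 4,000 for the two-mode experiment — sizes
at which each effect is comfortably identifiable while a full run of
the suite stays fast. Key defaults: K = 8; trim 20% (probes) / 15%
(seed values); α = 0.1; Huber c = 1.345; block tolerance 1e-4 with 20
outer rounds; ddG ceiling 10; palindrome tolerance 0.1 mean per-column
L1; held-out fraction 0.1; mode p ≤ 0.01 and incremental R² ≥ 0.01.

## Known limitations

* Overlapping views are summed independently (no competition between
  the protein copies occupying overlapping windows), following the
  intensity model literally.
* The seed stage's coefficient *magnitudes* are distorted at sparse
  coverage (singleton oligomers absorb probe residuals); only the
  ranking over supported oligomers is meaningful there.
* Coordinate-descent convergence along near-flat gauge directions is
  slow; reported matrices are converged to the 1e-4 block tolerance,
  not to machine precision, and weakly constrained high-ddG entries
  carry the largest uncertainty.
* Motif-length growth can overshoot by one column when the held-out
  split is small and noisy.
* Promoter scoring uses a plain unweighted sliding-window sum; window
  weighting is left as a hook.
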