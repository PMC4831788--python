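# Methods

## Model

The pipeline treats structure–function coupling as a shared latent factor
problem. Let **X** ∈ ℝ^{k_x×m} hold one microstructural index per retained
structural connection (rows) per subject (columns), and **Y** ∈ ℝ^{k_y×m}
the corresponding functional connectivity values. Rank-1 sparse CCA seeks

  max u′ X Y′ v  s.t.  ‖u‖₂ ≤ 1, ‖v‖₂ ≤ 1, Σ_j w_j|u_j| ≤ c_u, Σ_j w_j|v_j| ≤ c_v.

Because m ≪ k_x, k_y, the within-set covariances are singular; following
the penalised-matrix-decomposition family of sparse CCA methods, the L2
unit balls replace the whitening constraints and the cross-product matrix
X Y′ is decomposed directly. Each constrained subproblem
(max u·a over the L2 ball ∩ weighted-L1 ball) is solved exactly by
soft-thresholding `a` at level Δ·w_j with bisection on Δ ≥ 0 until the
weighted L1 constraint is active.

### Solver details

- **Initialisation**: the leading singular pair of X Y′ (deterministic power
  iteration from a fixed starting vector), plus `n_restarts` (default 2)
  restarts initialised at the largest-|entry| positions of X Y′; the run
  with the best final objective wins. The restarts matter under tight
  budgets: alternating maximisation from the singular-pair init alone can
  stall in a local optimum, whereas a restart at the top cross-product entry
  guarantees the global single-pair solution when c = 1.
- **Convergence**: alternating updates stop when the max elementwise change
  of (u, v) is below `tol = 1e-6`, capped at `max_iter = 200`; the result
  reports `converged`.
- **Sign convention**: u's largest-magnitude entry is made positive, then
  v's sign is chosen so the canonical correlation ρ = corr(u′X, v′Y) ≥ 0.
- **Degenerate inputs**: a zero vector entering the L1/L2 projection is an
  error; if a canonical score has zero variance, ρ is reported as 0.

## Stability selection and inference

`bootstrap_stability` runs B (default 1000) iterations. Each iteration
draws m subjects with replacement (duplicates retained, standard
bootstrap), recomputes the common-edge mask *within the resample* — the
available-edge count therefore varies across iterations, and is generally
larger than the full-sample intersection because resamples contain fewer
distinct subjects — re-standardises both panels (rows constant within a
resample are dropped for that iteration and logged), draws fresh penalty
factors w ~ U[weakness, 1] per variable (randomised Lasso), and fits one
sparse canonical pair. Edges with nonzero loadings are counted as selected;
per-edge tested-iteration counts and mean loadings are recorded alongside.

With the budgets fixed across iterations and indices, the chance
probability of selecting any one available edge is

  p_chance = mean_b(#selected_b) / mean_b(#available_b),

and each edge's selection count is compared with the exact tails of
Binomial(B, p_chance): `k_hi` is the smallest count with
P(K ≥ k_hi) < α and `k_lo` the largest with P(K ≤ k_lo) < α
(α = 0.05 default, no multiple-comparison correction, matching the
per-edge tail tests the decision rule is defined by). Functional edges
receive selection probabilities too; accept/reject reporting defaults to
the structural panel.

### Defaults and their calibration

| parameter | default | rationale |
|---|---|---|
| c_u, c_v (L1 budgets) | 2.0 | calibrated once on the synthetic study conditions so one fit selects ≈20 of ≈450 available structural edges — the regime the binomial inference is designed around |
| weakness | 0.5 | mid-range randomised-Lasso perturbation; 1.0 recovers the plain Lasso |
| B | 1000 | selection probabilities resolved to 10⁻³ |
| α | 0.05 | two-tailed binomial level |
| tol / max_iter | 1e-6 / 200 | canonical-vector convergence |

Sample standard deviations use denominator m−1 throughout (standardisation
and ρ).

## Connectome construction

- **Functional**: the precision (inverse covariance) matrix of region time
  series. Default covariance estimator is Ledoit–Wolf shrinkage toward a
  scaled identity, because a ~300-sample series over 68 regions makes raw
  inversion unstable; `shrinkage="none"` gives the unregularised inverse.
  Electrophysiological connectomes apply the same estimator to Hilbert
  envelopes of band-passed series (zero-phase 4th-order Butterworth;
  δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–70 Hz), computed over the whole
  series. Precision matrices are stored as-is, without partial-correlation
  rescaling.
- **Structural**: per-edge weighted averages Σ value_i·count_i / Σ count_i
  of a voxelwise index along the tract, weighted by streamline visitation
  counts (down-weighting voxels unlikely to belong to the tract); or a
  streamline count normalised by the mean endpoint-region voxel count.
  ODI = 2/π·arctan(1/κ), extended continuously to ODI(0) = 1; the inverse
  is κ = cot(π·ODI/2).
- **Missing edges** are NaN on disk and an explicit mask in memory; zero is
  a legitimate value except for streamline counts, where zero means the
  tract is absent and the edge is treated as missing. Connections missing
  in any subject are excluded from panels rather than zero-filled.

## Synthetic data

The generator produces every input the pipeline consumes, with ground
truth. Coupled panels: one latent score z_s ~ N(0,1) per subject; s_x
structural and s_y functional edge rows equal loading·z_s plus unit
Gaussian noise, with loading magnitude `coupling` (an effect size in noise
SD units, random signs); all other rows are unit noise. Defaults emulate
the study conditions the pipeline targets: m = 17 subjects, a 68-region
bilateral atlas (2278 edges), and per-subject edge knockout at rate 0.09
with interhemispheric odds ×3 (tractography under-recovers long-range
connections), which puts the mean per-resample available-edge count near
450. Stacks devectorise the panels into labeled symmetric matrices;
functional matrices are complete (precision matrices are defined on every
pair). Gaussian series with a prescribed sparse precision, band-centred
oscillations with shared slow envelope components (modulator bandwidth
band.low/6 so AM sidebands stay in-band while envelope correlations
stabilise over ~10⁴-sample series), and streamline visitation records
cover the remaining inputs. All generators are pure functions of
(configuration, seed).

What the generator does *not* emulate: spatial autocorrelation between
edges, subject-level covariates, heavy-tailed or heteroscedastic noise,
indirect (network-mediated) functional coupling, and realistic diffusion
or BOLD physics. Passing recovery tests on this generator therefore show
the statistical machinery is sound under the model's own assumptions, not
that real acquisitions satisfy them.

## Known limitations

- **The binomial null is approximate.** The accept/reject rule models
  per-edge selection counts as Binomial(B, p_chance). Bootstrap iterations
  resample the *same* subjects, so an edge whose chance correlation happens
  to be extreme in the observed sample stays extreme across resamples:
  per-edge selection probabilities are heterogeneous and the count
  distribution is an overdispersed binomial mixture. On fully decoupled
  panels at m = 17 this inflates the fraction of edges crossing the upper
  threshold to roughly twice the nominal α, and a goodness-of-fit test
  against the binomial (provided as `selection_count_gof`) rejects. The
  randomised-Lasso perturbation reduces but cannot remove this dependence.
  Decisions near the thresholds should be read accordingly; with strong
  true coupling the selected set is driven by edges whose counts sit far
  above the threshold, where the approximation is immaterial.
- Rank-1 only: a single canonical variate is fitted (K = 1); multi-factor
  coupling is projected onto its dominant direction.
- Linear model: sCCA encodes only linear structure–function relationships.
- Edges missing in any subject are excluded, which disproportionately
  removes interhemispheric connections and limits what can be said about
  them.
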