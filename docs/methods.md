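# Methods

## Task model

The simulator (`arbrl.task`) generates probabilistic reversal-learning
blocks of 80 trials. Each block draws a reward schedule uniformly from
80/20, 70/30, 60/40 (`p_better` ∈ {0.8, 0.7, 0.6}; the worse option pays
the complement), a reversal trial uniformly from the inclusive range
30–50, and an initially better option. The better/worse assignment flips
at and after the reversal trial. In the What-only task every block is a
What block (reward follows stimulus identity); in the What/Where task each
block is independently a What or a Where block (reward follows screen
side) with probability ½. Two stimuli (A/B) are assigned to the left/right
sides independently per trial with probability ½; an exact
within-block counterbalancing option exists behind a flag
(`balanced_sides=True`), since the original side-assignment scheme is only
described as pseudo-random. Every simulated trial completes (no aborts),
and the degenerate 100/0 schedule is available only as an explicit
`BlockSpec` for tests. Sessions default to 20 blocks.

What the generator does *not* emulate: reaction times, aborted/repeated
trials, eye movements, satiation or other session-level drifts, and any
across-block carryover of stimulus familiarity (stimuli are novel each
block by design). Passing tests therefore demonstrate correctness of the
algorithms under the task's reward structure, not robustness to those
real-data features.

## Model family

Eight models share one engine (`arbrl.models`, jitted kernel in
`arbrl._kernel`):

| id | free parameters | k |
|---|---|---|
| `stim_only`, `action_only` | α₊, α₋, ζ, β₁, β₀ | 5 |
| `static_omega` | + ω | 6 |
| `dynamic_omega_{vcho,absrpe,absdv,sumv}` | + ω₀, α_ω, ζ_ω | 8 |
| `dynamic_omega_rho` | + ρ | 9 (8 with ρ pinned) |

Parameter bounds: all rate/weight parameters in [0, 1], β₁ ∈ [0, 100],
β₀ ∈ [−5, 5]. These are repository defaults, overridable per fit.

Fixed per-trial order of operations:

1. overall values from the current state and the trial's side layout;
2. softmax choice probability (logit β₁·ΔOV + β₀, natural parameters);
3. observe (or draw) choice and reward;
4. reliability signal ΔRel and both RPEs from the **pre-update** values;
5. value update (α₊ on rewarded, α₋ on unrewarded trials; unchosen value
   multiplied by 1 − ζ in both systems);
6. arbitration update (dynamic models): ΔRel > 0 moves ω toward 1 at rate
   α_ω·ΔRel, ΔRel < 0 toward 0 at rate α_ω·|ΔRel|, and the decay
   ζ_ω(ω₀ − ω) applies on every trial.

The pre-update convention in step 4 is what makes the identity
ΔV_cho = RPE_Action − RPE_Stim hold exactly on every trial (both sides use
the same V(t)); computing ΔRel from post-update values would merely rescale
it by (1 − α±) but break that identity against the recorded RPEs. The
simultaneous form of the ω update can overshoot [0, 1] marginally at
extreme corners (α_ω·ΔRel and ζ_ω both near 1 with ω₀ near 1), so the
result is clipped to [0, 1]; a sequential decay-then-drive form would be
closed but disagrees with the update's stated arithmetic.

Value initialization is not an observable of the task; all four values
start at `v_init = 0.5` (midpoint of the 0/1 reward range, making the
initial ΔRel zero so arbitration starts unbiased), configurable to 0. The
full state — both value systems and ω — resets at every block start: the
stimuli are novel each block, and resetting action values too keeps the
systems symmetric (carrying action values across blocks is a plausible
alternative we did not adopt; the flag-level machinery fits either choice).

Likelihoods are natural-log with per-trial probabilities clipped to
[1e−10, 1 − 1e−10]. Entropies are in bits. The effective weight
Ω = ρω/(ρω + (1−ρ)(1−ω)) is defined at the degenerate corner
(denominator 0) by continuity along ρ = 0.5, i.e. it returns ω's corner
value.

## ERDS

ERDS is the plug-in conditional entropy H(stay/switch | previous reward)
in bits, computed from the empirical 2×2 counts with the 0·log 0 = 0
convention and no smoothing; windows containing only wins (or only losses)
reduce to the entropy of the observed branch. Stay flags never cross block
boundaries and the first trial of a block is masked. The 10-trial
dominance window is trailing (causal) — chosen so labels could be aligned
with concurrent behavior such as reaction times — and trials whose window
is incomplete are unlabeled; ties (ERDS_Stim = ERDS_Action) are labeled
for exclusion downstream.

## Fitting

Per-session maximum likelihood by L-BFGS-B from `n_starts` uniform-random
initial points within bounds (β₁ starts drawn from [0, 20]: uniform starts
over the full [0, 100] bound put nearly all mass in the saturated-softmax
plateau). Convergence tolerance 1e−9 on the objective; the best start is
kept and logged. The paper-scale protocol is 100 starts; the desk-scale
profile used in tests and experiments is 10–20.

ρ is a subject-level constant: stage 1 fits one parameter set to all of a
subject's sessions jointly (valid because the state resets at block
boundaries, so the likelihood factorizes over blocks), stage 2 refits each
session with ρ pinned. Per-session fits of the ω-ρ model with ρ free are
*not* identified — the choice logit constrains only the products β₁ρω and
β₁(1−ρ)(1−ω), and the optimizer drifts to large-β₁/extreme-ρ ridges. The
parameter-recovery experiment therefore organizes sessions into synthetic
subjects (10 sessions each) exactly as the two-stage procedure expects.
Relatedly, in the deterministic-reward limit with saturated β₁ the gain
learning rate α₊ is unidentified (it only controls how fast the chosen
value approaches a ceiling the choice rule no longer resolves), while α₋
is pinned tightly by post-reversal switching; tests assert the latter.

AIC = 2k + 2·(−LL) with k the number of free (non-pinned) parameters; ties
break toward fewer parameters. McFadden R² = 1 − ΣLL_model/ΣLL_null with
the null at −LL = 80·ln 2 per 80-trial block (log-base cancels in the
ratio). Cross-validation partitions a subject's blocks into k = 5
near-equal folds per repeat, fits one parameter set to the training folds
and scores each held-out block; the headline score is the mean held-out
−LL per block over all blocks and repeats.

## Arbitration rates

ψ₊ = [ΔΩ]⁺/(1 − Ω), ψ₋ = [ΔΩ]⁻/(0 − Ω) per trial, with ψ₊ := 0 at Ω = 1
and ψ₋ := 0 at Ω = 0 (no headroom in that direction). The pair exactly
inverts to the Ω trajectory, which is tested. Δψ is the post-reversal
mean ψ₊ minus mean ψ₋ (trials at or after the reversal, avoiding the
ω₀-dominated acquisition phase).

Two Δψ summaries exist and differ systematically. Averaging per-block Δψ
carries a negative offset whenever Ω < 0.5, because the 1/Ω normalization
of ψ₋ amplifies downward fluctuations relative to upward ones; under the
canonical grid parameters this offset masks the regime pattern. Reading ψ
off the reversal-aligned *across-block mean* Ω trajectory — the quantity
the averaged-trajectory figures display — removes the fluctuation term and
recovers the pattern: Δψ > 0 for the control-like cell (ω₀ = 0.374,
ρ = 0.5), |Δψ| smaller for the amygdala-like cell (ω₀ = 0.179), Δψ < 0 for
the VS-like cells (ρ = 0.4). `lesion_grid_sim` reports the mean-trajectory
version as `delta_psi` and the per-block average as `delta_psi_block`.

Trajectory alignment uses three 20-trial segments per block (forward from
block start, forward from reversal, backward from block end); the 5-trial
moving-average smoothing is applied within each segment only, so nothing
leaks across the acquisition/reversal boundary, and bins a short block
cannot fill are NaN-masked. The group permutation test shuffles group
labels (default 10,000 shuffles) and counts the observed labeling in both
numerator and denominator, so p is never 0.

## Simulation experiments and problem sizes

The grid experiments fix α₊ = α₋ = 0.5, β₀ = 0, ζ = 0.3, α_ω = 0.2,
ζ_ω = 0.05 (the canonical simulation values) and sweep ω₀ × ρ × β₁. Grid
defaults follow the mechanism-figure conventions — a single 80/20
schedule, reversal pinned at trial 40 so trajectories align without
truncation, β₁ = 20 — with the experiment's randomized draws available via
`p_better=None` / `reversal_trial=None`; with mixed schedules the
control-vs-amygdala |Δψ| contrast sinks to simulation-noise level. The
long-horizon variant uses 200-trial blocks with reversal at trial 100.

Recovery experiments sample generating parameters uniformly from a
plausible-behavior envelope (α± ∈ [0.2, 0.8], ζ ∈ [0.05, 0.5],
β₁ ∈ [2, 15], β₀ ∈ [−0.5, 0.5], ω's ∈ [0.1, 0.9], α_ω ∈ [0.05, 0.5],
ζ_ω ∈ [0.01, 0.2], ρ ∈ [0.3, 0.7]); the original protocol sampled from
kernel densities over fitted animal parameters, which requires the animal
data. Cohort generation uses truncated-normal group distributions whose
ω₀ means follow the fitted group values (control 0.374 ± 0.058, amygdala
0.179 ± 0.053) and whose VS-like group lowers ρ to 0.4.

Desk-scale sizes (used by the test suite and `scripts/acceptance.py`, all
single-CPU): parameter recovery 30 sessions × 20 blocks with 20 optimizer
starts; ρ recovery one 10-session subject; model recovery 200 sessions of
30 blocks with 10 starts; cross-validation one 30-block subject, k = 5,
10 repeats, 10 starts; grids 2,000 blocks per cell (the headline
simulations used 10,000); ERDS-interaction 8 subjects × 100 blocks per
generating model. The ERDS-interaction regression uses the within-subject
fixed-effects form (subject-mean-centered predictor plus subject
dummies) — the transparent analogue of a random-intercept model with an
equivalent point estimate for this balanced design.

## Known limitations

- Recovery quality is reported for the envelope above; near parameter
  bounds (β₁ → 0, α_ω → 0) identifiability degrades as expected.
- The ANOVA-style claim that ω₀ drives simulated performance is tested
  directionally (monotone P(Better) across the ω₀ grid), not as an exact
  F statistic, whose original design is underdetermined.
- Mixed-effects group inference on fitted parameters is out of scope; the
  permutation test covers the small-sample group contrast (ρ).
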