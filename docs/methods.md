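# Methods

## The trial and its endpoints

An experimental hut trial exposes wild, free-flying mosquitoes to
candidate bednets under semi-natural conditions: volunteers sleep in
standardized huts, mosquitoes enter through baffled window slits, and
each morning every mosquito in the hut is collected and scored. The
design analysed here has 10 huts, 10 sleepers and 5 arms with 2
replicate nets each: an untreated net (negative control), a
pyrethroid-only net, a pyrethroid+PBO net, a pyrethroid+pyrrole
dual-ingredient net, and the candidate — a pyrethroid net with an
insecticide-free trap compartment mounted on its roof, exploiting the
concentration of host-seeking activity there.

Every collected mosquito gets exactly one fate: `trapped` (in the trap
compartment), `dead_untrapped` (dead in the room or window traps),
`alive_delayed_dead` (collected alive, dead after 24–36 h of holding
with sugar access), or `alive_survived`. The **kill count** is the sum
of the first three: a trapped mosquito is counted as killed even if
alive at collection, because trapping removes it from the biting and
breeding population as surely as insecticide. Mortality is kills over
entries; the **trap-attributable share** is trapped kills over all
kills. Only the kill endpoint is analysed: deterrence, exit rate and
blood-feeding inhibition are deliberately out of scope, since the
insecticidal half of the candidate is a standard, already-characterised
net and the trap compartment's contribution is mortality.

## The increased killing effect

The candidate's added value over a reference net is expressed as a
percentage of a normalising catch. Two variants circulate in print for
this statistic, and they disagree:

* methods variant: `100·(K_cand − K_ref)/T_ref`, normalised by the
  reference arm's own catch;
* control-adjusted variant:
  `100·[(K_cand − K_un) − (K_ref − K_un)]/T_un`, normalised by the
  untreated-control catch. The control kill count `K_un` cancels
  algebraically, so the value reduces to `100·(K_cand − K_ref)/T_un`;
  the implementation keeps the full form in its inputs and the test
  suite verifies the cancellation as a quantified property.

Applied to the published arm totals, the control-adjusted variant
yields 58.89 / 38.44 / 31.78 % against the pyrethroid, PBO and
dual-ingredient references — within 0.5 points of the printed
58.5 / 38 / 31.5 — while the methods variant yields 52.06 / 24.79 /
23.40 % and cannot reproduce the printed values. Both are implemented;
`control_adjusted` is the default, and the reproduction table flags the
discrepancy rather than hiding it. The residual ≤0.44-point gap under
the preferred variant is unexplained by either printed formula (likely
rounding or a slightly different denominator in the original
spreadsheet) and is documented, not corrected for.

## Rotation design

Sleepers rotate huts by a daily cyclic shift; physical nets rotate
every 3 nights (the rotation period is configurable) following a
randomized Latin square over nets × huts — a random row, column and
symbol permutation of the cyclic square, which preserves the Latin
property. Over a full cycle of `n_huts` blocks each net occupies each
hut exactly once, so each arm (2 nets) accumulates exactly
`2 × period` nights per hut per cycle; a trial length that is not a
multiple of the period truncates the final block. The validator checks
occupancy, sleeper permutations, block-constancy of the net layout and
per-net hut coverage, and returns named violations rather than
raising. The total number of nights is free; the default of 34 nights
matches the ≈68 hut-nights per arm implied by the published daily
means. Huts are treated as exchangeable units (their empirical
comparability is what the blank pre-trial collections establish);
hut-position effects beyond the simulator's random hut multipliers are
not modelled.

## Inference

Nightly counts are overdispersed, so all comparisons are rank-based
with mid-ranks and tie-corrected variances throughout:

* **Kruskal–Wallis** with the tie-corrected H and a chi-square
  reference distribution (k−1 df). A `method="exact"` option enumerates
  every assignment of the pooled observations to groups of the observed
  sizes, giving the exact permutation p-value for small samples; it
  exists so the asymptotic path can be checked against enumeration.
* **Conover–Iman** pairwise comparisons: t statistics on rank means
  using the pooled tie-corrected rank variance
  `S² = (ΣR² − N(N+1)²/4)/(N−1)` scaled by `(N−1−H)/(N−k)`, referred to
  Student's t with N−k df, two-sided, with Bonferroni multiplication by
  k(k−1)/2 capped at 1. No scipy/statsmodels implementation of this
  procedure exists, so it is implemented here and oracle-checked
  against exact permutation tests. Degenerate inputs (no residual rank
  variance) yield p = 1 for tied pairs and p = 0 for separated ones.
* **Rank-sum (Wilcoxon/Mann–Whitney)** for head-to-head comparisons of
  the candidate against each arm; read as the two-sample test, since
  arms sit in different huts and are not paired. Exact conditional
  enumeration of the rank sum given the observed (tied) ranks when the
  combined n ≤ 12; otherwise the normal approximation with
  tie-corrected variance and no continuity correction, keeping p-values
  symmetric in the samples and invariant under monotone transforms.
* **Compact letter display** by insert-and-absorb: start with one class
  holding all groups; every significant pair splits each class
  containing both; absorbed (subset) classes are dropped; letters are
  assigned a, b, c … in first-use order. The defining biconditional —
  two groups share a letter iff their difference is non-significant —
  holds by construction and is verified exhaustively in the tests.

Alpha is 0.05 everywhere, matching the trial's analysis.

## Simulator

The generator reproduces the statistical structure the analysis
assumes, not mosquito behaviour. Per hut-night and species group,
entries are negative binomial with mean
`baseline · hut_effect · night_effect · entry_multiplier · species share`
and dispersion `k` (variance μ + μ²/k). Defaults:

| parameter | default | rationale |
|---|---|---|
| `baseline_entry_mean` | 23.0 (calibrated set) | published total catch of 7835 over 340 hut-nights; the An. gambiae stream then averages ≈8.9/hut-night as in the published table |
| `entry_dispersion` k | 1.5 | published daily mean 11.2 with SD 10.6 implies variance ≈ μ + μ²/1.5 |
| `hut_effect_sd` | 0.15 | modest log-scale hut heterogeneity; mean-one log-normal |
| `night_effect_sd` | 0.25 | nightly swings shared across huts (weather, moon); sleeper attractiveness folds in here, it is not separately identifiable |
| `species_mix` | 0.388 | published An. gambiae share 3041/7835 |

Fates are drawn sequentially per entrant — trap, then immediate
insecticide kill, then delayed death — mirroring the roof-first
approach behaviour and making the categories mutually exclusive; the
holding window is a single Bernoulli, not time-resolved. The closed
forms

    mortality  m = p_trap + (1−p_trap)·p_imm + (1−p_trap)(1−p_imm)·p_del
    trap share = p_trap / m

are exposed per arm, and expected killing effects follow from expected
kill and entry totals.

The generic `ArmEffects` default sets `entry_multiplier = 1` for every
arm (the published entry letters show no significant entry
differences). The calibrated set `source_trial_params()` is different by
design: its fate probabilities solve the closed forms for each arm's
published mortality (and the candidate's 317/678 trap share), and its
entry multipliers are the arms' published entry totals relative to the
grand mean (0.74–1.26). The entry imbalance matters because the
killing-effect statistic is built from raw counts: with equal expected
entries the control-adjusted effect would collapse to
`100·(m_cand − m_ref)` ≈ 8 %, whereas the published ≈59 % value is
driven largely by the candidate's higher catch (760 vs 509 vs 450).
Immediate-kill probabilities (0.55–0.70 for treated arms, 0.15
untreated) apportion mortality between immediate and delayed death in
realistic proportions; only their combination is identified by the
published totals.

What the simulator does **not** emulate: spatial/behavioural dynamics
around the net, insecticide decay, sleeper-specific attractiveness,
escape or scavenging losses, and any arm-by-night interaction.
Passing recovery tests therefore show the estimator chain is unbiased
under the assumed count model — not that the model captures every
feature of field data.

## Verification strategy and problem sizes

* The in-report worked example (printed totals → 89.2 % mortality,
  46.75 % trap share, species split, killing effects) is recomputed
  exactly; it is pure arithmetic and runs in milliseconds.
* Rank tests are checked against independent brute-force permutation
  enumeration (combined n ≤ 9; 100 random instances; agreement to
  1e-9), Latin squares and schedules across 200 seeds, the letter
  biconditional across 200 random significance patterns up to 8 groups.
* Parameter recovery simulates 2 huts/arm × 2000 nights for three
  seeds — large enough that binomial noise on mortality is ≈0.2
  percentage points, against a 1-point tolerance — and scores
  killing-effect deviations in Monte-Carlo standard errors estimated
  from 12 independent replicate simulations (≈3–5 points at this size;
  the dominant noise source is the negative-binomial entry process, as
  the balanced rotation averages hut effects out). The numbered
  analysis scripts use a shorter 1000-night version of the same check.

## Known limitations

* The published daily SDs and significance letters cannot be validated
  against the raw nightly data (unpublished); they are covered by
  properties and simulation only.
* The Conover–Iman implementation follows the classical pooled-variance
  formulation; it can flag pairs that small-sample exact pairwise tests
  cannot reach (by design — it borrows df across groups), so its
  small-sample behaviour is checked structurally, not by p-value
  identity.
* The control-adjusted killing effect is a ratio of random totals;
  its estimator carries O(1/N) ratio bias, negligible at the trial
  sizes simulated here but not corrected for.
* Window-trap versus in-room location of untrapped dead mosquitoes is
  collapsed into one category; no published endpoint distinguishes
  them.
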