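# Methods

## Model overview

The model compares three newborn screening strategies on a closed cohort of
9,560,000 neonates followed for 78 annual cycles. Each strategy is a
decision tree evaluated in expectation (no microsimulation at the screening
stage): branch probabilities are multiplied down every root-to-leaf path,
yielding expected person-counts per outcome category. Each category maps to
an initial state of a Markov cohort model with states

| state | utility | annual cost (USD) | first-year cost (USD) |
|---|---|---|---|
| normal hearing | 1.00 | — | — |
| unwarned mtDNA carrier | 1.00 | — | — |
| mild/moderate (M/M) loss, untreated | 0.80 | — | — |
| M/M with hearing aid | 0.96 | 302 | 1,960 |
| severe/profound (S/P) loss, untreated | 0.54 | — | — |
| S/P with cochlear implant | 0.80 | 1,500 | 30,000 |
| ototoxic deafness | 0.54 | — | — |
| dead | 0 | — | — |

Every alive state dies with the age-specific annual probability q(a); device
and untreated states otherwise persist (no late-detection pathway for
undetected hearing loss — this persistence is exactly what generates the
incremental QALYs of screening). Unwarned mtDNA 12S rRNA carriers acquire
ototoxic (aminoglycoside-induced) deafness with a constant annual hazard;
warned carriers avoid it entirely (all-or-nothing medication avoidance).

Costs and utilities accrue once per cycle entered alive and are discounted
by (1+r)^-t with t = 0 for the first cycle; there is **no half-cycle
correction**. One-time screening-phase costs (hearing screen 11.93, gene
panel 34.1, hearing diagnosis 170, genetic diagnosis 335 USD) and first-year
device costs are charged at t = 0; annual device maintenance starts at the
second cycle. These conventions are pinned by closed-form unit tests (a
one-person hearing-aid cohort over two cycles costs exactly 1,960 + 302 and
yields 2 × 0.96 QALYs).

## Tree topologies

The three topologies live in a declared YAML file
(`data/topology_default.yaml`); alternative branch attachments can be tested
by passing a different file — no code changes needed. Branch probabilities
are parameter names or small arithmetic expressions over them. The source
branch tables for the referral subtree are not mutually consistent between
arms; the default file implements the following documented reading:

- **Referrals (fail UNHS, 1.06%)** are all audiologically diagnosed in every
  arm: 20.82% have hearing loss (76.94% M/M, 23.06% S/P). Diagnosed M/M
  cases receive hearing aids with 100% uptake; S/P cases receive cochlear
  implants with 50% uptake (a sweepable policy parameter, range 0.2–1.0).
  In the targeted arm the gene-panel split (pass 0.92 / fail 0.08 among
  normal-hearing referrals; 0.4507/0.5493 among hearing-loss referrals)
  routes diagnosis costs and mtDNA warnings and leaves the audiological
  tallies untouched, so UNHS-only and targeted report identical diagnosed /
  hearing-aid / implant counts, as in the source performance table.
- **Delayed hearing loss among UNHS-passers** has marginal probability 0.003
  in *every* arm (disease prevalence must not depend on the screening
  strategy). The double-pass residual 0.00047 stays hidden; the concurrent
  arm detects the remainder — the derived conditional rate
  (0.003 − 0.9513·0.00047)/(0.0487·(1 − 0.0577)) ≈ 5.6% of pass-UNHS
  gene-screen failures, about 24,000 newborns — and routes it to early
  intervention. Both published rates are honored; only the conditional
  detection rate is derived.
- **mtDNA 12S rRNA carriers.** The identified-carrier masses are taken
  per-arm as published: concurrent identifies cohort × 0.9894 × 0.0487 ×
  0.0577 + cohort × 0.0106 × 0.149 × 0.0303 ≈ 27,036; targeted identifies
  cohort × 0.0106 × 0.7918 × 0.08 × 0.0029 ≈ 19. Arms that do not screen a
  subpopulation carry the same latent mass as unwarned carriers, so carrier
  prevalence is strategy-invariant even though the two published
  identification readings disagree. Carriers are split out of
  normal-hearing branches only (≈0.3% of carriers with concurrent hearing
  loss are approximated as normal-hearing).
- The concurrent arm's published "diagnosed 34,224 / 17,775 hearing aids /
  8,225 implants" cannot be derived from any combination of the published
  branch probabilities; those tallies are intentionally not pinned anywhere.

Reported tallies are rounded half-up to integers at reporting time only;
internal arithmetic is real-valued throughout (linearity in cohort size is a
tested invariant).

## Parameters

All 55 parameters (baseline, one-way range, PSA distribution) live in
`data/default_config.yaml`. Ranges published as ±20% are materialized to
explicit (low, high) at load time, clamped to [0, 1] for probabilities and
utilities; explicit intervals are taken verbatim. Sibling branches that
must sum to one are declared as probability groups; overriding one member
rescales the rest proportionally (overriding the UNHS failure rate to 0.0124
makes the pass rate exactly 0.9876). Currency is USD throughout.

One parameter is the package's own: `ototoxic_annual = 0.002/yr` (±20%),
the ototoxic-deafness hazard of an *unwarned* carrier, equivalent to a ≈14%
lifetime risk. The source model implies a nonzero risk (otherwise warnings
would carry no health benefit and the targeted arm's QALY gain would be
exactly zero, leaving its ICER undefined); 0.002 reflects historically
common aminoglycoside exposure and high penetrance in m.1555A>G carriers.
It is deliberately conservative and fully sweepable.

## Mortality

The census life table used by the source analysis is not redistributable, so
the model ships a parametric stand-in (`lifetable.csv`, regenerable with
`hearscreen lifetable`): q(0) = 0.005 (infant mortality) and for a ≥ 1 the
Gompertz–Makeham form q(a) = 1 − exp(−(c + b·e^{g·a})) with c = 3×10⁻⁴,
b = 2×10⁻⁵, g = 0.101, table to age 110. These values were fixed once so
that life expectancy at birth is 78.4 years (target ≈78, the figure that
motivates the 78-year horizon); a test pins the calibration to [77, 79].
Mortality is sex-averaged and identical across alive states (hearing loss
is not assumed to raise mortality). The synthetic table reproduces the
*shape* real schedules share (infant spike, low child/adult mortality,
exponential senescent rise) but none of their cohort-specific structure, so
absolute lifetime totals should be read as model-conventional, not
demographic, quantities.

## Sensitivity analyses

**One-way (tornado).** Each parameter with a nondegenerate range is set to
its low and high bound (siblings renormalized), the full pipeline re-runs,
and the ICER span is tabulated; entries are sorted by span, top-20 by
default. Degenerate ranges yield zero-span entries, flagged not dropped.

**Probabilistic.** Probabilities and utilities are drawn from beta
distributions, costs from gammas, each fitted by the method of moments with
the mean at the baseline and sd = (high − low)/(2·1.96) — ranges are read as
95% intervals. This convention is the most common one; it is isolated in
`fit_beta`/`fit_gamma` so it can be swapped. Beta fits whose implied
variance exceeds mean(1−mean) are variance-capped at 99% of that bound.
After sampling, each probability group is renormalized to sum to one. Each
draw owns a spawned random substream of the master seed, so enlarging the
sample never changes earlier draws and same-seed reruns are byte-identical.
CE-plane draws on an axis count toward the positive side; CEAC ties split
equally — deterministic, testable tie rules.

## Verification

- A seeded individual-level Monte Carlo simulator (10,000 persons) agrees
  with the cohort-matrix engine within 3 standard errors for cost and QALY
  under every strategy.
- Closed-form limits: zero mortality gives horizon × cohort QALYs; constant
  mortality matches the geometric series; the hand-computed two-cycle
  hearing-aid case pins cycle timing.
- ICER arithmetic is verified against published incremental tables to the
  printed 2-decimal precision.
- Property tests cover probability conservation at every chance node under
  arbitrary single-parameter perturbations, group renormalization, tree
  linearity, survival-curve monotonicity, and discount-rate monotonicity of
  the totals.

## Known limitations

- The targeted arm's only QALY channel is its 19 ototoxicity warnings, so
  its ICER versus UNHS-only is far *above* the concurrent arm's here,
  whereas the source analysis reports the reverse ordering; its published
  incremental QALYs (650,218 undiscounted from 19 warnings) cannot arise
  from per-year utilities ≤ 1 under any hazard, so the orderings of
  absolute ICERs between the two gene-screening arms are not reproducible
  within this accounting. Incremental *directions* (both arms more costly
  and more effective than UNHS-only; gene-screening cost monotonically
  worsening the concurrent ICER) are reproduced and tested.
- No indirect/societal costs, no DALYs, no false-positive/negative test
  characteristics beyond the pass/fail rates, no late detection of missed
  cases, no device re-implantation events (maintenance is folded into the
  annual cost), and a single birth cohort.
- Problem sizes used by the shipped analyses: full 9.56M-newborn trees
  (deterministic expectations, so cohort size costs nothing), 10,000-person
  micro-simulation, 1,000 PSA draws.
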