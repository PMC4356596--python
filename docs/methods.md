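# Methods

This note documents the model encoded by `autoswitch`, the numerical
protocols built on top of it, the choices made where the design was
genuinely open, and what the tests do and do not establish.

## The rule-based model

The model tracks seven molecule types with explicit binding sites and
phosphosites:

| molecule | sites | role |
|---|---|---|
| `rapa` | `mtor` | FKBP1A-bound rapamycin (rapamycin\*); input |
| `AMPK` | `ulk1`, `T172~P`, `ST~0~P` | AMPK\*; input.  `ST` lumps the ULK1-phosphorylated inhibitory residues |
| `MTOR` | `HEAT`, `FRB` | kinase of MTORC1; active only when RPTOR-bound |
| `RPTOR` | `RNC`, `ulk1`, `WD40`, `S792~0~P`, `S855_S859~0~P~PP` | MTORC1 scaffold; ULK1/AMPK substrate |
| `ULK1` | `straptor`, `stampk`, `S317~0~P`, `S758~0~P`, `S778~0~P` | autophagy-initiating kinase |
| `EIF4EBP1` | `RCR`, `S65_T70~0~P` | translation reporter (MTORC1 substrate) |
| `AMBRA1` | `ST~0~P` | autophagy reporter (ULK1 substrate) |

Twenty-nine rewrite rules (two of them reversible) encode: mutually
exclusive binding of rapamycin\* and RPTOR to MTOR; RPTOR–ULK1 binding
(destabilized ~100-fold when RPTOR is fully phosphorylated at S792 +
S855/S859); RPTOR–EIF4EBP1 binding; AMPK–ULK1 binding (blocked by ULK1
pS758); MTORC1-mediated phosphorylation of ULK1 S758 and EIF4EBP1;
ULK1-mediated phosphorylation of RPTOR S792 and S855/S859, AMBRA1, and AMPK
(the slow negative feedback, rate constant `p6`); AMPK-mediated activation of
ULK1 at S317/S778; AMPK-mediated phosphorylation of RPTOR S792 (rate `p9`,
nominally zero); and first-order dephosphorylation of every site.

Only orders of magnitude are assigned to rate constants (one significant
digit).  Complex-colocalized phosphorylations are fast pseudo-first-order
steps (10 s⁻¹); bimolecular phosphorylations (`p5`, `p6`, `p9`) are
kcat/KM-style pseudo-second-order constants; the common dephosphorylation
constant `u0 = 10⁻² s⁻¹` sets the ~100 s characteristic response time, with
RPTOR pS792 protected (`u1 = 0.1·u0`) and the AMPK feedback sites much
slower (`u2 = 0.01·u0`, the oscillation time scale).  Effective abundances
are 10⁴–2·10⁴ copies/cell.  Inputs enter as fixed totals of the `rapa` and
`AMPK` seed monomers; nothing in the model creates or destroys molecules
(outside the sweep drift described below), so per-type totals are conserved.

Notable encoding choices where the source material left room:

* **AMPK T172.**  Every AMPK copy in the model carries activating
  kinase-domain phosphorylation (that is what AMPK\* means), so `T172` is
  declared as a state site fixed at `P`; rules that test `T172~P` apply
  verbatim and the site can never change.
* **Rules are the executable specification.**  The prose description of ULK1
  activity also mentions S758, but the kinase-competence context actually
  used by the rules is "straptor free + S317~P + S778~P"; we implement the
  rules exactly as written.  Likewise both S792 dephosphorylation rules
  (with `u1` and with `u0`) are present — the 27-rule unidirectional census
  only closes with both — so the effective relaxation rate of pS792 is
  `u0 + u1`.
* **Site-name variants.**  The parser normalizes the spelling variants
  `S855_Ser859` and `S855-9` to the canonical `S855_S859`.

## Network generation

Expansion applies every rule to every species (or ordered species pair) and
adds novel products until closure, with these semantics:

* A reactant pattern must embed within a single species; patterns separated
  by `+` must match *separate* complexes.  Mentioned sites without a bond
  are required free; unmentioned sites are unconstrained.
* One unidirectional reaction is generated per (rule, reactant tuple,
  embedding); reactions identical in rule, reactants and products are merged
  by an embedding multiplicity (the nominal model never exceeds 1, which a
  regression test enforces — the only doubled transitions, `2*p4` and
  `2*u0`, carry explicit statistical factors instead).  Identical reactions
  from *different* rules are kept distinct.
* Reactions are generated symbolically, regardless of the numeric rate
  value: `p9 = 0` still contributes its reactions and the species reachable
  only through them.  This matches how network-generation tools treat rate
  parameters and is what the published census counts.

Under these semantics the nominal model closes at **173 species and 6,581
reactions**, which was verified against an independent hand enumeration of
the reachable complex classes (45 species outside RPTOR–ULK1 complexes plus
four 32-state RPTOR–ULK1 complex families; per-rule reaction counting sums
to 6,581, dominated by the 74×74 `p9` pairs).  Canonical species labels come
from Weisfeiler–Lehman-style refinement with an exhaustive permutation
fallback; the toy fixtures and the permutation/brute-force oracles in the
test suite guard both the labeling and the matcher.

## ODE simulation

The mass-action system d**x**/dt = S·v(**x**) (v_r = k_r·∏ reactant amounts,
squared for a doubled reactant) is integrated with SciPy's BDF using an
analytically assembled sparse Jacobian.  Default tolerances are
`rtol = 1e-8`, `atol = 1e-6` copies/cell for trajectory work; the regime
classification sweeps use `rtol = 1e-6`, `atol = 1e-3`, which changes regime
labels by nothing and branch values by ≪ the 0.2 bistability threshold.
Conservation of the seven per-type totals over a stress trajectory is better
than 10⁻¹⁰ relative and is asserted to < 10⁻³ in the tests.

Stress scenarios start from the unstressed steady state (AMPK\* = 30,000,
no rapamycin\*, relaxed until max |dx/dt|/max(1,|x|) < 10⁻¹⁰) and reset the
input totals at t = 0 by adding or removing *free unmodified monomer* only,
leaving complexes untouched — step-stimulus semantics.

## Numerical bifurcation protocol

Stable steady states and stable limit cycles are found by *slow drift*: the
network is augmented with a zeroth-order source (up sweep) or a saturating
sink (down sweep, rate `k_eps·y/(y+10)` so removal switches off smoothly as
the free pool empties) acting on the free monomer of the drifted input.  The
default drift traverses the sweep range in 5,000 characteristic response
times (`k_eps = range·u0/5000`, i.e. ~5·10⁵ s of model time), slow enough
that halving it moves quiet-branch values by well under 1% (checked by
`check_drift_rate` and a regression test; the residual drift-rate dependence
concentrates at the jump points).  The recorded abscissa is the actual
conserved total of the drifted molecule type, so the sink's nonlinearity
cannot bias branch positions.  Unstable steady states and unstable cycles
are invisible to this protocol by construction, and bifurcation-point
coordinates are therefore only ever reported as bracketing grid intervals.

* **Bistability**: input intervals where up- and down-sweep AMBRA1-P
  fractions differ by > 0.2 (large enough to exclude numerical ripple and
  drift lag, small enough to catch every branch separation of the switch,
  whose open-vs-closed branches differ by ~0.9).
* **Limit cycles at fixed inputs**: after a discarded 40 h transient,
  40 h analysis windows are integrated until two consecutive windows agree;
  oscillation means peak-to-trough of AMBRA1-P > 0.01 with ≥ 2 detected
  peaks.  The period is the mean mid-level crossing interval; below
  amplitude 0.05 (small cycles near a supercritical Hopf) the mean peak
  spacing is used instead.
* **Phase durations**: the autophagy (translation) phase is the time per
  cycle above (below) AMBRA1-P = 0.5; the two durations sum to the period.
* **Two-parameter maps** are stacks of 1D up+down sweeps (one row per value
  of the second parameter), each cell labeled oscillatory / bistable /
  translation / autophagy from the windowed sweep statistics.  Maps are
  deterministic and traversal-order-free by construction.
* **Rate-constant sweeps** (no monomer pool to drift) fall back to stepped
  quasi-static continuation, carrying the state between log-spaced values.

## Sensitivity protocol

Each of the 22 rate constants (all but `p9`) is scaled by 10^(n/4),
n = −8..8, and two input scans are classified: AMPK\* 0→10⁶ (rapamycin\*
absent) and rapamycin\* 0→10⁵ (AMPK\* = 3·10⁴).  A scan is *canonical* when
its regime sequence is exactly translation → oscillatory → autophagy.
Scans are single slow up-drift sweeps with 40 windowed labels rather than
per-point limit-cycle runs — the same observable, ~40× cheaper, and the form
in which the response-pattern examples were originally generated.  Because
the period diverges at the SNIC onset, windows there can contain less than
one cycle; maximal runs of such ambiguous windows are re-swept over their
own subrange with proportionally slower drift (one refinement level) before
the sequence is read off.  The robustness bar of a parameter is the largest
contiguous multiplier run containing n = 0 on which **both** scans are
canonical; the outward scan from n = 0 stops at the first failure per side,
so bars are contiguous and contain the nominal value by construction.
Results are cached per (parameter, multiplier, scan) to make the full
22×17×2 protocol — hours on one CPU — restartable; the reduced grid
n ∈ {−8, −3, 0, 3, 8} covers the headline checks in minutes.

### The p6 upper boundary

The reduced protocol reproduces: `p4` robust across the full hundredfold
range on both scans; `u0` and `u2` (response time and feedback time scale)
the most fragile, losing the pattern at the hundredfold extremes; `p6`
(feedback strength) canonical at 10^(3/4)× and at 10^(−2/4)× but switching
abruptly without oscillations at 10^(−3/4)×.  At 10^(4/4)× the two accounts
of the source analysis disagree with each other (the stated robustness bound
includes it; the plotted example calls it monotonic).  Our computed
resolution: at `p6`×10 the AMPK\*-scan is still genuinely canonical — fixed
input integration shows stable limit cycles of amplitude ~0.8 for AMPK\*
between ~1.5·10⁵ and ~3·10⁵ — while the rapamycin\*-scan loses the pattern
from 10^(2/4)× on, so the *both-scans* robustness bar of `p6` ends at
10^(1/4)×.  The package reports these computed bounds.

### Phase-duration insensitivity

Across probes at AMPK\* = 60–120·10³ the period falls from 5.5 h to 1.8 h;
the translation phase carries essentially the whole decrease (5.1 h →
1.2 h) while the autophagy phase moves only 0.42 h → 0.54 h (max/min 1.29).
"Nearly constant" is therefore encoded in the tests as: autophagy-phase
change < 10% of the period change, and max/min < 1.35 — the measured
behavior of this model, in which the autophagy pulse does lengthen mildly
toward the cyclic-fold end of the window.

## What the tests show — and what they do not

The engine tests compare against independent oracles (hand-enumerated toy
networks, brute-force subgraph matching, exhaustive label permutation); the
dynamics tests are regression tests of the model's own qualitative structure
at documented problem sizes (coarse regime-map grids, reduced multiplier
sets, minute-scale sweep durations).  None of this validates the biology:
the model omits transcriptional regulation (TFEB, ZKSCAN3), MTORC2, the
TSC2/RHEB route of AMPK action, AMBRA1→ULK1 positive feedback, additional
phosphosites, isoform differences, spatial compartmentalization and
stochastic fluctuations — the latter two being exactly the effects most
likely to mask the predicted oscillations in real single-cell data.
Quantitative trajectory values also depend mildly on solver tolerances and
drift rates; only the qualitative structure (regimes, orderings, windows) is
asserted.
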