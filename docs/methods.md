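# Methods

## Chemical scope and data

The model covers the eleven inorganic nitrogen solutes
NO3-, NO2-, NO, N2O, N2, NH2OH, NH3OH+, N2H4, N2H5+, NH4+, NH3 —
this fixed order defines every concentration vector — plus O2, H+, H2O
and the electron as bookkeeping species. Standard Gibbs energies of
formation (kJ/mol, 1 M aqueous standard state, 298.15 K; dissolved-gas
values for NO, N2O, N2, O2) are curated from standard sources (CRC
Handbook; Thauer et al. 1977; Amend & Shock 2001; Stumm & Morgan 1996),
with per-species citations in `data/species.csv`. Internal consistency
checks: the table reproduces pKa(NH4+) = 9.25, pKa(N2H5+) = 8.0,
pKa(NH3OH+) = 5.8, E0(NO3-/NO2-) = 0.82 V and E0(O2/H2O, aq) = 1.27 V.
The table is an input file, not code: replacing it with any other
curated set changes no algorithm.

Temperature: runs default to 288.15 K. The 298.15 K formation energies
are applied unchanged at run temperature (no enthalpy correction); the
~10 K offset shifts RT by 3.5%, well inside the uncertainty of the
formation energies themselves, and no reliable enthalpy set exists for
all eleven solutes.

## Reaction enumeration

The curated couple table holds 38 reduction couples: all 28 pairs of the
eight dominant-protonation-state species (NO3-, NO2-, NO, N2O, N2,
NH2OH, N2H4, NH4+), nine couples involving the minor protonation forms
(NH3 with NO3-/NO2-/NO/N2O/N2; NH3OH+ with NO/N2; N2H5+ with N2/NH4+),
and O2 + 4H+ + 4e- = 2H2O. Each couple is balanced programmatically:
nitrogen is conserved at the lcm of the two species' N counts, water
balances O, protons balance H, electrons balance charge.

Every unordered pair of couples is combined twice (each member once as
the reduction), scaling both to the lcm of their electron numbers so
electrons cancel exactly. Stoichiometry is exact rational arithmetic
throughout; canonical form divides by the gcd and sorts species ids, and
duplicate detection is exact equality on canonical forms — no
tolerances. Directions are distinct reactions. The shipped tables
produce 1078 unique directed reactions. The three acid-base equilibria
(NH4+/NH3, NH3OH+/NH2OH, N2H5+/N2H4, both directions) are shipped as
curated extras, but with this couple table each already arises as the
difference of two protonation-variant couples, so the default pipeline
skips them as duplicates (logged); `append_extra` treats a collision as
an error unless explicitly told to skip. Output order is a pure function
of the input tables, so reaction indices are reproducible.

## Dynamics

State: molar concentrations M of the eleven nitrogen species in an open,
well-mixed reactor,

    dM/dt = I - D M + C r(M),

with ammonia the sole nitrogen source (I nonzero only in the NH3 slot,
default 1e-5 per model time unit), first-order washout D (default 1e-3),
and C the (11 x n_reactions) net stoichiometry matrix. [O2] and [H+] are
environmental constants; water has unit activity. Time units are
arbitrary model units — at steady state only the ratio I/D and the
relative rate scales matter.

Rates are irreversible mass action over the reactant side,
r_i = k_i [O2]^a [H+]^b prod_j M_j^e_ij, with the BEP-weighted constant

    k_i = k_def exp(-p dG0_i / RT)       if dG0_i < 0,
    k_i = k_def exp(-(1-p) dG0_i / RT)   otherwise.

For every forward/reverse pair k_f/k_r = exp(-dG0_f/RT) = K_eq exactly,
at every p in [0, 1]: the weighting accelerates favourable reactions
without moving any equilibrium. An optional unweighted mode
(`bep_weighted=False`) sets k_i = k_def for all i; it deliberately
breaks this consistency and is used for the no-weighting comparison.
ln k_i is capped at 300 (configurable) with a logged warning; exponent
arithmetic is done in log space throughout.

Steady-state diagnostics per reaction: in-situ dG_i = dG0_i + RT ln Q
(activity = molar concentration, floored at 1e-30 inside logarithms so
depleted species stay evaluable), rate r_i, and power P_i = -dG_i r_i.

### Solver

At strong weighting the rate constants span more than 100 decades and
quasi-steady trace species sit at ~1e-80 M; no adaptive stiff integrator
tracks that in double precision. `solve_steady_state` therefore has two
backends behind one interface:

* **integrate** — LSODA with the analytic Jacobian, rtol 1e-8, atol
  1e-30, over doubling time windows (first window 1e3, horizon 1e7),
  declaring convergence when the scale-aware criterion (below) holds at
  two consecutive window ends. Used automatically while max ln k <= 40
  and always for closed systems (it preserves the linear conserved
  totals to integration accuracy).
* **ptc** — for the extreme regime, pseudo-transient continuation on
  z = ln M: backward-Euler steps solved by a frozen-Jacobian Newton
  iteration with an LU-factorised chord matrix, the pseudo-timestep
  growing on acceptance and shrinking on rejection, and all iterates
  confined to the invariant region implied by the washout bound (total
  nitrogen can never exceed max(initial, I/D)). When the waterfall
  plateaus, per-species Gauss-Seidel relaxation takes over: each
  species' own balance is strictly decreasing in its own concentration
  (consumption grows, production does not), so its conditional root is
  bracketed and bisected in log space, immune to the rate-scale spread.
  A damped Newton on the full system and a high-precision root solve
  finish; the final state is accepted only if it improves the residual.

Convergence criterion: max_k |dM_k/dt| / (D M_k + I + M_k/t) < 1e-6
(configurable), a scale-aware form whose M_k/t term also makes closed
systems (I = D = 0) measurable as relative drift. The `converged` flag
always reflects this criterion at the reported state; non-convergence
returns the state with the flag down rather than raising.

The continuation backend finds a root of the steady-state equations
rather than following the trajectory exactly; the model is assumed to
have a unique attracting steady state per condition (single initial
condition, uniform 1e-5 M). The assumption is cross-checked in the test
suite: at mild weighting, where true integration is feasible, both
backends agree to 1e-5 relative. Within grid sweeps each condition
warm-starts from its oxygen-axis neighbour, which typically skips the
waterfall entirely.

### Exact equilibrium oracle

For closed systems the in-situ Gibbs energies are affine in ln M, so the
equilibrium set {dG = 0} is an affine subspace and the conserved
quantities (the left null space of C, which contains every elemental
total) select a unique point, computed by a strictly monotone Newton
iteration on the null-space coordinates. This oracle is independent of
the kinetics and is used in tests to verify that the dynamics lands on
the true equilibrium — and that the unweighted mode, which breaks
detailed balance, demonstrably does not.

## Networks

A reaction's link set pairs every nitrogen reactant with every nitrogen
product (no self-pairs), regardless of atom routing. The energetically
superior network is the link union of the top-k reactions (default
k = 10) ranked by power, rate, or negative in-situ dG — descending
value, ties broken by ascending reaction id. Key reactions are the
minimal power-ranked prefix supplying a fraction theta (default 0.9999)
of P_tot = sum max(0, P_i); non-positive powers never qualify.

The enzyme-level network is a 13-link curated table
(`data/enzyme_links.csv`): nitrate reduction and nitrite ammonification
(DNRA), the denitrification chain NO2- -> NO -> N2O -> N2, nitrification
NH3 -> NH2OH -> NO -> NO2- -> NO3- (ammonia monooxygenase acts on NH3,
not NH4+), hydroxylamine oxidation to N2O, and the ANAMMOX hydrazine
route (NO and NH4+ to N2H4, N2H4 -> N2). Nitrogen fixation is excluded.
One link (NH2OH, N2O) is the least certain attribution; the table is
data, so any correction is a one-line edit. The community-level network
is its transitive closure (self-loops dropped: a species is never its
own transformation product), computed with networkx. Edge overlaps
D = |E_ref ∩ E_w| / |E_w| compare a superior network against either
reference; E_enz ⊆ E_com makes D_com >= D_enz a theorem, asserted as
such in the tests.

## Sweeps

The default grid spans log10[O2] in [-12, -3] step 0.2 and pH in
[2, 12] step 0.5 — 966 conditions (step 0.1 for oxygen is available via
config). Non-converged conditions are excluded from averages with the
exclusion counted. Sweeps are deterministic; re-running a configuration
reproduces the tables byte for byte. The acceptance script and test
suite run scaled-down 6 x 5 sub-grids (log10[O2] in [-10, -4] step 1.2,
pH in [4, 10] step 1.5) with p in {0.01, 0.1, 0.2, 0.3} and k_def in
{0.1, 1, 10}, chosen to bracket the published parameter ranges while
keeping a full run in minutes on one CPU.

## Synthetic systems

The generator emits abstract species over a core element Q (the
conserved nitrogen analogue) with proton/water/electron bookkeeping, and
builds couples with the same balancing routine as the nitrogen tables,
so synthetic systems flow through the identical pipeline entry points.
Two styles:

* **aqueous** (default): random Q/H/O compositions and charges in
  [-2, 2]; exercises the balance and enumeration algebra in full
  generality. These systems are *not* guaranteed to equilibrate: when a
  species' equilibrium abundance is astronomically small, the closed
  system freezes into a long-lived quasi-steady glass — a property of
  the chemistry, not a solver defect.
* **ladder**: all species share composition Q with strictly descending
  charges, so every couple is a pure 1-2 electron transfer; the
  adjacent-couple reactions are bimolecular and span the full
  stoichiometric rank, so the closed system genuinely reaches
  equilibrium within the horizon. The detailed-balance audits use this
  style.

Formation energies are uniform in +/-8 kJ/mol (a few RT): large enough
for equilibrium constants far from unity, small enough that every
species stays resolvable at equilibrium. The equilibrium audit
integrates the closed system and passes iff the integrator converged,
every uncapped reaction has |dG| < 1e-4 kJ/mol at the end state, the
conserved Q total drifted < 1e-8 relative, and every resolvable species
matches the exact-equilibrium oracle within 0.25 log units.

A constructed `planted_overlap_system` provides a known-ground-truth
recovery check: two competing channels of identical kinetic order in the
energy-rich feed, the strongly exergonic one carrying a fixed [H+]^3
kinetic penalty. Without weighting the cheap channel out-powers it by
~1e6; at p = 0.9 the BEP boost (~1e13) overwhelms the penalty and the
top-power network matches the planted link set exactly — a miniature of
the full pipeline's weighting-drives-overlap behaviour.

Synthetic data emulate the algebraic structure of the nitrogen input
class (balance, conservation, redox coupling), not real nitrogen
thermochemistry; passing audits demonstrate the correctness of the
enumeration algebra and the thermodynamic consistency of the weighted
kinetics, and say nothing about which real reactions are energetically
superior.

## Known limitations

* Activity coefficients are unity (no ionic-strength correction), by
  design.
* Quantitative steady states depend on the curated formation energies;
  counts of top-k links and exact overlap values can shift with a
  different thermodynamic table, which is why the table is a swappable
  input. Structural results (subset theorem, monotonicity in p,
  detailed balance) are table-independent.
* The continuation solver assumes a unique attracting steady state;
  multistability, if present at some condition, would be reported as
  whichever root the continuation reaches.
* The 1078-reaction count reflects the shipped couple table; a different
  curated couple set changes the count but not the algorithms.
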