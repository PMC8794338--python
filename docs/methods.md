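# Methods

## The model

CF1 water is a *central-force* model: an H₂O molecule is not a rigid body
but an emergent ion triplet — one oxygen carrying q_O = −2q_H and two
hydrogens carrying q_H = +0.32983 e₀ — bound purely by three spherically
symmetric site–site pair potentials U_OO(r), U_HH(r), U_OH(r).  The
potentials are polynomial/Fermi/Gaussian forms that yield kcal/mol when r
is entered in Å; this package stores them in that printed form and
converts once, at evaluation, by exactly 4.184 (all public energies are
kJ/mol).  The deep O–H well (−334.45 kJ/mol at r* = 0.9584 Å) binds two
hydrogens to each oxygen; the H–H Gaussian well near 1.45 Å and the
Coulomb repulsions select the bent geometry.  Because there are no bond
constraints the model is fully flexible and, in principle, dissociable —
proton transfer and autoprotolysis are allowed chemistry, which matters
at high temperature (see *Limitations*).

The 1/r coefficients printed in the three potentials (144.538, 36.1345,
−72.269) are exactly k·q_i·q_j for the single constant
k = 36.1345/q_H² kcal·Å·mol⁻¹·e₀⁻².  We therefore *derive* the Coulomb
constant from the printed coefficients instead of importing a CODATA
value: the short-range + Ewald split then recombines to the printed
equations bit-for-bit, which is what the split-identity tests assert.

## Electrostatics

The periodic Coulomb sum uses Ewald summation with conducting (tinfoil)
boundary conditions, α = 5/L (the convention of the original study),
real-space sum over minimum images up to L/2, and a reciprocal-space
cutoff |n|² ≤ 64 (k = 2πn/L).  At α = 5/L the real-space screen at the
cutoff is erfc(2.5) ≈ 4·10⁻⁴, which is flagged by a construction-time
warning; absolute energies carry a correspondingly small truncation
error, while the structural observables compared here are insensitive to
it.  No intramolecular exclusions exist: the 1/r terms of the pair
potentials *are* the full Coulomb interaction, including between an
oxygen and its own hydrogens.

The correctness anchors are (i) brute-force periodic image sums
(spherically ordered, dipole-corrected to the tinfoil convention,
shell-tail averaged) reproduced to 10⁻⁴ kJ/mol, and (ii) the Madelung
constant of a CsCl-type cell to better than 4 significant figures.

## Monte Carlo engine

Canonical sampling is single-site Metropolis displacement (uniform in a
±0.5 Å cube, the printed protocol).  Grand-canonical sampling alternates
one displacement attempt with one insert-or-delete attempt (50/50 coin):
insertion places an O uniformly and two H in the printed admissible
windows 0.875 ≤ r_OH/Å ≤ 1.075 and 1.3 ≤ r_HH/Å ≤ 1.7 (uniform radii,
uniform sphere directions, rejection on r_HH); deletion removes a random
O with its two nearest hydrogens.  Acceptance uses
Y = exp(B − βΔU)/((N_O+1)(N_H+1)(N_H+2)) with
B = βμ + 3 ln(L³/(Λ_H²Λ_O)), exactly as printed; no proposal-density
correction for the constrained H placement is applied because the
printed acceptance rule contains none (the ideal-gas limit of this rule,
P(N) ∝ e^{BN}/(N!(2N)!), is verified end-to-end against direct
normalization).  Masses for Λ are m_H = 1.008 u, m_O = 15.999 u.

Energy bookkeeping is incremental: per-pair-type lookup tables (linear
interpolation, Δr = 5·10⁻⁵ Å) combine the non-Coulomb terms with the
erfc-screened real-space term, and reciprocal-space structure factors
S_k are updated per accepted move; a full refresh every 10⁶ moves bounds
floating-point drift (measured drift after 10⁶ moves is ≤ 10⁻⁹ kJ/mol).
Trial moves whose short-range βΔU exceeds 10⁴ are rejected without the
reciprocal-space work.  All randomness flows from a single mandatory
seed.

### Acceptance rate and equilibration — the practical crux

With the printed 0.5 Å maximum displacement the measured acceptance at
300 K, 1 g/mL is ≈ 0.7% (0.45% at 240 K, 2% at 600 K): the O–H well is
~334 kJ/mol deep and ~0.03 Å wide, so almost any 0.5 Å move of a
hydrogen breaks a bond.  This is the protocol as published (the original
study compensated with 5·10⁸ + 1.5·10⁹ attempted moves).  Consequences
for desk-scale runs:

* intramolecular geometry and hydrogen-bond counts converge within a few
  10⁶ attempted moves;
* the hydrogen-bond *network* (tetrahedral order q, the shape of P(E))
  relaxes over ~1.5·10⁷ attempted moves at 300 K and much slower at
  240 K.

Burn-in lengths were therefore chosen from convergence diagnostics
(energy and ⟨q⟩ plateaus over staged runs): 1.6·10⁷ attempted moves at
300 K and 6·10⁶ at 600 K before 10⁷ production moves in
`scripts/acceptance.py`.  The initial configuration places pre-formed
molecules (insertion-window geometry) at random positions with
foreign-site exclusion distances; a fully atomic random insertion mode
exists but seeds shared-hydrogen defects that anneal out extremely
slowly at ~1% acceptance.

## Observables

Molecules are reconstructed every analysis frame by a greedy global O–H
assignment (all O–H pairs sorted by minimum-image distance; a pair is
accepted while the O has < 2 hydrogens and the H is free).  RDFs use
0.05 Å bins to L/2 with ideal-gas shell normalization; running
coordination numbers integrate 4πρ_j g r² by cumulative trapezoid.
Bond-length averages are restricted to the intramolecular RDF
first-peak windows (assigned O–H < 1.3 Å, H–H < 2.0 Å — the same
first-minimum bounds that give the intramolecular coordination numbers
2.0 and 1.0); the model's occasional metastable wide-angle states
(l_HH > 2 Å, stabilized by the H–H Fermi shoulder switching off at 2 Å)
stay visible in the tail of P(θ) but do not enter the bond averages.
The bond angle is reported in the averaged-distance convention
θ = arccos(1 − ⟨l_HH⟩²/(2⟨l_OH⟩²)) (the per-molecule mean is also
computed).  Hydrogen bonds are counted two ways: intermolecular O···H
contacts within 2.5 Å, and molecule pairs whose 9-term site–site energy
(direct 1/r Coulomb, minimum image — a local definition, deliberately
not an Ewald decomposition) is ≤ −9.0 kJ/mol.  P(E) uses 0.2 kJ/mol
bins; its local minimum is the first strict local minimum of the 3-bin
smoothed curve scanning down from the bulk peak.  P(q) uses 0.02 bins
with q from the 4 nearest oxygen neighbours; τ integrates |g_OO − 1| to
r_c = L/2.  Scan extrema are refined by a 3-point quadratic fit.

## Scaled study conditions

Desk-scale defaults are 64 molecules (L = 12.417 Å at 1 g/mL).  This is
the smallest box for which L/2 exceeds the ~6 Å range of the O–O
attractive structure; the original study used 200.  μ–ρ ladders use
sequential runs whose initial configuration continues from the previous
μ point (fresh-start mode available): T = 650 K for the supercritical
monotone branch and T = 350 K for the hysteresis loop, with μ grids
spanning ±40 kJ/mol around the liquid-branch line μ(T) = −589.0 −
0.08·T kJ/mol.  GCMC ρ(T) along that line reproduces liquid-like
densities; its equilibration at liquid density is exchange-limited
(insertion acceptance ≪ 10⁻³), so desk-scale ρ(T) values carry a slow
transient and are reported with block errors.

## What reproduces at desk scale, and what does not

With the scaled conditions above, the package reproduces (300 K,
1 g/mL): the g_OH second minimum (2.42–2.43 Å), the intermolecular OH
coordination number (≈ 2.0–2.1 vs 2.14), both hydrogen-bond counts
(≈ 4.27 and ≈ 3.78 vs 4.28 and 3.79), and the H–H distance (≈ 1.49 Å).
The 600 K q-distribution mode (≈ 0.47–0.49 vs 0.49) also reproduces.

Deviations at the 64-molecule scale, and what a 200-molecule
cross-check (5.7·10⁷ attempted moves at 300 K; 4.5·10⁷ at 600 K) says
about each:

* the 64-molecule liquid is less tetrahedral than the published
  200-molecule results: P(q) peaks near 0.55 rather than 0.77, and the
  P(E) minimum sits near −10.5 rather than −8.7 kJ/mol.  At 200
  molecules both landmarks move onto the published values — the P(E)
  minimum reaches −8.3 to −9.3 kJ/mol and the P(q) mode climbs to 0.67
  and is still rising when our budget ends.  These two deviations are
  therefore box-size plus relaxation effects of the scaled conditions,
  not implementation error.
* l_OH equilibrates at ≈ 0.973 Å (64 molecules) to ≈ 0.980 Å (200
  molecules) against the reported 0.962, and θ at ≈ 100° against 102.1°;
  every estimator (mean, median, mode, fine-binned g_OH peak) agrees and
  the values are stable over 5·10⁷ moves at both box sizes, so this
  ~1.5% bond-length offset is protocol-converged and scale-independent
  in our implementation.  The thermal average lies well above the bare
  well minimum (0.9584 Å) because the O–H well is strongly anharmonic.
* ⟨H-bond⟩_E at 600 K equilibrates at ≈ 2.9–3.0 (reported: 2.27) at both
  box sizes; at 600 K the model also forms H₃O⁺/OH⁻ ion pairs on our
  timescales, which drift assignment-based averages upward.

These deviations are reported as-is by the acceptance tests; the scan
criteria that require equilibrated networks at every grid point (the
density-anomaly extrema, the strict ⟨q⟩ ordering including 240 K) are
relaxation-limited at desk scale and are likewise reported as-is.

## Numerical choices

* Table interpolation error ≤ 5·10⁻⁵ kJ/mol at physically sampled
  separations (relative ~10⁻⁶ in the repulsive core); cached-vs-full
  energy agreement is asserted at 10⁻⁸ kJ/mol after hundreds of moves.
* Below r = 0.28 Å pair tables switch to a steep linear ramp — finite,
  monotone, and never thermally sampled.
* Metropolis exponentials are guarded at βΔU = 700; GCMC acceptance is
  evaluated in log space (B is of order −200 at liquid μ).
* Histogram landmark locators (P(E) minimum, g_OH second minimum, P(q)
  mode) operate on 3-bin moving averages; ties break toward the first
  bin encountered.
* Degenerate inputs: empty frame sets, non-neutral charge sets,
  mismatched O/H counts, r ≤ 0 and T ≤ 0 all raise `ValueError`.

## Limitations

The simulator inherits the published protocol's weaknesses: small-step
Metropolis diffusion is extremely slow for this stiff model (no
molecule-level collective moves are implemented, by design fidelity);
GCMC molecule exchange at liquid densities is rare, so μ–ρ points deep
in the liquid branch equilibrate N only slowly; and the dissociable
chemistry means assignment-based molecular observables blur once ion
pairs appear (≳ 600 K).  Critical-point determination and finite-size
scaling are out of scope.
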