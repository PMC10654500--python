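# Methods

`strandgate` packages the analysis layer of a simulation-guided engineering
workflow for photodissociable split GFP: given structural ensembles of the
split barrel with the chromophore in its *cis* or *trans* state, it
quantifies the inter-strand interaction network, reconstructs the
free-energy profile along the chromophore twisting coordinate, detects and
dissects strand-dissociation events in temperature-ramped trajectories,
turns that evidence into ranked mutation-site nominations, and fits the
strand-exchange kinetics used to score engineered variants. Because
microsecond molecular-dynamics and QM/MM ensembles cannot be regenerated at
desk scale, the package ships a first-class synthetic-data module that
emulates those inputs with planted ground truth; every analysis stage is
validated against what was planted.

## The reduced structural model

The synthetic barrel fragment holds the three strands that matter for
dissociation — strand 10 (the dissociating strand, canonical numbering
197–209) flanked by strands 7 (144–156) and 11 (213–225) — placed
antiparallel on a 12 Å-radius cylindrical arc with 25° angular spacing and
3.4 Å Cα rise. Residues are reduced to backbone N/CA/C/O plus CB and a
single sidechain interaction-site atom (`SC`); the site's hydrogen-bonding
polarity, charge and aromaticity come from a fixed per-residue table. A
pseudo-chromophore (residue 66) carries a five-atom chain defining the two
twisting dihedrals phi_P and phi_I (degrees on (−180, 180], cis = 0,
IUPAC sign convention) plus two hydrogen-bond anchors: a phenolate-like O
("OH", moves with phi_I) and an imidazolinone-like N ("NX"). An Asn121
analog sits on the helix side opposite the dissociating strand.

Interactions are *planted*: the generator positions the relevant atoms so a
contact satisfies the default geometric criteria exactly (backbone N···O at
2.9 Å, sidechain hydrogen bonds at 2.85 Å, salt bridges at 3.75 Å —
inside the 4.0 Å salt cutoff but outside the 3.5 Å hydrogen-bond cutoff so
the two kinds never overlap — stackings at 4.6 Å), while all non-planted
inter-strand pairs stay outside the cutoffs in noise-free frames. Backbone
bonds keep each atom's own offset along the chain and close the gap
laterally, so both directions of a registry pair can be planted without the
donor and acceptor of one residue colliding. Thermal disorder is isotropic
per-atom Gaussian noise. Alternating contacts (the Ser202 analog switching
between the Asn149 and Asn225 analogs) flip the satisfied partner on a
two-frame period, giving each partner 0.5 occupancy and zero co-occurrence.

A planted dissociation event breaks anchors at given frames (by reverting
their planted placement), displaces the cleaved-end residues at a
"solvation" frame, and after the onset frame drifts the whole strand
radially outward at 1 Å/frame. The default annealing fixture loses the
Lys214/Arg215/His217 sidechain anchors early (frames 10/18/26), the Lys209
anchor last (frame 44), with onset 48 under a 300→450→600 K schedule.
Lys209's anchoring is represented by its Asp216 salt bridge alone; its
His217-mainchain hydrogen bond is omitted from the reduced fixture because
the inter-strand corridor at the cleaved end is too crowded to plant a
third independent contact there without violating the "nothing
non-planted" guarantee.

What the generator does *not* emulate: real rotamer chemistry and sidechain
entropy, solvent granularity (solvation is a geometric displacement, not
water), force-field energetics, and correlated thermal motion. Passing
tests therefore demonstrate that the analysis operators recover planted
truth under controlled noise — not that they would resolve ambiguous
contacts in real ensembles.

## Interaction criteria

Structures carry no hydrogens, so hydrogen bonds use a heavy-atom proxy:
donor–acceptor distance ≤ 3.5 Å and a proxy angle (partner, atom, nearest
same-residue neighbor) ≥ 90° at **both** ends. Donor/acceptor capability is
resolved at the atom-class level: mainchain amide N pairs only with
carbonyl O; sidechain sites (and chromophore N/O atoms) pair with each
other or with a carbonyl O, never with a mainchain N. Salt bridges:
oppositely charged sites within 4.0 Å, no angle term. Stacking: aromatic
sites within 5.5 Å with CB→site axes within 30° of parallel (folded to
[0, 90]°). Persistence and alternation thresholds default to 0.5 and 0.2
occupancy; alternation additionally requires a per-frame co-occurrence
Jaccard index ≤ 0.2. All cutoffs live in `InteractionCriteria`. The source
literature reports interactions without geometric definitions, so these are
package conventions chosen at literature-standard values; the detector is
verified by exact set-equality against an independent all-pairs enumeration
on random structures.

## Free-energy profiles (WHAM)

Umbrella windows are harmonic in the dihedral with minimal-image periodic
displacement; the generator draws exact i.i.d. samples from the biased
Boltzmann density by inverse-CDF sampling on a 0.1° grid (no Markov-chain
correlation, so oracle comparisons are clean). The default force constant,
0.02 kcal mol⁻¹ deg⁻², makes the bias standard deviation (≈ 5.5° at 300 K)
about half the default 10° window spacing — the usual overlap rule of
thumb; window spacing and force constant are free parameters.

The estimator is standard self-consistent WHAM on a 72-bin periodic grid
(R = 1.98720425864083×10⁻³ kcal mol⁻¹ K⁻¹), iterated until window free
energies move < 10⁻⁴ kcal/mol, capped at 10⁵ iterations. Bins with fewer
than 10 total samples are left unreported: a couple of far-tail samples
carry an exp(+βu) reweighting factor that produces arbitrarily low spurious
free energies (we observed such bins capturing the region minimum and
biasing barrier differences by ~1 kcal/mol). Reported bins must form a
single arc on the circle; interior gaps raise a coverage error naming the
empty bins. Profiles are anchored at zero minimum. The 90–100° stretch
around the conical intersection is flagged (annotation only — classical
sampling is unreliable there) and excluded from RMSE comparisons but not
from barrier paths. Barriers are measured as the maximum along the lower of
the two circular paths between the cis-region and trans-region minima,
minus the cis minimum; the measure is invariant to the anchoring constant.

## Dissociation analysis

Disorder is tracked through the fraction of native contacts Q: residue
pairs across strands whose minimum heavy-atom distance is ≤ 5.5 Å in the
reference frame, retained while ≤ 1.2× that cutoff. An event onset is the
first frame where Q stays below 0.2 for 10 consecutive frames; the onset
temperature is read from the annealing schedule. Absence of an event is a
valid result.

Anchor losses are ordered by the end of each sidechain interaction's last
presence run after closing gaps shorter than the smoothing window (default
5 frames): a broken anchor stays broken, a thermal flicker does not
register. Ties break by residue number, then interaction kind. Terminal
solvation is the first sustained frame where the mean relative SASA of the
three cleaved-end residues exceeds 0.5. Relative SASA divides a residue's
in-context Shrake–Rupley area (960 sphere points, 1.4 Å probe, single-atom
van der Waals radii) by the same residue's isolated area — a
self-consistent reference for pseudo-atom residues that have no tabulated
Gly-X-Gly values. The register-shift scan reports, per frame and neighbor
strand, the integer residue shift (relative to the frame-0 pairing) that
maximizes the number of Cα pairs within 5.5 Å; gap-opening versus register
shift is left as a raw signal, since no classifier for the two late-stage
scenarios is defined.

## Design rules

Orientation labels come from the sign of (Cα→Cβ) projected on the radial
vector from the barrel axis — the first principal component of strand Cα
positions (the literature never defines "into/out of the barrel"
geometrically; note that for a three-strand fragment this axis lies near
the sheet rather than on the cylinder axis, which is immaterial for sign
classification). "Exposed" overrides in/out for residues within three
positions of the cleavage site on the dissociating strand whose relative
SASA is ≥ 0.5; glycine follows backbone exposure only.

Nomination applies three criteria. (1) Dissociation sites: on the
dissociating strand, facing out or exposed, and either holding a sidechain
interaction across strands at ≥ 0.3 occupancy in the pre-dissociation trans
segment (a lower bar than the 0.5 cis persistence, because the trans
complex keeps fewer stable interactions) or appearing in the anchor-loss
order. (2) Isomerization sites: sidechain contacts the chromophore in at
least one interior phi_I window (strictly between the cis and trans
endpoint windows) at ≥ 0.05 occupancy. (3) Exclusivity: an isomerization
site is flagged excluded — never silently dropped — when its effect could
not be deconvolved from dissociation: it lies on the dissociating strand,
or it interacts (≥ 0.3 occupancy, any moiety, either state) with
dissociating-strand residues. Dissociation candidates rank by total trans
sidechain occupancy, ties broken toward later anchor loss; the ranking is a
heuristic (no quantitative rule distinguishes the sites), and because
single-site effects compose unpredictably, the engine also enumerates all
1-/2-/3-site combination variants rather than single mutants only.
Substitution proposals are alanine (removing polar interactions) or the
bulky nonpolar set Ile/Val/Leu/Trp (introducing steric clashes); Gly, Ala
and Pro sites return an empty proposal with a note. Variant names
concatenate the one-letter residues at the named strand positions from N-
to C-terminus (YSK → AAA, IWI), with a hyphen suffix for off-strand
additions (IWI-A).

## Kinetics

The two-step scheme is linear: light drives cis→trans isomerization at an
effective rate k_iso (incident power and quantum efficiency folded in — all
reference measurements used a single power, so no explicit photon-flux
model); trans relaxes back (k_rev) or loses the strand light-independently
(k_diss); the empty barrel binds excess labeled strand pseudo-first-order
(k_bind); a slow dark channel (k_dark) drains cis directly. All rates in
min⁻¹, initial state pure cis. Integration uses Radau (rtol 10⁻⁹,
atol 10⁻¹²); a matrix-exponential solution of the same linear system is the
independent cross-check (agreement ≤ 10⁻⁶ required in tests). In the
rapid-pre-equilibrium, fast-binding limit the exchanged fraction is
single-exponential with k_obs = k_iso·k_diss/(k_rev + k_diss).

Exchange traces are fitted to offset + amplitude·(1 − e^{−kt}) by nonlinear
least squares (k bounded non-negative), with initial guesses from a
log-linearized decay; the functional form is assumed since none is
published. The standard error of k_obs comes from the fit covariance; a
constant trace returns k_obs = 0 flagged with infinite standard error.
Rate ratios propagate uncertainty to first order. The exchange readout is
modeled as linear in the exchanged fraction; fluorescence quantum yields
and excited-state photophysics are out of scope.

## Problem sizes and determinism

Default study conditions: 19 umbrella windows × 5000 samples for profile
reconstruction; 100-frame annealing trajectories at 0.2 Å noise, 25 event
and 25 no-event fixtures plus 20 seeds for anchor ordering; 200 noisy
traces (1% amplitude noise, 30 points over three time constants) for rate
recovery. Every stochastic step takes an explicit integer seed and is
bit-reproducible; `scripts/acceptance.py` derives all sub-seeds from its
single `--seed` argument.

## Known limitations

The fixture geometry is a three-strand fragment, not a closed barrel, so
absolute SASA values and the fitted axis differ from what a full barrel
would give; only relative/sign quantities are used downstream. Interaction
presence is binary per frame with no energetic scoring. The ground-state
classical profile carries no excited-state information, and values inside
the flagged conical-intersection window are reported but untrustworthy.
Candidate nominations are hypotheses for mutagenesis, not rate predictions.
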