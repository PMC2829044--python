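# Methods

## Scope and model

`unfoldkit` analyses protein unfolding trajectories to locate the
transition-state ensemble (TSE) and quantify unfolding cooperativity.
The underlying picture is two-state kinetic stability: a native basin of
tightly restricted conformational fluctuation, a single dominant barrier,
and an unfolded side where conformational entropy explodes.  On that
picture three independent observables should agree about where a
trajectory crosses the barrier — the exit from the native cluster in an
all-versus-all structural comparison, and the bottleneck crossing on two
property landscapes — and the per-snapshot similarity count
(cooperativity profile) should drop like a cliff at the crossing.  A
gradually unfolding protein breaks all of these signatures at once, which
is precisely what the toolkit is built to measure.

## Superposition and two-fit Cα RMSD

All structural comparisons use least-squares (Kabsch) rigid superposition
over Cα atoms, with reflections excluded.  The *two-fit* RMSD makes the
comparison robust to a small number of badly aligning residues: after a
first fit over all Cα atoms, atoms whose deviations exceed the mean plus
two population standard deviations are discarded (strict inequality, so
ties are kept, with a 1e-8 Å absolute epsilon so numerically zero
deviation vectors are never flagged); a second fit and the RMSD are then
computed over the retained atoms only.  Exactly two passes are made.
Because the second pass re-minimises over a subset, the two-fit RMSD
never exceeds the one-fit RMSD.  On the synthetic unfolding runs the rule
discards about 4% of Cα atoms on average.  Pairwise matrices are computed
with a batched 3×3-SVD implementation over the upper triangle and
mirrored, so they are exactly symmetric with a zero diagonal.

## Contacts, hydrogen bonds, surface

Two heavy atoms are in contact when closer than 4.6 Å — 5.4 Å when
either is carbon or sulfur — and their residues are more than two
positions apart in the chain.  Sequence separation is counted on ordinal
chain position (insertion codes count as steps), not author numbering,
because homology-based numbering has gaps and insertions that would
distort the rule.  A residue pair is in contact when any atom pair
joining it is; a contact is *native* when the residue pair is in contact
in the crystal structure, and this residue-level nativeness is also what
classifies individual atom contacts.  Contacts are classified
intra-/inter-domain against a named residue partition (N-domain, bridge,
C-domain); domain-bridge categories (bridge–bridge, bridge–other) are
counted at atom level because the bridge is small.  Contact density is
the number of native residue–residue contacts per residue: for the full
protein each contact counts once; for a proper subset, pairs with at
least one endpoint in the subset count, reflecting packing of the subset
against the whole molecule.

Backbone hydrogen bonds use a hydrogen-free criterion suited to
heavy-atom structures: donor N to acceptor O distance ≤ 3.5 Å, N–O=C
angle ≥ 90°, pairs closer than three residues excluded; both the
distance and the angle are configurable.

SASA is Shrake–Rupley quadrature (mdtraj's C implementation) with a
1.4 Å probe and 960 sphere points by default; element radii are C 1.70,
N 1.55, O 1.52, S 1.80 Å.  Polarity splits N/O (polar) from C/S
(non-polar); NPSASA is the non-polar total.  Two numerical caveats of
any fixed-orientation quadrature sphere: rigid-body rotation of a
structure changes which points are occluded, so total SASA is invariant
under rigid motion only to about 1% at 960 points (not to machine
precision), and doubling the point count from 960 still moves the total
by a few tenths of a percent.  Relative residue exposure divides a
residue's SASA by a reference maximum computed internally from the same
residue placed in an extended Gly-X-Gly tripeptide with the same probe
and radii — self-consistent rather than taken from literature tables.  A
domain-interface residue is *buried* when it has at least one
inter-domain crystal contact and relative exposure below 5%; the same 5%
threshold (configurable) decides "exposed" when classing buried
residues as exposed at the TSE, exposed within 600 ps after it, or still
buried.

## Fluctuation metrics

**ALF** slides a 90 ps window over 10 ps snapshots: each window holds 10
snapshots, hence 45 pairwise two-fit RMSDs, whose mean is assigned to the
window midpoint; an 8.1 ns run yields 801 windows.  **Cooperativity**
counts, for each snapshot, the snapshots of the run whose two-fit RMSD to
it is strictly below 3 Å (thresholds of 3.5 and 4 Å behave similarly,
and counts are monotone in the threshold).  The snapshot itself is
included, so a perfectly cooperative run reads *j* (the number of
native-phase snapshots) up to the transition and a much smaller *k*
after it.  Counts depend only on the RMSD matrix and are therefore
invariant to frame reordering; the profile against time is not.  Values
are counts × snapshot interval; both are emitted.

## Clustering and landscapes

Conformational clustering embeds the pairwise two-fit RMSD matrix with
classical (Torgerson) MDS — double-centred squared distances, top-3
eigenpairs, coordinates scaled by the square roots of the eigenvalues,
negative eigenvalues truncated to zero with a warning, axis signs fixed
by the first frame.  Classical MDS is implemented directly on `eigh`
because the widely available MDS implementations are iterative (SMACOF)
rather than spectral; exact recovery of Euclidean configurations is
asserted in the tests.

The original procedure located the native-cluster exit *visually*; this
package substitutes an automated surrogate and labels its outputs as
such.  The native cluster is estimated from the frames inside a
presumed-native early window (at least 10 frames): centroid, plus a
radius at the 95th percentile of those frames' centroid distances,
widened by a factor 1.5 because a short window under-samples the native
ensemble's thermal spread (the native/unfolded separation in the
embedding is roughly an order of magnitude larger than the native
radius, so the widening cannot delay a real exit).  The exit is the last
frame inside the radius after which no later frame re-enters — permanent
departure, so brief excursions do not count.

Two landscapes are built over the pooled frames of all runs: native
residue contacts × NPSASA, binned 5 contacts × 50 Å² anchored at the
origin, and the first two principal components of ten z-scaled per-frame
properties (Cα RMSD to the crystal; native/non-native ×
intra/inter-domain atom contacts; radius of gyration; non-polar and
polar SASA; non-native and native backbone hydrogen bonds), binned at
0.1 units anchored at −5.  Bin values are −ln(count), so occupied-bin
counts are recoverable; these are sampling densities of non-equilibrium
trajectories, not free energies.  Components are oriented so the
earliest frames score negative, putting the native basin at low PC1.
The Cα RMSD property uses the plain single-fit superposition; the
two-fit rule is reserved for clustering, ALF and cooperativity.

**Barrier crossing.**  Crossing detection needs a native and a
non-native region on the landscape coordinates.  Explicit box or bin
regions can be supplied; the automatic default scales both axes by their
standard deviation and takes the centroid of the earliest 5% of frames
as the native anchor: the native basin is the disc out to the early
frames' 90th-percentile centroid distance plus 15% of the gap to the
endpoint ensemble (the latest 20% of frames), and the non-native basin
is everything beyond the middle of that gap.  This replaces an earlier
bin-connected-component design (dense bins at the median occupied count,
4-connectivity): with 0.1-unit PC bins the native cluster fragments into
many single-count bins and with coarse contact/SASA bins single stray
frames rewire the components, so component-based basins proved unstable
across grid resolutions, while centroid-distance basins are
self-calibrating and direction-free (broad excursions of the unfolded
ensemble can never read as a return to the native basin).  A crossing is
a passage from the native to the non-native region without re-entering
the native region in between; since the actual barrier passage happens
between two saved frames, the reported crossing time is the midpoint
between the last native frame (with no subsequent return) and the first
non-native frame after it.  The crossing count is reported as well; it
can over-count by one on noisy runs when a single spike frame (often a
discrete property such as an H-bond count shifting by one) briefly exits
the native disc, but the crossing *time* is anchored on the permanence
rule and unaffected.

**TSE.**  The frames spanning each run's crossing — a 10 ps window
centred on the crossing time, at the run's save interval, so 10 frames
per run at 1 ps saves — are pooled; five runs give 50 members.  The
deviation map superposes each member onto the crystal structure by
ordinary least squares over all Cα and averages per-Cα deviations.  This
is a deliberate simplification: the original analysis used
maximum-likelihood superposition, which weights residues by their
variance; least squares leaks a small amount of deviation from mobile
onto static residues (bounded in the tests at 10% for an isolated
displaced residue) but preserves the map's qualitative content.

## Synthetic unfolding trajectories

The generator is geometric, not physical — no force field, no
integrator.  It exists to give every analysis stage inputs with known
ground truth, and its defaults are the study conditions of the test
suite: a 26-residue toy protein (two 12-residue pseudo-β-hairpin domains
of 4-atom residues packed across an interface, joined by a 4-residue
bridge labelled with chymotrypsin-style insertion codes 120A–120D), 2 ns
runs at 10 ps saves, transition at 0.8 ns, 0.15 Å thermal jitter,
interface contacts lost twice as fast as intra-domain ones.

Unfolding is realised by moves that can never break covalent geometry:
domain separation along the interface normal (the bridge is re-solved
every frame as a constant-link sagging chain spanning the gap); hairpin
opening, a rigid rotation of each domain's outer strand about a hinge at
its turn; a late outward *curl* of each outer strand's free half about a
mid-strand pivot, which makes the chain form new non-native intra-domain
contacts with itself as collapsing unfolded chains do (the outward sense
matters — an inward curl would swing the segment back through its native
cross-strand register); rigid per-domain reorientation and lateral drift
(the separation-axis component is projected out so wander never closes
the opened interface); and sequence-correlated thermal jitter plus an
independent wobble on non-CA atoms.  The interface gap is wedge-shaped
so inter-domain contacts break sequentially rather than in unison, and
the backbone N/C/O offsets are chosen so cross-strand hydrogen-bonded
N···O pairs sit near 2.6 Å while the nearest non-bonded pairs sit beyond
4 Å — without that margin, thermal jitter flickers spurious hydrogen
bonds in and out and the discrete property produces large z-score spikes
that confuse any landscape method.

Contact loss is *programmed*, not emergent: target native intra- and
inter-domain contact-fraction schedules follow the unfolding progress
variable (a flat native phase, a jump to progress 0.6 at the transition
and exponential approach to 1 for `two_state`; linear progress for
`gradual`), with the inter-domain loss rate `interface_bias` times the
intra-domain rate, and are realised by inverting calibration curves of
contact loss versus separation and hinge angle measured on the toy with
the package's own contact rule (plateaus collapsed so the inverse is
continuous).  The jump to 0.6 encodes *extreme* cooperativity: with a
smaller jump the 26-residue toy's first unfolded conformations sit
within the 3 Å cooperativity threshold of native and no method could
(or should) report a sharp transition.  Each domain also acquires a
progress-scaled rigid reorientation of fixed magnitude and seed-random
axis, so the unfolded branch is a genuinely distinct region of
conformational space, and all wander terms ramp with the programmed
inter-domain loss so that early in a gradual run the realised contact
fractions stay on schedule.  Post-transition random walks on the hinge
angles and separation enter as absolute offsets — diversification can
make the toy more unfolded, never re-fold it.  A final safety pass
clamps any backbone Cα–Cα link beyond 4.45 Å, so bonded neighbours stay
within 4.5 Å in every frame.

What the generator does *not* emulate: real secondary-structure
energetics, side chains, disulfides, solvent, or any force-field
physics.  Passing tests on it demonstrates that the analysis code
recovers programmed transitions, rate biases and cooperativity contrasts
from trajectories with realistic bookkeeping (frame counts, contact and
SASA scales, noise) — not that it would reach the same biological
conclusions on any particular real protein.

## Problem sizes, determinism, defaults

Frames follow the convention t = s, 2s, …, T (the t = 0 snapshot is
excluded), so 8.1 ns at 10 ps is exactly 810 frames, ALF has 801
windows, five 8.1 ns runs at 1 ps pool 40500 conformations, and the
configured simulation set (1 × 12.1 + 5 × 8.1 + 1 × 3.6 + 4 × 10.1 ns)
sums to 96.6 ns.  The test suite and the acceptance script run the full
pipeline at these sizes on the toy protein, with SASA quadrature reduced
to 64–240 sphere points for long trajectories (the quadrature error of a
few Å² is far below the 50 Å² landscape bin); single-structure analyses
default to 960 points.  The parameter-recovery study uses 1 ns runs at
10 ps saves with the transition at 0.4 ns, 20 seeds, and its
interface-bias check fits initial contact-loss slopes on gradual-mode
runs, where both losses are in their linear regime and the rate ratio is
identifiable (after a two-state jump the inter-domain loss saturates
almost immediately, so a time-domain slope fit there estimates nothing);
with only ~10 inter-domain contacts in the toy the per-seed ratio is
granular, so it is averaged over seeds.  Everything is driven by
explicit integer seeds through one `numpy` generator per trajectory;
identical configs give byte-identical outputs.

Key defaults in one place: contact cutoffs 4.6/5.4 Å, > 2 residue
separation; cooperativity threshold 3 Å at 10 ps stride; ALF 90 ps / 10
ps; H-bond 3.5 Å / 90°; probe 1.4 Å; burial 5%; landscape bins 5
contacts × 50 Å² and 0.1 PC units; TSE window 10 ps; smoothing window 19
points; native-cluster radius percentile 95 with scale 1.5.

## Known limitations

* The crystal-structure contact-density worked examples require the
  published PDB entries (1SSX, 5PTP), which are not redistributable with
  the package; the corresponding tests look for them under `tests/data/`.
* Atomic radii follow the SASA backend's element table (which matches
  the values above); per-atom radius overrides affect the contact and
  exposure machinery but not the quadrature itself.
* The automatic basin detection assumes the run starts native and ends
  unfolded; trajectories that never leave, or analyses needing other
  basin definitions, should pass explicit regions.
* The crossing count (not the crossing time) can over-count on noisy
  runs; see above.
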