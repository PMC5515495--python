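# Methods

`discsim` is an off-lattice, agent-based model of planar cell polarization
and growth in the *Drosophila* wing primordium.  Cells are soft discs that
express the protocadherins Fat (Ft) and Dachsous (Ds) and the Golgi kinase
Four-jointed (Fj) under the control of an abstract morphogen, bind Ft–Ds
trans-heterodimers with their Delaunay neighbours, and read two things out
of the spatial asymmetry of their bond distribution: the direction and
magnitude of Dachs polarization, and a boost to their growth rate.

## Model structure

**Geometry and mechanics.**  Each cell has a centre and a radius.
Pairwise forces act between pruned Delaunay neighbours only: linear
repulsion `k_rep (1 − d/d_eq)` inside contact (`d_eq` = sum of radii) and
a short-range attraction `−k_att (d/d_eq − 1) exp(−(d/d_eq − 1)/λ)`
outside, zero exactly at contact and at long range.  Motion is overdamped
(displacement = mobility × net force × dt) with a per-step displacement
cap of 0.25 × the mean cell radius for stability.  Forces do nothing but
maintain packing; they do not feed back on signalling.

**Neighbour graph.**  Adjacency is the Delaunay triangulation of the cell
centres (scipy/Qhull; a deterministic per-cell jitter of ±1 nm breaks
cocircular ties), pruned by removing edges longer than
1.5 × (r_i + r_j).  Every edge carries the step at which the pair first
became adjacent; edges younger than a 30-minute grace period are excluded
from polarity read-outs (but not from binding).  After a division only
the local patch {mother, daughter, former neighbours} is re-triangulated;
spurious edges between two former neighbours are discarded, and
daughter–neighbour edges inherit the age of the mother–neighbour edge
they replace, because the bonds on that interface are inherited too.

**Signalling fields.**  The morphogen is radially symmetric,

    M(r, t) = C0 exp(t/t0 − A r / R),

with amplitude e-folding time t0 = 1200 min and a decay length that
scales with the disc radius R.  Fj falls linearly with radius
(`fj_min + slope (R − r)`); its intercept rises as R grows but its slope
is constant, so the Fj difference between neighbours is stable in time.
The Ds expression rate is a repressive Hill function of M with threshold
M_half and coefficient n; the inflection ring (the "Ds front") starts at
8 µm in a 40 µm disc and moves outward as the amplitude grows, with
closed form r* = (R/A)(t/t0 + ln(C0/M_half)).  In the stationary-front
variant the same Hill profile is pinned at a fixed relative radius
(default 0.85 R) with the same spatial width R/(nA); we deliberately did
not put the Hill on the linear position ratio, which would have produced
a transition ~0.5 R wide instead of the intended few cell diameters.

**Protein pools and binding.**  Each cell keeps integer counts of free
Ft and Ds, split into unphosphorylated and phosphorylated states.  New
protein is phosphorylated at birth with probability `fj/(fj + phos_K)`;
membrane protein is never phosphorylated afterwards, and only free
protein dephosphorylates or degrades.  Every step a cell partitions each
free pool evenly across its interfaces (remainders on uniformly random
interfaces), and each interface performs K = min(#Ft, #Ds) pairing
attempts: one Ft and one Ds drawn uniformly without replacement, binding
with probability 0.05 (Ft–Ds), 0.7 (FtP–Ds), 0.05 (Ft–DsP) or 0.2
(FtP–DsP).  Failed participants return to the free pool.  Drawing
without replacement is implemented exactly with nested hypergeometric
draws for the pair composition followed by binomial draws per type.
Bonds dissolve, and free protein degrades, by binomial thinning with
per-step probability `min(k dt, 1)`.

**Polarity.**  A cell's bound-Ft count toward each *mature* neighbour
feeds the adjusted minimum fraction (smallest count / total × number of
neighbours); asymmetry x = 1 − that.  Dachs is a vector pointing from
the cell centre toward the mature neighbour with the least bound Ft
(ties broken by a seeded random pick), with magnitude equal to the
bound-Ft asymmetry.  Cells whose mature neighbours share no bonds at all
read x = 1 — this convention is what makes ft⁻/ds⁻ discs overgrow.
Cells with no mature neighbours are recorded as unpolarised (x = 0).

**Adaptation and growth.**  Each of the three growth signals (normalised
morphogen M/(M+K_M), Ft asymmetry, Ds asymmetry) passes through an
integral-feedback filter: an internal integrator y relaxes toward the raw
signal with time constant tau_adapt = 300 min and only the excess
max(0, raw − y) drives growth, so constant inputs fade while changes pass
through.  The per-step radius ratio is

    r_n / r_{n−1} = 1 + G0 (1 + C_Ft x_Ft)(1 + C_Ds x_Ds)(1 + C_M x_M) / (1 + U),

with U proportional to the cell's free (unbound) Ft + Ds.  Cells cannot
shrink.  Division probability is logistic in the radius (midpoint
1.9 µm, steepness 0.05 µm), making division nearly deterministic in size
but asynchronous in time.  Daughters are placed half a mother-radius to
each side of a random axis with radius r/√2 (area conserved); free pools
split binomially, and each interface's bonds follow the daughter that
keeps that neighbour (binomial split when shared).  The daughter–daughter
interface starts bond-free and age zero.

**Step order.**  One step applies: fields → expression → degradation →
dephosphorylation → bond dissolution → partitioning + binding → polarity
(from step 100) → adaptation → growth → division → mechanics → graph
rebuild.  Degradation runs *before* dissolution so that protein released
from a bond always gets one binding pass before it is ever exposed to
degradation.  This matters: binding is assumed fast relative to turnover
(cadherin-scale replacement times), and racing degradation against
re-binding within the same step roughly doubles the decay rate of the
bond-distribution memory, which is the quantity the wake retention of
polarity rests on.

## Parameters

| parameter | default | units | origin |
|---|---|---|---|
| k_dissoc, k_deg_ft, k_deg_ds | 0.08 | /min | stated wild-type rates |
| binding weights (uu, pu, up, pp) | 0.05, 0.7, 0.05, 0.2 | — | stated wild-type weights |
| t0 | 1200 | min | measured Dpp amplification time |
| Fj slope, fj_min | 0.025 /µm, 0.1 | a.u. | stated wild-type profile |
| Ds rate_high | 20 | /min | stated peripheral expression rate |
| uniform-Fj level | 10 | a.u. | ~10× wild-type overexpression |
| clone Ds rate | 200 | /min | stated clone overexpression |
| A, C0, M_half | 2.5, 0.5·e^0.5, 0.5 | — | calibrated: front(0, 40 µm) = 8 µm |
| hill_n | 8 | — | transition region a few cells wide |
| Ds rate_low | 0.5 | /min | calibrated, see below |
| ft_rate | 40 | /min | calibrated, see below |
| phos_K | 0.5 | a.u. | central Fj saturating, edge Fj low |
| k_dephos | 0.02 | /min | slower than binding, state is a memory |
| grace period | 30 | min | several bond-replenishment time constants |
| G0 | 7e-4 | /step | calibrated: ~8 h division interval |
| C_M = C_Ft = C_Ds | 0.9 | — | every C·x stays below 1 |
| u_scale | 5e-4 | /molecule | keeps U well below 1 at typical free pools |
| tau_adapt | 300 | min | asymmetry near a static front fades in hours |
| r_div, steepness | 1.9, 0.05 | µm | division at ~3.8 µm diameter |
| cutoff_factor | 1.5 | — | keeps touching pairs, removes hull edges |

Calibration notes.  The absolute expression floor `rate_low` and the
(uniform) Ft supply are not constrained by published values; they control
how long a cell's bond distribution remembers the passage of the Ds
front.  With a high floor, the post-front bond counts are large enough
that counting noise (~√N per interface) swamps the decaying front
contrast within a few hours; with rate_low = 0.5/min (a 40:1 high:low
contrast) and Ft in modest excess over Ds supply (40 vs 20/min, so that
the peripheral Ds pool is predominantly bound and therefore protected
from degradation), the wake retains its inward polarization for most of
a simulated third instar, which is the model's central behaviour.  G0
was set so that mid-run wild-type cells divide roughly every 8–10 h
under the adaptation-filtered growth law.

## What the simulator emulates, and what it does not

All inputs are self-generated: the initial disc is a rejection-sampled,
mechanically relaxed packing of 1000 cells (radii U[1.1, 1.5] µm) that
relaxes to R ≈ 42 µm with the centre compressed relative to the edge.
The published geometry is internally inconsistent at this point (1000
cells of 3–4 µm diameter cannot fit a 40 µm disc); we keep 1000 cells and
R ≈ 40 µm and let cells grow into the 3–4 µm diameter band over the
course of a cycle (newborns 2.7 µm, dividing cells 3.8 µm).  The model
is two-dimensional, has no mitotic apical rounding, no cell
rearrangement beyond mechanical relaxation, no mechanotransduction, and
no explicit Dpp/Wg transport — the morphogen formula stands in for all
upstream patterning.  Dachs is a pure read-out: it does not feed back on
division orientation or mechanics.

Passing tests therefore show that the *mechanism* — a moving expression
front writing a durable, division-proof asymmetry into bond
distributions — behaves as described under these synthetic conditions;
they say nothing about parameter values in real discs.

## Numerical choices

- All randomness flows through one `numpy` Generator per run; replicate
  seeds are spawned from the base seed.  Bond-dissolution draws are made
  in canonical pair order so trajectories are independent of ledger
  storage order, and a saved run resumes bit-identically (state CSVs are
  written with `%.17g` and read with round-trip float parsing).
- Per-step probabilities are `min(k dt, 1)`, so halved or doubled time
  steps need no re-tuning and the stated per-step rates are reproduced
  literally at dt = 1.
- Cocircularity is broken by a fixed per-cell jitter (±1 nm) assigned at
  birth; collinear point sets (which occur in the division repair of a
  three-cell row) fall back to a principal-axis chain.
- Argmin ties in the Dachs direction are broken by seeded random choice;
  the disc radius estimator is the 99th percentile of centre distance +
  cell radius; the disc centroid is the unweighted mean of positions.

## Problem sizes used by the test suite

The full 1000-cell, 2880-step wild-type run is supported but slow;
the shipped tests exercise the model at reduced scale: 250–300 starting
cells and 960–1200 steps for the front-geometry and genotype-ordering
checks (with the initial radius scaled as 40 √(n/1000) µm to keep the
packing density), 50 cells × 500 steps for conservation accounting, and
a three-cell chain for the division-retention mechanism.

## Known limitations

- The never-swept core of the disc stays weakly polarized for the whole
  run; only cells the front has passed over acquire stable distal
  polarization.  This matches the intended behaviour but means
  whole-disc mean alignment depends on how far the front has travelled.
- Uniform-morphogen and no-morphogen genotypes have no front and
  therefore no defined front radius; summaries report it as missing.
- Interface bonds between cells that drift apart stop being counted
  (the pair leaves the neighbour graph) but keep dissolving at k_dissoc;
  they are not force-released on separation.
- The growth law is only calibrated near the wild-type regime; extreme
  rate variants (10× faster dissociation/degradation) run but their
  absolute cell counts should be read qualitatively.
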