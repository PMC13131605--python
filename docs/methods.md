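# Methods

## Model

Cells are space-filling polyhedra in a slab that is periodic in x and y.  The
slab is layered from bottom to top: a basement-membrane layer (its floor
vertices pinned), a single basal stem-cell monolayer, one or more suprabasal
layers, and a ghost layer that closes the tissue at the ceiling.  The
dynamical degrees of freedom are the shared polyhedral vertices.  The tissue
energy is

    E = Σ_c K_V (V_c − V0_c)² + Σ_c K_S (S_c − S0_c)² + Σ_f σ_ij A_f ,

summing over non-ghost cells c and over interfaces f between cells of
different types.  The first term resists volume changes; the second encodes
the competition between cortical contractility and adhesion through a
preferred surface area; the third carries the heterotypic interfacial
tensions.  The dimensionless target shape index s0 = S0·V0^(−2/3) controls
tissue rigidity: low s0 is solid-like, high s0 fluid-like.  Ghost cells keep
full topology but contribute to none of the sums.

Vertices follow overdamped Langevin dynamics, integrated with
Euler–Maruyama:

    r ← r + μ F dt + sqrt(2 D_t dt) ξ,    F = −∇E (analytic).

Forces are exact gradients of the triangulated polyhedral volume, area, and
interfacial terms; each face is triangulated about its own centroid, so the
two cells sharing a face see identical triangles and the summed cell volumes
tile the box exactly (the confluence audit is satisfied to round-off at all
times, not just after construction).

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| K_V, K_S | 1 | volume and surface moduli (nondimensional convention) |
| V0 | 1 | target volume; sets the length unit |
| μ | 1 | vertex mobility |
| dt | 0.01 τ | integration step |
| D_t | 0.02 | vertex noise strength; chosen so an undivided basal layer is quiescent but not frozen (unconstrained by the main-text sources; configurable) |
| s0_ref (basal) | 5.40 | reference basal target shape index, near the 3D rigidity transition of this model family |
| s0 suprabasal | 5.50 | slightly fluid suprabasal compartment (configurable) |
| s0 basement | 5.40 | basement layer (its floor is pinned anyway) |
| t_retess | 1 τ | re-tessellation cadence (see below) |
| ell_sep | 0.3 V0^(1/3) | daughter-seed separation at division |
| t_pop | t_div / 2 | homeostasis check interval (at least as often as divisions) |

Developmental stages enter as triplets (σ_a, σ_b, Δs): σ_a is the
basal–suprabasal heterotypic tension, σ_b the basal–basement wetting
tension, and Δs lowers the basal target shape index from s0_ref (stiffening
the basal layer).  The shipped presets are E14 = (0.044, 0.062, 0) and
E16 = (0.116, 0.067, 0.14).

Times are reported in the natural unit τ; the droplet calibration ties
τ ≈ 0.1 min, so one estimated day is 14400 τ and the division rate per basal
cell per day is λ = 14400/(N_basal · t_div).

## Topology maintenance by cadence re-tessellation

Neighbour exchanges are realized by periodically rebuilding the tessellation
from the Voronoi diagram of the current cell centroids (default every 1 τ),
rather than by an explicit catalog of reconnection (T1) moves.  Divisions
always trigger a rebuild.  Because a rebuild snaps vertices to raw Voronoi
positions — which is not a mechanical equilibrium — every rebuild is followed
by a brief energy minimization (FIRE, 30 iterations by default) before
dynamics resume.  Without this relaxation the snap acts as an artificial
energy pump.  The rebuild resolves periodic images exactly: boundary-crossing
faces are stitched by identifying each duplicate ridge with its canonical
copy via whole-lattice-vector offsets, so no tolerance-based vertex merging
is involved.

A known consequence of cadence-based rebuilds is an effective plasticity:
deformations that persist over several cadence periods are partially
imprinted into the topology.  The droplet rheometer (below) is therefore run
in the regime of modest strain.

## Proliferation and stratification

Exactly one basal cell at a time carries a growth coefficient α; its target
volume grows linearly and its target surface follows S0 = s0·V0^(2/3).  In
the experiment drivers α defaults to 1/t_div so the grower roughly doubles
its target volume within one division interval at any division rate; a cell
that merely splits without having grown would otherwise halve the lineage's
target volume every generation.  At each division interval the grower is
replaced by two daughter seeds displaced ±(ell_sep/2)·n̂ along the prescribed
mitotic axis n̂(θ, φ); the tessellation is rebuilt, the parent's V0 is split
equally (conserved exactly), both daughters are basal, and the energy is
re-minimized.

A basal cell stratifies homotypically when its centroid rises above the
basal–suprabasal interface (the mean height of shared basal–suprabasal face
centroids) while no longer touching the basement layer; its parameters
switch to suprabasal instantly (N_homo).  Under the homeostatic protocol,
whenever the basal count exceeds its initial reference by more than two at a
t_pop check, one uniformly random basal cell switches identity (N_fate); the
densifying protocol omits this.  Every basal→suprabasal transition converts
the top-most suprabasal cell into a ghost, so the non-ghost tissue keeps a
quasi-steady thickness while material fluxes upward.  Detection runs at the
re-tessellation cadence, since contact queries need fresh adjacency.  The
`+2` threshold is always compared against the initial basal count.

## Droplet rheometer

A contiguous blob of cells (default 17) is re-typed as a droplet with
s_droplet = 5.8 (fluid regime, no shear-modulus contribution) inside a fully
periodic bulk tissue (no layered architecture — the experiment is a bulk
calibration), distinguished by a heterotypic tension σ (default 0.8).  During
actuation every droplet vertex receives F = f·(x − x_cm)·x̂, which sums to
zero exactly.  The strain is defined from the gyration tensor of the droplet
vertices as ε = ℓ_∥/ℓ_⊥ − 1 (elongation along the force axis relative to the
mean transverse axis), positive under stretch and zero for a sphere; the
literal (b − a)/a with a the major axis would be non-positive under stretch,
so the sign convention here is chosen to make stretch positive.  The
recovery branch after force-off is fit by a generalized-Maxwell form

    ε(t) = A1 exp(−t/τ1) + A2 exp(−t/τ2),  τ1 < τ2,

with nonnegative amplitudes and τ2 = r·τ1, r ≥ 1.2, multi-started over
log-spaced guesses.  The default box in this package is reduced
(7×7×6 = 294 cells) relative to a full-size droplet tissue of 2115 cells,
and the default dipole strength is scaled down accordingly to stay in linear
response (peak strain ≲ 0.3); at full size, reference parameters are
s0 = 5.8, σ = 0.8, f = 0.5.  Fitted timescales at reduced size are expected
to agree with full-size values only in order of magnitude; the package
asserts recovery and the insensitivity of the longer timescale to s0 and σ,
which are size-robust statements.

## Analysis conventions

* Long-axis orientation: the ellipsoid fit is the eigen-decomposition of the
  unweighted gyration tensor of a cell's vertices; θ_long = arcsin|n_z| of
  the leading eigenvector, in [0, π/2].  Distributions are histogrammed,
  mirrored about π/2, normalized on [0, π], and divided by the reference
  measure P_iso(θ) = sin(θ)/2.  Note this reference is the 3D uniform
  measure of the polar angle; it is the convention under which the reference
  peak values at π/2 are finite, and the package's isotropy check feeds
  sin-distributed samples accordingly.  FWHM is measured on the ratio curve
  around its global peak with linear interpolation between bins.
* Division-angle bins: planar [0, π/6], oblique (π/6, π/3], perpendicular
  (π/3, π/2]; stage weights are normalized observed fractions
  (E14: 0.20/0.25/0.55; E16: 0.60/0.25/0.15).
* Daughter separation: per division event, s(t) = r_d1 − r_d2 with minimal
  image and temporal unwrapping; Δd²(t) = ⟨|s(t) − s(t0)|²⟩ over the event
  ensemble at fixed time-since-division (no time-window averaging); pairs
  are censored once either daughter leaves the basal layer.
* Errors: events are split into equal subgroups (reference partition:
  40 → 5×8); the binned-mean error is std(subgroup means)/√n_subgroups, and
  the diffusion-coefficient error is the std over per-subgroup slopes.
* D is the raw slope of Δd² vs t on the late-time window (default: last 40%
  of available lags, Δt = 5 τ bins), with no dimensional prefactor.
* Orientation-weighted averages: ⟨X⟩ = Σ_θ W(θ) X(θ); the quoted spread is
  the unweighted standard deviation of the mean over the three angle bins.

## Problem sizes used in the shipped tests and acceptance script

The package's own verification runs use reduced systems chosen to keep a
full desk run short: tissues of 9–36 basal cells (36–144 cells total),
droplet boxes of 180–294 cells with 9–17 droplet cells, run lengths of
10²–10³ τ, and small seed ensembles.  Specifically: stratification-yield
grids run both stages at θ ∈ {0, π/4, π/2} with t_div = 60 τ for 420 τ,
pooling two seeds; fluidization runs compare t_div = 25 τ (400 τ) against
t_div = 100 τ (800 τ) at 16 basal cells, a 4:1 rate ratio mirroring the
reference fast:slow contrast; droplet recovery averages a three-seed
ensemble of 294-cell runs (40 τ on, 350 τ off), with the s0/σ sweep at a
180-cell box.  At desk scale the absolute per-cell daily division rates of
a 150-cell tissue are not reachable, because the cost of accumulating
division events at fixed per-cell rate is independent of tissue size.  All
trend assertions (monotonicity in θ, stage ordering, rate ordering) are
made at these reduced conditions.

## What the reduced verification runs do and do not show

The stratification-yield orderings (monotonicity in θ; E14 above E16) are
robust at the shipped scales and are asserted directly.  Two reference
behaviours do not survive the reduction and are knowingly out of reach of
the desk runs:

* the absolute long-axis peak of a growing cell at π/2 — cadence
  re-tessellation keeps snapping shapes toward near-isotropic Voronoi cells,
  so only the *stage ordering* of the distribution metrics (peak, anisotropy
  ratio, FWHM) is asserted, not the peak location;
* the daughter-pair diffusion orderings at the reference per-cell division
  rates — in small periodic boxes planar pairs are cage-limited while the
  rare perpendicular pairs that escape censoring show inflated relative
  motion (survivor bias), so parts of the fluidization check fail at desk
  scale and are documented as such rather than loosened.

## Known limitations

* Cadence re-tessellation is an approximation to explicit reconnection
  dynamics; it adds a small effective plasticity and caps how deeply the
  system can relax between rebuilds.
* The minimizer cannot reach arbitrarily small force residuals on jittered
  tissues: shrinking faces make the energy landscape locally nonsmooth, so
  practical tolerances are 10⁻²–10⁻¹ in force units (the perfect cube
  lattice, an exact minimum, is used where a zero-force state is needed).
* The synthetic initial tissues are jittered cubic lattices; they emulate
  disordered confluent packings after brief relaxation but carry no lineage
  structure, curvature, or basement-membrane remodeling.  Passing tests
  therefore validate the model's mechanics and statistics, not agreement
  with any particular imaging dataset.
* Suprabasal/basement target shape indices, D_t, α, ell_sep, and t_pop are
  exposed configuration with documented defaults rather than literature
  values.
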