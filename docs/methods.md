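# Methods

`hipposim` is a rate-based simulation toolkit for the attractor theory of
hippocampal episodic memory: the CA3 recurrent-collateral system as a
diluted autoassociative network, the dentate gyrus as a competitive
pattern-separation stage with a sparse, randomizing mossy-fiber projection
into CA3, perforant-path/CA1/backprojection pattern associators, and mixed
continuous + discrete (object–place) attractor memories. This note records
the model, its assumptions, the parameters that matter, and the numerical
and design choices behind the implementation.

## Patterns and sparseness

All stages exchange length-N vectors of non-negative firing rates. The
population sparseness of a rate vector is

    a = (Σ_i r_i / N)² / Σ_i (r_i² / N),

ranging from 1/N (one active neuron) to 1.0 (uniform firing). For binary
vectors it reduces exactly to the fraction of active units.

Binary ensembles draw `round(a·N)` active units per pattern uniformly
without replacement; the active rate is fixed at 1.0 because the sparseness
measure, cosine overlap, and k-WTA dynamics are all scale-free. Rounding is
half-away-from-zero so that small networks never round to zero active
units. Graded ensembles draw i.i.d. exponential or gamma rates, subtract a
threshold, rectify at zero, and bisect on the threshold until the measured
sparseness is within ±0.01 of the target; thresholding can only lower the
sparseness of a sample, so targets above the raw sample's sparseness (≈0.5
for exponential) are rejected rather than silently approximated.

Correlated binary ensembles (used to probe pattern separation) use a
shared-core construction: every pattern contains a common active core of
`s ≈ r·a·(1−a)·N` units plus independent random active units, which gives a
mean pairwise Pearson correlation of approximately `r`.

A caveat worth recording: because each binary pattern has an *exactly*
fixed active count, two units' rates within one pattern have covariance
−a(1−a)/(N−1), not zero. Accumulated over p patterns the mean covariance
weight is therefore a small negative number growing with p (≈ −p·a(1−a)/N),
not exactly zero; it is negligible relative to the a(1−a) weight scale and
is absorbed by the k-WTA inhibition.

## Global inhibition as k-winners-take-all

Feedback inhibition keeping the number of active principal cells roughly
constant is modelled as exact k-WTA: the `round(a·N)` most strongly driven
units fire, ties broken toward the lowest neuron index so every run is
bit-reproducible. The default output is binary (winners at rate 1.0): the
stored ensembles are binary, and binary winner rates make each stored
pattern an exact fixed point of the retrieval map at low load, which
graded threshold-linear rates only approximate. A graded output mode
(threshold-linear above the largest losing drive) is used where rate
profiles are the object of interest: dentate rate maps and the continuous
attractor pool.

## CA3 autoassociator

Wiring: each of N neurons receives exactly C afferents sampled uniformly
from the other neurons (no autapses; duplicates only in the explicit
multi-synapse experiment). Dilution is C/N — 12,000/300,000 = 0.04 for the
rat preset. Weights live on the edge list (N×C), never on a dense N×N
matrix; dilution is the point of the model.

Storage: Hebbian accumulation `Δw_ij = k·r_i·r_j` over wired edges, or the
default covariance variant that subtracts `a_prior·r̄` (sparseness × active
rate scale) from both factors. The covariance variant is the default
because efficient storage requires heterosynaptic depression as well as
potentiation; pure Hebb is retained for pedagogy.

Retrieval: the cue is applied as a *sustained* external input of strength
`cue_gain` on every iteration while the recurrent drive
`h_i = Σ_c w_ic r_{aff(i,c)}` iterates through k-WTA. This mirrors the
division of labour in the theory — the numerically large perforant-path
input relays the retrieval cue, and the recurrent collaterals then complete
the pattern. The default `cue_gain = 2.0` (in units of rule constant ×
rate²) is comparable to the recurrent drive contributed by two co-active
afferents. The sustained input matters quantitatively at desk scale:
with C·a ≈ 2.5–5 expected active afferents per neuron, a fraction e^(−C·a)
of each pattern's units receives zero recurrent drive, so purely free
dynamics from a transient cue cannot reach high-overlap retrieval however
low the load; the constant-gain field restores the regime in which
simulated capacity is linear in C and monotone in 1/(a·ln(1/a)), the
structure the analytic theory predicts. Setting `cue_gain = 0` recovers
free attractor dynamics, used for the overload analysis below. Synchronous
updates are the deterministic default; an asynchronous mode visits neurons
in a seeded random sweep against the previous sweep's winning threshold.

Analytic capacity: `p_max = round(k · C / (a · ln(1/a)))` with the
prefactor k exposed as a free parameter (biologically plausible networks
put it roughly at 0.2–0.3; the rat preset uses 0.235, which reproduces the
~36,000-memory figure for C = 12,000, a = 0.02).

Simulated capacity: doubling search then exact binary search for the
largest p such that ≥ 90% of stored patterns are retrieved with cosine
overlap ≥ 0.9 from full-pattern cues under the sustained-cue protocol. The
criterion is configurable and its text is recorded inside every estimate.
Retrieval is evaluated on a random subsample of at most 40 stored patterns
per load for tractability. The empirical prefactor `k̂ = p_max·a·ln(1/a)/C`
is reported; at N = 1000, C = 100, a = 0.05 it is ≈ 0.12 — inside the
asymptotic 0.2–0.3 range widened downward by finite size. Overloading is
real: storing 3× the measured capacity and running *free* dynamics
(cue_gain = 0) from full cues collapses mean overlap to near chance; the
sustained field would mask this by construction, so the overload analysis
always uses free dynamics.

Multi-synapse experiment: a matched network rewires a given fraction of
afferent slots to duplicate an existing (pre, post) pair; replacement is
sequential so duplicates compound (at fraction 1 with C = 2 every neuron
ends with one doubled afferent). Duplicated edges carry independent weights
that sum in the drive, distorting the energy landscape; measured capacity
drops severalfold at 30% duplication — the argument for why recurrent
cortical connectivity is diluted.

## Dentate pathway

Grid inputs are 1-D periodic tuning curves on a unit ring:
`rate = peak · max(0, cos(2π·f·(x − φ)))^ρ` with integer frequency f
(peaks per traversal), phase φ, and sharpening exponent ρ (default 3; it
sets field width without changing peak count). A 1-D ring is used because
the reference rate profiles are 1-D; 2-D grids are out of scope.

The competitive network is the canonical normalized form: activations
h = w·r, k-WTA at `round(a_dg·n_dg)` winners, winner update Δw = η·r
(Hebb gated by the postsynaptic winner), followed by L2 renormalization of
the updated rows. Presentations scan the track uniformly with a seeded
shuffle per epoch. Defaults mirror the training regime the package's
experiments use: 50 grid cells with frequencies 2–9, 500 granule units at
a_dg = 0.02, η = 0.05, 100 positions, 20 epochs.

Two rate maps are distinguished when quantifying the grid→place
transformation. Place *fields* are counted on the post-inhibition firing
map (a field = maximal circularly contiguous run of positions with rate
≥ 50% of the unit's peak, the standard half-max convention). Spatial
*sparseness* — the sparseness formula applied across positions — is
computed on the rectified pre-inhibition drive map, i.e. the unit's tuning
curve: on the firing map the measure counts win events and actually rises
as scattered wins consolidate into one contiguous field, whereas on the
tuning curve it falls as broad mixed tuning sharpens into a single bump.
Training raises the single-field fraction among active units (≈0.61→0.88
at the default conditions) and lowers tuning sparseness (≈0.93→0.77).

The mossy projection gives each CA3 cell `fan_in` (default 46) distinct
granule afferents of equal fixed strength; the drive is thresholded by
k-WTA to the CA3 sparseness. With 10^6 granule cells the dilution is
0.000046. An optional non-associative facilitation flag (off by default)
amplifies strongly firing fibers by raising the presynaptic term to
1 + facilitation. Separation is quantified as mean pairwise output
correlation / mean pairwise input correlation; correlated inputs at r = 0.5
come through a 46-fiber projection with an index well below 1 in ≥ 95% of
wiring seeds (expansion recoding decorrelates).

## Pattern associators and backprojections

A pattern associator is one feed-forward stage: each output neuron samples
C_PA distinct inputs, stores `Δw = k·post·pre` per pair, and recalls in a
single pass through k-WTA — no recurrence, hence generalization from
partial input cues but no completion and no reverse retrieval (cueing with
a stored output leaves input overlap at the chance level a_o). Analytic
capacity `p_max = round(C_PA / (a_o·ln(1/a_o)))` has the same form as the
recurrent capacity, so at equal sparseness the feed-forward/recurrent ratio
is just C_PA/C_RC = 3600/12000 = 0.3 for the rat.

The recall signal grows as √C: storing p random pairs and measuring
(mean target drive − mean non-target drive)/sd(non-target drive) across
C ∈ {100, 400, 1600} yields a log-log slope ≈ 0.5 — the reason the
numerically large perforant path suits cue relay.

Backprojection budget: `C_HBP = round(k′·C_RC·a_nc/a_CA3)` with the slowly
varying prefactor k′ defaulting to 1 (ratio-only use). With matching
sparsenesses each neocortical stage needs as many backprojection afferents
as CA3 has recurrent collaterals, which forces a multistage pathway. The
hierarchy simulation uses 4 stages sized (300, 400, 600, 1000) with
non-decreasing sizes (divergence grows toward neocortex), p = 3 stored
chains, sparseness 0.05 throughout, and a desk-scale reference count
C_ref = 150 for the budget. C_ref was chosen from a Poisson argument made
before running the experiment: at budget, each output neuron expects
C·a ≈ 7.5 active afferents (near-reliable single-stage transmission), while
half-budget (≈ 3.75) is sampling-noise limited; successive halvings of C
then degrade final-stage overlap monotonically.

## Mixed continuous/discrete attractor

The joint network concatenates a ring of 1000 spatially tuned neurons and
500 discrete object neurons with dense recurrent weights (no
self-connections). A memory is a Gaussian bump
`r_i = peak·exp(−d(i, center)²/(2σ²))` (ring-wrapped distance d) plus a
binary object set. Storage is Hebbian outer-product accumulation (the
covariance option centers each subpopulation on its own mean so cross-pool
associations between co-active parts stay positive); storage is additive
and order-independent.

Inhibition is applied per subpopulation — separate k-WTA budgets for the
spatial pool (graded output, preserving the bump profile) and the object
pool (binary) — because a single global threshold would let the larger pool
silence the smaller. Retrieval iterates the joint dynamics to a fixed
point; translation modes zero the other pool in the cue. The retrieved bump
center is the circular center of mass of the supra-threshold continuous
rates.

Unstated layout parameters were fixed once: σ = 20 index units (a place
field covering a few percent of the ring), 25 active object units of 500,
and a continuous activity budget of 4σ = 80 units (the ±2σ support of the
stored bump). With two memories at centers 300 and 500, object cues
retrieve the bump center exactly and place cues retrieve the object set at
Jaccard 1.0; retrieval is symmetric in both directions, unlike the
feed-forward associator control. Training a dense manifold (bump centers
every 10 indices) turns the ring into a continuous attractor: a free-
running bump drifts less than 2 indices over 200 iterations and stays
unimodal under the default inhibition.

## Experiments, seeds, reproducibility

Every experiment is a pure function of a flat JSON config plus one root
seed, spawned into per-component child seeds via `numpy.random.SeedSequence`
(children are drawn from the same sequence, so partial spawns agree across
matched runs — the duplicate-synapse experiment relies on this to compare
networks with identical wiring seeds and patterns). Identical (config,
seed) reproduce all tables byte-identically. Unknown config keys are
rejected before any computation. Results are written as CSV tables, a JSON
summary with a config hash, the fully resolved config, and a run log
recording the resolved seed and timing.

Problem sizes in the shipped experiments and tests are desk-scale
(N ≤ 2000, 20 wiring seeds, 3-seed capacity averages), chosen so a full
capacity scan completes in seconds on one core while remaining in the
sparse regime (C·a of a few) that the anatomical parameters imply.

## What the synthetic data does and does not show

All inputs are generated internally: random sparse binary/graded patterns,
idealized periodic grid tuning, and Gaussian bumps. These reproduce the
statistical structure the theory analyses — sparseness, dilution, pattern
correlations — but none of the biological texture: no spiking noise or
Poisson variability, no temporal dynamics within a theta cycle, no 2-D
environments, no neurogenesis turnover, no inhibitory circuitry beyond the
k-WTA abstraction. Passing tests therefore validate the rate-level
computational claims (capacity scaling, separation, completion,
object–place symmetry), not predictions about spike-level dynamics or
behaving animals.

## Known limitations

- Simulated capacity depends on the retrieval criterion and the sustained
  cue gain; both are recorded in every estimate, but absolute p_max values
  should be compared only within a fixed protocol.
- The k-WTA surrogate enforces the active count exactly; real inhibition
  keeps it only "relatively constant", so near-threshold effects (e.g.
  graded bump edges) are sharper here than in a biophysical model.
- The bilaterality correction to the recurrent connectivity (≈2% effective
  vs 4% unilateral) is not modelled; dilution is reported as C/N only.
- The optimal mossy fan-in (~35–50) is taken as a parameter, not re-derived
  from information theory; `fan_in` is exposed and separation can be
  measured against it.
- CA1 is modelled as a plain pattern associator; a competitive recoding
  stage for CA1 is not implemented.
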