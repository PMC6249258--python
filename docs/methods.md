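# Methods

`nemataxis` simulates salt chemotaxis of *Caenorhabditis elegans* on an agar
plate and asks a representational question: how can a worm whose two salt
sensors sit millimetres apart at most — effectively a single sensing point at
the nose tip — maintain internal estimates of the chemical gradient both
*parallel* and *perpendicular* to its direction of travel, the two quantities
that drive its pirouette and weathervane steering strategies?  The package
contains the full stack needed to pose and test that question in
simulation: the diffusing NaCl environment, a multibody undulating body, the
stochastic behaviour layer, the two-filter computational model that forms
the internal gradient representations, geometric "true gradient" oracles,
and a connectome-style recurrent network trained to generate the same
representations from the same inputs.

## Environment

NaCl spreads from `K` point sources on a thin agar sheet.  Concentration at
position `x` (cm) and diffusion time `t` (s) is

    c(x, t) = N0 * sum_k exp(-|x - x_k| / (r1 D t)) / (r2 E D t)

with diffusion coefficient `D = 1.5e-5 cm^2/s` (NaCl in agar), agar
thickness `E = 0.2 cm`, and dimensionless constants `r1`, `r2` shaping the
kernel.  The exponent uses the plain distance; a `squared_distance` switch
selects the conventional Gaussian kernel instead, without any other change.
The worm is released at the plate centre after a 3600 s pre-run diffusion
period, and the field keeps decaying as `1/t` during the 1200 s run.

Defaults place four sources 1.1 cm from the centre with `r1 = 18` (decay
length `r1*D*t` grows from about 1.0 to 1.3 cm during a run), so each source
has a localised peak whose attraction basin reaches the release point, and
`N0 = 6e-3 mM`.  The amplitude deserves a comment: the absolute
concentration scale cancels from every correlation-based statistic, and the
behavioural gains are calibrated jointly with it, so `N0` is fixed by the
error statistics this stack is validated against — with a crawl speed of
0.12 mm/s, those error magnitudes (~1e-6 mM/s parallel, ~1e-4 mM/cm
perpendicular) imply sensed signals of the same order, i.e. peak
concentrations of order 1e-3 mM.  One consequence is physical and worth
stating plainly: at this signal scale the pirouette-rate law (below) is in
its flat region, so pirouettes fire at an essentially constant base rate and
the chemotaxis performance is carried by the weathervane strategy.

## Multibody worm

The body is a chain of 12 rigid modules (total length 1 mm).  Module
headings are defined at the centroids and adjacent centroids are exactly one
module length apart along the mean heading of the pair, so link lengths are
conserved by construction.  The posture is *prescribed*: joint angles follow

    q_i(t) = q_max sin(omega t - phi_i(t)) + kappa(t)

with `q_max = 0.5 rad`, `omega = pi rad/s` (2 s undulation period — three
head-bend cycles per 6 s reversal), and forward phases advancing by
`2*pi*psi` per joint with `psi = 0.125` (1.375 body wavelengths).  Only the
global rigid translation and rotation are dynamic: each 0.01 s step solves
the linearised overdamped force/torque balance under anisotropic viscous
friction (`C_n / C_t = 5`), the standard resistive-force picture of
crawling.  The balance residual is first order in the per-step rotation
(relative residual below ~1 % in practice).  An inertial mode integrates
the global Newton equations instead; it exists as a config option and is not
used by the shipped experiments.  Gravity acts normal to the crawling plane
and never enters.

`q_max` and the drag ratio were calibrated once so the straight crawl speed
matches the 0.12 mm/s measured on chemotaxis plates.  A published figure of
1.28 mm/s for a comparable simulation is treated as a decimal slip of the
same number; the gradient statistics below are internally consistent only
with 0.12 mm/s.  The sign of a joint angle (which side is "ventral") is a
convention; it is fixed so that a positive head bend swings the nose toward
the side that the lateral-gradient oracle counts as positive.  Random
wriggling of the nose tip is deliberately not modelled.

## Behaviour

Three steering mechanisms act on the gait:

* **Weathervane**: a curvature bias `kappa_w = -C_w d_s`, with `d_s` the
  perceived lateral gradient in mM/mm.  `|C_w| = 450` was calibrated so
  that, at the lateral-gradient scale of the default field, the bias reaches
  the few-hundredths-of-a-radian range producing turn radii of a few
  millimetres (the scale of measured weathervane curving).  Its sign encodes
  attraction given the oracle's right-handed lateral convention.
* **Pirouette**: initiation is Bernoulli per step with probability
  `f_p dt`, where

      f_p(d_t) = 0.023 / (0.4 + exp(140 d_t)) + 0.0033   [events/s]

  is decreasing in the perceived parallel gradient `d_t` (mM/s).  Scaling by
  `dt` makes the realised event rate match the events/s unit.  A pirouette
  is a 6.0 s reversal (the travelling wave is flipped by the
  posture-continuous phase map `phi -> pi + 2 omega T_p0 - phi`) followed by
  a 3.18 s sharp turn.
* **Random walk**: every 12 s a curvature target is drawn from
  `N(0, C_r)` (`C_r = 0.008 rad`, matching the ~1 rad/cm curvature spread
  of worms crawling without a gradient) and the applied curvature moves
  linearly between successive targets.

The sharp turn needs a design note.  The published mechanism manipulates the
gait phases piecewise linearly (ramp up, hold, ramp down).  A phase shift
shared by all joints merely re-parametrises the same shape sequence in time,
and a reciprocal shape sequence in an overdamped resistive medium produces
no net displacement or rotation (the scallop-theorem argument; confirmed
numerically at <0.02 rad for any ramp size).  This implementation therefore
(a) grades the phase delay along the body — zero at the head joint up to the
maximum `C_p` at the tail joint — which transiently shortens the body
wavelength and produces the S -> Omega -> S posture sequence, and (b) adds a
ventral curvature bias `kappa_turn = 1.2 rad` per joint with a trapezoidal
envelope over the same three segments, which is what actually reorients the
body.  With these defaults the reorientation across a pirouette is
2.6–3.0 rad, satisfying the >1.75 rad sharp-turn definition.  The ramps
cancel and the phase state is restored exactly at turn end.  Weathervane and
random-walk biases are suspended during reversal and turn.

## Internal gradient representations

The computational core is two first-order filters driven by the time
derivative of nose-tip concentration, `dc/dt`, and the head-bending angle
`q0`:

    dy_p/dt = -a_p y_p + b_p dc/dt + eps_p
    dy_w/dt = -a_w y_w + sign(q0) b_w dc/dt + eps_w

with `a_p = 0.58 /s`, `a_w = 0.73 /s`, `b_p = 1.20`, `b_w = 1.46`, `eps = 0`
by default, integrated by forward Euler at 0.01 s (`a << 1/dt`).  `y_p`
low-passes the sensed derivative, removing the head-swing oscillation and
keeping the drift along the path — the parallel gradient times speed.
`y_w` multiplies the sensed derivative by the sign of the head bend before
filtering: the nose samples alternately ventral and dorsal of the path, so
this demodulation extracts the lateral gradient.  The `q0 = 0` tie takes
the negative branch.

Two unit gains relate the filter outputs to physical gradient units (the
filters' own gains leave the outputs on an arbitrary scale):
`scale_p = a_p/b_p` divides out the DC gain so `y_p` is an unbiased mM/s
estimate, and `scale_w = 52` (the reciprocal of the demodulation gain
0.0193, measured once by crawling the default gait through a linear fixture
field) restores mM/cm.  Both are pure unit conversions: correlations are
unaffected, and the behaviour gains absorb them.

## True-gradient oracles

The "true" parallel gradient along the body-centre path is the total time
difference `[c(x_g(t), t) - c(x_g(t - Dt), t - Dt)] / Dt` (it includes the
field's own decay).  The true perpendicular gradient is a central difference
between two points displaced `delta = 0.01 cm` to either side of the path,
perpendicular to the displacement direction, using the rotation
`[[0, 1], [-1, 0]]`; it converges as `O(delta^2)` to the lateral directional
derivative.  Degenerate displacements (turn apices) reuse the last
well-defined direction.

The path-sampling interval of the oracles is an analysis parameter.  At the
raw 10 ms step the body centre's displacement direction is dominated by the
undulation wobble rather than travel, so the oracles are evaluated on the
path sampled once per undulation period (2 s) and linearly interpolated back
onto the trace grid.  This defines "travelling direction" on the behavioural
timescale; the interval is config-exposed.

## Connectome-style network

A 22-neuron recurrent network (ASE, AIA, AIB, AIY, AIZ, RIA, RIB, RIM, RIV,
AVB, PVC left/right pairs) with a hand-curated, explicitly replaceable edge
list approximating the salt-chemotaxis circuit.  Inputs: the encoded
nose-tip concentration derivative through ASEL (ON cell) and ASER (ON/OFF,
stronger OFF limb) log-compressive encoders, and the head-bending angle
through RIV.  Neuron dynamics are a discrete leaky integrator with chemical
weights, derivative synapses (transmitting per-step changes) on the same
edges, and symmetric gap junctions with difference coupling; the read-out is
a sigmoid potential.

By default chemical and derivative synapses transmit the sigmoid potential
`U_j`.  The alternative of transmitting the membrane current `u_j` directly
is available as `transmit="current"`, but it makes the recurrence purely
linear, and a linear system cannot demodulate `sign(q0) * dc/dt`; producing
the perpendicular representation then becomes provably impossible, which is
why the nonlinear transmission is the default.

Training minimises the masked halved squared error between output-neuron
potentials and teachers normalised to [0, 1], by plain gradient descent with
exact reverse-mode gradients through the recurrence (including the gap
coupling, the two-step derivative-synapse term, and the tau-dependence of
the leak factors).  The shared gap conductance is updated with the sum of
both directional partials, preserving symmetry exactly; tau is clamped at
zero.  Gradients are verified against central finite differences to 1e-5
relative tolerance on small instances, for both transmission modes.
Teachers are the normalised true gradients; datasets take the first 600 s of
a recorded trace, downsampled to the 0.1 s network sampling time, with
0–300 s for training and 300–600 s held out.  The per-step recursions are
numba-compiled when numba is importable, with an exactly equivalent numpy
fallback; several networks (one per dataset) are trained simultaneously as
a stacked batch, which is mathematically identical to training them one at
a time.

Default training protocol: chemical/derivative learning rate 0.05, gap and
tau rates 0.002 (faster gap growth destabilises the recurrence), 9000
epochs, chemical weights initialised at N(0, 1) so the sensory signal
survives the multi-hop sigmoid attenuation, gap conductances at 0.05, tau
at 1.  Because plain gradient descent sits close to the recurrence's
stability boundary, training runs in 1000-epoch chunks; a chunk in which a
network's rollout goes non-finite is rerun from the checkpoint with that
network's rates halved (the update rule itself is unchanged).  A known
limitation of this plain-gradient-descent protocol deserves
emphasis: within the shipped epoch budget the optimiser preferentially fits
the training window through trace-specific integrated features rather than
the input-output law, so training-window correlations rise steadily while
held-out-window correlations stay low and trace-dependent (a control
experiment with a teacher generated by a network of the identical
architecture shows the same behaviour, so this is an optimisation property,
not a teacher or expressivity problem).  Runs where the optimiser does find
a law-like solution generalise well; most do not within this budget.

## What the shipped experiments show — and what they do not

The default experiment (10 seeded 1200 s runs) reproduces the study
conditions: correlations of `y_p`/`y_w` with the oracles around 0.85–0.87,
RMSEs at the 1e-6 mM/s / 1e-4 mM/cm scale, chemotaxis index around 0.6,
and near-zero dependence of the representation errors on the head-bend
input.  The dependence of the parallel error on `dc/dt` itself remains
around -0.3 here: the filter passes an attenuated, phase-lagged copy of the
head-swing oscillation, and that residual is correlated with the input by
construction.  Reproducing a smaller value would require a body with a much
weaker sensed oscillation, which in this model would simultaneously destroy
the perpendicular representation (the oscillation *is* its carrier).  This
trade-off is intrinsic to single-point sensing and is discussed honestly
rather than tuned away.

The synthetic environment omits several features of real plates: no
evaporation or boundary effects, no NaCl depletion, no 3-D diffusion, no
sensory noise, and no random nose wriggling.  Passing statistics here
demonstrate the internal consistency of the model stack under its own
assumptions, not quantitative agreement with any particular animal
experiment.

## Numerical choices

Time step 0.01 s throughout the simulator (forward Euler everywhere;
all rate constants are far below 1/dt).  The overdamped solve is a single
3x3 linear system per step, first-order accurate in the per-step rotation.
Pirouette initiation, random-walk targets and the initial heading all draw
from one seeded generator per run; a full run is bit-reproducible from its
seed, and trace CSVs are written at full float precision so statistics
survive a round trip exactly.  Undefined correlations (zero-variance
series) are reported as NaN in analysis summaries but raise in the
low-level evaluation API.
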