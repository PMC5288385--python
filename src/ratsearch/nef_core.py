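"""Minimal Neural Engineering Framework (NEF) core.

Implements the standard NEF pipeline for representing vectors in
populations of leaky integrate-and-fire (LIF) neurons:

* encoding -- each neuron ``i`` has a preferred-direction vector ``e_i``,
  a gain ``alpha_i`` and a bias current, so its input current for a
  represented value ``x`` is ``alpha_i * e_i . x + bias_i``;
* decoding -- linear decoders ``d_i`` obtained by regularised
  least squares over rate-model activities reconstruct ``x`` (or an
  arbitrary function ``f(x)``) from spike trains filtered by an
  exponential post-synaptic kernel ``h(t) = exp(-t/tau)/tau``;
* connecting -- two populations are wired with the factored weights
  ``W_ji = alpha_j * e_j^T (T d_i)``; the runtime always uses the
  factored form (decode, transform, re-encode), which is algebraically
  identical to the full weight matrix.

A small :class:`Network` / :class:`Simulator` pair runs such circuits in
discrete time.  Spike timing uses sub-step interpolation so that the
spiking rate of a neuron under constant current matches the closed-form
LIF rate curve closely even at coarse timesteps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "LIFParams",
    "SynapticFilter",
    "Ensemble",
    "Decoders",
    "Connection",
    "Node",
    "Probe",
    "Network",
    "Simulator",
    "lif_rate",
    "rate_to_current",
    "configure_ensemble",
    "solve_decoders",
    "step_lif",
    "filter_decode",
    "connect",
    "alpha_rate_estimate",
]


class NEFError(Exception):
    """Base error for NEF construction and simulation problems."""


class SimulationError(NEFError):
    """Raised when a simulation produces non-finite state."""


# ---------------------------------------------------------------------------
# Neuron model
# ---------------------------------------------------------------------------


@dataclass
class LIFParams:
    """Leaky integrate-and-fire neuron parameters (normalised units).

    The membrane voltage evolves as ``dV/dt = (J - V)/tau_rc``, spikes at
    the normalised threshold ``V = 1`` and is then clamped at rest for the
    refractory period ``tau_ref``.

    Parameters
    ----------
    tau_rc
        Membrane time constant in seconds.
    tau_ref
        Absolute refractory period in seconds.
    dt
        Default simulation timestep in seconds; must resolve the membrane
        dynamics (``dt < tau_rc``).
    """

    tau_rc: float = 0.02
    tau_ref: float = 0.002
    dt: float = 0.001

    def __post_init__(self) -> None:
        if not self.tau_rc > 0:
            raise ValueError(f"tau_rc must be positive, got {self.tau_rc}")
        if self.tau_ref < 0:
            raise ValueError(f"tau_ref must be non-negative, got {self.tau_ref}")
        if not 0 < self.dt < self.tau_rc:
            raise ValueError(
                f"dt must satisfy 0 < dt < tau_rc, got dt={self.dt}, tau_rc={self.tau_rc}"
            )


def lif_rate(J, params: LIFParams):
    """Steady-state LIF firing rate (Hz) for normalised input current ``J``.

    Returns 0 for currents at or below the normalised threshold of 1 and
    ``1 / (tau_ref - tau_rc * log(1 - 1/J))`` above it.  The rate is
    monotone in ``J`` and saturates at ``1 / tau_ref``.
    """
    J = np.asarray(J, dtype=float)
    if not np.all(np.isfinite(J)):
        raise ValueError("input current contains non-finite values")
    out = np.zeros_like(J)
    above = J > 1.0
    with np.errstate(divide="ignore"):
        out[above] = 1.0 / (
            params.tau_ref - params.tau_rc * np.log1p(-1.0 / J[above])
        )
    return out if out.ndim else float(out)


def rate_to_current(rate, params: LIFParams):
    """Inverse of :func:`lif_rate`: current producing a given rate (> 0 Hz)."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate <= 0) or np.any(rate >= 1.0 / params.tau_ref):
        raise ValueError("rates must lie strictly in (0, 1/tau_ref)")
    J = 1.0 / (1.0 - np.exp((params.tau_ref - 1.0 / rate) / params.tau_rc))
    return J if J.ndim else float(J)


# ---------------------------------------------------------------------------
# Synapse
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynapticFilter:
    """First-order exponential synapse ``h(t) = exp(-t/tau) / tau``."""

    tau: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"synaptic tau must be positive, got {self.tau}")

    def decay(self, dt: float) -> float:
        return float(np.exp(-dt / self.tau))

    def kernel(self, dt: float, t_max: Optional[float] = None) -> np.ndarray:
        """Discrete impulse response, bin-integrated and normalised to sum 1.

        Each tap integrates the continuous kernel over one timestep; the
        result is renormalised so that filtering conserves total decoded
        area regardless of the truncation horizon (default ``10 * tau``).
        """
        if t_max is None:
            t_max = 10.0 * self.tau
        n = max(1, int(round(t_max / dt)))
        edges = np.arange(n + 1) * dt
        taps = np.exp(-edges[:-1] / self.tau) - np.exp(-edges[1:] / self.tau)
        return taps / taps.sum()


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


@dataclass
class Ensemble:
    """A population of LIF neurons representing a D-dimensional vector."""

    n_neurons: int
    dimensions: int
    encoders: np.ndarray  # (n, D), unit rows
    gains: np.ndarray  # (n,), > 0
    biases: np.ndarray  # (n,)
    neuron_params: LIFParams = field(default_factory=LIFParams)
    label: str = ""
    # optional elementwise nonlinearity applied to the summed input value
    # before encoding (used e.g. for input-current cut-off thresholds)
    input_transform: Optional[Callable[[np.ndarray], np.ndarray]] = None
    voltage: np.ndarray = field(init=False)
    refractory_time: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.encoders = np.asarray(self.encoders, dtype=float)
        if self.encoders.shape != (self.n_neurons, self.dimensions):
            raise ValueError("encoders must have shape (n_neurons, dimensions)")
        norms = np.linalg.norm(self.encoders, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("encoder rows must have unit norm")
        if np.any(self.gains <= 0):
            raise ValueError("gains must be strictly positive")
        self.reset_state()

    def reset_state(self) -> None:
        self.voltage = np.zeros(self.n_neurons)
        self.refractory_time = np.zeros(self.n_neurons)

    def currents(self, x: np.ndarray) -> np.ndarray:
        """Input currents ``alpha_i e_i . x + bias_i`` for represented x."""
        x = np.asarray(x, dtype=float)
        return self.gains * (self.encoders @ x.T).T + self.biases

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Rate-model activities at one or more represented values."""
        return lif_rate(self.currents(x), self.neuron_params)


def _unit_vectors(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, d))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _sample_intercepts(
    n: int, d: int, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform intercepts in 1-D; cosine-similarity-adjusted for D > 1.

    In high dimensions the dot product of a random encoder with a unit
    vector concentrates near zero, so intercepts are drawn from the
    distribution of cosines between random directions (via a stretched
    Beta) and clipped to the requested range.  This keeps roughly half of
    the neurons active for any represented unit vector.
    """
    if d <= 1:
        return rng.uniform(lo, hi, size=n)
    a = (d - 1) / 2.0
    x = 2.0 * rng.beta(a, a, size=n) - 1.0
    return np.clip(x, lo, min(hi, 1.0 - 1e-6))


def configure_ensemble(
    n_neurons: int,
    dimensions: int,
    max_rate_range: tuple = (200.0, 400.0),
    intercept_range: tuple = (-1.0, 1.0),
    encoders: Union[str, np.ndarray, None] = None,
    neuron_params: Optional[LIFParams] = None,
    label: str = "",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Ensemble:
    """Build an ensemble with randomly sampled tuning curves.

    Gains and biases are solved so that each neuron fires at its sampled
    maximum rate when ``e_i . x = 1`` and goes silent exactly at its
    sampled intercept.  Encoders are drawn uniformly from the unit
    hypersphere unless given explicitly; ``encoders="positive"`` assigns
    ``+1`` to every neuron of a 1-D ensemble, giving a population of
    monotonically increasing tuning curves.
    """
    if n_neurons <= 0:
        raise ValueError(f"n_neurons must be positive, got {n_neurons}")
    if dimensions <= 0:
        raise ValueError(f"dimensions must be positive, got {dimensions}")
    params = neuron_params or LIFParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    lo_r, hi_r = max_rate_range
    if not 0 < lo_r <= hi_r < 1.0 / params.tau_ref:
        raise ValueError("max rates must lie within (0, 1/tau_ref)")
    lo_i, hi_i = intercept_range
    if not -1.0 <= lo_i <= hi_i <= 1.0:
        raise ValueError("intercepts must lie within [-1, 1]")

    if encoders is None:
        enc = _unit_vectors(n_neurons, dimensions, rng)
    elif isinstance(encoders, str):
        if encoders != "positive":
            raise ValueError(f"unknown encoder mode {encoders!r}")
        if dimensions != 1:
            raise ValueError("'positive' encoders require a 1-D ensemble")
        enc = np.ones((n_neurons, 1))
    else:
        enc = np.asarray(encoders, dtype=float)

    max_rates = rng.uniform(lo_r, hi_r, size=n_neurons)
    intercepts = _sample_intercepts(n_neurons, dimensions, lo_i, hi_i, rng)

    # alpha * 1 + bias = J_max (current at e.x = 1, firing at max_rate)
    # alpha * intercept + bias = 1 (threshold current at the intercept)
    j_max = rate_to_current(max_rates, params)
    gains = (j_max - 1.0) / (1.0 - intercepts)
    biases = 1.0 - gains * intercepts
    return Ensemble(
        n_neurons=n_neurons,
        dimensions=dimensions,
        encoders=enc,
        gains=gains,
        biases=biases,
        neuron_params=params,
        label=label,
    )


# ---------------------------------------------------------------------------
# Decoders
# ---------------------------------------------------------------------------


@dataclass
class Decoders:
    """Linear decoding weights for an ensemble.

    ``matrix`` has shape ``(n_neurons, D_out)``; multiplying filtered
    spike activities by it reconstructs ``f(x)``.
    """

    matrix: np.ndarray
    target_function: str = "identity"
    eval_points: Optional[np.ndarray] = None
    regularization: float = 0.1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("decoder matrix contains non-finite entries")


def _default_eval_points(
    ensemble: Ensemble, n_points: int, rng: np.random.Generator
) -> np.ndarray:
    d = ensemble.dimensions
    if d == 1:
        return np.linspace(-1.0, 1.0, n_points)[:, None]
    # uniform in the unit ball
    directions = _unit_vectors(n_points, d, rng)
    radii = rng.uniform(0, 1, size=n_points) ** (1.0 / d)
    return directions * radii[:, None]


def solve_decoders(
    ensemble: Ensemble,
    function: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    eval_points: Optional[np.ndarray] = None,
    regularization: float = 0.1,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Decoders:
    """Least-squares decoders for ``f(x)`` from rate-model activities.

    Minimises the regularised squared reconstruction error over the
    evaluation points.  The ridge term adds ``(regularization * max
    activity)**2`` times the number of points to the Gram diagonal, the
    standard NEF conditioning choice.  With ``regularization=0`` an
    ill-conditioned activity matrix raises a numerical error rather than
    returning a silently bad solution.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if eval_points is None:
        eval_points = _default_eval_points(
            ensemble, max(500, 2 * ensemble.n_neurons), rng
        )
    eval_points = np.atleast_2d(np.asarray(eval_points, dtype=float))
    if eval_points.shape[1] != ensemble.dimensions:
        raise ValueError("eval_points dimensionality does not match ensemble")

    if function is None:
        targets = eval_points
        fname = "identity"
    else:
        targets = np.atleast_2d(np.asarray([function(x) for x in eval_points], dtype=float))
        if targets.ndim == 1 or targets.shape[0] != eval_points.shape[0]:
            targets = targets.reshape(eval_points.shape[0], -1)
        fname = getattr(function, "__name__", "custom")

    activities = ensemble.rates(eval_points)  # (k, n)
    k = activities.shape[0]
    gram = activities.T @ activities
    if regularization > 0:
        sigma = regularization * activities.max() if activities.max() > 0 else regularization
        gram = gram + (sigma**2 * k) * np.eye(ensemble.n_neurons)
        try:
            d = np.linalg.solve(gram, activities.T @ targets)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise NEFError(f"decoder solve failed: {exc}") from exc
    else:
        cond = np.linalg.cond(gram)
        if not np.isfinite(cond) or cond > 1e12:
            raise NEFError(
                "activity matrix is ill-conditioned "
                f"(cond={cond:.3g}); use regularization > 0"
            )
        d = np.linalg.solve(gram, activities.T @ targets)
    return Decoders(
        matrix=d,
        target_function=fname,
        eval_points=eval_points,
        regularization=regularization,
    )


# ---------------------------------------------------------------------------
# Spiking dynamics
# ---------------------------------------------------------------------------


def step_lif(ensemble: Ensemble, J: np.ndarray, dt: float) -> np.ndarray:
    """Advance the LIF membrane state one step; return spike indicators.

    Integrates the leak dynamics over the part of the step outside the
    refractory window, detects threshold crossings, and back-interpolates
    the exact crossing time so that the refractory period starts at the
    true spike time.  Voltage is clamped to [0, 1].
    """
    J = np.asarray(J, dtype=float)
    p = ensemble.neuron_params
    V = ensemble.voltage
    refr = ensemble.refractory_time

    refr -= dt
    delta_t = np.clip(dt - refr, 0.0, dt)
    V -= (J - V) * np.expm1(-delta_t / p.tau_rc)

    spiked = V > 1.0
    if np.any(spiked):
        # back-interpolate the threshold crossing along the exponential
        # approach toward J; t_spike is the remainder of the step after it
        t_spike = dt + p.tau_rc * np.log1p(
            -(V[spiked] - 1.0) / np.maximum(J[spiked] - 1.0, 1e-12)
        )
        t_spike = np.clip(t_spike, 0.0, dt)
        refr[spiked] = p.tau_ref + t_spike
        V[spiked] = 0.0
    np.clip(V, 0.0, 1.0, out=V)
    return spiked.astype(float)


def filter_decode(
    spikes: np.ndarray,
    decoders: Decoders,
    synapse: SynapticFilter,
    dt: float,
) -> np.ndarray:
    """Exponentially filtered linear decode of a spike-train matrix.

    ``spikes`` is a (T, n) array of 0/1 indicators sampled at ``dt``.
    Each spike is treated as a unit-area impulse, so the decoded trace of
    a constant represented value settles to that value.
    """
    spikes = np.atleast_2d(np.asarray(spikes, dtype=float))
    if spikes.shape[1] != decoders.matrix.shape[0]:
        raise ValueError(
            f"spike trains for {spikes.shape[1]} neurons do not match "
            f"decoders for {decoders.matrix.shape[0]} neurons"
        )
    weighted = (spikes / dt) @ decoders.matrix  # (T, D)
    alpha = 1.0 - synapse.decay(dt)
    out = np.empty_like(weighted)
    state = np.zeros(weighted.shape[1])
    for t in range(weighted.shape[0]):
        state = state + alpha * (weighted[t] - state)
        out[t] = state
    return out


def alpha_rate_estimate(
    spikes: np.ndarray, alpha: float, dt: float = 0.001
) -> np.ndarray:
    """Smooth firing-rate estimate from a spike train via an alpha kernel.

    Convolves the 0/1 spike indicator train with the normalised kernel
    ``h(t) = alpha^2 t exp(-alpha t)`` (unit area), so an isolated spike
    contributes integral 1 and a regular train plateaus at its rate in Hz.
    The kernel peaks ``1/alpha`` seconds after each spike.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    spikes = np.asarray(spikes, dtype=float)
    single = spikes.ndim == 1
    spikes = np.atleast_2d(spikes.T).T  # (T, n)
    n_taps = max(2, int(round(10.0 / alpha / dt)))
    t = (np.arange(n_taps) + 0.5) * dt
    kernel = alpha**2 * t * np.exp(-alpha * t)
    kernel /= kernel.sum() * dt  # unit area in continuous time
    out = np.empty_like(spikes)
    for j in range(spikes.shape[1]):
        out[:, j] = np.convolve(spikes[:, j], kernel)[: spikes.shape[0]]
    return out[:, 0] if single else out


# ---------------------------------------------------------------------------
# Network graph
# ---------------------------------------------------------------------------


class Node:
    """External signal source: a constant vector or a callable of time."""

    def __init__(self, output, size_out: Optional[int] = None, label: str = ""):
        self.label = label
        if callable(output):
            self.fn = output
            probe = np.atleast_1d(np.asarray(output(0.0), dtype=float))
            self.size_out = size_out or probe.size
        else:
            vec = np.atleast_1d(np.asarray(output, dtype=float))
            self.fn = None
            self.value = vec
            self.size_out = vec.size

    def output(self, t: float) -> np.ndarray:
        if self.fn is not None:
            return np.atleast_1d(np.asarray(self.fn(t), dtype=float))
        return self.value


class Probe:
    """Records a decoded value or spike raster at every timestep."""

    def __init__(self, target, attr: str = "decoded", synapse: Optional[SynapticFilter] = None, label: str = ""):
        if attr not in ("decoded", "spikes"):
            raise ValueError(f"unknown probe attribute {attr!r}")
        self.target = target
        self.attr = attr
        self.synapse = synapse
        self.label = label
        self.size_in = None  # resolved by the simulator for decoded probes


class Connection:
    """A factored NEF connection ``pre -> post``.

    ``kind='decoded'`` computes ``T @ f_dec(x_pre)`` through the synapse
    and delivers it as represented-value input to the post ensemble (or
    probe).  ``kind='inhibitory'`` delivers a current
    ``inh_gain * value * (gain_j + bias_j)`` directly into every post
    neuron j; scaling by each neuron's maximum drive lets a unit-valued
    gating signal silence the population outright -- a decoded negative
    input cannot guarantee that.
    """

    def __init__(
        self,
        pre,
        post,
        decoders: Optional[Decoders] = None,
        transform: Optional[np.ndarray] = None,
        synapse: Optional[SynapticFilter] = SynapticFilter(0.005),
        kind: str = "decoded",
        inh_gain: float = -10.0,
        post_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
        label: str = "",
    ):
        if kind not in ("decoded", "inhibitory"):
            raise ValueError(f"unknown connection kind {kind!r}")
        self.pre = pre
        self.post = post
        self.decoders = decoders
        self.transform = None if transform is None else np.atleast_2d(np.asarray(transform, dtype=float))
        self.synapse = synapse
        self.kind = kind
        self.inh_gain = inh_gain
        self.post_fn = post_fn
        self.label = label

        pre_size = decoders.matrix.shape[1] if decoders is not None else pre.size_out
        self.size_out = self.transform.shape[0] if self.transform is not None else pre_size
        if self.transform is not None and self.transform.shape[1] != pre_size:
            raise ValueError(
                f"transform shape {self.transform.shape} incompatible with "
                f"pre output size {pre_size}"
            )
        if kind == "inhibitory" and self.size_out != 1:
            raise ValueError("inhibitory connections must carry a scalar value")
        if kind == "decoded" and isinstance(post, Ensemble):
            if self.size_out != post.dimensions:
                raise ValueError(
                    f"connection delivers {self.size_out}-D value to "
                    f"{post.dimensions}-D ensemble {post.label!r}"
                )
        self.state = np.zeros(self.size_out)

    def full_weight_matrix(self) -> np.ndarray:
        """Materialise ``W_ji = alpha_j e_j^T (T d_i)`` for inspection.

        Only valid for decoded ensemble-to-ensemble connections; the
        runtime never uses this matrix, but the factored currents it
        implies are identical to what the simulator computes.
        """
        if self.decoders is None or not isinstance(self.post, Ensemble):
            raise NEFError("full weights require a decoded ensemble-to-ensemble connection")
        d = self.decoders.matrix  # (n_pre, D)
        if self.transform is not None:
            d = d @ self.transform.T  # (n_pre, D_post)
        post = self.post
        return post.gains[:, None] * (post.encoders @ d.T)  # (n_post, n_pre)


def connect(
    pre,
    post,
    function: Optional[Callable] = None,
    transform: Optional[np.ndarray] = None,
    synapse: Optional[SynapticFilter] = SynapticFilter(0.005),
    kind: str = "decoded",
    inh_gain: float = -10.0,
    eval_points: Optional[np.ndarray] = None,
    regularization: float = 0.1,
    label: str = "",
    rng: Optional[np.random.Generator] = None,
) -> Connection:
    """Create a connection, solving decoders for ensemble sources."""
    decoders = None
    if isinstance(pre, Ensemble):
        decoders = solve_decoders(
            pre, function=function, eval_points=eval_points,
            regularization=regularization, rng=rng,
        )
    elif function is not None:
        raise ValueError("functions can only be decoded from ensembles")
    return Connection(
        pre, post, decoders=decoders, transform=transform,
        synapse=synapse, kind=kind, inh_gain=inh_gain, label=label,
    )


class Network:
    """Container for ensembles, nodes, connections and probes."""

    def __init__(self, label: str = ""):
        self.label = label
        self.ensembles: list[Ensemble] = []
        self.nodes: list[Node] = []
        self.connections: list[Connection] = []
        self.probes: list[Probe] = []

    def add_ensemble(self, ensemble: Ensemble) -> Ensemble:
        self.ensembles.append(ensemble)
        return ensemble

    def add_node(self, node: Node) -> Node:
        self.nodes.append(node)
        return node

    def add_connection(self, conn: Connection) -> Connection:
        self.connections.append(conn)
        return conn

    def connect(self, pre, post, **kwargs) -> Connection:
        conn = connect(pre, post, **kwargs)
        return self.add_connection(conn)

    def probe(self, target, attr: str = "decoded", synapse: Optional[SynapticFilter] = SynapticFilter(0.01), label: str = "") -> Probe:
        probe = Probe(target, attr=attr, synapse=synapse, label=label)
        self.probes.append(probe)
        return probe


class Simulator:
    """Discrete-time simulator for a :class:`Network`.

    One step: evaluate node outputs, update every connection's filtered
    decoded value from the previous step's spikes, sum represented-value
    inputs and broadcast inhibitory currents per ensemble, then advance
    the LIF state.  Probe traces are recorded every step.
    """

    def __init__(self, network: Network, dt: float = 0.001):
        self.network = network
        self.dt = dt
        self.time = 0.0
        self._spikes: dict[int, np.ndarray] = {}
        self._probe_conns: dict[int, Connection] = {}
        self.data: dict[int, list] = {p_id: [] for p_id in map(id, network.probes)}
        self.trange_: list[float] = []

        for ens in network.ensembles:
            ens.reset_state()
            self._spikes[id(ens)] = np.zeros(ens.n_neurons)
        for conn in network.connections:
            conn.state = np.zeros(conn.size_out)
        for probe in network.probes:
            if probe.attr == "decoded":
                if isinstance(probe.target, Connection):
                    self._probe_conns[id(probe)] = probe.target
                elif isinstance(probe.target, Ensemble):
                    conn = connect(probe.target, probe, synapse=probe.synapse)
                    self._probe_conns[id(probe)] = conn
        for conn in self._probe_conns.values():
            conn.state = np.zeros(conn.size_out)

    def step(self) -> None:
        net = self.network
        dt = self.dt
        t = self.time + dt

        # 1. update connection states from node outputs / previous spikes
        seen: set = set()
        all_conns = [
            c
            for c in list(net.connections) + list(self._probe_conns.values())
            if not (id(c) in seen or seen.add(id(c)))
        ]
        for conn in all_conns:
            if isinstance(conn.pre, Node):
                value = conn.pre.output(t)
            else:
                value = (self._spikes[id(conn.pre)] / dt) @ conn.decoders.matrix
            if conn.transform is not None:
                value = conn.transform @ value
            if conn.synapse is None:
                conn.state = np.atleast_1d(np.asarray(value, dtype=float))
            else:
                alpha = 1.0 - conn.synapse.decay(dt)
                conn.state = conn.state + alpha * (value - conn.state)

        # 2. accumulate inputs and step neurons
        new_spikes = {}
        for ens in net.ensembles:
            x = np.zeros(ens.dimensions)
            direct = np.zeros(ens.n_neurons)
            for conn in net.connections:
                if conn.post is not ens:
                    continue
                if conn.kind == "decoded":
                    value = conn.state
                    if conn.post_fn is not None:
                        value = conn.post_fn(value)
                    x = x + value
                else:
                    # silencing current, scaled per neuron by its maximum
                    # drive (gain + bias) so even high-gain neurons shut off
                    direct += (
                        conn.inh_gain
                        * max(float(conn.state[0]), 0.0)
                        * (ens.gains + ens.biases)
                    )
            if ens.input_transform is not None:
                x = ens.input_transform(x)
            J = ens.currents(x) + direct
            if not np.all(np.isfinite(J)):
                raise SimulationError(
                    f"non-finite input current in ensemble {ens.label!r} at t={t:.3f}s"
                )
            new_spikes[id(ens)] = step_lif(ens, J, dt)
        self._spikes.update(new_spikes)
        self.time = t

        # 3. record probes
        self.trange_.append(t)
        for probe in net.probes:
            if probe.attr == "spikes":
                self.data[id(probe)].append(self._spikes[id(probe.target)].copy())
            else:
                conn = self._probe_conns[id(probe)]
                self.data[id(probe)].append(np.atleast_1d(conn.state).copy())

    def run(self, duration: float) -> None:
        n_steps = int(round(duration / self.dt))
        for _ in range(n_steps):
            self.step()

    def trange(self) -> np.ndarray:
        return np.asarray(self.trange_)

    def probe_data(self, probe: Probe) -> np.ndarray:
        return np.asarray(self.data[id(probe)])
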