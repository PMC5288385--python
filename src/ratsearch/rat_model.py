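"""The spiking cognitive architecture for three-cue association search.

The model is two interacting spiking networks built from the NEF parts
in :mod:`ratsearch.nef_core`:

* a **cue selection network** -- each of the three cue vectors passes
  through a group of gating neurons into a *primary cue* ensemble.  A
  three-way winner-take-all over scalar selection ensembles, seeded by
  white noise, decides which gate is open: the winner silences its
  *inversion* group (a population biased to represent 1), which in turn
  stops inhibiting the corresponding gate.  A periodic reset signal
  inhibits the selection ensembles, forcing a fresh, noise-driven
  reselection of the primary cue;

* a **response network** -- a clean-up memory with one small neuron
  group per vocabulary word.  Each group represents the similarity of
  the network's input to its word (thresholded so weak matches stay
  silent), competes with every other group through lateral inhibition
  and supports itself through self-excitation, so a single word wins.
  Its input is the superposition of the associates of all three cues
  (weak), of the primary cue (strong), and of the current response
  (the feedback that produces local, chain-like search), each obtained
  through the linear association transform ``A~``;

* a **response inhibition** ensemble -- a leaky integrator accumulating
  the recent winners.  It inhibits the clean-up memory, so the active
  word is subject to growing inhibition until a new word displaces it,
  and the additive mixture of the last few words cannot immediately
  reappear.

The three selection ensembles share identical tuning curves so that
reselection is decided by the noise process rather than by frozen
random differences between the populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nef_core as nef
from .association_data import AssociationMatrix, binarize, prune
from .semantic_vectors import Vocabulary, association_transform
from .synthetic_data import RATProblem

__all__ = [
    "ModelConfig",
    "RATNetwork",
    "SimulationResult",
    "build_network",
    "run_trial",
    "extract_responses",
    "make_generation_matrix",
    "RATProblem",
]


@dataclass
class ModelConfig:
    """Free parameters of the search model.

    The first block carries the model's behavioural parameters under
    their conventional names; the second holds engineering choices
    (neuron counts, timing, read-out) that the behavioural level does
    not pin down.
    """

    d: int = 2048  # word-vector dimensionality
    th: Tuple[float, float] = (0.6, 0.8)  # pruned fraction range per simulation
    assoc_th: float = 0.05  # WTA cut-off input threshold
    cue_strength: float = 0.1  # strength of each cue's associates into the WTA
    primary_cue_strength: float = 0.7  # strength of the primary cue's associates
    wta_feedback_strength: float = 0.5  # strength of the current response's associates
    noise_std: float = 0.01  # white-noise std in the cue selection network
    integrator_feedback: float = 0.95  # recurrent gain of the response inhibition

    # --- engineering fields ---
    neurons_per_group: int = 50  # per 1-D word-similarity group
    neurons_per_dim: int = 20  # per dimension of high-D ensembles
    neurons_scalar: int = 50  # per scalar selection/inversion ensemble
    reset_period: float = 1.0  # s between cue reselections
    reset_pulse: float = 0.15  # s the reset signal stays high
    trial_duration: float = 60.0  # s of simulated search
    detection_threshold: float = 0.3  # similarity read-out threshold
    min_dwell: float = 0.2  # s a word must stay dominant to count
    rep_threshold: float = 0.1  # representation threshold of similarity groups
    lateral_inhibition: float = 2.5  # between similarity groups
    self_excitation: float = 1.5  # within a similarity group
    sel_bias: float = 0.5  # drive of the selection race
    sel_lateral: float = 1.5  # inhibition between selection ensembles
    sel_self: float = 0.3  # self-excitation of selection ensembles
    inhib_gate_gain: float = -2.0  # silencing drive per unit gating value
    integrator_tau: float = 0.15  # s, recurrent synapse of the integrator
    integrator_input_strength: float = 0.12
    response_inhib_strength: float = 5.0
    wta_winner_threshold: float = 0.3  # step level at which a group counts as winning
    integrator_input_cutoff: float = 0.15  # WTA value below which nothing is integrated
    integrator_output_cutoff: float = 0.1  # integrator level below which nothing is inhibited
    synapse_tau: float = 0.005  # s, feedforward synapse
    dt: float = 0.001  # s, simulation timestep
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        lo, hi = self.th
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError(f"th bounds must satisfy 0 <= lo <= hi <= 1, got {self.th}")
        if not self.reset_period > 0:
            raise ValueError("reset_period must be positive")
        for name in (
            "assoc_th", "cue_strength", "primary_cue_strength",
            "wta_feedback_strength", "noise_std", "integrator_feedback",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class SimulationResult:
    """Decoded output of one simulated trial.

    ``responses`` lists (word, onset_s, offset_s) in emission order with
    consecutive duplicates merged; ``primary_cue_trace`` holds the
    decoded similarity of the primary-cue ensemble to each of the three
    cues over time; ``word_trace`` the clean-up memory's similarity to
    every vocabulary word.
    """

    responses: List[Tuple[str, float, float]]
    times: np.ndarray
    primary_cue_trace: np.ndarray  # (T, 3)
    reset_trace: np.ndarray  # (T,)
    word_trace: Optional[np.ndarray] = None  # (T, N)
    problem: Optional[RATProblem] = None

    def __post_init__(self) -> None:
        onsets = [r[1] for r in self.responses]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("response onsets must be strictly increasing")
        words = [r[0] for r in self.responses]
        if any(a == b for a, b in zip(words, words[1:])):
            raise ValueError("consecutive duplicate responses must be merged")

    def words(self) -> List[str]:
        return [r[0] for r in self.responses]

    def primary_cue_at(self, t: float, floor: float = 0.1) -> Optional[int]:
        """Index of the cue dominating the primary-cue ensemble at time t."""
        if len(self.times) == 0:
            return None
        i = int(np.searchsorted(self.times, t))
        i = min(max(i, 0), len(self.times) - 1)
        lo = max(0, i - 25)
        window = self.primary_cue_trace[lo : i + 1].mean(axis=0)
        if window.max() < floor:
            return None
        return int(np.argmax(window))

    def solution_onset(self) -> Optional[float]:
        if self.problem is None:
            return None
        for word, onset, _ in self.responses:
            if word == self.problem.solution:
                return onset
        return None


class _NoiseNode(nef.Node):
    """Gaussian white-noise source using the 1/sqrt(dt) power convention."""

    def __init__(self, std: float, dt: float, label: str = ""):
        self.std = std
        self.dt = dt
        self.rng = np.random.default_rng(0)
        super().__init__(self._draw, size_out=1, label=label)

    def _draw(self, t: float) -> np.ndarray:
        return self.rng.normal(0.0, self.std / np.sqrt(self.dt), size=1)

    def reseed(self, seed) -> None:
        self.rng = np.random.default_rng(seed)


class RATNetwork(nef.Network):
    """The assembled model with named component handles."""

    def __init__(self, vocab: Vocabulary, problem: RATProblem, config: ModelConfig):
        super().__init__(label="rat-model")
        self.vocab = vocab
        self.problem = problem
        self.config = config
        self.components: Dict[str, object] = {}
        self.noise_nodes: List[_NoiseNode] = []
        self.wta_probe: Optional[nef.Probe] = None
        self.primary_probe: Optional[nef.Probe] = None
        self.reset_probe: Optional[nef.Probe] = None


def _build_cleanup_wta(
    n_words: int,
    n_per_group: int,
    rep_threshold: float,
    params: nef.LIFParams,
    rng: np.random.Generator,
    regularization: float = 0.05,
    step_threshold: float = 0.3,
    intercept_range: Optional[Tuple[float, float]] = None,
    identity_threshold: float = 0.0,
) -> Tuple[nef.Ensemble, nef.Decoders, nef.Decoders]:
    """Clean-up memory: one thresholded 1-D neuron group per word.

    Every neuron's preferred direction is the one-hot axis of its word,
    with intercepts sampled at or above the representation threshold so
    groups stay silent for weak inputs.  Two decoder sets are solved per
    group and assembled block-diagonally: an identity decode of the
    represented similarity, and a steep step decode (0 below
    ``step_threshold``, 1 above) used for first-past-the-post lateral
    competition -- a group only starts inhibiting its rivals once it is
    clearly active, and then at full strength.
    """
    n_total = n_words * n_per_group
    encoders = np.zeros((n_total, n_words))
    gains = np.empty(n_total)
    biases = np.empty(n_total)
    dec = np.zeros((n_total, n_words))
    dec_step = np.zeros((n_total, n_words))
    grid = np.linspace(0.0, 1.6, 160)[:, None]
    for g in range(n_words):
        sl = slice(g * n_per_group, (g + 1) * n_per_group)
        group = nef.configure_ensemble(
            n_per_group,
            1,
            max_rate_range=(150.0, 300.0),
            intercept_range=intercept_range or (rep_threshold, 0.95),
            encoders="positive",
            neuron_params=params,
            rng=rng,
        )
        encoders[sl, g] = 1.0
        gains[sl] = group.gains
        biases[sl] = group.biases
        # identity saturating at 1: a winner pushed past the represented
        # range by self-excitation still transmits a clean capped value;
        # an optional dead zone near 0 keeps recurrent loops from
        # latching onto decode noise at rest
        d = nef.solve_decoders(
            group,
            function=lambda x: (
                min(float(x[0]), 1.0) if x[0] >= identity_threshold else 0.0
            ),
            eval_points=grid,
            regularization=regularization,
        )
        dec[sl, g] = d.matrix[:, 0]
        d_step = nef.solve_decoders(
            group,
            function=lambda x: float(x[0] >= step_threshold),
            eval_points=grid,
            regularization=regularization,
        )
        dec_step[sl, g] = d_step.matrix[:, 0]
    ens = nef.Ensemble(
        n_neurons=n_total,
        dimensions=n_words,
        encoders=encoders,
        gains=gains,
        biases=biases,
        neuron_params=params,
        label="response-wta",
    )
    decoders = nef.Decoders(matrix=dec, target_function="min(x, 1) blockwise")
    step_decoders = nef.Decoders(
        matrix=dec_step, target_function=f"step(>= {step_threshold})"
    )
    return ens, decoders, step_decoders


def build_network(
    vocab: Vocabulary,
    generation_matrix: AssociationMatrix,
    problem: RATProblem,
    config: Optional[ModelConfig] = None,
) -> RATNetwork:
    """Assemble the full spiking model for one problem.

    The generation matrix must be aligned with the vocabulary; it is
    collapsed into the association transform ``A~ = V^T A^T V``, which
    appears on three connections: cue input, primary-cue input, and the
    response feedback loop.
    """
    config = config or ModelConfig()
    missing = [w for w in (*problem.cues, problem.solution) if w not in vocab]
    if missing:
        raise ValueError(f"problem words missing from vocabulary: {missing}")

    params = nef.LIFParams(dt=config.dt)
    rng = np.random.default_rng(config.seed)
    net = RATNetwork(vocab, problem, config)
    syn = nef.SynapticFilter(config.synapse_tau)

    V = vocab.vectors  # (N, D)
    n_words, dims = V.shape
    a_tilde = association_transform(generation_matrix, vocab).matrix  # (D, D)
    VA = V @ a_tilde  # (N, D): input vector -> similarity drive of associates

    cue_vecs = np.stack([vocab[c] for c in problem.cues])  # (3, D)

    # ---- cue selection -------------------------------------------------
    # identical tuning across the three selection ensembles: the race is
    # decided by noise, not by frozen tuning asymmetries
    sel_seed = int(rng.integers(2**31))
    sel = [
        nef.configure_ensemble(
            config.neurons_scalar, 1,
            intercept_range=(0.0, 0.95), encoders="positive",
            neuron_params=params, label=f"select-{i}", seed=sel_seed,
        )
        for i in range(3)
    ]
    inv = [
        nef.configure_ensemble(
            config.neurons_scalar, 1,
            intercept_range=(0.0, 0.95), encoders="positive",
            neuron_params=params, label=f"invert-{i}", rng=rng,
        )
        for i in range(3)
    ]
    gates = [
        nef.configure_ensemble(
            config.neurons_per_dim * dims, dims,
            neuron_params=params, label=f"gate-{i}", rng=rng,
        )
        for i in range(3)
    ]
    primary = nef.configure_ensemble(
        config.neurons_per_dim * dims, dims,
        neuron_params=params, label="primary-cue", rng=rng,
    )
    for e in (*sel, *inv, *gates, primary):
        net.add_ensemble(e)

    bias_node = net.add_node(nef.Node(1.0, label="bias"))
    sel_bias_node = net.add_node(nef.Node(config.sel_bias, label="select-bias"))
    for i in range(3):
        noise = _NoiseNode(config.noise_std, config.dt, label=f"noise-{i}")
        net.add_node(noise)
        net.noise_nodes.append(noise)
        net.connect(noise, sel[i], synapse=syn)
        net.connect(sel_bias_node, sel[i], synapse=syn)
        net.connect(bias_node, inv[i], synapse=syn)
        # winner silences its inversion group, opening its gate; gating
        # signals are decoded through steep threshold functions so the
        # gates switch crisply between fully open and fully closed
        net.add_connection(
            nef.connect(
                sel[i], inv[i], kind="inhibitory",
                function=lambda x: float(x[0] > 0.3),
                inh_gain=config.inhib_gate_gain, synapse=syn, rng=rng,
            )
        )
        net.add_connection(
            nef.connect(
                inv[i], gates[i], kind="inhibitory",
                function=lambda x: float(x[0] > 0.5),
                inh_gain=config.inhib_gate_gain, synapse=syn, rng=rng,
            )
        )
        cue_node = net.add_node(nef.Node(cue_vecs[i], label=f"cue-{i}"))
        net.connect(cue_node, gates[i], synapse=syn)
        net.connect(gates[i], primary, synapse=syn, rng=rng)
    # selection race: mutual inhibition plus self-excitation
    for i in range(3):
        for j in range(3):
            if i == j:
                net.connect(
                    sel[i], sel[i], transform=[[config.sel_self]],
                    synapse=syn, rng=rng,
                )
            else:
                net.connect(
                    sel[i], sel[j], transform=[[-config.sel_lateral]],
                    synapse=syn, rng=rng,
                )

    period, pulse = config.reset_period, config.reset_pulse
    reset_node = net.add_node(
        nef.Node(lambda t: 1.0 if (t % period) < pulse else 0.0, size_out=1, label="reset")
    )
    for i in range(3):
        net.add_connection(
            nef.Connection(
                reset_node, sel[i], kind="inhibitory",
                inh_gain=config.inhib_gate_gain, synapse=syn,
            )
        )

    # ---- response network ---------------------------------------------
    wta, wta_dec, wta_step_dec = _build_cleanup_wta(
        n_words, config.neurons_per_group, config.rep_threshold, params, rng,
        step_threshold=config.wta_winner_threshold,
    )
    net.add_ensemble(wta)
    cutoff = config.assoc_th

    def input_cutoff(x: np.ndarray) -> np.ndarray:
        return np.where(x >= cutoff, x, 0.0)

    # associates of all three cues, weakly, straight from the inputs
    cues_node = net.add_node(nef.Node(cue_vecs.sum(axis=0), label="cues-combined"))
    net.add_connection(
        nef.Connection(
            cues_node, wta,
            transform=config.cue_strength * VA, synapse=syn,
            post_fn=input_cutoff, label="cues->wta",
        )
    )
    # associates of the primary cue, strongly
    primary_dec = nef.solve_decoders(primary, rng=rng)
    net.add_connection(
        nef.Connection(
            primary, wta, decoders=primary_dec,
            transform=config.primary_cue_strength * VA, synapse=syn,
            post_fn=input_cutoff, label="primary->wta",
        )
    )
    # self-excitation keeps the current winner latched ...
    net.add_connection(
        nef.Connection(
            wta, wta, decoders=wta_dec,
            transform=config.self_excitation * np.eye(n_words), synapse=syn,
            label="wta-self",
        )
    )
    # ... while lateral inhibition is all-or-none: only a clearly active
    # group (step decode) suppresses its rivals, so simultaneous weak
    # risers do not crash each other before a winner emerges
    net.add_connection(
        nef.Connection(
            wta, wta, decoders=wta_step_dec,
            transform=-config.lateral_inhibition * (1.0 - np.eye(n_words)),
            synapse=syn, label="wta-lateral",
        )
    )
    # associates of the current response fed back as additional input
    feedback = config.wta_feedback_strength * (VA @ V.T)  # (N, N)
    net.add_connection(
        nef.Connection(
            wta, wta, decoders=wta_dec, transform=feedback, synapse=syn,
            post_fn=input_cutoff, label="wta-assoc-feedback",
        )
    )

    # ---- response inhibition -------------------------------------------
    # a leaky integrator over the recent-response mixture; represented in
    # the word-similarity basis of the clean-up memory (preferred
    # directions on the word axes), so each word's suppression decays
    # independently instead of rotating away inside a dense mixture
    # threshold-style intercepts make the integrator leak faster at small
    # charges: that damps decode-noise accumulation (silent at rest) while
    # the strong input drives genuine responses into the well-retained
    # upper range
    integrator, int_dec, _ = _build_cleanup_wta(
        n_words, max(40, config.neurons_per_group), 0.0, params, rng
    )
    integrator.label = "response-inhibition"
    net.add_ensemble(integrator)
    tau_int = nef.SynapticFilter(config.integrator_tau)
    eye = np.eye(n_words)
    in_cut = config.integrator_input_strength * config.integrator_input_cutoff
    out_cut = config.response_inhib_strength * config.integrator_output_cutoff

    def integrate_cutoff(x: np.ndarray) -> np.ndarray:
        # only genuine winners charge the integrator, not decode flicker
        return np.where(x >= in_cut, x, 0.0)

    def inhibit_cutoff(x: np.ndarray) -> np.ndarray:
        # (values arrive negated) only charged words inhibit the memory
        return np.where(x <= -out_cut, x, 0.0)

    net.add_connection(
        nef.Connection(
            wta, integrator, decoders=wta_dec,
            transform=config.integrator_input_strength * eye, synapse=tau_int,
            post_fn=integrate_cutoff, label="wta->integrator",
        )
    )
    net.add_connection(
        nef.Connection(
            integrator, integrator, decoders=int_dec,
            transform=config.integrator_feedback * eye, synapse=tau_int,
            label="integrator-recurrent",
        )
    )
    net.add_connection(
        nef.Connection(
            integrator, wta, decoders=int_dec,
            transform=-config.response_inhib_strength * eye, synapse=syn,
            post_fn=inhibit_cutoff, label="integrator->wta",
        )
    )

    net.components = {
        "cue_gates": gates,
        "cue_selection": sel,
        "inverters": inv,
        "primary_cue": primary,
        "response_wta": wta,
        "response_inhibition": integrator,
        "reset": reset_node,
    }
    net.wta_probe = net.probe(
        nef.Connection(wta, None, decoders=wta_dec, synapse=nef.SynapticFilter(0.01)),
        label="word-similarity",
    )
    net.primary_probe = net.probe(
        nef.Connection(
            primary, None, decoders=primary_dec,
            transform=cue_vecs, synapse=nef.SynapticFilter(0.01),
        ),
        label="primary-cue",
    )
    net.reset_probe = net.probe(
        nef.Connection(reset_node, None, synapse=nef.SynapticFilter(0.005)),
        label="reset",
    )
    return net


def extract_responses(
    trace: np.ndarray,
    words: Sequence[str],
    dt: float,
    detection_threshold: float = 0.3,
    min_dwell: float = 0.05,
) -> List[Tuple[str, float, float]]:
    """Read a word sequence off a decoded similarity trace.

    A word is emitted when its similarity is both the maximum and above
    ``detection_threshold`` continuously for at least ``min_dwell``
    seconds; consecutive emissions of the same word are merged into one
    response spanning both intervals.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != len(words):
        raise ValueError("trace must be (timesteps, n_words)")
    dwell_steps = max(1, int(round(min_dwell / dt)))
    winner = np.where(
        trace.max(axis=1) >= detection_threshold, trace.argmax(axis=1), -1
    )
    responses: List[Tuple[str, float, float]] = []
    run_word, run_start = -1, 0
    for t in range(len(winner) + 1):
        w = winner[t] if t < len(winner) else -2
        if w == run_word:
            continue
        if run_word >= 0 and t - run_start >= dwell_steps:
            onset, offset = run_start * dt, t * dt
            if responses and responses[-1][0] == words[run_word]:
                prev = responses[-1]
                responses[-1] = (prev[0], prev[1], offset)
            else:
                responses.append((words[run_word], onset, offset))
        run_word, run_start = w, t
    return responses


def run_trial(
    network: RATNetwork,
    duration: Optional[float] = None,
    dt: Optional[float] = None,
    seed: Optional[int] = None,
) -> SimulationResult:
    """Run one full spiking simulation and decode the response sequence.

    The seed drives the white-noise processes of the cue selection
    network (one independent stream per noise source), so identical
    seeds on the same network give identical response sequences.
    """
    config = network.config
    duration = config.trial_duration if duration is None else duration
    dt = config.dt if dt is None else dt
    if not duration > 0:
        raise ValueError("duration must be positive")
    streams = np.random.SeedSequence(seed).spawn(len(network.noise_nodes))
    for node, stream in zip(network.noise_nodes, streams):
        node.reseed(stream)
    sim = nef.Simulator(network, dt=dt)
    sim.run(duration)
    times = sim.trange()
    word_trace = sim.probe_data(network.wta_probe)
    primary_trace = sim.probe_data(network.primary_probe)
    reset_trace = sim.probe_data(network.reset_probe)[:, 0]
    responses = extract_responses(
        word_trace, network.vocab.words, dt,
        detection_threshold=config.detection_threshold,
        min_dwell=config.min_dwell,
    )
    return SimulationResult(
        responses=responses,
        times=times,
        primary_cue_trace=primary_trace,
        reset_trace=reset_trace,
        word_trace=word_trace,
        problem=network.problem,
    )


def make_generation_matrix(
    norms: AssociationMatrix,
    config: ModelConfig,
    seed: Optional[int] = None,
) -> AssociationMatrix:
    """Binarise the norms and prune a random fraction of associations.

    Binarisation keeps only link existence; pruning removes a fraction
    drawn uniformly from ``config.th`` per simulation, modelling
    individual differences in associative networks.
    """
    rng = np.random.default_rng(seed)
    fraction = float(rng.uniform(*config.th))
    return prune(binarize(norms), fraction, seed=rng)
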