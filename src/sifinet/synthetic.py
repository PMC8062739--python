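"""Synthetic generators for every input the pipeline consumes.

Three generators are provided:

* :func:`simulate_coupled_network` — trial ensembles from a linear
  vector-autoregressive network with per-link transmission delays and an
  optional quadratic coupling term, plus analytic ground truth
  (stationary covariance via the discrete Lyapunov equation).
* :func:`simulate_tf_experiment` — a 2x2 between-groups design (Age x
  Propensity) with band-limited oscillatory amplitude effects localized
  in a sensor subset and time window, on top of broadband noise.
* :func:`simulate_behavior` — per-trial flash-count responses of the
  sound-induced flash illusion task (two beeps / one flash reported as
  two flashes counts as an illusion), with per-group, per-SOA illusion
  probabilities.

All generators take an explicit integer seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov

from .containers import TrialEnsemble

__all__ = [
    "GroundTruthNetwork",
    "EffectSpec",
    "PsychometricSpec",
    "simulate_coupled_network",
    "simulate_tf_experiment",
    "simulate_behavior",
    "default_source_network",
    "SOURCE_LABELS",
]

#: Labels for the eight cortical sources entering the network analysis:
#: bilateral primary auditory (BA22) and visual (BA18) cortex, bilateral
#: fusiform gyrus, right middle temporal and right middle frontal gyrus.
SOURCE_LABELS = ["lBA22", "rBA22", "lBA18", "rBA18", "lFFG", "rFFG", "rMTG", "rMFG"]


@dataclass
class GroundTruthNetwork:
    """Directed linear stochastic network with per-link delays.

    Node ``i`` evolves as::

        x_i[t] = a_i * x_i[t-1] + sum_links c_ji * f(x_j[t - d_ji]) + noise

    with ``f`` the identity (or a centred quadratic when the simulator is
    run with ``nonlinearity='quadratic'``).

    Parameters
    ----------
    n_nodes : int
    links : list of (source, target, strength, delay)
        Directed couplings; delays in samples, >= 1; no self-links.
    noise_sd : float
        Innovation standard deviation (same for all nodes).
    self_coefficients : array-like, shape (n_nodes,)
        Lag-1 autoregressive weight per node.
    node_names : list of str, optional
    """

    n_nodes: int
    links: list[tuple[int, int, float, int]] = field(default_factory=list)
    noise_sd: float = 1.0
    self_coefficients: np.ndarray | float = 0.5
    node_names: list[str] | None = None

    def __post_init__(self) -> None:
        if np.isscalar(self.self_coefficients):
            self.self_coefficients = np.full(self.n_nodes, float(self.self_coefficients))
        self.self_coefficients = np.asarray(self.self_coefficients, dtype=float)
        if self.self_coefficients.shape != (self.n_nodes,):
            raise ValueError("self_coefficients must have one entry per node")
        for s, t, _, d in self.links:
            if s == t:
                raise ValueError(f"self-link {s}->{t} not allowed")
            if not (0 <= s < self.n_nodes and 0 <= t < self.n_nodes):
                raise ValueError(f"link {s}->{t} outside node range")
            if d < 1:
                raise ValueError(f"link {s}->{t}: delay must be >= 1 sample")
        if self.node_names is None:
            self.node_names = [f"n{i}" for i in range(self.n_nodes)]
        if len(self.node_names) != self.n_nodes:
            raise ValueError("node_names length mismatch")

    @property
    def max_delay(self) -> int:
        return max([d for *_, d in self.links], default=1)

    def lag_matrices(self) -> np.ndarray:
        """Coefficient matrices ``A[k-1][t, s]`` for lags k = 1..max_delay."""
        p = self.max_delay
        A = np.zeros((p, self.n_nodes, self.n_nodes))
        A[0] += np.diag(self.self_coefficients)
        for s, t, c, d in self.links:
            A[d - 1, t, s] += c
        return A

    def companion_matrix(self) -> np.ndarray:
        """First-order (companion) form of the delayed linear system."""
        A = self.lag_matrices()
        p, n = A.shape[0], self.n_nodes
        C = np.zeros((n * p, n * p))
        for k in range(p):
            C[:n, k * n:(k + 1) * n] = A[k]
        if p > 1:
            C[n:, :-n] = np.eye(n * (p - 1))
        return C

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion_matrix()))))

    def stationary_covariance(self) -> np.ndarray:
        """Analytic zero-lag covariance of the linear system.

        Solves the discrete Lyapunov equation for the companion form and
        returns the contemporaneous (first) block.
        """
        C = self.companion_matrix()
        n = self.n_nodes
        Q = np.zeros_like(C)
        Q[:n, :n] = np.eye(n) * self.noise_sd**2
        S = solve_discrete_lyapunov(C, Q)
        return S[:n, :n]

    def adjacency(self) -> np.ndarray:
        """Boolean presence matrix, ``A[i, j]`` true for link i -> j."""
        A = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for s, t, *_ in self.links:
            A[s, t] = True
        return A


def default_source_network() -> GroundTruthNetwork:
    """Default 8-source ground truth used by the demo pipeline.

    Ten feed-forward links (strength 0.4, delays 2-8 samples) over the
    eight sources of the illusion network.  The graph is acyclic, so the
    linear system is stationary (spectral radius = self coefficient), and
    it contains chains and shared drivers that produce the cascade /
    common-drive artifacts the model-pruning stage is designed to remove.
    """
    name = {lab: i for i, lab in enumerate(SOURCE_LABELS)}
    raw = [
        ("lBA22", "lFFG", 3), ("rBA22", "rFFG", 4), ("lFFG", "rMTG", 2),
        ("lBA22", "rFFG", 6), ("lBA18", "lBA22", 4), ("rBA18", "lBA18", 5),
        ("rMFG", "rBA22", 8), ("rMFG", "rBA18", 5), ("rFFG", "rMTG", 4),
        ("lFFG", "rFFG", 2),
    ]
    links = [(name[s], name[t], 0.4, d) for s, t, d in raw]
    return GroundTruthNetwork(
        n_nodes=8, links=links, noise_sd=1.0, self_coefficients=0.5,
        node_names=list(SOURCE_LABELS),
    )


def simulate_coupled_network(
    net: GroundTruthNetwork,
    n_trials: int,
    n_samples: int,
    sampling_rate: float = 300.0,
    nonlinearity: str = "none",
    seed: int = 0,
    tmin: float = -1.0,
    conditions: list[str] | None = None,
    modulation: dict[tuple[int, int], float] | None = None,
    modulated_condition: str = "illusion",
    subject: str = "S00",
    burn_in: int = 200,
) -> TrialEnsemble:
    """Simulate independent trials of the coupled stochastic network.

    Parameters
    ----------
    net : GroundTruthNetwork
        Generating system; must be stationary (spectral radius < 1).
    n_trials, n_samples : int
        Ensemble shape; ``n_samples`` must exceed the largest delay + 20.
    nonlinearity : {'none', 'quadratic'}
        With 'quadratic' each coupling transmits the centred square
        ``x**2 - 1`` of the source instead of ``x``.
    conditions : list of str, optional
        Condition label per trial (default all ``'default'``).
    modulation : dict (source, target) -> multiplier, optional
        Coupling-strength multiplier applied on trials whose condition
        equals ``modulated_condition`` (condition-dependent effective
        connectivity, the generative counterpart of a B-matrix).

    Returns
    -------
    TrialEnsemble
        Independent realizations of the stationary process; each trial
        is burnt in from zero initial conditions.
    """
    if nonlinearity not in ("none", "quadratic"):
        raise ValueError("nonlinearity must be 'none' or 'quadratic'")
    rho = net.spectral_radius()
    if rho >= 1.0:
        raise ValueError(f"unstable system: spectral radius {rho:.3f} >= 1")
    if n_samples <= net.max_delay + 20:
        raise ValueError("n_samples must exceed max delay + 20")
    if conditions is not None and len(conditions) != n_trials:
        raise ValueError("conditions length mismatch")

    rng = np.random.default_rng(seed)
    n = net.n_nodes
    T = n_samples + burn_in
    a = net.self_coefficients

    # per-trial link strengths (modulation scales couplings on labelled trials)
    base_strengths = np.array([c for _, _, c, _ in net.links], dtype=float)
    strengths = np.tile(base_strengths, (n_trials, 1))
    if modulation:
        mod_mask = np.array([c == modulated_condition for c in (conditions or [])])
        for li, (s, t, _, _) in enumerate(net.links):
            if (s, t) in modulation and mod_mask.any():
                strengths[mod_mask, li] *= modulation[(s, t)]

    x = np.zeros((n_trials, n, T))
    eps = rng.standard_normal((n_trials, n, T)) * net.noise_sd
    for t in range(1, T):
        x[:, :, t] = a * x[:, :, t - 1] + eps[:, :, t]
        for li, (s, tgt, _, d) in enumerate(net.links):
            if t - d < 0:
                continue
            src = x[:, s, t - d]
            if nonlinearity == "quadratic":
                src = src**2 - 1.0
            x[:, tgt, t] += strengths[:, li] * src

    times = tmin + np.arange(n_samples) / sampling_rate
    return TrialEnsemble(
        data=x[:, :, burn_in:],
        sfreq=sampling_rate,
        subject=subject,
        channel_names=list(net.node_names),
        times=times,
        conditions=list(conditions) if conditions is not None else [],
    )


@dataclass
class EffectSpec:
    """Localized band-limited amplitude effect for a 2x2 group design.

    ``multipliers[(a_level, b_level)]`` scales the oscillatory amplitude
    in ``sensors`` within ``time_window`` for subjects of that design
    cell; everything else is broadband noise.
    """

    sensors: list[int]
    time_window: tuple[float, float] = (-0.25, 0.075)
    freq_band: tuple[float, float] = (12.0, 25.0)
    multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    a_levels: tuple[str, str] = ("young", "older")
    b_levels: tuple[str, str] = ("PPI", "PPNI")
    base_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.multipliers:
            self.multipliers = {(a, b): 1.0 for a in self.a_levels for b in self.b_levels}
        for cell, m in self.multipliers.items():
            if m <= 0:
                raise ValueError(f"multiplier for {cell} must be > 0")
        if self.freq_band[0] >= self.freq_band[1]:
            raise ValueError("freq_band must be (low, high) with low < high")


def simulate_tf_experiment(
    effects: EffectSpec,
    n_per_cell: int,
    n_sensors: int,
    seed: int = 0,
    sfreq: float = 300.0,
    tmin: float = -1.0,
    tmax: float = 0.62,
    n_trials: int = 20,
    noise_sd: float = 1.0,
    design: pd.DataFrame | None = None,
):
    """Generate per-subject trial ensembles for a 2x2 group TF design.

    Subjects in design cell (a, b) carry a band-limited oscillation
    (centre frequency of ``effects.freq_band``, random phase per trial)
    of amplitude ``base_amplitude * multipliers[(a, b)]`` in the effect
    sensors within the effect window; all sensors additionally receive
    white broadband noise.

    Returns
    -------
    ensembles : list of TrialEnsemble
    design : DataFrame with columns subject, age_group, propensity
    positions : ndarray (n_sensors, 2), jittered planar grid for adjacency

    Notes
    -----
    When ``design`` (columns ``subject, age_group, propensity``) is
    given, one ensemble is generated per design row instead of
    ``n_per_cell`` per cell — used by the pipeline to attach TF data to
    already-stratified subjects.
    """
    if design is None and n_per_cell < 2:
        raise ValueError("need at least 2 subjects per design cell")
    f0 = float(np.mean(effects.freq_band))
    if effects.freq_band[1] >= sfreq / 2:
        raise ValueError("effect band exceeds Nyquist frequency")
    if not all(0 <= s < n_sensors for s in effects.sensors):
        raise ValueError("effect sensors outside sensor range")

    rng = np.random.default_rng(seed)
    n_samples = int(round((tmax - tmin) * sfreq)) + 1
    times = tmin + np.arange(n_samples) / sfreq
    if not (times[0] <= effects.time_window[0] < effects.time_window[1] <= times[-1]):
        raise ValueError("effect window outside epoch")
    win = (times >= effects.time_window[0]) & (times <= effects.time_window[1])

    # sensor layout: square grid with small jitter (for adjacency building)
    side = int(np.ceil(np.sqrt(n_sensors)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    positions = np.c_[gx.ravel(), gy.ravel()][:n_sensors].astype(float)
    positions += rng.uniform(-0.05, 0.05, positions.shape)

    if design is None:
        rows = [{"subject": f"sub{i:03d}", "age_group": a, "propensity": b}
                for i, (a, b) in enumerate(
                    (a, b) for a in effects.a_levels for b in effects.b_levels
                    for _ in range(n_per_cell))]
        design = pd.DataFrame(rows)
    ensembles = []
    for _, row in design.iterrows():
        amp = effects.base_amplitude * effects.multipliers[
            (row["age_group"], row["propensity"])]
        data = rng.standard_normal((n_trials, n_sensors, n_samples)) * noise_sd
        phases = rng.uniform(0, 2 * np.pi, n_trials)
        osc = np.cos(2 * np.pi * f0 * times[None, :] + phases[:, None])
        osc = osc * win[None, :] * amp
        for s in effects.sensors:
            data[:, s, :] += osc
        ensembles.append(TrialEnsemble(
            data=data, sfreq=sfreq, subject=str(row["subject"]), times=times,
            channel_names=[f"MEG{i:03d}" for i in range(n_sensors)],
        ))
    return ensembles, design.reset_index(drop=True), positions


@dataclass
class PsychometricSpec:
    """Illusion-task response probabilities for two age groups.

    ``p_illusion[group]`` gives the probability of reporting two flashes
    on a 2 beeps / 1 flash trial, per SOA.  ``control_error`` is the
    miscount probability in the audiovisual control conditions.
    ``between_subject_sd`` spreads per-subject illusion propensities
    around the group mean (clipped to [0, 1]); the default 0 makes every
    subject follow the group probability exactly.
    """

    soas_ms: tuple[int, ...] = (50, 100, 150, 200, 250, 300, 500)
    p_illusion: dict[str, tuple[float, ...]] = field(default_factory=lambda: {
        # group means rise for older adults at SOAs >= 100 ms
        "young": (0.70, 0.62, 0.45, 0.35, 0.28, 0.22, 0.12),
        "older": (0.72, 0.65, 0.60, 0.55, 0.50, 0.45, 0.35),
    })
    control_error: float = 0.05
    n_2b1f: int = 10          # trials per SOA in the illusion condition
    n_control: int = 10       # per SOA and control condition
    between_subject_sd: float = 0.0

    def __post_init__(self) -> None:
        for g, ps in self.p_illusion.items():
            ps = tuple(ps)
            if len(ps) != len(self.soas_ms):
                raise ValueError(f"group {g}: need one probability per SOA")
            if any(not 0 <= p <= 1 for p in ps):
                raise ValueError("illusion probabilities must lie in [0, 1]")
            self.p_illusion[g] = ps
        if not 0 <= self.control_error <= 1:
            raise ValueError("control_error must lie in [0, 1]")
        if self.n_2b1f <= 0 or self.n_control <= 0:
            raise ValueError("trial counts must be > 0")


def simulate_behavior(
    spec: PsychometricSpec,
    n_subjects: int | dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a per-trial behavioral table for the illusion task.

    Each row is one trial with columns ``subject, age_group, condition,
    soa_ms, n_beeps, n_flashes, response``.  On 2 beeps / 1 flash trials
    a response of 2 is an illusion; control trials err with probability
    ``spec.control_error``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(n_subjects, int):
        n_subjects = {g: n_subjects for g in spec.p_illusion}
    rows = []
    sid = 0
    for group, n_sub in n_subjects.items():
        p_group = np.asarray(spec.p_illusion[group])
        for _ in range(n_sub):
            name = f"sub{sid:03d}"
            sid += 1
            if spec.between_subject_sd > 0:
                shift = rng.normal(0, spec.between_subject_sd)
            else:
                shift = 0.0
            p_sub = np.clip(p_group + shift, 0.0, 1.0)
            for soa, p in zip(spec.soas_ms, p_sub):
                resp = np.where(rng.random(spec.n_2b1f) < p, 2, 1)
                for r in resp:
                    rows.append((name, group, "2b1f", soa, 2, 1, int(r)))
                err = rng.random(spec.n_control) < spec.control_error
                for e in err:
                    rows.append((name, group, "1b1f", soa, 1, 1, 2 if e else 1))
                err = rng.random(spec.n_control) < spec.control_error
                for e in err:
                    rows.append((name, group, "2b2f", soa, 2, 2, 1 if e else 2))
    return pd.DataFrame(
        rows,
        columns=["subject", "age_group", "condition", "soa_ms",
                 "n_beeps", "n_flashes", "response"],
    )
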