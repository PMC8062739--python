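"""Morlet time-frequency power and factorial cluster-permutation statistics.

The statistical core is a 2x2 independent-groups cluster-based
permutation ANOVA on sensor-level power: per-bin F values for the two
main effects and the interaction are thresholded at the nominal critical
F, suprathreshold bins are clustered through the sensor adjacency graph,
and the observed maximum cluster mass (sum of F within a cluster) is
compared against a permutation null.  Permutations for a main effect
shuffle that factor's labels within the levels of the other factor; the
interaction uses the approximate scheme of permuting whole subjects
across cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import scipy.sparse as sp
from scipy import signal, stats
from scipy.sparse.csgraph import connected_components

from .containers import TrialEnsemble

__all__ = [
    "TFRepresentation", "SensorAdjacency", "ClusterResult",
    "morlet_tfr", "build_adjacency", "cluster_anova_2x2",
    "band_window_power", "permute_design",
]


@dataclass
class TFRepresentation:
    """Trial-averaged power on a sensor x frequency x time grid."""

    power: np.ndarray                      # (n_sensors, n_freqs, n_times) >= 0
    freqs: np.ndarray
    times: np.ndarray
    baseline: tuple[float, float] = (-1.0, -0.5)
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        for ax in (self.freqs, self.times):
            if np.any(np.diff(ax) <= 0):
                raise ValueError("axes must be strictly increasing")

    def relchange(self) -> np.ndarray:
        """Relative change vs. the baseline-window mean, per sensor/freq."""
        mask = (self.times >= self.baseline[0]) & (self.times <= self.baseline[1])
        if not mask.any():
            raise ValueError("baseline window outside epoch")
        base = self.power[:, :, mask].mean(axis=2, keepdims=True)
        return self.power / base - 1.0


def morlet_tfr(
    ensemble: TrialEnsemble,
    freqs=None,
    wavelet_width: float = 5.0,
    gaussian_width: float = 3.0,
    baseline: tuple[float, float] = (-1.0, -0.5),
) -> TFRepresentation:
    """Single-trial Morlet wavelet power, averaged across trials.

    Wavelets have ``wavelet_width`` cycles (temporal SD = width / (2 pi
    f)) and are truncated at ``gaussian_width`` standard deviations of
    the Gaussian taper on each side.  Default frequency grid is 2-60 Hz
    in 2 Hz steps.

    Raises if a requested frequency is at/above Nyquist or if the epoch
    is too short for the lowest-frequency wavelet.
    """
    if freqs is None:
        freqs = np.arange(2.0, 61.0, 2.0)
    freqs = np.asarray(freqs, dtype=float)
    sf = ensemble.sfreq
    if np.any(freqs >= sf / 2):
        raise ValueError("requested frequency at or above Nyquist")
    n_times = ensemble.n_samples
    power = np.zeros((ensemble.n_channels, freqs.size, n_times))
    data = ensemble.data  # (trials, channels, samples)
    for fi, f in enumerate(freqs):
        sd_t = wavelet_width / (2 * np.pi * f)
        half = int(np.round(gaussian_width * sd_t * sf))
        if 2 * half + 1 > n_times:
            raise ValueError(
                f"epoch too short for {f} Hz wavelet "
                f"({2 * half + 1} samples needed, {n_times} available)")
        t = np.arange(-half, half + 1) / sf
        taper = np.exp(-(t**2) / (2 * sd_t**2))
        wav = taper * np.exp(2j * np.pi * f * t)
        wav /= np.sqrt(0.5 * np.sum(np.abs(wav) ** 2) * sf)  # unit energy
        conv = signal.fftconvolve(data, wav[None, None, :], mode="same", axes=2)
        power[:, fi, :] = np.mean(np.abs(conv) ** 2, axis=0)
    return TFRepresentation(
        power=power, freqs=freqs, times=ensemble.times.copy(),
        baseline=baseline, channel_names=list(ensemble.channel_names),
    )


def band_window_power(
    tfr: TFRepresentation,
    band: tuple[float, float] = (12.0, 25.0),
    window: tuple[float, float] = (-0.25, 0.075),
    baseline_mode: str = "relchange",
) -> np.ndarray:
    """Per-sensor power averaged over a frequency band and time window.

    ``baseline_mode`` is ``'relchange'`` (power / baseline mean - 1,
    applied per sensor and frequency before averaging) or ``'none'``.
    """
    if baseline_mode == "relchange":
        p = tfr.relchange()
    elif baseline_mode == "none":
        p = tfr.power
    else:
        raise ValueError("baseline_mode must be 'relchange' or 'none'")
    fm = (tfr.freqs >= band[0]) & (tfr.freqs <= band[1])
    tm = (tfr.times >= window[0]) & (tfr.times <= window[1])
    if not fm.any() or not tm.any():
        raise ValueError("band or window selects no bins")
    return p[:, fm][:, :, tm].mean(axis=(1, 2))


# --------------------------------------------------------------------------
# sensor adjacency
# --------------------------------------------------------------------------

@dataclass
class SensorAdjacency:
    """Symmetric, irreflexive neighbor structure over sensors."""

    neighbors: list[set]

    def __post_init__(self) -> None:
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValueError("adjacency must be irreflexive")
            for j in nb:
                if i not in self.neighbors[j]:
                    raise ValueError("adjacency must be symmetric")

    @property
    def n_sensors(self) -> int:
        return len(self.neighbors)

    @property
    def mean_neighbors(self) -> float:
        return float(np.mean([len(nb) for nb in self.neighbors]))

    def to_sparse(self) -> sp.csr_matrix:
        rows = [i for i, nb in enumerate(self.neighbors) for _ in nb]
        cols = [j for nb in self.neighbors for j in nb]
        data = np.ones(len(rows), dtype=bool)
        return sp.csr_matrix((data, (rows, cols)),
                             shape=(self.n_sensors, self.n_sensors))


def build_adjacency(positions, rule: str = "distance",
                    threshold: float | None = None,
                    k: int | None = None) -> SensorAdjacency:
    """Neighbor sets from sensor positions.

    ``rule='distance'`` links sensors closer than ``threshold``;
    ``rule='knn'`` links each sensor to its ``k`` nearest and
    symmetrizes.  Isolated sensors are retained (with a warning) as
    singleton clusters-to-be.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2:
        raise ValueError("need >= 2 sensors with coordinate positions")
    n = pos.shape[0]
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    neighbors = [set() for _ in range(n)]
    if rule == "distance":
        if threshold is None:
            raise ValueError("distance rule requires threshold")
        for i in range(n):
            neighbors[i] = set(np.flatnonzero(d[i] < threshold).tolist())
    elif rule == "knn":
        if k is None:
            raise ValueError("knn rule requires k")
        for i in range(n):
            for j in np.argsort(d[i])[:k]:
                neighbors[i].add(int(j))
                neighbors[int(j)].add(i)
    else:
        raise ValueError("rule must be 'distance' or 'knn'")
    if any(len(nb) == 0 for nb in neighbors):
        warnings.warn("isolated sensor(s) retained as singletons")
    return SensorAdjacency(neighbors=neighbors)


# --------------------------------------------------------------------------
# factorial cluster permutation ANOVA
# --------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Clusters for one effect of the 2x2 design."""

    effect: str                       # 'A', 'B' or 'AB'
    f_values: np.ndarray              # per-bin F map
    threshold: float                  # cluster-forming critical F
    clusters: list[dict]              # {'members', 'mass', 'p'}
    n_perm: int
    null_max_mass: np.ndarray

    @property
    def significant(self) -> list[dict]:
        return [c for c in self.clusters if c["p"] <= 0.05]


def _effect_design(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Effect-coded design matrix [1, A, B, AB]."""
    xa = np.where(a == 1, 1.0, -1.0)
    xb = np.where(b == 1, 1.0, -1.0)
    return np.c_[np.ones_like(xa), xa, xb, xa * xb]


def _f_maps(Y: np.ndarray, a: np.ndarray, b: np.ndarray,
            only: str | None = None) -> dict[str, np.ndarray]:
    """Per-bin Type-III F values for the main effects and the interaction."""
    X = _effect_design(a, b)
    n, p = X.shape
    df2 = n - p
    ss_full = _ssr(Y, X)
    out = {}
    for name, col in (("A", 1), ("B", 2), ("AB", 3)):
        if only is not None and name != only:
            continue
        Xr = np.delete(X, col, axis=1)
        ss_red = _ssr(Y, Xr)
        out[name] = np.maximum(ss_red - ss_full, 0.0) / (ss_full / df2)
    return out


def _ssr(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return np.einsum("ij,ij->j", resid, resid)


def _cluster_masses(fmap: np.ndarray, threshold: float,
                    adj: sp.csr_matrix) -> list[tuple[np.ndarray, float]]:
    above = fmap > threshold
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    sub = adj[np.ix_(idx, idx)]
    n_comp, labels = connected_components(sub, directed=False)
    clusters = []
    for c in range(n_comp):
        members = idx[labels == c]
        clusters.append((members, float(fmap[members].sum())))
    return clusters


def permute_design(rng: np.random.Generator, a: np.ndarray, b: np.ndarray,
                   effect: str) -> tuple[np.ndarray, np.ndarray]:
    """One permutation of the design under the scheme for ``effect``.

    Main effects permute their own factor's labels within each level of
    the other factor (the other factor's cell counts are untouched); the
    interaction permutes whole subjects across cells (approximate test).
    """
    a, b = a.copy(), b.copy()
    if effect == "A":
        for lev in np.unique(b):
            m = b == lev
            a[m] = rng.permutation(a[m])
    elif effect == "B":
        for lev in np.unique(a):
            m = a == lev
            b[m] = rng.permutation(b[m])
    elif effect == "AB":
        order = rng.permutation(a.size)
        a, b = a[order], b[order]
    else:
        raise ValueError("effect must be 'A', 'B' or 'AB'")
    return a, b


def _n_exact_permutations(a: np.ndarray, b: np.ndarray, effect: str) -> int:
    if effect in ("A", "B"):
        fac, strat = (a, b) if effect == "A" else (b, a)
        total = 1
        for lev in np.unique(strat):
            m = strat == lev
            total *= comb(int(m.sum()), int(fac[m].sum()))
        return total
    # interaction: distinct multiset permutations of the cell labels
    n = a.size
    total = 1
    remaining = n
    for cell in {(x, y) for x, y in zip(a.tolist(), b.tolist())}:
        k = int(np.sum((a == cell[0]) & (b == cell[1])))
        total *= comb(remaining, k)
        remaining -= k
    return total


def _exact_permutations(a: np.ndarray, b: np.ndarray, effect: str):
    """Yield all distinct label assignments for ``effect``."""
    if effect in ("A", "B"):
        fac, strat = (a, b) if effect == "A" else (b, a)
        strata = [np.flatnonzero(strat == lev) for lev in np.unique(strat)]
        counts = [int(fac[s].sum()) for s in strata]

        def rec(i, current):
            if i == len(strata):
                if effect == "A":
                    yield current, b
                else:
                    yield a, current
                return
            for ones in combinations(strata[i].tolist(), counts[i]):
                nxt = current.copy()
                nxt[strata[i]] = 0
                nxt[list(ones)] = 1
                yield from rec(i + 1, nxt)

        yield from rec(0, fac.copy())
    else:
        cells = sorted({(x, y) for x, y in zip(a.tolist(), b.tolist())})
        counts = [int(np.sum((a == x) & (b == y))) for x, y in cells]
        n = a.size

        def rec(ci, free, aa, bb):
            if ci == len(cells):
                yield aa.copy(), bb.copy()
                return
            for chosen in combinations(sorted(free), counts[ci]):
                aa2, bb2 = aa.copy(), bb.copy()
                for s in chosen:
                    aa2[s], bb2[s] = cells[ci]
                yield from rec(ci + 1, free - set(chosen), aa2, bb2)

        yield from rec(0, set(range(n)), np.empty(n, dtype=a.dtype),
                       np.empty(n, dtype=b.dtype))


def cluster_anova_2x2(
    maps: np.ndarray,
    factor_a,
    factor_b,
    adjacency: SensorAdjacency,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int = 0,
    extra_shape: tuple[int, ...] = (),
) -> dict[str, ClusterResult]:
    """Cluster-based permutation 2x2 independent-groups ANOVA.

    Parameters
    ----------
    maps : ndarray (n_subjects, n_sensors) or (n_subjects, n_sensors, ...)
        Per-subject power maps (e.g. band/window-averaged relative
        power).  Trailing dimensions, if any, are clustered along a
        lattice (declare them via ``extra_shape``).
    factor_a, factor_b : sequences of two levels each
        Subject labels for the two between factors (Age, Propensity).
    cluster_alpha : float
        Bin-level alpha for the cluster-forming F threshold (nominal F
        distribution with the design's degrees of freedom).
    n_perm : int
        Monte-Carlo permutations; if the number of distinct permutations
        for an effect is smaller, all of them are enumerated instead.

    Returns
    -------
    dict effect -> ClusterResult, effects keyed 'A', 'B', 'AB'.
    """
    maps = np.asarray(maps, dtype=float)
    n_sub = maps.shape[0]
    Y = maps.reshape(n_sub, -1)
    a = _binarize(factor_a, "factor_a")
    b = _binarize(factor_b, "factor_b")
    for aa in (0, 1):
        for bb in (0, 1):
            if np.sum((a == aa) & (b == bb)) < 2:
                raise ValueError("need >= 2 subjects per design cell")
    n_bins_space = adjacency.n_sensors
    if extra_shape:
        adj = _lattice_adjacency(adjacency.to_sparse(), extra_shape)
        expected = n_bins_space * int(np.prod(extra_shape))
    else:
        adj = adjacency.to_sparse()
        expected = n_bins_space
    if Y.shape[1] != expected:
        raise ValueError("adjacency does not cover all data bins")

    threshold = stats.f.ppf(1 - cluster_alpha, 1, n_sub - 4)
    observed = _f_maps(Y, a, b)
    rng = np.random.default_rng(seed)

    results = {}
    for effect in ("A", "B", "AB"):
        obs_clusters = _cluster_masses(observed[effect], threshold, adj)
        n_exact = _n_exact_permutations(a, b, effect)
        null_max = []
        if n_exact <= n_perm:
            for pa, pb in _exact_permutations(a, b, effect):
                fm = _f_maps(Y, pa, pb, only=effect)[effect]
                cl = _cluster_masses(fm, threshold, adj)
                null_max.append(max((m for _, m in cl), default=0.0))
            n_used = len(null_max)
        else:
            for _ in range(n_perm):
                pa, pb = permute_design(rng, a, b, effect)
                fm = _f_maps(Y, pa, pb, only=effect)[effect]
                cl = _cluster_masses(fm, threshold, adj)
                null_max.append(max((m for _, m in cl), default=0.0))
            n_used = n_perm
        null_max = np.asarray(null_max)
        clusters = []
        for members, mass in sorted(obs_clusters, key=lambda c: -c[1]):
            p = (1 + int(np.sum(null_max >= mass))) / (1 + n_used)
            clusters.append({"members": members, "mass": mass, "p": p})
        results[effect] = ClusterResult(
            effect=effect, f_values=observed[effect], threshold=float(threshold),
            clusters=clusters, n_perm=n_used, null_max_mass=null_max,
        )
    return results


def _binarize(labels, name: str) -> np.ndarray:
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if levels.size != 2:
        raise ValueError(f"{name} must have exactly 2 levels, got {levels}")
    return (labels == levels[1]).astype(int)


def _lattice_adjacency(sensor_adj: sp.csr_matrix,
                       extra_shape: tuple[int, ...]) -> sp.csr_matrix:
    """Adjacency over sensors x lattice bins: neighbors along one axis at a time."""
    lat = None
    for size in extra_shape:
        step = sp.diags([np.ones(size - 1), np.ones(size - 1)], [1, -1],
                        format="csr", dtype=bool)
        lat = step if lat is None else (
            sp.kron(lat, sp.identity(size, dtype=bool, format="csr"))
            + sp.kron(sp.identity(lat.shape[0], dtype=bool, format="csr"), step)
        )
    n_lat = int(np.prod(extra_shape))
    eye_lat = sp.identity(n_lat, dtype=bool, format="csr")
    eye_s = sp.identity(sensor_adj.shape[0], dtype=bool, format="csr")
    return (sp.kron(sensor_adj, eye_lat) + sp.kron(eye_s, lat)).tocsr()
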