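"""Multivariate EMD (MEMD) and its noise-assisted variant (NA-MEMD).

MEMD extends sifting to a P-channel signal x(t) in R^P by projecting it onto
V quasi-uniform direction vectors on the unit (P-1)-sphere (a low-discrepancy
Hammersley point set).  For each direction the projection's maxima mark time
instants at which the full P-dimensional signal is interpolated with cubic
splines, giving one directional envelope; the local mean M(t) is the average
over directions.  Sifting subtracts M(t) until the stoppage criterion

    mean_t [ ||M(t)||_1 / P ] / e(t) < gamma,     e(t) = (1/P) sum_p |c_p(t) - M_p(t)|

is met (gamma = 0.2 by default, a value calibrated on lower-limb surface EMG).
Because every channel is sifted against the same shared local mean, all
channels receive the same number of IMFs — the structural guarantee that
makes same-index cross-channel comparison meaningful.

NA-MEMD appends K extra channels of independent white Gaussian noise (power
set by default to the average channel STD), runs MEMD on the composite, and
discards the noise channels' IMFs.  The broadband noise populates every
dyadic frequency band with extrema, which stabilises the filter-bank
behaviour and reduces mode mixing in the signal channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import ndtri

from ._exceptions import EnvelopeUndefinedError, InvalidInputError
from .sift import SiftParams, find_extrema, _mirrored_knots

__all__ = [
    "MultichannelRecording",
    "DirectionSet",
    "MultivariateEnvelope",
    "MvStopParams",
    "MultivariateDecomposition",
    "NoiseAssistParams",
    "hammersley_directions",
    "project",
    "multivariate_mean",
    "mv_stop",
    "memd",
    "na_memd",
]


@dataclass(frozen=True)
class MultichannelRecording:
    """A uniformly sampled multichannel recording (rows = time, columns = channels)."""

    samples: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2:
            raise InvalidInputError("samples must be a T x P matrix")
        T, P = samples.shape
        if P < 2:
            raise InvalidInputError("need at least 2 channels")
        if T < 64:
            raise InvalidInputError("need at least 64 samples")
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("recording contains non-finite samples")
        if not self.sampling_rate > 0:
            raise InvalidInputError("sampling_rate must be positive")
        names = tuple(self.channel_names) or tuple(f"ch{i + 1}" for i in range(P))
        if len(names) != P or len(set(names)) != P:
            raise InvalidInputError("channel_names must be unique, one per channel")
        object.__setattr__(self, "channel_names", names)

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.samples.shape[1])


@dataclass(frozen=True)
class DirectionSet:
    """V unit vectors on the (P-1)-sphere, rows of ``vectors`` (V x P)."""

    vectors: np.ndarray
    generator_tag: str = ""

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=np.float64)
        object.__setattr__(self, "vectors", vectors)
        norms = np.linalg.norm(vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise InvalidInputError("direction vectors must have unit norm")

    @property
    def n_directions(self) -> int:
        return int(self.vectors.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.vectors.shape[1])


@dataclass
class MultivariateEnvelope:
    """Direction-averaged local mean plus the per-direction bookkeeping."""

    mean: np.ndarray  # T x P
    n_used_directions: int
    projection_extrema: list[np.ndarray] = field(default_factory=list)


@dataclass(frozen=True)
class MvStopParams:
    """Multivariate stoppage rule: stop when mean_t(||M||_1/P / e) < gamma."""

    gamma: float = 0.2
    max_sift_iters: int = 100
    reduction: Literal["mean", "max"] = "mean"

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise InvalidInputError("gamma must be positive")


@dataclass
class MultivariateDecomposition:
    """IMF stack of shape (M, T, P) plus a T x P residual.

    The IMF count M is identical for every channel by construction; each
    channel reconstructs as sum of its IMFs plus its residual column.
    """

    imfs: np.ndarray
    residual: np.ndarray
    channel_names: tuple[str, ...] = ()

    @property
    def n_imfs(self) -> int:
        return int(self.imfs.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.residual.shape[1])

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residual

    def channel_imfs(self, j: int) -> np.ndarray:
        """The (M, T) IMF stack of channel ``j``."""
        return self.imfs[:, :, j]


@dataclass(frozen=True)
class NoiseAssistParams:
    """NA-MEMD controls: K noise channels at a given power.

    ``noise_power_rule`` is either the string ``"average-std"`` (noise STD =
    mean of the per-channel STDs of the input, the standard choice for EMG)
    or a fixed positive float.
    """

    n_noise_channels: int = 4
    noise_power_rule: float | str = "average-std"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_noise_channels < 0:
            raise InvalidInputError("n_noise_channels must be >= 0")
        if isinstance(self.noise_power_rule, str):
            if self.noise_power_rule != "average-std":
                raise InvalidInputError("noise_power_rule must be 'average-std' or a float")
        elif not self.noise_power_rule >= 0:
            raise InvalidInputError("fixed noise power must be >= 0")


_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53)


def _radical_inverse(base: int, indices: np.ndarray) -> np.ndarray:
    """van der Corput radical inverse of each index in the given base."""
    out = np.zeros(indices.shape, dtype=np.float64)
    frac = 1.0 / base
    i = indices.copy()
    while np.any(i > 0):
        out += (i % base) * frac
        i //= base
        frac /= base
    return out


def hammersley_directions(n_directions: int, n_channels: int) -> DirectionSet:
    """Quasi-uniform unit vectors on the (P-1)-sphere from a Hammersley set.

    Coordinate k of point i is the radical inverse of i in the k-th prime
    base (2, 3, 5, ...); each coordinate is pushed through the inverse
    normal CDF and the resulting Gaussian-like vector normalised to unit
    length.  Each point is paired with its antipode, so the set is exactly
    symmetric under negation: envelopes are interpolated at projection
    *maxima* only, and the antipodal partner of every direction covers the
    corresponding minima.  The construction is deterministic, so the same
    (V, P) always yields the same direction matrix.
    """
    V, P = int(n_directions), int(n_channels)
    if P < 2:
        raise InvalidInputError("need at least 2 channels")
    if V < P:
        raise InvalidInputError("need at least as many directions as channels")
    if P > len(_PRIMES):
        raise InvalidInputError(f"at most {len(_PRIMES)} channels supported")
    half = (V + 1) // 2
    idx = np.arange(1, half + 1)
    u = np.stack([_radical_inverse(_PRIMES[k], idx) for k in range(P)], axis=1)
    z = ndtri(u)
    norms = np.linalg.norm(z, axis=1)
    norms[norms < 1e-12] = 1.0
    base = z / norms[:, None]
    vectors = np.empty((2 * half, P))
    vectors[0::2] = base
    vectors[1::2] = -base
    return DirectionSet(
        vectors=vectors[:V], generator_tag=f"hammersley-ndtri-antithetic V={V} P={P}"
    )


def project(recording: MultichannelRecording | np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Project each time sample onto a direction vector (plain inner product)."""
    X = recording.samples if isinstance(recording, MultichannelRecording) else np.asarray(recording)
    d = np.asarray(direction, dtype=np.float64)
    if d.shape != (X.shape[1],):
        raise InvalidInputError("direction length must equal the channel count")
    return X @ d


def multivariate_mean(
    samples: np.ndarray,
    directions: DirectionSet,
    boundary_mirror_count: int = 2,
) -> MultivariateEnvelope:
    """Direction-averaged local mean of a T x P signal.

    For each direction, the time instants of the projection's maxima are
    found; the full P-channel signal at those instants is interpolated with
    one cubic spline per channel (mirrored boundary knots) to give a
    directional envelope.  Directions whose projection has fewer than two
    maxima are skipped; if none are usable the residual has been reached.
    Projection minima are covered implicitly because the quasi-uniform
    direction set contains near-antipodal vectors.
    """
    X = np.asarray(samples, dtype=np.float64)
    T, P = X.shape
    acc = np.zeros((T, P))
    used = 0
    extrema: list[np.ndarray] = []
    grid = np.arange(T)
    for d in directions.vectors:
        w = X @ d
        maxima, _ = find_extrema(w)
        if maxima.size < 2:
            continue
        knots_t, _ = _mirrored_knots(maxima, w[maxima], T, boundary_mirror_count)
        # mirror the P-channel values with the same index pattern as knots_t
        vals = X[maxima]
        m = boundary_mirror_count
        ml = min(m, maxima.size)
        left = vals[:ml][::-1]
        right = vals[-ml:][::-1]
        full = np.concatenate([left, vals, right], axis=0)
        t_all = np.concatenate(
            [-maxima[:ml][::-1], maxima, 2 * (T - 1) - maxima[-ml:][::-1]]
        )
        keep = np.concatenate([[True], np.diff(t_all) > 0])
        acc += CubicSpline(t_all[keep], full[keep], axis=0)(grid)
        used += 1
        extrema.append(maxima)
    if used == 0:
        raise EnvelopeUndefinedError("no direction projection has 2 maxima")
    return MultivariateEnvelope(mean=acc / used, n_used_directions=used, projection_extrema=extrema)


def mv_stop(
    candidate: np.ndarray, envelope_mean: np.ndarray, params: MvStopParams | None = None
) -> bool:
    """Evaluate the multivariate stoppage criterion.

    The per-sample numerator is the channel-average magnitude of the local
    mean, the denominator the channel-average deviation of the candidate
    from it (floored at 1e-12); the time-varying ratio is reduced to a
    scalar (mean by default) and compared against gamma.  Returns True when
    the candidate should be accepted as an IMF.
    """
    params = params or MvStopParams()
    c = np.asarray(candidate, dtype=np.float64)
    M = np.asarray(envelope_mean, dtype=np.float64)
    if c.shape != M.shape:
        raise InvalidInputError("candidate and envelope mean shapes must match")
    num = np.mean(np.abs(M), axis=1)
    den = np.maximum(np.mean(np.abs(c - M), axis=1), 1e-12)
    ratio = num / den
    scalar = float(ratio.mean() if params.reduction == "mean" else ratio.max())
    return scalar < params.gamma


def _sift_mv_imf(
    h: np.ndarray,
    directions: DirectionSet,
    stop: MvStopParams,
    mirror: int,
) -> np.ndarray:
    """Sift one multivariate IMF out of ``h`` (T x P)."""
    for _ in range(stop.max_sift_iters):
        try:
            env = multivariate_mean(h, directions, mirror)
        except EnvelopeUndefinedError:
            return h  # cannot refine further; accept as-is
        c = h - env.mean
        if mv_stop(c, env.mean, stop):
            return c
        h = c
    return h


def memd(
    recording: MultichannelRecording,
    directions: int | DirectionSet = 64,
    stop: MvStopParams | None = None,
    sift: SiftParams | None = None,
) -> MultivariateDecomposition:
    """Multivariate empirical mode decomposition.

    ``directions`` may be a direction count (a Hammersley set is built for
    the recording's channel dimension) or a prebuilt :class:`DirectionSet`.
    Extraction ends when no direction projection retains two maxima, or when
    a generous dyadic cap on the IMF count is hit.
    """
    stop = stop or MvStopParams()
    sift = sift or SiftParams()
    X = recording.samples
    T, P = X.shape
    if isinstance(directions, DirectionSet):
        dirs = directions
        if dirs.n_channels != P:
            raise InvalidInputError("direction set dimensionality != channel count")
    else:
        dirs = hammersley_directions(int(directions), P)
    cap = sift.max_imfs if sift.max_imfs is not None else int(np.ceil(np.log2(T))) + 4
    residual = X.copy()
    imfs: list[np.ndarray] = []
    floor = 1e-14 * max(float(X.std()), 1.0)
    while len(imfs) < cap:
        try:
            multivariate_mean(residual, dirs, sift.boundary_mirror_count)
        except EnvelopeUndefinedError:
            break
        imf = _sift_mv_imf(residual.copy(), dirs, stop, sift.boundary_mirror_count)
        if imf.std() <= floor:
            break
        imfs.append(imf)
        residual = residual - imf
    stack = np.array(imfs) if imfs else np.empty((0, T, P))
    return MultivariateDecomposition(
        imfs=stack, residual=residual, channel_names=recording.channel_names
    )


def na_memd(
    recording: MultichannelRecording,
    na: NoiseAssistParams | None = None,
    directions: int | DirectionSet = 64,
    stop: MvStopParams | None = None,
    sift: SiftParams | None = None,
) -> MultivariateDecomposition:
    """Noise-assisted MEMD.

    K independent white-Gaussian-noise channels (drawn once per call) are
    appended to the recording, the composite is decomposed with MEMD, and
    only the original channels' IMFs and residual are returned.  With K=0
    this is exactly :func:`memd` on the original recording.
    """
    na = na or NoiseAssistParams()
    if na.n_noise_channels == 0:
        return memd(recording, directions, stop, sift)
    X = recording.samples
    T, P = X.shape
    if na.noise_power_rule == "average-std":
        power = float(np.mean(X.std(axis=0)))
    else:
        power = float(na.noise_power_rule)
    rng = np.random.default_rng([na.seed, 0])
    noise = rng.normal(0.0, power, size=(T, na.n_noise_channels))
    composite = MultichannelRecording(
        samples=np.hstack([X, noise]),
        sampling_rate=recording.sampling_rate,
        channel_names=recording.channel_names
        + tuple(f"wgn{k + 1}" for k in range(na.n_noise_channels)),
    )
    if isinstance(directions, DirectionSet):
        dirs: int | DirectionSet = hammersley_directions(
            directions.n_directions, composite.n_channels
        )
    else:
        dirs = directions
    full = memd(composite, dirs, stop, sift)
    return MultivariateDecomposition(
        imfs=full.imfs[:, :, :P],
        residual=full.residual[:, :P],
        channel_names=recording.channel_names,
    )
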