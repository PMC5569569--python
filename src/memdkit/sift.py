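"""Univariate empirical mode decomposition (EMD) and its ensemble variant (EEMD).

EMD represents a signal as a sum of intrinsic mode functions (IMFs) plus a
residual,

    x(t) = sum_m c_m(t) + r(t),

where each IMF is extracted by *sifting*: the local mean of the cubic-spline
envelopes through the maxima and minima is repeatedly subtracted until the
candidate satisfies the two IMF criteria, (a) the numbers of extrema and
zero crossings differ by at most one, and (b) the envelope mean is (near)
zero.  Criterion (b) cannot be met exactly in floating point, so it is
enforced as RMS(envelope mean) / STD(candidate) < ``envelope_mean_tol``.

EEMD decomposes many white-noise-perturbed copies of the signal and averages
same-indexed IMFs, which stabilises the dyadic filter-bank behaviour of EMD
on real, noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from ._exceptions import DegenerateEnvelopeError, InvalidInputError, NoImfError

__all__ = [
    "Signal",
    "SiftParams",
    "EnsembleParams",
    "Decomposition",
    "find_extrema",
    "count_zero_crossings",
    "spline_envelope",
    "sift_imf",
    "emd",
    "eemd",
]


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples : array-like of float
        The signal values, at least 16 of them, all finite.
    sampling_rate : float
        Sampling frequency in Hz, strictly positive.
    """

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 16:
            raise InvalidInputError("signal must be 1-D with at least 16 samples")
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("signal contains non-finite samples")
        if not self.sampling_rate > 0:
            raise InvalidInputError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class SiftParams:
    """Controls for the sifting loop.

    ``envelope_mean_tol`` is the criterion-(b) threshold: sifting of one IMF
    stops once RMS of the envelope mean falls below this fraction of the
    current component's STD (and criterion (a) holds).  ``boundary_mirror_count``
    extrema are mirrored about each end of the record before envelope spline
    fitting, which keeps the spline from swinging wildly at the boundaries.
    """

    max_sift_iters: int = 100
    envelope_mean_tol: float = 0.05
    boundary_mirror_count: int = 2
    max_imfs: int | None = None

    def __post_init__(self) -> None:
        if self.max_sift_iters < 1:
            raise InvalidInputError("max_sift_iters must be >= 1")
        if self.envelope_mean_tol < 0:
            raise InvalidInputError("envelope_mean_tol must be >= 0")
        if self.boundary_mirror_count < 1:
            raise InvalidInputError("boundary_mirror_count must be >= 1")
        if self.max_imfs is not None and self.max_imfs < 1:
            raise InvalidInputError("max_imfs must be >= 1 or None")


@dataclass(frozen=True)
class EnsembleParams:
    """Ensemble controls for EEMD.

    ``noise_amplitude`` is the STD of the added white Gaussian noise expressed
    as a fraction of the input signal's STD.  Per-realization noise streams
    are derived from ``seed`` by seeding a generator with the pair
    ``(seed, realization_index)``, so the ensemble is reproducible and each
    realization independent.
    """

    n_realizations: int = 50
    noise_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise InvalidInputError("n_realizations must be >= 1")
        if self.noise_amplitude < 0:
            raise InvalidInputError("noise_amplitude must be >= 0")


@dataclass
class Decomposition:
    """Ordered IMFs plus residual for one channel.

    ``imfs`` has shape (M, T), highest-frequency mode first; ``residual`` has
    shape (T,).  For plain EMD the element-wise sum of IMFs and residual
    reproduces the input to floating-point accuracy.
    """

    imfs: np.ndarray
    residual: np.ndarray
    params: SiftParams = field(default_factory=SiftParams)

    @property
    def n_imfs(self) -> int:
        return int(self.imfs.shape[0])

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residual


def find_extrema(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Locate strict interior local maxima and minima.

    A plateau (a run of equal samples) flanked by lower values on both sides
    contributes a single maximum at the run's midpoint, and symmetrically for
    minima.  Endpoints never count as extrema.

    Returns
    -------
    (maxima, minima) : pair of integer index arrays, each sorted ascending.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 3:
        raise InvalidInputError("need at least 3 samples to find extrema")
    dx = np.diff(x)
    nz = np.flatnonzero(dx)
    if nz.size < 2:
        empty = np.empty(0, dtype=np.intp)
        return empty, empty
    s = np.sign(dx[nz])
    turn = np.flatnonzero(s[1:] != s[:-1])  # slope sign changes
    if turn.size == 0:
        empty = np.empty(0, dtype=np.intp)
        return empty, empty
    # Plateau between the end of one monotone run and the start of the next:
    # samples nz[k]+1 .. nz[k+1] share one value; the extremum sits midway.
    left = nz[turn] + 1
    right = nz[turn + 1]
    idx = (left + right) // 2
    is_max = s[turn] > 0
    return idx[is_max], idx[~is_max]


def count_zero_crossings(samples: np.ndarray) -> int:
    """Count sign changes along the sequence.

    Exact zeros are transparent: a zero between opposite signs counts as one
    crossing, runs of zeros collapse, and a zero-touch between equal signs
    does not count.
    """
    x = np.asarray(samples, dtype=np.float64)
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def _mirrored_knots(
    indices: np.ndarray, values: np.ndarray, n: int, mirror: int
) -> tuple[np.ndarray, np.ndarray]:
    """Reflect up to ``mirror`` extrema about each end of a length-``n`` record."""
    m_left = min(mirror, indices.size)
    m_right = min(mirror, indices.size)
    left_t = -indices[:m_left][::-1]
    left_v = values[:m_left][::-1]
    right_t = 2 * (n - 1) - indices[-m_right:][::-1]
    right_v = values[-m_right:][::-1]
    t = np.concatenate([left_t, indices, right_t])
    v = np.concatenate([left_v, values, right_v])
    # reflections of an extremum at an exact endpoint would duplicate a knot
    keep = np.concatenate([[True], np.diff(t) > 0])
    return t[keep], v[keep]


def spline_envelope(
    samples: np.ndarray,
    extrema_indices: np.ndarray,
    boundary_mirror_count: int = 2,
) -> np.ndarray:
    """Cubic-spline envelope through one family of extrema.

    Knots are the extrema, extended by mirroring ``boundary_mirror_count`` of
    them about each end of the record.  With only two knots the spline
    degenerates to the straight line through them.
    """
    x = np.asarray(samples, dtype=np.float64)
    idx = np.asarray(extrema_indices, dtype=np.intp)
    if idx.size < 2:
        raise DegenerateEnvelopeError("need at least 2 extrema for an envelope")
    t, v = _mirrored_knots(idx, x[idx], x.size, boundary_mirror_count)
    return CubicSpline(t, v)(np.arange(x.size))


def _is_imf(candidate: np.ndarray, maxima: np.ndarray, minima: np.ndarray) -> bool:
    """Criterion (a): extrema and zero-crossing counts differ by at most one."""
    n_ext = maxima.size + minima.size
    return abs(n_ext - count_zero_crossings(candidate)) <= 1


def sift_imf(signal: Signal | np.ndarray, params: SiftParams | None = None) -> np.ndarray:
    """Extract one IMF candidate by iterative envelope-mean subtraction.

    Sifting stops when the mean-subtracted candidate satisfies criterion (a)
    and the envelope mean is small relative to the component's STD
    (criterion (b)), or after ``max_sift_iters`` passes.
    """
    params = params or SiftParams()
    h = np.array(signal.samples if isinstance(signal, Signal) else signal, dtype=np.float64)
    maxima, minima = find_extrema(h)
    if maxima.size < 2 or minima.size < 2:
        raise NoImfError("fewer than 2 maxima or 2 minima; nothing to sift")
    for _ in range(params.max_sift_iters):
        upper = spline_envelope(h, maxima, params.boundary_mirror_count)
        lower = spline_envelope(h, minima, params.boundary_mirror_count)
        mean = 0.5 * (upper + lower)
        h_new = h - mean
        scale = h.std()
        small_mean = scale > 0 and float(
            np.sqrt(np.mean(mean**2))
        ) < params.envelope_mean_tol * scale
        maxima, minima = find_extrema(h_new)
        if small_mean and _is_imf(h_new, maxima, minima):
            return h_new
        h = h_new
        if maxima.size < 2 or minima.size < 2:
            break  # over-sifted into a residual-like component
    return h


def emd(signal: Signal | np.ndarray, params: SiftParams | None = None) -> Decomposition:
    """Full empirical mode decomposition.

    IMFs are peeled off highest-frequency first until the residual has too
    few extrema to sift (it is then monotone or close to it), or until
    ``max_imfs`` is reached.  The decomposition is exactly additive: the sum
    of IMFs plus residual telescopes back to the input.
    """
    params = params or SiftParams()
    x = np.array(signal.samples if isinstance(signal, Signal) else signal, dtype=np.float64)
    residual = x.copy()
    imfs: list[np.ndarray] = []
    cap = params.max_imfs if params.max_imfs is not None else int(np.ceil(np.log2(x.size))) + 2
    while len(imfs) < cap:
        maxima, minima = find_extrema(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        try:
            imf = sift_imf(residual, params)
        except NoImfError:
            break
        if imf.std() <= 1e-14 * max(x.std(), 1.0):
            break  # numerically empty component; sifting has stalled
        imfs.append(imf)
        residual = residual - imf
    stack = np.array(imfs) if imfs else np.empty((0, x.size))
    return Decomposition(imfs=stack, residual=residual, params=params)


def eemd(
    signal: Signal | np.ndarray,
    sift: SiftParams | None = None,
    ens: EnsembleParams | None = None,
    sampling_rate: float | None = None,
) -> Decomposition:
    """Ensemble EMD: average of EMDs over noise-perturbed realizations.

    Each of the ``n_realizations`` copies gets independent white Gaussian
    noise of STD ``noise_amplitude * STD(x)``.  Realizations may produce
    different IMF counts; they are aligned by IMF index and zero-padded to
    the maximum count before averaging, then trailing all-near-zero averaged
    IMFs (energy below 1e-12 of the input's) are folded into the residual.

    With ``noise_amplitude=0`` and ``n_realizations=1`` this reduces exactly
    to :func:`emd`.
    """
    sift = sift or SiftParams()
    ens = ens or EnsembleParams()
    x = np.array(signal.samples if isinstance(signal, Signal) else signal, dtype=np.float64)
    scale = x.std()
    max_m = 0
    per_imfs: list[np.ndarray] = []
    per_res: list[np.ndarray] = []
    for n in range(ens.n_realizations):
        rng = np.random.default_rng([ens.seed, n])
        noise = rng.normal(0.0, ens.noise_amplitude * scale, x.size) if ens.noise_amplitude > 0 else 0.0
        d = emd(x + noise, sift)
        per_imfs.append(d.imfs)
        per_res.append(d.residual)
        max_m = max(max_m, d.n_imfs)
    avg = np.zeros((max_m, x.size))
    for stack in per_imfs:
        if stack.shape[0]:
            avg[: stack.shape[0]] += stack
    avg /= ens.n_realizations
    residual = np.mean(per_res, axis=0)
    # drop trailing numerically-empty averaged modes into the residual
    energy_floor = 1e-12 * float(np.sum(x**2))
    m = max_m
    while m > 0 and float(np.sum(avg[m - 1] ** 2)) < energy_floor:
        residual = residual + avg[m - 1]
        m -= 1
    return Decomposition(imfs=avg[:m], residual=residual, params=sift)
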