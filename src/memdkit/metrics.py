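"""Decomposition quality metrics: IMF counts, mode-alignment, mode-mixing.

Three criteria score how well an EMD-family method decomposes a multichannel
recording:

* **IMF counts** — mean and sample STD of the number of IMFs per channel.
  Multivariate methods guarantee equal counts across channels; channel-wise
  methods (EMD/EEMD) do not.
* **Mode-alignment** — same-indexed IMFs should occupy the same frequency
  band in every channel.  Each IMF is STD-normalised, its power spectral
  density estimated, and c(i, j) is the mean Pearson correlation between the
  PSD of IMF i in channel j and the PSDs of IMF i in the other channels.
  Row means of the resulting matrix summarise alignment per IMF index, and
  their mean over retained IMFs gives one scalar per recording.
* **Mode-mixing** — adjacent IMFs within one channel should not share
  frequency content.  For each IMF the 20%- and 80%-cumulative-energy
  frequencies (f2, f8) delimit its energy band of width D = f8 - f2; the
  mixing score of a pair is the length of the band intersection divided by
  the narrower band's width, and a channel's score aggregates the
  adjacent-pair values (mean by default).

Surface EMG carries its useful energy roughly in 20–500 Hz, so IMFs whose
spectral central frequency falls below a 20 Hz cutoff are excluded from the
metrics and synthesised into a single low-frequency remainder trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import welch

from ._exceptions import (
    DegenerateImfError,
    InvalidInputError,
    UndefinedMetricError,
)

__all__ = [
    "PsdParams",
    "PsdEstimate",
    "BandSummary",
    "AlignmentMatrix",
    "MixingResult",
    "normalize_imf",
    "estimate_psd",
    "band_summary",
    "mode_mixing_pair",
    "channel_mode_mixing",
    "mode_alignment",
    "filter_low_frequency_imfs",
    "imf_count_table",
]


@dataclass(frozen=True)
class PsdParams:
    """Welch estimator settings: Hann window, 50% overlap by default."""

    nperseg: int = 1024
    window: str = "hann"
    overlap_fraction: float = 0.5


@dataclass
class PsdEstimate:
    """One-sided power spectral density on a strictly increasing frequency grid."""

    frequencies: np.ndarray
    density: np.ndarray
    params: PsdParams = field(default_factory=PsdParams)

    @property
    def total_energy(self) -> float:
        return float(np.trapezoid(self.density, self.frequencies))


@dataclass(frozen=True)
class BandSummary:
    """The 20–80% cumulative-energy band of one IMF's spectrum."""

    f2: float
    f8: float
    central_frequency: float

    @property
    def width(self) -> float:
        return self.f8 - self.f2


@dataclass
class AlignmentMatrix:
    """Cross-channel PSD-correlation matrix c(i, j) with its row means."""

    values: np.ndarray  # I x J, NaN where a channel's IMF was degenerate
    row_means: np.ndarray
    scalar_summary: float


@dataclass
class MixingResult:
    """Adjacent-pair mixing scores and their per-channel aggregate."""

    pairwise: np.ndarray
    aggregate: float
    aggregate_rule: str = "mean"


def normalize_imf(imf: np.ndarray) -> np.ndarray:
    """Scale an IMF to unit standard deviation."""
    x = np.asarray(imf, dtype=np.float64)
    sd = float(x.std())
    if sd < 1e-12:
        raise DegenerateImfError("IMF has (near-)zero variance")
    return x / sd


def estimate_psd(
    sequence: np.ndarray, sampling_rate: float, params: PsdParams | None = None
) -> PsdEstimate:
    """Welch-averaged periodogram of a sequence.

    The density integrates (trapezoidally) to approximately the sequence
    variance, so cumulative-energy band edges are well defined.
    """
    params = params or PsdParams()
    x = np.asarray(sequence, dtype=np.float64)
    nperseg = min(params.nperseg, x.size)
    if x.size < 8:
        raise InvalidInputError("sequence too short for a PSD estimate")
    freqs, density = welch(
        x,
        fs=sampling_rate,
        window=params.window,
        nperseg=nperseg,
        noverlap=int(nperseg * params.overlap_fraction),
        detrend="constant",
        scaling="density",
    )
    return PsdEstimate(frequencies=freqs, density=density, params=params)


def band_summary(psd: PsdEstimate) -> BandSummary:
    """20%/80% cumulative-energy frequencies and the spectral centroid.

    Each frequency bin carries the energy ``density * bin width``; f_q is
    the first bin frequency at which the cumulative energy reaches a
    fraction q of the total, so a spectrum concentrated in one bin gets a
    zero-width band at that bin.  The central frequency is the
    density-weighted mean frequency.
    """
    f, S = psd.frequencies, psd.density
    mass = S * np.gradient(f)
    cum = np.cumsum(mass)
    total = cum[-1]
    if total <= 0:
        raise DegenerateImfError("zero-energy spectrum")
    f2 = float(f[np.searchsorted(cum, 0.2 * total)])
    f8 = float(f[np.searchsorted(cum, 0.8 * total)])
    centroid = float(np.sum(f * mass) / total)
    return BandSummary(f2=f2, f8=f8, central_frequency=centroid)


def mode_mixing_pair(band_i: BandSummary, band_j: BandSummary) -> float:
    """Overlap of two energy bands relative to the narrower band.

    Nested bands score exactly 1, disjoint bands exactly 0.  If both bands
    have zero width the score is defined as 0 (with a warning).
    """
    lo = max(band_i.f2, band_j.f2)
    hi = min(band_i.f8, band_j.f8)
    intersection = max(0.0, hi - lo)
    denom = min(band_i.width, band_j.width)
    if denom <= 0:
        if band_i.width <= 0 and band_j.width <= 0:
            warnings.warn("both bands have zero width; mixing defined as 0", stacklevel=2)
        return 0.0
    return min(1.0, intersection / denom)


def channel_mode_mixing(
    bands: Sequence[BandSummary], aggregate_rule: Literal["mean", "sum"] = "mean"
) -> MixingResult:
    """Aggregate adjacent-pair mixing scores for one channel's IMF sequence."""
    if len(bands) < 2:
        raise UndefinedMetricError("mode mixing needs at least 2 retained IMFs")
    pairwise = np.array(
        [mode_mixing_pair(bands[i], bands[i + 1]) for i in range(len(bands) - 1)]
    )
    agg = float(pairwise.sum() if aggregate_rule == "sum" else pairwise.mean())
    return MixingResult(pairwise=pairwise, aggregate=agg, aggregate_rule=aggregate_rule)


def _psd_vector(imf: np.ndarray, sampling_rate: float, params: PsdParams) -> np.ndarray | None:
    try:
        norm = normalize_imf(imf)
    except DegenerateImfError:
        return None
    return estimate_psd(norm, sampling_rate, params).density


def mode_alignment(
    per_channel_imfs: Sequence[np.ndarray],
    sampling_rate: float,
    psd_params: PsdParams | None = None,
) -> AlignmentMatrix:
    """Cross-channel spectral alignment of same-indexed IMFs.

    Parameters
    ----------
    per_channel_imfs : sequence of (M_j, T) arrays
        One IMF stack per channel.  The compared index range is truncated to
        the smallest stack (relevant for channel-wise methods such as EEMD).
    sampling_rate : float
        Hz, shared by all channels.

    Entry c(i, j) is the mean Pearson correlation between channel j's IMF-i
    PSD and every other channel's IMF-i PSD; degenerate (zero-variance) IMFs
    are excluded and rows with fewer than two usable channels skipped.
    """
    psd_params = psd_params or PsdParams()
    J = len(per_channel_imfs)
    if J < 2:
        raise InvalidInputError("alignment needs at least 2 channels")
    I = min(stack.shape[0] for stack in per_channel_imfs)
    if I == 0:
        raise UndefinedMetricError("no IMFs to align")
    values = np.full((I, J), np.nan)
    for i in range(I):
        psds = [_psd_vector(per_channel_imfs[j][i], sampling_rate, psd_params) for j in range(J)]
        usable = [j for j, p in enumerate(psds) if p is not None]
        if len(usable) < 2:
            continue
        mat = np.vstack([psds[j] for j in usable])
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(mat)
        for pos, j in enumerate(usable):
            others = np.delete(corr[pos], pos)
            values[i, j] = float(np.nanmean(others))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_means = np.nanmean(values, axis=1)
        scalar = float(np.nanmean(row_means))
    return AlignmentMatrix(values=values, row_means=row_means, scalar_summary=scalar)


def filter_low_frequency_imfs(
    imfs: np.ndarray,
    sampling_rate: float,
    cutoff: float = 20.0,
    psd_params: PsdParams | None = None,
    measure: Literal["centroid", "peak"] = "centroid",
) -> tuple[list[int], np.ndarray]:
    """Drop IMFs whose central frequency is below the cutoff.

    Surface EMG energy is concentrated above ~20 Hz; slower IMFs mostly carry
    baseline wander and are synthesised into one remainder trace so that the
    regrouped components still sum to the original channel.

    Parameters
    ----------
    imfs : (M, T) array
        One channel's ordered IMF stack.
    measure : {"centroid", "peak"}
        How the central frequency is measured: spectral centroid (default)
        or the peak-density frequency.

    Returns
    -------
    (retained_indices, remainder) where ``remainder`` is the element-wise sum
    of the excluded IMFs (zeros if none were excluded).
    """
    imfs = np.asarray(imfs, dtype=np.float64)
    if imfs.ndim != 2 or imfs.shape[0] == 0:
        raise InvalidInputError("need a non-empty (M, T) IMF stack")
    psd_params = psd_params or PsdParams()
    retained: list[int] = []
    remainder = np.zeros(imfs.shape[1])
    for m in range(imfs.shape[0]):
        try:
            psd = estimate_psd(normalize_imf(imfs[m]), sampling_rate, psd_params)
            if measure == "peak":
                fc = float(psd.frequencies[np.argmax(psd.density)])
            else:
                fc = band_summary(psd).central_frequency
        except DegenerateImfError:
            fc = 0.0
        if fc >= cutoff:
            retained.append(m)
        else:
            remainder += imfs[m]
    if not retained:
        warnings.warn("all IMFs fall below the cutoff; nothing retained", stacklevel=2)
    return retained, remainder


def imf_count_table(counts: dict[str, dict[str, Sequence[int]]]) -> pd.DataFrame:
    """Mean ± sample-STD table of IMF counts.

    ``counts[method][channel]`` is the list of per-recording IMF counts for
    that cell.  Returns a DataFrame indexed by method with one column per
    channel holding ``(mean, std)`` tuples alongside a formatted string.
    """
    rows = {}
    for method, by_channel in counts.items():
        row = {}
        for channel, values in by_channel.items():
            arr = np.asarray(list(values), dtype=np.float64)
            mean = float(arr.mean())
            std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            row[channel] = f"{mean:.2f} ± {std:.2f}"
        rows[method] = row
    return pd.DataFrame(rows).T
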