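"""Delimited-text I/O for recordings, decompositions, and direction sets.

Recordings travel as CSV with a header of channel names and one row per
sample; the sampling rate is supplied out of band (flag or sidecar JSON).
Decompositions are written one file per channel with columns
``imf1..imfM,residual``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import InvalidInputError
from .memd import DirectionSet, MultichannelRecording, MultivariateDecomposition
from .sift import Decomposition

__all__ = [
    "read_recording",
    "write_recording",
    "write_decomposition",
    "read_imf_stack",
    "write_direction_set",
]


def read_recording(path, sampling_rate: float | None = None) -> MultichannelRecording:
    """Read a multichannel recording from delimited text.

    If ``sampling_rate`` is omitted, a sidecar ``<path>.json`` with a
    ``sampling_rate`` key is consulted.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if sampling_rate is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise InvalidInputError(
                f"no sampling rate given and no sidecar {sidecar.name} found"
            )
        sampling_rate = float(json.loads(sidecar.read_text())["sampling_rate"])
    return MultichannelRecording(
        samples=df.to_numpy(dtype=np.float64),
        sampling_rate=sampling_rate,
        channel_names=tuple(str(c) for c in df.columns),
    )


def write_recording(recording: MultichannelRecording, path, sidecar: dict | None = None) -> None:
    """Write a recording as CSV plus a sidecar JSON with the sampling rate."""
    path = Path(path)
    pd.DataFrame(recording.samples, columns=list(recording.channel_names)).to_csv(
        path, index=False
    )
    meta = {"sampling_rate": recording.sampling_rate}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def write_decomposition(
    decomp: Decomposition | MultivariateDecomposition, outdir, prefix: str = "imfs"
) -> list[str]:
    """Write IMF stacks as ``<prefix>_<channel>.csv`` (imf1..imfM,residual)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if isinstance(decomp, MultivariateDecomposition):
        for j, name in enumerate(decomp.channel_names):
            stack = decomp.channel_imfs(j)
            df = pd.DataFrame(
                {f"imf{m + 1}": stack[m] for m in range(stack.shape[0])}
            )
            df["residual"] = decomp.residual[:, j]
            p = outdir / f"{prefix}_{name}.csv"
            df.to_csv(p, index=False)
            written.append(str(p))
    else:
        df = pd.DataFrame({f"imf{m + 1}": decomp.imfs[m] for m in range(decomp.n_imfs)})
        df["residual"] = decomp.residual
        p = outdir / f"{prefix}.csv"
        df.to_csv(p, index=False)
        written.append(str(p))
    return written


def read_imf_stack(path) -> tuple[np.ndarray, np.ndarray]:
    """Read one channel's ``(imfs, residual)`` back from a decomposition CSV."""
    df = pd.read_csv(path)
    if "residual" not in df.columns:
        raise InvalidInputError("decomposition file lacks a 'residual' column")
    imf_cols = [c for c in df.columns if c.startswith("imf")]
    imfs = df[imf_cols].to_numpy(dtype=np.float64).T
    return imfs, df["residual"].to_numpy(dtype=np.float64)


def write_direction_set(directions: DirectionSet, path) -> None:
    """Export a direction set as delimited text for audit."""
    np.savetxt(path, directions.vectors, delimiter=",", header=directions.generator_tag)
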