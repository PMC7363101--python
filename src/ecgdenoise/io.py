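"""Plain-text signal and decomposition I/O.

Signals travel as single-column CSV/text (one sample per line); the
sampling rate is supplied out of band.  Decompositions are written as CSV
with columns IMF1..IMFK, residual.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .emd import Decomposition, Signal


def read_signal(path: str | Path, fs: float) -> Signal:
    """Read a one-sample-per-line text/CSV file into a Signal."""
    samples = np.loadtxt(path, delimiter=",", ndmin=1)
    if samples.ndim > 1:
        samples = samples[:, 0]
    return Signal(samples=samples, fs=fs)


def write_signal(path: str | Path, signal: Signal | np.ndarray) -> None:
    samples = signal.samples if isinstance(signal, Signal) else np.asarray(signal)
    np.savetxt(path, samples, fmt="%.10g")


def write_decomposition(path: str | Path, decomposition: Decomposition) -> None:
    """CSV with one column per IMF plus the residual."""
    header = [f"IMF{k + 1}" for k in range(decomposition.K)] + ["residual"]
    table = np.column_stack([*decomposition.imfs, decomposition.residual])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(np.round(table, 10).tolist())


def read_decomposition(path: str | Path) -> Decomposition:
    table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return Decomposition(imfs=table[:, :-1].T, residual=table[:, -1])
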