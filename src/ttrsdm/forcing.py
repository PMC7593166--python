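"""Canonical per-record forcing matrix.

Every model in the package consumes the environment as a 2-D float array with
one row per record (grid cell or occurrence point) and 49 columns:

* columns 0..11   — daytime air temperature per month (degC)
* columns 12..23  — soil temperature per month (degC)
* columns 24..35  — soil moisture per month (fraction of capacity)
* columns 36..47  — solar radiation per month (MJ m-2 day-1)
* column 48       — soil nitrogen (g m-2; constant over months)

Daytime temperature is taken as ``(tmax + tmean) / 2`` and soil temperature
as ``tmean``.
"""

from __future__ import annotations

import numpy as np

N_MONTHS = 12
N_FORCING_COLS = 4 * N_MONTHS + 1

COLS = {
    "t_day": slice(0, 12),
    "t_soil": slice(12, 24),
    "moisture": slice(24, 36),
    "radiation": slice(36, 48),
    "nitrogen": slice(48, 49),
}


def forcing_matrix(tmean, tmax, moisture, radiation, nitrogen) -> np.ndarray:
    """Assemble the canonical matrix from per-cell monthly fields.

    Parameters are arrays of shape ``(n, 12)`` except ``nitrogen`` which is
    ``(n,)``.
    """
    tmean = np.asarray(tmean, float)
    n = tmean.shape[0]
    out = np.empty((n, N_FORCING_COLS))
    out[:, COLS["t_day"]] = (np.asarray(tmax, float) + tmean) / 2.0
    out[:, COLS["t_soil"]] = tmean
    out[:, COLS["moisture"]] = np.asarray(moisture, float)
    out[:, COLS["radiation"]] = np.asarray(radiation, float)
    out[:, 48] = np.asarray(nitrogen, float)
    return out


def validate_forcing(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_FORCING_COLS:
        raise ValueError(
            f"forcing matrix must have {N_FORCING_COLS} columns, got {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("forcing matrix contains non-finite values")
    W = X[:, COLS["moisture"]]
    if W.min() < 0 or W.max() > 1:
        raise ValueError("soil moisture must lie in [0, 1]")
    return X


def unique_forcing(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deduplicate rows; returns (unique rows, inverse index).

    Records sharing a grid cell share one steady-state simulation.
    """
    return np.unique(np.asarray(X, float), axis=0, return_inverse=True)
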