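"""Feature extraction and scaling for e-nose sniffs and acoustic taps.

The e-nose pathway: per sniff cycle, the baseline resistance S0 of each
channel is estimated as the mean over the baseline-purge window and the
peak draw resistance Smax as the maximum over the sample-draw window; the
fractional response (Smax - S0) / S0 is the dimensionless feature that
compensates channel-to-channel gain differences and slow drift.  The
first sniff of each fruit is discarded (residual volatiles from the
previous sample contaminate it).

The acoustic pathway: a firmness index FI = M^(2/3) * f0^2 / scaling is
computed from a fruit's resonance frequency f0 after a tap and its mass
M; FI and the instrument-supplied alternative firmness index AFI are
averaged over locations and repeats per fruit.

Both blocks are autoscaled column-wise (zero mean, unit sd) before any
fusion or modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from aromafuse.synthetic import SniffTrace


class InvalidBaselineError(ValueError):
    """Baseline resistance is non-positive, so the fractional response is undefined."""


@dataclass
class ScalingRecord:
    """Per-column autoscaling statistics, reusable on held-out data."""

    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    block: str = ""

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in df.columns]
        if missing:
            raise ValueError(f"columns missing from input: {missing}")
        return (df[self.columns] - self.means) / self.sds

    def inverse_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return df[self.columns] * self.sds + self.means


def fractional_response(s0: np.ndarray, smax: np.ndarray) -> np.ndarray:
    """Baseline-corrected sensor response (Smax - S0) / S0, element-wise.

    Dimensionless and invariant to rescaling both readings by the same
    positive gain.
    """
    s0 = np.asarray(s0, dtype=float)
    smax = np.asarray(smax, dtype=float)
    if s0.shape != smax.shape:
        raise ValueError(f"shape mismatch: S0 {s0.shape} vs Smax {smax.shape}")
    if np.any(s0 <= 0):
        raise InvalidBaselineError("baseline resistance S0 must be positive")
    return (smax - s0) / s0


def _window_mask(time: np.ndarray, window: tuple[float, float],
                 closed_right: bool = False) -> np.ndarray:
    lo, hi = window
    if closed_right:
        return (time >= lo) & (time <= hi)
    return (time >= lo) & (time < hi)


def extract_baseline(trace: SniffTrace) -> np.ndarray:
    """Per-channel baseline S0: mean resistance over the baseline-purge window."""
    mask = _window_mask(trace.time, trace.baseline_window)
    if mask.sum() < 2:
        raise ValueError("baseline window contains fewer than 2 samples")
    return trace.resistance[mask].mean(axis=0)


def extract_smax(trace: SniffTrace) -> np.ndarray:
    """Per-channel peak resistance over the sample-draw window."""
    mask = _window_mask(trace.time, trace.draw_window, closed_right=True)
    if mask.sum() < 2:
        raise ValueError("draw window contains fewer than 2 samples")
    return trace.resistance[mask].max(axis=0)


def trace_fractional_response(trace: SniffTrace) -> np.ndarray:
    """Fractional-response smellprint of one sniff cycle."""
    return fractional_response(extract_baseline(trace), extract_smax(trace))


def discard_first_sniff(df: pd.DataFrame, fruit_col: str = "fruit_id",
                        sniff_col: str = "sniff_index") -> pd.DataFrame:
    """Drop every fruit's first sniff (``sniff_index == 1``).

    A fruit contributing only a single sniff is dropped entirely with a
    warning, since nothing of it would survive.
    """
    for col in (fruit_col, sniff_col):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    counts = df.groupby(fruit_col)[sniff_col].size()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        warnings.warn(
            f"dropping {len(singletons)} fruit(s) with a single sniff: "
            f"{singletons[:5]}",
            stacklevel=2,
        )
        df = df[~df[fruit_col].isin(singletons)]
    return df[df[sniff_col] != 1].reset_index(drop=True)


def firmness_index(f0: float | np.ndarray, mass: float | np.ndarray,
                   scaling: float = 1.0) -> float | np.ndarray:
    """Acoustic firmness index M^(2/3) * f0^2 / scaling.

    f0 is the dominant resonance frequency (Hz) of the fruit after a tap
    and ``mass`` its mass (g); the scaling factor is an instrument
    constant (dimensionless here, default 1) — downstream use is scale
    invariant after autoscaling.
    """
    f0 = np.asarray(f0, dtype=float)
    mass = np.asarray(mass, dtype=float)
    if np.any(f0 <= 0) or np.any(mass <= 0) or scaling <= 0:
        raise ValueError("f0, mass and scaling must all be positive")
    out = mass ** (2.0 / 3.0) * f0 ** 2 / scaling
    return float(out) if out.ndim == 0 else out


def average_acoustic(records: pd.DataFrame, fruit_col: str = "fruit_id") -> pd.DataFrame:
    """Per-fruit mean FI and AFI over all location x repeat measurements."""
    if records.empty:
        raise ValueError("no acoustic records")
    for col in (fruit_col, "FI", "AFI"):
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
    return records.groupby(fruit_col, as_index=False)[["FI", "AFI"]].mean()


def autoscale(
    matrix: pd.DataFrame,
    fit_stats: ScalingRecord | None = None,
    block: str = "",
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Column-wise scaling to zero mean and unit standard deviation.

    Without ``fit_stats`` the statistics are estimated from the data
    (sd with the n-1 denominator); with ``fit_stats`` the supplied
    statistics are applied, as required when projecting held-out rows.
    Zero-variance columns cannot be scaled and are dropped with a warning.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix, dtype=float))
        matrix.columns = [str(c) for c in matrix.columns]
    if fit_stats is not None:
        return fit_stats.transform(matrix), fit_stats
    if len(matrix) < 2:
        raise ValueError("autoscale needs at least 2 rows")
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    dead = sds[sds == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance column(s): {dead}", stacklevel=2)
        matrix = matrix.drop(columns=dead)
        means = means.drop(dead)
        sds = sds.drop(dead)
    record = ScalingRecord(
        columns=list(matrix.columns),
        means=means.to_numpy(),
        sds=sds.to_numpy(),
        block=block,
    )
    return (matrix - means) / sds, record
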