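"""Normative measure database with interquartile-range outlier fencing.

For each of the six scalar measures (three components x amplitude,
latency) the database stores mean, SD, min, max and the "best" value
after a single pass of 1.5 x IQR fencing: values above Q3 + 1.5*IQR or
below Q1 - 1.5*IQR are excluded before any statistic is computed.
Quartiles use linear interpolation between order statistics.

"Best" encodes the clinically ideal direction: the shortest latency for
every component, the most negative amplitude for N100/N400 (signed
convention) and the most positive amplitude for P300.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .detect import MEASURE_IDS

#: measure id -> which kept extreme is "best" ("min" or "max")
BEST_DIRECTION = {
    "N100_amplitude": "min",
    "N100_latency": "min",
    "P300_amplitude": "max",
    "P300_latency": "min",
    "N400_amplitude": "min",
    "N400_latency": "min",
}


@dataclass
class NormativeStats:
    """Post-fencing summary of one measure's normative distribution."""

    measure_id: str
    mu: float
    sigma: float
    min: float
    max: float
    best: float
    n_kept: int
    n_removed: int

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0 (degenerate normative sample)")
        if not (self.min <= self.mu <= self.max):
            raise ValueError("mean outside [min, max]")
        if self.best not in (self.min, self.max):
            raise ValueError("best must equal min or max")


def iqr_fence(values) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass 1.5 x IQR outlier exclusion.

    Returns (kept, removed) preserving input order within each. Quartiles
    by linear interpolation; with IQR = 0 the fences collapse onto the
    common quartile value and nothing strictly outside survives.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be 1-D")
    if arr.size < 4:
        raise ValueError("need at least 4 values to estimate quartiles")
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (arr >= lo) & (arr <= hi)
    return arr[keep], arr[~keep]


def normative_stats(measure_id: str, values) -> NormativeStats:
    """Fence one measure array, then summarize the kept values."""
    if measure_id not in BEST_DIRECTION:
        raise KeyError(f"unknown measure id {measure_id!r}")
    kept, removed = iqr_fence(values)
    if kept.size < 2:
        raise ValueError("fewer than 2 values kept; cannot form normative stats")
    mn, mx = float(kept.min()), float(kept.max())
    best = mn if BEST_DIRECTION[measure_id] == "min" else mx
    return NormativeStats(
        measure_id=measure_id,
        mu=float(kept.mean()),
        sigma=float(kept.std(ddof=1)),
        min=mn,
        max=mx,
        best=best,
        n_kept=int(kept.size),
        n_removed=int(removed.size),
    )


def build_normative(measure_arrays: dict[str, "np.ndarray"], source: str = "synthetic") -> dict:
    """Build the full database from per-measure value arrays.

    ``measure_arrays`` must be keyed by the six measure ids. Returns
    ``{"source": ..., "measures": {id: NormativeStats}}``.
    """
    missing = set(MEASURE_IDS) - set(measure_arrays)
    if missing:
        raise KeyError(f"missing measure arrays: {sorted(missing)}")
    measures = {mid: normative_stats(mid, measure_arrays[mid]) for mid in MEASURE_IDS}
    return {"source": source, "measures": measures}


def save_normative(db: dict, path: str | Path) -> None:
    payload = {
        "source": db["source"],
        "measures": {mid: asdict(s) for mid, s in db["measures"].items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_normative(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {
        "source": payload["source"],
        "measures": {mid: NormativeStats(**s) for mid, s in payload["measures"].items()},
    }
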