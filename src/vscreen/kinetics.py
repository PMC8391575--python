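"""Fluorometric enzyme-inhibition kinetics.

In the linear kinetic regime, product fluorescence grows linearly with
time; the reaction rate is the slope of RFU vs time, and inhibition is
expressed relative to the uninhibited enzyme control (EC)::

    % relative inhibition = (slope_EC - slope_sample) / slope_EC * 100

The default slope is the two-point estimate (dRFU / dT over the first and
last reading, matching the usual 0/15-min protocol); a least-squares
regression slope is available for noisy multi-read traces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["slope", "relative_inhibition", "dose_response"]


def slope(times, rfus, method: str = "two-point") -> float:
    """Reaction rate in RFU/min from a kinetic trace.

    ``two-point`` uses the first and last reading; ``regression`` fits all
    readings by least squares.  Times must be strictly increasing.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(rfus, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("need at least two (time, RFU) readings")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if method == "two-point":
        return float((y[-1] - y[0]) / (t[-1] - t[0]))
    if method == "regression":
        return float(np.polyfit(t, y, 1)[0])
    raise ValueError("method must be 'two-point' or 'regression'")


def relative_inhibition(sample_slope: float, ec_slope: float) -> float:
    """Percent inhibition of a sample relative to the enzyme control.

    Negative values (activation) are reported as-is, not clipped.
    """
    if ec_slope == 0:
        raise ValueError("enzyme-control slope of zero: relative inhibition undefined")
    return (ec_slope - sample_slope) / ec_slope * 100.0


def dose_response(plate: pd.DataFrame, method: str = "two-point") -> pd.DataFrame:
    """Per-(compound, concentration) mean percent inhibition with SEM.

    Expects a long-format plate table with columns ``well``, ``role``
    ('enzyme-control', 'inhibitor-control' or 'test'), ``compound``,
    ``concentration_uM``, ``time_min``, ``rfu``.  The EC slope is the mean
    over enzyme-control wells; SEM = SD / sqrt(n) over replicate wells.
    Inhibitor-control wells (reference inhibitor) are summarized the same
    way and appear under their compound name.
    """
    required = {"well", "role", "time_min", "rfu"}
    if missing := required - set(plate.columns):
        raise ValueError(f"plate table missing columns: {sorted(missing)}")

    def well_slope(grp):
        grp = grp.sort_values("time_min")
        return slope(grp["time_min"], grp["rfu"], method=method)

    slopes = (
        plate.groupby(["well", "role"], sort=False)
        .apply(well_slope, include_groups=False)
        .rename("slope")
        .reset_index()
    )
    meta_cols = [c for c in ("compound", "concentration_uM") if c in plate.columns]
    meta = plate.groupby("well", sort=False)[meta_cols].first() if meta_cols else None

    ec = slopes[slopes["role"] == "enzyme-control"]
    if len(ec) == 0:
        raise ValueError("no enzyme-control wells in the plate")
    ec_slope = float(ec["slope"].mean())

    rows = []
    samples = slopes[slopes["role"] != "enzyme-control"]
    if meta is not None and len(samples):
        samples = samples.join(meta, on="well")
    if len(samples):
        group_cols = [c for c in ("compound", "concentration_uM", "role") if c in samples.columns]
        for key, grp in samples.groupby(group_cols, dropna=False, sort=False):
            inh = np.array([relative_inhibition(s, ec_slope) for s in grp["slope"]])
            sem = float(inh.std(ddof=1) / np.sqrt(len(inh))) if len(inh) > 1 else 0.0
            rec = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
            rec.update(
                {
                    "n_replicates": len(inh),
                    "mean_percent_inhibition": float(inh.mean()),
                    "sem_percent_inhibition": sem,
                }
            )
            rows.append(rec)
    columns = [
        "compound",
        "concentration_uM",
        "role",
        "n_replicates",
        "mean_percent_inhibition",
        "sem_percent_inhibition",
    ]
    return pd.DataFrame(rows, columns=columns if rows else columns[:0])
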