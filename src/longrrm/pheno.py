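"""Phenotype table cleaning: implausible-value flagging and inclusion filters.

Works on long-format tables with one row per measurement and columns
``iid, sex, age, source`` plus at least one of ``bmi`` or ``weight``/``height``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["derive_log_bmi", "flag_implausible", "apply_inclusion_filters"]

REQUIRED_COLUMNS = ("iid", "age")


def derive_log_bmi(table: pd.DataFrame) -> pd.DataFrame:
    """Fill ``bmi`` (= weight / height^2 where absent) and ``log_bmi`` columns.

    Raises a row-level error naming the offending record for non-positive
    weight, height or bmi.
    """
    out = table.copy()
    if "bmi" not in out.columns:
        out["bmi"] = np.nan
    bmi = out["bmi"].to_numpy(dtype=float)
    need = ~np.isfinite(bmi)
    if need.any():
        if "weight" not in out.columns or "height" not in out.columns:
            raise ValueError("rows lack bmi and no weight/height columns present")
        w = out["weight"].to_numpy(dtype=float)
        h = out["height"].to_numpy(dtype=float)
        bad = need & (~np.isfinite(w) | ~np.isfinite(h) | (w <= 0) | (h <= 0))
        if bad.any():
            r = out.index[bad][0]
            raise ValueError(
                f"invalid weight/height for iid={out.loc[r, 'iid']} at age={out.loc[r, 'age']}"
            )
        bmi[need] = w[need] / h[need] ** 2
    if np.any(bmi <= 0):
        r = out.index[bmi <= 0][0]
        raise ValueError(
            f"non-positive bmi for iid={out.loc[r, 'iid']} at age={out.loc[r, 'age']}"
        )
    out["bmi"] = bmi
    out["log_bmi"] = np.log(bmi)
    return out


def flag_implausible(
    table: pd.DataFrame,
    window: int = 5,
    z_threshold: float = 4.0,
    value_col: str = "log_bmi",
    min_sigma: float = 0.05,
) -> np.ndarray:
    """Flag measurements far from an age-weighted average of the rest.

    For each measurement the reference is an exponentially weighted average of
    the individual's *other* unflagged measurements within the ``window``
    nearest ages (weights exp(-|age difference|)).  The residuals per
    individual are scaled by a robust SD (1.4826 * MAD, floored at
    ``min_sigma``); the worst measurement exceeding ``z_threshold`` robust SDs
    is flagged and references are recomputed without it, until no further
    exceedance (iterative peeling avoids a gross outlier swamping its
    neighbours' references).  Individuals with a single measurement are never
    flagged.

    Returns a boolean vector aligned with ``table`` rows.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    flags = np.zeros(len(table), dtype=bool)
    pos = {idx: i for i, idx in enumerate(table.index)}
    for _, grp in table.groupby("iid", sort=False):
        if len(grp) < 2:
            continue
        ages = grp["age"].to_numpy(dtype=float)
        vals = grp[value_col].to_numpy(dtype=float)
        m = len(grp)
        excluded = np.zeros(m, dtype=bool)
        while excluded.sum() < m - 1:
            resid = np.full(m, np.nan)
            for j in np.nonzero(~excluded)[0]:
                others = np.nonzero(~excluded)[0]
                others = others[others != j]
                dist = np.abs(ages[others] - ages[j])
                keep = others[np.argsort(dist, kind="stable")[:window]]
                w = np.exp(-np.abs(ages[keep] - ages[j]))
                resid[j] = vals[j] - np.average(vals[keep], weights=w)
            live = resid[~excluded]
            mad = np.median(np.abs(live - np.median(live)))
            sigma = max(1.4826 * mad, min_sigma)
            z = np.abs(resid) / sigma
            worst = np.nanargmax(z)
            if z[worst] > z_threshold:
                excluded[worst] = True
            else:
                break
        for j, idx in enumerate(grp.index):
            flags[pos[idx]] = excluded[j]
    return flags


def apply_inclusion_filters(
    table: pd.DataFrame,
    min_age: float = 1.0,
    max_age: float = 18.0,
    min_measurements: int = 4,
):
    """Restrict to the age window, then drop under-measured individuals.

    Rows outside [min_age, max_age] are removed first; individuals left with
    fewer than ``min_measurements`` rows are then removed entirely.  Returns
    ``(filtered_table, report)`` where the report's row counts sum exactly to
    the number of rows removed.
    """
    if min_age >= max_age:
        raise ValueError("min_age must be strictly below max_age")
    if len(table) == 0:
        raise ValueError("empty phenotype table")
    n_in = len(table)
    in_window = (table["age"] >= min_age) & (table["age"] <= max_age)
    windowed = table[in_window]
    rows_age = int(n_in - len(windowed))

    counts = windowed.groupby("iid")["age"].transform("size")
    kept = windowed[counts >= min_measurements]
    rows_minmeas = int(len(windowed) - len(kept))
    indiv_removed = int(
        windowed.loc[counts < min_measurements, "iid"].nunique()
    )

    report = {
        "rows_in": n_in,
        "rows_out": int(len(kept)),
        "rows_removed_age_window": rows_age,
        "rows_removed_min_measurements": rows_minmeas,
        "individuals_removed_min_measurements": indiv_removed,
        "individuals_out": int(kept["iid"].nunique()),
    }
    return kept.copy(), report
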