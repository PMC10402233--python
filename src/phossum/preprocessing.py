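"""Normalization, trial averaging, outlier removal and design-table assembly.

The analysis pipeline transforms per-drawing shape descriptors into a tidy
design table, in this order:

1. *Standard-pulse normalization*: each participant's descriptors are
   expressed as multiples of the mean descriptor that participant produced
   under the standard pulse train (2x threshold amplitude, 20 Hz), pooled
   over all of their recorded electrodes.  This absorbs per-participant
   drawing bias and variance.
2. *Trial averaging*: descriptors (and phosphene counts) are averaged across
   trials of the same (participant, electrode(s), amplitude, frequency)
   combination, eliminating repeated measures.
3. *Power transform*: area is taken to the 1/3 power, perimeter and the axis
   lengths to the 1/2 power, to keep regression residuals normal.
4. *Outlier removal*: rows whose transformed descriptors fall more than
   2.5 SD from their within-participant mean are dropped (single-electrode
   analyses only).
5. *Predictor standardization*: z-scoring across all participants.

SDs and z-scores use the population convention (ddof=0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DESCRIPTORS",
    "POWER_EXPONENTS",
    "normalize_descriptors",
    "average_trials",
    "remove_outliers",
    "power_transform",
    "zscore",
    "assemble_design_table",
]

DESCRIPTORS = ["area", "perimeter", "major_axis_length", "minor_axis_length"]

#: 1/n power-transform exponents per descriptor kind.
POWER_EXPONENTS = {
    "area": 1.0 / 3.0,
    "perimeter": 1.0 / 2.0,
    "major_axis_length": 1.0 / 2.0,
    "minor_axis_length": 1.0 / 2.0,
}

#: Standard pulse train used as each participant's normalization reference.
STANDARD_PULSE = {"amplitude": 2.0, "frequency": 20.0}

KEY_COLS = ["participant", "electrodes", "amplitude", "frequency"]


class MissingStandardPulseError(ValueError):
    """A participant has no standard-pulse drawings to normalize against."""


def _is_standard(df: pd.DataFrame, standard: dict) -> pd.Series:
    single = df["electrodes"].astype(str).str.count(r"\+") == 0 \
        if "electrodes" in df else pd.Series(True, index=df.index)
    return (
        np.isclose(df["amplitude"], standard["amplitude"])
        & np.isclose(df["frequency"], standard["frequency"])
        & single
    )


def normalize_descriptors(
    records: pd.DataFrame,
    standard: dict | None = None,
    descriptors: list[str] = DESCRIPTORS,
) -> pd.DataFrame:
    """Express descriptors as multiples of the participant's standard-pulse mean.

    ``records`` holds one row per drawing with at least ``participant``,
    ``amplitude`` (multiples of threshold), ``frequency`` (Hz) and the four
    descriptor columns.  The reference is the mean descriptor over all of the
    participant's single-electrode standard-pulse drawings, across all their
    electrodes.  Raises :class:`MissingStandardPulseError` naming any
    participant without standard-pulse drawings.
    """
    standard = STANDARD_PULSE if standard is None else standard
    df = records.copy()
    is_std = _is_standard(df, standard)
    missing = sorted(
        set(df["participant"].unique())
        - set(df.loc[is_std, "participant"].unique())
    )
    if missing:
        raise MissingStandardPulseError(
            f"participants without standard-pulse drawings: {missing}"
        )
    ref = df[is_std].groupby("participant")[descriptors].mean()
    for col in descriptors:
        denom = df["participant"].map(ref[col])
        if (denom <= 0).any():
            bad = sorted(df.loc[denom <= 0, "participant"].unique())
            raise MissingStandardPulseError(
                f"standard-pulse mean {col} is zero for participants {bad}"
            )
        df[col] = df[col] / denom
    return df


def average_trials(
    records: pd.DataFrame,
    descriptors: list[str] = DESCRIPTORS,
    key_cols: list[str] = KEY_COLS,
) -> pd.DataFrame:
    """Average descriptors and phosphene counts over trials of the same key.

    One output row per (participant, electrode-or-pair, amplitude,
    frequency); ``n_trials`` records how many drawings entered each mean.
    """
    value_cols = [c for c in descriptors + ["number_of_phosphenes"]
                  if c in records.columns]
    grouped = records.groupby(key_cols, sort=True, dropna=False)
    out = grouped[value_cols].mean()
    out["n_trials"] = grouped.size()
    return out.reset_index()


def remove_outliers(
    df: pd.DataFrame,
    cols: list[str],
    k: float = 2.5,
    group: str | list[str] | None = "participant",
) -> tuple[pd.DataFrame, pd.Series]:
    """Drop rows with any |z| > k among ``cols`` within each group.

    z-scores use the population SD (ddof=0) of each group; zero-variance
    columns never flag anything.  Returns the kept rows and a boolean mask
    aligned with ``df`` (True = kept) so removals can be logged.
    """
    if len(df) < 3:
        raise ValueError("outlier removal needs at least 3 rows")
    if group is None:
        groups = [(None, df)]
    else:
        groups = df.groupby(group)
    keep = pd.Series(True, index=df.index)
    for _, g in groups:
        vals = g[cols].to_numpy(dtype=float)
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs(vals - mu) / sd
        z[:, sd == 0] = 0.0
        keep.loc[g.index] = ~(z > k).any(axis=1)
    return df[keep], keep


def power_transform(value, kind: str):
    """1/n power transform for a descriptor kind (n=3 area, n=2 otherwise)."""
    if kind not in POWER_EXPONENTS:
        raise KeyError(f"unknown descriptor kind {kind!r}")
    arr = np.asarray(value, dtype=float)
    if (arr < 0).any():
        raise ValueError("descriptor values must be non-negative")
    out = arr ** POWER_EXPONENTS[kind]
    return float(out) if out.ndim == 0 else out


def zscore(values) -> np.ndarray:
    """Population z-score; raises on zero variance."""
    arr = np.asarray(values, dtype=float)
    sd = arr.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a constant column")
    return (arr - arr.mean()) / sd


def assemble_design_table(
    shape_rows: pd.DataFrame,
    distance_table: pd.DataFrame | None = None,
    predictors: list[str] | None = None,
    descriptors: list[str] = DESCRIPTORS,
    k_outlier: float = 2.5,
    remove_outliers_from: str = "single",
    standardize_after_outliers: bool = True,
) -> pd.DataFrame:
    """Build the tidy analysis table from trial-averaged shape rows.

    ``shape_rows`` is the output of :func:`average_trials` on normalized
    records, with an ``electrodes`` key of the form ``"B3"`` (single) or
    ``"B3+C5"`` (pair).  ``distance_table``, if given, is joined on
    (participant, electrodes) and may contribute predictor columns
    (``efd_um``, ``erd_um``, ``between_axon_um``, ``along_axon_um``).

    Steps: join, power-transform descriptors, within-participant 2.5-SD
    outlier removal (single-electrode rows only, mirroring the study's
    outcome), then z-score the requested predictors across all participants
    (after outlier removal by default, so removed rows do not influence
    scaling).  Unmatched join keys raise with the offending keys listed.
    """
    df = shape_rows.copy()
    dup = df.duplicated(subset=KEY_COLS)
    if dup.any():
        raise ValueError(f"repeated design keys: {df.loc[dup, KEY_COLS].values}")
    if distance_table is not None:
        merged = df.merge(
            distance_table, on=["participant", "electrodes"], how="left",
            indicator=True, validate="many_to_one",
        )
        joinable = [c for c in distance_table.columns
                    if c not in ("participant", "electrodes")]
        missing = merged["_merge"] == "left_only"
        needs = merged["electrodes"].astype(str).str.contains(r"\+")
        if (missing & needs).any():
            keys = merged.loc[missing & needs, ["participant", "electrodes"]]
            raise ValueError(f"no distances for keys: {keys.values.tolist()}")
        df = merged.drop(columns="_merge")
        del joinable
    df["is_paired"] = df["electrodes"].astype(str).str.contains(r"\+")

    for col in descriptors:
        df[col + "_t"] = power_transform(df[col].to_numpy(), col)
        if col + "_sum_single" in df.columns:
            df[col + "_sum_single_t"] = power_transform(
                df[col + "_sum_single"].to_numpy(), col
            )

    tcols = [c + "_t" for c in descriptors]
    if remove_outliers_from == "single":
        single = df[~df["is_paired"]]
        if len(single) >= 3:
            _, keep_single = remove_outliers(single, tcols, k=k_outlier)
            df = pd.concat([single[keep_single], df[df["is_paired"]]])
            df = df.sort_index()
    elif remove_outliers_from == "all":
        _, keep = remove_outliers(df, tcols, k=k_outlier)
        df = df[keep]
    elif remove_outliers_from != "none":
        raise ValueError("remove_outliers_from must be 'single', 'all' or 'none'")

    if predictors:
        if not standardize_after_outliers:
            raise NotImplementedError(
                "pre-outlier standardization is selectable only via "
                "calling zscore() before assembly"
            )
        for col in predictors:
            if col not in df.columns:
                raise KeyError(f"predictor column {col!r} missing")
            vals = df[col].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            z = np.full_like(vals, np.nan)
            sd = vals[ok].std(ddof=0)
            if sd == 0:
                raise ValueError(f"predictor {col!r} is constant")
            z[ok] = (vals[ok] - vals[ok].mean()) / sd
            df[col + "_z"] = z
    return df.reset_index(drop=True)
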