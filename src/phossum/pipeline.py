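"""End-to-end analysis pipeline.

Chains the stages: drawings -> validated phosphenes and shape descriptors ->
axonal distance tables -> normalized/averaged/transformed design tables ->
the regression battery (within-participant standardized OLS, across-
participant mixed models, no-intercept summation regression, and the
between- vs along-axon model comparison for phosphene counts).

The pipeline is deterministic: identical inputs produce byte-identical
design tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocessing as prep
from .drawing import extract_phosphenes, validate_drawing
from .geometry import AxonMapModel, electrode_fovea_distance
from .stats import (
    MixedShapeModel,
    ModelComparison,
    RegressionResult,
    StandardizedOLS,
    SummationRegression,
    compare_models,
)

__all__ = [
    "shapes_from_trials",
    "distance_table",
    "PipelineResult",
    "run_pipeline",
]


def shapes_from_trials(trials, close_radius: int = 1) -> pd.DataFrame:
    """Per-drawing shape descriptor rows from a list of trials.

    ``trials`` is an iterable of objects with ``drawing`` (a
    :class:`~phossum.drawing.Drawing`), ``participant``, ``electrodes``,
    ``amplitude``, ``frequency`` and ``trial`` attributes.  Drawings are
    validated (contour closing + hole filling), grouped by stimulus key so
    the small-region prevalence filter sees whole trial sets, and summarized
    into per-drawing descriptor totals and phosphene counts.
    """
    groups: dict[tuple, list] = {}
    for t in trials:
        key = (t.participant, t.electrodes, float(t.amplitude), float(t.frequency))
        groups.setdefault(key, []).append(t)

    rows = []
    for key in sorted(groups):
        ts = groups[key]
        validated = [validate_drawing(t.drawing, close_radius=close_radius)
                     for t in ts]
        extracted = extract_phosphenes(validated)
        for t, (_, sd) in zip(ts, extracted):
            rows.append(
                {
                    "participant": key[0],
                    "electrodes": key[1],
                    "amplitude": key[2],
                    "frequency": key[3],
                    "trial": t.trial,
                    "number_of_phosphenes": sd.number_of_phosphenes,
                    "area": sd.area,
                    "perimeter": sd.perimeter,
                    "major_axis_length": sd.major_axis_length,
                    "minor_axis_length": sd.minor_axis_length,
                }
            )
    return pd.DataFrame(rows)


def distance_table(
    layouts: dict,
    keys: pd.DataFrame,
    model: AxonMapModel | None = None,
    erd_um: dict | None = None,
) -> pd.DataFrame:
    """Neuroanatomical predictors per (participant, electrode-or-pair) key.

    Singles get their electrode-fovea distance; pairs additionally get the
    between-/along-axon decomposition, with the pair's EFD (and ERD, when
    provided per electrode) averaged over the two electrodes.
    """
    model = model or AxonMapModel()
    erd_um = erd_um or {}
    rows = []
    seen = set()
    for _, row in keys[["participant", "electrodes"]].drop_duplicates().iterrows():
        pid, key = row["participant"], str(row["electrodes"])
        if (pid, key) in seen:
            continue
        seen.add((pid, key))
        layout = layouts[pid]
        pos = layout.as_dict()
        out = {"participant": pid, "electrodes": key}
        names = key.split("+")
        if len(names) == 1:
            xy = pos[names[0]]
            out["efd_um"] = electrode_fovea_distance(xy)
            out["erd_um"] = float(erd_um.get((pid, names[0]), 0.0))
        else:
            e1, e2 = (np.asarray(pos[n]) for n in names)
            pdist = model.pair_distances(e1, e2, names=tuple(names))
            out["efd_um"] = 0.5 * (
                electrode_fovea_distance(e1) + electrode_fovea_distance(e2)
            )
            out["erd_um"] = 0.5 * (
                float(erd_um.get((pid, names[0]), 0.0))
                + float(erd_um.get((pid, names[1]), 0.0))
            )
            out["euclidean_um"] = pdist.euclidean
            out["between_axon_um"] = pdist.between_axon
            out["along_axon_um"] = pdist.along_axon
        rows.append(out)
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    """All tables and fits of one pipeline run."""

    shapes: pd.DataFrame
    design: pd.DataFrame
    single_fits: dict = field(default_factory=dict)
    mixed_fits: dict = field(default_factory=dict)
    summation_fits: dict = field(default_factory=dict)
    count_fit_between: RegressionResult | None = None
    count_fit_along: RegressionResult | None = None
    count_comparison: ModelComparison | None = None

    def summary(self) -> str:
        parts = []
        for label, fits in (("within-participant", self.single_fits),
                            ("mixed", self.mixed_fits),
                            ("summation", self.summation_fits)):
            for key, fit in fits.items():
                parts.append(f"[{label}] {key}\n{fit.summary()}")
        if self.count_comparison is not None:
            parts.append("[phosphene count: along (A) vs between (B)]\n"
                         + self.count_comparison.summary())
        return "\n\n".join(parts)


def _attach_sum_of_singles(avg: pd.DataFrame) -> pd.DataFrame:
    """For each paired row, add the sum of the matching single rows'
    descriptors (same participant, each electrode at the pair's amplitude
    and frequency)."""
    singles = avg[~avg["electrodes"].astype(str).str.contains(r"\+")]
    idx = singles.set_index(["participant", "electrodes", "amplitude",
                            "frequency"])
    out = avg.copy()
    for col in prep.DESCRIPTORS:
        out[col + "_sum_single"] = np.nan
    paired_mask = out["electrodes"].astype(str).str.contains(r"\+")
    for i in out.index[paired_mask]:
        pid = out.at[i, "participant"]
        amp = out.at[i, "amplitude"]
        freq = out.at[i, "frequency"]
        names = str(out.at[i, "electrodes"]).split("+")
        try:
            parts = [idx.loc[(pid, n, amp, freq)] for n in names]
        except KeyError:
            continue
        for col in prep.DESCRIPTORS:
            out.at[i, col + "_sum_single"] = float(sum(p[col] for p in parts))
    return out


def run_pipeline(
    trials,
    layouts: dict,
    model: AxonMapModel | None = None,
    erd_um: dict | None = None,
    close_radius: int = 1,
    fit: bool = True,
    min_n_single: int = 10,
) -> PipelineResult:
    """Run the full analysis on a set of drawing trials.

    Steps: shape extraction, normalization by the standard pulse, trial
    averaging, distance lookup, power transforms, outlier removal
    (single-electrode rows), predictor standardization, then the regression
    battery.  ``layouts`` maps participant id to an
    :class:`~phossum.geometry.ImplantLayout`.
    """
    model = model or AxonMapModel()
    shapes = shapes_from_trials(trials, close_radius=close_radius)
    normalized = prep.normalize_descriptors(shapes)
    avg = prep.average_trials(normalized)
    avg = _attach_sum_of_singles(avg)
    dists = distance_table(layouts, avg, model=model, erd_um=erd_um)
    design = prep.assemble_design_table(
        avg, dists, predictors=["amplitude", "frequency", "efd_um"],
    )
    result = PipelineResult(shapes=shapes, design=design)
    if not fit:
        return result

    single = design[~design["is_paired"]]
    paired = design[design["is_paired"]]
    tcols = [c + "_t" for c in prep.DESCRIPTORS]

    # within-participant standardized OLS per descriptor
    for pid, g in single.groupby("participant"):
        predictors, pnames = [], []
        for col, nm in (("amplitude", "amplitude"), ("frequency", "frequency"),
                        ("efd_um", "EFD")):
            if g[col].nunique() > 1:
                predictors.append(col)
                pnames.append(nm)
        if len(g) < max(min_n_single, len(predictors) + 2):
            continue
        for resp in tcols:
            fit_ = StandardizedOLS(
                g[resp].to_numpy(), g[predictors].to_numpy(),
                predictor_names=pnames,
                name=f"{pid}: {resp} ~ " + " + ".join(pnames),
            ).fit()
            result.single_fits[(pid, resp)] = fit_

    # across-participant mixed model per descriptor
    if single["participant"].nunique() >= 2:
        for resp in tcols:
            try:
                result.mixed_fits[resp] = MixedShapeModel.from_dataframe(
                    single, resp, ["amplitude", "frequency", "efd_um"],
                ).fit()
            except (RuntimeError, ValueError):
                pass

    # paired summation: descriptor totals vs sum of singles (untransformed,
    # normalized scale, no intercept) so the slope reads as the gain
    ok = paired.dropna(subset=[c + "_sum_single" for c in prep.DESCRIPTORS])
    if len(ok) >= 3:
        for col in prep.DESCRIPTORS:
            result.summation_fits[col] = SummationRegression(
                ok[col].to_numpy(), ok[col + "_sum_single"].to_numpy(),
                name=f"paired {col} ~ 0 + sum of singles",
            ).fit()

    # phosphene count: between- vs along-axon models
    need = ["number_of_phosphenes", "amplitude", "efd_um",
            "between_axon_um", "along_axon_um"]
    cnt = paired.dropna(subset=[c for c in need if c in paired.columns])
    if len(cnt) >= 8 and {"between_axon_um", "along_axon_um"} <= set(cnt.columns):
        extras = [c for c in ("amplitude", "efd_um") if cnt[c].nunique() > 1]
        a = StandardizedOLS(
            cnt["number_of_phosphenes"].to_numpy(),
            cnt[extras + ["along_axon_um"]].to_numpy(),
            predictor_names=extras + ["along_axon"],
            name="count ~ " + " + ".join(extras + ["along_axon"]),
        ).fit()
        b = StandardizedOLS(
            cnt["number_of_phosphenes"].to_numpy(),
            cnt[extras + ["between_axon_um"]].to_numpy(),
            predictor_names=extras + ["between_axon"],
            name="count ~ " + " + ".join(extras + ["between_axon"]),
        ).fit()
        result.count_fit_along = a
        result.count_fit_between = b
        result.count_comparison = compare_models(a, b)
    return result
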