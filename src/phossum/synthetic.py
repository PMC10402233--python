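"""Synthetic phosphene-drawing generator.

Emulates the statistical structure of the paired-stimulation drawing study so
that every pipeline stage can be exercised without clinical data:

- per-electrode characteristic shapes elongated along the electrode's nerve
  fiber bundle (axon-map percept model): the latent intensity at a retinal
  point is ``exp(-d_perp^2 / 2 rho_eff^2) * exp(-d_along^2 / 2 lambda_eff^2)``
  where ``d_perp`` is the distance from the bundle and ``d_along`` the
  arc-length offset from the electrode's foot point;
- amplitude grows the radial spread (``rho_eff = rho0 * amplitude^a``),
  frequency and retinal eccentricity grow the axonal spread
  (``lambda_eff = lambda0 * (1 + f log(freq/20)) * (1 + c EFD)``);
- paired stimulation combines the two percepts by pixelwise maximum with a
  sub-unit gain ``g``: each constituent percept's spatial scales are
  multiplied by ``sqrt(g)``, so each component's *area* is attenuated by
  exactly ``g`` and paired descriptor totals of non-overlapping percepts sum
  linearly with slope ``g`` (perimeter and axis totals attenuate by
  ``sqrt(g)``).  Overlapping percepts merge into one region, which ties the
  perceived phosphene count to the between-axon distance;
- per-participant drawing noise: a multiplicative size bias (lognormal) and
  integer-pixel centroid jitter per trial.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drawing import Drawing
from .geometry import (
    AxonMapModel,
    ImplantLayout,
    place_implant,
    electrode_fovea_distance,
    UM_PER_DEG,
)

__all__ = [
    "ParticipantParams",
    "GeneratorConfig",
    "SyntheticTrial",
    "SyntheticDataset",
    "PhospheneRenderer",
    "render_single",
    "render_paired",
    "sample_dataset",
]


@dataclass
class ParticipantParams:
    """Latent percept and drawing-noise parameters of one simulated participant.

    rho0_um, lambda0_um : radial / axonal current-spread scales (um).
    amp_exponent : amplitude -> size effect (rho_eff = rho0 * amp^a).
    freq_coef : frequency -> elongation effect per log-unit of freq/20.
    ecc_coef : eccentricity -> elongation effect per um of EFD.
    gain : paired-summation gain in (0, 1].
    jitter_px, size_bias_sd : drawing noise (centroid jitter SD in px;
        lognormal sigma of the participant's multiplicative size bias).
    rotation_deg, center_x_um, center_y_um, eye : implant placement.
    """

    rho0_um: float = 150.0
    lambda0_um: float = 800.0
    amp_exponent: float = 0.5
    freq_coef: float = 0.25
    ecc_coef: float = 2.5e-4
    gain: float = 0.7
    jitter_px: float = 3.0
    size_bias_sd: float = 0.1
    rotation_deg: float = -35.0
    center_x_um: float = -1500.0
    center_y_um: float = 300.0
    eye: str = "RE"

    def __post_init__(self) -> None:
        if self.rho0_um <= 0 or self.lambda0_um <= 0:
            raise ValueError("spread scales must be positive")
        if not 0.0 < self.gain <= 1.0:
            raise ValueError("gain must lie in (0, 1]")

    def spreads(self, amplitude: float, frequency: float, efd_um: float,
                scale: float = 1.0) -> tuple[float, float]:
        """(rho_eff, lambda_eff) in um for a stimulus at eccentricity EFD."""
        if amplitude <= 0 or frequency <= 0:
            raise ValueError("amplitude and frequency must be positive")
        rho = self.rho0_um * amplitude**self.amp_exponent
        elong = max(1.0 + self.freq_coef * math.log(frequency / 20.0), 0.2)
        lam = self.lambda0_um * elong * (1.0 + self.ecc_coef * efd_um)
        # radial current spread is isotropic, so the axonal scale can only
        # add elongation on top of it: in the lambda0 -> 0 limit the percept
        # degenerates to a compact blob, not to a sliver across the bundle
        lam = max(lam, rho)
        return rho * scale, lam * scale

    def layout(self) -> ImplantLayout:
        return place_implant(
            rotation_deg=self.rotation_deg,
            center_x_um=self.center_x_um,
            center_y_um=self.center_y_um,
            eye=self.eye,
        )


def _default_participants() -> dict[str, ParticipantParams]:
    """Three participants echoing the study's qualitative repertoire:
    blobs/wedges with a strong amplitude effect, long lines/arcs with a weak
    amplitude effect, and a strongly frequency-modulated drawer."""
    return {
        "P1": ParticipantParams(
            rho0_um=180.0, lambda0_um=600.0, amp_exponent=0.6, freq_coef=0.15,
            gain=0.69, jitter_px=4.0, rotation_deg=-38.0,
            center_x_um=-1200.0, center_y_um=500.0,
        ),
        "P2": ParticipantParams(
            rho0_um=100.0, lambda0_um=1100.0, amp_exponent=0.2, freq_coef=0.2,
            gain=0.73, jitter_px=3.0, rotation_deg=-30.0,
            center_x_um=-1600.0, center_y_um=-300.0,
        ),
        "P3": ParticipantParams(
            rho0_um=140.0, lambda0_um=800.0, amp_exponent=0.7, freq_coef=0.45,
            gain=0.58, jitter_px=3.0, rotation_deg=-44.0,
            center_x_um=-1100.0, center_y_um=200.0,
        ),
    }


@dataclass
class GeneratorConfig:
    """Study design and raster geometry of a synthetic dataset.

    The raster emulates a 1024x768 touchscreen viewed at 76.2 cm; at that
    distance one degree of visual angle subtends about 26 px.
    """

    participants: dict[str, ParticipantParams] = field(
        default_factory=_default_participants
    )
    canvas: tuple[int, int] = (768, 1024)  # (rows, cols)
    px_per_deg: float = 26.0
    threshold: float = 0.5
    n_electrodes: int = 30
    trials_per_stim: int = 5
    amplitudes: tuple[float, ...] = (1.25, 1.5, 4.0)
    frequencies: tuple[float, ...] = (6.0, 60.0, 120.0)
    extra_cells_per_electrode: int = 2
    n_pairs: int = 30
    pair_amplitudes: tuple[float, ...] = (1.25, 2.0, 3.0)
    max_pair_pitch: int = 3
    noise: bool = True

    @property
    def px_per_um(self) -> float:
        return self.px_per_deg / UM_PER_DEG


@dataclass
class SyntheticTrial:
    """One rendered trial plus its latent ground truth."""

    drawing: Drawing
    participant: str
    electrodes: str           # "B3" or "B3+C5"
    amplitude: float
    frequency: float
    trial: int
    truth: dict = field(default_factory=dict)

    def record(self) -> dict:
        e = self.electrodes.split("+")
        return {
            "participant": self.participant,
            "trial": self.trial,
            "electrode_1": e[0],
            "electrode_2": e[1] if len(e) > 1 else "",
            "amplitude_x_threshold": self.amplitude,
            "frequency_hz": self.frequency,
        }


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset: trials, layouts and ground truth."""

    config: GeneratorConfig
    seed: int
    trials: list[SyntheticTrial]
    layouts: dict[str, ImplantLayout]
    ground_truth: pd.DataFrame

    def trial_table(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            row = t.record()
            row["electrodes"] = t.electrodes
            rows.append(row)
        return pd.DataFrame(rows)


class PhospheneRenderer:
    """Renders latent percept intensities onto the drawing raster.

    Caches the axon bundle (and the electrode's arc-length foot point) per
    electrode so repeated trials are cheap.
    """

    def __init__(self, model: AxonMapModel, config: GeneratorConfig):
        self.model = model
        self.config = config
        self._bundles: dict[tuple[float, float], tuple] = {}
        self._mask_cache: dict[tuple, tuple] = {}

    # -- raster <-> retina -------------------------------------------------
    def px_center(self) -> tuple[float, float]:
        rows, cols = self.config.canvas
        return (rows / 2.0, cols / 2.0)

    def um_to_px(self, xy_um: np.ndarray) -> np.ndarray:
        """Retinal um -> (row, col) px; fovea maps to the raster center."""
        c = self.px_center()
        s = self.config.px_per_um
        xy_um = np.atleast_2d(xy_um)
        return np.column_stack([c[0] - xy_um[:, 1] * s, c[1] + xy_um[:, 0] * s])

    def px_to_um(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        c = self.px_center()
        s = self.config.px_per_um
        return np.column_stack([(cols - c[1]) / s, (c[0] - rows) / s])

    # -- bundles -----------------------------------------------------------
    def _bundle(self, electrode_xy) -> tuple:
        key = (round(float(electrode_xy[0]), 3), round(float(electrode_xy[1]), 3))
        if key not in self._bundles:
            bundle = self.model.axon_bundle(np.asarray(electrode_xy, float))
            _, s_foot = bundle.project(np.asarray(electrode_xy, float)[None, :])
            self._bundles[key] = (bundle, float(s_foot[0]))
        return self._bundles[key]

    # -- intensity fields ---------------------------------------------------
    #: fine resampling step (um) of the bundle segment used for rendering
    RENDER_STEP_UM = 5.0

    def intensity(self, electrode_xy, rho_um: float, lam_um: float) -> np.ndarray:
        """Full-canvas latent intensity of one percept (float in [0, 1]).

        The field is evaluated only where it can exceed the binarization
        threshold (elsewhere it is left at 0), using a nearest-vertex lookup
        on the bundle resampled at :attr:`RENDER_STEP_UM`; the resulting
        distance error is far below the spread scales.
        """
        rows_n, cols_n = self.config.canvas
        out = np.zeros((rows_n, cols_n), dtype=float)
        bundle, s_foot = self._bundle(electrode_xy)
        arc = bundle.arc_length
        # support of {intensity > threshold} is the ellipse
        # (d_perp/rho)^2 + (d_along/lam)^2 < 2 ln(1/thr); pad by a margin
        reach = math.sqrt(2.0 * math.log(1.0 / self.config.threshold)) + 0.35
        lo, hi = s_foot - reach * lam_um, s_foot + reach * lam_um
        sel = (arc >= lo - bundle.step_um) & (arc <= hi + bundle.step_um)
        if sel.sum() < 2:
            k = int(np.argmin(np.abs(arc - s_foot)))
            sel = np.zeros_like(sel)
            sel[max(k - 1, 0) : k + 2] = True
        sub = bundle.xy[sel]
        sub_s = arc[sel]
        # fine resample (arc-length parameterized) for nearest-vertex lookup
        n_fine = max(int(np.ceil((sub_s[-1] - sub_s[0]) / self.RENDER_STEP_UM)), 1) + 1
        fine_s = np.linspace(sub_s[0], sub_s[-1], n_fine)
        fine = np.column_stack(
            [np.interp(fine_s, sub_s, sub[:, 0]), np.interp(fine_s, sub_s, sub[:, 1])]
        )
        # candidate pixels: union of padded per-chunk bounding boxes along
        # the polyline (a tight corridor, much smaller than the global bbox)
        pad = reach * rho_um + 2.0 * self.RENDER_STEP_UM
        fine_px = self.um_to_px(fine)
        pad_px = pad * self.config.px_per_um + 1.0
        g_r0 = int(np.clip(np.floor(fine_px[:, 0].min() - pad_px), 0, rows_n - 1))
        g_r1 = int(np.clip(np.ceil(fine_px[:, 0].max() + pad_px), 0, rows_n - 1))
        g_c0 = int(np.clip(np.floor(fine_px[:, 1].min() - pad_px), 0, cols_n - 1))
        g_c1 = int(np.clip(np.ceil(fine_px[:, 1].max() + pad_px), 0, cols_n - 1))
        if g_r1 <= g_r0 or g_c1 <= g_c0:
            return out
        sel = np.zeros((g_r1 - g_r0 + 1, g_c1 - g_c0 + 1), dtype=bool)
        chunk = 16
        for k in range(0, len(fine_px), chunk):
            seg = fine_px[max(k - 1, 0) : k + chunk + 1]
            r0 = int(np.clip(np.floor(seg[:, 0].min() - pad_px), g_r0, g_r1))
            r1 = int(np.clip(np.ceil(seg[:, 0].max() + pad_px), g_r0, g_r1))
            c0 = int(np.clip(np.floor(seg[:, 1].min() - pad_px), g_c0, g_c1))
            c1 = int(np.clip(np.ceil(seg[:, 1].max() + pad_px), g_c0, g_c1))
            sel[r0 - g_r0 : r1 - g_r0 + 1, c0 - g_c0 : c1 - g_c0 + 1] = True
        rr, cc = np.nonzero(sel)
        rr = rr + g_r0
        cc = cc + g_c0
        pts = self.px_to_um(rr.astype(float), cc.astype(float))
        from scipy.spatial import cKDTree

        # pixels farther than the perpendicular reach cannot switch on
        d_perp, idx = cKDTree(fine).query(pts, distance_upper_bound=pad)
        hit = np.isfinite(d_perp)
        if hit.any():
            d_along = fine_s[idx[hit]] - s_foot
            out[rr[hit], cc[hit]] = np.exp(
                -0.5 * (d_perp[hit] / rho_um) ** 2
            ) * np.exp(-0.5 * (d_along / lam_um) ** 2)
        return out

    # -- drawings ----------------------------------------------------------
    def _binarize(self, intensity: np.ndarray) -> np.ndarray:
        return (intensity > self.config.threshold).astype(np.uint8)

    def _mask_crop(self, electrode_xy, rho_um: float, lam_um: float):
        """Cached binarized percept as (row0, col0, crop) for compositing.

        Binarization commutes with pixelwise maximum, so paired percepts can
        be composed as the union of cached single-percept masks.
        """
        key = (
            round(float(electrode_xy[0]), 3), round(float(electrode_xy[1]), 3),
            round(float(rho_um), 3), round(float(lam_um), 3),
        )
        if key not in self._mask_cache:
            mask = self._binarize(self.intensity(electrode_xy, rho_um, lam_um))
            rows = np.flatnonzero(mask.any(axis=1))
            cols = np.flatnonzero(mask.any(axis=0))
            if rows.size == 0:
                self._mask_cache[key] = (0, 0, np.zeros((0, 0), dtype=np.uint8))
            else:
                r0, r1 = rows[0], rows[-1]
                c0, c1 = cols[0], cols[-1]
                self._mask_cache[key] = (
                    int(r0), int(c0), mask[r0 : r1 + 1, c0 : c1 + 1].copy()
                )
        return self._mask_cache[key]

    def _compose(self, crops) -> np.ndarray:
        out = np.zeros(self.config.canvas, dtype=np.uint8)
        for r0, c0, crop in crops:
            if crop.size:
                out[r0 : r0 + crop.shape[0], c0 : c0 + crop.shape[1]] |= crop
        return out

    @staticmethod
    def _jitter(mask: np.ndarray, rng: np.random.Generator, sd_px: float) -> np.ndarray:
        if sd_px <= 0:
            return mask
        dr, dc = np.round(rng.normal(0.0, sd_px, size=2)).astype(int)
        out = np.zeros_like(mask)
        r0, r1 = max(dr, 0), mask.shape[0] + min(dr, 0)
        c0, c1 = max(dc, 0), mask.shape[1] + min(dc, 0)
        if r1 > r0 and c1 > c0:
            out[r0:r1, c0:c1] = mask[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        return out

    def render_single(
        self,
        electrode_xy,
        amplitude: float,
        frequency: float,
        params: ParticipantParams,
        rng: np.random.Generator | None = None,
        size_bias: float = 1.0,
    ) -> np.ndarray:
        """Binary drawing mask of a single-electrode percept.

        ``size_bias`` multiplies the spatial scales (the participant's
        drawing bias); centroid jitter is applied when ``rng`` is given.
        """
        efd = electrode_fovea_distance(np.asarray(electrode_xy, float))
        rho, lam = params.spreads(amplitude, frequency, efd, scale=size_bias)
        mask = self._compose([self._mask_crop(electrode_xy, rho, lam)])
        if rng is not None:
            mask = self._jitter(mask, rng, params.jitter_px)
        return mask

    def render_paired(
        self,
        e1,
        e2,
        amplitude: float,
        params: ParticipantParams,
        rng: np.random.Generator | None = None,
        size_bias: float = 1.0,
        frequency: float = 20.0,
    ) -> np.ndarray:
        """Binary drawing mask of a paired-electrode percept.

        Each constituent percept is rendered with spatial scales multiplied
        by sqrt(gain) (so each component's area is attenuated by exactly the
        gain); the two intensity fields are combined by pixelwise maximum
        before binarization, which for binary output equals the union of the
        component masks.  Percepts on nearby bundles therefore merge into a
        single region.
        """
        e1 = np.asarray(e1, float)
        e2 = np.asarray(e2, float)
        if np.allclose(e1, e2):
            raise ValueError("paired stimulation needs two distinct electrodes")
        scale = size_bias * math.sqrt(params.gain)
        crops = []
        for e in (e1, e2):
            efd = electrode_fovea_distance(e)
            rho, lam = params.spreads(amplitude, frequency, efd, scale=scale)
            crops.append(self._mask_crop(e, rho, lam))
        mask = self._compose(crops)
        if rng is not None:
            mask = self._jitter(mask, rng, params.jitter_px)
        return mask


def render_single(electrode_xy, amplitude, frequency, params=None,
                  model=None, config=None, rng=None, noise=False):
    """Convenience wrapper; see :meth:`PhospheneRenderer.render_single`."""
    params = params or ParticipantParams()
    model = model or AxonMapModel()
    config = config or GeneratorConfig()
    return PhospheneRenderer(model, config).render_single(
        electrode_xy, amplitude, frequency, params, rng=rng if noise else None
    )


def render_paired(e1, e2, amplitude, params=None, model=None, config=None,
                  rng=None, noise=False):
    """Convenience wrapper; see :meth:`PhospheneRenderer.render_paired`."""
    params = params or ParticipantParams()
    model = model or AxonMapModel()
    config = config or GeneratorConfig()
    return PhospheneRenderer(model, config).render_paired(
        e1, e2, amplitude, params, rng=rng if noise else None
    )


def _mask_truth(mask: np.ndarray) -> dict:
    """Latent descriptor totals and region count of a binary mask."""
    from .drawing import Drawing as _D, _label_regions, ShapeDescriptors

    if not mask.any():
        return {
            "true_count": 0, "true_area": 0.0, "true_perimeter": 0.0,
            "true_major_axis_length": 0.0, "true_minor_axis_length": 0.0,
        }
    regions = _label_regions(_D(mask))
    sd = ShapeDescriptors.from_phosphenes(regions)
    return {
        "true_count": sd.number_of_phosphenes,
        "true_area": sd.area,
        "true_perimeter": sd.perimeter,
        "true_major_axis_length": sd.major_axis_length,
        "true_minor_axis_length": sd.minor_axis_length,
    }


def _choose_pairs(rng, names, coords, n_pairs, max_pair_pitch, pitch_um):
    """Random electrode pairs within a grid-distance cap."""
    idx = np.arange(len(names))
    candidates = []
    for i in idx:
        for j in idx[idx > i]:
            d = np.hypot(*(coords[i] - coords[j]))
            if d <= max_pair_pitch * pitch_um + 1.0:
                candidates.append((i, j))
    if not candidates:
        raise ValueError("no electrode pairs within max_pair_pitch")
    take = min(n_pairs, len(candidates))
    chosen = rng.choice(len(candidates), size=take, replace=False)
    return [candidates[k] for k in sorted(chosen)]


def sample_dataset(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    model: AxonMapModel | None = None,
    out_dir=None,
    include_pairs: bool = True,
) -> SyntheticDataset:
    """Generate a reproducible synthetic dataset.

    Every participant gets a guaranteed standard-pulse (2x threshold, 20 Hz)
    stimulus on every sampled electrode, plus randomly assigned amplitude or
    frequency cells, plus paired-electrode cells at 20 Hz.  With ``out_dir``
    set, drawings are written as PNG masks alongside the trial table,
    per-participant placement YAML and the ground-truth table.
    """
    config = config or GeneratorConfig()
    model = model or AxonMapModel()
    rng = np.random.default_rng(seed)
    renderer = PhospheneRenderer(model, config)

    trials: list[SyntheticTrial] = []
    truth_rows: list[dict] = []
    layouts: dict[str, ImplantLayout] = {}

    for pid in sorted(config.participants):
        pp = config.participants[pid]
        layout = pp.layout()
        layouts[pid] = layout
        size_bias = float(np.exp(rng.normal(0.0, pp.size_bias_sd))) \
            if config.noise else 1.0

        n_el = min(config.n_electrodes, len(layout.names))
        el_idx = np.sort(rng.choice(len(layout.names), size=n_el, replace=False))
        names = [layout.names[i] for i in el_idx]
        coords = layout.coords[el_idx]
        name_to_xy = dict(zip(names, coords))

        # pairs are drawn first so that matching single-electrode cells (the
        # summation analysis needs singles at the pair's amplitude) can be
        # added to the single-electrode design
        pairs: list[tuple[int, int, float]] = []
        if include_pairs and config.n_pairs > 0:
            for i, j in _choose_pairs(rng, names, coords, config.n_pairs,
                                      config.max_pair_pitch, layout.pitch_um):
                pairs.append((i, j, float(rng.choice(config.pair_amplitudes))))

        # stimulus cells: the standard pulse on every electrode, plus extras,
        # plus the singles backing each pair
        cells: list[tuple[str, float, float]] = []
        menu = [(a, 20.0) for a in config.amplitudes] + [
            (1.5, f) for f in config.frequencies
        ]
        for name in names:
            cells.append((name, 2.0, 20.0))
            if config.extra_cells_per_electrode > 0 and menu:
                picks = rng.choice(
                    len(menu),
                    size=min(config.extra_cells_per_electrode, len(menu)),
                    replace=False,
                )
                for k in sorted(picks):
                    cells.append((name, float(menu[k][0]), float(menu[k][1])))
        for i, j, amp in pairs:
            cells.append((names[i], amp, 20.0))
            cells.append((names[j], amp, 20.0))
        cells = sorted(set(cells))
        for name, amp, freq in cells:
            xy = name_to_xy[name]
            clean = renderer.render_single(xy, amp, freq, pp)
            truth_rows.append(
                {
                    "participant": pid, "electrodes": name, "amplitude": amp,
                    "frequency": freq,
                    "efd_um": electrode_fovea_distance(xy),
                    **_mask_truth(clean),
                }
            )
            base = renderer.render_single(xy, amp, freq, pp, size_bias=size_bias)
            for t in range(config.trials_per_stim):
                mask = (
                    renderer._jitter(base, rng, pp.jitter_px)
                    if config.noise else base
                )
                trials.append(
                    SyntheticTrial(
                        drawing=Drawing(mask, trial_id=t, participant_id=pid),
                        participant=pid, electrodes=name, amplitude=amp,
                        frequency=freq, trial=t,
                    )
                )

        if pairs:
            for i, j, amp in pairs:
                e1, e2 = coords[i], coords[j]
                key = f"{names[i]}+{names[j]}"
                clean = renderer.render_paired(e1, e2, amp, pp)
                singles = [
                    renderer.render_single(e, amp, 20.0, pp)
                    for e in (e1, e2)
                ]
                truth_single = [_mask_truth(m) for m in singles]
                pd_ = model.pair_distances(e1, e2, names=(names[i], names[j]))
                row = {
                    "participant": pid, "electrodes": key, "amplitude": amp,
                    "frequency": 20.0, "gain": pp.gain,
                    "efd_um": 0.5 * (electrode_fovea_distance(e1)
                                     + electrode_fovea_distance(e2)),
                    "between_axon_um": pd_.between_axon,
                    "along_axon_um": pd_.along_axon,
                    "euclidean_um": pd_.euclidean,
                    **_mask_truth(clean),
                }
                for k in ("true_area", "true_perimeter",
                          "true_major_axis_length", "true_minor_axis_length"):
                    row[k + "_sum_single"] = truth_single[0][k] + truth_single[1][k]
                truth_rows.append(row)
                base = renderer.render_paired(e1, e2, amp, pp,
                                              size_bias=size_bias)
                for t in range(config.trials_per_stim):
                    mask = (
                        renderer._jitter(base, rng, pp.jitter_px)
                        if config.noise else base
                    )
                    trials.append(
                        SyntheticTrial(
                            drawing=Drawing(mask, trial_id=t, participant_id=pid),
                            participant=pid, electrodes=key, amplitude=amp,
                            frequency=20.0, trial=t,
                        )
                    )

    dataset = SyntheticDataset(
        config=config, seed=seed, trials=trials, layouts=layouts,
        ground_truth=pd.DataFrame(truth_rows),
    )
    if out_dir is not None:
        _write_dataset(dataset, out_dir)
    return dataset


def sample_pair_experiment(
    seed: int,
    config: GeneratorConfig | None = None,
    model: AxonMapModel | None = None,
    renderer: PhospheneRenderer | None = None,
    n_pairs: int = 20,
) -> pd.DataFrame:
    """Paired-stimulation phosphene-count experiment (no drawing noise).

    For each participant, draws ``n_pairs`` electrode pairs, renders the
    noiseless paired percept, and tabulates the perceived phosphene count
    (connected components) against the pair's stimulus amplitude,
    electrode-fovea distance and between-/along-axon distances.  The count
    depends on whether the two percepts merge, which by construction is
    governed by the between-axon separation of the underlying bundles.
    """
    config = config or GeneratorConfig()
    model = model or AxonMapModel()
    renderer = renderer or PhospheneRenderer(model, config)
    rng = np.random.default_rng(seed)
    rows = []
    for pid in sorted(config.participants):
        pp = config.participants[pid]
        layout = pp.layout()
        coords = layout.coords
        names = layout.names
        for i, j in _choose_pairs(rng, names, coords, n_pairs,
                                  config.max_pair_pitch, layout.pitch_um):
            amp = float(rng.choice(config.pair_amplitudes))
            e1, e2 = coords[i], coords[j]
            mask = renderer.render_paired(e1, e2, amp, pp)
            truth = _mask_truth(mask)
            pdist = model.pair_distances(e1, e2, names=(names[i], names[j]))
            rows.append(
                {
                    "participant": pid,
                    "electrodes": f"{names[i]}+{names[j]}",
                    "amplitude": amp,
                    "efd_um": 0.5 * (electrode_fovea_distance(e1)
                                     + electrode_fovea_distance(e2)),
                    "between_axon_um": pdist.between_axon,
                    "along_axon_um": pdist.along_axon,
                    "euclidean_um": pdist.euclidean,
                    "count": truth["true_count"],
                }
            )
    return pd.DataFrame(rows)


def _write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    from pathlib import Path

    import imageio.v3 as iio
    import yaml

    out = Path(out_dir)
    (out / "drawings").mkdir(parents=True, exist_ok=True)
    rows = []
    for k, t in enumerate(dataset.trials):
        rel = f"drawings/{t.participant}_{t.electrodes.replace('+', '-')}" \
              f"_a{t.amplitude:g}_f{t.frequency:g}_t{t.trial}.png"
        iio.imwrite(out / rel, t.drawing.pixels * np.uint8(255))
        row = t.record()
        row["image_path"] = rel
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "trials.csv", index=False)
    dataset.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    placements = {
        pid: {
            "rotation_deg": float(lay.rotation_deg),
            "center_x_um": float(lay.center_x_um),
            "center_y_um": float(lay.center_y_um),
            "eye": lay.eye,
        }
        for pid, lay in dataset.layouts.items()
    }
    with open(out / "placement.yaml", "w") as fh:
        yaml.safe_dump(placements, fh)
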