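"""Implant layout and retinal nerve-fiber-bundle geometry.

Coordinates are retinal microns in a canonical right-eye frame: the fovea is
the origin, the optic disc lies toward +x (nasal), and the temporal raphe
falls on the horizontal axis at -x.  Left-eye placements are mirrored into
this frame at ingest.

The axon map is the spiral trajectory family of Jansonius et al. (2009),
fitted to fundus photographs of sighted eyes: each nerve-fiber bundle is
indexed by its angle of entry into the optic disc, with separate parameter
regimes for the superior and inferior hemiretina that meet at the temporal
raphe.  The family is evaluated in a horizontal-raphe frame (optic disc on
the +x axis) and a nasal-side vertical shear then lifts the disc to its
anatomical elevation, so that the raphe stays exactly on y = 0 while bundles
still terminate at the configured disc center.

From this map the module derives the distance decomposition used for
electrode pairs: the *between-axon* distance (shortest distance from the more
nasal electrode's center to the bundle passing through the more temporal
electrode) and the *along-axon* distance (arc length along that reference
bundle between the temporal electrode and the between-axon foot point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UM_PER_DEG",
    "ELECTRODE_DIAMETER_UM",
    "JANSONIUS_CONFIG",
    "um_to_deg",
    "deg_to_um",
    "oct_pixels_to_um",
    "electrode_fovea_distance",
    "ImplantLayout",
    "place_implant",
    "AxonBundle",
    "AxonMapModel",
    "PairDistances",
]

#: Retinal magnification: microns of retina per degree of visual angle.
UM_PER_DEG = 288.0

#: Argus II platinum disc electrode diameter (microns).
ELECTRODE_DIAMETER_UM = 200.0

#: Argus II inter-electrode spacing (microns) on the 6 x 10 grid.
ELECTRODE_PITCH_UM = 575.0

#: Versioned constants of the fiber-bundle trajectory family
#: (Jansonius et al. 2009 parameterization).  Angles in degrees, radial
#: coordinates in degrees of visual angle about the optic disc center.
JANSONIUS_CONFIG: dict[str, float] = {
    "version": 1.0,
    # superior hemiretina (phi0 > 0):
    #   b =  exp(beta_sup + b1_sup * tanh(-(phi0 - mu_sup) / w_sup))
    #   c =  c0_sup + c1_sup * tanh((phi0 - mu_sup) / w_sup)
    "beta_sup": -1.9, "b1_sup": 3.9, "mu_sup": 121.0, "w_sup": 14.0,
    "c0_sup": 1.9, "c1_sup": 1.4,
    # inferior hemiretina (phi0 < 0), mirrored in -phi0:
    #   b = -exp(beta_inf + b1_inf * tanh(-(-phi0 - mu_inf) / w_inf))
    #   c =  c0_inf + c1_inf * tanh((-phi0 - mu_inf) / w_inf)
    "beta_inf": 0.5, "b1_inf": 1.5, "mu_inf": 90.0, "w_inf": 25.0,
    "c0_inf": 1.0, "c1_inf": 0.5,
    # radius of the optic disc region where trajectories originate (deg)
    "r0_deg": 4.0,
    # maximal modeled radial extent about the disc (deg)
    "rmax_deg": 45.0,
}

#: Default optic-disc center in the canonical frame (um): ~(16 deg, 0.9 deg).
OPTIC_DISC_UM = (4600.0, 260.0)


# ---------------------------------------------------------------------------
# scalar conversions
# ---------------------------------------------------------------------------

def um_to_deg(d_um, um_per_deg: float = UM_PER_DEG):
    """Retinal distance (um) to visual angle (deg)."""
    d_um = np.asarray(d_um, dtype=float)
    if np.any(d_um < 0):
        raise ValueError("distance must be non-negative")
    out = d_um / um_per_deg
    return float(out) if out.ndim == 0 else out


def deg_to_um(d_deg, um_per_deg: float = UM_PER_DEG):
    """Visual angle (deg) to retinal distance (um)."""
    d_deg = np.asarray(d_deg, dtype=float)
    if np.any(d_deg < 0):
        raise ValueError("angle must be non-negative")
    out = d_deg * um_per_deg
    return float(out) if out.ndim == 0 else out


def oct_pixels_to_um(
    distance_px: float,
    shadow_width_px: float,
    electrode_diameter_um: float = ELECTRODE_DIAMETER_UM,
) -> float:
    """Convert an OCT pixel count to microns.

    The opaque electrode casts a shadow of known physical width (the
    electrode diameter), which calibrates the pixel size of the scan:
    ``distance_px * (diameter / shadow_width_px)``.
    """
    if shadow_width_px <= 0:
        raise ValueError("shadow_width_px must be positive")
    if distance_px < 0:
        raise ValueError("distance_px must be non-negative")
    return float(distance_px) * electrode_diameter_um / float(shadow_width_px)


def electrode_fovea_distance(p) -> float:
    """Euclidean distance (um) from a retinal point to the fovea (origin)."""
    p = np.asarray(p, dtype=float)
    return float(np.hypot(p[..., 0], p[..., 1])) if p.ndim > 1 else float(
        np.hypot(p[0], p[1])
    )


# ---------------------------------------------------------------------------
# implant layout
# ---------------------------------------------------------------------------

#: Physiological bound on retinal coordinates (um).
RETINA_BOUND_UM = 15_000.0


@dataclass
class ImplantLayout:
    """A placed Argus II array: 6 rows (A-F) x 10 columns (1-10)."""

    rotation_deg: float = 0.0
    center_x_um: float = 0.0
    center_y_um: float = 0.0
    eye: str = "RE"
    pitch_um: float = ELECTRODE_PITCH_UM
    names: list[str] = field(default_factory=list)
    coords: np.ndarray = field(default=None)  # (60, 2) um
    out_of_retina: bool = False

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {n: (float(x), float(y)) for n, (x, y) in zip(self.names, self.coords)}


def place_implant(
    rotation_deg: float = 0.0,
    center_x_um: float = 0.0,
    center_y_um: float = 0.0,
    eye: str = "RE",
    pitch_um: float = ELECTRODE_PITCH_UM,
    n_rows: int = 6,
    n_cols: int = 10,
) -> ImplantLayout:
    """Generate the 60 electrode centers of a placed Argus II array.

    The unrotated grid has columns 1-10 advancing along +x and rows A-F
    advancing along +y, centered on the origin at ``pitch_um`` spacing.  The
    grid is rotated by ``rotation_deg`` (counter-clockwise) and then
    translated to (``center_x_um``, ``center_y_um``).  Left eyes (``eye='LE'``)
    are mirrored across the vertical axis into the canonical right-eye frame.

    Placements that leave the physiological retina raise a warning and set
    ``out_of_retina``.
    """
    if not -180.0 <= rotation_deg <= 180.0:
        raise ValueError("rotation_deg must lie in [-180, 180]")
    if abs(center_x_um) > RETINA_BOUND_UM or abs(center_y_um) > RETINA_BOUND_UM:
        raise ValueError("implant center outside physiological bounds")
    if eye not in ("RE", "LE"):
        raise ValueError("eye must be 'RE' or 'LE'")

    cols = np.arange(n_cols) - (n_cols - 1) / 2.0
    rows = np.arange(n_rows) - (n_rows - 1) / 2.0
    names, pts = [], []
    row_letters = [chr(ord("A") + i) for i in range(n_rows)]
    for ri, rlab in enumerate(row_letters):
        for ci in range(n_cols):
            names.append(f"{rlab}{ci + 1}")
            pts.append((cols[ci] * pitch_um, rows[ri] * pitch_um))
    pts = np.asarray(pts, dtype=float)

    th = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    pts = pts @ rot.T
    pts[:, 0] += center_x_um
    pts[:, 1] += center_y_um
    if eye == "LE":
        pts[:, 0] = -pts[:, 0]

    out_of_retina = bool(
        (np.abs(pts) > RETINA_BOUND_UM).any()
        or (np.hypot(pts[:, 0], pts[:, 1]) > RETINA_BOUND_UM).any()
    )
    if out_of_retina:
        warnings.warn("implant placement leaves the physiological retina",
                      stacklevel=2)
    return ImplantLayout(
        rotation_deg=rotation_deg,
        center_x_um=center_x_um,
        center_y_um=center_y_um,
        eye=eye,
        pitch_um=pitch_um,
        names=names,
        coords=pts,
        out_of_retina=out_of_retina,
    )


# ---------------------------------------------------------------------------
# axon bundles
# ---------------------------------------------------------------------------


def _polyline_project(points: np.ndarray, poly: np.ndarray):
    """Project points onto a polyline.

    Returns ``(dist, s)``: for each query point, the minimum Euclidean
    distance to the polyline and the arc-length position (from the first
    vertex) of the closest point.  Exact segment-wise projection.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a = poly[:-1]  # (S, 2)
    d = poly[1:] - a  # segment vectors
    seg_len2 = np.einsum("ij,ij->i", d, d)
    seg_len2 = np.where(seg_len2 == 0, 1e-300, seg_len2)
    seg_s0 = np.concatenate(
        [[0.0], np.cumsum(np.sqrt(np.einsum("ij,ij->i", d, d)))]
    )[:-1]
    # t parameter per (point, segment)
    w = points[:, None, :] - a[None, :, :]  # (M, S, 2)
    t = np.clip(np.einsum("msj,sj->ms", w, d) / seg_len2[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * d[None, :, :]
    diff = points[:, None, :] - proj
    dist2 = np.einsum("msj,msj->ms", diff, diff)
    idx = np.argmin(dist2, axis=1)
    m = np.arange(points.shape[0])
    dist = np.sqrt(dist2[m, idx])
    s = seg_s0[idx] + t[m, idx] * np.sqrt(seg_len2[idx])
    return dist, s


def _polyline_project_chunked(points, poly, chunk: int = 2048):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    dists, ss = [], []
    for i in range(0, points.shape[0], chunk):
        d, s = _polyline_project(points[i : i + chunk], poly)
        dists.append(d)
        ss.append(s)
    return np.concatenate(dists), np.concatenate(ss)


@dataclass
class AxonBundle:
    """A discretized nerve-fiber-bundle trajectory.

    Vertices run from the peripheral seed toward the optic disc; the terminal
    vertex is the disc center.  ``phi0`` is the disc entry angle (deg) that
    indexes the bundle in the trajectory family.
    """

    xy: np.ndarray  # (N, 2) um, periphery -> disc
    phi0: float
    step_um: float

    @property
    def arc_length(self) -> np.ndarray:
        seg = np.diff(self.xy, axis=0)
        return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def project(self, points):
        """Min distance and arc position of closest point for query points."""
        return _polyline_project_chunked(points, self.xy)

    def distance_to(self, point) -> float:
        d, _ = self.project(np.asarray(point, dtype=float)[None, :])
        return float(d[0])

    def resample(self, step_um: float) -> "AxonBundle":
        s = self.arc_length
        n = max(int(np.ceil(s[-1] / step_um)) + 1, 2)
        si = np.linspace(0.0, s[-1], n)
        xy = np.column_stack(
            [np.interp(si, s, self.xy[:, 0]), np.interp(si, s, self.xy[:, 1])]
        )
        return AxonBundle(xy=xy, phi0=self.phi0, step_um=step_um)


class AxonMapModel:
    """Jansonius-family axon map in the canonical fovea-centered frame.

    Parameters
    ----------
    optic_disc_um :
        Optic disc center (um).  Trajectories are generated with the disc on
        the horizontal axis and a nasal-side vertical shear then maps the
        disc to this point, keeping the raphe exactly on y = 0.
    um_per_deg :
        Retinal magnification used to convert the angular trajectory model
        to microns.
    step_um :
        Arc-length discretization step of returned polylines.
    n_seeds :
        Number of disc-entry angles per hemifield in the dense search fan
        used by closest-bundle queries.
    config :
        Trajectory-family constants; defaults to :data:`JANSONIUS_CONFIG`.
    """

    def __init__(
        self,
        optic_disc_um: tuple[float, float] = OPTIC_DISC_UM,
        um_per_deg: float = UM_PER_DEG,
        step_um: float = 10.0,
        n_seeds: int = 181,
        config: dict | None = None,
    ):
        if optic_disc_um[0] <= 0:
            raise ValueError(
                "canonical frame requires the optic disc at x > 0 (nasal)"
            )
        self.optic_disc_um = (float(optic_disc_um[0]), float(optic_disc_um[1]))
        self.um_per_deg = float(um_per_deg)
        self.step_um = float(step_um)
        self.n_seeds = int(n_seeds)
        self.config = dict(JANSONIUS_CONFIG if config is None else config)
        self._fan_cache: dict[float, list[AxonBundle]] = {}
        self._point_cache: dict[tuple[float, float], AxonBundle] = {}

    # -- trajectory family --------------------------------------------------
    def _spiral_coef(self, phi0: float) -> tuple[float, float]:
        """(b, c) of phi(r) = phi0 + b (r - r0)^c for entry angle phi0."""
        cfg = self.config
        if phi0 > 0:  # superior
            z = (phi0 - cfg["mu_sup"]) / cfg["w_sup"]
            b = np.exp(cfg["beta_sup"] + cfg["b1_sup"] * np.tanh(-z))
            c = cfg["c0_sup"] + cfg["c1_sup"] * np.tanh(z)
        else:  # inferior
            z = (-phi0 - cfg["mu_inf"]) / cfg["w_inf"]
            b = -np.exp(cfg["beta_inf"] + cfg["b1_inf"] * np.tanh(-z))
            c = cfg["c0_inf"] + cfg["c1_inf"] * np.tanh(z)
        return float(b), float(c)

    def bundle_from_seed(self, phi0: float, step_um: float | None = None) -> AxonBundle:
        """Trajectory for disc entry angle ``phi0`` in (-180, 0) u (0, 180].

        The polyline runs from the peripheral end toward the disc and
        terminates at the disc center.  Superior bundles are clipped where
        the spiral would cross the temporal raphe (phi = 180), inferior
        bundles at phi = -180, so no bundle crosses the horizontal raphe.
        """
        if phi0 == 0.0 or not -180.0 <= phi0 <= 180.0:
            raise ValueError("phi0 must lie in [-180, 0) or (0, 180]")
        step = self.step_um if step_um is None else float(step_um)
        cfg = self.config
        r0, rmax = cfg["r0_deg"], cfg["rmax_deg"]
        b, c = self._spiral_coef(phi0)
        r = np.linspace(r0, rmax, 3000)
        phi = phi0 + b * (r - r0) ** c
        # clip at the raphe (trajectories may not cross +-180 deg)
        lim = 180.0 if phi0 > 0 else -180.0
        crossed = (phi > lim) if phi0 > 0 else (phi < lim)
        if crossed.any():
            k = int(np.argmax(crossed))
            if k > 0:
                # interpolate the exact crossing radius
                r_cross = np.interp(
                    lim, [phi[k - 1], phi[k]][:: 1 if phi0 > 0 else -1],
                    [r[k - 1], r[k]][:: 1 if phi0 > 0 else -1],
                )
                r = np.concatenate([r[:k], [r_cross]])
                phi = np.concatenate([phi[:k], [lim]])
            else:
                r = np.array([r0])
                phi = np.array([phi0])
        # disc-centered polar -> horizontal-raphe frame (um)
        d_deg = self.optic_disc_um[0] / self.um_per_deg
        x_deg = d_deg + r * np.cos(np.deg2rad(phi))
        y_deg = r * np.sin(np.deg2rad(phi))
        xy = np.column_stack([x_deg, y_deg]) * self.um_per_deg
        # periphery -> disc ordering, then terminal vertex at the disc center
        xy = xy[::-1]
        xy = np.vstack([xy, [self.optic_disc_um[0], 0.0]])
        # nasal-side shear lifts the disc to its anatomical elevation while
        # leaving the temporal half-plane (and hence the raphe) untouched
        y_od = self.optic_disc_um[1]
        if y_od != 0.0:
            xy = xy.copy()
            xy[:, 1] += y_od * np.clip(xy[:, 0] / self.optic_disc_um[0], 0.0, 1.0)
        bundle = AxonBundle(xy=xy, phi0=float(phi0), step_um=step)
        return bundle.resample(step)

    # -- closest-bundle queries ---------------------------------------------
    def _fan(self, step_um: float | None = None) -> list[AxonBundle]:
        step = self.step_um if step_um is None else float(step_um)
        if step not in self._fan_cache:
            phis = np.concatenate(
                [
                    np.linspace(-179.9, -0.1, self.n_seeds),
                    np.linspace(0.1, 180.0, self.n_seeds),
                ]
            )
            self._fan_cache[step] = [self.bundle_from_seed(p, step) for p in phis]
        return self._fan_cache[step]

    def _in_disc(self, p) -> bool:
        od = np.asarray(self.optic_disc_um)
        r0_um = self.config["r0_deg"] * self.um_per_deg
        return bool(np.hypot(*(np.asarray(p, dtype=float) - od)) < r0_um)

    def axon_bundle(self, p, refine_tol_deg: float = 1e-4) -> AxonBundle:
        """The modeled fiber bundle passing closest to retinal point ``p``.

        Searches a dense fan of disc-entry angles, then refines the entry
        angle by golden-section search.  The returned polyline passes within
        about one discretization step of ``p`` for points inside the modeled
        region.  Points inside the optic-disc region are rejected.
        """
        p = np.asarray(p, dtype=float)
        if self._in_disc(p):
            raise ValueError("point lies inside the optic-disc region")
        cache_key = (round(float(p[0]), 3), round(float(p[1]), 3))
        if cache_key in self._point_cache:
            return self._point_cache[cache_key]
        fan = self._fan()
        dists = np.array([b.distance_to(p) for b in fan])
        k = int(np.argmin(dists))
        # refine within the bracketing neighbors of the same hemifield
        phi_k = fan[k].phi0
        lo = fan[k - 1].phi0 if k > 0 and np.sign(fan[k - 1].phi0) == np.sign(phi_k) \
            else phi_k
        hi = fan[k + 1].phi0 if k + 1 < len(fan) and \
            np.sign(fan[k + 1].phi0) == np.sign(phi_k) else phi_k
        if lo == hi:
            self._point_cache[cache_key] = fan[k]
            return fan[k]
        phi = self._golden(lambda f: self.bundle_from_seed(f).distance_to(p),
                           lo, hi, refine_tol_deg)
        best = self.bundle_from_seed(phi)
        if best.distance_to(p) > dists[k]:
            best = fan[k]
        self._point_cache[cache_key] = best
        return best

    @staticmethod
    def _golden(fn, lo: float, hi: float, tol: float) -> float:
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = fn(c), fn(d)
        while abs(b - a) > tol:
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = fn(c)
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = fn(d)
        return (a + b) / 2.0

    # -- pair distances -------------------------------------------------------
    def pair_distances(self, e1, e2, names: tuple[str, str] | None = None,
                       reference: str = "temporal") -> "PairDistances":
        """Decompose the separation of two electrodes into axonal components.

        Roles are assigned by x coordinate (larger x = more nasal, toward the
        optic disc; at equal x the electrode with larger ``|y|`` is temporal).
        The reference bundle is the axon of the *temporal* electrode (default;
        ``reference='nasal'`` selects the variant wording that follows the
        nasal electrode's closest axon instead).  Then

        - ``between_axon``: minimum distance from the nasal electrode center
          to the reference bundle;
        - ``along_axon``: arc length along the reference bundle from the
          temporal electrode's foot point to the between-axon foot point.

        Deterministic and independent of argument order.
        """
        e1 = np.asarray(e1, dtype=float)
        e2 = np.asarray(e2, dtype=float)
        if np.allclose(e1, e2):
            raise ValueError("pair distances need two distinct electrodes")
        if reference not in ("temporal", "nasal"):
            raise ValueError("reference must be 'temporal' or 'nasal'")
        order = ((tuple(e1), names[0] if names else None),
                 (tuple(e2), names[1] if names else None))
        # nasal = larger x; tie-break: larger |y| is temporal
        (p1, n1), (p2, n2) = order
        if (p1[0], -abs(p1[1])) > (p2[0], -abs(p2[1])):
            nasal, nasal_name, temporal, temporal_name = p1, n1, p2, n2
        else:
            nasal, nasal_name, temporal, temporal_name = p2, n2, p1, n1
        nasal = np.asarray(nasal)
        temporal = np.asarray(temporal)

        anchor = temporal if reference == "temporal" else nasal
        query = nasal if reference == "temporal" else temporal
        bundle = self.axon_bundle(anchor)
        (d_q, s_q) = bundle.project(query[None, :])
        (_, s_a) = bundle.project(anchor[None, :])
        euclid = float(np.hypot(*(nasal - temporal)))
        # the reference bundle passes through the anchor up to discretization
        # (sub-step residual near clipped bundle ends), so the between-axon
        # distance can never truly exceed the Euclidean separation
        between = min(float(d_q[0]), euclid)
        along = float(abs(s_q[0] - s_a[0]))
        return PairDistances(
            euclidean=euclid,
            between_axon=between,
            along_axon=along,
            nasal=tuple(map(float, nasal)),
            temporal=tuple(map(float, temporal)),
            nasal_name=nasal_name,
            temporal_name=temporal_name,
            reference_bundle=bundle,
        )


@dataclass
class PairDistances:
    """Axonal distance decomposition for one electrode pair (um)."""

    euclidean: float
    between_axon: float
    along_axon: float
    nasal: tuple[float, float]
    temporal: tuple[float, float]
    nasal_name: str | None = None
    temporal_name: str | None = None
    reference_bundle: AxonBundle | None = None

    def as_row(self) -> dict[str, float]:
        return {
            "euclidean_um": self.euclidean,
            "between_axon_um": self.between_axon,
            "along_axon_um": self.along_axon,
            "efd_nasal_um": float(np.hypot(*self.nasal)),
            "efd_temporal_um": float(np.hypot(*self.temporal)),
        }
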