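"""Parametric asymmetric AAA geometry.

The vessel is a 190 mm long tube with an asymmetric aneurysmal bulge, bounded
by five exponential boundary curves: two lateral (coronal plane, symmetric),
two anterior and one posterior (sagittal plane, asymmetric).  Each curve is a
baseline radius plus a localized Gaussian-type bump,

    y(x) = C0 + A * exp(-P1 * (x - x_c)^2 / C2),        A = kappa * C1 * C3 * P2,

with the published coefficient table as defaults.  "Middle" curves (and the
posterior curve) are centred at the bulge apex x_c = 95 mm; "near end" curves
carry one bump at each end station and set the neck diameter.  The typeset
source formula is ambiguous, so the per-curve amplitude scales ``kappa`` are
fixed once by calibrating against the four published dimensions of the shape:
64.8 mm maximum lateral diameter, 54.6 mm maximum anterior-posterior diameter,
21.6 mm neck diameter and 190 mm total length.  See docs/methods.md.

Coordinates: x axial (0 at the proximal inlet), y lateral, z anterior (+) /
posterior (-).  All lengths in this module are millimetres.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, GeometryError

# Published overall dimensions of the shape (mm); the amplitude calibration
# reproduces these, see calibrate_parse().
TOTAL_LENGTH = 190.0
MAX_LATERAL_DIAMETER = 64.8
MAX_AP_DIAMETER = 54.6
NECK_DIAMETER = 21.6
WALL_THICKNESS = 1.5
BULGE_CENTER = TOTAL_LENGTH / 2.0  # apex at mid-length, consistent with the sagittal profile

CURVE_NAMES = (
    "lateral-near-end",
    "lateral-middle",
    "anterior-near-ends",
    "anterior-middle",
    "posterior",
)

#: Curves centred at the end stations rather than at the bulge apex.
_NEAR_END = frozenset({"lateral-near-end", "anterior-near-ends"})


@dataclass(frozen=True)
class CurveSpec:
    """One boundary-curve row: baseline C0, amplitude factors C1/C3/P2 and
    Gaussian width factors C2/P1 (all per the published coefficient table)."""

    name: str
    c0: float  # mm
    c1: float  # mm
    c2: float  # mm^2
    c3: float  # mm^2
    p1: float  # dimensionless
    p2: float  # dimensionless

    def __post_init__(self):
        if self.name not in CURVE_NAMES:
            raise ConfigurationError(f"unknown curve name {self.name!r}")
        if self.c0 <= 0 or self.c1 < 0 or self.c2 <= 0 or self.c3 <= 0:
            raise ConfigurationError(f"invalid coefficients for curve {self.name!r}")

    @property
    def amplitude_factor(self) -> float:
        """Unscaled bump amplitude C1*C3*P2 (mm)."""
        return self.c1 * self.c3 * self.p2

    def shape(self, x) -> np.ndarray:
        """Unit-amplitude bump profile at axial position(s) x (mm)."""
        x = np.asarray(x, dtype=float)
        rate = self.p1 / self.c2
        if self.name in _NEAR_END:
            return np.exp(-rate * x**2) + np.exp(-rate * (TOTAL_LENGTH - x) ** 2)
        return np.exp(-rate * (x - BULGE_CENTER) ** 2)


def table1_curves() -> dict[str, CurveSpec]:
    """The five default boundary curves (published coefficient table)."""
    rows = [
        ("lateral-near-end", 10.2, 100.0, 7.0, 0.8, 0.009, 0.85),
        ("lateral-middle", 10.0, 100.0, 10.0, 0.8, 0.007, 0.75),
        ("anterior-near-ends", 9.7, 100.0, 8.0, 0.8, 0.0095, 0.95),
        ("anterior-middle", 10.5, 100.0, 9.0, 0.8, 0.006, 0.81),
        ("posterior", 10.4, 100.0, 8.0, 0.8, 0.008, 0.39),
    ]
    return {r[0]: CurveSpec(*r) for r in rows}


# --------------------------------------------------------------------------
# Calibrated parse


@dataclass(frozen=True)
class CalibratedParse:
    """Amplitude scales fixing the ambiguous curve formula.

    kappa maps each curve name to the scale in A = kappa * C1 * C3 * P2.
    blend_sigma (mm) is the axial width of the smooth weight that hands the
    lateral/anterior edges over from the near-end curves to the middle ones.
    """

    kappa: dict[str, float]
    blend_sigma: float = 35.0

    def amplitude(self, spec: CurveSpec) -> float:
        return self.kappa[spec.name] * spec.amplitude_factor

    def end_weight(self, x) -> np.ndarray:
        """Smooth weight: ~1 at the end stations, ~0 at the bulge apex."""
        x = np.asarray(x, dtype=float)
        s = self.blend_sigma
        return np.exp(-((x / s) ** 2)) + np.exp(-(((TOTAL_LENGTH - x) / s) ** 2))


@lru_cache(maxsize=None)
def calibrate_parse(blend_sigma: float = 35.0) -> CalibratedParse:
    """Solve for the five amplitude scales from the four published dimensions.

    Linear system in the five bump amplitudes A_i: lateral half-width equals
    32.4 mm at the apex and 10.8 mm at the ends; the anterior-posterior chord
    equals 54.6 mm at the apex and 21.6 mm at the ends; the anterior-middle
    and posterior amplitudes keep their tabulated C1*C3*P2 ratio (one ratio
    constraint closes the system).
    """
    curves = table1_curves()
    order = list(CURVE_NAMES)
    parse0 = CalibratedParse({n: 1.0 for n in order}, blend_sigma)

    def edge_coeffs(x: float) -> tuple[np.ndarray, dict[str, float]]:
        """Coefficient row: edge values as affine functions of the A_i."""
        w = float(parse0.end_weight(x))
        coeff = {n: 0.0 for n in order}
        coeff["lateral-near-end"] = w * float(curves["lateral-near-end"].shape(x))
        coeff["lateral-middle"] = (1 - w) * float(curves["lateral-middle"].shape(x))
        coeff["anterior-near-ends"] = w * float(curves["anterior-near-ends"].shape(x))
        coeff["anterior-middle"] = (1 - w) * float(curves["anterior-middle"].shape(x))
        coeff["posterior"] = float(curves["posterior"].shape(x))
        base_lat = w * curves["lateral-near-end"].c0 + (1 - w) * curves["lateral-middle"].c0
        base_ant = w * curves["anterior-near-ends"].c0 + (1 - w) * curves["anterior-middle"].c0
        base_post = curves["posterior"].c0
        return coeff, {"lat": base_lat, "ant": base_ant, "post": base_post}

    A = np.zeros((5, 5))
    b = np.zeros(5)
    # E1: lateral half-width at apex = 32.4
    c, base = edge_coeffs(BULGE_CENTER)
    A[0] = [c["lateral-near-end"], c["lateral-middle"], 0, 0, 0]
    b[0] = MAX_LATERAL_DIAMETER / 2 - base["lat"]
    # E2: lateral half-width at the end = 10.8
    c, base = edge_coeffs(0.0)
    A[1] = [c["lateral-near-end"], c["lateral-middle"], 0, 0, 0]
    b[1] = NECK_DIAMETER / 2 - base["lat"]
    # E3: anterior-posterior chord at apex = 54.6
    c, base = edge_coeffs(BULGE_CENTER)
    A[2] = [0, 0, c["anterior-near-ends"], c["anterior-middle"], c["posterior"]]
    b[2] = MAX_AP_DIAMETER - base["ant"] - base["post"]
    # E4: anterior-posterior chord at the end = 21.6
    c, base = edge_coeffs(0.0)
    A[3] = [0, 0, c["anterior-near-ends"], c["anterior-middle"], c["posterior"]]
    b[3] = NECK_DIAMETER - base["ant"] - base["post"]
    # E5: anterior-middle / posterior amplitudes keep the tabulated ratio
    A[4] = [0, 0, 0, 1.0 / curves["anterior-middle"].amplitude_factor,
            -1.0 / curves["posterior"].amplitude_factor]
    b[4] = 0.0

    amps = np.linalg.solve(A, b)
    kappa = {n: float(a / curves[n].amplitude_factor) for n, a in zip(order, amps)}
    return CalibratedParse(kappa, blend_sigma)


def eval_boundary_curve(spec: CurveSpec, x, parse: CalibratedParse | None = None) -> np.ndarray:
    """Radial offset (mm) of a single named boundary curve at axial x (mm)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > TOTAL_LENGTH):
        raise DomainError(f"axial position outside [0, {TOTAL_LENGTH}] mm")
    parse = parse or calibrate_parse()
    out = spec.c0 + parse.amplitude(spec) * spec.shape(x)
    return out if out.ndim else float(out)


def _blended_edge(near: CurveSpec, middle: CurveSpec, x, parse: CalibratedParse) -> np.ndarray:
    w = parse.end_weight(x)
    y_near = near.c0 + parse.amplitude(near) * near.shape(x)
    y_mid = middle.c0 + parse.amplitude(middle) * middle.shape(x)
    return w * y_near + (1 - w) * y_mid


# --------------------------------------------------------------------------
# Geometry container


@dataclass(frozen=True)
class AAAGeometry:
    """Discretized vessel: per-station inner boundary radii and metadata.

    x: axial stations (mm); lateral: coronal half-width y(x) (mm);
    anterior / posterior: signed sagittal extents z_a(x) > 0 > z_p(x) (mm).
    Cross-sections are ellipses through the four extremal points.
    """

    x: np.ndarray
    lateral: np.ndarray
    anterior: np.ndarray
    posterior: np.ndarray
    thickness: float = WALL_THICKNESS
    n_circumferential: int = 32
    superellipse_exponent: float = 2.0

    @property
    def n_stations(self) -> int:
        return len(self.x)

    @property
    def length(self) -> float:
        return float(self.x[-1] - self.x[0])

    @property
    def center(self) -> np.ndarray:
        """Sagittal centerline z_c(x) = (z_a + z_p)/2 (mm)."""
        return 0.5 * (self.anterior + self.posterior)

    @property
    def ap_semi(self) -> np.ndarray:
        """Anterior-posterior semi-chord b(x) = (z_a - z_p)/2 (mm)."""
        return 0.5 * (self.anterior - self.posterior)

    def surface_points(self) -> np.ndarray:
        """Inner-surface point cloud, shape (n_stations, n_circ, 3), mm."""
        phi = np.linspace(0.0, 2 * np.pi, self.n_circumferential, endpoint=False)
        e = self.superellipse_exponent
        c, s = np.cos(phi), np.sin(phi)
        cs = np.sign(c) * np.abs(c) ** (2.0 / e)
        ss = np.sign(s) * np.abs(s) ** (2.0 / e)
        y = self.lateral[:, None] * ss[None, :]
        z = self.center[:, None] + self.ap_semi[:, None] * cs[None, :]
        x = np.broadcast_to(self.x[:, None], y.shape)
        return np.stack([x, y, z], axis=-1)

    def surface_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Closed triangulated inner surface: (vertices (V,3), faces (F,3))."""
        pts = self.surface_points()
        n, m = pts.shape[:2]
        verts = pts.reshape(-1, 3)
        faces = []
        for i in range(n - 1):
            for j in range(m):
                a = i * m + j
                b = i * m + (j + 1) % m
                c = (i + 1) * m + j
                d = (i + 1) * m + (j + 1) % m
                faces.append((a, b, d))
                faces.append((a, d, c))
        # end caps: triangle fans about the station centroids
        c0 = len(verts)
        c1 = c0 + 1
        verts = np.vstack([verts, pts[0].mean(axis=0), pts[-1].mean(axis=0)])
        for j in range(m):
            faces.append((c0, (j + 1) % m, j))
            faces.append((c1, (n - 1) * m + j, (n - 1) * m + (j + 1) % m))
        return verts, np.asarray(faces, dtype=np.int64)


@dataclass(frozen=True)
class DiameterReport:
    """Extremal inner diameters of a generated geometry (mm)."""

    max_lateral: float
    max_anterior_posterior: float
    proximal_neck: float
    distal_neck: float
    axial_location_of_max: float

    def as_dict(self) -> dict[str, float]:
        return {
            "max_lateral_diameter_mm": self.max_lateral,
            "max_anterior_posterior_diameter_mm": self.max_anterior_posterior,
            "proximal_neck_diameter_mm": self.proximal_neck,
            "distal_neck_diameter_mm": self.distal_neck,
            "axial_location_of_max_mm": self.axial_location_of_max,
        }


def build_geometry(
    curves: dict[str, CurveSpec] | None = None,
    n_stations: int = 200,
    n_circumferential: int = 32,
    parse: CalibratedParse | None = None,
) -> AAAGeometry:
    """Discretize the vessel bounded by the five curves.

    Lateral and anterior edges blend their near-end and middle curves with the
    parse's smooth axial weight; the posterior edge is a single curve.
    """
    curves = curves if curves is not None else table1_curves()
    missing = set(CURVE_NAMES) - set(curves)
    if missing:
        raise ConfigurationError(f"missing boundary curves: {sorted(missing)}")
    if n_stations < 20 or n_circumferential < 16:
        raise ConfigurationError("need n_stations >= 20 and n_circumferential >= 16")
    parse = parse or calibrate_parse()

    x = np.linspace(0.0, TOTAL_LENGTH, n_stations)
    lat = _blended_edge(curves["lateral-near-end"], curves["lateral-middle"], x, parse)
    ant = _blended_edge(curves["anterior-near-ends"], curves["anterior-middle"], x, parse)
    post = -(curves["posterior"].c0 + parse.amplitude(curves["posterior"]) * curves["posterior"].shape(x))

    if np.any(lat <= 0) or np.any(ant - post <= 0):
        raise GeometryError("cross-sections self-intersect or have non-positive extent")
    return AAAGeometry(x=x, lateral=lat, anterior=ant, posterior=post,
                       n_circumferential=n_circumferential)


def measure_diameters(geom: AAAGeometry) -> DiameterReport:
    """Extremal inner diameters by direct search over the stations."""
    if np.any(geom.lateral <= 0) or np.any(geom.anterior - geom.posterior <= 0):
        raise GeometryError("degenerate geometry: non-positive radius")
    lat_d = 2.0 * geom.lateral
    ap_d = geom.anterior - geom.posterior
    i_max = int(np.argmax(lat_d))
    neck = lambda i: 0.5 * (lat_d[i] + ap_d[i])
    return DiameterReport(
        max_lateral=float(lat_d[i_max]),
        max_anterior_posterior=float(np.max(ap_d)),
        proximal_neck=float(neck(0)),
        distal_neck=float(neck(-1)),
        axial_location_of_max=float(geom.x[i_max]),
    )


def sagittal_profile(geom: AAAGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Anterior and posterior polylines [(x, z), ...] (mm) bounding the
    sagittal-plane fluid domain."""
    ant = np.column_stack([geom.x, geom.anterior])
    post = np.column_stack([geom.x, geom.posterior])
    return ant, post


def axially_stretched(geom: AAAGeometry, factor: float) -> AAAGeometry:
    """Lengthen the vessel by scaling the axial coordinate (radii unchanged).

    Used for the length-sensitivity study: a longer vessel (longer necks)
    offers more flow resistance, hence a larger inlet-outlet pressure drop.
    """
    if factor <= 0:
        raise DomainError("stretch factor must be positive")
    return replace(geom, x=geom.x * factor)


# --------------------------------------------------------------------------
# Export

def export_surface(geom: AAAGeometry, path, fmt: str = "stl") -> None:
    """Write the closed inner surface as STL ('stl', 'stl-ascii') or legacy
    VTK polydata ('vtk').  Units are mm."""
    import trimesh

    verts, faces = geom.surface_mesh()
    fmt = fmt.lower()
    if fmt in ("stl", "stl-binary", "stl-ascii"):
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        kind = "stl_ascii" if fmt == "stl-ascii" else "stl"
        data = trimesh.exchange.export.export_mesh(mesh, None, file_type=kind)
        mode = "wb" if isinstance(data, bytes) else "w"
        try:
            with open(path, mode) as fh:
                fh.write(data)
        except OSError as exc:
            raise IOError(f"cannot write surface to {path}: {exc}") from exc
    elif fmt == "vtk":
        _write_legacy_vtk_polydata(path, verts, faces)
    else:
        raise ConfigurationError(f"unknown surface format {fmt!r}")


def _write_legacy_vtk_polydata(path, verts: np.ndarray, faces: np.ndarray) -> None:
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\naaafsi surface (mm)\nASCII\nDATASET POLYDATA\n")
    buf.write(f"POINTS {len(verts)} float\n")
    for v in verts:
        buf.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
    buf.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
    for f in faces:
        buf.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    try:
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
    except OSError as exc:
        raise IOError(f"cannot write surface to {path}: {exc}") from exc


def export_profile_csv(geom: AAAGeometry, path) -> None:
    """Per-station (x, lateral half-width, z_a, z_p) table in mm."""
    df = pd.DataFrame({
        "x_mm": geom.x,
        "lateral_halfwidth_mm": geom.lateral,
        "z_anterior_mm": geom.anterior,
        "z_posterior_mm": geom.posterior,
    })
    df.to_csv(path, index=False)
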