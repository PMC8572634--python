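"""Synthetic head-neck CTA phantoms with a Circle of Willis vessel tree.

The generator produces paired (volume, mask) data with exactly known
ground truth: a tubular arterial tree on HU-scale intensities inside a
soft-tissue head with a bone shell and air background, plus smooth
multiplicative intensity inhomogeneity and additive Gaussian noise.
Anatomical *topology* (which segments exist and how they connect) is what
matters for the segmentation and variant-classification tasks, so
centerlines are piecewise-cubic curves through hand-designed waypoints
scaled to the volume, not patient-derived geometry.

Supported ground-truth manipulations:

* per-segment status: ``normal`` / ``hypoplastic`` (radius scaled to 25 %
  of the contralateral homologue, comfortably beyond the "over 70 %
  thinner" variation rule) / ``absent`` (contributes no voxels);
* focal stenosis: a cosine-shaped radius dip reaching ``1 - severity/100``
  of the nominal radius at its center.

The anterior communicating artery (Aco) is given the smallest default
radius of all ring segments: sub-voxel-scale vessels are the known hard
case for both manual and automatic detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .volume import Volume

# ---------------------------------------------------------------------------
# Naming and topology

SEGMENT_NAMES = (
    "ICA_L", "ICA_R", "BA", "VA_L", "VA_R",
    "A1_L", "A1_R", "Aco", "P1_L", "P1_R",
    "Pco_L", "Pco_R", "M1_L", "M1_R",
    "pACA_L", "pACA_R", "pPCA_L", "pPCA_R",
)

#: the seven ring segments whose normal/variation status defines CoW completeness
COW_RING_SEGMENTS = ("Aco", "A1_L", "A1_R", "Pco_L", "Pco_R", "P1_L", "P1_R")

CONTRALATERAL = {}
for _n in SEGMENT_NAMES:
    if _n.endswith("_L"):
        CONTRALATERAL[_n] = _n[:-2] + "_R"
    elif _n.endswith("_R"):
        CONTRALATERAL[_n] = _n[:-2] + "_L"

DEFAULT_RADII_MM = {
    "ICA_L": 2.0, "ICA_R": 2.0, "BA": 1.8, "VA_L": 1.4, "VA_R": 1.4,
    "A1_L": 1.1, "A1_R": 1.1, "Aco": 0.6, "P1_L": 1.1, "P1_R": 1.1,
    "Pco_L": 0.8, "Pco_R": 0.8, "M1_L": 1.5, "M1_R": 1.5,
    "pACA_L": 1.0, "pACA_R": 1.0, "pPCA_L": 1.0, "pPCA_R": 1.0,
}

# Waypoints in normalized volume coordinates (fractions of physical extent);
# (x, y, z): x left->right, y anterior->posterior, z inferior->superior.
# The communicating ring sits in the z ~ 0.6 plane; ICA/VA/BA feed it from below,
# post-communicating stubs (pACA/pPCA) and M1 leave it.
_W = {
    "ICA_L": [(0.32, 0.42, 0.08), (0.34, 0.46, 0.35), (0.32, 0.42, 0.60)],
    "VA_L": [(0.44, 0.70, 0.08), (0.47, 0.68, 0.18), (0.50, 0.66, 0.28)],
    "BA": [(0.50, 0.66, 0.28), (0.50, 0.64, 0.45), (0.50, 0.63, 0.58)],
    "A1_L": [(0.32, 0.42, 0.60), (0.37, 0.34, 0.61), (0.44, 0.30, 0.62)],
    "Aco": [(0.44, 0.30, 0.62), (0.50, 0.30, 0.62), (0.56, 0.30, 0.62)],
    "P1_L": [(0.50, 0.63, 0.58), (0.43, 0.62, 0.60), (0.36, 0.58, 0.62)],
    "Pco_L": [(0.36, 0.58, 0.62), (0.33, 0.50, 0.61), (0.32, 0.42, 0.60)],
    "M1_L": [(0.32, 0.42, 0.60), (0.22, 0.43, 0.61), (0.13, 0.44, 0.62)],
    "pACA_L": [(0.44, 0.30, 0.62), (0.44, 0.29, 0.72), (0.44, 0.28, 0.82)],
    "pPCA_L": [(0.36, 0.58, 0.62), (0.34, 0.62, 0.72), (0.32, 0.66, 0.82)],
}


def _mirror(points):
    return [(1.0 - x, y, z) for x, y, z in points]


def canonical_waypoints() -> dict[str, np.ndarray]:
    """Normalized-coordinate waypoints for every segment (right side mirrored)."""
    out = {}
    for name, pts in _W.items():
        out[name] = np.asarray(pts, dtype=float)
        if name.endswith("_L"):
            out[name[:-2] + "_R"] = np.asarray(_mirror(pts), dtype=float)
    return out


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class VesselSegment:
    """One artery segment: a centerline polyline with a radius profile.

    ``centerline`` is (n, 3) world-mm points, densely sampled; ``radius_profile``
    gives the local tube radius (mm) at each point. ``status`` records the
    generative ground truth; absent segments rasterize to nothing.
    """

    name: str
    centerline: np.ndarray
    radius_profile: np.ndarray
    status: str = "normal"

    def __post_init__(self):
        if self.name not in SEGMENT_NAMES:
            raise ValueError(f"unknown segment name {self.name!r}")
        if self.status not in ("normal", "hypoplastic", "absent"):
            raise ValueError(f"invalid status {self.status!r}")
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        self.radius_profile = np.asarray(self.radius_profile, dtype=float)
        if self.status != "absent" and np.any(self.radius_profile <= 0):
            raise ValueError(f"{self.name}: radius profile must be positive")

    @property
    def arclength_mm(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)))


@dataclass
class PhantomSpec:
    """Full generative recipe for one phantom; identical specs with identical
    seeds produce bit-identical phantoms."""

    volume_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    segment_statuses: dict[str, str] = field(default_factory=dict)
    base_radii_mm: dict[str, float] = field(default_factory=dict)
    stenoses: list[tuple[str, float, float]] = field(default_factory=list)
    vessel_hu: float = 350.0
    tissue_hu: float = 40.0
    bone_hu: float = 1200.0
    air_hu: float = -1000.0
    noise_sd: float = 15.0
    bias_field_amplitude: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        radii = {**DEFAULT_RADII_MM, **self.base_radii_mm}
        for name, status in self.segment_statuses.items():
            if name not in SEGMENT_NAMES:
                raise ValueError(f"unknown segment {name!r}")
            if status not in ("normal", "hypoplastic", "absent"):
                raise ValueError(f"invalid status {status!r} for {name}")
            if status == "hypoplastic" and name not in CONTRALATERAL:
                raise ValueError(f"{name} has no contralateral homologue; "
                                 "hypoplastic status undefined")
        for seg, pos, sev in self.stenoses:
            if seg not in SEGMENT_NAMES:
                raise ValueError(f"stenosis on unknown segment {seg!r}")
            if self.segment_statuses.get(seg, "normal") == "absent":
                raise ValueError(f"contradictory spec: stenosis on absent segment {seg}")
            if not (0.0 <= pos <= 1.0):
                raise ValueError(f"stenosis position {pos} outside [0, 1]")
            if not (0.0 <= sev < 100.0):
                raise ValueError(f"stenosis severity {sev} outside [0, 100)")
        if any(n <= 0 for n in self.volume_shape) or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("volume shape and spacing must be positive")
        for name, r in radii.items():
            if r <= 0:
                raise ValueError(f"non-positive base radius for {name}")


@dataclass
class CoWConfiguration:
    """Normal/variation status of the seven ring segments (the classification
    ground truth), plus the fused-ACA flag that exempts a missing Aco."""

    statuses: dict[str, str]
    aco_fused_flag: bool = False

    def __post_init__(self):
        for name in COW_RING_SEGMENTS:
            if name not in self.statuses:
                raise ValueError(f"missing status for ring segment {name}")
        for name, s in self.statuses.items():
            if s not in ("normal", "variation"):
                raise ValueError(f"invalid ring status {s!r}")


@dataclass
class Phantom:
    volume: Volume
    mask: Volume
    tree: list[VesselSegment]
    config: CoWConfiguration
    spec: PhantomSpec

    def segment(self, name: str) -> VesselSegment:
        for s in self.tree:
            if s.name == name:
                return s
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Geometry construction


def _spline_points(waypoints: np.ndarray, step_mm: float) -> np.ndarray:
    """Densely sample a natural cubic spline through the waypoints."""
    chord = np.linalg.norm(np.diff(waypoints, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    if t[-1] <= 0:
        return waypoints[:1]
    spline = CubicSpline(t, waypoints, axis=0, bc_type="natural")
    n = max(int(np.ceil(t[-1] / step_mm)) + 1, 4)
    return spline(np.linspace(0.0, t[-1], n))


def build_tree(spec: PhantomSpec) -> list[VesselSegment]:
    """Instantiate the CoW tree in world mm for a given phantom spec."""
    spec.validate()
    extent = np.array(spec.volume_shape) * np.array(spec.spacing_mm)
    radii = {**DEFAULT_RADII_MM, **spec.base_radii_mm}
    step = 0.25 * min(spec.spacing_mm)
    tree = []
    for name, wp_norm in canonical_waypoints().items():
        status = spec.segment_statuses.get(name, "normal")
        pts = _spline_points(wp_norm * extent, step)
        r0 = radii[name]
        if status == "hypoplastic":
            r0 = 0.25 * radii[CONTRALATERAL[name]]
        prof = np.full(len(pts), r0)
        # arclength parameter in [0, 1] for stenosis placement
        seglen = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        t = seglen / max(seglen[-1], 1e-12)
        for sseg, pos, sev in spec.stenoses:
            if sseg != name:
                continue
            halfwidth = 0.06  # stenotic arc spans ~12 % of segment length
            d = np.abs(t - pos)
            in_arc = d <= halfwidth
            dip = 0.5 * (1.0 + np.cos(np.pi * d[in_arc] / halfwidth))
            prof[in_arc] *= 1.0 - (sev / 100.0) * dip
        tree.append(VesselSegment(name, pts, prof, status))
    # sizing check: the tree (tube surfaces included) must fit in the volume
    for seg in tree:
        if seg.status == "absent":
            continue
        lo = seg.centerline - seg.radius_profile[:, None]
        hi = seg.centerline + seg.radius_profile[:, None]
        if np.any(lo < 0) or np.any(hi > extent):
            raise ValueError(
                f"volume of extent {tuple(extent)} mm too small to contain "
                f"segment {seg.name}")
    return tree


# ---------------------------------------------------------------------------
# Rasterization

_SUPERSAMPLE = 3  # sub-voxel samples per axis for partial-volume occupancy


def _segment_distance_field(seg: VesselSegment, vol_shape, spacing, points):
    """Signed-ish margin d(p) - r(nearest centerline sample) for query points."""
    from scipy.spatial import cKDTree

    tree = cKDTree(seg.centerline)
    k = min(8, len(seg.centerline))
    dists, idx = tree.query(points, k=k)
    if k == 1:
        dists, idx = dists[:, None], idx[:, None]
    margin = dists - seg.radius_profile[idx]
    return margin.min(axis=1)


def rasterize_segment(seg: VesselSegment, shape, spacing_mm,
                      partial_volume: bool = False) -> np.ndarray:
    """Binary mask (or occupancy fraction) of one segment on the voxel grid.

    A voxel belongs to the binary mask iff its *center* lies within the local
    radius of the centerline. With ``partial_volume=True`` the returned array
    is the sub-voxel occupancy fraction estimated on a 3x3x3 sub-grid.
    """
    out = np.zeros(shape, dtype=float if partial_volume else bool)
    if seg.status == "absent":
        return out
    spacing = np.asarray(spacing_mm, dtype=float)
    rmax = float(seg.radius_profile.max())
    halfdiag = 0.5 * float(np.linalg.norm(spacing))
    lo = np.maximum(np.floor((seg.centerline.min(0) - rmax) / spacing - 1), 0).astype(int)
    hi = np.minimum(np.ceil((seg.centerline.max(0) + rmax) / spacing + 1),
                    np.asarray(shape)).astype(int)
    if np.any(hi <= lo):
        return out
    axes = [(np.arange(l, h) + 0.5) * s for l, h, s in zip(lo, hi, spacing)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    sub = tuple(h - l for l, h in zip(lo, hi))
    centers = grid.reshape(-1, 3)
    margin = _segment_distance_field(seg, shape, spacing, centers)
    if not partial_volume:
        out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = (margin <= 0).reshape(sub)
        return out
    occ = np.where(margin <= -halfdiag, 1.0, 0.0)
    boundary = (margin > -halfdiag) & (margin <= halfdiag)
    if np.any(boundary):
        bpts = centers[boundary]
        offs = (np.stack(np.meshgrid(*[np.arange(_SUPERSAMPLE)] * 3,
                                     indexing="ij"), -1).reshape(-1, 3)
                + 0.5) / _SUPERSAMPLE - 0.5
        frac = np.zeros(len(bpts))
        for off in offs:
            m = _segment_distance_field(seg, shape, spacing, bpts + off * spacing)
            frac += (m <= 0)
        occ[boundary] = frac / len(offs)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = occ.reshape(sub)
    return out


def _bias_field(shape, amplitude, rng) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * (random quadratic in [-1, 1])."""
    if amplitude == 0:
        return np.ones(shape)
    coords = [np.linspace(-1, 1, n) for n in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    basis = [X, Y, Z, X * Y, X * Z, Y * Z, X**2, Y**2, Z**2]
    c = rng.standard_normal(len(basis))
    f = sum(ci * b for ci, b in zip(c, basis))
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak
    return 1.0 + amplitude * f


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render a phantom volume and its exact ground-truth mask."""
    spec.validate()
    tree = build_tree(spec)
    shape = tuple(spec.volume_shape)
    spacing = tuple(spec.spacing_mm)
    rng = np.random.default_rng(spec.seed)

    mask = np.zeros(shape, dtype=bool)
    occupancy = np.zeros(shape, dtype=float)
    for seg in tree:
        if seg.status == "absent":
            continue
        mask |= rasterize_segment(seg, shape, spacing, partial_volume=False)
        occupancy = np.maximum(
            occupancy, rasterize_segment(seg, shape, spacing, partial_volume=True))

    # head = ellipsoid of soft tissue, thin bone shell, air outside
    coords = [np.linspace(-1, 1, n) for n in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    rho = np.sqrt((X / 0.90) ** 2 + (Y / 0.90) ** 2 + (Z / 0.95) ** 2)
    intensity = np.full(shape, spec.air_hu)
    intensity[rho <= 1.10] = spec.bone_hu
    intensity[rho <= 1.00] = spec.tissue_hu
    intensity = intensity + occupancy * (spec.vessel_hu - spec.tissue_hu) * (rho <= 1.0)

    bias = _bias_field(shape, spec.bias_field_amplitude, rng)
    intensity = spec.air_hu + (intensity - spec.air_hu) * bias
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, shape)

    statuses = {
        name: ("variation" if spec.segment_statuses.get(name, "normal") != "normal"
               else "normal")
        for name in COW_RING_SEGMENTS
    }
    config = CoWConfiguration(statuses)
    volume = Volume(intensity.astype(np.float32), spacing)
    return Phantom(volume, Volume(mask, spacing), tree, config, spec)


# ---------------------------------------------------------------------------
# Cohorts

#: per-side variation probabilities reproducing the young-normal per-patient
#: prevalences (Aco 36 %, A1 11 %, Pco 85 %, P1 25 %) under independent sides:
#: per-side p solves 1 - (1-p)^2 = per-patient rate for bilateral segments.
DEFAULT_VARIATION_FREQS = {
    "Aco": 0.36,
    "A1_L": 0.057, "A1_R": 0.057,
    "Pco_L": 0.613, "Pco_R": 0.613,
    "P1_L": 0.134, "P1_R": 0.134,
}


def _validate_freqs(freqs: dict[str, float]) -> None:
    for name, p in freqs.items():
        if name not in SEGMENT_NAMES:
            raise ValueError(f"unknown segment {name!r}")
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability {p} for {name} outside [0, 1]")


def _draw_spec(rng, base: PhantomSpec, variation_freqs, stenosis_freqs,
               hypoplasia_fraction: float) -> PhantomSpec:
    statuses: dict[str, str] = {}
    variant = {s: rng.random() < p for s, p in sorted(variation_freqs.items())}
    for segname, is_var in variant.items():
        if not is_var:
            continue
        contra = CONTRALATERAL.get(segname)
        if contra is not None and not variant.get(contra, False):
            # unambiguous ground truth: hypoplastic only vs a normal homologue
            statuses[segname] = ("hypoplastic"
                                 if rng.random() < hypoplasia_fraction else "absent")
        else:
            statuses[segname] = "absent"
    stenoses = []
    for segname, p in sorted(stenosis_freqs.items()):
        if statuses.get(segname, "normal") != "absent" and rng.random() < p:
            stenoses.append((segname,
                             float(rng.uniform(0.3, 0.7)),
                             float(rng.uniform(30.0, 90.0))))
    return replace(base, segment_statuses=statuses, stenoses=stenoses,
                   seed=int(rng.integers(0, 2**31 - 1)))


def sample_cohort_specs(
    n: int,
    variation_freqs: dict[str, float] | None = None,
    stenosis_freqs: dict[str, float] | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    hypoplasia_fraction: float = 0.5,
) -> list[PhantomSpec]:
    """Draw ``n`` phantom specs with independent per-segment variations.

    ``variation_freqs`` maps segment name -> probability of a variation
    (realized as hypoplasia with probability ``hypoplasia_fraction`` when the
    contralateral homologue is normal, otherwise absence; Aco variations are
    always absences); ``None`` uses
    the published young-normal prevalences (``DEFAULT_VARIATION_FREQS``),
    ``{}`` disables variations. ``stenosis_freqs`` maps segment name ->
    probability of one focal stenosis with severity ~ U[30, 90] % at
    position ~ U[0.3, 0.7].
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    variation_freqs = DEFAULT_VARIATION_FREQS if variation_freqs is None else variation_freqs
    stenosis_freqs = stenosis_freqs or {}
    _validate_freqs(variation_freqs)
    _validate_freqs(stenosis_freqs)
    if not (0.0 <= hypoplasia_fraction <= 1.0):
        raise ValueError("hypoplasia_fraction outside [0, 1]")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    return [_draw_spec(rng, base, variation_freqs, stenosis_freqs,
                       hypoplasia_fraction) for _ in range(n)]


def generate_cohort(
    n: int,
    variation_freqs: dict[str, float] | None = None,
    stenosis_freqs: dict[str, float] | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    hypoplasia_fraction: float = 0.5,
) -> list[Phantom]:
    """Generate ``n`` fully rendered phantoms (see ``sample_cohort_specs``)."""
    specs = sample_cohort_specs(n, variation_freqs, stenosis_freqs, seed,
                                base_spec, hypoplasia_fraction)
    return [generate_phantom(s) for s in specs]


def spec_to_yaml(spec: PhantomSpec, path: str) -> None:
    """Write a PhantomSpec as YAML."""
    import yaml

    payload = {
        "volume_shape": list(spec.volume_shape),
        "spacing_mm": list(spec.spacing_mm),
        "segment_statuses": dict(spec.segment_statuses),
        "base_radii_mm": dict(spec.base_radii_mm),
        "stenoses": [list(s) for s in spec.stenoses],
        "vessel_hu": spec.vessel_hu, "tissue_hu": spec.tissue_hu,
        "bone_hu": spec.bone_hu, "air_hu": spec.air_hu,
        "noise_sd": spec.noise_sd,
        "bias_field_amplitude": spec.bias_field_amplitude,
        "seed": spec.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def spec_from_yaml(path: str) -> PhantomSpec:
    """Read a PhantomSpec from YAML and validate it."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    payload["volume_shape"] = tuple(payload["volume_shape"])
    payload["spacing_mm"] = tuple(payload["spacing_mm"])
    payload["stenoses"] = [tuple(s) for s in payload.get("stenoses", [])]
    spec = PhantomSpec(**payload)
    spec.validate()
    return spec


def cohort_status_table(phantoms: list[Phantom]):
    """Ground-truth configuration table: one row per phantom, one column per
    segment status (CSV-friendly)."""
    import pandas as pd

    rows = []
    for i, ph in enumerate(phantoms):
        row = {"phantom": i}
        for seg in ph.tree:
            row[seg.name] = seg.status
        rows.append(row)
    return pd.DataFrame(rows).set_index("phantom")
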