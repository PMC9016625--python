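"""Ground-truthed synthetic cryo-ET scene generator.

Renders the structures quantified by the measurement modules — two-start
helical actin filaments (bare ~37 nm and cofilin-like ~27 nm half-repeat
classes), hexagonally packed crosslinked bundles, ~70 deg branches, and
13-protofilament microtubules carrying lumenal particles, lattice defects
and blunt/flared/tapered ends — as sums of Gaussian blobs on a voxel grid,
then degrades the volume with a single-axis missing wedge (Fourier sector
mask) and additive Gaussian noise.

Density model: each subunit is an isotropic Gaussian of s.d.
``radius / 1.5`` and unit peak amplitude; crosslinkers are single
fascin-scale blobs at the inter-filament midpoint.  The targeted
measurements live at nanometre scale, so no atomic detail is modelled.

Actin is modelled as a two-start long-pitch helix: subunits every 5.5 nm per
strand, strands staggered by 2.75 nm and offset 180 deg in azimuth, with a
long-pitch twist of ``t`` degrees per subunit so the apparent strand
crossover (half helical repeat) is ``L = 5.5 * 180 / t`` nm.

The microtubule wall is a continuous B-style helical lattice (seam omitted,
invisible at blob resolution): ``n`` protofilaments at equal azimuths,
monomers every ``dimer_rise/2`` along each, with the monomer grid of
neighbouring protofilaments shifted axially by ``lateral_rise`` (the 3-start
monomer helix).  The polarity-bearing feature is the cross-sectional wall
skew: a weaker outer-surface lobe azimuthally offset with a fixed
handedness relative to the plus end (see ``MTSpec.wall_skew``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    CONSTANTS,
    Centerline,
    MissingWedge,
    OutOfBoundsError,
    ValidationError,
    Volume3D,
    arc_position,
    tangent_frame,
)

__all__ = [
    "FilamentSpec",
    "BundleSpec",
    "BranchSpec",
    "MTSpec",
    "ParticleSpec",
    "DefectSpec",
    "EndSpec",
    "ScenePlan",
    "SceneTruth",
    "render_scene",
    "apply_missing_wedge",
    "add_noise",
    "make_filament",
    "make_bundle",
    "make_branch",
    "make_mt",
    "poisson_defect_population",
    "DEFAULT_NOISE_SD",
]

# Default noise gives blob peak SNR ~ 3 (unit blob peak / 0.33 noise s.d.),
# comparable to the visual quality of 4x-binned cellular tomograms.
DEFAULT_NOISE_SD = 0.33

# Spacing of monomers along one protofilament (half the dimer rise).
_MONOMER_RISE_FRACTION = 0.5


@dataclass
class FilamentSpec:
    """A two-start helical actin filament.

    ``phase_offset`` is an integer number of 5.5 nm subunit shifts applied as
    an axial translation of the whole subunit pattern (the quantity measured
    by :func:`gcmorph.actin.subunit_offset`).
    """

    centerline: Centerline
    strand_spacing: float = 5.5
    stagger: float = 2.75
    long_pitch_twist: float = 26.68  # deg/subunit -> crossover 37.1 nm
    subunit_radius: float = 2.5
    helix_radius: float = 2.0
    repeat_class: str = "long"
    phase_offset: int = 0
    azimuth0: float = 0.0  # deg

    def __post_init__(self) -> None:
        if self.long_pitch_twist <= 0:
            raise ValidationError("long_pitch_twist must be positive")
        L = self.crossover_length
        if not np.isfinite(L) or L <= 0:
            raise ValidationError("crossover length must be finite and positive")
        windows = {"long": (33.0, 42.0), "short": (23.0, 31.0)}
        if self.repeat_class not in windows:
            raise ValidationError(f"unknown repeat_class {self.repeat_class!r}")
        lo, hi = windows[self.repeat_class]
        if not (lo <= L <= hi):
            raise ValidationError(
                f"repeat_class {self.repeat_class!r} inconsistent with "
                f"crossover {L:.1f} nm (expected {lo}-{hi} nm)"
            )

    @property
    def crossover_length(self) -> float:
        """Half helical repeat L = strand_spacing * 180 / twist, in nm."""
        return self.strand_spacing * 180.0 / self.long_pitch_twist

    def subunit_points(self) -> np.ndarray:
        """World coordinates of all subunit centres, shape (n, 3)."""
        L = self.centerline.length
        pts = []
        for j in (0, 1):
            # axial positions s = k*spacing + j*stagger within [0, L]
            k_lo = math.ceil(-j * self.stagger / self.strand_spacing)
            k_hi = math.floor((L - j * self.stagger) / self.strand_spacing)
            if k_hi < k_lo:
                continue
            ks = np.arange(k_lo, k_hi + 1)
            ss = ks * self.strand_spacing + j * self.stagger
            # rotating by -phase_offset twists translates the subunit pattern
            # by +phase_offset subunits along the axis (helix equivalence)
            thetas = np.radians(
                self.azimuth0 + 180.0 * j
                + (ks - self.phase_offset) * self.long_pitch_twist
            )
            p, e1, e2 = _frames_at(self.centerline, ss)
            pts.append(
                p
                + self.helix_radius
                * (np.cos(thetas)[:, None] * e1 + np.sin(thetas)[:, None] * e2)
            )
        return np.concatenate(pts, axis=0) if pts else np.empty((0, 3))


@dataclass
class BundleSpec:
    """A hexagonally packed, periodically crosslinked filament bundle."""

    filaments: list[FilamentSpec]
    lattice_constant: float = CONSTANTS.hex_spacing_short
    n_wide: int = 1
    n_high: int = 1
    crosslink_period: float = CONSTANTS.crosslink_period
    crosslink_radius: float = 2.5  # fascin-scale (~55 kDa) crosslinker
    crosslink_phase: float = 10.0  # nm, axial position of the first crosslink
    positional_jitter: float = 0.0  # nm s.d. already realized in the centerlines
    crosslink_pairs: str = "neighbors"  # 'neighbors' | 'none'
    cross_section_zy: list[tuple[float, float]] = field(default_factory=list)

    def neighbor_pairs(self) -> list[tuple[int, int]]:
        """Index pairs of filaments adjacent on the hexagonal lattice."""
        if self.crosslink_pairs == "none" or len(self.filaments) < 2:
            return []
        starts = np.array([f.centerline.points[0] for f in self.filaments])
        pairs = []
        cutoff = 1.3 * self.lattice_constant
        for i in range(len(starts)):
            for j in range(i + 1, len(starts)):
                if np.linalg.norm(starts[i] - starts[j]) < cutoff:
                    pairs.append((i, j))
        return pairs


@dataclass
class BranchSpec:
    """An Arp2/3-style branch: a child filament leaving a mother filament."""

    parent: str  # parent filament label
    branch_arc_position: float
    branch_angle: float = CONSTANTS.branch_angle
    child: FilamentSpec | None = None


@dataclass
class ParticleSpec:
    """A lumenal particle inside a microtubule."""

    axial_position: float
    radial_offset: float = 0.0
    diameter: float = CONSTANTS.particle_diam_mean
    shape: str = "globular"  # 'globular' | 'ring'
    azimuth: float = 0.0  # deg, direction of the radial offset

    def validate(self, inner_radius: float) -> None:
        if self.shape == "globular" and \
                self.radial_offset + self.diameter / 2 > inner_radius + 1e-9:
            raise ValidationError(
                f"particle (offset {self.radial_offset} + r {self.diameter / 2}) "
                f"does not fit inside lumen radius {inner_radius}"
            )


@dataclass
class DefectSpec:
    """A lattice defect: tubulin subunits missing over an axial interval."""

    start: float
    length: float
    pf_span: int = 13
    pf_start: int = 0

    @property
    def size_class(self) -> str:
        return "small" if self.length < CONSTANTS.defect_size_class_threshold else "large"


@dataclass
class EndSpec:
    """Terminal morphology of a microtubule.

    ``kind`` is 'blunt' (all protofilaments end together), 'flared' (terminal
    ~16 nm bends radially outward) or 'curved_sheet_taper' (protofilament
    terminations staggered over ``taper_length`` nm).
    """

    kind: str = "blunt"
    taper_length: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("blunt", "flared", "curved_sheet_taper"):
            raise ValidationError(f"unknown end kind {self.kind!r}")
        if self.kind == "curved_sheet_taper" and self.taper_length <= 0:
            raise ValidationError("curved_sheet_taper requires taper_length > 0")


@dataclass
class MTSpec:
    """A microtubule: helical wall lattice plus particles, defects and ends."""

    centerline: Centerline
    pf_number: int = CONSTANTS.pf_number
    dimer_rise: float = CONSTANTS.dimer_rise
    lateral_rise: float = 0.92  # nm per anticlockwise pf step viewed from the plus end
    outer_diameter: float = CONSTANTS.mt_outer_diameter
    wall_subunit_radius: float = 2.5
    # cross-sectional skew of the wall density: each subunit carries a weaker
    # lobe on the outer wall surface, azimuthally offset by this angle (deg)
    # anticlockwise when viewed from the plus end, so the density ridge
    # rotates anticlockwise from the inner to the outer wall surface in that
    # view.  This models the skewed outward-facing decoration of the tubulin
    # lattice and is the polarity-bearing feature the rotational-average
    # slew reads out (a radially symmetric wall would make the two
    # polarities indistinguishable from shaft structure alone).
    wall_skew: float = 12.0
    polarity: str = "plus_toward_end"
    particles: list[ParticleSpec] = field(default_factory=list)
    defects: list[DefectSpec] = field(default_factory=list)
    end_start: EndSpec = field(default_factory=EndSpec)
    end_end: EndSpec = field(default_factory=EndSpec)
    azimuth0: float = 0.0

    def __post_init__(self) -> None:
        if self.pf_number < 9:
            raise ValidationError("pf_number must be >= 9")
        if self.polarity not in ("plus_toward_end", "minus_toward_end"):
            raise ValidationError(f"unknown polarity {self.polarity!r}")
        inner_r = self.outer_diameter / 2 - 2 * self.wall_subunit_radius
        for p in self.particles:
            p.validate(inner_r)
        L = self.centerline.length
        for d in self.defects:
            if d.length <= 0 or d.start < 0 or d.start + d.length > L:
                raise ValidationError("defect must lie within the MT and have length > 0")

    @property
    def wall_radius(self) -> float:
        """Radius of the wall subunit centres."""
        return self.outer_diameter / 2 - self.wall_subunit_radius

    def wall_points(self) -> np.ndarray:
        """World coordinates of all wall monomer centres."""
        n = self.pf_number
        rise = self.dimer_rise * _MONOMER_RISE_FRACTION
        L = self.centerline.length
        s_list, theta_list, radial_extra = [], [], []
        for i in range(n):
            off = i * self.lateral_rise
            k_lo = math.ceil(-off / rise)
            k_hi = math.floor((L - off) / rise)
            if k_hi < k_lo:
                continue
            ks = np.arange(k_lo, k_hi + 1)
            ss = ks * rise + off
            keep = np.ones(len(ss), dtype=bool)
            # lattice defects: remove monomers on the spanned protofilaments
            for d in self.defects:
                on_pf = (i - d.pf_start) % n < d.pf_span
                if on_pf:
                    keep &= ~((ss >= d.start) & (ss < d.start + d.length))
            # end morphologies shorten or flare individual protofilaments
            lo_cut, hi_cut = self._end_cuts(i)
            keep &= (ss >= lo_cut) & (ss <= L - hi_cut)
            ss = ss[keep]
            if len(ss) == 0:
                continue
            s_list.append(ss)
            theta_list.append(np.full(len(ss), 2 * np.pi * i / n + np.radians(self.azimuth0)))
            radial_extra.append(self._flare_offsets(ss, L))
        if not s_list:
            return np.empty((0, 3))
        ss = np.concatenate(s_list)
        thetas = np.concatenate(theta_list)
        rr = self.wall_radius + np.concatenate(radial_extra)
        return self._to_world(ss, thetas, rr, L)

    def outer_lobe_points(self) -> np.ndarray:
        """Skewed outer-surface lobes realizing the polarity-bearing wall slew."""
        if self.wall_skew == 0.0:
            return np.empty((0, 3))
        main = self._lattice_ss_thetas()
        if main is None:
            return np.empty((0, 3))
        ss, thetas = main
        rr = np.full(len(ss), self.wall_radius + 1.8)
        return self._to_world(ss, thetas + np.radians(self.wall_skew), rr,
                              self.centerline.length)

    def _lattice_ss_thetas(self):
        """(s, theta) of intact lattice sites (no flare), for the lobes."""
        n = self.pf_number
        rise = self.dimer_rise * _MONOMER_RISE_FRACTION
        L = self.centerline.length
        s_list, theta_list = [], []
        for i in range(n):
            off = i * self.lateral_rise
            ks = np.arange(math.ceil(-off / rise), math.floor((L - off) / rise) + 1)
            if len(ks) == 0:
                continue
            ss = ks * rise + off
            keep = np.ones(len(ss), dtype=bool)
            for d in self.defects:
                if (i - d.pf_start) % n < d.pf_span:
                    keep &= ~((ss >= d.start) & (ss < d.start + d.length))
            lo_cut, hi_cut = self._end_cuts(i)
            keep &= (ss >= lo_cut) & (ss <= L - hi_cut)
            if not np.any(keep):
                continue
            s_list.append(ss[keep])
            theta_list.append(np.full(int(keep.sum()),
                                      2 * np.pi * i / n + np.radians(self.azimuth0)))
        if not s_list:
            return None
        return np.concatenate(s_list), np.concatenate(theta_list)

    def _to_world(self, ss: np.ndarray, thetas: np.ndarray, rr: np.ndarray,
                  L: float) -> np.ndarray:
        if self.polarity == "minus_toward_end":
            # the same physical MT flipped end for end (rotation about e1)
            ss = L - ss
            thetas = -thetas
        p, e1, e2 = _frames_at(self.centerline, ss)
        return p + rr[:, None] * (np.cos(thetas)[:, None] * e1 + np.sin(thetas)[:, None] * e2)

    def _end_cuts(self, i: int) -> tuple[float, float]:
        """Per-protofilament exclusion lengths at the two termini."""
        n = self.pf_number
        cuts = []
        for end in (self.end_start, self.end_end):
            if end.kind == "curved_sheet_taper":
                cuts.append(end.taper_length * i / max(n - 1, 1))
            else:
                cuts.append(0.0)
        return cuts[0], cuts[1]

    def _flare_offsets(self, ss: np.ndarray, L: float) -> np.ndarray:
        """Outward radial displacement near flared termini (up to +3 nm)."""
        extra = np.zeros(len(ss))
        flare_len, flare_amp = 16.0, 3.0
        if self.end_start.kind == "flared":
            m = ss < flare_len
            extra[m] += flare_amp * (1 - ss[m] / flare_len)
        if self.end_end.kind == "flared":
            m = ss > L - flare_len
            extra[m] += flare_amp * (1 - (L - ss[m]) / flare_len)
        return extra

    def particle_points(self) -> list[tuple[float, float, np.ndarray]]:
        """(sigma, amplitude, points) groups for all lumenal particles."""
        groups: list[tuple[float, float, np.ndarray]] = []
        L = self.centerline.length
        for part in self.particles:
            s = part.axial_position
            s_eff = L - s if self.polarity == "minus_toward_end" else s
            p, e1, e2 = _frames_at(self.centerline, np.array([s_eff]))
            az = np.radians(part.azimuth)
            centre = p[0] + part.radial_offset * (np.cos(az) * e1[0] + np.sin(az) * e2[0])
            if part.shape == "ring":
                sigma_t = 1.0
                r_ring = max(part.diameter / 2 - 1.1775 * sigma_t, 1.0)
                ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
                pts = centre + r_ring * (
                    np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2
                )
                groups.append((sigma_t, 0.8, pts))
            else:
                groups.append((part.diameter / 3.0, 1.0, centre[None, :]))
        return groups


@dataclass
class ScenePlan:
    """Everything needed to render one reproducible synthetic tomogram."""

    shape: tuple[int, int, int]  # (nx, ny, nz) voxels
    voxel_size: float = 1.0
    filaments: list[FilamentSpec] = field(default_factory=list)
    bundles: list[BundleSpec] = field(default_factory=list)
    branches: list[BranchSpec] = field(default_factory=list)
    mts: list[MTSpec] = field(default_factory=list)
    wedge: MissingWedge | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def all_filaments(self) -> list[FilamentSpec]:
        out = list(self.filaments)
        for b in self.bundles:
            out.extend(b.filaments)
        for br in self.branches:
            if br.child is not None:
                out.append(br.child)
        return out


@dataclass
class SceneTruth:
    """Ground-truth annotation recorded alongside a rendered scene."""

    seed: int
    voxel_size: float
    filaments: list[dict] = field(default_factory=list)
    crosslinks: list[dict] = field(default_factory=list)
    branches: list[dict] = field(default_factory=list)
    mts: list[dict] = field(default_factory=list)


def _frames_at(cl: Centerline, ss: np.ndarray):
    """Points and parallel-transported transverse frames at arc lengths ``ss``.

    The frame at the first sample starts from :func:`tangent_frame` (e1 in the
    beam-perpendicular plane) and is transported with minimal rotation, which
    keeps azimuths continuous along curved paths.
    """
    ss = np.asarray(ss, dtype=float)
    if len(cl.points) == 2:  # straight path: constant frame, fully vectorized
        p0, p1 = cl.points
        t = (p1 - p0) / cl.length
        e1, e2 = tangent_frame(t)
        pts = p0[None, :] + ss[:, None] * t[None, :]
        ones = np.ones((len(ss), 1))
        return pts, ones * e1, ones * e2
    order = np.argsort(ss)
    pts = np.empty((len(ss), 3))
    e1s = np.empty((len(ss), 3))
    e2s = np.empty((len(ss), 3))
    prev_e1 = None
    for idx in order:
        p, t = arc_position(cl, float(ss[idx]))
        if prev_e1 is None:
            e1, e2 = tangent_frame(t)
        else:
            e1 = prev_e1 - np.dot(prev_e1, t) * t
            nrm = np.linalg.norm(e1)
            e1 = e1 / nrm if nrm > 1e-8 else tangent_frame(t)[0]
            e2 = np.cross(t, e1)
        pts[idx], e1s[idx], e2s[idx] = p, e1, e2
        prev_e1 = e1
    return pts, e1s, e2s


def _crosslink_points(f1: FilamentSpec, f2: FilamentSpec, period: float,
                      phase: float) -> tuple[np.ndarray, np.ndarray]:
    """Globular crosslinker blobs midway between two filaments every
    ``period`` nm (fascin-like compact bridges).

    Returns (points, axial positions of the crosslink centres).
    """
    L = min(f1.centerline.length, f2.centerline.length)
    ss = np.arange(phase, L, period)
    pts = []
    for s in ss:
        p1, _ = arc_position(f1.centerline, float(s))
        p2, _ = arc_position(f2.centerline, float(s))
        pts.append((p1 + p2) / 2)
    return np.asarray(pts).reshape(-1, 3), ss


def _deposit(grid: np.ndarray, idx_zyx: np.ndarray, weights: np.ndarray) -> None:
    """Trilinear scatter-add of point masses at fractional (z, y, x) indices."""
    base = np.floor(idx_zyx).astype(np.int64)
    frac = idx_zyx - base
    nz, ny, nx = grid.shape
    flat = grid.ravel()
    for dz in (0, 1):
        wz = frac[:, 0] if dz else 1 - frac[:, 0]
        z = base[:, 0] + dz
        for dy in (0, 1):
            wy = frac[:, 1] if dy else 1 - frac[:, 1]
            y = base[:, 1] + dy
            for dx in (0, 1):
                wx = frac[:, 2] if dx else 1 - frac[:, 2]
                x = base[:, 2] + dx
                ok = (z >= 0) & (z < nz) & (y >= 0) & (y < ny) & (x >= 0) & (x < nx)
                lin = (z[ok] * ny + y[ok]) * nx + x[ok]
                np.add.at(flat, lin, (weights * wz * wy * wx)[ok])


def render_scene(plan: ScenePlan) -> tuple[Volume3D, SceneTruth]:
    """Render a :class:`ScenePlan` into a density volume plus ground truth.

    The noiseless, unwedged density is an exact sum of Gaussian blobs (unit
    peak per subunit); the missing wedge and noise are applied afterwards if
    the plan requests them.  A fixed seed gives a byte-identical volume.
    """
    nx, ny, nz = plan.shape
    vox = plan.voxel_size
    extent = np.array([nx, ny, nz], dtype=float) * vox
    truth = SceneTruth(seed=plan.seed, voxel_size=vox)

    # (sigma_nm, amplitude) -> list of point arrays
    groups: dict[tuple[float, float], list[np.ndarray]] = {}

    def add(sigma: float, amp: float, pts: np.ndarray) -> None:
        if len(pts):
            groups.setdefault((round(sigma, 6), round(amp, 6)), []).append(pts)

    for f in plan.all_filaments():
        pts = f.subunit_points()
        add(f.subunit_radius / 1.5, 1.0, pts)
        truth.filaments.append({
            "label": f.centerline.label,
            "repeat_class": f.repeat_class,
            "crossover_length": f.crossover_length,
            "phase_offset": f.phase_offset,
            "n_subunits": int(len(pts)),
            "centerline": f.centerline.points.tolist(),
        })
    for b in plan.bundles:
        for (i, j) in b.neighbor_pairs():
            pts, ss = _crosslink_points(
                b.filaments[i], b.filaments[j], b.crosslink_period, b.crosslink_phase)
            add(b.crosslink_radius / 1.5, 1.0, pts)
            truth.crosslinks.append({
                "pair": [b.filaments[i].centerline.label, b.filaments[j].centerline.label],
                "positions": ss.tolist(),
                "period": b.crosslink_period,
            })
    for br in plan.branches:
        truth.branches.append({
            "parent": br.parent,
            "child": br.child.centerline.label if br.child else None,
            "branch_arc_position": br.branch_arc_position,
            "branch_angle": br.branch_angle,
        })
    mt_lines = []
    for m in plan.mts:
        add(m.wall_subunit_radius / 1.5, 1.0, m.wall_points())
        add(1.4, 0.4, m.outer_lobe_points())
        for sigma, amp, pts in m.particle_points():
            add(sigma, amp, pts)
        mt_lines.append(m.centerline)
        truth.mts.append({
            "label": m.centerline.label,
            "pf_number": m.pf_number,
            "polarity": m.polarity,
            "lateral_rise": m.lateral_rise,
            "length": m.centerline.length,
            "centerline": m.centerline.points.tolist(),
            "particles": [
                {"axial_position": p.axial_position, "diameter": p.diameter,
                 "radial_offset": p.radial_offset, "shape": p.shape}
                for p in m.particles
            ],
            "defects": [
                {"start": d.start, "length": d.length, "pf_span": d.pf_span,
                 "size_class": d.size_class}
                for d in m.defects
            ],
            "ends": {"start": [m.end_start.kind, m.end_start.taper_length],
                     "end": [m.end_end.kind, m.end_end.taper_length]},
        })

    # overlapping MTs are physically impossible but renderable: warn only
    for i in range(len(mt_lines)):
        for j in range(i + 1, len(mt_lines)):
            d = np.min(np.linalg.norm(
                mt_lines[i].points[:, None, :] - mt_lines[j].points[None, :, :], axis=2))
            if d < plan.mts[i].outer_diameter:
                warnings.warn("overlapping microtubules in scene", stacklevel=2)

    grid = np.zeros((nz, ny, nx), dtype=np.float32)
    for (sigma, amp), pt_lists in groups.items():
        pts = np.concatenate(pt_lists, axis=0)
        if np.any(pts < -1e-6) or np.any(pts >= extent[None, :] - 1e-6):
            raise OutOfBoundsError("scene geometry extends outside the volume")
        sub = np.zeros_like(grid)
        sigma_vox = sigma / vox
        mass = amp * (2 * np.pi) ** 1.5 * sigma_vox ** 3
        _deposit(sub, (pts / vox)[:, ::-1], np.full(len(pts), mass, dtype=float))
        grid += ndimage.gaussian_filter(sub, sigma_vox, truncate=4.0, mode="constant")

    vol = Volume3D(grid, voxel_size=vox)
    if plan.wedge is not None:
        vol = apply_missing_wedge(vol, plan.wedge)
    if plan.noise_sd:
        vol = add_noise(vol, plan.noise_sd, plan.seed)
    return vol, truth


def apply_missing_wedge(v: Volume3D, w: MissingWedge) -> Volume3D:
    """Zero all Fourier coefficients outside the sampled tilt sector.

    A tilt series about the x axis over ``[tilt_min, tilt_max]`` samples the
    spatial frequencies whose in-plane angle ``atan(kz/ky)`` lies within the
    tilt range (central-slice theorem); everything else is set to zero.  The
    zero-frequency term always survives, so total density is conserved.
    Raises :class:`ValidationError` if the volume already carries a wedge.
    """
    if v.wedge is not None:
        raise ValidationError("missing wedge already applied to this volume")
    nz, ny, nx = v.data.shape
    kz = np.fft.fftfreq(nz)[:, None]
    ky = np.fft.fftfreq(ny)[None, :]
    ang = np.degrees(np.arctan2(kz, np.broadcast_to(ky, (nz, ny))))
    ang = np.where(ang > 90.0, ang - 180.0, ang)
    ang = np.where(ang <= -90.0, ang + 180.0, ang)
    keep = (ang >= w.tilt_min) & (ang <= w.tilt_max)
    keep[0, 0] = True  # ky = kz = 0 plane is sampled at every tilt
    from scipy import fft as sfft

    F = sfft.rfftn(v.data, axes=(0, 1, 2))
    F *= keep[:, :, None]
    out = sfft.irfftn(F, s=v.data.shape, axes=(0, 1, 2)).astype(v.data.dtype, copy=False)
    return Volume3D(out, voxel_size=v.voxel_size, wedge=w, origin_offset=v.origin_offset)


def add_noise(v: Volume3D, sd: float, seed: int) -> Volume3D:
    """Additive zero-mean Gaussian noise, deterministic under a fixed seed."""
    if sd < 0:
        raise ValidationError("noise s.d. must be >= 0")
    if sd == 0:
        return v.copy()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(size=v.data.shape, dtype=np.float32) * np.float32(sd)
    data = v.data + noise.astype(v.data.dtype, copy=False)
    return Volume3D(data, voxel_size=v.voxel_size, wedge=v.wedge,
                    origin_offset=v.origin_offset)


# ---------------------------------------------------------------------------
# Scene factory helpers: straight-geometry building blocks for study scenes.
# ---------------------------------------------------------------------------

_REPEAT_DEFAULTS = {
    # repeat_class -> (twist deg/subunit, subunit blob radius nm)
    # twists chosen so the crossover L = 5.5*180/twist hits the two
    # half-repeat classes (37.1 nm bare actin, 27.3 nm cofilin-decorated,
    # which appears wider, hence the larger blob radius)
    "long": (26.68, 2.5),
    "short": (36.26, 3.0),
}


def make_filament(start, direction, length: float, repeat_class: str = "long",
                  phase_offset: int = 0, label: str = "fil",
                  azimuth0: float = 0.0, twist: float | None = None) -> FilamentSpec:
    """A straight filament from ``start`` along ``direction`` (normalized)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    cl = Centerline(np.array([start, np.asarray(start) + length * d]), label=label)
    default_twist, radius = _REPEAT_DEFAULTS[repeat_class]
    return FilamentSpec(cl, long_pitch_twist=twist or default_twist,
                        subunit_radius=radius, repeat_class=repeat_class,
                        phase_offset=phase_offset, azimuth0=azimuth0)


def hex_lattice_offsets(n_wide: int, n_high: int, a: float) -> np.ndarray:
    """(y, z) offsets of an ``n_wide x n_high`` hexagonal lattice, row pitch
    ``sqrt(3)/2 * a``, centred on the origin."""
    offs = []
    for r in range(n_high):
        for c in range(n_wide):
            offs.append((c * a + (r % 2) * a / 2, r * a * math.sqrt(3) / 2))
    offs = np.asarray(offs, dtype=float)
    return offs - offs.mean(axis=0)


def make_bundle(centre, direction, length: float, n_wide: int, n_high: int,
                lattice_constant: float = CONSTANTS.hex_spacing_short,
                crosslink_period: float = CONSTANTS.crosslink_period,
                positional_jitter: float = 0.0,
                phase_offsets: list[int] | None = None,
                rng: np.random.Generator | None = None,
                label: str = "bundle") -> BundleSpec:
    """A hexagonal bundle of parallel long-class filaments along ``direction``.

    Lattice positions live in the plane perpendicular to the filament axis;
    ``positional_jitter`` (nm s.d., needs ``rng``) perturbs them in-plane.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    e1, e2 = tangent_frame(d)
    offs = hex_lattice_offsets(n_wide, n_high, lattice_constant)
    if positional_jitter > 0:
        if rng is None:
            raise ValidationError("positional_jitter requires an rng")
        offs = offs + rng.normal(0.0, positional_jitter, size=offs.shape)
    fils = []
    for idx, (u, w) in enumerate(offs):
        origin = np.asarray(centre, dtype=float) + u * e1 + w * e2
        phase = phase_offsets[idx] if phase_offsets else 0
        fils.append(make_filament(origin, d, length, "long", phase_offset=phase,
                                  label=f"{label}/f{idx}"))
    return BundleSpec(fils, lattice_constant=lattice_constant,
                      n_wide=n_wide, n_high=n_high,
                      crosslink_period=crosslink_period,
                      positional_jitter=positional_jitter,
                      cross_section_zy=offs.tolist())


def make_branch(parent: FilamentSpec, s_branch: float, child_length: float,
                branch_angle: float = CONSTANTS.branch_angle,
                label: str = "child") -> BranchSpec:
    """A child filament leaving ``parent`` at ``s_branch`` with the given
    in-plane branch angle (rotation about the beam axis)."""
    origin, t = arc_position(parent.centerline, s_branch)
    a = math.radians(branch_angle)
    rot = np.array([[math.cos(a), -math.sin(a), 0.0],
                    [math.sin(a), math.cos(a), 0.0],
                    [0.0, 0.0, 1.0]])
    child_dir = rot @ t
    child = make_filament(origin, child_dir, child_length, "long", label=label)
    return BranchSpec(parent=parent.centerline.label,
                      branch_arc_position=s_branch,
                      branch_angle=branch_angle, child=child)


def poisson_defect_population(total_length_um: float, seed: int,
                              mt_length: float = 4100.0,
                              rate_per_um: float = 0.05,
                              margin: float = 40.0) -> list[MTSpec]:
    """Microtubule population whose lattice defects follow a Poisson process.

    Defects are placed at ``rate_per_um`` along a population of straight MTs
    (one per future render volume) totalling at least ``total_length_um``.
    Defect sizes follow the observed mixture: mostly one or two missing
    dimers, with a tail of longer holes; dimer-scale defects span a few
    protofilaments, larger ones the full circumference.  Defects keep clear
    of the termini and of each other so every one is individually countable.
    """
    rng = np.random.default_rng(seed)
    n_mts = math.ceil(total_length_um * 1000.0 / mt_length)
    specs = []
    for i in range(n_mts):
        n_def = rng.poisson(rate_per_um * mt_length / 1000.0)
        defects: list[DefectSpec] = []
        attempts = 0
        while len(defects) < n_def and attempts < 100 * (n_def + 1):
            attempts += 1
            u = rng.random()
            if u < 0.5:
                n_dimer = 1
            elif u < 0.8:
                n_dimer = 2
            else:
                n_dimer = 3 + rng.geometric(0.15)  # tail up to ~hundreds of nm
            length = min(n_dimer * CONSTANTS.dimer_rise, 600.0)
            start = rng.uniform(margin, mt_length - margin - length)
            if any(start < d.start + d.length + 60.0 and d.start < start + length + 60.0
                   for d in defects):
                continue
            span = 13 if length >= 16.0 else int(rng.integers(3, 14))
            defects.append(DefectSpec(start=float(start), length=float(length),
                                      pf_span=span,
                                      pf_start=int(rng.integers(0, 13))))
        specs.append(make_mt((margin, 24.0, 24.0), (1, 0, 0), mt_length,
                             label=f"mt{i}", defects=defects))
    return specs


def make_mt(start, direction, length: float, label: str = "mt",
            **kwargs) -> MTSpec:
    """A straight microtubule from ``start`` along ``direction``.

    Unless given explicitly, the outer diameter scales with the
    protofilament number (lateral tubulin spacing is fixed, so the
    circumference grows by one subunit per added protofilament).
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    cl = Centerline(np.array([start, np.asarray(start) + length * d]), label=label)
    if "outer_diameter" not in kwargs:
        pf = kwargs.get("pf_number", CONSTANTS.pf_number)
        kwargs["outer_diameter"] = CONSTANTS.mt_outer_diameter * pf / CONSTANTS.pf_number
    return MTSpec(cl, **kwargs)
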