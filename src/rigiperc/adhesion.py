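"""Surface-tension model of cell-cell contacts and the rigidifying rhombus.

The relative cell-cell tension ``alpha = gamma_cc / (2 gamma_cf)`` controls
contact geometry: two cells of radius ``R_c`` meet at an equilibrium
contact angle ``theta_e`` with ``alpha = cos(theta_e / 2)``; low tension
(high adhesion) opens the angle and expands the contact.

The four-cell rhombus is the minimal model of how adhesion rewires contact
*topology*: four equal cells on a rhombus have four contacts — a bar-joint
mechanism with one floppy mode.  As ``alpha`` decreases the contacts widen
until, on the sharp-vertex cells, the two contact rims meet in a
tricellular junction; the interstitial gap at the centre collapses and a
fifth contact appears along the short diagonal, turning the contact graph
rigid (the pebble game count goes to zero floppy modes).  The threshold
sits near ``alpha ≈ 0.85-0.9`` and depends mildly on the rhombus shape.

Cells are modelled as equal discs truncated by straight contact chords
(the midplane of each touching pair), which reproduces the doublet angle
relation exactly; circular free arcs meet the chords at the endpoint rims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

from .lattice import Lattice
from .rigidity import floppy_modes, pebble_game

__all__ = [
    "TensionState",
    "DoubletGeometry",
    "RhombusGeometry",
    "RhombusState",
    "alpha_from_angle",
    "angle_from_alpha",
    "doublet_geometry",
    "doublet_energy",
    "rhombus_equilibrium",
    "rhombus_rigidity_threshold",
]


def alpha_from_angle(theta_e: float) -> float:
    """Relative cell-cell tension from the contact angle, ``cos(theta_e/2)``."""
    if not 0.0 <= theta_e <= math.pi:
        raise ValueError("contact angle must lie in [0, pi]")
    return math.cos(theta_e / 2.0)


def angle_from_alpha(alpha: float) -> float:
    """Contact angle from the relative tension, ``2 arccos(alpha)``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("relative tension must lie in [0, 1]")
    return 2.0 * math.acos(alpha)


@dataclass(frozen=True)
class TensionState:
    """Surface tensions of a cell pair and the equilibrium contact angle."""

    gamma_cc: float
    gamma_cf: float

    def __post_init__(self) -> None:
        if self.gamma_cc < 0 or self.gamma_cf <= 0:
            raise ValueError("tensions must satisfy gamma_cc >= 0, gamma_cf > 0")

    @property
    def alpha(self) -> float:
        return self.gamma_cc / (2.0 * self.gamma_cf)

    @property
    def contact_angle(self) -> float:
        return angle_from_alpha(self.alpha)


@dataclass(frozen=True)
class DoubletGeometry:
    """Contact and fluid-exposed areas of a symmetric cell doublet."""

    alpha: float
    cell_radius: float
    contact_area: float        # A_cc = pi [R_c sin(theta_e/2)]^2
    fluid_area: float          # A_cf = 2 pi R_c^2 [1 + cos(theta_e/2)] per cell
    energy: float              # E = 2 gamma_cf A_cf + gamma_cc A_cc (gamma_cf = 1)


def doublet_geometry(alpha: float, cell_radius: float = 1.0) -> DoubletGeometry:
    """Evaluate the doublet area formulas at the equilibrium angle.

    Uses unit cell-fluid tension, so ``gamma_cc = 2 alpha``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("relative tension must lie in [0, 1]")
    if cell_radius <= 0:
        raise ValueError("cell radius must be > 0")
    half = angle_from_alpha(alpha) / 2.0
    a_cc = math.pi * (cell_radius * math.sin(half)) ** 2
    a_cf = 2.0 * math.pi * cell_radius**2 * (1.0 + math.cos(half))
    energy = 2.0 * a_cf + (2.0 * alpha) * a_cc
    return DoubletGeometry(alpha, cell_radius, a_cc, a_cf, energy)


def doublet_energy(theta_e: float, alpha: float, cell_radius: float = 1.0) -> float:
    """Doublet surface energy at an arbitrary trial contact angle.

    The truncated-sphere radius is rescaled so each cell conserves the
    volume of the isolated sphere of radius ``cell_radius``; the minimum of
    this landscape over ``theta_e`` sits exactly at ``cos(theta_e/2) =
    alpha``.
    """
    if not 0.0 <= theta_e <= math.pi:
        raise ValueError("contact angle must lie in [0, pi]")
    half = theta_e / 2.0
    c = math.cos(half)
    v0 = 4.0 * math.pi / 3.0 * cell_radius**3
    v_unit = 4.0 * math.pi / 3.0 - (math.pi / 3.0) * (1.0 - c) ** 2 * (2.0 + c)
    R = (v0 / v_unit) ** (1.0 / 3.0)
    a_cf = 2.0 * math.pi * R**2 * (1.0 + c)
    a_cc = math.pi * (R * math.sin(half)) ** 2
    return 2.0 * a_cf + (2.0 * alpha) * a_cc


# ---------------------------------------------------------------------------
# four-cell rhombus


@dataclass(frozen=True)
class RhombusGeometry:
    """Shape of the four-cell rhombus cluster.

    ``sharp_half_angle`` is half the vertex angle at the long-diagonal
    cells (30 degrees = the equilateral two-triangle rhombus); the contact
    topology rigidifies when ``alpha`` drops below ``cos(sharp_half_angle)``
    as the contact rims on the sharp cells meet.
    """

    sharp_half_angle_deg: float = 30.0
    cell_radius: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.sharp_half_angle_deg < 45.0:
            raise ValueError("sharp half-angle must lie in (0, 45) degrees")
        if self.cell_radius <= 0:
            raise ValueError("cell radius must be > 0")


@dataclass
class RhombusState:
    """Equilibrium configuration of the four-cell rhombus at one alpha."""

    alpha: float
    geometry: RhombusGeometry
    radius: float                      # truncated-disc radius after area rescale
    centers: np.ndarray                # (4, 2); 0,1 = sharp (long diagonal), 2,3 = blunt
    contacts: list[tuple[int, int]]
    contact_lengths: dict[tuple[int, int], float]
    areas: np.ndarray
    tricellular_junctions: list[tuple[int, int, int]]
    rigid: bool
    floppy_modes: int
    meta: dict = field(default_factory=dict)

    @property
    def gap_open(self) -> bool:
        return not self.tricellular_junctions

    def contact_lattice(self) -> Lattice:
        """The contact graph as a 4-node lattice consumable by the
        rigidity module."""
        return Lattice(self.centers, self.contacts, L=2,
                       meta={"generator": "rhombus", "alpha": self.alpha})


def _disc(center: np.ndarray, radius: float, resolution: int) -> Polygon:
    return Point(center).buffer(radius, quad_segs=max(8, resolution // 4))


def _halfplane(center: np.ndarray, toward: np.ndarray, dist: float, big: float) -> Polygon:
    """Halfplane {x : (x - center).u <= dist} with u pointing at ``toward``."""
    u = (toward - center) / np.linalg.norm(toward - center)
    w = np.array([-u[1], u[0]])
    base = center + dist * u
    pts = [base + big * w, base - big * w,
           base - big * w - big * u, base + big * w - big * u]
    return Polygon(pts)


def rhombus_equilibrium(
    alpha: float,
    geometry: RhombusGeometry | None = None,
    resolution: int = 256,
) -> RhombusState:
    """Equal-area equilibrium of the four-cell rhombus at tension ``alpha``.

    Each cell is a disc truncated by the midplane chord of every contact;
    the chord sits at ``R * alpha`` from the centre, which enforces the
    doublet angle relation at the rims.  Each cell's radius is rescaled so
    it keeps the area of the isolated disc (exact, because the truncated
    shape is similar in the radius); before any junction the four cells
    are congruent and share one radius, afterwards the three-contact cells
    are slightly larger and shared interfaces are taken from the nominal
    symmetric construction.  A tricellular junction is declared when two
    chords of one cell cross inside the disc (rim endpoints within 1e-3 R
    of meeting), which collapses the central gap and adds the
    short-diagonal contact.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("relative tension must lie in (0, 1]")
    geometry = geometry or RhombusGeometry()
    phi = math.radians(geometry.sharp_half_angle_deg)
    # unit radius; side length of the rhombus of touching contact pairs
    d = 2.0 * alpha
    a, b = d * math.cos(phi), d * math.sin(phi)
    centers = np.array([[-a, 0.0], [a, 0.0], [0.0, b], [0.0, -b]])
    sides = [(0, 2), (0, 3), (1, 2), (1, 3)]

    # tricellular junctions: two chords of one cell crossing inside the disc;
    # the junction on a host cell puts its two neighbours in contact
    tol = 1e-3
    junctions: list[tuple[int, int, int]] = []  # (host, neighbour, neighbour)
    neighbours = {i: sorted(j for pair in sides for j in pair
                            if i in pair and j != i) for i in range(4)}
    contacts = list(sides)
    for host in range(4):
        js = neighbours[host]
        for p in range(len(js)):
            for q in range(p + 1, len(js)):
                u1 = centers[js[p]] - centers[host]
                u2 = centers[js[q]] - centers[host]
                cos_gap = float(np.dot(u1, u2)
                                / (np.linalg.norm(u1) * np.linalg.norm(u2)))
                half_gap = 0.5 * math.acos(min(1.0, max(-1.0, cos_gap)))
                # chords at distance alpha intersect at alpha / cos(half_gap)
                if alpha / math.cos(half_gap) <= 1.0 + tol:
                    junctions.append((host, js[p], js[q]))
                    new = (min(js[p], js[q]), max(js[p], js[q]))
                    if new not in contacts:
                        contacts.append(new)

    # geometry of each cell at unit nominal radius: disc cut by the midplane
    # halfplane of every contact (midplane distance equals the tension chord
    # distance R*alpha by construction of the touching-pair rhombus)
    big = 10.0
    cell_contacts: dict[int, list[int]] = {i: [] for i in range(4)}
    for (p, q) in contacts:
        cell_contacts[p].append(q)
        cell_contacts[q].append(p)
    polys = []
    for i in range(4):
        poly = _disc(centers[i], 1.0, resolution)
        for other in cell_contacts[i]:
            dist = 0.5 * float(np.linalg.norm(centers[other] - centers[i]))
            poly = poly.intersection(
                _halfplane(centers[i], centers[other], dist, big))
        polys.append(poly)

    # per-cell rescale conserves every cell's area exactly (shapes are
    # similar in the radius, so area scales quadratically); before a
    # junction all four cells are congruent and the scales coincide
    disc_area = _disc(np.zeros(2), 1.0, resolution).area
    target = disc_area * geometry.cell_radius**2
    areas_unit = np.array([p.area for p in polys])
    scales = np.sqrt(target / areas_unit)

    def _clipped_half_chord(i: int, other: int) -> tuple[float, float]:
        """[t_lo, t_hi] span of cell i's contact chord toward ``other``,
        clipped by the disc rim and the cell's remaining chords."""
        ci = centers[i]
        u = centers[other] - ci
        D = float(np.linalg.norm(u))
        u = u / D
        dist = 0.5 * D
        h = math.sqrt(max(1.0 - dist * dist, 0.0))
        w = np.array([-u[1], u[0]])
        t_lo, t_hi = -h, h
        for r in cell_contacts[i]:
            if r == other:
                continue
            ur = centers[r] - ci
            Dr = float(np.linalg.norm(ur))
            ur = ur / Dr
            slope = float(np.dot(w, ur))
            rhs = 0.5 * Dr - dist * float(np.dot(u, ur))
            if abs(slope) < 1e-12:
                if rhs < 0:
                    return 0.0, 0.0
                continue
            if slope > 0:
                t_hi = min(t_hi, rhs / slope)
            else:
                t_lo = max(t_lo, rhs / slope)
        return t_lo, t_hi

    lengths: dict[tuple[int, int], float] = {}
    for (p, q) in contacts:
        lo_p, hi_p = _clipped_half_chord(p, q)
        lo_q, hi_q = _clipped_half_chord(q, p)
        lengths[(p, q)] = 0.5 * (max(0.0, hi_p - lo_p) * scales[p]
                                 + max(0.0, hi_q - lo_q) * scales[q])

    scale = float(scales.mean())
    lat = Lattice(centers * scale, contacts, L=2, meta={"generator": "rhombus"})
    fmodes = floppy_modes(lat)
    _, _, state = pebble_game(lat)
    rigid = fmodes == 0 and len(contacts) >= 5

    return RhombusState(
        alpha=alpha,
        geometry=geometry,
        radius=scale,
        centers=centers * scale,
        contacts=contacts,
        contact_lengths=lengths,
        areas=areas_unit * scales**2,
        tricellular_junctions=junctions,
        rigid=rigid,
        floppy_modes=fmodes,
        meta={"resolution": resolution, "n_independent": state.n_independent,
              "cell_radii": (scales).tolist()},
    )


def rhombus_rigidity_threshold(
    alpha_grid: np.ndarray | None = None,
    geometry: RhombusGeometry | None = None,
    resolution: int = 256,
) -> tuple[float | None, list[RhombusState]]:
    """Largest alpha on a descending grid with a rigid contact topology.

    Returns ``(alpha_star, states)``; ``alpha_star`` is None when no grid
    point rigidifies.  The reported threshold carries the grid step as its
    uncertainty.
    """
    if alpha_grid is None:
        alpha_grid = np.arange(1.0, 0.5, -0.005)
    alpha_grid = np.asarray(alpha_grid, float)
    if len(alpha_grid) > 1 and np.any(np.diff(alpha_grid) >= 0):
        raise ValueError("alpha grid must be strictly descending")
    if np.any((alpha_grid <= 0) | (alpha_grid > 1)):
        raise ValueError("alpha grid must lie in (0, 1]")
    states = []
    alpha_star = None
    for alpha in alpha_grid:
        st = rhombus_equilibrium(float(alpha), geometry, resolution)
        states.append(st)
        if st.rigid and alpha_star is None:
            alpha_star = float(alpha)
    return alpha_star, states
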