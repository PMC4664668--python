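"""Geometry and dose bookkeeping for interleaved minibeam arrays.

Interleaving aims two planar minibeam arrays at the target from 90
degrees apart, with the second array's minibeam planes offset by half
the on-center spacing of the first, so that inside the target the
planes of the pair fill each other's gaps and form a solid field, while
every tissue outside the target sees only one array's comb.  Carbon
ions broaden little, so their arrays are still comb-like at brain
depths — the regime this planner covers.  A four-directional layout is
two such orthogonal pairs; the pairs (not the arrays within a pair) add
up at the target.

Dose arithmetic follows the in-beam "pedestal" convention: the incident
in-beam plateau dose of each array is the pedestal; the SOBP dose a
pair delivers at the target is pedestal * pedestal_to_sobp_ratio (the
ratio depends on the accelerator's SOBP weighting and is a plan input);
the target physical dose is that, times the number of pairs; GyE is
physical dose times the scalar RBE.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, PlanError, TransportRangeError
from .ion_physics import (
    WATER,
    EnergySpec,
    IonSpecies,
    Material,
    energy_for_range,
)
from .mcs_transport import (
    FWHM_PER_SIGMA,
    BeamShape,
    BeamSpec,
    propagate_moments,
    total_fwhm,
)
from .minibeam_array import ArrayDoseMap

__all__ = [
    "Direction",
    "TargetBox",
    "InterleavePlan",
    "PlanReport",
    "check_coverage",
    "max_proximal_depth",
    "compose_interleaved_dose",
    "carbon_incident_factor",
]

#: minibeam width limit (mm) above which tissue sparing starts to fade
DEFAULT_WIDTH_LIMIT = 0.7
#: tolerated relative deviation from exact plane abutment (both sides);
#: overlap beyond +10% flags an over-dose seam, gaps beyond -10% fail coverage
ABUTMENT_TOLERANCE = 0.10
#: default margin (mm) added to the proximal depth for the target span when
#: searching the maximum allowable proximal depth
DEFAULT_TARGET_MARGIN = 20.0


class Direction(str, enum.Enum):
    XPLUS = "+x"
    XMINUS = "-x"
    YPLUS = "+y"
    YMINUS = "-y"

    @property
    def axis(self) -> str:
        return "x" if self in (Direction.XPLUS, Direction.XMINUS) else "y"


#: the two orthogonal 90-degree pairs of the four-directional layout
PAIRS = ((Direction.XPLUS, Direction.YPLUS), (Direction.XMINUS, Direction.YMINUS))


@dataclass(frozen=True)
class TargetBox:
    """Axis-aligned target box, mm.

    ``x`` is the depth axis of the +x array (entry surface at x=0), ``v``
    the interleaving (plane-stacking) axis shared by all four arrays.
    The phantom is assumed symmetric, so the -x array's proximal depth
    equals ``phantom_extent - x_max``.
    """

    x_min: float
    x_max: float
    v_min: float
    v_max: float
    phantom_extent: float = 0.0  # mm; 0 => symmetric (x_min + x_max)

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.v_max <= self.v_min:
            raise DomainError("degenerate target box")
        if self.phantom_extent == 0.0:
            object.__setattr__(self, "phantom_extent", self.x_min + self.x_max)

    @property
    def span_mm(self) -> float:
        return self.x_max - self.x_min


@dataclass
class InterleavePlan:
    """Interleaved-array treatment plan."""

    species: IonSpecies
    target: TargetBox
    incident_width_fwhm: float = 0.3  # mm
    spacing_on_center: float = 1.05  # mm
    directions: tuple[Direction, ...] = (
        Direction.XPLUS,
        Direction.YPLUS,
        Direction.XMINUS,
        Direction.YMINUS,
    )
    pedestal_dose: float = 14.0  # Gy, incident in-beam plateau
    pedestal_to_sobp_ratio: float = 20.0 / 14.0
    rbe: float = 3.0
    width_limit: float = DEFAULT_WIDTH_LIMIT  # mm

    def __post_init__(self) -> None:
        dirs = tuple(Direction(d) for d in self.directions)
        self.directions = dirs
        if len(set(dirs)) != len(dirs):
            raise PlanError("duplicate array directions")
        for pair in self.pairs:
            if len(pair) == 2 and pair[0].axis == pair[1].axis:  # pragma: no cover
                raise PlanError("arrays of a pair must be orthogonal")

    @property
    def pairs(self) -> list[tuple[Direction, ...]]:
        """90-degree pairs present in the plan (a lone array counts as a half pair)."""
        out = []
        for pair in PAIRS:
            present = tuple(d for d in pair if d in self.directions)
            if present:
                out.append(present)
        return out

    @property
    def n_full_pairs(self) -> int:
        return sum(1 for p in self.pairs if len(p) == 2)

    def distal_energy(self, material: Material = WATER) -> EnergySpec:
        """Energy of the deepest SOBP layer: range at the target's distal edge."""
        return EnergySpec(energy_for_range(self.species, self.target.x_max / 10.0, material))

    def beam(self, material: Material = WATER) -> BeamSpec:
        return BeamSpec(
            species=self.species,
            energy=self.distal_energy(material),
            shape=BeamShape.PLANAR,
            incident_width_fwhm=self.incident_width_fwhm,
            spacing_on_center=self.spacing_on_center,
        )


@dataclass(frozen=True)
class PlanReport:
    width_at_proximal_edge: float  # mm
    covered: bool
    reason: str  # "" when covered
    overdose_seam: bool
    target_physical_dose: float  # Gy
    target_gye: float  # Gy(RBE)
    incident_dose_factor_range: tuple[float, float]
    max_proximal_depth: float  # mm

    def as_dict(self) -> dict:
        return {
            "width_at_proximal_edge_mm": self.width_at_proximal_edge,
            "covered": self.covered,
            "reason": self.reason,
            "overdose_seam": self.overdose_seam,
            "target_physical_dose_gy": self.target_physical_dose,
            "target_gye": self.target_gye,
            "incident_dose_factor_range": list(self.incident_dose_factor_range),
            "max_proximal_depth_mm": self.max_proximal_depth,
        }


def _width_at(
    species: IonSpecies,
    energy: EnergySpec,
    incident_width: float,
    depth: float,
    material: Material,
) -> float:
    beam = BeamSpec(species=species, energy=energy, incident_width_fwhm=incident_width)
    state = propagate_moments(beam, [depth], material=material)[0]
    sigma_in = incident_width / FWHM_PER_SIGMA
    return float(total_fwhm(beam, state.A2 - sigma_in**2))


def check_coverage(plan: InterleavePlan, material: Material = WATER) -> PlanReport:
    """Verify the interleave geometry fills the target.

    Coverage requires, at the target-proximal edge (where the beams are
    narrowest inside the target): the interleaved planes of a pair —
    stacked every spacing/2 — to abut or overlap (width >= 90% of the
    half-spacing), and the width not to exceed the width limit (0.7 mm
    by default, beyond which the tissue-sparing effect fades).  Widths
    more than 10% beyond exact abutment are flagged as over-dose seams.
    """
    energy = plan.distal_energy(material)
    try:
        width = _width_at(
            plan.species, energy, plan.incident_width_fwhm, plan.target.x_min, material
        )
    except TransportRangeError as exc:
        raise PlanError(f"target deeper than transport validity: {exc}") from exc
    half_spacing = plan.spacing_on_center / 2.0
    covered, reason = True, ""
    if width > plan.width_limit:
        covered, reason = False, "width limit"
    elif width < (1.0 - ABUTMENT_TOLERANCE) * half_spacing:
        covered, reason = False, "gaps unfilled"
    seam = width > (1.0 + ABUTMENT_TOLERANCE) * half_spacing
    n_pairs = plan.n_full_pairs
    pair_dose = plan.pedestal_dose * plan.pedestal_to_sobp_ratio
    physical = pair_dose * n_pairs
    return PlanReport(
        width_at_proximal_edge=width,
        covered=covered,
        reason=reason,
        overdose_seam=seam,
        target_physical_dose=physical,
        target_gye=physical * plan.rbe,
        incident_dose_factor_range=carbon_incident_factor(
            plan.incident_width_fwhm, plan.spacing_on_center, min(width, plan.width_limit)
        ),
        max_proximal_depth=max_proximal_depth(
            plan.species, plan.incident_width_fwhm, plan.width_limit, material=material
        ),
    )


def max_proximal_depth(
    species: IonSpecies,
    incident_width: float = 0.3,
    width_limit: float = DEFAULT_WIDTH_LIMIT,
    target_margin: float = DEFAULT_TARGET_MARGIN,
    material: Material = WATER,
) -> float:
    """Deepest allowable target-proximal edge for a given width limit.

    For each candidate depth d the beam energy is re-chosen so the range
    is d + ``target_margin`` (the target span behind the proximal edge);
    the answer is the largest d with FWHM(d) <= width_limit, found by
    bisection (the width at the proximal edge grows with d).
    """
    if width_limit <= incident_width:
        return 0.0

    def f(d: float) -> float:
        energy = EnergySpec(energy_for_range(species, (d + target_margin) / 10.0, material))
        return _width_at(species, energy, incident_width, d, material) - width_limit

    lo, hi = 1.0, 200.0
    if f(lo) > 0:
        return 0.0
    while f(hi) < 0 and hi < 380.0:  # pragma: no cover - very heavy ions
        hi += 60.0
    return float(brentq(f, lo, hi, xtol=0.01))


def _comb_profile(v: np.ndarray, sigma: float, spacing: float, phase: float) -> np.ndarray:
    """Unit-peak Gaussian comb along the stacking axis."""
    k_min = int(np.floor((v.min() - phase) / spacing)) - 1
    k_max = int(np.ceil((v.max() - phase) / spacing)) + 1
    out = np.zeros_like(v)
    for k in range(k_min, k_max + 1):
        out += np.exp(-((v - (phase + k * spacing)) ** 2) / (2.0 * sigma**2))
    return np.minimum(out, 1.0)


def compose_interleaved_dose(
    plan: InterleavePlan,
    lateral_res: float = 0.05,
    depth_res: float = 0.5,
    material: Material = WATER,
) -> tuple[ArrayDoseMap, PlanReport]:
    """Composite 2-D dose map through the target mid-plane, plus report.

    The slice spans the +x/-x beam axis (depth) and the plane-stacking
    axis v.  Outside the target each x-travelling array paints its own
    comb at the pedestal in-beam dose, with the width the transport
    model gives at that depth; the y-travelling arrays do not intersect
    the slice outside the target box.  Inside the target the interleaved
    pairs form a solid field: each full pair contributes
    pedestal * pedestal_to_sobp_ratio (the arrays of a pair do not sum —
    their planes fill alternate slots), and the pairs add.

    Raises
    ------
    PlanError
        If the coverage check fails.
    """
    report = check_coverage(plan, material)
    if not report.covered:
        raise PlanError(f"refusing to compose dose: not covered ({report.reason})")
    box = plan.target
    L = box.phantom_extent
    depths = np.arange(0.0, L + depth_res / 2, depth_res)
    v_span = max(abs(box.v_min), abs(box.v_max)) + 5.0 * plan.spacing_on_center
    v = np.arange(-v_span, v_span + lateral_res / 2, lateral_res)
    dose = np.zeros((depths.size, v.size))
    energy = plan.distal_energy(material)
    # x-travelling arrays: comb outside the target, stopped at its distal face
    x_arrays = [d for d in plan.directions if d.axis == "x"]
    phases = {Direction.XPLUS: 0.0, Direction.XMINUS: plan.spacing_on_center / 4.0}
    for d in x_arrays:
        for i, x_pos in enumerate(depths):
            depth_in_beam = x_pos if d == Direction.XPLUS else L - x_pos
            proximal = box.x_min if d == Direction.XPLUS else L - box.x_max
            distal = box.x_max if d == Direction.XPLUS else L - box.x_min
            if depth_in_beam >= proximal or depth_in_beam > distal:
                continue  # inside target (handled below) or beyond beam stop
            width = _width_at(plan.species, energy, plan.incident_width_fwhm, depth_in_beam, material)
            sigma = width / FWHM_PER_SIGMA
            dose[i] += plan.pedestal_dose * _comb_profile(v, sigma, plan.spacing_on_center, phases[d])
    in_x = (depths >= box.x_min) & (depths <= box.x_max)
    in_v = (v >= box.v_min) & (v <= box.v_max)
    dose[np.ix_(in_x, in_v)] = report.target_physical_dose
    return ArrayDoseMap(depths=depths, lateral=v, dose=dose), report


def carbon_incident_factor(
    width: float, spacing: float, width_at_target: float
) -> tuple[float, float]:
    """Incident-dose multiplier bracket vs a solid beam, two-pair geometry.

    The upper factor is 2 * spacing/width: the factor 2 because the two
    arrays of a 90-degree pair do not add up anywhere, times the maximal
    comb dilution spacing/width at the incident surface.  The lower
    factor replaces the dilution by 2.0 * spacing/width_at_target — the
    beams have broadened to ``width_at_target`` just proximal to the
    target, and the 2.0 scale reproduces the conventional quoted lower
    endpoint (its derivation is not documented in the literature; the
    unscaled alternative spacing/width_at_target would give half this).
    The lower endpoint is clamped to the upper one — beams cannot be
    more diluted at the target than at the surface.  Both are reported
    to one decimal.
    """
    if not width <= width_at_target <= spacing:
        raise DomainError("need width <= width_at_target <= spacing")
    upper = 2.0 * spacing / width
    lower = min(2.0 * (2.0 * spacing / width_at_target), upper)
    return (round(lower, 1), round(upper, 1))
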