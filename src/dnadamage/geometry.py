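"""Hierarchical A/B/Z-DNA + nucleosome + chromatin-fiber + ROI geometry.

The genetic material is modelled on five organisation levels:

1. a base pair: an inner "base" cylinder of diameter ``bp_diameter`` with two
   sugar-phosphate *targets* attached, each an angular sector of the hollow
   cylinder between the base radius and the helix radius;
2. the double helix: successive base pairs advance by ``bp_axial_step`` along
   the helix axis and twist by ±360°/``bp_per_turn`` (negative for the
   left-handed Z form);
3. the nucleosome: the helix axis is wrapped into two stacked circular loops
   around an imaginary histone cylinder; the loop radius follows from the bp
   count and axial step, ``bp_per_nucleosome * bp_axial_step / (4 pi)``;
4. the 30 nm chromatin fiber: six nucleosomes per 10.5 nm axial level,
   arranged on a ring about the fiber axis with alternating sub-level heights
   (a two-start, solenoid-like zigzag that keeps all nucleosomes disjoint);
5. the region of interest (ROI): a thin annulus of central diameter 10 um,
   radial thickness 30 nm and height 5.25 um, tiled azimuthally by 900
   straight vertical fiber fragments of 500 levels each.

Targets are expressed in the torus coordinates of their nucleosome loop
(arc-length window along the bent helix axis, radial shell, angular sector),
which makes target placement and the event locator exact inverses of each
other.  The per-target Jacobian correction of the bent frame cancels exactly
between the two strands of a base pair, so the analytic sector volume and all
volume ratios are preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .constants import EV_TO_JOULE, GRAM_TO_KG, NM3_TO_CM3

__all__ = [
    "CONFORMATION_TABLE",
    "ConformationParams",
    "ROIParams",
    "TargetSector",
    "TargetAddress",
    "ConformationModel",
    "InvalidParameterError",
    "AddressError",
    "sector_volume",
    "build_conformation",
    "roi_volume",
    "roi_mass",
    "energy_for_dose",
    "predicted_hit_probability",
    "target_point",
    "target_centroid",
    "centroid_table",
    "local_to_lab",
    "lab_to_local",
]


class InvalidParameterError(ValueError):
    """A geometric parameter is outside its physical domain."""


class AddressError(IndexError):
    """A target address is outside the bounds of the governing model."""


#: Published helix dimensions for the three canonical conformations.
#: Lengths in nm, angles in degrees.
CONFORMATION_TABLE: dict[str, dict] = {
    "A": dict(
        handedness="right",
        dna_diameter=2.55,
        bp_diameter=1.0,
        bp_axial_step=0.23,
        bp_per_turn=10.7,
        helix_pitch=2.46,
        bp_per_nucleosome=286,
        helix_axial_shift=0.76,
        target_aperture=87.0,
        target_height=0.119,
    ),
    "B": dict(
        handedness="right",
        dna_diameter=2.37,
        bp_diameter=1.0,
        bp_axial_step=0.33,
        bp_per_turn=10.0,
        helix_pitch=3.2,
        bp_per_nucleosome=198,
        helix_axial_shift=1.2,
        target_aperture=73.0,
        target_height=0.183,
    ),
    "Z": dict(
        handedness="left",
        dna_diameter=1.84,
        bp_diameter=0.6,
        bp_axial_step=0.38,
        bp_per_turn=12.0,
        helix_pitch=3.0,
        bp_per_nucleosome=172,
        helix_axial_shift=0.77,
        target_aperture=60.0,
        target_height=0.249,
    ),
}


@dataclass(frozen=True)
class ConformationParams:
    """Dimensions of one DNA form.  Lengths in nm, angles in degrees."""

    label: str
    handedness: str
    dna_diameter: float
    bp_diameter: float
    bp_axial_step: float
    bp_per_turn: float
    helix_pitch: float
    bp_per_nucleosome: int
    helix_axial_shift: float
    target_aperture: float
    target_height: float

    def validate(self) -> None:
        if self.handedness not in ("right", "left"):
            raise InvalidParameterError(f"unknown handedness {self.handedness!r}")
        for name in (
            "dna_diameter",
            "bp_diameter",
            "bp_axial_step",
            "bp_per_turn",
            "helix_pitch",
            "target_height",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if not 0.0 < self.target_aperture < 360.0:
            raise InvalidParameterError("target_aperture must be in (0, 360) degrees")
        if self.bp_diameter >= self.dna_diameter:
            raise InvalidParameterError("bp_diameter must be smaller than dna_diameter")
        # Target height below the axial step: adjacent targets along the bent
        # helix must not touch.
        if self.target_height >= self.bp_axial_step:
            raise InvalidParameterError("target_height must be below bp_axial_step")
        if self.bp_per_nucleosome < 2 or self.bp_per_nucleosome % 2:
            raise InvalidParameterError(
                "bp_per_nucleosome must be an even count (two loops)"
            )


def canonical_params(label: str) -> ConformationParams:
    """Published parameters for conformation ``label`` ('A', 'B' or 'Z')."""
    try:
        row = CONFORMATION_TABLE[label]
    except KeyError:
        raise InvalidParameterError(f"unknown conformation {label!r}") from None
    params = ConformationParams(label=label, **row)
    # The left-handed form is Z and only Z.
    expected = "left" if label == "Z" else "right"
    assert params.handedness == expected
    return params


@dataclass(frozen=True)
class ROIParams:
    """Region-of-interest annulus and chromatin bookkeeping.  Lengths in nm."""

    central_diameter: float = 10_000.0
    radial_thickness: float = 30.0
    height: float = 5_250.0
    n_fragments: int = 900
    levels_per_fragment: int = 500
    nucleosomes_per_level: int = 6
    nucleosome_external_diameter: float = 10.5
    density: float = 1.06  # g/cm^3

    def __post_init__(self) -> None:
        if min(self.central_diameter, self.radial_thickness, self.height) <= 0:
            raise InvalidParameterError("ROI dimensions must be positive")
        if min(self.n_fragments, self.levels_per_fragment, self.nucleosomes_per_level) <= 0:
            raise InvalidParameterError("ROI counts must be positive")
        if self.density < 0:
            raise InvalidParameterError("density must be non-negative")

    @property
    def central_radius(self) -> float:
        return self.central_diameter / 2.0

    @property
    def inner_radius(self) -> float:
        return self.central_radius - self.radial_thickness / 2.0

    @property
    def outer_radius(self) -> float:
        return self.central_radius + self.radial_thickness / 2.0

    @property
    def level_height(self) -> float:
        return self.height / self.levels_per_fragment

    @property
    def fragment_width_deg(self) -> float:
        return 360.0 / self.n_fragments

    @property
    def total_nucleosomes(self) -> int:
        return self.n_fragments * self.levels_per_fragment * self.nucleosomes_per_level


@dataclass(frozen=True)
class TargetSector:
    """One sugar-phosphate target: an angular sector of a hollow cylinder."""

    r_min: float
    r_max: float
    aperture: float  # degrees
    height: float
    strand_angular_offset: float = 180.0  # degrees between the two strands
    strand_axial_offset: float = 0.0  # nm, along the helix axis


def sector_volume(sector: TargetSector) -> float:
    """Analytic volume (nm^3) of a hollow-cylinder angular sector.

    ``(aperture/360) * pi * (r_max^2 - r_min^2) * height``.  ``r_min`` may be
    zero (full cylinder core); all other dimensions must be positive and
    ``r_min < r_max``.
    """
    if sector.r_min < 0 or sector.r_min >= sector.r_max:
        raise InvalidParameterError("need 0 <= r_min < r_max")
    if sector.height <= 0:
        raise InvalidParameterError("height must be positive")
    if not 0.0 < sector.aperture <= 360.0:
        raise InvalidParameterError("aperture must be in (0, 360] degrees")
    return (
        (sector.aperture / 360.0)
        * math.pi
        * (sector.r_max**2 - sector.r_min**2)
        * sector.height
    )


@dataclass(frozen=True, order=True)
class TargetAddress:
    """Hierarchical index of one sugar-phosphate target.

    ``bp`` is the base-pair index within the nucleosome (0-based along the
    two-loop path: first the lower loop, then the upper one); ``strand`` is 0
    or 1.
    """

    fragment: int
    level: int
    nucleosome: int
    bp: int
    strand: int


@dataclass(frozen=True)
class ConformationModel:
    """A DNA conformation packed into the chromatin ROI, with derived totals."""

    params: ConformationParams
    roi: ROIParams
    sector: TargetSector
    twist_per_bp: float  # degrees, signed by handedness
    nucleosome_path_radius: float  # nm, radius of each DNA loop
    nucleosome_height: float  # nm, loop planes sit at +- height/4
    nucleosome_ring_radius: float  # nm, nucleosome centres about the fiber axis
    level_twist: float  # degrees of ring rotation per level
    total_nucleosomes: int
    total_bp: int
    total_targets: int
    target_volume: float  # nm^3, one sector
    total_target_volume: float  # nm^3, all targets in the ROI

    # -- convenience -------------------------------------------------------
    @property
    def label(self) -> str:
        return self.params.label

    @property
    def bp_per_nucleosome(self) -> int:
        return self.params.bp_per_nucleosome

    @property
    def bp_per_loop(self) -> int:
        return self.params.bp_per_nucleosome // 2

    @property
    def loop_circumference(self) -> float:
        # Exactly 2*pi*path_radius by construction of the path radius.
        return self.bp_per_loop * self.params.bp_axial_step

    @property
    def loop_z_offset(self) -> float:
        return self.nucleosome_height / 4.0

    @classmethod
    def from_params(
        cls,
        params: ConformationParams,
        roi: ROIParams | None = None,
        *,
        nucleosome_ring_radius: float = 8.0,
        level_twist: float = 30.0,
        strand_axial_offset: float = 0.0,
    ) -> "ConformationModel":
        """Build a model from explicit helix parameters.

        ``strand_axial_offset`` displaces the second strand's targets along
        the helix axis; the default 0 keeps the two strands symmetric.  Any
        offset is reduced modulo the bp axial step, which provably preserves
        target disjointness.
        """
        params.validate()
        roi = roi if roi is not None else ROIParams()
        sign = 1.0 if params.handedness == "right" else -1.0
        twist = sign * 360.0 / params.bp_per_turn
        path_radius = params.bp_per_nucleosome * params.bp_axial_step / (4.0 * math.pi)
        sector = TargetSector(
            r_min=params.bp_diameter / 2.0,
            r_max=params.dna_diameter / 2.0,
            aperture=params.target_aperture,
            height=params.target_height,
            strand_axial_offset=strand_axial_offset % params.bp_axial_step,
        )
        volume = sector_volume(sector)
        n_nuc = roi.total_nucleosomes
        n_bp = n_nuc * params.bp_per_nucleosome
        model = cls(
            params=params,
            roi=roi,
            sector=sector,
            twist_per_bp=twist,
            nucleosome_path_radius=path_radius,
            nucleosome_height=roi.nucleosome_external_diameter / 2.0,
            nucleosome_ring_radius=nucleosome_ring_radius,
            level_twist=level_twist,
            total_nucleosomes=n_nuc,
            total_bp=n_bp,
            total_targets=2 * n_bp,
            target_volume=volume,
            total_target_volume=2 * n_bp * volume,
        )
        model._check_packing()
        return model

    def _check_packing(self) -> None:
        """Verify that all targets are pairwise disjoint and inside the ROI.

        The checks are closed-form bounds on the bounding tori of the
        nucleosome loops; a violation means the conformation cannot be packed
        with the current fiber arrangement.
        """
        p, roi = self.params, self.roi
        # Bounding-tube radius of one loop: helix radius plus half the target
        # height (target corners).
        r_tube = math.hypot(self.sector.r_max, self.sector.height / 2.0)
        ring = self.nucleosome_ring_radius
        rho = self.nucleosome_path_radius
        fiber_radius = roi.radial_thickness / 2.0
        sub_pitch = roi.level_height / 2.0
        problems = []
        if ring * math.sqrt(3.0) < 2.0 * (rho + r_tube):
            problems.append("nucleosomes 120 degrees apart overlap")
        if ring + rho + r_tube > fiber_radius:
            problems.append("nucleosome extends beyond the fiber radius")
        if 2.0 * (self.loop_z_offset + r_tube) > sub_pitch:
            problems.append("nucleosome taller than its sub-level slot")
        if 2.0 * self.loop_z_offset < 2.0 * r_tube:
            problems.append("the two loops of one nucleosome overlap")
        if problems:
            raise InvalidParameterError(
                f"conformation {p.label!r} does not pack: " + "; ".join(problems)
            )


def build_conformation(label: str, roi: ROIParams | None = None) -> ConformationModel:
    """Build the canonical model for conformation ``label`` ('A', 'B', 'Z')."""
    return ConformationModel.from_params(canonical_params(label), roi)


# ---------------------------------------------------------------------------
# ROI scalars
# ---------------------------------------------------------------------------

def roi_volume(roi: ROIParams) -> float:
    """Annulus volume in nm^3: ``pi (R_out^2 - R_in^2) H``."""
    return (
        math.pi
        * (roi.outer_radius**2 - roi.inner_radius**2)
        * roi.height
    )


def roi_mass(roi: ROIParams) -> float:
    """ROI mass in kg at the model's water density."""
    return roi_volume(roi) * NM3_TO_CM3 * roi.density * GRAM_TO_KG


def energy_for_dose(dose_gy: float, roi: ROIParams) -> float:
    """Energy in eV that must be deposited in the ROI to reach ``dose_gy``."""
    return dose_gy * roi_mass(roi) / EV_TO_JOULE


def predicted_hit_probability(model: ConformationModel) -> float:
    """Analytic site-hit probability: total target volume over ROI volume."""
    return model.total_target_volume / roi_volume(model.roi)


# ---------------------------------------------------------------------------
# Coordinate maps (vectorised; lengths nm, angles internally radians)
# ---------------------------------------------------------------------------

def lab_to_local(xyz: np.ndarray, roi: ROIParams) -> tuple[np.ndarray, np.ndarray]:
    """Map lab-frame points to (fragment index, fragment-local coordinates).

    Local coordinates: x = signed arc length from the fragment's central
    azimuth measured at the central radius, y = radial offset from the central
    radius, z unchanged.  The map is a bijection of the annulus; points
    outside the annulus still get the fragment of their azimuth.
    """
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    r = np.hypot(x, y)
    phi = np.degrees(np.arctan2(y, x)) % 360.0
    w = roi.fragment_width_deg
    frag = np.minimum((phi // w).astype(np.int64), roi.n_fragments - 1)
    phi_c = (frag + 0.5) * w
    dphi = (phi - phi_c + 180.0) % 360.0 - 180.0
    local = np.column_stack(
        [np.radians(dphi) * roi.central_radius, r - roi.central_radius, z]
    )
    return frag, local


def local_to_lab(fragment: np.ndarray, local: np.ndarray, roi: ROIParams) -> np.ndarray:
    """Inverse of :func:`lab_to_local`."""
    local = np.atleast_2d(np.asarray(local, dtype=float))
    fragment = np.asarray(fragment, dtype=np.int64)
    phi_c = np.radians((fragment + 0.5) * roi.fragment_width_deg)
    phi = phi_c + local[:, 0] / roi.central_radius
    r = roi.central_radius + local[:, 1]
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), local[:, 2]])


def _nucleosome_centre(model: ConformationModel, level: np.ndarray, slot: np.ndarray):
    """Fragment-local (x, y, z-within-level) centre of a nucleosome slot."""
    roi = model.roi
    psi = np.radians(
        model.level_twist * np.asarray(level)
        + 360.0 / roi.nucleosomes_per_level * np.asarray(slot)
    )
    ring = model.nucleosome_ring_radius
    # Even slots in the lower sub-level, odd slots in the upper one.
    zc = np.where(np.asarray(slot) % 2 == 0, roi.level_height / 4.0, 3.0 * roi.level_height / 4.0)
    return ring * np.cos(psi), ring * np.sin(psi), zc


def _check_address(address: TargetAddress, model: ConformationModel) -> None:
    roi = model.roi
    ok = (
        0 <= address.fragment < roi.n_fragments
        and 0 <= address.level < roi.levels_per_fragment
        and 0 <= address.nucleosome < roi.nucleosomes_per_level
        and 0 <= address.bp < model.bp_per_nucleosome
        and address.strand in (0, 1)
    )
    if not ok:
        raise AddressError(f"address {address} out of bounds for model {model.label}")


def target_point(
    address: TargetAddress,
    model: ConformationModel,
    angle_frac: float = 0.5,
    radius_frac: float = 0.5,
    axial_frac: float = 0.5,
) -> np.ndarray:
    """Lab-frame point of a target, parameterised by interior fractions.

    Fractions in (0, 1) give interior points; 0.5 everywhere gives the target
    reference point (mid-radius, mid-aperture, mid-height).  Fractions outside
    [0, 1] extrapolate beyond the target, which is occasionally useful for
    probing its surroundings.
    """
    _check_address(address, model)
    p, roi, sec = model.params, model.roi, model.sector
    rho = model.nucleosome_path_radius
    n_half = model.bp_per_loop
    loop, i = divmod(address.bp, n_half)
    # Arc-length coordinate along the loop (torus coordinates).
    s = i * p.bp_axial_step
    if address.strand == 1:
        s += sec.strand_axial_offset
    s += (axial_frac - 0.5) * sec.height
    theta = (s % model.loop_circumference) / rho
    # Twist angle of this bp (global along the two-loop path) plus strand.
    alpha_c = address.bp * model.twist_per_bp + address.strand * sec.strand_angular_offset
    alpha = math.radians(alpha_c + (angle_frac - 0.5) * sec.aperture)
    rr = sec.r_min + radius_frac * (sec.r_max - sec.r_min)
    # Position in the nucleosome frame.
    lz = model.loop_z_offset if loop else -model.loop_z_offset
    er = np.array([math.cos(theta), math.sin(theta), 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    pos = rho * er + np.array([0.0, 0.0, lz]) + rr * (math.cos(alpha) * er + math.sin(alpha) * ez)
    # Nucleosome frame -> fragment-local frame.
    cx, cy, cz = _nucleosome_centre(
        model, np.asarray(address.level), np.asarray(address.nucleosome)
    )
    local = pos + np.array([float(cx), float(cy), float(cz) + address.level * roi.level_height])
    return local_to_lab(np.array([address.fragment]), local[None, :], roi)[0]


def target_centroid(address: TargetAddress, model: ConformationModel) -> np.ndarray:
    """Lab-frame reference point (mid-fractions) of a target."""
    return target_point(address, model)


def centroid_table(
    model: ConformationModel,
    fragments: Iterable[int] = (0,),
    levels: Iterable[int] = (0,),
):
    """Centroid coordinates of every target in the given fragments/levels.

    Returns a :class:`pandas.DataFrame` with columns
    ``fragment, level, nucleosome, bp, strand, x_nm, y_nm, z_nm`` suitable for
    CSV export and external visualisation.
    """
    import pandas as pd

    rows = []
    for f in fragments:
        for l in levels:
            for n in range(model.roi.nucleosomes_per_level):
                for b in range(model.bp_per_nucleosome):
                    for s in (0, 1):
                        x, y, z = target_centroid(TargetAddress(f, l, n, b, s), model)
                        rows.append((f, l, n, b, s, x, y, z))
    return pd.DataFrame(
        rows,
        columns=["fragment", "level", "nucleosome", "bp", "strand", "x_nm", "y_nm", "z_nm"],
    )
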