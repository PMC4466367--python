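"""Analytic geometry: sector volumes, totals, ROI scalars, predictions."""

import math

import numpy as np
import pytest

from dnadamage import (
    InvalidParameterError,
    TargetSector,
    build_conformation,
    energy_for_dose,
    predicted_hit_probability,
    roi_mass,
    roi_volume,
    sector_volume,
)
from dnadamage.geometry import ROIParams, canonical_params, ConformationModel

from conftest import LABELS, rng_for


# Published per-conformation reference values: (target volume rounded to two
# decimals, total bp to three significant digits, predicted volume ratio to
# three decimals).
REFERENCE = {
    "A": (0.12, 7.72e8, 0.038),
    "B": (0.13, 5.35e8, 0.029),
    "Z": (0.10, 4.64e8, 0.018),
}


def mc_sector_volume(sector, n, rng):
    """Independent rejection-sampling estimate of the sector volume.

    Samples the bounding cylinder (radius r_max, height h) uniformly and
    tests membership with direct inequalities.
    """
    x = rng.uniform(-sector.r_max, sector.r_max, size=n)
    y = rng.uniform(-sector.r_max, sector.r_max, size=n)
    rr = np.hypot(x, y)
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    half = sector.aperture / 2.0
    inside = (
        (rr >= sector.r_min)
        & (rr < sector.r_max)
        & ((ang < half) | (ang >= 360.0 - half))
    )
    box = (2.0 * sector.r_max) ** 2 * sector.height
    frac = inside.mean()
    se = math.sqrt(frac * (1 - frac) / n) * box
    return frac * box, se


class TestSectorVolume:
    @pytest.mark.parametrize("label", LABELS)
    def test_published_rounding(self, models, label):
        assert round(models[label].target_volume, 2) == REFERENCE[label][0]

    def test_b_dna_value(self):
        sector = TargetSector(r_min=0.5, r_max=1.185, aperture=73.0, height=0.183)
        assert sector_volume(sector) == pytest.approx(0.1346, abs=5e-4)

    def test_full_cylinder_degenerate(self):
        sector = TargetSector(r_min=0.0, r_max=2.0, aperture=360.0, height=1.5)
        assert sector_volume(sector) == pytest.approx(math.pi * 4.0 * 1.5)

    @pytest.mark.parametrize("label", LABELS)
    def test_agrees_with_mc_rejection_oracle(self, models, label):
        sector = models[label].sector
        est, se = mc_sector_volume(sector, 400_000, rng_for("mc-sector", label))
        assert abs(est - sector_volume(sector)) < 3.0 * se

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(InvalidParameterError):
            sector_volume(TargetSector(r_min=1.0, r_max=0.5, aperture=90.0, height=0.1))
        with pytest.raises(InvalidParameterError):
            sector_volume(TargetSector(r_min=0.1, r_max=0.5, aperture=90.0, height=-1.0))


class TestConformationModel:
    @pytest.mark.parametrize("label", LABELS)
    def test_structural_totals(self, models, label):
        model = models[label]
        assert model.total_nucleosomes == 900 * 500 * 6 == 2_700_000
        assert model.total_bp == 2_700_000 * model.params.bp_per_nucleosome
        assert model.total_targets == 2 * model.total_bp
        # Three significant digits against the published totals.
        ref = REFERENCE[label][1]
        assert abs(model.total_bp - ref) / ref < 5e-3

    def test_twist_sign_follows_handedness(self, models):
        assert models["Z"].twist_per_bp == pytest.approx(-30.0)
        assert models["A"].twist_per_bp == pytest.approx(360.0 / 10.7)
        assert models["B"].twist_per_bp == pytest.approx(36.0)

    @pytest.mark.parametrize("label", LABELS)
    def test_path_radius_closes_two_loops(self, models, label):
        # Two full loops of the path radius have arc length n_bp * step.
        model = models[label]
        arc = 2.0 * 2.0 * math.pi * model.nucleosome_path_radius
        assert arc == pytest.approx(
            model.params.bp_per_nucleosome * model.params.bp_axial_step
        )
        assert model.nucleosome_path_radius == pytest.approx(5.2, abs=0.05)

    def test_odd_bp_count_rejected(self):
        import dataclasses

        params = dataclasses.replace(canonical_params("B"), bp_per_nucleosome=199)
        with pytest.raises(InvalidParameterError):
            ConformationModel.from_params(params)


class TestROIScalars:
    def test_annulus_volume(self, roi):
        # Independent arithmetic: pi (R_out^2 - R_in^2) H = pi * D * t * H.
        expected = math.pi * (5015.0**2 - 4985.0**2) * 5250.0
        assert roi_volume(roi) == pytest.approx(expected)
        assert roi_volume(roi) == pytest.approx(math.pi * 10_000.0 * 30.0 * 5250.0)

    def test_volume_vanishes_with_thickness(self):
        thin = ROIParams(radial_thickness=1e-9)
        assert roi_volume(thin) < 1e-3 * roi_volume(ROIParams())

    def test_mass_and_dose_energy(self, roi):
        # Hand conversion: 4.948e9 nm^3 x 1.06 g/cm^3 = 5.24e-15 kg.
        assert roi_mass(roi) == pytest.approx(5.245e-15, rel=1e-3)
        assert energy_for_dose(100.0, roi) == pytest.approx(3.274e6, rel=1e-3)
        assert roi_mass(ROIParams(density=0.0)) == 0.0

    @pytest.mark.parametrize("label", LABELS)
    def test_predicted_probability_matches_published(self, models, label):
        # Printed to three decimals (truncated); agree within one last-digit ulp.
        pred = predicted_hit_probability(models[label])
        assert abs(pred - REFERENCE[label][2]) < 1e-3

    def test_zero_bp_gives_zero_probability(self, roi):
        import dataclasses

        model = dataclasses.replace(
            build_conformation("B", roi), total_bp=0, total_targets=0, total_target_volume=0.0
        )
        assert predicted_hit_probability(model) == 0.0
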