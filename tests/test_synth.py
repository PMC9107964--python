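"""Synthetic field generators: realistic AII-like mosaics and regular contrasts."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from retmosaic import (
    RegularMosaicConfig,
    SimConfig,
    default_template,
    generate_realistic_field,
    generate_regular_mosaic,
    generate_retina,
    nearest_neighbor_distances,
    read_field,
    regularity_index,
    simulate_field,
    write_field,
)


class TestRealisticField:
    def test_degenerate_limit_matches_hardcore_simulator(self):
        # z_jitter 0 and circular somas: same law as the 2-D hard-core RSA
        template = default_template()
        template.z_jitter_sd = 0.0
        template.ellipticity = 1.0
        template.ellipticity_sd = 0.0
        quad, region = "nasal", 3
        k = region - 1
        density = template.density_by_region[quad][k]
        n = round(density * template.window.area_mm2)
        cfg = SimConfig(
            n_cells=n,
            diameter_mean=template.diameter_mean_by_region[k],
            diameter_sd=template.diameter_sd_by_region[k],
            window=template.window,
        )
        ri_synth, ri_hard = [], []
        for s in range(30):
            f = generate_realistic_field(template, quad, region, s)
            g = simulate_field(cfg, trial_seed=s)
            ri_synth.append(regularity_index(nearest_neighbor_distances(f)).regularity_index)
            ri_hard.append(regularity_index(nearest_neighbor_distances(g)).regularity_index)
        assert ks_2samp(ri_synth, ri_hard).pvalue > 0.01

    def test_depth_jitter_produces_subcontact_nnds(self):
        # 3 μm depth displacement projected away: apparent XY overlap
        template = default_template()
        template.z_jitter_sd = 3.0
        hits = 0
        trials = 40
        for s in range(trials):
            f = generate_realistic_field(template, "dorsal", 4, s)
            if nearest_neighbor_distances(f).min() < 8.0:
                hits += 1
        assert hits >= trials // 2

    def test_regional_density_ordering(self):
        template = default_template()
        for s in range(20):
            f1 = generate_realistic_field(template, "dorsal", 1, s)
            f4 = generate_realistic_field(template, "dorsal", 4, s)
            assert f4.n > f1.n

    def test_realistic_regularity_range(self):
        # mid-to-high-density fields land in the regularity range reported
        # for real AII mosaics
        template = default_template()
        for quad, region in [("ventral", 1), ("dorsal", 4)]:
            ris = [
                regularity_index(
                    nearest_neighbor_distances(generate_realistic_field(template, quad, region, s))
                ).regularity_index
                for s in range(5)
            ]
            assert 3.5 <= np.mean(ris) <= 5.0

    def test_morphology_recorded(self):
        f = generate_realistic_field(default_template(), "temporal", 2, 0)
        assert f.diameter is not None and (f.diameter > 0).all()
        assert np.all(f.feret_max >= f.feret_min)
        # area-preserving ellipse: feret product equals diameter squared
        np.testing.assert_allclose(f.feret_max * f.feret_min, f.diameter**2, rtol=1e-9)

    def test_unknown_quadrant_rejected(self):
        with pytest.raises(ValueError, match="quadrant"):
            generate_realistic_field(default_template(), "central", 1, 0)


class TestRegularMosaic:
    def test_more_regular_than_soma_matched_hardcore(self):
        # a d_min exclusion zone twice the soma diameter tightens the NND
        # distribution far beyond the soma-contact constraint
        n = 110
        reg_cfg = RegularMosaicConfig(n_cells=n, exclusion_mean=18.0, exclusion_sd=1.0)
        hard_cfg = SimConfig(n_cells=n, diameter_mean=9.0, diameter_sd=0.4)
        wins = 0
        pairs = 20
        for s in range(pairs):
            m = generate_regular_mosaic(reg_cfg, s)
            h = simulate_field(hard_cfg, trial_seed=s)
            ri_m = regularity_index(nearest_neighbor_distances(m)).regularity_index
            ri_h = regularity_index(nearest_neighbor_distances(h)).regularity_index
            wins += ri_m > ri_h
        assert wins >= int(0.95 * pairs)

    def test_zero_sd_equivalent_to_fixed_diameter_hardcore(self):
        reg_cfg = RegularMosaicConfig(n_cells=120, exclusion_mean=9.0, exclusion_sd=0.0)
        hard_cfg = SimConfig(n_cells=120, diameter_mean=9.0, diameter_sd=0.0)
        nnd_reg, nnd_hard = [], []
        for s in range(20):
            nnd_reg.append(nearest_neighbor_distances(generate_regular_mosaic(reg_cfg, s)))
            nnd_hard.append(nearest_neighbor_distances(simulate_field(hard_cfg, trial_seed=s)))
        nnd_reg, nnd_hard = np.concatenate(nnd_reg), np.concatenate(nnd_hard)
        assert nnd_reg.min() >= 9.0 - 1e-9
        assert nnd_hard.min() >= 9.0 - 1e-9
        assert ks_2samp(nnd_reg, nnd_hard).pvalue > 0.01

    def test_single_cell(self):
        f = generate_regular_mosaic(RegularMosaicConfig(n_cells=1), 0)
        assert f.n == 1


class TestRetina:
    @pytest.fixture(scope="class")
    def retina(self):
        return generate_retina(default_template(), seed=7)

    def test_sixteen_labelled_fields(self, retina):
        assert len(retina) == 16
        labels = {(f.quadrant, f.region_index) for f in retina}
        assert labels == {
            (q, r) for q in ("dorsal", "ventral", "nasal", "temporal") for r in (1, 2, 3, 4)
        }

    def test_same_seed_reproduces_retina(self, retina):
        again = generate_retina(default_template(), seed=7)
        for a, b in zip(retina, again):
            np.testing.assert_array_equal(a.x, b.x)
            np.testing.assert_array_equal(a.y, b.y)

    def test_dorsal_gradient_steeper_than_ventral(self, retina):
        by = {(f.quadrant, f.region_index): f.n for f in retina}
        dorsal_ratio = by[("dorsal", 4)] / by[("dorsal", 1)]
        ventral_ratio = by[("ventral", 4)] / by[("ventral", 1)]
        assert dorsal_ratio > ventral_ratio

    def test_round_trip_through_field_format(self, retina, tmp_path):
        f = retina[0]
        write_field(f, tmp_path / "f.csv")
        g = read_field(tmp_path / "f.csv")
        assert g.field_id == f.field_id
        assert g.quadrant == f.quadrant
        assert g.region_index == f.region_index
        assert g.window == f.window
        np.testing.assert_allclose(g.x, f.x, atol=1e-6)
        np.testing.assert_allclose(g.diameter, f.diameter, atol=1e-6)
        np.testing.assert_allclose(g.feret_min, f.feret_min, atol=1e-6)
        np.testing.assert_array_equal(g.edge_included, f.edge_included)
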