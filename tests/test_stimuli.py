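import numpy as np
import pytest

from matodd import stimuli as st
from matodd.psychophysics import OddityDesign, TaskCondition, simulate_oddity_pc

SIZE = 128


class TestRenderer:
    def test_deterministic(self, scene_obj2):
        a = st.render_object(scene_obj2, st.MaterialSpec("GC", 0.06), SIZE)
        b = st.render_object(scene_obj2, st.MaterialSpec("GC", 0.06), SIZE)
        assert np.array_equal(a, b)

    def test_off_grid_parameter_names_grid(self, scene_obj2):
        with pytest.raises(ValueError, match="valid grid"):
            st.MaterialSpec("GC", 0.05)
        with pytest.raises(ValueError, match="valid grid"):
            st.MaterialSpec("OT", 0.5)

    def test_specular_energy_monotone_in_rho_s(self, scene_obj2):
        energies = [
            st.render_layers(scene_obj2, st.MaterialSpec("GC", v), SIZE)[
                "specular"
            ].mean()
            for v in st.PARAMETER_GRIDS["GC"]
        ]
        assert np.all(np.diff(energies) > 0)

    def test_highlight_sharpness_monotone_in_doi(self, scene_obj2):
        peaks = [
            st.render_layers(scene_obj2, st.MaterialSpec("GD", v), SIZE)[
                "specular"
            ].max()
            for v in st.PARAMETER_GRIDS["GD"]
        ]
        assert np.all(np.diff(peaks) > 0)

    def test_translucent_show_through_monotone_in_scale(self, scene_obj2):
        means = []
        for v in st.PARAMETER_GRIDS["OT"]:
            layers = st.render_layers(scene_obj2, st.MaterialSpec("OT", v), SIZE)
            means.append(layers["shading"][layers["mask"]].mean())
        # denser medium -> less backlight bleeds through -> darker body...
        # here the opaque milk body is brighter than the transmitted backlight
        assert np.all(np.diff(means) > 0)

    def test_blend_identity_at_zero_weight(self, scene_obj2):
        for dim in ("MP", "MG"):
            img0 = st.render_object(scene_obj2, st.MaterialSpec(dim, 0.0), SIZE)
            img0b = st.render_object(scene_obj2, st.MaterialSpec(dim, 0.0), SIZE)
            assert np.array_equal(img0, img0b)
            img_mid = st.render_object(scene_obj2, st.MaterialSpec(dim, 0.4), SIZE)
            assert not np.array_equal(img0, img_mid)

    def test_blend_monotone(self, scene_obj2):
        """Pixel distance from the pure endpoint grows with the blend weight."""
        for dim in ("MP", "MG"):
            ref = st.render_object(scene_obj2, st.MaterialSpec(dim, 0.0), SIZE)
            dists = [
                np.mean(
                    (
                        st.render_object(
                            scene_obj2, st.MaterialSpec(dim, v), SIZE
                        ).astype(float)
                        - ref
                    )
                    ** 2
                )
                for v in st.PARAMETER_GRIDS[dim]
            ]
            assert np.all(np.diff(dists) > 0)

    def test_geometry_presets_reproducible(self):
        for obj_id, geom in st.OBJECTS.items():
            sc = st.SceneSpec(geom, 1, 36)
            a = st.render_layers(sc, st.MaterialSpec("GC", 0.06), SIZE)["shading"]
            b = st.render_layers(sc, st.MaterialSpec("GC", 0.06), SIZE)["shading"]
            assert np.array_equal(a, b)

    def test_pose_must_be_multiple_of_36(self):
        with pytest.raises(ValueError):
            st.SceneSpec(st.OBJECTS[1], 1, 30)


class TestInconsistentHighlights:
    def test_histogram_matched_exactly(self, scene_obj2):
        inc = st.make_inconsistent_highlights(scene_obj2, 0.96, seed=3, size=SIZE)
        cons = st.render_object(scene_obj2, st.MaterialSpec("GP", 0.96), SIZE)
        for ch in range(3):
            h1 = np.bincount(inc[..., ch].ravel(), minlength=256)
            h2 = np.bincount(cons[..., ch].ravel(), minlength=256)
            assert np.array_equal(h1, h2)

    def test_identity_mapping_reproduces_consistent_render(self, scene_obj2):
        ident = st.make_inconsistent_highlights(
            scene_obj2, 0.96, seed=3, size=SIZE, identity=True
        )
        cons = st.render_object(scene_obj2, st.MaterialSpec("GP", 0.96), SIZE)
        assert np.array_equal(ident, cons)

    def test_displaced_highlights_less_coherent_on_all_objects(self):
        for obj_id, geom in st.OBJECTS.items():
            sc = st.SceneSpec(geom, 1, 0)
            _, layers = st.make_inconsistent_highlights(
                sc, 0.96, seed=11, size=SIZE, return_layers=True
            )
            coh_cons = st.highlight_shading_coherence(
                layers["shading"], layers["specular"], layers["mask"]
            )
            coh_inc = st.highlight_shading_coherence(
                layers["shading"], layers["remapped_specular"], layers["mask"]
            )
            assert coh_inc < coh_cons, f"object {obj_id}"


class TestOddityDisplay:
    def test_illumination1_four_images_distinct_poses(self):
        cond = TaskCondition("GC", 2, 1, 0.12)
        disp = st.make_oddity_display(cond, seed=5, size=SIZE)
        assert disp.m == 4
        assert 0 <= disp.target_index < 4
        # images pairwise distinct (different poses)
        for i in range(4):
            for j in range(i + 1, 4):
                if i != disp.target_index and j != disp.target_index:
                    assert not np.array_equal(disp.images[i], disp.images[j])

    def test_illumination3_three_distinct_proxies(self):
        cond = TaskCondition("OT", 1, 3, 0.0625)
        disp = st.make_oddity_display(cond, seed=5, size=SIZE)
        assert disp.m == 3
        for i in range(3):
            for j in range(i + 1, 3):
                assert not np.array_equal(disp.images[i], disp.images[j])

    def test_gp_restricted_to_illumination1(self):
        with pytest.raises(ValueError, match="illumination condition 1"):
            st.make_oddity_display(TaskCondition("GP", 1, 2, 0.96), seed=0)

    def test_anchor_target_gives_chance_accuracy(self):
        """No informative difference -> the simulated observer is at chance."""
        cond = TaskCondition("GC", 2, 2, 0.06)  # target equals the anchor
        link = lambda delta: 3.0 * (abs(delta) / 0.06)
        hits = [
            st.simulate_observer(cond, link, lapse=0.0, seed=s).correct
            for s in range(3000)
        ]
        pc = np.mean(hits)
        assert abs(pc - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / 3000)

    def test_design_counts_match_stimulus_table(self):
        """6 tasks under illumination 1; 5 under illuminations 2 and 3."""
        from matodd.pipeline import PipelineConfig, default_conditions

        conds = default_conditions(PipelineConfig())
        by_ill = {}
        for c in conds:
            by_ill.setdefault(c.illumination, set()).add((c.dimension, c.object_id))
        assert len({d for d, _ in by_ill[1]}) == 6
        assert len({d for d, _ in by_ill[2]}) == 5
        assert len({d for d, _ in by_ill[3]}) == 5
        for ill in (1, 2, 3):
            dims = {d for d, _ in by_ill[ill]}
            for d in dims:
                assert len({o for dd, o in by_ill[ill] if dd == d}) == 5


class TestSimulatedObserver:
    COND = TaskCondition("GC", 2, 2, 0.12)

    def test_zero_link_is_chance(self):
        hits = [
            st.simulate_observer(self.COND, lambda d: 0.0, 0.0, seed=s).correct
            for s in range(3000)
        ]
        assert abs(np.mean(hits) - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / 3000)

    def test_strong_link_saturates(self):
        hits = [
            st.simulate_observer(self.COND, lambda d: 10.0 if d > 0 else 0.0, 0.0, seed=s).correct
            for s in range(500)
        ]
        assert np.mean(hits) > 0.98

    def test_consistent_with_psychometric_simulation(self):
        """Observer accuracy at link = 2 matches the psychometric function."""
        link = lambda delta: 2.0 if delta > 0 else 0.0
        n = 20_000
        hits = [
            st.simulate_observer(self.COND, link, 0.0, seed=s).correct
            for s in range(n)
        ]
        pc_obs = np.mean(hits)
        pc_ref = simulate_oddity_pc(2.0, OddityDesign(m=3, n_sim=500_000, seed=1))
        se = np.sqrt(pc_ref * (1 - pc_ref) * (1 / n + 1 / 500_000))
        assert abs(pc_obs - pc_ref) < 3 * se

    def test_lapse_bounds(self):
        with pytest.raises(ValueError):
            st.simulate_observer(self.COND, lambda d: 1.0, 0.6, seed=0)
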