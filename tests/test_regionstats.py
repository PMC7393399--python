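"""Regional statistics, lesion exclusion, and network overlap metrics."""

import math

import numpy as np
import pytest

import lesioncorr as lc
from oracles import brute_region_stats, count_map


def uniform_parc(n, name="Region", rid=1):
    return lc.Parcellation(
        np.full(n, rid, dtype=np.int32),
        {0: ("Unknown", (25, 5, 25)), rid: (name, (100, 100, 100))},
    )


class TestRegionStats:
    def test_uniform_thickness_closed_form(self, icosphere3):
        """One region of area A with thickness t has volume t*A/1000 ml."""
        t = 2.5
        parc = uniform_parc(icosphere3.n_vertices)
        rows = lc.region_stats(
            icosphere3, lc.VertexScalarField(np.full(icosphere3.n_vertices, t), "mm"), parc
        )
        area = lc.triangle_areas(icosphere3).sum()
        assert rows[0].mean_thickness_mm == pytest.approx(t, rel=1e-12)
        assert rows[0].volume_ml == pytest.approx(t * area / 1000.0, rel=1e-9)

    def test_fully_excluded_region_is_flagged(self, icosphere3):
        parc = uniform_parc(icosphere3.n_vertices)
        overlay = lc.SurfaceLabel("lh.all-lesions", "lh", np.arange(icosphere3.n_vertices))
        rows = lc.region_stats(
            icosphere3,
            lc.VertexScalarField(np.full(icosphere3.n_vertices, 2.0), "mm"),
            parc,
            exclude=overlay,
        )
        assert rows[0].num_vertices == 0
        assert not rows[0].thickness_defined
        assert math.isnan(rows[0].mean_thickness_mm)
        assert rows[0].volume_ml == 0.0

    def test_length_mismatch_rejected(self, icosphere3):
        parc = uniform_parc(icosphere3.n_vertices)
        with pytest.raises(ValueError, match="thickness"):
            lc.region_stats(icosphere3, lc.VertexScalarField(np.ones(5), "mm"), parc)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        subject = lc.make_subject(seed, subdivisions=3)
        for hemi in ("lh", "rh"):
            mesh = subject.meshes[hemi]
            th = subject.thickness[hemi]
            parc = subject.parcellations[hemi]
            overlay = lc.combine_labels(subject.lesions[hemi], hemi)
            rows = lc.region_stats(mesh, th, parc, overlay, hemi)
            want = brute_region_stats(mesh, th.values, parc, overlay.vertex_ids)
            for row in rows:
                w = want[row.region_name]
                assert row.num_vertices == w["num_vertices"]
                assert row.surface_area_mm2 == pytest.approx(w["area"], rel=1e-9)
                assert row.mean_thickness_mm == pytest.approx(w["mean_th"], rel=1e-9)
                assert row.volume_ml == pytest.approx(w["volume"], rel=1e-9)

    def test_unweighted_mean_option(self, subject3):
        mesh, th, parc = (
            subject3.meshes["lh"],
            subject3.thickness["lh"],
            subject3.parcellations["lh"],
        )
        rows = lc.region_stats(mesh, th, parc, area_weighted=False)
        want = brute_region_stats(mesh, th.values, parc, (), area_weighted=False)
        for row in rows:
            assert row.mean_thickness_mm == pytest.approx(want[row.region_name]["mean_th"], rel=1e-9)


class TestCorrectedStats:
    def test_empty_overlay_is_identity(self, subject3):
        mesh, th, parc = (
            subject3.meshes["lh"],
            subject3.thickness["lh"],
            subject3.parcellations["lh"],
        )
        overlay = lc.combine_labels([], "lh")
        pre, post = lc.corrected_stats(mesh, th, parc, overlay)
        for a, b in zip(pre, post):
            assert a == b

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_area_conservation(self, seed):
        """Per region: pre area = post area + lesion-overlap area."""
        subject = lc.make_subject(seed, subdivisions=3)
        mesh, th, parc = (
            subject.meshes["lh"],
            subject.thickness["lh"],
            subject.parcellations["lh"],
        )
        overlay = lc.combine_labels(subject.lesions["lh"], "lh")
        pre, post = lc.corrected_stats(mesh, th, parc, overlay)
        va = lc.vertex_areas(mesh).values
        ind = overlay.indicator(mesh.n_vertices)
        for a, b in zip(pre, post):
            rid = [i for i, (n, _c) in parc.region_table.items() if n == a.region_name][0]
            overlap = va[(parc.region_id_per_vertex == rid) & ind].sum()
            assert a.surface_area_mm2 == pytest.approx(
                b.surface_area_mm2 + overlap, rel=1e-6
            )

    def test_monotonicity_under_growing_exclusion(self, subject3):
        mesh, th, parc = (
            subject3.meshes["lh"],
            subject3.thickness["lh"],
            subject3.parcellations["lh"],
        )
        rng = np.random.default_rng(0)
        ids = np.sort(rng.choice(mesh.n_vertices, 200, replace=False))
        small = lc.SurfaceLabel("lh.all-lesions", "lh", ids[:80])
        large = lc.SurfaceLabel("lh.all-lesions", "lh", ids)
        rows_small = lc.region_stats(mesh, th, parc, small)
        rows_large = lc.region_stats(mesh, th, parc, large)
        for a, b in zip(rows_small, rows_large):
            assert b.surface_area_mm2 <= a.surface_area_mm2 + 1e-12
            assert b.num_vertices <= a.num_vertices

    def test_removing_thin_patch_raises_mean_thickness(self, icosphere3):
        n = icosphere3.n_vertices
        th = np.full(n, 2.5)
        lesion_ids = np.arange(60)
        th[lesion_ids] = 0.0
        parc = uniform_parc(n)
        overlay = lc.SurfaceLabel("lh.all-lesions", "lh", lesion_ids)
        pre, post = lc.corrected_stats(icosphere3, lc.VertexScalarField(th, "mm"), parc, overlay)
        assert post[0].mean_thickness_mm > pre[0].mean_thickness_mm
        assert post[0].mean_thickness_mm == pytest.approx(2.5, rel=1e-12)


class TestOverlapMetrics:
    def test_entire_network_lesioned_is_100(self, subject3):
        parc = subject3.parcellations["lh"]
        mesh = subject3.meshes["lh"]
        rid = 5
        lesion = lc.SurfaceLabel(
            "lh.lesion-01", "lh", np.flatnonzero(parc.region_id_per_vertex == rid)
        )
        pct = lc.pct_surface_area_affected(mesh, parc, [lesion])
        assert pct[parc.name_of(rid)] == pytest.approx(100.0)

    def test_no_lesions_is_zero_everywhere(self, subject3):
        pct = lc.pct_surface_area_affected(
            subject3.meshes["lh"], subject3.parcellations["lh"], []
        )
        assert all(v == 0.0 for v in pct.values())

    def test_planted_fraction_recovered(self, subject3):
        """The generator's achieved area fraction is reproduced exactly."""
        pct = lc.pct_surface_area_affected(
            subject3.meshes["lh"], subject3.parcellations["lh"], subject3.lesions["lh"]
        )
        for gt in subject3.ground_truth["lesions"]:
            assert pct[gt["network"]] / 100.0 == pytest.approx(gt["achieved_fraction"], rel=1e-9)
            assert (
                abs(gt["achieved_fraction"] - gt["target_fraction"]) <= gt["quantization_bound"]
            )

    def test_pct_volume_change_arithmetic(self):
        assert lc.pct_volume_change(90.0, 90.0) == 0.0
        assert lc.pct_volume_change(90.0, 100.0, "pre") == pytest.approx(100 / 9)
        assert lc.pct_volume_change(90.0, 100.0, "post") == pytest.approx(10.0)
        with pytest.raises(ValueError, match="> 0"):
            lc.pct_volume_change(0.0, 1.0, "pre")
        with pytest.raises(ValueError, match="denominator"):
            lc.pct_volume_change(1.0, 1.0, "both")

    def test_uniform_thickness_volume_tracks_area(self, subject3):
        """With flat thickness, % volume change (pre) = -% area affected."""
        mesh = subject3.meshes["lh"]
        parc = subject3.parcellations["lh"]
        th = lc.VertexScalarField(np.full(mesh.n_vertices, 2.5), "mm")
        overlay = lc.combine_labels(subject3.lesions["lh"], "lh")
        pre, post = lc.corrected_stats(mesh, th, parc, overlay)
        pct_area = lc.pct_surface_area_affected(mesh, parc, subject3.lesions["lh"])
        for a, b in zip(pre, post):
            dv = lc.pct_volume_change(a.volume_ml, b.volume_ml, "pre")
            assert dv == pytest.approx(-pct_area[a.region_name], abs=1e-9)


class TestLesionCounts:
    def test_single_network_lesion(self, subject3):
        parc = subject3.parcellations["lh"]
        rid = 3
        inside = np.flatnonzero(parc.region_id_per_vertex == rid)[:5]
        lesion = lc.SurfaceLabel("lh.lesion-01", "lh", inside)
        counts = lc.lesions_per_network(parc, [lesion])
        for name, (n, flag) in counts.items():
            assert (n, flag) == ((1, True) if name == parc.name_of(rid) else (0, False))
        assert lc.networks_per_lesion(parc, lesion) == 1

    def test_straddling_lesion_multi_counted(self, subject3):
        parc = subject3.parcellations["lh"]
        picks = [np.flatnonzero(parc.region_id_per_vertex == rid)[0] for rid in (1, 2, 3)]
        lesion = lc.SurfaceLabel("lh.lesion-01", "lh", np.array(picks))
        counts = lc.lesions_per_network(parc, [lesion])
        assert sum(n for n, _f in counts.values()) == 3  # one lesion, counted thrice
        assert lc.networks_per_lesion(parc, lesion) == 3

    def test_all_networks_covered(self, subject3):
        parc = subject3.parcellations["lh"]
        lesion = lc.SurfaceLabel("lh.lesion-01", "lh", np.arange(parc.n_vertices))
        assert lc.networks_per_lesion(parc, lesion) == 7

    @pytest.mark.parametrize("seed", [8, 9])
    def test_counts_match_membership_oracle(self, seed):
        subject = lc.make_subject(
            seed,
            subdivisions=3,
            lesion_specs=[("Limbic", 0.1), ("Visual", 0.08), ("DefaultMode", 0.05)],
        )
        parc = subject.parcellations["lh"]
        counts = lc.lesions_per_network(parc, subject.lesions["lh"])
        for rid in parc.region_ids():
            want = sum(
                any(parc.region_id_per_vertex[int(v)] == rid for v in lab.vertex_ids)
                for lab in subject.lesions["lh"]
            )
            assert counts[parc.name_of(rid)][0] == want


class TestGroupFrequencyMap:
    def test_single_subject_is_indicator(self, subject3):
        overlay = lc.combine_labels(subject3.lesions["lh"], "lh")
        n = subject3.meshes["lh"].n_vertices
        freq = lc.group_frequency_map([overlay], n)
        np.testing.assert_array_equal(freq.values, overlay.indicator(n).astype(float))

    def test_two_identical_overlays(self, subject3):
        overlay = lc.combine_labels(subject3.lesions["lh"], "lh")
        n = subject3.meshes["lh"].n_vertices
        freq = lc.group_frequency_map([overlay, overlay], n)
        assert set(np.unique(freq.values)) <= {0.0, 2.0}

    def test_cohort_matches_counting_oracle(self):
        overlays = []
        for seed in range(6):
            s = lc.make_subject(seed, subdivisions=2)
            overlays.append(lc.combine_labels(s.lesions["lh"], "lh"))
        n = 10 * 4**2 + 2
        freq = lc.group_frequency_map(overlays, n)
        np.testing.assert_array_equal(freq.values, count_map(overlays, n))
        assert freq.values.max() <= len(overlays)

    def test_mismatched_mesh_rejected(self):
        overlay = lc.SurfaceLabel("lh.all-lesions", "lh", np.array([500]))
        with pytest.raises(ValueError, match="template"):
            lc.group_frequency_map([overlay], 100)
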