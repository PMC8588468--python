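import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ioneda as io
from ioneda.geometry import TrajectoryFrame, atom, detect_fragments, Fragment
from ioneda.slab import (BULK, EJECTED, INTERFACE, DensityProfile, GDSResult,
                         NoInterfaceError, carve_two_shell_cluster,
                         classify_environment, compute_rdf, locate_gds,
                         mass_density_profile, minimum_image)
from ioneda.synth import SlabSpec, generate_slab

RHO_W = 0.997


def _uniform_water_frames(n_frames=3, n_w=300, box=(20.0, 20.0, 60.0),
                          z_range=(15.0, 45.0), seed=3):
    rng = np.random.default_rng(seed)
    frames = []
    for f in range(n_frames):
        atoms = []
        for _ in range(n_w):
            o = rng.uniform([0, 0, z_range[0]], [box[0], box[1], z_range[1]])
            atoms += [atom("O", o), atom("H", o + [0.96, 0, 0]),
                      atom("H", o + [-0.24, 0.93, 0])]
        frames.append(TrajectoryFrame(atoms, np.array(box), time_ps=float(f),
                                      frame_id=f))
    return frames


class TestDensityProfile:
    def test_flat_profile_at_analytic_density(self):
        frames = _uniform_water_frames(n_frames=6, n_w=400)
        prof = mass_density_profile(frames, "z", 1.5)
        # analytic density of 400 waters in 20x20x30 A^3
        rho = 400 * 18.015 / 6.02214076e23 / (20 * 20 * 30 * 1e-24)
        mid = (prof.bin_centers > 20) & (prof.bin_centers < 40)
        vals = prof.density[mid]
        sd = vals.std()
        assert abs(vals.mean() - rho) < 3 * sd / np.sqrt(mid.sum()) + 0.02 * rho

    def test_vacuum_bins_are_zero(self):
        frames = _uniform_water_frames()
        prof = mass_density_profile(frames, "z", 1.0)
        assert np.all(prof.density[prof.bin_centers < 13.0] == 0)
        assert np.all(prof.density[prof.bin_centers > 47.0] == 0)

    def test_mass_conservation_exact(self):
        frames = _uniform_water_frames(n_frames=2, n_w=150)
        prof = mass_density_profile(frames, "z", 0.8)
        box = frames[0].box
        nbins = len(prof.bin_centers)
        bin_vol = box[0] * box[1] * (box[2] / nbins) * 1e-24  # cm^3
        total_g = (prof.density * bin_vol).sum()
        expect_g = 150 * 18.015 / 6.02214076e23
        assert total_g == pytest.approx(expect_g, rel=1e-12)

    def test_no_frames_is_an_error(self):
        with pytest.raises(ValueError):
            mass_density_profile([], "z", 1.0)


class TestLocateGDS:
    def test_step_profile_recovered_within_half_bin(self):
        z = np.arange(0.5, 60.0, 1.0)
        rho = np.where((z > 15.0) & (z < 45.0), RHO_W, 0.0)
        prof = DensityProfile("z", z, rho, 1, np.array([20, 20, 60.0]))
        gds = locate_gds(prof)
        assert abs(gds.z_upper - 45.0) <= 0.5
        assert abs(gds.z_lower - 15.0) <= 0.5

    @pytest.mark.parametrize("z_gds,d", [(58.0, 1.0), (62.0, 1.5), (55.0, 2.5)])
    def test_tanh_profile_parameter_recovery(self, z_gds, d):
        z = np.arange(0.25, 80.0, 0.5)
        z_lo = 80.0 - z_gds
        rho = RHO_W * 0.25 * ((1 - np.tanh((z - z_gds) / d))
                              * (1 + np.tanh((z - z_lo) / d)))
        prof = DensityProfile("z", z, rho, 1, np.array([20, 20, 80.0]))
        gds = locate_gds(prof)
        assert abs(gds.z_upper - z_gds) < 0.2
        assert abs(gds.z_lower - z_lo) < 0.2
        assert abs(gds.width_upper - d) < 0.2 * d
        assert gds.bulk_density == pytest.approx(RHO_W, rel=0.02)

    def test_uniform_liquid_has_no_interface(self):
        z = np.arange(0.5, 60.0, 1.0)
        prof = DensityProfile("z", z, np.full_like(z, RHO_W), 1,
                              np.array([20, 20, 60.0]))
        with pytest.raises(NoInterfaceError):
            locate_gds(prof)


class TestClassify:
    GDS = GDSResult(z_lower=15.0, z_upper=45.0, bulk_density=RHO_W,
                    width_lower=1.5, width_upper=1.5, residual=0.0)

    @pytest.mark.parametrize("z,expect", [
        (43.0, INTERFACE),   # 2 A below upper GDS
        (42.0, INTERFACE),   # exactly 3 A below: boundary inclusive
        (35.0, BULK),        # 10 A deep
        (16.5, INTERFACE),   # near the lower face
        (47.0, EJECTED),     # above the liquid
    ])
    def test_examples(self, z, expect):
        assert classify_environment(z, self.GDS, 3.0) == expect

    @given(st.floats(0.0, 15.0))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_depth(self, depth):
        env = classify_environment(45.0 - depth, self.GDS, 3.0)
        assert env == (INTERFACE if depth <= 3.0 else BULK)


class TestCarve:
    def _frame(self):
        atoms = [atom("Cl", [10.0, 10.0, 10.0])]
        for o in ([12.0, 10, 10], [10, 15.9, 10], [10, 16.1, 10],
                  [1.0, 10, 10]):
            o = np.asarray(o, float)
            atoms += [atom("O", o), atom("H", o + [0.72, 0.64, 0]),
                      atom("H", o + [-0.72, 0.64, 0])]
        return TrajectoryFrame(atoms, np.array([20.0, 20.0, 20.0]))

    def test_cutoff_is_sharp_on_oxygen_distance(self):
        frame = self._frame()
        ion = Fragment("ion", (0,), -1)
        snap = carve_two_shell_cluster(frame, ion, r_cut=6.0)
        # waters at 2.0 and 5.9 in range; 6.1 out; the one at x=1 wraps to
        # distance 9 -> out
        assert snap.n_waters == 2

    def test_matches_brute_force_distance_scan(self):
        spec = SlabSpec(box=(18.0, 18.0, 50.0), slab_thickness=14.0,
                        depth=7.0, n_frames=1, seed=11)
        frame = generate_slab(spec)[0]
        ion, _ = detect_fragments(frame.atoms, "Cl-")
        r_cut = 5.0
        snap = carve_two_shell_cluster(frame, ion, r_cut)
        box = frame.box
        ion_pos = frame.atoms[ion.indices[0]].position
        expected = 0
        for i, a in enumerate(frame.atoms):
            if a.symbol != "O" or i in ion.indices:
                continue
            d = np.linalg.norm(minimum_image(a.position - ion_pos, box))
            expected += d <= r_cut
        assert snap.n_waters == expected

    def test_minimum_image_water_is_unwrapped(self):
        # ion at the box edge; a water across the periodic boundary is
        # 1.5 A away through the wall but 18.5 A away in direct space
        atoms = [atom("Cl", [1.0, 10.0, 10.0])]
        for o in ([19.5, 10.0, 10.0], [4.0, 10.0, 10.0]):
            o = np.asarray(o, float)
            atoms += [atom("O", o), atom("H", o + [0.72, 0.64, 0]),
                      atom("H", o + [-0.72, 0.64, 0])]
        fr = TrajectoryFrame(atoms, np.array([20.0, 20.0, 20.0]))
        snap = carve_two_shell_cluster(fr, Fragment("ion", (0,), -1),
                                       r_cut=6.0)
        assert snap.n_waters == 2
        xs = [snap.atoms[w.indices[0]].position[0] for w in snap.waters]
        # the wrapped water is unwrapped to x = -0.5, contiguous with the ion
        assert min(xs) == pytest.approx(-0.5)

    def test_empty_cluster_raises(self):
        atoms = [atom("Cl", [10, 10, 10])]
        o = np.array([1.0, 1.0, 1.0])
        atoms += [atom("O", o), atom("H", o + [0.72, 0.64, 0]),
                  atom("H", o + [-0.72, 0.64, 0])]
        fr = TrajectoryFrame(atoms, np.array([40.0, 40.0, 40.0]))
        with pytest.raises(ValueError, match="no waters"):
            carve_two_shell_cluster(fr, Fragment("ion", (0,), -1), r_cut=3.0)


class TestRDF:
    def test_ideal_gas_is_unity(self):
        rng = np.random.default_rng(5)
        box = np.array([25.0, 25.0, 25.0])
        frames = []
        for f in range(8):
            atoms = [atom("O", rng.uniform(0, 25, 3)) for _ in range(250)]
            frames.append(TrajectoryFrame(atoms, box, frame_id=f))
        rdf = compute_rdf(frames, "O", "O", dr=0.5, r_max=10.0)
        sel = rdf.r > 1.5
        assert np.all(np.abs(rdf.g[sel] - 1.0) < 0.25)
        assert abs(rdf.g[sel].mean() - 1.0) < 0.03

    def test_fixed_pair_single_bin(self):
        box = np.array([20.0, 20.0, 20.0])
        atoms = [atom("Cl", [5, 5, 5]), atom("O", [8.5, 5, 5])]
        fr = TrajectoryFrame(atoms, box)
        rdf = compute_rdf([fr], "Cl", "O", dr=0.2, r_max=9.0)
        nz = np.nonzero(rdf.g)[0]
        assert len(nz) == 1
        assert rdf.r[nz[0]] == pytest.approx(3.5, abs=0.1)

    def test_pair_counts_match_double_loop(self):
        rng = np.random.default_rng(9)
        box = np.array([12.0, 12.0, 12.0])
        atoms = [atom("O", rng.uniform(0, 12, 3)) for _ in range(40)]
        fr = TrajectoryFrame(atoms, box)
        r_max, dr = 5.0, 0.25
        rdf = compute_rdf([fr], "O", "O", dr=dr, r_max=r_max)
        counts = np.zeros(int(np.ceil(r_max / dr)))
        pos = fr.coords()
        for i in range(40):
            for j in range(40):
                if i == j:
                    continue
                d = np.linalg.norm(minimum_image(pos[j] - pos[i], box))
                if d < r_max:
                    counts[int(d / dr)] += 1
        vol = box.prod()
        edges = np.arange(len(counts) + 1) * dr
        shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        g_oracle = counts / (40 * 40 / vol * shell)
        np.testing.assert_allclose(rdf.g, g_oracle, atol=1e-10)

    def test_empty_selection_raises(self):
        fr = TrajectoryFrame([atom("O", [1, 1, 1])], np.array([10.0, 10, 10]))
        with pytest.raises(ValueError):
            compute_rdf([fr], "Cl", "O", dr=0.2, r_max=4.0)


class TestEnsemble:
    def test_deep_ion_all_bulk_and_spacing(self):
        spec = SlabSpec(box=(18.0, 18.0, 60.0), slab_thickness=24.0,
                        depth=10.0, n_frames=8, frame_spacing_ps=10.0, seed=2)
        frames = generate_slab(spec)
        bulk, interface = io.build_ensemble(frames, "Cl-", n_snapshots=5,
                                            spacing_ps=10.0, r_cut=5.0)
        assert len(bulk) == 5
        assert len(interface) == 0
        assert all(s.environment == BULK for s in bulk)

    def test_shallow_ion_all_interface(self):
        spec = SlabSpec(box=(18.0, 18.0, 60.0), slab_thickness=24.0,
                        depth=1.0, n_frames=6, seed=2)
        frames = generate_slab(spec)
        with pytest.warns(UserWarning):
            bulk, interface = io.build_ensemble(frames, "Cl-", n_snapshots=6,
                                                spacing_ps=10.0, r_cut=5.0)
        assert len(bulk) == 0
        assert all(s.environment == INTERFACE for s in interface)

    def test_51_snapshots_at_10ps_spacing_bookkeeping(self):
        # lightweight frames: classification bookkeeping only
        gds = GDSResult(z_lower=10.0, z_upper=50.0, bulk_density=RHO_W,
                        width_lower=1.5, width_upper=1.5, residual=0.0)
        times = []
        o = np.array([5.0, 5.0, 40.0])
        base = [atom("Cl", [5, 5, 40.0]), atom("O", o + [0, 3, 0]),
                atom("H", o + [0.72, 3.64, 0]), atom("H", o + [-0.72, 3.64, 0])]
        frames = [TrajectoryFrame(base, np.array([20.0, 20.0, 60.0]),
                                  time_ps=2.0 * k, frame_id=k)
                  for k in range(1001)]  # 2 ns at 2 ps resolution
        bulk, interface = io.build_ensemble(
            frames, "Cl-", n_snapshots=51, spacing_ps=10.0, gds=gds, r_cut=6.0)
        assert len(bulk) == 51
        times = [frames[s.source_frame].time_ps for s in bulk]
        assert np.allclose(np.diff(times), 10.0)
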