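"""Monte Carlo engine: estimator correctness, physics toggles, determinism."""

import numpy as np
import pytest

from pinholesim import materials
from pinholesim.emission import EmissionLine, EmissionSpectrum, make_energy_window
from pinholesim.geometry import (
    CameraConfig,
    DetectorSpec,
    PinholeSpec,
    analytic_point_sensitivity,
    default_camera,
)
from pinholesim.phantoms import BoxSource, SourceModel, make_point_source
from pinholesim.transport import (
    AcquisitionProtocol,
    detector_absorb,
    phantom_attenuation,
    run_simulation,
    sample_direction,
)

MONO = EmissionSpectrum((EmissionLine(113.0, 1.0),))
WIDE = (make_energy_window([113.0], 0.9),)


def _ideal_protocol(n, seed, target="aperture", sampling="cone"):
    return AcquisitionProtocol(
        n_primaries=n,
        seed=seed,
        penetration=False,
        attenuation=False,
        ideal_detector=True,
        spectrum=MONO,
        windows=WIDE,
        direction_sampling=sampling,
        cone_target=target,
    )


def _oracle_camera(**kw):
    """Thin (knife-edge) aperture and gap-free detector: the regime in which
    the closed-form cos^3 sensitivity applies without vignetting terms."""
    kw.setdefault("pinhole", PinholeSpec(edge_profile="knife_edge"))
    kw.setdefault("detector", DetectorSpec(crystal_size_mm=1.2, septa_mm=0.0))
    return CameraConfig(**kw)


class TestProtocolValidation:
    def test_exactly_one_decay_driver(self):
        with pytest.raises(ValueError):
            AcquisitionProtocol()
        with pytest.raises(ValueError):
            AcquisitionProtocol(duration_s=1.0, n_primaries=100)

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionProtocol(duration_s=1.0, cone_margin_deg=-1.0)


class TestRunBasics:
    def test_zero_activity_gives_zero_image(self):
        src = make_point_source(0.0, 0.0, 100.0)
        img = run_simulation(src, default_camera(), AcquisitionProtocol(duration_s=1.0, seed=0))
        assert img.total_counts() == 0

    def test_same_seed_identical_images(self):
        src = make_point_source(0.0, 1000.0, 100.0)
        prot = AcquisitionProtocol(duration_s=0.002, seed=9)
        a = run_simulation(src, default_camera(), prot)
        b = run_simulation(src, default_camera(), prot)
        for w in a.windows:
            assert np.array_equal(a.counts[w], b.counts[w])
            assert np.array_equal(a.weights[w], b.weights[w])

    def test_meta_records_reproducibility_inputs(self):
        src = make_point_source(0.0, 1000.0, 100.0)
        img = run_simulation(src, default_camera(), AcquisitionProtocol(duration_s=0.001, seed=4))
        for key in ("seed", "batch_size", "camera_hash", "n_emitted", "n_accepted"):
            assert key in img.meta


class TestDirectionSampling:
    def test_full_4pi_weight_is_one_and_isotropic(self):
        rng = np.random.default_rng(0)
        origins = np.tile([0.0, 0.0, 100.0], (50_000, 1))
        d, w = sample_direction("full_4pi", default_camera(), origins, rng)
        assert np.all(w == 1.0)
        assert abs(d[:, 2].mean()) < 4 / np.sqrt(len(d))  # <cos> = 0 on the sphere

    def test_cone_weight_is_solid_angle_fraction(self):
        """weight = (1 - cos(alpha)) / 2; a 60-degree half angle gives 1/4."""
        rng = np.random.default_rng(0)
        cam = default_camera()
        origins = np.array([[0.0, 0.0, 100.0]])
        d, w = sample_direction("cone", cam, origins, rng, cone_margin_deg=2.0)
        s = cam.detector.active_side_mm / 2.0
        corner = np.array([s, s, -cam.pinhole_to_detector_mm]) - origins[0]
        axis = np.array([0.0, 0.0, -1.0])
        alpha = np.arccos(corner @ axis / np.linalg.norm(corner)) + np.radians(2.0)
        assert w[0] == pytest.approx((1 - np.cos(alpha)) / 2)
        assert (1 - np.cos(np.pi / 3)) / 2 == pytest.approx(0.25)

    def test_cone_directions_inside_cone(self):
        rng = np.random.default_rng(1)
        origins = np.tile([30.0, -20.0, 150.0], (5000, 1))
        d, w = sample_direction("cone", default_camera(), origins, rng)
        axis = -origins[0] / np.linalg.norm(origins[0])
        alpha = np.arccos(1 - 2 * w[0])
        assert np.all(d @ axis >= np.cos(alpha) - 1e-12)

    def test_cone_needs_origin_in_front(self):
        with pytest.raises(ValueError):
            sample_direction(
                "cone", default_camera(), np.array([[0.0, 0.0, 0.0]]), np.random.default_rng(0)
            )


class TestEstimator:
    def test_mc_acceptance_matches_analytic_oracle(self):
        """Ideal opaque thin aperture: accepted fraction equals
        d^2 cos^3(theta) / (16 h^2) within 3 sigma on >= 1e5 accepted events."""
        cam = _oracle_camera()
        src = make_point_source(0.0, 1000.0, 100.0, water_sphere_diameter_mm=0.0)
        img = run_simulation(src, cam, _ideal_protocol(25_000_000, seed=21))
        assert img.meta["n_accepted"] >= 100_000
        est = img.total_estimate() / img.meta["n_emitted"]
        err = img.total_error() / img.meta["n_emitted"]
        g = analytic_point_sensitivity(cam, [0.0, 0.0, 100.0])
        assert abs(est - g) < 3 * err

    def test_cone_and_full_4pi_agree(self):
        """The cone estimator is unbiased: same sensitivity as full 4 pi."""
        cam = _oracle_camera(
            pinhole=PinholeSpec(diameter_mm=6.0, edge_profile="knife_edge"),
            object_to_pinhole_mm=50.0,
        )
        src = make_point_source(0.0, 1000.0, 50.0, water_sphere_diameter_mm=0.0)
        cone = run_simulation(src, cam, _ideal_protocol(1_000_000, 31, target="detector"))
        full = run_simulation(src, cam, _ideal_protocol(3_000_000, 32, sampling="full_4pi"))
        est_c = cone.total_estimate() / cone.meta["n_emitted"]
        err_c = cone.total_error() / cone.meta["n_emitted"]
        est_f = full.total_estimate() / full.meta["n_emitted"]
        err_f = full.total_error() / full.meta["n_emitted"]
        assert abs(est_c - est_f) < 3 * np.hypot(err_c, err_f)

    def test_poisson_linearity(self):
        """Doubling duration doubles expected counts (4 sigma)."""
        cam = _oracle_camera()
        src = make_point_source(0.0, 500.0, 100.0, water_sphere_diameter_mm=0.0)
        base = dict(
            penetration=False, attenuation=False, ideal_detector=True,
            spectrum=MONO, windows=WIDE, direction_sampling="cone",
            cone_target="aperture",
        )
        n1 = run_simulation(src, cam, AcquisitionProtocol(duration_s=0.01, seed=41, **base))
        n2 = run_simulation(src, cam, AcquisitionProtocol(duration_s=0.02, seed=42, **base))
        c1, c2 = n1.total_counts(), n2.total_counts()
        sigma = np.sqrt(4 * c1 + c2)
        assert abs(c2 - 2 * c1) < 4 * sigma

    def test_inverse_square_depth_ratio(self):
        """On-axis counts at 125 vs 100 mm fall by 0.64 (3 sigma)."""
        cam = _oracle_camera()
        imgs = {}
        for z, seed in ((100.0, 51), (125.0, 52)):
            src = make_point_source(0.0, 1000.0, z, water_sphere_diameter_mm=0.0)
            imgs[z] = run_simulation(src, cam, _ideal_protocol(4_000_000, seed))
        r100 = imgs[100.0].total_estimate() / imgs[100.0].meta["n_emitted"]
        r125 = imgs[125.0].total_estimate() / imgs[125.0].meta["n_emitted"]
        ratio = r125 / r100
        rel = np.hypot(
            imgs[100.0].total_error() / imgs[100.0].total_estimate(),
            imgs[125.0].total_error() / imgs[125.0].total_estimate(),
        )
        assert abs(ratio - 0.64) < 3 * 0.64 * rel

    def test_window_partition_sums_to_union(self):
        """Disjoint windows partitioning the union reproduce its counts."""
        lo = make_energy_window([113.0], 0.10)
        hi = make_energy_window([208.37], 0.25)
        union = make_energy_window([113.0, 208.37], 0.35)
        assert lo.high < hi.low  # genuinely disjoint sub-windows
        src = make_point_source(0.0, 1000.0, 100.0)
        prot = AcquisitionProtocol(
            duration_s=0.01, seed=61, windows=(lo, hi, union),
            direction_sampling="cone", cone_target="aperture",
        )
        img = run_simulation(src, default_camera(), prot)
        inside = (
            img.counts[lo]
            + img.counts[hi]
        )
        # union also contains energies between the sub-windows; it must hold
        # at least the partition's counts and equal them where the recorded
        # energy can only come from the two peaks
        assert np.all(img.counts[union] >= inside)
        assert img.total_counts(union) >= img.total_counts(lo) + img.total_counts(hi)

    def test_mirror_symmetry_of_centered_source(self):
        """A centred symmetric source images to a centred distribution."""
        cam = default_camera()
        src = SourceModel((BoxSource((0.0, 0.0, 102.0), (60.0, 60.0, 4.0), 100.0),))
        prot = AcquisitionProtocol(
            duration_s=0.02, seed=71, windows=WIDE, spectrum=MONO,
            direction_sampling="cone", cone_target="aperture",
        )
        img = run_simulation(src, cam, prot)
        c = img.counts[WIDE[0]].astype(float)
        total = c.sum()
        centers = cam.detector.pixel_centers()
        cu = (c.sum(axis=0) * centers).sum() / total
        cv = (c.sum(axis=1) * centers).sum() / total
        spread = 10.0 / np.sqrt(total)  # ~rms/sqrt(N) with rms ~ 10 mm
        assert abs(cu) < 5 * spread and abs(cv) < 5 * spread


class TestAttenuation:
    def test_no_regions_is_transparent(self):
        src = SourceModel((BoxSource((0, 0, 110.0), (10, 10, 10), 1.0),))
        t = phantom_attenuation(
            np.array([[0.0, 0.0, 100.0]]), np.array([[0.0, 0.0, -1.0]]), src, np.array([208.0])
        )
        assert t[0] == 1.0

    def test_slab_oracle_100mm_water(self):
        """10 cm water at 208 keV: exp(-mu * 100 mm) closed form."""
        from pinholesim.phantoms import BoxRegion

        src = SourceModel(
            (BoxSource((0, 0, 150.0), (200, 200, 100), 1.0),),
            (BoxRegion((0, 0, 150.0), (200.0, 200.0, 100.0)),),
        )
        origin = np.array([[0.0, 0.0, 200.0]])  # back face, straight through
        direction = np.array([[0.0, 0.0, -1.0]])
        t = phantom_attenuation(origin, direction, src, np.array([208.0]))
        mu = materials.linear_attenuation_mm("water", 208.0)
        assert t[0] == pytest.approx(np.exp(-mu * 100.0), rel=1e-9)

    def test_overlapping_same_material_regions_count_once(self):
        from pinholesim.phantoms import BoxRegion, SphereRegion

        box = BoxRegion((0, 0, 150.0), (100.0, 100.0, 100.0))
        sphere = SphereRegion((0, 0, 150.0), 20.0)  # entirely inside the box
        src = SourceModel(
            (BoxSource((0, 0, 150.0), (10, 10, 10), 1.0),), (box, sphere)
        )
        origin = np.array([[0.0, 0.0, 200.0]])
        direction = np.array([[0.0, 0.0, -1.0]])
        t = phantom_attenuation(origin, direction, src, np.array([113.0]))
        mu = materials.linear_attenuation_mm("water", 113.0)
        assert t[0] == pytest.approx(np.exp(-mu * 100.0), rel=1e-9)

    def test_attenuation_toggle_off(self):
        src = make_point_source(0.0, 1000.0, 100.0, water_sphere_diameter_mm=50.0)
        on = run_simulation(
            src, default_camera(),
            AcquisitionProtocol(duration_s=0.004, seed=81, windows=WIDE, spectrum=MONO,
                                direction_sampling="cone", cone_target="aperture"),
        )
        off = run_simulation(
            src, default_camera(),
            AcquisitionProtocol(duration_s=0.004, seed=81, windows=WIDE, spectrum=MONO,
                                attenuation=False,
                                direction_sampling="cone", cone_target="aperture"),
        )
        assert off.total_counts() > on.total_counts()

    def test_voxel_mu_map_matches_analytic_slab(self):
        from pinholesim.phantoms import VoxelVolume

        mu = materials.linear_attenuation_mm("water", 113.0)
        vol = VoxelVolume(np.full((20, 10, 10), mu), 2.0, (-10.0, -10.0, 100.0), kind="mu")
        src = SourceModel((BoxSource((0, 0, 120.0), (5, 5, 5), 1.0),), (), attenuation_map=vol)
        origin = np.array([[0.0, 0.0, 140.0]])
        direction = np.array([[0.0, 0.0, -1.0]])
        t = phantom_attenuation(origin, direction, src, np.array([113.0]))
        assert t[0] == pytest.approx(np.exp(-mu * 40.0), rel=0.02)


class TestDetector:
    def test_ideal_detector_records_every_crystal_hit_at_true_energy(self):
        cam = default_camera()
        rng = np.random.default_rng(0)
        prot = AcquisitionProtocol(duration_s=1.0, ideal_detector=True)
        u = np.array([0.0, 0.3, 24.0])
        v = np.zeros(3)
        d = np.tile([0.0, 0.0, -1.0], (3, 1))
        e = np.full(3, 113.0)
        i, j, e_rec, absorbed = detector_absorb(u, v, d, e, cam, rng, prot)
        assert absorbed.all()
        assert np.all(e_rec == 113.0)

    def test_absorption_probability_matches_slab_formula(self):
        """5 mm scintillator at normal incidence: 1 - exp(-mu t), 4 sigma."""
        cam = default_camera()
        rng = np.random.default_rng(3)
        prot = AcquisitionProtocol(duration_s=1.0)
        n = 200_000
        u = np.zeros(n)
        v = np.zeros(n)
        d = np.tile([0.0, 0.0, -1.0], (n, 1))
        e = np.full(n, 208.37)
        _, _, _, absorbed = detector_absorb(u, v, d, e, cam, rng, prot)
        mu = materials.linear_attenuation_mm(cam.detector.material, 208.37)
        p = 1 - np.exp(-mu * cam.detector.crystal_thickness_mm)
        assert abs(absorbed.mean() - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_hits_outside_active_area_are_dropped(self):
        cam = default_camera()
        rng = np.random.default_rng(0)
        prot = AcquisitionProtocol(duration_s=1.0, ideal_detector=True)
        _, _, _, absorbed = detector_absorb(
            np.array([30.0]), np.array([0.0]), np.array([[0.0, 0.0, -1.0]]),
            np.array([113.0]), cam, rng, prot,
        )
        assert not absorbed.any()

    def test_septa_discard_fraction_matches_fill_factor(self):
        cam = default_camera()
        rng = np.random.default_rng(5)
        prot = AcquisitionProtocol(duration_s=1.0, ideal_detector=True)
        n = 200_000
        u = rng.uniform(-24.0, 24.0, n)
        v = rng.uniform(-24.0, 24.0, n)
        d = np.tile([0.0, 0.0, -1.0], (n, 1))
        _, _, _, absorbed = detector_absorb(u, v, d, np.full(n, 113.0), cam, rng, prot)
        fill = (cam.detector.crystal_size_mm / cam.detector.pitch_mm) ** 2
        assert abs(absorbed.mean() - fill) < 4 * np.sqrt(fill * (1 - fill) / n)
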