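"""Docking template, strand-side docking, distance maps, accessibility."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from origamech import access, synth
from origamech.access import (
    build_docking_template,
    classify_accessible,
    correlate_with_experiment,
    distance_maps,
    dock_to_site,
    local_occupancy,
    probe_template,
    site_accessibility,
)
from origamech.errors import ArgumentError, UndefinedCorrelationError
from origamech.geometry import LocalFrame, build_ideal_helix, estimate_site_frame
from origamech.io import ParticleCloud
from origamech.sites import scan_recognition_sites
from origamech.synth import make_probe_cloud, make_raft_scene

from conftest import random_rigid_motion


def _crystal_cloud_from_helix(helix, rotation=None, translation=None):
    """ParticleCloud mimicking a crystal duplex: one C1' anchor per nucleotide."""
    r = np.eye(3) if rotation is None else rotation
    t = np.zeros(3) if translation is None else translation
    anch = helix.anchors() @ r.T + t
    n = helix.n_bp
    labels = [("B", i + 1, "C1'") for i in range(n)]
    labels += [("C", j + 1, "C1'") for j in range(n)]
    order = list(range(n)) + [n + (n - 1 - j) for j in range(n)]
    return ParticleCloud(anch[order], labels, "dna")


# -- docking template -------------------------------------------------------


def test_template_identity_when_crystal_equals_helix():
    helix = build_ideal_helix(10, "AAAGCGCAAA")
    probe = make_probe_cloud(1.0, 50, offset=2.0, seed=0)
    crystal = _crystal_cloud_from_helix(helix)
    tmpl = build_docking_template(
        ParticleCloud(probe.positions, probe.labels, "protein"), crystal, helix
    )
    assert tmpl.superposition_rmsd < 1e-9
    np.testing.assert_allclose(tmpl.protein_local, probe.positions, atol=1e-9)


def test_template_invariant_under_crystal_frame_choice():
    """Pre-rotating the whole crystal leaves the template unchanged."""
    helix = build_ideal_helix(10, "AAAGCGCAAA")
    probe = make_probe_cloud(1.0, 50, offset=2.0, seed=1)
    r = Rotation.from_euler("xyz", [30, -70, 110], degrees=True).as_matrix()
    t = np.array([5.0, 1.0, -3.0])
    crystal = _crystal_cloud_from_helix(helix, r, t)
    moved_probe = ParticleCloud(probe.positions @ r.T + t, probe.labels, "protein")
    tmpl = build_docking_template(moved_probe, crystal, helix)
    assert tmpl.superposition_rmsd < 1e-9
    np.testing.assert_allclose(tmpl.protein_local, probe.positions, atol=1e-9)


def test_template_radial_extent_brute_force():
    """Probe ball radius 1.5 at offset 2 -> max axis distance 3.5 nm."""
    helix = build_ideal_helix(10, "AAAGCGCAAA")
    probe = make_probe_cloud(1.5, 20_000, offset=2.0, seed=2)
    crystal = _crystal_cloud_from_helix(helix)
    tmpl = build_docking_template(probe, crystal, helix)
    radial = np.linalg.norm(tmpl.protein_local[:, :2], axis=1)  # axis = z
    brute = np.linalg.norm(probe.positions[:, :2], axis=1).max()
    assert radial.max() == pytest.approx(brute, abs=1e-9)
    assert radial.max() <= 3.5 + 1e-9
    assert radial.max() >= 3.5 - 0.05  # order statistics of 20k samples


def test_template_from_synthetic_pdb_roundtrip(tmp_path):
    """Full path: synthetic complex PDB -> reader -> template."""
    from origamech.io import read_pdb_particles
    from origamech.synth import write_synthetic_complex_pdb

    helix = build_ideal_helix(10, "AAAGCGCAAA")
    probe = make_probe_cloud(1.0, 40, offset=2.5, seed=3)
    r = Rotation.from_euler("z", 42, degrees=True).as_matrix()
    path = tmp_path / "complex.pdb"
    write_synthetic_complex_pdb(path, helix, probe.positions, rotation=r,
                                translation=np.array([1.0, 2.0, 3.0]))
    protein, dna = read_pdb_particles(path)
    tmpl = build_docking_template(protein, dna, helix)
    assert tmpl.superposition_rmsd < 1e-3  # PDB stores 3 decimals in angstrom
    np.testing.assert_allclose(
        np.sort(np.linalg.norm(tmpl.protein_local, axis=1)),
        np.sort(np.linalg.norm(probe.positions, axis=1)),
        atol=1e-3,
    )


# -- docking to a site ------------------------------------------------------


def _duplex_site(scene):
    found = scan_recognition_sites(scene.design, scene.topology, "GCGC")
    assert len(found) == 1
    return found[0]


def test_dock_identity_on_verbatim_helix():
    """Config containing the ideal helix verbatim: protein lands unchanged."""
    scene = synth.make_duplex_scene("AAAGCGCAAA", n_frames=1, seed=0)
    site = _duplex_site(scene)
    helix = build_ideal_helix(10, "AAAGCGCAAA")
    tmpl = probe_template(2.0, 100, seed=0, helix=helix)
    placed, tf, rmsd = dock_to_site(tmpl, scene.trajectory[0], site, "scaffold")
    assert rmsd < 1e-9
    np.testing.assert_allclose(placed, tmpl.protein_local, atol=1e-9)


def test_dock_equivariance_under_rigid_motion():
    scene = synth.make_duplex_scene("AAAGCGCAAA", n_frames=1, seed=0)
    site = _duplex_site(scene)
    tmpl = probe_template(2.0, 100, seed=0)
    cfg = scene.trajectory[0]
    placed, _, _ = dock_to_site(tmpl, cfg, site, "scaffold")
    r, t = random_rigid_motion(np.random.default_rng(0))
    placed2, _, _ = dock_to_site(tmpl, cfg.transformed(r, t), site, "scaffold")
    np.testing.assert_allclose(placed2, placed @ r.T + t, atol=1e-9)


def test_staple_side_is_pseudo_dyad_flip():
    """On the ideal palindromic duplex the staple-side placement equals the
    explicit 180-degree dyad rotation of the scaffold-side placement."""
    seq = "ATAGCGCTAT"  # palindromic 10-mer around GCGC
    scene = synth.make_duplex_scene(seq, n_frames=1, seed=0)
    site = _duplex_site(scene)
    helix = build_ideal_helix(10, seq)
    tmpl = probe_template(2.0, 200, seed=1, helix=helix)
    cfg = scene.trajectory[0]
    scaf, _, r1 = dock_to_site(tmpl, cfg, site, "scaffold")
    stap, _, r2 = dock_to_site(tmpl, cfg, site, "staple")
    assert r1 < 1e-9 and r2 < 1e-9
    # oracle: explicit dyad matrix of the construction. bp i ranges 0..9 with
    # azimuth phi_i = i*twist; the dyad axis lies in-plane at
    # (phi_0+phi_9)/2 + 90 deg through the window midpoint.
    twist = np.deg2rad(helix.twist_deg)
    psi = (0 + 9 * twist) / 2 + np.pi / 2
    d = np.array([np.cos(psi), np.sin(psi), 0.0])
    flip = Rotation.from_rotvec(np.pi * d).as_matrix()
    mid = helix.bp_centers().mean(0)
    expected = (scaf - mid) @ flip.T + mid
    np.testing.assert_allclose(np.sort(stap, axis=0), np.sort(expected, axis=0),
                               atol=1e-9)
    np.testing.assert_allclose(stap, expected, atol=1e-9)


def test_unpaired_window_signals_skip():
    from origamech.errors import SiteSkip

    scene = synth.make_duplex_scene("AAAGCGCAAA", n_frames=1, seed=0)
    site = _duplex_site(scene)
    site.window_staple_indices = site.window_staple_indices.copy()
    site.window_staple_indices[4] = -1
    tmpl = probe_template(2.0, 50, seed=0)
    with pytest.raises(SiteSkip):
        dock_to_site(tmpl, scene.trajectory[0], site, "scaffold")


# -- distance maps ----------------------------------------------------------


def _straight_frame():
    return LocalFrame(
        origin=np.array([0.0, 0.0, 1.53]),
        axis=np.array([0.0, 0.0, 1.0]),
        reference=np.array([1.0, 0.0, 0.0]),
        third=np.array([0.0, 1.0, 0.0]),
    )


def _bp_centers():
    return np.stack([np.zeros(10), np.zeros(10), 0.34 * np.arange(10)], axis=1)


def test_empty_environment_gives_infinite_min_map():
    maps = distance_maps(
        np.array([[1.0, 0.0, 1.5]]), _straight_frame(), _bp_centers(),
        np.empty((0, 3)),
    )
    assert np.all(np.isinf(maps.min_map))
    assert classify_accessible(maps)


def test_single_environment_particle_lands_in_its_cell():
    """Particle at azimuth 32 deg beside bp 5 (row index 4): one finite cell."""
    centers = _bp_centers()
    z5 = centers[4, 2]
    r = 1.2
    theta = np.deg2rad(32)  # interior of a 5-degree bin, not an edge
    env = np.array([[r * np.cos(theta), r * np.sin(theta), z5]])
    maps = distance_maps(
        np.array([[0.05, 0.0, z5]]), _straight_frame(), centers, env, n_theta=72
    )
    finite = np.argwhere(np.isfinite(maps.min_map))
    assert finite.shape == (1, 2)
    row, tbin = finite[0]
    assert row == 4
    assert tbin == int((np.deg2rad(32) + np.pi) // (2 * np.pi / 72))
    assert maps.min_map[row, tbin] == pytest.approx(1.2, abs=1e-9)


def test_maps_match_double_loop_oracle():
    """Random scene: maps equal a brute-force per-cell recomputation."""
    rng = np.random.default_rng(0)
    frame = _straight_frame()
    centers = _bp_centers()
    prot = rng.normal(0, 2, (100, 3)) + [0, 0, 1.5]
    env = rng.normal(0, 3, (100, 3)) + [0, 0, 1.5]
    n_theta = 24
    maps = distance_maps(prot, frame, centers, env, n_theta=n_theta)

    def cell_of(p):
        local = frame.to_local(p[None])[0]
        zc = frame.to_local(centers)[:, 2]
        row = int(np.abs(local[2] - zc).argmin())
        tbin = int(
            np.clip((np.arctan2(local[1], local[0]) + np.pi) // (2 * np.pi / n_theta),
                    0, n_theta - 1)
        )
        return row, tbin

    mx = np.full((10, n_theta), -np.inf)
    mn = np.full((10, n_theta), np.inf)
    for p in prot:  # direct double loop, no shared code path
        row, tbin = cell_of(p)
        mx[row, tbin] = max(mx[row, tbin], np.linalg.norm(p - centers[row]))
    for p in env:
        row, tbin = cell_of(p)
        mn[row, tbin] = min(mn[row, tbin], np.linalg.norm(p - centers[row]))
    np.testing.assert_allclose(maps.max_map, mx, atol=1e-12)
    np.testing.assert_allclose(maps.min_map, mn, atol=1e-12)


def test_classification_simple_cases_and_oracle():
    from origamech.access import DistanceMaps

    base = np.full((10, 12), -np.inf)
    inf = np.full((10, 12), np.inf)
    assert classify_accessible(DistanceMaps(base.copy(), inf.copy()))
    blocked = base.copy()
    blocked[3, 4] = 2.0
    mins = inf.copy()
    mins[3, 4] = 1.5
    assert not classify_accessible(DistanceMaps(blocked, mins))
    rng = np.random.default_rng(1)
    for _ in range(200):
        mx = np.where(rng.random((10, 12)) < 0.5, rng.uniform(0, 4, (10, 12)), -np.inf)
        mn = np.where(rng.random((10, 12)) < 0.5, rng.uniform(0, 4, (10, 12)), np.inf)
        expect = all(
            mx[i, j] < mn[i, j] for i in range(10) for j in range(12)
        )
        assert classify_accessible(DistanceMaps(mx, mn)) is expect


# -- site accessibility over trajectories -----------------------------------


def test_isolated_duplex_fully_accessible(duplex_scene, probe3):
    site = _duplex_site(duplex_scene)
    res = site_accessibility(duplex_scene.trajectory, site, probe3)
    assert res.fractions == {"scaffold": 1.0, "staple": 1.0, "both": 1.0}
    assert res.n_skipped == 0


def test_raft_blocked_and_clear_fractions(probe3):
    blocked = make_raft_scene(gap_schedule=[0.5] * 4, probe_extent=3.0, seed=0)
    site = scan_recognition_sites(blocked.design, blocked.topology, "GCGC")[0]
    res = site_accessibility(blocked.trajectory, site, probe3)
    assert res.fractions["scaffold"] == 0.0
    assert res.fractions["staple"] == 0.0
    clear = make_raft_scene(gap_schedule=[10.0] * 4, probe_extent=3.0, seed=0)
    site = scan_recognition_sites(clear.design, clear.topology, "GCGC")[0]
    res = site_accessibility(clear.trajectory, site, probe3)
    assert res.fractions["scaffold"] == 1.0


def test_alternating_raft_matches_ground_truth_per_frame(
    raft_alternating, raft_site, probe3
):
    res = site_accessibility(raft_alternating.trajectory, raft_site, probe3)
    truth = raft_alternating.ground_truth["clear"]
    for side in ("scaffold", "staple"):
        assert np.array_equal(res.per_frame[side], truth)
    assert res.fractions["scaffold"] == 0.5
    assert res.fractions["both"] == 0.5


def test_accessibility_invariant_under_rigid_motion(raft_alternating, raft_site, probe3):
    from origamech.io import Trajectory

    rng = np.random.default_rng(8)
    r, t = random_rigid_motion(rng)
    moved = Trajectory(
        topology=raft_alternating.topology,
        frames=[f.transformed(r, t) for f in raft_alternating.trajectory],
    )
    res0 = site_accessibility(raft_alternating.trajectory, raft_site, probe3)
    res1 = site_accessibility(moved, raft_site, probe3)
    assert res0.fractions == res1.fractions
    for side in res0.per_frame:
        assert np.array_equal(res0.per_frame[side], res1.per_frame[side])


def test_accessibility_monotone_in_gap(probe3):
    fracs = []
    for gap in np.linspace(0.5, 10.0, 10):
        scene = make_raft_scene(gap_schedule=[gap] * 2, probe_extent=3.0, seed=0)
        site = scan_recognition_sites(scene.design, scene.topology, "GCGC")[0]
        res = site_accessibility(scene.trajectory, site, probe3)
        fracs.append(res.fractions["scaffold"])
    assert all(b >= a for a, b in zip(fracs, fracs[1:]))


def test_probe_shrunk_to_axis_never_less_accessible(raft_alternating, raft_site):
    """Radially scaling the probe toward the axis cannot reduce accessibility."""
    from origamech.access import DockingTemplate

    big = probe_template(3.0, 2000, seed=0)
    prev = None
    for scale in (1.0, 0.5, 0.1):
        local = big.protein_local.copy()
        mid = big.helix.bp_centers().mean(0)
        local = (local - mid) * scale + mid
        tmpl = DockingTemplate(local, big.helix, 0.0)
        res = site_accessibility(raft_alternating.trajectory, raft_site, tmpl)
        frac = res.fractions["scaffold"]
        if prev is not None:
            assert frac >= prev
        prev = frac
    assert prev == 1.0  # near-zero-extent probe with distant environment


def test_both_fraction_bounded_by_each_side(raft_alternating, raft_site, probe3):
    res = site_accessibility(raft_alternating.trajectory, raft_site, probe3)
    assert res.fractions["both"] <= min(
        res.fractions["scaffold"], res.fractions["staple"]
    )


# -- local occupancy --------------------------------------------------------


def test_neighbor_along_reference_projects_to_x_axis():
    """Raft neighbours sit along +-x of the site frame; spans match the gaps."""
    scene = make_raft_scene(gap_schedule=[2.0, 6.0], probe_extent=3.0, seed=0)
    site = scan_recognition_sites(scene.design, scene.topology, "GCGC")[0]
    tmpl = probe_template(3.0, 200, seed=0)
    nb = scene.ground_truth["neighbor_indices"]
    occ = local_occupancy(scene.trajectory, site, nb, tmpl)
    # two frames, axis separations 4 and 8 nm; neighbour COM distance from
    # the site axis equals the separation exactly (rigid construction)
    for name, xy in occ.neighbor_xy.items():
        d = np.linalg.norm(xy, axis=1)
        np.testing.assert_allclose(np.sort(d), [4.0, 8.0], atol=1e-6)
    assert set(occ.footprint_xy) == {"scaffold", "staple"}


def test_local_occupancy_rigid_motion_invariant():
    from origamech.io import Trajectory

    scene = make_raft_scene(gap_schedule=[3.0, 5.0], probe_extent=3.0, seed=0)
    site = scan_recognition_sites(scene.design, scene.topology, "GCGC")[0]
    tmpl = probe_template(3.0, 100, seed=0)
    nb = scene.ground_truth["neighbor_indices"]
    occ0 = local_occupancy(scene.trajectory, site, nb, tmpl)
    r, t = random_rigid_motion(np.random.default_rng(2))
    moved = Trajectory(
        topology=scene.topology,
        frames=[f.transformed(r, t) for f in scene.trajectory],
    )
    occ1 = local_occupancy(moved, site, nb, tmpl)
    for name in occ0.neighbor_xy:
        np.testing.assert_allclose(
            occ1.neighbor_xy[name], occ0.neighbor_xy[name], atol=1e-8
        )


def test_empty_neighbor_set_rejected(duplex_scene, probe3):
    site = _duplex_site(duplex_scene)
    with pytest.raises(ArgumentError):
        local_occupancy(duplex_scene.trajectory, site, {}, probe3)


# -- theory vs experiment ---------------------------------------------------


def test_pearson_perfect_and_inverted():
    theory = {1: 0.1, 2: 0.5, 3: 0.9, 4: 0.3}
    r, used = correlate_with_experiment(theory, dict(theory))
    assert r == pytest.approx(1.0)
    assert used == [1, 2, 3, 4]
    inverted = {k: -v for k, v in theory.items()}
    r, _ = correlate_with_experiment(theory, inverted)
    assert r == pytest.approx(-1.0)


def test_pearson_matches_textbook_formula():
    rng = np.random.default_rng(0)
    theory = {i: float(v) for i, v in enumerate(rng.random(12))}
    experiment = {i: float(v) for i, v in enumerate(rng.random(12))}
    r, _ = correlate_with_experiment(theory, experiment)
    x = np.array([theory[i] for i in range(12)])
    y = np.array([experiment[i] for i in range(12)])
    xc, yc = x - x.mean(), y - y.mean()
    manual = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    assert r == pytest.approx(manual, abs=1e-12)


def test_pearson_excludes_crossover_sites_and_guards():
    theory = {1: 0.1, 2: 0.5, 3: 0.9, 4: 0.2}
    experiment = {1: 0.2, 2: 0.4, 3: 0.8, 4: 0.99}
    r_all, used_all = correlate_with_experiment(theory, experiment)
    r_ex, used_ex = correlate_with_experiment(theory, experiment, exclude={4})
    assert used_ex == [1, 2, 3]
    assert r_ex != r_all
    with pytest.raises(ArgumentError):
        correlate_with_experiment({1: 0.1, 2: 0.2}, {1: 0.1, 2: 0.2})
    with pytest.raises(UndefinedCorrelationError):
        correlate_with_experiment({1: 0.5, 2: 0.5, 3: 0.5}, {1: 0.1, 2: 0.2, 3: 0.3})
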