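"""RMSD, radius of gyration, SASA, distance and hydrogen-bond series."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ensdock import synthetic_fixtures as sf
from ensdock import trajectory_metrics as tm
from ensdock.interaction_geometry import HBondCriteria, MoleculeAnnotation, detect_hbonds
from ensdock.structure_io import Structure

from conftest import make_atom


def test_rmsd_zero_for_identical_sets(rng):
    coords = rng.uniform(-5, 5, (10, 3))
    assert tm.kabsch_rmsd(coords, coords) == pytest.approx(0.0, abs=1e-12)


def test_rmsd_invariant_under_rigid_motion(rng):
    coords = rng.uniform(-5, 5, (10, 3))
    for _ in range(5):
        R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
        moved = coords @ R.T + rng.uniform(-50, 50, 3)
        assert tm.kabsch_rmsd(moved, coords) < 1e-9


def test_rmsd_matches_rotation_grid_oracle(rng):
    """4-point asymmetric set vs a perturbed copy: Kabsch must match a dense
    rotation-grid search (coarse Euler grid + local refinement) to 1e-3 A."""
    P = np.array([[0.0, 0, 0], [3, 0, 0], [0, 2, 0], [1, 1, 2.5]])
    Q = P + rng.normal(scale=0.3, size=P.shape)
    kabsch = tm.kabsch_rmsd(P, Q)

    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def rmsd_of(rot):
        return np.sqrt(np.mean(np.sum((Pc @ rot.as_matrix().T - Qc) ** 2, axis=1)))

    # stage 1: 15-degree Euler grid, then repeated 5x grid refinement
    # around the running best until the step is < 0.01 degrees
    grid = np.deg2rad(np.arange(0, 360, 15))
    half = np.deg2rad(np.arange(-90, 91, 15))
    best, best_angles = np.inf, None
    for a in grid:
        for b in half:
            for c in grid:
                r = rmsd_of(Rotation.from_euler("zyz", [a, b, c]))
                if r < best:
                    best, best_angles = r, (a, b, c)
    step = np.deg2rad(15.0)
    while step > np.deg2rad(0.01):
        step /= 5.0
        offsets = step * np.arange(-5, 6)
        for da in offsets:
            for db in offsets:
                for dc in offsets:
                    angles = (best_angles[0] + da, best_angles[1] + db,
                              best_angles[2] + dc)
                    r = rmsd_of(Rotation.from_euler("zyz", angles))
                    if r < best:
                        best, best_angles = r, angles
    assert kabsch <= best + 1e-12
    assert abs(kabsch - best) < 1e-3


def test_rmsd_requires_matching_counts(rng):
    with pytest.raises(ValueError):
        tm.kabsch_rmsd(rng.uniform(size=(4, 3)), rng.uniform(size=(5, 3)))


def test_rg_single_atom_zero():
    s = Structure([make_atom()], "one")
    assert tm.radius_of_gyration(s) == 0.0


def test_rg_two_point_system_exact():
    s = Structure([make_atom(serial=1, coords=(0, 0, 0)),
                   make_atom(serial=2, coords=(2, 0, 0))], "two")
    assert tm.radius_of_gyration(s) == pytest.approx(0.1)  # nm, atoms at +/- 1 A


def test_rg_matches_direct_formula(rng):
    coords = rng.uniform(-10, 10, (100, 3))
    atoms = [make_atom(serial=i + 1, coords=c) for i, c in enumerate(coords)]
    s = Structure(atoms, "r")
    direct = np.sqrt(np.mean(np.sum((coords - coords.mean(axis=0)) ** 2, axis=1))) / 10
    assert tm.radius_of_gyration(s) == pytest.approx(direct)
    # mass weighting with uniform elements changes nothing
    assert tm.radius_of_gyration(s, mass_weighted=True) == pytest.approx(direct)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def test_sasa_isolated_atom_analytic():
    s = Structure([make_atom(element="N")], "one")  # r = 1.55
    result = tm.sasa(s, probe_radius=1.4, n_sphere_points=960)
    analytic = 4 * np.pi * (1.55 + 1.4) ** 2
    assert result.total == pytest.approx(analytic, rel=0.01)


def test_sasa_additive_at_large_separation():
    s1 = Structure([make_atom()], "a")
    s2 = Structure([make_atom(serial=1, coords=(0, 0, 0)),
                    make_atom(serial=2, resnum=2, coords=(100, 0, 0))], "b")
    lone = tm.sasa(s1, n_sphere_points=240).total
    assert tm.sasa(s2, n_sphere_points=240).total == pytest.approx(2 * lone, rel=1e-6)


def test_sasa_buried_atom_zero():
    centre = make_atom(serial=1, coords=(0, 0, 0))
    shell = [make_atom(serial=i + 2, resnum=2, coords=d)
             for i, d in enumerate(tm._sphere_points(32) * 1.0)]
    result = tm.sasa(Structure([centre] + shell, "buried"), n_sphere_points=240)
    assert result.per_atom[0] == 0.0


def test_sasa_per_residue_sums_to_total(rng):
    s = sf.make_toy_peptide(10, "random", seed=4)
    result = tm.sasa(s, n_sphere_points=120)
    assert sum(result.per_residue.values()) == pytest.approx(result.total)


def test_sasa_converges_with_sphere_points():
    s = Structure([make_atom(element="C")], "one")
    analytic = 4 * np.pi * (1.7 + 1.4) ** 2
    errors = [abs(tm.sasa(s, n_sphere_points=n).total - analytic) / analytic
              for n in (60, 960)]
    assert errors[1] < 0.01
    assert errors[1] <= errors[0]


def test_sasa_unknown_element_rejected():
    s = Structure([make_atom(element="XX")], "bad")
    with pytest.raises(ValueError, match="radius"):
        tm.sasa(s)


# ---------------------------------------------------------------------------
# Series metrics
# ---------------------------------------------------------------------------

def two_group_structure(sep=5.0):
    atoms = [make_atom(serial=1, coords=(0, 0, 0)),
             make_atom(serial=2, name="C1", resname="LIG", resnum=2, chain="L",
                       coords=(sep, 0, 0))]
    return Structure(atoms, "pair")


def test_min_distance_coincident_groups_zero():
    traj = sf.make_trajectory(two_group_structure(sep=0.0), n_frames=4)
    series = tm.min_distance_series(traj, [0], [1])
    assert series.values.tolist() == [0.0] * 4


def test_min_distance_static_half_nanometre():
    traj = sf.make_trajectory(two_group_structure(sep=5.0), n_frames=6)
    series = tm.min_distance_series(traj, [0], [1])
    assert series.mean == pytest.approx(0.5)
    assert series.std == pytest.approx(0.0)


def test_min_distance_matches_brute_force(rng):
    base = sf.make_toy_peptide(12, "random", seed=8)
    traj = sf.make_trajectory(base, n_frames=10, noise_amplitude=0.5, seed=3)
    group_a, group_b = list(range(6)), list(range(6, 12))
    series = tm.min_distance_series(traj, group_a, group_b)
    for frame, value in zip(traj.frames, series.values):
        c = frame.coords
        brute = min(np.linalg.norm(c[i] - c[j]) for i in group_a for j in group_b)
        assert value == pytest.approx(brute / 10.0)


def test_min_distance_empty_mask_rejected():
    traj = sf.make_trajectory(two_group_structure(), n_frames=2)
    with pytest.raises(ValueError):
        tm.min_distance_series(traj, [], [1])


def hbond_base_structure():
    atoms = [make_atom(serial=1, name="OG", element="O", resname="SER",
                       coords=(0, 0, 0)),
             make_atom(serial=2, name="HG", element="H", resname="SER",
                       coords=(0.95, 0, 0)),
             make_atom(serial=3, name="O1", element="O", resname="LIG",
                       resnum=2, chain="L", coords=(2.9, 0, 0))]
    ann_a = MoleculeAnnotation(donors=[(0, 1)], acceptors=[], label="pep")
    ann_b = MoleculeAnnotation(donors=[], acceptors=[2], label="lig")
    return Structure(atoms, "hb"), ann_a, ann_b


def test_persistent_hbond_mean_one():
    base, ann_a, ann_b = hbond_base_structure()
    traj = sf.make_trajectory(base, n_frames=8, planted_events=[
        {"kind": "hbond", "donor": 0, "hydrogen": 1, "acceptor": 2,
         "frames": set(range(8))}])
    series, per_residue = tm.hbond_series(traj, ann_a, ann_b)
    assert series.mean == pytest.approx(1.0)
    assert per_residue["SER1"] == pytest.approx(1.0)


def test_intermittent_hbond_mean_half():
    base, ann_a, ann_b = hbond_base_structure()
    traj = sf.make_trajectory(base, n_frames=10, planted_events=[
        {"kind": "hbond", "donor": 0, "hydrogen": 1, "acceptor": 2,
         "frames": set(range(5))}])
    series, _ = tm.hbond_series(traj, ann_a, ann_b)
    assert series.mean == pytest.approx(0.5)


def test_hbond_series_matches_frame_by_frame_recount(rng):
    base, ann_a, ann_b = hbond_base_structure()
    traj = sf.make_trajectory(base, n_frames=5, noise_amplitude=0.4, seed=9)
    series, _ = tm.hbond_series(traj, ann_a, ann_b)
    for frame, count in zip(traj.frames, series.values):
        recount = detect_hbonds(frame, frame, ann_a, ann_b, HBondCriteria())
        assert count == len(recount)


def test_static_trajectory_hbond_mean_equals_single_frame():
    base, ann_a, ann_b = hbond_base_structure()
    traj = sf.make_trajectory(base, n_frames=6)  # no noise: every frame = base
    series, _ = tm.hbond_series(traj, ann_a, ann_b)
    frame1 = detect_hbonds(base, base, ann_a, ann_b, HBondCriteria())
    assert series.mean == pytest.approx(len(frame1))


def test_end_to_end_extended_chain():
    s = sf.make_toy_peptide(10, "extended")
    traj = sf.make_trajectory(s, n_frames=3)
    expected = np.linalg.norm(s.coords[-1] - s.coords[0]) / 10.0
    series = tm.end_to_end_series(traj)
    assert series.values == pytest.approx([expected] * 3)


def test_end_to_end_circularized_zero():
    s = sf.make_toy_peptide(10, "extended")
    coords = s.coords
    coords[-1] = coords[0]
    traj = sf.make_trajectory(s.with_coords(coords), n_frames=2)
    assert tm.end_to_end_series(traj).mean == pytest.approx(0.0)


def test_end_to_end_missing_anchor_errors():
    traj = sf.make_trajectory(sf.make_toy_peptide(5, "extended"), n_frames=1)
    with pytest.raises(ValueError, match="anchor"):
        tm.end_to_end_series(traj, anchor_name="CB")


def test_metrics_invariant_under_global_rigid_motion(rng):
    base = sf.make_toy_peptide(12, "random", seed=6)
    traj = sf.make_trajectory(base, n_frames=4, noise_amplitude=0.3, seed=1)
    R = Rotation.random(random_state=7).as_matrix()
    t = np.array([12.0, -3.0, 40.0])
    moved = tm.Trajectory([f.with_coords(f.coords @ R.T + t) for f in traj.frames])
    for metric in (tm.rg_series, tm.end_to_end_series):
        np.testing.assert_allclose(metric(traj).values, metric(moved).values,
                                   atol=1e-9)
    np.testing.assert_allclose(
        tm.min_distance_series(traj, list(range(6)), list(range(6, 12))).values,
        tm.min_distance_series(moved, list(range(6)), list(range(6, 12))).values,
        atol=1e-9)
    # RMSD against a co-transformed reference is unchanged
    np.testing.assert_allclose(tm.rmsd_series(traj).values,
                               tm.rmsd_series(moved).values, atol=1e-9)
    # SASA is rotation invariant up to sphere-point discretization
    s0 = tm.sasa(traj.frames[0], n_sphere_points=480).total
    s1 = tm.sasa(moved.frames[0], n_sphere_points=480).total
    assert s1 == pytest.approx(s0, rel=0.02)


def test_metric_series_statistics_recomputable(rng):
    values = rng.uniform(size=20)
    series = tm.MetricSeries("x", values, "nm")
    assert series.mean == pytest.approx(float(np.mean(values)))
    assert series.std == pytest.approx(float(np.std(values)))
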