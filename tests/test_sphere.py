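"""Icosphere meshes, spherical patch projection, entropy, and maxima."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cowtrack as ct
from cowtrack import sphere
from cowtrack.sphere import DegenerateFieldError, SphericalField
from cowtrack.volume import Volume

from conftest import single_tube_gt


@pytest.mark.parametrize("level,n_vertices,n_faces", [(0, 12, 20), (1, 42, 80), (2, 162, 320)])
def test_icosphere_counts(level, n_vertices, n_faces):
    mesh = ct.make_icosphere(level)
    assert mesh.n_vertices == n_vertices
    assert len(mesh.faces) == n_faces
    assert np.allclose(np.linalg.norm(mesh.vertices, axis=1), 1.0, atol=1e-9)


def test_icosphere_euler_characteristic(mesh2):
    edges = set()
    for a, b, c in mesh2.faces:
        edges.update({frozenset((a, b)), frozenset((b, c)), frozenset((a, c))})
    assert mesh2.n_vertices - len(edges) + len(mesh2.faces) == 2


def test_icosphere_negative_level_rejected():
    with pytest.raises(ValueError):
        ct.make_icosphere(-1)


# ---------------------------------------------------------------------------
# projection


def test_project_constant_volume_gives_constant_field(mesh1):
    vol = Volume(np.full((20, 20, 20), 3.5), spacing=1.0, origin=(0, 0, 0))
    field = ct.project_patch(vol, center=(10, 10, 10), radius=4.0, mesh=mesh1)
    assert np.allclose(field.values, 3.5)


def _tube_volume(axis: int) -> Volume:
    """Bright 2 mm tube through the center along a grid axis."""
    shape = (48, 48, 48)
    vol = np.zeros(shape)
    ax = [np.arange(s) * 0.5 - (s - 1) * 0.25 for s in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    coords = [gx, gy, gz]
    perp = [coords[k] for k in range(3) if k != axis]
    r2 = perp[0] ** 2 + perp[1] ** 2
    vol[r2 <= 1.0] = 100.0
    return Volume(vol, spacing=0.5, origin=[-(s - 1) * 0.25 for s in shape])


@pytest.mark.parametrize("axis", [0, 2])
def test_tube_projection_peaks_along_axis(mesh2, axis):
    vol = _tube_volume(axis)
    field = ct.project_patch(vol, center=(0, 0, 0), radius=5.0, mesh=mesh2)
    unit = np.zeros(3)
    unit[axis] = 1.0
    top2 = np.argsort(field.values)[-2:]
    dots = np.abs(mesh2.vertices[top2] @ unit)
    # both strongest vertices are the ones nearest +-axis
    nearest = np.max(np.abs(mesh2.vertices @ unit))
    assert np.all(dots >= nearest - 1e-9)


def test_tube_rotation_rotates_argmax(mesh2):
    """A 90-degree rotation of the tube rotates the field's maxima with it."""
    f_z = ct.project_patch(_tube_volume(2), (0, 0, 0), 5.0, mesh2).values
    f_y = ct.project_patch(_tube_volume(1), (0, 0, 0), 5.0, mesh2).values
    rot = np.array([[1.0, 0, 0], [0, 0, 1.0], [0, -1.0, 0]])  # +z -> +y
    argmax_rotated = rot @ mesh2.vertices[np.argmax(f_z)]
    expected = mesh2.vertices[np.argmax(f_y)]
    assert abs(float(argmax_rotated @ expected)) > np.cos(np.deg2rad(10))


def test_projection_near_boundary_rejected(mesh1):
    vol = Volume(np.zeros((20, 20, 20)), spacing=1.0)
    with pytest.raises(ValueError, match="radius"):
        ct.project_patch(vol, center=(2, 10, 10), radius=5.0, mesh=mesh1)


# ---------------------------------------------------------------------------
# aggregation and normalization


def test_aggregate_single_and_identical_fields(mesh1):
    rng = np.random.default_rng(0)
    f = SphericalField(mesh1, rng.random(42))
    single = ct.aggregate_scales([f])
    assert np.allclose(single.values, sphere.standardize_values(f.values))
    double = ct.aggregate_scales([f, SphericalField(mesh1, f.values.copy())])
    assert np.allclose(double.values, single.values)


def test_aggregate_prefers_stronger_standardized_peak(mesh1):
    iz = int(np.argmax(mesh1.vertices[:, 2]))
    ix = int(np.argmax(mesh1.vertices[:, 0]))
    iy = int(np.argmax(mesh1.vertices[:, 1]))
    a = np.ones(42)
    a[iz] = a[iy] = 3.0  # broad two-vertex elevation, smaller standardized peak
    b = np.ones(42)
    b[ix] = 30.0  # single sharp peak at +x
    agg = ct.aggregate_scales([SphericalField(mesh1, a), SphericalField(mesh1, b)])
    assert int(np.argmax(agg.values)) == ix


def test_aggregate_mesh_mismatch_rejected(mesh1, mesh2):
    with pytest.raises(ValueError, match="mesh"):
        ct.aggregate_scales([SphericalField(mesh1, np.ones(42)), SphericalField(mesh2, np.ones(162))])


def test_normalize_field_conventions(mesh1):
    uniform = ct.normalize_field(SphericalField(mesh1, np.zeros(42)))
    assert np.allclose(uniform.values, 1 / 42)
    onehot = np.zeros(42)
    onehot[5] = 1.0
    assert np.allclose(ct.normalize_field(SphericalField(mesh1, onehot)).values, onehot)
    two = np.zeros(42)
    two[:2] = 2.0
    assert np.allclose(ct.normalize_field(SphericalField(mesh1, two)).values[:2], 0.5)
    with pytest.raises(ValueError):
        ct.normalize_field(SphericalField(mesh1, -np.ones(42)))


# ---------------------------------------------------------------------------
# entropy


@pytest.mark.parametrize("level", [0, 1, 2, 3])
def test_uniform_field_entropy_is_one(level):
    mesh = ct.make_icosphere(level)
    field = ct.normalize_field(SphericalField(mesh, np.ones(mesh.n_vertices)))
    assert ct.entropy(field) == pytest.approx(1.0, abs=1e-12)


def test_onehot_entropy_is_zero(mesh1):
    vals = np.zeros(42)
    vals[0] = 1.0
    assert ct.entropy(SphericalField(mesh1, vals, normalized=True)) == pytest.approx(0.0, abs=1e-12)


def test_two_point_distribution_entropy_closed_form():
    # H((1/2, 1/2, 0, 0)) = ln 2 / ln 4 = 1/2
    assert sphere.entropy_rows(np.array([[0.5, 0.5, 0.0, 0.0]]))[0] == pytest.approx(0.5)


def test_entropy_requires_normalized_field(mesh1):
    with pytest.raises(ValueError, match="normalized"):
        ct.entropy(SphericalField(mesh1, np.ones(42), normalized=False))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_entropy_bounds_random_fields(seed):
    mesh = ct.make_icosphere(1)
    vals = np.random.default_rng(seed).random(42) ** 3
    h = ct.entropy(ct.normalize_field(SphericalField(mesh, vals)))
    assert 0.0 <= h <= 1.0
    if np.ptp(vals) > 1e-6:
        assert h < 1.0


# ---------------------------------------------------------------------------
# top-2 maxima


def test_top2_antipodal_peaks(mesh2):
    iz = int(np.argmax(mesh2.vertices[:, 2]))
    imz = int(np.argmax(-mesh2.vertices[:, 2]))
    vals = np.ones(162) * 0.1
    vals[iz], vals[imz] = 2.0, 1.5
    d1, d2 = ct.top2_directions(SphericalField(mesh2, vals))
    assert np.allclose(d1, mesh2.vertices[iz])
    assert np.allclose(d2, mesh2.vertices[imz])


def test_top2_uniform_field_degenerate(mesh1):
    with pytest.raises(DegenerateFieldError):
        ct.top2_directions(SphericalField(mesh1, np.ones(42)))


def _top2_bruteforce(mesh, vals, min_sep_deg=60.0):
    """Independent exhaustive scan applying the same admissibility rule."""
    maxima = []
    for i in range(mesh.n_vertices):
        ring = mesh.adjacency[i][mesh.adjacency[i] >= 0]
        if all(vals[i] > vals[j] for j in ring):
            maxima.append(i)
    if len(maxima) < 2:
        return None
    maxima.sort(key=lambda i: (-vals[i], i))
    v1 = mesh.vertices[maxima[0]]
    for j in maxima[1:]:
        if float(v1 @ mesh.vertices[j]) <= np.cos(np.deg2rad(min_sep_deg)) + 1e-12:
            return v1, mesh.vertices[j]
    return None


@pytest.mark.parametrize("seed", range(15))
def test_top2_matches_bruteforce_oracle(mesh3, seed):
    vals = np.random.default_rng(seed).random(mesh3.n_vertices)
    expected = _top2_bruteforce(mesh3, vals)
    field = SphericalField(mesh3, vals)
    if expected is None:
        with pytest.raises(DegenerateFieldError):
            ct.top2_directions(field)
    else:
        d1, d2 = ct.top2_directions(field)
        assert np.allclose(d1, expected[0])
        assert np.allclose(d2, expected[1])


# ---------------------------------------------------------------------------
# multi-scale robustness


@pytest.mark.parametrize("diameter", [0.6, 1.2, 2.5])
def test_scale_robust_orientation_recovery(mesh2, diameter):
    """The multi-scale aggregate recovers the tube axis within 15 degrees
    for diameters spanning hypoplastic to large-normal calibres."""
    gt = single_tube_gt(diameter=diameter)
    noise = ct.NoiseSpec(background_mean=20, background_sd=3, lumen_peak=100, seed=11)
    vol = ct.rasterize(gt, shape=(96, 72, 72), spacing=0.5, noise=noise, origin=(-24, -18, -18))
    provider = ct.MatchedFilterProvider(vol, mesh=mesh2, n_radial=8)
    f = provider.fields(np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]]))
    for row in f:
        d1, d2 = ct.top2_directions(SphericalField(mesh2, row, normalized=True))
        for d in (d1, d2):
            angle = np.rad2deg(np.arccos(min(1.0, abs(float(d @ [1.0, 0, 0])))))
            assert angle < 15.0
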