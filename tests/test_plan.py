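import numpy as np
import pytest
from scipy import stats

from psrdose.model import (Jaw, ParticleBatch, ToySpectrum,
                           build_toy_beam_model, sample_source_particles)
from psrdose.plan import (PlanControlPoint, assign_control_points_biased,
                          assign_control_points_weighting,
                          build_fluence_maps, build_inverse_lookup,
                          calculate_plan_dose, compute_cpdf,
                          count_less_useful, load_plan,
                          particle_reduction_factor, rotate_to_beam,
                          save_plan)
from psrdose.transport import (Collimator, DoseGrid, collimate,
                               transport_and_tally)
from psrdose import synthetic as syn


def _open_cp(jaw=Jaw(5.0, 5.0), mu=1.0, angle=0.0, index=0):
    return PlanControlPoint(index, angle, mu, jaw,
                            np.tile([-jaw.half_x - 1.0, jaw.half_x + 1.0],
                                    (10, 1)))


def _fm_for(cps, **kw):
    return build_fluence_maps(cps, **kw)


# ---------------------------------------------------------------------------
# fluence maps

def test_open_aperture_fm_equals_mu():
    cps = [_open_cp(mu=0.3, index=0), _open_cp(mu=0.7, angle=10.0, index=1)]
    fm = _fm_for(cps)
    for k, mu in enumerate((0.3, 0.7)):
        vals = fm.values[:, :, k][fm.in_jaw]
        assert np.allclose(vals, mu)
    assert not np.any(fm.values[:, :, :][~fm.in_jaw])


def test_closed_aperture_fm_is_transmission():
    jaw = Jaw(5.0, 5.0)
    cp = PlanControlPoint(0, 0.0, 1.0, jaw, np.tile([0.0, 0.0], (10, 1)))
    fm = _fm_for([cp], transmission=0.015)
    vals = fm.values[:, :, 0][fm.in_jaw]
    assert np.allclose(vals, 0.015)


def test_single_open_strip_matches_point_in_aperture_oracle():
    jaw = Jaw(5.0, 5.0)
    leaves = np.tile([0.0, 0.0], (10, 1))
    leaves[4] = [-1.0, 2.0]     # one pair open on one control point
    cps = [PlanControlPoint(0, 0.0, 0.5, jaw, np.tile([0.0, 0.0], (10, 1))),
           PlanControlPoint(1, 10.0, 0.5, jaw, leaves)]
    fm = _fm_for(cps, transmission=0.015)
    ny, nx, _ = fm.values.shape
    xc = fm.origin[0] + (np.arange(nx) + 0.5) * fm.pixel_size
    yc = fm.origin[1] + (np.arange(ny) + 0.5) * fm.pixel_size
    lw = 2 * jaw.half_y / 10
    for iy in range(ny):
        for ix in range(nx):
            in_jaw = abs(xc[ix]) <= 5.0 and abs(yc[iy]) <= 5.0
            pair = min(int((yc[iy] + 5.0) // lw), 9) if in_jaw else -1
            inside = (in_jaw and pair == 4
                      and -1.0 < xc[ix] < 2.0)
            expected = 0.5 * (1.0 if inside else (0.015 if in_jaw else 0.0))
            assert fm.values[iy, ix, 1] == pytest.approx(expected)


def test_empty_arc_rejected():
    with pytest.raises(ValueError):
        build_fluence_maps([])


# ---------------------------------------------------------------------------
# CPDF and inverse table

def test_cpdf_forced_values():
    cps = [_open_cp(mu=0.25, index=0), _open_cp(mu=0.75, index=1)]
    fm = _fm_for(cps)
    iy, ix = np.argwhere(fm.in_jaw)[0]
    c = compute_cpdf(fm, (iy, ix))
    np.testing.assert_allclose(c.values, [0.25, 1.0])

    single = _fm_for([_open_cp()])
    c1 = compute_cpdf(single, tuple(np.argwhere(single.in_jaw)[0]))
    np.testing.assert_allclose(c1.values, [1.0])


def test_cpdf_uniform_178_control_points():
    cps = [_open_cp(mu=1.0 / 178, angle=a, index=k)
           for k, a in enumerate(np.linspace(0, 357.98, 178))]
    fm = _fm_for(cps)
    iy, ix = np.argwhere(fm.in_jaw)[0]
    c = compute_cpdf(fm, (iy, ix))
    np.testing.assert_allclose(c.values, (np.arange(178) + 1) / 178,
                               rtol=1e-12)


def test_cpdf_zero_mass_pixel_raises():
    fm = _fm_for([_open_cp()])
    dead = np.argwhere(~fm.in_jaw)[0]
    with pytest.raises(ValueError):
        compute_cpdf(fm, tuple(dead))


def test_inverse_table_uniform_quartiles():
    cps = [_open_cp(mu=0.25, angle=10.0 * k, index=k) for k in range(4)]
    fm = _fm_for(cps)
    table = build_inverse_lookup(fm, n_prob_bins=8)
    iy, ix = np.argwhere(fm.in_jaw)[0]
    np.testing.assert_array_equal(table.table[iy, ix],
                                  [0, 0, 1, 1, 2, 2, 3, 3])
    single = build_inverse_lookup(_fm_for([_open_cp()]), n_prob_bins=8)
    assert not np.any(single.table)


def test_inverse_table_agrees_with_sequential_search():
    """Nearest-bin lookups match a linear CPDF scan except within half a
    bin of a CPDF jump, and the disagreement rate shrinks as the table
    resolution grows."""
    arc = syn.make_toy_vmat_arc(12, "sweeping_slit", "peaked", 3)
    fm = _fm_for(arc)
    K = fm.n_control_points
    rng = np.random.default_rng(9)
    pix = np.argwhere(fm.total > 0)
    sel = pix[rng.integers(0, len(pix), 10_000)]
    gam = rng.random(10_000)
    rates = {}
    for factor in (4, 64):
        table = build_inverse_lookup(fm, n_prob_bins=factor * K)
        half_bin = 0.5 / table.n_prob_bins
        mismatches = 0
        for (iy, ix), g in zip(sel, gam):
            c = np.cumsum(fm.values[iy, ix]) / fm.total[iy, ix]
            c[-1] = 1.0
            k_scan = min(int(np.searchsorted(c, g, side="right")), K - 1)
            k_tab = int(table.table[iy, ix,
                                    min(int(g * table.n_prob_bins),
                                        table.n_prob_bins - 1)])
            if k_tab != k_scan:
                mismatches += 1
                # the offending jump must lie within half a bin of gamma
                edges = np.concatenate([[0.0], c])
                assert np.min(np.abs(edges - g)) <= half_bin + 1e-12
        rates[factor] = mismatches / len(gam)
    assert rates[64] < rates[4]
    assert rates[64] < 0.02


# ---------------------------------------------------------------------------
# control-point assignment

def _plane_batch(n, jaw, model, seed, fm=None):
    """Sample + jaw-collimate (as the plan pipeline does); optionally drop
    the rare wide-angle stragglers that leave the padded FM grid."""
    batch = sample_source_particles(model, n, jaw, rng_seed=seed)
    batch, _ = collimate(batch, Collimator(jaw))
    if fm is not None:
        from psrdose.plan import _fm_plane_positions, _inside_fm_grid
        x, y = _fm_plane_positions(batch, fm)
        batch = batch.select(_inside_fm_grid(fm, x, y))
    return batch


def test_single_nonzero_cp_always_selected(small_model):
    jaw = Jaw(5.0, 5.0)
    cps = [PlanControlPoint(0, 0.0, 0.0, jaw, np.tile([0., 0.], (10, 1))),
           _open_cp(jaw=jaw, mu=1.0, angle=45.0, index=1)]
    fm = _fm_for(cps, transmission=0.5)
    table = build_inverse_lookup(fm)
    batch = _plane_batch(2000, jaw, small_model, 4, fm)
    out, _ = assign_control_points_biased(batch, fm, table, rng_seed=0)
    assert np.all(out.cp_index[out.weight > 0] == 1)


def test_biased_draw_frequencies_match_fm():
    """At one pixel with FM = (0.2, 0.8) MU the empirical control-point
    frequencies follow the multinomial (chi-square, alpha = 0.01)."""
    jaw = Jaw(5.0, 5.0)
    cps = [_open_cp(jaw=jaw, mu=0.2, index=0),
           _open_cp(jaw=jaw, mu=0.8, angle=10.0, index=1)]
    fm = _fm_for(cps)
    # fine probability table so the nearest-bin quantization (up to half a
    # bin per CPDF jump) is far below the sampling noise
    table = build_inverse_lookup(fm, n_prob_bins=20001)
    spec = ToySpectrum(angular_width_0=(0, 0, 0),
                       angular_width_slope=(0, 0, 0))
    model = build_toy_beam_model(3, 2, spec)
    batch = _plane_batch(100_000, jaw, model, 5, fm)
    out, _ = assign_control_points_biased(batch, fm, table, rng_seed=6)
    keep = out.weight > 0
    counts = np.bincount(out.cp_index[keep], minlength=2)
    expected = np.array([0.2, 0.8]) * keep.sum()
    chi2 = ((counts - expected) ** 2 / expected).sum()
    assert chi2 < stats.chi2.ppf(0.99, 1)


@pytest.mark.parametrize("method", ["biased", "weighting"])
def test_assignment_unbiasedness(method, small_model):
    """E[weight * 1{k=m}] = FM(pixel, m) for both estimators."""
    arc = syn.make_toy_vmat_arc(6, "sweeping_slit", "peaked", 2)
    fm = _fm_for(arc)
    table = build_inverse_lookup(fm, n_prob_bins=20001)
    jaw = arc[0].jaw
    batch = _plane_batch(200_000, jaw, small_model, 7, fm)
    if method == "biased":
        out, _ = assign_control_points_biased(batch, fm, table, rng_seed=8)
    else:
        out, _ = assign_control_points_weighting(batch, fm, rng_seed=8)
    from psrdose.plan import _fm_plane_positions
    x, y = _fm_plane_positions(batch, fm)
    iy, ix = fm.pixel_of(x, y)
    # pick the most-populated pixel with mass
    flat = iy * fm.values.shape[1] + ix
    flat[fm.total[iy, ix] <= 0] = -1
    vals, counts = np.unique(flat[flat >= 0], return_counts=True)
    pick = vals[np.argmax(counts)]
    py, px = divmod(int(pick), fm.values.shape[1])
    at = flat == pick
    n_at = int(at.sum())
    total = fm.total[py, px]
    for m in range(fm.n_control_points):
        w = np.where(out.cp_index[at] == m, out.weight[at], 0.0)
        est = w.mean() / batch.weight[at].mean()
        # analytic multinomial SE (covers control points never drawn):
        # both estimators draw k=m with some p and weight w_m such that
        # p * w_m = FM_m; Var <= E[w^2 1{k=m}] = w_m * FM_m
        p = (fm.values[py, px, m] / total if method == "biased"
             else 1.0 / fm.n_control_points)
        w_m = fm.values[py, px, m] / max(p, 1e-300)
        se = np.sqrt(max(w_m * fm.values[py, px, m] - fm.values[py, px, m] ** 2,
                         0.0) / n_at)
        tol = 3 * se + 1e-9 * total + 0.5 * total / 20001
        assert abs(est - fm.values[py, px, m]) <= tol


def test_biased_weights_constant_per_pixel_dominate_variance(small_model):
    """Per-pixel weight variance: biased = 0 <= FM weighting."""
    arc = syn.make_toy_vmat_arc(8, "sweeping_slit", "uniform", 1)
    fm = _fm_for(arc)
    table = build_inverse_lookup(fm)
    batch = _plane_batch(50_000, arc[0].jaw, small_model, 3, fm)
    b, _ = assign_control_points_biased(batch, fm, table, rng_seed=1)
    w, _ = assign_control_points_weighting(batch, fm, rng_seed=1)
    from psrdose.plan import _fm_plane_positions
    x, y = _fm_plane_positions(batch, fm)
    iy, ix = fm.pixel_of(x, y)
    flat = iy * fm.values.shape[1] + ix
    vals, counts = np.unique(flat[fm.total[iy, ix] > 0], return_counts=True)
    for pick in vals[np.argsort(counts)[-5:]]:
        at = (flat == pick) & (fm.total[iy, ix] > 0)
        var_b = np.var(b.weight[at])
        var_w = np.var(w.weight[at])
        assert var_b <= var_w + 1e-18


def test_outside_fm_grid_raises(small_model):
    fm = _fm_for([_open_cp(jaw=Jaw(1.0, 1.0))], pad=0.1)
    table = build_inverse_lookup(fm)
    batch = _plane_batch(5000, Jaw.square(30), small_model, 2)
    with pytest.raises(ValueError):
        assign_control_points_biased(batch, fm, table, rng_seed=0)


# ---------------------------------------------------------------------------
# rotation

def test_rotation_identity_half_turn_and_inverse(small_model):
    batch = _plane_batch(100, Jaw.square(10), small_model, 1)
    iso = (0.0, 0.0, 100.0)

    cp0 = _open_cp(angle=0.0)
    batch.cp_index[:] = 0
    r0 = rotate_to_beam(batch, [cp0], isocenter=iso)
    np.testing.assert_array_equal(r0.direction, batch.direction)
    np.testing.assert_array_equal(r0.pos3, batch.positions3())

    cp180 = _open_cp(angle=180.0)
    r180 = rotate_to_beam(batch, [cp180], isocenter=iso)
    np.testing.assert_allclose(r180.direction[:, 2], -batch.direction[:, 2],
                               atol=1e-12)
    np.testing.assert_allclose(r180.direction[:, 0], -batch.direction[:, 0],
                               atol=1e-12)
    np.testing.assert_array_equal(r180.direction[:, 1],
                                  batch.direction[:, 1])

    fwd = rotate_to_beam(batch, [_open_cp(angle=73.0)], isocenter=iso)
    back = rotate_to_beam(fwd, [_open_cp(angle=-73.0)], isocenter=iso)
    np.testing.assert_allclose(back.pos3, batch.positions3(), atol=1e-12)
    np.testing.assert_allclose(back.direction, batch.direction, atol=1e-12)
    assert np.allclose(np.linalg.norm(fwd.direction, axis=1), 1.0,
                       atol=1e-12)


# ---------------------------------------------------------------------------
# less-useful accounting

def test_less_useful_open_arc_is_zero(small_model):
    arc = [_open_cp()]
    fm = _fm_for(arc)
    table = build_inverse_lookup(fm)
    batch = _plane_batch(5000, arc[0].jaw, small_model, 6, fm)
    out, _ = assign_control_points_biased(batch, fm, table, rng_seed=3)
    stats_ = count_less_useful(out, fm)
    assert stats_.count == 0
    assert stats_.fraction == 0.0


def test_less_useful_half_open_fraction():
    """Half-open single control point: ~50% of uniform in-jaw particles
    land under the closed half (3-sigma binomial)."""
    jaw = Jaw(5.0, 5.0)
    leaves = np.tile([-5.0, 0.0], (10, 1))     # open left half
    cp = PlanControlPoint(0, 0.0, 1.0, jaw, leaves)
    fm = _fm_for([cp])
    table = build_inverse_lookup(fm)
    spec = ToySpectrum(angular_width_0=(0, 0, 0),
                       angular_width_slope=(0, 0, 0))
    model = build_toy_beam_model(6, 2, spec)
    batch = sample_source_particles(model, 40_000, jaw, margin=0.0,
                                    rng_seed=4)
    # keep only particles whose projection is strictly inside the jaw
    from psrdose.plan import _fm_plane_positions
    x, y = _fm_plane_positions(batch, fm)
    inside = (np.abs(x) < 5.0) & (np.abs(y) < 5.0)
    batch = batch.select(inside)
    out, _ = assign_control_points_biased(batch, fm, table, rng_seed=5)
    st = count_less_useful(out, fm)
    n = st.total
    # in-jaw particle density is radially symmetric; open/closed halves
    # carry equal mass
    p = 0.5
    assert abs(st.count - p * n) <= 3 * np.sqrt(n * p * (1 - p))


def test_biased_reduces_less_useful_fraction(small_model):
    """Sparse-aperture arc: the biased method hits closed leaves less often
    than FM weighting at equal n (one-sided binomial, alpha = 0.01)."""
    arc = syn.make_toy_vmat_arc(24, "sweeping_slit", "uniform", 2)
    fm = _fm_for(arc)
    table = build_inverse_lookup(fm)
    batch = _plane_batch(30_000, arc[0].jaw, small_model, 8, fm)
    b, _ = assign_control_points_biased(batch, fm, table, rng_seed=9)
    w, _ = assign_control_points_weighting(batch, fm, rng_seed=9)
    st_b = count_less_useful(b, fm)
    st_w = count_less_useful(w, fm)
    assert st_b.fraction < st_w.fraction
    test = stats.binomtest(st_b.count, st_b.total, st_w.fraction,
                           alternative="less")
    assert test.pvalue < 0.01


def test_unassigned_particles_rejected(small_model):
    arc = [_open_cp()]
    fm = _fm_for(arc)
    batch = _plane_batch(10, arc[0].jaw, small_model, 0)
    with pytest.raises(ValueError):
        count_less_useful(batch, fm)


# ---------------------------------------------------------------------------
# plan dose

def test_single_cp_plan_equals_static_field_bit_exact(iso_phantom):
    spec = ToySpectrum(angular_width_0=(0, 0, 0),
                       angular_width_slope=(0, 0, 0))
    model = build_toy_beam_model(4, 3, spec)
    jaw = Jaw.square(8.0)
    cp = PlanControlPoint(0, 0.0, 1.0, jaw, np.tile([-6.0, 6.0], (10, 1)))
    n, seed = 20_000, 9
    res = calculate_plan_dose([cp], model, iso_phantom, method="biased",
                              n_particles=n, batch_particles=n,
                              rng_seed=seed)
    ss = np.random.SeedSequence(seed)
    child = np.random.default_rng(ss.spawn(1)[0])
    batch = sample_source_particles(model, n, jaw, rng_seed=child)
    batch, _ = collimate(batch, Collimator(jaw, sad=model.sad,
                                           source_z=model.source_z))
    ref = transport_and_tally(batch, iso_phantom, n_batches=1,
                              n_histories=n)
    assert np.array_equal(res.dose.values, ref.batch_doses[0].values)
    assert res.dose.values.max() > 0


def test_methods_agree_in_expectation_on_toy_arc(small_model, iso_phantom):
    """Mean doses of the two estimators agree within 3 combined standard
    errors at matched particle counts."""
    arc = syn.make_toy_vmat_arc(6, "oscillating", "uniform", 4)
    res_b = calculate_plan_dose(arc, small_model, iso_phantom,
                                method="biased", n_particles=120_000,
                                batch_particles=12_000, rng_seed=21)
    res_w = calculate_plan_dose(arc, small_model, iso_phantom,
                                method="weighting", n_particles=360_000,
                                batch_particles=36_000, rng_seed=22)
    stack_b = np.stack([g.values for g in res_b.batch_doses])
    stack_w = np.stack([g.values for g in res_w.batch_doses])
    mean_b, mean_w = stack_b.mean(0), stack_w.mean(0)
    se = np.sqrt(stack_b.var(0, ddof=1) / 10 + stack_w.var(0, ddof=1) / 10)
    hot = mean_w > 0.5 * mean_w.max()
    z = np.abs(mean_b - mean_w)[hot] / np.maximum(se[hot], 1e-300)
    # fraction beyond 3 SE should be at the Gaussian tail level
    assert np.mean(z > 3.0) < 0.02


def test_reduction_factor_helper():
    assert particle_reduction_factor(60.0, 21.6) == pytest.approx(2.7778,
                                                                  abs=1e-3)
    with pytest.raises(ValueError):
        particle_reduction_factor(1.0, 0.0)


def test_plan_json_round_trip(tmp_path):
    arc = syn.make_toy_vmat_arc(5, "oscillating", "peaked", 6)
    save_plan([arc], tmp_path / "plan.json")
    back = load_plan(tmp_path / "plan.json")[0]
    assert len(back) == 5
    for a, b in zip(arc, back):
        assert a.gantry_angle_deg == b.gantry_angle_deg
        assert a.mu_weight == b.mu_weight
        np.testing.assert_array_equal(a.leaves, b.leaves)
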