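"""Condition-difference analysis: averaging, differencing, C4
symmetrization, thresholding and domain aggregation."""

import numpy as np
import pytest

from twistgate import net_fda as nf
from twistgate import synthetic_data as sd
from twistgate.errors import ConfigError, InputError
from twistgate.model_io import DomainMap
from twistgate.pairwise_forces import PairForceTable
from twistgate.units import KJ_MOL_NM_TO_PN

A1 = ("A", 1)
A2 = ("A", 2)


def _table(vectors, cls="coulomb", residues=(A1, A2)):
    """PairForceTable with a single pair carrying the given frame vectors."""
    arr = np.atleast_2d(np.asarray(vectors, dtype=float))
    t = PairForceTable(residues=list(residues), n_frames=len(arr))
    for f, v in enumerate(arr):
        t.add(A1, A2, cls, f, v)
    return t


# ---------------------------------------------------------------------------
# time averages and Eq.-style differencing


def test_time_average_of_constant_series_is_the_vector():
    t = _table([[1.0, 2.0, 3.0]] * 5)
    out = nf.time_average(t)
    np.testing.assert_allclose(out.get(A1, A2), [1, 2, 3])


def test_time_average_of_opposite_vectors_is_zero():
    t = _table([[1.0, -2.0, 0.5], [-1.0, 2.0, -0.5]])
    np.testing.assert_allclose(nf.time_average(t).get(A1, A2), 0.0, atol=1e-15)


def test_time_average_recovers_known_mean_within_sampling_bound(rng):
    mu = np.array([3.0, -1.0, 2.0])
    vectors = mu + rng.normal(0, 1.0, size=(100, 3))
    out = nf.time_average(_table(vectors))
    assert np.all(np.abs(out.get(A1, A2) - mu) < 4.0 / np.sqrt(100))


def test_time_average_empty_window_raises():
    with pytest.raises(InputError):
        nf.time_average(_table([[1, 1, 1]]), window=slice(5, 5))


def test_net_fda_identical_conditions_gives_zero():
    t = _table([[1.0, 2.0, 3.0]] * 4)
    net = nf.net_fda([t, t], [t, t])
    assert len(net.entries) == 0 or not np.any(net.get(A1, A2))


def test_net_fda_recovers_injected_offset_exactly():
    base = [[1.0, 0.0, 0.0]] * 3
    delta = np.array([0.5, -1.0, 2.0])
    forced = _table(np.asarray(base) + delta)
    free = _table(base)
    net = nf.net_fda([forced, forced], [free, free])
    np.testing.assert_allclose(net.get(A1, A2), delta, atol=1e-12)


def test_net_fda_linearity_under_common_offset(rng):
    v1 = rng.normal(size=(4, 3))
    v2 = rng.normal(size=(4, 3))
    offset = np.array([2.0, 2.0, -1.0])
    net_a = nf.net_fda([_table(v1)], [_table(v2)])
    net_b = nf.net_fda([_table(v1 + offset)], [_table(v2 + offset)])
    np.testing.assert_allclose(net_a.get(A1, A2), net_b.get(A1, A2), atol=1e-12)


def test_net_fda_rejects_mismatched_universes():
    t1 = _table([[1, 1, 1]])
    t2 = _table([[1, 1, 1]], residues=(A1, A2, ("A", 9)))
    with pytest.raises(InputError):
        nf.net_fda([t1], [t2])


def test_generator_delta_recovered_within_noise_bound():
    cfg = sd.GeneratorConfig(seed=3)
    forced, free, manifest = sd.make_net_force_pair(cfg)
    net = nf.net_fda(forced, free)
    se = manifest["noise_sigma"] / np.sqrt(cfg.n_frames)
    for (trp, lh), delta in cfg.delta_pairs.items():
        err = net.get(tuple(trp), tuple(lh)) - np.asarray(delta)
        assert np.all(np.abs(err) < 4 * se)


# ---------------------------------------------------------------------------
# C4 symmetrization


def _c4_map():
    return nf.SymmetryMap(axis=[0, 0, 1], center=[0, 0, 0],
                          chain_cycle=("A", "B", "C", "D"))


def _rot_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0],
                     [0, 0, 1.0]])


def _sym_table(v_ref):
    """Net table exactly C4-symmetric: chain k carries R(90k) v_ref."""
    net = nf.NetForceTable()
    for k, c in enumerate("ABCD"):
        key, sign = PairForceTable.canonical((c, 1), (c, 2))
        net.entries[key] = {"coulomb": sign * (_rot_z(90 * k) @ v_ref)}
    return net


def test_symmetrize_fixed_point_on_exactly_symmetric_input():
    v = np.array([1.0, 2.0, 3.0])
    out = nf.symmetrize_c4(_sym_table(v), _c4_map())
    np.testing.assert_allclose(out.get(("A", 1), ("A", 2)), v, atol=1e-12)


def test_symmetrize_single_chain_gives_quarter_vector():
    net = nf.NetForceTable()
    v = np.array([4.0, 0.0, 8.0])
    key, sign = PairForceTable.canonical(("B", 1), ("B", 2))
    net.entries[key] = {"coulomb": sign * v}
    out = nf.symmetrize_c4(net, _c4_map())
    # chain B sits one 90 deg step from the reference chain
    np.testing.assert_allclose(
        out.get(("A", 1), ("A", 2)), _rot_z(-90) @ v / 4, atol=1e-12
    )


def test_symmetrize_is_idempotent(rng):
    net = nf.NetForceTable()
    for c in "ABCD":
        key, sign = PairForceTable.canonical((c, 1), (c, 2))
        net.entries[key] = {"coulomb": sign * rng.normal(size=3)}
    once = nf.symmetrize_c4(net, _c4_map())
    twice = nf.symmetrize_c4(once, _c4_map())
    for key in once.entries:
        np.testing.assert_allclose(once.total(key), twice.total(key), atol=1e-12)


def test_symmetrize_reduces_noise_on_noisy_symmetric_input(rng):
    v = np.array([5.0, 1.0, -2.0])
    truth = _sym_table(v)
    noisy = nf.NetForceTable()
    for key, classed in truth.entries.items():
        noisy.entries[key] = {
            "coulomb": classed["coulomb"] + rng.normal(0, 0.5, size=3)
        }
    out = nf.symmetrize_c4(noisy, _c4_map())
    err_sym = np.linalg.norm(out.get(("A", 1), ("A", 2)) - v)
    errs_single = [
        np.linalg.norm(
            _rot_z(-90 * k) @ noisy.get((c, 1), (c, 2)) - v
        )
        for k, c in enumerate("ABCD")
    ]
    assert err_sym < max(errs_single)
    # averaging four independent copies should beat the mean single error
    assert err_sym < np.mean(errs_single) + 1e-12


# ---------------------------------------------------------------------------
# thresholding & aggregation


def _net_with_magnitudes_pn(mags_pn):
    net = nf.NetForceTable()
    for i, m in enumerate(mags_pn):
        key, sign = PairForceTable.canonical(("A", 1), ("A", 10 + i))
        vec = np.array([m / KJ_MOL_NM_TO_PN, 0.0, 0.0])
        net.entries[key] = {"coulomb": sign * vec}
    return net


def test_threshold_zero_is_identity():
    net = _net_with_magnitudes_pn([1.0, 10.0])
    out = nf.threshold_filter(net, 0.0)
    assert set(out.entries) == set(net.entries)


def test_threshold_five_pn_boundary_is_strict():
    net = _net_with_magnitudes_pn([4.9, 5.1, 5.0])
    out = nf.threshold_filter(net, 5.0)
    mags = sorted(
        np.linalg.norm(out.total(k)) * KJ_MOL_NM_TO_PN for k in out.entries
    )
    np.testing.assert_allclose(mags, [5.0, 5.1])


def test_threshold_removes_everything_below():
    net = _net_with_magnitudes_pn([1.0, 2.0, 4.99])
    assert nf.threshold_filter(net, 5.0).entries == {}


def test_threshold_negative_raises():
    with pytest.raises(ConfigError):
        nf.threshold_filter(nf.NetForceTable(), -1.0)


def _lh_trp_map():
    return DomainMap([("LH", "A", 1230, 1260), ("TRP", "A", 1565, 1590)])


def test_aggregate_single_pair():
    net = nf.NetForceTable()
    v = np.array([1.0, 2.0, 3.0])
    key, sign = PairForceTable.canonical(("A", 1571), ("A", 1244))
    net.entries[key] = {"coulomb": sign * v}
    per_res, total = nf.aggregate_domains(net, _lh_trp_map(), "LH", "TRP")
    np.testing.assert_allclose(per_res[("A", 1571)], v)
    np.testing.assert_allclose(total, v)


def test_aggregate_opposite_forces_cancel():
    net = nf.NetForceTable()
    v = np.array([1.0, 0.0, 0.0])
    for lh, vec in ((1244, v), (1236, -v)):
        key, sign = PairForceTable.canonical(("A", 1571), ("A", lh))
        net.entries[key] = {"coulomb": sign * vec}
    per_res, total = nf.aggregate_domains(net, _lh_trp_map(), "LH", "TRP")
    np.testing.assert_allclose(per_res[("A", 1571)], 0.0, atol=1e-15)
    np.testing.assert_allclose(total, 0.0, atol=1e-15)


def test_force_concentrates_on_two_interface_residues():
    """The generator plants the condition difference mostly on two TRP
    residues (the two major points of force application); aggregation
    must rank exactly those two on top."""
    cfg = sd.GeneratorConfig(seed=5)
    forced, free, _ = sd.make_net_force_pair(cfg)
    net = nf.net_fda(forced, free)
    dmap = _lh_trp_map()
    per_res, _ = nf.aggregate_domains(net, dmap, "LH", "TRP")
    ranked = sorted(per_res, key=lambda r: -np.linalg.norm(per_res[r]))
    assert set(ranked[:2]) == {("A", 1571), ("A", 1581)}
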