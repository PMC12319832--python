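"""Three-level binary HGF: golden trajectories, identities, symmetries."""

import numpy as np
import pytest

from mmnflow import hgf
from mmnflow.hgf import HGFParams, HGFState, filter_sequence, hgf_step

# Step-by-step trajectories for u = [1, 0, 1] with kappa=1, omega2=-2,
# omega3=-6, mu2_0=0, sigma2_0=0.1, mu3_0=1, sigma3_0=1, computed
# independently from the update equations at 50-digit precision and frozen.
GOLDEN_PARAMS = dict(kappa=1.0, omega2=-2.0, omega3=-6.0, mu2_0=0.0,
                     sigma2_0=0.1, mu3_0=1.0, sigma3_0=1.0)
GOLDEN = {
    "ehgf": [
        {"muhat1": 0.5, "pihat1": 4.0, "delta1": 0.5,
         "mu2": 0.20944139040992926, "sigma2": 0.41888278081985853,
         "pi2": 2.3873027151957631, "pihat2": 2.1373027151957631,
         "delta2": -0.010966424004211103, "mu3": 0.99567802978426616,
         "sigma3": 0.76677176766300756, "pi3": 1.3041690398276311,
         "pihat3": 0.99752737684336523, "psi2": 0.41888278081985853,
         "psi3": 1.6388233809616009, "eps2": 0.20944139040992926,
         "eps3": -0.017972032063639696, "surprise": 0.69314718055994531,
         "w2": 0.78626972848042369},
        {"muhat1": 0.55216978156576192, "pihat1": 4.044026280603237,
         "delta1": -0.55216978156576192, "mu2": -0.15361833919890577,
         "sigma2": 0.65751466619437886, "pi2": 1.5208786228113935,
         "pihat2": 1.2736003089200128, "delta2": 0.0052871536510505943,
         "mu3": 0.99662671340068701, "sigma3": 0.70987426874590372,
         "pi3": 1.4087001656879966, "pihat3": 1.2999666223279492,
         "psi2": 0.65751466619437886, "psi3": 0.90409608796915114,
         "eps2": -0.36305972960883504, "eps3": 0.0047800949324066568,
         "surprise": 0.80334109510626345, "w2": 0.46651076094655418},
        {"muhat1": 0.46167076191509123, "pihat1": 4.0236450384626902,
         "delta1": 0.53832923808490877, "mu2": 0.28585370659126606,
         "sigma2": 0.81636295170141858, "pi2": 1.2249453480414015,
         "pihat2": 0.97641447853357109, "delta2": -0.01431092089305255,
         "mu3": 0.99480194570149127, "sigma3": 0.68091808289481829,
         "pi3": 1.4686054389224826, "pihat3": 1.4037983564734486,
         "psi2": 0.81636295170141858, "psi3": 0.66485827483382293,
         "eps2": 0.43947204579017184, "eps3": -0.0095147341762382312,
         "surprise": 0.77290327849394634, "w2": 0.3579931600796405},
    ],
    "hgf": [
        {"muhat1": 0.5, "delta1": 0.5, "mu2": 0.20944139040992926,
         "mu3": 0.99669422944385649, "pi3": 1.3041690398276311,
         "eps2": 0.20944139040992926, "eps3": -0.017972032063639696,
         "surprise": 0.69314718055994531},
        {"muhat1": 0.55216978156576192, "delta1": -0.55216978156576192,
         "mu2": -0.15376253233395614, "mu3": 0.99756829019749026,
         "pi3": 1.4088189347277721, "eps2": -0.36320392274388541,
         "eps3": 0.0047676215682611246, "surprise": 0.80334109510626345},
        {"muhat1": 0.46163492566798243, "delta1": 0.53836507433201757,
         "mu2": 0.28594720244491237, "mu3": 0.9958234262103843,
         "pi3": 1.4687678923135012, "eps2": 0.43970973477886851,
         "eps3": -0.0095091595630227463, "surprise": 0.77298090445815025},
    ],
}


def random_states(rng, n):
    for _ in range(n):
        yield HGFState(mu2=rng.normal(0, 2),
                       sigma2=rng.uniform(0.01, 2.0),
                       mu3=rng.normal(0, 2),
                       sigma3=rng.uniform(0.01, 2.0))


@pytest.mark.parametrize("variant", ["ehgf", "hgf"])
def test_golden_three_trial_trajectory(variant):
    params = HGFParams(variant=variant, **GOLDEN_PARAMS)
    traj = filter_sequence(np.array([1, 0, 1]), params)
    for k, expected in enumerate(GOLDEN[variant]):
        for col, val in expected.items():
            got = traj.table.loc[k, col]
            assert got == pytest.approx(val, abs=1e-10), \
                f"{variant} trial {k} {col}: {got} vs {val}"


def test_step_basics():
    params = HGFParams()
    state = HGFState(mu2=0.0, sigma2=0.1, mu3=1.0, sigma3=1.0)
    rec, _, _ = hgf_step(state, 1, params)
    assert rec["muhat1"] == 0.5
    assert rec["pihat1"] == 4.0
    assert rec["delta1"] == 0.5
    assert rec["surprise"] == pytest.approx(np.log(2), abs=1e-12)


def test_pwpe_identities_random_steps():
    rng = np.random.default_rng(7)
    params = HGFParams()
    for state in random_states(rng, 500):
        u = int(rng.integers(2))
        rec, new, _ = hgf_step(state, u, params)
        assert rec["eps2"] == rec["psi2"] * rec["delta1"]
        assert rec["eps3"] == rec["psi3"] * rec["delta2"]
        assert 0 < rec["muhat1"] < 1
        assert -1 < rec["delta1"] < 1
        assert rec["pi2"] > 0 and rec["pi3"] > 0
        assert new.sigma2 > 0 and new.sigma3 > 0


def test_constant_input_convergence():
    traj = filter_sequence(np.ones(500, dtype=int))
    m = traj.muhat1
    assert np.all(np.diff(m[1:]) >= -1e-12)
    assert m[-1] > 0.9


def test_decoupled_top_level_with_tiny_kappa():
    u = (np.arange(200) % 2).astype(int)
    traj = filter_sequence(u, HGFParams(kappa=1e-8))
    assert np.all(np.abs(traj.mu3 - 1.0) < 1e-6)


def test_determinism():
    u = np.random.default_rng(3).integers(0, 2, 300)
    a = filter_sequence(u)
    b = filter_sequence(u)
    assert (a.table.to_numpy() == b.table.to_numpy()).all()


def test_tone_relabelling_mirror_symmetry():
    u = np.random.default_rng(11).integers(0, 2, 400)
    params = HGFParams(mu2_0=0.0)
    a = filter_sequence(u, params)
    b = filter_sequence(1 - u, params)
    np.testing.assert_allclose(a.muhat1, 1 - b.muhat1, atol=1e-12)
    np.testing.assert_allclose(a.surprise, b.surprise, atol=1e-12)


def test_mean_delta1_near_zero_for_unbiased_sequence():
    u = np.random.default_rng(5).integers(0, 2, 5000)
    traj = filter_sequence(u)
    assert abs(traj.delta1.mean()) < 3 / np.sqrt(5000)


def test_observer_beats_coin_flip_on_structured_sequences():
    from mmnflow import paradigm
    sched = paradigm.default_schedule(600)
    for seed in (0, 1):
        seq = paradigm.sample_sequence(sched, seed)
        traj = filter_sequence(seq)
        assert traj.surprise.sum() < len(seq) * np.log(2)


def test_total_surprise_agrees_with_filter():
    rng = np.random.default_rng(9)
    u = rng.integers(0, 2, 250)
    for variant in ("ehgf", "hgf"):
        for w2, w3 in [(-3, -6), (-1.5, -4), (-5, -8)]:
            p = HGFParams(omega2=w2, omega3=w3, variant=variant)
            assert hgf.total_surprise(u, p) == pytest.approx(
                filter_sequence(u, p).surprise.sum(), rel=1e-12)


def test_precision_violation_classical_variant():
    u = np.array([1] * 20 + [0] + [1] * 5 + [0] * 5, dtype=np.int8)
    params = HGFParams(omega2=-1, omega3=2, sigma3_0=0.01, variant="hgf")
    with pytest.raises(hgf.PrecisionViolation, match="trial 20"):
        filter_sequence(u, params)
    # ehgf floors the precision instead of raising
    traj = filter_sequence(u, HGFParams(omega2=-1, omega3=2, sigma3_0=0.01,
                                        variant="ehgf"))
    assert np.all(traj.pi3 > 0)
    # and the fast kernel penalises the classical case with +inf
    assert hgf.total_surprise(u, params) == np.inf


def test_psi2_convention_switch():
    u = np.random.default_rng(2).integers(0, 2, 50)
    a = filter_sequence(u, HGFParams(psi2_convention="unit_input"))
    b = filter_sequence(u, HGFParams(psi2_convention="pihat1_ratio"))
    np.testing.assert_allclose(a.psi2, 1 / a.pi2)
    np.testing.assert_allclose(b.psi2, b.pihat1 / b.pi2)
    # the non-psi2 trajectories agree between conventions
    np.testing.assert_allclose(a.mu2, b.mu2)


class TestCollinearity:
    def test_self_and_mirror(self, short_trajectories):
        t = short_trajectories
        assert hgf.regressor_collinearity(t, ("delta1", "delta1")) == \
            pytest.approx(1.0)
        t2 = t.table.copy()
        t2["neg"] = -t2["delta1"]
        traj2 = hgf.HGFTrajectories(table=t2, params=t.params)
        assert hgf.regressor_collinearity(traj2, ("delta1", "neg")) == \
            pytest.approx(-1.0)

    def test_matches_numpy_corrcoef(self, short_trajectories):
        t = short_trajectories
        r = hgf.regressor_collinearity(t, ("eps2", "eps3"))
        expected = np.corrcoef(t.eps2, t.eps3)[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)

    def test_mask_and_errors(self, short_trajectories):
        t = short_trajectories
        mask = np.zeros(len(t), bool)
        mask[:2] = True
        with pytest.raises(ValueError, match="3 retained"):
            hgf.regressor_collinearity(t, ("delta1", "psi2"), mask)
        t2 = t.table.copy()
        t2["const"] = 1.0
        traj2 = hgf.HGFTrajectories(table=t2, params=t.params)
        with pytest.raises(ValueError, match="zero variance"):
            hgf.regressor_collinearity(traj2, ("delta1", "const"))


def test_trajectory_tsv_export(tmp_path, short_trajectories):
    import json
    path = tmp_path / "traj.tsv"
    short_trajectories.to_tsv(path)
    lines = path.read_text().splitlines()
    header = json.loads(lines[0][2:])
    assert header["params"]["variant"] == "ehgf"
    assert lines[1].split("\t") == ["muhat1", "delta1", "psi2", "eps2",
                                    "delta2", "psi3", "eps3", "surprise"]
    assert len(lines) == 2 + len(short_trajectories)
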