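"""Model catalog structure and the coalescent expected-SFS engine."""
import numpy as np
import pytest

from lakestream.demographic_models import (
    Deme,
    DemographicModel,
    Pulse,
    Split,
    best_estimates,
    get_model,
    model_catalog,
    simulate_expected_sfs,
    simulate_sfs_counts,
)
from lakestream.sfs_core import fold_array


def one_deme_model(n2e=2000.0, n_diploids=2):
    return DemographicModel(
        "one", [Deme("P", "N", True, n_diploids)], [], [],
        defaults={"N": n2e}, free={"N": (100.0, 1e6)},
    )


# ---------------------------------------------------------------------------
# Catalog structure
# ---------------------------------------------------------------------------

def test_catalog_3a_has_two_split_times():
    m = get_model("3a")
    assert {s.time_param for s in m.splits} == {"T_RR", "T_WE"}
    assert {d.name for d in m.demes} == {"RHONE", "RHINE", "VISTULA"}


def test_ho_variants_have_distinct_pulse_targets():
    targets = {v: {p.dest for p in get_model(f"HO{v}x").pulses} for v in "abc"}
    assert targets["a"] == {"STREAM"}
    assert targets["b"] == {"LAKE"}
    assert targets["c"] == {"CANC"}
    # source letters select the West lineage(s)
    assert {p.source for p in get_model("HOai").pulses} == {"RHINE"}
    assert {p.source for p in get_model("HOao").pulses} == {"RHONE"}
    assert {p.source for p in get_model("HOax").pulses} == {"RHINE", "RHONE"}


def test_catalog_free_param_counts_and_validation():
    for mid, m in model_catalog().items():
        assert m.n_free_params == len(m.free)
        m.validate()  # defaults internally consistent
    with pytest.raises(KeyError, match="valid ids"):
        get_model("HOzz")


def test_best_estimate_scenarios_validate():
    for sc, e in best_estimates().items():
        get_model(e["model_id"]).validate(e["params"])


def test_yaml_round_trip(tmp_path):
    m = get_model("HOcx")
    p = tmp_path / "m.yaml"
    m.to_yaml(str(p))
    m2 = DemographicModel.from_yaml(str(p))
    assert m2.model_id == m.model_id
    assert m2.defaults == m.defaults
    assert [s.time_param for s in m2.splits] == [s.time_param for s in m.splits]
    assert [x.dest for x in m2.pulses] == [x.dest for x in m.pulses]


def test_validation_errors():
    m = get_model("HOax")
    with pytest.raises(ValueError, match=r"outside \[0, 100\]"):
        m.validate({"A_RHINE": 150.0})
    with pytest.raises(ValueError, match="activity window"):
        m.validate({"T_ADM": 2000.0, "T_LS": 1000.0})  # a-pulse after the split
    with pytest.raises(ValueError, match="must be > 0"):
        one_deme_model().validate({"N": -5.0})


# ---------------------------------------------------------------------------
# Expected SFS
# ---------------------------------------------------------------------------

def test_neutral_single_deme_sfs_is_one_over_i():
    # constant-size coalescent: E[xi_i] proportional to 1/i
    e = simulate_expected_sfs(one_deme_model(), n_sims=40_000, seed=7, folded=False)
    poly = e.probs.copy()
    poly[0] = poly[-1] = 0.0
    ratios = poly[1:4] / poly[1]
    assert np.allclose(ratios, [1.0, 0.5, 1.0 / 3.0], rtol=0.05)
    assert e.probs.sum() == pytest.approx(1.0)
    assert np.all(e.probs >= 0)


def test_folded_equals_fold_of_unfolded_same_replicates():
    m = one_deme_model()
    u = simulate_expected_sfs(m, n_sims=5000, seed=3, folded=False)
    f = simulate_expected_sfs(m, n_sims=5000, seed=3, folded=True)
    assert np.allclose(f.probs, fold_array(u.probs, u.sample_sizes))


def test_total_pulse_relabels_population():
    # B receives 100% from A just after present: B's spectrum must match a
    # single-deme model of A's size (equivalence under relabelling)
    m = DemographicModel(
        "pulse100",
        [Deme("A", "N_A", True, 0), Deme("B", "N_B", True, 2)],
        [("ROOT", "N_A")],
        [Split("T", ["A", "B"], "ROOT")],
        pulses=[Pulse("T_P", "B", "A", "A_P")],
        defaults={"N_A": 2000.0, "N_B": 50_000.0, "T": 8000.0, "T_P": 1.0, "A_P": 100.0},
        free={},
    )
    e_pulse = simulate_expected_sfs(m, sample_sizes={"B": 2}, n_sims=30_000, seed=5, folded=False)
    e_one = simulate_expected_sfs(one_deme_model(2000.0), n_sims=30_000, seed=6, folded=False)
    # compare polymorphic shapes (MC tolerance)
    a = e_pulse.probs.copy(); a[0] = a[-1] = 0
    b = e_one.probs.copy(); b[0] = b[-1] = 0
    assert np.allclose(a / a.sum(), b / b.sum(), atol=0.02)


def test_no_gene_flow_marginal_factorizes():
    # the RHONE marginal of model 3a equals a single lineage with the same
    # size history (deme -> West ancestor -> root), since there is no gene flow
    entry = best_estimates()["3pop"]
    m3a = get_model("3a")
    e3 = simulate_expected_sfs(m3a, entry["params"], {"RHONE": 4}, n_sims=30_000, seed=11, folded=True)
    collapsed = DemographicModel(
        "rhone_line",
        [Deme("RHONE", "N_RHONE", True, 4)],
        [("PANC", "N_WANC"), ("ROOT", "N_ROOT")],
        [Split("T_RR", ["RHONE"], "PANC"), Split("T_WE", ["PANC"], "ROOT")],
        defaults={k: entry["params"][k] for k in ("N_RHONE", "N_WANC", "N_ROOT", "T_RR", "T_WE")},
    )
    e1 = simulate_expected_sfs(collapsed, n_sims=30_000, seed=12, folded=True)
    assert np.allclose(e3.probs, e1.probs, atol=3e-4)


def test_deep_split_concentrates_on_fixed_differences():
    # two demes, no migration, very old split: polymorphic mass concentrates
    # on opposite-corner fixed differences (folded: the (2n1, 0) cell family)
    m = DemographicModel(
        "deep",
        [Deme("A", "N", True, 2), Deme("B", "N", True, 2)],
        [("ROOT", "N")],
        [Split("T", ["A", "B"], "ROOT")],
        defaults={"N": 1000.0, "T": 500_000.0},
    )
    e = simulate_expected_sfs(m, n_sims=20_000, seed=1, folded=True)
    poly = e.probs.copy()
    poly[0, 0] = 0.0
    fixed_diff = poly[4, 0] + poly[0, 4]
    assert fixed_diff / poly.sum() > 0.9


def test_more_sims_reduce_monte_carlo_error():
    m = one_deme_model()
    def batch_sd(n_sims, seeds):
        probs = [simulate_expected_sfs(m, n_sims=n_sims, seed=s, folded=False).probs[1]
                 for s in seeds]
        return np.std(probs)
    sd_small = batch_sd(400, range(1, 9))
    sd_large = batch_sd(3200, range(11, 19))
    # 8x the replicates: expect ~1/sqrt(8) = 0.35x the error (allow slack)
    assert sd_large < 0.7 * sd_small


def test_simulate_sfs_counts_total_and_determinism():
    m = one_deme_model()
    s1 = simulate_sfs_counts(m, n_sites=10_000, n_sims=2000, seed=4)
    s2 = simulate_sfs_counts(m, n_sites=10_000, n_sims=2000, seed=4)
    assert s1.total_sites == 10_000
    assert np.array_equal(s1.counts, s2.counts)
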