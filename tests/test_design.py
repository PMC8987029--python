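import itertools

import numpy as np
import pytest

from metalswitch import (
    ConfigError,
    DesignConfig,
    DomainDefinition,
    count_double_variants,
    load_two_state,
    select_pairs,
)
from metalswitch.design import load_design_config
from metalswitch.sasa import relative_sasa, shrake_rupley_sasa
from metalswitch.structures import cbeta_distance_matrix

from conftest import two_state_ensemble

DOMS_AB = [DomainDefinition("left", [("A", 1, 999)]),
           DomainDefinition("right", [("B", 1, 999)])]


def _toy_ensemble():
    """Pair 1 (A:1, B:1): 10.5 Å closed, 14.0 Å open.  Pair 2 (A:2, B:2): 5.0 Å
    closed — inside no window.  Residues are far apart so all are exposed."""
    chains = ["A", "B", "A", "B"]
    numbers = [1, 1, 2, 2]
    closed = [(0, 0, 0), (10.5, 0, 0), (0, 60, 0), (5.0, 60, 0)]
    opened = [(0, 0, 0), (14.0, 0, 0), (0, 60, 0), (5.0, 60, 0)]
    return two_state_ensemble(closed, opened, chain_ids=chains, numbers=numbers)


def test_select_pairs_toy_selected_and_rejected():
    pairs = select_pairs(_toy_ensemble(), DOMS_AB, DesignConfig())
    assert len(pairs) == 1
    p = pairs[0]
    assert (p.site_i.key, p.site_j.key) == (("A", 1), ("B", 1))
    assert p.delta_distance == pytest.approx(3.5)
    assert p.d_closed == pytest.approx(10.5)
    assert p.rank == 1


def test_window_predicate_rejects_regardless_of_other_properties():
    # widen everything except the window: the 5.0 A pair must stay out
    cfg = DesignConfig(min_delta_distance=0.0, min_relative_sasa=0.0)
    pairs = select_pairs(_toy_ensemble(), DOMS_AB, cfg)
    assert all(p.d_closed >= cfg.window[0] for p in pairs)
    assert ("A", 2) not in {p.site_i.key for p in pairs}


def test_exposure_predicate():
    # a single bare carbon has rel SASA ~0.94 vs the ALA reference
    assert select_pairs(_toy_ensemble(), DOMS_AB, DesignConfig(min_relative_sasa=0.95)) == []


def test_cross_domain_predicate():
    ens = _toy_ensemble()
    one_domain = [DomainDefinition("all", [("A", 1, 999), ("B", 1, 999)])]
    assert select_pairs(ens, one_domain, DesignConfig()) == []


def test_uncovered_residue_is_config_error():
    with pytest.raises(ConfigError, match="not covered"):
        select_pairs(_toy_ensemble(), [DomainDefinition("left", [("A", 1, 999)])],
                     DesignConfig())


def test_missing_label_is_config_error():
    with pytest.raises(ConfigError, match="missing_label"):
        select_pairs(_toy_ensemble(), DOMS_AB, DesignConfig(open_label="missing_label"))


def test_same_label_for_both_states_gives_empty_output():
    cfg = DesignConfig(open_label="closed", min_delta_distance=2.0)
    assert select_pairs(_toy_ensemble(), DOMS_AB, cfg) == []


def brute_force_pairs(ens, domains, cfg):
    """Exhaustive four-predicate filter over all C(n,2) pairs, plain loops."""
    sites = ens.representative(cfg.closed_label).sites
    n = len(sites)

    def mean_mat(label):
        mats = [cbeta_distance_matrix(f) for f in ens.frames(label)]
        return sum(mats) / len(mats)

    d_c, d_o = mean_mat(cfg.closed_label), mean_mat(cfg.open_label)
    rel = np.zeros(n)
    for f in ens.frames(cfg.closed_label):
        sasa = shrake_rupley_sasa(f, cfg.sasa_probe_radius, cfg.sasa_points)
        rel += [relative_sasa(a, s.residue_name) for a, s in zip(sasa, f.sites)]
    rel /= ens.frame_count(cfg.closed_label)

    def domain(site):
        hits = [d.name for d in domains if d.contains(site.chain_id, site.residue_number)]
        assert len(hits) == 1
        return hits[0]

    lo, hi = cfg.window
    selected = []
    for i, j in itertools.combinations(range(n), 2):
        if not (lo <= d_c[i, j] <= hi):
            continue
        if rel[i] < cfg.min_relative_sasa or rel[j] < cfg.min_relative_sasa:
            continue
        if abs(d_o[i, j] - d_c[i, j]) < cfg.min_delta_distance:
            continue
        if domain(sites[i]) == domain(sites[j]):
            continue
        a, b = sorted((sites[i].key, sites[j].key))
        selected.append((a, b, abs(d_o[i, j] - d_c[i, j])))
    selected.sort(key=lambda t: (-t[2], t[0], t[1]))
    return selected


def test_select_pairs_equals_exhaustive_oracle_on_fixture(hinge_fixture):
    ens = load_two_state(hinge_fixture.closed_path, hinge_fixture.open_path)
    doms = [DomainDefinition("propeller", [("A", 1, 40)]),
            DomainDefinition("peptidase", [("B", 1, 40)])]
    cfg = DesignConfig(distance_halfwidth=1.0)
    got = [(p.site_i.key, p.site_j.key, p.delta_distance) for p in select_pairs(ens, doms, cfg)]
    expected = brute_force_pairs(ens, doms, cfg)
    assert [(a, b) for a, b, _ in got] == [(a, b) for a, b, _ in expected]
    assert np.allclose([d for *_, d in got], [d for *_, d in expected])


def test_ranks_are_a_permutation_sorted_by_delta(hinge_fixture):
    ens = load_two_state(hinge_fixture.closed_path, hinge_fixture.open_path)
    doms = [DomainDefinition("a", [("A", 1, 40)]), DomainDefinition("b", [("B", 1, 40)])]
    pairs = select_pairs(ens, doms, DesignConfig(distance_halfwidth=1.0))
    assert [p.rank for p in pairs] == list(range(1, len(pairs) + 1))
    deltas = [p.delta_distance for p in pairs]
    assert deltas == sorted(deltas, reverse=True)


@pytest.mark.parametrize(
    "tighter",
    [dict(distance_halfwidth=0.5), dict(min_delta_distance=4.0),
     dict(min_relative_sasa=0.6)],
)
def test_tightening_any_threshold_never_adds_pairs(hinge_fixture, tighter):
    ens = load_two_state(hinge_fixture.closed_path, hinge_fixture.open_path)
    doms = [DomainDefinition("a", [("A", 1, 40)]), DomainDefinition("b", [("B", 1, 40)])]
    base_cfg = dict(distance_halfwidth=1.0, min_delta_distance=2.0, min_relative_sasa=0.2)
    loose = {(p.site_i.key, p.site_j.key)
             for p in select_pairs(ens, doms, DesignConfig(**base_cfg))}
    tight = {(p.site_i.key, p.site_j.key)
             for p in select_pairs(ens, doms, DesignConfig(**(base_cfg | tighter)))}
    assert tight <= loose


def test_output_invariant_to_residue_order():
    ens = _toy_ensemble()
    perm = [2, 0, 3, 1]
    chains = ["A", "B", "A", "B"]
    numbers = [1, 1, 2, 2]
    closed = [(0, 0, 0), (10.5, 0, 0), (0, 60, 0), (5.0, 60, 0)]
    opened = [(0, 0, 0), (14.0, 0, 0), (0, 60, 0), (5.0, 60, 0)]
    shuffled = two_state_ensemble(
        [closed[i] for i in perm], [opened[i] for i in perm],
        chain_ids=[chains[i] for i in perm], numbers=[numbers[i] for i in perm],
    )
    a = [(p.site_i.key, p.site_j.key) for p in select_pairs(ens, DOMS_AB, DesignConfig())]
    b = [(p.site_i.key, p.site_j.key) for p in select_pairs(shuffled, DOMS_AB, DesignConfig())]
    assert a == b


def test_count_double_variants():
    assert count_double_variants(616) == 189_420
    assert count_double_variants(2) == 1
    assert count_double_variants(10) == len(list(itertools.combinations(range(10), 2)))
    with pytest.raises(ValueError):
        count_double_variants(1)


def test_config_loader_roundtrip_and_validation(tmp_path):
    good = tmp_path / "design.yaml"
    good.write_text(
        "design:\n  distance_halfwidth: 1.0\n  min_delta_distance: 1.5\n"
        "domains:\n  - name: left\n    ranges: [[A, 1, 40]]\n"
        "  - name: right\n    ranges: [[B, 1, 40]]\n"
    )
    cfg, doms = load_design_config(good)
    assert cfg.window == (9.5, 11.5)
    assert cfg.min_delta_distance == 1.5
    assert [d.name for d in doms] == ["left", "right"]

    bad = tmp_path / "bad.yaml"
    bad.write_text("design:\n  not_a_key: 1\ndomains:\n  - name: a\n    ranges: [[A, 1, 2]]\n")
    with pytest.raises(ConfigError, match="not_a_key"):
        load_design_config(bad)


def test_paper_window_preset():
    cfg = DesignConfig.paper_window()
    assert cfg.window == (9.5, 11.5)
    assert DesignConfig().window == (10.0, 11.0)
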