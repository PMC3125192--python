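import numpy as np
import pandas as pd
import pytest

from afas_screen.io_model import DataError, ScreenParams
from afas_screen.screens import (
    PairProfile,
    afas_dominant_pairs,
    balance_reversal_screen,
    build_pair_profiles,
    cancer_normal_ratio,
    cdna_pair_screen,
    concerted_change_count,
    direction_concordance,
    fold_change_screen,
    priming_correlation,
)
from afas_screen.synthetic_data import SimulationConfig, simulate_dataset

from conftest import (
    bf_balance_screen,
    bf_concerted,
    bf_dominant,
    bf_fold_screen,
    bf_pearson,
    random_pairs,
)


def const_pair(sc, sn, ac, an, n=6, pid="G000-01"):
    return PairProfile(
        gene_id=pid.rsplit("-", 1)[0],
        sense_probe_id=pid.rsplit("-", 1)[0] + "-S",
        afas_probe_id=pid,
        patients=list(range(1, n + 1)),
        sense_cancer=np.full(n, float(sc)),
        sense_normal=np.full(n, float(sn)),
        afas_cancer=np.full(n, float(ac)),
        afas_normal=np.full(n, float(an)),
    )


# -- cancer/normal ratio ----------------------------------------------------


def test_ratio_examples(params, small_dataset):
    m, ann, _ = small_dataset
    pid = ann.afas["probe_id"].iloc[0]
    cancer = m.select("cancer", "random").loc[pid]
    normal = m.select("normal", "random").loc[pid]
    expected = max(np.median(cancer), 1.0) / max(np.median(normal), 1.0)
    assert cancer_normal_ratio(pid, m, params) == pytest.approx(expected)


def test_ratio_floor_engaged(params):
    from conftest import full_design, make_matrix

    keys = full_design(1)
    m = make_matrix({"A": [100.0, 100.0, 0.0, 0.0]}, keys)  # normal arrays 100, cancer 0
    assert cancer_normal_ratio("A", m, params, priming="random") == pytest.approx(0.01)


def test_ratio_missing_probe_errors(params, small_dataset):
    m, _, _ = small_dataset
    with pytest.raises(DataError, match="absent"):
        cancer_normal_ratio("nope", m, params)


# -- balance reversal -------------------------------------------------------


def test_full_support_pair(params):
    pair = const_pair(200, 100, 100, 200)
    res = balance_reversal_screen([pair], params, "sense_up_afas_down")
    assert len(res) == 1
    assert res[0].support == 6
    assert res[0].direction == "sense_up_afas_down"


def test_nine_percent_change_fails_condition(params):
    # sense cancer 109 vs normal 100: a 9% change < 10% margin
    pair = const_pair(109, 100, 50, 200)
    assert balance_reversal_screen([pair], params, "sense_up_afas_down") == []


def test_exact_ten_percent_inclusive(params):
    pair = const_pair(110.0, 100.0, 100.0, 110.0)
    res = balance_reversal_screen([pair], params, "sense_up_afas_down")
    assert len(res) == 1


def test_opposite_direction_mirror(params):
    pair = const_pair(100, 200, 200, 100)
    assert balance_reversal_screen([pair], params, "sense_up_afas_down") == []
    res = balance_reversal_screen([pair], params, "sense_down_afas_up")
    assert len(res) == 1 and res[0].support == 6


def test_balance_screen_matches_enumeration(params):
    rng = np.random.default_rng(0)
    for rep in range(10):
        pairs = random_pairs(rng, 50)
        for direction in ("sense_up_afas_down", "sense_down_afas_up"):
            got = {r.afas_probe_id for r in balance_reversal_screen(pairs, params, direction)}
            assert got == bf_balance_screen(pairs, params, direction)


def test_margin_monotone_nesting(params):
    rng = np.random.default_rng(1)
    pairs = random_pairs(rng, 200, scale=10.0)
    sets = []
    for margin in (0.10, 0.20, 0.30):
        p = ScreenParams(margin=margin)
        sets.append({r.afas_probe_id for r in balance_reversal_screen(pairs, p, "sense_up_afas_down")})
    assert sets[2] <= sets[1] <= sets[0]


def test_incomplete_pair_skipped(params, small_dataset, caplog):
    m, ann, _ = small_dataset
    m2 = m.copy()
    victim = ann.afas["probe_id"].iloc[0]
    m2.values.loc[victim, m2.sample_ids[3]] = np.nan
    with caplog.at_level("INFO", logger="afas_screen"):
        pairs = build_pair_profiles(m2, ann, params, "random")
    assert victim not in {p.afas_probe_id for p in pairs}
    assert any("missing" in r.message for r in caplog.records)


# -- relaxed preset ---------------------------------------------------------


def test_cdna_preset_reports_without_dominance(params):
    # sense up 50%, afas down 50%, but sense NEVER above afas in cancer
    pair = const_pair(sc=150, sn=100, ac=1000, an=2000)
    assert balance_reversal_screen([pair], params, "sense_up_afas_down") == []
    res = cdna_pair_screen([pair], params)
    assert len(res) == 1 and res[0].support == 6


def test_cdna_boundary_inclusive(params):
    pair = const_pair(sc=110, sn=100, ac=100, an=110)
    res = cdna_pair_screen([pair], params)
    assert len(res) == 1


def test_cdna_empty_when_no_support(params):
    pair = const_pair(100, 100, 100, 100)
    assert cdna_pair_screen([pair], params) == []


def test_cdna_union_deduplicated(params):
    rng = np.random.default_rng(2)
    pairs = random_pairs(rng, 100)
    res = cdna_pair_screen(pairs, params)
    ids = [r.afas_probe_id for r in res]
    assert len(ids) == len(set(ids))
    expected = bf_balance_screen(pairs, params, "sense_up_afas_down", False) | bf_balance_screen(
        pairs, params, "sense_down_afas_up", False
    )
    assert set(ids) == expected


# -- fold change ------------------------------------------------------------


def test_fold_strictness(params):
    m, ann, _ = simulate_dataset(SimulationConfig(n_genes=10, seed=0))
    # constant pairs: ratio exactly 2 is in neither list
    up, down = fold_change_screen(m, ann, params)
    ratios = {pid: cancer_normal_ratio(pid, m, params) for pid in ann.afas["probe_id"]}
    for pid, r in ratios.items():
        assert (pid in up) == (r > 2.0)
        assert (pid in down) == (r < 0.5)
    assert not (set(up) & set(down))


def test_fold_boundary_exact():
    from conftest import full_design, make_matrix
    from afas_screen.io_model import ProbeAnnotation

    keys = full_design(1)
    # columns: normal dT, normal random, cancer dT, cancer random
    m = make_matrix(
        {"g-01": [0, 100, 0, 200], "g-02": [0, 100, 0, 201], "g-03": [0, 100, 0, 49]},
        keys,
    )
    ann = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": ["g-01", "g-02", "g-03"],
                "gene_id": ["g"] * 3,
                "probe_class": ["afas"] * 3,
                "afas_index": [1, 2, 3],
                "truncated": [False] * 3,
            }
        )
    )
    up, down = fold_change_screen(m, ann, ScreenParams())
    assert up == ["g-02"]  # 2.01 up; 2.0 excluded (strict)
    assert down == ["g-03"]  # 0.49 down


def test_fold_invariant_under_global_rescale(params):
    m, ann, _ = simulate_dataset(SimulationConfig(n_genes=20, seed=4))
    up1, down1 = fold_change_screen(m, ann, params)
    m2 = m.copy()
    m2.values *= 7.0
    up2, down2 = fold_change_screen(m2, ann, params)
    assert (up1, down1) == (up2, down2)


def test_fold_matches_enumeration(params):
    rng = np.random.default_rng(3)
    pairs = random_pairs(rng, 80)
    from afas_screen.screens import count_fold, _stack

    sc, sn, ac, an = _stack(pairs)
    bf_up, bf_down = bf_fold_screen(pairs, params)
    assert count_fold(ac, an, params, "up") == len(bf_up)
    assert count_fold(ac, an, params, "down") == len(bf_down)


# -- dominance --------------------------------------------------------------


def test_dominance_inclusive_boundary(params):
    pair = const_pair(sc=100, sn=100, ac=300, an=300)
    assert len(afas_dominant_pairs([pair], params)) == 1


def test_dominance_one_tissue_only_excluded(params):
    pair = const_pair(sc=100, sn=100, ac=300, an=100)
    assert afas_dominant_pairs([pair], params) == []


def test_dominance_matches_enumeration(params):
    rng = np.random.default_rng(4)
    pairs = random_pairs(rng, 120)
    got = {p.afas_probe_id for p in afas_dominant_pairs(pairs, params)}
    assert got == bf_dominant(pairs, params)


# -- concerted change -------------------------------------------------------


def test_concerted_observed_count(params):
    pairs = [
        const_pair(200, 100, 200, 100),  # both up
        const_pair(200, 100, 50, 100),  # discordant
        const_pair(50, 100, 50, 100),  # both down
        const_pair(50, 100, 200, 100),  # discordant
    ]
    observed, _ = concerted_change_count(pairs, params)
    assert observed == 2


def test_concerted_expected_closed_form(params):
    # marginals 0.6 up sense, 0.7 up afas over 10 pairs -> 10*(0.42+0.12)=5.4
    pairs = []
    for i in range(10):
        s_up = i < 6
        a_up = i < 7
        pairs.append(
            const_pair(200 if s_up else 50, 100, 200 if a_up else 50, 100, pid=f"G{i:03d}-01")
        )
    _, expected = concerted_change_count(pairs, params)
    assert expected == pytest.approx(5.4)


def test_concerted_symmetric_marginals(params):
    pairs = []
    for i in range(100):
        s_up = i % 2 == 0
        a_up = (i // 2) % 2 == 0
        pairs.append(
            const_pair(200 if s_up else 50, 100, 200 if a_up else 50, 100, pid=f"G{i:03d}-01")
        )
    _, expected = concerted_change_count(pairs, params)
    assert expected == pytest.approx(50.0)


def test_concerted_ties_excluded(params):
    pairs = [const_pair(100, 100, 200, 100), const_pair(200, 100, 200, 100)]
    observed, expected = concerted_change_count(pairs, params)
    assert observed == 1  # tied pair dropped


def test_concerted_matches_enumeration(params):
    rng = np.random.default_rng(5)
    pairs = random_pairs(rng, 150)
    got = concerted_change_count(pairs, params)
    exp = bf_concerted(pairs, params)
    assert got[0] == exp[0]
    assert got[1] == pytest.approx(exp[1])


# -- priming correlation ----------------------------------------------------


def test_priming_correlation_identical_vectors(small_dataset):
    m, ann, _ = small_dataset
    m2 = m.copy()
    # copy random-priming data onto the oligo-dT columns -> r = 1 everywhere
    for k, sid in zip(m2.samples, m2.sample_ids):
        if k.priming == "oligo_dT":
            twin = [
                s for kk, s in zip(m2.samples, m2.sample_ids)
                if kk.patient_id == k.patient_id and kk.tissue == k.tissue and kk.priming == "random"
            ][0]
            m2.values[sid] = m2.values[twin]
    series, mean = priming_correlation(m2, ann, "sense")
    assert np.allclose(series.to_numpy(), 1.0)
    assert mean == pytest.approx(1.0)


def test_priming_correlation_matches_formula(small_dataset):
    m, ann, _ = small_dataset
    series, mean = priming_correlation(m, ann, "afas")
    frames = {
        pr: pd.concat([m.select(t, pr) for t in ("normal", "cancer")], axis=1)
        for pr in ("oligo_dT", "random")
    }
    for pid in list(series.index)[:20]:
        a = list(frames["oligo_dT"].loc[pid])
        b = list(frames["random"].loc[pid])
        assert series[pid] == pytest.approx(bf_pearson(a, b), abs=1e-12)
    assert mean == pytest.approx(series.mean())


def test_priming_correlation_negation():
    from conftest import full_design, make_matrix
    from afas_screen.io_model import ProbeAnnotation

    keys = full_design(3)
    # dT value x, random value 20 - x: exact negation around the mean -> r = -1
    dt_vals = [3.0, 7.0, 11.0, 5.0, 9.0, 1.0]
    row = []
    i = 0
    for k in keys:
        if k.priming == "oligo_dT":
            row.append(dt_vals[i])
        else:
            row.append(20.0 - dt_vals[i])
            i += 1
    m = make_matrix({"g-S": row}, keys)
    ann = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": ["g-S"],
                "gene_id": ["g"],
                "probe_class": ["sense"],
                "afas_index": [pd.NA],
                "truncated": [False],
            }
        )
    )
    series, mean = priming_correlation(m, ann, "sense")
    assert mean == pytest.approx(-1.0)


# -- direction concordance --------------------------------------------------


def test_concordance_full_agreement():
    ref = {f"g{i}": "up" for i in range(14)}
    res = direction_concordance(ref, dict(ref))
    assert (res.n_agree_up, res.n_total_up) == (14, 14)
    assert (res.n_agree_down, res.n_total_down) == (0, 0)


def test_concordance_mixed():
    res = direction_concordance({"A": "up", "B": "down"}, {"A": "up", "B": "up"})
    assert (res.n_agree_up, res.n_total_up, res.n_agree_down, res.n_total_down) == (1, 1, 0, 1)


def test_concordance_unmatched_reported():
    res = direction_concordance({"A": "up", "B": "down"}, {"A": "up"})
    assert res.unmatched == ["B"]
    assert res.n_total_down == 0


def test_concordance_matches_enumeration():
    rng = np.random.default_rng(6)
    genes = [f"g{i}" for i in range(50)]
    ref = {g: ("up" if rng.random() < 0.5 else "down") for g in genes}
    obs = {g: ("up" if rng.random() < 0.5 else "down") for g in genes if rng.random() < 0.9}
    res = direction_concordance(ref, obs)
    agree_up = sum(1 for g in genes if g in obs and ref[g] == "up" and obs[g] == "up")
    total_up = sum(1 for g in genes if g in obs and ref[g] == "up")
    agree_down = sum(1 for g in genes if g in obs and ref[g] == "down" and obs[g] == "down")
    total_down = sum(1 for g in genes if g in obs and ref[g] == "down")
    assert (res.n_agree_up, res.n_total_up, res.n_agree_down, res.n_total_down) == (
        agree_up,
        total_up,
        agree_down,
        total_down,
    )


def test_concordance_bad_direction_rejected():
    with pytest.raises(DataError):
        direction_concordance({"A": "sideways"}, {"A": "up"})


# -- pairing rule -----------------------------------------------------------


def test_every_afas_probe_pairs_with_single_sense(small_dataset, params):
    m, ann, _ = small_dataset
    pairs = build_pair_profiles(m, ann, params, "random")
    sense_of = ann.sense_probe_of()
    assert len(pairs) == len(ann.afas)
    for p in pairs:
        assert p.sense_probe_id == sense_of[p.gene_id]


def test_mixed_mode_uses_dt_for_sense(small_dataset, params):
    m, ann, _ = small_dataset
    mixed = build_pair_profiles(m, ann, params, "mixed")
    dt = m.select("cancer", "oligo_dT")
    rnd = m.select("cancer", "random")
    p = mixed[0]
    assert np.allclose(p.sense_cancer, dt.loc[p.sense_probe_id].to_numpy())
    assert np.allclose(p.afas_cancer, rnd.loc[p.afas_probe_id].to_numpy())
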