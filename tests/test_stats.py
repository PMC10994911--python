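"""Covariate-adjusted tests, permutation inference, edge labeling, mediation."""

import numpy as np
import pandas as pd
import pytest

from suscnet import (
    CohortDesign,
    adjusted_group_test,
    label_edges_by_network,
    mediation,
    permutation_test,
)
from suscnet.errors import CatalogError, CollinearityError, ModelError, ParameterError


def _design(rng, n_per_group=20, groups=("HC", "PAT"), age_by_group=None):
    rows = []
    for g in groups:
        for i in range(n_per_group):
            age = rng.normal(70, 6)
            if age_by_group:
                age = rng.normal(age_by_group[g], 3)
            rows.append(
                {
                    "subject_id": f"{g}{i}",
                    "group": g,
                    "age": age,
                    "gender": "F" if rng.random() < 0.5 else "M",
                    "education": rng.normal(12, 3),
                }
            )
    return CohortDesign(table=pd.DataFrame(rows))


def test_null_two_group_test_is_calibrated(rng):
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        design = _design(rng)
        values = rng.normal(size=40)
        _, p = adjusted_group_test(values, design)
        hits += p < 0.05
    assert 0.02 <= hits / n_rep <= 0.09


def test_planted_shift_gives_power(rng):
    hits = 0
    for _ in range(200):
        design = _design(rng, n_per_group=30)
        shift = (design.table["group"] == "PAT").to_numpy(float) * 2.0
        values = rng.normal(size=60) + shift
        _, p = adjusted_group_test(values, design)
        hits += p < 0.01
    assert hits >= 190  # >= 95% power


def test_age_confound_is_absorbed_by_adjustment(rng):
    design = _design(rng, n_per_group=30, age_by_group={"HC": 60, "PAT": 75})
    # the "group effect" is pure age
    values = 0.1 * design.table["age"].to_numpy() + rng.normal(0, 0.1, 60)
    t_adj, p_adj = adjusted_group_test(values, design)
    t_raw, p_raw = adjusted_group_test(values, design, covariates=("education",))
    assert p_adj > 0.01  # adjusted: no residual group effect
    assert p_raw < 1e-6  # unadjusted-for-age: spurious effect
    assert p_adj / p_raw > 1e3


def test_three_group_test_returns_f(rng):
    design = _design(rng, groups=("A", "B", "C"))
    f, p = adjusted_group_test(rng.normal(size=60), design)
    assert f >= 0 and 0 < p <= 1


def test_collinear_design_raises(rng):
    design = _design(rng)
    design.table["education"] = design.table["age"] * 2.0
    with pytest.raises(CollinearityError):
        adjusted_group_test(rng.normal(size=40), design)


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def test_constant_feature_has_p_one(rng):
    design = _design(rng, n_per_group=10)
    y = np.column_stack([np.full(20, 3.0), rng.normal(size=20)])
    res = permutation_test(y, design, n_perm=200, seed=0, alpha=0.05)
    assert res.p_perm[0] == 1.0


def test_minimum_p_is_one_over_nperm_plus_one(rng):
    design = _design(rng, n_per_group=15)
    effect = (design.table["group"] == "PAT").to_numpy(float) * 10.0
    y = (effect + rng.normal(0, 0.1, 30))[:, None]
    res = permutation_test(y, design, n_perm=199, seed=1, alpha=0.05)
    assert res.p_perm[0] == pytest.approx(1.0 / 200.0)
    assert np.all(res.p_perm >= 1.0 / 200.0)


def test_permutation_p_invariant_to_group_relabeling(rng):
    design = _design(rng, n_per_group=12)
    y = rng.normal(size=(24, 5))
    res1 = permutation_test(y, design, n_perm=300, seed=3)
    relabeled = CohortDesign(
        table=design.table.assign(
            group=design.table["group"].map({"HC": "zzz", "PAT": "aaa"})
        )
    )
    res2 = permutation_test(y, relabeled, n_perm=300, seed=3)
    np.testing.assert_allclose(res1.p_perm, res2.p_perm)


def test_too_few_permutations_raise_or_warn(rng):
    design = _design(rng, n_per_group=10)
    y = rng.normal(size=(20, 2))
    with pytest.raises(ParameterError):
        permutation_test(y, design, n_perm=50)
    with pytest.warns(UserWarning, match="cannot resolve"):
        permutation_test(y, design, n_perm=100, alpha=0.001)


# ---------------------------------------------------------------------------
# Edge labeling
# ---------------------------------------------------------------------------

def test_edge_labels_and_counts():
    partition = {1: "DMN", 2: "DMN", 3: "VN", 4: "SN"}
    edges = [(1, 2), (1, 3), (3, 1), (2, 4), (3, 4)]
    labels, counts = label_edges_by_network(edges, partition)
    assert labels[0] == "DMN-DMN"
    assert labels[1] == labels[2] == "DMN-VN"
    assert counts.sum() == len(edges)
    assert counts["DMN-VN"] == 2
    with pytest.raises(CatalogError):
        label_edges_by_network([(1, 9)], partition)


# ---------------------------------------------------------------------------
# Mediation
# ---------------------------------------------------------------------------

def test_mediation_paths_decompose_exactly(rng):
    n = 100
    x = rng.normal(size=n)
    m = 0.5 * x + rng.normal(0, 1, n)
    y = 0.4 * m + 0.3 * x + rng.normal(0, 1, n)
    cov = rng.normal(size=(n, 2))
    res = mediation(x, m, y, covariates=cov, n_boot=200, seed=0)
    assert res.indirect == pytest.approx(res.a * res.b)
    assert res.a * res.b + res.c_prime == pytest.approx(res.c, abs=1e-10)
    assert res.ci_low <= res.ci_high


def test_full_mediation_construction(rng):
    n = 150
    x = rng.normal(size=n)
    m = 1.2 * x + rng.normal(0, 0.3, n)
    y = m.copy()  # y is exactly the mediator
    res = mediation(x, m, y, n_boot=200, seed=1)
    assert res.c_prime == pytest.approx(0.0, abs=1e-10)
    assert res.indirect == pytest.approx(res.c, abs=1e-10)


def test_planted_indirect_effect_is_recovered(rng):
    n = 200
    x = rng.normal(size=n)
    m = 0.5 * x + rng.normal(0, 1, n)
    y = 0.5 * m + rng.normal(0, 1, n)
    res = mediation(x, m, y, n_boot=1000, seed=2)
    assert 0.15 <= res.indirect <= 0.35
    assert res.ci_low > 0  # CI excludes zero for this seeded draw


def test_null_indirect_ci_usually_covers_zero(rng):
    covered = 0
    n_rep = 30
    for i in range(n_rep):
        n = 50
        x = rng.normal(size=n)
        m = rng.normal(size=n)  # a = 0
        y = 0.5 * m + rng.normal(size=n)
        res = mediation(x, m, y, n_boot=500, seed=100 + i)
        covered += res.ci_low <= 0.0 <= res.ci_high
    assert covered >= 25


def test_mediation_agrees_with_pingouin_oracle(rng):
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    n = 200
    x = rng.normal(size=n)
    m = 0.5 * x + rng.normal(size=n)
    y = 0.5 * m + 0.2 * x + rng.normal(size=n)
    table = pingouin.mediation_analysis(
        data=pd.DataFrame({"X": x, "M": m, "Y": y}), x="X", m="M", y="Y",
        n_boot=5000, seed=42,
    ).set_index("path")
    mine = mediation(x, m, y, n_boot=5000, seed=42)
    assert mine.indirect == pytest.approx(table.loc["Indirect", "coef"], abs=1e-9)
    assert mine.c == pytest.approx(table.loc["Total", "coef"], abs=1e-9)
    assert mine.c_prime == pytest.approx(table.loc["Direct", "coef"], abs=1e-9)
    # CIs use independent bootstrap streams; agree to Monte-Carlo accuracy
    assert mine.ci_low == pytest.approx(table.loc["Indirect", "CI2.5"], abs=0.03)
    assert mine.ci_high == pytest.approx(table.loc["Indirect", "CI97.5"], abs=0.03)


def test_mediation_input_validation(rng):
    with pytest.raises(ModelError):
        mediation(np.ones(30), rng.normal(size=30), rng.normal(size=30))
    with pytest.raises(ModelError):
        mediation(rng.normal(size=10), rng.normal(size=10), rng.normal(size=10))
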