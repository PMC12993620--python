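import math

import numpy as np
import pytest
from scipy import stats

from rivertide import abundance as ab
from rivertide import temporal as tmp
from rivertide.core_io import AbundanceMatrix, Compartment, SampleRecord, ValidationError


def presence_of(counts, n):
    present = np.zeros((len(counts), n), dtype=bool)
    for i, c in enumerate(counts):
        present[i, :c] = True
    return ab.PresenceMatrix(
        [f"g{i}" for i in range(len(counts))], [f"s{j}" for j in range(n)], present
    )


@pytest.mark.parametrize(
    "n_det,n,expected",
    [
        (13, 17, "persistent"),  # 0.765
        (12, 16, "persistent"),  # exactly 0.75, inclusive
        (4, 16, "ephemeral"),  # exactly 0.25, inclusive
        (5, 16, "intermittent"),
        (11, 16, "intermittent"),
    ],
)
def test_persistence_boundaries(n_det, n, expected):
    (call,) = tmp.classify_persistence(presence_of([n_det], n), "SW")
    assert call.persistence_class == expected
    assert call.fraction == pytest.approx(n_det / n)


def test_persistence_matches_brute_force_everywhere():
    """Exhaustive check over all detection counts at n = 4..20."""
    for n in range(4, 21):
        calls = tmp.classify_persistence(presence_of(list(range(1, n + 1)), n), "PW")
        for call in calls:
            frac = call.n_detected / n
            if frac >= 0.75:
                expected = "persistent"
            elif frac <= 0.25:
                expected = "ephemeral"
            else:
                expected = "intermittent"
            assert call.persistence_class == expected


def test_persistence_rejects_zero_detections():
    with pytest.raises(ValidationError, match="zero detections"):
        tmp.classify_persistence(presence_of([0], 8), "SW")


def _tmm_matrix(rows):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return AbundanceMatrix(
        genome_ids=[f"g{i}" for i in range(rows.shape[0])],
        sample_ids=[f"s{j}" for j in range(rows.shape[1])],
        values=rows,
        state="tmm",
        norm_factors=np.ones(rows.shape[1]),
        library_sizes=np.ones(rows.shape[1]),
    )


def _persistent_calls(matrix, compartment="SW"):
    return [
        tmp.PersistenceCall(g, compartment, matrix.values.shape[1],
                            matrix.values.shape[1], 1.0, "persistent")
        for g in matrix.genome_ids
    ]


def stability_class_bruteforce(x):
    med = float(np.median(x))
    n_fluct = sum(1 for v in x if abs(v - med) > 0.25 * med)
    frac = n_fluct / len(x)
    if frac <= 0.25:
        return "stable"
    if frac >= 0.75:
        return "unstable"
    return "intermediate"


@pytest.mark.parametrize("n_beyond,n,expected", [(3, 15, "stable"), (12, 15, "unstable")])
def test_stability_fraction_classes(n_beyond, n, expected):
    med = 10.0
    x = np.full(n, med)
    x[:n_beyond] = med * 1.6  # clearly beyond the 25% band
    # keep the median at 10 by construction (n_beyond < n/2 for stable case)
    if n_beyond < n / 2:
        mat = _tmm_matrix(x)
        (call,) = tmp.classify_stability(mat, _persistent_calls(mat))
        assert call.stability_class == expected
    else:
        # for the unstable case alternate above/below so the median stays put
        x = np.full(n, med)
        x[: n_beyond // 2] = med * 1.6
        x[n_beyond // 2 : n_beyond] = med * 0.4
        mat = _tmm_matrix(x)
        (call,) = tmp.classify_stability(mat, _persistent_calls(mat))
        assert call.stability_class == expected
        assert call.n_fluctuating == n_beyond


def test_stability_matches_brute_force_recount():
    rng = np.random.default_rng(11)
    for _ in range(1000):
        x = rng.lognormal(2.0, 0.8, size=16)
        mat = _tmm_matrix(x)
        (call,) = tmp.classify_stability(mat, _persistent_calls(mat))
        assert call.stability_class == stability_class_bruteforce(x)
        assert call.n_fluctuating == sum(
            1 for v in x if abs(v - np.median(x)) > 0.25 * np.median(x)
        )


def test_stability_invariant_under_rescaling():
    rng = np.random.default_rng(4)
    x = rng.lognormal(1.0, 0.5, size=15)
    m1 = _tmm_matrix(x)
    m2 = _tmm_matrix(x * 7.3)
    (c1,) = tmp.classify_stability(m1, _persistent_calls(m1))
    (c2,) = tmp.classify_stability(m2, _persistent_calls(m2))
    assert c1.stability_class == c2.stability_class
    assert c1.n_fluctuating == c2.n_fluctuating


def test_exact_quarter_deviation_is_not_fluctuating():
    """The +/- 25% band is a tolerance: its boundary is non-fluctuating."""
    x = np.array([10.0] * 10 + [12.5, 7.5])  # exactly 25% of the median
    mat = _tmm_matrix(x)
    (call,) = tmp.classify_stability(mat, _persistent_calls(mat))
    assert call.n_fluctuating == 0


# ---------------------------------------------------------------------------
# Bray-Curtis and compartment comparison


def test_bray_curtis_examples():
    assert tmp.bray_curtis(np.array([1.0, 2, 3]), np.array([1.0, 2, 3])) == 0
    assert tmp.bray_curtis(np.array([1.0, 0, 0]), np.array([0.0, 2, 3])) == 1
    assert tmp.bray_curtis(np.array([1.0, 2, 3]), np.array([3.0, 2, 1])) == pytest.approx(1 / 3)


def test_consecutive_bray_curtis_uses_time_order():
    samples = [
        SampleRecord("late", Compartment.SW, 6.0, 10),
        SampleRecord("early", Compartment.SW, 0.0, 10),
        SampleRecord("mid", Compartment.SW, 3.0, 10),
    ]
    mat = AbundanceMatrix(
        ["g0"], ["late", "early", "mid"], np.array([[4.0, 1.0, 2.0]]), state="tmm",
        norm_factors=np.ones(3), library_sizes=np.ones(3),
    )
    out = tmp.consecutive_bray_curtis(mat, samples)
    assert [s for s, _ in out] == ["mid", "late"]
    assert out[0][1] == pytest.approx(1 / 3)  # BC(1, 2)
    assert out[1][1] == pytest.approx(2 / 6)  # BC(2, 4)


def test_welch_t_matches_textbook_formula():
    rng = np.random.default_rng(8)
    sw = rng.normal(0.2, 0.05, size=14)
    pw = rng.normal(0.5, 0.10, size=16)
    t, df, p = tmp.compare_compartments(sw, pw)
    va, vb = sw.var(ddof=1) / sw.size, pw.var(ddof=1) / pw.size
    t_direct = (sw.mean() - pw.mean()) / math.sqrt(va + vb)
    df_direct = (va + vb) ** 2 / (va**2 / (sw.size - 1) + vb**2 / (pw.size - 1))
    p_direct = 2 * stats.t.sf(abs(t_direct), df_direct)
    assert t == pytest.approx(t_direct, abs=1e-10)
    assert df == pytest.approx(df_direct, abs=1e-10)
    assert p == pytest.approx(p_direct, abs=1e-12)
    # antisymmetry
    t2, _, p2 = tmp.compare_compartments(pw, sw)
    assert t2 == pytest.approx(-t, abs=1e-12)
    assert p2 == pytest.approx(p, abs=1e-12)


def test_identical_groups_give_null_result():
    t, df, p = tmp.compare_compartments([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
    assert t == 0.0 and p == 1.0


# ---------------------------------------------------------------------------
# Fisher's exact test


def test_fisher_2x2_balanced_and_extreme():
    assert tmp.fisher_class_counts([[5, 5], [5, 5]]) == pytest.approx(1.0)
    assert tmp.fisher_class_counts([[10, 0], [0, 10]]) == pytest.approx(
        2 / math.comb(20, 10), rel=1e-12
    )


def test_fisher_2x2_agrees_with_scipy():
    rng = np.random.default_rng(2)
    for _ in range(20):
        t = rng.integers(1, 15, size=(2, 2))
        ours = tmp.fisher_class_counts(t)
        assert ours == pytest.approx(stats.fisher_exact(t)[1], rel=1e-9)


def test_fisher_2x3_enumeration_consistent_with_monte_carlo():
    rng = np.random.default_rng(6)
    for _ in range(5):
        t = rng.integers(1, 11, size=(2, 3))
        p_enum = tmp.fisher_class_counts(t)
        draws = 30000
        p_mc = tmp.fisher_class_counts(
            t, enumeration_max_total=1, monte_carlo_draws=draws, seed=9
        )
        se = math.sqrt(p_enum * (1 - p_enum) / draws)
        assert abs(p_mc - p_enum) <= 3 * se + 2 / draws


def test_fisher_rejects_empty_margins():
    with pytest.raises(ValidationError):
        tmp.fisher_class_counts([[0, 0], [1, 2]])


def test_stability_class_table_shape():
    calls_sw = [tmp.StabilityCall("g", "SW", 1.0, 1, 15, "stable")]
    calls_pw = [tmp.StabilityCall("h", "PW", 1.0, 14, 15, "unstable")]
    table = tmp.stability_class_table(calls_sw, calls_pw)
    assert table.tolist() == [[1, 0, 0], [0, 0, 1]]
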