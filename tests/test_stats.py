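"""Group statistics: ANOVA, post-hoc tests, letter displays, ΔΔCT, Pearson r."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from coldomics.stats import (
    PosthocResult,
    QpcrRecord,
    compact_letter_display,
    concordance,
    one_way_anova,
    pairwise_posthoc,
    qpcr_relative_expression,
)


def random_design(rng, k=None, n=None, spread=1.0):
    k = k or int(rng.integers(2, 6))
    n = n or int(rng.integers(3, 8))
    return {
        f"g{i}": rng.normal(rng.uniform(0, spread * 3), 1.0, n).tolist() for i in range(k)
    }


class TestAnova:
    def test_hand_computed_two_group_case(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [4, 5, 6]})
        # SSB = 13.5, SSW = 4, df (1, 4) -> F = 13.5
        assert res.f == pytest.approx(13.5)
        assert res.p == pytest.approx(float(sps.f.sf(13.5, 1, 4)))

    def test_identical_constant_groups_degenerate(self):
        res = one_way_anova({"a": [5, 5, 5], "b": [5, 5, 5]})
        assert res.degenerate and res.f == 0.0 and res.p == 1.0

    def test_separated_constant_groups_degenerate(self):
        res = one_way_anova({"a": [1, 1], "b": [2, 2]})
        assert res.degenerate and res.p == 0.0

    def test_matches_scipy_f_oneway(self, rng):
        for _ in range(25):
            design = random_design(rng)
            res = one_way_anova(design)
            ref = sps.f_oneway(*design.values())
            assert res.f == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_rejects_singleton_groups(self):
        with pytest.raises(ValueError, match="n >= 2"):
            one_way_anova({"a": [1.0], "b": [2.0, 3.0]})

    def test_null_pvalues_uniform(self):
        """Under the global null, ANOVA p values are ~Uniform(0,1) (KS check)."""
        rng = np.random.default_rng(7)
        pvals = [
            one_way_anova({g: rng.normal(0, 1, 5).tolist() for g in "abc"}).p
            for _ in range(1000)
        ]
        d = sps.kstest(pvals, "uniform").statistic
        assert d < 0.05


class TestPosthoc:
    def test_identical_groups_nothing_significant(self):
        design = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        for method in ("tukey_hsd", "fisher_lsd"):
            res = pairwise_posthoc(design, method=method)
            assert not res.significant.any()

    def test_separated_groups_significant_under_both(self, rng):
        design = {"lo": rng.normal(0, 0.1, 5).tolist(), "hi": rng.normal(10, 0.1, 5).tolist()}
        for method in ("tukey_hsd", "fisher_lsd"):
            res = pairwise_posthoc(design, method=method)
            assert res.significant[0, 1] and res.significant[1, 0]

    def test_lsd_pvalues_never_exceed_tukey(self, rng):
        """Unadjusted pairwise t p-values are <= studentized-range p-values,
        so (unprotected) LSD flags a superset of Tukey's pairs."""
        for _ in range(30):
            design = random_design(rng)
            tuk = pairwise_posthoc(design, method="tukey_hsd")
            lsd = pairwise_posthoc(design, method="fisher_lsd")
            assert (lsd.pvalues <= tuk.pvalues + 1e-12).all()
            omnibus = one_way_anova(design)
            if omnibus.p < 0.05:  # protected-LSD gate open
                assert (lsd.significant | ~tuk.significant).all()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            pairwise_posthoc({"a": [1, 2], "b": [3, 4]}, method="duncan")


def manual_posthoc(labels, sig_pairs):
    k = len(labels)
    m = np.zeros((k, k), dtype=bool)
    for a, b in sig_pairs:
        i, j = labels.index(a), labels.index(b)
        m[i, j] = m[j, i] = True
    return PosthocResult(labels, m, np.where(m, 0.0, 1.0), "manual", 0.05)


def display_is_consistent(letters, posthoc):
    idx = {g: i for i, g in enumerate(posthoc.labels)}
    for a, b in itertools.combinations(posthoc.labels, 2):
        share = bool(set(letters[a]) & set(letters[b]))
        if share == bool(posthoc.significant[idx[a], idx[b]]):
            return False
    return True


def brute_force_min_letters(posthoc):
    """Smallest number of letter sets satisfying the iff-invariant."""
    labels = posthoc.labels
    idx = {g: i for i, g in enumerate(labels)}
    nonsig_pairs = [
        (a, b) for a, b in itertools.combinations(labels, 2)
        if not posthoc.significant[idx[a], idx[b]]
    ]
    # candidate letter sets = cliques of the non-significance graph
    cliques = [
        set(c)
        for r in range(1, len(labels) + 1)
        for c in itertools.combinations(labels, r)
        if all(not posthoc.significant[idx[a], idx[b]]
               for a, b in itertools.combinations(c, 2))
    ]
    for size in range(1, len(cliques) + 1):
        for combo in itertools.combinations(cliques, size):
            if all(any(a in s and b in s for s in combo) for a, b in nonsig_pairs) \
                    and all(any(g in s for s in combo) for g in labels):
                return size
    raise AssertionError("no consistent display found")


class TestCompactLetterDisplay:
    def test_two_groups_not_different_share_a(self):
        ph = manual_posthoc(["x", "y"], [])
        assert compact_letter_display(ph, {"x": 2.0, "y": 1.0}) == {"x": "a", "y": "a"}

    def test_two_groups_different_get_a_and_b(self):
        ph = manual_posthoc(["x", "y"], [("x", "y")])
        letters = compact_letter_display(ph, {"x": 1.0, "y": 2.0})
        assert letters == {"y": "a", "x": "b"}  # larger mean carries 'a'

    def test_four_group_chain_only_adjacent_share(self):
        labels = ["g1", "g2", "g3", "g4"]
        means = {"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0}
        sig = [("g1", "g3"), ("g1", "g4"), ("g2", "g4")]
        ph = manual_posthoc(labels, sig)
        letters = compact_letter_display(ph, means)
        assert display_is_consistent(letters, ph)
        n_letters = len({ch for s in letters.values() for ch in s})
        assert n_letters == brute_force_min_letters(ph)

    def test_iff_invariant_on_random_matrices(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 7))
            labels = [f"g{i}" for i in range(k)]
            means = {g: float(rng.normal()) for g in labels}
            m = np.triu(rng.random((k, k)) < 0.4, 1)
            ph = manual_posthoc(
                labels,
                [(labels[i], labels[j]) for i in range(k) for j in range(k) if m[i, j]],
            )
            letters = compact_letter_display(ph, means)
            assert display_is_consistent(letters, ph)

    def test_top_mean_group_gets_letter_a(self, rng):
        design = {
            "hi": rng.normal(10, 0.1, 5).tolist(),
            "mid": rng.normal(5, 0.1, 5).tolist(),
            "lo": rng.normal(0, 0.1, 5).tolist(),
        }
        ph = pairwise_posthoc(design, method="tukey_hsd")
        letters = compact_letter_display(ph, {g: float(np.mean(v)) for g, v in design.items()})
        assert letters == {"hi": "a", "mid": "b", "lo": "c"}

    def test_asymmetric_matrix_rejected(self):
        ph = manual_posthoc(["x", "y"], [])
        ph.significant[0, 1] = True
        with pytest.raises(ValueError, match="symmetric"):
            compact_letter_display(ph, {"x": 1.0, "y": 2.0})


class TestQpcr:
    def test_calibrator_geometric_averages_to_one(self):
        records = [
            QpcrRecord("c1", 22.0, 20.0, "ctrl", True),
            QpcrRecord("c2", 23.5, 20.5, "ctrl", True),
            QpcrRecord("s1", 24.0, 20.0, "cold"),
        ]
        expr = qpcr_relative_expression(records)
        geo = math.sqrt(expr["c1"] * expr["c2"])
        assert geo == pytest.approx(1.0, rel=1e-12)

    def test_forced_two_fold_squared_case(self):
        # calibrator ΔCT = 5; sample ΔCT = 3 → ΔΔCT = −2 → expression 4
        records = [
            QpcrRecord("cal", 25.0, 20.0, "ctrl", True),
            QpcrRecord("s", 23.0, 20.0, "cold"),
        ]
        assert qpcr_relative_expression(records)["s"] == pytest.approx(4.0)

    def test_matches_naive_step_by_step_oracle(self, rng):
        records = [
            QpcrRecord(f"s{i}", float(rng.uniform(18, 30)), float(rng.uniform(18, 25)),
                       "ctrl" if i < 3 else "cold", is_calibrator=i < 3)
            for i in range(10)
        ]
        expr = qpcr_relative_expression(records)
        dct = {r.sample_id: r.target_ct - r.reference_ct for r in records}
        cal = np.mean([dct[r.sample_id] for r in records if r.is_calibrator])
        for r in records:
            assert expr[r.sample_id] == pytest.approx(2 ** -(dct[r.sample_id] - cal))

    def test_missing_ct_names_the_sample(self):
        with pytest.raises(ValueError, match="s1"):
            qpcr_relative_expression(
                [QpcrRecord("cal", 25.0, 20.0, "ctrl", True),
                 QpcrRecord("s1", math.nan, 20.0, "cold")]
            )

    def test_no_calibrator_rejected(self):
        with pytest.raises(ValueError, match="calibrator"):
            qpcr_relative_expression([QpcrRecord("s", 23.0, 20.0, "cold")])


class TestConcordance:
    def test_identical_vectors(self):
        vals = {"a": 1.0, "b": 2.0, "c": 3.5}
        assert concordance(vals, dict(vals)) == (pytest.approx(1.0), True)

    def test_exact_negation(self):
        a = {"a": 1.0, "b": 2.0, "c": 3.5}
        b = {g: -v for g, v in a.items()}
        r, defined = concordance(a, b)
        assert defined and r == pytest.approx(-1.0)

    def test_known_correlation_structure_within_sampling_band(self):
        """Bivariate normal, ρ = 0.9, n = 27: envelope from 1000 seeded draws."""
        rng = np.random.default_rng(11)
        cov = [[1.0, 0.9], [0.9, 1.0]]
        rs = []
        for _ in range(1000):
            xy = rng.multivariate_normal([0, 0], cov, size=27)
            a = {f"g{i}": xy[i, 0] for i in range(27)}
            b = {f"g{i}": xy[i, 1] for i in range(27)}
            r, _ = concordance(a, b)
            rs.append(r)
        lo, hi = np.quantile(rs, [0.001, 0.999])
        assert 0.9 == pytest.approx(np.median(rs), abs=0.05)
        assert lo > 0.5 and hi < 1.0

    def test_too_few_shared_genes_rejected(self):
        with pytest.raises(ValueError, match="shared genes"):
            concordance({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})

    def test_zero_variance_flagged(self):
        r, defined = concordance({g: 1.0 for g in "abc"}, {"a": 1.0, "b": 2.0, "c": 3.0})
        assert not defined and math.isnan(r)
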