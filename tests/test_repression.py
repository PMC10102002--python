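import math

import numpy as np
import pandas as pd
import pytest

from tdmdscreen.io_formats import MiRNA, Transcript
from tdmdscreen.repression import (
    TargetSets,
    cumulative_fold_change,
    mann_whitney_two_sided,
    organ_normalized_correlation,
    predict_seed_targets,
    revcomp,
)
from tdmdscreen.synthetic import sim_cfc_logfc

from .oracles import oracle_mw_two_sided


def _random_rna(rng, n):
    return "".join("ACGU"[b] for b in rng.integers(0, 4, n))


@pytest.fixture
def mirna(rng):
    return MiRNA("mir-x", _random_rna(rng, 22))


def _tx(tid, cds, utr, cds_end=None):
    seq = cds + utr
    return Transcript(tid, tid, seq, cds_end=len(cds) if cds_end is None else cds_end)


class TestSeedTargets:
    def test_site_classes(self, mirna, rng):
        m = mirna.sequence
        site8 = revcomp(m[1:8]) + "A"
        site7m8 = revcomp(m[1:8]) + "C"
        site7a1 = revcomp(m[1:7]) + "A"
        # the base 5' of the 7mer-A1 site must not complement miRNA
        # position 8, or the site would be promoted to an 8mer
        guard = "A" if revcomp(m[7]) != "A" else "C"
        cds = _random_rna(rng, 60)
        txs = [
            _tx("t8", cds, _random_rna(rng, 10) + site8 + _random_rna(rng, 10)),
            _tx("t7m8", cds, site7m8 + _random_rna(rng, 12)),
            _tx("t7a1", cds, _random_rna(rng, 11) + guard + site7a1),
            _tx("none", cds, "A" * 30),
        ]
        targets, skipped = predict_seed_targets(mirna, txs)
        assert targets == {"t8": "8mer", "t7m8": "7mer-m8", "t7a1": "7mer-A1"}
        assert skipped == []

    def test_cds_site_does_not_count(self, mirna, rng):
        site = revcomp(mirna.sequence[1:8]) + "A"
        t = _tx("t", _random_rna(rng, 30) + site + _random_rna(rng, 30), "A" * 30)
        targets, _ = predict_seed_targets(mirna, [t])
        assert targets == {}

    def test_unannotated_transcript_skipped(self, mirna, rng):
        t = Transcript("t", "t", _random_rna(rng, 60), cds_end=None)
        targets, skipped = predict_seed_targets(mirna, [t])
        assert skipped == ["t"]

    def test_position_independence(self, mirna, rng):
        site = revcomp(mirna.sequence[1:8]) + "A"
        utr = _random_rna(rng, 40)
        for shift in (0, 7, 19):
            t = _tx("t", _random_rna(rng, 50), utr[:shift] + site + utr[shift:])
            targets, _ = predict_seed_targets(mirna, [t])
            assert "t" in targets


class TestTargetSets:
    def test_overlap_and_non_targets_disjoint(self):
        ts = TargetSets.build(
            all_predicted={"a", "b", "c"},
            conserved_predicted={"b"},
            clash_targets={"c", "d"},
            universe={"a", "b", "c", "d", "e", "f"},
        )
        assert ts.overlap == {"c"}
        assert ts.non_targets == {"e", "f"}
        for name, group in ts.as_dict().items():
            if name != "non_targets":
                assert not (ts.non_targets & group)


class TestCfc:
    def _diff(self, values, kept=True):
        return pd.DataFrame(
            {"baseMean": 500.0, "log2fc": values, "kept": kept},
            index=[f"g{i}" for i in range(len(values))],
        )

    def test_curves_are_proper_cdfs(self, rng):
        vals = rng.normal(0, 1, 100)
        ts = TargetSets.build(set(), set(), set(), {f"g{i}" for i in range(100)})
        curves = cumulative_fold_change(self._diff(vals), ts)
        c = curves["non_targets"]
        assert c.cdf(-10) == 0.0 and c.cdf(10) == 1.0
        grid = np.linspace(-3, 3, 20)
        assert all(c.cdf(a) <= c.cdf(b) for a, b in zip(grid, grid[1:]))

    def test_shifted_set_dominated_at_every_quantile(self, rng):
        n = 200
        genes = [f"g{i}" for i in range(2 * n)]
        vals = np.concatenate([rng.normal(-0.3, 0.4, n), rng.normal(0, 0.4, n)])
        ts = TargetSets.build(set(genes[:n]), set(), set(), set(genes))
        curves = cumulative_fold_change(
            self._diff(list(vals)), ts
        )
        t, nt = curves["all_predicted"], curves["non_targets"]
        for q in np.linspace(-1, 1, 15):
            assert t.cdf(q) >= nt.cdf(q) - 1e-12

    def test_small_set_flagged(self):
        ts = TargetSets.build({"g0"}, set(), set(), {"g0", "g1", "g2"})
        curves = cumulative_fold_change(self._diff([0.1, 0.2, 0.3]), ts)
        assert curves["all_predicted"].low_n


class TestMannWhitney:
    def test_textbook_exact_case(self):
        u, p = mann_whitney_two_sided([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney_two_sided([1, 2, 2, 5], [1, 2, 2, 5])
        assert p == pytest.approx(1.0)

    def test_exact_path_matches_enumeration(self, rng):
        for _ in range(150):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 10 - n1 + 1))
            x = rng.integers(0, 6, n1).astype(float)  # many ties
            y = rng.integers(0, 6, n2).astype(float)
            u, p = mann_whitney_two_sided(x, y)
            u_ref, p_ref = oracle_mw_two_sided(list(x), list(y))
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_two_sided([], [1.0])

    def test_type_one_error_control_under_null(self):
        """Null rejection rate at P<0.05 stays within 5% +/- 2 points."""
        n = 300
        rejections = sum(
            mann_whitney_two_sided(*sim_cfc_logfc(0.0, seed=s))[1] < 0.05
            for s in range(n)
        )
        assert 0.03 <= rejections / n <= 0.07

    def test_power_under_planted_repression(self):
        rejections = sum(
            mann_whitney_two_sided(*sim_cfc_logfc(0.3, seed=s))[1] < 0.01
            for s in range(50)
        )
        assert rejections / 50 >= 0.95


class TestOrganCorrelation:
    def _mats(self, m_vals, t_vals):
        organs = ["head", "gut", "muscle"]
        mm = pd.DataFrame(
            {o: [1.0] * len(m_vals) for o in organs}
            | {"whole_body": m_vals},
            index=[f"mir{i}" for i in range(len(m_vals))],
        )
        tm = pd.DataFrame(
            {o: [1.0] * len(t_vals) for o in organs}
            | {"whole_body": t_vals},
            index=[f"tx{i}" for i in range(len(t_vals))],
        )
        pairs = [(f"mir{i}", f"tx{i}") for i in range(len(m_vals))]
        return mm, tm, pairs

    def test_perfect_negative_line_gives_r_minus_one(self):
        mm, tm, pairs = self._mats([1, 2, 3, 4], [8, 6, 4, 2])
        _, r, p = organ_normalized_correlation(mm, tm, pairs)
        assert r == pytest.approx(-1.0)
        assert p == pytest.approx(0.0, abs=1e-6)

    def test_constant_trigger_values_error(self):
        mm, tm, pairs = self._mats([1, 2, 3], [5, 5, 5])
        with pytest.raises(ValueError, match="variance"):
            organ_normalized_correlation(mm, tm, pairs)

    def test_matches_direct_pearson_formula(self, rng):
        m_vals = rng.uniform(1, 10, 5)
        t_vals = rng.uniform(1, 10, 5)
        mm, tm, pairs = self._mats(list(m_vals), list(t_vals))
        _, r, _ = organ_normalized_correlation(mm, tm, pairs)
        x, y = np.asarray(m_vals), np.asarray(t_vals)
        r_ref = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(r_ref)

    def test_zero_organ_mean_pair_skipped(self):
        mm, tm, pairs = self._mats([1, 2, 3, 4], [8, 6, 4, 2])
        tm.loc["tx0", ["head", "gut", "muscle"]] = 0.0
        table, r, _ = organ_normalized_correlation(mm, tm, pairs)
        assert table["skipped"].sum() == 1
        assert not math.isnan(r)
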