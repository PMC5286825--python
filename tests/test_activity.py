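import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panminer.activity import (BinaryTransactionMatrix, DiscretizedActivity,
                               PathwayActivityProfile, binarize, decode,
                               discretize_activity, infer_pathway_activity,
                               inverse_relationship_count, make_item,
                               moderated_t, moderated_t_matrix,
                               moderated_t_test, parse_item,
                               pathway_set_activity)
from panminer.enrichment import tstat_score
from panminer.io_formats import CASE, CONTROL, OmicsMatrix
from tests.conftest import two_class_labels


def matrix_from(vals, labels, genes=None):
    genes = genes or [f"g{i+1}" for i in range(len(vals))]
    return OmicsMatrix(pd.DataFrame(vals, index=genes,
                                    columns=list(labels)), labels)


def zscore(x):
    x = np.asarray(x, dtype=float)
    return (x - x.mean(axis=-1, keepdims=True)) / x.std(axis=-1, ddof=1,
                                                        keepdims=True)


class TestCorgInference:
    def test_single_member_gene(self):
        rng = np.random.default_rng(0)
        samples, labels = two_class_labels(5, 5)
        vals = rng.normal(0, 1, (3, 10))
        m = matrix_from(vals, labels)
        act, corg, signs = infer_pathway_activity(m, ["g2"])
        assert corg == ["g2"]
        # activity is the (possibly sign-flipped) z-score of that gene
        assert np.allclose(act.to_numpy(), signs[0] * zscore(vals[1]))

    def test_greedy_matches_exhaustive_on_toy(self):
        """3-gene set, 2 informative + 1 noise: the greedy CORG achieves the
        exhaustive-subset maximum |t| and drops the noise gene."""
        rng = np.random.default_rng(0)
        samples, labels = two_class_labels(20, 20)
        vals = rng.normal(0, 1, (3, 40))
        vals[0, :20] += 2.0
        vals[1, :20] += 2.0
        m = matrix_from(vals, labels)
        act, corg, _ = infer_pathway_activity(m, ["g1", "g2", "g3"])
        assert "g3" not in corg and set(corg) == {"g1", "g2"}
        is_case = np.array([True] * 20 + [False] * 20)
        greedy_t = abs(tstat_score(act[is_case], act[~is_case]))
        z = zscore(vals)
        best = -np.inf
        for r in range(1, 4):
            for sub in itertools.combinations(range(3), r):
                gsigns = [np.sign(tstat_score(z[i, is_case], z[i, ~is_case])) or 1.0
                          for i in sub]
                a = sum(s * z[i] for s, i in zip(gsigns, sub)) / np.sqrt(r)
                best = max(best, abs(tstat_score(a[is_case], a[~is_case])))
        assert greedy_t == pytest.approx(best)

    def test_duplicate_gene_never_decreases_t(self):
        rng = np.random.default_rng(1)
        samples, labels = two_class_labels(10, 10)
        base = rng.normal(0, 1, 20)
        base[:10] += 2.0
        vals = np.stack([base, base + rng.normal(0, 1e-9, 20)])
        m = matrix_from(vals, labels)
        act, corg, _ = infer_pathway_activity(m, ["g1", "g2"])
        is_case = np.array([True] * 10 + [False] * 10)
        t_single = abs(tstat_score(zscore(base)[is_case], zscore(base)[~is_case]))
        t_both = abs(tstat_score(act[is_case], act[~is_case]))
        assert t_both >= t_single - 1e-6
        # activity proportional to the shared pattern
        assert abs(np.corrcoef(act, base)[0, 1]) > 0.999

    def test_down_regulated_pathway_keeps_low_activity_in_cases(self):
        rng = np.random.default_rng(2)
        samples, labels = two_class_labels(15, 15)
        vals = rng.normal(0, 1, (4, 30))
        vals[:, :15] -= 2.0  # all member genes DOWN in cases
        m = matrix_from(vals, labels)
        act, _, _ = infer_pathway_activity(m, ["g1", "g2", "g3", "g4"])
        case_mean = act[[labels[s] == CASE for s in act.index]].mean()
        ctrl_mean = act[[labels[s] == CONTROL for s in act.index]].mean()
        assert case_mean < ctrl_mean

    def test_no_member_gene_is_error(self):
        _, labels = two_class_labels(3, 3)
        m = matrix_from(np.eye(2, 6), labels)
        with pytest.raises(ValueError, match="no member gene"):
            infer_pathway_activity(m, ["absent"])


class TestDiscretize:
    def profile(self, rows, pathways=None):
        pathways = pathways or [f"P{i+1}" for i in range(len(rows))]
        df = pd.DataFrame(rows, index=pathways,
                          columns=[f"s{i+1}" for i in range(len(rows[0]))])
        return PathwayActivityProfile(df)

    def test_median_threshold_hand_example(self):
        # median of [0.1, 0.9, -0.5, 0.4] is 0.25
        states = discretize_activity(self.profile([[0.1, 0.9, -0.5, 0.4]]))
        assert states.states.iloc[0].tolist() == [-1, 1, -1, 1]

    def test_increasing_row_splits_evenly(self):
        states = discretize_activity(self.profile([[1.0, 2.0, 3.0, 4.0]]))
        assert states.states.iloc[0].tolist() == [-1, -1, 1, 1]

    def test_constant_row_all_down(self):
        states = discretize_activity(self.profile([[2.0, 2.0, 2.0, 2.0]]))
        assert states.states.iloc[0].tolist() == [-1, -1, -1, -1]

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=3, max_size=9))
    def test_invariant_under_monotone_transform(self, row):
        # quantize so exp() cannot collapse distinct values in float64
        row = [round(v, 2) for v in row]
        base = discretize_activity(self.profile([row])).states
        transformed = discretize_activity(
            self.profile([list(np.exp(0.5 * np.asarray(row)))])).states
        assert base.equals(transformed)


class TestBinarize:
    def test_fig8_style_encoding(self, toy_states):
        sub = DiscretizedActivity(toy_states.states.iloc[:3, :1])
        sub.states.iloc[:, 0] = [1, -1, 1]
        bits = binarize(sub)
        assert bits.bits.iloc[:, 0].tolist() == [1, 0, 1, 0, 1, 0]

    def test_all_up_two_pathways(self):
        states = DiscretizedActivity(
            pd.DataFrame([[1], [1]], index=["A", "B"], columns=["s1"]))
        assert binarize(states).bits.iloc[:, 0].tolist() == [1, 1, 0, 0]

    def test_item_names_pair_up_and_down(self, toy_states):
        bits = binarize(toy_states)
        assert bits.items[:4] == ["A:up", "B:up", "C:up", "D:up"]
        assert bits.items[4:] == ["A:down", "B:down", "C:down", "D:down"]

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(1, 6), st.integers(1, 8), st.integers(0, 2**31 - 1))
    def test_roundtrip_and_complement_invariant(self, n, m, seed):
        rng = np.random.default_rng(seed)
        states = DiscretizedActivity(pd.DataFrame(
            rng.choice([-1, 1], size=(n, m)),
            index=[f"P{i}" for i in range(n)],
            columns=[f"s{j}" for j in range(m)]))
        bits = binarize(states)
        arr = bits.bits.to_numpy()
        assert ((arr[:n] + arr[n:]) == 1).all()
        assert arr.sum(axis=0).tolist() == [n] * m
        assert decode(bits).states.equals(states.states)

    def test_decode_rejects_corrupted_bits(self, toy_states):
        bits = binarize(toy_states)
        bits.bits.iloc[0, 0] = 1 - bits.bits.iloc[0, 0]
        with pytest.raises(ValueError, match="complementary"):
            decode(bits)

    def test_item_name_parsing(self):
        assert parse_item(make_item("KEGG_SPLICEOSOME", -1)) == \
            ("KEGG_SPLICEOSOME", -1)
        with pytest.raises(ValueError):
            parse_item("no_suffix_here")


class TestModeratedT:
    def test_zero_prior_equals_pooled_t(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 14)
        is_case = np.array([True] * 7 + [False] * 7)
        a, b = x[is_case], x[~is_case]
        sp2 = (6 * a.var(ddof=1) + 6 * b.var(ddof=1)) / 12
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 7))
        assert moderated_t(x, is_case) == pytest.approx(expected)

    def test_equal_means_give_zero(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        assert moderated_t(x, np.array([1, 1, 1, 0, 0, 0], bool)) == 0.0

    def test_shrinkage_reduces_spread_on_null_features(self):
        rng = np.random.default_rng(4)
        scale = np.sqrt(2.0 / rng.chisquare(3, 200))
        x = rng.normal(0, 1, (200, 12)) * scale[:, None]
        is_case = np.array([True] * 6 + [False] * 6)
        raw = np.array([moderated_t(row, is_case) for row in x])
        mod = moderated_t_matrix(x, is_case)
        assert np.std(mod) < np.std(raw)

    def test_matches_limma_reference(self, tmp_path):
        """Feature-wise moderated t and p equal Bioconductor limma eBayes."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript is required for the limma cross-check")
        rng = np.random.default_rng(7)
        sd = np.sqrt(0.5 / rng.chisquare(4, 150) * 4)
        x = rng.normal(0, 1, (150, 16)) * sd[:, None]
        x[:15, :8] += 0.8
        is_case = np.array([True] * 8 + [False] * 8)
        df = pd.DataFrame(x)
        df.to_csv(tmp_path / "x.tsv", sep="\t")
        script = (
            "suppressMessages(library(limma));"
            f'x <- as.matrix(read.delim("{tmp_path}/x.tsv", row.names=1));'
            "design <- cbind(1, c(rep(1,8), rep(0,8)));"
            "fit <- eBayes(lmFit(x, design));"
            f'write.table(cbind(fit$t[,2], fit$p.value[,2]), "{tmp_path}/r.txt",'
            "row.names=FALSE, col.names=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        ref = np.loadtxt(tmp_path / "r.txt")
        t, p = moderated_t_test(x, is_case)
        assert np.abs(t - ref[:, 0]).max() < 1e-8
        assert np.abs(p - ref[:, 1]).max() < 1e-8

    def test_degenerate_class_sizes_rejected(self):
        with pytest.raises(ValueError):
            moderated_t(np.arange(4.0), np.array([True, False, False, False]))


class TestPathwaySetActivity:
    def make_profile(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        samples, labels = two_class_labels(n, n)
        a = rng.normal(0, 1, (3, 2 * n))
        a[0, :n] += 2.0   # P1 up in case
        a[1, :n] -= 2.0   # P2 down in case
        df = pd.DataFrame(a, index=["P1", "P2", "P3"], columns=samples)
        return PathwayActivityProfile(df), labels

    def test_singleton_up_is_identity(self):
        profile, labels = self.make_profile()
        act = pathway_set_activity(profile, labels, ["P1:up"])
        assert np.allclose(act, profile.activities.loc["P1"])

    def test_singleton_down_is_sign_flip(self):
        profile, labels = self.make_profile()
        act = pathway_set_activity(profile, labels, ["P2:down"])
        assert np.allclose(act, -profile.activities.loc["P2"])

    def test_combination_beats_singletons(self):
        profile, labels = self.make_profile(seed=5)
        is_case = np.array([labels[s] == CASE for s in profile.samples])

        def t_of(items):
            v = pathway_set_activity(profile, labels, items).to_numpy()
            return abs(tstat_score(v[is_case], v[~is_case]))

        t_pair = t_of(["P1:up", "P2:down"])
        assert t_pair >= max(t_of(["P1:up"]), t_of(["P2:down"])) - 1e-9

    def test_noise_pathway_excluded_from_combination(self):
        profile, labels = self.make_profile(seed=6)
        act_with_noise = pathway_set_activity(
            profile, labels, ["P1:up", "P2:down", "P3:up"])
        act_clean = pathway_set_activity(profile, labels, ["P1:up", "P2:down"])
        assert np.allclose(act_with_noise, act_clean)

    def test_empty_set_is_error(self):
        profile, labels = self.make_profile()
        with pytest.raises(ValueError):
            pathway_set_activity(profile, labels, [])

    def test_fit_samples_restrict_estimation(self):
        profile, labels = self.make_profile(seed=7)
        train = profile.samples[:8] + profile.samples[-8:]
        act = pathway_set_activity(profile, labels, ["P1:up", "P3:up"],
                                   fit_samples=train)
        assert list(act.index) == profile.samples


class TestInverseRelationship:
    def states_from(self, rows, pathways, samples):
        return DiscretizedActivity(
            pd.DataFrame(rows, index=pathways, columns=samples))

    def test_opposite_majorities_flagged(self):
        samples, labels = two_class_labels(3, 3)
        expr = self.states_from([[1, 1, 1, -1, -1, -1]], ["A"], samples)
        meth = self.states_from([[-1, -1, 1, 1, 1, 1]], ["A"], samples)
        n, flags = inverse_relationship_count(expr, meth, labels, CASE)
        assert n == 1 and flags["A"]

    def test_identical_matrices_give_zero(self):
        samples, labels = two_class_labels(3, 3)
        expr = self.states_from([[1, 1, -1, -1, 1, 1], [1, -1, 1, -1, 1, -1]],
                                ["A", "B"], samples)
        n, _ = inverse_relationship_count(expr, expr, labels, CASE)
        assert n == 0

    def test_planted_opposites_counted_exactly(self):
        samples, labels = two_class_labels(4, 4)
        up = [1, 1, 1, 1, -1, -1, -1, -1]
        down = [-1, -1, -1, -1, 1, 1, 1, 1]
        expr = self.states_from([up, up, up, down, down],
                                list("ABCDE"), samples)
        meth = self.states_from([down, down, down, down, down],
                                list("ABCDE"), samples)
        n, flags = inverse_relationship_count(expr, meth, labels, CASE)
        assert n == 3
        assert [p for p, f in sorted(flags.items()) if f] == ["A", "B", "C"]

    def test_tie_is_not_inverse(self):
        samples, labels = two_class_labels(4, 2)
        expr = self.states_from([[1, 1, -1, -1, 1, 1]], ["A"], samples)
        meth = self.states_from([[-1, -1, -1, -1, 1, 1]], ["A"], samples)
        n, flags = inverse_relationship_count(expr, meth, labels, CASE)
        assert n == 0 and not flags["A"]

    def test_differing_sample_sets_per_datatype(self):
        expr_samples, _ = two_class_labels(3, 3, "case", "ctrl")
        meth_samples = [f"mcase_{i}" for i in range(4)] + \
            [f"mctrl_{i}" for i in range(4)]
        labels = {s: CASE for s in expr_samples[:3]}
        labels.update({s: CONTROL for s in expr_samples[3:]})
        labels.update({s: CASE for s in meth_samples[:4]})
        labels.update({s: CONTROL for s in meth_samples[4:]})
        expr = self.states_from([[1, 1, 1, -1, -1, -1]], ["A"], expr_samples)
        meth = self.states_from([[-1, -1, -1, 1, 1, 1, 1, 1]], ["A"],
                                meth_samples)
        n, _ = inverse_relationship_count(expr, meth, labels, CASE)
        assert n == 1

    def test_no_shared_pathways_is_error(self):
        samples, labels = two_class_labels(2, 2)
        a = self.states_from([[1, 1, -1, -1]], ["A"], samples)
        b = self.states_from([[1, 1, -1, -1]], ["B"], samples)
        with pytest.raises(ValueError, match="shared"):
            inverse_relationship_count(a, b, labels, CASE)
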