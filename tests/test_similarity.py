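import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsmda.dataio import InteractionTable, SymptomCooccurrenceTable
from tsmda.similarity import (
    build_symptom_profiles,
    build_target_profiles,
    cosine_similarity_matrix,
    gene_frequency,
    load_functional_similarity,
)


def naive_cosine(P):
    """Independent double-loop cosine with zero-row convention."""
    n = P.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            ni, nk = np.linalg.norm(P[i]), np.linalg.norm(P[k])
            if ni == 0 or nk == 0:
                out[i, k] = 0.0
            else:
                out[i, k] = float(P[i] @ P[k] / (ni * nk))
    return out


class TestGeneFrequency:
    def test_counts_incident_edges(self):
        t = InteractionTable({("m1", "g1"), ("m2", "g1"), ("m3", "g1")})
        assert gene_frequency(t) == {"g1": 3}

    def test_single_edge(self):
        assert gene_frequency(InteractionTable({("m1", "g1")})) == {"g1": 1}

    def test_absent_gene_not_in_map(self):
        freq = gene_frequency(InteractionTable({("m1", "g1")}))
        with pytest.raises(KeyError):
            freq["g2"]


class TestTargetProfiles:
    def test_log2_frequency_weights(self):
        # g1 is targeted by 8 miRNAs -> weight log2(8) = 3 on each edge
        edges = {(f"m{i}", "g1") for i in range(8)}
        prof = build_target_profiles(InteractionTable(edges), [f"m{i}" for i in range(8)])
        j = prof.gene_ids.index("g1")
        assert prof.weights[:, j].tolist() == [3.0] * 8

    def test_unique_gene_weight_zero(self):
        prof = build_target_profiles(InteractionTable({("m1", "g1")}), ["m1"])
        assert prof.weights[0, 0] == 0.0  # log2(1) = 0

    def test_non_edge_zero_and_missing_mirna_zero_profile(self):
        edges = {("m1", "g1"), ("m2", "g1")}
        prof = build_target_profiles(InteractionTable(edges), ["m1", "m2", "m3"])
        assert prof.weights[2].sum() == 0.0  # m3 has no targets
        # the weight is nonzero only where an edge exists
        assert (prof.weights[0] > 0).sum() == 1


class TestSymptomProfiles:
    def test_tfidf_natural_log(self):
        # W=3, N=4 diseases, symptom appears in n_j=2 -> w = 3 ln 2
        counts = np.array([[3], [1], [0], [0]])
        prof = build_symptom_profiles(
            SymptomCooccurrenceTable([f"d{i}" for i in range(4)], ["s1"], counts)
        )
        assert prof.weights[0, 0] == pytest.approx(3 * math.log(2), abs=1e-9)

    def test_ubiquitous_symptom_zeroed(self):
        counts = np.array([[2], [5], [1]])
        prof = build_symptom_profiles(
            SymptomCooccurrenceTable(["d1", "d2", "d3"], ["s1"], counts)
        )
        assert np.all(prof.weights == 0.0)  # n_j = N -> log 1 = 0

    def test_zero_count_zero_weight(self):
        counts = np.array([[0, 3], [2, 0]])
        prof = build_symptom_profiles(
            SymptomCooccurrenceTable(["d1", "d2"], ["s1", "s2"], counts)
        )
        assert prof.weights[0, 0] == 0.0
        assert prof.weights[1, 1] == 0.0

    def test_log_base_option_rescales(self):
        counts = np.array([[3], [1], [0], [0]])
        table = SymptomCooccurrenceTable([f"d{i}" for i in range(4)], ["s1"], counts)
        nat = build_symptom_profiles(table, "natural")
        two = build_symptom_profiles(table, "log2")
        assert two.weights[0, 0] == pytest.approx(nat.weights[0, 0] / math.log(2))


class TestCosine:
    def test_identities(self):
        P = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 2.0]])
        sim = cosine_similarity_matrix(["a", "b", "c"], P, "target")
        assert sim.values[0, 1] == pytest.approx(1.0)
        assert sim.values[0, 2] == pytest.approx(0.0)

    def test_half_overlap(self):
        P = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
        sim = cosine_similarity_matrix(["a", "b"], P, "target")
        assert sim.values[0, 1] == pytest.approx(1 / math.sqrt(2), abs=1e-12)

    def test_zero_profile_zero_everywhere_even_diagonal(self):
        P = np.array([[0.0, 0.0], [1.0, 2.0]])
        sim = cosine_similarity_matrix(["z", "a"], P, "target")
        assert sim.values[0].tolist() == [0.0, 0.0]
        assert sim.values[1, 1] == pytest.approx(1.0)

    def test_matches_naive_double_loop(self, rng):
        for _ in range(5):
            P = rng.integers(0, 5, size=(5, 5)).astype(float)
            sim = cosine_similarity_matrix([f"e{i}" for i in range(5)], P, "target")
            assert np.allclose(sim.values, naive_cosine(P), atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.lists(st.integers(0, 9), min_size=3, max_size=3),
            min_size=2,
            max_size=6,
        ),
        st.integers(1, 1000),
    )
    def test_scale_invariance(self, rows, scale):
        P = np.array(rows, dtype=float)
        ids = [f"e{i}" for i in range(P.shape[0])]
        base = cosine_similarity_matrix(ids, P, "target").values
        Q = P.copy()
        Q[0] *= scale
        scaled = cosine_similarity_matrix(ids, Q, "target").values
        assert np.allclose(base, scaled, atol=1e-9)

    def test_symmetric_and_bounded(self, rng):
        P = rng.random((10, 6))
        sim = cosine_similarity_matrix([f"e{i}" for i in range(10)], P, "target")
        assert np.allclose(sim.values, sim.values.T, atol=1e-12)
        assert sim.values.min() >= 0.0 and sim.values.max() <= 1.0


class TestLoadFunctionalSimilarity:
    def _write(self, tmp_path, ids, values):
        import pandas as pd

        p = tmp_path / "mfs.csv"
        pd.DataFrame(values, index=ids, columns=ids).to_csv(p)
        return p

    def test_identity_restricted(self, tmp_path):
        p = self._write(tmp_path, ["m1", "m2", "m3"], np.eye(3))
        sim = load_functional_similarity(p, ["m1", "m3"])
        assert np.array_equal(sim.values, np.eye(2))

    def test_permuted_file_reordered_to_registry(self, tmp_path):
        vals = np.array([[1.0, 0.4, 0.1], [0.4, 1.0, 0.7], [0.1, 0.7, 1.0]])
        p1 = self._write(tmp_path, ["m1", "m2", "m3"], vals)
        perm = [2, 0, 1]
        p2 = tmp_path / "perm.csv"
        import pandas as pd

        ids_p = [["m1", "m2", "m3"][i] for i in perm]
        pd.DataFrame(vals[np.ix_(perm, perm)], index=ids_p, columns=ids_p).to_csv(p2)
        a = load_functional_similarity(p1, ["m1", "m2", "m3"])
        b = load_functional_similarity(p2, ["m1", "m2", "m3"])
        assert np.allclose(a.values, b.values)

    def test_missing_mirna_named_in_error(self, tmp_path):
        p = self._write(tmp_path, ["m1"], np.eye(1))
        with pytest.raises(ValueError, match="mX"):
            load_functional_similarity(p, ["m1", "mX"])

    def test_asymmetry_warned_and_averaged(self, tmp_path):
        vals = np.array([[1.0, 0.2], [0.4, 1.0]])
        p = self._write(tmp_path, ["m1", "m2"], vals)
        with pytest.warns(UserWarning, match="asymmetric"):
            sim = load_functional_similarity(p, ["m1", "m2"])
        assert sim.values[0, 1] == pytest.approx(0.3)
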