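import numpy as np
import pandas as pd
import pytest

from tmbsubtype.io_cohort import VariantClass
from tmbsubtype.signatures import (
    CATEGORIES_96,
    ContextMatrix,
    ReferenceCatalog,
    bayesian_nmf,
    classify_96,
    compare_pattern_by_subtype,
    cosine_match,
    cosine_similarity,
    load_default_catalog,
    reverse_complement,
    signature_pattern,
    snv_category,
)
from tmbsubtype.subtyping import SubtypeAssignment, Subtype, ThresholdRule

from conftest import snv


@pytest.fixture(scope="module")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="module")
def three_profiles(catalog):
    p = np.column_stack(
        [catalog.profile(n) for n in ("Signature 2", "Signature 4", "Signature 6")]
    )
    return p / p.sum(axis=0)


class TestCategories:
    def test_96_categories_fixed_order(self):
        assert len(CATEGORIES_96) == 96
        assert CATEGORIES_96[0] == "A[C>A]A"
        assert CATEGORIES_96[16] == "A[C>G]A"  # second substitution block
        assert CATEGORIES_96[-1] == "T[T>G]T"

    def test_purine_ref_reverse_complemented(self):
        assert snv_category("G", "T", "AGC") == "G[C>A]T"

    def test_pyrimidine_ref_unchanged(self):
        assert snv_category("C", "T", "ACG") == "A[C>T]G"

    def test_context_ref_mismatch_rejected(self):
        with pytest.raises(ValueError):
            snv_category("C", "T", "AAG")


class TestClassify96:
    def test_conservation(self, tiny_cohort):
        cohort, truth = tiny_cohort
        cm = classify_96(cohort.mutations, cohort.sample_ids)
        n_snv_with_ctx = sum(
            1 for m in cohort.mutations if m.is_snv and m.context is not None
        )
        assert cm.counts.sum() == n_snv_with_ctx
        assert np.array_equal(
            cm.counts.sum(axis=0).astype(int),
            truth.samples.loc[cm.sample_ids, "n_snv"].to_numpy(),
        )

    def test_snvs_without_context_skipped(self):
        muts = [snv(context="ACG"), snv(pos=2, context=None)]
        cm = classify_96(muts, ["S1"])
        assert cm.counts.sum() == 1

    def test_strand_involution(self, rng):
        muts, flipped = [], []
        for i in range(200):
            cat = CATEGORIES_96[rng.integers(96)]
            five, ref, alt, three = cat[0], cat[2], cat[4], cat[6]
            ctx = five + ref + three
            muts.append(snv(pos=i + 1, ref=ref, alt=alt, context=ctx))
            comp = str.maketrans("ACGT", "TGCA")
            flipped.append(snv(
                pos=i + 1,
                ref=ref.translate(comp),
                alt=alt.translate(comp),
                context=reverse_complement(ctx),
            ))
        a = classify_96(muts, ["S1"]).counts
        b = classify_96(flipped, ["S1"]).counts
        assert np.array_equal(a, b)

    def test_multinomial_recovery(self, rng):
        probs = rng.dirichlet(np.ones(96))
        n = 5000
        draws = rng.multinomial(n, probs)
        muts = []
        pos = 1
        for cat, count in zip(CATEGORIES_96, draws):
            five, ref, alt, three = cat[0], cat[2], cat[4], cat[6]
            for _ in range(count):
                muts.append(snv(pos=pos, ref=ref, alt=alt, context=five + ref + three))
                pos += 1
        cm = classify_96(muts, ["S1"])
        freq = cm.counts[:, 0] / n
        tol = 4 * np.sqrt(probs * (1 - probs) / n) + 1e-9
        assert (np.abs(freq - probs) <= tol).all()


class TestContextMatrix:
    def test_shape_enforced(self):
        with pytest.raises(ValueError):
            ContextMatrix(np.zeros((95, 2)), ["a", "b"])

    def test_negative_rejected(self):
        m = np.zeros((96, 1))
        m[0] = -1
        with pytest.raises(ValueError):
            ContextMatrix(m, ["a"])

    def test_frame_roundtrip(self, rng):
        cm = ContextMatrix(rng.poisson(3, (96, 4)).astype(float), list("abcd"))
        assert ContextMatrix.from_frame(cm.to_frame()).counts.tolist() == cm.counts.tolist()


class TestBayesianNmf:
    def test_exact_two_block_factorization(self):
        w0 = np.zeros((96, 2))
        w0[:20, 0] = 1 / 20
        w0[50:80, 1] = 1 / 30
        h0 = np.array([[100.0, 0.0, 50.0, 10.0], [0.0, 80.0, 40.0, 90.0]])
        model = bayesian_nmf(w0 @ h0, k_max=10, seed=2, n_restarts=3)
        assert model.k_effective == 2
        for j in range(2):
            best = max(
                cosine_similarity(model.w[:, i], w0[:, j])
                for i in range(model.k_effective)
            )
            assert best >= 0.99

    def test_identical_columns_rank_one(self, rng):
        v = np.tile(rng.poisson(5, 96)[:, None].astype(float), (1, 8))
        assert bayesian_nmf(v, k_max=10, seed=3, n_restarts=3).k_effective == 1

    def test_three_profile_simulation(self, three_profiles):
        rng = np.random.default_rng(11)
        exposures = rng.dirichlet([2, 2, 2], size=60).T * 200
        v = rng.poisson(three_profiles @ exposures).astype(float)
        model = bayesian_nmf(v, k_max=20, seed=11, n_restarts=3)
        assert model.k_effective == 3
        for j in range(3):
            best = max(
                cosine_similarity(model.w[:, i], three_profiles[:, j])
                for i in range(model.k_effective)
            )
            assert best >= 0.90

    def test_objective_monotone(self, three_profiles):
        rng = np.random.default_rng(4)
        exposures = rng.dirichlet([1, 1, 1], size=20).T * 100
        v = rng.poisson(three_profiles @ exposures).astype(float)
        model = bayesian_nmf(
            v, k_max=8, seed=4, n_restarts=1, max_iter=400, track_objective=True
        )
        trace = np.array(model.objective_trace)
        assert trace.size > 10
        rel_increase = np.diff(trace) / np.maximum(np.abs(trace[:-1]), 1.0)
        assert (rel_increase <= 1e-9).all()

    def test_signature_columns_sum_to_one(self, tiny_cohort):
        cohort, _ = tiny_cohort
        cm = classify_96(cohort.mutations, cohort.sample_ids)
        model = bayesian_nmf(cm, k_max=6, seed=1, n_restarts=2)
        assert np.allclose(model.w.sum(axis=0), 1.0, atol=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            bayesian_nmf(np.zeros((96, 3)), seed=0)

    def test_bad_kmax_rejected(self, rng):
        with pytest.raises(ValueError):
            bayesian_nmf(rng.poisson(2, (96, 3)).astype(float), k_max=0, seed=0)


class TestCosineMatch:
    def test_catalog_column_matches_itself(self, catalog):
        model_w = catalog.profiles[:, [3]]  # Signature 4 column
        from tmbsubtype.signatures import SignatureModel

        model = SignatureModel(
            w=model_w / model_w.sum(), h=np.ones((1, 2)), relevance=np.ones(1),
            k_effective=1, reconstruction_error=0.0, objective=0.0,
            sample_ids=["a", "b"],
        )
        ((_, name, sim),) = cosine_match(model, catalog)
        assert name == catalog.names[3]
        assert sim == pytest.approx(1.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(96), np.ones(96))

    def test_simulation_recovers_names(self, catalog, three_profiles):
        rng = np.random.default_rng(12)
        exposures = rng.dirichlet([2, 2, 2], size=60).T * 200
        v = rng.poisson(three_profiles @ exposures).astype(float)
        model = bayesian_nmf(v, k_max=20, seed=12, n_restarts=3)
        names = {name for _, name, _ in cosine_match(model, catalog)}
        assert names == {"Signature 2", "Signature 4", "Signature 6"}


class TestSignaturePattern:
    def test_single_signature_conserves_totals(self, rng):
        v = rng.poisson(5, (96, 4)).astype(float)
        model = bayesian_nmf(v, k_max=1, seed=0, n_restarts=1)
        pattern = signature_pattern(model)
        assert np.allclose(pattern.sum(axis=0), model.h.sum(axis=0))

    def test_scaled_exactly_to_observed_totals(self, rng):
        v = rng.poisson(5, (96, 4)).astype(float)
        cm = ContextMatrix(v, list("abcd"))
        model = bayesian_nmf(cm, k_max=3, seed=0, n_restarts=2)
        pattern = signature_pattern(model, cm)
        assert np.allclose(pattern.sum(axis=0), v.sum(axis=0))
        assert (pattern.to_numpy() >= 0).all()

    def test_zero_mutation_sample_gets_zero(self, rng):
        v = rng.poisson(5, (96, 4)).astype(float)
        v[:, 2] = 0.0
        model = bayesian_nmf(v, k_max=3, seed=0, n_restarts=2)
        pattern = signature_pattern(model)
        assert pattern.iloc[:, 2].sum() == pytest.approx(0.0, abs=1e-6)

    def test_attribution_close_to_generating_counts(self, three_profiles):
        rng = np.random.default_rng(13)
        n = 60
        exposures = rng.dirichlet([2, 2, 2], size=n).T * 200
        counts = np.zeros((96, n))
        true_attr = np.zeros((3, n))
        for s in range(n):
            for k in range(3):
                nk = rng.poisson(exposures[k, s])
                true_attr[k, s] = nk
                counts[:, s] += rng.multinomial(nk, three_profiles[:, k])
        model = bayesian_nmf(counts, k_max=10, seed=13, n_restarts=3)
        assert model.k_effective == 3
        pattern = signature_pattern(model)
        # align extracted to generating profiles
        row_for = {}
        for i in range(3):
            sims = [
                cosine_similarity(model.w[:, i], three_profiles[:, j])
                for j in range(3)
            ]
            row_for[int(np.argmax(sims))] = i
        est = np.vstack([pattern.to_numpy()[row_for[j]] for j in range(3)])
        rmse = np.sqrt(np.mean((est - true_attr) ** 2))
        assert rmse <= 0.15 * true_attr.mean() * 3  # within 15% of per-sample scale


class TestComparePattern:
    @staticmethod
    def _subtypes(sample_ids, labels):
        return SubtypeAssignment(
            threshold=0.0, rule=ThresholdRule.MEAN,
            sample_ids=tuple(sample_ids),
            labels=tuple(Subtype.TMB_H if l == "H" else Subtype.TMB_L for l in labels),
        )

    def test_identical_groups_null(self, rng):
        vals = np.concatenate([np.arange(10.0), np.arange(10.0)])
        samples = [f"S{i}" for i in range(20)]
        pattern = pd.DataFrame([vals], index=["W1"], columns=samples)
        subtypes = self._subtypes(samples, "H" * 10 + "L" * 10)
        res = compare_pattern_by_subtype(pattern, subtypes, "W1")
        assert res.p > 0.9

    def test_shifted_signature_detected(self, default_cohort):
        from tmbsubtype.signatures import classify_96
        from tmbsubtype.subtyping import assign_subtypes, compute_tmb

        cohort, truth = default_cohort
        cm = classify_96(cohort.mutations, cohort.sample_ids)
        model = bayesian_nmf(cm, k_max=10, seed=5, n_restarts=3)
        matches = cosine_match(model, load_default_catalog())
        smoking = next(s for s, ref, _ in matches if ref == "Signature 4")
        pattern = signature_pattern(model)
        subtypes = assign_subtypes(compute_tmb(cohort))
        res = compare_pattern_by_subtype(pattern, subtypes, smoking)
        assert res.p < 0.01

    def test_empty_group_rejected(self):
        pattern = pd.DataFrame([[1.0, 2.0]], index=["W1"], columns=["a", "b"])
        subtypes = self._subtypes(["a", "b"], "HH")
        with pytest.raises(ValueError):
            compare_pattern_by_subtype(pattern, subtypes, "W1")
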