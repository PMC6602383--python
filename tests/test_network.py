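"""Co-methylation network: filters, bicor, TOM, modules, trait models."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from methcortex import network as nw
from methcortex import synthdata as sd
from methcortex.ioformats import FormatError


def _frame(arr):
    return pd.DataFrame(
        arr, index=[f"cg{i}" for i in range(arr.shape[0])], columns=[f"s{j}" for j in range(arr.shape[1])]
    )


class TestVariableProbeFilter:
    def test_constant_probe_removed(self):
        beta = _frame(np.vstack([np.full(20, 0.5), np.linspace(0, 1, 20)]))
        kept = nw.variable_probe_filter(beta)
        assert list(kept) == ["cg1"]

    def test_exact_threshold_removed(self):
        # a probe whose central range equals the threshold exactly is
        # removed (strict > convention)
        vals = np.linspace(0.5, 0.5 + 0.05 / 0.8, 10)
        beta = _frame(vals[None, :])
        q10, q90 = np.quantile(vals, [0.1, 0.9])
        assert q90 - q10 == pytest.approx(0.05, abs=1e-9)
        assert len(nw.variable_probe_filter(beta, min_range=float(q90 - q10))) == 0

    def test_full_span_kept(self):
        beta = _frame(np.linspace(0, 1, 50)[None, :])
        assert len(nw.variable_probe_filter(beta)) == 1


class TestResidualize:
    @staticmethod
    def _pheno(n, rng):
        return pd.DataFrame(
            {
                "donor_id": [f"d{i}" for i in range(n)],
                "region": "PFC",
                "diagnosis": ["CTL"] * (n // 2) + ["iASD"] * (n - n // 2),
                "age": rng.uniform(10, 70, n),
                "sex": rng.choice(["M", "F"], n),
                "bank": "A",
                "neuronal_proportion": rng.uniform(0.2, 0.6, n),
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_empty_removal_is_identity(self):
        rng = np.random.default_rng(0)
        ph = self._pheno(20, rng)
        beta = _frame(rng.uniform(0.2, 0.8, (5, 20)))
        beta.columns = ph.index
        out = nw.residualize(beta, ph, remove=())
        pd.testing.assert_frame_equal(out, beta)

    def test_planted_age_slope_removed(self):
        rng = np.random.default_rng(1)
        ph = self._pheno(40, rng)
        age = ph["age"].to_numpy()
        beta = _frame(0.5 + 0.004 * (age - age.mean())[None, :] + rng.normal(0, 0.01, (30, 40)))
        beta.columns = ph.index
        out = nw.residualize(beta, ph, remove=("age",), keep=("diagnosis", "sex"))
        corr = np.array([np.corrcoef(out.iloc[i], age)[0, 1] for i in range(30)])
        assert np.abs(corr).mean() < 0.1

    def test_protected_diagnosis_effect_survives(self):
        rng = np.random.default_rng(2)
        ph = self._pheno(40, rng)
        case = (ph["diagnosis"] == "iASD").to_numpy(float)
        beta = _frame(0.5 + 0.1 * case[None, :] + rng.normal(0, 0.01, (10, 40)))
        beta.columns = ph.index
        out = nw.residualize(beta, ph, remove=("age", "cets"), keep=("diagnosis", "sex"))
        diff = out.loc[:, case == 1].mean(axis=1) - out.loc[:, case == 0].mean(axis=1)
        assert diff.mean() == pytest.approx(0.1, abs=0.01)


class TestBicor:
    def test_perfect_and_inverse(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        assert nw.bicor(x, x) == pytest.approx(1.0)
        assert nw.bicor(x, -x) == pytest.approx(-1.0)

    def test_gaussian_matches_pearson(self):
        rng = np.random.default_rng(4)
        rho = 0.5
        x = rng.normal(size=5000)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=5000)
        assert nw.bicor(x, y) == pytest.approx(rho, abs=0.03)
        assert nw.bicor(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.02)

    def test_robust_to_outlier(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        y = 0.8 * x + 0.6 * rng.normal(size=200)
        y_out = y.copy()
        y_out[0] = 500.0
        assert abs(nw.bicor(x, y_out) - nw.bicor(x, y)) < 0.05
        assert abs(np.corrcoef(x, y_out)[0, 1] - np.corrcoef(x, y)[0, 1]) > 0.3

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(6, 50))
        mat = nw.bicor_matrix(x)
        for i in range(6):
            for j in range(6):
                assert mat[i, j] == pytest.approx(nw.bicor(x[i], x[j]), abs=1e-10)

    def test_zero_mad_falls_back_to_pearson(self):
        x = np.array([0.0] * 30 + [1.0] * 30)  # MAD = 0, median 0.5... degenerate
        y = np.linspace(0, 1, 60)
        r = nw.bicor(x, y)
        assert np.isfinite(r)


class TestAdjacencyAndTom:
    def test_signed_adjacency_endpoints(self):
        r = np.array([[1.0, 1.0, -1.0, 0.0]] * 4)
        a = nw.signed_adjacency(r, 7)
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(0.0)
        assert a[0, 3] == pytest.approx(0.5**7)
        assert (np.diag(a) == 0).all()

    def test_two_node_tom_equals_adjacency(self):
        a = np.array([[0.0, 0.3], [0.3, 0.0]])
        tom = nw.topological_overlap(a)
        assert tom[0, 1] == pytest.approx(0.3)
        assert tom[0, 0] == 1.0

    def test_complete_graph_tom_is_one(self):
        a = np.ones((5, 5))
        np.fill_diagonal(a, 0.0)
        tom = nw.topological_overlap(a)
        np.testing.assert_allclose(tom, 1.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 1, (50, 50))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = nw.topological_overlap(a)
        k = a.sum(axis=1)
        for i in range(50):
            for j in range(50):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(50) if u not in (i, j))
                # the vectorised form includes u = i and u = j in the product
                shared_full = sum(a[i, u] * a[u, j] for u in range(50))
                expected = (shared_full + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert abs(tom[i, j] - expected) < 1e-10

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(8)
        r = np.clip(rng.normal(0, 0.3, (40, 40)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        a = nw.signed_adjacency(r, 7)
        tom = nw.topological_overlap(a)
        for m in (a, tom):
            assert np.allclose(m, m.T)
            assert m.min() >= 0.0 and m.max() <= 1.0


def _two_block_data(rng, n_per_block=150, n_noise=0, n_samples=60, rho=0.7):
    blocks = []
    truth = []
    for b in range(2):
        f = rng.normal(size=n_samples)
        blocks.append(
            np.sqrt(rho) * f[None, :] + np.sqrt(1 - rho) * rng.normal(size=(n_per_block, n_samples))
        )
        truth += [b + 1] * n_per_block
    if n_noise:
        blocks.append(rng.normal(size=(n_noise, n_samples)))
        truth += [0] * n_noise
    return _frame(np.vstack(blocks)), np.array(truth)


class TestModuleDetection:
    def test_two_planted_blocks_exactly_recovered(self):
        rng = np.random.default_rng(9)
        data, truth = _two_block_data(rng)
        tom = nw.topological_overlap(nw.signed_adjacency(nw.bicor_matrix(data), 7))
        labels = nw.detect_modules(tom, data=data, min_module_size=100)
        assert labels.max() == 2
        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)

    def test_blocks_survive_surrounding_noise(self):
        rng = np.random.default_rng(10)
        data, truth = _two_block_data(rng, n_noise=300)
        labels, _ = nw.build_network(data, min_module_size=100)
        assert adjusted_rand_score(truth, labels.loc[data.index]) > 0.8

    def test_pure_noise_yields_no_modules(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            data = _frame(rng.normal(size=(400, 60)))
            tom = nw.topological_overlap(nw.signed_adjacency(nw.bicor_matrix(data), 7))
            labels = nw.detect_modules(tom, data=data, min_module_size=100)
            assert labels.max() == 0

    def test_duplicate_blocks_merged(self):
        rng = np.random.default_rng(12)
        f = rng.normal(size=60)
        block = lambda: np.sqrt(0.9) * f[None, :] + np.sqrt(0.1) * rng.normal(size=(120, 60))  # noqa: E731
        data = _frame(np.vstack([block(), block()]))
        tom = nw.topological_overlap(nw.signed_adjacency(nw.bicor_matrix(data), 7))
        labels = nw.detect_modules(tom, data=data, min_module_size=100)
        assert labels.max() == 1  # same latent factor: merged by eigengene rule

    def test_too_few_probes_all_unassigned(self):
        rng = np.random.default_rng(13)
        data = _frame(rng.normal(size=(30, 40)))
        tom = nw.topological_overlap(nw.signed_adjacency(nw.bicor_matrix(data), 7))
        labels = nw.detect_modules(tom, data=data, min_module_size=100)
        assert (labels == 0).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(14)
        data, _ = _two_block_data(rng, n_per_block=120, n_noise=100)
        shuffled = data.sample(frac=1.0, random_state=0)
        labels_a, _ = nw.build_network(data, min_module_size=100)
        labels_b, _ = nw.build_network(shuffled, min_module_size=100)
        # identical after aligning on probe id (labels may permute)
        aligned = labels_b.loc[labels_a.index]
        assert adjusted_rand_score(labels_a, aligned) == pytest.approx(1.0)


class TestEigengene:
    def test_identical_probes_give_standardised_values(self):
        rng = np.random.default_rng(15)
        row = rng.uniform(0.2, 0.8, 40)
        data = _frame(np.tile(row, (5, 1)))
        eig = nw.module_eigengene(data, data.index)
        expected = (row - row.mean()) / row.std(ddof=1)
        np.testing.assert_allclose(eig.to_numpy(), expected, atol=1e-8)

    def test_rank_one_factor_recovered(self):
        rng = np.random.default_rng(16)
        f = rng.normal(size=50)
        load = rng.uniform(0.5, 1.5, 80)
        data = _frame(load[:, None] * f[None, :] + rng.normal(0, 0.1, (80, 50)))
        eig = nw.module_eigengene(data, data.index)
        assert abs(np.corrcoef(eig, f)[0, 1]) > 0.99

    def test_single_probe_module(self):
        rng = np.random.default_rng(17)
        data = _frame(rng.uniform(0, 1, (1, 30)))
        eig = nw.module_eigengene(data, data.index)
        assert eig.std(ddof=1) == pytest.approx(1.0)
        assert np.corrcoef(eig, data.iloc[0])[0, 1] > 0.999

    def test_unit_variance_and_sign_anchor(self):
        rng = np.random.default_rng(18)
        data, _ = _two_block_data(rng, n_per_block=60)
        eig = nw.module_eigengene(data, data.index[:60])
        assert eig.std(ddof=1) == pytest.approx(1.0)
        assert np.corrcoef(eig, data.iloc[:60].mean(axis=0))[0, 1] > 0


class TestTraitAssociation:
    def test_planted_diagnosis_module_reaches_fdr(self):
        rng = np.random.default_rng(19)
        design = sd.SyntheticDesign(
            n_probes=900,
            n_chromosomes=2,
            n_donors_per_group={"CTL": 30, "iASD": 30},
            regions=("PFC", "TC"),
            noise_sd=0.03,
            donor_sd=0.01,
            sex_chrom=False,
            baseline_beta_profile=np.random.default_rng(99).uniform(0.2, 0.8, 900),
            seed=20,
        )
        man = sd.generate_manifest(design)
        mods = sd.plant_modules(
            man, sizes=[150, 150], loading=0.04, diagnosis_shift={"iASD": 0.5}, rng=rng
        )
        design = design.with_(planted_modules=mods)
        beta, _, pheno, truth = sd.generate_cohort(design, man)
        labels, eig = nw.build_network(nw.residualize(beta, pheno, remove=("age",)), min_module_size=100)
        assert labels.max() >= 2
        assoc = nw.module_trait_association(eig, pheno, contrasts=(("iASD", "CTL"),))
        assert assoc["significant"].any()
        # the significant modules overlap the planted ones
        planted = set(truth.modules["probe_id"])
        for m in assoc.loc[assoc["significant"], "module"]:
            members = set(labels.index[labels == int(str(m)[1:])])
            assert len(members & planted) / len(members) > 0.5

    def test_null_eigengene_not_called(self):
        rng = np.random.default_rng(21)
        n = 40
        pheno = pd.DataFrame(
            {
                "donor_id": [f"d{i // 2}" for i in range(n)],
                "region": ["PFC", "TC"] * (n // 2),
                "diagnosis": ["CTL"] * (n // 2) + ["iASD"] * (n // 2),
                "age": rng.uniform(10, 70, n),
                "sex": rng.choice(["M", "F"], n),
                "bank": "A",
                "neuronal_proportion": np.nan,
            },
            index=[f"s{i}" for i in range(n)],
        )
        hits = 0
        reps = 40
        for _ in range(reps):
            eig = pd.DataFrame({"M1": rng.normal(size=n)}, index=pheno.index)
            assoc = nw.module_trait_association(
                eig, pheno, contrasts=(("iASD", "CTL"),), covariates=("age", "sex")
            )
            hits += int(assoc["significant"].iloc[0])
        assert hits <= 0.15 * reps

    def test_empty_contrast_group_rejected(self):
        rng = np.random.default_rng(22)
        pheno = pd.DataFrame(
            {
                "donor_id": ["d1", "d2"],
                "region": ["PFC", "PFC"],
                "diagnosis": ["CTL", "CTL"],
                "age": [30.0, 40.0],
                "sex": ["M", "F"],
                "bank": "A",
                "neuronal_proportion": np.nan,
            },
            index=["s1", "s2"],
        )
        eig = pd.DataFrame({"M1": rng.normal(size=2)}, index=pheno.index)
        with pytest.raises(FormatError):
            nw.module_trait_association(eig, pheno, contrasts=(("iASD", "CTL"),))

    def test_fdr_monotone_in_p(self):
        rng = np.random.default_rng(23)
        n = 60
        pheno = pd.DataFrame(
            {
                "donor_id": [f"d{i // 2}" for i in range(n)],
                "region": ["PFC", "TC"] * (n // 2),
                "diagnosis": ["CTL"] * (n // 2) + ["iASD"] * (n // 2),
                "age": rng.uniform(10, 70, n),
                "sex": rng.choice(["M", "F"], n),
                "bank": "A",
                "neuronal_proportion": np.nan,
            },
            index=[f"s{i}" for i in range(n)],
        )
        case = (pheno["diagnosis"] == "iASD").to_numpy(float)
        eig = pd.DataFrame(
            {f"M{k}": 0.05 * k * case + rng.normal(size=n) for k in range(1, 8)},
            index=pheno.index,
        )
        assoc = nw.module_trait_association(
            eig, pheno, contrasts=(("iASD", "CTL"),), covariates=("age", "sex")
        )
        df = assoc.sort_values("p_value")
        assert df["fdr"].is_monotonic_increasing
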