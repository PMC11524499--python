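"""PCA-LDA: eigenstructure, oracle equivalence, loadings and attribution."""

import numpy as np
import pandas as pd
import pytest

import ramclav as rc
from ramclav.chemometrics import attribute_loadings, lda_fit, pca_fit, pca_lda
from ramclav.spectra_io import SpectrumMeta


def _labelled_set(X, labels_meta=None):
    """Wrap a matrix as a SpectrumSet with minimal metadata."""
    x = np.linspace(594.0, 1704.0, X.shape[1])
    spectra = []
    for i in range(X.shape[0]):
        meta = labels_meta[i] if labels_meta else None
        spectra.append(rc.RamanSpectrum(x, X[i], meta))
    return rc.SpectrumSet(spectra)


class TestPca:
    def test_two_spectra_one_nonzero_component(self, rng):
        X = np.vstack([rng.normal(size=50), rng.normal(size=50)])
        model = pca_fit(X, n_components=None)
        assert model.n_retained == 1
        assert model.explained_variance_[0] > 0

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(12, 40))
        model = pca_fit(X, n_components=None)
        Xr = model.inverse_transform(model.transform(X))
        assert np.abs(Xr - X).max() < 1e-8

    def test_orthonormal_loadings_and_sorted_variance(self, rng):
        X = rng.normal(size=(30, 60))
        model = pca_fit(X, n_components=10)
        G = model.components_ @ model.components_.T
        assert np.abs(G - np.eye(10)).max() < 1e-8
        assert (np.diff(model.explained_variance_) <= 1e-12).all()

    def test_three_factor_elbow(self, rng):
        factors = np.linalg.qr(rng.normal(size=(60, 3)))[0].T  # 3 orthonormal rows
        weights = rng.normal(size=(40, 3)) * np.array([10.0, 6.0, 3.0])
        X = 5.0 + weights @ factors + 1e-4 * rng.normal(size=(40, 60))
        model = pca_fit(X, n_components=None)
        ev = model.explained_variance_
        assert ev[:3].sum() / ev.sum() >= 0.99

    def test_scores_centered(self, rng):
        X = rng.normal(loc=3.0, size=(25, 30))
        model = pca_fit(X, n_components=5)
        assert np.abs(model.transform(X).mean(axis=0)).max() < 1e-8

    def test_variance_fraction_policy(self, rng):
        X = rng.normal(size=(30, 20))
        model = pca_fit(X, variance_fraction=0.5)
        cum = np.cumsum(model.explained_variance_)
        assert model.n_retained >= 1


class TestLda:
    def _clouds(self, rng, n_classes=3, sep=10.0, n=20, p=5):
        centers = rng.normal(size=(n_classes, p)) * sep
        X = np.vstack([centers[c] + rng.normal(size=(n, p)) for c in range(n_classes)])
        y = np.repeat(np.arange(n_classes), n)
        return X, y

    def test_three_classes_two_discriminants(self, rng):
        X, y = self._clouds(rng)
        model = lda_fit(X, y)
        assert model.directions.shape[1] == 2
        assert model.eigenvalues[0] >= model.eigenvalues[1]

    def test_separated_clouds_no_overlap_on_ld1(self, rng):
        X, y = self._clouds(rng, n_classes=2, sep=10.0)
        model = lda_fit(X, y)
        proj = X @ model.directions[:, 0]
        a, b = proj[y == 0], proj[y == 1]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or (
            a.max() < b.min() or b.max() < a.min()
        )

    def test_singleton_class_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        y = np.array(["a", "a", "b", "b", "solo"])
        with pytest.raises(ValueError, match="solo"):
            lda_fit(X, y)

    def test_shuffled_labels_collapse_eigenvalues(self, rng):
        X, y = self._clouds(rng, n_classes=2, sep=10.0, n=30)
        ev0 = lda_fit(X, y).eigenvalues[0]
        collapsed = 0
        for _ in range(100):
            ys = rng.permutation(y)
            collapsed += lda_fit(X, ys).eigenvalues[0] < 0.1 * ev0
        assert collapsed >= 95

    def test_eigenvalues_match_brute_force_solve(self, rng):
        """Oracle: generalized eigenvalues equal eig(inv(Sw+ridge) @ Sb)."""
        for _ in range(10):
            n_per, p = 20 // 2, 50
            X = rng.normal(size=(20, p)) @ rng.normal(size=(p, p)) * 0.3
            y = np.repeat([0, 1], n_per)
            X[y == 1] += rng.normal(size=p)
            T = pca_fit(X, n_components=10).transform(X)
            model = lda_fit(T, y)

            classes = np.unique(y)
            mu = T.mean(axis=0)
            Sw = np.zeros((T.shape[1],) * 2)
            Sb = np.zeros_like(Sw)
            for c in classes:
                Tc = T[y == c]
                mc = Tc.mean(axis=0)
                Sw += (Tc - mc).T @ (Tc - mc)
                Sb += len(Tc) * np.outer(mc - mu, mc - mu)
            M = np.linalg.inv(Sw + model.ridge * np.eye(T.shape[1])) @ Sb
            brute = np.sort(np.real(np.linalg.eigvals(M)))[::-1][: len(classes) - 1]
            assert np.allclose(model.eigenvalues, brute, rtol=1e-6)


def _age_cohort_single_cause(default_spec, seed=0, band="phosphate",
                             mults=(1.0, 1.15, 1.35)):
    """Cohort where *only* one band's amplitude differs by age group; the
    remaining within-class variation is isotropic measurement noise.

    The protein envelope (amide I) is strengthened so the varied band's own
    normalized contrast dominates the contrast that vector normalization
    couples into every other band.
    """
    effects = rc.GroupEffectSpec(
        age={band: dict(zip(rc.AGE_GROUPS, mults))},
        cv_individual=0.0,
        cv_measurement=0.0,
    )
    from dataclasses import replace

    bands = tuple(
        rc.BandModel("amide_i", 1660.0, 60.0, 0.9, 1500.0)
        if b.name == "amide_i" else b
        for b in default_spec.bands
    )
    spec = replace(default_spec, effects=effects, bands=bands, seed=seed)
    return rc.preprocess_set(rc.simulate_cohort(spec))


class TestPcaLda:
    def test_single_cause_loading_peaks_in_phosphate_window(self, default_spec):
        processed = _age_cohort_single_cause(default_spec)
        res = pca_lda(processed, "age_group")
        L = res.loadings
        x = L["wavenumber_cm1"].to_numpy()
        v = np.abs(L["LD1"].to_numpy())
        peak_wn = x[np.argmax(v)]
        assert 930.0 <= peak_wn <= 990.0
        top = res.attribution.table
        assert top[(top.ld == "LD1") & (top["rank"] == 1)].band.iloc[0] == "phosphate"

    def test_class_means_ordered_with_generative_multipliers(self, default_spec):
        processed = _age_cohort_single_cause(default_spec)
        res = pca_lda(processed, "age_group")
        means = res.class_means.set_index("label")["LD1"]
        diffs = np.diff([means[g] for g in rc.AGE_GROUPS])
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_single_cause_amide_iii_attributed(self, default_spec):
        processed = _age_cohort_single_cause(
            default_spec, band="amide_iii", mults=(1.0, 0.85, 0.7)
        )
        res = pca_lda(processed, "age_group")
        top = res.attribution.table
        assert top[(top.ld == "LD1") & (top["rank"] == 1)].band.iloc[0] == "amide_iii"

    def test_relabeling_symmetry(self, default_spec):
        processed = _age_cohort_single_cause(default_spec)
        res1 = pca_lda(processed, "age_group")
        swap = {"13-18": "30-40", "18-30": "18-30", "30-40": "13-18"}
        labels = np.array([swap[s.meta.age_group] for s in processed])
        res2 = pca_lda(processed, labels)
        assert np.allclose(
            res1.loadings["LD1"], res2.loadings["LD1"], atol=1e-8
        )

    def test_spectrum_order_invariance(self, default_spec):
        processed = _age_cohort_single_cause(default_spec)
        res1 = pca_lda(processed, "age_group")
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(processed))
        shuffled = rc.SpectrumSet([processed[int(i)] for i in perm])
        res2 = pca_lda(shuffled, "age_group")
        assert np.allclose(res1.lda.eigenvalues, res2.lda.eigenvalues, rtol=1e-8)
        assert np.allclose(
            res1.loadings["LD1"], res2.loadings["LD1"], atol=1e-7
        )

    def test_sign_convention(self, processed):
        res = pca_lda(processed, "age_group")
        for col in ("LD1", "LD2"):
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0


class TestAttribution:
    def test_loading_confined_to_phosphate_window(self):
        x = np.arange(594.0, 1705.0)
        v = np.where((x >= 930) & (x <= 990), 0.5, 0.0)
        df = pd.DataFrame({"wavenumber_cm1": x, "LD1": v})
        res = attribute_loadings(df)
        assert res.table[res.table["rank"] == 1].band.iloc[0] == "phosphate"
        assert not res.degenerate

    def test_all_zero_loading_degenerate(self):
        x = np.arange(594.0, 1705.0)
        df = pd.DataFrame({"wavenumber_cm1": x, "LD1": np.zeros_like(x)})
        res = attribute_loadings(df)
        assert res.table.empty
        assert res.degenerate == ["LD1"]
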