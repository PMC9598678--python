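"""Ground-truth contracts of the synthetic crossover generator."""

import numpy as np
import pytest
from scipy import stats

from crossmet import SimulationConfig, generate_dataset, render_spectrum
from crossmet.peaks import PeakDef, serum_peak_library, synthetic_peak_library
from crossmet.synthetic import ConfigurationError, default_study_config, true_concentrations


def paired_effect(ds, metabolite, pair):
    """Paired Cohen's d_z from the generator's stored true concentrations."""
    tc = true_concentrations(ds)
    d = ds.design
    a = tc[d["treatment"] == pair[0]].copy()
    b = tc[d["treatment"] == pair[1]].copy()
    a.index = d.loc[d["treatment"] == pair[0], "subject"]
    b.index = d.loc[d["treatment"] == pair[1], "subject"]
    diff = (a - b.loc[a.index])[metabolite]
    return diff.mean() / diff.std(ddof=1)


class TestRenderSpectrum:
    def test_zero_concentrations_zero_noise_gives_flat_zero(self):
        lib = serum_peak_library()
        ppm = np.linspace(0.5, 9.0, 500)
        s = render_spectrum({}, lib, ppm, noise_sd=0.0)
        assert np.all(s.intensity == 0.0)

    def test_single_peak_maximum_at_center(self):
        lib = [PeakDef("x", 3.0, 0.01, 1.0)]
        ppm = np.linspace(2.0, 4.0, 2001)  # grid passes through 3.0 exactly
        s = render_spectrum({"x": 2.0}, lib, ppm)
        assert s.ppm[np.argmax(s.intensity)] == pytest.approx(3.0, abs=1e-12)
        assert s.intensity.max() == pytest.approx(2.0)

    def test_doubling_level_doubles_isolated_integral(self):
        lib = [PeakDef("x", 3.0, 0.01, 1.0)]
        ppm = np.linspace(2.0, 4.0, 4001)
        s1 = render_spectrum({"x": 1.0}, lib, ppm)
        s2 = render_spectrum({"x": 2.0}, lib, ppm)
        i1 = np.trapezoid(s1.intensity, s1.ppm)
        i2 = np.trapezoid(s2.intensity, s2.ppm)
        assert i2 == pytest.approx(2 * i1, rel=1e-12)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            render_spectrum({"x": 1.0}, [], np.linspace(0, 1, 10))

    def test_unknown_metabolite_rejected(self):
        lib = [PeakDef("x", 3.0, 0.01)]
        with pytest.raises(KeyError, match="ghost"):
            render_spectrum({"ghost": 1.0}, lib, np.linspace(0, 5, 10))


class TestGenerateDataset:
    def test_study_shape_33_subjects_3_treatments(self):
        ds = generate_dataset(SimulationConfig(n_subjects=33, render_spectra=False, seed=0))
        assert len(ds.design) == 99
        assert (ds.design.groupby("subject").size() == 3).all()
        assert ds.design["treatment"].value_counts().tolist() == [33, 33, 33]

    def test_no_subject_effect_gives_null_between_block(self):
        cfg = SimulationConfig(
            n_subjects=40, treatments=("A", "B"), sigma_between=0.0,
            sigma_within=0.1, render_spectra=False, seed=3,
        )
        tc = true_concentrations(generate_dataset(cfg))
        subj_means = tc.groupby([s.split("_")[0] for s in tc.index]).mean()
        centered = subj_means - subj_means.mean()
        # subject means deviate only by sampling noise of K-sample averages
        assert centered.to_numpy().std() == pytest.approx(0.1 / np.sqrt(2), rel=0.25)

    def test_paired_effect_round_trip(self):
        # planted +2 SD on acetone recovers d = 2.0 +/- 0.3 averaged over seeds
        ds_recovered = []
        for seed in range(50):
            cfg = SimulationConfig(
                n_subjects=33, treatments=("FOO", "VOO"),
                planted_effects={("FOO", "VOO"): {"acetone": 2.0}},
                render_spectra=False, seed=seed,
            )
            ds_recovered.append(paired_effect(generate_dataset(cfg), "acetone", ("FOO", "VOO")))
        assert np.mean(ds_recovered) == pytest.approx(2.0, abs=0.3)

    def test_same_seed_byte_identical_output(self, tmp_path):
        cfg = default_study_config(seed=11, n_subjects=6, n_points=512)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_dataset(cfg).save(d1)
        generate_dataset(cfg).save(d2)
        for f1 in sorted(d1.rglob("*")):
            if f1.is_file():
                f2 = d2 / f1.relative_to(d1)
                assert f1.read_bytes() == f2.read_bytes(), f1.name

    def test_variance_decomposition(self):
        # total variance ~ sigma_b^2 + sigma_w^2 + planted component
        sb, sw, d = 0.12, 0.08, 2.0
        delta = d * np.sqrt(2) * sw
        expected = sb**2 + sw**2 + (delta / 2) ** 2
        tot = []
        for seed in range(100):
            cfg = SimulationConfig(
                n_subjects=20, treatments=("A", "B"), sigma_between=sb, sigma_within=sw,
                planted_effects={("A", "B"): {"glycine": d}}, render_spectra=False, seed=seed,
            )
            tc = true_concentrations(generate_dataset(cfg))
            tot.append(tc["glycine"].var(ddof=0))
        assert np.mean(tot) == pytest.approx(expected, rel=0.1)

    def test_copula_rank_correlations_recovered(self):
        cfg = SimulationConfig(
            n_subjects=200, treatments=("A", "B"),
            clinical_loadings={("glutamine", "HDL-C"): 0.48,
                               ("histidine", "triglycerides"): -0.33},
            render_spectra=False, seed=1,
        )
        ds = generate_dataset(cfg)
        r1 = stats.spearmanr(ds.features["glutamine"], ds.clinical["HDL-C"]).statistic
        r2 = stats.spearmanr(ds.features["histidine"], ds.clinical["triglycerides"]).statistic
        assert r1 == pytest.approx(0.48, abs=0.1)
        assert r2 == pytest.approx(-0.33, abs=0.1)

    def test_rendered_dataset_carries_spectra_with_anchor(self):
        cfg = SimulationConfig(n_subjects=3, treatments=("A", "B"), n_points=2048, seed=0)
        ds = generate_dataset(cfg)
        assert len(ds.spectra) == 6
        s = ds.spectra[0]
        window = (s.ppm > 5.17) & (s.ppm < 5.28)
        assert s.intensity[window].max() > 10 * s.intensity[(s.ppm > 8.5)].std()

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(treatments=("A",)), "K >= 2"),
            (dict(sigma_within=0.0), "sigma_within"),
            (dict(sigma_between=-1.0), "sigma_between"),
            (dict(planted_effects={("A", "B"): {"unobtainium": 1.0}},
                  treatments=("A", "B")), "unobtainium"),
            (dict(planted_effects={("A", "A"): {"glycine": 1.0}},
                  treatments=("A", "B")), "invalid treatment pair"),
            (dict(clinical_loadings={("glycine", "NOPE"): 0.3}), "NOPE"),
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs, match):
        with pytest.raises(ConfigurationError, match=match):
            SimulationConfig(render_spectra=False, **kwargs)

    def test_overloaded_clinical_variable_rejected(self):
        cfg = SimulationConfig(
            treatments=("A", "B"), render_spectra=False,
            clinical_loadings={("glutamine", "HDL-C"): 0.9, ("glycine", "HDL-C"): 0.9},
        )
        with pytest.raises(ConfigurationError, match="latent variance"):
            generate_dataset(cfg)

    def test_synthetic_library_supports_arbitrary_names(self):
        names = [f"v{i}" for i in range(8)]
        lib = synthetic_peak_library(names)
        cfg = SimulationConfig(
            n_subjects=4, treatments=("A", "B"), peak_library=lib,
            planted_effects={("A", "B"): {"v3": 1.0}},
            baselines={n: 1.0 for n in names}, render_spectra=False, seed=0,
        )
        ds = generate_dataset(cfg)
        assert list(ds.features.columns) == names + ["glucose"]
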