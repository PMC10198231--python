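import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

from tremormpp.errors import (
    CalibrationError,
    InvalidBandError,
    ValidationError,
)
from tremormpp.signal_model import (
    DEFAULT_DRUGS,
    KO,
    WT,
    BackgroundModel,
    CohortDesign,
    DrugModel,
    EpochSchedule,
    EpochSpec,
    Genotype,
    TremorModel,
    alcohol_model,
    effect_multiplier,
    expected_mpp,
    flat_spectrum_chance_fraction,
    ganaxolone_model,
    invert_expected_mpp,
    simulate_background,
    simulate_cohort,
    simulate_session,
    simulate_tremor,
)
from tremormpp.spectral_mpp import compute_mpp, estimate_psd, band_power


def welch_band_fraction(x, fs=128.0):
    f, p = sps.welch(x, fs=fs, nperseg=1024, noverlap=512, detrend="constant")
    df = f[1] - f[0]
    band = p[(f >= 9) & (f <= 16)].sum() * df
    total = p[(f >= 0.25) & (f <= 32)].sum() * df
    return band / total


class TestChanceFraction:
    def test_tremor_band_value(self):
        # direct arithmetic oracle: (16-9)/(32-0.25)
        assert flat_spectrum_chance_fraction(9, 16, 0.25, 32) == pytest.approx(
            7.0 / 31.75
        )

    def test_identity_band(self):
        assert flat_spectrum_chance_fraction(0.25, 32, 0.25, 32) == 1.0

    def test_degenerate_band(self):
        assert flat_spectrum_chance_fraction(9, 9.000001, 0.25, 32) == pytest.approx(
            0.0, abs=1e-6
        )

    @pytest.mark.parametrize("args", [(16, 9, 0.25, 32), (0.25, 16, 9, 32), (9, 40, 0.25, 32)])
    def test_ordering_violation(self, args):
        with pytest.raises(InvalidBandError):
            flat_spectrum_chance_fraction(*args)


class TestEpochSchedule:
    def test_default_layout(self):
        sched = EpochSchedule.default()
        assert sched.labels == ("B", "H1", "H2", "E1", "E2", "E3", "E4")
        gaps = {e.label: e.gap_before_s for e in sched}
        assert gaps["E1"] == 600.0 and gaps["H1"] == 300.0 and gaps["B"] == 0.0
        assert all(e.duration_s == 900.0 for e in sched)

    def test_rejects_out_of_order(self):
        with pytest.raises(ValidationError):
            EpochSchedule((EpochSpec("H1"), EpochSpec("B")))

    def test_rejects_duplicates(self):
        with pytest.raises(ValidationError):
            EpochSchedule((EpochSpec("B"), EpochSpec("B")))


class TestBackgroundModel:
    def test_fraction_must_exceed_chance(self):
        with pytest.raises(CalibrationError):
            BackgroundModel(in_band_fraction=0.20)
        with pytest.raises(CalibrationError):
            BackgroundModel(in_band_fraction=1.0)

    def test_chance_level_fraction(self, rng):
        # mixing weight ~0: reduces to the flat-spectrum oracle
        model = BackgroundModel(in_band_fraction=0.2205, fraction_sd=0.0)
        tr = simulate_background(900, 128, model, rng)
        assert welch_band_fraction(tr.samples) == pytest.approx(0.2205, abs=0.02)

    def test_default_fraction_calibration(self, rng):
        model = BackgroundModel(in_band_fraction=0.32, fraction_sd=0.0)
        tr = simulate_background(900, 128, model, rng)
        assert welch_band_fraction(tr.samples) == pytest.approx(0.32, abs=0.02)

    def test_zero_variance_gives_zero_trace(self, rng):
        model = BackgroundModel(total_variance=0.0)
        tr = simulate_background(900, 128, model, rng)
        assert np.all(tr.samples == 0.0)

    def test_total_variance_calibration(self, rng):
        # components are exactly scaled; only their sample cross-covariance
        # perturbs the sum
        model = BackgroundModel(total_variance=3.5, fraction_sd=0.0)
        tr = simulate_background(300, 128, model, rng)
        assert tr.samples.var() == pytest.approx(3.5, rel=0.02)


class TestTremorModel:
    def test_support_must_stay_in_band(self):
        with pytest.raises(ValidationError):
            TremorModel(center_hz=9.0, bandwidth_hz=4.0)

    def test_full_suppression_is_silent(self, rng):
        x = simulate_tremor(120, 128, 1.0, TremorModel(), 1.0, rng)
        assert np.all(x == 0.0)

    def test_variance_ratio(self, rng):
        x = simulate_tremor(900, 128, 2.0, TremorModel(variance_ratio=2.24), 0.0, rng)
        assert x.var() / 2.0 == pytest.approx(2.24, rel=0.05)

    def test_band_confinement(self, rng):
        # periodogram-integration oracle: >= 99% of power in 9-16 Hz
        x = simulate_tremor(
            900, 128, 1.0, TremorModel(center_hz=12.0, bandwidth_hz=3.0), 0.0, rng
        )
        f, p = sps.periodogram(x, fs=128.0)
        in_band = p[(f >= 9) & (f <= 16)].sum() / p.sum()
        assert in_band >= 0.99

    def test_suppression_scales_variance(self, rng):
        x = simulate_tremor(300, 128, 1.0, TremorModel(), 0.5, rng)
        assert x.var() == pytest.approx(2.24 * 0.5, rel=1e-9)


class TestEffectMultiplier:
    def test_zero_dose(self):
        for drug in DEFAULT_DRUGS.values():
            assert effect_multiplier(drug, 0.0, "E1", WT) == 0.0

    def test_alcohol_cleared_after_e1(self):
        assert effect_multiplier(alcohol_model(), 0.575, "E3", WT) == 0.0

    def test_knockout_never_responds(self):
        assert effect_multiplier(ganaxolone_model(), 10.0, "E4", KO) == 0.0

    def test_pre_injection_epochs_unaffected(self):
        for ep in ("B", "H1", "H2"):
            assert effect_multiplier(alcohol_model(), 0.575, ep, WT) == 0.0

    def test_monotone_in_dose(self):
        for drug in DEFAULT_DRUGS.values():
            epoch = sorted(drug.active_epochs)[0]
            s = [effect_multiplier(drug, d, epoch, WT) for d in drug.dose_levels]
            assert all(a <= b for a, b in zip(s, s[1:]))
            assert s[-1] > 0

    def test_hill_formula(self):
        drug = DrugModel("x", (0.0, 1.0), "u", emax=0.8, ed50=1.0, hill=2.0,
                         active_epochs=frozenset({"E1"}))
        assert effect_multiplier(drug, 1.0, "E1", WT) == pytest.approx(0.4)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValidationError):
            effect_multiplier(alcohol_model(), -1.0, "E1", WT)


class TestSession:
    def test_epoch_structure(self, rng, short_schedule, background):
        traces = simulate_session(
            WT, 0.0, short_schedule, background, TremorModel(), alcohol_model(), rng
        )
        assert [t.epoch for t in traces] == ["B", "H1", "E1"]
        assert all(t.n_samples == 120 * 128 for t in traces)

    def test_baseline_only_schedule_is_tremor_free(self, rng, deterministic_background):
        sched = EpochSchedule((EpochSpec("B", 120.0),))
        traces = simulate_session(
            WT, 0.575, sched, deterministic_background, TremorModel(),
            alcohol_model(), rng,
        )
        assert len(traces) == 1
        # all power at chance-ish levels: no 9-16 Hz excess beyond mixture weight
        assert welch_band_fraction(traces[0].samples) == pytest.approx(0.32, abs=0.03)

    def test_variance_additivity(self, rng, deterministic_background, deterministic_tremor):
        sched = EpochSchedule((EpochSpec("H1", 900.0),))
        traces = simulate_session(
            WT, 0.0, sched, deterministic_background, deterministic_tremor,
            alcohol_model(), rng,
        )
        assert traces[0].samples.var() == pytest.approx(1.0 + 2.24, rel=0.05)

    def test_vehicle_profile_low_baseline_high_tremor(self, rng, short_schedule, background):
        traces = simulate_session(
            WT, 0.0, short_schedule, background, TremorModel(), alcohol_model(), rng
        )
        mpps = {t.epoch: compute_mpp(t).mpp for t in traces}
        assert mpps["B"] < 45 < mpps["H1"]
        assert mpps["E1"] > 60

    def test_hardware_filter_path(self, rng, deterministic_background):
        sched = EpochSchedule((EpochSpec("B", 120.0),))
        traces = simulate_session(
            WT, 0.0, sched, deterministic_background, TremorModel(),
            alcohol_model(), rng, hardware_filter=True,
        )
        spec = estimate_psd(traces[0])
        # high-pass attenuates the sub-1 Hz content
        low = band_power(spec, 0.25, 0.75)
        mid = band_power(spec, 2.0, 3.0)
        assert low < mid


class TestExpectedMPP:
    def test_closed_form_matches_monte_carlo(self, deterministic_background):
        tm = TremorModel(animal_sd=0.0, epoch_sd=0.0)
        sched = EpochSchedule((EpochSpec("H1", 300.0),))
        vals = []
        for i in range(10):
            tr = simulate_session(
                WT, 0.0, sched, deterministic_background, tm, alcohol_model(),
                np.random.default_rng(i),
            )[0]
            vals.append(compute_mpp(tr).mpp)
        assert np.mean(vals) == pytest.approx(
            expected_mpp(deterministic_background, 2.24), abs=2.0
        )

    def test_inverse_roundtrip(self, background):
        for r in (0.0, 0.5, 2.24, 5.0):
            assert invert_expected_mpp(background, expected_mpp(background, r)) == (
                pytest.approx(r, abs=1e-12)
            )

    def test_suppression_monotone_in_dose(self, background):
        drug = alcohol_model()
        mpps = [
            expected_mpp(background, 2.24, effect_multiplier(drug, d, "E1", WT))
            for d in drug.dose_levels
        ]
        assert all(a >= b for a, b in zip(mpps, mpps[1:]))


class TestCohort:
    def _design(self, sizes, genotypes=(WT,), seed=7):
        return CohortDesign(
            drug=alcohol_model(),
            genotypes=genotypes,
            group_sizes={g.label: sizes for g in genotypes},
            schedule=EpochSchedule((EpochSpec("B", 60.0), EpochSpec("H1", 60.0))),
            background=BackgroundModel(),
            tremor=TremorModel(),
            master_seed=seed,
        )

    def test_determinism(self):
        t1, m1 = simulate_cohort(self._design((2, 2, 2, 2)))
        t2, m2 = simulate_cohort(self._design((2, 2, 2, 2)))
        assert m1.equals(m2)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.samples, b.samples)

    def test_published_group_sizes(self):
        design = self._design((11, 11, 12, 11))
        assert design.n_animals("WT") == 45
        _, manifest = simulate_cohort(design)
        assert len(manifest) == 45

    def test_empty_genotypes(self):
        design = CohortDesign(
            drug=alcohol_model(),
            genotypes=(),
            group_sizes={},
            schedule=EpochSchedule((EpochSpec("B", 60.0),)),
            background=BackgroundModel(),
            tremor=TremorModel(),
            master_seed=0,
        )
        traces, manifest = simulate_cohort(design)
        assert traces == []
        assert list(manifest.columns) == [
            "animal_id", "genotype", "drug", "dose", "group", "seed",
        ]

    def test_group_size_independence(self):
        # adding animals to one cell leaves other cells' traces untouched
        small, _ = simulate_cohort(self._design((2, 2, 2, 2)))
        big, _ = simulate_cohort(self._design((2, 4, 2, 2)))
        small_d0 = [t for t in small if t.animal_id.startswith("WT-d0")]
        big_d0 = [t for t in big if t.animal_id.startswith("WT-d0")]
        for a, b in zip(small_d0, big_d0):
            assert np.array_equal(a.samples, b.samples)

    def test_cell_size_minimum(self):
        with pytest.raises(ValidationError):
            self._design((1, 2, 2, 2))


class TestGenotypeNull:
    def test_ko_distribution_matches_vehicle(self):
        # KS oracle: KO at top dose vs WT vehicle, E1 MPP, 100 animals each
        sched = EpochSchedule((EpochSpec("E1", 120.0),))
        bg, tm, drug = BackgroundModel(), TremorModel(), ganaxolone_model()
        ko = [
            compute_mpp(
                simulate_session(KO, 10.0, sched, bg, tm, drug,
                                 np.random.default_rng(1000 + i))[0]
            ).mpp
            for i in range(100)
        ]
        veh = [
            compute_mpp(
                simulate_session(WT, 0.0, sched, bg, tm, drug,
                                 np.random.default_rng(2000 + i))[0]
            ).mpp
            for i in range(100)
        ]
        assert stats.ks_2samp(ko, veh).pvalue > 0.01

    def test_ko_rejects_responsive_flag(self):
        with pytest.raises(ValidationError):
            Genotype("KO", drug_responsive=True)
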