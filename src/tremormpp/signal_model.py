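"""Synthetic motion-sensor signal generator.

Generates per-animal load-platform traces with the statistical structure the
downstream analysis assumes: a broadband background ("locomotion") spectrum,
a band-limited 9-16 Hz tremor component whose variance is scaled by a
dose/epoch/genotype-dependent suppression multiplier, and deterministic
per-animal seeding so cohorts regenerate bit-identically.

All components are realised as brick-wall band-limited Gaussian noise,
synthesised in the frequency domain and rescaled to an exact target variance,
so band confinement and variance book-keeping are exact rather than
approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .errors import (
    CalibrationError,
    InvalidBandError,
    ManifestError,
    ValidationError,
)

EPOCH_ORDER: tuple[str, ...] = ("B", "H1", "H2", "E1", "E2", "E3", "E4")
#: epochs recorded after drug/vehicle injection
POST_INJECTION_EPOCHS: tuple[str, ...] = ("E1", "E2", "E3", "E4")
#: epochs in which the tremorgenic agent is on board
TREMOR_EPOCHS: tuple[str, ...] = ("H1", "H2", "E1", "E2", "E3", "E4")

TREMOR_BAND: tuple[float, float] = (9.0, 16.0)
TOTAL_BAND: tuple[float, float] = (0.25, 32.0)
DEFAULT_SAMPLE_RATE_HZ: float = 128.0
DEFAULT_EPOCH_DURATION_S: float = 900.0


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EpochSpec:
    """One recorded epoch: its label, length, and the unrecorded gap before it."""

    label: str
    duration_s: float = DEFAULT_EPOCH_DURATION_S
    gap_before_s: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in EPOCH_ORDER:
            raise ValidationError(f"unknown epoch label {self.label!r}")
        if self.duration_s <= 0:
            raise ValidationError("epoch duration must be positive")
        if self.gap_before_s < 0:
            raise ValidationError("gap_before_s must be nonnegative")


@dataclass(frozen=True)
class EpochSchedule:
    """Ordered recording schedule; a subset of B, H1, H2, E1..E4 in that order."""

    epochs: tuple[EpochSpec, ...]

    def __post_init__(self) -> None:
        labels = [e.label for e in self.epochs]
        if len(set(labels)) != len(labels):
            raise ValidationError("epoch labels must be unique")
        order = [EPOCH_ORDER.index(lab) for lab in labels]
        if order != sorted(order):
            raise ValidationError(
                f"epochs must appear in canonical order {EPOCH_ORDER}, got {labels}"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.epochs)

    def __iter__(self) -> Iterator[EpochSpec]:
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    @classmethod
    def default(
        cls,
        duration_s: float = DEFAULT_EPOCH_DURATION_S,
        rest_s: float = 300.0,
        post_injection_gap_s: float = 600.0,
    ) -> "EpochSchedule":
        """Full session: B, H1, H2, then E1-E4 resuming after the injection gap."""
        specs = []
        for lab in EPOCH_ORDER:
            if lab == "B":
                gap = 0.0
            elif lab == "E1":
                gap = post_injection_gap_s
            else:
                gap = rest_s
            specs.append(EpochSpec(lab, duration_s, gap))
        return cls(tuple(specs))


def flat_spectrum_chance_fraction(
    band_lo: float, band_hi: float, total_lo: float = TOTAL_BAND[0], total_hi: float = TOTAL_BAND[1]
) -> float:
    """Fraction of a flat spectrum's band power that falls in [band_lo, band_hi].

    This is the chance-level value of the band-power ratio for a white
    (spectrally flat) signal: (band_hi - band_lo) / (total_hi - total_lo).
    """
    if not (total_lo <= band_lo < band_hi <= total_hi):
        raise InvalidBandError(
            f"require total_lo <= band_lo < band_hi <= total_hi, got "
            f"({band_lo}, {band_hi}) within ({total_lo}, {total_hi})"
        )
    return (band_hi - band_lo) / (total_hi - total_lo)


@dataclass(frozen=True)
class BackgroundModel:
    """Two-component background spectrum over the total analysis band.

    A flat component spanning ``total_band`` plus a band-limited component
    confined to ``tremor_band``; the mixing weight is chosen so the expected
    fraction of background power inside the tremor band equals
    ``in_band_fraction``.  ``fraction_sd`` adds per-animal jitter to that
    fraction (baseline individuality).
    """

    total_variance: float = 1.0
    in_band_fraction: float = 0.32
    tremor_band: tuple[float, float] = TREMOR_BAND
    total_band: tuple[float, float] = TOTAL_BAND
    fraction_sd: float = 0.038

    def __post_init__(self) -> None:
        if self.total_variance < 0:
            raise ValidationError("total_variance must be >= 0")
        chance = self.chance_fraction
        if not (chance < self.in_band_fraction < 1.0):
            raise CalibrationError(
                f"in_band_fraction must lie strictly between the flat-spectrum "
                f"chance value {chance:.4f} and 1, got {self.in_band_fraction}"
            )
        if self.fraction_sd < 0:
            raise ValidationError("fraction_sd must be >= 0")

    @property
    def chance_fraction(self) -> float:
        lo, hi = self.tremor_band
        tlo, thi = self.total_band
        return flat_spectrum_chance_fraction(lo, hi, tlo, thi)

    @property
    def band_mix_weight(self) -> float:
        """Variance share of the band-limited component implied by in_band_fraction."""
        c = self.chance_fraction
        return (self.in_band_fraction - c) / (1.0 - c)


@dataclass(frozen=True)
class TremorModel:
    """Band-limited tremor component plus its between/within-animal variability.

    ``variance_ratio`` is the tremor variance expressed as a multiple of the
    background total variance.  Per-animal (``animal_sd``) and per-epoch
    (``epoch_sd``) lognormal multipliers give cohorts realistic dispersion;
    both are mean-corrected so the expected ratio stays ``variance_ratio``.
    """

    variance_ratio: float = 2.24
    center_hz: float = 12.0
    bandwidth_hz: float = 4.0
    animal_sd: float = 0.18
    epoch_sd: float = 0.07

    def __post_init__(self) -> None:
        if self.variance_ratio < 0:
            raise ValidationError("variance_ratio must be >= 0")
        if self.bandwidth_hz <= 0:
            raise ValidationError("bandwidth_hz must be > 0")
        lo, hi = self.band
        if lo < TREMOR_BAND[0] or hi > TREMOR_BAND[1]:
            raise ValidationError(
                f"tremor support [{lo}, {hi}] must lie within {TREMOR_BAND}"
            )
        if self.animal_sd < 0 or self.epoch_sd < 0:
            raise ValidationError("variability SDs must be >= 0")

    @property
    def band(self) -> tuple[float, float]:
        half = self.bandwidth_hz / 2.0
        return (self.center_hz - half, self.center_hz + half)


@dataclass(frozen=True)
class DrugModel:
    """Sigmoidal (Emax/Hill) dose -> fractional tremor-variance suppression.

    The drug acts only during ``active_epochs`` (its clearance profile) and
    only in drug-responsive genotypes.
    """

    name: str
    dose_levels: tuple[float, ...]
    dose_unit: str
    emax: float
    ed50: float
    hill: float
    active_epochs: frozenset[str]

    def __post_init__(self) -> None:
        if not 0.0 <= self.emax <= 1.0:
            raise ValidationError("emax must be in [0, 1]")
        if self.ed50 <= 0 or self.hill <= 0:
            raise ValidationError("ed50 and hill must be > 0")
        if any(d < 0 for d in self.dose_levels):
            raise ValidationError("doses must be nonnegative")
        if list(self.dose_levels) != sorted(self.dose_levels):
            raise ValidationError("dose_levels must be ordered")
        bad = set(self.active_epochs) - set(POST_INJECTION_EPOCHS)
        if bad:
            raise ValidationError(f"active_epochs must be within E1..E4, got {bad}")


@dataclass(frozen=True)
class Genotype:
    label: str
    drug_responsive: bool

    def __post_init__(self) -> None:
        if self.label not in ("WT", "KO"):
            raise ValidationError("genotype label must be 'WT' or 'KO'")
        if self.label == "KO" and self.drug_responsive:
            raise ValidationError("KO genotype cannot be drug-responsive")


WT = Genotype("WT", drug_responsive=True)
KO = Genotype("KO", drug_responsive=False)


def alcohol_model() -> DrugModel:
    """Rapidly cleared drug active only during E1; doses in g/kg."""
    return DrugModel(
        name="alcohol",
        dose_levels=(0.0, 0.40, 0.50, 0.575),
        dose_unit="g/kg",
        emax=0.8,
        ed50=0.48,
        hill=16.0,
        active_epochs=frozenset({"E1"}),
    )


def ganaxolone_model() -> DrugModel:
    """Long-acting drug active through E1-E4; doses in mg/kg."""
    return DrugModel(
        name="ganaxolone",
        dose_levels=(0.0, 3.5, 7.0, 10.0),
        dose_unit="mg/kg",
        emax=0.8,
        ed50=5.0,
        hill=8.0,
        active_epochs=frozenset(POST_INJECTION_EPOCHS),
    )


DEFAULT_DRUGS: dict[str, DrugModel] = {}
for _f in (alcohol_model, ganaxolone_model):
    _m = _f()
    DEFAULT_DRUGS[_m.name] = _m


@dataclass(frozen=True)
class MotionTrace:
    """One epoch of uniformly sampled motion-sensor signal plus metadata."""

    sample_rate_hz: float
    samples: np.ndarray
    animal_id: str = ""
    genotype: str = ""
    drug: str = ""
    dose: float = 0.0
    epoch: str = ""
    seed: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("trace samples must be finite")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class CohortDesign:
    """Genotypes x doses x group sizes x epoch schedule, plus generator models."""

    drug: DrugModel
    genotypes: tuple[Genotype, ...]
    group_sizes: Mapping[str, tuple[int, ...]]  # genotype label -> n per dose
    schedule: EpochSchedule
    background: BackgroundModel
    tremor: TremorModel
    master_seed: int
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    hardware_filter: bool = False

    def __post_init__(self) -> None:
        for g in self.genotypes:
            sizes = self.group_sizes.get(g.label)
            if sizes is None:
                raise ValidationError(f"group_sizes missing genotype {g.label!r}")
            if len(sizes) != len(self.drug.dose_levels):
                raise ValidationError(
                    f"group_sizes[{g.label!r}] must have one entry per dose"
                )
            if any(n < 2 for n in sizes):
                raise ValidationError("every (genotype, dose) cell needs n >= 2")

    def n_animals(self, genotype_label: str) -> int:
        return int(sum(self.group_sizes[genotype_label]))


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------


def _band_limited_noise(
    n: int,
    sample_rate_hz: float,
    lo: float,
    hi: float,
    variance: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise brick-wall limited to [lo, hi] Hz, rescaled to an exact variance."""
    if variance < 0:
        raise ValidationError("variance must be >= 0")
    if variance == 0.0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    idx = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    # sample the band's Fourier coefficients directly (equivalent to FFT of
    # white noise, cheaper than transforming a full-length realisation)
    spec = np.zeros(freqs.size, dtype=complex)
    spec[idx] = rng.standard_normal(idx.size) + 1j * rng.standard_normal(idx.size)
    if idx.size and idx[0] == 0:
        spec[0] = spec[0].real
    if idx.size and idx[-1] == freqs.size - 1 and n % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, n)
    v = x.var()
    if v <= 0:  # band contained no resolvable bins
        return np.zeros(n)
    return x * np.sqrt(variance / v)


def simulate_background(
    duration_s: float,
    sample_rate_hz: float,
    model: BackgroundModel,
    rng: np.random.Generator,
    *,
    in_band_fraction: float | None = None,
    **trace_meta,
) -> MotionTrace:
    """Simulate the drug-free background signal.

    The expected fraction of power inside the tremor band equals the model's
    ``in_band_fraction`` (or the per-animal override).
    """
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    n = int(round(duration_s * sample_rate_hz))
    if in_band_fraction is not None:
        model = replace(model, in_band_fraction=in_band_fraction)
    w = model.band_mix_weight
    v = model.total_variance
    flat = _band_limited_noise(
        n, sample_rate_hz, *model.total_band, (1.0 - w) * v, rng
    )
    band = _band_limited_noise(
        n, sample_rate_hz, *model.tremor_band, w * v, rng
    )
    return MotionTrace(sample_rate_hz, flat + band, **trace_meta)


def simulate_tremor(
    duration_s: float,
    sample_rate_hz: float,
    background_variance: float,
    model: TremorModel,
    suppression: float,
    rng: np.random.Generator,
    *,
    variance_ratio: float | None = None,
) -> np.ndarray:
    """Band-limited tremor component with variance ratio*(1-suppression)*background.

    Returns raw samples (a component, not a standalone trace).
    """
    if not 0.0 <= suppression <= 1.0:
        raise ValidationError("suppression must be in [0, 1]")
    ratio = model.variance_ratio if variance_ratio is None else variance_ratio
    n = int(round(duration_s * sample_rate_hz))
    var = ratio * background_variance * (1.0 - suppression)
    return _band_limited_noise(n, sample_rate_hz, *model.band, var, rng)


def effect_multiplier(
    drug: DrugModel, dose: float, epoch_label: str, genotype: Genotype
) -> float:
    """Fractional tremor-variance suppression for a design cell at one epoch.

    Zero before injection (B, H1, H2), zero in non-responsive genotypes, zero
    outside the drug's active epochs, otherwise Emax/Hill in dose.
    """
    if dose < 0:
        raise ValidationError("dose must be nonnegative")
    if epoch_label not in EPOCH_ORDER:
        raise ValidationError(f"unknown epoch label {epoch_label!r}")
    if epoch_label not in POST_INJECTION_EPOCHS:
        return 0.0
    if not genotype.drug_responsive:
        return 0.0
    if epoch_label not in drug.active_epochs:
        return 0.0
    if dose == 0.0:
        return 0.0
    dh = dose**drug.hill
    return drug.emax * dh / (drug.ed50**drug.hill + dh)


def _hardware_bandpass(x: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """Optional amplifier emulation: 2nd-order Butterworth band-pass, 1-70 Hz.

    The upper edge is clipped below Nyquist (70 Hz exceeds Nyquist at 128 Hz
    sampling, where the analog filter corner is invisible anyway).
    """
    nyq = sample_rate_hz / 2.0
    hi = min(70.0, 0.99 * nyq)
    sos = _sig.butter(2, [1.0, hi], btype="bandpass", fs=sample_rate_hz, output="sos")
    return _sig.sosfilt(sos, x)


def simulate_session(
    genotype: Genotype,
    dose: float,
    schedule: EpochSchedule,
    background: BackgroundModel,
    tremor: TremorModel,
    drug: DrugModel,
    rng: np.random.Generator,
    *,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    hardware_filter: bool = False,
    animal_id: str = "",
    seed_label: str = "",
) -> list[MotionTrace]:
    """Simulate one animal's full recording session (one trace per epoch).

    A single latent animal trait drives both the baseline in-band fraction
    and the tremor-variance multiplier, so one animal's MPP offset is shared
    across all epochs (the compound-symmetry structure the downstream mixed
    ANOVA assumes); a smaller per-epoch multiplier adds within-animal
    variation.  B is tremor-free; H1/H2 carry the full tremor; E1-E4 are
    scaled by ``1 - effect_multiplier``.
    """
    chance = background.chance_fraction
    z_i = rng.standard_normal()  # latent per-animal motion trait
    f_i = background.in_band_fraction
    if background.fraction_sd > 0:
        f_i = float(
            np.clip(
                f_i + background.fraction_sd * z_i,
                chance + 1e-3,
                0.98,
            )
        )
    # mean-corrected lognormal multiplier: E[ratio] stays at variance_ratio
    a_i = tremor.animal_sd * z_i - tremor.animal_sd**2 / 2.0

    traces: list[MotionTrace] = []
    for spec in schedule:
        meta = dict(
            animal_id=animal_id,
            genotype=genotype.label,
            drug=drug.name,
            dose=dose,
            epoch=spec.label,
            seed=seed_label,
        )
        bg = simulate_background(
            spec.duration_s,
            sample_rate_hz,
            background,
            rng,
            in_band_fraction=f_i,
            **meta,
        )
        x = bg.samples
        if spec.label in TREMOR_EPOCHS and tremor.variance_ratio > 0:
            e_ie = tremor.epoch_sd * rng.standard_normal() - tremor.epoch_sd**2 / 2.0
            ratio_ie = tremor.variance_ratio * np.exp(a_i + e_ie)
            s = effect_multiplier(drug, dose, spec.label, genotype)
            x = x + simulate_tremor(
                spec.duration_s,
                sample_rate_hz,
                background.total_variance,
                tremor,
                s,
                rng,
                variance_ratio=ratio_ie,
            )
        if hardware_filter:
            x = _hardware_bandpass(x, sample_rate_hz)
        traces.append(MotionTrace(sample_rate_hz, x, **meta))
    return traces


def animal_seed(master_seed: int, genotype_index: int, dose_index: int, animal_index: int) -> np.random.SeedSequence:
    """Counter-based per-animal seed: independent of group sizes elsewhere."""
    return np.random.SeedSequence(
        entropy=master_seed, spawn_key=(genotype_index, dose_index, animal_index)
    )


def iter_cohort_sessions(
    design: CohortDesign,
) -> Iterator[tuple[dict, list[MotionTrace]]]:
    """Yield (manifest row, session traces) per animal, streaming.

    Seeds are derived per animal from the master seed and the animal's
    position in the design, so regeneration is bit-identical and adding
    animals to one cell never perturbs another.
    """
    for gi, genotype in enumerate(design.genotypes):
        sizes = design.group_sizes[genotype.label]
        for di, (dose, n) in enumerate(zip(design.drug.dose_levels, sizes)):
            for ai in range(n):
                ss = animal_seed(design.master_seed, gi, di, ai)
                rng = np.random.default_rng(ss)
                animal_id = f"{genotype.label}-d{di}-a{ai:02d}"
                seed_label = f"{design.master_seed}:{gi}.{di}.{ai}"
                traces = simulate_session(
                    genotype,
                    dose,
                    design.schedule,
                    design.background,
                    design.tremor,
                    design.drug,
                    rng,
                    sample_rate_hz=design.sample_rate_hz,
                    hardware_filter=design.hardware_filter,
                    animal_id=animal_id,
                    seed_label=seed_label,
                )
                row = dict(
                    animal_id=animal_id,
                    genotype=genotype.label,
                    drug=design.drug.name,
                    dose=dose,
                    group=f"{genotype.label}:{dose}",
                    seed=seed_label,
                )
                yield row, traces


def simulate_cohort(design: CohortDesign) -> tuple[list[MotionTrace], pd.DataFrame]:
    """Materialise a full cohort: all traces plus the design manifest."""
    traces: list[MotionTrace] = []
    rows: list[dict] = []
    for row, session in iter_cohort_sessions(design):
        rows.append(row)
        traces.extend(session)
    manifest = pd.DataFrame(
        rows, columns=["animal_id", "genotype", "drug", "dose", "group", "seed"]
    )
    if manifest["animal_id"].duplicated().any():
        raise ManifestError("duplicate animal ids in cohort manifest")
    return traces, manifest


def expected_mpp(
    background: BackgroundModel, tremor_variance_ratio: float, suppression: float = 0.0
) -> float:
    """Closed-form expected motion-power percentage for the generator.

    E[MPP] = 100 * (f*B + T) / (B + T) with f the background in-band fraction,
    B the background variance and T the effective tremor variance.
    """
    f = background.in_band_fraction
    t = tremor_variance_ratio * (1.0 - suppression)
    return 100.0 * (f + t) / (1.0 + t)


def invert_expected_mpp(background: BackgroundModel, mpp: float) -> float:
    """Effective tremor-variance ratio implied by an expected MPP value.

    Inverse of :func:`expected_mpp`; used for effect-size recovery in
    variance units.
    """
    m = mpp / 100.0
    f = background.in_band_fraction
    if m >= 1.0:
        raise ValidationError("mpp must be < 100 to invert")
    return max(0.0, (m - f) / (1.0 - m))
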