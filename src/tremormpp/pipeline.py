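"""End-to-end experiment orchestration: simulate -> quantify -> analyze -> report.

An :class:`ExperimentConfig` fully describes one drug x mouse-line
experiment (both genotypes); :func:`run_experiment` produces a tidy MPP
table, per-genotype repeated-measures fits, protected LSD dose comparisons
for the post-injection epochs, and figure-style mean +/- SE curves, all
reproducible bit-identically from the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .errors import LookupError_, ValidationError
from .rm_stats import (
    ComparisonResult,
    NormalityReport,
    RMAnovaFit,
    check_residual_normality,
    fit_rm_anova,
    lsd_compare,
    summarize_experiment,
)
from .signal_model import (
    DEFAULT_DRUGS,
    DEFAULT_SAMPLE_RATE_HZ,
    KO,
    POST_INJECTION_EPOCHS,
    WT,
    BackgroundModel,
    CohortDesign,
    DrugModel,
    EpochSchedule,
    EpochSpec,
    Genotype,
    TremorModel,
    iter_cohort_sessions,
)
from .spectral_mpp import (
    DEFAULT_OVERLAP,
    DEFAULT_WINDOW_S,
    MPP_COLUMNS,
    BandDefinition,
    compute_mpp,
)

logger = logging.getLogger("tremormpp")

#: per-dose group sizes for each published drug x line experiment
PUBLISHED_GROUP_SIZES: dict[tuple[str, str], dict[str, tuple[int, ...]]] = {
    ("alcohol", "delta"): {"WT": (11, 11, 12, 11), "KO": (11, 11, 12, 11)},
    ("alcohol", "alpha6"): {"WT": (12, 11, 12, 12), "KO": (12, 12, 12, 12)},
    ("ganaxolone", "delta"): {"WT": (11, 11, 10, 11), "KO": (11, 11, 11, 11)},
    ("ganaxolone", "alpha6"): {"WT": (12, 12, 12, 12), "KO": (12, 12, 12, 12)},
}

_GENOTYPES = {"WT": WT, "KO": KO}


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun one experiment deterministically."""

    drug: DrugModel
    line: str
    genotypes: tuple[str, ...]
    group_sizes: Mapping[str, tuple[int, ...]]
    schedule: EpochSchedule
    background: BackgroundModel = BackgroundModel()
    tremor: TremorModel = TremorModel()
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    hardware_filter: bool = False
    window_length_s: float = DEFAULT_WINDOW_S
    overlap_fraction: float = DEFAULT_OVERLAP
    alpha: float = 0.05
    master_seed: int = 0
    output_dir: str | None = None
    keep_traces: bool = False

    def __post_init__(self) -> None:
        for g in self.genotypes:
            if g not in _GENOTYPES:
                raise ValidationError(f"unknown genotype label {g!r}")
            if g not in self.group_sizes:
                raise ValidationError(f"group_sizes missing genotype {g!r}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "drug": {
                "name": self.drug.name,
                "dose_levels": list(self.drug.dose_levels),
                "dose_unit": self.drug.dose_unit,
                "emax": self.drug.emax,
                "ed50": self.drug.ed50,
                "hill": self.drug.hill,
                "active_epochs": sorted(self.drug.active_epochs),
            },
            "line": self.line,
            "genotypes": list(self.genotypes),
            "group_sizes": {k: list(v) for k, v in self.group_sizes.items()},
            "schedule": [
                {"label": e.label, "duration_s": e.duration_s, "gap_before_s": e.gap_before_s}
                for e in self.schedule
            ],
            "background": dataclasses.asdict(self.background)
            | {
                "tremor_band": list(self.background.tremor_band),
                "total_band": list(self.background.total_band),
            },
            "tremor": dataclasses.asdict(self.tremor),
            "sample_rate_hz": self.sample_rate_hz,
            "hardware_filter": self.hardware_filter,
            "window_length_s": self.window_length_s,
            "overlap_fraction": self.overlap_fraction,
            "alpha": self.alpha,
            "master_seed": self.master_seed,
            "output_dir": self.output_dir,
            "keep_traces": self.keep_traces,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        drug = DrugModel(
            name=d["drug"]["name"],
            dose_levels=tuple(d["drug"]["dose_levels"]),
            dose_unit=d["drug"]["dose_unit"],
            emax=d["drug"]["emax"],
            ed50=d["drug"]["ed50"],
            hill=d["drug"]["hill"],
            active_epochs=frozenset(d["drug"]["active_epochs"]),
        )
        bg = dict(d["background"])
        bg["tremor_band"] = tuple(bg["tremor_band"])
        bg["total_band"] = tuple(bg["total_band"])
        return cls(
            drug=drug,
            line=d["line"],
            genotypes=tuple(d["genotypes"]),
            group_sizes={k: tuple(v) for k, v in d["group_sizes"].items()},
            schedule=EpochSchedule(tuple(EpochSpec(**e) for e in d["schedule"])),
            background=BackgroundModel(**bg),
            tremor=TremorModel(**d["tremor"]),
            sample_rate_hz=d["sample_rate_hz"],
            hardware_filter=d["hardware_filter"],
            window_length_s=d["window_length_s"],
            overlap_fraction=d["overlap_fraction"],
            alpha=d["alpha"],
            master_seed=d["master_seed"],
            output_dir=d.get("output_dir"),
            keep_traces=d.get("keep_traces", False),
        )

    def to_yaml(self, path: Path | str) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def design(self) -> CohortDesign:
        return CohortDesign(
            drug=self.drug,
            genotypes=tuple(_GENOTYPES[g] for g in self.genotypes),
            group_sizes=dict(self.group_sizes),
            schedule=self.schedule,
            background=self.background,
            tremor=self.tremor,
            master_seed=self.master_seed,
            sample_rate_hz=self.sample_rate_hz,
            hardware_filter=self.hardware_filter,
        )


def make_published_defaults(
    drug_name: str, line_name: str, master_seed: int = 0, **overrides
) -> ExperimentConfig:
    """Config reproducing a published experiment's design cells.

    ``drug_name`` in {alcohol, ganaxolone}; ``line_name`` in {delta, alpha6}.
    """
    key = (drug_name, line_name)
    if key not in PUBLISHED_GROUP_SIZES:
        raise LookupError_(
            f"unknown experiment {key}; choose drug in {{alcohol, ganaxolone}} "
            f"and line in {{delta, alpha6}}"
        )
    cfg = ExperimentConfig(
        drug=DEFAULT_DRUGS[drug_name],
        line=line_name,
        genotypes=("WT", "KO"),
        group_sizes=PUBLISHED_GROUP_SIZES[key],
        schedule=EpochSchedule.default(),
        master_seed=master_seed,
    )
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def simulate_and_quantify(config: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stream cohort simulation into an MPP table; returns (mpp, manifest).

    Traces are discarded after quantification unless ``config.keep_traces``
    (written under <output_dir>/traces).
    """
    design = config.design()
    bands = BandDefinition(
        total_lo=config.background.total_band[0],
        total_hi=config.background.total_band[1],
        tremor_lo=config.background.tremor_band[0],
        tremor_hi=config.background.tremor_band[1],
    )
    min_dur = min(60.0, min(e.duration_s for e in config.schedule))
    rows: list[dict] = []
    manifest_rows: list[dict] = []
    trace_dir = (
        Path(config.output_dir) / "traces"
        if (config.keep_traces and config.output_dir)
        else None
    )
    for mrow, session in iter_cohort_sessions(design):
        manifest_rows.append(mrow)
        for trace in session:
            rec = compute_mpp(
                trace,
                bands,
                config.window_length_s,
                config.overlap_fraction,
                min_duration_s=min_dur,
            )
            rows.append(rec.__dict__)
            if trace_dir is not None:
                _io.write_trace(trace, trace_dir)
    mpp = pd.DataFrame(rows, columns=list(MPP_COLUMNS))
    manifest = pd.DataFrame(
        manifest_rows, columns=["animal_id", "genotype", "drug", "dose", "group", "seed"]
    )
    return mpp, manifest


def analyze_mpp(
    mpp: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, RMAnovaFit], dict[str, NormalityReport]]:
    """Per-genotype fits + protected LSD dose-vs-vehicle comparisons at E1-E4."""
    results = []
    fits: dict[str, RMAnovaFit] = {}
    reports: dict[str, NormalityReport] = {}
    for genotype in sorted(mpp["genotype"].unique()):
        sub = mpp[mpp["genotype"] == genotype]
        fit = fit_rm_anova(sub, alpha=alpha)
        fits[genotype] = fit
        reports[genotype] = check_residual_normality(fit)
        vehicle = min(fit.doses)
        comparisons: list[ComparisonResult] = []
        for epoch in fit.epochs:
            if epoch not in POST_INJECTION_EPOCHS:
                continue
            for dose in fit.doses:
                if dose == vehicle:
                    continue
                comparisons.append(lsd_compare(fit, epoch, dose, vehicle))
        results.append(summarize_experiment(fit, comparisons))
    table = (
        pd.concat(results, ignore_index=True)
        if results
        else summarize_experiment(next(iter(fits.values())), [])
    )
    return table, fits, reports


def curves_table(fits: Mapping[str, RMAnovaFit]) -> pd.DataFrame:
    """Figure-style long table: model-based mean +/- pooled SE per cell."""
    rows = []
    for genotype, fit in sorted(fits.items()):
        for dose in fit.doses:
            for epoch in fit.epochs:
                rows.append(
                    dict(
                        genotype=genotype,
                        dose=dose,
                        epoch=epoch,
                        mean=float(fit.cell_means.loc[dose, epoch]),
                        pooled_se=float(fit.pooled_se.loc[dose, epoch]),
                    )
                )
    return pd.DataFrame(rows, columns=["genotype", "dose", "epoch", "mean", "pooled_se"])


@dataclass(frozen=True)
class ExperimentReport:
    """Bundle of every artifact from one experiment run."""

    config: ExperimentConfig
    manifest: pd.DataFrame
    mpp: pd.DataFrame
    results: pd.DataFrame
    curves: pd.DataFrame
    fits: Mapping[str, RMAnovaFit]
    normality: Mapping[str, NormalityReport]
    provenance: dict


def _provenance(config: ExperimentConfig) -> dict:
    import scipy

    from . import __version__

    return {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "versions": {
            "tremormpp": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }


def _model_summary_text(fits: Mapping[str, RMAnovaFit]) -> str:
    lines = []
    for genotype, fit in sorted(fits.items()):
        lines.append(f"== genotype {genotype} (drug {fit.drug}) ==")
        lines.append(
            f"n per dose: {dict(zip(fit.doses, fit.n_per_dose))}; epochs: {fit.epochs}"
        )
        lines.append(
            f"variance components: animal {fit.sigma2_animal:.4f}, "
            f"residual {fit.sigma2_residual:.4f}"
        )
        for e in fit.effects:
            lines.append(
                f"F({e.name}) = {e.f:.4g} on ({e.df_num:.0f}, {e.df_den:.0f}) df, p = {e.p:.4g}"
            )
        for ep, e in fit.dose_within_epoch.items():
            lines.append(
                f"F(dose @ {ep}) = {e.f:.4g} on ({e.df_num:.0f}, {e.df_den:.1f}) df, "
                f"p = {e.p:.4g}"
            )
        lines.append("")
    return "\n".join(lines)


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Simulate, quantify, analyze, and (optionally) write artifacts to disk."""
    logger.info(
        "running experiment drug=%s line=%s seed=%d",
        config.drug.name,
        config.line,
        config.master_seed,
    )
    mpp, manifest = simulate_and_quantify(config)
    results, fits, normality = analyze_mpp(mpp, alpha=config.alpha)
    curves = curves_table(fits)
    report = ExperimentReport(
        config=config,
        manifest=manifest,
        mpp=mpp,
        results=results,
        curves=curves,
        fits=fits,
        normality=normality,
        provenance=_provenance(config),
    )
    if config.output_dir:
        write_report(report, config.output_dir)
    return report


def write_report(report: ExperimentReport, out_dir: Path | str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.config.to_yaml(out / "config.yaml")
    _io.write_manifest(report.manifest, out / "cohort_manifest.csv")
    report.mpp.to_csv(out / "mpp.csv", index=False)
    report.results.to_csv(out / "results.csv", index=False)
    report.curves.to_csv(out / "curves.csv", index=False)
    (out / "summary.txt").write_text(_model_summary_text(report.fits))
    with open(out / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2)
    for genotype, rep in report.normality.items():
        qq = pd.DataFrame(
            {
                "theoretical_quantile": rep.theoretical_quantiles,
                "observed_quantile": rep.observed_quantiles,
            }
        )
        qq.to_csv(out / f"qq_{genotype}.csv", index=False)


def plot_report(report: ExperimentReport, path: Path | str) -> None:
    """Dose-curve panels (one per genotype), mean +/- pooled SE per epoch."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genotypes = sorted(report.fits)
    fig, axes = plt.subplots(
        1, len(genotypes), figsize=(5 * len(genotypes), 4), squeeze=False
    )
    for ax, genotype in zip(axes[0], genotypes):
        fit = report.fits[genotype]
        xs = np.arange(len(fit.epochs))
        for dose in fit.doses:
            means = fit.cell_means.loc[dose].to_numpy()
            ses = fit.pooled_se.loc[dose].to_numpy()
            ax.errorbar(
                xs, means, yerr=ses, marker="o", capsize=3,
                label=f"{dose:g} {report.config.drug.dose_unit}",
            )
        ax.set_xticks(xs, fit.epochs)
        ax.set_ylabel("motion power percentage (%)")
        ax.set_title(f"{report.config.drug.name}, {report.config.line} {genotype}")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
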