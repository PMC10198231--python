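"""Repeated-measures mixed ANOVA on MPP tables, with protected Fisher LSD.

The model has fixed dose, epoch and dose x epoch effects and a per-animal
random intercept (compound-symmetry within-animal covariance).  For complete
within-animal data this is fitted in closed form by the classical split-plot
stratum decomposition, whose variance-component estimates coincide with REML
under compound symmetry; a unit test cross-checks against statsmodels'
iterative MixedLM fit.

Dose comparisons at a fixed epoch mix the between-animal and within-animal
strata, so their pooled variance is the combined mean square
((p-1)*MS_within + MS_between)/p with Satterthwaite degrees of freedom.
The Fisher-LSD comparisons are *protected*: a comparison is flagged
significant only when both the experiment-wide omnibus test (dose main
effect or dose x epoch interaction) and the dose-within-epoch simple-effect
test are significant at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import (
    DegenerateSampleError,
    DesignRankError,
    LookupError_,
    UnbalancedDesignError,
    ValidationError,
)
from .signal_model import EPOCH_ORDER

_TINY = 1e-12


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectTest:
    """One omnibus F test."""

    name: str
    ss: float
    df_num: float
    df_den: float
    f: float
    p: float


@dataclass(frozen=True)
class RMAnovaFit:
    """Fitted repeated-measures ANOVA for one genotype's MPP table."""

    genotype: str
    drug: str
    doses: tuple[float, ...]
    epochs: tuple[str, ...]
    n_per_dose: tuple[int, ...]
    cell_means: pd.DataFrame  # index: dose, columns: epoch
    pooled_se: pd.DataFrame  # SE of each cell mean, same shape
    ms_between: float
    df_between: float
    ms_within: float  # nan when only one epoch
    df_within: float
    comparison_variance: float  # combined between+within mean square
    comparison_df: float  # Satterthwaite df for the combined variance
    sigma2_animal: float
    sigma2_residual: float
    effects: tuple[EffectTest, ...]  # dose, epoch, dose:epoch
    dose_within_epoch: dict[str, EffectTest]
    residuals: np.ndarray
    alpha: float = 0.05

    def effect(self, name: str) -> EffectTest:
        for e in self.effects:
            if e.name == name:
                return e
        raise LookupError_(name)

    @property
    def omnibus_significant(self) -> bool:
        """Experiment-wide gate for protected LSD."""
        ps = [e.p for e in self.effects if e.name in ("dose", "dose:epoch")]
        ps = [p for p in ps if np.isfinite(p)]
        return bool(ps) and min(ps) <= self.alpha

    def n_for_dose(self, dose: float) -> int:
        try:
            return self.n_per_dose[self.doses.index(dose)]
        except ValueError as exc:
            raise LookupError_(f"dose {dose} not in fit") from exc


@dataclass(frozen=True)
class ComparisonResult:
    """One protected Fisher-LSD dose-vs-reference comparison at one epoch."""

    genotype: str
    drug: str
    epoch: str
    dose: float
    reference_dose: float
    mean_difference: float
    se: float
    t: float
    df: float
    p: float
    significant: bool


@dataclass(frozen=True)
class NormalityReport:
    """Shapiro-Wilk statistic plus normal quantile-plot coordinates."""

    w: float
    p: float
    theoretical_quantiles: np.ndarray
    observed_quantiles: np.ndarray


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def _as_wide(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[float], list[str]]:
    """Validate and reshape a tidy MPP table to an animals x epochs matrix.

    Returns (Y, dose per animal, ordered doses, ordered epochs); animals are
    sorted by id so the fit is invariant to input row order.
    """
    required = {"animal_id", "dose", "epoch", "mpp"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"MPP table missing columns {sorted(missing)}")
    df = table.copy()
    per_animal_dose = df.groupby("animal_id")["dose"].nunique()
    if (per_animal_dose > 1).any():
        bad = per_animal_dose[per_animal_dose > 1].index.tolist()
        raise ValidationError(f"animals in more than one dose group: {bad}")

    epochs = [e for e in EPOCH_ORDER if e in set(df["epoch"])]
    unknown = set(df["epoch"]) - set(EPOCH_ORDER)
    if unknown:
        raise ValidationError(f"unknown epoch labels {sorted(unknown)}")

    wide = df.pivot_table(
        index="animal_id", columns="epoch", values="mpp", aggfunc="first", sort=True
    )
    dup = df.duplicated(subset=["animal_id", "epoch"])
    if dup.any():
        raise ValidationError("duplicate (animal, epoch) rows")
    wide = wide.reindex(columns=epochs)
    if wide.isna().any().any():
        incomplete = wide.index[wide.isna().any(axis=1)].tolist()
        raise UnbalancedDesignError(
            f"animals missing epochs (no silent listwise deletion): {incomplete}"
        )
    dose_map = df.drop_duplicates("animal_id").set_index("animal_id")["dose"]
    dose_of = dose_map.reindex(wide.index).to_numpy(dtype=float)
    doses = sorted(set(dose_of.tolist()))
    return wide.to_numpy(dtype=float), dose_of, doses, epochs


def fit_rm_anova(table: pd.DataFrame, alpha: float = 0.05) -> RMAnovaFit:
    """Fit the repeated-measures (split-plot) ANOVA to one genotype's table."""
    genotypes = sorted(set(table.get("genotype", pd.Series(dtype=str)).astype(str)))
    if len(genotypes) > 1:
        raise ValidationError(
            f"fit one genotype at a time, got {genotypes}; filter the table first"
        )
    genotype = genotypes[0] if genotypes else ""
    drugs = sorted(set(table.get("drug", pd.Series(dtype=str)).astype(str)))
    drug = drugs[0] if len(drugs) == 1 else ""

    y, dose_of, doses, epochs = _as_wide(table)
    n_animals, p = y.shape
    d = len(doses)
    if d < 2:
        raise DesignRankError("need at least 2 dose groups")
    group_idx = [np.flatnonzero(dose_of == dv) for dv in doses]
    n_per = [len(ix) for ix in group_idx]
    if min(n_per) < 2:
        raise DesignRankError("need at least 2 animals per dose group")

    animal_means = y.mean(axis=1)
    grand = animal_means.mean()
    group_means = np.array([animal_means[ix].mean() for ix in group_idx])
    cell = np.vstack([y[ix].mean(axis=0) for ix in group_idx])  # D x p

    # between-animal stratum
    ss_dose = p * float(np.sum(np.array(n_per) * (group_means - grand) ** 2))
    ss_b_err = p * float(
        sum(np.sum((animal_means[ix] - gm) ** 2) for ix, gm in zip(group_idx, group_means))
    )
    df_b = n_animals - d
    ms_b = ss_b_err / df_b

    if p > 1:
        # within-animal stratum: residuals about animal mean + group profile
        resid = np.empty_like(y)
        for ix, gm, prof in zip(group_idx, group_means, cell):
            resid[ix] = y[ix] - animal_means[ix, None] - (prof - gm)[None, :]
        ss_w_err = float(np.sum(resid**2))
        df_w = (n_animals - d) * (p - 1)
        ms_w = ss_w_err / df_w

        col_means = y.mean(axis=0)
        ss_epoch = n_animals * float(np.sum((col_means - grand) ** 2))
        ss_cells_within = float(
            sum(n * np.sum((prof - gm) ** 2) for n, gm, prof in zip(n_per, group_means, cell))
        )
        ss_inter = max(0.0, ss_cells_within - ss_epoch)
        df_e, df_i = p - 1, (d - 1) * (p - 1)

        comb_var = ((p - 1) * ms_w + ms_b) / p
        denom = ((p - 1) * ms_w / p) ** 2 / df_w + (ms_b / p) ** 2 / df_b
        comb_df = comb_var**2 / denom if denom > _TINY else df_b
        sigma2_resid = ms_w
        sigma2_animal = max(0.0, (ms_b - ms_w) / p)
        residuals = resid.ravel()
    else:
        ms_w, df_w = float("nan"), 0.0
        ss_epoch = ss_inter = float("nan")
        df_e = df_i = 0
        comb_var, comb_df = ms_b, float(df_b)
        sigma2_resid = ms_b
        sigma2_animal = 0.0
        residuals = np.concatenate(
            [y[ix, 0] - cell[k, 0] for k, ix in enumerate(group_idx)]
        )

    def _ftest(name: str, ss: float, dfn: float, dfd: float, ms_err: float) -> EffectTest:
        if not np.isfinite(ss) or dfn <= 0:
            return EffectTest(name, float("nan"), dfn, dfd, float("nan"), float("nan"))
        if ss <= _TINY:
            return EffectTest(name, ss, dfn, dfd, 0.0, 1.0)
        if ms_err <= _TINY:
            return EffectTest(name, ss, dfn, dfd, float("inf"), 0.0)
        f = (ss / dfn) / ms_err
        return EffectTest(name, ss, dfn, dfd, f, float(_st.f.sf(f, dfn, dfd)))

    effects = (
        _ftest("dose", ss_dose, d - 1, df_b, ms_b),
        _ftest("epoch", ss_epoch, df_e, df_w, ms_w),
        _ftest("dose:epoch", ss_inter, df_i, df_w, ms_w),
    )

    # simple main effect of dose at each epoch, on the combined variance
    n_arr = np.asarray(n_per, dtype=float)
    dose_within: dict[str, EffectTest] = {}
    for j, ep in enumerate(epochs):
        col = cell[:, j]
        wbar = float(np.sum(n_arr * col) / n_animals)
        ss_e = float(np.sum(n_arr * (col - wbar) ** 2))
        dose_within[ep] = _ftest(f"dose@{ep}", ss_e, d - 1, comb_df, comb_var)

    cell_df = pd.DataFrame(cell, index=pd.Index(doses, name="dose"), columns=epochs)
    se_df = pd.DataFrame(
        np.sqrt(comb_var / n_arr)[:, None] * np.ones((1, p)),
        index=cell_df.index,
        columns=epochs,
    )

    return RMAnovaFit(
        genotype=genotype,
        drug=drug,
        doses=tuple(doses),
        epochs=tuple(epochs),
        n_per_dose=tuple(n_per),
        cell_means=cell_df,
        pooled_se=se_df,
        ms_between=ms_b,
        df_between=float(df_b),
        ms_within=ms_w,
        df_within=float(df_w),
        comparison_variance=comb_var,
        comparison_df=float(comb_df),
        sigma2_animal=sigma2_animal,
        sigma2_residual=sigma2_resid,
        effects=effects,
        dose_within_epoch=dose_within,
        residuals=residuals,
        alpha=alpha,
    )


# --------------------------------------------------------------------------
# comparisons and diagnostics
# --------------------------------------------------------------------------


def lsd_compare(
    fit: RMAnovaFit, epoch: str, dose: float, reference_dose: float = 0.0
) -> ComparisonResult:
    """Protected Fisher-LSD comparison of two dose means at one epoch.

    Two-sided t-type test on model-based cell means with the model's pooled
    SE.  ``significant`` applies the protection rule (omnibus and
    simple-effect gates) on top of p <= alpha.
    """
    if epoch not in fit.epochs:
        raise LookupError_(f"epoch {epoch!r} not in fit")
    for dv in (dose, reference_dose):
        if dv not in fit.doses:
            raise LookupError_(f"dose {dv} not in fit")
    m1 = float(fit.cell_means.loc[dose, epoch])
    m0 = float(fit.cell_means.loc[reference_dose, epoch])
    n1 = fit.n_for_dose(dose)
    n0 = fit.n_for_dose(reference_dose)
    se = float(np.sqrt(fit.comparison_variance * (1.0 / n1 + 1.0 / n0)))
    if dose == reference_dose:
        diff, t, p = 0.0, 0.0, 1.0
    else:
        diff = m1 - m0
        if se <= _TINY:
            t = 0.0 if abs(diff) <= _TINY else float("inf") * np.sign(diff)
            p = 1.0 if abs(diff) <= _TINY else 0.0
        else:
            t = diff / se
            p = float(2.0 * _st.t.sf(abs(t), fit.comparison_df))
    gate = (
        fit.omnibus_significant
        and fit.dose_within_epoch[epoch].p <= fit.alpha
    )
    return ComparisonResult(
        genotype=fit.genotype,
        drug=fit.drug,
        epoch=epoch,
        dose=dose,
        reference_dose=reference_dose,
        mean_difference=diff,
        se=se,
        t=t,
        df=fit.comparison_df,
        p=p,
        significant=bool(gate and p <= fit.alpha),
    )


def check_residual_normality(fit: RMAnovaFit) -> NormalityReport:
    """Shapiro-Wilk test and normal quantile-plot coordinates for the residuals."""
    resid = np.asarray(fit.residuals, dtype=float)
    if resid.size < 3:
        raise DegenerateSampleError("need at least 3 residuals")
    if np.ptp(resid) <= _TINY:
        raise DegenerateSampleError("residuals are constant")
    w, p = _st.shapiro(resid)
    (osm, osr) = _st.probplot(resid, dist="norm", fit=False)
    return NormalityReport(
        w=float(w),
        p=float(p),
        theoretical_quantiles=np.asarray(osm),
        observed_quantiles=np.asarray(osr),
    )


def significance_stars(p: float, significant: bool) -> str:
    """Figure-legend star convention at 0.05 / 0.01 / 0.001."""
    if not significant:
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    return "*"


SUMMARY_COLUMNS = (
    "genotype",
    "drug",
    "epoch",
    "dose",
    "reference_dose",
    "mean",
    "pooled_se",
    "diff_vs_vehicle",
    "se_diff",
    "t",
    "df",
    "p",
    "significant",
    "stars",
)


def summarize_experiment(
    fit: RMAnovaFit, comparisons: Iterable[ComparisonResult]
) -> pd.DataFrame:
    """Tidy per-epoch, per-dose results table mirroring figure annotations."""
    rows = []
    for c in comparisons:
        rows.append(
            dict(
                genotype=c.genotype,
                drug=c.drug,
                epoch=c.epoch,
                dose=c.dose,
                reference_dose=c.reference_dose,
                mean=float(fit.cell_means.loc[c.dose, c.epoch]),
                pooled_se=float(fit.pooled_se.loc[c.dose, c.epoch]),
                diff_vs_vehicle=c.mean_difference,
                se_diff=c.se,
                t=c.t,
                df=c.df,
                p=c.p,
                significant=c.significant,
                stars=significance_stars(c.p, c.significant),
            )
        )
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
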