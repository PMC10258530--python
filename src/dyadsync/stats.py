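"""Mixed-effects models linking neural coupling to behavioral synchrony.

The core analysis fits a ladder of linear mixed models (random intercept per
dyad) of increasing fixed-effect interaction depth — main effects only, all
2-way interactions, the full factorial — and selects the deepest model that
significantly improves fit.  Model comparison uses likelihood-ratio chi2 on
maximum-likelihood refits (REML likelihoods are not comparable across fixed-
effect structures); fixed-effect p-values use the normal approximation.
Per-cell simple slopes of the dependent on coupling, and real-vs-pseudo
group contrasts with Bonferroni correction, are derived from the fitted
models by linear contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats as spstats
import statsmodels.formula.api as smf

REQUIRED_COLUMNS = ("condition", "roi_pair", "wtc_z")


@dataclass
class ModelSpec:
    dependent: str = "total_sync"
    fixed: tuple[str, ...] = ("condition", "roi_pair", "wtc_z")
    grouping: str = "dyad_id"
    max_depth: int = 3
    alpha: float = 0.05
    correction: str = "bonferroni"

    def formula(self, depth: int) -> str:
        terms = " + ".join(self.fixed)
        if depth <= 1 or len(self.fixed) < 2:
            rhs = terms
        else:
            rhs = f"({terms}) ** {min(depth, len(self.fixed))}"
        return f"{self.dependent} ~ {rhs}"


@dataclass
class ModelReport:
    spec: ModelSpec
    fits: list = field(default_factory=list)           # MixedLMResults (ML)
    fits_reml: list = field(default_factory=list)      # REML refits (inference)
    formulas: list[str] = field(default_factory=list)
    comparisons: pd.DataFrame | None = None
    selected: int = 0
    eta_p2: float | None = None
    metadata: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def selected_fit(self):
        return self.fits[self.selected]

    @property
    def selected_formula(self) -> str:
        return self.formulas[self.selected]


def _check_data(data: pd.DataFrame, spec: ModelSpec) -> list[str]:
    notes = []
    for col in spec.fixed + (spec.dependent, spec.grouping):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    if data[spec.dependent].isna().any():
        raise ValueError("missing dependent values; apply outlier exclusion first")
    for col in spec.fixed:
        if data[col].nunique() < 2:
            notes.append(f"factor {col!r} has a single level")
    n_dup = int(data.duplicated().sum())
    if n_dup:
        notes.append(
            f"data-integrity warning: {n_dup} duplicate rows "
            "(estimates unchanged, precision artificially doubled)"
        )
    counts = data.groupby(
        [c for c in ("condition", "roi_pair") if c in data.columns]
    ).size()
    if counts.nunique() > 1:
        notes.append("unbalanced cells")
    return notes


def fit_model_ladder(data: pd.DataFrame, spec: ModelSpec | None = None) -> ModelReport:
    """Fit main-effects -> 2-way -> 3-way mixed models and select by LRT.

    Successive models are compared with a likelihood-ratio chi2 whose df is
    the difference in fixed-effect parameter counts; the deepest model that
    improves significantly on its predecessor (sequentially, at
    ``spec.alpha``) is flagged selected.  Singular fits are reported in the
    warnings list, never silently dropped.
    """
    spec = spec or ModelSpec()
    notes = _check_data(data, spec)
    report = ModelReport(spec=spec, warnings=notes)
    report.metadata = {
        "estimation": "ML for model comparison; REML refits for inference",
        "comparison": "likelihood-ratio chi2, df = parameter-count difference",
        "p_values": "normal approximation for fixed effects (REML covariance)",
    }

    rows = []
    for depth in range(1, spec.max_depth + 1):
        formula = spec.formula(depth)
        model = smf.mixedlm(formula, data, groups=data[spec.grouping])
        import warnings as _w

        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            fit = model.fit(reml=False)
            fit_reml = smf.mixedlm(
                formula, data, groups=data[spec.grouping]
            ).fit(reml=True)
        for c in caught:
            msg = str(c.message)
            if "singular" in msg.lower() or "converge" in msg.lower():
                report.warnings.append(f"depth {depth}: {msg}")
        report.fits.append(fit)
        report.fits_reml.append(fit_reml)
        report.formulas.append(formula)
        rows.append(
            dict(depth=depth, formula=formula, llf=fit.llf,
                 n_params=fit.model.k_fe)
        )
        if formula == spec.formula(min(depth + 1, spec.max_depth)):
            break  # fewer factors than depth: ladder saturated

    comp_rows = []
    selected = 0
    for k in range(1, len(report.fits)):
        chi2 = 2.0 * (report.fits[k].llf - report.fits[k - 1].llf)
        df = rows[k]["n_params"] - rows[k - 1]["n_params"]
        p = float(spstats.chi2.sf(max(chi2, 0.0), df)) if df > 0 else np.nan
        comp_rows.append(
            dict(model_a=rows[k - 1]["depth"], model_b=rows[k]["depth"],
                 chi2=float(chi2), df=int(df), p=p)
        )
        if p < spec.alpha and selected == k - 1:
            selected = k
    report.selected = selected
    report.comparisons = pd.DataFrame(comp_rows)

    if comp_rows:
        # partial eta^2 for the highest-order tested interaction, from the
        # chi2 statistic and residual df (ANOVA-style decomposition analogue)
        last = comp_rows[-1]
        resid_df = len(data) - rows[-1]["n_params"]
        report.eta_p2 = float(last["chi2"] / (last["chi2"] + resid_df))
    return report


def _design_row(fit, row: pd.DataFrame) -> np.ndarray:
    design_info = fit.model.data.design_info
    return np.asarray(dmatrix(design_info, row, return_type="matrix"))


def _wald(fit, c: np.ndarray):
    beta = fit.fe_params.to_numpy()
    cov = fit.cov_params().to_numpy()[: beta.size, : beta.size]
    est = float(c @ beta)
    se = float(np.sqrt(c @ cov @ c))
    t = est / se if se > 0 else np.nan
    p = float(2 * spstats.norm.sf(abs(t))) if np.isfinite(t) else np.nan
    return est, se, t, p


def simple_slopes(
    report: ModelReport,
    data: pd.DataFrame,
    moderator: str = "wtc_z",
    min_cell_n: int = 3,
    model: str = "deepest",
) -> pd.DataFrame:
    """Marginal slope of the dependent on ``moderator`` per condition x ROI
    cell (Est., S.E., t, p table).

    By default slopes are read off the deepest fitted model (REML refit): a
    cell-specific slope is only identifiable when the condition x roi x
    moderator interaction is present, even if model selection favoured a
    shallower fit.  ``model="selected"`` uses the LRT-selected model instead.
    """
    fit = (
        report.fits_reml[-1] if model == "deepest"
        else report.fits_reml[report.selected]
    )
    if moderator not in report.spec.fixed:
        raise ValueError(f"model does not include {moderator!r}")
    out = []
    cells = data.groupby(["condition", "roi_pair"]).size()
    for (cond, roi), n in cells.items():
        if n < min_cell_n:
            raise ValueError(
                f"cell {cond} x {roi} has fewer than {min_cell_n} observations"
            )
        base = {"condition": cond, "roi_pair": roi, moderator: 0.0}
        for col in report.spec.fixed:
            if col not in base:
                base[col] = data[col].iloc[0]
        row0 = pd.DataFrame([base])
        row1 = pd.DataFrame([{**base, moderator: 1.0}])
        c = (_design_row(fit, row1) - _design_row(fit, row0)).ravel()
        est, se, t, p = _wald(fit, c)
        out.append(
            dict(condition=cond, roi_pair=roi, estimate=est, se=se, t=t,
                 p=p, significant=p < report.spec.alpha)
        )
    return pd.DataFrame(out)


def real_vs_pseudo_contrast(
    data: pd.DataFrame,
    dependent: str = "wtc_z",
    grouping: str = "unit_id",
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Real-vs-pseudo group contrast per condition x ROI-pair cell.

    A single mixed model with full condition x roi_pair x group interactions
    and a random intercept per unit is fitted; each cell's real-minus-pseudo
    mean difference is a linear contrast of the fixed effects, with
    Bonferroni adjustment over cells by default.
    """
    if data[grouping].nunique() < 2:
        raise ValueError("need at least 2 units")
    cells = data.groupby(["condition", "roi_pair"])
    for (cond, roi), sub in cells:
        if sub["group"].nunique() < 2:
            raise ValueError(f"cell {cond} x {roi} is missing a group")
    model = smf.mixedlm(
        f"{dependent} ~ (condition + roi_pair + group) ** 3",
        data, groups=data[grouping],
    )
    fit = model.fit(reml=True)

    rows = []
    cell_keys = list(cells.groups)
    m = len(cell_keys)
    for cond, roi in cell_keys:
        deltas = []
        for grp, sign in (("real", 1.0), ("pseudo", -1.0)):
            row = pd.DataFrame(
                [{"condition": cond, "roi_pair": roi, "group": grp}]
            )
            deltas.append(sign * _design_row(fit, row).ravel())
        c = deltas[0] + deltas[1]
        est, se, t, p = _wald(fit, c)
        p_adj = min(1.0, p * m) if correction == "bonferroni" else p
        rows.append(
            dict(condition=cond, roi_pair=roi, estimate=est, se=se, t=t,
                 p=p, p_adjusted=p_adj, significant=p_adj < alpha)
        )
    return pd.DataFrame(rows)


def merge_sync_coupling(
    sync: pd.DataFrame, coupling: pd.DataFrame
) -> pd.DataFrame:
    """Join behavioral summaries with coupling records on unit x condition
    (x group), producing the modeling table."""
    sync = sync.rename(columns={"dyad_id": "unit_id"})
    merged = coupling.merge(
        sync[["unit_id", "condition", "group", "total_sync"]],
        on=["unit_id", "condition", "group"],
        how="inner",
    )
    return merged.rename(columns={"unit_id": "dyad_id"})
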