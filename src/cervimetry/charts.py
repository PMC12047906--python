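"""Normative gestational-age charts, covariate adjustment and agreement statistics.

Per-subject volumetry and biometry are collected into a measurement table;
each response gets a least-squares polynomial trend in gestational age
with homoscedastic Gaussian centiles (5th/50th/95th as mean +/- 1.645 sd),
covariate effects are examined by ANCOVA (a single linear model with
type-II sums of squares, so the adjustment is order-invariant), and
method/rater agreement is quantified by the intraclass correlation
ICC(2,1) — two-way random effects, absolute agreement, single measure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

GA_RANGE_WEEKS = (16.0, 40.0)

VOLUME_RESPONSES = ["canal_volume", "inner_volume", "outer_volume", "total_canal_volume"]
BIOMETRY_RESPONSES = ["cervical_length", "inlet_diameter", "outlet_diameter"]
CHART_RESPONSES = VOLUME_RESPONSES + BIOMETRY_RESPONSES

REQUIRED_COLUMNS = [
    "subject_id",
    "ga",
    "field_strength",
    "maternal_age",
    "height",
    "weight",
    "bmi",
    "ethnicity",
    "canal_volume",
    "inner_volume",
    "outer_volume",
    "cyst_volume",
    "total_canal_volume",
    "cervical_length",
    "inlet_diameter",
    "outlet_diameter",
]


class ChartError(ValueError):
    pass


@dataclass
class MeasurementTable:
    """Validated per-subject volumetry + biometry + covariates table."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ChartError(f"measurement table missing columns: {missing}")
        ga = df["ga"].to_numpy(dtype=float)
        lo, hi = GA_RANGE_WEEKS
        if np.any((ga < lo) | (ga > hi)):
            raise ChartError(f"gestational ages outside [{lo}, {hi}] weeks")
        vols = df[["canal_volume", "inner_volume", "outer_volume", "cyst_volume"]]
        if (vols.to_numpy(dtype=float) < 0).any():
            raise ChartError("negative volumes in measurement table")
        total = df["canal_volume"] + df["cyst_volume"]
        if not np.allclose(df["total_canal_volume"], total, rtol=1e-6, atol=1e-6):
            raise ChartError("total_canal_volume != canal_volume + cyst_volume")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path) -> "MeasurementTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_cohort(cls, cases, measured: bool = False) -> "MeasurementTable":
        """Build a table from simulated cohort cases.

        With ``measured=False`` the analytic truths populate the table
        (chart-scale cohorts need no rasterisation); with ``measured=True``
        the label volumes and biometry are computed from the rasterised
        label maps, exercising the measurement pipeline itself.
        """
        from .biometry import measure
        from .volumes import label_volumes_mm3

        rows = []
        for case in cases:
            if measured:
                if case.labels is None:
                    raise ChartError(f"{case.subject_id}: no rasterised labels available")
                vols = label_volumes_mm3(case.labels)
                bio = measure(case.labels)
                length = bio.cervical_length
                din, dout = bio.inlet_diameter, bio.outlet_diameter
            else:
                vols = {
                    "endocervical_canal": case.truth.label_volumes_mm3["endocervical_canal"],
                    "inner_stroma": case.truth.label_volumes_mm3["inner_stroma"],
                    "outer_stroma": case.truth.label_volumes_mm3["outer_stroma"],
                    "cyst": case.truth.label_volumes_mm3["cyst"],
                }
                length = case.truth.true_cervical_length
                din = case.truth.true_inlet_diameter
                dout = case.truth.true_outlet_diameter
            rows.append(
                {
                    "subject_id": case.subject_id,
                    "ga": case.ga,
                    **case.covariates,
                    "canal_volume": vols["endocervical_canal"],
                    "inner_volume": vols["inner_stroma"],
                    "outer_volume": vols["outer_stroma"],
                    "cyst_volume": vols["cyst"],
                    "total_canal_volume": vols["endocervical_canal"] + vols["cyst"],
                    "cervical_length": length,
                    "inlet_diameter": din,
                    "outlet_diameter": dout,
                }
            )
        return cls(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# trend fitting


@dataclass
class TrendModel:
    """Polynomial-in-GA mean curve with homoscedastic Gaussian centiles."""

    response: str
    degree: int
    coefficients: list[float]       # ascending powers of GA
    residual_sd: float
    n: int
    ga_range: tuple[float, float]
    slope: float                    # linear GA coefficient
    p_value_ga: float               # p-value of the linear GA term
    aic: float

    Z_90 = 1.645  # two-sided 90% band: 5th/95th centiles

    def mean(self, ga) -> np.ndarray:
        ga = np.asarray(ga, dtype=float)
        return sum(c * ga**k for k, c in enumerate(self.coefficients))

    def centile(self, ga, which: int) -> np.ndarray:
        """5th / 50th / 95th centile curve; the 50th equals the mean curve."""
        mu = self.mean(ga)
        if which == 50:
            return mu
        if which == 5:
            return mu - self.Z_90 * self.residual_sd
        if which == 95:
            return mu + self.Z_90 * self.residual_sd
        raise ChartError(f"unsupported centile {which}; use 5, 50 or 95")

    def to_json(self) -> str:
        d = asdict(self)
        d["ga_range"] = list(d["ga_range"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrendModel":
        d = json.loads(text)
        d["ga_range"] = tuple(d["ga_range"])
        return cls(**d)


def fit_trend(tbl: MeasurementTable, response: str, degree: int = 1) -> TrendModel:
    """Least-squares polynomial trend of a response against gestational age.

    ``degree`` 1 or 2, or the string ``"auto"`` to pick the lower-AIC of
    the two.  A constant response yields a zero-slope model with a warning.
    """
    if degree == "auto":
        m1 = fit_trend(tbl, response, 1)
        m2 = fit_trend(tbl, response, 2)
        return m1 if m1.aic <= m2.aic else m2
    if degree not in (1, 2):
        raise ChartError("degree must be 1 or 2 (or 'auto')")
    if response not in tbl.data.columns:
        raise ChartError(f"response {response!r} not in table")
    df = tbl.data
    if len(df) < 3 * (degree + 1):
        raise ChartError(
            f"need at least {3 * (degree + 1)} rows to fit degree {degree}, have {len(df)}"
        )
    y = df[response].to_numpy(dtype=float)
    ga = df["ga"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        import warnings

        warnings.warn(f"constant response {response!r}: zero-slope trend", stacklevel=2)
        return TrendModel(
            response, degree, [float(y[0])] + [0.0] * degree, 0.0, len(df),
            (float(ga.min()), float(ga.max())), 0.0, 1.0, float("nan"),
        )
    x = np.column_stack([ga**k for k in range(1, degree + 1)])
    model = sm.OLS(y, sm.add_constant(x)).fit()
    coefs = [float(c) for c in model.params]
    resid_sd = float(np.sqrt(model.scale))
    return TrendModel(
        response=response,
        degree=degree,
        coefficients=coefs,
        residual_sd=resid_sd,
        n=len(df),
        ga_range=(float(ga.min()), float(ga.max())),
        slope=coefs[1],
        p_value_ga=float(model.pvalues[1]),
        aic=float(model.aic),
    )


# ---------------------------------------------------------------------------
# ANCOVA


def ancova(
    tbl: MeasurementTable,
    response: str,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """ANCOVA: linear model ``response ~ ga + covariates``, type-II tests.

    Categorical covariates (ethnicity, field_strength) enter as factors.
    Returns one row per term with the estimate (slope for numeric terms,
    first contrast for factors), F statistic, p-value and df.
    """
    covariates = list(covariates) if covariates is not None else [
        "field_strength", "maternal_age", "height", "weight", "bmi", "ethnicity"
    ]
    if response not in tbl.data.columns:
        raise ChartError(f"response {response!r} not in table")
    df = tbl.data.copy()
    terms = ["ga"]
    for cov in covariates:
        if cov not in df.columns:
            raise ChartError(f"covariate {cov!r} not in table")
        if cov in ("ethnicity",) or df[cov].dtype == object:
            if df[cov].nunique() < 2:
                continue  # single level: no contrast to estimate
            terms.append(f"C({cov})")
        elif cov == "field_strength":
            if df[cov].nunique() < 2:
                continue
            terms.append("C(field_strength)")
        else:
            terms.append(cov)
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        names = model.model.exog_names
        raise ChartError(f"rank-deficient design (aliased terms among {names})")
    table = anova_lm(model, typ=2)

    rows = []
    for term in table.index:
        if term == "Residual":
            continue
        est = np.nan
        for pname, pval in model.params.items():
            if pname == term or (term.startswith("C(") and pname.startswith(term)):
                est = float(pval)
                break
        rows.append(
            {
                "term": term,
                "estimate": est,
                "F": float(table.loc[term, "F"]),
                "p_value": float(table.loc[term, "PR(>F)"]),
                "df": float(table.loc[term, "df"]),
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["formula"] = formula
    out.attrs["n"] = len(df)
    return out


# ---------------------------------------------------------------------------
# intraclass correlation


def icc_absolute_agreement(x, y=None) -> float | None:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Accepts either two equal-length paired vectors (k = 2 raters) or a
    single (n_subjects, k_raters) matrix.  Computed from the two-way ANOVA
    mean squares:

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Returns ``None`` (flagged undefined) when the total variance is zero.
    """
    if y is not None:
        x = np.column_stack([np.asarray(x, dtype=float), np.asarray(y, dtype=float)])
    else:
        x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ChartError("need an (n, k>=2) matrix or two paired vectors")
    n, k = x.shape
    if n < 3:
        raise ChartError(f"need at least 3 subjects for the ICC, have {n}")
    if not np.all(np.isfinite(x)):
        raise ChartError("non-finite measurements")
    grand = x.mean()
    if np.allclose(x, grand):
        return None
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return None
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# chart bundles


def build_charts(
    tbl: MeasurementTable,
    out_dir,
    responses: list[str] | None = None,
    degree=1,
) -> dict[str, TrendModel]:
    """Fit and plot one normative chart per response; serialise models as JSON.

    Writes ``<response>_chart.png`` and ``<response>_model.json`` per
    response (default: the four layer volumes including total canal, the
    cervical length and the two os diameters).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    responses = responses or CHART_RESPONSES
    models: dict[str, TrendModel] = {}
    units = {r: ("mm^3" if r.endswith("_volume") else "mm") for r in responses}
    for resp in responses:
        model = fit_trend(tbl, resp, degree=degree)
        models[resp] = model
        (out_dir / f"{resp}_model.json").write_text(model.to_json())

        ga = tbl.data["ga"].to_numpy(dtype=float)
        y = tbl.data[resp].to_numpy(dtype=float)
        gg = np.linspace(ga.min(), ga.max(), 200)
        fig, ax = plt.subplots(figsize=(5.5, 4))
        ax.fill_between(
            gg, model.centile(gg, 5), model.centile(gg, 95),
            alpha=0.2, color="tab:blue", label="5th-95th centile",
        )
        ax.plot(gg, model.centile(gg, 50), color="tab:blue", label="median trend")
        ax.scatter(ga, y, s=12, color="k", alpha=0.5)
        ax.set_xlim(ga.min(), ga.max())
        ax.set_xlabel("gestational age (weeks)")
        ax.set_ylabel(f"{resp} ({units[resp]})")
        ax.set_title(f"{resp} vs GA (n={model.n}, slope={model.slope:.3g}/wk)")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(out_dir / f"{resp}_chart.png", dpi=110)
        plt.close(fig)
    return models
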