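"""Polynomial models of experimental thermal limits against occupancy-derived
thermal affinity, and thermal safety margins.

The core model is ordinary least squares of

    Tmax = a + b * x + c * x**2 + error

where x is a species' mean thermal affinity, optionally with functional-
group structure: *pooled* (no group terms), *additive* (per-group
intercepts, shared curvature) or *interaction* (a separate quadratic per
group, sharing one error variance).  The quadratic is fitted on a centred
basis for conditioning but coefficients, covariances and Wald intervals are
always reported on the raw basis, so the vertex -b/(2c) — the affinity at
which fitted Tmax peaks — is directly computable.

Nested model forms are compared with extra-sum-of-squares F tests.  Thermal
safety margins are Tmax minus mean affinity, binned into cold (<=10 °C),
moderate (>10 and <=20 °C) and warm (>20 °C) affinity classes.

The model API follows the statsmodels convention: build a
:class:`ThermalLimitModel` from data, call :meth:`~ThermalLimitModel.fit`,
and read estimates off the returned :class:`ThermalLimitResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ThermalLimitModel",
    "ThermalLimitResults",
    "ModelComparison",
    "compare_models",
    "safety_margins",
    "bin_margin_table",
    "AFFINITY_BINS",
]

FORMS = ("pooled", "additive", "interaction")

#: Affinity bin labels and their (closed-above) upper edges in °C.
AFFINITY_BINS = (("cold", 10.0), ("moderate", 20.0), ("warm", np.inf))


class ThermalLimitModel:
    """Quadratic Tmax ~ thermal-affinity model with optional group structure.

    Parameters
    ----------
    tmax, affinity : array-like
        Per-species experimental upper limit and mean thermal affinity (°C).
    group : array-like of str, optional
        Functional-group key per species; required for the additive and
        interaction forms.
    form : {"pooled", "additive", "interaction"}
        pooled — one quadratic across all species; additive — per-group
        intercepts with shared linear and quadratic terms; interaction — a
        separate quadratic per group (one shared error variance).
    """

    def __init__(self, tmax, affinity, group=None, form: str = "pooled"):
        if form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}")
        y = np.asarray(tmax, dtype=float)
        x = np.asarray(affinity, dtype=float)
        if y.shape != x.shape or y.ndim != 1:
            raise ValueError("tmax and affinity must be 1-D arrays of equal length")
        keep = np.isfinite(y) & np.isfinite(x)
        if group is not None:
            g = np.asarray(group, dtype=object)
            keep &= pd.notna(g)
        elif form != "pooled":
            raise ValueError(f"form {form!r} requires a group vector")
        self.endog = y[keep]
        self.exog_affinity = x[keep]
        self.group = g[keep].astype(str) if group is not None else None
        self.form = form
        self.groups_ = (
            sorted(set(self.group)) if self.group is not None else []
        )
        n_params = self._n_params()
        if self.endog.size < n_params + 2:
            raise ValueError(
                f"need at least {n_params + 2} complete species for form {form!r}, "
                f"got {self.endog.size}"
            )
        if form == "interaction":
            for gname in self.groups_:
                if np.sum(self.group == gname) < 3:
                    raise ValueError(
                        f"group {gname!r} has fewer than 3 species; interaction "
                        "design would be rank deficient"
                    )
        # centring constant for the internal basis
        self._center = float(np.mean(self.exog_affinity))

    def _n_params(self) -> int:
        k = len(self.groups_)
        return {"pooled": 3, "additive": k + 2, "interaction": 3 * k}[self.form]

    # -- design ------------------------------------------------------------

    def _design(self) -> tuple[np.ndarray, list[str]]:
        """Design matrix on the centred basis u = x - mean(x)."""
        u = self.exog_affinity - self._center
        if self.form == "pooled":
            X = np.column_stack([np.ones_like(u), u, u * u])
            names = ["intercept", "linear", "quadratic"]
        elif self.form == "additive":
            dummies = np.column_stack(
                [(self.group == gname).astype(float) for gname in self.groups_]
            )
            X = np.column_stack([dummies, u, u * u])
            names = [f"intercept[{gname}]" for gname in self.groups_] + [
                "linear",
                "quadratic",
            ]
        else:  # interaction: block-diagonal per-group quadratics
            cols, names = [], []
            for gname in self.groups_:
                d = (self.group == gname).astype(float)
                cols += [d, d * u, d * u * u]
                names += [
                    f"intercept[{gname}]",
                    f"linear[{gname}]",
                    f"quadratic[{gname}]",
                ]
            X = np.column_stack(cols)
        return X, names

    def _raw_transform(self, names: list[str]) -> np.ndarray:
        """Matrix A with params_raw = A @ params_centred.

        On the centred basis, a' + b'u + c'u² with u = x - m expands to
        (a' - b'm + c'm²) + (b' - 2c'm)x + c'x² on the raw basis; the map is
        linear, so covariances and Wald intervals transform exactly.
        """
        m = self._center
        k = len(names)
        A = np.eye(k)
        lin_of = {}
        quad_of = {}
        for j, name in enumerate(names):
            tag = name.split("[")[1][:-1] if "[" in name else None
            if name.startswith("linear"):
                lin_of[tag] = j
            elif name.startswith("quadratic"):
                quad_of[tag] = j
        for j, name in enumerate(names):
            if name.startswith("intercept"):
                tag = name.split("[")[1][:-1] if "[" in name else None
                lin = lin_of.get(tag, lin_of.get(None))
                quad = quad_of.get(tag, quad_of.get(None))
                A[j, lin] += -m
                A[j, quad] += m * m
            elif name.startswith("linear"):
                tag = name.split("[")[1][:-1] if "[" in name else None
                A[j, quad_of.get(tag, quad_of.get(None))] += -2.0 * m
        return A

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "ThermalLimitResults":
        X, names = self._design()
        res = sm.OLS(self.endog, X).fit()
        A = self._raw_transform(names)
        params = A @ res.params
        cov = A @ res.cov_params() @ A.T
        tss = float(np.sum((self.endog - self.endog.mean()) ** 2))
        rsquared = 1.0 - res.ssr / tss if tss > 0 else 0.0  # constant response
        return ThermalLimitResults(
            model=self,
            param_names=names,
            params=params,
            cov_params=cov,
            rss=float(res.ssr),
            df_resid=int(res.df_resid),
            rsquared=float(np.clip(rsquared, 0.0, 1.0)),
            nobs=int(res.nobs),
        )


@dataclass
class ThermalLimitResults:
    """Raw-basis estimates from a :class:`ThermalLimitModel` fit."""

    model: ThermalLimitModel
    param_names: list[str]
    params: np.ndarray
    cov_params: np.ndarray
    rss: float
    df_resid: int
    rsquared: float
    nobs: int

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """t-based Wald intervals, (k, 2)."""
        tcrit = sps.t.ppf(1 - alpha / 2, self.df_resid)
        se = self.bse
        return np.column_stack([self.params - tcrit * se, self.params + tcrit * se])

    def _coef(self, prefix: str, group: str | None = None) -> float:
        target = prefix if group is None else f"{prefix}[{group}]"
        for name, value in zip(self.param_names, self.params):
            if name == target:
                return float(value)
        # additive form shares linear/quadratic across groups
        if group is not None and prefix in self.param_names:
            return float(self.params[self.param_names.index(prefix)])
        raise KeyError(target)

    def coefficients(self, group: str | None = None) -> tuple[float, float, float]:
        """(intercept, linear, quadratic) on the raw basis.

        For group-structured forms, pass the group whose curve is wanted;
        the additive form returns that group's intercept with the shared
        linear and quadratic terms.
        """
        if self.model.form == "pooled":
            return tuple(float(self._coef(p)) for p in ("intercept", "linear", "quadratic"))
        if group is None:
            raise ValueError(f"form {self.model.form!r} needs a group for its curve")
        return (
            self._coef("intercept", group),
            self._coef("linear", group),
            self._coef("quadratic", group),
        )

    def vertex(self, group: str | None = None) -> dict | None:
        """Affinity at maximum fitted Tmax: -b/(2c) when the curvature is
        concave (c < 0), else None.  Flagged ``extrapolated`` when the
        vertex lies outside the observed affinity range."""
        _, b, c = self.coefficients(group)
        # numerically-zero curvature (exact linear data) is not concave
        scale = max(1.0, abs(b)) * np.finfo(float).eps * 1e3
        if c >= -scale:
            return None
        x_star = -b / (2.0 * c)
        lo, hi = float(self.model.exog_affinity.min()), float(self.model.exog_affinity.max())
        return {
            "affinity_at_max": float(x_star),
            "tmax_at_max": float(self.predict(np.asarray([x_star]), group=group)[0]),
            "extrapolated": bool(x_star < lo or x_star > hi),
        }

    def predict(self, affinity: np.ndarray, group: str | None = None) -> np.ndarray:
        a, b, c = self.coefficients(group)
        x = np.asarray(affinity, dtype=float)
        return a + b * x + c * x * x

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Thermal limit ~ quadratic(thermal affinity), form={self.model.form}",
            f"n={self.nobs}  R^2={self.rsquared:.4f}  df_resid={self.df_resid}  RSS={self.rss:.4g}",
            f"{'parameter':<28}{'estimate':>12}{'std err':>12}{'[0.025':>12}{'0.975]':>12}",
        ]
        for name, p, se, (lo, hi) in zip(self.param_names, self.params, self.bse, ci):
            lines.append(f"{name:<28}{p:>12.4f}{se:>12.4f}{lo:>12.4f}{hi:>12.4f}")
        v = self.vertex(self.model.groups_[0]) if self.model.form != "pooled" else self.vertex()
        if self.model.form == "pooled" and v is not None:
            lines.append(
                f"vertex: max Tmax {v['tmax_at_max']:.2f} degC at affinity "
                f"{v['affinity_at_max']:.2f} degC"
                + (" (extrapolated)" if v["extrapolated"] else "")
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "form": self.model.form,
            "n": self.nobs,
            "r_squared": self.rsquared,
            "df_resid": self.df_resid,
            "rss": self.rss,
            "params": {
                name: {"estimate": float(p), "se": float(se),
                       "ci_low": float(lo), "ci_high": float(hi)}
                for name, p, se, (lo, hi) in zip(self.param_names, self.params, self.bse, ci)
            },
            "vertex": self.vertex() if self.model.form == "pooled" else {
                g: self.vertex(g) for g in self.model.groups_
            },
        }


@dataclass
class ModelComparison:
    """Extra-sum-of-squares comparison of two nested fits."""

    df_num: int
    df_den: int
    f_statistic: float
    p_value: float
    delta_rsquared: float

    def __str__(self) -> str:
        return (
            f"F({self.df_num}, {self.df_den}) = {self.f_statistic:.3f}, "
            f"p = {self.p_value:.4f}, dR^2 = {self.delta_rsquared:.4f}"
        )


def compare_models(
    fit_nested: ThermalLimitResults, fit_full: ThermalLimitResults
) -> ModelComparison:
    """Nested-model F test: ((RSS_n - RSS_f)/dp) / (RSS_f/df_f).

    The two fits must share the response vector and the nested form must be
    a restriction of the full one (pooled < additive < interaction).
    Comparing a model with itself is the degenerate restriction: F = 0.
    """
    order = {f: i for i, f in enumerate(FORMS)}
    if fit_nested.nobs != fit_full.nobs or not np.array_equal(
        fit_nested.model.endog, fit_full.model.endog
    ):
        raise ValueError("fits do not share a response vector; not nested")
    if order[fit_nested.model.form] > order[fit_full.model.form]:
        raise ValueError(
            f"form {fit_nested.model.form!r} is not nested in {fit_full.model.form!r}"
        )
    df_num = fit_nested.df_resid - fit_full.df_resid
    df_den = fit_full.df_resid
    if df_num < 0:
        raise ValueError("the 'nested' model has more parameters than the full one")
    if df_num == 0:
        if not np.isclose(fit_nested.rss, fit_full.rss):
            raise ValueError("equal parameter counts but different fits; not nested")
        return ModelComparison(0, df_den, 0.0, 1.0, 0.0)
    f_stat = ((fit_nested.rss - fit_full.rss) / df_num) / (fit_full.rss / df_den)
    f_stat = max(f_stat, 0.0)  # guard tiny negative from round-off
    return ModelComparison(
        df_num=df_num,
        df_den=df_den,
        f_statistic=float(f_stat),
        p_value=float(sps.f.sf(f_stat, df_num, df_den)),
        delta_rsquared=float(fit_full.rsquared - fit_nested.rsquared),
    )


# ---------------------------------------------------------------------------
# Safety margins
# ---------------------------------------------------------------------------


def assign_affinity_bin(affinity: np.ndarray) -> np.ndarray:
    """cold (<=10), moderate (>10 and <=20), warm (>20) — boundaries closed
    above, so 10.0 is cold and 20.0 moderate."""
    x = np.asarray(affinity, dtype=float)
    out = np.where(x <= 10.0, "cold", np.where(x <= 20.0, "moderate", "warm"))
    return np.where(np.isnan(x), "", out).astype(object)


def _exact_decomposition(
    tmax: np.ndarray, affinity: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(margin, tmax) pair with margin + affinity == tmax bit-exactly.

    ``tmax - affinity`` alone can round such that adding the affinity back
    does not reproduce tmax.  The margin is first nudged by ulps toward a
    representable exact solution; when none exists (possible when both
    operand binades are coarser than tmax's, so their sums skip over it)
    the stored tmax becomes the correctly rounded sum itself — within one
    ulp of the source value, i.e. ~1e-15 °C, far below any measurement
    precision — so the decomposition is exact by construction for every
    species.
    """
    m = tmax - affinity
    t_out = tmax.copy()
    bad = np.where((m + affinity) != tmax)[0]
    for i in bad:
        mi, ai, ti = m[i], affinity[i], tmax[i]
        for _ in range(8):
            s = mi + ai
            if s == ti:
                break
            mi = np.nextafter(mi, np.inf if s < ti else -np.inf)
        m[i] = mi
        t_out[i] = mi + ai
    return m, t_out


def safety_margins(
    limits: pd.DataFrame,
    affinities: pd.DataFrame,
    measure: str = "grid_t_at_depth",
) -> pd.DataFrame:
    """Per-species thermal safety margin: Tmax minus mean affinity.

    ``limits`` is the one-row-per-species output of
    :func:`thermaffin.tmax_prep.prepare_limits`; ``affinities`` the tidy
    table of :func:`thermaffin.affinity_stats.summarize_affinities`.
    Species without a mean affinity for the chosen measure are omitted (and
    logged).  The stored (margin, affinity, tmax) triple is exactly
    consistent: margin + affinity reproduces the stored tmax bit-exactly
    (see :func:`_exact_decomposition`; the stored tmax can differ from the
    input by at most one ulp).
    """
    aff = affinities.loc[
        (affinities["measure"] == measure) & affinities["mean"].notna(),
        ["species_id", "mean"],
    ].rename(columns={"mean": "affinity"})
    merged = limits.merge(aff, on="species_id", how="inner")
    omitted = set(limits["species_id"]) - set(merged["species_id"])
    if omitted:
        import logging

        logging.getLogger(__name__).info(
            "%d species omitted from margins (no %s affinity)", len(omitted), measure
        )
    tmax = merged["tmax"].to_numpy(dtype=float)
    affinity = merged["affinity"].to_numpy(dtype=float)
    margin, tmax_out = _exact_decomposition(tmax, affinity)
    merged["tmax"] = tmax_out
    merged["margin"] = margin
    merged["affinity_bin"] = assign_affinity_bin(affinity)
    cols = ["species_id", "group_key", "tmax", "affinity", "margin", "affinity_bin"]
    return merged[[c for c in cols if c in merged.columns]]


def bin_margin_table(
    margins: pd.DataFrame,
    exclude_groups: tuple[str, ...] = ("birds", "mammals", "nekton"),
) -> pd.DataFrame:
    """Group x affinity-bin table of margin mean ± SD.

    One row per (group, bin) actually occupied — empty cells are absent, not
    zero.  Sparse groups (few species: birds, mammals, nekton by default)
    are excluded, configurably.
    """
    df = margins[~margins["group_key"].isin(exclude_groups)].copy()
    rows = []
    for (gname, bname), grp in df.groupby(["group_key", "affinity_bin"], sort=True):
        vals = grp["margin"].to_numpy(dtype=float)
        rows.append(
            {
                "group_key": gname,
                "affinity_bin": bname,
                "n": vals.size,
                "mean_margin": float(np.mean(vals)),
                "sd_margin": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["group_key", "affinity_bin", "n", "mean_margin", "sd_margin"])
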