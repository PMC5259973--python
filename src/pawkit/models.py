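"""Fitted models for the crossover study, statsmodels-style.

Two model classes, each built from a long-format DataFrame and fitted
with ``.fit()`` returning a Results object:

:class:`CrossoverKineticModel`
    Linear mixed model on baseline-subtracted kinetic responses with
    treatment, time and treatment x time fixed effects and a random
    intercept per cat (equivalent to a compound-symmetry within-cat
    covariance).  Provides the overall treatment test, per-timepoint
    Tukey-adjusted treatment contrasts, and Dunnett-adjusted
    time-versus-baseline comparisons.

:class:`OrdinalPainModel`
    Proportional-odds repeated-measures model of the ordinal pain score
    with treatment, period, time, time x treatment and period x time
    terms.  Default estimation is a subject-clustered marginal fit
    (GEE); a maximum-likelihood random-intercept fit (Gauss-Hermite
    quadrature) is available, but at four subjects the marginal fit is
    the stabler choice.  The results expose the fitted probability that
    the score sits at its baseline level as a function of time, and the
    time at which that probability first reaches 0.5 (an LD50-like
    crossing time).

Inference at four subjects uses t references with containment-style
denominator degrees of freedom (observations minus fixed-effect rank
minus between-subject degrees of freedom) rather than Wald normals,
which keeps the null treatment-term size near nominal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools import numdiff

from .stats import CrossingTime, crossing_time

__all__ = [
    "EstimationError",
    "CrossoverKineticModel",
    "CrossoverKineticResults",
    "OrdinalPainModel",
    "OrdinalPainResults",
    "fit_kinetic_mixed_model",
    "fit_ordinal_repeated",
    "dunnett_vs_baseline",
]


class EstimationError(RuntimeError):
    """A model fit failed (non-convergence or complete separation)."""


def _containment_df(n_obs: int, x_rank: int, n_subjects: int) -> int:
    df = n_obs - x_rank - (n_subjects - 1)
    if df < 1:
        raise EstimationError(
            f"no residual degrees of freedom (n={n_obs}, rank={x_rank}, "
            f"subjects={n_subjects})"
        )
    return df


# ---------------------------------------------------------------------------
# kinetic crossover mixed model
# ---------------------------------------------------------------------------

class CrossoverKineticModel:
    """Mixed model for one baseline-subtracted kinetic response.

    Parameters
    ----------
    deltas : DataFrame
        Long format, one row per subject x period x timepoint, with the
        response column holding the baseline-subtracted value.
    response : str
        Column to model (e.g. ``"si_pvf"``).
    reference_treatment : str
        Treatment coded 0; contrasts are treatment-minus-reference.
    """

    def __init__(
        self,
        deltas: pd.DataFrame,
        response: str,
        subject: str = "cat",
        treatment: str = "treatment",
        time: str = "timepoint_h",
        reference_treatment: str = "control",
    ) -> None:
        need = {subject, treatment, time, response}
        missing = need - set(deltas.columns)
        if missing:
            raise ValueError(f"deltas missing columns: {sorted(missing)}")
        data = deltas.dropna(subset=[response]).copy()
        if data.empty:
            raise ValueError(f"no observations for response {response!r}")
        self.data = data
        self.response = response
        self.subject = subject
        self.treatment = treatment
        self.time = time
        self.reference = reference_treatment
        self.times = sorted(data[time].unique())
        trts = sorted(data[treatment].unique())
        if reference_treatment not in trts or len(trts) != 2:
            raise ValueError(
                f"need exactly two treatments incl. {reference_treatment!r}; got {trts}"
            )
        self.active = next(t for t in trts if t != reference_treatment)

    @classmethod
    def from_session_summaries(
        cls, summaries: pd.DataFrame, response: str, **kwargs
    ) -> "CrossoverKineticModel":
        """Build from per-session summaries (applies baseline adjustment)."""
        from .kinetics import baseline_adjust

        return cls(baseline_adjust(summaries), response, **kwargs)

    def _frame(self) -> pd.DataFrame:
        d = self.data
        return pd.DataFrame(
            {
                "resp": d[self.response].to_numpy(dtype=float),
                "treat": (d[self.treatment] == self.active).astype(float).to_numpy(),
                "tlab": pd.Categorical(
                    [f"t{t:07.1f}" for t in d[self.time]]
                ),
                "subj": d[self.subject].to_numpy(),
                "cell": [
                    f"{s}|{p}"
                    for s, p in zip(d[self.subject], d.get("period", d[self.treatment]))
                ],
            }
        )

    def fit(self, reml: bool = True) -> "CrossoverKineticResults":
        """REML fit with cat random intercept + cat x period component.

        The cat x period variance component carries the disturbance that
        baseline subtraction shares across the six timepoints of one
        period (the analogue of the within-subject repeated covariance
        in the source analysis); without it the treatment test is badly
        anticonservative.
        """
        frame = self._frame()
        model = smf.mixedlm(
            "resp ~ treat + C(tlab) + treat:C(tlab)",
            data=frame,
            groups="subj",
            vc_formula={"cell": "0 + C(cell)"},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=reml)
            except (np.linalg.LinAlgError, ValueError) as e:  # pragma: no cover
                raise EstimationError(f"mixed model fit failed: {e}") from e
        beta = np.asarray(res.fe_params)
        names = list(res.fe_params.index)
        cov = np.asarray(res.cov_params())[: beta.size, : beta.size]
        # subplot (within cat x period) degrees of freedom for contrasts
        # that involve time
        df = _containment_df(
            len(frame),
            np.linalg.matrix_rank(model.exog),
            frame["cell"].nunique(),
        )
        return CrossoverKineticResults(
            model=self,
            mixed_result=res,
            param_names=names,
            params=beta,
            cov=cov,
            df_resid=df,
        )


@dataclass
class CrossoverKineticResults:
    """Estimates, contrasts and tests from a fitted crossover model."""

    model: CrossoverKineticModel
    mixed_result: object
    param_names: list[str]
    params: np.ndarray
    cov: np.ndarray
    df_resid: int

    def _contrast(self, c: np.ndarray) -> tuple[float, float, float, float]:
        est = float(c @ self.params)
        se = float(np.sqrt(c @ self.cov @ c))
        t = est / se if se > 0 else 0.0
        p = float(2 * sps.t.sf(abs(t), df=self.df_resid))
        return est, se, t, p

    def _treatment_contrast_vector(self, time_value: float) -> np.ndarray:
        names = self.param_names
        c = np.zeros(len(names))
        c[names.index("treat")] = 1.0
        key = f"treat:C(tlab)[T.t{time_value:07.1f}]"
        if key in names:
            c[names.index(key)] = 1.0
        return c

    @property
    def treatment_effect(self) -> float:
        """Average treatment-minus-reference difference across timepoints."""
        c = self._overall_vector()
        return float(c @ self.params)

    def _overall_vector(self) -> np.ndarray:
        cs = [self._treatment_contrast_vector(t) for t in self.model.times]
        return np.mean(cs, axis=0)

    @property
    def treatment_pvalue(self) -> float:
        """Overall treatment test, exact whole-plot form.

        In this balanced two-treatment crossover the mixed-model test of
        the average treatment difference reduces to a paired comparison
        of per-cat treatment means, whose t statistic has an exact
        t(n_cats - 1) null distribution; computing it in that form keeps
        the test calibrated at four cats.
        """
        m = self.model
        cell = m.data.groupby([m.subject, m.treatment])[m.response].mean().unstack()
        diff = (cell[m.active] - cell[m.reference]).dropna()
        n = len(diff)
        if n < 2:
            raise EstimationError("need >= 2 subjects with both treatments")
        sd = diff.std(ddof=1)
        if sd == 0:
            return 1.0 if np.allclose(diff, 0) else 0.0
        t = diff.mean() / (sd / np.sqrt(n))
        return float(2 * sps.t.sf(abs(t), df=n - 1))

    def contrasts(self) -> pd.DataFrame:
        """Per-timepoint treatment contrasts with Tukey adjustment.

        The Tukey family is the full set of treatment x time cell means
        (12 at six times), so adjusted p-values are conservative for the
        six within-time comparisons reported.
        """
        k_means = 2 * len(self.model.times)
        rows = []
        for t in self.model.times:
            est, se, tt, p = self._contrast(self._treatment_contrast_vector(t))
            p_tukey = float(
                sps.studentized_range.sf(abs(tt) * np.sqrt(2.0), k_means, self.df_resid)
            )
            rows.append(
                {
                    "timepoint_h": t,
                    "estimate": est,
                    "se": se,
                    "tstat": tt,
                    "pvalue": p,
                    "pvalue_tukey": min(1.0, p_tukey),
                    "direction": (
                        f"{self.model.active} > {self.model.reference}"
                        if est > 0
                        else f"{self.model.active} < {self.model.reference}"
                    ),
                }
            )
        out = pd.DataFrame(rows)
        assert (out["pvalue_tukey"] + 1e-12 >= out["pvalue"]).all()
        return out

    def significant_timepoints(self, alpha: float = 0.05) -> list[float]:
        c = self.contrasts()
        return c.loc[c["pvalue_tukey"] < alpha, "timepoint_h"].tolist()

    def effect_table(self) -> pd.DataFrame:
        """One-row overall summary in the published-table shape."""
        est, se, _, _ = self._contrast(self._overall_vector())
        p = self.treatment_pvalue
        sig = self.significant_timepoints()
        direction = (
            f"{self.model.active} > {self.model.reference}"
            if est > 0
            else f"{self.model.active} < {self.model.reference}"
        )
        return pd.DataFrame(
            [
                {
                    "response": self.model.response,
                    "estimate": est,
                    "se": se,
                    "pvalue": p,
                    "direction": (
                        f"{direction} at {', '.join(f'{t:g}' for t in sig)} h"
                        if sig
                        else "no adjusted per-timepoint differences"
                    ),
                }
            ]
        )

    def summary(self):
        from statsmodels.iolib.summary2 import Summary

        s = Summary()
        s.add_title(
            f"Crossover mixed model: {self.model.response} "
            f"(random intercept per {self.model.subject})"
        )
        coef = pd.DataFrame(
            {
                "coef": self.params,
                "se": np.sqrt(np.diag(self.cov)),
            },
            index=self.param_names,
        )
        coef["t"] = coef["coef"] / coef["se"]
        coef["P>|t|"] = 2 * sps.t.sf(np.abs(coef["t"]), df=self.df_resid)
        s.add_df(coef.round(4))
        s.add_df(self.contrasts().round(4))
        s.add_text(
            f"Overall treatment effect {self.treatment_effect:.3f}, "
            f"p = {self.treatment_pvalue:.4f} (t, df={self.df_resid})"
        )
        return s


def fit_kinetic_mixed_model(
    deltas: pd.DataFrame, response: str, **kwargs
) -> CrossoverKineticResults:
    """Convenience wrapper: build and fit a :class:`CrossoverKineticModel`."""
    return CrossoverKineticModel(deltas, response, **kwargs).fit()


def dunnett_vs_baseline(
    deltas: pd.DataFrame,
    response: str,
    subject: str = "cat",
    time: str = "timepoint_h",
    n_mc: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare each timepoint to baseline with Dunnett adjustment.

    ``deltas`` holds baseline-subtracted values for a single treatment
    arm, so each timepoint's cell mean is its difference from baseline;
    the joint null distribution of the six t statistics (multivariate t
    with the estimated contrast correlation) supplies the adjustment,
    evaluated by seeded Monte Carlo.
    """
    d = deltas.dropna(subset=[response])
    times = sorted(d[time].unique())
    X = np.column_stack([(d[time] == t).astype(float) for t in times])
    y = d[response].to_numpy(dtype=float)
    groups = d[subject].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MixedLM(y, X, groups=groups).fit(reml=True)
    beta = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[: len(times), : len(times)]
    se = np.sqrt(np.diag(cov))
    tstat = beta / se
    df = _containment_df(len(y), np.linalg.matrix_rank(X), len(np.unique(groups)))
    p_raw = 2 * sps.t.sf(np.abs(tstat), df=df)

    corr = cov / np.outer(se, se)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(len(times)))
    z = rng.standard_normal((n_mc, len(times))) @ L.T
    w = rng.chisquare(df, size=n_mc)
    tmax = np.max(np.abs(z) * np.sqrt(df / w)[:, None], axis=1)
    p_adj = np.array([(tmax >= abs(t0)).mean() for t0 in tstat])
    p_adj = np.maximum(p_adj, p_raw)  # adjustment can only increase p
    return pd.DataFrame(
        {
            "timepoint_h": times,
            "estimate": beta,
            "se": se,
            "tstat": tstat,
            "pvalue": p_raw,
            "pvalue_dunnett": np.minimum(1.0, p_adj),
        }
    )


# ---------------------------------------------------------------------------
# ordinal pain model
# ---------------------------------------------------------------------------

class OrdinalPainModel:
    """Proportional-odds repeated-measures model for ordinal pain scores.

    Fixed effects: treatment, period, time (hours, scaled by 1/72),
    time x treatment and period x time; the within-cat dependence is
    handled either marginally (subject-clustered GEE, default) or by a
    normal random intercept (maximum likelihood via Gauss-Hermite
    quadrature).
    """

    TIME_SCALE_H = 72.0

    def __init__(
        self,
        data: pd.DataFrame,
        subject: str = "cat",
        treatment: str = "treatment",
        period: str = "period",
        time: str = "time_h",
        score: str = "score",
        reference_treatment: str = "control",
    ) -> None:
        need = {subject, treatment, period, time, score}
        missing = need - set(data.columns)
        if missing:
            raise ValueError(f"pain data missing columns: {sorted(missing)}")
        d = data.copy()
        if "is_baseline" in d.columns:
            d = d[~d["is_baseline"]]
        d = d[d[time] >= 0]
        if d[subject].nunique() < 2:
            raise ValueError("need at least 2 subjects")
        if set(d[period].unique()) != {1, 2}:
            raise ValueError("both periods must be present")
        self.data = d
        self.cols = dict(
            subject=subject, treatment=treatment, period=period, time=time, score=score
        )
        self.reference = reference_treatment
        trts = sorted(d[treatment].unique())
        self.active = next((t for t in trts if t != reference_treatment), None)
        if self.active is None or len(trts) != 2:
            raise ValueError("need exactly two treatment arms")
        self.levels = np.array(sorted(d[score].unique()))
        if len(self.levels) < 2:
            raise EstimationError(
                "pain scores are constant; ordinal model is unidentifiable"
            )

    # -- design -----------------------------------------------------------
    def _design(self, d: pd.DataFrame | None = None) -> pd.DataFrame:
        d = self.data if d is None else d
        c = self.cols
        z = (d[c["treatment"]] == self.active).astype(float)
        per = (d[c["period"]] == 2).astype(float)
        ts = d[c["time"]] / self.TIME_SCALE_H
        return pd.DataFrame(
            {
                "treatment": z.to_numpy(),
                "period": per.to_numpy(),
                "time": ts.to_numpy(),
                "time:treatment": (ts * z).to_numpy(),
                "period:time": (per * ts).to_numpy(),
            },
            index=d.index,
        )

    def _design_point(self, period: int, treatment: str, t_h: np.ndarray) -> np.ndarray:
        z = 1.0 if treatment == self.active else 0.0
        per = 1.0 if period == 2 else 0.0
        ts = np.asarray(t_h, dtype=float) / self.TIME_SCALE_H
        return np.column_stack(
            [np.full_like(ts, z), np.full_like(ts, per), ts, ts * z, per * ts]
        )

    # -- fitting ----------------------------------------------------------
    def fit(self, method: str = "gee") -> "OrdinalPainResults":
        if method == "gee":
            return self._fit_gee()
        if method == "random_intercept":
            return self._fit_random_intercept()
        raise ValueError(f"unknown method {method!r}")

    def _fit_gee(self) -> "OrdinalPainResults":
        X = self._design()
        y = self.data[self.cols["score"]].to_numpy()
        groups = self.data[self.cols["subject"]].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.OrdinalGEE(y, X, groups=groups).fit()
            except Exception as e:
                raise EstimationError(
                    f"marginal ordinal fit failed ({e}); the scores may be "
                    "completely separated by a covariate"
                ) from e
        params = res.params
        if not np.all(np.isfinite(params)) or np.any(np.abs(params) > 50):
            raise EstimationError(
                "marginal ordinal fit diverged (possible complete separation)"
            )
        n_cut = len(self.levels) - 1
        # statsmodels models P(Y > level_k) = expit(icept_k + X beta)
        icepts = np.asarray(params[:n_cut])
        beta = pd.Series(np.asarray(params[n_cut:]), index=list(X.columns))
        se = pd.Series(
            np.sqrt(np.diag(np.asarray(res.cov_params())))[n_cut:], index=list(X.columns)
        )
        return OrdinalPainResults(
            model=self,
            method="gee",
            intercepts=icepts,
            beta=beta,
            beta_se=se,
            sigma_u=None,
            raw_result=res,
        )

    def _fit_random_intercept(
        self, n_quad: int = 25
    ) -> "OrdinalPainResults":
        X = self._design().to_numpy()
        y_idx = np.searchsorted(self.levels, self.data[self.cols["score"]].to_numpy())
        groups = self.data[self.cols["subject"]].to_numpy()
        uniq = np.unique(groups)
        gidx = [np.nonzero(groups == g)[0] for g in uniq]
        K = len(self.levels)
        p = X.shape[1]
        nodes, wts = np.polynomial.hermite.hermgauss(n_quad)
        z_nodes = np.sqrt(2.0) * nodes
        log_w = np.log(wts / np.sqrt(np.pi))

        # cumulative-logit cutpoints: P(Y <= k | u) = expit(th_k - x beta - u)
        cum = np.cumsum(np.bincount(y_idx, minlength=K))[:-1] / len(y_idx)
        th0 = np.log(cum / (1 - cum))
        start = np.concatenate(
            [[th0[0]], np.log(np.maximum(np.diff(th0), 0.1)), np.zeros(p), [np.log(0.5)]]
        )

        def unpack(par):
            th = np.empty(K - 1)
            th[0] = par[0]
            if K > 2:
                th[1:] = par[0] + np.cumsum(np.exp(par[1 : K - 1]))
            beta = par[K - 1 : K - 1 + p]
            sigma = np.exp(par[-1])
            return th, beta, sigma

        def nll(par):
            th, beta, sigma = unpack(par)
            eta = X @ beta
            th_hi = np.concatenate([th, [np.inf]])[y_idx]
            th_lo = np.concatenate([[-np.inf], th])[y_idx]
            total = 0.0
            for idx in gidx:
                # obs x quad-node matrix of log P(y | u)
                u = sigma * z_nodes
                hi = expit(th_hi[idx, None] - eta[idx, None] - u[None, :])
                lo = expit(th_lo[idx, None] - eta[idx, None] - u[None, :])
                logp = np.log(np.maximum(hi - lo, 1e-300)).sum(axis=0)
                m = np.max(logp + log_w)
                total += m + np.log(np.sum(np.exp(logp + log_w - m)))
            return -total

        from scipy import optimize

        res = optimize.minimize(nll, start, method="BFGS", options={"maxiter": 500})
        th, beta, sigma = unpack(res.x)
        if not res.success and res.status != 2:  # 2 = precision loss, usually benign
            raise EstimationError(f"random-intercept ordinal fit failed: {res.message}")
        if np.any(np.abs(beta) > 50):
            raise EstimationError(
                "random-intercept ordinal fit diverged (possible complete separation)"
            )
        H = numdiff.approx_hess(res.x, nll)
        try:
            cov_all = np.linalg.inv(H)
            se_full = np.sqrt(np.maximum(np.diag(cov_all), 0.0))
        except np.linalg.LinAlgError:
            se_full = np.full(res.x.size, np.nan)
        se_beta = pd.Series(se_full[K - 1 : K - 1 + p], index=list(self._design().columns))
        # convert cumulative cutpoints to the P(Y > k) intercept convention
        return OrdinalPainResults(
            model=self,
            method="random_intercept",
            intercepts=-th,
            beta=pd.Series(beta, index=list(self._design().columns)),
            beta_se=se_beta,
            sigma_u=float(sigma),
            raw_result=res,
            _ri_cutpoints=th,
            _ri_beta=beta,
        )


@dataclass
class OrdinalPainResults:
    """Fitted ordinal pain model: term tests and baseline-probability curves."""

    model: OrdinalPainModel
    method: str
    intercepts: np.ndarray  # P(Y > level_k) = expit(icept_k + X beta) convention
    beta: pd.Series
    beta_se: pd.Series
    sigma_u: float | None
    raw_result: object
    _ri_cutpoints: np.ndarray | None = None
    _ri_beta: np.ndarray | None = None

    TERMS = ("treatment", "period", "time", "time:treatment", "period:time")

    def effect_table(self) -> pd.DataFrame:
        """Wald tests per fixed-effect term (ANOVA-table shape)."""
        rows = []
        for term in self.TERMS:
            z = self.beta[term] / self.beta_se[term]
            rows.append(
                {
                    "effect": term,
                    "estimate": float(self.beta[term]),
                    "se": float(self.beta_se[term]),
                    "statistic": float(z),
                    "pvalue": float(2 * sps.norm.sf(abs(z))),
                }
            )
        return pd.DataFrame(rows)

    def _prob_gt(self, X: np.ndarray, k: int) -> np.ndarray:
        """P(score > level_k | x), marginally over any random intercept."""
        if self.method == "gee":
            return expit(self.intercepts[k] + X @ self.beta.to_numpy())
        # integrate the conditional model over the random intercept
        nodes, wts = np.polynomial.hermite.hermgauss(25)
        z = np.sqrt(2.0) * nodes
        w = wts / np.sqrt(np.pi)
        eta = X @ self._ri_beta
        le = expit(
            self._ri_cutpoints[k] - eta[:, None] - self.sigma_u * z[None, :]
        )
        return 1.0 - le @ w

    def category_probabilities(
        self, period: int, treatment: str, times_h: np.ndarray
    ) -> np.ndarray:
        """P(score = level) for every level at each time; rows sum to 1."""
        X = self.model._design_point(period, treatment, times_h)
        K = len(self.model.levels)
        gt = np.column_stack(
            [np.ones(len(X))] + [self._prob_gt(X, k) for k in range(K - 1)] + [np.zeros(len(X))]
        )
        gt = np.minimum.accumulate(gt, axis=1)  # enforce monotone survivor curve
        return -np.diff(gt, axis=1)

    def baseline_probability_curve(
        self,
        period: int,
        treatment: str,
        times_h: np.ndarray | None = None,
        baseline_level: int = 0,
    ) -> tuple[np.ndarray, np.ndarray]:
        """P(score == baseline level) over time for one period x arm."""
        if times_h is None:
            times_h = np.arange(
                min(self.model.data[self.model.cols["time"]]), 72.0 + 0.25, 0.5
            )
        times_h = np.asarray(times_h, dtype=float)
        k = int(np.searchsorted(self.model.levels, baseline_level))
        probs = self.category_probabilities(period, treatment, times_h)[:, k]
        return times_h, probs

    def crossing_times(
        self, level: float = 0.5, baseline_level: int = 0
    ) -> dict[tuple[int, str], CrossingTime]:
        """LD50-like crossing time per period x treatment."""
        out = {}
        for period in (1, 2):
            for trt in (self.model.reference, self.model.active):
                t, p = self.baseline_probability_curve(
                    period, trt, baseline_level=baseline_level
                )
                out[(period, trt)] = crossing_time(t, p, level=level)
        return out

    def summary(self):
        from statsmodels.iolib.summary2 import Summary

        s = Summary()
        s.add_title(
            f"Ordinal pain model ({'marginal GEE' if self.method == 'gee' else 'random intercept ML'})"
        )
        s.add_df(self.effect_table().round(4))
        cross = self.crossing_times()
        s.add_text(
            "Time to 0.5 probability of baseline score: "
            + "; ".join(
                f"period {p}, {t}: {ct}" for (p, t), ct in cross.items()
            )
        )
        if self.sigma_u is not None:
            s.add_text(f"Random-intercept SD: {self.sigma_u:.3f}")
        return s

    def plot_probability_curves(self, ax=None):
        """Fitted probability-of-baseline-score curves, one panel per period."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
        else:
            axes = np.atleast_1d(ax)
        for i, period in enumerate((1, 2)):
            a = axes[i % len(axes)]
            for trt, color in [(self.model.reference, "tab:red"),
                               (self.model.active, "tab:blue")]:
                t, p = self.baseline_probability_curve(period, trt)
                a.plot(t, p, color=color, label=trt)
            a.axhline(0.5, color="grey", lw=0.8, ls="--")
            a.set_title(f"Period {period}")
            a.set_xlabel("hours after treatment")
            a.set_ylim(0, 1)
        axes[0].set_ylabel("P(score at baseline)")
        axes[0].legend()
        return axes


def fit_ordinal_repeated(
    pain_data: pd.DataFrame, method: str = "gee", **kwargs
) -> OrdinalPainResults:
    """Convenience wrapper: build and fit an :class:`OrdinalPainModel`."""
    return OrdinalPainModel(pain_data, **kwargs).fit(method=method)
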