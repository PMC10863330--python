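"""Dose-response inference: mixed models, LR tests, PDP, importance.

Implements the statistical chain applied to the MEP tables: GESD outlier
screening of model residuals, the mixed-model families (current or
electric field on normalized MEP, current/field on absolute MEP, current
on latency difference), likelihood-ratio tests with Benjamini-Hochberg
FDR control, partial dependence with cluster-bootstrap BCa confidence
intervals, permutation variable importance, and extraction of the
optimal field value E_opt and its normalized-MEP gain over sham.

Models are estimated by maximum likelihood with independent variance
components (no random correlations); the random-effect standard
deviations across stimulation-current levels share a single parameter by
construction.  The nonlinear field effect enters through first- to
third-order polynomials orthonormalized against the observed EFDI
values.  Fixed-effect designs are built from explicit dummy and product
columns so that likelihood-ratio tests remove exactly the named columns
(interactions are not re-coded when a main effect is dropped).  Natural
logarithms are used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import patsy
import scipy.stats as st
import statsmodels.formula.api as smf

from .mep import MEPDataset, normalize_to_baseline

__all__ = [
    "LMMSpec",
    "PrepInfo",
    "DoseResponseFit",
    "LRTest",
    "gesd_outliers",
    "orthonormal_basis",
    "prepare_analysis_table",
    "build_spec",
    "fit_lmm",
    "drop_term_group",
    "lr_test",
    "lr_screen",
    "bh_fdr",
    "partial_dependence",
    "bootstrap_bca",
    "permutation_importance",
    "optimal_field",
    "FAMILIES",
]

FAMILIES = ("current_nmep", "field_nmep", "current_absolute", "field_absolute", "latency")

_GROUP_COL = "participant"


# ---------------------------------------------------------------------------
# outlier screening


def gesd_outliers(
    residuals: np.ndarray,
    alpha: float = 0.05,
    max_outliers: int | None = None,
) -> np.ndarray:
    """Generalized extreme Studentized deviate (Rosner) outlier test.

    Returns positions (into ``residuals``) of detected outliers; at most
    ``max_outliers`` (default 5% of n).  Degenerate zero-variance input
    yields an empty set.
    """
    x = np.asarray(residuals, dtype=float)
    n = len(x)
    if max_outliers is None:
        max_outliers = max(1, int(0.05 * n))
    if n <= max_outliers + 2:
        raise ValueError("too few observations for the requested outlier cap")
    if np.std(x) == 0:
        return np.array([], dtype=int)
    idx = np.arange(n)
    removed: list[int] = []
    stats: list[float] = []
    lams: list[float] = []
    xr = x.copy()
    for i in range(1, max_outliers + 1):
        mu, sd = xr.mean(), xr.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(xr - mu)
        j = int(np.argmax(dev))
        stats.append(dev[j] / sd)
        m = n - i  # observations remaining after this removal
        p = 1.0 - alpha / (2.0 * (m + 1))
        t = st.t.ppf(p, m - 1)
        lams.append(m * t / np.sqrt((m - 1 + t**2) * (m + 1)))
        removed.append(int(idx[j]))
        xr = np.delete(xr, j)
        idx = np.delete(idx, j)
    n_out = 0
    for i, (r, lam) in enumerate(zip(stats, lams), start=1):
        if r > lam:
            n_out = i
    return np.array(removed[:n_out], dtype=int)


# ---------------------------------------------------------------------------
# orthonormal polynomial basis


def orthonormal_basis(
    x: np.ndarray, degree: int = 3
) -> tuple[np.ndarray, Callable[[np.ndarray], np.ndarray]]:
    """Polynomials of ``x`` orthonormalized under the empirical inner product.

    Gram-Schmidt (via QR) on ``{1, x, ..., x^degree}`` with
    ``<f, g> = sum f(x_i) g(x_i) / n``; returns the degree 1..``degree``
    columns (the constant is absorbed by the model intercept) and an
    evaluator for new ``x`` values, as needed for partial-dependence grids.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if len(np.unique(x)) < degree + 1:
        raise ValueError(f"need at least {degree + 1} distinct x values")
    V = np.vander(x, degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    sign = np.sign(np.diag(R))
    sign[sign == 0] = 1.0
    Q = Q * sign
    R = R * sign[:, None]
    coef = np.linalg.solve(R, np.eye(degree + 1)) * np.sqrt(n)

    def evaluate(new_x: np.ndarray) -> np.ndarray:
        v = np.vander(np.atleast_1d(np.asarray(new_x, dtype=float)), degree + 1, increasing=True)
        return (v @ coef)[:, 1:]

    return Q[:, 1:] * np.sqrt(n), evaluate


# ---------------------------------------------------------------------------
# design columns and data preparation

_POLY = ("ef_p1", "ef_p2", "ef_p3")
_CUR = ("cur05", "cur10", "cur15", "cur20")
_CUR_LEVELS = {"cur05": 0.5, "cur10": 1.0, "cur15": 1.5, "cur20": 2.0}


@dataclass
class PrepInfo:
    """State needed to (re)build the model design columns from source data."""

    family: str
    evaluator: Callable[[np.ndarray], np.ndarray] | None = None
    logb_mean: float | None = None

    def refresh(self, df: pd.DataFrame) -> pd.DataFrame:
        """Recompute every derived design column from the source columns.

        Called after any source column (direction, timepoint, gender,
        time_of_day, condition_mA, log_baseline, E_FDI) changes, e.g.
        during partial dependence or permutation importance.
        """
        df = df.copy()
        df["dirAP"] = (df["direction"] == "AP").astype(float)
        df["male"] = (df["gender"] == "M").astype(float)
        df["morning"] = (df["time_of_day"] == "morning").astype(float)
        df["current"] = df["condition_mA"].astype(str)
        for name, tp in (("tp0", "0min"), ("tp15", "15min"), ("tp30", "30min")):
            df[name] = (df["timepoint"] == tp).astype(float)
        for name, lvl in _CUR_LEVELS.items():
            df[name] = (df["condition_mA"] == lvl).astype(float)
        if "log_baseline" in df.columns:
            if self.logb_mean is None:
                self.logb_mean = float(df["log_baseline"].mean())
            df["log_baseline_c"] = df["log_baseline"] - self.logb_mean
        if self.evaluator is not None:
            df[list(_POLY)] = self.evaluator(df["E_FDI"].to_numpy())
        # interaction products (cheap; build the union used by any family)
        tps = ("tp0", "tp15", "tp30")
        for a in ("dirAP",):
            for t in tps:
                df[f"{a}_{t}"] = df[a] * df[t]
        mains = list(_CUR) + (list(_POLY) if self.evaluator is not None else [])
        for m in mains:
            df[f"{m}_dirAP"] = df[m] * df["dirAP"]
            df[f"{m}_male"] = df[m] * df["male"]
            df[f"{m}_morning"] = df[m] * df["morning"]
            if "log_baseline_c" in df.columns:
                df[f"{m}_logbc"] = df[m] * df["log_baseline_c"]
            for t in tps:
                df[f"{m}_{t}"] = df[m] * df[t]
                df[f"{m}_dirAP_{t}"] = df[m] * df["dirAP"] * df[t]
        return df


def prepare_analysis_table(
    data: MEPDataset | pd.DataFrame, family: str
) -> tuple[pd.DataFrame, PrepInfo]:
    """Transform a long MEP table into the model-ready analysis table.

    Adds the response (log normalized MEP, log MEP or latency difference),
    the log baseline covariate, and the dummy/product design columns;
    field families additionally carry the orthonormal field polynomial
    columns ``ef_p1..3``.  Returns the table and the :class:`PrepInfo`
    that can rebuild the design columns for modified data.
    """
    table = data.table if isinstance(data, MEPDataset) else data
    if family not in FAMILIES:
        raise ValueError(f"unknown model family '{family}'")
    evaluator = None
    if family in ("current_nmep", "field_nmep"):
        df = normalize_to_baseline(table)
        df["log_nmep"] = np.log(df["normalized_mep"])
        df["log_baseline"] = np.log(df["baseline_mep_uV"])
    elif family in ("current_absolute", "field_absolute"):
        df = table.copy()
        df["log_mep"] = np.log(df["mep_size_uV"])
    else:  # latency
        df = table.copy()
        key = ["participant", "session_number"]
        ref = (
            df[(df["timepoint"] == "baseline") & (df["direction"] == "PA")]
            .set_index(key)["latency_ms"]
        )
        idx = pd.MultiIndex.from_frame(df[key])
        if not idx.isin(ref.index).all():
            raise ValueError("missing PA baseline latency for some session")
        df["latency_diff"] = df["latency_ms"].to_numpy() - ref.loc[idx].to_numpy()
        df = df[~((df["timepoint"] == "baseline") & (df["direction"] == "PA"))].copy()
    if family.startswith("field"):
        if "E_FDI" not in df.columns:
            raise ValueError("field families require an E_FDI column")
        _, evaluator = orthonormal_basis(df["E_FDI"].to_numpy(), degree=3)
    prep = PrepInfo(family, evaluator)
    return prep.refresh(df.reset_index(drop=True)), prep


# ---------------------------------------------------------------------------
# model specification


@dataclass
class LMMSpec:
    """Term lists and random structure for one mixed-model family."""

    family: str
    response: str
    fixed_terms: tuple[str, ...]
    vc_formula: dict[str, str]
    re_formula: str
    term_groups: dict[str, tuple[str, ...]]
    permute_sources: dict[str, tuple[str, ...]]
    no_intercept: bool = False

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed_terms)
        if self.no_intercept:
            rhs = "0 + " + rhs
        return f"{self.response} ~ {rhs}"


def _with_interactions(mains: Sequence[str], tps: Sequence[str], baseline: bool) -> list[str]:
    """Main + its interaction product columns with the design factors."""
    out = []
    for m in mains:
        out.append(m)
        out.append(f"{m}_dirAP")
        out.extend(f"{m}_{t}" for t in tps)
        out.extend(f"{m}_dirAP_{t}" for t in tps)
        out.append(f"{m}_male")
        out.append(f"{m}_morning")
        if baseline:
            out.append(f"{m}_logbc")
    return out


def build_spec(family: str, lean: bool = False) -> LMMSpec:
    """Exact fixed-term column lists and random structure for each family.

    Normalized-MEP families use the post-tDCS time points (reference
    0 min); absolute and latency families include the baseline time point
    (reference baseline).  ``lean=True`` yields the reduced simulation
    variant used by the calibration studies.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown model family '{family}'")
    base_vc = {
        "curr": "0 + C(current)",
        "dir": "0 + C(direction)",
        "tp": "0 + C(timepoint)",
        "tod": "0 + C(time_of_day)",
        "bl": "0 + log_baseline",
    }
    if family == "current_nmep":
        tps = ("tp15", "tp30")
        terms = tuple(
            _with_interactions(_CUR, tps, baseline=True)
            + ["dirAP", *tps, *(f"dirAP_{t}" for t in tps)]
            + ["male", "morning", "log_baseline", "session_number"]
        )
        groups = {
            "current": _CUR,
            "direction": ("dirAP",),
            "timepoint": tps,
            "gender": ("male",),
            "time_of_day": ("morning",),
            "baseline": ("log_baseline",),
            "session": ("session_number",),
        }
        sources = {
            "current": ("condition_mA",),
            "direction": ("direction",),
            "timepoint": ("timepoint",),
            "gender": ("gender",),
            "time_of_day": ("time_of_day",),
            "baseline": ("log_baseline",),
            "session": ("session_number",),
        }
        return LMMSpec(family, "log_nmep", terms, base_vc, "1", groups, sources)
    if family == "field_nmep":
        if lean:
            terms = (*_POLY, "dirAP", "tp15", "tp30", "log_baseline")
            groups = {
                "field": _POLY,
                "field_order3": ("ef_p3",),
                "baseline": ("log_baseline",),
            }
            sources = {"field": ("E_FDI",), "baseline": ("log_baseline",)}
            vc = {"curr": "0 + C(current)", "ef": "0 + E_FDI"}
            return LMMSpec(family, "log_nmep", terms, vc, "1", groups, sources)
        tps = ("tp15", "tp30")
        terms = tuple(
            _with_interactions(_POLY, tps, baseline=True)
            + ["dirAP", *tps, *(f"dirAP_{t}" for t in tps)]
            + ["male", "morning", "log_baseline", "session_number"]
        )
        groups = {
            "field": _POLY,
            "field_order1": tuple(_with_interactions(["ef_p1"], tps, True)),
            "field_order2": tuple(_with_interactions(["ef_p2"], tps, True)),
            "field_order3": tuple(_with_interactions(["ef_p3"], tps, True)),
            "direction": ("dirAP",),
            "timepoint": tps,
            "gender": ("male",),
            "time_of_day": ("morning",),
            "baseline": ("log_baseline",),
            "session": ("session_number",),
        }
        sources = {
            "field": ("E_FDI",),
            "direction": ("direction",),
            "timepoint": ("timepoint",),
            "gender": ("gender",),
            "time_of_day": ("time_of_day",),
            "baseline": ("log_baseline",),
            "session": ("session_number",),
        }
        vc = dict(base_vc)
        vc["ef"] = "0 + E_FDI"
        return LMMSpec(family, "log_nmep", terms, vc, "1", groups, sources)
    if family in ("current_absolute", "field_absolute"):
        mains = _CUR if family == "current_absolute" else _POLY
        dose_name = "current" if family == "current_absolute" else "field"
        tps = ("tp0", "tp15", "tp30")
        dose_terms = []
        for m in mains:
            dose_terms.append(m)
            dose_terms.append(f"{m}_dirAP")
            dose_terms.extend(f"{m}_{t}" for t in tps)
            dose_terms.extend(f"{m}_dirAP_{t}" for t in tps)
        terms = tuple(
            dose_terms
            + ["dirAP", *tps, *(f"dirAP_{t}" for t in tps)]
            + ["session_number", "male", "morning"]
        )
        groups = {
            dose_name: mains,
            "direction": ("dirAP",),
            "timepoint": tps,
        }
        sources = {
            dose_name: ("condition_mA",) if family == "current_absolute" else ("E_FDI",),
            "direction": ("direction",),
            "timepoint": ("timepoint",),
        }
        vc = {
            "dir": "0 + C(direction)",
            "tp": "0 + C(timepoint)",
            "tod": "0 + C(time_of_day)",
            "sess": "0 + session_number",
        }
        if family == "field_absolute":
            vc["ef"] = "0 + E_FDI"
        else:
            vc["curr"] = "0 + C(current)"
        return LMMSpec(family, "log_mep", terms, vc, "1", groups, sources)
    # latency: difference from the PA baseline; no terms featuring
    # intercepts.  The (PA, baseline) reference cell is absent from the
    # data, so the direction x timepoint interaction would be rank
    # deficient and is omitted; the current interactions carry the
    # tDCS-vs-sham contrasts of interest.
    tps = ("tp0", "tp15", "tp30")
    cur_terms = [f"{c}_{t}" for c in _CUR for t in tps] + [f"{c}_dirAP" for c in _CUR]
    terms = tuple(["dirAP", *tps] + cur_terms)
    groups = {
        "current": tuple(cur_terms),
        "direction": ("dirAP",),
        "timepoint": tps,
    }
    sources = {
        "current": ("condition_mA",),
        "direction": ("direction",),
        "timepoint": ("timepoint",),
    }
    vc = {"dir": "0 + C(direction)", "tp": "0 + C(timepoint)"}
    return LMMSpec(family, "latency_diff", terms, vc, "0", groups, sources, no_intercept=True)


def drop_term_group(spec: LMMSpec, group: str) -> LMMSpec:
    """Reduced spec with one named fixed-effect term group removed."""
    if group not in spec.term_groups:
        raise ValueError(f"unknown term group '{group}'")
    dropped = set(spec.term_groups[group])
    terms = tuple(t for t in spec.fixed_terms if t not in dropped)
    if not terms:
        terms = ("1",) if not spec.no_intercept else ("0",)
    return replace(spec, fixed_terms=terms)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class DoseResponseFit:
    """Fitted mixed model plus everything needed for downstream inference."""

    spec: LMMSpec
    result: object  # statsmodels MixedLMResults
    data: pd.DataFrame
    prep: PrepInfo | None = None
    excluded_outliers: tuple[int, ...] = ()

    @property
    def loglik(self) -> float:
        return float(self.result.llf)

    @property
    def n_fixed(self) -> int:
        return len(self.result.fe_params)

    def fixed_design(self, df: pd.DataFrame) -> np.ndarray:
        di = self.result.model.data.design_info
        return np.asarray(patsy.build_design_matrices([di], df)[0])

    def predict_fixed(self, df: pd.DataFrame) -> np.ndarray:
        return self.fixed_design(df) @ np.asarray(self.result.fe_params)

    def re_contributions(self) -> dict[str, np.ndarray]:
        """Per-row random-effect contribution, split by random term."""
        res = self.result
        df = self.data
        groups = df[_GROUP_COL].to_numpy()
        blups = res.random_effects
        out: dict[str, np.ndarray] = {}
        if self.spec.re_formula == "1":
            out["Group"] = np.array([blups[g].get("Group", 0.0) for g in groups])
        for comp, f in self.spec.vc_formula.items():
            D = patsy.dmatrix(f, df, return_type="dataframe")
            contrib = np.zeros(len(df))
            for col in D.columns:
                key = f"{comp}[{col}]"
                coef = np.array([blups[g].get(key, 0.0) for g in groups])
                contrib += D[col].to_numpy() * coef
            out[comp] = contrib
        return out


def fit_lmm(
    spec: LMMSpec,
    table: pd.DataFrame,
    prep: PrepInfo | None = None,
    screen_outliers: bool = True,
    gesd_alpha: float = 0.05,
    maxiter: int = 500,
) -> DoseResponseFit:
    """Maximum-likelihood fit of one model family.

    Residuals of the initial fit are screened with the GESD test; if
    outliers are found the flagged rows are excluded and the model
    refitted once.  Raises on optimizer failure.
    """
    df = table.reset_index(drop=True)

    def _fit(d: pd.DataFrame):
        model = smf.mixedlm(
            spec.formula,
            d,
            groups=d[_GROUP_COL],
            vc_formula=spec.vc_formula or None,
            re_formula=spec.re_formula,
        )
        # quasi-Newton steps alone stall well short of the ML optimum for
        # these variance-component models; polish with derivative-free
        # optimizers and keep the best log-likelihood
        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "powell", "nm"):
                try:
                    kw = {}
                    if best is not None:
                        kw["start_params"] = best.params_object
                    res = model.fit(reml=False, method=method, maxiter=maxiter, **kw)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if np.isfinite(res.llf) and (best is None or res.llf > best.llf):
                    best = res
        if best is None:
            raise RuntimeError(f"mixed-model fit failed to converge for {spec.family}")
        return best

    res = _fit(df)
    excluded: tuple[int, ...] = ()
    if screen_outliers:
        resid = np.asarray(res.resid)
        out = gesd_outliers(resid, alpha=gesd_alpha)
        if len(out):
            excluded = tuple(int(i) for i in out)
            df = df.drop(index=list(out)).reset_index(drop=True)
            res = _fit(df)
    return DoseResponseFit(spec, res, df, prep, excluded)


# ---------------------------------------------------------------------------
# inference


@dataclass(frozen=True)
class LRTest:
    term: str
    chi2: float
    df: int
    p: float
    fdr_significant: bool | None = None


def lr_test(full: DoseResponseFit, reduced: DoseResponseFit, term: str = "") -> LRTest:
    """Likelihood-ratio test of nested ML fits."""
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = full.n_fixed - reduced.n_fixed
    if df <= 0:
        raise ValueError("reduced model is not nested with fewer fixed parameters")
    p = float(st.chi2.sf(chi2, df))
    return LRTest(term, float(chi2), int(df), p)


def lr_screen(
    full: DoseResponseFit,
    groups: Sequence[str] | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """LR test of each fixed-effect term group, with BH-FDR flags.

    Refits the reduced model for every group on the same (outlier-screened)
    rows as the full fit.
    """
    spec = full.spec
    names = list(groups) if groups is not None else list(spec.term_groups)
    tests = []
    for g in names:
        red = fit_lmm(drop_term_group(spec, g), full.data, full.prep, screen_outliers=False)
        tests.append(lr_test(full, red, g))
    mask = bh_fdr(np.array([t.p for t in tests]), q=q)
    return pd.DataFrame(
        {
            "term": [t.term for t in tests],
            "chi2": [t.chi2 for t in tests],
            "df": [t.df for t in tests],
            "p": [t.p for t in tests],
            "fdr_significant": mask,
        }
    )


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up procedure; boolean significance mask."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p)
    thresh = q * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    mask = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.nonzero(passed)[0].max()
        mask[order[: kmax + 1]] = True
    return mask


# ---------------------------------------------------------------------------
# partial dependence and optimal field


def partial_dependence(
    fit: DoseResponseFit,
    variable: str,
    grid: Sequence,
    per_participant: bool = False,
) -> pd.DataFrame:
    """Average model prediction with ``variable`` pinned to each grid value.

    ``variable`` is a source column (``E_FDI``, ``condition_mA``,
    ``direction``, ...); the derived design columns are rebuilt for each
    grid value.  The prediction is averaged over the observed covariate
    rows (fixed effects only); with ``per_participant`` the participant
    curves additionally condition on that participant's estimated random
    effects and average over the participant's own rows.
    """
    df = fit.data
    if fit.prep is None:
        raise ValueError("fit carries no preparation info; cannot rebuild design")
    re_contrib = None
    if per_participant:
        re_contrib = np.zeros(len(df))
        for v in fit.re_contributions().values():
            re_contrib += v
    rows = []
    for gval in grid:
        mod = df.copy()
        mod[variable] = gval
        mod = fit.prep.refresh(mod)
        pred = fit.predict_fixed(mod)
        row = {"grid": gval, "pdp": float(pred.mean())}
        if per_participant:
            total = pred + re_contrib
            for pid, sel in df.groupby(_GROUP_COL).indices.items():
                row[f"pdp_{pid}"] = float(total[sel].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def optimal_field(
    fit: DoseResponseFit,
    grid_step: float = 0.005,
    per_participant: bool = False,
) -> dict:
    """Field value maximizing the fitted dose-response curve.

    Returns ``E_opt`` (V/m), ``delta_nmep_pct`` — the percent change of the
    normalized MEP at ``E_opt`` relative to sham (field 0), computed on the
    log-response scale — a boundary flag, and optionally per-participant
    optima from the random-effect-conditioned curves.
    """
    if "E_FDI" not in fit.data.columns:
        raise ValueError("fit does not involve the electric field")
    emax = float(fit.data["E_FDI"].max())
    if emax <= 0:
        raise ValueError("no field variation in the data (sham only)")
    grid = np.arange(0.0, emax + grid_step / 2, grid_step)
    pdp = partial_dependence(fit, "E_FDI", grid, per_participant=per_participant)
    curve = pdp["pdp"].to_numpy()
    i_opt = int(np.argmax(curve))
    out = {
        "E_opt": float(grid[i_opt]),
        "delta_nmep_pct": float(100.0 * (np.exp(curve[i_opt] - curve[0]) - 1.0)),
        "at_boundary": i_opt in (0, len(grid) - 1),
        "grid": grid,
        "curve": curve,
    }
    if per_participant:
        per = {}
        for col in pdp.columns:
            if col.startswith("pdp_"):
                c = pdp[col].to_numpy()
                j = int(np.argmax(c))
                per[col[4:]] = {
                    "E_opt": float(grid[j]),
                    "delta_nmep_pct": float(100.0 * (np.exp(c[j] - c[0]) - 1.0)),
                }
        out["per_participant"] = per
    return out


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_bca(
    statistic: Callable[[pd.DataFrame], float],
    table: pd.DataFrame,
    B: int = 10000,
    seed: int = 0,
    cluster: str | None = _GROUP_COL,
    alpha: float = 0.05,
) -> dict:
    """BCa confidence interval for a statistic of the MEP table.

    Resampling is by participant (cluster bootstrap) by default, since
    observations within a participant are dependent; resampled clusters
    get fresh labels so duplicated participants stay distinct for the
    grouped refits.  Set ``cluster=None`` for row-level resampling.
    """
    rng = np.random.default_rng(seed)
    theta = float(statistic(table))
    if cluster is not None:
        ids = table[cluster].unique()
        groups = {g: table[table[cluster] == g] for g in ids}

        def resample() -> pd.DataFrame:
            chosen = rng.choice(ids, size=len(ids), replace=True)
            parts = []
            for j, g in enumerate(chosen):
                part = groups[g].copy()
                part[cluster] = f"B{j:03d}"
                parts.append(part)
            return pd.concat(parts, ignore_index=True)

        jack_units = [table[table[cluster] != g] for g in ids]
    else:
        n = len(table)

        def resample() -> pd.DataFrame:
            return table.iloc[rng.integers(0, n, size=n)].reset_index(drop=True)

        jack_units = [table.drop(index=i) for i in table.index]

    boots = np.array([float(statistic(resample())) for _ in range(B)])
    if np.allclose(boots, boots[0]):
        return {"estimate": theta, "lo": theta, "hi": theta, "boots": boots}
    # bias correction
    z0 = st.norm.ppf(np.clip(np.mean(boots < theta), 1e-12, 1 - 1e-12))
    # acceleration from the jackknife
    jack = np.array([float(statistic(u)) for u in jack_units])
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    zlo, zhi = st.norm.ppf(alpha / 2), st.norm.ppf(1 - alpha / 2)

    def adj(z):
        return st.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))

    lo, hi = np.quantile(boots, [adj(zlo), adj(zhi)])
    return {"estimate": theta, "lo": float(lo), "hi": float(hi), "boots": boots}


# ---------------------------------------------------------------------------
# permutation variable importance


def permutation_importance(
    fit: DoseResponseFit,
    n_perm: int = 1000,
    seed: int = 0,
    predictors: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Permutation importance of fixed and random predictors.

    A predictor's source column(s) are permuted (the derived design
    columns, including interactions, are rebuilt from the permuted
    parents, keeping the design consistent), a new prediction is computed
    without refitting, and the importance is the drop in the coefficient
    of determination, averaged over ``n_perm`` permutations.
    Random-effect predictors are permuted at the participant level (their
    estimated effects are reassigned among participants).
    """
    rng = np.random.default_rng(seed)
    df = fit.data
    y = df[fit.spec.response].to_numpy()
    fixed0 = fit.predict_fixed(df)
    re_parts = fit.re_contributions()
    re_total = np.zeros(len(df))
    for v in re_parts.values():
        re_total += v
    pred0 = fixed0 + re_total
    ss_tot = np.sum((y - y.mean()) ** 2)

    def r2(pred: np.ndarray) -> float:
        return 1.0 - np.sum((y - pred) ** 2) / ss_tot

    r2_0 = r2(pred0)
    groups = df[_GROUP_COL].to_numpy()
    uids = np.unique(groups)

    names: list[tuple[str, str]] = []
    if predictors is None:
        names = [("fixed", g) for g in fit.spec.permute_sources]
        names += [("random", comp) for comp in re_parts]
    else:
        for p in predictors:
            kind = "fixed" if p in fit.spec.permute_sources else "random"
            names.append((kind, p))

    rows = []
    for kind, name in names:
        scores = np.empty(n_perm)
        for b in range(n_perm):
            if kind == "fixed":
                perm = rng.permutation(len(df))
                mod = df.copy()
                for col in fit.spec.permute_sources[name]:
                    mod[col] = df[col].to_numpy()[perm]
                mod = fit.prep.refresh(mod)
                pred = fit.predict_fixed(mod) + re_total
            else:
                relabel = dict(zip(uids, rng.permutation(uids)))
                # reassign this component's estimated effects among participants
                contrib = re_parts[name]
                per_group = {g: contrib[groups == g] for g in uids}
                permuted = np.empty(len(df))
                for g in uids:
                    src = per_group[relabel[g]]
                    sel = groups == g
                    permuted[sel] = np.resize(src, int(sel.sum()))
                pred = pred0 - contrib + permuted
            scores[b] = r2_0 - r2(pred)
        rows.append(
            {
                "predictor": name,
                "kind": kind,
                "importance": scores.mean(),
                "mc_se": scores.std(ddof=1) / np.sqrt(n_perm),
            }
        )
    return pd.DataFrame(rows).sort_values("importance", ascending=False).reset_index(drop=True)
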