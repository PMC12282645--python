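"""Night-level agreement statistics: mixed-model ICC and Bland-Altman.

Scratch outcomes are compared across sources (Reference, devices, single
raters) with a linear mixed model on the log scale: a fixed effect for the
source, a random intercept per participant, and a random intercept per night
nested within participant,

    y_ijl = mu + beta_l + a_i + b_ij + e_ijl,
    a_i ~ N(0, s2_p),  b_ij ~ N(0, s2_n),  e_ijl ~ N(0, s2_e).

The intraclass correlation is formed from the variance components
(two-way mixed model, interaction absent, absolute-agreement convention):

    adjusted ICC   = (s2_p + s2_n) / (s2_p + s2_n + s2_e)
    unadjusted ICC = (s2_p + s2_n) / (s2_p + s2_n + s2_e + var(fixed effects))

Both definitions are always computed; the adjusted one is reported by
default.  Confidence intervals are percentile intervals over a cluster
bootstrap that resamples whole participants (500 resamples by default),
respecting the repeated-measures structure.

Fitting: for a fully balanced design (every participant with the same number
of nights, every night observed by every source) the restricted-maximum-
likelihood solution coincides with the closed-form balanced-ANOVA
variance-component estimators whenever those are non-negative, and that
closed form is used (it vectorises across bootstrap resamples).  Unbalanced
data fall back to a numerical REML fit (statsmodels ``MixedLM``).
Non-convergent fits are flagged, never silently replaced.

The TSO-duration comparison uses a repeated-measures Bland-Altman analysis:
per-night differences d = DHT - Reference are modelled with an
intercept-only mixed model (participant random intercept); the bias is the
intercept and the 95% limits of agreement are
``bias +- 1.96 * sqrt(s2_between + s2_within)``, with bootstrap CIs from the
same cluster-resampling engine.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "ICCResult",
    "BlandAltmanResult",
    "fit_variance_components",
    "icc_from_components",
    "bootstrap_icc",
    "bland_altman_repeated",
    "DEFAULT_N_BOOTSTRAP",
]

DEFAULT_N_BOOTSTRAP = 500
_Z95 = 1.959963984540054  # two-sided 95% normal quantile
_DEGENERATE_TOL = 1e-9


@dataclass(frozen=True)
class VarianceComponents:
    """REML variance components and fixed source effects on the log scale."""

    var_participant: float
    var_night: float
    var_residual: float
    fixed_source_effects: dict
    var_fixed: float
    converged: bool = True
    boundary: bool = False
    method: str = "anova"
    message: Optional[str] = None


@dataclass(frozen=True)
class ICCResult:
    estimate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    definition: str
    n_bootstrap: int
    n_used: int
    n_dropped: int
    flagged: bool
    components: VarianceComponents


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    bias_ci: tuple[float, float]
    loa_low_ci: tuple[float, float]
    loa_high_ci: tuple[float, float]
    n_pairs: int
    n_participants: int
    var_between: float
    var_within: float
    method: str = "anova"


# ---------------------------------------------------------------------------
# data wrangling


_ALIASES = {
    "participant": ("participant", "participant_id"),
    "night": ("night", "night_id"),
    "source": ("source",),
    "y": ("y", "value"),
}


def _canonical(table: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    for canon, names in _ALIASES.items():
        for name in names:
            if name in table.columns:
                cols[name] = canon
                break
        else:
            raise ValueError(f"long table is missing a {canon!r} column (any of {names})")
    df = table.rename(columns=cols)[["participant", "night", "source", "y"]].copy()
    if df["y"].isna().any():
        raise ValueError("long table contains missing outcome values")
    return df


def _balanced_cube(df: pd.DataFrame) -> Optional[np.ndarray]:
    """Reshape to a (participants, nights, sources) cube, or None if unbalanced.

    Balance requires: every (participant, night) observed by every source
    exactly once, the same number of nights for every participant, and at
    least 2 participants, 2 nights and 2 sources.
    """
    sources = sorted(df["source"].unique())
    k = len(sources)
    if k < 2:
        return None
    pivot = df.pivot_table(
        index=["participant", "night"], columns="source", values="y", aggfunc="count"
    )
    if pivot.isna().any().any() or (pivot != 1).any().any():
        return None
    nights_per = pivot.reset_index().groupby("participant")["night"].count()
    n = int(nights_per.iloc[0])
    if not (nights_per == n).all() or n < 2 or len(nights_per) < 2:
        return None
    wide = df.pivot(index=["participant", "night"], columns="source", values="y")
    wide = wide.sort_index()[sources]
    p = len(nights_per)
    return wide.to_numpy(dtype=float).reshape(p, n, k)


# ---------------------------------------------------------------------------
# balanced closed form (vectorises over leading axes)


def _anova_components_cube(Y: np.ndarray):
    """Variance components from a (..., p, n, k) cube of log outcomes.

    Returns ``(var_p, var_n, var_e, var_fixed, boundary)`` with the two
    between-level components truncated at zero (REML boundary).
    """
    p, n, k = Y.shape[-3:]
    gm = Y.mean(axis=(-3, -2, -1), keepdims=True)
    src = Y.mean(axis=(-3, -2), keepdims=True)
    part = Y.mean(axis=(-2, -1), keepdims=True)
    night = Y.mean(axis=-1, keepdims=True)
    ss_p = (n * k) * ((part - gm) ** 2).sum(axis=(-3, -2, -1))
    ss_n = k * ((night - part) ** 2).sum(axis=(-3, -2, -1))
    resid = Y - night - src + gm
    ss_e = (resid**2).sum(axis=(-3, -2, -1))
    ms_p = ss_p / (p - 1)
    ms_n = ss_n / (p * (n - 1))
    ms_e = ss_e / ((p * n - 1) * (k - 1))
    raw_n = (ms_n - ms_e) / k
    raw_p = (ms_p - ms_n) / (n * k)
    boundary = (raw_n < 0) | (raw_p < 0)
    var_fixed = ((src - gm) ** 2).mean(axis=(-3, -2, -1))
    return (
        np.maximum(raw_p, 0.0),
        np.maximum(raw_n, 0.0),
        ms_e,
        var_fixed,
        boundary,
    )


def _fit_balanced(df: pd.DataFrame, Y: np.ndarray) -> VarianceComponents:
    var_p, var_n, var_e, var_fixed, boundary = _anova_components_cube(Y)
    sources = sorted(df["source"].unique())
    src_means = Y.mean(axis=(0, 1))
    effects = {s: float(m - src_means.mean()) for s, m in zip(sources, src_means)}
    return VarianceComponents(
        var_participant=float(var_p),
        var_night=float(var_n),
        var_residual=float(var_e),
        fixed_source_effects=effects,
        var_fixed=float(var_fixed),
        converged=True,
        boundary=bool(boundary),
        method="anova",
    )


# ---------------------------------------------------------------------------
# profiled REML for "complete nights" designs (all sources present in every
# analyzable night; nights per participant may differ)
#
# Transforming each night cell into its mean and orthonormal within-night
# contrasts splits the restricted likelihood exactly: contrasts carry the
# source effects and the residual variance, night means follow a one-way
# unbalanced model with components (s2_p, w = s2_n + s2_e / k).  The one-way
# REML is a one-dimensional profile optimization, which makes the
# participant-level bootstrap cheap.


def _oneway_reml(sums: np.ndarray, sumsqs: np.ndarray, ns: np.ndarray):
    """REML for ``m_ij = mu + a_i + eta_ij`` from per-group sufficient stats.

    Returns ``(mu, var_between, var_within)``.
    """
    from scipy.optimize import minimize_scalar

    ns = np.asarray(ns, dtype=float)
    N = ns.sum()
    means = sums / ns
    ssw = np.maximum(sumsqs - sums**2 / ns, 0.0)
    SSW = float(ssw.sum())

    def profile(log_theta: float):
        th = math.exp(log_theta)
        wt = ns / (1.0 + ns * th)  # 1' V^-1 1 up to 1/w
        mu = float((wt * means).sum() / wt.sum())
        Q = SSW + float((wt * (means - mu) ** 2).sum())
        return mu, Q, wt

    def neg2reml(log_theta: float) -> float:
        _, Q, wt = profile(log_theta)
        th = math.exp(log_theta)
        if Q <= 0:
            return np.inf
        return (N - 1.0) * math.log(Q) + float(np.log1p(ns * th).sum()) + math.log(wt.sum())

    res = minimize_scalar(neg2reml, bounds=(-18.0, 18.0), method="bounded",
                          options={"xatol": 1e-8})
    log_theta = float(res.x)
    if neg2reml(-18.0) <= res.fun:  # boundary: no between-group variance
        log_theta = -np.inf
    th = math.exp(log_theta) if np.isfinite(log_theta) else 0.0
    mu, Q, _ = profile(log_theta if np.isfinite(log_theta) else -18.0)
    w = Q / (N - 1.0)
    return mu, th * w, w


@dataclass
class _CompleteNightsStats:
    """Per-participant sufficient statistics for the profiled REML fit."""

    sources: list
    night_means: list  # list of 1-d arrays, one per participant
    src_sums: np.ndarray  # (p, k) sums of (y - night mean) per source
    sse: np.ndarray  # (p,) sum of squared within-night deviations
    n_nights: np.ndarray  # (p,) int

    @property
    def k(self) -> int:
        return len(self.sources)

    def fit(self, idx: Optional[np.ndarray] = None) -> VarianceComponents:
        if idx is None:
            idx = np.arange(len(self.n_nights))
        k = self.k
        ns = self.n_nights[idx].astype(float)
        total_nights = ns.sum()
        counts = ns  # each source observed once per night
        S = self.src_sums[idx].sum(axis=0)  # (k,)
        centers = S / total_nights
        ss_resid = float(self.sse[idx].sum() - total_nights * (centers**2).sum())
        df_e = (total_nights - 1.0) * (k - 1.0)
        var_e = max(ss_resid, 0.0) / df_e
        sums = np.array([self.night_means[i].sum() for i in idx])
        sumsqs = np.array([(self.night_means[i] ** 2).sum() for i in idx])
        _, var_p, w = _oneway_reml(sums, sumsqs, ns)
        raw_n = w - var_e / k
        effects = {s: float(c - centers.mean()) for s, c in zip(self.sources, centers)}
        var_fixed = float((centers**2).mean() - centers.mean() ** 2)
        return VarianceComponents(
            var_participant=float(var_p),
            var_night=float(max(raw_n, 0.0)),
            var_residual=float(var_e),
            fixed_source_effects=effects,
            var_fixed=var_fixed,
            converged=True,
            boundary=bool(raw_n < 0 or var_p <= 0),
            method="profile",
        )


def _complete_nights_stats(df: pd.DataFrame) -> Optional[_CompleteNightsStats]:
    sources = sorted(df["source"].unique())
    k = len(sources)
    if k < 2:
        return None
    cell = df.groupby(["participant", "night"])["source"]
    if (cell.count() != k).any() or (cell.nunique() != k).any():
        return None
    wide = df.pivot(index=["participant", "night"], columns="source", values="y")[sources]
    nm = wide.mean(axis=1)
    dev = wide.sub(nm, axis=0)
    pidx = wide.index.get_level_values("participant")
    participants = pidx.unique()
    night_means, src_sums, sse, n_nights = [], [], [], []
    for p in participants:
        mask = pidx == p
        night_means.append(nm.to_numpy()[mask])
        src_sums.append(dev.to_numpy()[mask].sum(axis=0))
        sse.append(float((dev.to_numpy()[mask] ** 2).sum()))
        n_nights.append(int(mask.sum()))
    if min(n_nights) < 1 or len(participants) < 2 or sum(n_nights) < 3:
        return None
    return _CompleteNightsStats(
        sources=sources,
        night_means=night_means,
        src_sums=np.asarray(src_sums),
        sse=np.asarray(sse),
        n_nights=np.asarray(n_nights),
    )


# ---------------------------------------------------------------------------
# degenerate (zero-residual) and numerical REML paths


def _degenerate_components(df: pd.DataFrame) -> Optional[VarianceComponents]:
    """Handle data with (numerically) no residual variation.

    When outcomes are identical across sources within every night (after
    removing source offsets), REML is undefined at the boundary; the
    components are then read off the night and participant means directly.
    """
    src_means = df.groupby("source")["y"].mean()
    grand = df["y"].mean()
    offsets = df["source"].map(src_means - grand)
    # residual after removing the night mean and the source offset
    adj = df["y"] - offsets
    night_adj = adj.groupby([df["participant"], df["night"]]).transform("mean")
    resid = adj - night_adj
    scale = max(1.0, float(np.abs(df["y"]).max()))
    if float(np.abs(resid).max()) > _DEGENERATE_TOL * scale:
        return None
    nm = adj.groupby([df["participant"], df["night"]]).mean()
    part_means = nm.groupby(level=0).mean()
    var_p = float(np.var(part_means, ddof=1)) if len(part_means) > 1 else 0.0
    within = nm.groupby(level=0).var(ddof=1).dropna()
    var_n = float(within.mean()) if len(within) else 0.0
    effects = {s: float(m - grand) for s, m in src_means.items()}
    return VarianceComponents(
        var_participant=var_p,
        var_night=var_n,
        var_residual=0.0,
        fixed_source_effects=effects,
        var_fixed=float(np.var(df["source"].map(src_means), ddof=0)),
        converged=True,
        boundary=True,
        method="degenerate",
    )


def _fit_mixedlm(df: pd.DataFrame) -> VarianceComponents:
    import statsmodels.formula.api as smf

    data = df.copy()
    data["participant"] = data["participant"].astype(str)
    data["night"] = data["night"].astype(str)
    data["source"] = data["source"].astype(str)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "y ~ C(source)",
                data,
                groups="participant",
                re_formula="1",
                vc_formula={"night": "0 + C(night)"},
            )
            res = model.fit(reml=True)
        converged = bool(res.converged)
        var_p = float(np.asarray(res.cov_re)[0, 0])
        var_n = float(np.asarray(res.vcomp)[0])
        var_e = float(res.scale)
        fe = res.fe_params
        sources = sorted(data["source"].unique())
        values = {}
        for s in sources:
            key = f"C(source)[T.{s}]"
            values[s] = float(fe.get(key, 0.0))
        mean_val = np.mean(list(values.values()))
        effects = {s: v - mean_val for s, v in values.items()}
        row_fixed = data["source"].map(values)
        var_fixed = float(np.var(row_fixed, ddof=0))
        boundary = var_p < 1e-10 or var_n < 1e-10
        return VarianceComponents(
            var_participant=var_p,
            var_night=var_n,
            var_residual=var_e,
            fixed_source_effects=effects,
            var_fixed=var_fixed,
            converged=converged,
            boundary=boundary,
            method="reml",
            message=None if converged else "REML optimizer did not converge",
        )
    except (np.linalg.LinAlgError, ValueError) as exc:
        return VarianceComponents(
            var_participant=float("nan"),
            var_night=float("nan"),
            var_residual=float("nan"),
            fixed_source_effects={},
            var_fixed=float("nan"),
            converged=False,
            boundary=False,
            method="reml",
            message=f"REML fit failed: {exc}",
        )


def fit_variance_components(long_table: pd.DataFrame, method: str = "auto") -> VarianceComponents:
    """Estimate the variance components of the source-agreement mixed model.

    ``long_table`` has columns ``participant``, ``night``, ``source`` and
    ``y`` (log-scale outcome; apply the log/offset policy upstream).

    ``method`` is ``"auto"`` (balanced closed form when the design allows,
    numerical REML otherwise), ``"anova"`` (balanced closed form, error if
    unbalanced) or ``"reml"`` (always numerical).
    """
    df = _canonical(long_table)
    per_night = df.groupby(["participant", "night"])["source"].nunique()
    if (per_night < 2).all():
        raise ValueError("need at least 2 sources per participant-night to fit agreement")
    deg = _degenerate_components(df)
    if deg is not None:
        return deg
    if method not in ("auto", "anova", "profile", "reml"):
        raise ValueError(f"unknown method {method!r}")
    if method in ("auto", "anova"):
        Y = _balanced_cube(df)
        if Y is not None:
            return _fit_balanced(df, Y)
        if method == "anova":
            raise ValueError("design is not balanced; use method='auto' or 'reml'")
    if method in ("auto", "profile"):
        stats = _complete_nights_stats(df)
        if stats is not None:
            return stats.fit()
        if method == "profile":
            raise ValueError("design does not have complete nights; use 'auto' or 'reml'")
    return _fit_mixedlm(df)


def icc_from_components(
    vc: VarianceComponents, definition: str = "adjusted"
) -> Optional[float]:
    """ICC from variance components; ``None`` when undefined (all-zero)."""
    if definition not in ("adjusted", "unadjusted"):
        raise ValueError(f"unknown ICC definition {definition!r}")
    num = vc.var_participant + vc.var_night
    den = num + vc.var_residual
    if definition == "unadjusted":
        den += vc.var_fixed
    if not np.isfinite(den) or den <= 0:
        return None
    return float(num / den)


# ---------------------------------------------------------------------------
# bootstrap


def _resample_participants(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    pids = df["participant"].unique()
    take = rng.choice(pids, size=len(pids), replace=True)
    parts = []
    for new_id, pid in enumerate(take):
        block = df[df["participant"] == pid].copy()
        block["participant"] = f"b{new_id}"
        parts.append(block)
    return pd.concat(parts, ignore_index=True)


def bootstrap_icc(
    long_table: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOTSTRAP,
    seed: Optional[int] = None,
    definition: str = "adjusted",
    method: str = "auto",
    ci_method: str = "cluster-t",
) -> ICCResult:
    """Point ICC with a 95% CI from a participant-level (cluster) bootstrap.

    Resamples whole participants with replacement; non-convergent or
    undefined replicates are dropped and counted, and the result is flagged
    when more than 20% of replicates were lost.

    ``ci_method`` selects the interval construction: ``"cluster-t"``
    (default; point estimate +- t quantile on participants-1 df times the
    bootstrap SE — with a few dozen clusters this calibrates closest to the
    nominal 95%), ``"percentile"`` (raw bootstrap quantiles) or ``"basic"``
    (reversed percentile).  Bounds are clipped to [0, 1].
    """
    df = _canonical(long_table)
    point_vc = fit_variance_components(df, method=method)
    point = icc_from_components(point_vc, definition)
    rng = np.random.default_rng(seed)
    Y = _balanced_cube(df) if method in ("auto", "anova") else None
    values: np.ndarray
    stats = (
        _complete_nights_stats(df) if Y is None and point_vc.method != "degenerate" else None
    )
    if point_vc.method == "degenerate":
        # no residual variation: every resample returns the same ICC
        values = np.full(n_boot, point if point is not None else np.nan)
    elif Y is not None:
        p = Y.shape[0]
        idx = rng.integers(0, p, size=(n_boot, p))
        var_p, var_n, var_e, var_fixed, _ = _anova_components_cube(Y[idx])
        num = var_p + var_n
        den = num + var_e + (var_fixed if definition == "unadjusted" else 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(den > 0, num / den, np.nan)
    elif stats is not None:
        p = len(stats.n_nights)
        vals = []
        for _ in range(n_boot):
            idx = rng.integers(0, p, size=p)
            icc = icc_from_components(stats.fit(idx), definition)
            vals.append(np.nan if icc is None else icc)
        values = np.asarray(vals, dtype=float)
    else:
        vals = []
        for _ in range(n_boot):
            sample = _resample_participants(df, rng)
            vc = fit_variance_components(sample, method=method)
            if not vc.converged:
                vals.append(np.nan)
                continue
            icc = icc_from_components(vc, definition)
            vals.append(np.nan if icc is None else icc)
        values = np.asarray(vals, dtype=float)
    good = values[np.isfinite(values)]
    n_dropped = n_boot - good.size
    flagged = (not point_vc.converged) or (n_dropped > 0.2 * n_boot)
    ci_low = ci_high = None
    if good.size and point is not None:
        qlo, qhi = (float(q) for q in np.percentile(good, [2.5, 97.5]))
        if ci_method == "percentile":
            ci_low, ci_high = qlo, qhi
        elif ci_method == "basic":
            ci_low, ci_high = 2.0 * point - qhi, 2.0 * point - qlo
        elif ci_method == "cluster-t":
            from scipy.stats import t as _tdist

            n_clusters = df["participant"].nunique()
            half = float(_tdist.ppf(0.975, max(n_clusters - 1, 1)) * good.std(ddof=1))
            ci_low, ci_high = point - half, point + half
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        ci_low = float(np.clip(min(ci_low, point), 0.0, 1.0))
        ci_high = float(np.clip(max(ci_high, point), 0.0, 1.0))
    return ICCResult(
        estimate=point,
        ci_low=ci_low,
        ci_high=ci_high,
        definition=definition,
        n_bootstrap=n_boot,
        n_used=int(good.size),
        n_dropped=int(n_dropped),
        flagged=flagged,
        components=point_vc,
    )


# ---------------------------------------------------------------------------
# repeated-measures Bland-Altman


def _ba_balanced(D: np.ndarray):
    """Bias and variance components from a (..., p, m) difference matrix."""
    p, m = D.shape[-2:]
    gm = D.mean(axis=(-2, -1))
    row = D.mean(axis=-1, keepdims=True)
    ss_b = m * ((row[..., 0] - gm[..., None]) ** 2).sum(axis=-1)
    ss_w = ((D - row) ** 2).sum(axis=(-2, -1))
    ms_b = ss_b / (p - 1)
    if m > 1:
        ms_w = ss_w / (p * (m - 1))
        var_w = ms_w
        var_b = np.maximum((ms_b - ms_w) / m, 0.0)
    else:
        var_w = np.zeros_like(gm)
        var_b = ms_b
    return gm, var_b, var_w


def _ba_oneway(sums: np.ndarray, sumsqs: np.ndarray, ns: np.ndarray):
    """Bias and variance components of the intercept-only participant model."""
    if len(ns) < 2:
        raise ValueError("need at least 2 participants")
    mu, var_b, w = _oneway_reml(sums, sumsqs, ns)
    return float(mu), float(var_b), float(w)


def bland_altman_repeated(
    pairs: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOTSTRAP,
    seed: Optional[int] = None,
) -> BlandAltmanResult:
    """Repeated-measures Bland-Altman of paired nightly TSO durations.

    ``pairs`` has a ``participant`` column plus either a precomputed ``diff``
    column or ``dht_tso_hours`` and ``ref_tso_hours`` (differences are then
    DHT minus Reference).  Nights missing either measurement must be dropped
    upstream.  Limits of agreement are ``bias +- 1.96 * sqrt(total var)``
    where total var sums the between- and within-participant components.
    """
    df = pairs.copy()
    if "participant" not in df.columns:
        if "participant_id" in df.columns:
            df = df.rename(columns={"participant_id": "participant"})
        else:
            raise ValueError("pairs table needs a 'participant' column")
    if "diff" in df.columns:
        df["d"] = df["diff"].astype(float)
    elif {"dht_tso_hours", "ref_tso_hours"} <= set(df.columns):
        df["d"] = df["dht_tso_hours"].astype(float) - df["ref_tso_hours"].astype(float)
    else:
        raise ValueError("pairs table needs 'diff' or dht/ref TSO hour columns")
    pids = df["participant"].unique()
    if len(pids) < 2:
        raise ValueError("Bland-Altman requires at least 2 participants")
    n_pairs = len(df)
    d = df["d"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    if float(np.ptp(d)) < 1e-12:
        bias = float(d[0])
        ci = (bias, bias)
        return BlandAltmanResult(
            bias, bias, bias, ci, ci, ci, n_pairs, len(pids), 0.0, 0.0, "degenerate"
        )

    counts = df.groupby("participant")["d"].count()
    balanced = bool((counts == counts.iloc[0]).all())
    if balanced:
        m = int(counts.iloc[0])
        D = (
            df.sort_values(["participant"], kind="stable")
            .groupby("participant")["d"]
            .apply(lambda s: s.to_numpy())
        )
        D = np.stack(D.to_numpy())  # (p, m)
        bias, var_b, var_w = (float(x) for x in _ba_balanced(D))
        method = "anova"
        idx = rng.integers(0, D.shape[0], size=(n_boot, D.shape[0]))
        bb, vb, vw = _ba_balanced(D[idx])
        half = _Z95 * np.sqrt(vb + vw)
        boot_bias, boot_low, boot_high = bb, bb - half, bb + half
    else:
        grp = df.groupby("participant")["d"]
        sums = grp.sum().to_numpy()
        sumsqs = grp.apply(lambda s: float((s**2).sum())).to_numpy()
        ns = grp.count().to_numpy()
        bias, var_b, var_w = _ba_oneway(sums, sumsqs, ns)
        method = "profile"
        p = len(ns)
        boot_bias = np.empty(n_boot)
        boot_low = np.empty(n_boot)
        boot_high = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, p, size=p)
            sb, vbb, vww = _ba_oneway(sums[idx], sumsqs[idx], ns[idx])
            half = _Z95 * math.sqrt(vbb + vww)
            boot_bias[b] = sb
            boot_low[b] = sb - half
            boot_high[b] = sb + half
    half = _Z95 * float(np.sqrt(var_b + var_w))

    def pct(x: np.ndarray) -> tuple[float, float]:
        lo, hi = np.percentile(x[np.isfinite(x)], [2.5, 97.5])
        return (float(lo), float(hi))

    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - half,
        loa_high=bias + half,
        bias_ci=pct(boot_bias),
        loa_low_ci=pct(boot_low),
        loa_high_ci=pct(boot_high),
        n_pairs=n_pairs,
        n_participants=len(pids),
        var_between=var_b,
        var_within=var_w,
        method=method,
    )
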