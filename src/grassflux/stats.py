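"""Model-evaluation statistics for paired observed/simulated series.

Implements the Smith-style criterion suite used to validate process models
against field measurements — correlation (r), RMSE as a percentage of the
observed mean, modelling efficiency (EF), the scatter-ratio coefficient of
determination (CD, reported as "R2" in the field's tables even though it can
exceed 1), relative error (RE), mean deviation (MD) and maximum error (ME) —
together with their 95%-confidence variants when replicate standard errors
are available, plus one-way ANOVA with least-significant-difference (LSD)
thresholds for treatment comparison.

Sign conventions: MD = mean(O - P) and RE = 100·(Ō - P̄)/Ō, so negative
values indicate over-estimation by the model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSeries",
    "StatsReport",
    "AnovaResult",
    "stats_suite",
    "r_significance",
    "one_way_anova",
    "relative_error",
]


@dataclass(frozen=True)
class PairedSeries:
    """Paired observed/simulated records in identical units.

    ``se`` and ``replicates`` are optional per-observation standard errors
    and replicate counts of the observed means; when present they enable the
    95%-confidence variants RMSE95 and RE95.
    """

    observed: np.ndarray
    simulated: np.ndarray
    se: np.ndarray | None = None
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float)
        sim = np.asarray(self.simulated, dtype=float)
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "simulated", sim)
        if obs.shape != sim.shape or obs.ndim != 1:
            raise ValueError("observed and simulated must be 1-d arrays of equal length")
        if obs.size < 2:
            raise ValueError("need at least two paired records")
        if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(sim))):
            raise ValueError("paired series must be finite")
        if self.se is not None:
            se = np.asarray(self.se, dtype=float)
            if se.shape != obs.shape or np.any(se < 0):
                raise ValueError("se must match observed length and be non-negative")
            object.__setattr__(self, "se", se)
        if self.replicates is not None:
            reps = np.asarray(self.replicates, dtype=int)
            if reps.shape != obs.shape or np.any(reps < 2):
                raise ValueError("replicates must match observed length and be >= 2")
            object.__setattr__(self, "replicates", reps)

    @property
    def n(self) -> int:
        return self.observed.size


@dataclass(frozen=True)
class StatsReport:
    """Criterion suite for one observed/simulated comparison."""

    r: float
    rmse_pct: float
    ef: float
    cd: float
    re_pct: float
    md: float
    me: float
    n: int
    rmse95_pct: float | None = None
    re95_pct: float | None = None
    r_significant_5pct: bool | None = None
    md_bias_significant_5pct: bool | None = None

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "r": self.r,
            "RMSE_pct": self.rmse_pct,
            "RMSE95_pct": self.rmse95_pct,
            "EF": self.ef,
            "R2": self.cd,
            "RE_pct": self.re_pct,
            "RE95_pct": self.re95_pct,
            "MD": self.md,
            "ME": self.me,
            "r_significant_5pct": self.r_significant_5pct,
            "md_bias_significant_5pct": self.md_bias_significant_5pct,
        }

    def format_table(self) -> str:
        """Render in the layout validation tables conventionally use."""
        def fmt(v):
            if v is None:
                return "-"
            if isinstance(v, bool):
                return "*" if v else ""
            return f"{v:.3g}"

        rows = [
            ("r", fmt(self.r) + ("*" if self.r_significant_5pct else "")),
            ("RMSE (RMSE95)", f"{fmt(self.rmse_pct)} ({fmt(self.rmse95_pct)})"),
            ("EF", fmt(self.ef)),
            ("R2", fmt(self.cd)),
            ("RE (RE95)", f"{fmt(self.re_pct)} ({fmt(self.re95_pct)})"),
            ("MD", fmt(self.md)),
            ("ME", fmt(self.me)),
            ("n", str(self.n)),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


@dataclass(frozen=True)
class AnovaResult:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    df_total: int
    ms_between: float
    ms_within: float
    f: float
    p: float
    lsd: dict = field(default_factory=dict)  # {0.05: ..., 0.01: ..., 0.001: ...}


def stats_suite(data: PairedSeries) -> StatsReport:
    """Compute the full criterion suite for a paired series.

    EF is undefined (NaN) when the observations have zero variance; the
    percentage statistics are undefined when the observed mean is zero.
    """
    obs, sim, n = data.observed, data.simulated, data.n
    obar = obs.mean()
    pbar = sim.mean()
    resid = sim - obs
    sse = float(resid @ resid)
    sso = float(((obs - obar) ** 2).sum())

    if np.std(obs) == 0 or np.std(sim) == 0:
        r = math.nan
    else:
        r = float(np.corrcoef(obs, sim)[0, 1])

    ef = 1.0 - sse / sso if sso > 0 else math.nan
    ssp = float(((sim - obar) ** 2).sum())
    cd = sso / ssp if ssp > 0 else math.nan

    if obar != 0:
        rmse = 100.0 / obar * math.sqrt(sse / n)
        re = 100.0 * (obar - pbar) / obar
    else:
        rmse = math.nan
        re = math.nan

    md = float((obs - sim).mean())
    me = float(np.max(np.abs(obs - sim)))

    rmse95 = re95 = None
    if data.se is not None:
        reps = data.replicates if data.replicates is not None else np.full(n, 2)
        halfwidth = sps.t.ppf(0.975, reps - 1) * data.se
        if obar != 0:
            rmse95 = float(100.0 / obar * math.sqrt((halfwidth**2).sum() / n))
            re95 = float(100.0 / obar * halfwidth.mean())

    r_sig = r_significance(r, n) if math.isfinite(r) and n >= 3 else None
    diffs = obs - sim
    if np.std(diffs, ddof=1) > 0:
        md_sig = bool(sps.ttest_1samp(diffs, 0.0).pvalue < 0.05)
    else:
        md_sig = bool(abs(md) > 0)

    return StatsReport(
        r=r, rmse_pct=rmse, ef=ef, cd=cd, re_pct=re, md=md, me=me, n=n,
        rmse95_pct=rmse95, re95_pct=re95,
        r_significant_5pct=r_sig, md_bias_significant_5pct=md_sig,
    )


def r_significance(r: float, n: int, alpha: float = 0.05) -> bool:
    """Two-tailed t-test of a Pearson correlation against zero."""
    if n < 3:
        raise ValueError("r significance requires n >= 3")
    if abs(r) >= 1.0:
        return True
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return bool(p < alpha)


def relative_error(observed_mean: float, simulated_mean: float) -> float:
    """RE = 100·(Ō − P̄)/Ō; positive when the model under-estimates."""
    if observed_mean == 0:
        raise ValueError("relative error undefined for zero observed mean")
    return 100.0 * (observed_mean - simulated_mean) / observed_mean


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA with LSD thresholds at 5/1/0.1%.

    For unbalanced groups the LSD uses the harmonic mean group size and a
    warning is emitted.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(arrays)

    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    ss_total = float(((all_vals - grand) ** 2).sum())
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within > 0:
        f = ms_between / ms_within
        p = float(sps.f.sf(f, df_between, df_within))
    else:
        f = math.inf if ms_between > 0 else 0.0
        p = 0.0 if ms_between > 0 else 1.0

    sizes = {a.size for a in arrays}
    if len(sizes) == 1:
        n_eff = arrays[0].size
    else:
        warnings.warn("unbalanced groups: LSD uses the harmonic mean group size")
        n_eff = k / sum(1.0 / a.size for a in arrays)
    lsd = {
        alpha: float(sps.t.ppf(1 - alpha / 2, df_within) * math.sqrt(2 * ms_within / n_eff))
        for alpha in (0.05, 0.01, 0.001)
    }
    return AnovaResult(
        ss_between=ss_between, ss_within=ss_within, ss_total=ss_total,
        df_between=df_between, df_within=df_within, df_total=n_total - 1,
        ms_between=ms_between, ms_within=ms_within, f=f, p=p, lsd=lsd,
    )


def groups_with_moments(
    group_means: Sequence[float], ss_within_per_group: Sequence[float], n_per_group: int
) -> list[np.ndarray]:
    """Construct raw groups carrying exact means and within-group sums of squares.

    Useful for recomputing a published ANOVA from its printed decomposition:
    each group is mean + c·x for a fixed zero-mean unit-sum-of-squares
    pattern x, so the ANOVA of the constructed data reproduces the printed
    mean squares and F exactly.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    x = np.zeros(n_per_group)
    x[0], x[1] = 1.0, -1.0
    x /= math.sqrt(float(x @ x))
    out = []
    for m, ssw in zip(group_means, ss_within_per_group, strict=True):
        if ssw < 0:
            raise ValueError("within-group sum of squares must be >= 0")
        out.append(m + math.sqrt(ssw) * x)
    return out
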