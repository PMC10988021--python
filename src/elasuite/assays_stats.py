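"""Plate-based assay readouts and the study's statistical conventions.

Minimal-inhibitory-concentration (MIC) calling on two-fold dilution series
with the ">max" and replicate-range ("16-32" style) reporting conventions,
voltage-sensitive dye (DiSC) trace summaries, inhibition-zone arithmetic,
competition abundance, and the unpaired two-tailed Student's t-test with
95% confidence interval and significance-star binning used throughout the
figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

EN_DASH = "–"  # range separator in MIC tables


@dataclass
class AssayMatrix:
    """A rectangular time-or-concentration by well matrix of RFU/OD values."""

    values: pd.DataFrame  # index: time (min) or concentration; columns: wells
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("assay matrix contains non-finite values")

    @classmethod
    def from_csv(cls, path, **metadata) -> "AssayMatrix":
        return cls(pd.read_csv(path, index_col=0), metadata)

    def to_csv(self, path) -> None:
        self.values.to_csv(path)


# ---------------------------------------------------------------------------
# MIC calling

def _fmt(x: float) -> str:
    return f"{x:g}"


@dataclass
class MICResult:
    value: str                  # "1", ">128" or "16-32"-style range
    per_replicate: list[float]  # np.inf encodes growth at all concentrations
    nonmonotone: bool = False


def mic_call(concentrations, growth, od_threshold: float = 0.05) -> MICResult:
    """MIC = lowest concentration of a two-fold series with no growth.

    ``growth`` is (n_concentrations x n_replicates), boolean or OD600
    (OD > ``od_threshold`` counts as growth).  Growth at every
    concentration reports ">max"; replicates disagreeing by one dilution
    step report the range "a-b"; a growth-positive well above a
    growth-negative one is flagged non-monotone and the MIC is placed at
    the highest transition (lowest concentration above the last growth).
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    g = np.atleast_2d(np.asarray(growth))
    if g.shape[0] != len(conc) and g.shape[1] == len(conc):
        g = g.T
    if g.dtype != bool:
        g = g.astype(float) > od_threshold

    per_rep: list[float] = []
    nonmono = False
    for rep in range(g.shape[1]):
        col = g[:, rep]
        grown = np.nonzero(col)[0]
        if len(grown) == len(conc):
            per_rep.append(np.inf)
            continue
        if len(grown) == 0:
            per_rep.append(float(conc[0]))
            continue
        first_clear = int(np.nonzero(~col)[0][0])
        last_growth = int(grown[-1])
        if last_growth > first_clear:
            nonmono = True
            idx = last_growth + 1
            per_rep.append(float(conc[idx]) if idx < len(conc) else np.inf)
        else:
            per_rep.append(float(conc[first_clear]))

    finite = sorted({m for m in per_rep})
    if all(np.isinf(m) for m in per_rep):
        value = f">{_fmt(conc[-1])}"
    elif any(np.isinf(m) for m in per_rep):
        lo = min(m for m in per_rep if np.isfinite(m))
        value = f"{_fmt(lo)}{EN_DASH}>{_fmt(conc[-1])}"
    elif len(finite) == 1:
        value = _fmt(finite[0])
    else:
        value = f"{_fmt(min(finite))}{EN_DASH}{_fmt(max(finite))}"
    return MICResult(value=value, per_replicate=per_rep, nonmonotone=nonmono)


def mic_fold_change(mic_variant: float, mic_parent: float) -> float:
    """Fold change in susceptibility (variant MIC over parent MIC)."""
    if mic_parent <= 0:
        raise ValueError("parent MIC must be positive")
    return mic_variant / mic_parent


# ---------------------------------------------------------------------------
# DiSC trace summary

@dataclass
class DiscSummary:
    baseline: float
    addition_time: float
    release: float
    time_to_plateau: float | None  # minutes after addition; None if no plateau
    baseline_stable: bool


def disc_summary(times, values, addition_time: float,
                 tolerance_frac: float = 0.02,
                 baseline_window: float = 5.0,
                 plateau_window: float = 2.0) -> DiscSummary:
    """Summarize a dye-release trace around the compound addition.

    Baseline is the mean of the last ``baseline_window`` minutes before
    addition (flagged unstable when its range exceeds the tolerance);
    the plateau is the first post-addition time whose forward
    ``plateau_window``-minute value range stays within the tolerance
    (2% of the trace's dynamic range by default); release is the plateau
    level minus the baseline.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and values must be matching 1-D arrays")
    dynamic = float(v.max() - v.min())
    tol = tolerance_frac * dynamic if dynamic > 0 else tolerance_frac

    pre = (t < addition_time) & (t >= addition_time - baseline_window)
    if not pre.any():
        raise ValueError("no pre-addition samples in the baseline window")
    baseline = float(v[pre].mean())
    stable = float(v[pre].max() - v[pre].min()) < tol

    plateau_t: float | None = None
    level = float(v[-1])
    for i in np.nonzero(t >= addition_time)[0]:
        win = (t >= t[i]) & (t <= t[i] + plateau_window)
        if t[win].max() - t[i] < plateau_window - 1e-9:
            break  # window runs past the trace end
        if float(v[win].max() - v[win].min()) < tol:
            plateau_t = float(t[i] - addition_time)
            level = float(v[win].mean())
            break
    release = level - baseline if plateau_t is not None else float("nan")
    return DiscSummary(baseline=baseline, addition_time=addition_time,
                       release=release, time_to_plateau=plateau_t,
                       baseline_stable=stable)


# ---------------------------------------------------------------------------
# inhibition zones and competition

def zone_area(total_area: float, spot_area: float) -> float:
    """Net inhibition zone: total inhibition area minus the producer spot."""
    if spot_area > total_area:
        raise ValueError("producer spot area exceeds total inhibition area")
    return total_area - spot_area


def competition_abundance(counts_a: int, counts_b: int) -> float:
    """Percent of species A among all counted cells."""
    if counts_a < 0 or counts_b < 0 or counts_a + counts_b == 0:
        raise ValueError("counts must be non-negative and not both zero")
    return 100.0 * counts_a / (counts_a + counts_b)


def classify_morphology(records, aspect_threshold: float = 1.5) -> tuple[int, int]:
    """Split segmented cells into (rods, cocci) by aspect ratio."""
    rods = sum(1 for r in records if r.aspect_ratio > aspect_threshold)
    return rods, len(records) - rods


# ---------------------------------------------------------------------------
# t-test and star binning

@dataclass
class StatResult:
    t: float
    p: float
    df: float
    ci_low: float
    ci_high: float
    stars: str


def star_class(p: float) -> str:
    """Map a p-value to the figure-legend star bins.

    Bin boundaries go to the more significant bin, except p = .05 which is
    reported "ns" (documented convention): ns p >= .05; * (.01, .05);
    ** (.001, .01]; *** (.0001, .001]; **** p <= .0001.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value outside [0, 1]")
    if p >= 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    if p > 0.0001:
        return "***"
    return "****"


def ttest(group_a, group_b, welch: bool = False) -> StatResult:
    """Unpaired two-tailed Student's t-test with a 95% CI of the mean
    difference.

    Pooled-variance Student's t by default (matching the study's stated
    convention); Welch's unequal-variance test behind the flag.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = ma - mb
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            return _degenerate(diff, float(na + nb - 2))
        se = np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        df = float(na + nb - 2)
        if sp2 == 0:
            return _degenerate(diff, df)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(0.975, df))
    return StatResult(t=float(t), p=p, df=float(df),
                      ci_low=float(diff - tcrit * se),
                      ci_high=float(diff + tcrit * se),
                      stars=star_class(p))


def _degenerate(diff: float, df: float) -> StatResult:
    if diff == 0:  # identical constant groups
        return StatResult(t=0.0, p=1.0, df=df, ci_low=0.0, ci_high=0.0, stars="ns")
    t = np.inf if diff > 0 else -np.inf
    return StatResult(t=float(t), p=0.0, df=df, ci_low=diff, ci_high=diff,
                      stars="****")
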