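"""Population-level quantification and event classification.

Summaries (counts, intensity means/SDs, Weibull fits of the intensity
distributions), lipid-exchange percentages from mask-transferred intensities,
relative change metrics vs a control condition (ΔN, Δ⟨I_int⟩, N×⟨I_int⟩),
pooled-variance two-sample t-tests, and the fusion/fission/lipid-exchange
rule table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "WeibullFit",
    "PopulationSummary",
    "ChangeMetrics",
    "EventThresholds",
    "summarize",
    "weibull_mode",
    "fit_weibull",
    "lipid_exchange_pct",
    "change_metrics",
    "compare_groups",
    "classify_event",
]

INTENSITY_VARS = ("i_int", "i_tot", "i_peak")


def weibull_mode(k: float, lam: float) -> float:
    """Mode of a two-parameter Weibull: λ((k−1)/k)^(1/k) for k > 1, else 0."""
    if k <= 0 or lam <= 0:
        raise ValueError("Weibull parameters must be positive")
    if k <= 1:
        return 0.0
    return lam * ((k - 1.0) / k) ** (1.0 / k)


@dataclass(frozen=True)
class WeibullFit:
    """Maximum-likelihood two-parameter Weibull fit (location fixed at 0)."""

    shape: float
    scale: float

    @property
    def mode(self) -> float:
        return weibull_mode(self.shape, self.scale)


def fit_weibull(values: Sequence[float]) -> WeibullFit:
    """MLE fit of a Weibull to positive values (non-positive values dropped)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if len(x) < 3:
        raise ValueError(f"need >= 3 positive values for a Weibull fit, got {len(x)}")
    shape, _loc, scale = stats.weibull_min.fit(x, floc=0.0)
    return WeibullFit(shape=float(shape), scale=float(scale))


@dataclass
class PopulationSummary:
    """Per-condition summary of one channel's detected spots.

    ``n_per_image`` (the N of the change metrics) is the mean spot count per
    image; means/SDs are over all pooled spots. ``weibull`` maps intensity
    variable name → fit, absent when too few positive values were available
    (``fit_flagged`` lists those).
    """

    n_spots: int
    n_images: int
    n_per_image: float
    mean: dict[str, float]
    sd: dict[str, float]
    weibull: dict[str, WeibullFit] = field(default_factory=dict)
    fit_flagged: list[str] = field(default_factory=list)
    channel: str = ""


def summarize(
    spots: Sequence,
    n_images: int = 1,
    channel: str = "",
    fit_vars: Sequence[str] = INTENSITY_VARS,
) -> PopulationSummary:
    """Summarize spots from one channel/condition pooled over ``n_images``."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    weibull: dict[str, WeibullFit] = {}
    flagged: list[str] = []
    for var in INTENSITY_VARS:
        vals = np.array([getattr(s, var) for s in spots], dtype=float)
        vals = vals[np.isfinite(vals)]
        mean[var] = float(vals.mean()) if len(vals) else math.nan
        sd[var] = float(vals.std(ddof=0)) if len(vals) else math.nan
        if var in fit_vars:
            try:
                weibull[var] = fit_weibull(vals)
            except ValueError:
                flagged.append(var)
    return PopulationSummary(
        n_spots=len(spots),
        n_images=n_images,
        n_per_image=len(spots) / n_images,
        mean=mean,
        sd=sd,
        weibull=weibull,
        fit_flagged=flagged,
        channel=channel,
    )


def lipid_exchange_pct(
    masked: Union[float, PopulationSummary], detected: Union[float, PopulationSummary]
) -> float:
    """Lipid exchange as 100 × ⟨I_tot⟩(transferred mask) / ⟨I_tot⟩(detected).

    Arguments are mean I_tot values, or summaries carrying them.
    """
    masked_mean = masked.mean["i_tot"] if isinstance(masked, PopulationSummary) else float(masked)
    detected_mean = (
        detected.mean["i_tot"] if isinstance(detected, PopulationSummary) else float(detected)
    )
    if not detected_mean > 0:
        raise ValueError(f"detected-vesicle mean I_tot must be > 0, got {detected_mean}")
    return 100.0 * masked_mean / detected_mean


@dataclass
class ChangeMetrics:
    """Relative population changes of a test condition vs its control."""

    delta_n: float
    delta_i: float
    total_signal_change: float
    colocalization_pct: float = math.nan
    delta_coloc_points: float = math.nan
    lipid_exchange_pct: Optional[dict[str, float]] = None
    p_values: dict[str, float] = field(default_factory=dict)


def change_metrics(
    test: PopulationSummary,
    control: PopulationSummary,
    coloc=None,
    control_coloc_pct: Optional[float] = None,
) -> ChangeMetrics:
    """ΔN, Δ⟨I_int⟩ and the change in total signal N×⟨I_int⟩, in percent.

    ``coloc`` may be a ColocalizationResult or a plain percentage; the
    colocalization change is measured against ``control_coloc_pct`` (0 when
    not given).
    """
    if control.n_per_image <= 0:
        raise ValueError("control has no spots; change metrics undefined")
    mean_test = test.mean["i_int"]
    mean_ctrl = control.mean["i_int"]
    if not (math.isfinite(mean_ctrl) and mean_ctrl != 0):
        raise ValueError(f"control mean I_int must be finite and nonzero, got {mean_ctrl}")
    delta_n = 100.0 * (test.n_per_image / control.n_per_image - 1.0)
    delta_i = 100.0 * (mean_test / mean_ctrl - 1.0)
    total = 100.0 * (
        (test.n_per_image * mean_test) / (control.n_per_image * mean_ctrl) - 1.0
    )
    coloc_pct = math.nan
    if coloc is not None:
        coloc_pct = coloc.fraction if hasattr(coloc, "fraction") else float(coloc)
    baseline = 0.0 if control_coloc_pct is None else float(control_coloc_pct)
    delta_coloc = coloc_pct - baseline if math.isfinite(coloc_pct) else math.nan
    return ChangeMetrics(
        delta_n=delta_n,
        delta_i=delta_i,
        total_signal_change=total,
        colocalization_pct=coloc_pct,
        delta_coloc_points=delta_coloc,
    )


def compare_groups(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided pooled-variance two-sample t-test p-value.

    Two constant groups with equal means give p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    result = stats.ttest_ind(a, b, equal_var=True)
    return float(result.pvalue)


@dataclass(frozen=True)
class EventThresholds:
    """Cut-offs below which a change counts as "unchanged"."""

    delta_n_pct: float = 15.0
    delta_i_pct: float = 15.0
    coloc_points: float = 5.0


def classify_event(metrics: ChangeMetrics, thresholds: EventThresholds = EventThresholds()) -> str:
    """Rule-table classification into fusion / fission / lipid_exchange / none.

    fusion: colocalization up, N down, per-channel intensity not decreased;
    lipid_exchange: colocalization up, N unchanged, intensity down;
    fission: colocalization unchanged, N up, intensity down.
    """
    dn, di = metrics.delta_n, metrics.delta_i
    dc = metrics.delta_coloc_points
    if math.isnan(dc):
        dc = 0.0
    t = thresholds
    coloc_up = dc > t.coloc_points
    coloc_flat = abs(dc) <= t.coloc_points
    if coloc_up and dn < -t.delta_n_pct and di >= -t.delta_i_pct:
        return "fusion"
    if coloc_up and abs(dn) <= t.delta_n_pct and di < -t.delta_i_pct:
        return "lipid_exchange"
    if coloc_flat and dn > t.delta_n_pct and di < -t.delta_i_pct:
        return "fission"
    return "none"
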