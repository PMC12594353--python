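"""Posterior comparison with HDI, probability of direction, and ROPE.

Condition and group effects are decided on group-level posterior differences:
an 89% highest density interval (the shortest interval holding 89% of the
mass) that excludes zero flags a difference, the probability of direction
(p_dir, posterior mass on the dominant sign) indexes the existence of an
effect, and the region of practical equivalence (ROPE, +-0.1 around zero)
indexes its practical size.  An effect is called meaningful when p_dir exceeds
95% and less than 2.5% of the posterior falls inside the ROPE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ComparisonResult",
    "hdi",
    "prob_direction",
    "rope_fraction",
    "compare",
    "comparison_report",
    "DEFAULT_ROPE",
]

DEFAULT_ROPE = (-0.1, 0.1)
P_DIR_THRESHOLD = 95.0
ROPE_THRESHOLD = 2.5


def hdi(samples, mass: float = 0.89) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("cannot compute an HDI of no samples")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    m = int(math.ceil(mass * x.size))
    if m >= x.size:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: x.size - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def prob_direction(samples) -> float:
    """100 x the posterior mass on the dominant sign; zeros count to neither."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot compute p_dir of no samples")
    pos = np.mean(x > 0)
    neg = np.mean(x < 0)
    return 100.0 * max(pos, neg)


def rope_fraction(
    samples,
    rope: tuple[float, float] = DEFAULT_ROPE,
    standardize: bool = False,
    within_hdi: bool = False,
    hdi_mass: float = 0.89,
) -> float:
    """Percent of the posterior inside the region of practical equivalence.

    With ``standardize`` the samples are divided by their posterior SD before
    the +-0.1 band is applied.  ``within_hdi`` restricts the computation to
    the samples inside the 89% HDI (the alternative reading of the decision
    rule); the default uses the whole posterior.
    """
    lo, hi = rope
    if not lo < hi:
        raise ValueError("rope must satisfy lo < hi")
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot compute a ROPE fraction of no samples")
    if standardize:
        sd = x.std()
        if sd > 0:
            x = x / sd
    if within_hdi:
        h_lo, h_hi = hdi(x, hdi_mass)
        x = x[(x >= h_lo) & (x <= h_hi)]
    return 100.0 * float(np.mean((x >= lo) & (x <= hi)))


@dataclass
class ComparisonResult:
    """Decision summary for one posterior difference."""

    param: str
    contrast: str
    hdi_low: float
    hdi_high: float
    p_dir: float
    rope_fraction: float
    significant_hdi: bool   # 89% HDI excludes zero
    meaningful: bool        # p_dir > 95 and rope_fraction < 2.5

    def to_dict(self) -> dict:
        return asdict(self)


def _group_draws(fit, param: str, scale: str) -> np.ndarray:
    try:
        return fit.group_posterior(param, scale=scale)
    except AttributeError:
        raise TypeError("expected a fitted HierarchicalModel (or array input to compare_samples)")


def compare_samples(
    diff: np.ndarray,
    param: str = "",
    contrast: str = "",
    rope: tuple[float, float] = DEFAULT_ROPE,
    standardize: bool = False,
    hdi_mass: float = 0.89,
) -> ComparisonResult:
    """Decision summary of an already-formed difference distribution."""
    lo, hi = hdi(diff, hdi_mass)
    p = prob_direction(diff)
    rf = rope_fraction(diff, rope=rope, standardize=standardize)
    return ComparisonResult(
        param=param,
        contrast=contrast,
        hdi_low=lo,
        hdi_high=hi,
        p_dir=p,
        rope_fraction=rf,
        significant_hdi=bool(lo > 0 or hi < 0),
        meaningful=bool(p > P_DIR_THRESHOLD and rf < ROPE_THRESHOLD),
    )


def compare(
    fit_a,
    fit_b=None,
    param: str | tuple[str, str] = "eta_neg",
    contrast: str = "",
    scale: str = "natural",
    rope: tuple[float, float] = DEFAULT_ROPE,
    standardize: bool = False,
    hdi_mass: float = 0.89,
    seed: int = 0,
) -> ComparisonResult:
    """Compare group-level posteriors: ``fit_a - fit_b`` on one parameter, or
    a within-fit contrast when ``param`` is a pair of names.

    Cross-fit posteriors are independent, so their draws are paired after a
    seeded shuffle of the second fit's draws (reproducible, order-free); draw
    counts are aligned to the smaller fit.  Learning rates and the indecision
    point are compared on their natural scales; so is the value-sensitivity
    parameter beta on (0, 10).
    """
    if isinstance(param, tuple):
        if fit_b is not None:
            raise ValueError("within-fit contrasts take a single fit")
        a = _group_draws(fit_a, param[0], scale)
        b = _group_draws(fit_a, param[1], scale)
        diff = a - b  # paired within the joint posterior
        label = contrast or f"{param[0]} - {param[1]}"
        name = f"{param[0]}-{param[1]}"
    else:
        if fit_b is None:
            raise ValueError("cross-fit comparison needs fit_b")
        a = _group_draws(fit_a, param, scale)
        b = _group_draws(fit_b, param, scale)
        n = min(a.size, b.size)
        rng = np.random.default_rng(seed)
        a = a[rng.permutation(a.size)[:n]]
        b = b[rng.permutation(b.size)[:n]]
        diff = a - b
        label = contrast or "a - b"
        name = param
    return compare_samples(
        diff, param=name, contrast=label, rope=rope, standardize=standardize,
        hdi_mass=hdi_mass,
    )


def comparison_report(
    fits: dict,
    contrasts: list[tuple[str, str]],
    params: list[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """One row per (parameter, contrast): the condition/group comparison table.

    ``fits`` maps labels (e.g. condition names) to fitted models; each
    contrast is a pair of labels compared as ``first - second``.
    """
    rows = []
    for label_a, label_b in contrasts:
        fa, fb = fits[label_a], fits[label_b]
        names = params or list(fa.spec_.param_names)
        for p in names:
            res = compare(fa, fb, param=p, contrast=f"{label_a} - {label_b}", **kwargs)
            rows.append(res.to_dict())
    return pd.DataFrame(rows)
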