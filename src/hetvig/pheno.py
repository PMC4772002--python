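"""Phenotype-level heterosis statistics.

Heterosis (hybrid vigor) for a quantitative trait is quantified against
the mid-parent value MPV = (P1 + P2)/2 via the rate of heterosis

    RH = 100 * (F1 - MPV) / MPV   [percent],

where F1, P1, P2 are the line means. Significance of the F1 mean against
the mid-parent is assessed with a normal-approximation contrast using the
lines' standard errors,

    z = (F1 - MPV) / sqrt(SE_F1^2 + (SE_P1^2 + SE_P2^2)/4),

marked ** at p < 0.01 and * at p < 0.05. Published tables often compute
RH from the MPV rounded to two decimals; ``round_mpv`` reproduces that,
full precision is retained otherwise.

Also included: delta-delta-Ct relative expression for qPCR-style
validation, fold change = 2^-ddCt.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "PhenotypeSummary",
    "HeterosisResult",
    "round_half_up",
    "mid_parent_value",
    "heterosis_rate",
    "mpv_significance_test",
    "heterosis_table_row",
    "ddct_relative_expression",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, the convention of printed summary tables.

    Built-in round() is banker's rounding on binary floats, so a value
    like (104.78 + 91.49)/2 = 98.135 — stored as 98.134999... — would
    round down. The float is first snapped to 10 decimals to recover the
    intended decimal value, then rounded half-up.
    """
    snapped = Decimal(repr(round(float(x), 10)))
    q = Decimal(1).scaleb(-ndigits)
    return float(snapped.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PhenotypeSummary:
    """Mean +/- SE summary of one line's trait (e.g. body weight in ug)."""

    line_id: str
    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error cannot be negative")
        if self.se > 0 and self.n < 2:
            raise ValueError("a reported SE requires n >= 2")


@dataclass(frozen=True)
class HeterosisResult:
    cross_id: str
    mpv: float
    rh: float
    statistic: float
    p_value: float
    mark: str  # "ns", "*", or "**"


def mid_parent_value(p1: PhenotypeSummary, p2: PhenotypeSummary) -> float:
    """Arithmetic mean of the two parental means."""
    return (p1.mean + p2.mean) / 2.0


def heterosis_rate(
    f1: PhenotypeSummary,
    p1: PhenotypeSummary,
    p2: PhenotypeSummary,
    round_mpv: bool = False,
) -> float:
    """Rate of heterosis in percent: 100 * (F1 - MPV)/MPV.

    ``round_mpv`` rounds the MPV to two decimals before the ratio, the
    convention used in published summary tables.
    """
    mpv = mid_parent_value(p1, p2)
    if round_mpv:
        mpv = round_half_up(mpv, 2)
    if mpv == 0:
        raise ValueError("mid-parent value is zero; heterosis rate undefined")
    return 100.0 * (f1.mean - mpv) / mpv


def mpv_significance_test(
    f1: PhenotypeSummary, p1: PhenotypeSummary, p2: PhenotypeSummary
) -> tuple[float, float, str]:
    """Normal contrast of the F1 mean against the mid-parent value.

    Returns (z statistic, two-sided p, significance mark).
    """
    se = np.sqrt(f1.se**2 + (p1.se**2 + p2.se**2) / 4.0)
    if se == 0:
        raise ValueError("all standard errors are zero; no test possible")
    z = (f1.mean - mid_parent_value(p1, p2)) / se
    p = 2.0 * stats.norm.sf(abs(z))
    mark = "**" if p < 0.01 else "*" if p < 0.05 else "ns"
    return float(z), float(p), mark


def heterosis_table_row(
    cross_id: str,
    f1: PhenotypeSummary,
    p1: PhenotypeSummary,
    p2: PhenotypeSummary,
    round_mpv: bool = True,
) -> HeterosisResult:
    """One summary-table row: MPV, RH (percent) and the mid-parent test."""
    mpv = mid_parent_value(p1, p2)
    rh = heterosis_rate(f1, p1, p2, round_mpv=round_mpv)
    z, p, mark = mpv_significance_test(f1, p1, p2)
    return HeterosisResult(
        cross_id=cross_id, mpv=mpv, rh=rh, statistic=z, p_value=p, mark=mark
    )


def ddct_relative_expression(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Fold change 2^-ddCt from four cycle-threshold values.

    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,ctrl - Ct_ref,ctrl).
    """
    for v in (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
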