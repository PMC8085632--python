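"""Population attributable fractions (PAF) and burden attribution.

The PAF expresses the proportional reduction in an adverse health outcome
that would be expected if population exposure to a risk factor were removed:

    PAF = P * (RR - 1) / (P * (RR - 1) + 1)

where ``P`` is the proportion of the population exposed and ``RR`` is the
exposure-response measure (a relative risk; odds ratios and incidence-rate
ratios are substituted directly, without a rare-disease correction).

Protective point estimates or confidence limits (RR < 1) give a negative
excess and are floored at zero, so attributable burdens are never negative.

Uncertainty ranges are formed by evaluating the formula at the paired lower
and upper 95% confidence limits of ``P`` and ``RR``.  This is an interval
propagation, not a simulation: it brackets but does not characterise the
sampling distribution of the PAF.
"""

from __future__ import annotations

from dataclasses import dataclass


def compute_paf(p: float, rr: float) -> float:
    """Attributable fraction for exposure prevalence ``p`` and risk ratio ``rr``.

    Parameters
    ----------
    p
        Proportion of the population exposed, in [0, 1].
    rr
        Exposure-response measure (> 0).  Values below 1 floor the result
        at 0 rather than producing a negative (protective) fraction.

    Returns
    -------
    float
        PAF in [0, 1].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"exposure proportion p={p!r} outside [0, 1]")
    if not rr > 0.0:
        raise ValueError(f"exposure-response measure rr={rr!r} must be > 0")
    excess = p * (rr - 1.0)
    return max(0.0, excess / (excess + 1.0))


def compute_paf_bounds(
    p_lo: float, p_hi: float, rr_lo: float, rr_hi: float
) -> tuple[float, float]:
    """Uncertainty range of the PAF from paired 95% CI limits.

    The lower bound evaluates the formula at (``p_lo``, ``rr_lo``) and the
    upper at (``p_hi``, ``rr_hi``); both are floored at zero.
    """
    if p_lo > p_hi:
        raise ValueError(f"p_lo={p_lo!r} exceeds p_hi={p_hi!r}")
    if rr_lo > rr_hi:
        raise ValueError(f"rr_lo={rr_lo!r} exceeds rr_hi={rr_hi!r}")
    return compute_paf(p_lo, rr_lo), compute_paf(p_hi, rr_hi)


@dataclass(frozen=True)
class PAFResult:
    """Point estimate and uncertainty range of a PAF, as fractions in [0, 1]."""

    paf: float
    paf_lo: float
    paf_hi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.paf_lo <= self.paf <= self.paf_hi <= 1.0:
            raise ValueError(
                "PAF bounds must satisfy 0 <= paf_lo <= paf <= paf_hi <= 1, got "
                f"({self.paf_lo}, {self.paf}, {self.paf_hi})"
            )

    @classmethod
    def from_inputs(
        cls,
        p: float,
        rr: float,
        p_lo: float | None = None,
        p_hi: float | None = None,
        rr_lo: float | None = None,
        rr_hi: float | None = None,
    ) -> "PAFResult":
        point = compute_paf(p, rr)
        lo, hi = compute_paf_bounds(
            p if p_lo is None else p_lo,
            p if p_hi is None else p_hi,
            rr if rr_lo is None else rr_lo,
            rr if rr_hi is None else rr_hi,
        )
        # Flooring at zero can leave the point below the nominal lower bound
        # only when rr < 1 < rr_lo is impossible, so clamp defensively.
        lo = min(lo, point)
        hi = max(hi, point)
        return cls(paf=point, paf_lo=lo, paf_hi=hi)

    @property
    def percent(self) -> tuple[float, float, float]:
        """(point, lo, hi) on the percentage scale."""
        return 100.0 * self.paf, 100.0 * self.paf_lo, 100.0 * self.paf_hi


def attribute(total: float, paf: float) -> float:
    """Attributable share of a nonnegative population-level total.

    Attribution always uses the *unrounded* PAF; rounding only happens at
    the reporting layer (using a pre-rounded percentage visibly distorts
    large totals).
    """
    if total < 0:
        raise ValueError(f"population total {total!r} must be nonnegative")
    if not 0.0 <= paf <= 1.0:
        raise ValueError(f"paf={paf!r} outside [0, 1]")
    return total * paf


def attribute_interval(total: float, result: PAFResult) -> tuple[float, float, float]:
    """(point, lo, hi) attributable amounts for one population total."""
    return (
        attribute(total, result.paf),
        attribute(total, result.paf_lo),
        attribute(total, result.paf_hi),
    )
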