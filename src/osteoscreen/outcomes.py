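"""Incremental cost-effectiveness results: ICERs, dominance, NMB, per-10k scaling."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .engine import ArmOutcome

__all__ = ["IncrementalResult", "incremental", "per_10k", "nmb", "classify_dominance"]


def classify_dominance(delta_cost: float, delta_qaly: float) -> str:
    """Dominance label over the sign grid of (ΔC, ΔQ).

    ``dominant``: screening gains QALYs at no extra cost (or saves money at
    no QALY loss). ``dominated``: costs more without gaining. ``icer``: a
    meaningful ratio exists (both deltas share a sign and are nonzero).
    ``indifferent``: both deltas exactly zero.
    """
    if delta_qaly > 0 and delta_cost > 0:
        return "icer"
    if delta_qaly < 0 and delta_cost < 0:
        return "icer"
    if delta_qaly > 0 or (delta_qaly == 0 and delta_cost < 0):
        return "dominant"
    if delta_cost > 0 or (delta_cost == 0 and delta_qaly < 0):
        return "dominated"
    return "indifferent"


@dataclass(frozen=True)
class IncrementalResult:
    """Screening-vs-no-screening differences, per person unless ``scale`` says otherwise.

    ``delta_cost``, ``delta_qaly``, ``delta_ly`` are screening minus
    comparator; ``fractures_averted`` is comparator minus screening, so a
    beneficial screening program shows all four positive.
    """

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    fractures_averted: float
    icer: Optional[float]
    label: str
    se_cost: float = 0.0
    se_qaly: float = 0.0
    n: int = 0
    scale: float = 1.0


def incremental(screening: ArmOutcome, comparator: ArmOutcome) -> IncrementalResult:
    """Paired incremental result between two arms of the same cohort.

    Requires both outcomes to come from the same roster/flags (matching
    cohort identity); Monte-Carlo SEs are computed from the per-individual
    paired differences, which common random numbers keep small.
    """
    if screening.cohort_id != comparator.cohort_id or screening.n != comparator.n:
        raise ValueError("arm outcomes are not from the same cohort (pairing broken)")
    n = screening.n
    d_cost = screening.cost - comparator.cost
    d_qaly = screening.qaly - comparator.qaly
    dc, dq = float(d_cost.mean()), float(d_qaly.mean())
    label = classify_dominance(dc, dq)
    icer = dc / dq if label == "icer" else None
    return IncrementalResult(
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly=float((screening.life_years - comparator.life_years).mean()),
        fractures_averted=float((comparator.fractures.sum(axis=0)
                                 - screening.fractures.sum(axis=0)).mean()),
        icer=icer,
        label=label,
        se_cost=float(d_cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(d_qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        n=n,
    )


def per_10k(result: IncrementalResult) -> IncrementalResult:
    """Scale the per-person differences to a cohort of 10 000; the ICER is unchanged."""
    if result.scale != 1.0:
        raise ValueError("result is already scaled")
    k = 10_000.0
    return replace(result, delta_cost=result.delta_cost * k,
                   delta_qaly=result.delta_qaly * k, delta_ly=result.delta_ly * k,
                   fractures_averted=result.fractures_averted * k,
                   se_cost=result.se_cost * k, se_qaly=result.se_qaly * k, scale=k)


def nmb(result: IncrementalResult, wtp: float) -> float:
    """Net monetary benefit ``wtp * ΔQALY - ΔC`` at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValueError("wtp must be non-negative")
    return wtp * result.delta_qaly - result.delta_cost
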