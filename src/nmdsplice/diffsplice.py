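"""Bayes-factor differential splicing between two conditions and the global
NMD-direction summary.

The test compares two binomial isoform-ratio observations (k1 of n1 vs k2 of
n2 identifying reads). Under H0 the two conditions share one ratio p with a
uniform prior; under H1 each condition has its own ratio, again uniform.
Both marginal likelihoods are Beta integrals, so

    BF10 = B(k1+1, n1-k1+1) * B(k2+1, n2-k2+1) / B(k1+k2+1, n1+n2-k1-k2+1)

(the binomial coefficients are shared and cancel). The same quantity is the
reciprocal Savage-Dickey density ratio of delta = p1 - p2 at zero, which
:func:`savage_dickey_bf10` evaluates numerically as an internal cross-check.

An event is called differentially spliced when it has more than 20
identifying reads in each condition, an isoform-ratio change of at least 10
percentage points, and BF10 of at least 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.special import betaln
from scipy.stats import beta as beta_dist

from .models import (
    ClassSummary,
    DiffSpliceCall,
    GlobalSummary,
    PsiEstimate,
    SplicingEvent,
)


@dataclass(frozen=True)
class Thresholds:
    """Filter cascade for calling an event differentially spliced.

    ``min_reads`` is exclusive (a condition needs strictly more identifying
    reads); ``min_delta`` and ``min_bf`` are inclusive.
    """

    min_reads: int = 20
    min_delta: float = 0.10
    min_bf: float = 5.0


def _check_counts(k, n) -> None:
    k, n = np.asarray(k), np.asarray(n)
    if np.any(k < 0) or np.any(n < 0) or np.any(k > n):
        raise ValueError("counts must satisfy 0 <= k <= n")


def log_bayes_factor(k1, n1, k2, n2):
    """Natural-log BF10 for unequal vs shared isoform ratios (vectorized)."""
    _check_counts(k1, n1)
    _check_counts(k2, n2)
    k1, n1, k2, n2 = (np.asarray(x, dtype=float) for x in (k1, n1, k2, n2))
    if np.any(n1 + n2 <= 0):
        raise ValueError("need identifying reads in at least one condition")
    lm1 = betaln(k1 + 1, n1 - k1 + 1) + betaln(k2 + 1, n2 - k2 + 1)
    lm0 = betaln(k1 + k2 + 1, n1 + n2 - (k1 + k2) + 1)
    return lm1 - lm0


def bayes_factor(k1: int, n1: int, k2: int, n2: int) -> float:
    """BF10 favoring condition-specific isoform ratios over a shared ratio."""
    return float(np.exp(log_bayes_factor(k1, n1, k2, n2)))


def savage_dickey_bf10(k1: int, n1: int, k2: int, n2: int) -> float:
    """BF10 via the Savage-Dickey density ratio, evaluated numerically.

    The posterior density of delta = p1 - p2 at 0 is the overlap integral of
    the two Beta posteriors; the prior density of delta at 0 is exactly 1
    (triangular prior from two independent uniforms). Serves as an
    independent check of :func:`bayes_factor`.
    """
    _check_counts(k1, n1)
    _check_counts(k2, n2)
    f1 = beta_dist(k1 + 1, n1 - k1 + 1)
    f2 = beta_dist(k2 + 1, n2 - k2 + 1)
    post_at_zero, _ = quad(lambda p: f1.pdf(p) * f2.pdf(p), 0.0, 1.0, limit=200)
    return 1.0 / post_at_zero


def call_event(
    psi_cond1: PsiEstimate,
    psi_cond2: PsiEstimate,
    thresholds: Thresholds = Thresholds(),
) -> DiffSpliceCall:
    """Apply the filter cascade to one event's two per-condition estimates.

    delta_psi is psi2 - psi1 for the designated isoform. Events without
    identifying reads in a condition fail the read filter and carry NaN
    markers; they are never silently dropped here.
    """
    if psi_cond1.event_id != psi_cond2.event_id:
        raise ValueError(
            f"mismatched events {psi_cond1.event_id!r} vs {psi_cond2.event_id!r}"
        )
    k1, n1, k2, n2 = psi_cond1.k, psi_cond1.n, psi_cond2.k, psi_cond2.n
    passes_reads = n1 > thresholds.min_reads and n2 > thresholds.min_reads
    if n1 > 0 and n2 > 0:
        delta = psi_cond2.psi_hat - psi_cond1.psi_hat
        # inclusive boundary, robust to binary rounding of k/n differences
        passes_delta = abs(delta) >= thresholds.min_delta - 1e-12
    else:
        delta, passes_delta = math.nan, False
    if n1 + n2 > 0:
        bf10 = bayes_factor(k1, n1, k2, n2)
        passes_bf = bf10 >= thresholds.min_bf
    else:
        bf10, passes_bf = math.nan, False
    return DiffSpliceCall(
        psi_cond1.event_id,
        k1, n1, k2, n2,
        psi_cond1.psi_hat, psi_cond2.psi_hat,
        delta, bf10, passes_reads, passes_delta, passes_bf,
    )


def nmd_direction(call: DiffSpliceCall, event: SplicingEvent) -> str:
    """Direction of change of the predicted NMD-substrate isoform.

    ``ineligible`` when the event does not have exactly one substrate
    isoform; otherwise ``nmd_up``/``nmd_down`` for events passing the full
    cascade with rising/falling substrate ratio, else ``unchanged``.
    """
    if call.event_id != event.event_id:
        raise ValueError("call/event mismatch")
    if not event.eligible:
        return "ineligible"
    if not call.called:
        return "unchanged"
    return "nmd_up" if call.delta_psi > 0 else "nmd_down"


def call_events(
    psi1: Sequence[PsiEstimate],
    psi2: Sequence[PsiEstimate],
    catalog: Sequence[SplicingEvent],
    thresholds: Thresholds = Thresholds(),
) -> list[DiffSpliceCall]:
    """Call every cataloged event and attach its NMD-direction label."""
    by_event1 = {p.event_id: p for p in psi1}
    by_event2 = {p.event_id: p for p in psi2}
    calls = []
    for ev in catalog:
        p1 = by_event1.get(ev.event_id)
        p2 = by_event2.get(ev.event_id)
        if p1 is None or p2 is None:
            continue
        call = call_event(p1, p2, thresholds)
        call.nmd_direction = nmd_direction(call, ev)
        calls.append(call)
    return calls


def summarize_global(
    calls: Iterable[DiffSpliceCall],
    catalog: Sequence[SplicingEvent],
    thresholds: Thresholds = Thresholds(),
) -> GlobalSummary:
    """Per-event-class fractions of NMD substrates rising vs falling.

    Denominators are the NMD-eligible events with sufficient identifying
    reads in both conditions (the read filter); numerators count events
    labelled nmd_up / nmd_down by the full cascade. The enrichment ratio
    frac_up / frac_down is the headline asymmetry statistic; it is a NaN
    marker when nothing decreased.
    """
    by_event: Mapping[str, SplicingEvent] = {e.event_id: e for e in catalog}
    tallies: dict[str, ClassSummary] = {}
    for call in calls:
        ev = by_event.get(call.event_id)
        if ev is None or not ev.eligible or not call.passes_reads:
            continue
        cls = str(ev.event_class)
        t = tallies.setdefault(cls, ClassSummary(cls, 0, 0, 0))
        t.n_eligible += 1
        if call.nmd_direction == "nmd_up":
            t.n_up += 1
        elif call.nmd_direction == "nmd_down":
            t.n_down += 1
    return GlobalSummary(dict(sorted(tallies.items())))
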