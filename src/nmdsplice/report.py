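"""Human-readable summary of a run: the tabular analog of the global
up/down NMD-substrate pattern, plus the strongest individual calls."""

from __future__ import annotations

import math
from typing import Optional, Sequence

from .models import DiffSpliceCall, GlobalSummary, SplicingEvent


def _fmt_frac(x: float) -> str:
    return f"{100 * x:.2f}%"


def _fmt_enrich(x: float) -> str:
    return "undef" if math.isnan(x) else f"{x:.2f}"


def render_report(
    calls: Sequence[DiffSpliceCall],
    summary: GlobalSummary,
    catalog: Optional[Sequence[SplicingEvent]] = None,
    top_n: int = 10,
) -> str:
    """Render the per-class NMD-direction table and the top events by BF10."""
    lines = ["nmdsplice differential-splicing report", "=" * 40, ""]
    tested = [c for c in calls if c.passes_reads]
    if not tested:
        lines.append("*** no events tested (no event passed the identifying-read filter) ***")
        return "\n".join(lines) + "\n"

    lines.append("Predicted NMD substrates rising vs falling, per event class")
    lines.append("(fractions of eligible events with sufficient identifying reads)")
    lines.append("")
    header = f"{'class':<32}{'n_eligible':>11}{'up':>6}{'down':>6}{'frac_up':>10}{'frac_down':>11}{'enrichment':>12}"
    lines.append(header)
    lines.append("-" * len(header))
    rows = list(summary.classes.values()) + [summary.overall()]
    for c in rows:
        lines.append(
            f"{c.event_class:<32}{c.n_eligible:>11}{c.n_up:>6}{c.n_down:>6}"
            f"{_fmt_frac(c.frac_nmd_up):>10}{_fmt_frac(c.frac_nmd_down):>11}"
            f"{_fmt_enrich(c.enrichment):>12}"
        )
    lines.append("")
    lines.append(f"Events tested (read filter passed): {len(tested)}")
    called = [c for c in tested if c.called]
    lines.append(f"Events called differentially spliced: {len(called)}")
    lines.append("")
    if called:
        lines.append(f"Top events by Bayes factor (up to {top_n}):")
        lines.append(f"{'event_id':<48}{'delta_psi':>10}{'log10_bf10':>12}{'direction':>12}")
        for c in sorted(called, key=lambda c: -c.bf10)[:top_n]:
            lines.append(
                f"{c.event_id:<48}{c.delta_psi:>10.3f}{math.log10(c.bf10):>12.2f}{c.nmd_direction:>12}"
            )
    return "\n".join(lines) + "\n"
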