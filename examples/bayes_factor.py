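"""Bayes-factor differential splicing on junction-read counts.

Compares isoform-supporting read counts between two conditions for three
events and prints the per-condition PSI estimates with 95% credible
intervals, BF10, the filter verdicts, and the Savage-Dickey cross-check.
"""

import nmdsplice as ns

cases = {
    "no_change": (40, 100, 42, 100),
    "psi_doubles": (30, 100, 60, 100),
    "small_shift_low_depth": (5, 15, 9, 15),
}

for name, (k1, n1, k2, n2) in cases.items():
    p1 = ns.estimate_psi(k1, n1, name, "cond1")
    p2 = ns.estimate_psi(k2, n2, name, "cond2")
    call = ns.call_event(p1, p2)
    sd = ns.savage_dickey_bf10(k1, n1, k2, n2)
    print(f"{name}:")
    print(f"  cond1 psi={p1.psi_hat:.3f} [{p1.ci_low:.3f}, {p1.ci_high:.3f}]  "
          f"cond2 psi={p2.psi_hat:.3f} [{p2.ci_low:.3f}, {p2.ci_high:.3f}]")
    print(f"  delta_psi={call.delta_psi:+.3f}  BF10={call.bf10:.4g} "
          f"(Savage-Dickey {sd:.4g})")
    print(f"  filters: reads={call.passes_reads} delta={call.passes_delta} "
          f"bf={call.passes_bf} -> called={call.called}")

# An event is called differentially spliced only when it has >20 identifying
# reads in both conditions, |delta psi| >= 0.10 and BF10 >= 5; the
# Savage-Dickey value is an independent numerical evaluation of the same
# Bayes factor and should match the closed form.
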