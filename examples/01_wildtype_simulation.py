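"""Simulate the calibrated wild-type clock and read off its rhythm.

Runs the TD-activator / U-repressor model (the mechanism the screening
funnel selects) to its settled limit cycle and prints the period and the
peak phases of the three observables relative to subjective dawn.
"""

from kaiclock import HTD_HU, classify_wildtype, default_pto, default_ttfl, diagnose
from kaiclock.simulate import run_experiment

p, q = default_pto(), default_ttfl()
result = run_experiment(p, q, HTD_HU, burn_in=240.0, record=120.0)
diag = diagnose(result.wild_type)

print(f"period: {diag.period:.2f} h (sustained: {diag.sustained})")
for channel, label in (("mBC_rel", "kaiBC mRNA"),
                       ("UKaiC_frac", "unphosphorylated KaiC"),
                       ("PKaiC_frac", "phosphorylated KaiC")):
    print(f"{label:24s} peaks {diag.peak_phase[channel]:5.2f} h after dawn")
print(f"wild-type classification: {classify_wildtype(diag).verdict}")

# The period sits in the 24-26 h free-running window; unphosphorylated
# KaiC peaks in the early subjective day, total phosphorylation in the
# early night, and kaiBC transcript in between - the canonical LL
# phase relations this model family is judged against.
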