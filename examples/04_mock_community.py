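"""Score measured mock-community profiles against the expected composition.

Uses the eight-genus community standard as ground truth, simulates three
primer sets observing it with increasing distortion, and ranks them by
Pearson concordance (total-variation distance as tiebreak).
"""

from primerfusion import MockComposition, recovery_report, simulate_mock

expected = MockComposition.zymo()
print("expected composition:")
for genus, frac in expected.fractions.items():
    print(f"  {genus:15s} {frac:.1%}")

observed = {
    ps: simulate_mock(expected, noise, seed=11, primer_set=ps)
    for ps, noise in {"V5V8": 0.05, "V4": 0.3, "V6V9": 1.0}.items()
}
report = recovery_report(expected, observed)
print("\nrecovery ranking (best first):")
print(report.to_string(index=False))
# r near 1 and TV near 0 mean the primer set reproduces the known input;
# the planted noise ordering (V5V8 < V4 < V6V9) is recovered.
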