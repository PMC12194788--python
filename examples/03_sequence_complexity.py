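"""Sequence-complexity metrics used as breakend-context features.

Run:  python examples/03_sequence_complexity.py
"""

from cytosv import linguistic_complexity, read_diff, read_ratio, shannon_entropy

examples = {
    "poly-A tract     ": "A" * 40,
    "AC repeat        ": "AC" * 20,
    "balanced 4-letter": "ACGT" * 10,
}
print("sequence            H(k=1)  H(k=2)  H(k=3)  linguistic")
for name, seq in examples.items():
    h = [shannon_entropy(seq, k) for k in (1, 2, 3)]
    lc = linguistic_complexity(seq, 3)
    print(f"{name}  {h[0]:6.3f}  {h[1]:6.3f}  {h[2]:6.3f}  {lc:10.4f}")

# Low-complexity reference context near a breakpoint (entropy near 0,
# linguistic complexity near its floor) is a classic driver of artifact
# calls; the classifier sees these metrics for a +-100 bp window at each
# breakend.

print()
print("read metrics for an SV with 6 alt / 2 ref supporting reads:")
print(f"  read_diff  = {read_diff(6, 2)}   (alt - ref)")
print(f"  read_ratio = {read_ratio(6, 2)}  (alt / (alt + ref))")
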