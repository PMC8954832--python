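"""Adaptive Kennard-Stone subset selection on a training library.

KS-orders the 93 training samples in PCA score space, scores every prefix by
the D-optimal information per sample (log Det of the subset's score Gram
matrix), and keeps the argmax prefix.  The curve rises while added samples
contribute new spread and falls once they only duplicate information.
"""

from isolocal import aks_select, default_config, generate_library

lib = generate_library(default_config(seed=1))
result = aks_select(lib, pc=2)

print(f"KS ordering starts with: {[lib.sorted_by_id()[i].sample_id for i in result.ks_order[:4]]}")
print(f"chosen subset size: {result.chosen_n} of {len(lib)}")
print("\n  n   log Det(S'S/N)")
for n, info in result.info_curve[:: max(1, len(result.info_curve) // 12)]:
    marker = "  <-- maximum" if n == result.chosen_n else ""
    print(f"{n:>4}   {info:+.4f}{marker}")
print("\nThe subset at the curve's maximum is the most informative per "
      "sample: it spans the data space with the fewest redundant samples.")
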