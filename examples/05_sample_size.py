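"""Kappa-based sample-size planning for an agreement study.

How many patients per disease are needed to show that the masked-vs-original
diagnostic agreement (kappa) exceeds 0.6, if the true agreement is 0.85?
"""

from ocumask import kappa_sample_size

n = kappa_sample_size(k0=0.6, k1=0.85, rate1=0.3, rate2=0.7,
                      alpha=0.025, power=0.9)
print(f"reference design (k0=0.6, k1=0.85, rates 0.3/0.7, "
      f"alpha=0.025, power=0.9): n = {n}")

print("\nsensitivity to the alternative kappa (same design otherwise):")
for k1 in (0.75, 0.80, 0.85, 0.90):
    print(f"  k1 = {k1:.2f}: n = "
          f"{kappa_sample_size(0.6, k1, 0.3, 0.7, 0.025, 0.9)}")
print("\nSmaller true-vs-null gaps need more patients to demonstrate.")
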