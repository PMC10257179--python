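"""Detect and exclude an abnormal control litter with the iterative rank test.

One litter's controls are shifted +20 points (about 4 residual SDs) to mimic
a litter-level shock — pups of one dam running systematically high. The
procedure pools the control animals, gates on a Kruskal-Wallis test across
litters, picks the litter whose average rank is most deviant, and excludes it
only if a permutation test on the contrast statistic T rejects; it then
repeats on the survivors until forced to stop.
"""

import numpy as np

from neoscreen import iterative_exclusion

rng = np.random.default_rng(8)
by_litter = {f"E{e}:L{l}": rng.normal(41.0, 5.0, 6) for e in (1, 2, 3) for l in (1, 2)}
by_litter["E2:L1"] = by_litter["E2:L1"] + 20.0  # the perturbed litter

print("control litter means (percent loss):")
for key, values in by_litter.items():
    print(f"  {key}: n={values.size}  mean={values.mean():.1f}")

trace = iterative_exclusion(by_litter, n_perm=10_000, seed=1)
for it, step in enumerate(trace.iterations, 1):
    line = f"iteration {it}: KW H={step.kw_h:.2f} (p={step.kw_p:.4f})"
    if step.permutation is not None:
        line += (f", deviant litter {step.deviant_litter}, T={step.permutation.observed:.2f}, "
                 f"permutation p={step.permutation.p_value:.4f}")
    print(line + f" -> {step.action}")
print(f"excluded litters: {trace.excluded}")
print("The shifted litter E2:L1 is flagged and removed in the first pass; the "
      "second pass finds the remaining litters exchangeable and stops.")
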