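"""LFQ proteomics overlay: detection, coverage, fold-change calls.

Simulates triplicate LFQ intensities for an unpigmented and a pigmented
melanoma cell line with 10 proteins planted at 3-fold, then reports
per-line detection, coverage of the disease-protein list, and the >2-fold
differential calls.
"""

from pigmentnet import (
    SyntheticSpec,
    coverage,
    detect,
    fold_changes,
    gen_expression,
)

spec = SyntheticSpec(rng_seed=7)
proteins = [f"PG{i:04d}" for i in range(1, 301)]
expr, truth = gen_expression(spec, proteins)
line_a, line_b = spec.cell_lines

detected = detect(expr, min_replicates=2)
for line in (line_a, line_b):
    print(f"{line}: {len(detected[line])} of {len(proteins)} proteins detected "
          f"(quantified in >=2 of 3 replicates); coverage of the protein list: "
          f"{coverage(detected[line], proteins)}%")

attrs = fold_changes(expr, line_a, line_b, threshold=2.0)
called = {a.protein for a in attrs if a.differential}
print(f"\n{len(called)} proteins differential (> 2-fold between lines):")
for a in attrs:
    if a.differential:
        print(f"  {a.protein}: fold {a.fold_change:.2f}, higher in {a.direction}")

planted = set(truth.planted_differential)
quantifiable = planted & detected[line_a] & detected[line_b]
print(f"\nplanted 3-fold proteins: {len(planted)}, of which "
      f"{len(quantifiable)} quantifiable in both lines "
      f"(the rest lost replicates to dropout and are excluded from ratio calls)")
print("all quantifiable planted proteins called, no false positives:",
      called == quantifiable)
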