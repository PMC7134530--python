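"""Scar-burden agreement: correlation and Bland-Altman limits.

Compares the scar percentage measured from 2-SD thresholded masks with the
generator's ground truth across a small cohort — the same analysis used to
judge whether an automatic method can stand in for manual delineation when
staging patients by scar burden.
"""

import atriaseg as ag

cohort = ag.generate_cohort(ag.PhantomSpec(), 12, seed=30)
pairs = []
for sample in cohort:
    pred = ag.two_sd_threshold(ag.sample_from_phantom(sample))
    est = ag.scar_percentage(pred, sample.anatomy, sample.image.spacing,
                             wall_mm=sample.spec.wall_thickness_mm)
    ref = 100.0 * sample.true_scar_fraction
    pairs.append((est, ref))
    print(f"estimated {est:5.1f}%  true {ref:5.1f}%")

stats = ag.bland_altman(pairs)
print(f"\nPearson r = {stats.pearson_r:.3f}")
print(f"bias = {stats.bias:+.2f} percentage points; "
      f"95% limits of agreement [{stats.loa_low:+.2f}, {stats.loa_high:+.2f}]")
print("r near 1 means burden ranking is preserved; a negative bias means "
      "the threshold under-reads burden relative to ground truth.")
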