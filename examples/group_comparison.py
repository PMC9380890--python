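"""Compare a control cohort with an affected cohort end to end.

Simulates two cohorts of seven subjects — the affected one with a 40%
weaker force law and a 20% slower chewing rhythm — runs every session
through the full pipeline, and compares the per-subject estimated feeding
force and mean interpeak interval with two-tailed unpaired t-tests.
"""

from clef import AD_LIKE_EFFECT, SubjectModel, run_group_contrast

contrast = run_group_contrast(SubjectModel(), AD_LIKE_EFFECT, n_per_group=7, seed=2)

f, i = contrast.force_test, contrast.interpeak_test
print("estimated feeding force (g)")
print(f"  control : {f.mean1:7.2f} +/- {f.sd1:.2f}   (n={f.n1})")
print(f"  affected: {f.mean2:7.2f} +/- {f.sd2:.2f}   (n={f.n2})")
print(f"  t = {f.t:.2f}, df = {f.df:.0f}, p = {f.p:.4f}")
print("mean interpeak interval (s)")
print(f"  control : {i.mean1:7.4f} +/- {i.sd1:.4f}")
print(f"  affected: {i.mean2:7.4f} +/- {i.sd2:.4f}")
print(f"  t = {i.t:.2f}, df = {i.df:.0f}, p = {i.p:.4f}")
# A weaker force law shows up as a significantly lower estimated feeding
# force, and the slowed rhythm as a longer interpeak interval — the two
# signatures the pipeline is built to quantify.
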