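"""Rater reliability on a synthetic cohort.

Generates 20 subjects rated by 4 raters x 3 repeats with realistic
placement noise, estimates true landmark positions with the
random-intercept model, and prints combined intra-/inter-rater
variability for a few landmarks and for the deviation parameters.
"""

from dentasym import (
    SyntheticConfig,
    estimate_true_positions,
    generate,
    landmark_variability,
    parameter_variability,
)

records, truth = generate(SyntheticConfig(n_subjects=20, seed=42))
estimates = estimate_true_positions(records)

print(f"{len(records)} ratings, {len(estimates)} landmark position estimates\n")

lvar = {(e.target, e.mode, e.axis): e for e in landmark_variability(records, estimates)}
print("landmark variability (mean cell SD +- 95% CI half-width, mm):")
for landmark in ("N", "RPM_4", "mes11"):
    for mode in ("intra", "inter"):
        parts = [
            f"{axis}={lvar[(landmark, mode, axis)].mean_sd:.2f}+-{lvar[(landmark, mode, axis)].ci95_half_width:.2f}"
            for axis in ("x", "y", "z", "3D")
        ]
        print(f"  {landmark:>6s} {mode:5s}: " + "  ".join(parts))

print("\nparameter variability (mm / deg):")
for est in parameter_variability(records):
    print(
        f"  {est.target:>24s} {est.mode:5s}: {est.mean_sd:.2f} +- {est.ci95_half_width:.2f}"
    )

# The raphe landmark RPM_4 shows the characteristic anisotropy: small
# transverse (x) SD but sagittal (y) SD above 1 mm, which is why the
# fitted maxillary median plane is still transversally robust.
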