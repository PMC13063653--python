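"""Deviation profile of a single rating.

Builds a face whose maxillary complex is shifted 1 mm to the right and
whose dental midline sits a further 0.5 mm right of the skeletal
midline, then computes the seven deviation parameters.
"""

from dentasym import Point3, RatingRecord, compute_profile, template_face

landmarks = dict(template_face())
for name in ("RPM_1", "RPM_2", "RPM_3", "RPM_4", "RPM_5", "RPM_6", "mes11", "mes21"):
    p = landmarks[name]
    landmarks[name] = Point3(p.x + 1.0, p.y, p.z)
for name in ("mes11", "mes21"):
    p = landmarks[name]
    landmarks[name] = Point3(p.x + 0.5, p.y, p.z)

record = RatingRecord("demo", "R1", 1, "A", landmarks)
profile = compute_profile(record)

for name, value in profile.as_dict().items():
    unit = "deg" if "angle" in name else "mm"
    print(f"{name:>24s}: {value:+7.3f} {unit}")

# The dental midline sits 1.5 mm right of the facial median plane; 1.0 mm
# of that is skeletal (the maxMP gap at the dentMid level) and 0.5 mm is
# dentoalveolar (dentMid relative to maxMP). Positive = patient's right.
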