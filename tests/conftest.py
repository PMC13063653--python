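import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dentasym.io import Point3, RatingRecord
from dentasym.simulate import template_face


@pytest.fixture
def template_record() -> RatingRecord:
    return RatingRecord("S01", "R1", 1, "A", template_face())


def rigid_move(record: RatingRecord, rotvec, translation) -> RatingRecord:
    """Apply one rigid motion to every landmark of a record."""
    rot = Rotation.from_rotvec(rotvec).as_matrix()
    t = np.asarray(translation, dtype=float)
    return RatingRecord(
        record.subject_id,
        record.rater_id,
        record.repeat_index,
        record.group,
        {k: Point3.from_array(rot @ v.as_array() + t) for k, v in record.landmarks.items()},
    )


def mirror_x(record: RatingRecord) -> RatingRecord:
    """Reflect all landmarks about the x=0 plane, swapping paired names."""
    swap = {
        "OR": "OL", "OL": "OR", "EXR": "EXL", "EXL": "EXR",
        "ENR": "ENL", "ENL": "ENR", "PR": "PL", "PL": "PR",
        "mes11": "mes21", "mes21": "mes11",
    }
    landmarks = {
        swap.get(name, name): Point3(-p.x, p.y, p.z)
        for name, p in record.landmarks.items()
    }
    return RatingRecord(
        record.subject_id, record.rater_id, record.repeat_index, record.group, landmarks
    )
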