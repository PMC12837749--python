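from datetime import datetime

import numpy as np
import pytest

from camtrapnet.detections import DetectionRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rec(site, species, ts):
    """Shorthand DetectionRecord constructor; ts is 'YYYY-MM-DD HH:MM'."""
    return DetectionRecord(site, species, datetime.strptime(ts, "%Y-%m-%d %H:%M"))


@pytest.fixture
def make_detections_csv(tmp_path):
    def _write(rows, header="site_id,species,timestamp"):
        path = tmp_path / "detections.csv"
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return _write
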