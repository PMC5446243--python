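import numpy as np
import pytest
from hypothesis import settings

from smtk.defocalization import DefocalizationParams

settings.register_profile("default", derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def defoc():
    """Published-default defocalization constants (dz=0.7, a=0.15716, b=0.20811)."""
    return DefocalizationParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_track_csv(tmp_path, rows, name="tracks.csv"):
    """Write a minimal long-table trajectory file; rows = (id, frame, x, y)."""
    path = tmp_path / name
    lines = ["track_id,frame,x_um,y_um"]
    lines += [f"{i},{f},{x},{y}" for i, f, x, y in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
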