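import numpy as np
import pytest

from mirloc import (
    CameraModel,
    Rect,
    localize_stack,
    make_blink_schedule,
    render_frames,
    sample_csr,
)


@pytest.fixture(scope="session")
def camera():
    return CameraModel()


@pytest.fixture(scope="session")
def fov():
    """An 80 x 80 px field of view at 100 nm pixels."""
    return Rect(0.0, 0.0, 8000.0, 8000.0)


@pytest.fixture(scope="session")
def localized_run(camera):
    """A small end-to-end run shared by recovery-style tests.

    50 CSR emitters well inside an 80 x 80 px frame, 200 frames of sparse
    blinking with bright (>= 2000 photon) events, plus the recovered
    localization table.
    """
    inner = Rect(500.0, 500.0, 7500.0, 7500.0)
    scene = sample_csr(50, inner, seed=5)
    scene = make_blink_schedule(scene, 200, 0.01, 2000.0, seed=6,
                                min_photons=2000.0)
    stack = render_frames(scene, camera, 130.0, (200, 80, 80), seed=7)
    table = localize_stack(stack, camera)
    return scene, stack, table


def match_events(scene, table, max_dist_nm=100.0):
    """Match ground-truth blink events to localizations in the same frame.

    Returns per-axis errors (interleaved x, y) of the matched events and the
    recovered fraction.
    """
    d = table.data
    errs = []
    n_rec = 0
    for (x, y), fr in zip(scene.event_positions, scene.event_frame):
        sub = d[d.frame == fr]
        if not len(sub):
            continue
        dd = np.hypot(sub.x_nm - x, sub.y_nm - y)
        k = dd.idxmin()
        if dd[k] <= max_dist_nm:
            n_rec += 1
            errs.extend([d.x_nm[k] - x, d.y_nm[k] - y])
    return np.asarray(errs), n_rec / max(scene.n_events, 1)
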