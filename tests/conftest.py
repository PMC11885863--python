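import numpy as np
import pytest
from hypothesis import settings

from rootphen import RenderParams, SimParams, render_frames, simulate_root_system
from rootphen.pipeline import PipelineConfig, process_plant

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_plant():
    """One rendered synthetic plant (48 h, hourly frames) plus its ground
    truth, processed through the full per-plant pipeline."""
    params = SimParams(duration_h=48, seed=3, mr_wobble_sd=0.5)
    gt = simulate_root_system(params)
    rp = RenderParams(px_mm=0.1, image_shape=(250, 200))
    frames = render_frames(gt, rp)[::4]  # hourly
    cfg = PipelineConfig(px_mm=0.1)
    result = process_plant(frames, cfg)
    return {"params": params, "gt": gt, "frames": frames, "cfg": cfg, "result": result}


def make_mask(shape, polylines_px, seed_point=(2, 10)):
    """Rasterise 1-px polylines into a binary MaskFrame for topology tests."""
    from skimage.draw import line

    from rootphen import MaskFrame

    img = np.zeros(shape, dtype=np.uint8)
    for poly in polylines_px:
        pts = np.asarray(poly, dtype=int)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = line(r0, c0, r1, c1)
            img[rr, cc] = 1
    return MaskFrame(image=img, timestamp_h=0.0, px_mm=0.1,
                     plant_id="test", seed_point=seed_point)
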