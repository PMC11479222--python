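import numpy as np
import pytest

from vegdyn import metrics, raster_io, synthetic, trends
from vegdyn.containers import RasterGrid


@pytest.fixture(scope="session")
def grid120():
    return RasterGrid(n_rows=120, n_cols=120)


@pytest.fixture(scope="session")
def years23():
    return list(range(2000, 2023))


@pytest.fixture(scope="session")
def noisy_scene(grid120, years23):
    """The bundled six-block demo scene at the default noise level."""
    specs = synthetic.demo_scene_specs(noise_sd=0.02)
    return synthetic.build_scene(specs, grid120, years23, seed=1)


@pytest.fixture(scope="session")
def noiseless_scene(grid120, years23):
    specs = synthetic.demo_scene_specs(noise_sd=0.0)
    return synthetic.build_scene(specs, grid120, years23, seed=1)


@pytest.fixture(scope="session")
def classified(noisy_scene):
    """Full classification of the noisy demo scene."""
    return classify_scene(noisy_scene)


def classify_scene(scene, alpha=0.05):
    comp = metrics.growing_season_median(scene.monthly_ndvi)
    mask = raster_io.build_mask_set(
        scene.landcover, ["water", "impervious", "wetland", "glacier"],
        scene.lines, 250.0, scene.grid,
    )
    cv = metrics.focal_cv(comp, 3, mask)
    mean = metrics.period_mean(comp)
    nt = trends.fit_linear_trend(comp, 15, "NDVI")
    ct = trends.fit_linear_trend(cv, 15, "CV")
    classes = trends.classify_change(nt, ct, mean, alpha=alpha)
    return {
        "composite": comp, "mask": mask, "cv": cv, "mean": mean,
        "ndvi_trend": nt, "cv_trend": ct, "classes": classes,
    }


def block_recovery(scene, classes):
    """Fraction of valid interior block pixels carrying their truth label."""
    ok = tot = 0
    for spec in scene.specs:
        r0, c0, nr, nc = spec.block
        interior = np.zeros(scene.grid.shape, bool)
        interior[r0 + 1:r0 + nr - 1, c0 + 1:c0 + nc - 1] = True
        valid = interior & (classes >= 0)
        code = synthetic.CLASS_CODES[spec.class_label]
        ok += int(np.sum(classes[valid] == code))
        tot += int(valid.sum())
    return ok / tot
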