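import numpy as np
import pytest

from retinaquant.params import TwoStateParams
from retinaquant.pipeline import PipelineConfig, run_pipeline
from retinaquant.reference import TWO_STATE_FITS
from retinaquant.simulate import RetinaSimConfig, generate_retina_stack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


#: zero-noise benchmark expression: narrow shifted gamma clear of both the
#: cytoplasm-isointensity dead zone (level ~ 2) and the 8-bit ceiling (~5)
BENCH_EXPRESSION = TwoStateParams(9.0, 0.17, 1.0, 1.0, 0.0, shift=2.2)


@pytest.fixture(scope="session")
def clean_sim():
    """Small noise/attenuation/scatter-free retina for exact-recovery checks."""
    cfg = RetinaSimConfig(
        n_ommatidia=7,
        n_slices=25,
        seed=3,
        noise_sd=0.0,
        attenuation_coeff=0.0,
        curvature_radius_um=float("inf"),
        scatter_fraction=0.0,
    )
    stack, gt = generate_retina_stack(cfg, {"Rh3": BENCH_EXPRESSION})
    return cfg, stack, gt


@pytest.fixture(scope="session")
def default_sim():
    """Structural-only stack with the default optics (noise, curvature, scatter)."""
    cfg = RetinaSimConfig(n_ommatidia=19, n_slices=40, seed=2)
    stack, gt = generate_retina_stack(cfg)
    return cfg, stack, gt


@pytest.fixture(scope="session")
def default_result(default_sim):
    cfg, stack, gt = default_sim
    result = run_pipeline(stack, PipelineConfig(seed=0), sim_cfg=cfg)
    return cfg, stack, gt, result


@pytest.fixture(scope="session")
def quant_sim():
    """Small default-optics stack with one reporter channel for quantification."""
    cfg = RetinaSimConfig(n_ommatidia=7, n_slices=14, seed=5)
    stack, gt = generate_retina_stack(cfg, {"Rh6": TWO_STATE_FITS["Rh6@2wk"]})
    return cfg, stack, gt


@pytest.fixture(scope="session")
def quant_result(quant_sim):
    cfg, stack, gt = quant_sim
    result = run_pipeline(stack, PipelineConfig(seed=0), sim_cfg=cfg)
    return cfg, stack, gt, result
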