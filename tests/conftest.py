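import numpy as np
import pytest

from speckleflow import ScenarioConfig, SpeckleStack, make_flow_phantom, render_speckle_frame


def render_uniform_stack(
    tau_s: float,
    n_frames: int = 6,
    shape: tuple[int, int] = (128, 128),
    exposure_s: float = 5e-3,
    n_substeps: int = 64,
    seed: int = 5,
    anatomy_contrast: float = 0.0,
) -> SpeckleStack:
    """Stack of independent frames over a spatially uniform τ_c field.

    Anatomy modulation is off by default: these stacks are calibration
    targets for the contrast-vs-theory contract.
    """
    cfg = ScenarioConfig(
        image_shape=shape,
        pixel_pitch_mm=0.08,
        target_area_15min_mm2=0.0,
        baseline_tau_s=tau_s,
        n_substeps=n_substeps,
        exposure_s=exposure_s,
        anatomy_contrast=anatomy_contrast,
        seed=seed,
    )
    phantom = make_flow_phantom(cfg, 0.0)
    frames = np.stack(
        [render_speckle_frame(phantom, cfg, seed=(seed, k)) for k in range(n_frames)]
    )
    return SpeckleStack(frames, exposure_s, cfg.frame_rate_hz, cfg.pixel_pitch_mm)


@pytest.fixture(scope="session")
def stack_tau_eq_T() -> SpeckleStack:
    """Uniform τ_c = T: theory says K² = 1 + 0.5(e⁻² − 1) = 0.56767."""
    return render_uniform_stack(tau_s=5e-3, n_frames=8)


@pytest.fixture(scope="session")
def stack_frozen() -> SpeckleStack:
    """τ_c ≫ T: effectively static, fully developed speckle (K → 1)."""
    return render_uniform_stack(tau_s=5.0, n_frames=8)


@pytest.fixture(scope="session")
def speckle_frame(stack_frozen) -> np.ndarray:
    """A single static speckle frame, useful as a textured registration target."""
    return stack_frozen.frames[0]


@pytest.fixture(scope="session")
def anatomy_stack() -> SpeckleStack:
    """Dynamic frames sharing a persistent anatomy pattern — the realistic
    registration scenario: speckle decorrelates between frames, structure
    does not."""
    return render_uniform_stack(tau_s=1e-3, n_frames=8, anatomy_contrast=0.4, seed=11)
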