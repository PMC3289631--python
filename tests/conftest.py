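import numpy as np
import pytest

from strainseg import (
    Config,
    PixelImage,
    assemble,
    build_node_map,
    extract_foreground,
    material_from_image,
)
from strainseg.phantoms import PhantomSpec, generate


def build_system(image: PixelImage, threshold: float = 50.0, **cfg_kw):
    """Assemble the pixel FEM for an image; returns all intermediate layers."""
    cfg = Config(threshold=threshold, **cfg_kw)
    fg = extract_foreground(image, cfg.threshold)
    nm = build_node_map(fg)
    mat = material_from_image(image, fg, nm, cfg.e0, cfg.poisson_ratio)
    system = assemble(mat, nm, cfg.spring_factor, cfg.plane, cfg.solver_cutoff)
    return cfg, fg, nm, mat, system


def mask_image(mask: np.ndarray, value: float = 100.0) -> PixelImage:
    """Uniform-intensity image with the given foreground mask."""
    return PixelImage(np.asarray(mask, dtype=float) * value)


def balanced_random_force(node_map, n_dofs: int, seed: int) -> np.ndarray:
    """Random load with zero net force and torque (rigid modes removed).

    Balanced loads excite only elastic modes, so solve accuracy is not
    limited by the soft ground springs.
    """
    from strainseg.load_optimizer import _rigid_basis

    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n_dofs)
    rb = _rigid_basis(node_map)
    return f - rb @ (rb.T @ f)


@pytest.fixture(scope="session")
def small_dumbbell():
    """A small dumbbell phantom used across optimizer and strain tests."""
    return generate(
        PhantomSpec(
            kind="dumbbell", block_size=8, neck_width=2, neck_length=4, margin=2
        )
    )


@pytest.fixture(scope="session")
def default_dumbbell():
    return generate(PhantomSpec(kind="dumbbell"))


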