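import numpy as np
import pytest

from fetalplan.imaging_core import LabelMap
from fetalplan.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One moderately posed, noisy phantom shared by read-only tests."""
    cfg = PhantomConfig(
        seed=1, pose_rotation_deg=(20.0, -15.0, 30.0),
        pose_translation_mm=(5.0, -4.0, 3.0),
    )
    return (cfg, *generate_phantom(cfg))


@pytest.fixture(scope="session")
def straight_phantom():
    """Unposed, noiseless phantom (straight vessels, known axes)."""
    cfg = PhantomConfig(seed=2, noise_sigma=0.0)
    return (cfg, *generate_phantom(cfg))


def make_labels(mask: np.ndarray, spacing: float = 1.0, name: str = "S",
                affine: np.ndarray | None = None) -> LabelMap:
    """Single-structure label map on an identity-scaled grid."""
    if affine is None:
        affine = np.diag([spacing, spacing, spacing, 1.0])
    return LabelMap(mask.astype(np.uint16), affine, {name: 1})


def random_rigid_affine(rng: np.random.Generator, spacing=None) -> np.ndarray:
    """Random rotation x anisotropic scaling + translation, always invertible."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    s = np.diag(spacing if spacing is not None else rng.uniform(0.5, 3.0, 3))
    aff = np.eye(4)
    aff[:3, :3] = R @ s
    aff[:3, 3] = rng.uniform(-50, 50, 3)
    return aff
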