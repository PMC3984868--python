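import numpy as np
import pytest

from lpunwrap import (
    PhaseImage,
    ShearPhantomSpec,
    make_shear_phantom,
    wrap,
    wrapped_gradients,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def smooth_wrapped(rng):
    """Wrapped observation of a random smooth surface with sub-pi gradients."""
    truth = _smooth_surface(rng, 24, 20)
    return PhaseImage(truth, is_wrapped=False), PhaseImage(wrap(truth), is_wrapped=True)


def _smooth_surface(rng, m, n, amp=6.0):
    """Random band-limited surface whose per-pixel differences stay below pi."""
    i = np.linspace(0, 1, m)[:, None]
    j = np.linspace(0, 1, n)[None, :]
    coef = rng.normal(size=(3, 3))
    surf = np.zeros((m, n))
    for a in range(3):
        for b in range(3):
            surf += coef[a, b] * np.cos((a + 1) * np.pi * i) * np.cos((b + 1) * np.pi * j)
    surf *= amp / max(np.abs(surf).max(), 1e-9)
    # rescale until the Itoh condition holds with margin
    while max(
        np.abs(np.diff(surf, axis=0)).max(), np.abs(np.diff(surf, axis=1)).max()
    ) > 0.9 * np.pi:
        surf *= 0.8
    return surf


@pytest.fixture
def smooth_surface_factory(rng):
    def make(m=24, n=20, amp=6.0):
        return _smooth_surface(rng, m, n, amp)

    return make


@pytest.fixture
def default_phantom():
    spec = ShearPhantomSpec()
    truth, wrapped = make_shear_phantom(spec)
    return spec, truth, wrapped


@pytest.fixture
def shear_grad(default_phantom):
    _, _, wrapped = default_phantom
    return wrapped_gradients(wrapped)
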