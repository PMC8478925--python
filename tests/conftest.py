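import numpy as np
import pytest

from virtualck.patchflow import is_little_dyed, is_white_background, tile_pairs
from virtualck.phantoms import PhantomSpec, render_phantom_pair
from virtualck.registration import ShiftVector
from virtualck.virtual_stain import TrainingConfig, train


def reduced_training_config(seed: int = 0, **overrides) -> TrainingConfig:
    """Small CPU-friendly model configuration used throughout the tests."""
    kwargs = dict(
        seed=seed,
        gen_base=8,
        gen_depth=3,
        disc_base=8,
        disc_layers=1,
        patch_size=64,
        epochs=50,
        max_g_steps=150,
    )
    kwargs.update(overrides)
    return TrainingConfig(**kwargs)


@pytest.fixture(scope="session")
def registration_phantom():
    """A large noise-free phantom slide pair for registration tests."""
    spec = PhantomSpec(size=2048, seed=3, noise_sd=0.0)
    return render_phantom_pair(spec)


@pytest.fixture(scope="session")
def small_phantom():
    """A 512-px phantom pair with the default noise level."""
    return render_phantom_pair(PhantomSpec(size=512, seed=5))


@pytest.fixture(scope="session")
def training_pairs(small_phantom):
    """Eight informative 64x64 patch pairs cut from the small phantom."""
    he, ck, _ = small_phantom
    pairs = [
        p
        for p in tile_pairs(he, ck, 64)
        if not is_white_background(p.he) and not is_little_dyed(p.ck)
    ]
    assert len(pairs) >= 8
    return pairs[:8]


@pytest.fixture(scope="session")
def tiny_model(training_pairs):
    """A generator trained for 150 steps on the eight phantom pairs."""

    class _DS:
        pairs = training_pairs

    return train(_DS(), reduced_training_config(seed=0))


def brute_force_shift(mask_ref: np.ndarray, mask_mov: np.ndarray) -> tuple[int, int]:
    """Exhaustive-search displacement oracle (same convention as the FFT path:
    the returned (drow, dcol) is where mask_mov's content sits relative to
    mask_ref; ties resolve to the lexicographically smallest shift)."""
    a = np.asarray(mask_ref, dtype=np.int64)
    b = np.asarray(mask_mov, dtype=np.int64)
    H, W = a.shape
    best = None
    for dr in range(-H + 1, H):
        for dc in range(-W + 1, W):
            rs, cs = max(-dr, 0), max(-dc, 0)
            re, ce = min(H - dr, H), min(W - dc, W)
            s = 0
            if re > rs and ce > cs:
                s = int(np.sum(a[rs:re, cs:ce] * b[rs + dr : re + dr, cs + dc : ce + dc]))
            if best is None or s > best[0]:
                best = (s, (dr, dc))
    return best[1]


@pytest.fixture(scope="session")
def planted_shift_pair(registration_phantom):
    """The registration phantom with CK displaced by (64, -96)."""
    from virtualck.phantoms import make_shifted_pair

    return make_shifted_pair(registration_phantom, ShiftVector(64, -96))
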