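"""Conditional adversarial virtual CK staining of H&E patches.

A U-Net generator maps a 256x256 H&E patch to a virtual CK patch; a
patch-level discriminator, conditioned on the H&E input, judges (H&E, CK)
pairs real or fake.  The generator objective combines the adversarial term
with two reconstruction terms against the real CK patch: an L1 loss in RGB
(weight ``lambda1 = 10``) and an L1 loss in HED stain-concentration space
(weight ``lambda2 = 0.9``), the latter computed through a smooth,
quantization-free color deconvolution so gradients flow.  The generator has
no dropout: inference is deterministic, which the downstream tumor-stroma
scoring requires.

Training follows the standard conditional-GAN recipe: alternating
single-sample Adam updates (lr 2e-4, beta1 0.5) of discriminator and
generator, inputs scaled to [-1, 1], weights initialized N(0, 0.02).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .stains import RGBImage, StainBasis

__all__ = [
    "TrainingConfig",
    "LossTerms",
    "ModelState",
    "StitchResult",
    "hed_transform",
    "compute_losses",
    "train",
    "generator_forward",
    "generate_and_stitch",
]


@dataclass
class TrainingConfig:
    """Hyperparameters of the adversarial training run.

    ``lambda1``/``lambda2`` weight the RGB and HED L1 terms; both L1 terms
    use mean reduction so the weights are resolution-independent.  The
    reduced architecture fields (``gen_base``, ``gen_depth``, ``disc_base``,
    ``disc_layers``, ``patch_size``) allow a small CPU-friendly model; the
    defaults are the full-scale configuration.
    """

    lambda1: float = 10.0
    lambda2: float = 0.9
    batch_size: int = 1
    learning_rate: float = 0.0002
    epochs: int = 200
    beta1: float = 0.5
    beta2: float = 0.999
    seed: int = 0
    gen_base: int = 64
    gen_depth: int = 8
    disc_base: int = 64
    disc_layers: int = 3
    patch_size: int = 256
    max_g_steps: int | None = None
    hed_eps: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class LossTerms:
    """One evaluation of the objective's components."""

    adv: float  # E[log D(x,y)] + E[log(1 - D(x,G(x)))]
    adv_gen: float  # generator surrogate actually minimized: -E[log D(x,G(x))]
    l1_rgb: float
    l1_hed: float
    total: float


@dataclass
class ModelState:
    """Trained generator (and discriminator) plus training provenance."""

    generator: nn.UNetGenerator
    discriminator: nn.PatchDiscriminator | None
    config: TrainingConfig
    loss_log: list[dict] = field(default_factory=list)
    initial_l1_rgb: float | None = None


class StitchResult(RGBImage):
    """Stitched virtual CK raster; margins not covered by tiles are white."""

    def __init__(self, pixels, covered: tuple[int, int], margin_filled: bool):
        super().__init__(pixels)
        self.covered = covered
        self.margin_filled = margin_filled


def _to_net(rgb: np.ndarray) -> np.ndarray:
    """uint8 HxWx3 in [0,255] -> float32 (3,H,W) in [-1,1]."""
    return (np.asarray(rgb, dtype=np.float32).transpose(2, 0, 1) / 127.5) - 1.0


def _from_net(x: np.ndarray) -> np.ndarray:
    v = np.rint((x.transpose(1, 2, 0) + 1.0) * 127.5)
    return np.clip(v, 0, 255).astype(np.uint8)


def hed_transform(v01: np.ndarray, basis: StainBasis | None = None, eps: float = 1.0) -> np.ndarray:
    """Smooth RGB([0,1]) -> HED concentration map used inside the loss.

    Identical to the scoring-path deconvolution except that it skips 8-bit
    rounding and the non-negativity clamp, keeping the map differentiable.
    Channels-first ``(3,H,W)`` in, channels-first out.
    """
    basis = basis or StainBasis()
    od = -np.log10((v01 * 255.0 + eps) / 255.0)
    return np.einsum("chw,cs->shw", od, basis.inverse)


def _l1_rgb(y01: np.ndarray, yhat01: np.ndarray):
    diff = yhat01 - y01
    return float(np.mean(np.abs(diff))), np.sign(diff).astype(np.float32) / diff.size


def _l1_hed(y01: np.ndarray, yhat01: np.ndarray, basis: StainBasis, eps: float):
    hy = hed_transform(y01, basis, eps)
    hyhat = hed_transform(yhat01, basis, eps)
    diff = hyhat - hy
    loss = float(np.mean(np.abs(diff)))
    # back through conc = od @ inv(basis) and od = -log10((255 v + eps)/255)
    dconc = np.sign(diff) / diff.size
    dod = np.einsum("shw,cs->chw", dconc, basis.inverse)
    dv = dod * (-255.0 / ((yhat01 * 255.0 + eps) * np.log(10.0)))
    return loss, dv.astype(np.float32)


def compute_losses(x, y, y_hat, disc_scores_real, disc_scores_fake, config: TrainingConfig) -> LossTerms:
    """Evaluate all objective components on one (x, y, y_hat) triplet.

    ``x``/``y``/``y_hat`` are 8-bit RGB patches (H&E input, real CK, virtual
    CK); ``disc_scores_*`` are the discriminator's probability grids for the
    real and fake pair.  L1 terms are computed on [0,1]-scaled intensities.
    """
    yp = np.asarray(y.pixels if isinstance(y, RGBImage) else y, dtype=np.float64)
    yh = np.asarray(y_hat.pixels if isinstance(y_hat, RGBImage) else y_hat, dtype=np.float64)
    xp = np.asarray(x.pixels if isinstance(x, RGBImage) else x)
    if yp.shape != yh.shape or xp.shape != yp.shape:
        raise ValueError("x, y and y_hat must share a shape")
    tiny = 1e-12
    sr = np.clip(np.asarray(disc_scores_real, dtype=np.float64), tiny, 1 - tiny)
    sf = np.clip(np.asarray(disc_scores_fake, dtype=np.float64), tiny, 1 - tiny)
    adv = float(np.mean(np.log(sr)) + np.mean(np.log(1.0 - sf)))
    adv_gen = float(-np.mean(np.log(sf)))
    y01 = (yp / 255.0).transpose(2, 0, 1)
    yh01 = (yh / 255.0).transpose(2, 0, 1)
    l1_rgb, _ = _l1_rgb(y01, yh01)
    l1_hed, _ = _l1_hed(y01, yh01, StainBasis(), config.hed_eps)
    total = adv_gen + config.lambda1 * l1_rgb + config.lambda2 * l1_hed
    return LossTerms(adv=adv, adv_gen=adv_gen, l1_rgb=l1_rgb, l1_hed=l1_hed, total=total)


def _eval_l1_rgb(G: nn.UNetGenerator, pairs) -> float:
    vals = []
    for p in pairs:
        yhat = G.forward(_to_net(p.he))
        vals.append(np.mean(np.abs((yhat + 1) / 2 - (_to_net(p.ck) + 1) / 2)))
    return float(np.mean(vals))


def train(dataset, config: TrainingConfig) -> ModelState:
    """Adversarial training: alternating single-step D and G updates.

    Returns the final model state with a per-epoch loss log (mean adv,
    l1_rgb, l1_hed, total over the epoch) and the generator's pre-training
    mean RGB L1 for reference.
    """
    pairs = dataset.pairs if hasattr(dataset, "pairs") else list(dataset)
    if not pairs:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    G = nn.UNetGenerator(rng, base=config.gen_base, depth=config.gen_depth)
    D = nn.PatchDiscriminator(rng, base=config.disc_base, n_layers=config.disc_layers)
    optG = nn.Adam(G.params(), config.learning_rate, config.beta1, config.beta2)
    optD = nn.Adam(D.params(), config.learning_rate, config.beta1, config.beta2)
    basis = StainBasis()
    state = ModelState(G, D, config)
    state.initial_l1_rgb = _eval_l1_rgb(G, pairs)

    g_steps = 0
    for _ in range(config.epochs):
        order = rng.permutation(len(pairs))
        epoch = {"adv": [], "adv_gen": [], "l1_rgb": [], "l1_hed": [], "total": []}
        for idx in order:
            p = pairs[idx]
            x, y = _to_net(p.he), _to_net(p.ck)

            # --- discriminator step: push D(x,y) -> 1, D(x,G(x)) -> 0
            y_fake = G.forward(x)
            optD.zero_grad()
            zr = D.forward(np.concatenate([x, y], axis=0))
            loss_r, gz = nn.bce_with_logits(zr, 1.0)
            D.backward(0.5 * gz)
            zf = D.forward(np.concatenate([x, y_fake], axis=0))
            loss_f, gz = nn.bce_with_logits(zf, 0.0)
            D.backward(0.5 * gz)
            optD.step()

            # --- generator step: adversarial + lambda1 L1_rgb + lambda2 L1_hed
            y_fake = G.forward(x)
            optD.zero_grad()
            z = D.forward(np.concatenate([x, y_fake], axis=0))
            adv_gen, gz = nn.bce_with_logits(z, 1.0)
            g_in = D.backward(gz)
            g_y = g_in[3:]
            y01, yhat01 = (y + 1) / 2, (y_fake + 1) / 2
            l1_rgb, d_rgb = _l1_rgb(y01, yhat01)
            l1_hed, d_hed = _l1_hed(y01, yhat01, basis, config.hed_eps)
            # d(loss)/d(y_fake) with y_fake in [-1,1]: chain through v01 = (v+1)/2
            g_total = g_y + 0.5 * (config.lambda1 * d_rgb + config.lambda2 * d_hed)
            optG.zero_grad()
            G.backward(g_total.astype(np.float32))
            optG.step()
            g_steps += 1

            with np.errstate(over="ignore"):
                sig = 1.0 / (1.0 + np.exp(-zf.astype(np.float64)))
                sigr = 1.0 / (1.0 + np.exp(-zr.astype(np.float64)))
            epoch["adv"].append(float(np.mean(np.log(np.clip(sigr, 1e-12, 1)))
                                      + np.mean(np.log(np.clip(1 - sig, 1e-12, 1)))))
            epoch["adv_gen"].append(adv_gen)
            epoch["l1_rgb"].append(l1_rgb)
            epoch["l1_hed"].append(l1_hed)
            epoch["total"].append(adv_gen + config.lambda1 * l1_rgb + config.lambda2 * l1_hed)
            if config.max_g_steps is not None and g_steps >= config.max_g_steps:
                break
        state.loss_log.append({k: float(np.mean(v)) for k, v in epoch.items()})
        if config.max_g_steps is not None and g_steps >= config.max_g_steps:
            break
    return state


def generator_forward(he_patch, model_state: ModelState) -> RGBImage:
    """Run the trained generator on one H&E patch (deterministic)."""
    px = he_patch.pixels if isinstance(he_patch, RGBImage) else np.asarray(he_patch)
    out = model_state.generator.forward(_to_net(px))
    return RGBImage(_from_net(out))


def generate_and_stitch(he_region, model_state: ModelState, tile: int = 256) -> StitchResult:
    """Tile a region, stain each tile, and abut the outputs (no blending).

    Margins on the right/bottom not covered by a whole tile are filled white
    and flagged via ``margin_filled``.
    """
    px = he_region.pixels if isinstance(he_region, RGBImage) else np.asarray(he_region)
    H, W = px.shape[:2]
    if H < tile or W < tile:
        raise ValueError("region smaller than one tile")
    out = np.full_like(px, 255)
    for r in range(0, H - tile + 1, tile):
        for c in range(0, W - tile + 1, tile):
            out[r : r + tile, c : c + tile] = generator_forward(px[r : r + tile, c : c + tile], model_state).pixels
    covered = ((H // tile) * tile, (W // tile) * tile)
    return StitchResult(out, covered, margin_filled=covered != (H, W))


def save_model(state: ModelState, path) -> None:
    """Serialize generator weights + config to an .npz checkpoint."""
    arrays = {f"g{i}": p for i, (p, _) in enumerate(state.generator.params())}
    meta = dict(
        gen_base=state.config.gen_base,
        gen_depth=state.config.gen_depth,
        seed=state.config.seed,
    )
    np.savez(path, _meta=np.array([meta["gen_base"], meta["gen_depth"], meta["seed"]]), **arrays)


def load_model(path, config: TrainingConfig | None = None) -> ModelState:
    """Load a generator checkpoint written by :func:`save_model`."""
    data = np.load(path)
    base, depth, seed = (int(v) for v in data["_meta"])
    config = config or TrainingConfig(gen_base=base, gen_depth=depth, seed=seed)
    G = nn.UNetGenerator(np.random.default_rng(0), base=base, depth=depth)
    for i, (p, _) in enumerate(G.params()):
        p[...] = data[f"g{i}"]
    return ModelState(G, None, config)
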