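"""Counterfactual cycle-consistent GAN: models, losses, training loop.

Two resnet generators translate between the two image classes (G: X->Y,
F: Y->X) and two PatchGAN discriminators judge realism per patch.  On top
of the usual adversarial, cycle-consistency and identity terms, the
objective carries a *counterfactual loss*: the frozen classifier under
explanation scores every translated image, and the squared distance of its
softmax output from the one-hot vector of the opposite class is charged to
the generators,

    L_counter(G, F, C) = E_x || C2(G(x)) - (0,1) ||_2^2
                       + E_y || C2(F(y)) - (1,0) ||_2^2 ,

so the generators are penalised whenever a translation fails to cross the
classifier's decision boundary.  The combined objective is

    L = L_GAN(G, D_Y) + L_GAN(F, D_X)
        + lambda * L_cycle + mu * L_identity + gamma * L_counter .

Setting gamma = 0 recovers a vanilla CycleGAN (the ablation baseline);
setting mu = 0 as well recovers the original two-term-plus-cycle objective
exactly.

Generators work in [-1, 1]; the classifier consumes [0, 1].  The affine
bridge (g + 1) / 2 sits inside the differentiable path so counterfactual
gradients reach the generators while the frozen classifier's parameters
receive none.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .classifier import AlexNetSmall
from .data import CorpusPartitions
from .exceptions import (ConfigurationError, ContractError, DivergenceError,
                         ParameterError, ShapeError)
from .images import Label

__all__ = [
    "LossWeights", "GanConfig", "TrainingLog", "ImagePool",
    "ResnetGenerator", "PatchDiscriminator",
    "build_generator", "build_discriminator",
    "adversarial_loss", "cycle_loss", "identity_loss",
    "counterfactual_loss", "total_objective",
    "train_counterfactual_gan", "GanBundle",
    "save_gan", "load_gan",
]

_EPS = 1e-8   # guards log(0); documented clamp, never an error

LOG_COLUMNS = ("iteration", "epoch", "adv_g", "adv_f", "d_x", "d_y",
               "cycle", "identity", "counter", "total")


@dataclass(frozen=True)
class LossWeights:
    """Objective weights: cycle lambda, identity mu, counterfactual gamma."""

    lambda_cycle: float = 10.0
    mu_identity: float = 1.0
    gamma_counter: float = 1.0

    def __post_init__(self):
        if min(self.lambda_cycle, self.mu_identity, self.gamma_counter) < 0:
            raise ParameterError("loss weights must be >= 0")


@dataclass(frozen=True)
class GanConfig:
    """Training configuration (Adam 2e-4, betas 0.5/0.999, batch 1 by
    default).  ``target_g``/``target_f`` are the counterfactual target
    vectors: translated X-images should be classified (0, 1) (class Y) and
    translated Y-images (1, 0)."""

    optimizer: str = "adam"
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    batch_size: int = 1
    epochs: int = 20
    image_size: int = 64
    n_residual_blocks: int = 6
    base_filters: int = 32
    adversarial_form: str = "least_squares"   # or "log"
    pool_size: int = 50
    target_g: tuple[float, float] = (0.0, 1.0)
    target_f: tuple[float, float] = (1.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ParameterError("epochs and batch_size must be >= 1")
        if self.adversarial_form not in ("least_squares", "log"):
            raise ParameterError(f"unknown adversarial_form "
                                 f"{self.adversarial_form!r}")
        for t in (self.target_g, self.target_f):
            if min(t) < 0 or abs(sum(t) - 1.0) > 1e-9:
                raise ParameterError(f"target vector {t} must be a "
                                     "non-negative pair summing to 1")


@dataclass
class TrainingLog:
    """One record per iteration, one field per loss component."""

    records: list[dict[str, float]] = field(default_factory=list)

    def append(self, **values: float) -> None:
        self.records.append(values)

    def column(self, name: str) -> np.ndarray:
        return np.array([r[name] for r in self.records])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=LOG_COLUMNS)
            w.writeheader()
            w.writerows(self.records)
        return path

    def __len__(self) -> int:
        return len(self.records)


class ImagePool:
    """Replay buffer of past generated images for discriminator updates.

    Once full, each query either returns the incoming image (p = 0.5) or
    swaps it against a stored one — the standard CycleGAN history trick
    that stabilises the discriminators.
    """

    def __init__(self, capacity: int, rng: np.random.Generator):
        self.capacity = capacity
        self.rng = rng
        self._store: list[np.ndarray] = []

    def query(self, image: np.ndarray) -> np.ndarray:
        if self.capacity == 0:
            return image
        if len(self._store) < self.capacity:
            self._store.append(image.copy())
            return image
        if self.rng.random() < 0.5:
            k = int(self.rng.integers(self.capacity))
            out = self._store[k].copy()
            self._store[k] = image.copy()
            return out
        return image


# --------------------------------------------------------------------- models

class _ResidualBlock(nn.Module):
    def __init__(self, ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(ch, ch, 3, padding=1, init="gan", rng=rng)
        self.norm1 = nn.InstanceNorm2d()
        self.conv2 = nn.Conv2d(ch, ch, 3, padding=1, init="gan", rng=rng)
        self.norm2 = nn.InstanceNorm2d()

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        return x + h


class ResnetGenerator(nn.Module):
    """Encoder (2x stride-2 downsampling) -> residual blocks -> decoder
    (2x nearest-neighbour upsampling + conv), instance-normalised, tanh
    output in [-1, 1]. Fully convolutional: works at any size divisible
    by 4."""

    def __init__(self, base_filters: int, n_blocks: int,
                 rng: np.random.Generator):
        super().__init__()
        k = base_filters
        self.stem = nn.Sequential([
            nn.Conv2d(1, k, 7, padding=3, init="gan", rng=rng),
            nn.InstanceNorm2d(), nn.ReLU(),
            nn.Conv2d(k, 2 * k, 3, stride=2, padding=1, init="gan", rng=rng),
            nn.InstanceNorm2d(), nn.ReLU(),
            nn.Conv2d(2 * k, 4 * k, 3, stride=2, padding=1, init="gan", rng=rng),
            nn.InstanceNorm2d(), nn.ReLU(),
        ])
        self.blocks = nn.Sequential(
            [_ResidualBlock(4 * k, rng) for _ in range(n_blocks)])
        self.head_a = nn.Sequential([
            nn.Conv2d(4 * k, 2 * k, 3, padding=1, init="gan", rng=rng),
            nn.InstanceNorm2d(), nn.ReLU(),
        ])
        self.head_b = nn.Sequential([
            nn.Conv2d(2 * k, k, 3, padding=1, init="gan", rng=rng),
            nn.InstanceNorm2d(), nn.ReLU(),
        ])
        self.out = nn.Conv2d(k, 1, 7, padding=3, init="gan", rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.ndim != 4 or x.shape[2] % 4 or x.shape[3] % 4:
            raise ShapeError(f"generator input must be (N, 1, 4m, 4m), "
                             f"got {x.shape}")
        h = self.stem(x)
        h = self.blocks(h)
        h = self.head_a(h.upsample2x())
        h = self.head_b(h.upsample2x())
        return self.out(h).tanh()


class PatchDiscriminator(nn.Module):
    """Fully convolutional patch critic: three stride-2 stages and two
    stride-1 stages ending in a 1-channel grid of raw patch scores
    (spatial extent = input / 8).  Apply a sigmoid externally for the
    log-form adversarial loss; least-squares uses the raw scores."""

    def __init__(self, base_filters: int, rng: np.random.Generator):
        super().__init__()
        k = base_filters
        self.net = nn.Sequential([
            nn.Conv2d(1, k, 4, stride=2, padding=1, init="gan", rng=rng),
            nn.LeakyReLU(0.2),
            nn.Conv2d(k, 2 * k, 4, stride=2, padding=1, init="gan", rng=rng),
            nn.InstanceNorm2d(), nn.LeakyReLU(0.2),
            nn.Conv2d(2 * k, 4 * k, 4, stride=2, padding=1, init="gan", rng=rng),
            nn.InstanceNorm2d(), nn.LeakyReLU(0.2),
            nn.Conv2d(4 * k, 8 * k, 3, padding=1, init="gan", rng=rng),
            nn.InstanceNorm2d(), nn.LeakyReLU(0.2),
            nn.Conv2d(8 * k, 1, 3, padding=1, init="gan", rng=rng),
        ])

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.ndim != 4 or x.shape[2] < 16 or x.shape[2] % 8 or x.shape[3] % 8:
            raise ShapeError(f"discriminator input must be (N, 1, 8m, 8m) "
                             f"with size >= 16, got {x.shape}")
        return self.net(x)


def build_generator(config: GanConfig, seed: int | None = None) -> ResnetGenerator:
    if config.image_size % 4:
        raise ConfigurationError("image_size must be divisible by 4")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return ResnetGenerator(config.base_filters, config.n_residual_blocks, rng)


def build_discriminator(config: GanConfig, seed: int | None = None
                        ) -> PatchDiscriminator:
    if config.image_size < 16 or config.image_size % 8:
        raise ConfigurationError(
            "image_size must be a multiple of 8 and >= 16 for the patch stack")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return PatchDiscriminator(config.base_filters, rng)


# --------------------------------------------------------------------- losses

def _t(x) -> nn.Tensor:
    return x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x))


def adversarial_loss(real_scores, fake_scores, role: str,
                     form: str = "least_squares") -> nn.Tensor:
    """Patch-averaged adversarial loss.

    least_squares: discriminator 0.5*(mean (D(real)-1)^2 + mean D(fake)^2),
    generator mean (D(fake)-1)^2 (target flipping).  log: discriminator
    -(E log D(real) + E log(1 - D(fake))) summing both expectation terms,
    generator the non-saturating -E log D(fake).  Scores for the log form
    are probabilities in (0, 1); log arguments are clamped at 1e-8.
    """
    if role not in ("generator", "discriminator"):
        raise ParameterError(f"unknown role {role!r}")
    fake = _t(fake_scores)
    real = _t(real_scores) if real_scores is not None else None
    if role == "discriminator" and real is None:
        raise ParameterError("discriminator role requires real scores")
    if real is not None and real.shape != fake.shape:
        raise ShapeError(f"score grids differ: {real.shape} vs {fake.shape}")
    if form == "least_squares":
        if role == "discriminator":
            return 0.5 * (((real - 1.0) ** 2).mean() + (fake ** 2).mean())
        return ((fake - 1.0) ** 2).mean()
    if form == "log":
        if role == "discriminator":
            return -(real.clamp(_EPS, 1.0).log().mean()
                     + (1.0 - fake).clamp(_EPS, 1.0).log().mean())
        return -(fake.clamp(_EPS, 1.0).log().mean())
    raise ParameterError(f"unknown adversarial form {form!r}")


def cycle_loss(x, x_reconstructed, y, y_reconstructed) -> nn.Tensor:
    """Mean absolute reconstruction error, summed over the two directions."""
    x, xr, y, yr = _t(x), _t(x_reconstructed), _t(y), _t(y_reconstructed)
    if x.shape != xr.shape or y.shape != yr.shape:
        raise ShapeError("cycle_loss shape mismatch")
    return (xr - x).abs().mean() + (yr - y).abs().mean()


def identity_loss(y, g_of_y, x, f_of_x) -> nn.Tensor:
    """Mean absolute change each generator applies to an image already in
    its target domain, summed over both generators."""
    y, gy, x, fx = _t(y), _t(g_of_y), _t(x), _t(f_of_x)
    if y.shape != gy.shape or x.shape != fx.shape:
        raise ShapeError("identity_loss shape mismatch")
    return (gy - y).abs().mean() + (fx - x).abs().mean()


def counterfactual_loss(probs_gx, probs_fy,
                        targets: tuple = ((0.0, 1.0), (1.0, 0.0))) -> nn.Tensor:
    """Squared distance of the classifier's softmax on translated images
    from the opposite-class one-hot vectors (batch-averaged per term).

    Each term is bounded by 2 on the probability simplex, so the loss lies
    in [0, 4].
    """
    tg = np.asarray(targets[0], dtype=np.float32)
    tf = np.asarray(targets[1], dtype=np.float32)
    pg, pf = _t(probs_gx), _t(probs_fy)
    if pg.ndim == 1:
        pg = pg.reshape(1, 2)
    if pf.ndim == 1:
        pf = pf.reshape(1, 2)
    term_g = ((pg - tg) ** 2).sum(axis=1).mean()
    term_f = ((pf - tf) ** 2).sum(axis=1).mean()
    return term_g + term_f


def total_objective(components, weights: LossWeights):
    """Weighted sum  adv_G + adv_F + lambda*cycle + mu*identity +
    gamma*counter  over the five components (in that order)."""
    adv_g, adv_f, cyc, idt, cnt = components
    for c in components:
        if not np.isfinite(float(c)):
            raise DivergenceError("non-finite loss component")
    return (adv_g + adv_f + weights.lambda_cycle * cyc
            + weights.mu_identity * idt + weights.gamma_counter * cnt)


# ------------------------------------------------------------------- training

@dataclass
class GanBundle:
    G: ResnetGenerator
    F: ResnetGenerator
    D_X: PatchDiscriminator
    D_Y: PatchDiscriminator
    config: GanConfig
    weights: LossWeights
    log: TrainingLog


def _stack(images, size: int) -> np.ndarray:
    """(N, 1, S, S) batch in [-1, 1] from LabeledImages in [0, 1]."""
    arrs = []
    for im in images:
        px = im.pixels
        if px.shape != (size, size):
            raise ShapeError(f"image shape {px.shape} != ({size}, {size})")
        arrs.append(px * 2.0 - 1.0)
    return np.stack(arrs).astype(np.float32)[:, None, :, :]


def train_counterfactual_gan(partitions: CorpusPartitions,
                             classifier: AlexNetSmall,
                             config: GanConfig,
                             weights: LossWeights | None = None,
                             progress: bool = False) -> GanBundle:
    """Train the counterfactual CycleGAN against a frozen classifier.

    Per iteration: update D_X, then D_Y (on replay-buffer fakes), then take
    one joint G+F step minimising the full objective; counterfactual
    gradients flow through the frozen classifier into the generators.
    Raises ``ContractError`` if the classifier is not frozen and
    ``DivergenceError`` (with iteration index) on a non-finite total loss.
    """
    weights = weights or LossWeights()
    if not classifier.frozen:
        raise ContractError("classifier must be frozen (call .freeze()) "
                            "before GAN training")
    xs = partitions.by_label("train", Label.CLASS_X)
    ys = partitions.by_label("train", Label.CLASS_Y)
    if not xs or not ys:
        raise ParameterError("train partition must contain both classes")

    s = config.seed
    G = build_generator(config, seed=int(np.random.SeedSequence([s, 0]).generate_state(1)[0]))
    F = build_generator(config, seed=int(np.random.SeedSequence([s, 1]).generate_state(1)[0]))
    D_X = build_discriminator(config, seed=int(np.random.SeedSequence([s, 2]).generate_state(1)[0]))
    D_Y = build_discriminator(config, seed=int(np.random.SeedSequence([s, 3]).generate_state(1)[0]))
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([s, 4]))
    pool_x = ImagePool(config.pool_size, np.random.default_rng(np.random.SeedSequence([s, 5])))
    pool_y = ImagePool(config.pool_size, np.random.default_rng(np.random.SeedSequence([s, 6])))

    opt_g = nn.Adam(G.parameters() + F.parameters(), lr=config.learning_rate,
                    beta1=config.beta1, beta2=config.beta2)
    opt_dx = nn.Adam(D_X.parameters(), lr=config.learning_rate,
                     beta1=config.beta1, beta2=config.beta2)
    opt_dy = nn.Adam(D_Y.parameters(), lr=config.learning_rate,
                     beta1=config.beta1, beta2=config.beta2)

    form = config.adversarial_form
    log = TrainingLog()
    iteration = 0
    size = config.image_size
    n_iter = min(len(xs), len(ys)) // config.batch_size

    def scores(disc, batch):
        out = disc(batch)
        return out.sigmoid() if form == "log" else out

    for epoch in range(config.epochs):
        x_order = list(xs)
        y_order = list(ys)
        shuffle_rng.shuffle(x_order)
        shuffle_rng.shuffle(y_order)
        for it in range(n_iter):
            b = config.batch_size
            x = nn.Tensor(_stack(x_order[it * b:(it + 1) * b], size))
            y = nn.Tensor(_stack(y_order[it * b:(it + 1) * b], size))

            # fresh fakes for the discriminator updates (no generator grads)
            fake_y_np = G(x).data
            fake_x_np = F(y).data

            dx_loss = adversarial_loss(
                scores(D_X, x), scores(D_X, nn.Tensor(pool_x.query(fake_x_np))),
                role="discriminator", form=form)
            opt_dx.zero_grad()
            dx_loss.backward()
            opt_dx.step()

            dy_loss = adversarial_loss(
                scores(D_Y, y), scores(D_Y, nn.Tensor(pool_y.query(fake_y_np))),
                role="discriminator", form=form)
            opt_dy.zero_grad()
            dy_loss.backward()
            opt_dy.step()

            # joint generator step against the just-updated discriminators
            fake_y = G(x)
            fake_x = F(y)
            rec_x = F(fake_y)
            rec_y = G(fake_x)
            adv_g = adversarial_loss(None, scores(D_Y, fake_y),
                                     role="generator", form=form)
            adv_f = adversarial_loss(None, scores(D_X, fake_x),
                                     role="generator", form=form)
            cyc = cycle_loss(x, rec_x, y, rec_y)
            idt = identity_loss(y, G(y), x, F(x))
            # classifier consumes [0, 1]; the affine bridge stays in the graph
            probs_gx = classifier((fake_y + 1.0) * 0.5)
            probs_fy = classifier((fake_x + 1.0) * 0.5)
            cnt = counterfactual_loss(probs_gx, probs_fy,
                                      targets=(config.target_g, config.target_f))
            total = total_objective((adv_g, adv_f, cyc, idt, cnt), weights)
            if not np.isfinite(total.item()):
                raise DivergenceError(
                    f"non-finite total loss at iteration {iteration}", iteration)
            opt_g.zero_grad()
            total.backward()
            opt_g.step()

            log.append(iteration=iteration, epoch=epoch,
                       adv_g=adv_g.item(), adv_f=adv_f.item(),
                       d_x=dx_loss.item(), d_y=dy_loss.item(),
                       cycle=cyc.item(), identity=idt.item(),
                       counter=cnt.item(), total=total.item())
            iteration += 1
        if progress:
            last = log.records[-1]
            print(f"epoch {epoch + 1}/{config.epochs}  "
                  f"total {last['total']:.3f}  counter {last['counter']:.3f}")
    return GanBundle(G=G, F=F, D_X=D_X, D_Y=D_Y, config=config,
                     weights=weights, log=log)


# ---------------------------------------------------------------- persistence

def save_gan(bundle: GanBundle, path: str | Path) -> Path:
    """Checkpoint all four networks (npz) + config echo (json sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = {}
    for tag, net in (("G", bundle.G), ("F", bundle.F),
                     ("DX", bundle.D_X), ("DY", bundle.D_Y)):
        for k, v in net.state_dict().items():
            state[f"{tag}::{k}"] = v
    np.savez(path, **state)
    path.with_suffix(".json").write_text(json.dumps(
        {"config": asdict(bundle.config), "weights": asdict(bundle.weights)}))
    return path


def load_gan(path: str | Path) -> GanBundle:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = GanConfig(**{k: tuple(v) if isinstance(v, list) else v
                          for k, v in meta["config"].items()})
    weights = LossWeights(**meta["weights"])
    nets = {"G": build_generator(config), "F": build_generator(config),
            "DX": build_discriminator(config), "DY": build_discriminator(config)}
    with np.load(path) as blob:
        for tag, net in nets.items():
            net.load_state_dict(
                {k.split("::", 1)[1]: blob[k] for k in blob.files
                 if k.startswith(tag + "::")})
    return GanBundle(G=nets["G"], F=nets["F"], D_X=nets["DX"], D_Y=nets["DY"],
                     config=config, weights=weights, log=TrainingLog())
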