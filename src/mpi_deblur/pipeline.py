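"""Training, transfer learning and experiment orchestration.

Trains the deblurring network with the multi-supervised MSE loss on
phantom/native pairs, keeps the checkpoint with the lowest validation loss
(validation is a seeded 10% carve-out of the training split), and provides
the two reproduction studies: the two-target concentration-ratio study and
the module ablation study.  Every artifact records the seed and a config hash
so reruns with identical settings reproduce metrics exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .autodiff import Adam
from .baselines import BaselineConfig, run_baseline
from .forward_model import SimulationParams, build_psf
from .metrics import MetricsReport, evaluate
from .network import DeblurNet, NetworkConfig, multi_supervised_loss
from .phantoms import (
    PhantomSpec,
    assign_concentrations,
    generate_binary_phantom,
    render_native,
)

__all__ = [
    "ExperimentConfig",
    "TransferSpec",
    "TrainResult",
    "train",
    "predict",
    "overfit_single_pair",
    "save_checkpoint",
    "load_checkpoint",
    "transfer_learn",
    "run_concentration_study",
    "run_ablation",
    "CONCENTRATION_RATIOS",
    "ABLATION_VARIANTS",
]

#: the five two-target concentration ratios of the quantification study
CONCENTRATION_RATIOS = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class ExperimentConfig:
    """Dataset, network and optimizer settings for one training run."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    n_pairs: int = 2000
    n_test: int = 200
    optimizer: str = "adam"
    learning_rate: float = 2e-3
    lr_schedule: str = "cosine"  # "cosine" decay to lr/20, or "constant"
    batch_size: int = 16
    epochs: int = 30
    seed: int = 0
    val_fraction: float = 0.1
    sim: SimulationParams = field(default_factory=SimulationParams)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in [0, 1)")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class TransferSpec:
    """Freeze-and-fine-tune transfer from a pretrained base checkpoint.

    ``freeze_policy``: ``"all"`` freezes every tensor, ``"all_but_heads"``
    (default) leaves only the fusion stage and the prediction heads trainable.
    """

    base_checkpoint: str | Path
    freeze_policy: str = "all_but_heads"
    fine_tune_epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 16

    def __post_init__(self) -> None:
        if self.fine_tune_epochs < 1:
            raise ValueError("fine_tune_epochs must be >= 1")
        if self.freeze_policy not in ("all", "all_but_heads"):
            raise ValueError(f"unknown freeze_policy {self.freeze_policy!r}")


@dataclass
class TrainResult:
    net: DeblurNet
    history: list[dict]
    best_epoch: int
    best_val_loss: float
    config: ExperimentConfig


_TRAILING_PREFIXES = ("fuse_conv", "att_w1", "att_w2", "head_f_conv", "head_f", "head_a", "head_b")


def _as_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _epoch_pass(net, natives, phantoms, cfg, opt=None, rng=None):
    """One pass over the data; trains when ``opt`` is given, else evaluates."""
    total, count = 0.0, 0
    indices = _as_batches(len(natives), cfg.batch_size, rng) if opt is not None else (
        np.arange(start, min(start + cfg.batch_size, len(natives)))
        for start in range(0, len(natives), cfg.batch_size)
    )
    for idx in indices:
        xb = natives[idx][:, None, :, :]
        yb = phantoms[idx][:, None, :, :]
        out = net.forward(xb)
        loss = multi_supervised_loss(out, yb, net.config)
        if opt is not None:
            opt.zero_grad()
            loss.backward()
            opt.step()
        val = float(loss.data)
        if not np.isfinite(val):
            raise FloatingPointError("training diverged: loss is not finite")
        total += val * len(idx)
        count += len(idx)
    return total / count


def train(
    cfg: ExperimentConfig,
    natives: np.ndarray,
    phantoms: np.ndarray,
    trainable: list[str] | None = None,
    net: DeblurNet | None = None,
    log=None,
) -> TrainResult:
    """Train the network on stacked (N, H, W) native/phantom arrays.

    Inputs are the raw simulated native images (approximately [0, 1] after
    blur, with noise excursions); targets are the clean phantoms in [0, 1] —
    no per-image normalization, so absolute concentration ratios stay
    learnable.  A seeded ``val_fraction`` carve-out selects the
    best-by-validation checkpoint, restored before returning.
    """
    natives = np.asarray(natives, dtype=np.float32)
    phantoms = np.asarray(phantoms, dtype=np.float32)
    rng = np.random.default_rng(cfg.seed)
    if net is None:
        net = DeblurNet(cfg.network, rng_seed=cfg.seed)

    n = len(natives)
    n_val = int(round(cfg.val_fraction * n))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    tr_n, tr_p = natives[train_idx], phantoms[train_idx]
    va_n, va_p = natives[val_idx], phantoms[val_idx]

    params = dict(net.named_parameters())
    if trainable is not None:
        params = {k: v for k, v in params.items() if any(k.startswith(t) for t in trainable)}
    opt = Adam(params.values(), lr=cfg.learning_rate)

    history = []
    best_state, best_val, best_epoch = net.state_dict(), np.inf, -1
    base_lr = cfg.learning_rate
    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine" and cfg.epochs > 1:
            frac = epoch / (cfg.epochs - 1)
            floor = base_lr / 20.0
            opt.lr = floor + 0.5 * (base_lr - floor) * (1.0 + np.cos(np.pi * frac))
        train_loss = _epoch_pass(net, tr_n, tr_p, cfg, opt=opt, rng=rng)
        val_loss = _epoch_pass(net, va_n, va_p, cfg) if n_val else train_loss
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if log is not None:
            log(f"epoch {epoch:3d}  train {train_loss:.6f}  val {val_loss:.6f}")
        if val_loss < best_val:
            best_val, best_epoch, best_state = val_loss, epoch, net.state_dict()
    net.load_state_dict(best_state)
    return TrainResult(net=net, history=history, best_epoch=best_epoch,
                       best_val_loss=float(best_val), config=cfg)


def overfit_single_pair(
    net: DeblurNet,
    native: np.ndarray,
    phantom: np.ndarray,
    steps: int = 500,
    lr: float = 8e-3,
    betas: tuple[float, float] = (0.9, 0.99),
    warmup_steps: int = 30,
) -> list[float]:
    """Memorize one native/phantom pair; returns the per-step loss trace.

    A capacity probe: with a workable step size the network should drive the
    fusion head to a near-exact reconstruction of a single 50 x 50 pair
    within a few hundred Adam steps.  The default learning rate is higher
    than the full-training default because a single pair tolerates (and
    profits from) aggressive steps; cosine-decayed to lr/20 over the run, with
    a shorter second-moment horizon (beta2 = 0.99) suited to a stationary
    single-sample objective, after a short linear warmup that keeps the
    near-identity start from being destroyed by the first large steps.
    """
    x = np.asarray(native, dtype=np.float32)[None, None]
    y = np.asarray(phantom, dtype=np.float32)[None, None]
    opt = Adam(net.parameters(), lr=lr, betas=betas)
    trace = []
    for step in range(steps):
        if step < warmup_steps:
            opt.lr = lr * (step + 1) / warmup_steps
        elif steps > 1:
            floor = lr / 20.0
            frac = (step - warmup_steps) / max(steps - 1 - warmup_steps, 1)
            opt.lr = floor + 0.5 * (lr - floor) * (1.0 + np.cos(np.pi * frac))
        opt.zero_grad()
        loss = multi_supervised_loss(net.forward(x), y, net.config)
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
    return trace


def predict(net: DeblurNet, images, batch_size: int = 32, clip: bool = True) -> np.ndarray:
    """Deployed (fusion-head) predictions for a stack of images.

    Outputs are clipped to the valid relative-concentration range [0, 1] by
    default (``clip=False`` returns the raw head output).
    """
    images = np.asarray(images, dtype=np.float32)
    squeeze = images.ndim == 2
    if squeeze:
        images = images[None]
    outs = []
    for start in range(0, len(images), batch_size):
        batch = images[start : start + batch_size][:, None, :, :]
        outs.append(net.forward(batch).deployed.data[:, 0])
    result = np.concatenate(outs, axis=0).astype(float)
    if clip:
        result = np.clip(result, 0.0, 1.0)
    return result[0] if squeeze else result


def save_checkpoint(path: str | Path, result: TrainResult) -> None:
    """Persist weights + config + seed provenance as an .npz archive."""
    path = Path(path)
    meta = {
        "network": dataclasses.asdict(result.config.network),
        "experiment": dataclasses.asdict(result.config),
        "seed": result.config.seed,
        "config_hash": result.config.config_hash(),
        "package_version": __version__,
        "best_epoch": result.best_epoch,
        "best_val_loss": result.best_val_loss,
    }
    arrays = {f"param/{k}": v for k, v in result.net.state_dict().items()}
    np.savez(path, __meta__=json.dumps(meta, default=str), **arrays)


def load_checkpoint(path: str | Path) -> tuple[DeblurNet, dict]:
    """Load a checkpoint; returns the reconstructed network and its metadata."""
    with np.load(Path(path), allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k[len("param/"):]: archive[k] for k in archive.files if k.startswith("param/")}
    net_cfg = NetworkConfig(**meta["network"])
    net = DeblurNet(net_cfg, rng_seed=meta["seed"])
    net.load_state_dict(state)
    return net, meta


def transfer_learn(
    spec: TransferSpec,
    natives: np.ndarray,
    phantoms: np.ndarray,
    seed: int = 0,
) -> TrainResult:
    """Fine-tune a pretrained model on a new dataset with frozen early layers.

    Frozen tensors are bit-identical before and after fine-tuning; with
    ``freeze_policy="all"`` the returned weights equal the base weights.
    """
    net, meta = load_checkpoint(spec.base_checkpoint)
    base_state = net.state_dict()
    if spec.freeze_policy == "all":
        trainable: list[str] = []
    else:
        trainable = list(_TRAILING_PREFIXES)
    cfg = ExperimentConfig(
        network=net.config,
        n_pairs=len(natives),
        n_test=0,
        learning_rate=spec.learning_rate,
        batch_size=spec.batch_size,
        epochs=spec.fine_tune_epochs,
        seed=seed,
    )
    if not trainable:
        # nothing to optimize: return the base model untouched
        return TrainResult(net=net, history=[], best_epoch=-1, best_val_loss=np.nan, config=cfg)
    result = train(cfg, natives, phantoms, trainable=trainable, net=net)
    frozen = [k for k in base_state if not any(k.startswith(t) for t in trainable)]
    for k in frozen:
        if not np.array_equal(base_state[k], result.net.state_dict()[k]):
            raise AssertionError(f"frozen tensor {k} changed during fine-tuning")
    return result


def _two_target_phantoms(ratio: float, n: int, seed: int, spec: PhantomSpec | None = None):
    """Two-lesion phantoms with concentrations 1.0 and ``ratio``."""
    spec = spec or PhantomSpec(n_features=2)
    out = []
    rng = np.random.default_rng(seed)
    for _ in range(n):
        binary = generate_binary_phantom(
            replace(spec, n_features=2), int(rng.integers(0, 2**31 - 1))
        )
        out.append(assign_concentrations(binary, [1.0, ratio]))
    return np.stack(out)


def run_concentration_study(
    net: DeblurNet,
    sim: SimulationParams | None = None,
    ratios=CONCENTRATION_RATIOS,
    n_per_ratio: int = 10,
    snr_db: float = 10.0,
    seed: int = 0,
    fov_mm: float = 40.0,
    baseline_iterations: int = 30,
) -> dict[float, dict[str, MetricsReport]]:
    """Two-target quantification study across concentration ratios.

    For each ratio ``1 : r`` generates two-lesion phantoms, renders them
    through the forward model at the given SNR, and evaluates the native
    images, the three classical baselines and the learned model against the
    ground truth.  Returns ``{ratio: {method: MetricsReport}}``.
    """
    sim = sim or SimulationParams()
    pixel_mm = fov_mm / 50.0
    psf = build_psf(sim, fov_mm=25 * pixel_mm, grid_px=25)
    results: dict[float, dict[str, MetricsReport]] = {}
    for i, ratio in enumerate(ratios):
        phantoms = _two_target_phantoms(ratio, n_per_ratio, seed + 1000 * i)
        natives = np.stack([
            render_native(p, psf, snr_db, seed + 1000 * i + j).values
            for j, p in enumerate(phantoms)
        ])
        nsr = 10 ** (-snr_db / 10.0)
        methods = {
            "native": natives,
            "wiener": np.stack(run_baseline(natives, psf, BaselineConfig("wiener", noise_to_signal=nsr))),
            "lucy_richardson": np.stack(
                run_baseline(natives, psf, BaselineConfig("lucy_richardson", iterations=baseline_iterations))
            ),
            "blind": np.stack(
                run_baseline(natives, psf, BaselineConfig("blind", iterations=min(baseline_iterations, 10)))
            ),
            "model": predict(net, natives),
        }
        results[float(ratio)] = {name: evaluate(imgs, phantoms) for name, imgs in methods.items()}
    return results


#: the four module-combination variants of the ablation study, in table order
ABLATION_VARIANTS = ("cnn_only", "transformer_only", "fusion_no_attention", "full")


def _variant_config(base: NetworkConfig, variant: str) -> NetworkConfig:
    if variant == "cnn_only":
        return replace(base, use_transformer=False, use_fusion=False, use_channel_attention=False,
                       lambda_b=0.0)
    if variant == "transformer_only":
        return replace(base, use_cnn=False, use_fusion=False, use_channel_attention=False,
                       lambda_a=0.0)
    if variant == "fusion_no_attention":
        return replace(base, use_channel_attention=False)
    if variant == "full":
        return base
    raise ValueError(f"unknown ablation variant {variant!r}")


def run_ablation(
    cfg: ExperimentConfig,
    train_natives: np.ndarray,
    train_phantoms: np.ndarray,
    test_natives: np.ndarray,
    test_phantoms: np.ndarray,
    variants=ABLATION_VARIANTS,
    log=None,
) -> dict[str, dict]:
    """Train and evaluate the module-combination variants under one budget.

    All variants share the dataset, seed and optimizer settings; returns an
    ordered ``{variant: {"report": MetricsReport, "n_parameters": int}}``.
    """
    results: dict[str, dict] = {}
    for variant in variants:
        vcfg = replace(cfg, network=_variant_config(cfg.network, variant))
        if log is not None:
            log(f"training variant {variant}")
        res = train(vcfg, train_natives, train_phantoms, log=log)
        preds = predict(res.net, test_natives)
        results[variant] = {
            "report": evaluate(preds, test_phantoms),
            "n_parameters": res.net.num_parameters(),
            "result": res,
        }
    return results
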