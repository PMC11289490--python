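"""Alternating training of the fusion and segmentation networks.

Within any epoch only one network's parameters change: fusion phases minimize
content + similarity + semantic loss with the segmentation network frozen;
segmentation phases fuse with the frozen fusion network and minimize the
semantic (clustering) loss alone. The default schedule alternates fusion
phases of 20 epochs with segmentation phases of 10 epochs for five cycles.
Every source of randomness (weight init, batch order, photometric jitter,
k-means seeding) derives from the configured seed, so runs are reproducible.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from .attention import FusionModel
from .autograd import Tensor
from .config import RunConfig
from .losses import total_fusion_loss
from .nn import Adam
from .phantom import RegisteredPair
from .segmentation import PhotometricJitter, SegmentationNet, semantic_loss

__all__ = ["TrainState", "build_models", "train_fusion_phase",
           "train_seg_phase", "alternating_train", "schedule",
           "save_checkpoint", "load_checkpoint"]


class ConfigurationError(ValueError):
    pass


@dataclass
class TrainState:
    """Mutable state of an alternating training run."""

    config: RunConfig
    fusion: FusionModel
    seg: SegmentationNet
    fusion_opt: Adam
    seg_opt: Adam
    rng: np.random.Generator
    cycle: int = 0
    phase_index: int = 0          # phases completed within the current cycle
    history: list[dict] = field(default_factory=list)

    def log(self, record: dict, log_path: Path | None = None) -> None:
        self.history.append(record)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(record) + "\n")


def schedule(config: RunConfig) -> list[tuple[str, int]]:
    """The planned phase sequence: cycles x [(fusion, n), (seg, m)]."""
    t = config.training
    plan = []
    for _ in range(t.cycles):
        plan.append(("fusion", t.fusion_epochs_per_cycle))
        plan.append(("seg", t.seg_epochs_per_cycle))
    return plan


def build_models(config: RunConfig) -> tuple[FusionModel, SegmentationNet]:
    e, f, s = config.extract, config.fusion, config.semantic
    seed = config.training.seed
    fusion = FusionModel(channels=tuple(e.channels), n_branches=e.n_branches,
                         n_scales=e.n_scales, slope=e.leaky_slope,
                         reduction_kernel=f.reduction_kernel,
                         use_attention=f.use_attention,
                         share_extractors=e.share_weights, seed=seed)
    seg = SegmentationNet(feature_dim=s.feature_dim, hidden=s.hidden,
                          seed=seed + 1)
    return fusion, seg


def init_state(config: RunConfig) -> TrainState:
    fusion, seg = build_models(config)
    lr = config.training.learning_rate
    return TrainState(config=config, fusion=fusion, seg=seg,
                      fusion_opt=Adam(fusion.parameters(), lr=lr),
                      seg_opt=Adam(seg.parameters(), lr=lr),
                      rng=np.random.default_rng(config.training.seed))


def _jitter(config: RunConfig) -> PhotometricJitter:
    s = config.semantic
    return PhotometricJitter(s.jitter_brightness, s.jitter_contrast,
                             s.jitter_gamma)


def _batches(dataset: list[RegisteredPair], batch_size: int,
             rng: np.random.Generator):
    order = rng.permutation(len(dataset))
    for start in range(0, len(dataset), batch_size):
        idx = order[start:start + batch_size]
        a = np.stack([dataset[i].image_a for i in idx])[:, None]
        b = np.stack([dataset[i].image_b for i in idx])[:, None]
        yield Tensor(a), Tensor(b)


def train_fusion_phase(state: TrainState, dataset: list[RegisteredPair],
                       epochs: int, log_path: Path | None = None) -> TrainState:
    """Update fusion weights only; segmentation weights stay byte-identical."""
    if not dataset:
        raise ConfigurationError("training dataset is empty")
    cfg = state.config
    jitter = _jitter(cfg)
    state.fusion.train()
    state.seg.eval()
    for epoch in range(epochs):
        for a, b in _batches(dataset, cfg.training.batch_size, state.rng):
            fused = state.fusion(a, b)
            if cfg.semantic.enabled:
                sem, within, cross = semantic_loss(
                    fused, state.seg, cfg.semantic.K, state.rng, jitter,
                    use_geometric=cfg.semantic.use_geometric)
            else:
                sem, within, cross = 0.0, 0.0, 0.0
            total, breakdown = total_fusion_loss(
                fused, a, b, semantic_value=sem, alpha=cfg.loss.alpha,
                semantic_within=within, semantic_cross=cross)
            state.fusion_opt.zero_grad()
            state.seg_opt.zero_grad()
            total.backward()
            state.fusion_opt.step()   # seg gradients are discarded
            record = {"step": len(state.history), "phase": "fusion",
                      "cycle": state.cycle, "epoch": epoch}
            record.update(breakdown.as_dict())
            state.log(record, log_path)
        state.seg_opt.zero_grad()
    return state


def train_seg_phase(state: TrainState, dataset: list[RegisteredPair],
                    epochs: int, log_path: Path | None = None) -> TrainState:
    """Train segmentation weights on the semantic loss over images fused by
    the frozen fusion network; fusion weights stay byte-identical."""
    if not dataset:
        raise ConfigurationError("training dataset is empty")
    cfg = state.config
    jitter = _jitter(cfg)
    state.fusion.eval()
    state.seg.train()
    for epoch in range(epochs):
        for a, b in _batches(dataset, cfg.training.batch_size, state.rng):
            with ag.no_grad():
                fused = state.fusion(a, b)
            sem, within, cross = semantic_loss(
                Tensor(fused.data), state.seg, cfg.semantic.K, state.rng,
                jitter, use_geometric=cfg.semantic.use_geometric)
            state.seg_opt.zero_grad()
            sem.backward()
            state.seg_opt.step()
            record = {"step": len(state.history), "phase": "seg",
                      "cycle": state.cycle, "epoch": epoch,
                      "L": float(sem.data), "L_semantic": float(sem.data),
                      "L_within": within, "L_cross": cross}
            state.log(record, log_path)
    return state


def alternating_train(config: RunConfig, dataset: list[RegisteredPair],
                      out_dir: str | Path | None = None,
                      resume_from: str | Path | None = None) -> TrainState:
    """Run the full alternating schedule, checkpointing after each phase."""
    if not dataset:
        raise ConfigurationError("training dataset is empty")
    if resume_from is not None:
        state = load_checkpoint(resume_from)
    else:
        state = init_state(config)
    out = Path(out_dir) if out_dir is not None else None
    log_path = None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        log_path = out / "train_log.jsonl"
    plan = schedule(state.config)
    start = 2 * state.cycle + state.phase_index
    for step_idx in range(start, len(plan)):
        phase, epochs = plan[step_idx]
        if phase == "fusion":
            train_fusion_phase(state, dataset, epochs, log_path)
        else:
            train_seg_phase(state, dataset, epochs, log_path)
        state.phase_index += 1
        if state.phase_index == 2:
            state.phase_index = 0
            state.cycle += 1
        if out is not None:
            save_checkpoint(state, out / f"checkpoint_{step_idx:02d}.npz")
    if out is not None:
        save_checkpoint(state, out / "checkpoint_final.npz")
    return state


# ------------------------------------------------------------ checkpointing
def save_checkpoint(state: TrainState, path: str | Path) -> Path:
    """Single binary state file plus a JSON sidecar echoing the config."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for key, val in state.fusion.state_dict().items():
        arrays[f"fusion/{key}"] = val
    for key, val in state.seg.state_dict().items():
        arrays[f"seg/{key}"] = val
    for name, opt in (("fopt", state.fusion_opt), ("sopt", state.seg_opt)):
        sd = opt.state_dict()
        arrays[f"{name}/t"] = np.array(sd["t"])
        for i, m in enumerate(sd["m"]):
            arrays[f"{name}/m{i}"] = m
        for i, v in enumerate(sd["v"]):
            arrays[f"{name}/v{i}"] = v
    # deterministic npz (fixed zip timestamps) so re-saving an unchanged
    # state reproduces the file byte for byte
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for name in sorted(arrays):
            buf = io.BytesIO()
            np.save(buf, np.ascontiguousarray(arrays[name]))
            info = zipfile.ZipInfo(name + ".npy",
                                   date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())
    sidecar = {"config": state.config.to_dict(), "cycle": state.cycle,
               "phase_index": state.phase_index,
               "history": state.history,
               "rng_state": state.rng.bit_generator.state,
               "format_version": 1}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_checkpoint(path: str | Path) -> TrainState:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    config = RunConfig.from_dict(sidecar["config"])
    state = init_state(config)
    with np.load(path) as data:
        fusion_sd = {k[len("fusion/"):]: data[k] for k in data.files
                     if k.startswith("fusion/")}
        seg_sd = {k[len("seg/"):]: data[k] for k in data.files
                  if k.startswith("seg/")}
        state.fusion.load_state_dict(fusion_sd)
        state.seg.load_state_dict(seg_sd)
        for name, opt in (("fopt", state.fusion_opt), ("sopt", state.seg_opt)):
            n = len(opt.params)
            opt.load_state_dict({
                "t": int(np.asarray(data[f"{name}/t"]).ravel()[0]),
                "m": [data[f"{name}/m{i}"] for i in range(n)],
                "v": [data[f"{name}/v{i}"] for i in range(n)]})
    state.cycle = int(sidecar["cycle"])
    state.phase_index = int(sidecar["phase_index"])
    state.history = list(sidecar["history"])
    state.rng = np.random.default_rng()
    state.rng.bit_generator.state = sidecar["rng_state"]
    return state
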