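"""Trainable multi-label cervix parcellation network.

A 3D encoder-decoder (UNet-style) segmentation model over the six-code
label dictionary, trained on image/label pairs resampled-padded to a fixed
cubic grid with on-the-fly augmentation (smooth bias field, contrast
adjustment, affine rotations up to +/-45 degrees), a combined soft-Dice +
cross-entropy loss, and AdamW with a linearly decaying learning rate.
Defaults follow the full-scale recipe (five blocks, channels 32..512,
kernel 3, dropout 0.5, batch normalisation, batch size 1, lr 1e-3 decaying
to 0, weight decay 1e-5, 128^3 grid, 100k iterations); every field can be
overridden for desk-scale runs, and :meth:`NetConfig.reduced` provides the
scaled-down recipe used throughout the test-suite phantom experiments.

Semi-supervised staging (pretrain, pseudo-label a new batch, refine,
retrain) is available as :func:`pseudo_label_round`: iterative re-training
on model-labelled data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _nn
from .volumes import IntensityVolume, LabelVolume, LABELS, VolumeError

Pair = tuple[IntensityVolume, LabelVolume]


@dataclass(frozen=True)
class NetConfig:
    """Hyperparameters of the parcellation network and its training recipe."""

    n_blocks: int = 5
    channels: tuple[int, ...] = (32, 64, 128, 256, 512)
    kernel: int = 3
    convs_per_block: int = 2
    dropout: float = 0.5
    batch_norm: bool = True
    batch_size: int = 1
    n_classes: int = 6
    optimiser: str = "adamw"
    lr_init: float = 1e-3
    lr_floor: float = 0.0          # linear decay terminal LR
    weight_decay: float = 1e-5
    dice_weight: float = 1.0
    ce_weight: float = 1.0
    grid: int = 128
    iterations: int = 100_000
    # augmentation (probabilities per draw; rotation uniform +/- max per axis)
    rotate_prob: float = 0.5
    rotate_max_deg: float = 45.0
    bias_field_prob: float = 0.5
    bias_field_amplitude: float = 0.3
    contrast_prob: float = 0.5
    contrast_gamma_range: tuple[float, float] = (0.7, 1.5)
    histogram_match: bool = True
    checkpoint_every: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels) != self.n_blocks:
            raise ValueError("channels length must equal n_blocks")
        if self.grid % 2 ** (self.n_blocks - 1):
            raise ValueError(
                f"grid {self.grid} must be divisible by 2^{self.n_blocks - 1}"
            )
        if self.batch_size != 1:
            raise ValueError("only batch size 1 is supported")

    @classmethod
    def reduced(cls, iterations: int = 300, seed: int = 0, **over) -> "NetConfig":
        """Desk-scale recipe: 64^3 grid, channels 8..128, a few hundred iterations."""
        kw = dict(
            channels=(8, 16, 32, 64, 128),
            grid=64,
            iterations=iterations,
            convs_per_block=1,
            dropout=0.1,
            lr_init=3e-3,   # few-hundred-iteration runs need a hotter start
            lr_floor=6e-4,  # keep late iterations learning the hard canal class
            rotate_prob=0.15,
            bias_field_prob=0.25,
            contrast_prob=0.25,
            seed=seed,
        )
        kw.update(over)
        return cls(**kw)

    def lr_at(self, iteration: int) -> float:
        frac = min(iteration / max(self.iterations, 1), 1.0)
        return self.lr_floor + (self.lr_init - self.lr_floor) * (1.0 - frac)


# ---------------------------------------------------------------------------
# augmentation


def _rotation_matrix(angles_rad: np.ndarray) -> np.ndarray:
    ax, ay, az = angles_rad
    rx = np.array([[1, 0, 0], [0, math.cos(ax), -math.sin(ax)], [0, math.sin(ax), math.cos(ax)]])
    ry = np.array([[math.cos(ay), 0, math.sin(ay)], [0, 1, 0], [-math.sin(ay), 0, math.cos(ay)]])
    rz = np.array([[math.cos(az), -math.sin(az), 0], [math.sin(az), math.cos(az), 0], [0, 0, 1]])
    return rz @ ry @ rx


def _index_bias_field(shape, rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Random multiplicative quadratic field on the index grid, 1 +/- amplitude."""
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, n, dtype=np.float32) for n in shape], indexing="ij"
    )
    terms = [np.ones(shape, dtype=np.float32), *grids]
    terms += [grids[i] * grids[j] for i in range(3) for j in range(i, 3)]
    coef = rng.uniform(-1, 1, size=len(terms)).astype(np.float32)
    coef[0] = 0.0
    p = sum(c * t for c, t in zip(coef, terms))
    peak = np.abs(p).max()
    if peak > 0:
        p /= peak
    return 1.0 + amplitude * p


def augment(
    img: IntensityVolume, lab: LabelVolume, cfg: NetConfig, seed: int
) -> tuple[IntensityVolume, LabelVolume]:
    """Paired stochastic augmentation: one spatial transform for both volumes
    (trilinear for the image, nearest for labels), intensity transforms for
    the image only."""
    if img.shape != lab.shape:
        raise VolumeError(f"paired shapes differ: {img.shape} vs {lab.shape}")
    rng = np.random.default_rng(seed)
    im = img.data.astype(np.float32)
    lb = lab.data

    if rng.uniform() < cfg.rotate_prob:
        angles = np.radians(rng.uniform(-cfg.rotate_max_deg, cfg.rotate_max_deg, size=3))
        rot = _rotation_matrix(angles)
        centre = (np.asarray(im.shape) - 1) / 2.0
        minv = rot.T  # inverse mapping for ndimage.affine_transform
        offset = centre - minv @ centre
        im = ndimage.affine_transform(im, minv, offset=offset, order=1, mode="constant", cval=0.0)
        lb = ndimage.affine_transform(
            lb, minv, offset=offset, order=0, mode="constant", cval=0
        )
        lost = set(np.unique(lab.data)) - set(np.unique(lb))
        if lost:
            # a code can fall off the grid under rotation; this is legal but logged
            import logging

            logging.getLogger(__name__).info(
                "augmentation rotation cropped label code(s) %s", sorted(lost)
            )

    if rng.uniform() < cfg.bias_field_prob:
        im = im * _index_bias_field(im.shape, rng, cfg.bias_field_amplitude)

    if rng.uniform() < cfg.contrast_prob:
        lo_g, hi_g = cfg.contrast_gamma_range
        gamma = math.exp(rng.uniform(math.log(lo_g), math.log(hi_g)))
        lo, hi = float(im.min()), float(im.max())
        if hi > lo:
            im = ((im - lo) / (hi - lo)) ** gamma * (hi - lo) + lo

    return (
        IntensityVolume(im, img.geometry),
        LabelVolume(lb, lab.geometry, dict(lab.label_map)),
    )


# ---------------------------------------------------------------------------
# intensity standardisation


def intensity_landmarks(img: IntensityVolume, n: int = 11) -> np.ndarray:
    """Decile-style intensity landmarks used for histogram matching."""
    return np.quantile(img.data, np.linspace(0.0, 1.0, n)).astype(np.float64)


def histogram_match(img: IntensityVolume, reference_landmarks: np.ndarray) -> IntensityVolume:
    """Piecewise-linear landmark matching of an image onto reference landmarks.

    The conventional approach for harmonising T2w contrast across
    field strengths: source quantile landmarks are mapped onto the
    reference's by linear interpolation.
    """
    src = intensity_landmarks(img, n=len(reference_landmarks))
    src = np.maximum.accumulate(src)  # guard against flat quantiles
    matched = np.interp(img.data.ravel(), src, reference_landmarks)
    return IntensityVolume(matched.reshape(img.shape).astype(np.float32), img.geometry)


def _standardise(data: np.ndarray) -> np.ndarray:
    m, s = float(data.mean()), float(data.std())
    return ((data - m) / (s if s > 0 else 1.0)).astype(np.float32)


#: the cervix proper: canal, stromal layers and cysts — the structures the
#: training field of view must never truncate (the bladder, like in a real
#: cropped reconstruction, may run off the FOV edge)
CERVIX_CODES: tuple[int, ...] = (1, 2, 3, 4)


def fit_spacing(
    pairs: list[Pair],
    grid: int,
    margin_voxels: int = 4,
    focus_codes: tuple[int, ...] = CERVIX_CODES,
) -> float:
    """Smallest isotropic spacing (mm, 0.1 mm steps, >= 0.8) that fits every
    case's cervix bounding box into ``grid`` with a margin.

    The network consumes a fixed cubic grid; desk-scale grids are smaller
    than the anatomy at native resolution, so the whole cohort is resampled
    to one coarser common spacing chosen deterministically from the data.
    Only ``focus_codes`` constrain the fit: keeping the voxel size as fine
    as the cervix allows matters far more for the thin canal and the small
    cysts than full bladder coverage does.
    """
    worst = 0.0
    for _, lab in pairs:
        nz = np.nonzero(np.isin(lab.data, focus_codes))
        if not nz[0].size:
            continue
        ext = max(
            (a.max() - a.min() + 1) * s
            for a, s in zip(nz, lab.geometry.spacing)
        )
        worst = max(worst, float(ext))
    spacing = worst / max(grid - margin_voxels, 1)
    return max(0.8, float(np.ceil(spacing * 10.0) / 10.0))


def prepare_pair(
    img: IntensityVolume,
    lab: LabelVolume,
    grid: int,
    spacing: float,
    focus_codes: tuple[int, ...] = CERVIX_CODES,
) -> Pair:
    """Resample-pad an image/label pair onto the training grid, co-centred
    on the cervix bounding box (structures outside ``focus_codes`` may be
    truncated at the FOV edge)."""
    from .volumes import resample_pad

    scale = lab.geometry.spacing / spacing
    focus = np.isin(lab.data, focus_codes)
    nz = np.nonzero(focus if focus.any() else lab.data)
    centre = np.array([(a.min() + a.max()) / 2.0 for a in nz]) * scale
    lab_g = resample_pad(
        lab, grid, spacing=spacing, center_voxel=centre, guard_codes=focus_codes
    )
    img_g = resample_pad(img, grid, spacing=spacing, center_voxel=centre)
    return img_g, lab_g


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedModel:
    """A trained parcellation network plus its config and loss trajectory.

    ``spacing`` records the isotropic voxel size (mm) the training grid
    used; inference through :func:`segment_volume` resamples new images to
    the same spacing so the network sees anatomy at the scale it learned.
    """

    net: _nn.UNet3D
    config: NetConfig
    log: pd.DataFrame
    reference_landmarks: np.ndarray | None = None
    spacing: float | None = None

    def save(self, path) -> Path:
        """Serialise weights (npz) with a JSON config snapshot alongside."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, **self.net.state_dict())
        cfg = asdict(self.config)
        cfg["channels"] = list(cfg["channels"])
        cfg["contrast_gamma_range"] = list(cfg["contrast_gamma_range"])
        meta = {"config": cfg, "spacing": self.spacing}
        if self.reference_landmarks is not None:
            meta["reference_landmarks"] = [float(v) for v in self.reference_landmarks]
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        self.log.to_csv(path.with_suffix(".log.csv"), index=False)
        return path

    @classmethod
    def load(cls, path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg_d = meta["config"]
        cfg_d["channels"] = tuple(cfg_d["channels"])
        cfg_d["contrast_gamma_range"] = tuple(cfg_d["contrast_gamma_range"])
        cfg = NetConfig(**cfg_d)
        net = _build_net(cfg)
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
            net.load_state_dict(dict(z))
        log_path = path.with_suffix(".log.csv")
        log = pd.read_csv(log_path) if log_path.exists() else pd.DataFrame()
        ref = meta.get("reference_landmarks")
        return cls(
            net,
            cfg,
            log,
            np.asarray(ref) if ref is not None else None,
            meta.get("spacing"),
        )


def _build_net(cfg: NetConfig) -> _nn.UNet3D:
    return _nn.UNet3D(
        in_channels=1,
        n_classes=cfg.n_classes,
        channels=cfg.channels,
        kernel=cfg.kernel,
        convs_per_block=cfg.convs_per_block,
        dropout=cfg.dropout,
        seed=cfg.seed,
    )


def train(
    dataset: list[Pair],
    cfg: NetConfig,
    checkpoint_dir=None,
    log_every: int = 10,
    spacing: float | None = None,
) -> TrainedModel:
    """Train the parcellation network on image/label pairs.

    All volumes must already sit on the cfg.grid^3 array (use
    :func:`cervimetry.resample_pad`).  One randomly drawn case per
    iteration (batch size 1) with on-the-fly augmentation; deterministic
    given ``cfg.seed``.
    """
    if len(dataset) < 2:
        raise ValueError("training needs at least 2 cases")
    for img, lab in dataset:
        if img.shape != (cfg.grid,) * 3 or lab.shape != (cfg.grid,) * 3:
            raise VolumeError(
                f"volume shape {img.shape} / {lab.shape} is not the configured grid "
                f"{(cfg.grid,) * 3}; resample_pad first"
            )

    ref_landmarks = None
    if cfg.histogram_match:
        ref_landmarks = intensity_landmarks(dataset[0][0])
        dataset = [(histogram_match(im, ref_landmarks), lb) for im, lb in dataset]

    net = _build_net(cfg)
    opt = _nn.AdamW(net.params(), lr=cfg.lr_init, weight_decay=cfg.weight_decay)
    master = np.random.default_rng(cfg.seed)
    case_seeds = master.integers(0, 2**31 - 1, size=cfg.iterations)
    rows = []
    for it in range(cfg.iterations):
        rng = np.random.default_rng(case_seeds[it])
        idx = int(rng.integers(len(dataset)))
        img, lab = dataset[idx]
        img, lab = augment(img, lab, cfg, seed=int(rng.integers(0, 2**31 - 1)))
        x = _standardise(img.data)[np.newaxis]
        logits = net.forward(x, train=True, rng=rng)
        loss, dlogits, parts = _nn.dice_ce_loss(
            logits, lab.data, cfg.n_classes, cfg.dice_weight, cfg.ce_weight
        )
        opt.zero_grad()
        net.backward(dlogits)
        lr = cfg.lr_at(it)
        opt.step(lr=lr)
        if it % log_every == 0 or it == cfg.iterations - 1:
            rows.append(
                {"iteration": it, "loss": loss, "ce": parts["ce"],
                 "dice_loss": parts["dice_loss"], "lr": lr, "case": idx}
            )
        if (
            checkpoint_dir is not None
            and cfg.checkpoint_every
            and (it + 1) % cfg.checkpoint_every == 0
        ):
            TrainedModel(net, cfg, pd.DataFrame(rows), ref_landmarks, spacing).save(
                Path(checkpoint_dir) / f"checkpoint_{it + 1:06d}.npz"
            )
    return TrainedModel(net, cfg, pd.DataFrame(rows), ref_landmarks, spacing)


def pseudo_label_round(
    model: TrainedModel,
    labelled: list[Pair],
    unlabelled: list[IntensityVolume],
    cfg: NetConfig | None = None,
    refine=None,
) -> TrainedModel:
    """One semi-supervised stage: pseudo-label new images, optionally refine,
    then retrain on the enlarged set (emulating the staged manual-refinement
    workflow)."""
    cfg = cfg or model.config
    pseudo: list[Pair] = []
    for img in unlabelled:
        lab = predict(model, img)
        if refine is not None:
            lab = refine(img, lab)
        pseudo.append((img, lab))
    return train(labelled + pseudo, cfg)


# ---------------------------------------------------------------------------
# inference


def predict(model: TrainedModel, img: IntensityVolume) -> LabelVolume:
    """Argmax parcellation of an image already on the model grid.

    The output label volume carries the input geometry unchanged.  Images
    on a different grid must be passed through
    :func:`segment_volume`, which resamples in and out.
    """
    grid = model.config.grid
    if img.shape != (grid,) * 3:
        raise VolumeError(
            f"image shape {img.shape} does not match the model grid {(grid,) * 3}; "
            "use segment_volume() for automatic resampling"
        )
    if model.reference_landmarks is not None:
        img = histogram_match(img, model.reference_landmarks)
    x = _standardise(img.data)[np.newaxis]
    logits = model.net.forward(x, train=False)
    codes = np.argmax(logits, axis=0).astype(np.int16)
    return LabelVolume(codes, img.geometry, dict(LABELS))


def segment_volume(model: TrainedModel, img: IntensityVolume) -> LabelVolume:
    """Segment an arbitrary-geometry image: resample-pad to the model grid,
    predict, and map the labels back to the input geometry (nearest)."""
    from .volumes import resample_pad, voxel_to_world, world_to_voxel

    grid = model.config.grid
    spacing = model.spacing or float(np.min(img.geometry.spacing))
    on_grid = resample_pad(img, grid, spacing=spacing)
    pred = predict(model, on_grid)
    # sample predicted labels at the input voxel centres (nearest neighbour)
    idx = np.indices(img.shape).reshape(3, -1).T
    world = voxel_to_world(idx, img.geometry)
    pv = np.rint(world_to_voxel(world, pred.geometry)).astype(int)
    ok = np.all((pv >= 0) & (pv < grid), axis=1)
    out = np.zeros(img.shape, dtype=np.int16).reshape(-1)
    out[ok] = pred.data[pv[ok, 0], pv[ok, 1], pv[ok, 2]]
    return LabelVolume(out.reshape(img.shape), img.geometry, dict(LABELS))


def largest_component_cleanup(lab: LabelVolume, codes=None) -> LabelVolume:
    """Keep only the largest connected component of each foreground code."""
    data = lab.data.copy()
    for code in codes or [c for c in lab.label_map if c != 0]:
        mask = lab.data == code
        if not mask.any():
            continue
        comp, n = ndimage.label(mask)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        data[mask & (comp != keep)] = 0
    return LabelVolume(data, lab.geometry, dict(lab.label_map))


# ---------------------------------------------------------------------------
# overlap metrics


def dice(a: LabelVolume, b: LabelVolume, code: int) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) for one label code; 1.0 when both empty."""
    if a.shape != b.shape:
        raise VolumeError(f"shape mismatch: {a.shape} vs {b.shape}")
    ma = a.data == code
    mb = b.data == code
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom


def dice_table(a: LabelVolume, b: LabelVolume) -> dict[str, float]:
    """Dice per foreground label plus the mean over labels present in either."""
    out = {}
    present = []
    for code, name in sorted(a.label_map.items()):
        if code == 0:
            continue
        d = dice(a, b, code)
        out[name] = d
        if (a.data == code).any() or (b.data == code).any():
            present.append(d)
    out["mean_foreground"] = float(np.mean(present)) if present else 1.0
    return out
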