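"""Synthetic multi-scale thymoma-histopathology stand-in dataset.

Real slides for this task are not publicly deposited, so this module
generates co-registered patch triplets (one tissue field rendered at 40x and
exactly area-averaged to the 20x and 10x views) with the statistical
structure the two-stage architecture assumes:

* ten patch-level pathological-information classes built from two signal
  families — coarse low-frequency layout (fibrous-septa bands, perivascular
  rings, medullary blobs) that survives 4x downsampling, and fine 4-px-block
  texture (epithelial spot size/density grades, erythrocyte/lymphocyte
  specks, dense tumor fields) that is attenuated or exactly erased by it;
* slide-level bags whose thymoma type (A, AB, B1, B1+B2, B2, B2+B3, B3, TC)
  sets the mixture of patch classes via a row-stochastic composition matrix;
  mixed types average their components.

Two class pairs are distinguishable only through one family by construction:
fibrous septa vs perivascular space share one fine-clutter distribution and
differ only in zero-mean coarse layout, while the B2 vs B3 epithelial classes
place equal per-4x4-block ink (four 1-px spots vs one 2x2 spot aligned to the
averaging blocks), so their 10x views are identical in expectation. This makes
multi-branch fusion genuinely informative and is verified by the
learnability tests.

All rendering is vectorised and driven by an explicit generator; identical
config + seed reproduce a byte-identical dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cast import PATHO_CLASSES
from .wt import THYMOMA_TYPES

N_PATHO_CLASSES = 10
N_THYMOMA_TYPES = 8

# Row-stochastic 8x10 composition: P(patch class | thymoma type).
# Columns follow PATHO_CLASSES: spindle, B1-epi, B2-epi, B3-epi, fibrous septa,
# erythrocyte, lymphocyte, perivascular space, medullary areas, tumor.
# Type A concentrates on spindle cells + tumor; B1 on B1 epithelium with a
# lymphocyte excess and medullary areas; B2 balances epithelium and
# lymphocytes; B3 is epithelium-dominant; TC is tumor-dominant; mixed types
# (AB, B1+B2, B2+B3) average their component rows.
_A = np.array([0.50, 0.00, 0.00, 0.00, 0.12, 0.05, 0.05, 0.05, 0.05, 0.18])
_B1 = np.array([0.00, 0.25, 0.00, 0.00, 0.05, 0.03, 0.40, 0.04, 0.20, 0.03])
_B2 = np.array([0.00, 0.00, 0.35, 0.00, 0.06, 0.04, 0.35, 0.12, 0.04, 0.04])
_B3 = np.array([0.00, 0.00, 0.00, 0.50, 0.15, 0.04, 0.15, 0.08, 0.03, 0.05])
_TC = np.array([0.00, 0.00, 0.00, 0.10, 0.15, 0.08, 0.05, 0.05, 0.02, 0.55])
DEFAULT_TYPE_COMPOSITION = np.stack([
    _A,
    (_A + _B1) / 2,
    _B1,
    (_B1 + _B2) / 2,
    _B2,
    (_B2 + _B3) / 2,
    _B3,
    _TC,
])


@dataclass
class SynthConfig:
    """Generator settings; defaults are the full-scale study conditions."""

    n_wsis_per_type: int = 2
    patches_per_wsi: int = 3000
    noise_sd: float = 0.05
    clutter_pairs_per_block: int = 4
    clutter_amp: float = 0.42
    jitter_frac: float = 0.3
    scene_size: int = 256
    dirichlet_concentration: float = 500.0
    train_fraction: float = 0.75
    type_composition: np.ndarray = field(
        default_factory=lambda: DEFAULT_TYPE_COMPOSITION.copy())
    seed: int = 0

    def __post_init__(self):
        self.type_composition = np.asarray(self.type_composition, dtype=np.float64)
        if self.type_composition.shape != (N_THYMOMA_TYPES, N_PATHO_CLASSES):
            raise ValueError(
                f"type_composition must be {N_THYMOMA_TYPES}x{N_PATHO_CLASSES}, "
                f"got {self.type_composition.shape}")
        sums = self.type_composition.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"type_composition rows must sum to 1, got {sums}")
        if self.patches_per_wsi < 1:
            raise ValueError("patches_per_wsi must be >= 1")
        if self.scene_size % 4:
            raise ValueError("scene_size must be divisible by 4")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["type_composition"] = self.type_composition.tolist()
        return d


@dataclass
class PatchTriplet:
    """One tissue field at three magnifications plus its patch label."""

    img10: np.ndarray   # (s/4, s/4, 3)
    img20: np.ndarray   # (s/2, s/2, 3)
    img40: np.ndarray   # (s, s, 3)
    patho_label: int
    wsi_id: str
    position: tuple


@dataclass
class WSIBag:
    wsi_id: str
    thymoma_type: int
    triplets: list
    composition: np.ndarray

    def __post_init__(self):
        self.composition = np.asarray(self.composition, dtype=np.float64)
        if abs(self.composition.sum() - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.patho_label for t in self.triplets])


# -- rendering ---------------------------------------------------------------

_BG = np.array([0.92, 0.83, 0.88])          # eosin-like pale pink
_STROMA = np.array([0.55, 0.47, 0.52])      # mid-tone stroma (coarse-pair base)
_NUCLEUS = np.array([-0.55, -0.60, -0.30])  # haematoxylin-like purple (additive)
_RED = np.array([0.05, -0.45, -0.45])
_LYMPHO = np.array([-0.50, -0.55, -0.20])
_TUMOR = np.array([-0.45, -0.50, -0.25])

# fine-texture lattice offsets inside each aligned 4x4 block
_CLASS2_OFFSETS = ((0, 2), (1, 0), (2, 3), (3, 1))   # four scattered 1-px spots
_CLASS3_OFFSET = (1, 1)                              # one 2x2 spot (same ink)


def _block_lattice(s: int, offsets, rng=None, jitter_frac: float = 0.0,
                   block: int = 4):
    """Pixel coordinates of spots on the aligned block lattice, with an
    optional random per-spot removal mask."""
    nb = s // block
    by, bx = np.meshgrid(np.arange(nb) * block, np.arange(nb) * block, indexing="ij")
    ys, xs = [], []
    for oy, ox in offsets:
        ys.append((by + oy).ravel())
        xs.append((bx + ox).ravel())
    ys = np.concatenate(ys)
    xs = np.concatenate(xs)
    if rng is not None and jitter_frac > 0:
        keep = rng.random(ys.size) >= jitter_frac
        ys, xs = ys[keep], xs[keep]
    return ys, xs


def _paint(canvas, ys, xs, color, amp=1.0):
    canvas[ys, xs] += color * amp


def _paint_2x2(canvas, ys, xs, color, amp=1.0):
    for dy in (0, 1):
        for dx in (0, 1):
            canvas[ys + dy, xs + dx] += color * amp


def _balanced_clutter(canvas, rng, s, pairs_per_block, amp):
    """Strong 1-px brightness speckle arranged as +/- pairs inside each
    aligned 4x4 block, so every block sums to zero and the 4x4 area average
    (the 10x view) erases it exactly. Shared by the coarse-pair classes."""
    if pairs_per_block == 0 or amp == 0:
        return
    nb = s // 4
    n_blocks = nb * nb
    k = 2 * pairs_per_block
    # distinct within-block offsets per block: first half +amp, second -amp
    order = np.argsort(rng.random((n_blocks, 16)), axis=1)[:, :k]
    by = (np.arange(n_blocks) // nb) * 4
    bx = (np.arange(n_blocks) % nb) * 4
    ys = by[:, None] + order // 4
    xs = bx[:, None] + order % 4
    signs = np.concatenate([np.full(pairs_per_block, 1.0),
                            np.full(pairs_per_block, -1.0)])
    canvas[ys.ravel(), xs.ravel()] += np.repeat(signs[None], n_blocks, 0).ravel()[:, None] * amp


def _zero_mean(structure: np.ndarray) -> np.ndarray:
    return structure - structure.mean()


def render_template(patho_label: int, scene_size: int = 256) -> np.ndarray:
    """Deterministic noiseless class template (no clutter, no jitter)."""
    rng = np.random.default_rng(0)
    cfg = SynthConfig(noise_sd=0.0, clutter_pairs_per_block=0, jitter_frac=0.0,
                      scene_size=scene_size)
    return render_scene(patho_label, rng, cfg)


def render_scene(patho_label: int, rng: np.random.Generator,
                 cfg: SynthConfig) -> np.ndarray:
    """Render one 40x field (scene_size x scene_size x 3, values in [0, 1]).

    Deterministic given (label, generator state, config). Unknown labels are
    rejected.
    """
    if not (isinstance(patho_label, (int, np.integer)) and 0 <= patho_label <= 9):
        raise ValueError(
            f"unknown pathological-information label {patho_label!r}; "
            f"valid labels are integers 0..9")
    s = cfg.scene_size
    canvas = np.tile(_BG, (s, s, 1)).copy()
    jf = cfg.jitter_frac

    if patho_label == 0:      # spindle epithelial: oriented 4x1 streaks
        ys, xs = _block_lattice(s, ((1, 0),), rng, jf)
        for dx in range(4):
            canvas[ys, np.minimum(xs + dx, s - 1)] += _NUCLEUS
    elif patho_label == 1:    # B1 epithelium: sparse single spots
        ys, xs = _block_lattice(s, ((1, 1),), rng, jf)
        _paint(canvas, ys, xs, _NUCLEUS)
    elif patho_label == 2:    # B2 epithelium: four scattered 1-px spots/block
        ys, xs = _block_lattice(s, _CLASS2_OFFSETS, rng, jf)
        _paint(canvas, ys, xs, _NUCLEUS)
    elif patho_label == 3:    # B3 epithelium: one 2x2 spot/block (equal ink)
        ys, xs = _block_lattice(s, (_CLASS3_OFFSET,), rng, jf)
        _paint_2x2(canvas, ys, xs, _NUCLEUS)
    elif patho_label == 4:    # fibrous septa: faint zero-mean diagonal bands
        canvas[:] = _STROMA            # shared mid-tone base of the coarse pair
        yy, xx = np.meshgrid(np.arange(s), np.arange(s), indexing="ij")
        bands = 0.005 * np.sin(2 * np.pi * (yy + xx) / (s / 4.0))
        canvas += _zero_mean(bands)[:, :, None]
        _balanced_clutter(canvas, rng, s, cfg.clutter_pairs_per_block, cfg.clutter_amp)
    elif patho_label == 5:    # erythrocyte: red specks
        ys, xs = _block_lattice(s, ((2, 2),), rng, max(jf, 0.2))
        _paint(canvas, ys, xs, _RED)
    elif patho_label == 6:    # lymphocyte: denser dark specks
        ys, xs = _block_lattice(s, ((0, 1), (2, 3)), rng, jf)
        _paint(canvas, ys, xs, _LYMPHO)
    elif patho_label == 7:    # perivascular space: faint zero-mean ring,
        canvas[:] = _STROMA            # same base and clutter as fibrous septa
        yy, xx = np.meshgrid(np.arange(s), np.arange(s), indexing="ij")
        r = np.hypot(yy - s / 2.0, xx - s / 2.0)
        ring = 0.008 * ((r > 0.24 * s) & (r < 0.36 * s)).astype(np.float64)
        canvas += _zero_mean(ring)[:, :, None]
        _balanced_clutter(canvas, rng, s, cfg.clutter_pairs_per_block, cfg.clutter_amp)
    elif patho_label == 8:    # medullary differentiated areas: large light blobs
        yy, xx = np.meshgrid(np.arange(s), np.arange(s), indexing="ij")
        blob = np.zeros((s, s))
        for cy, cx in ((0.30, 0.35), (0.70, 0.65)):
            blob += np.exp(-(((yy - cy * s) ** 2 + (xx - cx * s) ** 2)
                             / (2 * (0.12 * s) ** 2)))
        canvas += (0.12 * blob)[:, :, None]
    elif patho_label == 9:    # tumor: dense irregular dark field
        ys, xs = _block_lattice(s, ((0, 0),), rng, max(jf, 0.2))
        _paint_2x2(canvas, ys, xs, _TUMOR)
        ys, xs = _block_lattice(s, ((2, 2),), rng, max(jf, 0.2))
        _paint_2x2(canvas, ys, xs, _TUMOR)

    if cfg.noise_sd > 0:
        canvas += rng.normal(0.0, cfg.noise_sd, size=canvas.shape)
    return np.clip(canvas, 0.0, 1.0)


def area_downsample(img: np.ndarray, factor: int) -> np.ndarray:
    """Exact area-average downsampling by an integer factor (conserves the mean)."""
    h, w, c = img.shape
    if h % factor or w % factor:
        raise ValueError(f"factor {factor} does not divide image {h}x{w}")
    return img.reshape(h // factor, factor, w // factor, factor, c).mean(axis=(1, 3))


def make_triplet(scene: np.ndarray, patho_label: int, wsi_id: str = "",
                 position: tuple = (0, 0)) -> PatchTriplet:
    """Build the co-registered triplet: 40x = scene, 20x = 2x2 average,
    10x = 4x4 average."""
    scene = np.asarray(scene, dtype=np.float64)
    if scene.ndim != 3 or scene.shape[0] != scene.shape[1] or scene.shape[2] != 3:
        raise ValueError(f"scene must be (s, s, 3), got {scene.shape}")
    if scene.shape[0] % 4:
        raise ValueError("scene side must be divisible by 4")
    return PatchTriplet(
        img10=area_downsample(scene, 4),
        img20=area_downsample(scene, 2),
        img40=scene,
        patho_label=int(patho_label),
        wsi_id=wsi_id,
        position=tuple(position),
    )


def sample_composition(thymoma_type: int, cfg: SynthConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Slide composition ~ Dirichlet centred on the type's mixture row."""
    if not (isinstance(thymoma_type, (int, np.integer))
            and 0 <= thymoma_type < N_THYMOMA_TYPES):
        raise ValueError(
            f"invalid thymoma type {thymoma_type!r}; valid types are 0..7 "
            f"({', '.join(THYMOMA_TYPES)})")
    alpha = cfg.dirichlet_concentration * cfg.type_composition[thymoma_type] + 1e-3
    comp = rng.dirichlet(alpha)
    return comp / comp.sum()


def sample_patch_labels(thymoma_type: int, n: int, cfg: SynthConfig,
                        rng: np.random.Generator):
    """(composition, labels): the per-slide mixture and n class draws from it."""
    comp = sample_composition(thymoma_type, cfg, rng)
    return comp, rng.choice(N_PATHO_CLASSES, size=n, p=comp)


def generate_wsi_bag(thymoma_type: int, cfg: SynthConfig, rng: np.random.Generator,
                     wsi_id: str | None = None) -> WSIBag:
    """Generate one slide bag: sample a composition, draw patch labels, render
    the configured number of triplets."""
    comp, labels = sample_patch_labels(thymoma_type, cfg.patches_per_wsi, cfg, rng)
    if wsi_id is None:
        wsi_id = f"type{thymoma_type}_wsi{rng.integers(0, 2**31):08x}"
    grid = int(np.ceil(np.sqrt(cfg.patches_per_wsi)))
    triplets = []
    for i, lab in enumerate(labels):
        scene = render_scene(int(lab), rng, cfg)
        triplets.append(make_triplet(scene, int(lab), wsi_id, (i // grid, i % grid)))
    return WSIBag(wsi_id=wsi_id, thymoma_type=int(thymoma_type),
                  triplets=triplets, composition=comp)


def generate_dataset(cfg: SynthConfig) -> list:
    """All bags for the configured study: n_wsis_per_type slides per type."""
    rng = np.random.default_rng(cfg.seed)
    bags = []
    for t in range(N_THYMOMA_TYPES):
        for j in range(cfg.n_wsis_per_type):
            bags.append(generate_wsi_bag(t, cfg, rng, wsi_id=f"type{t}_wsi{j:03d}"))
    return bags


def assign_splits(bags: list, train_fraction: float,
                  rng: np.random.Generator) -> dict:
    """Slide-level train/test partition, stratified by type; no slide appears
    in both splits."""
    split = {}
    by_type: dict[int, list] = {}
    for bag in bags:
        by_type.setdefault(bag.thymoma_type, []).append(bag.wsi_id)
    for t, ids in sorted(by_type.items()):
        ids = sorted(ids)
        rng.shuffle(ids)
        n_train = max(1, int(round(train_fraction * len(ids))))
        if len(ids) > 1:
            n_train = min(n_train, len(ids) - 1)   # keep at least one test slide
        for i, wid in enumerate(ids):
            split[wid] = "train" if i < n_train else "test"
    return split


def write_dataset(bags: list, out_dir, cfg: SynthConfig) -> Path:
    """Write patches as PNGs and one manifest row per triplet; returns the
    manifest path. Layout: ``<out>/images/<wsi_id>/<index>_<scale>.png``."""
    from .io import write_manifest  # local import: io depends on this module's types

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 1)
    split = assign_splits(bags, cfg.train_fraction, rng)
    rows = []
    for bag in bags:
        wdir = out_dir / "images" / bag.wsi_id
        wdir.mkdir(exist_ok=True)
        for i, t in enumerate(bag.triplets):
            paths = {}
            for scale, img in (("10x", t.img10), ("20x", t.img20), ("40x", t.img40)):
                rel = Path("images") / bag.wsi_id / f"{i:05d}_{scale}.png"
                _write_png(out_dir / rel, img)
                paths[scale] = str(rel)
            rows.append({
                "wsi_id": bag.wsi_id,
                "position_row": t.position[0],
                "position_col": t.position[1],
                "path_10x": paths["10x"],
                "path_20x": paths["20x"],
                "path_40x": paths["40x"],
                "patho_label": t.patho_label,
                "thymoma_type": bag.thymoma_type,
                "split": split[bag.wsi_id],
            })
    return write_manifest(out_dir / "manifest.csv", rows, seed=cfg.seed)


def _write_png(path: Path, img: np.ndarray) -> None:
    from PIL import Image

    arr = np.clip(np.round(np.asarray(img) * 255.0), 0, 255).astype(np.uint8)
    try:
        Image.fromarray(arr).save(path)
    except OSError as exc:
        raise OSError(f"failed writing patch image {path}: {exc}") from exc


def radial_power_spectrum(img: np.ndarray, n_bins: int = 16) -> np.ndarray:
    """Radially binned mean power spectrum of the luminance channel; used to
    compare the frequency content of renders across seeds."""
    lum = np.asarray(img, dtype=np.float64).mean(axis=-1)
    lum = lum - lum.mean()
    power = np.abs(np.fft.fftshift(np.fft.fft2(lum))) ** 2
    s = lum.shape[0]
    yy, xx = np.meshgrid(np.arange(s) - s // 2, np.arange(s) - s // 2, indexing="ij")
    r = np.hypot(yy, xx)
    edges = np.linspace(0, s / 2, n_bins + 1)
    out = np.zeros(n_bins)
    for i in range(n_bins):
        mask = (r >= edges[i]) & (r < edges[i + 1])
        out[i] = power[mask].mean() if mask.any() else 0.0
    return out


def synthetic_patch_embeddings(labels, rng: np.random.Generator, dim: int = 768,
                               signal: float = 1.0, noise_sd: float = 0.1) -> np.ndarray:
    """Synthetic stand-in for trained patch-classifier embeddings.

    Emulates the one property the slide stage relies on — embeddings cluster
    by pathological class — by placing ``signal`` on the label's coordinate of
    the first ``N_PATHO_CLASSES`` dimensions and filling the rest with
    Gaussian noise. Used to exercise the slide transformer without training a
    full patch classifier first.
    """
    labels = np.asarray(labels)
    emb = rng.normal(0.0, noise_sd, size=(len(labels), dim))
    emb[np.arange(len(labels)), labels] += signal
    return emb


def bags_to_patch_arrays(bags: list, split: dict | None = None,
                         which: str | None = None) -> dict:
    """Stack bag triplets into the array dict the training loops consume."""
    img10, img20, img40, labels = [], [], [], []
    for bag in bags:
        if split is not None and which is not None and split[bag.wsi_id] != which:
            continue
        for t in bag.triplets:
            img10.append(t.img10)
            img20.append(t.img20)
            img40.append(t.img40)
            labels.append(t.patho_label)
    return {
        "img10": np.asarray(img10), "img20": np.asarray(img20),
        "img40": np.asarray(img40), "label": np.asarray(labels),
    }
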