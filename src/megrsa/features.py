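"""Image-computable feature models: GIST, HMAX, and an activation-file loader.

GIST summarizes the spatial-envelope statistics of a scene: the image is
filtered with a bank of oriented Gabor filters (8 orientations x 4 spatial
frequencies = 32 filters) and response magnitudes are averaged within a
4x4 spatial grid, giving a 512-dimensional descriptor.

HMAX is a hierarchy of alternating simple (S: convolution) and complex
(C: max-pooling) layers, S1 -> C1 -> S2 -> C2, where S2 measures Gaussian
radial-basis similarity to a fixed dictionary of C1 patches and C2 is the
global maximum per dictionary patch.

Deep-network activations are not computed here; an activation table
(one feature vector per condition per layer) can be loaded from CSV and
plugged into the same RSA machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from skimage.transform import resize

from .design import Design
from .rsa import FeatureSet

GIST_IMAGE_SIDE = 128


# --------------------------------------------------------------------------
# GIST
# --------------------------------------------------------------------------


@dataclass
class GaborBank:
    """Frequency-domain bank of analytic (single-lobe) Gabor filters.

    Each transfer function is a Gaussian lobe in polar frequency
    coordinates centered on (f_s, theta_o); taking the magnitude of the
    complex filtered image yields the local oriented energy envelope. The
    DC bin of every filter is exactly zero, so descriptors are invariant
    to constant intensity shifts.
    """

    n_orientations: int = 8
    n_scales: int = 4
    side: int = GIST_IMAGE_SIDE
    base_frequency: float = 0.32  # cycles/pixel at the finest scale
    transfer: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        fy = np.fft.fftfreq(self.side)[:, None]
        fx = np.fft.fftfreq(self.side)[None, :]
        fr = np.hypot(fx, fy)
        ang = np.arctan2(fy, fx)
        filters = []
        for s in range(self.n_scales):
            f0 = self.base_frequency / (2.0**s)
            sigma_r = f0 / 2.0
            for o in range(self.n_orientations):
                theta = np.pi * o / self.n_orientations
                dtheta = np.angle(np.exp(1j * (ang - theta)))
                h = np.exp(-0.5 * ((fr - f0) / sigma_r) ** 2) * np.exp(
                    -0.5 * (dtheta / (np.pi / self.n_orientations)) ** 2
                )
                h[0, 0] = 0.0
                filters.append(h)
        self.transfer = np.stack(filters)

    @property
    def n_filters(self) -> int:
        return self.n_orientations * self.n_scales


def gist_descriptor(image: np.ndarray, bank: GaborBank | None = None, grid: int = 4) -> np.ndarray:
    """GIST descriptor: oriented energies pooled over a ``grid x grid`` mesh.

    The image is resized to the bank's working resolution (128 default)
    before filtering. Output length = n_filters * grid**2 (512 for the
    default 32-filter bank and 4x4 grid).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square grayscale")
    if image.shape[0] < grid:
        raise ValueError(f"image side {image.shape[0]} smaller than grid {grid}")
    bank = bank or GaborBank()
    if bank.side % grid:
        raise ValueError(f"bank side {bank.side} not divisible by grid {grid}")
    if image.shape[0] != bank.side:
        image = resize(image, (bank.side, bank.side), anti_aliasing=True)
    spectrum = np.fft.fft2(image)
    responses = np.abs(np.fft.ifft2(spectrum[None, :, :] * bank.transfer))
    cell = bank.side // grid
    pooled = responses.reshape(bank.n_filters, grid, cell, grid, cell).mean(axis=(2, 4))
    return pooled.reshape(-1)


def gist_features(images, condition_ids, bank: GaborBank | None = None, grid: int = 4) -> FeatureSet:
    """GIST descriptors for a stack of per-condition images."""
    bank = bank or GaborBank()
    vecs = np.stack([gist_descriptor(img, bank, grid) for img in images])
    return FeatureSet(features=vecs, condition_ids=np.asarray(condition_ids), layer="gist")


# --------------------------------------------------------------------------
# HMAX
# --------------------------------------------------------------------------


def _gabor_kernel(size: int, theta: float, wavelength: float, aspect: float = 0.3) -> np.ndarray:
    """Zero-mean, unit-norm spatial Gabor (cosine phase)."""
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    sigma = 0.8 * wavelength / (2 * np.pi) * 4.0
    g = np.exp(-(xr**2 + aspect * yr**2) / (2 * sigma**2)) * np.cos(2 * np.pi * xr / wavelength)
    g -= g.mean()
    return g / np.linalg.norm(g)


@dataclass
class HmaxParams:
    """Configuration of the four-layer S1 -> C1 -> S2 -> C2 hierarchy.

    ``s1_sizes`` are the S1 filter sizes in pixels, consumed in adjacent
    pairs as scale bands by C1 (so len(s1_sizes)/2 bands). The S2
    dictionary holds ``n_patches`` C1 patches of side ``patch_size``
    sampled with ``dictionary_seed`` from training images (use
    :meth:`build_dictionary`); ``s2_sigma`` is the radial-basis width.
    """

    n_orientations: int = 4
    s1_sizes: tuple[int, ...] = (7, 9, 11, 13)
    c1_pool: int = 8
    c1_stride: int = 4
    n_patches: int = 100
    patch_size: int = 4
    s2_sigma: float = 1.0
    dictionary_seed: int = 11
    dictionary: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.s1_sizes) % 2:
            raise ValueError("s1_sizes must pair up into scale bands")

    @property
    def n_bands(self) -> int:
        return len(self.s1_sizes) // 2

    def kernels(self) -> list[list[np.ndarray]]:
        thetas = [np.pi * o / self.n_orientations for o in range(self.n_orientations)]
        return [[_gabor_kernel(sz, th, wavelength=sz / 2 + 1.5) for th in thetas] for sz in self.s1_sizes]

    def build_dictionary(self, training_images) -> "HmaxParams":
        """Sample the S2 patch dictionary from C1 maps of training images."""
        rng = np.random.default_rng(self.dictionary_seed)
        patches = []
        c1_maps = [_c1(_s1(np.asarray(img, float), self), self) for img in training_images]
        while len(patches) < self.n_patches:
            c1 = c1_maps[rng.integers(len(c1_maps))]
            band = rng.integers(self.n_bands)
            fmap = c1[band]  # orientations x H x W
            h, w = fmap.shape[1:]
            if h < self.patch_size or w < self.patch_size:
                raise ValueError("C1 maps smaller than patch_size; use larger images")
            r = rng.integers(h - self.patch_size + 1)
            c = rng.integers(w - self.patch_size + 1)
            patches.append(fmap[:, r : r + self.patch_size, c : c + self.patch_size].ravel())
        self.dictionary = np.stack(patches)
        return self


def _s1(image: np.ndarray, params: HmaxParams) -> list[np.ndarray]:
    """S1: rectified Gabor responses, one (orientations x H x W) map per size."""
    return [
        np.stack([np.abs(signal.fftconvolve(image, k, mode="same")) for k in kernels])
        for kernels in params.kernels()
    ]


def _c1(s1_maps: list, params: HmaxParams) -> list[np.ndarray]:
    """C1: max over paired scales, then local spatial max-pool + subsample."""
    out = []
    for band in range(params.n_bands):
        merged = np.maximum(s1_maps[2 * band], s1_maps[2 * band + 1])
        pooled = ndimage.maximum_filter(merged, size=(1, params.c1_pool, params.c1_pool))
        out.append(pooled[:, :: params.c1_stride, :: params.c1_stride])
    return out


def _s2_c2(c1_maps: list, params: HmaxParams) -> tuple[np.ndarray, np.ndarray]:
    """S2: RBF similarity to dictionary patches at all positions;
    C2: global max per patch across positions and bands."""
    if params.dictionary is None or not len(params.dictionary):
        raise ValueError("empty S2 patch dictionary; call build_dictionary first")
    ps = params.patch_size
    band_maxima = []
    for fmap in c1_maps:
        n_or, h, w = fmap.shape
        if h < ps or w < ps:
            raise ValueError("C1 map smaller than S2 patch size")
        windows = np.lib.stride_tricks.sliding_window_view(fmap, (n_or, ps, ps))[0]
        flat = windows.reshape(-1, n_or * ps * ps)
        d2 = (
            np.square(flat).sum(axis=1)[:, None]
            - 2.0 * flat @ params.dictionary.T
            + np.square(params.dictionary).sum(axis=1)[None, :]
        )
        s2 = np.exp(-d2 / (2.0 * params.s2_sigma**2))
        band_maxima.append(s2.max(axis=0))
    band_maxima = np.stack(band_maxima)  # bands x patches
    return band_maxima, band_maxima.max(axis=0)


def _grid_average(fmap: np.ndarray, grid: int = 8) -> np.ndarray:
    """Average a (channels x H x W) map over a coarse spatial grid."""
    c, h, w = fmap.shape
    rows = np.array_split(np.arange(h), grid)
    cols = np.array_split(np.arange(w), grid)
    return np.stack(
        [[fmap[:, r[:, None], c_].mean(axis=(1, 2)) for c_ in cols] for r in rows]
    ).reshape(-1)


def hmax_features(image: np.ndarray, params: HmaxParams) -> dict[str, np.ndarray]:
    """Per-layer HMAX feature vectors for one image.

    Returns a dict with keys ``s1``, ``c1``, ``s2``, ``c2``. S1 and C1 are
    summarized on an 8x8 spatial grid per channel (the raw maps are
    positionwise and would dominate any RDM with pixel alignment); S2 is
    the per-band maximum per dictionary patch; C2 the global maximum per
    patch (length = dictionary size).
    """
    image = np.asarray(image, dtype=np.float64)
    biggest = max(params.s1_sizes)
    if image.ndim != 2 or min(image.shape) < biggest:
        raise ValueError(f"image must be 2-D with side >= largest S1 filter ({biggest})")
    s1 = _s1(image, params)
    c1 = _c1(s1, params)
    s2, c2 = _s2_c2(c1, params)
    return {
        "s1": np.concatenate([_grid_average(m) for m in s1]),
        "c1": np.concatenate([_grid_average(m, grid=4) for m in c1]),
        "s2": s2.ravel(),
        "c2": c2,
    }


def hmax_feature_sets(images, condition_ids, params: HmaxParams) -> list[FeatureSet]:
    """HMAX features for a stack of images, one FeatureSet per layer."""
    per_layer: dict[str, list[np.ndarray]] = {"s1": [], "c1": [], "s2": [], "c2": []}
    for img in images:
        feats = hmax_features(img, params)
        for layer, vec in feats.items():
            per_layer[layer].append(vec)
    cids = np.asarray(condition_ids)
    return [
        FeatureSet(features=np.stack(vecs), condition_ids=cids, layer=f"hmax_{layer}")
        for layer, vecs in per_layer.items()
    ]


# --------------------------------------------------------------------------
# Externally computed activations (deep networks etc.)
# --------------------------------------------------------------------------


def save_activation_features(path, feature_sets: list) -> None:
    """Write per-layer activation tables to a long-format CSV."""
    rows = []
    for fs in feature_sets:
        for cid, vec in zip(fs.condition_ids, fs.features):
            rows.append({"condition_id": cid, "layer": fs.layer, **{f"f{i}": v for i, v in enumerate(vec)}})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_activation_features(path, layers, design: Design) -> list[FeatureSet]:
    """Load per-layer activation tables (CSV: condition_id, layer, f0..fN).

    Rows are aligned to the design's condition order regardless of file
    order. Raises if any condition is missing for a layer or if feature
    dimensionality is ragged within a layer.
    """
    table = pd.read_csv(path)
    feature_cols = [c for c in table.columns if c.startswith("f")]
    sets = []
    for layer in layers:
        sub = table[table["layer"] == layer]
        if sub.empty:
            raise ValueError(f"no rows for layer {layer!r}")
        missing = set(design.condition_ids) - set(sub["condition_id"])
        if missing:
            raise ValueError(f"layer {layer!r} missing conditions {sorted(missing)}")
        aligned = sub.set_index("condition_id").loc[design.condition_ids.to_numpy(), feature_cols]
        aligned = aligned.dropna(axis=1, how="all")  # layers may differ in dimensionality
        values = aligned.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError(f"layer {layer!r} has ragged feature dimensions")
        sets.append(FeatureSet(features=values, condition_ids=design.condition_ids.to_numpy(), layer=layer))
    return sets
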