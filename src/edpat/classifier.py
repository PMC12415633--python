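"""Learning to sort pattern images into 2DZone vs 3DLaueIntersections.

The model is a lightweight classifier built for CPU desk-scale runs: each
image is reduced to a short vector of rotation- and roll-invariant
spot-geometry descriptors (spot count, radial statistics, Friedel-symmetry
completeness, nearest-neighbour regularity, and the residual of a
best-fitting 2D lattice through the spot centroids), and a small
multi-layer perceptron is fine-tuned on those descriptors for a fixed
number of epochs with class-balanced sampling.  Because the zonal class is
rare (a few percent of snapshots), plain epoch sampling lets a model score
high accuracy by always answering 3DLaueIntersections; drawing each
training sample with probability inversely proportional to its class size
removes that failure mode.

The classifier sees only pixels — never the integer hkl ground truth — so
its validation accuracy against the geometric labels is a genuine test of
image-based sorting.
"""

from __future__ import annotations

import copy
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from PIL import Image
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .dataset import DatasetManifest
from .zonal import NON_ZONAL, ZONAL

__all__ = ["TrainConfig", "Prediction", "TrainedModel",
           "balanced_sample_weights", "split_dataset", "image_features",
           "train", "classify", "sort_dataset", "save_model", "load_model"]

log = logging.getLogger("edpat")

#: Class order used everywhere (index 0 = non-zonal, 1 = zonal).
CLASS_ORDER = [NON_ZONAL, ZONAL]

FEATURE_NAMES = [
    "log_n_spots", "r_mean", "r_max", "r_std",
    "friedel_fraction", "nn_mean", "nn_cv",
    "lattice_residual", "off_lattice_fraction", "max_off_distance",
    "off_count_log", "lattice_residual_abs", "max_off_abs",
    "node_occupancy", "neighbour_occupancy", "phase_misfit",
    "fill_fraction",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    ``image_size`` is the square size images are downscaled to before
    feature extraction; ``split_fraction`` the training share of the
    stratified split; ``balanced_sampling`` toggles inverse-class-size
    draw probabilities.  ``backbone`` currently supports only ``"mlp"``,
    the lightweight invariant-feature perceptron.
    """

    epochs: int = 10
    image_size: int = 254
    split_fraction: float = 0.8
    balanced_sampling: bool = True
    seed: int = 0
    backbone: str = "mlp"
    hidden_units: tuple[int, ...] = (24,)
    alpha: float = 0.1          # L2 penalty of the perceptron
    max_iter_per_epoch: int = 200

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be ≥ 1")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.backbone != "mlp":
            raise ValueError(
                f"unsupported backbone {self.backbone!r}: this package ships "
                f"the lightweight invariant-feature MLP only")


@dataclass(frozen=True)
class Prediction:
    """Predicted class and its confidence (the model's class score)."""

    pattern_id: str
    predicted_label: str
    confidence: float


@dataclass
class TrainedModel:
    """Scaler + perceptron bundle with its training history."""

    scaler: StandardScaler
    mlp: MLPClassifier
    config: TrainConfig
    classes: list[str] = field(default_factory=lambda: list(CLASS_ORDER))
    metrics: list[dict] = field(default_factory=list)
    best_epoch: int = 0


def balanced_sample_weights(labels: Sequence[str]) -> np.ndarray:
    """Weight each sample by the inverse of its class size.

    Under weighted sampling with replacement the expected number of draws
    per class is then equal.  A single-class input degenerates to uniform
    weights (with a warning).
    """
    labels = list(labels)
    if not labels:
        raise ValueError("cannot weight an empty label list")
    counts = pd.Series(labels).value_counts()
    if len(counts) == 1:
        warnings.warn("single-class dataset: balanced weights are uniform")
    return np.array([1.0 / counts[lab] for lab in labels])


def split_dataset(manifest: DatasetManifest, split_fraction: float = 0.8,
                  seed: int = 0) -> tuple[list[str], list[str]]:
    """Stratified, reproducible train/validation split of pattern ids.

    The total training count is round(split_fraction · N), apportioned to
    the classes by largest remainder so both classes reach validation
    whenever they can.  A class with fewer than 2 members cannot be split
    and goes entirely to training (with a warning).
    """
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must lie in (0, 1)")
    df = manifest.records
    if (df["label"] == "").any():
        raise ValueError("manifest must be fully labelled before splitting")
    rng = np.random.default_rng(seed)
    groups = {lab: sub["pattern_id"].tolist()
              for lab, sub in df.groupby("label", sort=True)}
    splittable = {lab: ids for lab, ids in groups.items() if len(ids) >= 2}
    forced_train = []
    for lab, ids in groups.items():
        if len(ids) < 2:
            warnings.warn(f"class {lab!r} has {len(ids)} member(s); "
                          f"placed in training")
            forced_train.extend(ids)
    n_total = sum(len(v) for v in splittable.values())
    n_train_total = int(round(split_fraction * (n_total + len(forced_train))))
    n_train_total = min(max(n_train_total - len(forced_train), 0), n_total)
    # largest-remainder apportionment of training slots across classes
    labs = sorted(splittable)
    quotas = np.array([len(splittable[lab]) for lab in labs]) * (
        n_train_total / n_total) if n_total else np.array([])
    base = np.floor(quotas).astype(int)
    rem = n_train_total - base.sum()
    order = np.argsort(-(quotas - base))
    for j in order[:rem]:
        base[j] += 1
    train_ids, val_ids = list(forced_train), []
    for lab, n_train in zip(labs, base):
        ids = splittable[lab]
        # keep at least one member on each side when the class allows it
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[i] for i in perm[:n_train])
        val_ids.extend(ids[i] for i in perm[n_train:])
    return train_ids, val_ids


# ---------------------------------------------------------------------------
# invariant feature extraction

def _load_image(image, image_size: int) -> np.ndarray:
    if isinstance(image, (str, Path)):
        path = Path(image)
        try:
            with Image.open(path) as im:
                pil = im.convert("L")
        except (OSError, ValueError) as exc:
            raise OSError(f"cannot read pattern image {path}: {exc}") from exc
    elif isinstance(image, Image.Image):
        pil = image.convert("L")
    else:
        pil = Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L")
    if pil.size != (image_size, image_size):
        pil = pil.resize((image_size, image_size), Image.BOX)
    return np.asarray(pil)


_RASTER = 256  # FFT grid for the lattice-coherence analysis


def _refine_peak(mag: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Sub-bin peak position by separable parabolic interpolation."""
    out = m.astype(float).copy()
    size = mag.shape[0]
    for ax in range(2):
        lo = m.copy(); lo[ax] = (m[ax] - 1) % size
        hi = m.copy(); hi[ax] = (m[ax] + 1) % size
        L, C, R = mag[tuple(lo)], mag[tuple(m)], mag[tuple(hi)]
        denom = L - 2 * C + R
        if denom < 0:
            out[ax] += 0.5 * (L - R) / denom
    return out


def _lattice_features(pts: np.ndarray,
                      nn_scale: float) -> tuple[float, float, float, float]:
    """Phase-coherence test of the spot set against its best 2D net.

    The spot centroids (relative to the image centre, in half-width units)
    are splatted bilinearly onto a fine grid and Fourier transformed: a 2D
    lattice of spots concentrates the transform into sharp peaks at the
    dual lattice.  Candidate nets are non-collinear pairs of the strongest
    peaks; the pair whose lattice phases cohere with the most spots (median
    criterion, so a minority of off-net spots cannot steer the choice) is
    the fitted net.  Each spot is scored by how far its phase at those two
    frequencies deviates from the common lattice phase (0 = exactly on the
    net, 1 = half a period off); returned are the mean, the fraction
    exceeding 0.4 and the maximum of that per-spot deviation, plus the
    *peak indexing deviation*: the magnitude-weighted misfit of all other
    strong spectral peaks to integer combinations of the fitted pair.  A
    zonal net scores ≈ 0 on everything — its whole spectrum is generated
    by the two dual basis peaks — whereas a section through several Laue
    zones shows incommensurate peaks and incoherent spots.  Peak positions
    are global averages over all spots, so these tests do not degrade on
    fine nets the way a locally fitted basis extrapolated across many
    periods would.
    """
    n = len(pts)
    if n < 3 or nn_scale <= 0:
        return 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.5
    size = _RASTER
    px = np.clip((pts + 1.0) * (size / 2.0 - 0.5), 0.0, size - 1.001)
    grid = np.zeros((size, size))
    i0 = np.floor(px).astype(int)
    f = px - i0
    for dy in (0, 1):
        for dx in (0, 1):
            w = (f[:, 0] if dx else 1 - f[:, 0]) * (f[:, 1] if dy else 1 - f[:, 1])
            np.add.at(grid, (i0[:, 1] + dy, i0[:, 0] + dx), w)
    F = np.fft.fft2(grid)
    mag = np.abs(F)
    mm = np.fft.fftfreq(size) * size  # signed bin indices
    M1, M2 = np.meshgrid(mm, mm, indexing="ij")  # rows=ky, cols=kx
    radius = np.hypot(M1, M2)
    search = np.where(radius >= 6.0, mag, 0.0)
    # top peaks (half-plane: |F| is centrosymmetric for a real grid)
    search[M1 < 0] = 0.0
    peaks, peak_mags = [], []
    for _ in range(12):
        p = np.unravel_index(np.argmax(search), mag.shape)
        if search[p] <= 0:
            break
        refined = _refine_peak(mag, np.array(p))
        peaks.append(np.array([mm[p[0]] + (refined[0] - p[0]),
                               mm[p[1]] + (refined[1] - p[1])]))
        peak_mags.append(float(mag[p]))
        suppress = np.hypot(M1 - mm[p[0]], M2 - mm[p[1]]) < 4.0
        search[suppress] = 0.0
    per_peak_dev = []
    for q in peaks:
        phase = (px[:, 1] * q[0] + px[:, 0] * q[1]) / size  # cycles
        z = np.exp(2j * np.pi * phase)
        offset = np.angle(z.mean()) / (2 * np.pi)
        wrapped = phase - offset
        per_peak_dev.append(np.abs(wrapped - np.round(wrapped)) * 2.0)
    candidates = []
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            qi, qj = peaks[i], peaks[j]
            cross = abs(qi[0] * qj[1] - qi[1] * qj[0])
            if cross <= 0.2 * np.hypot(*qi) * np.hypot(*qj):
                continue
            dev = np.maximum(per_peak_dev[i], per_peak_dev[j])
            candidates.append((float(np.median(dev)), cross, dev, i, j))
    if not candidates:
        return 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.5  # collinear row
    # among (near-)equally coherent pairs prefer the smallest q-cell: that
    # is the primitive dual basis of the coarsest real-space net, so a
    # non-primitive pair cannot spoil the peak indexing, and an over-fine
    # net cannot absorb off-net spots
    min_med = min(c[0] for c in candidates)
    _, _, dev, bi, bj = min(
        (c for c in candidates if c[0] <= min_med + 0.02),
        key=lambda c: c[1])
    # index every spot on the selected net from its global phases, then
    # refit the real-space basis and origin by least squares: the residual
    # of each spot is now limited by its own centroid noise only, not by
    # basis extrapolation error
    Q = np.vstack([peaks[bi], peaks[bj]])  # rows: dual basis in bins
    cyc = (np.column_stack([px[:, 1], px[:, 0]]) @ Q.T) / size  # cycles
    offsets = np.array([
        np.angle(np.exp(2j * np.pi * c).mean()) / (2 * np.pi)
        for c in cyc.T])
    nodes = np.round(cyc - offsets)
    design = np.column_stack([nodes, np.ones(n)])
    keep = np.ones(n, dtype=bool)
    for _ in range(2):  # second pass refits without the off-net outliers
        sol, *_ = np.linalg.lstsq(design[keep], pts[keep], rcond=None)
        dist = np.linalg.norm(pts - design @ sol, axis=1) / nn_scale
        inliers = dist <= 0.2
        if inliers.sum() >= 3:
            keep = inliers
    residual = float(np.clip(dist.mean(), 0.0, 1.0))
    # an off-net spot must stand out both relative to the net spacing and
    # in absolute detector distance (above the centroid noise floor)
    off_mask = (dist > 0.25) & (dist * nn_scale > 0.008)
    off_fraction = float(off_mask.mean())
    off_count_log = float(np.log1p(off_mask.sum()))
    max_off = float(np.clip(dist.max(), 0.0, 1.0))
    # absolute-scale residuals (units of the image half-width, ×10): the
    # centroid noise floor is absolute, so dense nets are not flattered
    dist_abs = dist * nn_scale * 10.0
    res_abs = float(np.clip(dist_abs.mean(), 0.0, 1.0))
    max_abs = float(np.clip(dist_abs.max(), 0.0, 1.0))
    # occupancy of the fitted net inside the observed region: a zonal band
    # fills its net contiguously, whereas a union of Laue layers absorbed
    # by a finer commensurate net leaves systematic holes
    occupancy = _node_occupancy(pts, nodes, sol, nn_scale)
    # local variant: fraction of each spot's four adjacent net nodes that
    # hold a spot — a contiguous zonal band keeps this high even though its
    # annular window hollows out the hull-based occupancy, while a union of
    # Laue layers absorbed by a finer net leaves alternating holes
    node_set = {(int(a), int(b)) for a, b in nodes}
    neigh = [sum(((a + da, b + db) in node_set)
                 for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1))) / 4.0
             for a, b in node_set]
    neighbour_occ = float(np.mean(neigh))
    # raw phase-domain misfit retained as a basis-free view
    return (residual, off_fraction, max_off, off_count_log, res_abs, max_abs,
            occupancy, neighbour_occ, float(dev.mean()))


def _node_occupancy(pts: np.ndarray, nodes: np.ndarray, sol: np.ndarray,
                    nn_scale: float) -> float:
    """Fraction of fitted-net nodes inside the spot hull that hold a spot."""
    from scipy.spatial import Delaunay, QhullError
    lo = nodes.min(axis=0).astype(int)
    hi = nodes.max(axis=0).astype(int)
    if (hi - lo + 1).prod() > 6400:
        return 1.0  # degenerate fine net; other descriptors flag it
    m1, m2 = np.meshgrid(np.arange(lo[0], hi[0] + 1),
                         np.arange(lo[1], hi[1] + 1), indexing="ij")
    grid_nodes = np.column_stack([m1.ravel(), m2.ravel()]).astype(float)
    pos = np.column_stack([grid_nodes, np.ones(len(grid_nodes))]) @ sol
    try:
        hull = Delaunay(pts)
    except QhullError:
        return 0.0
    inside = hull.find_simplex(pos) >= 0
    if not inside.any():
        return 1.0
    d = cKDTree(pts).query(pos[inside], k=1)[0]
    return float((d < 0.35 * nn_scale).mean())


def _split_component(prop, k: int) -> list[tuple[float, float]]:
    """Sub-pixel centroid(s) of one connected component.

    Adjacent spots in a dense net can bridge through their anti-alias
    skirts after downscaling; the component's integrated intensity reveals
    the multiplicity ``k``, and an intensity-weighted k-means on its pixels
    (seeded with the brightest mutually separated pixels) recovers the
    individual spot positions.
    """
    if k <= 1:
        return [tuple(prop.centroid_weighted)]
    coords = prop.coords.astype(float)
    # row-major order of coords matches the flattened masked intensity
    weights = prop.image_intensity[prop.image].astype(float)
    order = np.argsort(-weights)
    seeds: list[np.ndarray] = []
    for idx in order:
        c = coords[idx]
        if all(np.linalg.norm(c - s) >= 2.0 for s in seeds):
            seeds.append(c)
        if len(seeds) == k:
            break
    while len(seeds) < k:
        seeds.append(coords[order[len(seeds) % len(coords)]])
    centres = np.array(seeds)
    for _ in range(8):
        assign = np.argmin(
            ((coords[:, None, :] - centres[None, :, :]) ** 2).sum(-1), axis=1)
        for j in range(k):
            m = assign == j
            if m.any():
                centres[j] = np.average(coords[m], axis=0, weights=weights[m])
    return [tuple(c) for c in centres]


def _window_centroid(arr: np.ndarray, lab: np.ndarray, prop) -> tuple[float, float]:
    """Intensity-weighted centroid over the component plus its grey skirt.

    The downscaling anti-alias skirt below the binarization threshold
    carries most of the sub-pixel position information; including it
    (while masking out pixels claimed by other components) removes the
    threshold bias of the plain weighted centroid.
    """
    r0, c0, r1, c1 = prop.bbox
    r0, c0 = max(r0 - 2, 0), max(c0 - 2, 0)
    r1, c1 = min(r1 + 2, arr.shape[0]), min(c1 + 2, arr.shape[1])
    win = arr[r0:r1, c0:c1].astype(float)
    wlab = lab[r0:r1, c0:c1]
    win[(wlab != 0) & (wlab != prop.label)] = 0.0
    total = win.sum()
    if total <= 0:
        return prop.centroid_weighted
    ys, xs = np.mgrid[r0:r1, c0:c1]
    return float((ys * win).sum() / total), float((xs * win).sum() / total)


def image_features(image, image_size: int = 254) -> np.ndarray:
    """Rotation/roll-invariant descriptor vector of one pattern image.

    The image is downscaled to ``image_size``, binarized, and decomposed
    into connected spots; the component covering the image centre (the
    enlarged primary-beam spot) is discarded.  See :data:`FEATURE_NAMES`
    for the descriptor order.  All positional quantities are normalized by
    the image half-width, so the descriptors are resolution-independent.
    """
    arr = _load_image(image, image_size)
    binary = arr > 32
    half = image_size / 2.0
    centre = np.array([(image_size - 1) / 2.0] * 2)
    fill = float(binary.mean())
    lab = cc_label(binary, connectivity=1)
    props = regionprops(lab, intensity_image=arr)
    centre_label = lab[int(round(centre[0])), int(round(centre[1]))]
    kept = []
    for p in props:
        cy, cx = p.centroid_weighted
        if p.label == centre_label and centre_label != 0:
            continue
        if centre_label == 0 and np.hypot(cy - centre[0], cx - centre[1]) < 2.5:
            continue  # central spot faded to sub-pixel size but still nearest
        kept.append(p)
    pts = []
    if kept:
        masses = np.array([p.image_intensity.sum() for p in kept], dtype=float)
        typical = float(np.median(masses))
        for p, mass in zip(kept, masses):
            k = max(1, int(round(mass / typical))) if typical > 0 else 1
            if k == 1:
                cy, cx = _window_centroid(arr, lab, p)
                pts.append([(cx - centre[1]) / half, (centre[0] - cy) / half])
            else:
                for cy, cx in _split_component(p, k):
                    pts.append([(cx - centre[1]) / half,
                                (centre[0] - cy) / half])
    n = len(pts)
    if n == 0:
        return np.array([0.0, 0, 0, 0, 0, 0, 0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
                         0.0, 0.0, 0.5, fill])
    pts = np.asarray(pts)
    radii = np.linalg.norm(pts, axis=1)
    tree = cKDTree(pts)
    if n >= 2:
        nn = tree.query(pts, k=2)[0][:, 1]
        nn_scale = float(np.median(nn))
        nn_mean = float(nn.mean())
        nn_cv = float(nn.std() / nn.mean()) if nn.mean() > 0 else 0.0
        mates = tree.query(-pts, k=1)[0]
        friedel = float((mates < 0.25 * nn_scale + 1.5 / half).mean())
    else:
        nn_scale, nn_mean, nn_cv, friedel = 0.0, 0.0, 0.0, 0.0
    (residual, off_fraction, max_off, off_count_log, res_abs, max_abs,
     occupancy, neighbour_occ, phase_misfit) = _lattice_features(pts, nn_scale)
    return np.array([
        np.log1p(n), float(radii.mean()), float(radii.max()),
        float(radii.std()), friedel, nn_mean, nn_cv,
        residual, off_fraction, max_off, off_count_log, res_abs, max_abs,
        occupancy, neighbour_occ, phase_misfit, fill,
    ])


def _features_for(manifest: DatasetManifest, ids: Sequence[str],
                  image_size: int) -> np.ndarray:
    paths = manifest.records.set_index("pattern_id").loc[list(ids), "image_path"]
    return np.vstack([image_features(p, image_size) for p in paths])


# ---------------------------------------------------------------------------
# training and inference

def train(manifest: DatasetManifest, config: TrainConfig) -> TrainedModel:
    """Fine-tune the lightweight classifier on a labelled image dataset.

    One epoch draws one bootstrap resample of the training split (each
    sample selected with probability inversely proportional to its class
    size when ``balanced_sampling`` is on) and re-optimizes the network on
    it by warm-started L-BFGS, so the zonal minority carries half the
    effective training weight in every epoch.  After every epoch the
    validation accuracy is logged and the best checkpoint is retained,
    ties broken by the earliest epoch.
    """
    df = manifest.records
    present = sorted(df["label"].unique())
    if len(present) < 2:
        raise ValueError(f"training needs both classes, found only {present}")
    train_ids, val_ids = split_dataset(manifest, config.split_fraction,
                                       config.seed)
    by_id = df.set_index("pattern_id")["label"]
    y_train = by_id.loc[train_ids].to_numpy()
    y_val = by_id.loc[val_ids].to_numpy()
    X_train = _features_for(manifest, train_ids, config.image_size)
    X_val = _features_for(manifest, val_ids, config.image_size)
    scaler = StandardScaler().fit(X_train)
    Xt, Xv = scaler.transform(X_train), scaler.transform(X_val)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if config.balanced_sampling:
        w = balanced_sample_weights(y_train)
        p = w / w.sum()
    else:
        p = None
    mlp = MLPClassifier(hidden_layer_sizes=config.hidden_units,
                        solver="lbfgs", alpha=config.alpha,
                        max_iter=config.max_iter_per_epoch,
                        warm_start=True, random_state=config.seed)
    model = TrainedModel(scaler=scaler, mlp=mlp, config=config)
    best_acc, best_state = -1.0, None
    n = len(train_ids)
    for epoch in range(1, config.epochs + 1):
        idx = rng.choice(n, size=n, replace=True, p=p)
        for _ in range(100):  # a bootstrap must contain both classes
            if len(np.unique(y_train[idx])) == 2:
                break
            idx = rng.choice(n, size=n, replace=True, p=p)
        with warnings.catch_warnings():
            # L-BFGS stopping at the per-epoch iteration cap is expected
            from sklearn.exceptions import ConvergenceWarning
            warnings.simplefilter("ignore", ConvergenceWarning)
            mlp.fit(Xt[idx], y_train[idx])
        val_acc = float((mlp.predict(Xv) == y_val).mean())
        model.metrics.append({"epoch": epoch,
                              "train_loss": float(mlp.loss_),
                              "val_accuracy": val_acc})
        log.info("epoch %d: train loss %.4f, val accuracy %.4f",
                 epoch, mlp.loss_, val_acc)
        if val_acc > best_acc:  # strict: ties keep the earliest epoch
            best_acc = val_acc
            best_state = copy.deepcopy(mlp)
            model.best_epoch = epoch
    model.mlp = best_state
    return model


def classify(model: TrainedModel, image) -> Prediction:
    """Classify one image; deterministic for fixed weights and pixels."""
    x = image_features(image, model.config.image_size).reshape(1, -1)
    proba = model.mlp.predict_proba(model.scaler.transform(x))[0]
    k = int(np.argmax(proba))
    pid = str(image) if isinstance(image, (str, Path)) else ""
    return Prediction(pattern_id=pid,
                      predicted_label=str(model.mlp.classes_[k]),
                      confidence=float(proba[k]))


def sort_dataset(model: TrainedModel, manifest: DatasetManifest,
                 hybrid_threshold: float = 0.99) -> dict:
    """Predict every record, fill the manifest, and summarize the sort.

    The summary carries per-class counts, the confusion matrix against the
    geometric labels (omitted when the manifest is unlabelled), the
    accuracy, and the *hybrid candidates*: patterns predicted zonal with
    confidence below ``hybrid_threshold``, which in practice are near-zone
    snapshots carrying a few reflections from another Laue layer and
    deserve manual review before unit-cell determination.
    """
    df = manifest.records
    if len(df) == 0:
        raise ValueError("cannot sort an empty manifest")
    preds = [classify(model, p) for p in df["image_path"]]
    df["predicted_label"] = [p.predicted_label for p in preds]
    df["confidence"] = [p.confidence for p in preds]
    summary: dict = {
        "n_patterns": len(df),
        "predicted_counts": df["predicted_label"].value_counts().to_dict(),
        "hybrid_candidates": df.loc[
            (df["predicted_label"] == ZONAL)
            & (df["confidence"] < hybrid_threshold), "pattern_id"].tolist(),
    }
    if (df["label"] != "").all():
        cm = pd.crosstab(df["label"], df["predicted_label"],
                         dropna=False).reindex(index=CLASS_ORDER,
                                               columns=CLASS_ORDER,
                                               fill_value=0)
        summary["confusion_matrix"] = cm.to_dict()
        summary["accuracy"] = float((df["label"] == df["predicted_label"]).mean())
    return summary


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize the bundle (joblib) with a JSON sidecar of its metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump({"scaler": model.scaler, "mlp": model.mlp,
                 "config": model.config.__dict__,
                 "classes": model.classes}, path)
    sidecar = {"config": dict(model.config.__dict__,
                              hidden_units=list(model.config.hidden_units)),
               "classes": model.classes,
               "metrics": model.metrics,
               "best_epoch": model.best_epoch}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    cfg = dict(blob["config"])
    cfg["hidden_units"] = tuple(cfg["hidden_units"])
    model = TrainedModel(scaler=blob["scaler"], mlp=blob["mlp"],
                         config=TrainConfig(**cfg), classes=blob["classes"])
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        model.metrics = meta.get("metrics", [])
        model.best_epoch = meta.get("best_epoch", 0)
    return model
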