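"""MLP committee for normal bone / hemangioma / metastasis recognition.

Several multilayer perceptrons are trained with backpropagation from
distinct seeded initializations and the one with the minimal final training
error represents the committee ("best-of-committee" selection).  Averaging
of committee outputs is available as an option.

Each network uses sigmoid units throughout and a mean-squared-error
objective against one-hot targets, producing three *independent* per-class
sigmoid scores in [0, 1].  The scores are deliberately not softmax
probabilities and need not sum to 1 — e.g. an ambiguous lesion can score
high for both hemangioma and metastasis, which is diagnostically
informative.  Selection by training error risks overfitting; the held-out
error, when a validation split is supplied, is logged with a warning.

Inputs are either the ROI resampled to 32x32 normalized pixels or its
1024-bit perceptual hash (the fingerprint the separability audit already
computes).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize as sk_resize

from .arcela import arcela_score
from .caldera import CalderaResult, detect_all
from .contrast_marker import contrast_marker
from .image_io import ImageFrame, Modality, ROIBox
from .separability_audit import PHASH_BITS, phash

logger = logging.getLogger("radiomarker")

__all__ = [
    "InputMode",
    "CommitteeConfig",
    "MLP",
    "Committee",
    "CommitteeReport",
    "encode_frame",
    "train_committee",
    "classify",
]

MODEL_FORMAT_VERSION = 1
DEFAULT_CLASSES = ("norm", "hema", "mst")


class InputMode(Enum):
    PIXELS_32x32 = "PIXELS_32x32"
    PHASH_BITS = "PHASH_BITS"


@dataclass(frozen=True)
class CommitteeConfig:
    """Committee hyperparameters; all config-exposed.

    ``learning_rate`` applies to per-sample (online) backpropagation steps;
    weights initialize uniformly in [-0.5, 0.5] with per-network seed =
    ``seed + network index``.
    """

    input_mode: InputMode = InputMode.PIXELS_32x32
    hidden_layers: tuple[int, ...] = (32,)
    n_networks: int = 5
    max_epochs: int = 300
    learning_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_networks < 1:
            raise ValueError("committee needs at least one network")
        if any(w < 1 for w in self.hidden_layers):
            raise ValueError("hidden layer widths must be >= 1")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLP:
    """Fully connected sigmoid network trained by online backpropagation."""

    def __init__(self, layer_sizes: Sequence[int], seed: int) -> None:
        self.layer_sizes = list(layer_sizes)
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.weights = [
            rng.uniform(-0.5, 0.5, size=(n_in, n_out))
            for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:])
        ]
        self.biases = [
            rng.uniform(-0.5, 0.5, size=n_out) for n_out in layer_sizes[1:]
        ]
        self._rng = rng

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = np.asarray(x, dtype=np.float64)
        for w, b in zip(self.weights, self.biases):
            a = _sigmoid(a @ w + b)
        return a

    def _forward_trace(self, x: np.ndarray) -> list[np.ndarray]:
        activations = [np.asarray(x, dtype=np.float64)]
        for w, b in zip(self.weights, self.biases):
            activations.append(_sigmoid(activations[-1] @ w + b))
        return activations

    def train(
        self, X: np.ndarray, T: np.ndarray, epochs: int, learning_rate: float
    ) -> float:
        """Online backprop on MSE; returns the final-epoch training error.

        The error is the mean over samples and output units of the squared
        residual, evaluated on the full set after the last epoch.
        """
        X = np.asarray(X, dtype=np.float64)
        T = np.asarray(T, dtype=np.float64)
        n = X.shape[0]
        for _ in range(epochs):
            for i in self._rng.permutation(n):
                acts = self._forward_trace(X[i])
                # output delta for MSE + sigmoid
                delta = (acts[-1] - T[i]) * acts[-1] * (1.0 - acts[-1])
                for layer in range(len(self.weights) - 1, -1, -1):
                    a_prev = acts[layer]
                    grad_w = np.outer(a_prev, delta)
                    grad_b = delta
                    if layer > 0:
                        delta = (self.weights[layer] @ delta) * a_prev * (1.0 - a_prev)
                    self.weights[layer] -= learning_rate * grad_w
                    self.biases[layer] -= learning_rate * grad_b
        return self.error(X, T)

    def error(self, X: np.ndarray, T: np.ndarray) -> float:
        pred = self.forward(np.asarray(X, dtype=np.float64))
        return float(np.mean((pred - np.asarray(T, dtype=np.float64)) ** 2))


@dataclass
class Committee:
    """Trained committee: member networks plus the selected-best index."""

    networks: list[MLP]
    training_errors: list[float]
    best_index: int
    config: CommitteeConfig
    class_names: tuple[str, ...] = DEFAULT_CLASSES

    def scores(self, x: np.ndarray, combine: str = "best") -> np.ndarray:
        """Per-class scores from the best network or the committee mean."""
        if combine == "best":
            return self.networks[self.best_index].forward(x)
        if combine == "mean":
            return np.mean([net.forward(x) for net in self.networks], axis=0)
        raise ValueError(f"unknown combine mode {combine!r}")

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "class_names": list(self.class_names),
            "best_index": self.best_index,
            "training_errors": self.training_errors,
            "config": {
                "input_mode": self.config.input_mode.value,
                "hidden_layers": list(self.config.hidden_layers),
                "n_networks": self.config.n_networks,
                "max_epochs": self.config.max_epochs,
                "learning_rate": self.config.learning_rate,
                "seed": self.config.seed,
            },
            "networks": [
                {
                    "layer_sizes": net.layer_sizes,
                    "weights": [w.tolist() for w in net.weights],
                    "biases": [b.tolist() for b in net.biases],
                }
                for net in self.networks
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Committee":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {payload.get('format_version')}"
            )
        cfg = payload["config"]
        config = CommitteeConfig(
            input_mode=InputMode(cfg["input_mode"]),
            hidden_layers=tuple(cfg["hidden_layers"]),
            n_networks=cfg["n_networks"],
            max_epochs=cfg["max_epochs"],
            learning_rate=cfg["learning_rate"],
            seed=cfg["seed"],
        )
        networks = []
        for spec in payload["networks"]:
            net = MLP(spec["layer_sizes"], seed=0)
            net.weights = [np.array(w, dtype=np.float64) for w in spec["weights"]]
            net.biases = [np.array(b, dtype=np.float64) for b in spec["biases"]]
            networks.append(net)
        return cls(
            networks=networks,
            training_errors=list(payload["training_errors"]),
            best_index=int(payload["best_index"]),
            config=config,
            class_names=tuple(payload["class_names"]),
        )


@dataclass
class CommitteeReport:
    """Recognition output: per-class scores plus the attached markers."""

    scores: dict[str, float]
    best_network_index: int
    training_error_best: float
    markers: dict[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Encoding / training / classification
# ---------------------------------------------------------------------------


def encode_frame(frame: ImageFrame, input_mode: InputMode) -> np.ndarray:
    """Encode a frame (or cropped ROI) as the network input vector."""
    if input_mode is InputMode.PHASH_BITS:
        return phash(frame).to_vector()
    small = sk_resize(
        frame.pixels,
        (32, 32),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return (small / 255.0).ravel()


def train_committee(
    dataset: Sequence[tuple[ImageFrame, str]],
    config: CommitteeConfig | None = None,
    validation: Sequence[tuple[ImageFrame, str]] | None = None,
) -> Committee:
    """Train ``config.n_networks`` seeded MLPs; select by training error.

    The dataset should have passed (or explicitly skipped) the separability
    audit and be intensity-normalized; frames whose mean is far outside the
    normalization target only trigger a warning.  Every class needs at
    least 5 examples.
    """
    if config is None:
        config = CommitteeConfig()
    class_names = tuple(sorted({label for _, label in dataset}))
    counts = {name: sum(1 for _, lbl in dataset if lbl == name) for name in class_names}
    for name, n in counts.items():
        if n < 5:
            raise ValueError(f"class {name!r} has only {n} examples (need >= 5)")

    means = [float(frame.pixels.mean()) for frame, _ in dataset]
    if not all(40.0 <= m <= 220.0 for m in means):
        logger.warning(
            "some training frames look non-normalized (mean outside [40, 220])"
        )

    X = np.stack([encode_frame(frame, config.input_mode) for frame, _ in dataset])
    T = np.zeros((len(dataset), len(class_names)))
    for i, (_, label) in enumerate(dataset):
        T[i, class_names.index(label)] = 1.0

    networks, errors = [], []
    for k in range(config.n_networks):
        sizes = [X.shape[1], *config.hidden_layers, len(class_names)]
        net = MLP(sizes, seed=config.seed + k)
        err = net.train(X, T, epochs=config.max_epochs, learning_rate=config.learning_rate)
        networks.append(net)
        errors.append(err)
    best = int(np.argmin(errors))

    committee = Committee(
        networks=networks,
        training_errors=errors,
        best_index=best,
        config=config,
        class_names=class_names,
    )
    if validation:
        Xv = np.stack([encode_frame(f, config.input_mode) for f, _ in validation])
        Tv = np.zeros((len(validation), len(class_names)))
        for i, (_, label) in enumerate(validation):
            Tv[i, class_names.index(label)] = 1.0
        val_err = networks[best].error(Xv, Tv)
        logger.warning(
            "best-by-training-error network: training MSE %.4f, held-out MSE %.4f "
            "(training-error selection risks overfitting)",
            errors[best],
            val_err,
        )
    return committee


def classify(
    frame: ImageFrame,
    roi: ROIBox,
    committee: Committee,
    with_markers: bool = False,
    disc_roi: Optional[ROIBox] = None,
) -> CommitteeReport:
    """Score an ROI with the committee's best network.

    With ``with_markers`` the Arcela score is always attached; the caldera
    result needs a disc ROI and the contrast marker is computed only for
    T1+contrast frames — mirroring the combined recognition report (class
    scores alongside Ca% and Ar).
    """
    roi.validate(frame.shape)
    x = encode_frame(frame.crop(roi), committee.config.input_mode)
    raw = committee.scores(x)
    scores = {name: float(s) for name, s in zip(committee.class_names, raw)}

    markers: dict[str, object] = {}
    if with_markers:
        markers["arcela"] = arcela_score(frame, roi)
        if disc_roi is not None:
            markers["caldera"] = detect_all(frame, roi, disc_roi)
        if frame.modality is Modality.T1C:
            markers["contrast"] = contrast_marker(frame, roi)
    return CommitteeReport(
        scores=scores,
        best_network_index=committee.best_index,
        training_error_best=committee.training_errors[committee.best_index],
        markers=markers,
    )
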