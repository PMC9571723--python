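"""Water-color classification and representative-color voting.

The 19 pond-water categories follow the two-part coding of the Taiwanese
aquatic production and sales resume system (FA-COA): a major color
(green 001, brown 002, red 003, yellow 004, dark 005, blue 006) and a
sub color, written "MMM-SSS" (e.g. 001-002 = dark green).  Patches whose
color is too far from every category are assigned the sentinel
``unknown``.

The regulatory scheme names the categories but publishes no colorimetric
definitions, so the default palette ships hand-assigned CIE Lab
centroids consistent with the category names; it is fully
user-overridable via YAML.  The default classifier is a deterministic
nearest-centroid model in Lab space with class probabilities given by a
softmax over negative centroid distances; a ResNet-style CNN head (the
same 19-way softmax contract) is available as an optional extra for
users with a deep-learning stack and labeled field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import color_spaces
from .errors import DomainError

__all__ = [
    "ColorCode",
    "UNKNOWN",
    "WATER_COLOR_CODES",
    "PaletteConfig",
    "ClassifierOutput",
    "classify_nearest",
    "NearestCentroidWaterColorClassifier",
    "representative_color",
    "CNNSpec",
    "build_cnn",
    "train_cnn",
    "classify_cnn",
]


@dataclass(frozen=True)
class ColorCode:
    """One water-color category of the 19-code scheme."""

    major_code: str
    major_name: str
    sub_code: str
    name: str

    @property
    def full_code(self) -> str:
        return f"{self.major_code}-{self.sub_code}"

    def __str__(self) -> str:
        return self.full_code


#: Sentinel for colors outside every category's tolerance.
UNKNOWN = ColorCode("unknown", "unknown", "", "unknown")

_CODE_ROWS = [
    ("001", "Green", "001", "Blue-green"),
    ("001", "Green", "002", "Dark green"),
    ("001", "Green", "003", "Green"),
    ("001", "Green", "004", "Light green"),
    ("002", "Brown", "001", "Dark brown"),
    ("002", "Brown", "002", "Brown"),
    ("002", "Brown", "003", "Light brown"),
    ("003", "Red", "001", "Dark red"),
    ("003", "Red", "002", "Pink"),
    ("003", "Red", "003", "Light red"),
    ("003", "Red", "004", "Red"),
    ("004", "Yellow", "001", "Tawny"),
    ("004", "Yellow", "002", "Dark yellow"),
    ("004", "Yellow", "003", "Light yellow"),
    ("004", "Yellow", "004", "Yellow"),
    ("005", "Dark", "001", "Dark gray"),
    ("005", "Dark", "002", "Dark"),
    ("005", "Dark", "003", "Gray"),
    ("006", "Blue", "001", "Blue"),
]

#: The 19 water-color categories, in coding order.
WATER_COLOR_CODES = tuple(ColorCode(m, mn, s, n) for m, mn, s, n in _CODE_ROWS)

_CODE_BY_FULL = {c.full_code: c for c in WATER_COLOR_CODES}
_CODE_BY_FULL[UNKNOWN.full_code] = UNKNOWN


def code_from_string(full_code: str) -> ColorCode:
    try:
        return _CODE_BY_FULL[full_code]
    except KeyError:
        raise DomainError(f"unknown water color code {full_code!r}") from None


# Hand-assigned nominal RGB anchors for the default palette, one per code,
# chosen to match the category names (pond-water greens/browns/reds/
# yellows/grays/blue).  Converted to Lab once at import.
_DEFAULT_PALETTE_RGB = {
    "001-001": (0, 140, 140),    # blue-green
    "001-002": (25, 80, 40),     # dark green
    "001-003": (40, 130, 60),    # green
    "001-004": (130, 190, 130),  # light green
    "002-001": (70, 45, 25),     # dark brown
    "002-002": (125, 80, 45),    # brown
    "002-003": (180, 140, 100),  # light brown
    "003-001": (110, 25, 30),    # dark red
    "003-002": (230, 160, 170),  # pink
    "003-003": (220, 110, 110),  # light red
    "003-004": (190, 40, 45),    # red
    "004-001": (150, 110, 40),   # tawny (yellowish brown)
    "004-002": (160, 140, 30),   # dark yellow
    "004-003": (235, 225, 150),  # light yellow
    "004-004": (220, 195, 60),   # yellow
    "005-001": (70, 70, 70),     # dark gray
    "005-002": (30, 30, 32),     # dark
    "005-003": (150, 150, 150),  # gray
    "006-001": (50, 90, 170),    # blue
}

_DEFAULT_RADIUS = 25.0  # Lab units


@dataclass
class PaletteConfig:
    """Per-code nominal Lab centroid and acceptance radius.

    ``centroids`` maps full code -> (3,) Lab array; ``radii`` maps full
    code -> tolerance radius in Lab units beyond which a sample is
    rejected as ``unknown``.
    """

    centroids: dict = field(default_factory=dict)
    radii: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.centroids:
            self.centroids = {
                code: color_spaces.rgb_to_lab(np.asarray(rgb, dtype=float))
                for code, rgb in _DEFAULT_PALETTE_RGB.items()
            }
        self.centroids = {
            k: np.asarray(v, dtype=float) for k, v in self.centroids.items()
        }
        if set(self.centroids) != set(_CODE_BY_FULL) - {UNKNOWN.full_code}:
            raise DomainError("palette must define exactly the 19 water color codes")
        for code in self.centroids:
            self.radii.setdefault(code, _DEFAULT_RADIUS)

    @property
    def codes(self) -> tuple:
        return WATER_COLOR_CODES

    def centroid_matrix(self) -> np.ndarray:
        """(19, 3) Lab centroids in coding order."""
        return np.stack([self.centroids[c.full_code] for c in WATER_COLOR_CODES])

    def radius_vector(self) -> np.ndarray:
        return np.array([self.radii[c.full_code] for c in WATER_COLOR_CODES])

    def min_pairwise_distance(self) -> float:
        c = self.centroid_matrix()
        d = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        return float(d[~np.eye(len(c), dtype=bool)].min())

    def to_yaml(self, path) -> None:
        payload = {
            c.full_code: {
                "name": c.name,
                "lab": [float(v) for v in self.centroids[c.full_code]],
                "radius": float(self.radii[c.full_code]),
            }
            for c in WATER_COLOR_CODES
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PaletteConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            centroids={k: np.asarray(v["lab"]) for k, v in payload.items()},
            radii={k: float(v.get("radius", _DEFAULT_RADIUS)) for k, v in payload.items()},
        )


@dataclass
class ClassifierOutput:
    """Per-patch class probabilities, prediction and confidence."""

    probabilities: np.ndarray  # (19,), sums to 1
    predicted: ColorCode
    confidence: float

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (len(WATER_COLOR_CODES),):
            raise DomainError("probabilities must cover the 19 classes")
        if np.any(self.probabilities < 0) or abs(self.probabilities.sum() - 1) > 1e-6:
            raise DomainError("probabilities must be non-negative and sum to 1")

    def to_dict(self) -> dict:
        return {
            "probabilities": {
                c.full_code: float(p)
                for c, p in zip(WATER_COLOR_CODES, self.probabilities)
            },
            "predicted": self.predicted.full_code,
            "confidence": float(self.confidence),
        }


class NearestCentroidWaterColorClassifier:
    """Deterministic nearest-centroid classifier in CIE Lab space.

    The mean Lab color of a patch is compared against the 19 class
    centroids; class probabilities are the softmax of the negative Lab
    distances (unit temperature), the prediction is the nearest centroid,
    and a sample farther than that class's tolerance radius from every
    centroid is labeled ``unknown``.

    The estimator can be used unfitted from a fixed palette (the default)
    or fitted on labeled patches, in which case per-class centroids are
    the mean Lab colors of the training patches.
    """

    def __init__(self, palette: PaletteConfig | None = None):
        self.palette = palette

    def get_params(self, deep: bool = True) -> dict:
        return {"palette": self.palette}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ----------------------------------------------------------
    def _patch_lab(self, patch: np.ndarray) -> np.ndarray:
        patch = np.asarray(patch, dtype=float)
        if patch.size == 0:
            raise DomainError("patch is empty")
        if patch.ndim >= 2 and patch.shape[-1] == 3:
            rgb = patch.reshape(-1, 3).mean(axis=0)
        else:
            raise DomainError(f"expected an RGB patch, got shape {patch.shape}")
        return color_spaces.rgb_to_lab(rgb)

    def fit(self, X=None, y=None) -> "NearestCentroidWaterColorClassifier":
        """Fit centroids from labeled patches, or adopt the palette.

        ``X`` is a sequence of RGB patches and ``y`` the matching full-code
        strings; with ``X=None`` the configured (or default) palette's
        centroids are adopted unchanged.
        """
        palette = self.palette or PaletteConfig()
        if X is None:
            self.centroids_ = palette.centroid_matrix()
        else:
            y = np.asarray(y)
            known = {c.full_code for c in WATER_COLOR_CODES}
            bad = set(np.unique(y)) - known
            if bad:
                raise DomainError(f"labels outside the 19-code scheme: {sorted(bad)}")
            centroids = palette.centroid_matrix().copy()
            for i, code in enumerate(WATER_COLOR_CODES):
                sel = np.flatnonzero(y == code.full_code)
                if sel.size:
                    labs = np.stack([self._patch_lab(X[j]) for j in sel])
                    centroids[i] = labs.mean(axis=0)
            self.centroids_ = centroids
        self.radii_ = palette.radius_vector()
        self.classes_ = np.array([c.full_code for c in WATER_COLOR_CODES])
        return self

    def _check_fitted(self):
        if not hasattr(self, "centroids_"):
            self.fit()

    # -- inference --------------------------------------------------------
    def predict_output(self, patch: np.ndarray) -> ClassifierOutput:
        """Full classifier output (probabilities, code, confidence) for one patch."""
        self._check_fitted()
        lab = self._patch_lab(patch)
        dist = np.linalg.norm(self.centroids_ - lab, axis=1)
        logits = -dist
        logits -= logits.max()
        probs = np.exp(logits)
        probs /= probs.sum()
        best = int(np.argmin(dist))
        predicted = WATER_COLOR_CODES[best]
        if dist[best] > self.radii_[best]:
            predicted = UNKNOWN
        return ClassifierOutput(
            probabilities=probs, predicted=predicted, confidence=float(probs[best])
        )

    def predict(self, X) -> np.ndarray:
        """Predicted full-code strings for a sequence of patches."""
        return np.array([self.predict_output(p).predicted.full_code for p in X])

    def predict_proba(self, X) -> np.ndarray:
        return np.stack([self.predict_output(p).probabilities for p in X])

    def score(self, X, y) -> float:
        """Mean accuracy against full-code string labels."""
        return float(np.mean(self.predict(X) == np.asarray(y)))


def classify_nearest(
    patch: np.ndarray, palette: PaletteConfig | None = None
) -> ClassifierOutput:
    """One-shot nearest-centroid classification of a single RGB patch."""
    return NearestCentroidWaterColorClassifier(palette).fit().predict_output(patch)


def representative_color(outputs: list) -> ColorCode:
    """Vote the representative pond color from the selected patches.

    A code held by more than half the patches wins outright; otherwise the
    unique most frequent code wins; if the mode is tied, the code of the
    single highest-confidence patch wins (ties on confidence break to the
    lexicographically smallest full code, for determinism).
    """
    if not outputs:
        raise DomainError("at least one classifier output is required")
    codes = [o.predicted.full_code for o in outputs]
    counts: dict[str, int] = {}
    for c in codes:
        counts[c] = counts.get(c, 0) + 1
    top = max(counts.values())
    modal = sorted(c for c, k in counts.items() if k == top)
    if top > len(outputs) / 2 or len(modal) == 1:
        return _CODE_BY_FULL[modal[0]]
    contenders = [o for o in outputs if o.predicted.full_code in modal]
    best = sorted(contenders, key=lambda o: (-o.confidence, o.predicted.full_code))[0]
    return best.predicted


# ---------------------------------------------------------------------------
# Optional CNN head (requires the `cnn` extra).
# ---------------------------------------------------------------------------


@dataclass
class CNNSpec:
    """Architecture and training hyperparameters of the CNN classifier.

    The backbone is a ResNet-50-style encoder: a 7x7/stride-2 stem
    convolution, 3x3 pooling, then four residual groups of 1x1/3x3/1x1
    bottleneck blocks repeated (3, 4, 6, 3) times up to 2048 channels.
    The head is a fully connected 2048 -> 1000 -> 100 -> 19 stack with a
    softmax output.  ``depth_scale`` divides the per-group repeats for
    desk-scale runs (minimum one block per group).
    """

    input_size: int = 224
    stem_kernel: int = 7
    stem_stride: int = 2
    block_repeats: tuple = (3, 4, 6, 3)
    bottleneck_channels: tuple = (256, 512, 1024, 2048)
    head_widths: tuple = (2048, 1000, 100, 19)
    n_classes: int = 19
    dropout: float = 0.5
    batch_size: int = 32
    max_epochs: int = 200
    learning_rate: float = 1e-4
    adam_betas: tuple = (0.9, 0.999)
    adam_eps: float = 1e-8
    depth_scale: int = 1

    def __post_init__(self):
        if self.head_widths[-1] != self.n_classes:
            raise DomainError("head output width must equal the class count")
        if self.n_classes != len(WATER_COLOR_CODES):
            raise DomainError("the classifier contract is a 19-way softmax")
        if len(self.block_repeats) != 4 or len(self.bottleneck_channels) != 4:
            raise DomainError("expected four residual groups")
        if self.depth_scale < 1:
            raise DomainError("depth_scale must be >= 1")
        if not 0 <= self.dropout < 1:
            raise DomainError("dropout must be in [0, 1)")

    def scaled_repeats(self) -> tuple:
        return tuple(max(1, r // self.depth_scale) for r in self.block_repeats)


def _require_torch():
    try:
        import torch  # noqa: F401
        import torch.nn  # noqa: F401
    except ImportError as exc:  # pragma: no cover - torch is an optional extra
        raise ImportError(
            "the CNN classifier requires the optional 'cnn' extra "
            "(pip install aquacolor[cnn]); the nearest-centroid classifier "
            "is the dependency-free default"
        ) from exc
    import torch

    return torch


def build_cnn(spec: CNNSpec):  # pragma: no cover - exercised only with torch
    """Build the ResNet-style classifier model (torch required)."""
    torch = _require_torch()
    from torch import nn

    class Bottleneck(nn.Module):
        def __init__(self, in_ch, out_ch, stride=1):
            super().__init__()
            mid = out_ch // 4
            self.conv = nn.Sequential(
                nn.Conv2d(in_ch, mid, 1, bias=False),
                nn.BatchNorm2d(mid),
                nn.ReLU(inplace=True),
                nn.Conv2d(mid, mid, 3, stride=stride, padding=1, bias=False),
                nn.BatchNorm2d(mid),
                nn.ReLU(inplace=True),
                nn.Conv2d(mid, out_ch, 1, bias=False),
                nn.BatchNorm2d(out_ch),
            )
            self.short = (
                nn.Identity()
                if in_ch == out_ch and stride == 1
                else nn.Sequential(
                    nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False),
                    nn.BatchNorm2d(out_ch),
                )
            )
            self.act = nn.ReLU(inplace=True)

        def forward(self, x):
            return self.act(self.conv(x) + self.short(x))

    layers: list = [
        nn.Conv2d(3, 64, spec.stem_kernel, stride=spec.stem_stride, padding=3, bias=False),
        nn.BatchNorm2d(64),
        nn.ReLU(inplace=True),
        nn.MaxPool2d(3, stride=2, padding=1),
    ]
    in_ch = 64
    for gi, (reps, out_ch) in enumerate(
        zip(spec.scaled_repeats(), spec.bottleneck_channels)
    ):
        for b in range(reps):
            stride = 2 if (gi > 0 and b == 0) else 1
            layers.append(Bottleneck(in_ch, out_ch, stride))
            in_ch = out_ch
    layers.append(nn.AdaptiveAvgPool2d(1))
    layers.append(nn.Flatten())
    widths = spec.head_widths
    for a, b in zip(widths[:-1], widths[1:]):
        layers.append(nn.Dropout(spec.dropout))
        layers.append(nn.Linear(a, b))
        if b != widths[-1]:
            layers.append(nn.ReLU(inplace=True))
    return nn.Sequential(*layers)


def train_cnn(model, dataset, spec: CNNSpec, validation=None):  # pragma: no cover
    """Train with Adam at the configured hyperparameters; keep the epoch
    with the best validation accuracy."""
    torch = _require_torch()
    from torch import nn, optim
    from torch.utils.data import DataLoader

    loader = DataLoader(dataset, batch_size=spec.batch_size, shuffle=True)
    opt = optim.Adam(
        model.parameters(),
        lr=spec.learning_rate,
        betas=spec.adam_betas,
        eps=spec.adam_eps,
    )
    loss_fn = nn.CrossEntropyLoss()
    best_acc, best_state = -1.0, None
    history = []
    for epoch in range(spec.max_epochs):
        model.train()
        for xb, yb in loader:
            opt.zero_grad()
            loss = loss_fn(model(xb), yb)
            loss.backward()
            opt.step()
        if validation is not None:
            model.eval()
            correct = total = 0
            with torch.no_grad():
                for xb, yb in DataLoader(validation, batch_size=spec.batch_size):
                    pred = model(xb).argmax(dim=1)
                    correct += int((pred == yb).sum())
                    total += len(yb)
            acc = correct / max(total, 1)
            history.append(acc)
            if acc > best_acc:
                best_acc = acc
                best_state = {k: v.clone() for k, v in model.state_dict().items()}
    if best_state is not None:
        model.load_state_dict(best_state)
    model.validation_history_ = history
    return model


def classify_cnn(model, patch: np.ndarray) -> ClassifierOutput:  # pragma: no cover
    """Classify one RGB patch with a trained CNN (torch required)."""
    torch = _require_torch()
    x = torch.as_tensor(
        np.asarray(patch, dtype=np.float32).transpose(2, 0, 1)[None] / 255.0
    )
    model.eval()
    with torch.no_grad():
        logits = model(x)[0]
        probs = torch.softmax(logits, dim=0).numpy().astype(float)
    best = int(probs.argmax())
    predicted = WATER_COLOR_CODES[best] if probs[best] >= 0.5 else UNKNOWN
    return ClassifierOutput(
        probabilities=probs, predicted=predicted, confidence=float(probs[best])
    )
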