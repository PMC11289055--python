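"""Regression-aware augmentation: lung-and-score replacement and CutMix.

Classification-style mixing augmentations need an answer to "what is the
label of the mixed image?". For severity *regression* the two operators
here answer it exactly:

* **Combined lung and score replacement** (offline): a new training
  image takes the left half of donor A and the right half of donor B;
  its per-lung scores are copied from the matching parents, so the
  global score is ``A.left + B.right`` with no approximation. Requires
  per-lung ground truth.
* **Score-correlated CutMix** (online): a rectangle of image A is
  replaced by the same rectangle of image B, and the global label is
  the pixel-provenance-weighted average ``lambda*y_A + (1-lambda)*y_B``
  where ``lambda`` is the exact fraction of output pixels kept from A.

``lambda`` follows the standard CutMix label rule (``lambda = 1`` keeps
A untouched). The alternative reading, weighting ``y_A`` by the donor
fraction instead, is available via ``lambda_from_donor=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .rubric import ScoredImage

__all__ = [
    "CutMixSpec",
    "AugmentationRecord",
    "MultiScoreImage",
    "mix_scores",
    "lung_replace",
    "offline_augment",
    "sample_cutmix_box",
    "cutmix",
    "cutmix_image",
]


@dataclass(frozen=True)
class CutMixSpec:
    """A sampled CutMix rectangle with exact pixel accounting.

    ``box`` is a half-open ``(row0, col0, row1, col1)`` rectangle in
    0-based pixel coordinates; ``lam`` is the fraction of output pixels
    *kept from the base image*, i.e. ``1 - box_area / (height*width)``
    by integer pixel count.
    """

    box: Tuple[int, int, int, int]
    lam: float
    height: int
    width: int
    donor_id: str = ""

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.box
        if not (0 <= r0 <= r1 <= self.height and 0 <= c0 <= c1 <= self.width):
            raise ValueError(f"box {self.box} outside a {self.height}x{self.width} frame")
        total = self.height * self.width
        expected = (total - (r1 - r0) * (c1 - c0)) / total
        if abs(self.lam - expected) > 1e-12:
            raise ValueError(
                f"lam {self.lam} inconsistent with box area (expected {expected})"
            )

    @property
    def box_area(self) -> int:
        r0, c0, r1, c1 = self.box
        return (r1 - r0) * (c1 - c0)


@dataclass(frozen=True)
class AugmentationRecord:
    """Provenance of one synthetic training image."""

    output_id: str
    parent_a: str
    parent_b: str
    method: str  # "lung_replacement" | "cutmix"
    score_type: str
    left_score: Optional[float]
    right_score: Optional[float]
    global_score: float
    lam: Optional[float] = None


@dataclass
class MultiScoreImage:
    """An image annotated with per-lung scores under several rubrics;
    ``scores`` maps score type -> (left, right)."""

    image: np.ndarray
    image_id: str
    scores: Dict[str, Tuple[float, float]]

    def as_scored(self, score_type: str) -> ScoredImage:
        left, right = self.scores[score_type]
        return ScoredImage(
            image=self.image,
            left_score=left,
            right_score=right,
            global_score=left + right,
            score_type=score_type,
            image_id=self.image_id,
        )


def mix_scores(lam: float, y_a: float, y_b: float) -> float:
    """Provenance-weighted label of a mixed image: ``lam*y_a + (1-lam)*y_b``."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    return lam * float(y_a) + (1.0 - lam) * float(y_b)


def _split_col(width: int) -> int:
    # odd widths give the extra column to the right half
    return width // 2


def lung_replace(a: ScoredImage, b: ScoredImage) -> ScoredImage:
    """Compose image-left of ``a`` with image-right of ``b``, carrying scores.

    The output's left score is ``a.left_score`` and its right score is
    ``b.right_score``; the global score is their sum. Both inputs must
    carry per-lung ground truth — a global-only annotation cannot say
    what either half is worth.
    """
    if a.image.shape != b.image.shape:
        raise ValueError("images must share dimensions")
    if a.score_type != b.score_type:
        raise ValueError("images must share a score type")
    if not (a.has_per_lung_scores and b.has_per_lung_scores):
        raise ValueError(
            "lung replacement requires per-lung ground-truth scores on both images"
        )
    cut = _split_col(a.image.shape[1])
    image = np.concatenate([a.image[:, :cut], b.image[:, cut:]], axis=1)
    return ScoredImage(
        image=image,
        left_score=a.left_score,
        right_score=b.right_score,
        global_score=a.left_score + b.right_score,
        score_type=a.score_type,
        image_id=f"{a.image_id}|{b.image_id}",
    )


def _draw_partners(n: int, rng: np.random.Generator) -> np.ndarray:
    """One uniformly drawn partner j != i for each i."""
    partners = rng.integers(0, n - 1, size=n)
    partners[partners >= np.arange(n)] += 1
    return partners


def _reciprocal_partners(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random disjoint swap pairs (n even required); partner of i is its mate."""
    if n % 2:
        raise ValueError("reciprocal pairing needs an even dataset size")
    perm = rng.permutation(n)
    partners = np.empty(n, dtype=int)
    partners[perm[0::2]] = perm[1::2]
    partners[perm[1::2]] = perm[0::2]
    return partners


def offline_augment(
    dataset: Sequence,
    score_types: Sequence[str],
    seed: int,
    pairing: str = "independent",
) -> Tuple[List[ScoredImage], List[AugmentationRecord]]:
    """Offline combined lung-and-score replacement over a training set.

    For each score type, every image ``i`` is paired with one partner
    ``j != i`` (seeded; ``pairing="reciprocal"`` instead swaps disjoint
    pairs) and contributes one synthetic image, so ``N`` originals with
    ``S`` score types yield ``N * (1 + S)`` training images.

    Returns the full augmented image list (originals first, tagged with
    their first requested score type when the input is a sample list)
    and the provenance records of the synthetic images.
    """
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least two images to pair")
    if not score_types:
        raise ValueError("score_types must be non-empty")

    def view(score_type: str) -> List[ScoredImage]:
        if hasattr(dataset[0], "as_scored"):
            return [s.as_scored(score_type) for s in dataset]
        if any(img.score_type != score_type for img in dataset):
            raise ValueError(
                "ScoredImage input must match the single requested score type"
            )
        return list(dataset)

    out: List[ScoredImage] = view(score_types[0])
    records: List[AugmentationRecord] = []
    root = np.random.SeedSequence(seed)
    for st, ss in zip(score_types, root.spawn(len(score_types))):
        rng = np.random.default_rng(ss)
        images = view(st)
        if pairing == "independent":
            partners = _draw_partners(n, rng)
        elif pairing == "reciprocal":
            partners = _reciprocal_partners(n, rng)
        else:
            raise ValueError(f"unknown pairing {pairing!r}")
        for i, j in enumerate(partners):
            synth = lung_replace(images[i], images[int(j)])
            synth.image_id = f"aug-{st}-{i:05d}"
            out.append(synth)
            records.append(
                AugmentationRecord(
                    output_id=synth.image_id,
                    parent_a=images[i].image_id,
                    parent_b=images[int(j)].image_id,
                    method="lung_replacement",
                    score_type=st,
                    left_score=synth.left_score,
                    right_score=synth.right_score,
                    global_score=synth.global_score,
                )
            )
    return out, records


def sample_cutmix_box(
    height: int,
    width: int,
    area_range: Tuple[float, float] = (0.05, 0.4),
    rng: Optional[np.random.Generator] = None,
    donor_id: str = "",
    max_tries: int = 100,
) -> CutMixSpec:
    """Sample a CutMix rectangle whose area fraction lies in ``area_range``.

    The box height is drawn uniformly over the feasible rows, the width
    uniformly over the widths keeping the integer pixel area inside the
    range, and the position uniformly among valid placements. ``lam``
    is computed from the exact pixel count.
    """
    lo, hi = area_range
    if not 0.0 < lo <= hi < 1.0:
        raise ValueError("area_range must satisfy 0 < lo <= hi < 1")
    total = height * width
    if hi * total < 1.0:
        raise ValueError(f"area_range {area_range} infeasible at {height}x{width}")
    rng = np.random.default_rng() if rng is None else rng
    h_min = max(1, int(np.ceil(lo * total / width)))
    for _ in range(max_tries):
        bh = int(rng.integers(h_min, height + 1))
        w_lo = max(1, int(np.ceil(lo * total / bh)))
        w_hi = min(width, int(np.floor(hi * total / bh)))
        if w_lo > w_hi:
            continue
        bw = int(rng.integers(w_lo, w_hi + 1))
        r0 = int(rng.integers(0, height - bh + 1))
        c0 = int(rng.integers(0, width - bw + 1))
        lam = (total - bh * bw) / total
        return CutMixSpec(
            box=(r0, c0, r0 + bh, c0 + bw),
            lam=lam,
            height=height,
            width=width,
            donor_id=donor_id,
        )
    raise RuntimeError(
        f"could not sample a box with area in {area_range} at {height}x{width}"
    )


def cutmix_image(
    image_a: np.ndarray, image_b: np.ndarray, spec: CutMixSpec
) -> np.ndarray:
    """Pixels of ``image_a`` with ``spec.box`` replaced by ``image_b``."""
    if image_a.shape != image_b.shape:
        raise ValueError("images must share dimensions")
    if image_a.shape[0] != spec.height or image_a.shape[1] != spec.width:
        raise ValueError("spec was sampled for a different frame size")
    r0, c0, r1, c1 = spec.box
    out = image_a.copy()
    out[r0:r1, c0:c1] = image_b[r0:r1, c0:c1]
    return out


def cutmix(
    a: ScoredImage,
    b: ScoredImage,
    spec: CutMixSpec,
    lambda_from_donor: bool = False,
) -> ScoredImage:
    """Score-correlated CutMix of two scored images.

    The output's global score mixes the parents' global scores by pixel
    provenance; per-lung scores are undefined for the output (the box
    need not respect the midline), so they are dropped.
    """
    if a.score_type != b.score_type:
        raise ValueError("images must share a score type")
    image = cutmix_image(a.image, b.image, spec)
    lam = 1.0 - spec.lam if lambda_from_donor else spec.lam
    return ScoredImage(
        image=image,
        global_score=mix_scores(lam, a.global_score, b.global_score),
        score_type=a.score_type,
        image_id=f"{a.image_id}+{b.image_id}",
    )
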