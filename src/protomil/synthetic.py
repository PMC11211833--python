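"""Synthetic feature-bag cohorts with planted phenotype structure.

Real slide cohorts provide bags of contrastively learned patch embeddings;
here bags are drawn from a Gaussian mixture whose components play the
role of tissue phenotypes. One component is designated the *signal*
phenotype: a bag is positive iff its realized fraction of signal
instances reaches a threshold ``tau``, emulating intratumoral
heterogeneity (positive and negative cell populations coexisting in one
section). This gives ground truth for prototype recovery, classification
and interpretability tests without any slide data or pretrained
extractor.

The default conditions are desk-scale: K=4 phenotypes in d1=64 with
center separation 8x the within-phenotype spread, 200 bags of 32-128
instances, 40% positive, and positive bags carrying 15-60% signal
instances against tau=0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bags import DEFAULT_PATCH_SIZE, FeatureBag
from .errors import ParameterError

__all__ = [
    "PhenotypeBank",
    "CohortSpec",
    "Cohort",
    "generate_phenotype_bank",
    "generate_bag",
    "generate_cohort",
]

_SPLIT_FRACS = {"train": 0.6, "val": 0.2, "test": 0.2}


@dataclass
class PhenotypeBank:
    """Planted phenotype centers in feature space.

    ``means`` is a ``(K, d1)`` matrix of cluster centers whose pairwise
    distances are at least ``separation * scale``; ``signal_index`` marks
    the label-driving phenotype.
    """

    means: np.ndarray
    scale: float
    signal_index: int
    separation: float
    seed: int

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def d1(self) -> int:
        return self.means.shape[1]


@dataclass
class CohortSpec:
    """Conditions for one synthetic cohort."""

    n_bags: int = 200
    bag_size_range: tuple[int, int] = (32, 128)
    positive_fraction: float = 0.4
    signal_fraction_range: tuple[float, float] = (0.15, 0.6)
    tau: float = 0.1
    d1: int = 64
    seed: int = 0
    hard_negatives: bool = False

    def __post_init__(self):
        if self.n_bags < 10:
            raise ParameterError("n_bags must be >= 10 (splits undefined below)")
        lo, hi = self.bag_size_range
        if not (1 <= lo <= hi):
            raise ParameterError("bag_size_range must satisfy 1 <= min <= max")
        if not (0.0 < self.positive_fraction < 1.0):
            raise ParameterError("positive_fraction must lie in (0, 1)")
        slo, shi = self.signal_fraction_range
        if not (0.0 < slo <= shi <= 1.0):
            raise ParameterError("signal_fraction_range must lie in (0, 1]")
        if slo < self.tau:
            raise ParameterError(
                "signal_fraction_range.min must be >= tau so positive bags are positive"
            )


@dataclass
class Cohort:
    """Generated bags plus a label-stratified split manifest."""

    bags: list[FeatureBag]
    manifest: pd.DataFrame  # columns: bag_id, label, split, path
    bank: PhenotypeBank | None = None
    spec: CohortSpec | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {b.bag_id: b for b in self.bags}

    def bag(self, bag_id: str) -> FeatureBag:
        return self._index[bag_id]

    def split_bags(self, split: str) -> list[FeatureBag]:
        ids = self.manifest.loc[self.manifest["split"] == split, "bag_id"]
        return [self._index[i] for i in ids]


def generate_phenotype_bank(
    K: int,
    d1: int,
    separation: float = 8.0,
    scale: float = 1.0,
    seed: int = 0,
    signal_index: int = 0,
) -> PhenotypeBank:
    """Draw K well-separated phenotype centers.

    Centers are sampled as random directions on a sphere of radius
    ``separation * scale`` and rejection-checked until all pairwise
    Euclidean distances reach ``separation * scale``; the radius grows
    geometrically if the check keeps failing (low d1 / high K), so the
    procedure always terminates with the separation invariant holding.
    """
    if K < 2:
        raise ParameterError("K must be >= 2")
    if d1 < 2:
        raise ParameterError("d1 must be >= 2")
    if separation <= 0 or scale <= 0:
        raise ParameterError("separation and scale must be positive")
    rng = np.random.default_rng(seed)
    min_dist = separation * scale
    radius = min_dist
    for attempt in range(10_000):
        dirs = rng.standard_normal((K, d1))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        means = radius * dirs
        diff = means[:, None, :] - means[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        if d[np.triu_indices(K, 1)].min() >= min_dist:
            return PhenotypeBank(
                means=means,
                scale=float(scale),
                signal_index=int(signal_index),
                separation=float(separation),
                seed=seed,
            )
        if attempt % 50 == 49:
            radius *= 1.25
    raise ParameterError("could not place separated centers")  # pragma: no cover


def generate_bag(
    bank: PhenotypeBank,
    n: int,
    mixture: np.ndarray,
    seed: int,
    tau: float = 0.1,
    bag_id: str = "bag",
    patch_size: int = DEFAULT_PATCH_SIZE,
) -> FeatureBag:
    """Draw one bag of `n` instances from the phenotype mixture.

    Each instance picks phenotype k with probability ``mixture[k]`` and
    adds isotropic Gaussian noise of the bank's scale around that center.
    Coordinates are laid on a ``patch_size``-pixel grid (patch j at
    column ``j mod W``, row ``j div W`` with ``W = ceil(sqrt(n))``). The
    label is 1 iff the realized signal fraction reaches ``tau``. The
    realized per-instance phenotype indices are kept in
    ``bag.extra['phenotypes']`` as generator ground truth.
    """
    mixture = np.asarray(mixture, dtype=np.float64)
    if n < 1:
        raise ParameterError("n must be >= 1")
    if mixture.shape != (bank.K,) or (mixture < 0).any() or abs(mixture.sum() - 1.0) > 1e-9:
        raise ParameterError("mixture must be a length-K simplex vector")
    rng = np.random.default_rng(seed)
    z = rng.choice(bank.K, size=n, p=mixture)
    feats = bank.means[z] + bank.scale * rng.standard_normal((n, bank.d1))
    W = int(np.ceil(np.sqrt(n)))
    j = np.arange(n)
    coords = np.stack([(j % W) * patch_size, (j // W) * patch_size], axis=1)
    frac = float(np.mean(z == bank.signal_index))
    bag = FeatureBag(
        bag_id=bag_id,
        features=feats,
        coords=coords,
        label=int(frac >= tau),
        patch_size=patch_size,
    )
    bag.extra["phenotypes"] = z
    bag.extra["signal_fraction"] = frac
    return bag


def _mixture_for(
    rng: np.random.Generator, bank: PhenotypeBank, positive: bool, spec: CohortSpec
) -> np.ndarray:
    K, s = bank.K, bank.signal_index
    others = [k for k in range(K) if k != s]
    mix = np.zeros(K)
    if positive:
        w = rng.uniform(*spec.signal_fraction_range)
    elif spec.hard_negatives:
        w = rng.uniform(0.0, 0.8 * spec.tau)
    else:
        w = 0.0
    mix[s] = w
    bg = rng.dirichlet(np.ones(len(others)))
    mix[others] = (1.0 - w) * bg
    return mix


def generate_cohort(spec: CohortSpec, bank: PhenotypeBank) -> Cohort:
    """Generate a cohort of bags with a stratified train/val/test split.

    Exactly ``round(positive_fraction * n_bags)`` bags are positive.
    Because instance phenotypes are drawn i.i.d., a positive bag's
    realized signal fraction can occasionally dip below tau (or a hard
    negative's rise above it); such bags are redrawn with a derived seed
    so labels match the design. Deterministic given ``spec.seed``.
    """
    if bank.d1 != spec.d1:
        raise ParameterError(f"bank d1={bank.d1} does not match spec d1={spec.d1}")
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.positive_fraction * spec.n_bags))
    labels = np.array([1] * n_pos + [0] * (spec.n_bags - n_pos))
    rng.shuffle(labels)

    bags: list[FeatureBag] = []
    for i, y in enumerate(labels):
        n = int(rng.integers(spec.bag_size_range[0], spec.bag_size_range[1] + 1))
        mix = _mixture_for(rng, bank, bool(y), spec)
        for attempt in range(64):
            bag_seed = int(rng.integers(0, 2**31 - 1))
            bag = generate_bag(
                bank, n, mix, seed=bag_seed, tau=spec.tau, bag_id=f"bag{i:04d}"
            )
            if bag.label == y:
                break
        else:  # pragma: no cover - vanishingly unlikely under valid specs
            raise ParameterError(f"could not realize label {y} for bag {i}")
        bags.append(bag)

    manifest = pd.DataFrame(
        {
            "bag_id": [b.bag_id for b in bags],
            "label": [b.label for b in bags],
            "split": _stratified_split(labels, rng),
            "path": ["" for _ in bags],
        }
    )
    return Cohort(bags=bags, manifest=manifest, bank=bank, spec=spec)


def _stratified_split(labels: np.ndarray, rng: np.random.Generator) -> list[str]:
    splits = np.empty(len(labels), dtype=object)
    for y in (0, 1):
        idx = np.flatnonzero(labels == y)
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(_SPLIT_FRACS["train"] * n))
        n_val = int(round(_SPLIT_FRACS["val"] * n))
        splits[idx[:n_train]] = "train"
        splits[idx[n_train : n_train + n_val]] = "val"
        splits[idx[n_train + n_val :]] = "test"
    return list(splits)
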