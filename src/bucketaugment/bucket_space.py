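"""The augmentation search space: random buckets of transforms.

A *bucket* is an ordered list of N_op transform specs whose magnitudes are
frozen at initialization; the search space holds N_b such buckets. A
TrivialAugment-style baseline sampler (one random transform at a random
strength per sample) is provided for comparison runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .transforms3d import (
    N_BINS,
    TRANSFORM_NAMES,
    TransformSpec,
    VolumePatch,
    apply_transform,
    spec_from_bin,
)


@dataclass(frozen=True)
class Bucket:
    """An ordered set of transforms applied sequentially, each with
    probability 1."""

    index: int
    specs: tuple[TransformSpec, ...]

    def __post_init__(self) -> None:
        if len(self.specs) == 0:
            raise ValueError("a bucket must hold at least one transform")
        object.__setattr__(self, "specs", tuple(self.specs))

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "specs": [
                {"name": s.name, "bin_index": s.bin_index,
                 "magnitude": s.magnitude, "params": s.params}
                for s in self.specs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Bucket":
        specs = tuple(
            TransformSpec(name=s["name"], bin_index=s["bin_index"],
                          magnitude=s["magnitude"], params=s.get("params", {}))
            for s in d["specs"]
        )
        return cls(index=int(d["index"]), specs=specs)


@dataclass(frozen=True)
class SearchSpace:
    buckets: tuple[Bucket, ...]
    n_buckets: int
    n_ops: int
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "buckets", tuple(self.buckets))
        if len(self.buckets) != self.n_buckets:
            raise ValueError("n_buckets does not match the number of buckets")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_buckets": self.n_buckets,
                "n_ops": self.n_ops,
                "seed": self.seed,
                "buckets": [b.to_dict() for b in self.buckets],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SearchSpace":
        d = json.loads(text)
        return cls(
            buckets=tuple(Bucket.from_dict(b) for b in d["buckets"]),
            n_buckets=int(d["n_buckets"]),
            n_ops=int(d["n_ops"]),
            seed=int(d["seed"]),
        )


def init_search_space(n_buckets: int, n_ops: int, seed: int) -> SearchSpace:
    """Randomly initialize N_b buckets of N_op transforms each.

    Transform names are drawn uniformly with replacement from the ten
    supported operations, each with a uniformly drawn magnitude bin.
    Deterministic under ``seed``.
    """
    if n_buckets < 1:
        raise ValueError(f"n_buckets must be >= 1, got {n_buckets}")
    if n_ops < 1:
        raise ValueError(f"n_ops must be >= 1, got {n_ops}")
    rng = np.random.default_rng(seed)
    buckets = []
    for i in range(n_buckets):
        specs = tuple(
            spec_from_bin(TRANSFORM_NAMES[int(rng.integers(len(TRANSFORM_NAMES)))],
                          int(rng.integers(N_BINS)))
            for _ in range(n_ops)
        )
        buckets.append(Bucket(index=i, specs=specs))
    return SearchSpace(buckets=tuple(buckets), n_buckets=n_buckets,
                       n_ops=n_ops, seed=seed)


def apply_bucket(patch: VolumePatch, bucket: Bucket,
                 rng: np.random.Generator) -> VolumePatch:
    """Apply a bucket's transforms left to right, each with probability 1."""
    out = patch
    for spec in bucket.specs:
        out = apply_transform(out, spec, rng)
    return out


def sample_trivial(patch: VolumePatch, rng: np.random.Generator) -> VolumePatch:
    """TrivialAugment baseline: one uniformly drawn transform at a
    uniformly drawn strength, applied once."""
    name = TRANSFORM_NAMES[int(rng.integers(len(TRANSFORM_NAMES)))]
    spec = spec_from_bin(name, int(rng.integers(N_BINS)))
    return apply_transform(patch, spec, rng)
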