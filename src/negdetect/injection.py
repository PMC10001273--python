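"""Nested injection of not-polyp images into dataset partitions.

A detection dataset built only from polyp-containing frames misrepresents the
real clinical stream, which is dominated by frames without polyps (and with
artifacts: instruments, water jets, feces, blood, blur, near-mucosa shots).
This module augments the training/validation/test partitions with negative
(not-polyp) images at incremental percentage levels — e.g. 2%, 5%, 10%, 15%
of each partition's base image count — under two hard guarantees:

* **same partition**: each negative image belongs to exactly one partition
  type across all levels, so no negative leaks between training and test;
* **nested supersets**: the negatives present at a lower level are a subset
  of those present at any higher level of the same partition, so successive
  levels differ only by newly added images.

Counts follow ``round_half_away(p/100 * base_size)`` per partition and level.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datasets_io import DatasetManifest, GroundTruthImage
from .errors import CapacityError, ConsistencyError, ValidationError


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (unlike banker's rounding of ``round``)."""
    factor = 10.0 ** ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / factor


def injected_count(level_pct: float, base_size: int) -> int:
    """Number of negatives injected at ``level_pct`` into a partition."""
    return int(round_half_away(level_pct / 100.0 * base_size))


@dataclass
class InjectionPlan:
    """Assignment of negative images to (partition, first injection level)."""

    base_partition_sizes: dict[str, int]
    levels: list[float]
    assignment: dict[str, tuple[str, float]]  # image_id -> (partition, first_level)
    seed: int

    def negatives_at(self, partition: str, level: float) -> list[str]:
        """Negative image ids present in ``partition`` at ``level`` (sorted
        by injection order is not kept; ids are returned sorted for
        determinism of downstream consumers)."""
        return sorted(
            image_id
            for image_id, (part, first) in self.assignment.items()
            if part == partition and first <= level
        )

    def to_csv(self, path: str | Path) -> None:
        """Serialize as a CSV body preceded by a ``#``-commented YAML header."""
        header = yaml.safe_dump(
            {
                "seed": self.seed,
                "levels": list(self.levels),
                "base_partition_sizes": dict(self.base_partition_sizes),
            },
            sort_keys=True,
        )
        rows = [
            {"image_id": image_id, "partition": part, "first_level": first}
            for image_id, (part, first) in sorted(self.assignment.items())
        ]
        buf = io.StringIO()
        for line in header.splitlines():
            buf.write(f"# {line}\n")
        pd.DataFrame(rows, columns=["image_id", "partition", "first_level"]).to_csv(
            buf, index=False
        )
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_csv(cls, path: str | Path) -> "InjectionPlan":
        text = Path(path).read_text()
        header_lines, body_lines = [], []
        for line in text.splitlines():
            (header_lines if line.startswith("#") else body_lines).append(line)
        stripped = [l[2:] if l.startswith("# ") else l[1:]
                    for l in header_lines]
        meta = yaml.safe_load("\n".join(stripped)) or {}
        df = pd.read_csv(io.StringIO("\n".join(body_lines)), dtype={"image_id": str})
        assignment = {
            str(r.image_id): (str(r.partition), float(r.first_level))
            for r in df.itertuples(index=False)
        }
        return cls(
            base_partition_sizes=dict(meta.get("base_partition_sizes", {})),
            levels=[float(v) for v in meta.get("levels", [])],
            assignment=assignment,
            seed=int(meta.get("seed", 0)),
        )


@dataclass
class AugmentedPartition:
    """A partition at a given injection level: base polyp images + negatives."""

    partition: str
    level: float
    polyp_images: list[GroundTruthImage]
    negative_images: list[GroundTruthImage] = field(default_factory=list)

    @property
    def images(self) -> list[GroundTruthImage]:
        return list(self.polyp_images) + list(self.negative_images)

    def as_manifest(self, name: str | None = None) -> DatasetManifest:
        name = name or f"{self.partition}+{self.level:g}pct"
        return DatasetManifest(self.images, name=name)


def plan_injection(
    base: Mapping[str, Sequence[str]],
    negative_pool: Sequence[str],
    levels: Sequence[float],
    seed: int,
) -> InjectionPlan:
    """Assign negatives from a pool to partitions at nested levels.

    The pool is shuffled once with a seeded RNG and consumed in order,
    partition by partition, level by level — which makes the nested-superset
    and partition-exclusivity properties hold by construction and the result
    reproducible for a given seed.

    Parameters
    ----------
    base:
        Mapping partition name -> base (polyp) image ids.
    negative_pool:
        Candidate not-polyp image ids; must be unique.
    levels:
        Strictly increasing percentages in (0, 100].
    seed:
        RNG seed for the pool shuffle.
    """
    levels = [float(p) for p in levels if p != 0]
    if any(p <= 0 or p > 100 for p in levels):
        raise ValidationError("levels must lie in (0, 100]")
    if sorted(levels) != levels or len(set(levels)) != len(levels):
        raise ValidationError("levels must be strictly increasing")
    if len(set(negative_pool)) != len(negative_pool):
        raise ValidationError("negative_pool contains duplicate ids")

    sizes = {part: len(ids) for part, ids in base.items()}
    top = levels[-1] if levels else 0.0
    required = sum(injected_count(top, n) for n in sizes.values())
    if required > len(negative_pool):
        raise CapacityError(
            f"negative pool too small: need {required}, have {len(negative_pool)}"
        )

    rng = np.random.default_rng(seed)
    shuffled = [negative_pool[i] for i in rng.permutation(len(negative_pool))]

    assignment: dict[str, tuple[str, float]] = {}
    cursor = 0
    for part in sorted(sizes):  # deterministic partition order
        n_base = sizes[part]
        prev = 0
        for level in levels:
            target = injected_count(level, n_base)
            for image_id in shuffled[cursor + prev : cursor + target]:
                assignment[image_id] = (part, level)
            prev = max(prev, target)
        cursor += injected_count(top, n_base) if levels else 0

    return InjectionPlan(
        base_partition_sizes=sizes,
        levels=levels,
        assignment=assignment,
        seed=seed,
    )


def materialize_partition(
    plan: InjectionPlan,
    partition: str,
    level: float,
    manifest: DatasetManifest,
    *,
    base_image_ids: Sequence[str] | None = None,
) -> AugmentedPartition:
    """Build the augmented partition at ``level`` from a manifest.

    The base polyp images are those of ``manifest`` assigned to ``partition``
    (or the explicit ``base_image_ids``); negatives are the plan's
    assignments with ``first_level <= level``. Level ``0`` returns the base
    partition unchanged.
    """
    if level != 0 and float(level) not in plan.levels:
        raise ValidationError(f"level {level} not among planned levels {plan.levels}")
    lookup = manifest.by_id()

    if base_image_ids is None:
        polyp_images = [
            img for img in manifest.images
            if img.partition == partition and img.has_polyp
        ]
    else:
        polyp_images = []
        for image_id in base_image_ids:
            if image_id not in lookup:
                raise ConsistencyError(f"base image {image_id!r} not in manifest")
            polyp_images.append(lookup[image_id])

    negatives: list[GroundTruthImage] = []
    for image_id in plan.negatives_at(partition, float(level)):
        if image_id not in lookup:
            raise ConsistencyError(f"planned negative {image_id!r} not in manifest")
        img = lookup[image_id]
        if img.has_polyp:
            raise ConsistencyError(
                f"planned negative {image_id!r} carries truth boxes"
            )
        negatives.append(img)

    return AugmentedPartition(
        partition=partition, level=float(level),
        polyp_images=polyp_images, negative_images=negatives,
    )
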