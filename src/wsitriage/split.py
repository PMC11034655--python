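"""Lab-held-out, stratified train/validation/test splitting.

The cohort comes from up to eight staining labs.  All slides from a random
subset of labs (two by default) are set aside for testing, plus a fraction
(10% by default) of each remaining lab's slides, stratified by category and
subcategory.  Of the rest, two thirds go to training and one third to
validation, stratified by (category, subcategory, lab).  Strata with fewer
than three slides fall back to category-level stratification (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .categories import Category
from .slide_io import Manifest

__all__ = ["SplitAssignment", "split_manifest"]

logger = logging.getLogger(__name__)

SPLITS = ("train", "valid", "test")


@dataclass
class SplitAssignment:
    """Partition of a cohort into train/valid/test."""

    assignment: dict[str, str]  # slide_id -> split name
    held_out_labs: frozenset[int]
    seed: int

    def slide_ids(self, split: str) -> list[str]:
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}")
        return sorted(s for s, sp in self.assignment.items() if sp == split)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["slide_id", "split"]
        )

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def _stratum_take(n: int, fraction: float) -> int:
    """Slides to take from a stratum at the target fraction (nearest int)."""
    return int(round(n * fraction))


def split_manifest(
    manifest: Manifest,
    n_heldout_labs: int = 2,
    test_fraction: float = 0.10,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    relabel: dict[str, Category] | None = None,
) -> SplitAssignment:
    """Assign every slide of the manifest to train, valid or test.

    ``relabel`` optionally overrides manifest categories before splitting
    (mirroring post-annotation label corrections); the manifest itself is
    authoritative otherwise.  Deterministic given ``seed``.
    """
    df = manifest.to_frame()
    if relabel:
        df = df.copy()
        for sid, cat in relabel.items():
            df.loc[df["slide_id"] == sid, "category"] = cat.value
    labs = sorted(df["lab_id"].unique())
    if len(labs) < n_heldout_labs + 1:
        raise ValueError(
            f"need more than {n_heldout_labs} labs, manifest has {len(labs)}"
        )

    rng = np.random.default_rng(seed)
    held_out = frozenset(
        int(l) for l in rng.choice(labs, size=n_heldout_labs, replace=False)
    )

    assignment: dict[str, str] = {}
    for sid in df.loc[df["lab_id"].isin(held_out), "slide_id"]:
        assignment[sid] = "test"

    rest = df[~df["lab_id"].isin(held_out)]

    def strata(frame: pd.DataFrame, keys: list[str]):
        """Yield stratum frames, falling back to category for tiny strata."""
        groups = dict(tuple(frame.groupby(keys, sort=True)))
        small_idx = []
        for key, g in groups.items():
            if len(g) < 3 and len(keys) > 1:
                logger.info("stratum %s has %d slides; falling back", key, len(g))
                small_idx.append(g.index)
            else:
                yield g
        if small_idx:
            fallback = frame.loc[np.concatenate([i.values for i in small_idx])]
            yield from dict(tuple(fallback.groupby("category", sort=True))).values()

    # Test slice of the remaining labs, stratified by (category, subcategory).
    remaining_parts = []
    for g in strata(rest, ["category", "subcategory"]):
        ids = sorted(g["slide_id"])
        rng.shuffle(ids)
        n_test = _stratum_take(len(ids), test_fraction)
        for sid in ids[:n_test]:
            assignment[sid] = "test"
        remaining_parts.append(g[~g["slide_id"].isin(ids[:n_test])])
    trainval = pd.concat(remaining_parts, ignore_index=True)

    # Train/valid, stratified by (category, subcategory, lab).
    for g in strata(trainval, ["category", "subcategory", "lab_id"]):
        ids = sorted(g["slide_id"])
        rng.shuffle(ids)
        n_train = _stratum_take(len(ids), train_fraction)
        for sid in ids[:n_train]:
            assignment[sid] = "train"
        for sid in ids[n_train:]:
            assignment[sid] = "valid"

    assert set(assignment) == set(df["slide_id"])
    return SplitAssignment(assignment=assignment, held_out_labs=held_out, seed=seed)
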