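"""Experimental schedules: field placement and visual-search Latin square.

Field experiment: ``n_blocks`` replicate blocks, each containing every
selected target exactly once, assigned to random tree slots and pinned at
uniform-random coordinates within a permitted placement rectangle.

Search experiment: n participants x n targets x n backgrounds.  Participant
``p`` sees target ``i`` on background ``(i + p) mod n`` — a cyclic pairing
that covers all n^2 (target, background) combinations exactly once while
giving each participant every target and every background once.  Trial
order within a participant follows a Williams balanced Latin square, so
each target also appears in each serial position exactly once across
participants (and first-order carryover is balanced).  The construction
requires an even n.  Practice trials are prepended and flagged; they reuse
random stimuli and are excluded from all balance guarantees.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import Target
from .typicality import TreatmentSelection

__all__ = [
    "PlacementError",
    "build_field_schedule",
    "williams_square",
    "build_search_schedule",
    "compose_stimulus",
    "DEFAULT_N_PRACTICE",
]

DEFAULT_N_PRACTICE = 10  # practice trials per participant


class PlacementError(ValueError):
    """Target placement violates the forbidden (extraction) region."""


def build_field_schedule(
    selection: TreatmentSelection,
    n_blocks: int = 10,
    seed: int = 0,
    region: tuple[int, int] = (1500, 1200),
) -> pd.DataFrame:
    """Randomized placement of every selected target in every block.

    Returns one row per (block, target): block (1-based), tree slot within
    the block, target provenance, treatment label, and uniform-random pin
    coordinates inside ``region`` (height, width).
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    targets = selection.all_targets()
    label = selection.treatment_of()
    rows = []
    for block in range(1, n_blocks + 1):
        order = rng.permutation(len(targets))
        for slot, idx in enumerate(order):
            t = targets[idx]
            rows.append({
                "block": block,
                "slot": slot,
                "tree_id": t[0],
                "patch_id": t[1],
                "treatment": label[t],
                "coord_row": float(rng.uniform(0, region[0])),
                "coord_col": float(rng.uniform(0, region[1])),
            })
    return pd.DataFrame(rows)


def williams_square(n: int) -> np.ndarray:
    """Williams balanced Latin square for even n (rows = sequences).

    Row 0 is the zig-zag sequence 0, 1, n-1, 2, n-2, ...; row r adds r
    modulo n.  Every symbol occurs once per row and once per column, and
    each ordered pair of symbols is adjacent exactly once over all rows.
    """
    if n < 2 or n % 2:
        raise ValueError("the Williams order-balancing construction needs an even n >= 2")
    base = np.empty(n, dtype=int)
    base[0::2] = np.arange((n + 1) // 2)
    base[1::2] = n - 1 - np.arange(n // 2)
    return (base[None, :] + np.arange(n)[:, None]) % n


def build_search_schedule(
    n: int = 48,
    seed: int = 0,
    n_practice: int = DEFAULT_N_PRACTICE,
) -> pd.DataFrame:
    """Participant x trial schedule covering all n^2 stimuli exactly once.

    Columns: participant (1..n), trial (1..n_practice+n), target, background
    (0-based ids), is_practice.  Test trials satisfy: each participant sees
    every target and every background exactly once; over participants every
    (target, background) pair occurs exactly once and every target occupies
    every trial position exactly once.
    """
    order = williams_square(n)
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n):
        for j in range(n_practice):
            rows.append({
                "participant": p + 1,
                "trial": j + 1,
                "target": int(rng.integers(n)),
                "background": int(rng.integers(n)),
                "is_practice": True,
            })
        for pos in range(n):
            target = int(order[p, pos])
            rows.append({
                "participant": p + 1,
                "trial": n_practice + pos + 1,
                "target": target,
                "background": (target + p) % n,
                "is_practice": False,
            })
    return pd.DataFrame(rows)


def compose_stimulus(
    background: np.ndarray,
    target: Target,
    coordinate: tuple[int, int],
    forbidden_region: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Alpha-blend a triangular target onto a background image.

    ``coordinate`` is the (row, col) of the target's top-left corner;
    ``forbidden_region`` is the half-open (row0, row1, col0, col1) box the
    target was extracted from, which its bounding box must not intersect
    (a prey item is never replaced at its own extraction site).
    """
    th, tw = target.mask.shape
    r, c = coordinate
    h, w = background.shape[:2]
    if r < 0 or c < 0 or r + th > h or c + tw > w:
        raise ValueError(f"target {th}x{tw} at {coordinate} exceeds background {h}x{w}")
    if forbidden_region is not None:
        fr0, fr1, fc0, fc1 = forbidden_region
        if r < fr1 and r + th > fr0 and c < fc1 and c + tw > fc0:
            raise PlacementError(
                f"placement at {coordinate} overlaps the extraction region {forbidden_region}"
            )
    out = background.copy()
    block = out[r: r + th, c: c + tw]
    block[target.mask] = target.pixels[target.mask]
    return out
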