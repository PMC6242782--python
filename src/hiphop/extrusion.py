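"""Loop-extrusion kinetics.

A fixed pool of extruders (cohesin-like factors) bind the chromatin chain as
a spring across a short initial span, enlarge the span stepwise
(i,i+2 → i-1,i+3 → i-2,i+4 ...), and unbind stochastically.  Each side moves
independently and is blocked by the polymer ends, by beads occupied by other
extruders (extruders cannot pass each other), and halts permanently — while
bound — at a realized CTCF anchor whose motif orientation opposes the
direction of motion.  The leftward-moving side halts at ``forward`` (or
``both``) anchors and the rightward side at ``reverse`` (or ``both``)
anchors, so persistent loops form only between convergent anchor pairs.
Unbinding is unaffected by halting.

Extrusion moves occur at regular intervals set by the extrusion speed
``kex`` (bp/τLJ): one move enlarges the loop by two beads, so the interval
is ``2·resolution/kex``.  Binding and unbinding are Poisson events with
rates ``kon`` and ``koff``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import AnchorSite

__all__ = ["Extruders", "le_update", "make_halting_arrays"]


@dataclass
class Extruders:
    """State of the fixed extruder pool."""

    n_beads: int
    left: np.ndarray          # int, -1 when unbound
    right: np.ndarray
    bound: np.ndarray         # bool
    halted_left: np.ndarray   # bool
    halted_right: np.ndarray
    time_to_move: np.ndarray  # τLJ until the next extrusion move
    init_gap: int = 2         # 2, or 3 in heteromorphic mode

    @classmethod
    def empty(cls, n_le: int, n_beads: int, init_gap: int = 2) -> "Extruders":
        return cls(
            n_beads=n_beads,
            left=np.full(n_le, -1, dtype=np.int64),
            right=np.full(n_le, -1, dtype=np.int64),
            bound=np.zeros(n_le, dtype=bool),
            halted_left=np.zeros(n_le, dtype=bool),
            halted_right=np.zeros(n_le, dtype=bool),
            time_to_move=np.zeros(n_le, dtype=float),
            init_gap=init_gap,
        )

    @property
    def n_le(self) -> int:
        return len(self.left)

    def occupied(self) -> set[int]:
        occ: set[int] = set()
        for k in range(self.n_le):
            if self.bound[k]:
                occ.add(int(self.left[k]))
                occ.add(int(self.right[k]))
        return occ

    def spans(self) -> list[tuple[int, int]]:
        return [(int(self.left[k]), int(self.right[k]))
                for k in range(self.n_le) if self.bound[k]]

    def spring_pairs(self) -> np.ndarray:
        """(m, 2) bead-index pairs of currently bound extruder springs."""
        m = self.bound.sum()
        out = np.empty((m, 2), dtype=np.int64)
        j = 0
        for k in range(self.n_le):
            if self.bound[k]:
                out[j, 0] = self.left[k]
                out[j, 1] = self.right[k]
                j += 1
        return out

    def check_invariants(self) -> None:
        """Spans must satisfy left < right and be nested or disjoint."""
        spans = self.spans()
        for l, r in spans:
            if not 0 <= l < r < self.n_beads:
                raise AssertionError(f"bad span ({l}, {r})")
        for a in range(len(spans)):
            for b in range(a + 1, len(spans)):
                l1, r1 = spans[a]
                l2, r2 = spans[b]
                nested = (l1 < l2 and r2 < r1) or (l2 < l1 and r1 < r2)
                disjoint = r1 < l2 or r2 < l1
                if not (nested or disjoint):
                    raise AssertionError(f"interleaved spans {spans[a]} {spans[b]}")


def make_halting_arrays(anchors: list[AnchorSite], n_beads: int):
    """Boolean per-bead arrays: halts the left-moving / right-moving side."""
    halt_left = np.zeros(n_beads, dtype=bool)   # forward or both
    halt_right = np.zeros(n_beads, dtype=bool)  # reverse or both
    for a in anchors:
        if a.orientation in ("forward", "both"):
            halt_left[a.bead_index] = True
        if a.orientation in ("reverse", "both"):
            halt_right[a.bead_index] = True
    return halt_left, halt_right


def _try_bind(ex: Extruders, k: int, move_interval: float,
              rng: np.random.Generator, max_tries: int = 20) -> None:
    gap = ex.init_gap
    if ex.n_beads <= gap:
        return
    occ = ex.occupied()
    for _ in range(max_tries):
        i = int(rng.integers(0, ex.n_beads - gap))
        if all(b not in occ for b in range(i, i + gap + 1)):
            ex.left[k] = i
            ex.right[k] = i + gap
            ex.bound[k] = True
            ex.halted_left[k] = False
            ex.halted_right[k] = False
            ex.time_to_move[k] = move_interval
            return
    # no free span found this window; remain unbound


def le_update(ex: Extruders, params, halt_left: np.ndarray,
              halt_right: np.ndarray, dt_window: float,
              rng: np.random.Generator) -> Extruders:
    """Advance extruder kinetics by ``dt_window`` τLJ (in place).

    Order per window: unbinding, extrusion moves (in random extruder order),
    then binding of free extruders.
    """
    n_le = ex.n_le
    move_interval = 2.0 * params.resolution / params.kex
    p_off = 1.0 - np.exp(-params.koff * dt_window)
    p_on = 1.0 - np.exp(-params.kon * dt_window)

    # unbinding (unaffected by halting)
    for k in range(n_le):
        if ex.bound[k] and rng.random() < p_off:
            ex.bound[k] = False
            ex.left[k] = -1
            ex.right[k] = -1
            ex.halted_left[k] = False
            ex.halted_right[k] = False

    # extrusion moves at regular intervals
    order = rng.permutation(n_le)
    for k in order:
        if not ex.bound[k]:
            continue
        ex.time_to_move[k] -= dt_window
        while ex.time_to_move[k] <= 0.0:
            occ = ex.occupied()
            l = int(ex.left[k])
            r = int(ex.right[k])
            # left side moves toward smaller indices
            if not ex.halted_left[k]:
                if halt_left[l]:
                    ex.halted_left[k] = True
                elif l - 1 >= 0 and (l - 1) not in occ:
                    ex.left[k] = l - 1
            # right side moves toward larger indices
            if not ex.halted_right[k]:
                if halt_right[r]:
                    ex.halted_right[k] = True
                elif r + 1 < ex.n_beads and (r + 1) not in occ:
                    ex.right[k] = r + 1
            ex.time_to_move[k] += move_interval

    # binding of free extruders (fixed pool size)
    for k in range(n_le):
        if not ex.bound[k] and rng.random() < p_on:
            _try_bind(ex, k, move_interval, rng)

    return ex
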