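"""Bidirectional subset search with lock constraints.

A greedy forward search grows a set from empty (adding items in descending
priority when the score improves) while a greedy backward search shrinks a
set from the full pool (removing items in ascending priority when the score
does not worsen).  Three rules connect them:

1. items added by the forward search can never be removed,
2. items removed by the backward search can never be added,
3. the search stops when both searches hold the same set.

The forward set ``F`` is therefore always a subset of the backward set
``B``; rule 3 fires when they meet.  If neither search can move and the two
sets still disagree, the better-scoring of the two endpoints is returned
(ties prefer the smaller set, then lexicographic order).  Scores are
minimised and cached, so an item subset is never evaluated twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable

Score = float
Evaluate = Callable[[frozenset], Score]

_TOL = 1e-12


@dataclass
class SearchState:
    """Lock bookkeeping for one bidirectional search."""

    current: set = field(default_factory=set)  # backward search's set B
    forward_locked: set = field(default_factory=set)  # F: added by forward search
    backward_locked: set = field(default_factory=set)  # removed by backward search
    passes: int = 0
    cache: dict = field(default_factory=dict)

    def check_invariants(self) -> None:
        assert not (self.forward_locked & self.backward_locked), "an item is both forward- and backward-locked"
        assert self.forward_locked <= self.current, "forward-locked item missing from the candidate set"
        assert not (self.current & self.backward_locked), "backward-locked item present in the candidate set"


def _subset_key(items: frozenset) -> tuple:
    return tuple(sorted(map(str, items)))


def bidirectional_search(
    items: Iterable[Hashable],
    priority: dict,
    evaluate: Evaluate,
    max_passes: int | None = None,
) -> tuple[frozenset, list[dict], SearchState]:
    """Run the locked forward/backward search over ``items``.

    ``priority`` orders candidates within a pass (higher = added earlier,
    removed later); ``evaluate`` maps a frozenset of items to a score to
    minimise and may return ``inf`` for infeasible subsets (e.g. empty).
    Returns the chosen subset, an event trace, and the final state.
    """
    pool = list(items)
    if len(set(pool)) != len(pool):
        raise ValueError("duplicate items in the search pool")
    missing = [it for it in pool if it not in priority]
    if missing:
        raise ValueError(f"priority is missing items: {missing}")
    if max_passes is None:
        max_passes = max(2 * len(pool), 2)

    state = SearchState(current=set(pool))
    trace: list[dict] = []

    def score(subset: set) -> float:
        key = frozenset(subset)
        if key not in state.cache:
            state.cache[key] = float(evaluate(key))
        return state.cache[key]

    def record(direction: str, item, accepted: bool, before: float, after: float) -> None:
        trace.append(
            {
                "pass": state.passes,
                "direction": direction,
                "item": item,
                "accepted": accepted,
                "score_before": before,
                "score_after": after,
            }
        )

    F = state.forward_locked
    B = state.current
    agreed: frozenset | None = None
    while state.passes < max_passes:
        state.passes += 1
        moved = False
        # forward pass: add into F, best-priority first, only items still in B
        for cand in sorted(B - F, key=lambda c: (-priority[c], str(c))):
            before, after = score(F), score(F | {cand})
            accept = after < before - _TOL
            record("forward", cand, accept, before, after)
            if accept:
                F.add(cand)
                moved = True
        state.check_invariants()
        if F == B:
            agreed = frozenset(F)
            break
        if state.passes >= max_passes:
            break
        state.passes += 1
        # backward pass: remove from B, worst-priority first, never touching F
        for cand in sorted(B - F, key=lambda c: (priority[c], str(c))):
            before, after = score(B), score(B - {cand})
            accept = after <= before + _TOL
            record("backward", cand, accept, before, after)
            if accept:
                B.discard(cand)
                state.backward_locked.add(cand)
                moved = True
        state.check_invariants()
        if F == B:
            agreed = frozenset(B)
            break
        if not moved:
            break
    if agreed is None:
        # the searches stalled apart: keep the better endpoint
        cands = sorted([frozenset(F), frozenset(B)], key=lambda s: (score(set(s)), len(s), _subset_key(s)))
        agreed = cands[0]
    return agreed, trace, state
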