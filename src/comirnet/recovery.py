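"""Scoring recovered modules against planted cooperative miRNA groups."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass
class RecoveryReport:
    """Per-group best matches plus summary recovery statistics."""

    matches: list  # dicts: group_index, module_rank (or None), jaccard
    mean_jaccard: float
    false_module_count: int
    unmatched_modules: list = field(default_factory=list)


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def match_modules(
    planted: Sequence[Iterable[str]],
    recovered: Sequence,
    false_threshold: float = 0.25,
    optimal: bool = False,
) -> RecoveryReport:
    """Greedy one-to-one matching of planted groups to recovered modules.

    Candidate pairs are ranked by descending membership Jaccard (ties
    broken by group then module order); each group and each module is
    used at most once. Groups left unmatched score 0. A recovered module
    is counted false when its Jaccard against every planted group is
    below ``false_threshold``. ``optimal=True`` switches to the optimal
    assignment (Hungarian algorithm) instead of the greedy pass.
    """
    groups = [frozenset(g) for g in planted]
    mods = [(i, frozenset(getattr(m, "members", m))) for i, m in enumerate(recovered)]
    jac = [[_jaccard(g, mem) for _, mem in mods] for g in groups]

    assigned: dict[int, int] = {}
    if groups and mods:
        if optimal:
            from scipy.optimize import linear_sum_assignment

            import numpy as np

            cost = -np.asarray(jac)
            rows, cols = linear_sum_assignment(cost)
            assigned = {int(r): int(c) for r, c in zip(rows, cols) if jac[r][c] > 0}
        else:
            pairs = sorted(
                ((jac[gi][mi], gi, mi) for gi in range(len(groups)) for mi in range(len(mods))),
                key=lambda t: (-t[0], t[1], t[2]),
            )
            used_g, used_m = set(), set()
            for val, gi, mi in pairs:
                if val <= 0:
                    break
                if gi in used_g or mi in used_m:
                    continue
                assigned[gi] = mi
                used_g.add(gi)
                used_m.add(mi)

    matches = []
    for gi in range(len(groups)):
        mi = assigned.get(gi)
        matches.append(
            {
                "group_index": gi,
                "module_rank": getattr(recovered[mi], "rank", mi) if mi is not None else None,
                "jaccard": jac[gi][mi] if mi is not None else 0.0,
            }
        )
    mean_j = sum(m["jaccard"] for m in matches) / len(matches) if matches else 0.0
    false_modules = [
        getattr(recovered[mi], "rank", mi)
        for mi, (_, mem) in enumerate(mods)
        if not groups or max(jac[gi][mi] for gi in range(len(groups))) < false_threshold
    ]
    unmatched = [
        getattr(recovered[mi], "rank", mi)
        for mi in range(len(mods))
        if mi not in assigned.values()
    ]
    return RecoveryReport(
        matches=matches,
        mean_jaccard=mean_j,
        false_module_count=len(false_modules),
        unmatched_modules=unmatched,
    )
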